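# thermolesion

Quantitative analysis of radiometric thermal images for monitoring
infantile hemangiomas (IHs) — the most common vascular tumors of
infancy.  An IH's increased blood flow warms the overlying skin, so a
calibrated long-wave-infrared camera can measure both the lesion's
extension and the temperature contrast it induces, without touching the
patient.  `thermolesion` implements the full measurement pipeline for
dermatologists and medical-imaging researchers who want objective,
session-to-session numbers instead of visual inspection:

1. **Frame I/O and calibration** — read/write radiometric frames (CSV,
   16-bit TIFF at 0.01 °C/unit, lossless `.npy` + JSON sidecar) and fit
   the linear count-to-temperature model `T = a·counts + b` against one
   or two reference thermometer readings.
2. **Skin segmentation** — histogram the temperatures, discard
   everything below a 34 °C background floor, and find the optimal
   threshold *TH* by Otsu's criterion, maximising the between-class
   variance ω₀ω₁(μ₀−μ₁)².
3. **Isotherm contours and areas** — marching-squares contour lines over
   the 35.5–38 °C band in which vascular anomalies express; enclosed
   area by the coordinate (shoelace) method
   `A = |S₁ − S₂| / 2`, `S₁ = Σ xᵢyᵢ₊₁`, `S₂ = Σ xᵢ₊₁yᵢ`,
   converted to cm² by the pinhole magnification `A·(d/f)²·W·L`.
4. **Lesion metrics** — per-session contrast
   `ΔT = T_core − T_surround` between the boundary-isotherm interior and
   a ring of surrounding healthy skin; contrasts below the 0.1 °C sensor
   resolution are classified *null*.
5. **Longitudinal assessment** — trend of ΔT across sessions, relative
   isotherm-area change, and the three thermography-vs-clinic agreement
   rules (warming ∧ negative clinical response; cooling ∧ positive
   response; flat ΔT ∧ substantially smaller area ∧ positive response).
6. **Synthetic phantoms** — Gaussian-lesion thermal scenes with analytic
   ground truth (iso-areas `π·2σ²·ln(A/(T_iso−T_skin))`, disk-mean
   contrasts), so every stage is testable without clinical data.

## Worked example

```python
import thermolesion as tl

spec = tl.PhantomSpec(
    height=160, width=160,
    skin_region=tl.SkinRegion("rect", 20, 20, 120, 120),
    lesions=(tl.GaussianLesion(x=80, y=80, sigma=15.0, amplitude=1.0),),
    noise_sd=0.0,
)
frame, truth = tl.generate_phantom(spec)

skin = tl.segment_skin(frame, floor=20.0)
print(f"TH = {skin.threshold_th:.2f} °C, skin px = {skin.n_skin_pixels}")

m = tl.measure(frame, boundary_level=36.7)
print(f"core = {m.core_temp:.3f}  surround = {m.surround_temp:.3f}  "
      f"ΔT = {m.delta_t:.3f} °C")
print(f"area = {m.area_px:.1f} px² (analytic {truth.iso_area(36.7):.1f})")
```

prints

```
TH = 25.05 °C, skin px = 14400
core = 36.923  surround = 36.516  ΔT = 0.407 °C
area = 979.4 px² (analytic 979.9)
```

The Otsu threshold lands just above the 25 °C background, so the skin
mask recovers the body region exactly (14 400 px).  The 36.7 °C boundary
isotherm encloses 979.4 px², within 0.05 % of the closed-form
`π·2σ²·ln(1/0.5)` for a σ = 15 px, 1 °C Gaussian lesion, and the
measured contrast 0.407 °C matches the analytic disk-mean core minus the
annulus-mean surround (0.406 °C).  A treated time course (lesion
amplitude scaled 1.0 → 0.6 → 0.4 across sessions) classifies as a
negative temperature trend with a −76 % area change, and the agreement
rules return *agree* against a positive clinical response.

The same pipeline is scriptable from the shell:

```sh
thermolesion phantom --seed 42 -o frame.tiff
thermolesion segment frame.tiff
thermolesion measure frame.tiff --level 36.7 -o measurement.json
thermolesion analyze frame.tiff -o report.json
```

All reports are JSON and embed the full effective configuration plus the
input file's SHA-256, so a run is reproducible from its output alone.

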