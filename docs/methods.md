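# Methods

## Measurement model

A radiometric frame is a 2-D raster of absolute temperatures (°C) with a
boolean validity mask.  Pixels removed by any step (background, hair,
dropouts) are marked invalid rather than zeroed, so no sentinel value
ever enters a temperature statistic.  A raw microbolometer frame is
calibrated by the linear model `T = a·counts + b`: with two reference
regions of known temperature the 2×2 system is solved exactly through
the (mean counts, temperature) pairs; with one reference the gain is
fixed (default 0.01 °C/count, the common centi-degree radiometric
encoding) and only the offset is fitted.  The fit is exact at the
references by construction.

### Skin segmentation

The temperature histogram of a bedside scene has up to four modes:
background, hair, skin, lesion.  Segmentation histograms the valid
pixels (default bin width 0.05 °C — half the 0.1 °C sensor resolution —
configurable), discards pixels below a floor (default 34 °C, below
which nothing is compatible with body surface temperature), and applies
Otsu's criterion to the remaining histogram: the threshold *TH* is the
bin edge maximising the between-class variance ω₀ω₁(μ₀−μ₁)², computed
with bin centers as class values.  Ties are broken toward the lowest
optimal edge, which keeps the most skin.  Histogram edges start at the
coldest valid pixel and extend in fixed steps past the hottest, so two
populations one bin-width apart always occupy distinct bins.

Which two classes *TH* separates depends on scene content: with the
34 °C floor the background is already gone and Otsu splits skin from the
warmer lesion; with a floor below the background temperature it splits
background from body.  Both uses are exposed (the floor is a parameter);
neither is hard-wired.

### Isotherms and areas

Contour lines are traced by marching squares with linear interpolation
between pixel centers (`skimage.measure.find_contours`), at six equally
spaced levels over 35.5–38 °C by default — the band in which skin
temperature varies in the presence of a vascular anomaly.  Invalid
pixels and a one-pixel pad around the frame are filled with a deep-cold
sentinel before tracing, which forces every chain to close; chains
closed along the image or mask border are flagged `touches_border`
(their areas are computable but truncated).  Coordinates are
(x, y) = (column, row) with pixel centers at integer positions.

The enclosed area uses the coordinate (shoelace) method with the closing
vertex duplicated: `S₁ = Σ xᵢyᵢ₊₁`, `S₂ = Σ xᵢ₊₁yᵢ`,
`A = |S₁ − S₂|/2` — orientation- and starting-vertex-invariant.  (Some
printed statements of the coordinate method carry an extra leading
`x₁y₂`/`x₂y₁` term; with the duplicated closing vertex the standard sums
already contain the wrap term, so the plain closed-polygon form is
implemented.)

Pixel areas convert to cm² by `A_abs = A·(d/f)²·W·L` with working
distance *d*, focal length *f* and pixel pitch *W*×*L* (all cm).
Pinhole geometry magnifies the image-plane pixel footprint by `(d/f)²`;
the reciprocal `(f/d)²` convention, which appears in some system
descriptions but demagnifies for d ≫ f, is available behind
`eq3_as_printed` for comparability.  The two coincide at d = f.

The lesion boundary at a chosen level is the largest-area contour at
that level, preferring contours that close without touching the border;
ties break toward the smallest centroid (row, then column).  Reusing the
same level across sessions makes areas comparable.

### Lesion contrast ΔT

`ΔT = T_core − T_surround`.  The *core* is the mean over valid pixel
centers strictly inside the boundary polygon (strict interior by
point-in-polygon; on-edge pixels excluded for determinism); a `peak`
option takes the hottest interior pixel instead, since "center of the
lesion" admits both readings.  The *surround* is the mean over pixels
within `ring_px` (default 10 px) of the boundary polygon, outside it,
valid, and inside the skin mask — hair and background therefore never
contaminate the healthy-skin reference.  When no skin mask is supplied,
the body mask (valid pixels at or above the 34 °C floor) is used rather
than the Otsu warmest class: the Otsu split isolates the lesion itself,
and a surround ring restricted to it would be biased warm.  ΔT is
invariant under adding a constant to the whole frame.  A contrast
smaller in magnitude than the sensor resolution (default 0.1 °C) is
classified *null* — the sensor cannot distinguish it from zero.

### Longitudinal assessment

A lesion's trend is `ΔT_last − ΔT_first` classified at sensor
resolution (a regression slope is available as `trend_slope`, but
sessions are compared pairwise by default).  The area course is the
relative change `(A_last − A_first)/A_first`.  Thermography and the
dermatologists' independent verdict *agree* when: (i) the lesion warmed
and the response was negative; (ii) it cooled and the response was
positive; or (iii) ΔT was flat but the isotherm area dropped
substantially — default threshold −20 %, configurable and echoed in
every report, since "substantially lower" is inherently a judgment call
— with a positive response.  Any other combination is a disagreement.

Cohort summaries count lesions per variation class, report
`100·(n_pos + n_neg)/n` rounded to one decimal as the percentage with
detectable variation, and give the mean ΔT with a 90 % Student-t
confidence interval (flagged degenerate for a single lesion).  For
multi-session input the mean last-minus-first change is reported as the
treatment effect.

## Packaged cohort encodings

`data/table1_counts.json` holds the first-phase counts (55 first-visit
hemangiomas, 48 with detectable variation, mean contrast 0.20 °C, 90 %
CI [0.16, 0.25]).  `data/table4_lesions.csv` encodes the 17 follow-up
lesions of the second-phase cohort, one row per lesion: 11 published
case rows expand to 17 lesions because two patients carried two lesions
each and one multifocal patient carried seven sites sharing one course.
Rows with an overall negative increment but a transient
post-discontinuation warming keep `trend=negative` and record the
transient as an event; the single no-variation lesion carries
`trend=null` with a −30 % area change, so agreement follows rule (iii).
Per-lesion ΔT values were not published, so area changes for
negative-trend rows (where the rules never consult the area) are nominal
−30 to −40 % placeholders.

## Synthetic phantoms

A phantom is background at `T_bg` (default 25 °C), a rectangular or
elliptic skin region at `T_skin` (default 36.2 °C), and radial Gaussian
lesions `T_skin + A·exp(−r²/2σ²)` — the minimal smooth profile that
produces the nested-isotherm structure seen over a real hemangioma; it
is a geometric stand-in, not a bio-heat (Pennes) model.  The isotherm at
`T_iso` is a circle of radius `σ·√(2·ln(A/(T_iso−T_skin)))`, giving the
closed-form area `π·2σ²·ln(A/(T_iso−T_skin))` and closed-form disk/
annulus mean excesses against which the pipeline is validated: on a
noiseless σ = 15 px lesion the recovered iso-area is within 5 % (0.05 %
in practice) and core/surround means within 0.05 °C (≈0.002 °C in
practice) of the analytic values.  Gaussian sensor noise (default sd
0.05 °C, half the sensor resolution) applies inside the skin region
only; hair is modeled as a random pixel fraction set to 30–33.9 °C,
which the 34 °C pre-filter removes — matching how hair-covered regions
are excluded in practice.  A fixed seed reproduces frames bit-for-bit;
treatment courses scale each lesion's amplitude and σ per session
(session *t* reseeds noise with `seed + t`).

Phantom frames carry a plausible acquisition geometry (30 cm working
distance, 0.95 mm focal length, 12 µm pixel pitch) so absolute-area code
paths run end-to-end.  What phantoms do **not** emulate: irregular
lesion shapes, skin-temperature gradients, camera non-uniformity and
vignetting, perspective at varying distance.  Passing phantom tests
therefore demonstrates correctness of the measurement chain, not
clinical accuracy on real frames.

## Numerical choices and limitations

- Marching squares with sub-pixel interpolation was chosen over pixel
  tracing for level-accurate isotherms; equivalence with pixel counting
  is asserted only to within half the contour perimeter.
- Analytic-recovery tolerances (5 % areas, 0.05 °C means) hold for
  σ ≥ 10 px; thinner lesions are dominated by discretisation.
- Problem sizes in the tests (160² px frames, 1000-case property sweeps,
  400-replicate CI coverage) keep the whole suite under a few seconds
  while leaving the tolerances comfortably slack.
- The agreement rules consume categorical inputs; they do not model
  observer uncertainty or multi-reader adjudication.
- Blood-flow inference from temperature is out of scope: the
  temperature–flow correlation is not part of the measurement model.
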