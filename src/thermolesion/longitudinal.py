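"""Longitudinal tracking and clinician-agreement rules.

A lesion followed across sessions (spaced months apart) yields a series
of delta_t measurements.  Its *temperature trend* is the sign of
``delta_t_last - delta_t_first`` at sensor resolution: a decreasing
contrast indicates involution, an increasing one regrowth.  The trend is
compared with the dermatologists' independent response-to-treatment
verdict by three agreement rules:

(i)   positive trend  and negative clinical response  -> agree;
(ii)  negative trend  and positive clinical response  -> agree;
(iii) null trend, but the isotherm area dropped substantially
      (default: by at least 20 %) and the response was positive -> agree;

any other combination is a disagreement between thermography and the
clinic.

Cohort summaries aggregate first-visit delta_t classifications: counts
per class, the percentage of lesions with a detectable variation, the
mean contrast with a 90 % Student-t confidence interval, and (for
multi-session series) the mean before/after-treatment change.

Reference encodings of the published 17-lesion follow-up cohort ship
with the package (``load_table4_lesions``); replaying the rules over
them reproduces the 17/17 thermography-clinic agreement.
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .lesion_metrics import SENSOR_RESOLUTION, LesionMeasurement, Variation, classify_variation

#: Default relative area change counted as "substantially lower" (rule iii).
DEFAULT_SUBSTANTIAL_FRAC = -0.2


class ClinicalResponse(str, enum.Enum):
    """Dermatologists' independent response-to-treatment verdict."""

    POSITIVE = "positive"
    NEGATIVE = "negative"


class Verdict(str, enum.Enum):
    """Whether thermography and the clinical verdict concur."""

    AGREE = "agree"
    DISAGREE = "disagree"


@dataclass
class SessionSeries:
    """Time-ordered measurements of one lesion across sessions."""

    lesion_id: str
    measurements: list[LesionMeasurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        stamps = [m.timestamp for m in self.measurements]
        if all(s is not None for s in stamps) and len(stamps) > 1:
            if any(a >= b for a, b in zip(stamps, stamps[1:])):
                raise ValueError("measurement timestamps must be strictly increasing")

    @property
    def delta_ts(self) -> np.ndarray:
        return np.array([m.delta_t for m in self.measurements])


@dataclass(frozen=True)
class EvolutionAssessment:
    """Trend, area change and agreement verdict for one lesion series."""

    trend: Variation
    area_change_frac: float
    clinical_response: ClinicalResponse
    verdict: Verdict


@dataclass(frozen=True)
class CohortSummary:
    """Aggregate statistics over a cohort of lesions (one record each)."""

    n_lesions: int
    n_positive: int
    n_negative: int
    n_null: int
    pct_with_variation: float
    mean_delta_t: float
    ci90: tuple[float, float]
    n_patients: int | None = None
    mean_treatment_change: float | None = None
    degenerate_ci: bool = False

    def __post_init__(self) -> None:
        if self.n_positive + self.n_negative + self.n_null != self.n_lesions:
            raise ValueError("class counts must sum to n_lesions")
        if not 0.0 <= self.pct_with_variation <= 100.0:
            raise ValueError("pct_with_variation must lie in [0, 100]")


def temperature_trend(series: SessionSeries, resolution: float = SENSOR_RESOLUTION) -> Variation:
    """Sign of ``delta_t_last - delta_t_first`` at sensor resolution."""
    if len(series.measurements) < 2:
        raise ValueError("temperature trend needs at least two measurements")
    d = series.measurements[-1].delta_t - series.measurements[0].delta_t
    return classify_variation(d, resolution=resolution)


def trend_slope(series: SessionSeries) -> float:
    """Least-squares slope of delta_t against session index (°C/session)."""
    if len(series.measurements) < 2:
        raise ValueError("slope needs at least two measurements")
    t = np.arange(len(series.measurements), dtype=float)
    return float(np.polyfit(t, series.delta_ts, 1)[0])


def area_change(series: SessionSeries) -> float:
    """Relative isotherm-area change, ``(area_last - area_first) / area_first``."""
    if len(series.measurements) < 2:
        raise ValueError("area change needs at least two measurements")
    first = series.measurements[0].area_px
    last = series.measurements[-1].area_px
    if first <= 0:
        raise ValueError("first-session area must be positive")
    return (last - first) / first


def agreement(
    trend: Variation | str,
    area_change_frac: float,
    clinical_response: ClinicalResponse | str,
    substantial_frac: float = DEFAULT_SUBSTANTIAL_FRAC,
) -> Verdict:
    """Apply the three thermography-vs-clinic agreement rules."""
    trend = Variation(trend)
    clinical_response = ClinicalResponse(clinical_response)
    agree = (
        (trend is Variation.POSITIVE and clinical_response is ClinicalResponse.NEGATIVE)
        or (trend is Variation.NEGATIVE and clinical_response is ClinicalResponse.POSITIVE)
        or (
            trend is Variation.NULL
            and area_change_frac <= substantial_frac
            and clinical_response is ClinicalResponse.POSITIVE
        )
    )
    return Verdict.AGREE if agree else Verdict.DISAGREE


def assess(
    series: SessionSeries,
    clinical_response: ClinicalResponse | str,
    resolution: float = SENSOR_RESOLUTION,
    substantial_frac: float = DEFAULT_SUBSTANTIAL_FRAC,
) -> EvolutionAssessment:
    """Trend + area change + agreement verdict for one lesion series."""
    trend = temperature_trend(series, resolution=resolution)
    frac = area_change(series)
    verdict = agreement(trend, frac, clinical_response, substantial_frac=substantial_frac)
    return EvolutionAssessment(
        trend=trend,
        area_change_frac=frac,
        clinical_response=ClinicalResponse(clinical_response),
        verdict=verdict,
    )


@dataclass(frozen=True)
class CohortRecord:
    """Minimal first-visit record: lesion id, delta_t, variation class."""

    lesion_id: str
    delta_t: float
    variation: Variation


def summarize_cohort(
    records: Sequence[CohortRecord] | Sequence[SessionSeries],
    n_patients: int | None = None,
) -> CohortSummary:
    """Aggregate a cohort of first-visit records or full session series.

    For series input the first-visit delta_t is classified and the mean
    last-minus-first change is reported as ``mean_treatment_change``.
    The 90 % confidence interval uses the Student-t distribution on the
    per-lesion delta_t values; with a single lesion the interval is
    undefined and flagged degenerate.
    """
    records = list(records)
    if not records:
        raise ValueError("cohort is empty")

    treatment_change: float | None = None
    if isinstance(records[0], SessionSeries):
        series: list[SessionSeries] = records  # type: ignore[assignment]
        recs = [
            CohortRecord(s.lesion_id, s.measurements[0].delta_t,
                         classify_variation(s.measurements[0].delta_t))
            for s in series
        ]
        changes = [
            s.measurements[-1].delta_t - s.measurements[0].delta_t
            for s in series
            if len(s.measurements) >= 2
        ]
        if changes:
            treatment_change = float(np.mean(changes))
    else:
        recs = records  # type: ignore[assignment]

    n = len(recs)
    n_pos = sum(1 for r in recs if r.variation is Variation.POSITIVE)
    n_neg = sum(1 for r in recs if r.variation is Variation.NEGATIVE)
    n_null = n - n_pos - n_neg
    pct = round(100.0 * (n_pos + n_neg) / n, 1)

    values = np.array([r.delta_t for r in recs], dtype=float)
    mean = float(values.mean())
    if n > 1 and values.std(ddof=1) > 0:
        lo, hi = stats.t.interval(0.90, n - 1, loc=mean, scale=stats.sem(values))
        ci, degenerate = (float(lo), float(hi)), False
    else:
        ci, degenerate = (float("nan"), float("nan")), True

    return CohortSummary(
        n_lesions=n,
        n_positive=n_pos,
        n_negative=n_neg,
        n_null=n_null,
        pct_with_variation=pct,
        mean_delta_t=mean,
        ci90=ci,
        n_patients=n_patients,
        mean_treatment_change=treatment_change,
        degenerate_ci=degenerate,
    )


# ---------------------------------------------------------------------------
# Packaged reference cohort encodings
# ---------------------------------------------------------------------------

def load_table1_counts() -> dict:
    """First-phase cohort counts (55 hemangiomas, first visit only)."""
    text = resources.files("thermolesion.data").joinpath("table1_counts.json").read_text()
    return json.loads(text)


def load_table4_lesions() -> list[dict]:
    """Per-lesion follow-up encodings of the published 17-lesion cohort.

    Each row carries the lesion's overall temperature trend, the
    dermatologists' clinical response, the relative isotherm-area change,
    and any transient events (regrowth after treatment discontinuation,
    ulceration) noted during follow-up.
    """
    text = resources.files("thermolesion.data").joinpath("table4_lesions.csv").read_text()
    rows = list(csv.DictReader(text.splitlines()))
    for row in rows:
        row["area_change_frac"] = float(row["area_change_frac"])
    return rows


def replay_agreement(
    lesions: Iterable[dict] | None = None,
    substantial_frac: float = DEFAULT_SUBSTANTIAL_FRAC,
) -> list[Verdict]:
    """Run the agreement rules over a cohort of per-lesion encodings."""
    if lesions is None:
        lesions = load_table4_lesions()
    return [
        agreement(
            row["trend"], row["area_change_frac"], row["clinical_response"],
            substantial_frac=substantial_frac,
        )
        for row in lesions
    ]
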