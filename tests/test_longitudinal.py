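"""Trend classification, agreement rules, and cohort summaries."""

import numpy as np
import pytest
from scipy import stats

import thermolesion as tl
from thermolesion.lesion_metrics import Variation
from thermolesion.longitudinal import ClinicalResponse, CohortRecord, Verdict


def _measurement(delta_t, area_px=100.0, session="s", timestamp=None):
    return tl.LesionMeasurement(
        session_id=session, core_temp=36.5 + delta_t, surround_temp=36.5,
        delta_t=delta_t, area_px=area_px, area_cm2=None, boundary_level=36.5,
        timestamp=timestamp,
    )


def _series(delta_ts, areas=None, stamps=None):
    areas = areas or [100.0] * len(delta_ts)
    stamps = stamps or [f"2021-{i + 1:02d}" for i in range(len(delta_ts))]
    return tl.SessionSeries(
        lesion_id="L1",
        measurements=[
            _measurement(d, a, f"s{i}", t)
            for i, (d, a, t) in enumerate(zip(delta_ts, areas, stamps))
        ],
    )


class TestTrend:
    @pytest.mark.parametrize("deltas,expected", [
        ((0.38, 0.30, 0.27), Variation.NEGATIVE),  # improving course
        ((0.2, 0.2, 0.2), Variation.NULL),
        ((0.1, 0.4), Variation.POSITIVE),
    ])
    def test_first_vs_last(self, deltas, expected):
        assert tl.temperature_trend(_series(deltas)) is expected

    def test_antisymmetric_under_time_reversal(self):
        fwd = tl.temperature_trend(_series((0.38, 0.30, 0.10)))
        rev = tl.temperature_trend(_series((0.10, 0.30, 0.38)))
        assert {fwd, rev} == {Variation.NEGATIVE, Variation.POSITIVE}

    def test_needs_two_measurements(self):
        with pytest.raises(ValueError):
            tl.temperature_trend(_series((0.2,)))

    def test_slope_option(self):
        assert tl.trend_slope(_series((0.4, 0.3, 0.2))) == pytest.approx(-0.1)

    def test_timestamps_must_increase(self):
        with pytest.raises(ValueError):
            _series((0.3, 0.2), stamps=["2021-02", "2021-01"])


class TestAreaChange:
    def test_halving(self):
        assert tl.area_change(_series((0.3, 0.2), areas=[100.0, 50.0])) == -0.5

    def test_unchanged(self):
        assert tl.area_change(_series((0.3, 0.2))) == 0.0

    def test_zero_initial_area_is_an_error(self):
        with pytest.raises(ValueError):
            tl.area_change(_series((0.3, 0.2), areas=[0.0, 10.0]))

    def test_phantom_shrinkage_matches_analytic_ratio(self):
        """sigma shrinking 20 -> 14 px: iso-area ratio follows the closed form."""
        base = tl.PhantomSpec(
            height=200, width=200, noise_sd=0.0,
            lesions=(tl.GaussianLesion(x=100.0, y=100.0, sigma=20.0, amplitude=1.0),),
        )
        frames = tl.generate_series(base, [(1.0, 1.0), (1.0, 0.7)])
        level = 36.7
        measurements = [
            tl.measure(f, level) for f, _ in frames
        ]
        series = tl.SessionSeries(
            lesion_id="p",
            measurements=[
                tl.LesionMeasurement(
                    session_id=m.session_id, core_temp=m.core_temp,
                    surround_temp=m.surround_temp, delta_t=m.delta_t,
                    area_px=m.area_px, area_cm2=m.area_cm2,
                    boundary_level=m.boundary_level, timestamp=f"{i}",
                )
                for i, m in enumerate(measurements)
            ],
        )
        truth0, truth1 = frames[0][1], frames[1][1]
        expected = truth1.iso_area(level) / truth0.iso_area(level) - 1.0
        assert tl.area_change(series) == pytest.approx(expected, abs=0.05)


class TestAgreement:
    @pytest.mark.parametrize("trend,frac,response,verdict", [
        # rule (ii): cooling lesion, clinicians see improvement
        (Variation.NEGATIVE, -0.4, ClinicalResponse.POSITIVE, Verdict.AGREE),
        # rule (i): warming lesion, clinicians see a bad response
        (Variation.POSITIVE, 0.1, ClinicalResponse.NEGATIVE, Verdict.AGREE),
        # rule (iii): flat temperature but area substantially down
        (Variation.NULL, -0.3, ClinicalResponse.POSITIVE, Verdict.AGREE),
        (Variation.NULL, -0.1, ClinicalResponse.POSITIVE, Verdict.DISAGREE),
        (Variation.NEGATIVE, -0.4, ClinicalResponse.NEGATIVE, Verdict.DISAGREE),
        (Variation.POSITIVE, -0.4, ClinicalResponse.POSITIVE, Verdict.DISAGREE),
        (Variation.NULL, -0.3, ClinicalResponse.NEGATIVE, Verdict.DISAGREE),
    ])
    def test_rule_table(self, trend, frac, response, verdict):
        assert tl.agreement(trend, frac, response) is verdict

    def test_accepts_plain_strings(self):
        assert tl.agreement("negative", -0.4, "positive") is Verdict.AGREE

    def test_substantial_threshold_is_configurable(self):
        assert tl.agreement("null", -0.15, "positive", substantial_frac=-0.1) is Verdict.AGREE

    def test_fixture_replay_is_seventeen_for_seventeen(self):
        verdicts = tl.replay_agreement()
        assert len(verdicts) == 17
        assert all(v is Verdict.AGREE for v in verdicts)

    def test_assess_composes_trend_area_and_verdict(self):
        series = _series((0.38, 0.30, 0.20), areas=[100.0, 80.0, 55.0])
        out = tl.assess(series, "positive")
        assert out.trend is Variation.NEGATIVE
        assert out.area_change_frac == pytest.approx(-0.45)
        assert out.verdict is Verdict.AGREE


class TestCohortSummary:
    def test_first_phase_percentage(self):
        counts = tl.load_table1_counts()
        records = [
            CohortRecord(f"v{i}", 0.2, Variation.POSITIVE)
            for i in range(counts["n_with_variation"])
        ] + [
            CohortRecord(f"n{i}", 0.0, Variation.NULL)
            for i in range(counts["n_hemangiomas"] - counts["n_with_variation"])
        ]
        summary = tl.summarize_cohort(records, n_patients=counts["n_patients"])
        assert summary.n_lesions == 55
        assert summary.pct_with_variation == 87.3

    def test_counts_conserve(self):
        rng = np.random.default_rng(2)
        classes = [Variation.POSITIVE, Variation.NEGATIVE, Variation.NULL]
        records = [
            CohortRecord(str(i), float(rng.normal(0.2, 0.1)), classes[rng.integers(3)])
            for i in range(40)
        ]
        s = tl.summarize_cohort(records)
        assert s.n_positive + s.n_negative + s.n_null == s.n_lesions == 40

    def test_single_record_has_degenerate_ci(self):
        s = tl.summarize_cohort([CohortRecord("a", 0.2, Variation.POSITIVE)])
        assert s.mean_delta_t == 0.2
        assert s.degenerate_ci
        assert np.isnan(s.ci90[0])

    def test_ci_coverage_monte_carlo(self):
        """90 % Student-t interval covers the true mean in ~90 % of replicates."""
        rng = np.random.default_rng(11)
        true_mean, hits, reps = 0.2, 0, 400
        for _ in range(reps):
            vals = rng.normal(true_mean, 0.05, 55)
            records = [
                CohortRecord(str(i), float(v), tl.classify_variation(v))
                for i, v in enumerate(vals)
            ]
            lo, hi = tl.summarize_cohort(records).ci90
            hits += lo <= true_mean <= hi
        coverage = hits / reps
        assert abs(coverage - 0.90) < 0.05

    def test_series_input_reports_treatment_change(self):
        series = [
            _series((0.38, 0.27)),
            _series((0.30, 0.20)),
        ]
        s = tl.summarize_cohort(series)
        assert s.mean_treatment_change == pytest.approx(-0.105)
        assert s.n_lesions == 2
        assert s.n_positive == 2  # first-visit contrasts are both positive

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(ValueError):
            tl.summarize_cohort([])

    def test_fixture_mean_and_ci_match_t_distribution(self):
        """Student-t interval from raw values agrees with scipy's direct formula."""
        vals = np.array([0.15, 0.22, 0.18, 0.25, 0.20])
        records = [
            CohortRecord(str(i), float(v), tl.classify_variation(v))
            for i, v in enumerate(vals)
        ]
        s = tl.summarize_cohort(records)
        lo, hi = stats.t.interval(0.90, len(vals) - 1, loc=vals.mean(), scale=stats.sem(vals))
        assert s.ci90 == pytest.approx((lo, hi))
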