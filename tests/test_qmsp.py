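import math

import numpy as np
import pandas as pd
import pytest

from methpanel.qmsp import (
    CurveFitError,
    SampleFailedError,
    StandardCurve,
    censor_ct,
    compute_pmr,
    derive_thresholds,
    fit_standard_curve,
    pmr_from_quantities,
    quantify,
    read_plate,
    score_sample,
    score_table,
    write_plate,
)
from methpanel.synthetic_data import SimulationConfig, generate_qmsp_plate


class TestCensoring:
    @pytest.mark.parametrize("ct, kept", [(34.9, True), (35.0, True), (35.1, False)])
    def test_cutoff_is_strictly_after_cycle_35(self, ct, kept):
        result = censor_ct(ct)
        assert (not math.isnan(result)) is kept

    def test_no_amplification_stays_censored(self):
        assert math.isnan(censor_ct(float("nan")))
        assert math.isnan(censor_ct(None))

    def test_nonpositive_ct_rejected(self):
        with pytest.raises(ValueError):
            censor_ct(-1.0)


class TestStandardCurve:
    def test_two_point_line(self):
        curve = fit_standard_curve([1.0, 10.0], [40.0, 36.68])
        assert curve.slope == pytest.approx(-3.32)
        assert curve.intercept == pytest.approx(40.0)
        assert curve.r_squared == pytest.approx(1.0)

    def test_requires_two_distinct_dilutions(self):
        with pytest.raises(CurveFitError):
            fit_standard_curve([10.0], [36.0])
        with pytest.raises(CurveFitError):
            fit_standard_curve([10.0, 10.0, 10.0], [36.0, 36.1, 35.9])

    def test_positive_slope_rejected(self):
        with pytest.raises(CurveFitError, match="slope"):
            fit_standard_curve([1.0, 10.0], [30.0, 35.0])

    def test_parameter_recovery_from_noisy_series(self):
        rng = np.random.default_rng(3)
        quantities = np.array([1e4, 1e3, 1e2, 1e1] * 3)
        cts = 40.0 - 3.32 * np.log10(quantities) + rng.normal(0, 0.1, len(quantities))
        curve = fit_standard_curve(quantities, cts)
        assert curve.slope == pytest.approx(-3.32, abs=0.1)
        assert curve.intercept == pytest.approx(40.0, abs=0.3)


class TestQuantify:
    curve = StandardCurve(slope=-3.32, intercept=40.0)

    def test_identities(self):
        assert quantify(40.0, self.curve) == pytest.approx(1.0)
        assert quantify(40.0 - 3.32, self.curve) == pytest.approx(10.0)

    def test_censored_quantifies_to_zero(self):
        assert quantify(float("nan"), self.curve) == 0.0


class TestPmr:
    def test_ratio_identities(self):
        assert pmr_from_quantities(5.0, 10.0, 50.0, 100.0) == pytest.approx(100.0)
        assert pmr_from_quantities(2.5, 10.0, 50.0, 100.0) == pytest.approx(50.0)
        assert pmr_from_quantities(0.0, 10.0, 50.0, 100.0) == 0.0

    def test_reference_censoring_fails_sample(self):
        with pytest.raises(SampleFailedError):
            pmr_from_quantities(5.0, 0.0, 50.0, 100.0)

    def test_rescaling_sample_quantities_is_invariant(self):
        base = pmr_from_quantities(3.0, 12.0, 50.0, 100.0)
        scaled = pmr_from_quantities(3.0 * 7.3, 12.0 * 7.3, 50.0, 100.0)
        assert scaled == pytest.approx(base)


def test_derive_thresholds_is_control_maximum():
    controls = pd.DataFrame(
        {
            "sample_id": ["c1", "c2", "c3"] * 2,
            "gene": ["A"] * 3 + ["B"] * 3,
            "pmr": [0.0, 0.0, 0.0, 0.0, 2.5, 1.0],
        }
    )
    thr = derive_thresholds(controls).set_index("gene")["threshold"]
    assert thr["A"] == 0.0
    assert thr["B"] == 2.5


class TestScoring:
    def test_zero_vs_zero_threshold_is_negative(self):
        assert score_sample(0.0, 0.0) is False

    def test_any_excess_over_zero_is_positive(self):
        assert score_sample(5.0, 0.0) is True

    def test_equality_with_positive_threshold_depends_on_rule(self):
        assert score_sample(2.5, 2.5, rule="strict") is False
        assert score_sample(2.5, 2.5, rule="inclusive") is True

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            score_sample(1.0, 0.0, rule="fuzzy")

    def test_score_table_flags_borderline_values(self, caplog):
        pmrs = pd.DataFrame(
            {"sample_id": ["s1", "s2"], "gene": ["A", "A"], "pmr": [2.5, 0.0]}
        )
        thr = pd.DataFrame({"gene": ["A"], "threshold": [2.5]})
        scored = score_table(pmrs, thr)
        assert list(scored["call"]) == [False, False]
        assert list(scored["borderline"]) == [True, False]

    def test_specificity_on_threshold_defining_controls_is_total(self):
        rng = np.random.default_rng(8)
        control_pmrs = pd.DataFrame(
            {
                "sample_id": [f"c{i}" for i in range(10)],
                "gene": ["A"] * 10,
                "pmr": np.abs(rng.normal(0, 1, 10)),
            }
        )
        thr = derive_thresholds(control_pmrs)
        scored = score_table(control_pmrs, thr, rule="strict")
        assert not scored["call"].any()


class TestPlatePipeline:
    def _plate(self, fractions, ct_noise_sd=0.0, seed=0):
        config = SimulationConfig(seed=seed, ct_noise_sd=ct_noise_sd)
        samples = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(fractions))],
                "group": ["BL"] * len(fractions),
                "methylation_fraction": fractions,
            }
        )
        return generate_qmsp_plate(samples, None, config, genes=["GENE"])

    def test_positive_control_scores_pmr_100_against_itself(self):
        plate = self._plate([0.5])
        table, _ = compute_pmr(plate)
        pos = table[table["sample_id"] == "POS_CONTROL"]
        assert pos["pmr"].iloc[0] == pytest.approx(100.0, abs=1e-9)

    def test_noise_free_recovery_is_exact(self):
        fractions = [0.0, 0.05, 0.25, 0.5, 1.0]
        table, failed = compute_pmr(self._plate(fractions))
        assert failed == []
        got = table.set_index("sample_id").drop("POS_CONTROL")
        for i, f in enumerate(fractions):
            assert got.loc[f"s{i}", "pmr"] == pytest.approx(100 * f, abs=1e-9)

    def test_error_shrinks_with_ct_noise(self):
        fractions = [0.25] * 10
        errors = []
        for sd in (0.6, 0.15, 0.0):
            table, _ = compute_pmr(self._plate(fractions, ct_noise_sd=sd, seed=4))
            got = table[table["sample_id"] != "POS_CONTROL"]["pmr"]
            errors.append(np.abs(got - 25.0).max())
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] < 1e-9

    def test_reference_failure_excludes_sample(self):
        plate = self._plate([0.5, 0.5])
        mask = (plate["sample_id"] == "s1") & (plate["assay_id"] == "ALU-C4")
        plate.loc[mask, "ct"] = 39.0  # beyond the cycle-35 cutoff
        table, failed = compute_pmr(plate)
        assert failed == ["s1"]
        assert "s1" not in set(table["sample_id"])
        assert "s0" in set(table["sample_id"])

    def test_plate_round_trip_with_no_ct_token(self, tmp_path):
        plate = self._plate([0.0, 1.0])
        write_plate(plate, tmp_path / "plate.csv")
        text = (tmp_path / "plate.csv").read_text()
        assert ",\n" in text or text.rstrip().endswith(",")  # empty ct field
        back = read_plate(tmp_path / "plate.csv")
        pd.testing.assert_frame_equal(plate, back)
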