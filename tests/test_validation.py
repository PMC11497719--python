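"""External validation: membership model, discrimination, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plasmapanel import subset_for_question
from plasmapanel.models import QuestionModel, develop_question_model, predict_probability
from plasmapanel.validation import (
    calibration_curve,
    calibration_metrics,
    membership_auc,
    recalculate_thresholds,
    transported_discrimination,
    validate_model,
)

PANEL = ("ptau181", "gfap", "nfl_age_corrected")


def toy_model(coefs=(-3.0, 1.2, 0.01, 0.05)) -> QuestionModel:
    return QuestionModel(
        question_id="Qtoy",
        markers=PANEL,
        coefficients={"intercept": coefs[0], "ptau181": coefs[1],
                      "gfap": coefs[2], "nfl_age_corrected": coefs[3]},
        marker_thresholds={m: {"cutoff": 1.0, "direction": "higher_abnormal"}
                           for m in PANEL},
        prob_thresholds={"youden": 0.5, "sens90": 0.3, "spec90": 0.7,
                         "inverted_zones": False},
        cv_auc={"auc": 0.8, "ci": [0.75, 0.85]},
    )


def sample_from_model(model, n, seed, lp_transform=None):
    """Validation data whose outcomes are drawn from the (transformed)
    frozen model — the self-consistency oracle."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "ptau181": rng.lognormal(0.6, 0.5, n),
            "gfap": rng.lognormal(4.6, 0.5, n),
            "nfl_age_corrected": rng.lognormal(2.9, 0.6, n),
        }
    )
    probs = predict_probability(model.coefficients, df[list(PANEL)])
    lp = np.log(probs / (1 - probs))
    if lp_transform is not None:
        lp = lp_transform(lp)
    df["outcome"] = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
    return df


class TestMembership:
    def test_identical_cohorts_auc_half(self):
        m = toy_model()
        dev = sample_from_model(m, 1500, 1)
        val = dev.copy()
        rep = membership_auc(dev, val, PANEL, question_id="Qtoy")
        # CV out-of-fold scoring under the null sits slightly below 0.5
        assert abs(rep.auc - 0.5) < 0.07

    def test_disjoint_cohorts_auc_one(self):
        m = toy_model()
        dev = sample_from_model(m, 400, 2)
        val = dev.copy()
        val[list(PANEL)] += 5 * dev[list(PANEL)].std()
        rep = membership_auc(dev, val, PANEL)
        assert rep.auc > 0.99

    def test_outcome_flag_changes_predictors(self):
        m = toy_model()
        dev = sample_from_model(m, 300, 3)
        val = sample_from_model(m, 300, 4)
        with_y = membership_auc(dev, val, PANEL, outcome_included=True)
        without = membership_auc(dev, val, PANEL, outcome_included=False)
        assert "question_outcome" in with_y.predictors_used
        assert "question_outcome" not in without.predictors_used


class TestTransportedDiscrimination:
    def test_hand_counted_confusion(self):
        m = toy_model()
        val = pd.DataFrame({"ptau181": [1.0, 1.0, 1.0], "gfap": [1.0] * 3,
                            "nfl_age_corrected": [1.0] * 3,
                            "outcome": [1, 0, 0]})
        # force specific probabilities through a stub model
        m2 = toy_model(coefs=(0.0, 0.0, 0.0, 0.0))
        probs = [0.9, 0.8, 0.1]
        m2.coefficients = {"intercept": 0.0, "ptau181": 0.0, "gfap": 0.0,
                           "nfl_age_corrected": 0.0}
        # patch: use ptau as the sole carrier of the probability
        lp = [np.log(p / (1 - p)) for p in probs]
        m2.coefficients["ptau181"] = 1.0
        val["ptau181"] = lp
        out = transported_discrimination(m2, val, cutoff=0.5)
        tp, fn = out["confusion_matrix"][0]
        fp, tn = out["confusion_matrix"][1]
        assert (tp, fn, fp, tn) == (1, 0, 1, 1)
        assert out["accuracy"] == pytest.approx(2 / 3)
        assert out["sensitivity"] == 1.0
        assert out["specificity"] == 0.5

    def test_self_consistency_auc(self):
        m = toy_model()
        val = sample_from_model(m, 4000, 5)
        out = transported_discrimination(m, val)
        # AUC of the generating model on its own data: a strong, stable value
        assert 0.7 < out["auc"] < 0.95

    def test_single_class_errors(self):
        m = toy_model()
        val = sample_from_model(m, 50, 6)
        val["outcome"] = 1
        with pytest.raises(ValueError, match="single"):
            transported_discrimination(m, val)

    def test_auc_invariant_to_monotone_probability_transform(self):
        m = toy_model()
        val = sample_from_model(m, 800, 7)
        base = transported_discrimination(m, val)["auc"]
        # doubling every coefficient is a strictly increasing transform of
        # the probabilities: AUC must not move
        m2 = toy_model(coefs=(-6.0, 2.4, 0.02, 0.10))
        assert transported_discrimination(m2, val)["auc"] == pytest.approx(base)


class TestCalibration:
    def test_perfect_calibration_limit(self):
        m = toy_model()
        val = sample_from_model(m, 20_000, 8)
        out = calibration_metrics(m, val)
        assert abs(out["citl"]) < 0.05
        assert abs(out["cal_slope"] - 1.0) < 0.05

    def test_offset_shifts_citl(self):
        m = toy_model()
        val = sample_from_model(m, 20_000, 9, lp_transform=lambda lp: lp + 1.0)
        out = calibration_metrics(m, val)
        assert out["citl"] == pytest.approx(1.0, abs=0.07)

    def test_doubled_predictor_doubles_slope(self):
        m = toy_model()
        val = sample_from_model(
            m, 20_000, 10, lp_transform=lambda lp: 2.0 * (lp - lp.mean()) + lp.mean()
        )
        out = calibration_metrics(m, val)
        assert out["cal_slope"] == pytest.approx(2.0, abs=0.1)

    def test_curve_bins_and_bands(self):
        m = toy_model()
        val = sample_from_model(m, 1000, 11)
        curve = calibration_curve(m, val, bins=10)
        assert len(curve["bins"]) == 10
        assert all(b["n"] == 100 for b in curve["bins"])
        # perfectly calibrated: each bin's observed rate within the binomial
        # 95% band around its mean predicted probability
        for b in curve["bins"]:
            se = np.sqrt(b["mean_predicted"] * (1 - b["mean_predicted"]) / b["n"])
            assert abs(b["observed_rate"] - b["mean_predicted"]) < 1.96 * se + 0.02
        assert len(curve["smoothed"]["grid"]) == 100

    def test_constant_predictions_single_bin(self):
        m = toy_model(coefs=(0.3, 0.0, 0.0, 0.0))
        val = sample_from_model(m, 60, 12)
        with pytest.warns(UserWarning, match="constant"):
            curve = calibration_curve(m, val)
        assert len(curve["bins"]) == 1


class TestRecalculateThresholds:
    def test_identity_on_development_data(self, synthetic_cohort):
        sub = subset_for_question(synthetic_cohort, "Q3_ad_vs_ftd")
        model = develop_question_model(sub, PANEL, seed=3)
        out = recalculate_thresholds(sub, model)
        for m in PANEL:
            assert out["markers"][m]["relative_difference"] == 0.0
        for k in ("youden", "sens90", "spec90"):
            assert out["probability"][k]["relative_difference"] == pytest.approx(0.0)

    def test_marker_cutoffs_scale_with_data(self, synthetic_cohort):
        sub = subset_for_question(synthetic_cohort, "Q3_ad_vs_ftd")
        model = develop_question_model(sub, PANEL, seed=3)
        scaled = sub.copy()
        for m in PANEL:
            scaled[m] = 2.0 * scaled[m]
        out = recalculate_thresholds(scaled, model)
        for m in PANEL:
            assert out["markers"][m]["validation"] == pytest.approx(
                2.0 * out["markers"][m]["development"], rel=1e-9
            )


def test_full_validation_workflow(synthetic_cohort, synthetic_cohort_alt):
    """End-to-end: develop on one synthetic cohort, validate on an
    independent draw from the same world — discrimination reproduces and
    calibration is near-perfect by construction."""
    dev = subset_for_question(synthetic_cohort, "Q4_ctrl_vs_ftd")
    val = subset_for_question(synthetic_cohort_alt, "Q4_ctrl_vs_ftd")
    model = develop_question_model(dev, PANEL, seed=6)
    report = validate_model(model, val, dev_subset=dev, seed=6)
    assert abs(report.auc - model.cv_auc["auc"]) < 0.08
    assert abs(report.citl) < 0.4
    assert 0.6 < report.cal_slope < 1.6
    assert sum(sum(row) for row in report.confusion_matrix) == len(
        val.dropna(subset=list(PANEL))
    )
    assert abs(report.membership.auc - 0.5) < 0.1  # same stated world
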