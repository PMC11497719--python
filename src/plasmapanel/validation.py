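"""Transportability of a frozen question model to an external cohort.

Follows the standard external-validation playbook for clinical prediction
models: a cohort-membership logistic model quantifies case-mix difference
(low AUC = similar case mix, high = different), the frozen model's pooled
probabilities give discrimination (AUC, accuracy, sensitivity, specificity
at the development Youden probability cutoff), and logistic recalibration
gives calibration-in-the-large (intercept with the linear predictor as
offset; perfect value 0) and the calibration slope (coefficient on the
linear predictor; perfect value 1), plus a decile-binned calibration plot
with a Loess-smoothed curve. Thresholds are also recomputed on the
validation cohort to assess their transportability.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .models import (
    QuestionModel,
    RocCurve,
    marker_youden_threshold,
    predict_probability,
    probability_thresholds,
)

__all__ = [
    "MembershipReport",
    "ValidationReport",
    "membership_auc",
    "transported_discrimination",
    "calibration_metrics",
    "calibration_curve",
    "recalculate_thresholds",
    "validate_model",
]


@dataclass
class MembershipReport:
    question_id: str
    auc: float
    predictors_used: tuple[str, ...]
    cv_folds: int


@dataclass
class ValidationReport:
    question_id: str
    auc: float
    auc_ci: tuple[float, float]
    accuracy: float
    sensitivity: float
    specificity: float
    confusion_matrix: list[list[int]]  # [[TP, FN], [FP, TN]]
    citl: float
    cal_slope: float
    calibration_curve: dict
    recalculated_thresholds: dict
    membership: MembershipReport | None = None
    cutoff_used: float = field(default=0.5)

    def to_json(self, path) -> None:
        payload = dict(self.__dict__)
        payload["auc_ci"] = list(self.auc_ci)
        if self.membership is not None:
            m = dict(self.membership.__dict__)
            m["predictors_used"] = list(m["predictors_used"])
            payload["membership"] = m
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def membership_auc(
    dev_subset: pd.DataFrame,
    val_subset: pd.DataFrame,
    markers,
    outcome_included: bool = True,
    folds: int = 10,
    seed: int = 0,
    question_id: str = "",
) -> MembershipReport:
    """Cohort-membership (Debray) model AUC.

    A logistic regression of cohort label (development = 1) on the panel
    markers — plus the outcome variable by default — scored by pooled
    out-of-fold probabilities over stratified folds. An AUC near 0.5 means
    the two cohorts have a similar case mix; a high AUC means the
    validation exercise probes transportability rather than
    reproducibility.
    """
    markers = list(markers)
    cols = markers + (["outcome"] if outcome_included else [])
    dev = dev_subset.dropna(subset=markers)[cols].copy()
    val = val_subset.dropna(subset=markers)[cols].copy()
    if len(dev) == 0 or len(val) == 0:
        raise ValueError("both cohorts must be non-empty after subsetting")
    dev["_member"] = 1
    val["_member"] = 0
    pooled = pd.concat([dev, val], ignore_index=True)
    y = pooled["_member"].to_numpy(int)
    # the question outcome becomes a predictor of the membership model
    predictors = markers + (["question_outcome"] if outcome_included else [])
    tmp = pd.DataFrame({m: pooled[m].to_numpy(float) for m in markers})
    if outcome_included:
        tmp["question_outcome"] = pooled["outcome"].to_numpy(float)
    tmp["outcome"] = y
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.full(len(tmp), np.nan)
    X = tmp[predictors].to_numpy(float)
    for tr, te in skf.split(X, y):
        # near-unpenalized sklearn fit: disjoint cohorts legitimately
        # separate perfectly and must yield AUC ~ 1, not an error
        clf = LogisticRegression(C=1e6, max_iter=5000)
        clf.fit(X[tr], y[tr])
        oof[te] = clf.predict_proba(X[te])[:, 1]
    roc = RocCurve.from_scores(oof, y)
    return MembershipReport(
        question_id=question_id,
        auc=roc.auc,
        predictors_used=tuple(predictors),
        cv_folds=folds,
    )


def _frozen_probs(model: QuestionModel, val_subset: pd.DataFrame):
    markers = list(model.markers)
    missing = [m for m in markers if m not in val_subset.columns]
    if missing:
        raise ValueError(f"validation subset lacks marker column(s): {missing}")
    cc = val_subset.dropna(subset=markers).reset_index(drop=True)
    probs = predict_probability(model.coefficients, cc[markers])
    y = cc["outcome"].to_numpy(int)
    return cc, probs, y


def transported_discrimination(
    model: QuestionModel, val_subset: pd.DataFrame, cutoff: float | None = None
):
    """Discrimination of the frozen model on external data (no refitting).

    Classification metrics are computed at the development Youden
    probability cutoff unless ``cutoff`` overrides it. The confusion matrix
    is [[TP, FN], [FP, TN]].
    """
    _, probs, y = _frozen_probs(model, val_subset)
    if len(np.unique(y)) < 2:
        raise ValueError("validation subset has a single outcome class")
    roc = RocCurve.from_scores(probs, y)
    if cutoff is None:
        cutoff = model.prob_thresholds["youden"]
    pred = (probs >= cutoff).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    return {
        "auc": roc.auc,
        "auc_ci": (roc.ci_low, roc.ci_high),
        "accuracy": (tp + tn) / len(y),
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "confusion_matrix": [[tp, fn], [fp, tn]],
        "cutoff_used": float(cutoff),
    }


def calibration_metrics(model: QuestionModel, val_subset: pd.DataFrame):
    """Calibration-in-the-large and calibration slope by logistic recalibration.

    With LP the frozen model's linear predictor on the validation subjects:
    citl is the intercept of ``outcome ~ 1 + offset(LP)`` and cal_slope the
    LP coefficient of ``outcome ~ 1 + LP``.
    """
    cc, probs, y = _frozen_probs(model, val_subset)
    lp = np.log(probs / (1.0 - probs))
    if np.ptp(lp) == 0:
        raise ValueError("constant linear predictor; calibration slope undefined")
    citl_fit = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial(),
                      offset=lp).fit()
    slope_fit = sm.GLM(y, sm.add_constant(lp), family=sm.families.Binomial()).fit()
    return {
        "citl": float(citl_fit.params[0]),
        "cal_slope": float(slope_fit.params[1]),
    }


def calibration_curve(
    model: QuestionModel, val_subset: pd.DataFrame, bins: int = 10,
    loess_frac: float = 0.75, grid_points: int = 100,
):
    """Binned calibration pairs plus a Loess-smoothed curve.

    Predicted probabilities are cut into equal-count quantile bins (deciles
    by default, per the TRIPOD reporting convention); each bin contributes
    (mean predicted, observed event rate). Bins are reduced with a warning
    when they would hold fewer than 5 subjects. The smoothed curve is a
    lowess fit of outcome on predicted probability sampled on a fixed grid.
    """
    _, probs, y = _frozen_probs(model, val_subset)
    n = len(probs)
    if n < bins:
        raise ValueError(f"need at least {bins} subjects, got {n}")
    if np.ptp(probs) == 0:
        warnings.warn("constant predictions; single calibration bin", stacklevel=2)
        binned = [{"mean_predicted": float(probs[0]),
                   "observed_rate": float(y.mean()), "n": n}]
        return {"bins": binned, "smoothed": {"grid": [], "curve": []}}
    while bins > 1 and n // bins < 5:
        bins -= 1
    if bins < 10:
        warnings.warn(f"reduced calibration bins to {bins} (<5 subjects/bin)",
                      stacklevel=2)
    labels = pd.qcut(probs, q=bins, labels=False, duplicates="drop")
    binned = []
    for b in sorted(pd.unique(labels)):
        sel = labels == b
        binned.append({
            "mean_predicted": float(probs[sel].mean()),
            "observed_rate": float(y[sel].mean()),
            "n": int(sel.sum()),
        })
    grid = np.linspace(probs.min(), probs.max(), grid_points)
    smoothed = sm.nonparametric.lowess(
        y, probs, frac=loess_frac, xvals=grid, return_sorted=False
    )
    return {
        "bins": binned,
        "smoothed": {"grid": grid.tolist(),
                     "curve": np.asarray(smoothed, float).tolist()},
    }


def recalculate_thresholds(val_subset: pd.DataFrame, model: QuestionModel):
    """Cohort-specific thresholds on the validation data vs development.

    Recomputes per-marker Youden cutoffs and the three probability cutoffs
    on the validation subset and reports each next to the development value
    with its relative difference.
    """
    cc, probs, y = _frozen_probs(model, val_subset)
    out: dict = {"markers": {}, "probability": {}}
    for m in model.markers:
        direction = model.marker_thresholds[m]["direction"]
        new = marker_youden_threshold(cc[m].to_numpy(float), y, direction)
        dev = model.marker_thresholds[m]["cutoff"]
        out["markers"][m] = {
            "development": dev,
            "validation": new,
            "relative_difference": (new - dev) / abs(dev) if dev != 0 else np.inf,
        }
    new_p = probability_thresholds(probs, y)
    for key in ("youden", "sens90", "spec90"):
        dev = model.prob_thresholds[key]
        out["probability"][key] = {
            "development": dev,
            "validation": new_p[key],
            "relative_difference": (new_p[key] - dev) / abs(dev) if dev else np.inf,
        }
    return out


def validate_model(
    model: QuestionModel,
    val_subset: pd.DataFrame,
    dev_subset: pd.DataFrame | None = None,
    folds: int = 10,
    seed: int = 0,
) -> ValidationReport:
    """Full validation workflow: membership, discrimination, calibration."""
    disc = transported_discrimination(model, val_subset)
    cal = calibration_metrics(model, val_subset)
    curve = calibration_curve(model, val_subset)
    thresholds = recalculate_thresholds(val_subset, model)
    membership = None
    if dev_subset is not None:
        membership = membership_auc(
            dev_subset, val_subset, model.markers,
            folds=folds, seed=seed, question_id=model.question_id,
        )
    return ValidationReport(
        question_id=model.question_id,
        auc=disc["auc"],
        auc_ci=disc["auc_ci"],
        accuracy=disc["accuracy"],
        sensitivity=disc["sensitivity"],
        specificity=disc["specificity"],
        confusion_matrix=disc["confusion_matrix"],
        citl=cal["citl"],
        cal_slope=cal["cal_slope"],
        calibration_curve=curve,
        recalculated_thresholds=thresholds,
        membership=membership,
        cutoff_used=disc["cutoff_used"],
    )
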