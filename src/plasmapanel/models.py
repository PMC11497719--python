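"""Per-question diagnostic models and threshold machinery.

Each clinical question gets a maximum-likelihood logistic regression of the
0/1 outcome on the raw (pg/mL-scale) panel markers, so the serialized
coefficient formula can be filled out directly with a patient's values.
Diagnostic accuracy is summarized by ROC-AUC with 10-fold cross-validation
(panel models refit per fold, single markers scored as-is) and a DeLong
confidence interval on the pooled out-of-fold scores. Interpretation rests
on three probability cutoffs computed without cross-validation: the Youden
cutoff, the largest cutoff keeping sensitivity >= 90% ("rule-out" bound)
and the smallest cutoff keeping specificity >= 90% ("rule-in" bound), which
bound the low / indeterminate / high likelihood zones.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .cohort import MARKER_DIRECTIONS, MarkerPanel
from .harmonization import AgeCorrectionSpec, correct_nfl_for_age

__all__ = [
    "SeparationError",
    "ConstantScoreError",
    "RocCurve",
    "QuestionModel",
    "PatientResult",
    "fit_logistic",
    "cross_validated_auc",
    "marker_youden_threshold",
    "probability_thresholds",
    "classify_patient",
    "develop_question_model",
    "delong_ci",
]


class SeparationError(RuntimeError):
    """The logistic likelihood is unbounded (perfectly separable data)."""


class ConstantScoreError(ValueError):
    """All scores identical; no informative cutoff exists."""


# ---------------------------------------------------------------------------
# DeLong confidence interval for a single AUC
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x)  # midranks, 1-based


def delong_ci(scores, labels, conf_level: float = 0.95):
    """AUC and DeLong CI for one score vector against binary labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes required for AUC")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # structural components
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = stats.norm.ppf(0.5 + conf_level / 2)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return float(auc), (float(lo), float(hi))


@dataclass
class RocCurve:
    """ROC curve with pooled AUC and a 95% DeLong interval."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_scores(cls, scores, labels) -> "RocCurve":
        fpr, tpr, thr = roc_curve(labels, scores)
        auc, (lo, hi) = delong_ci(scores, labels)
        return cls(
            thresholds=thr,
            sensitivity=tpr,
            specificity=1.0 - fpr,
            auc=auc,
            ci_low=lo,
            ci_high=hi,
        )


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

def _check_separation(X: np.ndarray, y: np.ndarray, markers) -> None:
    for j, m in enumerate(markers):
        pos = X[y == 1, j]
        neg = X[y == 0, j]
        if pos.min() > neg.max() or neg.min() > pos.max():
            raise SeparationError(
                f"marker {m!r} perfectly separates the outcome classes; "
                "logistic coefficients are unbounded"
            )


def fit_logistic(subset: pd.DataFrame, markers) -> dict[str, float]:
    """Maximum-likelihood logistic fit of outcome on raw marker values.

    Returns ``{"intercept": b0, marker: slope, ...}`` (log-odds per unit).
    Complete cases only; fewer than 10 events per parameter triggers a
    warning, perfect separation an explicit error naming the marker.
    """
    markers = list(markers)
    cc = subset.dropna(subset=markers)
    X = cc[markers].to_numpy(dtype=float)
    y = cc["outcome"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; cannot fit")
    _check_separation(X, y, markers)
    if len(y) < 10 * (len(markers) + 1):
        warnings.warn(
            f"only {len(y)} complete cases for {len(markers) + 1} parameters; "
            "coefficients may be unstable", stacklevel=2,
        )
    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
            raise SeparationError(str(exc)) from exc
    if not res.mle_retvals.get("converged", False):
        raise SeparationError("logistic fit did not converge (near-separation?)")
    params = res.params
    out = {"intercept": float(params[0])}
    out.update({m: float(b) for m, b in zip(markers, params[1:])})
    return out


def _linear_predictor(coefficients: dict[str, float], X: pd.DataFrame | dict):
    lp = coefficients["intercept"]
    for m, b in coefficients.items():
        if m == "intercept":
            continue
        lp = lp + b * (X[m] if not isinstance(X, dict) else X[m])
    return lp


def predict_probability(coefficients: dict[str, float], X) -> np.ndarray:
    """Inverse-logit of the linear predictor on a DataFrame or dict."""
    lp = np.asarray(_linear_predictor(coefficients, X), dtype=float)
    return 1.0 / (1.0 + np.exp(-lp))


# ---------------------------------------------------------------------------
# Cross-validated AUC
# ---------------------------------------------------------------------------

def cross_validated_auc(
    subset: pd.DataFrame,
    scorer,
    folds: int = 10,
    seed: int = 0,
    direction: str = "higher_abnormal",
) -> RocCurve:
    """ROC-AUC with stratified 10-fold cross-validation.

    ``scorer`` is either a single marker name — its raw value is the score
    (AUC is invariant to monotone transforms, so no per-fold refit is
    needed; for a lower-abnormal marker the sign is flipped) — or a list of
    marker names, in which case a logistic model is refit on each training
    fold and the out-of-fold probabilities are pooled before computing the
    AUC and its DeLong interval.
    """
    if isinstance(scorer, str):
        cc = subset.dropna(subset=[scorer])
        scores = cc[scorer].to_numpy(dtype=float)
        if direction == "lower_abnormal" or (
            direction == "auto"
            and MARKER_DIRECTIONS.get(scorer) == "lower_abnormal"
        ):
            scores = -scores
        labels = cc["outcome"].to_numpy(dtype=int)
        return RocCurve.from_scores(scores, labels)

    markers = list(scorer)
    cc = subset.dropna(subset=markers).reset_index(drop=True)
    y = cc["outcome"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.full(len(cc), np.nan)
    for tr, te in skf.split(cc[markers], y):
        coef = fit_logistic(cc.iloc[tr], markers)
        oof[te] = predict_probability(coef, cc.iloc[te][markers])
    assert not np.isnan(oof).any()
    return RocCurve.from_scores(oof, y)


# ---------------------------------------------------------------------------
# Threshold search
# ---------------------------------------------------------------------------

def _candidate_cutoffs(values: np.ndarray, bounded01: bool = False) -> np.ndarray:
    u = np.unique(values)
    mids = (u[:-1] + u[1:]) / 2.0
    if bounded01:
        lo, hi = 0.0, 1.0
    else:
        lo, hi = -np.inf, np.inf
    return np.concatenate([[lo], mids, [hi]])


def _sens_spec(scores, labels, cutoffs):
    """Vectorized sensitivity/specificity with positive call = score >= cutoff."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    sens = (pos[None, :] >= cutoffs[:, None]).mean(axis=1)
    spec = (neg[None, :] < cutoffs[:, None]).mean(axis=1)
    return sens, spec


def marker_youden_threshold(
    scores, labels, direction: str = "higher_abnormal"
) -> float:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidate cutoffs are midpoints between adjacent distinct values plus
    the two infinite boundaries. ``lower_abnormal`` flips the comparison
    (abnormal below the cutoff). Ties in J are broken toward the cutoff
    with the higher specificity, then the smaller absolute cutoff value.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required")
    if np.all(scores == scores[0]):
        raise ConstantScoreError("all scores identical; no informative cutoff")
    work = -scores if direction == "lower_abnormal" else scores
    cuts = _candidate_cutoffs(work)
    sens, spec = _sens_spec(work, labels, cuts)
    J = sens + spec - 1.0
    # lexicographic tie-break: max J, then max specificity, then min |cutoff|
    best = np.lexsort((np.abs(cuts), -spec, -J))[0]
    cutoff = cuts[best]
    return float(-cutoff if direction == "lower_abnormal" else cutoff)


def probability_thresholds(probs, labels) -> dict:
    """The three probability cutoffs bounding the likelihood zones.

    ``youden``: Youden-index cutoff on the development probabilities.
    ``sens90``: the largest cutoff with sensitivity >= 0.90 (probabilities
    below it miss fewer than 10% of cases — rule-out bound).
    ``spec90``: the smallest cutoff with specificity >= 0.90 (probabilities
    at or above it miscall fewer than 10% of controls — rule-in bound).
    When sens90 > spec90 the zones would invert (the model separates better
    than 90/90); the result carries ``inverted_zones=True`` and downstream
    interpretation degrades to the Youden cutoff alone.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.all(probs == probs[0]):
        raise ConstantScoreError("constant probabilities; thresholds undefined")
    youden = marker_youden_threshold(probs, labels, "higher_abnormal")
    cuts = _candidate_cutoffs(probs, bounded01=True)
    sens, spec = _sens_spec(probs, labels, cuts)
    sens_ok = cuts[sens >= 0.90]
    spec_ok = cuts[spec >= 0.90]
    sens90 = float(sens_ok.max()) if len(sens_ok) else 0.0
    spec90 = float(spec_ok.min()) if len(spec_ok) else 1.0
    return {
        "youden": float(youden),
        "sens90": sens90,
        "spec90": spec90,
        "inverted_zones": bool(sens90 > spec90),
    }


# ---------------------------------------------------------------------------
# The deployable model artifact
# ---------------------------------------------------------------------------

@dataclass
class QuestionModel:
    """The serializable per-question interpretation tool.

    Carries everything needed to score a new patient: logistic coefficients
    on raw marker units, per-marker Youden cutoffs with abnormal directions,
    the three probability cutoffs, the development CV-AUC, and the zone
    convention in force.
    """

    question_id: str
    markers: tuple[str, ...]
    coefficients: dict[str, float]
    marker_thresholds: dict[str, dict]
    prob_thresholds: dict
    cv_auc: dict
    development_cohort: str = ""
    positive_label: str = ""
    zone_convention: str = "rule_in_out"  # or "literal"
    age_correction: dict = field(
        default_factory=lambda: AgeCorrectionSpec().as_dict()
    )

    def to_json(self, path) -> None:
        payload = dict(self.__dict__)
        payload["markers"] = list(self.markers)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "QuestionModel":
        with open(path) as fh:
            d = json.load(fh)
        d["markers"] = tuple(d["markers"])
        return cls(**d)

    @property
    def age_correction_spec(self) -> AgeCorrectionSpec:
        return AgeCorrectionSpec.from_dict(self.age_correction)


@dataclass
class PatientResult:
    probability: float
    zone: str  # low | indeterminate | high
    flags: dict[str, bool]  # True = abnormal
    linear_predictor: float
    marker_values: dict[str, float]


def _zone(probability: float, model: QuestionModel) -> str:
    th = model.prob_thresholds
    if th.get("inverted_zones", False):
        return "high" if probability >= th["youden"] else "low"
    if model.zone_convention == "literal":
        # the literal pairing: low likelihood below the 90%-specificity
        # cutoff, high likelihood above the 90%-sensitivity cutoff
        lo_bound, hi_bound = th["spec90"], th["sens90"]
    else:
        lo_bound, hi_bound = th["sens90"], th["spec90"]
    if probability >= hi_bound:
        return "high"
    if probability <= lo_bound:
        return "low"
    return "indeterminate"


def classify_patient(
    panel: MarkerPanel, age: float, model: QuestionModel
) -> PatientResult:
    """Score one patient's marker panel under a fitted question model.

    NfL is age-corrected first (per the model's correction spec) when the
    model uses the age-corrected marker and the panel carries raw NfL only.
    The probability boundary is inclusive on the high side.
    """
    values = panel.as_dict()
    if "nfl_age_corrected" in model.markers and values.get("nfl_age_corrected") is None:
        if values.get("nfl") is None:
            raise ValueError("model requires NfL but the panel has none")
        values["nfl_age_corrected"] = float(
            correct_nfl_for_age(values["nfl"], age, model.age_correction_spec)
        )
    missing = [m for m in model.markers if values.get(m) is None]
    if missing:
        raise ValueError(f"panel is missing required marker(s): {missing}")

    mv = {m: float(values[m]) for m in model.markers}
    lp = float(_linear_predictor(model.coefficients, mv))
    prob = 1.0 / (1.0 + np.exp(-lp))
    flags = {}
    for m in model.markers:
        t = model.marker_thresholds[m]
        if t["direction"] == "lower_abnormal":
            flags[m] = mv[m] < t["cutoff"]
        else:
            flags[m] = mv[m] > t["cutoff"]
    return PatientResult(
        probability=prob,
        zone=_zone(prob, model),
        flags=flags,
        linear_predictor=lp,
        marker_values=mv,
    )


def develop_question_model(
    subset: pd.DataFrame,
    markers,
    folds: int = 10,
    seed: int = 0,
    development_cohort: str = "",
    age_correction: AgeCorrectionSpec | None = None,
    zone_convention: str = "rule_in_out",
) -> QuestionModel:
    """Fit the full per-question artifact from a labelled subset.

    Combines the logistic fit, per-marker Youden cutoffs (no cross-
    validation), the three probability cutoffs on the full-data fitted
    probabilities, and the cross-validated panel AUC.
    """
    markers = tuple(markers)
    cc = subset.dropna(subset=list(markers)).reset_index(drop=True)
    coef = fit_logistic(cc, markers)
    probs = predict_probability(coef, cc[list(markers)])
    y = cc["outcome"].to_numpy(dtype=int)

    marker_thresholds = {}
    for m in markers:
        direction = MARKER_DIRECTIONS.get(m, "higher_abnormal")
        cutoff = marker_youden_threshold(cc[m].to_numpy(float), y, direction)
        marker_thresholds[m] = {"cutoff": cutoff, "direction": direction}

    roc = cross_validated_auc(cc, list(markers), folds=folds, seed=seed)
    return QuestionModel(
        question_id=subset.attrs.get("question_id", ""),
        markers=markers,
        coefficients=coef,
        marker_thresholds=marker_thresholds,
        prob_thresholds=probability_thresholds(probs, y),
        cv_auc={"auc": roc.auc, "ci": [roc.ci_low, roc.ci_high]},
        development_cohort=development_cohort,
        positive_label=subset.attrs.get("positive_label", ""),
        zone_convention=zone_convention,
        age_correction=(age_correction or AgeCorrectionSpec()).as_dict(),
    )
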