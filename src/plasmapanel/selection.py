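"""Bootstrapped LASSO marker selection with cross-validated penalty tuning.

For each clinical question, the L1 penalty alpha is tuned once by minimizing
the mean squared error of a linear LASSO of the 0/1 outcome on standardized
candidate markers in seeded 10-fold cross-validation. The selection
frequency of each marker is then the fraction of 1000 bootstrap resamples
in which its coefficient is non-zero at that alpha. A marker enters the
final diagnostic panel if it is selected in 100% of the iterations for at
least one question (a deliberately strict stability rule).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

__all__ = [
    "SelectionConfig",
    "SelectionReport",
    "PanelDecision",
    "optimize_alpha",
    "bootstrap_select",
    "decide_panel",
]

#: Coefficients with absolute value above this count as "selected".
SELECTION_TOL = 1e-8

DEFAULT_CANDIDATES = ("abeta_ratio", "ptau181", "gfap", "nfl_age_corrected")


@dataclass
class SelectionConfig:
    n_bootstrap: int = 1000
    cv_folds: int = 10
    alpha_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-4, 0, 60)
    )
    seed: int = 0
    candidate_markers: tuple[str, ...] = DEFAULT_CANDIDATES

    def __post_init__(self) -> None:
        self.alpha_grid = np.sort(np.asarray(self.alpha_grid, dtype=float))
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if len(self.alpha_grid) == 0 or np.any(self.alpha_grid <= 0):
            raise ValueError("alpha_grid must be non-empty and positive")


@dataclass
class SelectionReport:
    question_id: str
    alpha_star: float
    frequencies: dict[str, float]
    n_bootstrap: int
    seed: int
    n_redrawn: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SelectionReport":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class PanelDecision:
    included_markers: tuple[str, ...]
    rule_trace: dict[str, float]

    def to_json(self, path) -> None:
        payload = {
            "included_markers": list(self.included_markers),
            "rule_trace": self.rule_trace,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _design(subset: pd.DataFrame, markers) -> tuple[np.ndarray, np.ndarray]:
    """Complete-case design matrix and outcome for the candidate markers."""
    cols = list(markers)
    cc = subset.dropna(subset=cols)
    X = cc[cols].to_numpy(dtype=float)
    y = cc["outcome"].to_numpy(dtype=float)
    return X, y


def _zscore(train: np.ndarray, other: np.ndarray | None = None):
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    zt = (train - mean) / sd_safe
    # constant columns carry no information; zero them out
    zt[:, sd == 0] = 0.0
    if other is None:
        return zt
    zo = (other - mean) / sd_safe
    zo[:, sd == 0] = 0.0
    return zt, zo


def optimize_alpha(subset: pd.DataFrame, config: SelectionConfig) -> float:
    """Pick the penalty minimizing mean CV squared error of the linear LASSO.

    Fold assignment is seeded so the tuning is fully reproducible; markers
    are z-scored with training-fold statistics before fitting.
    """
    X, y = _design(subset, config.candidate_markers)
    n = len(y)
    if n < 2 * config.cv_folds:
        raise ValueError(
            f"need at least {2 * config.cv_folds} complete-case subjects, got {n}"
        )
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; cannot tune alpha")

    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    grid = config.alpha_grid
    errors = np.zeros((config.cv_folds, len(grid)))
    for f, (tr, te) in enumerate(kf.split(X)):
        Xtr, Xte = _zscore(X[tr], X[te])
        ytr, yte = y[tr], y[te]
        for a, alpha in enumerate(grid):
            model = Lasso(alpha=alpha, max_iter=50_000)
            model.fit(Xtr, ytr)
            pred = model.predict(Xte)
            errors[f, a] = np.mean((yte - pred) ** 2)
    mean_err = errors.mean(axis=0)
    if np.allclose(mean_err, mean_err[0]):
        warnings.warn(
            "all alphas give identical CV error; picking the largest",
            stacklevel=2,
        )
        return float(grid[-1])
    return float(grid[int(np.argmin(mean_err))])


def bootstrap_select(
    subset: pd.DataFrame, alpha_star: float, config: SelectionConfig
) -> SelectionReport:
    """Selection frequency of each marker over seeded bootstrap resamples.

    Each resample (same n, with replacement) is z-scored internally and a
    linear LASSO at ``alpha_star`` is fitted; a marker counts as selected
    when its coefficient is non-zero. Resamples that happen to contain a
    single outcome class are redrawn (and counted) so the frequency
    denominator stays at ``n_bootstrap``.
    """
    if alpha_star <= 0:
        raise ValueError("alpha_star must be positive")
    X, y = _design(subset, config.candidate_markers)
    n = len(y)
    rng = np.random.default_rng(config.seed)
    hits = np.zeros(len(config.candidate_markers), dtype=int)
    n_redrawn = 0
    for _ in range(config.n_bootstrap):
        while True:
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if len(np.unique(yb)) == 2:
                break
            n_redrawn += 1
        Xb = _zscore(X[idx])
        model = Lasso(alpha=alpha_star, max_iter=50_000)
        model.fit(Xb, yb)
        hits += np.abs(model.coef_) > SELECTION_TOL
    freqs = {
        m: float(h) / config.n_bootstrap
        for m, h in zip(config.candidate_markers, hits)
    }
    return SelectionReport(
        question_id=subset.attrs.get("question_id", ""),
        alpha_star=float(alpha_star),
        frequencies=freqs,
        n_bootstrap=config.n_bootstrap,
        seed=config.seed,
        n_redrawn=n_redrawn,
    )


def decide_panel(reports) -> PanelDecision:
    """Apply the 100%-selection rule across questions.

    A marker joins the shared diagnostic panel exactly when some question
    selected it in every bootstrap iteration (frequency == 1.0).
    """
    reports = list(reports)
    if not reports:
        raise ValueError("need at least one selection report")
    markers: list[str] = []
    for r in reports:
        for m in r.frequencies:
            if m not in markers:
                markers.append(m)
    trace = {m: max(r.frequencies.get(m, 0.0) for r in reports) for m in markers}
    included = tuple(m for m in markers if trace[m] == 1.0)
    return PanelDecision(included_markers=included, rule_trace=trace)
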