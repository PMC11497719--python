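"""Inter-lot alignment, NfL age correction, and amyloid adjudication.

Plasma Simoa values measured with different kit lots are put on a common
scale with Passing-Bablok method-comparison regression fitted on paired
re-measurements. NfL, which rises strongly with age, can be expressed
relative to an age-expected reference value. The amyloid reference standard
is adjudicated from amyloid-PET reads or CSF assay cutoffs, PET taking
precedence over CSF.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "AlignmentModel",
    "AgeCorrectionSpec",
    "AmyloidEvidence",
    "fit_passing_bablok",
    "apply_alignment",
    "correct_nfl_for_age",
    "adjudicate_amyloid",
    "load_pairs",
]


@dataclass
class AlignmentModel:
    """Affine map y = intercept + slope * x from one kit lot to another."""

    marker: str
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    n_pairs: int
    direction: str = "validation_to_development"

    def to_json(self, path) -> None:
        payload = {
            "marker": self.marker,
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_ci": list(self.slope_ci),
            "intercept_ci": list(self.intercept_ci),
            "n_pairs": self.n_pairs,
            "direction": self.direction,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "AlignmentModel":
        with open(path) as fh:
            d = json.load(fh)
        d["slope_ci"] = tuple(d["slope_ci"])
        d["intercept_ci"] = tuple(d["intercept_ci"])
        return cls(**d)


def fit_passing_bablok(
    x, y, marker: str = "", conf_level: float = 0.95
) -> AlignmentModel:
    """Classical Passing-Bablok regression (part I, positive correlation).

    The slope is the shifted median of all pairwise slopes
    ``S_ij = (y_j - y_i) / (x_j - x_i)`` over i < j, excluding pairs with
    identical x and slopes exactly -1; the shift K is the number of slopes
    below -1. The intercept is ``median(y_i - slope * x_i)``. Confidence
    bounds use the rank-based normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input pairs")
    if np.all(x == x[0]):
        raise ValueError("all x values identical; slope undefined")

    slopes = []
    for i, j in combinations(range(n), 2):
        dx = x[j] - x[i]
        if dx == 0:
            continue
        s = (y[j] - y[i]) / dx
        if s == -1.0:
            continue
        slopes.append(s)
    slopes = np.sort(np.asarray(slopes))
    N = len(slopes)
    if N < 3:
        raise ValueError("fewer than 3 finite pairwise slopes")

    K = int(np.sum(slopes < -1.0))

    def shifted_median(offset: int) -> float:
        # median of the slope sequence shifted by `offset` ranks (1-indexed
        # classical formulas); even counts average the two central values
        if N % 2:
            idx = (N + 1) // 2 + offset  # 1-indexed
            return float(slopes[np.clip(idx - 1, 0, N - 1)])
        lo = N // 2 + offset
        hi = N // 2 + 1 + offset
        lo = int(np.clip(lo - 1, 0, N - 1))
        hi = int(np.clip(hi - 1, 0, N - 1))
        return float(0.5 * (slopes[lo] + slopes[hi]))

    slope = shifted_median(K)

    z = stats.norm.ppf(0.5 + conf_level / 2)
    c = z * np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(np.round((N - c) / 2.0))
    m2 = N - m1 + 1
    lo_idx = int(np.clip(m1 + K, 1, N)) - 1
    hi_idx = int(np.clip(m2 + K, 1, N)) - 1
    slope_lo = float(slopes[lo_idx])
    slope_hi = float(slopes[hi_idx])

    intercept = float(np.median(y - slope * x))
    intercept_lo = float(np.median(y - slope_hi * x))
    intercept_hi = float(np.median(y - slope_lo * x))

    if slope == 0 or not np.isfinite(slope):
        raise ValueError(f"degenerate Passing-Bablok slope {slope}")

    return AlignmentModel(
        marker=marker,
        slope=slope,
        intercept=intercept,
        slope_ci=(slope_lo, slope_hi),
        intercept_ci=(intercept_lo, intercept_hi),
        n_pairs=n,
    )


def apply_alignment(values, model: AlignmentModel):
    """Map marker values onto the reference lot scale: a + b * value.

    Values that become non-positive after alignment are flagged (returned
    mask) because a concentration cannot be negative.
    """
    values = np.asarray(values, dtype=float)
    aligned = model.intercept + model.slope * values
    flagged = aligned <= 0
    if np.any(flagged):
        warnings.warn(
            f"{int(flagged.sum())} aligned {model.marker or 'marker'} value(s) "
            "are non-positive", stacklevel=2,
        )
    return aligned, flagged


def load_pairs(path, sep: str = ","):
    """Read a paired re-measurement table (subject_id, marker, value_original,
    value_remeasured) into a DataFrame."""
    import pandas as pd

    df = pd.read_csv(path, sep=sep)
    required = {"subject_id", "marker", "value_original", "value_remeasured"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pairs file missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# NfL age correction
# ---------------------------------------------------------------------------

@dataclass
class AgeCorrectionSpec:
    """How to express NfL relative to its age-expected value.

    ``identity`` leaves NfL untouched. ``log_linear_reference`` divides by
    the reference curve exp(b0 + b1 * age); the published reference-curve
    coefficients are supplied by the user via ``coefficients`` (keys ``b0``,
    ``b1``) since no default curve is bundled.
    """

    form: str = "identity"
    coefficients: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.form not in ("identity", "log_linear_reference"):
            raise ValueError(f"unknown age-correction form {self.form!r}")
        if self.form == "log_linear_reference":
            if not {"b0", "b1"} <= set(self.coefficients):
                raise ValueError(
                    "log_linear_reference requires coefficients b0 and b1"
                )

    def as_dict(self) -> dict:
        return {"form": self.form, "coefficients": dict(self.coefficients)}

    @classmethod
    def from_dict(cls, d: dict) -> "AgeCorrectionSpec":
        return cls(form=d.get("form", "identity"), coefficients=d.get("coefficients", {}))


def correct_nfl_for_age(nfl, age, spec: AgeCorrectionSpec | None = None):
    """Return NfL corrected for age under ``spec`` (default: identity).

    The log-linear form returns the ratio of observed NfL to its
    age-expected reference value exp(b0 + b1 * age); 1.0 means exactly
    as expected for age.
    """
    spec = spec or AgeCorrectionSpec()
    nfl = np.asarray(nfl, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(nfl <= 0):
        raise ValueError("nfl must be positive")
    if np.any((age <= 0) | (age >= 120)):
        raise ValueError("age must lie in (0, 120)")
    if spec.form == "identity":
        return nfl if nfl.ndim else float(nfl)
    b0 = spec.coefficients["b0"]
    b1 = spec.coefficients["b1"]
    out = nfl / np.exp(b0 + b1 * age)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Amyloid adjudication
# ---------------------------------------------------------------------------

@dataclass
class AmyloidEvidence:
    """One piece of amyloid reference-standard evidence for a subject."""

    modality: str
    values: dict

    MODALITIES = (
        "pet_visual",
        "pet_centiloid",
        "csf_innotest",
        "csf_elecsys",
        "csf_lumipulse_ratio",
        "csf_lumipulse_ab42",
        "csf_lumipulse_spin",
        "external_record",
    )

    def __post_init__(self) -> None:
        if self.modality not in self.MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")


# precedence: PET reads first, centiloid quantification next, CSF assays
# after ("based on amyloid PET images ... and when unavailable based on CSF"),
# chart-derived records last
_PRECEDENCE = {
    "pet_visual": 0,
    "pet_centiloid": 1,
    "csf_innotest": 2,
    "csf_elecsys": 2,
    "csf_lumipulse_ratio": 2,
    "csf_lumipulse_ab42": 2,
    "csf_lumipulse_spin": 2,
    "external_record": 3,
}


def _positive(value: float, cutoff: float, direction: str) -> str:
    if direction == "gt":
        return "positive" if value > cutoff else "negative"
    return "positive" if value < cutoff else "negative"


def _evaluate(ev: AmyloidEvidence) -> str:
    v = ev.values
    m = ev.modality

    def need(*keys):
        for k in keys:
            if k not in v or v[k] is None or (
                not isinstance(v[k], str) and v[k] <= 0
            ):
                raise ValueError(f"{m}: missing or non-positive value {k!r}")

    if m == "pet_visual":
        read = str(v.get("read", "")).lower()
        if read not in ("positive", "negative"):
            raise ValueError("pet_visual requires read = positive|negative")
        return read
    if m == "pet_centiloid":
        # centiloid can legitimately be <= 0; only require presence
        if "centiloid" not in v:
            raise ValueError("pet_centiloid requires a centiloid value")
        return _positive(float(v["centiloid"]), 30.0, "gt")
    if m == "csf_innotest":
        if "ptau181" in v and "abeta42" in v:
            need("ptau181", "abeta42")
            return _positive(v["ptau181"] / v["abeta42"], 0.06, "gt")
        # abeta42-only fallback as used for Innotest in the Geneva cohort
        need("abeta42")
        return _positive(float(v["abeta42"]), 880.5, "lt")
    if m == "csf_elecsys":
        if "ratio" in v:
            need("ratio")
            ratio = float(v["ratio"])
        else:
            need("ptau181", "abeta42")
            ratio = v["ptau181"] / v["abeta42"]
        return _positive(ratio, 0.02, "gt")
    if m == "csf_lumipulse_ratio":
        need("ratio")
        return _positive(float(v["ratio"]), 0.069, "lt")
    if m == "csf_lumipulse_ab42":
        need("abeta42")
        return _positive(float(v["abeta42"]), 725.0, "lt")
    if m == "csf_lumipulse_spin":
        need("ratio")
        return _positive(float(v["ratio"]), 0.062, "lt")
    if m == "external_record":
        status = str(v.get("status", "")).lower()
        if status not in ("positive", "negative"):
            raise ValueError("external_record requires status = positive|negative")
        return status
    raise ValueError(f"unknown modality {m!r}")  # pragma: no cover


def adjudicate_amyloid(evidence) -> str:
    """Adjudicate amyloid status from an ordered collection of evidence.

    PET visual reads take precedence over centiloid quantification, which
    takes precedence over CSF assays, then chart records. Conflicting
    evidence at the same precedence level resolves to the first-listed item
    with a warning. Empty evidence returns ``"unknown"``.
    """
    evidence = list(evidence)
    if not evidence:
        return "unknown"
    calls = [(ev, _evaluate(ev)) for ev in evidence]
    best = min(_PRECEDENCE[ev.modality] for ev, _ in calls)
    top = [(ev, c) for ev, c in calls if _PRECEDENCE[ev.modality] == best]
    statuses = {c for _, c in top}
    if len(statuses) > 1:
        warnings.warn(
            "conflicting same-precedence amyloid evidence "
            f"({[(ev.modality, c) for ev, c in top]}); first-listed wins",
            stacklevel=2,
        )
    return top[0][1]
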