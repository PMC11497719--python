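"""Synthetic memory-clinic cohorts with realistic plasma marker structure.

Each diagnostic group's markers are drawn from a Gaussian copula with
lognormal marginals whose natural-scale mean and SD match the published
per-group summaries bundled in ``data/table1_defaults.yaml``. Lognormal
marginals (rather than normal) keep concentrations positive and right-
skewed even where the SD approaches the mean (e.g. NfL in FTD, 38.3 +/- 38
pg/mL). Amyloid status is fixed for the amyloid-stratified pre-dementia
groups, certain for AD dementia, and a Bernoulli mixture for FTD (17%
amyloid-positive co-pathology) and DLB (49%). An optional per-marker affine
site shift emulates a different assay kit lot, closing the loop with the
Passing-Bablok alignment module.

Known simplifications: markers are independent of age within a group by
default (a log-linear age effect on NfL can be switched on), FTD/DLB marker
levels are drawn from the pooled group distribution regardless of the
simulated amyloid label, and the uniform copula correlation of 0.3 is a
declared assumption, not an estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cohort import CohortTable
from .harmonization import AgeCorrectionSpec, correct_nfl_for_age

__all__ = [
    "GroupDistributionSpec",
    "CohortSimConfig",
    "lognormal_params_from_moments",
    "generate_group",
    "generate_cohort",
    "default_config",
    "load_config",
]

SIM_MARKERS = ("abeta_ratio", "ptau181", "gfap", "nfl")


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of a lognormal with the given natural moments.

    Method of moments: sigma^2 = ln(1 + sd^2/mean^2), mu = ln(mean) -
    sigma^2 / 2. ``sd = 0`` gives the degenerate point mass at ``mean``.
    """
    if mean <= 0:
        raise ValueError(f"mean must be positive, got {mean}")
    if sd < 0:
        raise ValueError(f"sd must be non-negative, got {sd}")
    if sd == 0:
        return float(np.log(mean)), 0.0
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


@dataclass
class GroupDistributionSpec:
    """Marginal distributions and mixture fractions for one diagnostic group."""

    label: str
    group: str
    n: int
    age_mean: float
    age_sd: float
    female_fraction: float
    markers: dict[str, tuple[float, float]]  # marker -> (mean, sd)
    amyloid: str | None = None  # fixed status for stratified groups
    abeta_positive_fraction: float | None = None  # mixture for unstratified

    def __post_init__(self) -> None:
        for m, (mean, sd) in self.markers.items():
            if mean <= 0 or sd < 0:
                raise ValueError(f"{self.label}/{m}: invalid moments ({mean}, {sd})")
        if self.amyloid is None and self.abeta_positive_fraction is None:
            raise ValueError(
                f"{self.label}: need a fixed amyloid status or a mixture fraction"
            )
        f = self.abeta_positive_fraction
        if f is not None and not (0 <= f <= 1):
            raise ValueError(f"{self.label}: mixture fraction {f} outside [0, 1]")


@dataclass
class CohortSimConfig:
    groups: list[GroupDistributionSpec]
    marker_correlation: float | np.ndarray = 0.3
    site_shift: dict[str, tuple[float, float]] | None = None  # marker -> (slope, b)
    seed: int = 0
    abeta_copathology_shift: dict[str, float] = field(default_factory=dict)
    nfl_age_slope: float = 0.0  # per-year log-scale age effect on NfL
    age_correction: AgeCorrectionSpec = field(default_factory=AgeCorrectionSpec)
    name: str = "synthetic"

    def correlation_matrix(self) -> np.ndarray:
        k = len(SIM_MARKERS)
        if np.isscalar(self.marker_correlation):
            rho = float(self.marker_correlation)
            R = np.full((k, k), rho)
            np.fill_diagonal(R, 1.0)
        else:
            R = np.asarray(self.marker_correlation, dtype=float)
        if R.shape != (k, k) or not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("correlation matrix must be symmetric with unit diagonal")
        if np.min(np.linalg.eigvalsh(R)) <= 0:
            raise ValueError("correlation matrix must be positive-definite")
        return R


def load_config(path) -> CohortSimConfig:
    """Read a cohort simulation config from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _config_from_mapping(raw)


def _config_from_mapping(raw: dict) -> CohortSimConfig:
    groups = []
    for g in raw["groups"]:
        groups.append(
            GroupDistributionSpec(
                label=g["label"],
                group=g["group"],
                n=int(g["n"]),
                age_mean=float(g["age_mean"]),
                age_sd=float(g["age_sd"]),
                female_fraction=float(g["female_fraction"]),
                markers={
                    m: (float(v["mean"]), float(v["sd"]))
                    for m, v in g["markers"].items()
                },
                amyloid=g.get("amyloid"),
                abeta_positive_fraction=g.get("abeta_positive_fraction"),
            )
        )
    shift = raw.get("site_shift")
    if shift is not None:
        shift = {m: (float(v[0]), float(v[1])) for m, v in shift.items()}
    return CohortSimConfig(
        groups=groups,
        marker_correlation=raw.get("marker_correlation", 0.3),
        site_shift=shift,
        seed=int(raw.get("seed", 0)),
        name=raw.get("name", "synthetic"),
    )


def default_config(seed: int = 0) -> CohortSimConfig:
    """The bundled development-cohort configuration (1199 subjects)."""
    ref = resources.files("plasmapanel.data") / "table1_defaults.yaml"
    with resources.as_file(ref) as path:
        cfg = load_config(path)
    cfg.seed = seed
    return cfg


def generate_group(
    spec: GroupDistributionSpec,
    config: CohortSimConfig,
    rng: np.random.Generator | None = None,
    n: int | None = None,
    id_prefix: str = "",
) -> pd.DataFrame:
    """Draw one diagnostic group as a cohort DataFrame fragment."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = spec.n if n is None else n
    R = config.correlation_matrix()
    L = np.linalg.cholesky(R)
    Z = rng.standard_normal((n, len(SIM_MARKERS))) @ L.T

    # amyloid labels first so a co-pathology shift can act on the markers
    if spec.amyloid is not None:
        amyloid = np.full(n, spec.amyloid, dtype=object)
    else:
        pos = rng.random(n) < spec.abeta_positive_fraction
        amyloid = np.where(pos, "positive", "negative").astype(object)

    age = stats.truncnorm.rvs(
        (18 - spec.age_mean) / spec.age_sd,
        (100 - spec.age_mean) / spec.age_sd,
        loc=spec.age_mean,
        scale=spec.age_sd,
        size=n,
        random_state=rng,
    )

    cols: dict[str, np.ndarray] = {}
    for j, m in enumerate(SIM_MARKERS):
        mean, sd = spec.markers[m]
        mu, sigma = lognormal_params_from_moments(mean, sd)
        log_x = mu + sigma * Z[:, j]
        if m == "nfl" and config.nfl_age_slope:
            log_x = log_x + config.nfl_age_slope * (age - spec.age_mean)
        x = np.exp(log_x)
        shift = config.abeta_copathology_shift.get(m, 0.0)
        if shift and spec.amyloid is None:
            x = np.where(amyloid == "positive", x * np.exp(shift), x)
        cols[m] = x

    sex = np.where(rng.random(n) < spec.female_fraction, "female", "male").astype(object)
    df = pd.DataFrame(
        {
            "subject_id": [f"{id_prefix}{spec.label}_{i:06d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "group": spec.group,
            "amyloid": amyloid,
            **cols,
        }
    )
    df["nfl_age_corrected"] = correct_nfl_for_age(
        df["nfl"].to_numpy(), df["age"].to_numpy(), config.age_correction
    )
    return df


def generate_cohort(config: CohortSimConfig) -> CohortTable:
    """Concatenate all configured groups into a validated cohort.

    A per-marker affine site shift, when configured, is applied last — the
    shifted values stand in for a different kit lot and can be re-aligned
    with Passing-Bablok regression.
    """
    rng = np.random.default_rng(config.seed)
    frames = [generate_group(spec, config, rng) for spec in config.groups]
    df = pd.concat(frames, ignore_index=True)
    if config.site_shift:
        for m, (slope, intercept) in config.site_shift.items():
            df[m] = intercept + slope * df[m]
        df["nfl_age_corrected"] = correct_nfl_for_age(
            df["nfl"].to_numpy(), df["age"].to_numpy(), config.age_correction
        )
    cohort = CohortTable(config.name, df, provenance={"generator_seed": config.seed})
    return cohort
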