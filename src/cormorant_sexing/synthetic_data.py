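"""Seeded generation of synthetic morphometric samples.

Emulates the measurement structure of a shot-bird cormorant dataset: two
sexes x two age classes, sex-specific multivariate-normal measurements
parameterised by means and coefficients of variation, a configurable
between-measurement correlation, and missing-completely-at-random cells
whose rates reproduce unequal per-measurement sample sizes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError

#: Canonical measurement order used throughout the package (all in mm).
MEASUREMENTS: tuple[str, ...] = (
    "wing_length",
    "bill_length",
    "max_bill_depth",
    "min_bill_depth",
    "tarsus_length",
)

SEXES: tuple[str, str] = ("F", "M")
AGES: tuple[str, str] = ("juv", "ad")

_PSD_TOL = 1e-10


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic population.

    Attributes
    ----------
    sex_means : mapping sex -> measurement -> mean (mm)
    cvs : mapping sex -> measurement -> coefficient of variation (proportion)
    adult_offset : mapping measurement -> additive mean shift for adults (mm);
        all-zero means both age classes share one distribution within a sex.
    correlation : (k, k) between-measurement correlation matrix shared by
        all groups, in :data:`MEASUREMENTS` order.
    group_sizes : mapping sex -> age -> count.
    missingness : mapping measurement -> probability a cell is missing.
    seed : integer seed; fixes the sample bit-for-bit.
    """

    sex_means: Mapping[str, Mapping[str, float]]
    cvs: Mapping[str, Mapping[str, float]]
    correlation: np.ndarray
    group_sizes: Mapping[str, Mapping[str, int]]
    missingness: Mapping[str, float] = field(
        default_factory=lambda: {m: 0.0 for m in MEASUREMENTS}
    )
    adult_offset: Mapping[str, float] = field(
        default_factory=lambda: {m: 0.0 for m in MEASUREMENTS}
    )
    seed: int = 0
    measurements: tuple[str, ...] = MEASUREMENTS

    def __post_init__(self):
        object.__setattr__(
            self, "correlation", np.asarray(self.correlation, dtype=float)
        )
        self.validate()

    def validate(self) -> None:
        k = len(self.measurements)
        r = self.correlation
        if r.shape != (k, k):
            raise ConfigurationError(
                f"correlation matrix must be {k}x{k}, got {r.shape}"
            )
        if not np.allclose(r, r.T, atol=1e-12):
            raise ConfigurationError(f"correlation matrix is not symmetric:\n{r}")
        if not np.allclose(np.diag(r), 1.0, atol=1e-12):
            raise ConfigurationError(f"correlation matrix diagonal is not 1:\n{r}")
        if np.linalg.eigvalsh(r).min() < -_PSD_TOL:
            raise ConfigurationError(
                f"correlation matrix is not positive semi-definite:\n{r}"
            )
        for sex in SEXES:
            for m in self.measurements:
                if self.sex_means[sex][m] <= 0:
                    raise ConfigurationError(f"non-positive mean for {sex}/{m}")
                if self.cvs[sex][m] <= 0:
                    raise ConfigurationError(f"non-positive CV for {sex}/{m}")
            for age in AGES:
                if self.group_sizes[sex][age] < 0:
                    raise ConfigurationError(f"negative group size for {sex}/{age}")
        for m, rate in self.missingness.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"missingness rate for {m} outside [0, 1]")

    def group_mean_vector(self, sex: str, age: str) -> np.ndarray:
        mu = np.array([self.sex_means[sex][m] for m in self.measurements])
        if age == "ad":
            mu = mu + np.array(
                [self.adult_offset.get(m, 0.0) for m in self.measurements]
            )
        return mu

    def group_covariance(self, sex: str) -> np.ndarray:
        # Sigma_ij = rho_ij * (CV_i * mu_i) * (CV_j * mu_j), mu the sex mean
        sd = np.array(
            [self.cvs[sex][m] * self.sex_means[sex][m] for m in self.measurements]
        )
        return self.correlation * np.outer(sd, sd)

    def to_dict(self) -> dict:
        return {
            "sex_means": {s: dict(self.sex_means[s]) for s in SEXES},
            "cvs": {s: dict(self.cvs[s]) for s in SEXES},
            "adult_offset": dict(self.adult_offset),
            "correlation": self.correlation.tolist(),
            "group_sizes": {s: dict(self.group_sizes[s]) for s in SEXES},
            "missingness": dict(self.missingness),
            "seed": int(self.seed),
            "measurements": list(self.measurements),
        }

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def uniform_correlation(rho: float, k: int = len(MEASUREMENTS)) -> np.ndarray:
    """Equicorrelation matrix: 1 on the diagonal, ``rho`` elsewhere."""
    return np.full((k, k), rho) + (1.0 - rho) * np.eye(k)


def config_from_dict(d: Mapping) -> SimulationConfig:
    corr = d["correlation"]
    measurements = tuple(d.get("measurements", MEASUREMENTS))
    if np.isscalar(corr):
        corr = uniform_correlation(float(corr), len(measurements))
    return SimulationConfig(
        sex_means=d["sex_means"],
        cvs=d["cvs"],
        correlation=np.asarray(corr, dtype=float),
        group_sizes=d["group_sizes"],
        missingness=d.get("missingness", {m: 0.0 for m in measurements}),
        adult_offset=d.get("adult_offset", {m: 0.0 for m in measurements}),
        seed=int(d.get("seed", 0)),
        measurements=measurements,
    )


def load_config(path) -> SimulationConfig:
    """Read a :class:`SimulationConfig` from a YAML file."""
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def default_config(**overrides) -> SimulationConfig:
    """The shipped parameterisation: published means, CVs and sample sizes.

    Keyword overrides replace top-level fields, e.g. ``seed=5`` or
    ``correlation=0.3`` (a scalar expands to an equicorrelation matrix).
    """
    text = resources.files("cormorant_sexing.data").joinpath(
        "default_config.yaml"
    ).read_text()
    d = yaml.safe_load(text)
    d.update(overrides)
    return config_from_dict(d)


@dataclass
class PopulationSample:
    """A simulated or loaded set of birds.

    ``data`` has columns ``id``, ``sex`` (F/M), ``age`` (juv/ad) followed by
    measurement columns in mm; missing cells are NaN. ``provenance`` records
    where the sample came from (seed, config hash, or source file).
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def measurements(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("id", "sex", "age")]

    def sex_subset(self, sex: str) -> pd.DataFrame:
        return self.data[self.data["sex"] == sex]

    def __len__(self) -> int:
        return len(self.data)


def generate_population(
    config: SimulationConfig, apply_missingness: bool = False
) -> PopulationSample:
    """Draw a population from the config's group-wise multivariate normals.

    Group sizes match the config exactly; any non-positive draw is redrawn
    (negligible probability at realistic CVs). Deterministic for a fixed
    config seed. When ``apply_missingness`` is set, the config's MCAR rates
    are applied with a seed derived from the config seed.
    """
    ss = np.random.SeedSequence(config.seed)
    draw_seed, miss_seed = ss.spawn(2)
    rng = np.random.default_rng(draw_seed)

    frames = []
    idx = 0
    for sex in SEXES:
        cov = config.group_covariance(sex)
        for age in AGES:
            n = config.group_sizes[sex][age]
            if n == 0:
                continue
            mu = config.group_mean_vector(sex, age)
            x = rng.multivariate_normal(mu, cov, size=n, method="cholesky")
            bad = (x <= 0).any(axis=1)
            while bad.any():  # truncation by redraw keeps marginals near-normal
                x[bad] = rng.multivariate_normal(
                    mu, cov, size=int(bad.sum()), method="cholesky"
                )
                bad = (x <= 0).any(axis=1)
            df = pd.DataFrame(x, columns=list(config.measurements))
            df.insert(0, "age", age)
            df.insert(0, "sex", sex)
            df.insert(0, "id", [f"sim-{idx + i:05d}" for i in range(n)])
            idx += n
            frames.append(df)

    if frames:
        data = pd.concat(frames, ignore_index=True)
    else:
        data = pd.DataFrame(
            columns=["id", "sex", "age", *config.measurements]
        )
    sample = PopulationSample(
        data=data,
        provenance={"seed": int(config.seed), "config_hash": config.config_hash()},
    )
    if apply_missingness:
        sample = inject_missingness(
            sample, config.missingness, seed=int(miss_seed.generate_state(1)[0])
        )
    return sample


def inject_missingness(
    sample: PopulationSample, rates: Mapping[str, float], seed: int
) -> PopulationSample:
    """Blank cells independently at each measurement's MCAR rate.

    Sex and age are never blanked. Deterministic under a fixed seed; returns
    a new sample, leaving the input untouched.
    """
    for m, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ConfigurationError(f"missingness rate for {m} outside [0, 1]")
    rng = np.random.default_rng(seed)
    data = sample.data.copy()
    for m in sample.measurements:
        rate = rates.get(m, 0.0)
        if rate > 0:
            mask = rng.random(len(data)) < rate
            data.loc[mask, m] = np.nan
    prov = dict(sample.provenance)
    prov["missingness_seed"] = int(seed)
    return PopulationSample(data=data, provenance=prov)
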