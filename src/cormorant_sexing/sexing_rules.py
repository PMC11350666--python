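"""Fixed linear sexing equations, grey zones, and cross-population validation.

A sexing rule is a published or fitted linear score D over named
measurements; the sign rule calls D < 0 female and D > 0 male. A grey zone
(t_F, t_M) leaves birds with t_F <= D <= t_M unsexed so that per-sex
misclassification outside the zone is held to a chosen target.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, IncompleteRecordError, InsufficientDataError
from .synthetic_data import PopulationSample

UNSEXED = "U"


@dataclass(frozen=True)
class SexingRule:
    """A linear sexing equation D = sum(coef_j * measurement_j) + constant."""

    name: str
    measurements: tuple[str, ...]
    coefficients: tuple[float, ...]
    constant: float
    greyzone: tuple[float, float] | None = None  # (t_F, t_M)
    provenance: str = ""

    def __post_init__(self):
        if len(self.measurements) == 0:
            raise ConfigurationError(f"rule {self.name!r} has no measurements")
        if len(set(self.measurements)) != len(self.measurements):
            raise ConfigurationError(f"rule {self.name!r} repeats a measurement")
        if len(self.coefficients) != len(self.measurements):
            raise ConfigurationError(
                f"rule {self.name!r}: {len(self.coefficients)} coefficients "
                f"for {len(self.measurements)} measurements"
            )
        if self.greyzone is not None and not self.greyzone[0] < self.greyzone[1]:
            raise ConfigurationError(
                f"rule {self.name!r}: grey zone lower bound must be below upper"
            )


def _load_presets() -> dict[str, SexingRule]:
    text = resources.files("cormorant_sexing.data").joinpath(
        "presets.yaml"
    ).read_text()
    raw = yaml.safe_load(text)
    out = {}
    for name, d in raw.items():
        out[name] = SexingRule(
            name=name,
            measurements=tuple(d["measurements"]),
            coefficients=tuple(float(c) for c in d["coefficients"]),
            constant=float(d["constant"]),
            greyzone=tuple(d["greyzone"]) if "greyzone" in d else None,
            provenance=d.get("provenance", ""),
        )
    return out


#: Published equations shipped with the package, keyed by preset name.
PRESETS: dict[str, SexingRule] = _load_presets()


def apply_equation(rule: SexingRule, record) -> float:
    """Evaluate the rule's discriminant score D on one record."""
    if isinstance(record, (pd.Series, Mapping)):
        missing = [
            m for m in rule.measurements
            if m not in record or pd.isna(record[m])
        ]
        if missing:
            raise IncompleteRecordError(
                f"rule {rule.name!r} requires measurement(s) {missing}"
            )
        x = np.array([float(record[m]) for m in rule.measurements])
    else:
        x = np.asarray(record, dtype=float)
        if np.isnan(x).any():
            raise IncompleteRecordError(
                f"rule {rule.name!r} given a record with missing values"
            )
    return float(x @ np.asarray(rule.coefficients) + rule.constant)


def score_sample(rule: SexingRule, data: pd.DataFrame) -> pd.Series:
    """Vectorised D over a DataFrame; NaN where the rule's inputs are missing."""
    missing_cols = [m for m in rule.measurements if m not in data.columns]
    if missing_cols:
        raise IncompleteRecordError(
            f"rule {rule.name!r} requires column(s) {missing_cols}"
        )
    X = data[list(rule.measurements)].to_numpy(dtype=float)
    d = X @ np.asarray(rule.coefficients) + rule.constant
    d[np.isnan(X).any(axis=1)] = np.nan
    return pd.Series(d, index=data.index, name="D")


def sex_from_score(D: float, rule: SexingRule | None = None,
                   use_greyzone: bool = False) -> str:
    """Map a score to "F", "M" or "U" (unsexed).

    Without a grey zone the sign rule applies, with D = 0 exactly left
    unsexed. With ``use_greyzone`` the rule's thresholds are used: female
    below t_F, male above t_M, unsexed between.
    """
    if not np.isfinite(D):
        raise ValueError(f"non-finite score {D}")
    if use_greyzone:
        if rule is None or rule.greyzone is None:
            raise ConfigurationError(
                "grey-zone classification requested on a rule without thresholds"
            )
        t_f, t_m = rule.greyzone
        if D < t_f:
            return "F"
        if D > t_m:
            return "M"
        return UNSEXED
    if D < 0:
        return "F"
    if D > 0:
        return "M"
    return UNSEXED


@dataclass(frozen=True)
class GreyZoneReport:
    """Thresholds plus the realized error and unsexed rates they induce."""

    t_F: float | None
    t_M: float | None
    male_misclassified_pct: float
    female_misclassified_pct: float
    unsexed_pct: float
    per_sex_error: float

    @property
    def empty(self) -> bool:
        return self.t_F is None


def derive_greyzone(
    scores_m, scores_f, per_sex_error: float = 0.01
) -> GreyZoneReport:
    """Empirical grey-zone thresholds for a target per-sex error rate.

    t_F is the ``per_sex_error`` quantile of male scores (males below it
    would be called female); t_M is the ``1 - per_sex_error`` quantile of
    female scores. Linear interpolation between order statistics. If the
    samples are nearly separable and t_F >= t_M the zone collapses to empty.
    """
    if not 0 < per_sex_error < 0.5:
        raise ValueError(f"per-sex error must be in (0, 0.5), got {per_sex_error}")
    sm = np.asarray(scores_m, dtype=float)
    sf = np.asarray(scores_f, dtype=float)
    sm, sf = sm[~np.isnan(sm)], sf[~np.isnan(sf)]
    if sm.size < 10 or sf.size < 10:
        raise InsufficientDataError(
            f"need >= 10 scores per sex, got M={sm.size}, F={sf.size}"
        )
    t_f = float(np.quantile(sm, per_sex_error))
    t_m = float(np.quantile(sf, 1.0 - per_sex_error))
    if t_f >= t_m:
        return GreyZoneReport(
            t_F=None, t_M=None,
            male_misclassified_pct=100.0 * float((sm < 0).mean()),
            female_misclassified_pct=100.0 * float((sf > 0).mean()),
            unsexed_pct=0.0, per_sex_error=per_sex_error,
        )
    pooled = np.concatenate([sm, sf])
    return GreyZoneReport(
        t_F=t_f, t_M=t_m,
        male_misclassified_pct=100.0 * float((sm < t_f).mean()),
        female_misclassified_pct=100.0 * float((sf > t_m).mean()),
        unsexed_pct=100.0 * float(((pooled >= t_f) & (pooled <= t_m)).mean()),
        per_sex_error=per_sex_error,
    )


def cross_validate_rules(
    rules: Sequence[SexingRule], sample: PopulationSample | pd.DataFrame
) -> pd.DataFrame:
    """Sign-rule accuracy of each equation on its complete cases.

    One row per rule: percent of males, of females, and of all complete
    cases assigned correctly (no grey zone), plus the usable n. A rule with
    zero complete cases is flagged rather than fatal.
    """
    df = sample.data if isinstance(sample, PopulationSample) else sample
    rows = []
    for rule in rules:
        try:
            d = score_sample(rule, df)
        except IncompleteRecordError:
            rows.append({
                "rule": rule.name, "n": 0, "male_pct": np.nan,
                "female_pct": np.nan, "overall_pct": np.nan, "flag": "no data",
            })
            continue
        ok = ~d.isna()
        if not ok.any():
            rows.append({
                "rule": rule.name, "n": 0, "male_pct": np.nan,
                "female_pct": np.nan, "overall_pct": np.nan,
                "flag": "no complete cases",
            })
            continue
        sexes = df.loc[ok, "sex"].to_numpy()
        calls = np.array([sex_from_score(v) for v in d[ok]])
        is_m, is_f = sexes == "M", sexes == "F"
        acc_m = 100.0 * float((calls[is_m] == "M").mean()) if is_m.any() else np.nan
        acc_f = 100.0 * float((calls[is_f] == "F").mean()) if is_f.any() else np.nan
        overall = 100.0 * float((calls == sexes).mean())
        rows.append({
            "rule": rule.name, "n": int(ok.sum()), "male_pct": acc_m,
            "female_pct": acc_f, "overall_pct": overall, "flag": "",
        })
    return pd.DataFrame(rows)
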