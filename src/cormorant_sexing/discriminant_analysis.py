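"""Two-group canonical discriminant analysis with stepwise selection.

Fits the linear discriminant function D = b'x + c for female/male groups,
with the conventions used in classical morphometric sexing studies:

* coefficients proportional to S_w^{-1} (mu_M - mu_F), scaled so the pooled
  within-group variance of scores is 1;
* male-positive orientation (D > 0 suggests a male);
* the constant centres the size-weighted mean of all case scores at 0;
* backward-stepwise variable selection on Wilks' lambda with partial-F
  thresholds (default: enter at 3.84, remove below 2.71);
* classification by squared Mahalanobis distance to each sex centroid with
  equal priors, reported as posterior probabilities.

For two groups the single canonical axis carries all between-group
structure, so Mahalanobis classification coincides with a cut at the
midpoint of the group score means.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CollinearityError,
    EmptyModelError,
    IncompleteRecordError,
    InsufficientDataError,
)
from .synthetic_data import PopulationSample

_COND_WARN = 1e8
_COND_ERROR = 1e12


@dataclass
class DiscriminantModel:
    """A fitted two-group canonical discriminant function."""

    variables: tuple[str, ...]
    coefficients: np.ndarray  # unstandardized, one per variable (per mm)
    constant: float
    std_coefficients: np.ndarray  # coefficients on within-group SD scale
    score_means: dict  # {"F": float, "M": float}
    wilks_lambda: float
    centroids: dict  # {"F": ndarray, "M": ndarray}
    pooled_cov: np.ndarray
    n: dict  # {"F": int, "M": int}
    priors: dict = field(default_factory=lambda: {"F": 0.5, "M": 0.5})

    def score(self, X) -> np.ndarray:
        """Discriminant scores D = b'x + c for rows over the model variables."""
        if isinstance(X, pd.DataFrame):
            X = X[list(self.variables)].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coefficients + self.constant

    def to_rule(self, name: str = "fitted"):
        from .sexing_rules import SexingRule

        return SexingRule(
            name=name,
            measurements=self.variables,
            coefficients=tuple(float(c) for c in self.coefficients),
            constant=float(self.constant),
            provenance=f"fitted model (n_M={self.n['M']}, n_F={self.n['F']})",
        )

    # -- plain-text serialization (bit-exact round trip via float repr) --
    def to_json(self) -> str:
        return json.dumps({
            "variables": list(self.variables),
            "coefficients": [float(c) for c in self.coefficients],
            "constant": float(self.constant),
            "std_coefficients": [float(c) for c in self.std_coefficients],
            "score_means": {k: float(v) for k, v in self.score_means.items()},
            "wilks_lambda": float(self.wilks_lambda),
            "centroids": {k: [float(x) for x in v] for k, v in self.centroids.items()},
            "pooled_cov": [[float(x) for x in row] for row in self.pooled_cov],
            "n": {k: int(v) for k, v in self.n.items()},
            "priors": {k: float(v) for k, v in self.priors.items()},
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DiscriminantModel":
        d = json.loads(text)
        return cls(
            variables=tuple(d["variables"]),
            coefficients=np.array(d["coefficients"]),
            constant=d["constant"],
            std_coefficients=np.array(d["std_coefficients"]),
            score_means=d["score_means"],
            wilks_lambda=d["wilks_lambda"],
            centroids={k: np.array(v) for k, v in d["centroids"].items()},
            pooled_cov=np.array(d["pooled_cov"]),
            n=d["n"],
            priors=d["priors"],
        )


@dataclass(frozen=True)
class ClassificationOutcome:
    """Prediction for one bird: sex, posteriors, squared Mahalanobis distances."""

    predicted: str
    posteriors: dict  # {"F": p, "M": p}, sums to 1
    d2: dict  # squared Mahalanobis distance to each sex centroid


def _as_matrix(records, variables=None):
    if isinstance(records, PopulationSample):
        records = records.data
    if isinstance(records, pd.DataFrame):
        if variables is None:
            variables = [
                c for c in records.columns if c not in ("id", "sex", "age")
            ]
        X = records[list(variables)].to_numpy(dtype=float)
    else:
        X = np.asarray(records, dtype=float)
        if variables is None:
            variables = [f"x{i}" for i in range(X.shape[1])]
    return X, tuple(variables)


def _complete_cases(X, y):
    keep = ~np.isnan(X).any(axis=1)
    return X[keep], y[keep]


def fit_lda(
    records,
    sexes: Sequence[str] | None = None,
    variables: Sequence[str] | None = None,
    priors: tuple[float, float] = (0.5, 0.5),
) -> DiscriminantModel:
    """Fit the canonical discriminant function on complete cases.

    ``records`` may be a PopulationSample, a DataFrame, or a plain matrix
    with ``sexes`` given separately ("F"/"M" labels). ``priors`` are the
    (female, male) prior probabilities used later in classification.
    """
    if isinstance(records, PopulationSample):
        sexes = records.data["sex"].to_numpy()
    elif isinstance(records, pd.DataFrame) and sexes is None:
        sexes = records["sex"].to_numpy()
    X, variables = _as_matrix(records, variables)
    y = np.asarray(sexes)
    X, y = _complete_cases(X, y)

    nf, nm = int((y == "F").sum()), int((y == "M").sum())
    if nf < 2 or nm < 2:
        raise InsufficientDataError(
            f"need >= 2 complete cases per sex, got F={nf}, M={nm}"
        )
    Xf, Xm = X[y == "F"], X[y == "M"]
    mu_f, mu_m = Xf.mean(axis=0), Xm.mean(axis=0)

    # pooled within-group covariance, df = n - 2
    Sw = ((nf - 1) * np.cov(Xf, rowvar=False, ddof=1)
          + (nm - 1) * np.cov(Xm, rowvar=False, ddof=1)) / (nf + nm - 2)
    Sw = np.atleast_2d(Sw)
    cond = np.linalg.cond(Sw)
    if cond > _COND_ERROR:
        raise CollinearityError(
            f"pooled within-group covariance is numerically singular "
            f"(condition number {cond:.2e}) over variables {variables}"
        )
    if cond > _COND_WARN:
        warnings.warn(
            f"ill-conditioned within-group covariance (cond {cond:.2e}) "
            f"over variables {variables}",
            RuntimeWarning,
            stacklevel=2,
        )

    b = np.linalg.solve(Sw, mu_m - mu_f)
    scale2 = float(b @ Sw @ b)  # pooled within-group score variance
    if scale2 <= 0:
        raise CollinearityError(f"degenerate discriminant over {variables}")
    b = b / np.sqrt(scale2)
    if b @ (mu_m - mu_f) < 0:  # male-positive orientation
        b = -b

    grand = (nm * mu_m + nf * mu_f) / (nm + nf)
    constant = -float(b @ grand)

    model = DiscriminantModel(
        variables=variables,
        coefficients=b,
        constant=constant,
        std_coefficients=b * np.sqrt(np.diag(Sw)),
        score_means={
            "F": float(b @ mu_f + constant),
            "M": float(b @ mu_m + constant),
        },
        wilks_lambda=wilks_lambda(X, y, variables=None),
        centroids={"F": mu_f, "M": mu_m},
        pooled_cov=Sw,
        n={"F": nf, "M": nm},
        priors={"F": float(priors[0]), "M": float(priors[1])},
    )
    return model


def wilks_lambda(records, sexes=None, variables=None) -> float:
    """Wilks' lambda |W|/|T| over the given variable subset's complete cases.

    W and T are the within-group and total cross-product matrices; lambda is
    1 with no separation, near 0 with strong separation.
    """
    if isinstance(records, PopulationSample):
        sexes = records.data["sex"].to_numpy()
    elif isinstance(records, pd.DataFrame) and sexes is None:
        sexes = records["sex"].to_numpy()
    X, names = _as_matrix(records, variables)
    if X.shape[1] == 0:
        raise InsufficientDataError("variable subset is empty")
    y = np.asarray(sexes)
    X, y = _complete_cases(X, y)
    if X.shape[0] < X.shape[1] + 2:
        raise InsufficientDataError(
            f"need >= p + 2 complete cases for lambda over {names}"
        )

    grand = X.mean(axis=0)
    T = (X - grand).T @ (X - grand)
    W = np.zeros_like(T)
    for g in np.unique(y):
        Xg = X[y == g]
        dg = Xg - Xg.mean(axis=0)
        W += dg.T @ dg
    sign_t, logdet_t = np.linalg.slogdet(T)
    sign_w, logdet_w = np.linalg.slogdet(W)
    if sign_t <= 0 or sign_w <= 0:
        raise CollinearityError(
            f"singular cross-product matrix over variables {names}"
        )
    return float(np.exp(logdet_w - logdet_t))


def partial_F(
    lambda_with: float,
    lambda_without: float,
    n: int,
    g: int = 2,
    p: int = 1,
) -> float:
    """Partial F for one variable's contribution to Wilks' lambda.

    ``lambda_with`` includes the variable, ``lambda_without`` excludes it,
    ``p`` counts the variables in the larger model:
    F = (lambda_without/lambda_with - 1) * (n - g - p + 1) / (g - 1).
    """
    if not (0 < lambda_with <= lambda_without * (1 + 1e-12) and lambda_without <= 1 + 1e-12):
        raise ValueError(
            f"need 0 < lambda_with <= lambda_without <= 1, "
            f"got {lambda_with}, {lambda_without}"
        )
    if n <= g + p - 1:
        raise InsufficientDataError(f"need n > g + p - 1, got n={n}, g={g}, p={p}")
    ratio = max(lambda_without / lambda_with - 1.0, 0.0)
    return ratio * (n - g - p + 1) / (g - 1)


def backward_stepwise(
    records,
    sexes=None,
    candidates: Sequence[str] | None = None,
    f_enter: float = 3.84,
    f_remove: float = 2.71,
    allow_reentry: bool = True,
    priors: tuple[float, float] = (0.5, 0.5),
    max_steps: int = 100,
):
    """Backward-stepwise selection on Wilks' lambda.

    Starts from all candidates. Each step removes the included variable with
    the smallest partial F if that F is below ``f_remove``; otherwise, when
    re-entry is allowed, brings back the excluded variable with the largest
    partial F if it reaches ``f_enter``; otherwise stops. Listwise deletion
    over the variable set under evaluation at each step. Exact F ties are
    broken toward the later-listed variable.

    Returns ``(model, trace)`` where the model is ``fit_lda`` on the final
    set and the trace lists each step's variable, direction, F and lambda.
    """
    if isinstance(records, PopulationSample):
        df = records.data
    elif isinstance(records, pd.DataFrame):
        df = records
    else:
        X, names = _as_matrix(records, candidates)
        df = pd.DataFrame(X, columns=list(names))
    if sexes is None:
        sexes = df["sex"].to_numpy()
    y = np.asarray(sexes)
    if candidates is None:
        candidates = [c for c in df.columns if c not in ("id", "sex", "age")]
    candidates = list(candidates)
    if not candidates:
        raise InsufficientDataError("no candidate variables")

    def lam(subset):
        return wilks_lambda(df[subset].to_numpy(dtype=float), y)

    def n_complete(subset):
        return int((~df[subset].isna().any(axis=1)).sum())

    current = list(candidates)
    trace: list[dict] = []
    seen = set()

    for _ in range(max_steps):
        state = frozenset(current)
        if state in seen:
            break  # cycle guard; f_enter > f_remove normally prevents this
        seen.add(state)

        # removal phase: partial F of each included variable, computed on
        # cases complete for the current (larger) set
        if len(current) >= 1:
            n = n_complete(current)
            if len(current) == 1:
                lam_with = lam(current)
                f_stats = [
                    (partial_F(lam_with, 1.0, n, p=1), current[0])
                ]
            else:
                keep = ~df[current].isna().any(axis=1)
                sub = df.loc[keep, current]
                ysub = y[keep.to_numpy()]
                lam_with = wilks_lambda(sub.to_numpy(dtype=float), ysub)
                f_stats = []
                for v in current:
                    rest = [u for u in current if u != v]
                    lam_without = wilks_lambda(
                        sub[rest].to_numpy(dtype=float), ysub
                    )
                    f_stats.append(
                        (partial_F(lam_with, lam_without, n, p=len(current)), v)
                    )
            f_min, v_min = min(
                f_stats, key=lambda t: (t[0], -current.index(t[1]))
            )
            if f_min < f_remove:
                current.remove(v_min)
                trace.append({
                    "variable": v_min, "direction": "remove",
                    "F": f_min,
                    "lambda": lam(current) if current else 1.0,
                })
                if not current:
                    raise EmptyModelError(
                        "stepwise selection removed every variable", trace
                    )
                continue

        # entry phase
        if allow_reentry:
            excluded = [v for v in candidates if v not in current]
            best = None
            for v in excluded:
                bigger = current + [v]
                keep = ~df[bigger].isna().any(axis=1)
                sub = df.loc[keep, bigger]
                ysub = y[keep.to_numpy()]
                lam_with = wilks_lambda(sub.to_numpy(dtype=float), ysub)
                lam_without = (
                    wilks_lambda(sub[current].to_numpy(dtype=float), ysub)
                    if current else 1.0
                )
                f = partial_F(lam_with, lam_without, len(sub), p=len(bigger))
                if best is None or f > best[0]:
                    best = (f, v)
            if best is not None and best[0] >= f_enter:
                current.append(best[1])
                trace.append({
                    "variable": best[1], "direction": "enter",
                    "F": best[0], "lambda": lam(current),
                })
                continue
        break

    keep = ~df[current].isna().any(axis=1)
    model = fit_lda(
        df.loc[keep, current].to_numpy(dtype=float),
        y[keep.to_numpy()],
        variables=current,
        priors=priors,
    )
    return model, trace


def classify(model: DiscriminantModel, record) -> ClassificationOutcome:
    """Classify one bird by squared Mahalanobis distance to each centroid.

    posterior_s is proportional to prior_s * exp(-d2_s / 2); the predicted
    sex maximises the posterior (with equal priors: the smaller distance).
    """
    if isinstance(record, (pd.Series, Mapping)):
        missing = [
            v for v in model.variables
            if v not in record or pd.isna(record[v])
        ]
        if missing:
            raise IncompleteRecordError(
                f"record is missing model variable(s) {missing}"
            )
        x = np.array([float(record[v]) for v in model.variables])
    else:
        x = np.asarray(record, dtype=float)
        if np.isnan(x).any():
            raise IncompleteRecordError("record contains missing values")

    d2 = {}
    for s in ("F", "M"):
        diff = x - model.centroids[s]
        d2[s] = float(diff @ np.linalg.solve(model.pooled_cov, diff))
    logp = {
        s: np.log(model.priors[s]) - d2[s] / 2.0 for s in ("F", "M")
    }
    m = max(logp.values())
    w = {s: np.exp(v - m) for s, v in logp.items()}
    z = sum(w.values())
    post = {s: float(w[s] / z) for s in ("F", "M")}
    predicted = "M" if post["M"] > post["F"] else "F"
    return ClassificationOutcome(predicted=predicted, posteriors=post, d2=d2)


def classify_sample(model: DiscriminantModel, records) -> pd.DataFrame:
    """Vectorised classification of a complete-case matrix or DataFrame.

    Returns a DataFrame with columns predicted, post_F, post_M, d2_F, d2_M.
    """
    X, _ = _as_matrix(records, model.variables)
    if np.isnan(X).any():
        raise IncompleteRecordError("records contain missing model variables")
    Sinv_diff = {
        s: np.linalg.solve(model.pooled_cov, (X - model.centroids[s]).T).T
        for s in ("F", "M")
    }
    d2 = {
        s: np.einsum("ij,ij->i", X - model.centroids[s], Sinv_diff[s])
        for s in ("F", "M")
    }
    lf = np.log(model.priors["F"]) - d2["F"] / 2
    lm = np.log(model.priors["M"]) - d2["M"] / 2
    mx = np.maximum(lf, lm)
    wf, wm = np.exp(lf - mx), np.exp(lm - mx)
    z = wf + wm
    return pd.DataFrame({
        "predicted": np.where(lm > lf, "M", "F"),
        "post_F": wf / z, "post_M": wm / z,
        "d2_F": d2["F"], "d2_M": d2["M"],
    })


def resubstitution_accuracy(model: DiscriminantModel, sample) -> dict:
    """Percent of males, females and all complete cases re-classified correctly.

    Overall is the case-weighted mean of the per-sex accuracies.
    """
    if isinstance(sample, PopulationSample):
        df = sample.data
    else:
        df = sample
    keep = ~df[list(model.variables)].isna().any(axis=1)
    df = df.loc[keep]
    sexes = df["sex"].to_numpy()
    nf, nm = int((sexes == "F").sum()), int((sexes == "M").sum())
    if nf == 0 or nm == 0:
        raise InsufficientDataError(
            f"both sexes required among complete cases (F={nf}, M={nm})"
        )
    pred = classify_sample(model, df)["predicted"].to_numpy()
    acc_m = 100.0 * (pred[sexes == "M"] == "M").mean()
    acc_f = 100.0 * (pred[sexes == "F"] == "F").mean()
    overall = (nm * acc_m + nf * acc_f) / (nm + nf)
    return {
        "male_pct": float(acc_m), "female_pct": float(acc_f),
        "overall_pct": float(overall), "n_m": nm, "n_f": nf,
    }
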