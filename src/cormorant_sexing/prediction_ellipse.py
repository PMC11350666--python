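"""Bivariate prediction ellipses and sex-overlap membership.

The 95% prediction ellipse is the region expected to contain a single new
observation from the same bivariate normal as the fitting sample:
{ x : (x - xbar)' S^{-1} (x - xbar) <= c } with
c = (2 (n-1)(n+1) / (n (n-2))) * F(level; 2, n-2), which tends to the
chi-square quantile (5.991 at 95%) as n grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import CollinearityError, InsufficientDataError

_COND_LIMIT = 1e12


@dataclass(frozen=True)
class Ellipse:
    """A bivariate prediction region."""

    center: np.ndarray  # (2,) mm
    shape: np.ndarray  # (2, 2) sample covariance, mm^2
    scale: float  # quadratic-form threshold c
    level: float
    n: int

    def mahalanobis_sq(self, points) -> np.ndarray:
        x = np.atleast_2d(np.asarray(points, dtype=float)) - self.center
        return np.einsum("ij,ij->i", x, np.linalg.solve(self.shape, x.T).T)

    def contains(self, points) -> np.ndarray:
        """Boundary counts as inside (<= scale)."""
        return self.mahalanobis_sq(points) <= self.scale


def prediction_ellipse(points, level: float = 0.95) -> Ellipse:
    """Fit the prediction ellipse for one new observation.

    ``points`` is an (n, 2) array of complete measurement pairs, n >= 4.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    x = np.asarray(points, dtype=float)
    x = x[~np.isnan(x).any(axis=1)]
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError(f"expected (n, 2) points, got shape {x.shape}")
    n = x.shape[0]
    if n < 4:
        raise InsufficientDataError(f"need >= 4 complete pairs, got {n}")
    S = np.cov(x, rowvar=False, ddof=1)
    if np.linalg.cond(S) > _COND_LIMIT:
        raise CollinearityError("degenerate (collinear) point cloud")
    c = (2.0 * (n - 1) * (n + 1) / (n * (n - 2))) * stats.f.ppf(level, 2, n - 2)
    return Ellipse(center=x.mean(axis=0), shape=S, scale=float(c),
                   level=level, n=n)


def overlap_membership(ellipse_a: Ellipse, ellipse_b: Ellipse, points) -> float:
    """Fraction of points lying inside both ellipses."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    pts = pts[~np.isnan(pts).any(axis=1)]
    if pts.shape[0] == 0:
        return 0.0
    inside = ellipse_a.contains(pts) & ellipse_b.contains(pts)
    return float(inside.mean())


def axis_lengths(ellipse: Ellipse) -> tuple[float, float]:
    """Semi-axis lengths (major, minor) of the ellipse boundary."""
    ev = np.linalg.eigvalsh(ellipse.shape)
    lengths = np.sqrt(ev * ellipse.scale)
    return float(lengths[1]), float(lengths[0])


def plot_ellipses(ellipses, points_by_label=None, path=None, xlabel="", ylabel=""):
    """Optional visual: ellipse outlines over scatter points; cosmetic only."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    theta = np.linspace(0, 2 * np.pi, 361)
    circle = np.stack([np.cos(theta), np.sin(theta)])
    styles = ["solid", "dashed", "dotted"]
    for i, (label, e) in enumerate(ellipses.items()):
        L = np.linalg.cholesky(e.shape)
        boundary = e.center[:, None] + np.sqrt(e.scale) * (L @ circle)
        ax.plot(boundary[0], boundary[1], color="black",
                linestyle=styles[i % len(styles)], label=label)
    if points_by_label:
        markers = {"M": ("o", "black"), "F": ("o", "white")}
        for label, pts in points_by_label.items():
            pts = np.asarray(pts)
            mk, col = markers.get(label, (".", "grey"))
            ax.scatter(pts[:, 0], pts[:, 1], marker=mk, facecolor=col,
                       edgecolor="black", s=12, label=label)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
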