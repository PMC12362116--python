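"""Locally estimated scatterplot smoothing (LOESS) for descriptive curves.

The smoother used here is the plain nearest-neighbour variant: at each
evaluation point the ``ceil(span * n)`` nearest observations (by |x - x0|)
receive tricube weights on distances scaled by the window's radius, a
polynomial of the requested degree is fitted by weighted least squares,
and its value at the evaluation point is the smoothed estimate.  Degree 1,
span 0.5 and zero robustness iterations are the defaults; those settings
are recorded on every curve so figures are reproducible.

Curves are evaluated on a fixed grid inside the observed x-range only (no
extrapolation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SmoothCurve",
    "InsufficientDataError",
    "loess_fit",
    "curves_by_stratum",
    "curves_to_frame",
]

log = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Too few points for the requested span/degree."""


@dataclass(frozen=True)
class SmoothCurve:
    grid_x: np.ndarray
    fitted_y: np.ndarray
    span: float
    degree: int
    stratum: str
    n_points: int


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None)
    return w**3


def loess_fit(
    x,
    y,
    span: float = 0.5,
    degree: int = 1,
    eval_x=None,
    n_eval: int = 200,
    stratum: str = "all",
) -> SmoothCurve:
    """Fit a LOESS curve to ``(x, y)``.

    ``span`` is the fraction of points in each local window (0 < span <= 1);
    the window holds ``ceil(span * n)`` nearest neighbours and must cover at
    least ``degree + 1`` points.  Ties in x are allowed.  Evaluation points
    default to ``n_eval`` equally spaced values across the data range.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    if n < degree + 2:
        raise InsufficientDataError(f"need at least {degree + 2} points, got {n}")
    q = int(np.ceil(span * n))
    if q < degree + 1:
        raise InsufficientDataError(
            f"window of {q} points cannot support a degree-{degree} fit"
        )

    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    if eval_x is None:
        eval_x = np.linspace(xs[0], xs[-1], n_eval)
    else:
        eval_x = np.asarray(eval_x, dtype=float)
        if np.any(eval_x < xs[0] - 1e-12) or np.any(eval_x > xs[-1] + 1e-12):
            raise ValueError("evaluation points outside the data range (no extrapolation)")

    fitted = np.empty_like(eval_x)
    for i, x0 in enumerate(eval_x):
        dist = np.abs(xs - x0)
        h = np.partition(dist, q - 1)[q - 1]
        if h <= 0.0:
            # window degenerate to tied x's: weighted fit collapses to their mean
            fitted[i] = ys[dist == 0.0].mean()
            continue
        w = _tricube(dist / h)
        sel = w > 0.0
        dx = xs[sel] - x0
        X = np.vander(dx, degree + 1, increasing=True)
        sw = np.sqrt(w[sel])
        coef, *_ = np.linalg.lstsq(X * sw[:, None], ys[sel] * sw, rcond=None)
        fitted[i] = coef[0]
    return SmoothCurve(eval_x, fitted, span, degree, stratum, n)


def curves_by_stratum(
    annotated: pd.DataFrame,
    stratify_by: str = "none",
    span: float = 0.5,
    degree: int = 1,
    min_points: int = 10,
    n_eval: int = 200,
    x_col: str = "ga_distance_deg",
    y_col: str = "sensitivity_db",
) -> list[SmoothCurve]:
    """One smoothed sensitivity-vs-distance curve per stratum.

    ``stratify_by`` is ``"none"`` (single pooled curve), ``"axis"`` or
    ``"visit"``.  Intralesional points are excluded.  Strata with fewer
    than ``min_points`` observations are skipped with a logged note, the
    way sparsely attended late visits are dropped from descriptive figures.
    """
    df = annotated
    if "inside_ga" in df.columns:
        df = df[~df["inside_ga"].astype(bool)]
    if stratify_by == "none":
        groups = [("all", df)]
    elif stratify_by == "axis":
        groups = [(str(a), g) for a, g in df.groupby("axis", sort=True)]
    elif stratify_by == "visit":
        groups = [(f"month_{m:g}", g) for m, g in df.groupby("visit_month", sort=True)]
    else:
        raise ValueError("stratify_by must be 'none', 'axis' or 'visit'")

    curves = []
    for label, g in groups:
        if len(g) < max(min_points, degree + 2):
            log.info("stratum %s skipped: only %d points", label, len(g))
            continue
        curves.append(
            loess_fit(
                g[x_col].to_numpy(),
                g[y_col].to_numpy(),
                span=span,
                degree=degree,
                n_eval=n_eval,
                stratum=label,
            )
        )
    return curves


def curves_to_frame(curves: list[SmoothCurve]) -> pd.DataFrame:
    """Long-format export: stratum, x_deg, fitted_db (+ settings columns)."""
    parts = [
        pd.DataFrame(
            {
                "stratum": c.stratum,
                "x_deg": c.grid_x,
                "fitted_db": c.fitted_y,
                "span": c.span,
                "degree": c.degree,
                "n_points": c.n_points,
            }
        )
        for c in curves
    ]
    if not parts:
        return pd.DataFrame(
            columns=["stratum", "x_deg", "fitted_db", "span", "degree", "n_points"]
        )
    return pd.concat(parts, ignore_index=True)
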