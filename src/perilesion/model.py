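"""Segmented (quadratic-then-linear) nonlinear mixed-effects model.

The model relates mesopic retinal sensitivity ``y`` (dB) at a test locus to
the locus's distance ``d`` (degrees) from the nearest geographic-atrophy
border and to time ``t`` (months since baseline)::

    E[y] = beta0 + beta_t * t
           + b1*(k - d) + b2*(k - d)^2      for d <  k
           + b3*(d - k)                     for d >= k

``k`` is the *knot* (change-point), estimated as a free parameter.  Both
segment terms vanish at ``d = k``, so the mean is continuous there by
construction, and the parameterization reproduces the sign convention of
the published estimates: with ``b1 < 0`` and ``b2 < 0`` sensitivity *rises*
as ``d`` increases toward the knot, at a per-degree rate of
``-b1 - 2*b2*(k - m)`` around midpoint ``m``, and rises linearly at ``b3``
beyond it.  An optional covariate ``beta_f * foveal_distance`` can be
enabled.

Clustering: observations sharing a (participant, visit) cluster share a
Gaussian random intercept ``u ~ N(0, sigma_u^2)`` on top of i.i.d. residual
noise ``N(0, sigma_e^2)``.  The within-cluster covariance is therefore
compound symmetric, ``sigma_e^2 I + sigma_u^2 J``, and the exact marginal
log-likelihood is evaluated cluster-by-cluster with the rank-one
determinant/inverse identities — no dense covariance is ever formed.

Fitting is direct maximum likelihood: a coarse profile grid over the knot
(each grid point profiling out the fixed effects by GLS and the variance
components by a 2-D quasi-Newton search), followed by local refinement of
the knot and a final joint simplex polish.  Standard errors come from the
inverse observed information (numerical Hessian) at the optimum; variance
parameters are optimized as log(sigma) and reported on the natural scale by
the delta method.  All 95% intervals are Wald, ``estimate +/- 1.96 se``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

__all__ = [
    "SegmentedModelParams",
    "FitOptions",
    "FitResult",
    "IntervalChange",
    "KnotStraddleError",
    "mean_function",
    "interval_change",
    "marginal_negloglik",
    "gls_estimates",
    "fit",
    "fit_with_foveal_covariate",
]

_LOG_2PI = math.log(2.0 * math.pi)
_Z95 = 1.96
_LOG_SIGMA_BOUNDS = (-13.8, 7.0)  # sigma in ~[1e-6, 1e3] dB


class KnotStraddleError(ValueError):
    """Closed-form interval change requested across the knot."""


@dataclass(frozen=True)
class SegmentedModelParams:
    """Parameters of the segmented mixed model.

    ``beta0`` is the mean sensitivity at the knot at ``t = 0`` (dB);
    ``beta_t`` the time slope (dB/month); ``b1``/``b2`` the before-knot
    coefficients on ``(k-d)`` and ``(k-d)^2``; ``b3`` the after-knot slope
    on ``(d-k)``; ``knot`` the change-point (degrees); ``beta_f`` an
    optional foveal-distance coefficient (dB/deg, None = term disabled);
    ``sigma_u``/``sigma_e`` the random-intercept and residual SDs (dB).
    """

    beta0: float
    beta_t: float
    b1: float
    b2: float
    b3: float
    knot: float
    beta_f: float | None = None
    sigma_u: float = 2.0
    sigma_e: float = 3.0

    def __post_init__(self) -> None:
        if self.knot <= 0:
            raise ValueError("knot must be positive")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be non-negative")
        if self.sigma_e <= 0:
            raise ValueError("sigma_e must be positive")


def mean_function(d_deg, t_months, params: SegmentedModelParams, foveal_deg=0.0):
    """Model mean sensitivity (dB) at GA distance ``d`` and time ``t``.

    Vectorized over all inputs; scalars in, scalar out.
    """
    d = np.asarray(d_deg, dtype=float)
    t = np.asarray(t_months, dtype=float)
    kd = params.knot - d
    below = d < params.knot
    seg = np.where(below, params.b1 * kd + params.b2 * kd**2, params.b3 * (d - params.knot))
    out = params.beta0 + params.beta_t * t + seg
    if params.beta_f is not None:
        out = out + params.beta_f * np.asarray(foveal_deg, dtype=float)
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class IntervalChange:
    """Change in mean sensitivity over a distance interval, with Wald CI."""

    estimate: float
    midpoint_deg: float
    width_deg: float
    segment: str  # "below" or "above" the knot
    se: float | None = None
    ci95: tuple[float, float] | None = None


def interval_change(
    params: SegmentedModelParams,
    midpoint_deg: float,
    width: float = 1.0,
    vcov: np.ndarray | None = None,
    param_names: Sequence[str] | None = None,
) -> IntervalChange:
    """Closed-form sensitivity change over ``[m - w/2, m + w/2]``.

    Below the knot the change is ``w * (-b1 - 2*b2*(k - m))``; above it,
    ``w * b3``.  If the interval straddles the knot a
    :class:`KnotStraddleError` is raised — compute the change by
    differencing :func:`mean_function` directly in that case.

    When ``vcov`` (and the matching ``param_names``) from a fit are given,
    a delta-method standard error and Wald 95% CI are attached, using the
    analytic gradient (below knot, w.r.t. ``(b1, b2, knot)``:
    ``(-w, -2w(k-m), -2w*b2)``; above knot, w.r.t. ``b3``: ``w``).
    """
    if width <= 0:
        raise ValueError("width must be positive")
    lo = midpoint_deg - width / 2.0
    hi = midpoint_deg + width / 2.0
    if lo < 0:
        raise ValueError("interval extends below zero distance")
    k = params.knot
    grad: dict[str, float] = {}
    if hi <= k:
        est = width * (-params.b1 - 2.0 * params.b2 * (k - midpoint_deg))
        grad = {
            "b1": -width,
            "b2": -2.0 * width * (k - midpoint_deg),
            "knot": -2.0 * width * params.b2,
        }
        segment = "below"
    elif lo >= k:
        est = width * params.b3
        grad = {"b3": width}
        segment = "above"
    else:
        raise KnotStraddleError(
            f"interval [{lo}, {hi}] straddles the knot at {k}; "
            "difference mean_function directly instead"
        )
    se = ci = None
    if vcov is not None:
        if param_names is None:
            raise ValueError("param_names required alongside vcov")
        g = np.zeros(len(param_names))
        for name, val in grad.items():
            g[list(param_names).index(name)] = val
        var = float(g @ np.asarray(vcov) @ g)
        se = math.sqrt(max(var, 0.0))
        ci = (est - _Z95 * se, est + _Z95 * se)
    return IntervalChange(est, midpoint_deg, width, segment, se, ci)


# ---------------------------------------------------------------------------
# Marginal likelihood core


class _MarginalCore:
    """Pre-indexed data for fast compound-symmetry likelihood evaluation.

    Arrays are sorted by cluster so per-cluster sums reduce to
    ``np.add.reduceat`` calls.
    """

    def __init__(self, y, d, t, cluster_codes, foveal=None):
        codes = np.asarray(cluster_codes)
        order = np.argsort(codes, kind="stable")
        self.y = np.asarray(y, dtype=float)[order]
        self.d = np.asarray(d, dtype=float)[order]
        self.t = np.asarray(t, dtype=float)[order]
        self.foveal = None if foveal is None else np.asarray(foveal, dtype=float)[order]
        codes = codes[order]
        self.starts = np.flatnonzero(np.r_[True, codes[1:] != codes[:-1]])
        self.n_c = np.diff(np.r_[self.starts, codes.size])
        self.n_obs = int(codes.size)
        self.n_clusters = int(self.starts.size)
        self.n_beta = 5 + (0 if self.foveal is None else 1)

    def design(self, k: float) -> np.ndarray:
        kd = k - self.d
        below = self.d < k
        cols = [
            np.ones_like(self.d),
            self.t,
            np.where(below, kd, 0.0),
            np.where(below, kd**2, 0.0),
            np.where(below, 0.0, -kd),
        ]
        if self.foveal is not None:
            cols.append(self.foveal)
        return np.column_stack(cols)

    def _nll_resid(self, r: np.ndarray, su2: float, se2: float) -> float:
        s1 = np.add.reduceat(r, self.starts)
        s2 = np.add.reduceat(r * r, self.starts)
        den = se2 + self.n_c * su2
        logdet = (self.n_obs - self.n_clusters) * math.log(se2) + np.log(den).sum()
        quad = s2.sum() / se2 - su2 * np.sum(s1 * s1 / (se2 * den))
        return 0.5 * (self.n_obs * _LOG_2PI + logdet + quad)

    def nll(self, beta: np.ndarray, k: float, su2: float, se2: float) -> float:
        r = self.y - self.design(k) @ beta
        return self._nll_resid(r, su2, se2)

    def gls(self, k: float, su2: float, se2: float) -> np.ndarray:
        """Generalized-least-squares fixed effects for fixed knot/variances."""
        X = self.design(k)
        Xs = np.add.reduceat(X, self.starts, axis=0)
        ys = np.add.reduceat(self.y, self.starts)
        c = su2 / (se2 * (se2 + self.n_c * su2))
        A = X.T @ X / se2 - (Xs * c[:, None]).T @ Xs
        b = X.T @ self.y / se2 - Xs.T @ (c * ys)
        try:
            return np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            # a knot candidate outside the observed distance range zeroes a
            # segment's columns; fall back to the minimum-norm solution
            return np.linalg.lstsq(A, b, rcond=None)[0]

    def profile_nll(self, k: float, log_su: float, log_se: float):
        su2 = math.exp(2.0 * log_su)
        se2 = math.exp(2.0 * log_se)
        beta = self.gls(k, su2, se2)
        return self.nll(beta, k, su2, se2), beta

    def nll_theta(self, theta: np.ndarray, knot_bounds: tuple[float, float]) -> float:
        """Full objective over (betas..., knot, log_su, log_se), with box penalty."""
        if not np.all(np.isfinite(theta)):
            return np.inf
        k = theta[self.n_beta]
        lsu, lse = theta[self.n_beta + 1], theta[self.n_beta + 2]
        lo, hi = _LOG_SIGMA_BOUNDS
        if not (knot_bounds[0] <= k <= knot_bounds[1] and lo <= lsu <= hi and lo <= lse <= hi):
            return np.inf
        return self.nll(theta[: self.n_beta], k, math.exp(2 * lsu), math.exp(2 * lse))


def _prepare(annotated: pd.DataFrame, options: "FitOptions"):
    df = annotated
    if options.exclude_intralesional and "inside_ga" in df.columns:
        df = df[~df["inside_ga"].astype(bool)]
    if df.empty:
        raise ValueError("no observations left after filtering")
    required = ["sensitivity_db", "ga_distance_deg", "visit_month", "participant_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"annotated table missing columns: {missing}")
    keys = list(zip(df["participant_id"], df["visit_month"]))
    codes = pd.factorize(pd.Series(keys))[0]
    foveal = None
    if options.include_foveal:
        if "foveal_distance_deg" not in df.columns:
            raise ValueError("foveal covariate requested but foveal_distance_deg absent")
        foveal = df["foveal_distance_deg"].to_numpy(float)
    core = _MarginalCore(
        df["sensitivity_db"].to_numpy(float),
        df["ga_distance_deg"].to_numpy(float),
        df["visit_month"].to_numpy(float),
        codes,
        foveal,
    )
    return core


def marginal_negloglik(
    params: SegmentedModelParams,
    annotated: pd.DataFrame,
    exclude_intralesional: bool = True,
) -> float:
    """Exact Gaussian marginal negative log-likelihood of ``params``.

    Clusters are (participant_id, visit_month); within-cluster covariance
    is ``sigma_e^2 I + sigma_u^2 J``.  Non-finite parameters yield ``inf``.
    """
    vals = [params.beta0, params.beta_t, params.b1, params.b2, params.b3,
            params.knot, params.sigma_u, params.sigma_e]
    if params.beta_f is not None:
        vals.append(params.beta_f)
    if not all(math.isfinite(v) for v in vals):
        return float("inf")
    options = FitOptions(
        include_foveal=params.beta_f is not None,
        exclude_intralesional=exclude_intralesional,
    )
    core = _prepare(annotated, options)
    beta = [params.beta0, params.beta_t, params.b1, params.b2, params.b3]
    if params.beta_f is not None:
        beta.append(params.beta_f)
    return core.nll(np.asarray(beta), params.knot, params.sigma_u**2, params.sigma_e**2)


def gls_estimates(
    annotated: pd.DataFrame,
    knot: float,
    sigma_u: float,
    sigma_e: float,
    include_foveal: bool = False,
    exclude_intralesional: bool = True,
) -> np.ndarray:
    """Profiled fixed effects at a fixed knot and variance components.

    Returns ``(beta0, beta_t, b1, b2, b3[, beta_f])`` — the exact GLS
    solution under the compound-symmetry covariance.
    """
    core = _prepare(
        annotated,
        FitOptions(include_foveal=include_foveal, exclude_intralesional=exclude_intralesional),
    )
    return core.gls(knot, sigma_u**2, sigma_e**2)


# ---------------------------------------------------------------------------
# Fitting


@dataclass(frozen=True)
class FitOptions:
    """Knobs for :func:`fit`.

    The knot is searched on ``[knot_min, knot_max]`` with a coarse profile
    grid of step ``knot_step`` followed by local refinement; coarser steps
    are useful in replicate simulation studies.
    """

    include_foveal: bool = False
    exclude_intralesional: bool = True
    knot_min: float = 0.25
    knot_max: float = 8.0
    knot_step: float = 0.25
    refine: bool = True
    polish_maxiter: int = 4000


@dataclass
class FitResult:
    """Maximum-likelihood fit of the segmented mixed model."""

    params: SegmentedModelParams
    param_names: list[str]
    theta: np.ndarray  # internal scale: betas, knot, log sigmas
    se: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    vcov: np.ndarray  # covariance of theta (internal scale)
    loglik: float
    n_obs: int
    n_clusters: int
    converged: bool
    message: str
    knot_profile: pd.DataFrame | None = None

    def interval_change(self, midpoint_deg: float, width: float = 1.0) -> IntervalChange:
        return interval_change(self.params, midpoint_deg, width, self.vcov, self.param_names)

    def predict(self, d_deg, t_months, foveal_deg=0.0):
        return mean_function(d_deg, t_months, self.params, foveal_deg)

    def to_frame(self) -> pd.DataFrame:
        """Fit report: one row per reported parameter (sigmas natural-scale)."""
        rows = []
        for name in self.param_names:
            if name.startswith("log_"):
                continue
            est = getattr(self.params, name)
            rows.append((name, est, self.se.get(name), *self.ci95.get(name, (None, None))))
        for name in ("sigma_u", "sigma_e"):
            rows.append(
                (name, getattr(self.params, name), self.se.get(name), *self.ci95.get(name, (None, None)))
            )
        frame = pd.DataFrame(rows, columns=["parameter", "estimate", "se", "ci95_low", "ci95_high"])
        frame.attrs["loglik"] = self.loglik
        return frame


def _numerical_hessian(f, x0: np.ndarray, rel_step: float = 1e-4, steps=None) -> np.ndarray:
    """Central-difference Hessian; symmetric by construction.

    ``steps`` overrides the per-coordinate step.  The objective is only
    piecewise smooth in the knot (a kink wherever the knot crosses an
    observed distance), so the knot coordinate needs a step wide enough to
    average over those kinks and recover the envelope curvature.
    """
    n = x0.size
    h = rel_step * np.maximum(1.0, np.abs(x0))
    if steps is not None:
        for i, s in steps.items():
            h[i] = s
    H = np.empty((n, n))
    f0 = f(x0)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        fpp = f(x0 + 2 * ei)
        fmm = f(x0 - 2 * ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / (4 * h[i] ** 2)
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            fpj = f(x0 + ei + ej)
            fmj = f(x0 - ei - ej)
            fpi_mj = f(x0 + ei - ej)
            fmi_pj = f(x0 - ei + ej)
            H[i, j] = H[j, i] = (fpj + fmj - fpi_mj - fmi_pj) / (4 * h[i] * h[j])
    return H


def fit(annotated: pd.DataFrame, options: FitOptions | None = None) -> FitResult:
    """Fit the segmented mixed model by exact marginal maximum likelihood.

    Requires at least 2 clusters and distances on both sides of the knot
    search range.  Non-convergence is reported through
    ``FitResult.converged`` / ``message`` rather than raised.
    """
    options = options or FitOptions()
    core = _prepare(annotated, options)
    if core.n_clusters < 2:
        raise ValueError("need at least 2 (participant, visit) clusters")
    if core.d.max() <= options.knot_min or core.d.min() >= options.knot_max:
        raise ValueError("distances do not span the knot search range")

    # Initialise variances from OLS residuals at a mid-range knot.
    k_mid = 0.5 * (options.knot_min + min(options.knot_max, core.d.max()))
    X0 = core.design(k_mid)
    beta0, *_ = np.linalg.lstsq(X0, core.y, rcond=None)
    resid = core.y - X0 @ beta0
    s2 = max(float(np.var(resid)), 1e-18)
    v = np.array([0.5 * math.log(s2 / 2.0 + 1e-300)] * 2)
    v = np.clip(v, *_LOG_SIGMA_BOUNDS)

    def inner(k: float, v_start: np.ndarray):
        res = minimize(
            lambda vv: core.profile_nll(k, vv[0], vv[1])[0],
            v_start,
            method="L-BFGS-B",
            bounds=[_LOG_SIGMA_BOUNDS] * 2,
            options={"maxfun": 200},
        )
        return res.fun, res.x

    # Stage 1: coarse profile grid over the knot.
    ks = np.arange(options.knot_min, options.knot_max + 1e-9, options.knot_step)
    ks = ks[ks <= min(options.knot_max, core.d.max())]
    profile = []
    best = (np.inf, None, None)
    for k in ks:
        nll_k, v = inner(float(k), v)
        profile.append((float(k), nll_k))
        if nll_k < best[0]:
            best = (nll_k, float(k), v.copy())
    nll_best, k_best, v_best = best
    profile_df = pd.DataFrame(profile, columns=["knot", "negloglik"])

    # Stage 2: refine the knot locally (inner profiling at each candidate).
    if options.refine:
        lo = max(options.knot_min, k_best - options.knot_step)
        hi = min(ks[-1], k_best + options.knot_step)
        res_k = minimize_scalar(
            lambda k: inner(float(k), v_best)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-4, "maxiter": 60},
        )
        if res_k.fun < nll_best:
            nll_best, k_best = float(res_k.fun), float(res_k.x)
            _, v_best = inner(k_best, v_best)

    su2 = math.exp(2 * v_best[0])
    se2 = math.exp(2 * v_best[1])
    beta_best = core.gls(k_best, su2, se2)
    theta0 = np.r_[beta_best, k_best, v_best]
    knot_bounds = (options.knot_min, options.knot_max)

    # Stage 3: joint simplex polish over every parameter at once.
    obj = lambda th: core.nll_theta(th, knot_bounds)
    res = minimize(
        obj,
        theta0,
        method="Nelder-Mead",
        options={"maxiter": options.polish_maxiter, "xatol": 1e-7, "fatol": 1e-9, "adaptive": True},
    )
    if res.fun <= nll_best + 1e-12:
        theta = res.x
        nll_final = float(res.fun)
        message = str(res.message)
        polished = bool(res.success)
    else:  # simplex failed to improve; keep the profiled solution
        theta = theta0
        nll_final = nll_best
        message = "profile solution retained (simplex polish did not improve)"
        polished = True

    names = ["beta0", "beta_t", "b1", "b2", "b3"]
    if options.include_foveal:
        names.append("beta_f")
    names += ["knot", "log_sigma_u", "log_sigma_e"]

    k_hat = float(theta[core.n_beta])
    boundary = k_hat <= options.knot_min + 1e-6 or k_hat >= options.knot_max - 1e-6
    if boundary:
        warnings.warn("knot estimate at the search boundary; widen the knot range", stacklevel=2)

    def obj_smooth(th):  # no box penalty: finite wherever sigmas are positive
        return core.nll(
            th[: core.n_beta],
            float(th[core.n_beta]),
            math.exp(2 * th[core.n_beta + 1]),
            math.exp(2 * th[core.n_beta + 2]),
        )

    H = _numerical_hessian(obj_smooth, theta, steps={core.n_beta: 0.05})
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(H)
    vcov = 0.5 * (vcov + vcov.T)
    diag = np.diag(vcov)
    se_ok = np.all(np.isfinite(diag)) and np.all(diag > -1e-8)
    se_theta = np.sqrt(np.clip(diag, 0.0, None))

    sigma_u = math.exp(theta[core.n_beta + 1])
    sigma_e = math.exp(theta[core.n_beta + 2])
    se: dict[str, float] = {}
    ci95: dict[str, tuple[float, float]] = {}
    for i, name in enumerate(names):
        if name == "log_sigma_u":
            nat, nat_name = sigma_u, "sigma_u"
        elif name == "log_sigma_e":
            nat, nat_name = sigma_e, "sigma_e"
        else:
            nat, nat_name = float(theta[i]), name
        s = float(se_theta[i])
        if name.startswith("log_"):
            s = nat * s  # delta method to the natural scale
        se[nat_name] = s
        ci95[nat_name] = (nat - _Z95 * s, nat + _Z95 * s)

    bidx = dict(zip(names, range(len(names))))
    params = SegmentedModelParams(
        beta0=float(theta[bidx["beta0"]]),
        beta_t=float(theta[bidx["beta_t"]]),
        b1=float(theta[bidx["b1"]]),
        b2=float(theta[bidx["b2"]]),
        b3=float(theta[bidx["b3"]]),
        knot=k_hat,
        beta_f=float(theta[bidx["beta_f"]]) if options.include_foveal else None,
        sigma_u=sigma_u,
        sigma_e=max(sigma_e, 1e-300),
    )
    converged = bool(polished and not boundary and se_ok and math.isfinite(nll_final))
    return FitResult(
        params=params,
        param_names=names,
        theta=theta,
        se=se,
        ci95=ci95,
        vcov=vcov,
        loglik=-nll_final,
        n_obs=core.n_obs,
        n_clusters=core.n_clusters,
        converged=converged,
        message=message,
        knot_profile=profile_df,
    )


def fit_with_foveal_covariate(
    annotated: pd.DataFrame, options: FitOptions | None = None
) -> FitResult:
    """:func:`fit` with the foveal-distance covariate enabled."""
    options = options or FitOptions()
    return fit(annotated, replace(options, include_foveal=True))
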