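"""Segmented mixed model: mean structure, likelihood, contrasts, fitting."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import multivariate_normal, norm

from perilesion.model import (
    FitOptions,
    KnotStraddleError,
    SegmentedModelParams,
    fit,
    fit_with_foveal_covariate,
    gls_estimates,
    interval_change,
    marginal_negloglik,
    mean_function,
)


def direct_dataset(
    rng,
    params,
    n_participants=8,
    months=(0.0, 6.0, 12.0),
    n_loci=25,
    sigma_u=2.0,
    sigma_e=3.0,
    d_max=10.0,
    with_foveal=False,
):
    """Data drawn straight from the model (no lesion rasters involved)."""
    rows = []
    for p in range(n_participants):
        for m in months:
            u = rng.normal(0, sigma_u)
            d = rng.uniform(0.05, d_max, n_loci)
            fov = rng.uniform(0, 15, n_loci)
            mu = mean_function(d, m, params, fov if with_foveal else 0.0)
            y = mu + u + rng.normal(0, sigma_e, n_loci)
            for i in range(n_loci):
                rows.append((f"P{p}", m, d[i], fov[i], y[i]))
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "visit_month",
            "ga_distance_deg",
            "foveal_distance_deg",
            "sensitivity_db",
        ],
    )


def dense_negloglik(params, df):
    """Oracle: explicit per-cluster multivariate-normal log-density."""
    total = 0.0
    for _, g in df.groupby(["participant_id", "visit_month"]):
        mu = mean_function(
            g["ga_distance_deg"].to_numpy(),
            g["visit_month"].to_numpy(),
            params,
            g.get("foveal_distance_deg", pd.Series(np.zeros(len(g)))).to_numpy(),
        )
        n = len(g)
        cov = params.sigma_e**2 * np.eye(n) + params.sigma_u**2 * np.ones((n, n))
        total -= multivariate_normal.logpdf(g["sensitivity_db"].to_numpy(), mean=mu, cov=cov)
    return total


class TestMeanFunction:
    def test_continuous_at_knot(self, published_params):
        p = published_params
        at = mean_function(p.knot, 5.0, p)
        just_below = mean_function(p.knot - 1e-8, 5.0, p)
        assert at == pytest.approx(p.beta0 + p.beta_t * 5.0, abs=1e-12)
        assert just_below == pytest.approx(at, abs=1e-6)

    @given(
        b1=st.floats(-5, 5),
        b2=st.floats(-2, 2),
        b3=st.floats(-2, 2),
        knot=st.floats(0.5, 6.0),
    )
    def test_continuity_for_any_parameters(self, b1, b2, b3, knot):
        p = SegmentedModelParams(beta0=5.0, beta_t=0.0, b1=b1, b2=b2, b3=b3, knot=knot)
        assert mean_function(knot - 1e-9, 0.0, p) == pytest.approx(
            mean_function(knot, 0.0, p), abs=1e-7
        )

    def test_published_worked_examples(self, published_params):
        p = published_params
        assert mean_function(1.0, 3.0, p) - mean_function(0.0, 3.0, p) == pytest.approx(
            2.96, abs=0.01
        )
        assert mean_function(3.05, 0.0, p) - mean_function(2.05, 0.0, p) == pytest.approx(
            0.56, abs=1e-12
        )

    def test_strictly_increasing_in_distance(self, published_params):
        d = np.linspace(0, 10, 400)
        y = mean_function(d, 0.0, published_params)
        assert np.all(np.diff(y) > 0)

    def test_foveal_covariate_term(self, published_params):
        p = dataclasses.replace(published_params, beta_f=-0.3)
        base = mean_function(3.0, 0.0, p, 0.0)
        assert mean_function(3.0, 0.0, p, 2.0) == pytest.approx(base - 0.6)


class TestIntervalChange:
    @pytest.mark.parametrize(
        "midpoint,expected",
        [(0.5, 2.96), (1.0, 2.50), (1.5, 2.04)],
    )
    def test_published_interval_changes(self, published_params, midpoint, expected):
        assert interval_change(published_params, midpoint).estimate == pytest.approx(
            expected, abs=0.01
        )

    def test_above_knot_change_is_slope(self, published_params):
        ic = interval_change(published_params, 4.0)
        assert ic.estimate == pytest.approx(0.56, abs=1e-12)
        assert ic.segment == "above"

    def test_no_quadratic_term_gives_constant_change(self, published_params):
        p = dataclasses.replace(published_params, b2=0.0)
        for m in (0.5, 1.0, 1.5):
            assert interval_change(p, m).estimate == pytest.approx(-p.b1)

    def test_straddling_interval_rejected(self, published_params):
        with pytest.raises(KnotStraddleError):
            interval_change(published_params, published_params.knot)

    def test_closed_form_agrees_with_mean_differencing(self, published_params):
        p = published_params
        for m in (0.6, 1.2, 4.0, 6.5):
            direct = mean_function(m + 0.5, 0.0, p) - mean_function(m - 0.5, 0.0, p)
            assert interval_change(p, m).estimate == pytest.approx(direct, abs=1e-12)

    @pytest.mark.parametrize("pname", ["b1", "b2", "knot"])
    def test_delta_gradient_matches_numerical(self, published_params, pname):
        # extract the analytic gradient via a basis vcov, compare to a
        # central difference of the estimate in that parameter
        names = ["beta0", "beta_t", "b1", "b2", "b3", "knot"]
        idx = names.index(pname)
        vcov = np.zeros((6, 6))
        vcov[idx, idx] = 1.0
        ic = interval_change(published_params, 1.0, vcov=vcov, param_names=names)
        h = 1e-6
        up = dataclasses.replace(published_params, **{pname: getattr(published_params, pname) + h})
        dn = dataclasses.replace(published_params, **{pname: getattr(published_params, pname) - h})
        numeric = (interval_change(up, 1.0).estimate - interval_change(dn, 1.0).estimate) / (2 * h)
        assert ic.se == pytest.approx(abs(numeric), rel=1e-5)


class TestMarginalLikelihood:
    def test_matches_dense_oracle(self, rng, published_params):
        for trial in range(5):
            df = direct_dataset(
                rng, published_params, n_participants=3, months=(0.0, 6.0), n_loci=int(rng.integers(2, 6))
            )
            p = dataclasses.replace(
                published_params,
                sigma_u=float(rng.uniform(0.3, 3.0)),
                sigma_e=float(rng.uniform(0.5, 4.0)),
            )
            assert marginal_negloglik(p, df) == pytest.approx(dense_negloglik(p, df), abs=1e-8)

    def test_sigma_u_zero_reduces_to_independence(self, rng, published_params):
        df = direct_dataset(rng, published_params, n_participants=2, n_loci=4)
        p = dataclasses.replace(published_params, sigma_u=0.0, sigma_e=2.2)
        mu = mean_function(
            df["ga_distance_deg"].to_numpy(), df["visit_month"].to_numpy(), p
        )
        iid = -norm.logpdf(df["sensitivity_db"].to_numpy(), loc=mu, scale=2.2).sum()
        assert marginal_negloglik(p, df) == pytest.approx(iid, abs=1e-10)

    def test_non_finite_parameters_rejected(self, rng, published_params):
        df = direct_dataset(rng, published_params, n_participants=2, n_loci=3)
        p = dataclasses.replace(published_params, b1=float("nan"))
        assert marginal_negloglik(p, df) == np.inf

    def test_profiled_gls_matches_dense_oracle(self, rng, published_params):
        df = direct_dataset(rng, published_params, n_participants=4, n_loci=6)
        knot, su, se = 2.0, 1.5, 2.5
        beta = gls_estimates(df, knot, su, se)
        # dense GLS: (X' S^-1 X)^-1 X' S^-1 y with the explicit block covariance
        X_parts, y_parts, blocks = [], [], []
        for _, g in df.groupby(["participant_id", "visit_month"]):
            d = g["ga_distance_deg"].to_numpy()
            t = g["visit_month"].to_numpy()
            kd = knot - d
            below = d < knot
            X_parts.append(
                np.column_stack(
                    [
                        np.ones_like(d),
                        t,
                        np.where(below, kd, 0.0),
                        np.where(below, kd**2, 0.0),
                        np.where(below, 0.0, d - knot),
                    ]
                )
            )
            y_parts.append(g["sensitivity_db"].to_numpy())
            n = len(g)
            blocks.append(se**2 * np.eye(n) + su**2 * np.ones((n, n)))
        X = np.vstack(X_parts)
        y = np.concatenate(y_parts)
        from scipy.linalg import block_diag

        S = block_diag(*blocks)
        Sinv = np.linalg.inv(S)
        expected = np.linalg.solve(X.T @ Sinv @ X, X.T @ Sinv @ y)
        assert np.allclose(beta, expected, atol=1e-6)


class TestFit:
    def test_noise_free_data_recovered_exactly(self, rng, published_params):
        df = direct_dataset(
            rng,
            published_params,
            n_participants=6,
            months=(0.0, 6.0, 12.0),
            n_loci=30,
            sigma_u=0.0,
            sigma_e=1e-6,
        )
        result = fit(df, FitOptions(knot_step=0.25))
        for name in ("beta0", "beta_t", "b1", "b2", "b3", "knot"):
            assert getattr(result.params, name) == pytest.approx(
                getattr(published_params, name), abs=1e-2
            ), name

    def test_perturbing_sigma_e_around_optimum_lowers_loglik(self, rng, published_params):
        df = direct_dataset(
            rng, published_params, n_participants=6, n_loci=20, sigma_u=1.0, sigma_e=1.5
        )
        result = fit(df, FitOptions(knot_step=0.5))
        doubled = dataclasses.replace(result.params, sigma_e=2 * result.params.sigma_e)
        halved = dataclasses.replace(result.params, sigma_e=result.params.sigma_e / 2)
        assert marginal_negloglik(doubled, df) > -result.loglik
        assert marginal_negloglik(halved, df) > -result.loglik

    def test_wald_intervals_consistent_with_se(self, rng, published_params):
        df = direct_dataset(
            rng, published_params, n_participants=6, n_loci=20, sigma_u=1.0, sigma_e=1.5
        )
        result = fit(df, FitOptions(knot_step=0.5))
        for name, (lo, hi) in result.ci95.items():
            centre = 0.5 * (lo + hi)
            assert hi - lo == pytest.approx(2 * 1.96 * result.se[name], rel=1e-6)
            assert centre == pytest.approx(
                getattr(result.params, name), rel=1e-6, abs=1e-9
            )
        assert np.allclose(result.vcov, result.vcov.T)

    def test_too_few_clusters_rejected(self, rng, published_params):
        df = direct_dataset(rng, published_params, n_participants=1, months=(0.0,))
        with pytest.raises(ValueError):
            fit(df)

    def test_report_frame_mirrors_model_rows(self, rng, published_params):
        df = direct_dataset(rng, published_params, n_participants=4, n_loci=10)
        result = fit(df, FitOptions(knot_step=1.0))
        frame = result.to_frame()
        assert list(frame["parameter"]) == [
            "beta0", "beta_t", "b1", "b2", "b3", "knot", "sigma_u", "sigma_e",
        ]
        assert frame.attrs["loglik"] == result.loglik


class TestFovealCovariate:
    """Scaled-down replicate studies of the supplementary covariate fit."""

    N_NULL_REPS = 16
    N_EFFECT_REPS = 10

    @pytest.fixture(scope="class")
    def null_fits(self):
        params = SegmentedModelParams(
            beta0=9.0, beta_t=-0.07, b1=-1.53, b2=-0.46, b3=0.56, knot=2.05
        )
        rng = np.random.default_rng(77)
        fits = []
        for _ in range(self.N_NULL_REPS):
            df = direct_dataset(rng, params, n_participants=8, n_loci=25, with_foveal=True)
            both = (
                fit_with_foveal_covariate(df, FitOptions(knot_step=0.5)),
                fit(df, FitOptions(knot_step=0.5)),
            )
            fits.append(both)
        return fits

    def test_null_foveal_effect_within_two_se(self, null_fits):
        covered = sum(
            abs(with_f.params.beta_f) < 2 * with_f.se["beta_f"] for with_f, _ in null_fits
        )
        assert covered >= int(0.75 * len(null_fits))

    def test_adding_null_covariate_barely_moves_other_estimates(self, null_fits):
        for name in ("beta0", "b2", "b3"):
            deltas = [
                abs(getattr(w.params, name) - getattr(wo.params, name))
                for w, wo in null_fits
            ]
            assert np.mean(deltas) < 0.2, name
        assert np.mean(
            [abs(w.params.beta_t - wo.params.beta_t) for w, wo in null_fits]
        ) < 0.02

    def test_nonzero_foveal_effect_recovered(self):
        truth = SegmentedModelParams(
            beta0=9.0, beta_t=-0.07, b1=-1.53, b2=-0.46, b3=0.56, knot=2.05, beta_f=-0.3
        )
        rng = np.random.default_rng(88)
        estimates = []
        for _ in range(self.N_EFFECT_REPS):
            df = direct_dataset(rng, truth, n_participants=8, n_loci=25, with_foveal=True)
            res = fit_with_foveal_covariate(df, FitOptions(knot_step=0.5))
            estimates.append(res.params.beta_f)
        bias = np.mean(estimates) - (-0.3)
        mc_se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(bias) <= 3 * mc_se
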