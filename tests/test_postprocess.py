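"""Standardization, R-squared, credible intervals, schema correlations."""

import numpy as np
import pytest

from esmvar import (
    DsemSpec,
    Posterior,
    between_correlations,
    credible_intervals,
    effect_table,
    standardize_within,
    stationary_cov,
    within_r2,
)
from conftest import TEST_SAMPLER


def lyapunov_fixed_point(phi, sigma, tol=1e-14, max_iter=100_000):
    """Independent oracle: V <- Sigma + Phi V Phi' iterated to convergence."""
    v = np.array(sigma, float)
    for _ in range(max_iter):
        nxt = sigma + phi @ v @ phi.T
        if np.abs(nxt - v).max() < tol:
            return nxt
        v = nxt
    raise RuntimeError("fixed point did not converge")


def make_posterior(phi_draws, sigma_draws, mu_draws=None, gamma_draws=None,
                   omega_draws=None, variables=("social_anxiety", "paranoia"),
                   var_h=1.0):
    """Posterior with one person whose effects equal the fixed effects."""
    k = len(variables)
    phi_draws = np.asarray(phi_draws)        # (D, K, K)
    nd = len(phi_draws)
    sigma_draws = np.asarray(sigma_draws)
    mu = (np.asarray(mu_draws) if mu_draws is not None
          else np.full((nd, k), 2.0))
    gamma = (np.asarray(gamma_draws) if gamma_draws is not None
             else np.zeros((nd, k)))
    eta = np.concatenate([mu, phi_draws.reshape(nd, k * k)], axis=1)[:, None, :]
    draws = {
        "mu_bar": mu[None], "phi_bar": phi_draws[None],
        "gamma": gamma[None], "sigma_w": sigma_draws[None],
        "eta": eta[None],
    }
    if omega_draws is not None:
        draws["omega"] = np.asarray(omega_draws)[None]
    spec = DsemSpec(variables=variables, sampler=TEST_SAMPLER)
    return Posterior(draws=draws, spec=spec, person_ids=np.array([0]),
                     var_h=var_h)


class TestStationaryCov:
    def test_matches_fixed_point_oracle(self):
        phi = np.array([[0.5, 0.2], [0.3, 0.4]])
        v = stationary_cov(phi, np.eye(2))
        assert np.allclose(v, lyapunov_fixed_point(phi, np.eye(2)), atol=1e-10)

    def test_ar1_closed_form(self):
        v = stationary_cov(np.array([[0.5]]), np.array([[0.75]]))
        assert v[0, 0] == pytest.approx(1.0)

    def test_nonstationary_rejected(self):
        with pytest.raises(ValueError, match="stationary"):
            stationary_cov(np.array([[1.01]]), np.array([[1.0]]))


class TestStandardize:
    def test_zero_dynamics_standardize_to_zero(self):
        nd = 120
        post = make_posterior(np.zeros((nd, 2, 2)),
                              np.tile(np.eye(2), (nd, 1, 1)))
        table = standardize_within(post)
        for name in ("phi_SA->SA", "phi_PAR->SA", "phi_SA->PAR", "phi_PAR->PAR"):
            assert table.row(name)["estimate"] == 0.0

    def test_univariate_standardized_equals_raw(self):
        nd = 120
        phis = np.full((nd, 1, 1), 0.6)
        post = make_posterior(phis, np.full((nd, 1, 1), 0.5),
                              variables=("social_anxiety",))
        table = standardize_within(post)
        assert table.row("phi_SA->SA")["estimate"] == pytest.approx(0.6)

    def test_bivariate_matches_lyapunov_oracle(self):
        phi = np.array([[0.5, 0.2], [0.3, 0.4]])
        sw = np.eye(2)
        nd = 120
        post = make_posterior(np.tile(phi, (nd, 1, 1)),
                              np.tile(sw, (nd, 1, 1)))
        table = standardize_within(post)
        sd = np.sqrt(np.diag(lyapunov_fixed_point(phi, sw)))
        expected = phi * (sd[None, :] / sd[:, None])
        for a, out in enumerate(("SA", "PAR")):
            for b, pred in enumerate(("SA", "PAR")):
                got = table.row(f"phi_{pred}->{out}")["estimate"]
                assert got == pytest.approx(expected[a, b], abs=1e-6)

    def test_means_stay_on_raw_scale(self):
        nd = 120
        mu = np.tile([2.2, 3.3], (nd, 1))
        post = make_posterior(np.zeros((nd, 2, 2)),
                              np.tile(np.eye(2), (nd, 1, 1)), mu_draws=mu)
        table = standardize_within(post)
        assert table.row("mu_SA")["estimate"] == pytest.approx(2.2)
        assert table.row("mu_PAR")["estimate"] == pytest.approx(3.3)

    def test_equal_sds_leave_coefficients_unchanged(self):
        # symmetric system: both variables share a stationary SD, so the
        # standardized matrix equals the raw matrix per draw
        phi = np.array([[0.4, 0.2], [0.2, 0.4]])
        sw = np.eye(2)
        post = make_posterior(np.tile(phi, (120, 1, 1)),
                              np.tile(sw, (120, 1, 1)))
        table = standardize_within(post)
        assert table.row("phi_PAR->SA")["estimate"] == pytest.approx(0.2)


class TestWithinR2:
    def test_zero_dynamics_zero_r2(self):
        nd = 120
        post = make_posterior(np.zeros((nd, 2, 2)),
                              np.tile(np.eye(2), (nd, 1, 1)))
        r2 = within_r2(post)
        assert np.allclose(r2["r2"], 0.0)

    def test_univariate_closed_form(self):
        nd = 120
        post = make_posterior(np.full((nd, 1, 1), 0.5),
                              np.full((nd, 1, 1), 1.0),
                              variables=("social_anxiety",))
        r2 = within_r2(post)
        assert r2["r2"].iloc[0] == pytest.approx(0.25)

    def test_monotone_in_autoregression(self):
        vals = []
        for phi in (0.2, 0.4, 0.6, 0.8):
            post = make_posterior(np.full((120, 1, 1), phi),
                                  np.full((120, 1, 1), 1.0),
                                  variables=("social_anxiety",))
            vals.append(within_r2(post)["r2"].iloc[0])
        assert vals == sorted(vals)
        assert vals[1] == pytest.approx(0.16)

    def test_trend_contribution_counts_as_explained(self):
        nd = 120
        post = make_posterior(np.zeros((nd, 1, 1)), np.full((nd, 1, 1), 1.0),
                              gamma_draws=np.full((nd, 1), 0.5),
                              variables=("social_anxiety",), var_h=4.0)
        # explained = gamma^2 var_h = 1; total = 1 + 1
        assert within_r2(post)["r2"].iloc[0] == pytest.approx(0.5)
        assert within_r2(post, include_trend=False)["r2"].iloc[0] == 0.0

    def test_bounds_on_fitted_posterior(self, study_fit):
        r2 = within_r2(study_fit["post"])
        assert ((r2["r2"] >= 0) & (r2["r2"] < 1)).all()


class TestCredibleIntervals:
    def test_point_mass(self):
        table = credible_intervals({"x": np.full(200, 0.5)})
        row = table.row("x")
        assert (row["lower"], row["upper"]) == (0.5, 0.5)
        assert row["significant"]

    def test_symmetric_draws_not_significant(self):
        draws = np.tile([-1.0, 1.0], 100)
        row = credible_intervals({"x": draws}).row("x")
        assert row["lower"] < 0 < row["upper"]
        assert not row["significant"]

    def test_bounds_equal_order_statistic_oracle(self):
        rng = np.random.default_rng(3)
        draws = np.sort(rng.standard_normal(1000))
        row = credible_intervals({"x": draws}).row("x")

        def quantile_oracle(sorted_x, q):
            # linear interpolation between order statistics
            h = (len(sorted_x) - 1) * q
            lo = int(np.floor(h))
            return sorted_x[lo] + (h - lo) * (sorted_x[min(lo + 1,
                                                           len(sorted_x) - 1)]
                                              - sorted_x[lo])

        assert row["lower"] == pytest.approx(quantile_oracle(draws, 0.025))
        assert row["upper"] == pytest.approx(quantile_oracle(draws, 0.975))

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="draws"):
            credible_intervals({"x": np.arange(50)})


class TestBetweenCorrelations:
    @staticmethod
    def _omega_draws(nd, q, rho):
        omega = np.eye(q + 2)
        omega[0, q] = omega[q, 0] = rho
        return np.tile(omega, (nd, 1, 1))

    def test_known_covariance_recovered(self):
        phi = np.zeros((120, 2, 2))
        post = make_posterior(phi, np.tile(np.eye(2), (120, 1, 1)),
                              omega_draws=self._omega_draws(120, 6, 0.8))
        table = between_correlations(post)
        assert len(table) == 12  # 6 effects x 2 schemas
        assert table.row("r(neg_self, mu_SA)")["estimate"] == pytest.approx(0.8)
        assert table.row("r(neg_other, mu_SA)")["estimate"] == 0.0

    def test_correlations_bounded(self, study_fit):
        table = between_correlations(study_fit["post"])
        assert len(table) == 24
        assert (table.table["estimate"].abs() <= 1).all()
        assert (table.table["lower"] >= -1).all()
        assert (table.table["upper"] <= 1).all()

    def test_missing_covariate_block_rejected(self):
        post = make_posterior(np.zeros((120, 2, 2)),
                              np.tile(np.eye(2), (120, 1, 1)),
                              omega_draws=np.tile(np.eye(6), (120, 1, 1)))
        with pytest.raises(ValueError, match="covariate block"):
            between_correlations(post)


class TestEffectTable:
    def test_fitted_table_shapes(self, study_fit):
        table = effect_table(study_fit["post"])
        assert len(table) == 12
        re_vars = table.table["random_effect_variance"]
        assert re_vars.notna().sum() == 12
        assert (table.table["lower"] <= table.table["upper"]).all()

    def test_interval_ordering_enforced(self):
        import pandas as pd

        from esmvar.postprocess import EffectTable
        bad = pd.DataFrame({"parameter": ["x"], "estimate": [0.0],
                            "lower": [1.0], "upper": [-1.0],
                            "significant": [False]})
        with pytest.raises(ValueError, match="lower"):
            EffectTable(table=bad)
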