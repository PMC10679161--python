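"""Synthetic ESM generator: schedules, person effects, series, missingness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from esmvar import (
    TrueParams,
    apply_missingness,
    bivariate_study_params,
    draw_person_effects,
    generate_schedule,
    simulate_series,
    simulate_study,
    trivariate_study_params,
)
from esmvar.params import beta_from_moments


def univariate_params(phi=0.5, var=0.75, mu=2.0, gamma=0.0, **kw):
    return TrueParams(
        variables=("social_anxiety",),
        mu_bar=[mu], phi_bar=[[phi]], gamma=[gamma],
        omega=np.zeros((2, 2)), sigma_w=[[var]], **kw,
    )


# ---------------------------------------------------------------------------
# prompt schedule
# ---------------------------------------------------------------------------

class TestSchedule:
    def test_default_design_counts_and_spacing(self):
        sched = generate_schedule(5, seed=1)
        per = sched.prompts_per_person()
        assert (per == 60).all()
        gaps = sched.times.groupby(["person_id", "day"])["minute"].diff().dropna()
        assert (gaps >= 15).all()
        assert sched.times["minute"].between(0, 780, inclusive="left").all()

    def test_single_prompt_per_day_uniform_in_window(self):
        sched = generate_schedule(400, n_days=1, prompts_per_day=1, seed=2)
        m = sched.times["minute"].to_numpy()
        assert ((m >= 0) & (m < 780)).all()
        # uniform on [0, 780): mean ~390, spread across quartiles
        assert abs(m.mean() - 390) < 30
        assert np.percentile(m, 25) < 260 and np.percentile(m, 75) > 520

    def test_seed_determinism(self):
        a = generate_schedule(3, seed=7).times
        b = generate_schedule(3, seed=7).times
        c = generate_schedule(3, seed=8).times
        pd.testing.assert_frame_equal(a, b)
        assert not a["minute"].equals(c["minute"])

    def test_infeasible_configuration_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            generate_schedule(1, prompts_per_day=60, min_gap=15,
                              waking_minutes=780, seed=0)


# ---------------------------------------------------------------------------
# person effects
# ---------------------------------------------------------------------------

class TestPersonEffects:
    def test_degenerate_covariance_gives_exact_fixed_effects(self):
        p = bivariate_study_params().with_(omega=np.zeros((6, 6)),
                                           schema_block=None)
        eff = draw_person_effects(p, 50, seed=3)
        assert np.allclose(eff.mu, p.mu_bar)
        assert np.allclose(eff.phi, p.phi_bar)

    def test_configured_schema_dynamics_correlation_recovered(self):
        # correlation 0.4 between negative-self and the paranoia->social-anxiety
        # coefficient; Monte-Carlo check against the configured joint normal
        p0 = trivariate_study_params()
        var_e = np.diag(p0.omega)
        block = np.zeros((12, 2))
        j = 4  # phi_PAR->SA in the stacked effect order
        block[j, 0] = 0.4 * np.sqrt(var_e[j]) * 4.0
        p = p0.with_(schema_block=block)
        eff = draw_person_effects(p, 20_000, seed=11)
        r = np.corrcoef(eff.schemas[:, 0], eff.phi[:, 0, 1])[0, 1]
        assert abs(r - 0.4) < 0.02

    def test_law_of_large_numbers_on_person_means(self):
        p = trivariate_study_params()
        eff = draw_person_effects(p, 20_000, seed=4)
        se = np.sqrt(np.diag(p.omega)[:3] / 20_000)
        assert np.all(np.abs(eff.mu.mean(axis=0) - p.mu_bar) < 3 * se)

    def test_all_draws_stationary(self):
        eff = draw_person_effects(trivariate_study_params(), 500, seed=5)
        rho = [np.max(np.abs(np.linalg.eigvals(f))) for f in eff.phi]
        assert max(rho) < 0.95

    def test_hopeless_stationarity_raises(self):
        p = bivariate_study_params().with_(
            omega=np.diag([0.1, 0.1, 25.0, 25.0, 25.0, 25.0]))
        with pytest.raises(RuntimeError, match="stationary"):
            draw_person_effects(p, 5, seed=1, max_attempts=3)

    def test_non_psd_joint_covariance_raises(self):
        p0 = trivariate_study_params()
        bad = np.full((12, 2), 10.0)  # wildly inconsistent cross covariance
        with pytest.raises(ValueError, match="positive semi-definite"):
            p0.with_(schema_block=bad)

    def test_compliance_beta_moments(self):
        a, b = beta_from_moments(0.721, 0.16)
        assert a > 0 and b > 0
        assert abs(a / (a + b) - 0.721) < 1e-12
        with pytest.raises(ValueError):
            beta_from_moments(0.5, 0.6)


# ---------------------------------------------------------------------------
# series simulation
# ---------------------------------------------------------------------------

class TestSimulateSeries:
    def test_white_noise_limit_has_no_lag1_autocorrelation(self):
        # phi = 0, gamma = 0: consecutive composites are independent
        p = univariate_params(phi=0.0, var=1.0)
        sched = generate_schedule(1300, seed=21)
        eff = draw_person_effects(p, 1300, seed=22)
        data = simulate_series(sched, eff, p, seed=23)
        y = data.data["social_anxiety"].to_numpy()
        pid = data.data["person_id"].to_numpy()
        ts = data.data["timestamp_minute"].to_numpy()
        # prompts under an hour apart can share a one-hour grid cell and
        # hence a latent state; the independence claim is about distinct cells
        ok = (pid[1:] == pid[:-1]) & (ts[1:] - ts[:-1] >= 60)
        x, z = y[:-1][ok], y[1:][ok]
        assert len(x) > 50_000
        r = np.corrcoef(x, z)[0, 1]
        assert abs(r) < 0.03

    def test_stationary_variance_matches_ar1_closed_form(self):
        # phi = 0.5, innovation variance 0.75 -> stationary variance 1.0
        p = univariate_params()
        assert np.isclose(p.stationary_cov()[0, 0], 1.0)
        sched = generate_schedule(300, seed=31)
        eff = draw_person_effects(p, 300, seed=32)
        data = simulate_series(sched, eff, p, seed=33)
        w = data.data["social_anxiety"].to_numpy() - 2.0
        assert abs(w.var() - 1.0) < 0.05

    def test_multivariate_stationary_covariance_matches_lyapunov(self):
        # long single-person series: empirical covariance of the centered
        # composites matches the analytic stationary covariance
        p = bivariate_study_params().with_(
            omega=np.zeros((6, 6)), gamma=np.zeros(2))
        sched = generate_schedule(1, n_days=160, seed=41)
        eff = draw_person_effects(p, 1, seed=42)
        data = simulate_series(sched, eff, p, seed=43)
        w = data.data[["social_anxiety", "paranoia"]].to_numpy() - p.mu_bar
        emp = np.cov(w.T)
        assert np.allclose(emp, p.stationary_cov(), atol=0.12)

    def test_likert_emulation_bounds(self):
        p = trivariate_study_params().with_(likert_emulation=True)
        sched = generate_schedule(10, seed=51)
        eff = draw_person_effects(p, 10, seed=52)
        data = simulate_series(sched, eff, p, seed=53)
        vals = data.data[list(p.variables)].to_numpy()
        assert vals.min() >= 1.0 and vals.max() <= 7.0

    def test_item_emission_composite_is_item_mean(self):
        p = trivariate_study_params().with_(likert_emulation=True)
        sched = generate_schedule(4, seed=61)
        eff = draw_person_effects(p, 4, seed=62)
        data = simulate_series(sched, eff, p, seed=63, emit_items=True)
        items = data.data[[c for c in data.data.columns
                           if c.startswith("paranoia_item")]]
        assert items.isin(range(1, 8)).all().all()
        assert np.allclose(items.mean(axis=1), data.data["paranoia"])

    def test_nonstationary_person_rejected(self):
        p = univariate_params()
        sched = generate_schedule(1, seed=71)
        eff = draw_person_effects(p, 1, seed=72)
        eff.phi[0, 0, 0] = 1.05
        with pytest.raises(ValueError, match="non-stationary"):
            simulate_series(sched, eff, p, seed=73)


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

class TestMissingness:
    def test_full_compliance_is_noop(self):
        p = univariate_params(compliance_mean=1.0, compliance_sd=0.0)
        sched = generate_schedule(5, seed=81)
        eff = draw_person_effects(p, 5, seed=82)
        data = simulate_series(sched, eff, p, seed=83)
        thinned = apply_missingness(data, eff, seed=84)
        pd.testing.assert_frame_equal(thinned.data, data.data)

    def test_aggregate_compliance_near_study_rate(self):
        data, _ = simulate_study(trivariate_study_params(), n_persons=134,
                                 seed=85)
        from esmvar import completion_stats
        rate = completion_stats(data).mean_rate
        assert abs(rate - 0.721) < 0.02

    def test_low_compliance_falls_below_exclusion_threshold(self):
        p = univariate_params(compliance_mean=0.2, compliance_sd=0.0)
        sched = generate_schedule(40, seed=86)
        eff = draw_person_effects(p, 40, seed=87)
        data = apply_missingness(simulate_series(sched, eff, p, seed=88),
                                 eff, seed=89)
        counts = data.completed_counts()
        assert abs(counts.mean() - 12) < 2.5
        assert (counts < 20).mean() > 0.9

    def test_retention_independent_of_response_values(self):
        # MAR: shifting every response leaves the retained rows unchanged
        p = univariate_params(compliance_mean=0.7, compliance_sd=0.0)
        sched = generate_schedule(10, seed=91)
        eff = draw_person_effects(p, 10, seed=92)
        data = simulate_series(sched, eff, p, seed=93)
        shifted = data
        shifted.data = data.data.copy()
        shifted.data["social_anxiety"] += 1.0
        kept_a = apply_missingness(data, eff, seed=94)
        kept_b = apply_missingness(shifted, eff, seed=94)
        assert kept_a.data["timestamp_minute"].equals(
            kept_b.data["timestamp_minute"])

    def test_study_generator_is_deterministic(self):
        a, ea = simulate_study(trivariate_study_params(), n_persons=8, seed=95)
        b, eb = simulate_study(trivariate_study_params(), n_persons=8, seed=95)
        pd.testing.assert_frame_equal(a.data, b.data)
        pd.testing.assert_frame_equal(ea.table, eb.table)


@given(st.integers(min_value=1, max_value=8),
       st.integers(min_value=2, max_value=12))
def test_schedule_blocks_partition_window(n_days, prompts_per_day):
    """One prompt lands in each equal-width block of the waking window."""
    sched = generate_schedule(1, n_days=n_days,
                              prompts_per_day=prompts_per_day, seed=777)
    block = 780 / prompts_per_day
    idx = (sched.times["minute"] // block).astype(int)
    expected = list(range(prompts_per_day)) * n_days
    assert idx.tolist() == expected
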