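"""Synthetic experience-sampling study generator.

Produces ESM datasets with the exact statistical structure the two-level
VAR(1) analysis assumes, so every downstream stage can be checked against a
known ground truth:

1. :func:`generate_schedule` — a signal-contingent prompt schedule
   (pseudo-randomized one prompt per equal-width block, minimum spacing
   enforced) within a daily waking window.
2. :func:`draw_person_effects` — person means and lag matrices drawn jointly
   multivariate normal with the two schema scores; non-stationary persons
   rejected and redrawn.
3. :func:`simulate_series` — the latent centered process simulated on a
   continuous one-hour grid spanning the study week (started from its
   stationary distribution), observed at the scheduled prompts.
4. :func:`apply_missingness` — Bernoulli prompt-level non-response with a
   per-person completion probability, a missing-at-random mechanism that
   never looks at the response values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_discrete_lyapunov

from .dataset import EsmDataset
from .params import TrueParams, beta_from_moments

__all__ = [
    "PromptSchedule",
    "PersonEffects",
    "generate_schedule",
    "draw_person_effects",
    "simulate_series",
    "apply_missingness",
    "simulate_study",
]

MINUTES_PER_DAY = 1440


@dataclass
class PromptSchedule:
    """Scheduled prompt times for every person-day.

    ``times`` has one row per prompt: person_id, day, prompt_index and
    ``minute`` (minutes since that day's waking window opened). Times are
    strictly increasing within a person-day with consecutive gaps of at
    least ``min_gap`` minutes.
    """

    times: pd.DataFrame
    waking_minutes: int = 780
    expiry_minutes: int = 15
    min_gap: int = 15

    def __post_init__(self):
        t = self.times
        gaps = t.groupby(["person_id", "day"])["minute"].diff().dropna()
        if (gaps < self.min_gap).any():
            raise ValueError("schedule violates the minimum prompt spacing")
        if ((t["minute"] < 0) | (t["minute"] >= self.waking_minutes)).any():
            raise ValueError("prompt outside the waking window")

    @property
    def persons(self) -> np.ndarray:
        return self.times["person_id"].unique()

    def prompts_per_person(self) -> pd.Series:
        return self.times.groupby("person_id").size()


def generate_schedule(
    n_persons: int,
    n_days: int = 6,
    prompts_per_day: int = 10,
    waking_minutes: int = 780,
    min_gap: int = 15,
    seed: int | None = None,
    expiry_minutes: int = 15,
    max_attempts: int = 10_000,
) -> PromptSchedule:
    """Pseudo-randomized block schedule: one prompt per equal-width block.

    The waking window is partitioned into ``prompts_per_day`` equal blocks;
    one time is drawn uniformly within each block, and the whole day is
    redrawn until all consecutive gaps are at least ``min_gap`` minutes
    (rejection sampling). Deterministic given ``seed``.
    """
    if n_persons < 1:
        raise ValueError("n_persons must be >= 1")
    if prompts_per_day * min_gap >= waking_minutes:
        raise ValueError(
            f"infeasible schedule: {prompts_per_day} prompts with gaps >= "
            f"{min_gap} min cannot fit a {waking_minutes}-min window"
        )
    rng = np.random.default_rng(seed)
    block = waking_minutes / prompts_per_day
    edges = np.arange(prompts_per_day) * block
    rows = []
    for pid in range(n_persons):
        for day in range(n_days):
            for _ in range(max_attempts):
                t = edges + rng.uniform(0.0, block, size=prompts_per_day)
                if prompts_per_day == 1 or np.all(np.diff(t) >= min_gap):
                    break
            else:  # pragma: no cover - unreachable for feasible configs
                raise RuntimeError("schedule rejection sampling did not converge")
            for j, m in enumerate(t):
                rows.append((pid, day, j, float(m)))
    df = pd.DataFrame(rows, columns=["person_id", "day", "prompt_index", "minute"])
    return PromptSchedule(times=df, waking_minutes=waking_minutes,
                          expiry_minutes=expiry_minutes, min_gap=min_gap)


@dataclass
class PersonEffects:
    """Person-level ground truth: means, lag matrices, covariates.

    ``table`` holds one row per person (person_id, mu_*, phi_* in row-major
    order, neg_self, neg_other, gender, completion_prob); ``mu`` and ``phi``
    expose the same values as stacked arrays.
    """

    table: pd.DataFrame
    variables: tuple[str, ...]
    mu: np.ndarray       # (n, K)
    phi: np.ndarray      # (n, K, K)
    schemas: np.ndarray  # (n, 2)
    gender: np.ndarray   # (n,)
    completion_prob: np.ndarray  # (n,)

    @property
    def n_persons(self) -> int:
        return len(self.table)

    def eta(self) -> np.ndarray:
        """Stacked effects (mu_i, vec_rows(Phi_i)) per person, shape (n, K+K^2)."""
        n, k = self.mu.shape
        return np.hstack([self.mu, self.phi.reshape(n, k * k)])

    def baseline_table(self) -> pd.DataFrame:
        """Between-person covariate table (schemas, gender) keyed by person."""
        return self.table[["person_id", "neg_self", "neg_other", "gender"]].copy()


def draw_person_effects(
    params: TrueParams,
    n_persons: int,
    seed: int | None = None,
    gender_shift: np.ndarray | None = None,
    max_attempts: int = 1000,
    rho_max: float = 0.95,
) -> PersonEffects:
    """Draw person effects and schema scores jointly multivariate normal.

    The stacked vector [mu_i, vec(Phi_i), neg_self, neg_other] is drawn from
    a single multivariate normal centered at (mu_bar, vec(phi_bar),
    schema_mean) with the joint covariance assembled from ``params``. A draw
    whose Phi_i has spectral radius >= ``rho_max`` is rejected and the whole
    person vector redrawn (up to ``max_attempts`` times), so the realized
    population is the stationary truncation of that normal. The bound sits
    below 1 because near-unit-root dynamics imply stationary within-person
    variances far beyond anything a bounded response scale can produce.

    ``gender_shift`` (K x K, optional) is added to Phi_i for persons with
    gender == 1, for moderation power studies. Gender itself is
    Bernoulli(0.5), independent of everything else.
    """
    rng = np.random.default_rng(seed)
    k, q = params.k, params.n_effects
    cov = params.joint_between_cov()
    mean = np.concatenate([params.eta_bar(), params.schema_mean])
    # eigendecomposition square root: exact for singular covariances
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() < -1e-8 * max(1.0, evals.max()):
        raise ValueError(
            "joint [effects; schemas] covariance is not positive semi-definite; "
            "check the omega / schema_block configuration"
        )
    chol = evecs * np.sqrt(np.clip(evals, 0.0, None))

    gender = rng.integers(0, 2, size=n_persons)
    draws = np.empty((n_persons, q + 2))
    for i in range(n_persons):
        for _ in range(max_attempts):
            z = mean + chol @ rng.standard_normal(q + 2)
            phi_i = z[k:q].reshape(k, k)
            if gender_shift is not None and gender[i] == 1:
                phi_i = phi_i + gender_shift
            if np.max(np.abs(np.linalg.eigvals(phi_i))) < rho_max:
                draws[i, :k] = z[:k]
                draws[i, k:q] = phi_i.ravel()
                draws[i, q:] = z[q:]
                break
        else:
            raise RuntimeError(
                f"could not draw a stationary Phi for person {i} in "
                f"{max_attempts} attempts; omega implies almost no stationary mass"
            )

    if params.compliance_sd > 0 and params.compliance_mean < 1.0:
        a, b = beta_from_moments(params.compliance_mean, params.compliance_sd)
        compl = rng.beta(a, b, size=n_persons)
    else:
        compl = np.full(n_persons, params.compliance_mean)

    mu = draws[:, :k]
    phi = draws[:, k:q].reshape(n_persons, k, k)
    schemas = draws[:, q:]
    cols = {"person_id": np.arange(n_persons)}
    from .params import abbrev
    for j, v in enumerate(params.variables):
        cols[f"mu_{abbrev(v)}"] = mu[:, j]
    for a_i, out in enumerate(params.variables):
        for b_i, pred in enumerate(params.variables):
            cols[f"phi_{abbrev(pred)}->{abbrev(out)}"] = phi[:, a_i, b_i]
    cols["neg_self"] = schemas[:, 0]
    cols["neg_other"] = schemas[:, 1]
    cols["gender"] = gender
    cols["completion_prob"] = compl
    return PersonEffects(
        table=pd.DataFrame(cols),
        variables=params.variables,
        mu=mu, phi=phi, schemas=schemas, gender=gender,
        completion_prob=compl,
    )


def _hour_center(params: TrueParams, waking_minutes: int) -> float:
    """Clock hour at the midpoint of the waking window (centering constant)."""
    return params.wake_minute / 60.0 + waking_minutes / 120.0


def simulate_series(
    schedule: PromptSchedule,
    effects: PersonEffects,
    params: TrueParams,
    seed: int | None = None,
    emit_items: bool = False,
) -> EsmDataset:
    """Simulate momentary composites at every scheduled prompt.

    Per person, a latent centered K-variate process is simulated on a
    continuous one-hour grid spanning the study week (including nights),
    started from the stationary distribution of (Phi_i, sigma_w) and
    evolving as ``w_t = Phi_i w_{t-1} + eps_t``. The observed composite at
    a prompt is ``mu_i + gamma * hour + w`` at the prompt's nearest grid
    cell, with the centered clock hour entering the decomposition as a
    diurnal trend term; with ``likert_emulation`` values are clipped to
    [1, 7]. With ``emit_items``, per-item responses (composite + Gaussian
    item noise, rounded and clipped to integer 1-7) are appended and the
    composite replaced by the item mean.
    """
    rng = np.random.default_rng(seed)
    k = params.k
    n_days = int(schedule.times["day"].max()) + 1
    n_hours = (n_days - 1) * 24 + int(np.ceil(schedule.waking_minutes / 60.0)) + 1
    hour_center = _hour_center(params, schedule.waking_minutes)
    # clock hour of each grid cell (cell 0 = waking start of day 0)
    clock_hour = ((params.wake_minute / 60.0 + np.arange(n_hours)) % 24.0)
    hour_cov = clock_hour - hour_center

    chol_w = np.linalg.cholesky(params.sigma_w + 1e-12 * np.eye(k))
    rows = []
    sched = schedule.times
    for i, pid in enumerate(effects.table["person_id"].to_numpy()):
        phi_i = effects.phi[i]
        rho = np.max(np.abs(np.linalg.eigvals(phi_i)))
        if rho >= 1.0:
            raise ValueError(
                f"person {pid} has non-stationary Phi (spectral radius {rho:.3f})"
            )
        v0 = solve_discrete_lyapunov(phi_i, params.sigma_w)
        w = np.empty((n_hours, k))
        w[0] = np.linalg.cholesky(v0 + 1e-12 * np.eye(k)) @ rng.standard_normal(k)
        eps = (chol_w @ rng.standard_normal((k, n_hours - 1))).T
        for t in range(1, n_hours):
            w[t] = phi_i @ w[t - 1] + eps[t - 1]
        sub = sched[sched["person_id"] == pid]
        for day, pidx, minute in zip(sub["day"], sub["prompt_index"], sub["minute"]):
            abs_minute = day * MINUTES_PER_DAY + params.wake_minute + minute
            cell = int(np.floor((day * MINUTES_PER_DAY + minute) / 60.0 + 0.5))
            y = effects.mu[i] + params.gamma * hour_cov[cell] + w[cell]
            rows.append((pid, day, pidx, float(minute), float(abs_minute), *y))

    cols = ["person_id", "day", "prompt_index", "scheduled_minute",
            "timestamp_minute", *params.variables]
    df = pd.DataFrame(rows, columns=cols)

    if emit_items:
        n_items = params.n_items or tuple([3] * k)
        for j, v in enumerate(params.variables):
            items = (df[v].to_numpy()[:, None]
                     + params.item_noise_sd
                     * rng.standard_normal((len(df), n_items[j])))
            items = np.clip(np.rint(items), 1, 7)
            for m in range(n_items[j]):
                df[f"{v}_item{m + 1}"] = items[:, m]
            df[v] = items.mean(axis=1)
    elif params.likert_emulation:
        for v in params.variables:
            df[v] = df[v].clip(1.0, 7.0)

    scheduled = schedule.prompts_per_person().reindex(
        effects.table["person_id"], fill_value=0)
    scheduled.index.name = "person_id"
    return EsmDataset(
        data=df, variables=params.variables, scheduled=scheduled,
        meta={"seed": seed, "hour_center": hour_center,
              "wake_minute": params.wake_minute},
    )


def apply_missingness(
    data: EsmDataset,
    effects: PersonEffects,
    seed: int | None = None,
) -> EsmDataset:
    """Thin prompts by person-level Bernoulli non-response (MAR).

    Each completed prompt is retained independently with that person's
    completion probability; retention never depends on the responses
    themselves. Realized per-person completion rates are recorded in
    ``meta['realized_completion']``.
    """
    probs = pd.Series(effects.completion_prob,
                      index=effects.table["person_id"].to_numpy())
    if ((probs <= 0) | (probs > 1)).any():
        raise ValueError("completion probabilities must be in (0, 1]")
    rng = np.random.default_rng(seed)
    p_row = probs.reindex(data.data["person_id"]).to_numpy()
    keep = rng.random(len(data.data)) < p_row
    thinned = data.data[keep].copy()
    realized = (thinned.groupby("person_id").size()
                .reindex(data.scheduled.index, fill_value=0) / data.scheduled)
    meta = dict(data.meta)
    meta["realized_completion"] = realized
    return EsmDataset(data=thinned, variables=data.variables,
                      scheduled=data.scheduled, meta=meta)


def simulate_study(
    params: TrueParams,
    n_persons: int = 134,
    n_days: int = 6,
    prompts_per_day: int = 10,
    waking_minutes: int = 780,
    min_gap: int = 15,
    seed: int | None = None,
    emit_items: bool = False,
) -> tuple[EsmDataset, PersonEffects]:
    """One-call study generator: schedule, effects, series, missingness.

    Child seeds for the four stages are derived deterministically from
    ``seed`` via ``numpy.random.SeedSequence`` spawning.
    """
    ss = np.random.SeedSequence(seed)
    s_sched, s_eff, s_sim, s_miss = [int(c.generate_state(1)[0] % (2**31))
                                     for c in ss.spawn(4)]
    schedule = generate_schedule(n_persons, n_days, prompts_per_day,
                                 waking_minutes, min_gap, seed=s_sched)
    effects = draw_person_effects(params, n_persons, seed=s_eff)
    full = simulate_series(schedule, effects, params, seed=s_sim,
                           emit_items=emit_items)
    observed = apply_missingness(full, effects, seed=s_miss)
    return observed, effects
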