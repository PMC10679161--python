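"""Model specification and Bayesian estimation of the two-level VAR(1).

``specify_model`` freezes all estimation choices into a :class:`DsemSpec`;
``fit`` runs the blocked Gibbs sampler over the gridded series and returns a
:class:`Posterior` of labelled draws; ``convergence`` computes split-chain
potential-scale-reduction diagnostics; ``gender_moderation`` adds gender as
a between-level predictor of the person-level dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._gibbs import pack_gridded, run_chain
from .design import GriddedSeries
from .params import abbrev

__all__ = [
    "SamplerSettings",
    "DsemSpec",
    "Posterior",
    "ConvergenceReport",
    "specify_model",
    "fit",
    "convergence",
    "gender_moderation",
    "SMOKE_SAMPLER",
    "FULL_SAMPLER",
]


@dataclass(frozen=True)
class SamplerSettings:
    """MCMC settings: chains, iterations per chain, thinning, burn-in.

    The first ``burn_frac`` of each chain is discarded before thinning.
    """

    chains: int = 4
    iterations: int = 5000
    thin: int = 10
    burn_frac: float = 0.5
    seed: int | None = None

    def retained_per_chain(self) -> int:
        burn = int(np.floor(self.burn_frac * self.iterations))
        return len(range(burn, self.iterations, self.thin))


#: Reduced profile for smoke runs and simulation studies.
SMOKE_SAMPLER = SamplerSettings(chains=2, iterations=500, thin=5)
#: Full profile matching the study analysis (4 chains x 5000, thinning 10).
FULL_SAMPLER = SamplerSettings(chains=4, iterations=5000, thin=10)


@dataclass(frozen=True)
class DsemSpec:
    """Frozen model definition for the two-level lag-1 VAR.

    ``random_effects=True`` gives every person their own means and lag
    matrix, jointly normal at the between level (K + K^2 random effects);
    False pools all persons into a single fixed-effects VAR (mainly for
    oracle checks against least squares).
    """

    variables: tuple[str, ...]
    random_effects: bool = True
    hour_trend: bool = True
    schema_covariates: bool = False
    gender_predictor: bool = False
    residual_df: float | None = None   # inverse-Wishart prior df for Sigma_w
    omega_df: float | None = None      # inverse-Wishart prior df for Omega
    sampler: SamplerSettings = field(default_factory=SamplerSettings)

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        if len(self.variables) == 0:
            raise ValueError("at least one variable required")
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("variable names must be unique")

    @property
    def k(self) -> int:
        return len(self.variables)

    @property
    def n_random_effects(self) -> int:
        """K means + K^2 lag coefficients (6 for K=2, 12 for K=3)."""
        return self.k + self.k * self.k if self.random_effects else 0

    def effect_names(self) -> list[str]:
        names = [f"mu_{abbrev(v)}" for v in self.variables]
        for out in self.variables:
            for pred in self.variables:
                names.append(f"phi_{abbrev(pred)}->{abbrev(out)}")
        return names


def specify_model(
    variables,
    include_hour_trend: bool = True,
    covariates: tuple[str, ...] = (),
    settings: SamplerSettings | None = None,
    random_effects: bool = True,
    available_columns=None,
) -> DsemSpec:
    """Build and validate a model specification.

    ``covariates`` may contain ``"schemas"`` (negative-self / negative-other
    enter the between-level joint covariance) and/or ``"gender"`` (enters as
    a between-level mean predictor). ``available_columns``, when given, is
    used to validate the variable names against the data.
    """
    variables = tuple(variables)
    if available_columns is not None:
        unknown = [v for v in variables if v not in available_columns]
        if unknown:
            raise ValueError(
                f"unknown variables {unknown}; available: {sorted(available_columns)}"
            )
    allowed = {"schemas", "gender"}
    bad = set(covariates) - allowed
    if bad:
        raise ValueError(f"unknown covariates {sorted(bad)}; allowed: {sorted(allowed)}")
    return DsemSpec(
        variables=variables,
        random_effects=random_effects,
        hour_trend=include_hour_trend,
        schema_covariates="schemas" in covariates,
        gender_predictor="gender" in covariates,
        sampler=settings or SamplerSettings(),
    )


@dataclass
class Posterior:
    """Labelled MCMC draws, (chain, draw, ...) per parameter.

    Keys: ``mu_bar`` (K,), ``phi_bar`` (K, K; row = outcome), ``gamma``
    (K,), ``sigma_w`` (K, K), and with random effects ``eta`` (N, K + K^2),
    ``omega`` (d, d), optionally ``theta_gender`` (K + K^2,). ``phi_bar``
    rows/cols follow ``spec.variables``.
    """

    draws: dict
    spec: DsemSpec
    person_ids: np.ndarray
    var_h: float
    meta: dict = field(default_factory=dict)
    imputed_mean: np.ndarray | None = None

    @property
    def n_chains(self) -> int:
        return self.draws["mu_bar"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws["mu_bar"].shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws with chains flattened: (chain*draw, ...)."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def save_draws(self, csv_path, index_path=None) -> None:
        """Columnar export of the scalar chains (chain, draw, one column per
        parameter) plus a JSON index of the parameter names."""
        import json

        scalars = self.scalar_dict()
        frames = {"chain": np.repeat(np.arange(self.n_chains), self.n_draws),
                  "draw": np.tile(np.arange(self.n_draws), self.n_chains)}
        for name, arr in scalars.items():
            frames[name] = arr.reshape(-1)
        pd.DataFrame(frames).to_csv(csv_path, index=False)
        if index_path is not None:
            Path(index_path).write_text(json.dumps(
                {"parameters": list(scalars), "chains": self.n_chains,
                 "draws_per_chain": self.n_draws}, indent=1))

    @staticmethod
    def load_scalar_draws(csv_path) -> dict:
        """Reload a ``save_draws`` export as (chain, draw) arrays."""
        df = pd.read_csv(csv_path)
        n_chains = df["chain"].nunique()
        out = {}
        for col in df.columns:
            if col in ("chain", "draw"):
                continue
            out[col] = df[col].to_numpy().reshape(n_chains, -1)
        return out

    def scalar_dict(self) -> dict:
        """Flatten to named scalar chains for diagnostics (chain, draw)."""
        out = {}
        names = self.spec.effect_names()
        k = self.spec.k
        for j, v in enumerate(self.spec.variables):
            out[names[j]] = self.draws["mu_bar"][:, :, j]
            out[f"gamma_{abbrev(v)}"] = self.draws["gamma"][:, :, j]
            out[f"sigma_w_{abbrev(v)}"] = self.draws["sigma_w"][:, :, j, j]
        for a in range(k):
            for b in range(k):
                out[names[k + a * k + b]] = self.draws["phi_bar"][:, :, a, b]
        if "omega" in self.draws:
            for j, nm in enumerate(names):
                out[f"omega_{nm}"] = self.draws["omega"][:, :, j, j]
        return out


def fit(grid: GriddedSeries, spec: DsemSpec, baseline: pd.DataFrame | None = None,
        seed: int | None = None) -> Posterior:
    """Estimate the model on gridded series by blocked Gibbs sampling.

    ``baseline``, required when the spec uses schema or gender covariates,
    is a per-person table with columns ``person_id``, ``neg_self``,
    ``neg_other`` and/or ``gender`` covering every person in the grid.
    Schema scores are grand-mean centered on the analyzed sample. The draws
    are deterministic given the data, spec, and seed.
    """
    if spec.random_effects and grid.n_persons < 2:
        raise ValueError("random-effects model needs at least 2 persons")
    # project the grid onto the modelled variables
    if tuple(grid.variables) != spec.variables:
        idx = [grid.variables.index(v) for v in spec.variables
               if v in grid.variables]
        if len(idx) != spec.k:
            missing = set(spec.variables) - set(grid.variables)
            raise ValueError(f"grid lacks variables {sorted(missing)}")
        sub = {}
        from .design import PersonGrid
        for pid, g in grid.grids.items():
            sub[pid] = PersonGrid(person_id=pid, origin_minute=g.origin_minute,
                                  values=g.values[:, idx],
                                  clock_hour=g.clock_hour)
        grid = GriddedSeries(grids=sub, variables=spec.variables,
                             interval_minutes=grid.interval_minutes,
                             hour_center=grid.hour_center,
                             collisions=grid.collisions)

    schemas = gender = None
    if spec.schema_covariates or spec.gender_predictor:
        if baseline is None:
            raise ValueError("spec uses between-level covariates; pass baseline")
        tab = baseline.set_index("person_id")
        missing = [p for p in grid.persons if p not in tab.index]
        if missing:
            raise ValueError(f"baseline table lacks persons {missing[:5]}")
        tab = tab.loc[grid.persons]
        if spec.schema_covariates:
            schemas = tab[["neg_self", "neg_other"]].to_numpy(float)
        if spec.gender_predictor:
            gender = tab["gender"].to_numpy(float)

    data = pack_gridded(grid, schemas=schemas, gender=gender)
    st = spec.sampler
    master = st.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    chain_seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(st.chains)]

    chain_draws = []
    imputed = None
    for cs in chain_seeds:
        res = run_chain(
            data, n_iter=st.iterations, thin=st.thin, burn_frac=st.burn_frac,
            seed=cs, random_effects=spec.random_effects,
            prior_sw_df=spec.residual_df, prior_omega_df=spec.omega_df,
        )
        imp = res.pop("imputed_mean", None)
        if imp is not None:
            imputed = imp if imputed is None else imputed + imp
        chain_draws.append(res)
    if imputed is not None:
        imputed = imputed / st.chains
    draws = {key: np.stack([c[key] for c in chain_draws])
             for key in chain_draws[0]}
    return Posterior(
        draws=draws, spec=spec, person_ids=data.person_ids, var_h=data.var_h,
        meta={"seed": master, "chain_seeds": chain_seeds,
              "n_transitions": int(len(data.idx_t)),
              "n_missing_cells": int((~data.mask).sum())},
        imputed_mean=imputed,
    )


@dataclass
class ConvergenceReport:
    """Split-chain PSR (R-hat) and effective sample size per parameter."""

    table: pd.DataFrame   # parameter, psr, ess
    threshold: float

    @property
    def worst_psr(self) -> float:
        return float(self.table["psr"].max())

    @property
    def passed(self) -> bool:
        return bool(self.worst_psr <= self.threshold)

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "worst_psr": self.worst_psr,
            "passed": self.passed,
            "parameters": self.table.to_dict(orient="records"),
        }


def diagnostics_from_draws(scalars: dict, threshold: float = 1.1
                           ) -> ConvergenceReport:
    """Split-chain PSR and ESS from named (chain, draw) arrays."""
    first = next(iter(scalars.values()))
    if first.shape[0] < 2:
        raise ValueError("convergence diagnostics require >= 2 chains")
    import arviz as az

    rows = []
    for name, arr in scalars.items():
        if np.allclose(arr, arr.ravel()[0]):
            psr, ess = 1.0, float("nan")  # constant chain: PSR 1 by convention
        else:
            psr = float(az.rhat(az.convert_to_dataset(arr))["x"].values)
            ess = float(az.ess(az.convert_to_dataset(arr))["x"].values)
        rows.append((name, psr, ess))
    table = pd.DataFrame(rows, columns=["parameter", "psr", "ess"])
    return ConvergenceReport(table=table, threshold=threshold)


def convergence(post: Posterior, threshold: float = 1.1) -> ConvergenceReport:
    """Split-chain potential scale reduction and ESS for the main parameters.

    Requires at least two chains. Constant chains yield PSR = 1 by
    convention (numerically, arviz returns NaN there; mapped to 1).
    """
    if post.n_chains < 2:
        raise ValueError("convergence diagnostics require >= 2 chains")
    return diagnostics_from_draws(post.scalar_dict(), threshold)


def gender_moderation(grid: GriddedSeries, spec: DsemSpec,
                      baseline: pd.DataFrame, seed: int | None = None):
    """Between-level regression of the random lag coefficients on gender.

    Refits the model with gender as a between-level mean predictor and
    summarizes the gender coefficients of the K^2 lag coefficients with
    equal-tailed 95% credible intervals and the exclusion-of-zero
    significance rule. Returns (EffectTable, Posterior).
    """
    if "gender" not in baseline.columns:
        raise ValueError("baseline table must contain a 'gender' column")
    if baseline["gender"].nunique() < 2:
        raise ValueError("gender is constant; no between-person variance")
    mod_spec = replace(spec, gender_predictor=True)
    post = fit(grid, mod_spec, baseline=baseline, seed=seed)
    from .postprocess import credible_intervals

    k = spec.k
    names = mod_spec.effect_names()
    draws = {f"gender:{names[k + j]}": post.stacked("theta_gender")[:, k + j]
             for j in range(k * k)}
    table = credible_intervals(draws)
    table.table_id = "gender moderation"
    return table, post
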