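"""Posterior summaries: standardized effects, R-squared, intervals, correlations.

Transforms labelled MCMC draws into the quantities the analysis reports:

* within-person standardized lag coefficients (per draw and person, scaled
  by the ratio of predictor to outcome stationary SDs, then averaged over
  persons) — means stay on the raw Likert scale;
* averaged within-person R^2 per variable;
* equal-tailed credible intervals with the exclusion-of-zero significance
  rule;
* between-person correlations of the random effects with the two schema
  scores, derived from the covariate blocks of Omega.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import DsemSpec, Posterior

__all__ = [
    "EffectTable",
    "stationary_cov",
    "standardize_within",
    "within_r2",
    "credible_intervals",
    "between_correlations",
    "effect_table",
]


@dataclass
class EffectTable:
    """Summarized estimates: point, 95% CrI, significance flag per row."""

    table: pd.DataFrame
    table_id: str = ""
    notes: dict = field(default_factory=dict)

    def __post_init__(self):
        req = {"parameter", "estimate", "lower", "upper", "significant"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"EffectTable missing columns {sorted(missing)}")
        if (self.table["lower"] > self.table["upper"]).any():
            raise ValueError("interval lower bound exceeds upper bound")

    def __len__(self) -> int:
        return len(self.table)

    def row(self, parameter: str) -> pd.Series:
        hit = self.table[self.table["parameter"] == parameter]
        if hit.empty:
            raise KeyError(parameter)
        return hit.iloc[0]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=1)


def stationary_cov(phi: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Stationary covariance of a VAR(1): solve V = Phi V Phi' + Sigma.

    Solved in vec form, (I - Phi (x) Phi) vec(V) = vec(Sigma); raises
    ``ValueError`` for non-stationary Phi.
    """
    k = phi.shape[0]
    if np.max(np.abs(np.linalg.eigvals(phi))) >= 1.0:
        raise ValueError("Phi is not stationary")
    a = np.eye(k * k) - np.kron(phi, phi)
    v = np.linalg.solve(a, sigma.reshape(-1)).reshape(k, k)
    return 0.5 * (v + v.T)


def _interval(draws: np.ndarray, level: float):
    lo = np.quantile(draws, (1 - level) / 2)
    hi = np.quantile(draws, 1 - (1 - level) / 2)
    return float(np.median(draws)), float(lo), float(hi)


def credible_intervals(draws: dict, level: float = 0.95,
                       min_draws: int = 100) -> EffectTable:
    """Equal-tailed credible intervals from labelled draws.

    Point estimate = posterior median; a parameter is flagged significant
    iff its interval excludes zero. Requires at least ``min_draws`` draws.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rows = []
    for name, arr in draws.items():
        arr = np.asarray(arr, float).ravel()
        if arr.size < min_draws:
            raise ValueError(
                f"{name}: {arr.size} draws < required {min_draws} for a "
                f"{level:.0%} interval"
            )
        est, lo, hi = _interval(arr, level)
        rows.append((name, est, lo, hi, not (lo <= 0.0 <= hi)))
    return EffectTable(
        table=pd.DataFrame(rows, columns=["parameter", "estimate", "lower",
                                          "upper", "significant"]),
    )


def _person_phi_draws(post: Posterior):
    """(chain*draw, N, K, K) person lag matrices from the eta draws."""
    k = post.spec.k
    eta = post.stacked("eta")
    return eta[:, :, k:].reshape(eta.shape[0], eta.shape[1], k, k)


def standardize_within(post: Posterior, spec: DsemSpec | None = None,
                       level: float = 0.95) -> EffectTable:
    """Within-person standardized fixed effects.

    Per draw and person, each lag coefficient ``phi[out, pred]`` is
    multiplied by ``sd(pred) / sd(out)`` where the SDs come from the
    stationary covariance ``V_i = Phi_i V_i Phi_i' + Sigma_w``; the
    standardized coefficients are averaged over persons within the draw and
    summarized across draws (median, equal-tailed CrI). Persons whose drawn
    Phi_i is non-stationary are excluded from that draw's average (count in
    ``notes['n_nonstationary']``). Means are reported on the raw scale.
    """
    spec = spec or post.spec
    k = spec.k
    if "eta" not in post.draws:
        # fixed-effects-only model: one shared Phi per draw
        phis = post.stacked("phi_bar")[:, None, :, :]
    else:
        phis = _person_phi_draws(post)
    sws = post.stacked("sigma_w")
    nd, npers = phis.shape[:2]
    std = np.full((nd, k, k), np.nan)
    n_nonstat = 0
    for d in range(nd):
        acc = np.zeros((k, k))
        cnt = 0
        for i in range(npers):
            try:
                v = stationary_cov(phis[d, i], sws[d])
            except ValueError:
                n_nonstat += 1
                continue
            sd = np.sqrt(np.diag(v))
            acc += phis[d, i] * (sd[None, :] / sd[:, None])
            cnt += 1
        if cnt:
            std[d] = acc / cnt
    names = spec.effect_names()
    draws = {}
    for j in range(k):
        draws[names[j]] = post.stacked("mu_bar")[:, j]
    for a in range(k):
        for b in range(k):
            draws[names[k + a * k + b]] = std[:, a, b]
    table = credible_intervals(draws, level=level,
                               min_draws=min(100, nd))
    table.table_id = "within-person standardized fixed effects"
    table.notes["n_nonstationary"] = n_nonstat
    return table


def within_r2(post: Posterior, spec: DsemSpec | None = None,
              include_trend: bool = True) -> pd.DataFrame:
    """Averaged within-person R^2 per variable.

    Per draw and person, ``R2_k = 1 - Sigma_w[k, k] / V[k, k]`` where
    ``V = V_i + var(h) * gamma gamma'`` is the stationary within-person
    variance plus the diurnal-trend contribution (counted as explained when
    ``include_trend``); averaged over persons, summarized across draws.
    """
    spec = spec or post.spec
    k = spec.k
    if "eta" in post.draws:
        phis = _person_phi_draws(post)
    else:
        phis = post.stacked("phi_bar")[:, None, :, :]
    sws = post.stacked("sigma_w")
    gammas = post.stacked("gamma")
    nd, npers = phis.shape[:2]
    r2 = np.full((nd, k), np.nan)
    for d in range(nd):
        trend = (post.var_h * np.outer(gammas[d], gammas[d])
                 if include_trend else 0.0)
        acc = np.zeros(k)
        cnt = 0
        for i in range(npers):
            try:
                v = stationary_cov(phis[d, i], sws[d]) + trend
            except ValueError:
                continue
            vd = np.diag(v)
            if np.any(vd < np.diag(sws[d]) - 1e-8):
                continue  # numerically inconsistent draw
            acc += 1.0 - np.diag(sws[d]) / vd
            cnt += 1
        if cnt:
            r2[d] = acc / cnt
    rows = []
    for j, v in enumerate(spec.variables):
        col = r2[:, j]
        col = col[~np.isnan(col)]
        rows.append((v, float(np.median(col)),
                     float(np.quantile(col, 0.025)),
                     float(np.quantile(col, 0.975))))
    return pd.DataFrame(rows, columns=["variable", "r2", "lower", "upper"])


def between_correlations(post: Posterior, spec: DsemSpec | None = None,
                         level: float = 0.95) -> EffectTable:
    """Correlations of the random effects with the two schema scores.

    Computed per draw from the covariate blocks of Omega as
    ``cov / sqrt(var_effect * var_schema)`` and summarized with equal-tailed
    CrIs and the exclusion-of-zero rule: K + K^2 effects x 2 schemas rows
    (24 cells for the three-variable model).
    """
    spec = spec or post.spec
    if "omega" not in post.draws:
        raise ValueError("posterior has no between-level covariance draws")
    omega = post.stacked("omega")
    q = spec.n_random_effects
    if omega.shape[1] != q + 2:
        raise ValueError("posterior Omega has no schema covariate block; "
                         "fit with schema covariates")
    var_e = np.einsum("dii->di", omega[:, :q, :q])
    var_s = np.einsum("dii->di", omega[:, q:, q:])
    corr = omega[:, :q, q:] / np.sqrt(var_e[:, :, None] * var_s[:, None, :])
    if np.any(np.abs(corr) > 1.0 + 1e-9):
        raise AssertionError("correlation outside [-1, 1]; Omega draw invalid")
    names = spec.effect_names()
    draws = {}
    for s, schema in enumerate(("neg_self", "neg_other")):
        for j, nm in enumerate(names):
            draws[f"r({schema}, {nm})"] = corr[:, j, s]
    table = credible_intervals(draws, level=level,
                               min_draws=min(100, corr.shape[0]))
    table.table_id = "between-person correlations with negative schemas"
    return table


def effect_table(post: Posterior, spec: DsemSpec | None = None,
                 level: float = 0.95) -> EffectTable:
    """Study-style effects table: standardized fixed effects plus the
    random-effect variances (diagonal of Omega) with their CrIs."""
    spec = spec or post.spec
    fixed = standardize_within(post, spec, level=level)
    tab = fixed.table.copy()
    tab["random_effect_variance"] = np.nan
    tab["re_var_lower"] = np.nan
    tab["re_var_upper"] = np.nan
    if "omega" in post.draws:
        omega = post.stacked("omega")
        names = spec.effect_names()
        for j, nm in enumerate(names):
            est, lo, hi = _interval(omega[:, j, j], level)
            sel = tab["parameter"] == nm
            tab.loc[sel, "random_effect_variance"] = est
            tab.loc[sel, "re_var_lower"] = lo
            tab.loc[sel, "re_var_upper"] = hi
    out = EffectTable(table=tab, table_id="fixed and random effects",
                      notes=dict(fixed.notes))
    return out
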