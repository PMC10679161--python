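"""Blocked Gibbs sampler for the two-level VAR(1) with latent-mean centering.

Model, per person i and one-hour grid cell t:

    y_it = mu_i + gamma * h_it + w_it        (observed at occupied cells)
    w_it = Phi_i w_{i,t-1} + eps_it,          eps ~ N(0, Sigma_w)

where h_it is the centered clock hour of the cell (a diurnal detrending
term in the decomposition; the latent dynamics are a pure VAR)

with (mu_i, vec_rows(Phi_i), schemas_i) jointly multivariate normal at the
between level (mean = fixed effects, optionally shifted by gender;
covariance Omega including the schema blocks).

All full conditionals are conjugate:

* latent ``w`` at unoccupied cells — because occupied cells pin the state
  exactly, missing runs between two anchors are conditionally independent
  Gaussian bridges, sampled exactly by forward filtering / backward sampling
  (the numba kernel below);
* Phi_i — multivariate normal (Kronecker-structured precision);
* mu_i — multivariate normal, with the design per transition depending on
  which of the two cells is observed;
* Sigma_w, Omega — inverse-Wishart;
* gamma, fixed effects / gender coefficients — multivariate normal.

The per-run bridge covariances depend only on (Phi_i, Sigma_w) and the
distance from the left anchor, so the gain and conditional-covariance
Cholesky factors are precomputed per person per sweep with batched numpy
and only consumed inside the numba kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.stats import invwishart

__all__ = ["PackedData", "pack_gridded", "GibbsState", "run_chain"]

_JITTER = 1e-10
_DIFFUSE_PREC = 1e-6  # prior precision for fixed effects / gamma (var 1e6)


# --------------------------------------------------------------------------
# data packing
# --------------------------------------------------------------------------

@dataclass
class PackedData:
    """Flat per-cell arrays for all persons, plus transition indexing."""

    person_ids: np.ndarray     # (N,)
    offsets: np.ndarray        # (N+1,) cell offsets into the flat arrays
    y: np.ndarray              # (Ttot, K), NaN where missing
    mask: np.ndarray           # (Ttot,), True where observed
    hourc: np.ndarray          # (Ttot,) centered clock hour of the cell
    var_h: float               # variance of hourc over occupied cells
    schemas: np.ndarray | None  # (N, 2) grand-mean-centered schema scores
    gender: np.ndarray | None   # (N,)
    idx_t: np.ndarray          # (Ntr,) flat index of transition targets
    idx_tm1: np.ndarray        # (Ntr,)
    tr_person: np.ndarray      # (Ntr,) person index per transition
    tr_starts: np.ndarray      # (N,) reduceat segment starts into transitions

    @property
    def n_persons(self) -> int:
        return len(self.person_ids)

    @property
    def k(self) -> int:
        return self.y.shape[1]


def pack_gridded(grid, schemas=None, gender=None) -> PackedData:
    """Pack a GriddedSeries (plus optional covariates) for the sampler.

    ``schemas``: DataFrame/array of two schema columns indexed like the grid
    persons; they are grand-mean centered here, on the analyzed sample.
    ``gender``: binary array aligned to the grid persons.
    """
    pids = list(grid.grids)
    offsets = [0]
    ys, masks, hours = [], [], []
    for pid in pids:
        g = grid.grids[pid]
        occ = g.occupied
        if occ.sum() < 2:
            raise ValueError(
                f"person {pid} has fewer than 2 occupied grid cells; "
                "exclude before fitting"
            )
        ys.append(g.values)
        masks.append(occ)
        hours.append(g.clock_hour - grid.hour_center)
        offsets.append(offsets[-1] + g.n_cells)
    y = np.vstack(ys)
    mask = np.concatenate(masks)
    hourc = np.concatenate(hours)
    offsets = np.asarray(offsets, np.int64)

    # zero within-person variance is unidentifiable
    for i, pid in enumerate(pids):
        seg = y[offsets[i]:offsets[i + 1]]
        obs = seg[mask[offsets[i]:offsets[i + 1]]]
        if np.any(obs.std(axis=0) < 1e-12):
            raise ValueError(
                f"person {pid} has zero within-person variance for at least "
                "one variable"
            )

    idx_t, idx_tm1, tr_person, tr_starts = [], [], [], []
    pos = 0
    for i in range(len(pids)):
        tr_starts.append(pos)
        lo, hi = offsets[i], offsets[i + 1]
        n = hi - lo - 1
        idx_t.append(np.arange(lo + 1, hi))
        idx_tm1.append(np.arange(lo, hi - 1))
        tr_person.append(np.full(n, i))
        pos += n
    sc = None
    if schemas is not None:
        sc = np.asarray(schemas, float)
        if sc.shape != (len(pids), 2):
            raise ValueError("schemas must be (n_persons, 2), aligned to the grid")
        sc = sc - sc.mean(axis=0, keepdims=True)
    gd = None
    if gender is not None:
        gd = np.asarray(gender, float)
        if gd.shape != (len(pids),):
            raise ValueError("gender must be length n_persons")
        if np.all(gd == gd[0]):
            raise ValueError("gender is constant; no between-person variance")
    return PackedData(
        person_ids=np.asarray(pids),
        offsets=offsets,
        y=y,
        mask=mask,
        hourc=hourc,
        var_h=float(hourc[mask].var()),
        schemas=sc,
        gender=gd,
        idx_t=np.concatenate(idx_t).astype(np.int64),
        idx_tm1=np.concatenate(idx_tm1).astype(np.int64),
        tr_person=np.concatenate(tr_person).astype(np.int64),
        tr_starts=np.asarray(tr_starts, np.int64),
    )


# --------------------------------------------------------------------------
# numba bridge kernel
# --------------------------------------------------------------------------

@njit(cache=True)
def _bridge_kernel(w, mask, hourc, offsets, phi, gamma, J, cholC, z, lmax):
    """Sample all missing cells as Gaussian bridges between observed anchors.

    ``J[i, s-1]`` and ``cholC[i, s-1]`` are the smoother gain and the
    Cholesky factor of the backward conditional covariance for a state s
    steps after its left anchor, for person i. ``z`` supplies one standard
    normal K-vector per missing cell, consumed in deterministic order.
    """
    n = offsets.shape[0] - 1
    k = w.shape[1]
    m = np.empty((lmax + 2, k))
    mean = np.empty(k)
    xnext = np.empty(k)
    zpos = 0
    for i in range(n):
        s1 = offsets[i + 1]
        t = offsets[i] + 1
        while t < s1:
            if mask[t]:
                t += 1
                continue
            a = t - 1
            b = t
            while not mask[b]:
                b += 1
            run = b - 1 - a
            for kk in range(k):
                m[0, kk] = w[a, kk]
            for s in range(1, run + 2):
                cell = a + s
                for kk in range(k):
                    acc = 0.0
                    for j in range(k):
                        acc += phi[i, kk, j] * m[s - 1, j]
                    m[s, kk] = acc + gamma[kk] * hourc[cell]
            for kk in range(k):
                xnext[kk] = w[b, kk]
            for s in range(run, 0, -1):
                cell = a + s
                for kk in range(k):
                    acc = m[s, kk]
                    for j in range(k):
                        acc += J[i, s - 1, kk, j] * (xnext[j] - m[s + 1, j])
                    mean[kk] = acc
                for kk in range(k):
                    acc = mean[kk]
                    for j in range(kk + 1):
                        acc += cholC[i, s - 1, kk, j] * z[zpos, j]
                    w[cell, kk] = acc
                zpos += 1
                for kk in range(k):
                    xnext[kk] = w[cell, kk]
            t = b
    return zpos


def _bridge_gains(phi: np.ndarray, sw: np.ndarray, lmax: int):
    """Batched smoother gains and conditional-cholesky factors per person.

    Forward (no-observation) variance recursion from a point anchor:
    P_0 = 0, P_s = Phi P_{s-1} Phi' + Sigma_w. The backward pass needs
    J_s = P_s Phi' P_{s+1}^{-1} and chol(P_s - J_s P_{s+1} J_s') for
    s = 1..lmax.
    """
    n, k, _ = phi.shape
    eye = np.eye(k) * _JITTER
    pred = np.empty((lmax + 2, n, k, k))
    pred[0] = 0.0
    p_prev = np.zeros((n, k, k))
    for s in range(1, lmax + 2):
        p_s = np.einsum("nij,njl,nkl->nik", phi, p_prev, phi) + sw
        pred[s] = p_s
        p_prev = p_s
    J = np.empty((lmax, n, k, k))
    cholC = np.empty((lmax, n, k, k))
    phi_t = np.swapaxes(phi, 1, 2)
    for s in range(1, lmax + 1):
        # J_s = P_s Phi' inv(P_{s+1});  P symmetric so solve on the left
        rhs = np.einsum("nij,njk->nik", phi, pred[s])          # Phi P_s
        J_s = np.swapaxes(np.linalg.solve(pred[s + 1] + eye, rhs), 1, 2)
        cond = pred[s] - np.einsum("nij,njl,nkl->nik", J_s, pred[s + 1], J_s)
        cond = 0.5 * (cond + np.swapaxes(cond, 1, 2)) + 10 * eye
        J[s - 1] = J_s
        cholC[s - 1] = np.linalg.cholesky(cond)
    return np.ascontiguousarray(np.swapaxes(J, 0, 1)), \
        np.ascontiguousarray(np.swapaxes(cholC, 0, 1))


# --------------------------------------------------------------------------
# sweep machinery
# --------------------------------------------------------------------------

@dataclass
class GibbsState:
    """Mutable sampler state for one chain."""

    mu: np.ndarray       # (N, K) person means
    phi: np.ndarray      # (N, K, K) person lag matrices
    w: np.ndarray        # (Ttot, K) latent centered state
    gamma: np.ndarray    # (K,)
    sigma_w: np.ndarray  # (K, K)
    alpha: np.ndarray | None    # (d,) between-level means (effects [+ schemas])
    theta_gender: np.ndarray | None  # (q,) gender coefficients on the effects
    omega: np.ndarray | None    # (d, d)


def _initial_state(data: PackedData, rng, random_effects: bool) -> GibbsState:
    n, k = data.n_persons, data.k
    q = k + k * k
    mu = np.empty((n, k))
    resid = []
    for i in range(n):
        lo, hi = data.offsets[i], data.offsets[i + 1]
        obs = data.y[lo:hi][data.mask[lo:hi]]
        mu[i] = obs.mean(axis=0)
        resid.append(obs - mu[i])
    mu += 0.1 * rng.standard_normal(mu.shape)  # overdisperse chains
    resid = np.vstack(resid)
    sw = np.cov(resid.T) if k > 1 else np.array([[resid.var()]])
    sw = np.atleast_2d(sw) + 0.05 * np.eye(k)
    phi = np.zeros((n, k, k))
    w = np.where(data.mask[:, None], data.y - mu[_person_of_cell(data)], 0.0)
    alpha = theta = omega = None
    if random_effects:
        d = q + (2 if data.schemas is not None else 0)
        alpha = np.zeros(d)
        alpha[:k] = mu.mean(axis=0) + 0.05 * rng.standard_normal(k)
        omega = np.eye(d) * 0.2
        if data.schemas is not None:
            omega[q:, q:] = np.cov(data.schemas.T) + 1e-3 * np.eye(2)
        if data.gender is not None:
            theta = np.zeros(q)
    return GibbsState(mu=mu, phi=phi, w=w, gamma=np.zeros(k), sigma_w=sw,
                      alpha=alpha, theta_gender=theta, omega=omega)


def _person_of_cell(data: PackedData) -> np.ndarray:
    out = np.empty(data.y.shape[0], np.int64)
    for i in range(data.n_persons):
        out[data.offsets[i]:data.offsets[i + 1]] = i
    return out


def _max_run(data: PackedData) -> int:
    lmax = 1
    for i in range(data.n_persons):
        seg = data.mask[data.offsets[i]:data.offsets[i + 1]]
        run = 0
        for v in seg:
            if v:
                lmax = max(lmax, run)
                run = 0
            else:
                run += 1
    return lmax


def _sample_mvn_from_prec(prec: np.ndarray, rhs: np.ndarray, z: np.ndarray):
    """Draw from N(prec^{-1} rhs, prec^{-1}) using one Cholesky factor."""
    L = np.linalg.cholesky(prec)
    tmp = np.linalg.solve(L, rhs)
    mean_part = np.linalg.solve(L.T, tmp)
    noise = np.linalg.solve(L.T, z)
    return mean_part + noise


def _batch_mvn_from_prec(prec: np.ndarray, rhs: np.ndarray, z: np.ndarray):
    """Batched draw from N(prec^{-1} rhs, prec^{-1}); shapes (n, d, d)/(n, d)."""
    L = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, rhs[..., None])[..., 0]
    noise = np.linalg.solve(np.swapaxes(L, 1, 2), z[..., None])[..., 0]
    return mean + noise


def _conditional_blocks(omega_eff: np.ndarray, k: int):
    """Gains and precisions for the (mu | phi) and (phi | mu) prior splits."""
    q = omega_eff.shape[0]
    eye_q = np.eye(q)
    c_mm = omega_eff[:k, :k]
    c_mp = omega_eff[:k, k:]
    c_pp = omega_eff[k:, k:]
    g_p = np.linalg.solve(c_mm + _JITTER * np.eye(k), c_mp).T       # (q-k, k)
    cov_p = c_pp - g_p @ c_mp
    cov_p = 0.5 * (cov_p + cov_p.T) + _JITTER * np.eye(q - k)
    q_p = np.linalg.inv(cov_p)
    g_m = np.linalg.solve(c_pp + _JITTER * np.eye(q - k), c_mp.T).T  # (k, q-k)
    cov_m = c_mm - g_m @ c_mp.T
    cov_m = 0.5 * (cov_m + cov_m.T) + _JITTER * np.eye(k)
    q_m = np.linalg.inv(cov_m)
    return g_p, q_p, g_m, q_m


def run_chain(
    data: PackedData,
    n_iter: int,
    thin: int,
    burn_frac: float,
    seed: int,
    random_effects: bool = True,
    prior_sw_df: float | None = None,
    prior_omega_df: float | None = None,
    track_imputed: bool = True,
) -> dict:
    """Run one MCMC chain; return retained draws keyed by parameter name.

    Retention: the first ``burn_frac`` of iterations is discarded, the rest
    kept every ``thin``-th sweep. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n, k = data.n_persons, data.k
    q = k + k * k
    has_schemas = random_effects and data.schemas is not None
    has_gender = random_effects and data.gender is not None
    d = q + (2 if has_schemas else 0)
    ntr = len(data.idx_t)
    n_missing = int((~data.mask).sum())
    lmax = _max_run(data)
    person_of_cell = _person_of_cell(data)
    eye_k = np.eye(k)
    zero_drift = np.zeros(k)

    state = _initial_state(data, rng, random_effects)
    sw_df0 = prior_sw_df if prior_sw_df is not None else k + 1
    om_df0 = prior_omega_df if prior_omega_df is not None else d + 1

    burn = int(np.floor(burn_frac * n_iter))
    keep_iters = [it for it in range(n_iter) if it >= burn and (it - burn) % thin == 0]
    n_keep = len(keep_iters)
    draws = {
        "mu_bar": np.empty((n_keep, k)),
        "phi_bar": np.empty((n_keep, k, k)),
        "gamma": np.empty((n_keep, k)),
        "sigma_w": np.empty((n_keep, k, k)),
    }
    if random_effects:
        draws["eta"] = np.empty((n_keep, n, q))
        draws["omega"] = np.empty((n_keep, d, d))
        if has_gender:
            draws["theta_gender"] = np.empty((n_keep, q))
    imputed_sum = np.zeros((data.y.shape[0], k)) if track_imputed else None

    # per-person masks and counts for the mu-update transition patterns
    a_prev = data.mask[data.idx_tm1]
    a_cur = data.mask[data.idx_t]
    pat11 = a_prev & a_cur
    pat01 = (~a_prev) & a_cur
    pat10 = a_prev & (~a_cur)
    n11 = np.add.reduceat(pat11.astype(float), data.tr_starts)
    n01 = np.add.reduceat(pat01.astype(float), data.tr_starts)
    n10 = np.add.reduceat(pat10.astype(float), data.tr_starts)

    # between-level prior pieces (refreshed every sweep from Omega)
    if random_effects:
        prior_mean_eta = np.tile(state.alpha[:q], (n, 1))
        g_p = q_p = g_m = q_m = None

    keep_ptr = 0
    for it in range(n_iter):
        # ----- 1. latent bridges ------------------------------------------
        yadj = data.y - np.outer(data.hourc, state.gamma)  # detrended observations
        state.w[data.mask] = yadj[data.mask] - state.mu[person_of_cell[data.mask]]
        J, cholC = _bridge_gains(state.phi, state.sigma_w, lmax)
        if n_missing:
            z = rng.standard_normal((n_missing, k))
            _bridge_kernel(state.w, data.mask, data.hourc, data.offsets,
                           state.phi, zero_drift, J, cholC, z, lmax)
        # mu-free (but trend-removed) values: y - gamma*h where observed, w where not
        u = np.where(data.mask[:, None], yadj, state.w)

        sw_inv = np.linalg.inv(state.sigma_w)

        # ----- 2. person effects ------------------------------------------
        if random_effects:
            g_p, q_p, g_m, q_m = _conditional_blocks(_omega_eff(state, q, has_schemas), k)
            prior_mean_eta = _prior_means(state, data, n, q, has_schemas, has_gender)
        # transition stats at current mu
        w_cent = u - data.mask[:, None] * state.mu[person_of_cell]
        x_all = w_cent[data.idx_tm1]
        r_all = w_cent[data.idx_t]
        xx = np.einsum("ni,nj->nij", x_all, x_all)
        xr = np.einsum("ni,nj->nij", x_all, r_all)
        sxx = np.add.reduceat(xx, data.tr_starts, axis=0)
        sxy = np.add.reduceat(xr, data.tr_starts, axis=0)

        if random_effects:
            z_phi = rng.standard_normal((n, q - k))
            z_mu = rng.standard_normal((n, k))
            # --- Phi_i | mu_i, batched over persons ---
            prec = (np.einsum("ab,ncd->nacbd", sw_inv, sxx)
                    .reshape(n, q - k, q - k) + q_p)
            p_prior = (prior_mean_eta[:, k:]
                       + (state.mu - prior_mean_eta[:, :k]) @ g_p.T)
            rhs = (np.einsum("ab,njb->naj", sw_inv, sxy).reshape(n, q - k)
                   + p_prior @ q_p)
            p_draw = _batch_mvn_from_prec(prec, rhs, z_phi)
            state.phi = np.ascontiguousarray(p_draw.reshape(n, k, k))
            # --- mu_i | Phi_i, batched ---
            pred = np.einsum("nij,nj->ni", state.phi[data.tr_person],
                             u[data.idx_tm1])
            r_tr = u[data.idx_t] - pred
            r11 = np.add.reduceat(r_tr * pat11[:, None], data.tr_starts, axis=0)
            r01 = np.add.reduceat(r_tr * pat01[:, None], data.tr_starts, axis=0)
            r10 = np.add.reduceat(r_tr * pat10[:, None], data.tr_starts, axis=0)
            a10 = np.einsum("nji,jl->nil", state.phi, sw_inv)   # Phi' Swinv
            t10 = np.einsum("nil,nlj->nij", a10, state.phi)
            imp = eye_k[None] - state.phi
            t11 = np.einsum("nji,jl,nlm->nim", imp, sw_inv, imp)
            prec_mu = (n01[:, None, None] * sw_inv
                       + n10[:, None, None] * t10
                       + n11[:, None, None] * t11 + q_m)
            m_prior = (prior_mean_eta[:, :k]
                       + (p_draw - prior_mean_eta[:, k:]) @ g_m.T)
            rhs_mu = (r01 @ sw_inv
                      - np.einsum("nil,nl->ni", a10, r10)
                      + np.einsum("nji,jl,nl->ni", imp, sw_inv, r11)
                      + m_prior @ q_m)
            state.mu = _batch_mvn_from_prec(prec_mu, rhs_mu, z_mu)
        else:
            # pooled fixed-effects-only model: shared Phi then shared mu
            prec = np.kron(sw_inv, sxx.sum(axis=0)) + _DIFFUSE_PREC * np.eye(q - k)
            rhs = (sw_inv @ sxy.sum(axis=0).T).ravel()
            p_draw = _sample_mvn_from_prec(prec, rhs, rng.standard_normal(q - k))
            phi_shared = p_draw.reshape(k, k)
            state.phi[:] = phi_shared
            r_all2 = u[data.idx_t] - u[data.idx_tm1] @ phi_shared.T
            imp = eye_k - phi_shared
            a10 = phi_shared.T @ sw_inv
            prec_mu = (pat01.sum() * sw_inv + pat10.sum() * a10 @ phi_shared
                       + pat11.sum() * imp.T @ sw_inv @ imp
                       + _DIFFUSE_PREC * eye_k)
            rhs_mu = (sw_inv @ r_all2[pat01].sum(axis=0)
                      - a10 @ r_all2[pat10].sum(axis=0)
                      + imp.T @ sw_inv @ r_all2[pat11].sum(axis=0))
            mu_shared = _sample_mvn_from_prec(prec_mu, rhs_mu,
                                              rng.standard_normal(k))
            state.mu[:] = mu_shared

        # refresh w with updated mu
        state.w[data.mask] = yadj[data.mask] - state.mu[person_of_cell[data.mask]]

        # ----- 3. residual covariance -------------------------------------
        w_now = state.w
        pred = np.einsum("nij,nj->ni", state.phi[data.tr_person], w_now[data.idx_tm1])
        eps = w_now[data.idx_t] - pred
        scale = np.eye(k) + eps.T @ eps
        state.sigma_w = invwishart.rvs(df=sw_df0 + ntr, scale=scale,
                                       random_state=rng)
        state.sigma_w = np.atleast_2d(state.sigma_w)
        sw_inv = np.linalg.inv(state.sigma_w)

        # ----- 3b. hour trend ---------------------------------------------
        # gamma enters the decomposition only at observed cells; per
        # transition the design is  D_t = h_t a_t I - h_{t-1} a_{t-1} Phi_i
        v = state.w + data.mask[:, None] * np.outer(data.hourc, state.gamma)
        r_hat = v[data.idx_t] - np.einsum("nij,nj->ni",
                                          state.phi[data.tr_person],
                                          v[data.idx_tm1])
        ha = data.hourc * data.mask
        c_t = ha[data.idx_t]
        c_tm1 = ha[data.idx_tm1]
        a1 = np.add.reduceat(c_t * c_t, data.tr_starts)
        a2 = np.add.reduceat(c_t * c_tm1, data.tr_starts)
        a3 = np.add.reduceat(c_tm1 * c_tm1, data.tr_starts)
        b1 = np.add.reduceat(c_t[:, None] * r_hat, data.tr_starts, axis=0)
        b2 = np.add.reduceat(c_tm1[:, None] * r_hat, data.tr_starts, axis=0)
        sw_phi = np.einsum("ij,njl->nil", sw_inv, state.phi)       # Swinv Phi_i
        phit_sw_phi = np.einsum("nji,njl->nil", state.phi, sw_phi)  # Phi' Swinv Phi
        prec_g = (a1.sum() * sw_inv
                  - np.einsum("n,nij->ij", a2, sw_phi)
                  - np.einsum("n,nij->ij", a2, sw_phi).T
                  + np.einsum("n,nij->ij", a3, phit_sw_phi)
                  + _DIFFUSE_PREC * eye_k)
        rhs_g = sw_inv @ b1.sum(axis=0) - np.einsum(
            "nji,jl,nl->i", state.phi, sw_inv, b2)
        state.gamma = _sample_mvn_from_prec(prec_g, rhs_g,
                                            rng.standard_normal(k))

        # ----- 4. between level -------------------------------------------
        if random_effects:
            eta = np.hstack([state.mu, state.phi.reshape(n, q - k)])
            z_full = np.hstack([eta, data.schemas]) if has_schemas else eta
            om_inv = np.linalg.inv(state.omega + _JITTER * np.eye(d))
            if has_gender:
                g_vec = data.gender
                nf = d + q
                prec_b = np.zeros((nf, nf))
                prec_b[:d, :d] = len(g_vec) * om_inv
                prec_b[:d, d:] = g_vec.sum() * om_inv[:, :q]
                prec_b[d:, :d] = prec_b[:d, d:].T
                prec_b[d:, d:] = (g_vec ** 2).sum() * om_inv[:q, :q]
                prec_b += _DIFFUSE_PREC * np.eye(nf)
                oz = z_full @ om_inv.T
                rhs_b = np.concatenate([oz.sum(axis=0),
                                        (g_vec[:, None] * oz[:, :q]).sum(axis=0)])
                coef = _sample_mvn_from_prec(prec_b, rhs_b,
                                             rng.standard_normal(nf))
                state.alpha = coef[:d]
                state.theta_gender = coef[d:]
                mean_z = state.alpha[None, :] + np.pad(
                    g_vec[:, None] * state.theta_gender[None, :],
                    ((0, 0), (0, d - q)))
            else:
                prec_b = n * om_inv + _DIFFUSE_PREC * np.eye(d)
                rhs_b = om_inv @ z_full.sum(axis=0)
                state.alpha = _sample_mvn_from_prec(prec_b, rhs_b,
                                                    rng.standard_normal(d))
                mean_z = state.alpha[None, :]
            resid_b = z_full - mean_z
            scale_b = np.eye(d) + resid_b.T @ resid_b
            state.omega = invwishart.rvs(df=om_df0 + n, scale=scale_b,
                                         random_state=rng)
            state.omega = np.atleast_2d(state.omega)

        # ----- 5. record ---------------------------------------------------
        if keep_ptr < n_keep and it == keep_iters[keep_ptr]:
            if random_effects:
                draws["mu_bar"][keep_ptr] = state.alpha[:k]
                draws["phi_bar"][keep_ptr] = state.alpha[k:q].reshape(k, k)
                draws["eta"][keep_ptr] = np.hstack(
                    [state.mu, state.phi.reshape(n, q - k)])
                draws["omega"][keep_ptr] = state.omega
                if has_gender:
                    draws["theta_gender"][keep_ptr] = state.theta_gender
            else:
                draws["mu_bar"][keep_ptr] = state.mu[0]
                draws["phi_bar"][keep_ptr] = state.phi[0]
            draws["gamma"][keep_ptr] = state.gamma
            draws["sigma_w"][keep_ptr] = state.sigma_w
            if track_imputed:
                y_imp = (state.mu[person_of_cell] + state.w
                         + np.outer(data.hourc, state.gamma))
                imputed_sum[~data.mask] += y_imp[~data.mask]
            keep_ptr += 1

    out = dict(draws)
    if track_imputed and n_keep:
        imputed_mean = np.full_like(imputed_sum, np.nan)
        imputed_mean[~data.mask] = imputed_sum[~data.mask] / n_keep
        out["imputed_mean"] = imputed_mean
    return out


def _omega_eff(state: GibbsState, q: int, has_schemas: bool) -> np.ndarray:
    """Effective prior covariance of eta_i: Omega conditioned on the schemas."""
    if not has_schemas:
        return state.omega[:q, :q]
    ee = state.omega[:q, :q]
    es = state.omega[:q, q:]
    ss = state.omega[q:, q:]
    w_gain = np.linalg.solve(ss + _JITTER * np.eye(ss.shape[0]), es.T).T
    cond = ee - w_gain @ es.T
    return 0.5 * (cond + cond.T)


def _prior_means(state: GibbsState, data: PackedData, n: int, q: int,
                 has_schemas: bool, has_gender: bool) -> np.ndarray:
    """Per-person conditional prior means of eta_i given schemas and gender."""
    mean = np.tile(state.alpha[:q], (n, 1))
    if has_gender:
        mean = mean + data.gender[:, None] * state.theta_gender[None, :]
    if has_schemas:
        es = state.omega[:q, q:]
        ss = state.omega[q:, q:]
        w_gain = np.linalg.solve(ss + _JITTER * np.eye(ss.shape[0]), es.T).T
        s_cent = data.schemas - state.alpha[q:][None, :]
        mean = mean + s_cent @ w_gain.T
    return mean
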