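"""Ground-truth parameter sets for the synthetic ESM study generator.

A :class:`TrueParams` object fully describes the data-generating process of a
two-level lag-1 vector autoregression on momentary symptom ratings:

* within person, observations decompose as ``y_t = mu_i + gamma * hour_t +
  w_t`` (a diurnal trend on the centered clock hour) and the centered state
  evolves on a one-hour grid as ``w_t = Phi_i w_{t-1} + eps_t`` with
  innovation covariance ``sigma_w``;
* between persons, the stacked random effects ``eta_i = (mu_i, vec(Phi_i))``
  are jointly normal with the two negative-schema scores, with covariance
  assembled from ``omega`` (effect block), ``schema_block`` (effect-schema
  cross covariance) and ``schema_cov``.

The stock parameter sets (:func:`bivariate_study_params`,
:func:`trivariate_study_params`) emulate a six-day, ten-prompt-per-day ESM
study of momentary social anxiety, paranoia and loneliness in a non-clinical
young-adult sample: grand means near 2 on the 1-7 Likert scale, sizeable
autoregressive ("inertia") effects, positive cross-lagged spill-over, and
person-level heterogeneity that correlates with negative-self and
negative-other core schemas.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TrueParams",
    "bivariate_study_params",
    "trivariate_study_params",
    "beta_from_moments",
]

_ABBREV = {
    "social_anxiety": "SA",
    "paranoia": "PAR",
    "loneliness": "LONE",
}


def abbrev(name: str) -> str:
    """Short label for a momentary variable (SA / PAR / LONE style)."""
    return _ABBREV.get(name, name.upper())


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Beta(a, b) shape parameters matched to a given mean and SD.

    Raises ``ValueError`` if the requested SD is infeasible for a Beta
    distribution with that mean (sd^2 must be < mean*(1-mean)).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"Beta mean must be in (0, 1); got {mean}")
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise ValueError(
            f"SD {sd} infeasible for Beta with mean {mean}; "
            f"need sd^2 < {mean * (1 - mean):.4f}"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def _check_psd(mat: np.ndarray, name: str, tol: float = 1e-8) -> None:
    mat = np.asarray(mat, float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square; got shape {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    evals = np.linalg.eigvalsh(mat)
    if evals.min() < -tol * max(1.0, evals.max()):
        raise ValueError(
            f"{name} is not positive semi-definite (min eigenvalue {evals.min():.3e})"
        )


@dataclass(frozen=True)
class TrueParams:
    """Full specification of the synthetic study's data-generating process.

    Parameters
    ----------
    variables
        Ordered names of the momentary variables (K = len(variables)).
    mu_bar
        Grand means, Likert units, length K.
    phi_bar
        Population-average lag-1 coefficient matrix, K x K; row = outcome,
        column = predictor; effects refer to a one-hour time step.
    gamma
        Hour-of-measurement slopes (Likert units per clock hour, on the
        centered hour covariate), length K.
    omega
        Between-person covariance of the stacked random effects
        ``(mu_i, vec_rows(Phi_i))``; shape q x q with q = K + K^2.
    sigma_w
        Within-person innovation (residual) covariance, K x K, common
        across persons.
    schema_block
        Covariance of the random effects with the two observed schema
        scores (negative-self, negative-other); shape q x 2. Zero by
        default (no schema coupling).
    schema_mean, schema_cov
        Mean vector (length 2) and covariance (2 x 2) of the schema scores,
        in questionnaire subscale units.
    compliance_mean, compliance_sd
        Moments of the per-person completion-probability distribution
        (Beta, matched by moments).
    likert_emulation
        If True, emitted composites are clipped to the 1-7 response range
        (and item-level responses, when emitted, are rounded to integers).
    wake_minute
        Clock minute at which the daily 13-hour sampling window opens
        (default 540 = 09:00).
    n_items
        Number of questionnaire items per variable, used only for optional
        item-level emission.
    item_noise_sd
        SD of independent Gaussian item noise around the composite.
    """

    variables: tuple[str, ...]
    mu_bar: np.ndarray
    phi_bar: np.ndarray
    gamma: np.ndarray
    omega: np.ndarray
    sigma_w: np.ndarray
    schema_block: np.ndarray | None = None
    schema_mean: np.ndarray = field(default_factory=lambda: np.zeros(2))
    schema_cov: np.ndarray = field(default_factory=lambda: np.eye(2))
    compliance_mean: float = 1.0
    compliance_sd: float = 0.0
    likert_emulation: bool = False
    wake_minute: int = 540
    n_items: tuple[int, ...] | None = None
    item_noise_sd: float = 0.5

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        k = len(self.variables)
        for attr in ("mu_bar", "phi_bar", "gamma", "omega", "sigma_w",
                     "schema_mean", "schema_cov"):
            object.__setattr__(self, attr, np.asarray(getattr(self, attr), float))
        if self.schema_block is not None:
            object.__setattr__(self, "schema_block",
                               np.asarray(self.schema_block, float))
        q = k + k * k
        if self.mu_bar.shape != (k,):
            raise ValueError(f"mu_bar must have length {k}")
        if self.phi_bar.shape != (k, k):
            raise ValueError(f"phi_bar must be {k}x{k}")
        if self.gamma.shape != (k,):
            raise ValueError(f"gamma must have length {k}")
        if self.omega.shape != (q, q):
            raise ValueError(f"omega must be {q}x{q} (K + K^2 random effects)")
        rho = np.max(np.abs(np.linalg.eigvals(self.phi_bar)))
        if rho >= 1.0:
            raise ValueError(
                f"phi_bar must be stationary (spectral radius {rho:.3f} >= 1)"
            )
        _check_psd(self.omega, "omega")
        _check_psd(self.sigma_w, "sigma_w")
        _check_psd(self.schema_cov, "schema_cov")
        if self.schema_block is not None:
            if self.schema_block.shape != (q, 2):
                raise ValueError(f"schema_block must be {q}x2")
            _check_psd(self.joint_between_cov(), "joint [effects; schemas] covariance")
        if not 0.0 < self.compliance_mean <= 1.0:
            raise ValueError("compliance_mean must be in (0, 1]")
        if self.compliance_sd < 0:
            raise ValueError("compliance_sd must be >= 0")

    # -- derived structure ------------------------------------------------

    @property
    def k(self) -> int:
        return len(self.variables)

    @property
    def n_effects(self) -> int:
        """Number of person-level random effects: K means + K^2 lag coefficients."""
        return self.k + self.k * self.k

    def effect_names(self) -> list[str]:
        """Labels of the stacked random effects, row-major lag coefficients."""
        names = [f"mu_{abbrev(v)}" for v in self.variables]
        for out in self.variables:
            for pred in self.variables:
                names.append(f"phi_{abbrev(pred)}->{abbrev(out)}")
        return names

    def eta_bar(self) -> np.ndarray:
        """Stacked fixed effects (mu_bar, vec_rows(phi_bar))."""
        return np.concatenate([self.mu_bar, self.phi_bar.ravel()])

    def joint_between_cov(self) -> np.ndarray:
        """Covariance of the stacked vector [random effects; schema scores]."""
        q = self.n_effects
        block = self.schema_block if self.schema_block is not None else np.zeros((q, 2))
        top = np.hstack([self.omega, block])
        bot = np.hstack([block.T, self.schema_cov])
        return np.vstack([top, bot])

    def stationary_cov(self) -> np.ndarray:
        """Stationary within-person covariance at the population-average Phi.

        Solves the discrete Lyapunov equation V = Phi V Phi' + Sigma_w.
        """
        from scipy.linalg import solve_discrete_lyapunov

        return solve_discrete_lyapunov(self.phi_bar, self.sigma_w)

    def with_(self, **changes) -> "TrueParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


def bivariate_study_params() -> TrueParams:
    """Ground truth for the two-variable study scenario (social anxiety, paranoia).

    Grand means near 2 Likert units, strong inertia (autoregressions ~0.5)
    and reciprocal positive spill-over between the two symptoms, with
    person-level heterogeneity in both means and lag coefficients. The
    lag-coefficient dispersions are kept small enough (SDs ~0.08-0.17) that
    the joint-normal person model places almost all of its mass on
    stationary dynamics, which the within-person model assumes; their
    relative magnitudes preserve the ordering of the mean dispersions.
    """
    variables = ("social_anxiety", "paranoia")
    mu_bar = [2.08, 2.02]
    # row = outcome, column = predictor
    phi_bar = [[0.50, 0.29],
               [0.20, 0.47]]
    # random-effect variances: [mu_SA, mu_PAR,
    #   phi_SA->SA, phi_PAR->SA, phi_SA->PAR, phi_PAR->PAR]
    omega = np.diag([0.80, 0.62, 0.0094, 0.0275, 0.0063, 0.0088])
    sigma_w = 0.75 * np.array([[1.0, 0.3],
                               [0.3, 1.0]])
    return TrueParams(
        variables=variables,
        mu_bar=mu_bar,
        phi_bar=phi_bar,
        gamma=[-0.02, -0.02],
        omega=omega,
        sigma_w=sigma_w,
        compliance_mean=0.721,
        compliance_sd=0.16,
    )


def trivariate_study_params() -> TrueParams:
    """Ground truth for the three-variable scenario (+ loneliness, + schemas).

    Adds momentary loneliness with the strongest inertia of the three
    variables and positive spill-over into both social anxiety and paranoia,
    plus a between-person coupling of the random effects with negative-self
    and negative-other schema scores: schema levels correlate strongly with
    all three person means, negative-self with the paranoia->social-anxiety
    path, and negative-other positively with social-anxiety->paranoia but
    negatively with loneliness->paranoia. As in the bivariate scenario, the
    lag-coefficient dispersions are scaled so the joint-normal person model
    is almost entirely stationary (rejection rate under 6%), keeping
    person-level ground truth essentially normal.
    """
    variables = ("social_anxiety", "paranoia", "loneliness")
    mu_bar = [1.94, 1.88, 1.96]
    phi_bar = [[0.41, 0.25, 0.26],
               [0.19, 0.31, 0.21],
               [0.05, 0.19, 0.61]]
    # effect order: mu_SA, mu_PAR, mu_LONE, then lag coefficients row-major
    # (outcome SA: SA->SA, PAR->SA, LONE->SA; outcome PAR: ...; outcome LONE: ...)
    var_effects = np.array([
        0.95, 0.72, 0.84,
        0.0125, 0.03125, 0.005,
        0.006875, 0.01125, 0.005,
        0.006875, 0.02375, 0.006875,
    ])
    omega = np.diag(var_effects)
    # correlations of each random effect with (negative-self, negative-other)
    r_schema = np.array([
        [0.45, 0.29],   # mu_SA
        [0.35, 0.23],   # mu_PAR
        [0.41, 0.27],   # mu_LONE
        [-0.08, 0.22],  # phi_SA->SA
        [0.32, 0.10],   # phi_PAR->SA
        [-0.06, -0.10],  # phi_LONE->SA
        [-0.04, 0.30],  # phi_SA->PAR
        [0.28, 0.10],   # phi_PAR->PAR
        [-0.05, -0.23],  # phi_LONE->PAR
        [-0.24, 0.03],  # phi_SA->LONE
        [0.24, 0.15],   # phi_PAR->LONE
        [0.27, 0.20],   # phi_LONE->LONE
    ])
    schema_sd = np.array([4.0, 4.0])
    schema_cov = np.array([[16.0, 8.0],
                           [8.0, 16.0]])
    schema_block = r_schema * np.sqrt(var_effects)[:, None] * schema_sd[None, :]
    sigma_w = 0.75 * np.array([[1.0, 0.3, 0.3],
                               [0.3, 1.0, 0.3],
                               [0.3, 0.3, 1.0]])
    return TrueParams(
        variables=variables,
        mu_bar=mu_bar,
        phi_bar=phi_bar,
        gamma=[-0.02, -0.02, -0.02],
        omega=omega,
        sigma_w=sigma_w,
        schema_block=schema_block,
        schema_mean=[6.0, 6.0],
        schema_cov=schema_cov,
        compliance_mean=0.721,
        compliance_sd=0.16,
    )
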