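"""Joint model: CJS m-array, productivity, state-space counts, process.

The female population at each site is split into local recruits (age 1,
locally born), adults (age >= 2) and immigrants (age 1, outside origin).
With a pre-breeding census, next year's recruits are fledglings that
survived their first year,

    N_rec[t+1] ~ Poisson( 0.5 * phi_juv[t] * sum_a N_a[t] kappa_a[t] zeta_a[t] ),

surviving birds of all stages collapse into the adult stage,

    N_ad[t+1] ~ Binomial( N_rec[t] + N_ad[t] + N_im[t], phi_ad[t] ),

and immigrants arrive as one-year-olds at a constant expected rate,

    N_im[t+1] ~ Poisson( omega ).

Males follow the same equations with male survival but female-produced
fledglings.  Demographic rates sit on link scales (logit for survival,
recapture and fledging probability; log for clutch size) with normal year
effects and optional covariate slopes; the fledging year effects are
correlated across the three female stage classes via a scaled
unit-lower-triangular factor (parameter-expanded Cholesky).  Observed
nest-box counts are lognormal around the latent totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln, logit as _logit

from . import FECUNDITY_STAGES, SEXES, SURVIVAL_STAGES
from .ingest import IPMData, MArraySet, NestAggregate

__all__ = [
    "ParameterSet",
    "PopulationState",
    "PriorConfig",
    "linear_predictor",
    "cjs_cell_probs",
    "marray_row_probs",
    "marray_loglik",
    "clutch_loglik",
    "fledge_loglik",
    "count_loglik",
    "stage_correlated_year_effects",
    "project_population",
    "mean_projection_matrix",
    "process_log_density",
    "joint_log_density",
]


def inv_logit(x):
    return expit(x)


def logit(p):
    return _logit(p)


# ---------------------------------------------------------------------------
# linear predictors
# ---------------------------------------------------------------------------


def linear_predictor(mu, slopes=None, covariates=None, eps=0.0, link="logit"):
    """Inverse-link of ``mu + slopes @ covariates + eps``.

    ``slopes`` and ``covariates`` are aligned 1-d arrays (standardized
    covariate values); ``link`` is ``"logit"`` (probabilities) or ``"log"``
    (clutch size).
    """
    eta = np.asarray(mu, dtype=float) + np.asarray(eps, dtype=float)
    if slopes is not None and covariates is not None:
        eta = eta + np.dot(np.asarray(slopes, float), np.asarray(covariates, float))
    if link == "logit":
        out = expit(eta)
    elif link == "log":
        out = np.exp(eta)
    else:
        raise ValueError(f"unknown link {link!r}")
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite rate from linear predictor")
    return out


# ---------------------------------------------------------------------------
# CJS multinomial cells
# ---------------------------------------------------------------------------


def _check_prob(x, name):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError(f"{name} outside [0, 1]")
    return x


def cjs_cell_probs(phi_juv, phi_ad, p_juv, p_ad, release_occasion, release_stage):
    """Multinomial row for one release cohort.

    ``phi_*[t]`` is survival over interval ``t -> t+1`` and ``p_*[t]`` the
    recapture probability at occasion ``t+1``.  A juvenile release survives
    its first interval with juvenile survival, all later intervals with
    adult survival; its detection at the first possible reencounter (a
    one-year-old first-year breeder) uses the juvenile recapture
    probability, later occasions the adult one.  Adult releases use adult
    rates throughout.  Returns first-recapture probabilities for occasions
    ``release+1 .. T-1`` plus the never-seen-again cell; the row sums to 1.
    """
    phi_juv = _check_prob(phi_juv, "phi_juv")
    phi_ad = _check_prob(phi_ad, "phi_ad")
    p_juv = _check_prob(p_juv, "p_juv")
    p_ad = _check_prob(p_ad, "p_ad")
    n_int = len(phi_ad)
    i = int(release_occasion)
    if release_stage not in ("juv", "ad"):
        raise ValueError("release_stage must be 'juv' or 'ad'")
    cells = np.zeros(n_int - i + 1)
    cum = phi_juv[i] if release_stage == "juv" else phi_ad[i]
    for t in range(i, n_int):
        p_t = p_juv[t] if (release_stage == "juv" and t == i) else p_ad[t]
        cells[t - i] = cum * p_t
        if t + 1 < n_int:
            cum *= (1.0 - p_t) * phi_ad[t + 1]
    cells[-1] = 1.0 - cells[:-1].sum()
    return cells


def marray_row_probs(phi_juv, phi_ad, p_juv, p_ad, release_stage):
    """Cell probabilities for every release occasion, padded to (T-1, T)."""
    n_int = len(phi_ad)
    out = np.zeros((n_int, n_int + 1))
    for i in range(n_int):
        row = cjs_cell_probs(phi_juv, phi_ad, p_juv, p_ad, i, release_stage)
        out[i, i : n_int] = row[:-1]
        out[i, -1] = row[-1]
    return out


def marray_loglik(mset: MArraySet, phi: np.ndarray, p: np.ndarray) -> float:
    """Multinomial log-likelihood of all m-arrays.

    ``phi[j, a, s, t]`` and ``p[j, a, s, t]`` hold survival over interval t
    and recapture at occasion t+1 for sex j, stage a (juv, ad), site s.
    Constant multinomial coefficients are omitted (they do not involve
    parameters); the empty m-array therefore contributes exactly 0.
    """
    total = 0.0
    for ji, j in enumerate(mset.sexes):
        for si, s in enumerate(mset.sites):
            for stage, arrs in (("juv", mset.juv), ("ad", mset.ad)):
                m = arrs[(j, s)]
                if m.sum() == 0:
                    continue
                pr = marray_row_probs(
                    phi[ji, 0, si], phi[ji, 1, si], p[ji, 0, si], p[ji, 1, si], stage
                )
                nz = m > 0
                with np.errstate(divide="ignore"):
                    lp = np.where(nz, np.log(np.where(nz, pr, 1.0)), 0.0)
                total += float((m * lp).sum())
    return total


# ---------------------------------------------------------------------------
# productivity and count likelihoods
# ---------------------------------------------------------------------------


def poisson_logpmf(x, mu):
    """Poisson log-pmf, continuous in x via the gamma function."""
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            mu > 0,
            x * np.log(np.where(mu > 0, mu, 1.0)) - mu - gammaln(x + 1.0),
            np.where(x == 0, 0.0, -np.inf),
        )
    return out


def binomial_logpmf(k, n, prob):
    """Binomial log-pmf, continuous in k and n via the gamma function."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    prob = np.asarray(prob, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        base = (
            gammaln(n + 1.0)
            - gammaln(k + 1.0)
            - gammaln(n - k + 1.0)
            + k * np.log(np.where(prob > 0, prob, 1.0))
            + (n - k) * np.log1p(-np.where(prob < 1, prob, 0.0))
        )
        out = np.where((k >= 0) & (k <= n), base, -np.inf)
        out = np.where((prob == 0) & (k > 0), -np.inf, out)
        out = np.where((prob == 1) & (k < n), -np.inf, out)
    return out


def clutch_loglik(nests: NestAggregate, kappa: np.ndarray) -> float:
    """Poisson likelihood of total eggs: c ~ Poisson(kappa * b).

    ``kappa[a, s, t]`` is mean clutch size; cells with zero broods carry no
    information and contribute 0.
    """
    if np.any(kappa <= 0):
        raise ValueError("clutch size must be positive")
    mask = nests.b > 0
    ll = poisson_logpmf(nests.c[mask], kappa[mask] * nests.b[mask])
    return float(ll.sum())


def fledge_loglik(nests: NestAggregate, zeta: np.ndarray) -> float:
    """Binomial likelihood of fledgling totals: f ~ Binomial(c, zeta)."""
    zeta = _check_prob(zeta, "zeta")
    if (nests.f > nests.c).any():
        raise ValueError("fledglings exceed eggs")
    mask = nests.c > 0
    k, n, z = nests.f[mask], nests.c[mask], zeta[mask]
    return float(binomial_logpmf(k, n, z).sum())


def count_loglik(y: np.ndarray, observed: np.ndarray, n_total: np.ndarray, tau) -> float:
    """Lognormal likelihood of counts: log y ~ Normal(log N, tau^2).

    The latent total N is the lognormal median; the 1/y Jacobian of the
    log transform is included so the value is a proper density in y.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau must be positive")
    yv = y[observed]
    nv = n_total[observed]
    if np.any(nv <= 0):
        return -np.inf
    tv = np.broadcast_to(tau[None, :, None], y.shape)[observed]
    resid = np.log(yv) - np.log(nv)
    ll = -np.log(yv) - np.log(tv) - 0.5 * np.log(2 * np.pi) - 0.5 * (resid / tv) ** 2
    return float(ll.sum())


# ---------------------------------------------------------------------------
# correlated fledging year effects
# ---------------------------------------------------------------------------


def stage_correlated_year_effects(factor, scalars, innovations):
    """Correlated year effects across the three fecundity stage classes.

    ``factor`` is unit-lower-triangular (3, 3), ``scalars`` the positive
    expansion scalars, ``innovations`` standard-normal draws of shape
    (3, ...).  Effects are ``diag(scalars) @ factor @ innovations`` with
    implied covariance ``diag @ (factor factor^T) @ diag``.
    """
    factor = np.asarray(factor, dtype=float)
    scalars = np.asarray(scalars, dtype=float)
    if factor.shape != (3, 3) or not np.allclose(np.diag(factor), 1.0):
        raise ValueError("factor must be 3x3 unit-lower-triangular")
    if np.any(np.triu(factor, 1) != 0):
        raise ValueError("factor must be lower-triangular")
    if np.any(scalars <= 0):
        raise ValueError("expansion scalars must be positive")
    L = scalars[:, None] * factor
    u = np.asarray(innovations, dtype=float)
    return np.tensordot(L, u, axes=(1, 0))


def implied_covariance(factor, scalars):
    L = np.asarray(scalars, float)[:, None] * np.asarray(factor, float)
    return L @ L.T


# ---------------------------------------------------------------------------
# population process
# ---------------------------------------------------------------------------


def project_population(state, phi, kappa, zeta, omega, mode="stochastic", rng=None):
    """One step of the stage-structured projection, all sites at once.

    ``state[j, a, s]`` with stages (rec, ad, im); ``phi[j, a, s]`` with
    survival stages (juv, ad); ``kappa[a, s]``, ``zeta[a, s]`` female
    fecundity; ``omega[j, s]`` expected immigrants.  ``mode`` is
    ``"stochastic"`` (Poisson/binomial draws) or ``"expectation"``.
    """
    state = np.asarray(state, dtype=float)
    phi = _check_prob(phi, "phi")
    if np.any(np.asarray(kappa) < 0) or np.any(np.asarray(omega) < 0):
        raise ValueError("negative rates")
    zeta = _check_prob(zeta, "zeta")
    n_sites = state.shape[2]
    fledge_pool = (state[0] * kappa * zeta).sum(axis=0)  # per site, from females
    new = np.zeros_like(state)
    if mode == "expectation":
        for ji in range(2):
            new[ji, 0] = 0.5 * phi[ji, 0] * fledge_pool
            new[ji, 1] = phi[ji, 1] * state[ji].sum(axis=0)
            new[ji, 2] = omega[ji]
        return new
    if mode != "stochastic":
        raise ValueError("mode must be 'stochastic' or 'expectation'")
    rng = np.random.default_rng(rng)
    for ji in range(2):
        new[ji, 0] = rng.poisson(0.5 * phi[ji, 0] * fledge_pool, size=n_sites)
        new[ji, 1] = rng.binomial(state[ji].sum(axis=0).astype(int), phi[ji, 1], size=n_sites)
        new[ji, 2] = rng.poisson(omega[ji], size=n_sites)
    return new


def mean_projection_matrix(phi_juv, phi_ad, kappa, zeta):
    """Female mean projection matrix (rec, ad, im) for one site, omega = 0.

    Its dominant eigenvalue is the asymptotic growth rate of the
    expectation projection without immigration.
    """
    kappa = np.asarray(kappa, float)
    zeta = np.asarray(zeta, float)
    top = 0.5 * phi_juv * kappa * zeta  # per origin stage
    A = np.array(
        [
            [top[0], top[1], top[2]],
            [phi_ad, phi_ad, phi_ad],
            [0.0, 0.0, 0.0],
        ]
    )
    return A


# ---------------------------------------------------------------------------
# parameters, state, priors
# ---------------------------------------------------------------------------


@dataclass
class PopulationState:
    """Latent abundances ``N[j, a, s, t]`` with stages (rec, ad, im)."""

    N: np.ndarray

    @property
    def totals(self) -> np.ndarray:
        return self.N.sum(axis=1)  # (2, S, T)

    def validate(self) -> None:
        if (self.N < 0).any():
            raise ValueError("latent abundances must be non-negative")


@dataclass
class ParameterSet:
    """Every model parameter of the joint model, on its sampling scale.

    Link-scale means/SDs/year effects for survival (``*_phi``), recapture
    (``*_p``), clutch size (``*_kappa``) and fledging (``*_zeta``); slope
    matrices for whatever covariates the model spec attaches; the
    parameter-expanded Cholesky pieces of the fledging year effects; log
    immigration expectations and count observation SDs.
    """

    mu_phi: np.ndarray          # (2, 2, S) logit
    sig_phi: np.ndarray         # (2, 2, S)
    eps_phi: np.ndarray         # (2, 2, S, T-1)
    mu_p: np.ndarray            # (2, 2, S) logit
    sig_p: np.ndarray
    eps_p: np.ndarray           # (2, 2, S, T-1)
    mu_kappa: np.ndarray        # (3, S) log
    sig_kappa: np.ndarray
    eps_kappa: np.ndarray       # (3, S, T)
    mu_zeta: np.ndarray         # (3, S) logit
    chol_factor: np.ndarray     # (3, 3) unit-lower-triangular
    expansion: np.ndarray       # (3,) positive
    zeta_innovations: np.ndarray  # (3, S, T) standard normal
    log_omega: np.ndarray       # (2, S)
    tau: np.ndarray             # (S,)
    beta_phi: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))   # (ncov, 2)
    beta_zeta: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))  # (ncov, 3)

    @property
    def n_sites(self) -> int:
        return self.mu_phi.shape[2]

    @property
    def n_years(self) -> int:
        return self.eps_kappa.shape[2]

    def survival(self, x_phi=None) -> np.ndarray:
        """phi[j, a, s, t] over intervals t = 0..T-2."""
        eta = self.mu_phi[..., None] + self.eps_phi
        if self.beta_phi.shape[0]:
            x = np.asarray(x_phi, float)  # (ncov, T-1)
            eta = eta + np.einsum("ka,kt->at", self.beta_phi, x)[None, :, None, :]
        return expit(eta)

    def recapture(self) -> np.ndarray:
        return expit(self.mu_p[..., None] + self.eps_p)

    def clutch(self) -> np.ndarray:
        return np.exp(self.mu_kappa[..., None] + self.eps_kappa)

    def zeta_effects(self) -> np.ndarray:
        return stage_correlated_year_effects(
            self.chol_factor, self.expansion, self.zeta_innovations
        )

    def fledging(self, x_zeta=None) -> np.ndarray:
        eta = self.mu_zeta[..., None] + self.zeta_effects()
        if self.beta_zeta.shape[0]:
            x = np.asarray(x_zeta, float)  # (ncov, T)
            eta = eta + np.einsum("ka,kt->at", self.beta_zeta, x)[:, None, :]
        return expit(eta)

    @property
    def omega(self) -> np.ndarray:
        return np.exp(self.log_omega)

    def zeta_covariance(self) -> np.ndarray:
        return implied_covariance(self.chol_factor, self.expansion)


@dataclass(frozen=True)
class PriorConfig:
    """Vaguely informative priors; every choice is overridable.

    Link-scale means are Normal(0, 1.5^2) on the logit scale and
    Normal(log 6, 1) for log clutch size; year-effect and observation SDs
    are Uniform(0, 5); covariate slopes Normal(0, 1.5^2); log immigration
    expectation Normal(0, 2^2); expansion scalars half-Normal(0, 1) with
    standard-normal factor off-diagonals and innovations; initial
    abundances per stage uniform on [0, 3 x first count].
    """

    mu_logit_sd: float = 1.5
    mu_logkappa_mean: float = float(np.log(6.0))
    mu_logkappa_sd: float = 1.0
    sigma_upper: float = 5.0
    tau_upper: float = 5.0
    beta_sd: float = 1.5
    log_omega_sd: float = 2.0
    expansion_sd: float = 1.0
    factor_sd: float = 1.0
    n0_factor: float = 3.0


def _norm_lpdf(x, mu, sd):
    return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((x - mu) / sd) ** 2


def prior_log_density(params: ParameterSet, priors: PriorConfig, n0, n0_upper) -> float:
    """Log prior over all parameters plus the initial abundances ``n0``.

    ``n0`` has shape (2, 3, S); ``n0_upper[j, s]`` is three times the first
    observed count of that sex and site (the uniform upper bound).
    """
    lp = 0.0
    for arr in (params.mu_phi, params.mu_p, params.mu_zeta):
        lp += _norm_lpdf(arr, 0.0, priors.mu_logit_sd).sum()
    lp += _norm_lpdf(params.mu_kappa, priors.mu_logkappa_mean, priors.mu_logkappa_sd).sum()
    for arr in (params.sig_phi, params.sig_p, params.sig_kappa):
        if np.any(arr <= 0) or np.any(arr >= priors.sigma_upper):
            return -np.inf
        lp += -np.log(priors.sigma_upper) * arr.size
    if np.any(params.tau <= 0) or np.any(params.tau >= priors.tau_upper):
        return -np.inf
    lp += -np.log(priors.tau_upper) * params.tau.size
    lp += _norm_lpdf(params.eps_phi, 0.0, params.sig_phi[..., None]).sum()
    lp += _norm_lpdf(params.eps_p, 0.0, params.sig_p[..., None]).sum()
    lp += _norm_lpdf(params.eps_kappa, 0.0, params.sig_kappa[..., None]).sum()
    lp += _norm_lpdf(params.zeta_innovations, 0.0, 1.0).sum()
    if np.any(params.expansion <= 0):
        return -np.inf
    lp += (_norm_lpdf(params.expansion, 0.0, priors.expansion_sd) + np.log(2.0)).sum()
    tri = np.tril_indices(3, -1)
    lp += _norm_lpdf(params.chol_factor[tri], 0.0, priors.factor_sd).sum()
    lp += _norm_lpdf(params.beta_phi, 0.0, priors.beta_sd).sum()
    lp += _norm_lpdf(params.beta_zeta, 0.0, priors.beta_sd).sum()
    lp += _norm_lpdf(params.log_omega, 0.0, priors.log_omega_sd).sum()
    n0 = np.asarray(n0, float)
    upper = np.broadcast_to(np.asarray(n0_upper, float)[:, None, :], n0.shape)
    if np.any(n0 < 0) or np.any(n0 > upper):
        return -np.inf
    lp += -np.log(upper).sum()
    return float(lp)


def process_log_density(N, phi, kappa, zeta, omega) -> float:
    """Log density of the latent trajectory under the projection equations.

    ``N[j, a, s, t]``; transitions t -> t+1 use interval-t rates.  The
    initial slice carries no process term (it has an explicit prior).
    Continuous relaxations of the Poisson/binomial pmfs keep the density
    differentiable in the latent states.
    """
    lp = 0.0
    T = N.shape[3]
    for t in range(T - 1):
        fledge_pool = (N[0, :, :, t] * kappa[:, :, t] * zeta[:, :, t]).sum(axis=0)
        for ji in range(2):
            mu_rec = 0.5 * phi[ji, 0, :, t] * fledge_pool
            lp += poisson_logpmf(N[ji, 0, :, t + 1], mu_rec).sum()
            lp += binomial_logpmf(
                N[ji, 1, :, t + 1], N[ji, :, :, t].sum(axis=0), phi[ji, 1, :, t]
            ).sum()
            lp += poisson_logpmf(N[ji, 2, :, t + 1], omega[ji]).sum()
    return float(lp)


def joint_log_density(
    data: IPMData,
    params: ParameterSet,
    state: PopulationState,
    priors: PriorConfig = PriorConfig(),
    x_phi=None,
    x_zeta=None,
    components: dict | None = None,
) -> float:
    """Sum of all likelihoods, the process density and the priors.

    ``x_phi``/``x_zeta`` are the standardized covariate matrices matching
    the slope blocks in ``params``.  Pass a dict as ``components`` to
    receive the individual terms.
    """
    phi = params.survival(x_phi)
    p = params.recapture()
    kappa = params.clutch()
    zeta = params.fledging(x_zeta)
    n_tot = state.totals
    first = np.argmax(data.counts.observed, axis=2)
    y0 = np.take_along_axis(data.counts.y, first[:, :, None], axis=2)[:, :, 0]
    y0 = np.where(np.isnan(y0), 50.0, y0)
    terms = {
        "marray": marray_loglik(data.marrays, phi, p),
        "clutch": clutch_loglik(data.nests, kappa),
        "fledge": fledge_loglik(data.nests, zeta),
        "count": count_loglik(data.counts.y, data.counts.observed, n_tot, params.tau),
        "process": process_log_density(state.N, phi, kappa, zeta, params.omega),
        "prior": prior_log_density(
            params, priors, state.N[:, :, :, 0], priors.n0_factor * y0
        ),
    }
    if components is not None:
        components.update(terms)
    return float(sum(terms.values()))
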