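"""Posterior sampling, convergence diagnostics and predictive checks.

``fit`` draws from the joint posterior of the integrated model with an
adaptive Metropolis-within-Gibbs sampler (see ``sampler``).  Defaults
are field-scale settings — three chains of 100,000 iterations, 10,000
discarded, every fifth retained — while tests and pipelines pass much
shorter configurations.  Convergence is monitored with the
rank-normalized split version of the Gelman-Rubin statistic (threshold
1.3), and absolute fit with posterior predictive p-values (Freeman-Tukey
discrepancies for counts and m-array cells, deviance for productivity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri
from scipy.stats import rankdata

from . import FECUNDITY_STAGES, SEXES, SURVIVAL_STAGES
from .ingest import IPMData
from .model import PriorConfig, marray_row_probs, poisson_logpmf, binomial_logpmf
from . import sampler as _kern


class InitializationError(RuntimeError):
    """The joint density could not be made finite at any tried start point."""


@dataclass(frozen=True)
class MCMCConfig:
    chains: int = 3
    iterations: int = 100_000
    burn_in: int = 10_000
    thin: int = 5

    @property
    def n_save(self) -> int:
        return int(np.ceil((self.iterations - self.burn_in) / self.thin))


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates attach to which rate (slopes are stage-specific).

    A covariate on survival gets one slope per survival stage (juv, ad); a
    covariate on fledging one slope per fecundity stage (rec, ad, im).
    ``exclusions`` are unordered name pairs barred from co-occurring in
    the same model (the correlation screen's output).
    """

    survival_covariates: tuple = ()
    fledging_covariates: tuple = ()
    priors: PriorConfig = PriorConfig()
    exclusions: tuple = ()

    def validate(self, data: IPMData) -> None:
        present = set(self.survival_covariates) | set(self.fledging_covariates)
        for name in present:
            if name not in data.covariates:
                raise ValueError(f"covariate {name!r} not in data")
        for pair in self.exclusions:
            pair = frozenset(pair)
            if pair <= present:
                a, b = sorted(pair)
                raise ValueError(
                    f"covariates {a!r} and {b!r} are correlated beyond the screening "
                    "threshold and may not enter the same model"
                )


#: recorded blocks, in the exact order the kernel packs them
def _layout(S, T, ncp, ncz):
    Tm1 = T - 1
    return [
        ("mu_phi", (2, 2, S)),
        ("sig_phi", (2, 2, S)),
        ("mu_p", (2, 2, S)),
        ("sig_p", (2, 2, S)),
        ("beta_phi", (ncp, 2)),
        ("mu_kappa", (3, S)),
        ("sig_kappa", (3, S)),
        ("mu_zeta", (3, S)),
        ("beta_zeta", (ncz, 3)),
        ("chol", (3,)),
        ("expansion", (3,)),
        ("log_omega", (2, S)),
        ("tau", (S,)),
        ("phi", (2, 2, S, Tm1)),
        ("p", (2, 2, S, Tm1)),
        ("kappa", (3, S, T)),
        ("zeta", (3, S, T)),
        ("N", (2, 3, S, T)),
        ("logpost", (1,)),
    ]


@dataclass
class PosteriorDraws:
    """Named posterior draws, chain-major: arrays of (chains, draws, ...)."""

    params: dict
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        arr = self.params[name]
        return arr.reshape(arr.shape[0] * arr.shape[1], *arr.shape[2:])

    def summary(self, names=None) -> pd.DataFrame:
        qs = (2.5, 7.5, 25.0, 50.0, 75.0, 92.5, 97.5)
        rows = []
        for name in names or self.params:
            flat = self.stacked(name).reshape(self.n_chains * self.n_draws, -1)
            shape = self.params[name].shape[2:]
            for idx in range(flat.shape[1]):
                sub = np.unravel_index(idx, shape) if shape else ()
                label = name + ("[" + ",".join(map(str, sub)) + "]" if sub else "")
                x = flat[:, idx]
                row = {"parameter": label, "mean": x.mean(), "sd": x.std(ddof=1)}
                for q in qs:
                    row[f"q{q}"] = np.percentile(x, q)
                rows.append(row)
        return pd.DataFrame(rows)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, arr in self.params.items():
            flat = arr.reshape(arr.shape[0] * arr.shape[1], -1)
            pd.DataFrame(flat).to_csv(outdir / f"{name}.csv", index=False)
        manifest = {
            "meta": _jsonable(self.meta),
            "shapes": {k: list(v.shape) for k, v in self.params.items()},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, outdir) -> "PosteriorDraws":
        outdir = Path(outdir)
        manifest = json.loads((outdir / "manifest.json").read_text())
        params = {}
        for name, shape in manifest["shapes"].items():
            flat = pd.read_csv(outdir / f"{name}.csv").to_numpy()
            params[name] = flat.reshape(shape)
        return cls(params=params, meta=manifest["meta"])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# data packing and initialization
# ---------------------------------------------------------------------------


def _pack_data(data: IPMData, spec: ModelSpec):
    sites = data.sites
    years = data.years
    S, T = len(sites), len(years)
    Tm1 = T - 1
    Mj = np.zeros((2, S, Tm1, T), dtype=np.int64)
    Ma = np.zeros_like(Mj)
    for ji, j in enumerate(SEXES):
        for si, s in enumerate(sites):
            Mj[ji, si] = data.marrays.juv[(j, s)]
            Ma[ji, si] = data.marrays.ad[(j, s)]
    bb = data.nests.b.astype(float)
    cc = data.nests.c.astype(float)
    ff = data.nests.f.astype(float)
    yobs = data.counts.observed.astype(float)
    ylog = np.where(data.counts.observed, np.log(np.where(data.counts.observed,
                                                          data.counts.y, 1.0)), 0.0)
    n0up = np.full((2, S), 150.0)
    for ji in range(2):
        for si in range(S):
            obs = np.flatnonzero(data.counts.observed[ji, si])
            if obs.size:
                n0up[ji, si] = 3.0 * data.counts.y[ji, si, obs[0]]
    def _x(names, length, offset=0):
        out = np.zeros((len(names), length))
        for k, name in enumerate(names):
            vals = np.asarray(data.covariates[name], float)[offset : offset + length]
            if np.isnan(vals).any():
                raise ValueError(f"covariate {name!r} has missing years inside the study span")
            out[k] = vals
        return out

    Xp = _x(spec.survival_covariates, Tm1)
    Xz = _x(spec.fledging_covariates, T)
    return Mj, Ma, bb, cc, ff, ylog, yobs, n0up, Xp, Xz


def _init_state(data: IPMData, spec: ModelSpec, rng):
    sites, years = data.sites, data.years
    S, T = len(sites), len(years)
    Tm1 = T - 1
    jit = lambda sd, shape=None: rng.normal(0.0, sd, shape)  # noqa: E731
    state = {}
    state["mu_phi"] = np.empty((2, 2, S))
    state["mu_phi"][:, 0, :] = np.log(0.15 / 0.85) + jit(0.2, (2, S))
    state["mu_phi"][:, 1, :] = 0.0 + jit(0.2, (2, S))
    state["sig_phi"] = np.full((2, 2, S), 0.3) * np.exp(jit(0.1, (2, 2, S)))
    state["eps_phi"] = np.zeros((2, 2, S, Tm1))
    state["mu_p"] = np.full((2, 2, S), 0.3) + jit(0.2, (2, 2, S))
    state["sig_p"] = np.full((2, 2, S), 0.3) * np.exp(jit(0.1, (2, 2, S)))
    state["eps_p"] = np.zeros((2, 2, S, Tm1))
    with np.errstate(divide="ignore", invalid="ignore"):
        cb = data.nests.c.sum() / max(data.nests.b.sum(), 1.0)
        fc = data.nests.f.sum() / max(data.nests.c.sum(), 1.0)
    cb = cb if np.isfinite(cb) and cb > 1 else 5.5
    fc = min(max(fc, 0.05), 0.95) if np.isfinite(fc) else 0.7
    state["mu_kappa"] = np.full((3, S), np.log(cb)) + jit(0.03, (3, S))
    state["sig_kappa"] = np.full((3, S), 0.05) * np.exp(jit(0.1, (3, S)))
    state["eps_kappa"] = np.zeros((3, S, T))
    state["mu_zeta"] = np.full((3, S), np.log(fc / (1 - fc))) + jit(0.1, (3, S))
    state["beta_phi"] = jit(0.02, (len(spec.survival_covariates), 2))
    state["beta_zeta"] = jit(0.02, (len(spec.fledging_covariates), 3))
    state["chol"] = jit(0.05, 3)
    state["expansion"] = np.abs(0.3 + jit(0.05, 3))
    state["u"] = np.zeros((3, S, T))
    state["log_omega"] = np.log(2.0) + jit(0.3, (2, S))
    state["tau"] = np.abs(0.1 + jit(0.02, S))
    # latent states track the counts (interpolated where missing)
    N = np.empty((2, 3, S, T))
    for ji in range(2):
        for si in range(S):
            y = data.counts.y[ji, si].copy()
            obs = np.flatnonzero(data.counts.observed[ji, si])
            if obs.size:
                y = np.interp(np.arange(T), obs, y[obs])
            else:
                y = np.full(T, 15.0)
            N[ji, 0, si] = 0.25 * y
            N[ji, 1, si] = 0.60 * y
            N[ji, 2, si] = 0.15 * y
            for t in range(T - 1):  # keep the adult binomial feasible
                tot = N[ji, :, si, t].sum()
                if N[ji, 1, si, t + 1] > 0.95 * tot:
                    N[ji, 1, si, t + 1] = 0.95 * tot
    state["N"] = N
    return state


_ORDER = (
    "mu_phi", "sig_phi", "eps_phi", "beta_phi",
    "mu_p", "sig_p", "eps_p",
    "mu_kappa", "sig_kappa", "eps_kappa",
    "mu_zeta", "beta_zeta", "chol", "expansion", "u",
    "log_omega", "tau", "N",
)


def _derived(state, Xp, Xz):
    """Natural-scale rates for a state dict (mirrors the kernel)."""
    beff = np.einsum("ka,kt->at", state["beta_phi"], Xp) if len(Xp) else np.zeros(
        (2, Xp.shape[1])
    )
    phi = expit(state["mu_phi"][..., None] + beff[None, :, None, :] + state["eps_phi"])
    p = expit(state["mu_p"][..., None] + state["eps_p"])
    kap = np.exp(state["mu_kappa"][..., None] + state["eps_kappa"])
    lam3 = state["chol"]
    L = np.array([[1, 0, 0], [lam3[0], 1, 0], [lam3[1], lam3[2], 1]], dtype=float)
    eff = np.einsum("ab,bst->ast", state["expansion"][:, None] * L, state["u"])
    beffz = np.einsum("ka,kt->at", state["beta_zeta"], Xz) if len(Xz) else np.zeros(
        (3, Xz.shape[1])
    )
    zet = expit(state["mu_zeta"][..., None] + beffz[:, None, :] + eff)
    return phi, p, kap, zet


def _total_logp_state(packed, state, priors: PriorConfig):
    Mj, Ma, bb, cc, ff, ylog, yobs, n0up, Xp, Xz = packed
    phi, p, kap, zet = _derived(state, Xp, Xz)
    return _kern._total_logp(
        Mj, Ma, bb, cc, ff, ylog, yobs, n0up,
        state["mu_phi"], state["sig_phi"], state["eps_phi"], state["beta_phi"],
        state["mu_p"], state["sig_p"], state["eps_p"],
        state["mu_kappa"], state["sig_kappa"], state["eps_kappa"],
        state["mu_zeta"], state["beta_zeta"], state["chol"], state["expansion"], state["u"],
        state["log_omega"], state["tau"], state["N"],
        phi, p, kap, zet,
        priors.mu_logit_sd, priors.mu_logkappa_mean, priors.mu_logkappa_sd,
        priors.sigma_upper, priors.tau_upper, priors.beta_sd,
        priors.log_omega_sd, priors.expansion_sd, priors.factor_sd,
    )


def fit(
    spec: ModelSpec,
    data: IPMData,
    config: MCMCConfig = MCMCConfig(),
    seed: int = 0,
    max_init_attempts: int = 30,
) -> PosteriorDraws:
    """Sample the joint posterior; reproducible given ``seed``."""
    spec.validate(data)
    packed = _pack_data(data, spec)
    Mj, Ma, bb, cc, ff, ylog, yobs, n0up, Xp, Xz = packed
    S = Mj.shape[1]
    T = bb.shape[2]
    ncp, ncz = Xp.shape[0], Xz.shape[0]
    layout = _layout(S, T, ncp, ncz)
    nflat = sum(int(np.prod(shape)) for _, shape in layout)
    priors = spec.priors

    ss = np.random.SeedSequence(seed)
    chain_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(config.chains)]
    chains_out = []
    for ci in range(config.chains):
        rng = np.random.default_rng(chain_seeds[ci])
        state = None
        for _ in range(max_init_attempts):
            cand = _init_state(data, spec, rng)
            if _total_logp_state(packed, cand, priors) > -1e299:
                state = cand
                break
        if state is None:
            raise InitializationError("joint density non-finite at every start point tried")
        out = np.empty((config.n_save, nflat))
        got = _kern.run_chain(
            Mj, Ma, bb, cc, ff, ylog, yobs, n0up, Xp, Xz,
            state["mu_phi"], state["sig_phi"], state["eps_phi"], state["beta_phi"],
            state["mu_p"], state["sig_p"], state["eps_p"],
            state["mu_kappa"], state["sig_kappa"], state["eps_kappa"],
            state["mu_zeta"], state["beta_zeta"], state["chol"], state["expansion"],
            state["u"], state["log_omega"], state["tau"], state["N"],
            priors.mu_logit_sd, priors.mu_logkappa_mean, priors.mu_logkappa_sd,
            priors.sigma_upper, priors.tau_upper, priors.beta_sd,
            priors.log_omega_sd, priors.expansion_sd, priors.factor_sd,
            config.iterations, config.burn_in, config.thin, chain_seeds[ci],
            out,
        )
        chains_out.append(out[:got])

    n_keep = min(len(c) for c in chains_out)
    stackedmat = np.stack([c[:n_keep] for c in chains_out])  # (C, n, nflat)
    params = {}
    col = 0
    for name, shape in layout:
        size = int(np.prod(shape))
        params[name] = stackedmat[:, :, col : col + size].reshape(
            config.chains, n_keep, *shape
        )
        col += size
    meta = {
        "seed": seed,
        "chain_seeds": chain_seeds,
        "chains": config.chains,
        "iterations": config.iterations,
        "burn_in": config.burn_in,
        "thin": config.thin,
        "sites": list(data.sites),
        "years": [int(y) for y in data.years.tolist()],
        "survival_covariates": list(spec.survival_covariates),
        "fledging_covariates": list(spec.fledging_covariates),
        "priors": asdict(priors),
    }
    return PosteriorDraws(params=params, meta=meta)


# ---------------------------------------------------------------------------
# convergence diagnostic
# ---------------------------------------------------------------------------


def _rhat_classic(z: np.ndarray) -> float:
    # z: (m, n) chains after splitting
    m, n = z.shape
    means = z.mean(axis=1)
    W = z.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    if W <= 0:
        return 1.0
    return float(np.sqrt(var_plus / W))


def rhat(draws: np.ndarray) -> float:
    """Rank-normalized split Gelman-Rubin statistic for one scalar series.

    ``draws`` has shape (chains, iterations); at least two chains and four
    iterations are required (each chain is split in half).
    """
    x = np.asarray(draws, float)
    if x.ndim != 2:
        raise ValueError("draws must be (chains, iterations)")
    C, n = x.shape
    if C < 2:
        raise ValueError("rhat needs at least 2 chains")
    if n < 4:
        raise ValueError("rhat needs at least 4 iterations per chain")
    half = n // 2
    split = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    r = rankdata(split.ravel()).reshape(split.shape)
    z = ndtri((r - 3.0 / 8.0) / (split.size + 0.25))
    return _rhat_classic(z)


def rhat_table(draws: PosteriorDraws, names=None) -> pd.DataFrame:
    rows = []
    for name in names or [n for n in draws.params if n != "logpost"]:
        arr = draws.params[name]
        flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
        for idx in range(flat.shape[2]):
            rows.append({"parameter": f"{name}[{idx}]", "rhat": rhat(flat[:, :, idx])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# posterior predictive checks
# ---------------------------------------------------------------------------


def posterior_predictive_pvalue(
    draws: PosteriorDraws, data: IPMData, n_rep: int = 200, seed: int = 0
) -> dict:
    """Posterior predictive p-values per data stream.

    Counts and m-array cells use Freeman-Tukey discrepancies, productivity
    a deviance; each replicate uses one retained posterior draw, and the
    p-value is P(D_rep >= D_obs) (so identical discrepancies give p = 1).
    """
    rng = np.random.default_rng(seed)
    C, D = draws.n_chains, draws.n_draws
    pick = rng.integers(0, C * D, size=min(n_rep, C * D))
    phi_d = draws.stacked("phi")
    p_d = draws.stacked("p")
    kap_d = draws.stacked("kappa")
    zet_d = draws.stacked("zeta")
    N_d = draws.stacked("N")
    tau_d = draws.stacked("tau")
    sites = data.sites
    ge_counts = ge_marr = ge_fec = 0
    yobs = data.counts.observed
    yv = data.counts.y
    bmask = data.nests.b > 0
    cmask = data.nests.c > 0
    for d in pick:
        ntot = N_d[d].sum(axis=1)  # (2, S, T)
        # counts
        tau_full = np.broadcast_to(tau_d[d][None, :, None], ntot.shape)
        d_obs = ((np.sqrt(yv[yobs]) - np.sqrt(ntot[yobs])) ** 2).sum()
        yrep = np.exp(rng.normal(np.log(np.maximum(ntot[yobs], 1e-9)), tau_full[yobs]))
        d_rep = ((np.sqrt(yrep) - np.sqrt(ntot[yobs])) ** 2).sum()
        ge_counts += d_rep >= d_obs
        # m-arrays
        do = dr = 0.0
        for ji in range(2):
            for si, s in enumerate(sites):
                for stage, arrs in (("juv", data.marrays.juv), ("ad", data.marrays.ad)):
                    m = arrs[(SEXES[ji], s)]
                    R = m.sum(axis=1)
                    if R.sum() == 0:
                        continue
                    pr = marray_row_probs(
                        phi_d[d][ji, 0, si], phi_d[d][ji, 1, si],
                        p_d[d][ji, 0, si], p_d[d][ji, 1, si], stage,
                    )
                    E = R[:, None] * pr
                    do += ((np.sqrt(m) - np.sqrt(E)) ** 2).sum()
                    for i in np.flatnonzero(R):
                        mrep = rng.multinomial(R[i], pr[i] / pr[i].sum())
                        dr += ((np.sqrt(mrep) - np.sqrt(E[i])) ** 2).sum()
        ge_marr += dr >= do
        # productivity deviance
        lam_c = kap_d[d] * data.nests.b
        d_obs = -2.0 * (
            poisson_logpmf(data.nests.c[bmask], lam_c[bmask]).sum()
            + binomial_logpmf(
                data.nests.f[cmask], data.nests.c[cmask], zet_d[d][cmask]
            ).sum()
        )
        crep = rng.poisson(lam_c[bmask])
        frep = rng.binomial(data.nests.c[cmask].astype(int), zet_d[d][cmask])
        d_rep = -2.0 * (
            poisson_logpmf(crep, lam_c[bmask]).sum()
            + binomial_logpmf(frep, data.nests.c[cmask], zet_d[d][cmask]).sum()
        )
        ge_fec += d_rep >= d_obs
    n = len(pick)
    return {
        "counts": ge_counts / n,
        "marray": ge_marr / n,
        "fecundity": ge_fec / n,
    }


def base_model() -> ModelSpec:
    """The covariate-free model (all year variation in the random effects)."""
    return ModelSpec()
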