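"""Ground-truth generator and forward simulator for all four data streams.

The generator draws a complete parameterization of the two-site population
process (survival, recapture, clutch size, fledging, immigration, count
error, optional covariate slopes) from configured ranges, then simulates:

* the latent stage-structured abundances with full demographic
  stochasticity (Poisson recruitment and immigration, binomial adult
  survival, even fledgling sex ratio);
* individual capture histories that are exactly consistent with the CJS
  rates (each marked bird lives and is detected according to the same
  stage/sex/site/year rates the likelihood uses);
* population-level productivity totals (Poisson eggs, binomial
  fledglings);
* lognormal nest-box counts and the annual covariate series.

Default parameter ranges mimic demographic estimates reported for the
Swiss pied flycatcher populations this model targets (juvenile apparent
survival near 0.15, adult near 0.5, clutches of 5-6 eggs, fledging
probability near 0.7, a few immigrants per year, populations of 15-25
breeding females per site).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields

import numpy as np
import yaml

from . import FECUNDITY_STAGES, SEXES
from .covariates import CovariateSeries
from .ingest import CaptureTable, CountSeries, NestAggregate
from .model import logit, project_population


class ConfigurationError(ValueError):
    """Invalid generator configuration (e.g. inverted range, no years)."""


DEFAULT_COVARIATES = (
    "precip_nest_init",
    "precip_hatchling",
    "temp_postfledge",
    "temp_hatchling_min",
    "temp_summer",
    "ndvi_winter",
    "init_date",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Ranges (uniform draws) and sizes for the ground-truth generator.

    Ranges may be degenerate (lo == hi) to pin a value exactly.
    """

    sites: tuple = ("site_a", "site_b")
    n_years: int = 40
    start_year: int = 1981
    phi_juv_range: tuple = (0.10, 0.22)
    phi_ad_range: tuple = (0.45, 0.55)
    sigma_phi_range: tuple = (0.20, 0.40)
    p_juv_range: tuple = (0.40, 0.60)
    p_ad_range: tuple = (0.55, 0.70)
    sigma_p_range: tuple = (0.20, 0.40)
    kappa_range: tuple = (5.4, 5.9)
    sigma_kappa_range: tuple = (0.03, 0.07)
    zeta_range: tuple = (0.60, 0.80)
    zeta_sd_range: tuple = (0.45, 0.75)
    zeta_corr_range: tuple = (0.30, 0.70)
    omega_f_range: tuple = (2.0, 4.0)
    omega_m_range: tuple = (1.0, 2.5)
    tau_range: tuple = (0.05, 0.12)
    n0_rec_range: tuple = (3, 6)
    n0_ad_range: tuple = (8, 16)
    n0_im_range: tuple = (2, 5)
    covariate_names: tuple = DEFAULT_COVARIATES
    mast_covariate: bool = True
    mast_prob: float = 0.25
    # planted effects: {(covariate, stage): slope}; stages "juv"/"ad" for
    # survival, "rec"/"ad"/"im" for fledging
    beta_phi: dict = field(default_factory=dict)
    beta_zeta: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_years < 2:
            raise ConfigurationError("need at least 2 study years")
        if len(self.sites) < 1:
            raise ConfigurationError("need at least one site")
        for f in fields(self):
            if f.name.endswith("_range"):
                lo, hi = getattr(self, f.name)
                if lo > hi:
                    raise ConfigurationError(f"{f.name}: min {lo} > max {hi}")


@dataclass
class TruthBundle:
    """The complete generating parameterization, plus realized quantities.

    Natural-scale means are stored (probabilities, eggs/brood, birds/year);
    year-effect SDs sit on the link scales.  After ``simulate_dataset`` the
    latent abundances and realized annual rates are filled in.
    """

    config: SyntheticConfig
    sites: tuple
    years: np.ndarray
    phi_mean: np.ndarray      # (2, 2, S) probability
    sig_phi: np.ndarray       # (2, 2, S) logit-scale SD
    p_mean: np.ndarray        # (2, 2, S)
    sig_p: np.ndarray
    kappa_mean: np.ndarray    # (3, S) eggs/brood
    sig_kappa: np.ndarray     # (3, S) log-scale SD
    zeta_mean: np.ndarray     # (3, S)
    zeta_cov: np.ndarray      # (3, 3) logit-scale covariance
    omega: np.ndarray         # (2, S) birds/year
    tau: np.ndarray           # (S,)
    n0: np.ndarray            # (2, 3, S) integers
    covariates: dict          # name -> (T,) values
    phi_cov_names: tuple = ()
    beta_phi: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    zeta_cov_names: tuple = ()
    beta_zeta: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    # filled by simulate_dataset
    N: np.ndarray | None = None            # (2, 3, S, T)
    phi_real: np.ndarray | None = None     # (2, 2, S, T-1)
    p_real: np.ndarray | None = None       # (2, 2, S, T-1)
    kappa_real: np.ndarray | None = None   # (3, S, T)
    zeta_real: np.ndarray | None = None    # (3, S, T)
    extinct: bool = False

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def validate(self) -> None:
        for name in ("phi_mean", "p_mean", "zeta_mean"):
            arr = getattr(self, name)
            if np.any(arr <= 0) or np.any(arr >= 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        for name in ("sig_phi", "sig_p", "sig_kappa", "tau", "omega"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be non-negative")
        if not np.allclose(self.zeta_cov, self.zeta_cov.T):
            raise ValueError("zeta_cov must be symmetric")
        if np.linalg.eigvalsh(self.zeta_cov).min() < -1e-9:
            raise ValueError("zeta_cov must be positive semi-definite")
        if np.any(self.n0 < 0):
            raise ValueError("initial abundances must be non-negative")

    def to_yaml(self, path) -> None:
        doc = {
            "sites": list(self.sites),
            "years": [int(y) for y in self.years.tolist()],
            "phi_mean": self.phi_mean.tolist(),
            "sig_phi": self.sig_phi.tolist(),
            "p_mean": self.p_mean.tolist(),
            "sig_p": self.sig_p.tolist(),
            "kappa_mean": self.kappa_mean.tolist(),
            "sig_kappa": self.sig_kappa.tolist(),
            "zeta_mean": self.zeta_mean.tolist(),
            "zeta_cov": self.zeta_cov.tolist(),
            "omega": self.omega.tolist(),
            "tau": self.tau.tolist(),
            "n0": self.n0.tolist(),
            "phi_cov_names": list(self.phi_cov_names),
            "beta_phi": self.beta_phi.tolist(),
            "zeta_cov_names": list(self.zeta_cov_names),
            "beta_zeta": self.beta_zeta.tolist(),
            "covariates": {k: np.asarray(v).tolist() for k, v in self.covariates.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path, config: SyntheticConfig | None = None) -> "TruthBundle":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            config=config or SyntheticConfig(),
            sites=tuple(doc["sites"]),
            years=np.array(doc["years"]),
            phi_mean=np.array(doc["phi_mean"]),
            sig_phi=np.array(doc["sig_phi"]),
            p_mean=np.array(doc["p_mean"]),
            sig_p=np.array(doc["sig_p"]),
            kappa_mean=np.array(doc["kappa_mean"]),
            sig_kappa=np.array(doc["sig_kappa"]),
            zeta_mean=np.array(doc["zeta_mean"]),
            zeta_cov=np.array(doc["zeta_cov"]),
            omega=np.array(doc["omega"]),
            tau=np.array(doc["tau"]),
            n0=np.array(doc["n0"]),
            covariates={k: np.array(v) for k, v in doc["covariates"].items()},
            phi_cov_names=tuple(doc["phi_cov_names"]),
            beta_phi=np.array(doc["beta_phi"]).reshape(-1, 2),
            zeta_cov_names=tuple(doc["zeta_cov_names"]),
            beta_zeta=np.array(doc["beta_zeta"]).reshape(-1, 3),
        )


def _draw(rng, rng_tuple, size=None):
    lo, hi = rng_tuple
    return rng.uniform(lo, hi, size=size)


def make_truth(config: SyntheticConfig | None = None, seed: int = 0) -> TruthBundle:
    """Draw a complete ground truth from the configured ranges."""
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    S = len(config.sites)
    T = config.n_years
    years = np.arange(config.start_year, config.start_year + T)

    phi_mean = np.empty((2, 2, S))
    phi_mean[:, 0, :] = _draw(rng, config.phi_juv_range, (2, S))
    phi_mean[:, 1, :] = _draw(rng, config.phi_ad_range, (2, S))
    sig_phi = _draw(rng, config.sigma_phi_range, (2, 2, S))
    p_mean = np.empty((2, 2, S))
    p_mean[:, 0, :] = _draw(rng, config.p_juv_range, (2, S))
    p_mean[:, 1, :] = _draw(rng, config.p_ad_range, (2, S))
    sig_p = _draw(rng, config.sigma_p_range, (2, 2, S))
    kappa_mean = _draw(rng, config.kappa_range, (3, S))
    sig_kappa = _draw(rng, config.sigma_kappa_range, (3, S))
    zeta_mean = _draw(rng, config.zeta_range, (3, S))
    sds = _draw(rng, config.zeta_sd_range, 3)
    rho = _draw(rng, config.zeta_corr_range)
    corr = np.full((3, 3), rho)
    np.fill_diagonal(corr, 1.0)
    zeta_cov = corr * np.outer(sds, sds)
    omega = np.stack(
        [_draw(rng, config.omega_f_range, S), _draw(rng, config.omega_m_range, S)]
    )
    tau = _draw(rng, config.tau_range, S)
    n0 = np.empty((2, 3, S), dtype=int)
    for ji in range(2):
        n0[ji, 0] = rng.integers(config.n0_rec_range[0], config.n0_rec_range[1] + 1, S)
        n0[ji, 1] = rng.integers(config.n0_ad_range[0], config.n0_ad_range[1] + 1, S)
        n0[ji, 2] = rng.integers(config.n0_im_range[0], config.n0_im_range[1] + 1, S)

    covs: dict[str, np.ndarray] = {}
    for name in config.covariate_names:
        x = rng.standard_normal(T)
        covs[name] = (x - x.mean()) / x.std(ddof=1)  # exactly standardized
    if config.mast_covariate:
        mast = (rng.random(T) < config.mast_prob).astype(float)
        covs["mast"] = mast
        covs["mast_lag"] = np.concatenate([[0.0], mast[:-1]])

    phi_cov_names = tuple(sorted({c for (c, _a) in config.beta_phi}))
    beta_phi = np.zeros((len(phi_cov_names), 2))
    for (c, a), v in config.beta_phi.items():
        beta_phi[phi_cov_names.index(c), ("juv", "ad").index(a)] = v
    zeta_cov_names = tuple(sorted({c for (c, _a) in config.beta_zeta}))
    beta_zeta = np.zeros((len(zeta_cov_names), 3))
    for (c, a), v in config.beta_zeta.items():
        beta_zeta[zeta_cov_names.index(c), FECUNDITY_STAGES.index(a)] = v
    for c in (*phi_cov_names, *zeta_cov_names):
        if c not in covs:
            raise ConfigurationError(f"planted effect on unknown covariate {c!r}")

    truth = TruthBundle(
        config=config,
        sites=tuple(config.sites),
        years=years,
        phi_mean=phi_mean,
        sig_phi=sig_phi,
        p_mean=p_mean,
        sig_p=sig_p,
        kappa_mean=kappa_mean,
        sig_kappa=sig_kappa,
        zeta_mean=zeta_mean,
        zeta_cov=zeta_cov,
        omega=omega,
        tau=tau,
        n0=n0,
        covariates=covs,
        phi_cov_names=phi_cov_names,
        beta_phi=beta_phi,
        zeta_cov_names=zeta_cov_names,
        beta_zeta=beta_zeta,
    )
    truth.validate()
    return truth


# ---------------------------------------------------------------------------
# realized annual rates
# ---------------------------------------------------------------------------


def realized_rates(truth: TruthBundle, rng) -> tuple:
    """Draw year effects and return (phi, p, kappa, zeta) realized series."""
    S, T = truth.n_sites, truth.n_years
    x_phi = np.array([truth.covariates[c][: T - 1] for c in truth.phi_cov_names])
    x_zeta = np.array([truth.covariates[c] for c in truth.zeta_cov_names])

    eta_phi = logit(truth.phi_mean)[..., None] + rng.normal(
        0.0, truth.sig_phi[..., None], (2, 2, S, T - 1)
    )
    if len(truth.phi_cov_names):
        eta_phi = eta_phi + np.einsum("ka,kt->at", truth.beta_phi, x_phi)[None, :, None, :]
    phi = 1.0 / (1.0 + np.exp(-eta_phi))

    eta_p = logit(truth.p_mean)[..., None] + rng.normal(
        0.0, truth.sig_p[..., None], (2, 2, S, T - 1)
    )
    p = 1.0 / (1.0 + np.exp(-eta_p))

    kappa = np.exp(
        np.log(truth.kappa_mean)[..., None]
        + rng.normal(0.0, truth.sig_kappa[..., None], (3, S, T))
    )

    L = np.linalg.cholesky(truth.zeta_cov + 1e-12 * np.eye(3))
    eps_zeta = np.einsum("ab,bst->ast", L, rng.standard_normal((3, S, T)))
    eta_zeta = logit(truth.zeta_mean)[..., None] + eps_zeta
    if len(truth.zeta_cov_names):
        eta_zeta = eta_zeta + np.einsum("ka,kt->at", truth.beta_zeta, x_zeta)[:, None, :]
    zeta = 1.0 / (1.0 + np.exp(-eta_zeta))
    return phi, p, kappa, zeta


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    """The four observed streams plus the (filled-in) generating truth."""

    captures: CaptureTable
    nests: NestAggregate
    counts: CountSeries
    covariates: dict  # name -> CovariateSeries
    truth: TruthBundle

    @property
    def extinct(self) -> bool:
        return self.truth.extinct

    def write(self, outdir) -> dict:
        """Write the streams as CSV (plus the truth as YAML); returns paths."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "captures": outdir / "captures.csv",
            "fecundity": outdir / "fecundity.csv",
            "counts": outdir / "counts.csv",
            "covariates": outdir / "covariates.csv",
            "truth": outdir / "truth.yaml",
        }
        self.captures.write_csv(paths["captures"])
        self.nests.write_csv(paths["fecundity"])
        self.counts.write_csv(paths["counts"])
        import pandas as pd

        rows = []
        for name, series in self.covariates.items():
            for y, v in zip(series.years.tolist(), series.values.tolist()):
                rows.append({"year": y, "name": name, "value": v})
        pd.DataFrame(rows).to_csv(paths["covariates"], index=False)
        self.truth.to_yaml(paths["truth"])
        return paths


def _simulate_bird(rng, det, first, age1_interval, phi_juv_first, phi_ad, p_age1, p_ad, T):
    """Detection history of one marked bird from its marking year on.

    ``age1_interval`` is the interval index over which the bird is one year
    old at the far end (None if marked at age >= 2); survival over that
    interval is ``phi_juv_first`` for juvenile-marked birds.
    """
    det[first] = 1
    t = first
    while t < T - 1:
        surv = phi_juv_first if (phi_juv_first is not None and t == first) else phi_ad[t]
        if rng.random() >= surv:
            return
        t += 1
        p_occ = p_age1[t - 1] if (age1_interval is not None and t - 1 == age1_interval) else p_ad[t - 1]
        if rng.random() < p_occ:
            det[t] = 1


def simulate_dataset(truth: TruthBundle, seed: int = 0) -> SimulatedDataset:
    """Simulate latent dynamics and all four observed data streams."""
    rng = np.random.default_rng(seed)
    S, T = truth.n_sites, truth.n_years
    phi, p, kappa, zeta = realized_rates(truth, rng)

    # latent abundances, Eqs of the stage-structured process
    N = np.zeros((2, 3, S, T))
    N[:, :, :, 0] = truth.n0
    for t in range(T - 1):
        N[:, :, :, t + 1] = project_population(
            N[:, :, :, t], phi[:, :, :, t], kappa[:, :, t], zeta[:, :, t],
            truth.omega, mode="stochastic", rng=rng,
        )
    totals = N.sum(axis=1)  # (2, S, T)
    extinct = bool((totals.sum(axis=0) == 0).any())
    if extinct:
        warnings.warn("population extinct mid-series; structural zeros emitted", stacklevel=2)

    # counts: lognormal around latent totals, rounded, support >= 1
    y = np.full((2, S, T), np.nan)
    obs = np.zeros((2, S, T), dtype=bool)
    for ji in range(2):
        for si in range(S):
            for t in range(T):
                n_tot = totals[ji, si, t]
                if n_tot > 0:
                    draw = np.exp(rng.normal(np.log(n_tot), truth.tau[si]))
                    y[ji, si, t] = max(1.0, np.round(draw))
                    obs[ji, si, t] = True
    counts = CountSeries(sites=truth.sites, years=truth.years, y=y, observed=obs)

    # productivity totals: broods = breeding females per stage
    b = N[0].astype(int)  # (3, S, T)
    c = rng.poisson(kappa * b)
    c[b == 0] = 0
    f = rng.binomial(c, zeta)
    nests = NestAggregate(sites=truth.sites, years=truth.years, b=b, c=c, f=f)

    # capture histories, individual-based and CJS-consistent
    ids, sexes_col, sites_col, first_years, stages, rows = [], [], [], [], [], []

    def add_bird(j, si, first, stage_label, age1_interval, phi_juv_first):
        det = np.zeros(T, dtype=np.int64)
        _simulate_bird(
            rng, det, first, age1_interval, phi_juv_first,
            phi[SEXES.index(j), 1, si], p[SEXES.index(j), 0, si], p[SEXES.index(j), 1, si], T,
        )
        ids.append(f"{truth.sites[si]}-{j}-{len(ids):05d}")
        sexes_col.append(j)
        sites_col.append(truth.sites[si])
        first_years.append(int(truth.years[first]))
        stages.append(stage_label)
        rows.append(det)

    for si in range(S):
        fledge_pool = (N[0, :, si, :] * kappa[:, si, :] * zeta[:, si, :]).sum(axis=0)  # per year
        for ji, j in enumerate(SEXES):
            # ringed nestlings (juvenile releases), fledging year t
            for t in range(T):
                n_marked = rng.poisson(0.5 * fledge_pool[t])
                for _ in range(n_marked):
                    if t >= T - 1:
                        # marked at the last occasion: history is just the mark
                        add_bird(j, si, t, "juv", None, None)
                    else:
                        add_bird(j, si, t, "juv", t, phi[ji, 0, si, t])
            # immigrants: age 1 on arrival, first capture = first detection
            for t in range(T):
                n_arrive = truth.n0[ji, 2, si] if t == 0 else rng.poisson(truth.omega[ji, si])
                for _ in range(n_arrive):
                    det = np.zeros(T, dtype=np.int64)
                    p_first = (
                        truth.p_mean[ji, 0, si] if t == 0 else p[ji, 0, si, t - 1]
                    )
                    if rng.random() < p_first:
                        det[t] = 1
                        first = t
                    else:
                        first = None
                    tt = t
                    alive = True
                    while alive and tt < T - 1:
                        alive = rng.random() < phi[ji, 1, si, tt]
                        if not alive:
                            break
                        tt += 1
                        if rng.random() < p[ji, 1, si, tt - 1]:
                            det[tt] = 1
                            if first is None:
                                first = tt
                    if first is not None:
                        det[:first] = 0
                        ids.append(f"{truth.sites[si]}-{j}-{len(ids):05d}")
                        sexes_col.append(j)
                        sites_col.append(truth.sites[si])
                        first_years.append(int(truth.years[first]))
                        stages.append("ad")
                        rows.append(det)
            # initial resident adults (unmarked at study start, age >= 2)
            for _ in range(int(truth.n0[ji, 1, si])):
                det = np.zeros(T, dtype=np.int64)
                first = None
                if rng.random() < truth.p_mean[ji, 1, si]:
                    det[0] = 1
                    first = 0
                tt = 0
                while tt < T - 1:
                    if rng.random() >= phi[ji, 1, si, tt]:
                        break
                    tt += 1
                    if rng.random() < p[ji, 1, si, tt - 1]:
                        det[tt] = 1
                        if first is None:
                            first = tt
                if first is not None:
                    det[:first] = 0
                    ids.append(f"{truth.sites[si]}-{j}-{len(ids):05d}")
                    sexes_col.append(j)
                    sites_col.append(truth.sites[si])
                    first_years.append(int(truth.years[first]))
                    stages.append("ad")
                    rows.append(det)

    captures = CaptureTable(
        ids=np.array(ids, dtype=object),
        sex=np.array(sexes_col, dtype=object),
        site=np.array(sites_col, dtype=object),
        first_year=np.array(first_years, dtype=int),
        stage=np.array(stages, dtype=object),
        years=truth.years,
        detections=np.vstack(rows) if rows else np.zeros((0, T), dtype=np.int64),
    )

    cov_series = {
        name: CovariateSeries(
            name=name, years=truth.years.copy(), values=np.asarray(vals, float).copy(),
            standardized=not name.startswith("mast"),
        )
        for name, vals in truth.covariates.items()
    }

    truth.N = N
    truth.phi_real = phi
    truth.p_real = p
    truth.kappa_real = kappa
    truth.zeta_real = zeta
    truth.extinct = extinct
    return SimulatedDataset(
        captures=captures, nests=nests, counts=counts, covariates=cov_series, truth=truth
    )


# ---------------------------------------------------------------------------
# deterministic expectation
# ---------------------------------------------------------------------------


@dataclass
class ExpectedTrajectory:
    EN: np.ndarray        # (2, 3, S, T)
    lam: np.ndarray       # (S, T-1) female growth rates, NaN where undefined


def expected_trajectory(truth: TruthBundle) -> ExpectedTrajectory:
    """Replace every stochastic draw by its mean (rates at their means).

    Female growth rates are ratios of successive expected female totals;
    a zero female total makes the following ratio undefined (NaN, with a
    warning).
    """
    S, T = truth.n_sites, truth.n_years
    EN = np.zeros((2, 3, S, T))
    EN[:, :, :, 0] = truth.n0
    phi = np.repeat(truth.phi_mean[..., None], T - 1, axis=3)
    kappa = np.repeat(truth.kappa_mean[..., None], T, axis=2)
    zeta = np.repeat(truth.zeta_mean[..., None], T, axis=2)
    for t in range(T - 1):
        EN[:, :, :, t + 1] = project_population(
            EN[:, :, :, t], phi[:, :, :, t], kappa[:, :, t], zeta[:, :, t],
            truth.omega, mode="expectation",
        )
    females = EN[0].sum(axis=0)  # (S, T)
    lam = np.full((S, T - 1), np.nan)
    nonzero = females[:, :-1] > 0
    lam[nonzero] = females[:, 1:][nonzero] / females[:, :-1][nonzero]
    if (~nonzero).any():
        warnings.warn("zero expected female abundance: growth rate undefined", stacklevel=2)
    return ExpectedTrajectory(EN=EN, lam=lam)
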