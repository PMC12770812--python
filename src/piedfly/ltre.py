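"""Transient life-table response experiment on the fitted model.

Realized annual growth rates are ratios of successive latent female
totals.  For each posterior draw, analytical sensitivities of the annual
growth rate to each demographic component are evaluated at that year's
realized states and rates; first-order contribution series
``c_x,t = s_bar_x (x_t - x_bar)`` are regressed against the realized
growth rate (share = Cov(c_x, lambda) / Var(lambda)); and each rate's
share is split into per-covariate parts (chain rule on the link scale)
plus an unexplained residual.  The split is exact bookkeeping: covariate
parts use the linearized effect of the fitted slopes, the residual is the
remainder of the component's contribution.

Components, in fixed order: juvenile and adult female apparent survival,
clutch size and fledging probability per female stage class (recruit,
adult, immigrant), and the realized immigrant inflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .inference import PosteriorDraws

COMPONENTS = (
    "phi_juv",
    "phi_ad",
    "kappa_rec",
    "kappa_ad",
    "kappa_im",
    "zeta_rec",
    "zeta_ad",
    "zeta_im",
    "immigration",
)
#: components entering the normalized sensitivity table (demographic rates only)
DEMOGRAPHIC = COMPONENTS[:-1]


def realized_lambda(draws: PosteriorDraws) -> np.ndarray:
    """Annual growth rates of the female population, per draw and site.

    Returns (n_draws, S, T-1) with ``lambda[s, t] = N_f[s, t+1] / N_f[s, t]``
    computed from the stored latent states.
    """
    N = draws.stacked("N")  # (D, 2, 3, S, T)
    tot = N[:, 0].sum(axis=1)  # (D, S, T)
    if np.any(tot[:, :, :-1] <= 0):
        raise ValueError("zero female abundance: growth rate undefined")
    return tot[:, :, 1:] / tot[:, :, :-1]


def geometric_mean_lambda(lam: np.ndarray) -> np.ndarray:
    return np.exp(np.log(lam).mean(axis=-1))


def sensitivities(n_f, phi_juv, kappa, zeta):
    """Analytical sensitivities of the one-step growth rate.

    ``n_f`` has the stage axis (rec, ad, im) first and year last; rates
    are aligned arrays.  From
    ``lambda_t = [0.5 phi_juv sum_a N_a kappa_a zeta_a + phi_ad N_tot + I]/N_tot``:

    * d lambda / d phi_juv = 0.5 sum_a N_a kappa_a zeta_a / N_tot
    * d lambda / d phi_ad  = 1
    * d lambda / d kappa_a = 0.5 phi_juv N_a zeta_a / N_tot
    * d lambda / d zeta_a  = 0.5 phi_juv N_a kappa_a / N_tot
    * d lambda / d I       = 1 / N_tot
    """
    n_f = np.asarray(n_f, float)
    tot = n_f.sum(axis=-2)
    if np.any(tot <= 0):
        raise ValueError("zero total abundance: sensitivities undefined")
    pool = (n_f * kappa * zeta).sum(axis=-2)
    out = {
        "phi_juv": 0.5 * pool / tot,
        "phi_ad": np.ones_like(tot),
        "immigration": 1.0 / tot,
    }
    pj = np.asarray(phi_juv, float)
    for ai, stage in enumerate(("rec", "ad", "im")):
        out[f"kappa_{stage}"] = 0.5 * pj * n_f[..., ai, :] * zeta[..., ai, :] / tot
        out[f"zeta_{stage}"] = 0.5 * pj * n_f[..., ai, :] * kappa[..., ai, :] / tot
    return out


def normalize_sensitivities(values: np.ndarray) -> np.ndarray:
    """Scale a non-negative vector to sum to one (last axis)."""
    values = np.asarray(values, float)
    tot = values.sum(axis=-1, keepdims=True)
    if np.any(tot == 0):
        raise ValueError("cannot normalize an all-zero sensitivity vector")
    return values / tot


def _cov(a, b):
    # population covariance along the last (time) axis
    return ((a - a.mean(-1, keepdims=True)) * (b - b.mean(-1, keepdims=True))).mean(-1)


@dataclass
class LTREResult:
    sites: tuple
    components: tuple
    lam: np.ndarray            # (D, S, T-1)
    lam_geo: np.ndarray        # (D, S)
    sens_mean: np.ndarray      # (D, n_comp, S) time-averaged sensitivities
    shares: np.ndarray         # (D, n_comp, S) contribution shares of Var(lambda)
    cov_shares: dict = field(default_factory=dict)    # (component, covariate) -> (D, S)
    resid_shares: np.ndarray | None = None            # (D, n_comp, S)

    def share_table(self) -> pd.DataFrame:
        rows = []
        for ci, comp in enumerate(self.components):
            for si, s in enumerate(self.sites):
                x = self.shares[:, ci, si]
                rows.append(
                    {
                        "site": s,
                        "component": comp,
                        "share_mean": x.mean(),
                        "share_lo95": np.percentile(x, 2.5),
                        "share_hi95": np.percentile(x, 97.5),
                        "residual_share_mean": self.resid_shares[:, ci, si].mean()
                        if self.resid_shares is not None
                        else x.mean(),
                    }
                )
        return pd.DataFrame(rows)

    def covariate_table(self) -> pd.DataFrame:
        rows = []
        for (comp, cov), arr in self.cov_shares.items():
            for si, s in enumerate(self.sites):
                x = arr[:, si]
                rows.append(
                    {
                        "site": s,
                        "component": comp,
                        "covariate": cov,
                        "share_mean": x.mean(),
                        "share_lo95": np.percentile(x, 2.5),
                        "share_hi95": np.percentile(x, 97.5),
                    }
                )
        return pd.DataFrame(rows)

    def sensitivity_table(self) -> pd.DataFrame:
        """Time-averaged sensitivities normalized over the demographic rates."""
        idx = [self.components.index(c) for c in DEMOGRAPHIC]
        sub = self.sens_mean[:, idx, :]  # (D, 8, S)
        norm = sub / sub.sum(axis=1, keepdims=True)
        rows = []
        for ci, comp in enumerate(DEMOGRAPHIC):
            for si, s in enumerate(self.sites):
                x = norm[:, ci, si]
                rows.append(
                    {
                        "site": s,
                        "component": comp,
                        "sensitivity_mean": x.mean(),
                        "sensitivity_lo95": np.percentile(x, 2.5),
                        "sensitivity_hi95": np.percentile(x, 97.5),
                    }
                )
        return pd.DataFrame(rows)

    def headline_split(self) -> pd.DataFrame:
        """Survival vs fecundity shares, renormalized to sum to 100%.

        Posterior-mean shares are renormalized (rather than per-draw
        ratios, which are unstable when a draw's summed share is near
        zero).  A slightly negative fecundity share — possible in a
        covariance decomposition — shows up as a value above 100%.
        """
        surv = self.shares[:, 0:2, :].sum(axis=1).mean(axis=0)  # (S,)
        fec = self.shares[:, 2:8, :].sum(axis=1).mean(axis=0)
        rows = []
        for si, s in enumerate(self.sites):
            tot = surv[si] + fec[si]
            rows.append(
                {
                    "site": s,
                    "survival_pct": float(100 * surv[si] / tot),
                    "fecundity_pct": float(100 * fec[si] / tot),
                }
            )
        return pd.DataFrame(rows)


def decompose(draws: PosteriorDraws, covariates: dict | None = None) -> LTREResult:
    """Variance decomposition of the realized growth rate, per posterior draw.

    ``covariates`` maps covariate names to their (T,) annual values; it is
    required when the fitted model carried covariates (for the per-covariate
    partition) and ignored otherwise.  The result is deterministic in the
    draws.
    """
    meta = draws.meta
    sites = tuple(meta.get("sites", ()))
    N = draws.stacked("N")          # (D, 2, 3, S, T)
    phi = draws.stacked("phi")      # (D, 2, 2, S, T-1)
    kap = draws.stacked("kappa")    # (D, 3, S, T)
    zet = draws.stacked("zeta")
    D, _, _, S, T = N.shape
    Tm1 = T - 1
    if not sites:
        sites = tuple(f"site_{i}" for i in range(S))

    lam = realized_lambda(draws)    # (D, S, Tm1)
    lam_geo = geometric_mean_lambda(lam)

    # stage axis second-to-last, year last: (D, S, 3, Tm1)
    n_f = np.moveaxis(N[:, 0, :, :, :Tm1], 1, 2)
    kap_t = np.moveaxis(kap[:, :, :, :Tm1], 1, 2)
    zet_t = np.moveaxis(zet[:, :, :, :Tm1], 1, 2)
    phi_juv = phi[:, 0, 0, :, :]    # (D, S, Tm1)
    phi_ad = phi[:, 0, 1, :, :]
    inflow = N[:, 0, 2, :, 1:]      # (D, S, Tm1) realized immigrant arrivals

    sens = sensitivities(n_f, phi_juv, kap_t, zet_t)

    series = {
        "phi_juv": phi_juv,
        "phi_ad": phi_ad,
        "kappa_rec": kap_t[:, :, 0],
        "kappa_ad": kap_t[:, :, 1],
        "kappa_im": kap_t[:, :, 2],
        "zeta_rec": zet_t[:, :, 0],
        "zeta_ad": zet_t[:, :, 1],
        "zeta_im": zet_t[:, :, 2],
        "immigration": inflow,
    }

    var_lam = _cov(lam, lam)  # (D, S)
    var_lam = np.where(var_lam > 0, var_lam, np.nan)

    sens_mean = np.empty((D, len(COMPONENTS), S))
    shares = np.empty((D, len(COMPONENTS), S))
    contrib = {}
    for ci, comp in enumerate(COMPONENTS):
        sbar = sens[comp].mean(axis=-1, keepdims=True)  # (D, S, 1)
        sens_mean[:, ci, :] = sbar[..., 0]
        x = series[comp]
        c_x = sbar * (x - x.mean(axis=-1, keepdims=True))
        contrib[comp] = (sbar, c_x)
        shares[:, ci, :] = _cov(c_x, lam) / var_lam

    # per-covariate partition via the link-scale chain rule
    cov_shares: dict = {}
    resid_shares = shares.copy()

    def _split(comp, rate_series, beta_draws, names):
        ci = COMPONENTS.index(comp)
        eta = logit(np.clip(rate_series, 1e-12, 1 - 1e-12))
        eta_bar = eta.mean(axis=-1, keepdims=True)
        deriv = expit(eta_bar) * (1.0 - expit(eta_bar))  # (D, S, 1)
        sbar = contrib[comp][0]
        for k, name in enumerate(names):
            xk = np.asarray(covariates[name], float)[:Tm1]
            xk = xk[None, None, :] - xk.mean()
            part = sbar * deriv * beta_draws[:, k][:, None, None] * xk
            share_k = _cov(part, lam) / var_lam
            cov_shares[(comp, name)] = share_k
            resid_shares[:, ci, :] = resid_shares[:, ci, :] - share_k

    surv_names = tuple(meta.get("survival_covariates", ()))
    fled_names = tuple(meta.get("fledging_covariates", ()))
    if surv_names:
        if covariates is None:
            raise ValueError("covariate values required for the per-covariate partition")
        beta = draws.stacked("beta_phi")  # (D, ncp, 2)
        _split("phi_juv", phi_juv, beta[:, :, 0], surv_names)
        _split("phi_ad", phi_ad, beta[:, :, 1], surv_names)
    if fled_names:
        if covariates is None:
            raise ValueError("covariate values required for the per-covariate partition")
        beta = draws.stacked("beta_zeta")  # (D, ncz, 3)
        for ai, stage in enumerate(("rec", "ad", "im")):
            _split(f"zeta_{stage}", zet_t[:, :, ai], beta[:, :, ai], fled_names)

    return LTREResult(
        sites=sites,
        components=COMPONENTS,
        lam=lam,
        lam_geo=lam_geo,
        sens_mean=sens_mean,
        shares=shares,
        cov_shares=cov_shares,
        resid_shares=resid_shares,
    )
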