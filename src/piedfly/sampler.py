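"""Adaptive Metropolis-within-Gibbs kernels for the joint model.

Single-site random-walk updates with per-parameter step sizes adapted
during burn-in (Robbins-Monro toward 0.44 acceptance).  Latent abundances
are sampled as continuous quantities under gamma-function extensions of
the Poisson/binomial process densities, which keeps every conditional
density well defined without integer-state proposals.

Each update recomputes only the likelihood pieces its parameter touches:

* juvenile survival / juvenile recapture year effects touch a single row
  of the juvenile-release m-array and one process term;
* adult survival / recapture parameters touch the full m-array pair of
  their sex and site;
* clutch, fledging and latent-state updates touch a handful of local
  Poisson/binomial terms plus (for females) the recruit terms they feed.

The layout of every array follows the package conventions: sexes (f, m),
survival stages (juv, ad), fecundity stages (rec, ad, im), years 0..T-1
with intervals indexed by their left year.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

LOG2PI = math.log(2.0 * math.pi)
NEG = -1.0e300


# ---------------------------------------------------------------------------
# scalar log-densities
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _pois(x, mu):
    if mu <= 0.0:
        return 0.0 if x == 0.0 else NEG
    if x < 0.0:
        return NEG
    return x * math.log(mu) - mu - math.lgamma(x + 1.0)


@njit(cache=True, inline="always")
def _binom(k, n, p):
    if k < 0.0 or k > n:
        return NEG
    if p <= 0.0:
        return 0.0 if k == 0.0 else NEG
    if p >= 1.0:
        return 0.0 if k == n else NEG
    return (
        math.lgamma(n + 1.0)
        - math.lgamma(k + 1.0)
        - math.lgamma(n - k + 1.0)
        + k * math.log(p)
        + (n - k) * math.log1p(-p)
    )


@njit(cache=True, inline="always")
def _norm(x, mu, sd):
    r = (x - mu) / sd
    return -0.5 * LOG2PI - math.log(sd) - 0.5 * r * r


@njit(cache=True, inline="always")
def _sigmoid(x):
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


# ---------------------------------------------------------------------------
# m-array likelihood pieces
# ---------------------------------------------------------------------------


@njit(cache=True)
def _marr_row(M, phi, p, j, s, i, is_juv):
    """Log-likelihood of row i of one m-array (release occasion i)."""
    Tm1 = phi.shape[3]
    R = 0.0
    for col in range(Tm1 + 1):
        R += M[j, s, i, col]
    if R == 0.0:
        return 0.0
    ll = 0.0
    cum = phi[j, 0, s, i] if is_juv else phi[j, 1, s, i]
    psum = 0.0
    for t in range(i, Tm1):
        pt = p[j, 0, s, t] if (is_juv and t == i) else p[j, 1, s, t]
        pr = cum * pt
        m = M[j, s, i, t]
        if m > 0:
            if pr <= 0.0:
                return NEG
            ll += m * math.log(pr)
        psum += pr
        if t + 1 < Tm1:
            cum *= (1.0 - pt) * phi[j, 1, s, t + 1]
    pnev = 1.0 - psum
    m = M[j, s, i, Tm1]
    if m > 0:
        if pnev <= 0.0:
            return NEG
        ll += m * math.log(pnev)
    return ll


@njit(cache=True)
def _marr_one(M, phi, p, j, s, is_juv):
    Tm1 = phi.shape[3]
    ll = 0.0
    for i in range(Tm1):
        v = _marr_row(M, phi, p, j, s, i, is_juv)
        if v <= NEG:
            return NEG
        ll += v
    return ll


@njit(cache=True)
def _marr_pair(Mj, Ma, phi, p, j, s):
    a = _marr_one(Mj, phi, p, j, s, True)
    if a <= NEG:
        return NEG
    b = _marr_one(Ma, phi, p, j, s, False)
    if b <= NEG:
        return NEG
    return a + b


# ---------------------------------------------------------------------------
# process, count, productivity pieces
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _pool(N, kap, zet, s, t):
    out = 0.0
    for a in range(3):
        out += N[0, a, s, t] * kap[a, s, t] * zet[a, s, t]
    return out


@njit(cache=True, inline="always")
def _rec_term(N, phi, kap, zet, j, s, t):
    """Poisson recruit term for transition t -> t+1 of sex j, site s."""
    return _pois(N[j, 0, s, t + 1], 0.5 * phi[j, 0, s, t] * _pool(N, kap, zet, s, t))


@njit(cache=True, inline="always")
def _ad_term(N, phi, j, s, t):
    ntot = N[j, 0, s, t] + N[j, 1, s, t] + N[j, 2, s, t]
    return _binom(N[j, 1, s, t + 1], ntot, phi[j, 1, s, t])


@njit(cache=True)
def _im_terms(N, lomega, j, s):
    om = math.exp(lomega[j, s])
    T = N.shape[3]
    ll = 0.0
    for t in range(T - 1):
        ll += _pois(N[j, 2, s, t + 1], om)
    return ll


@njit(cache=True)
def _proc_sex_site(N, phi, kap, zet, lomega, j, s):
    T = N.shape[3]
    ll = _im_terms(N, lomega, j, s)
    for t in range(T - 1):
        ll += _rec_term(N, phi, kap, zet, j, s, t)
        ll += _ad_term(N, phi, j, s, t)
    return ll


@njit(cache=True)
def _rec_terms_site(N, phi, kap, zet, s):
    T = N.shape[3]
    ll = 0.0
    for j in range(2):
        for t in range(T - 1):
            ll += _rec_term(N, phi, kap, zet, j, s, t)
    return ll


@njit(cache=True, inline="always")
def _count_term(ylog, yobs, N, tau, j, s, t):
    if yobs[j, s, t] == 0.0:
        return 0.0
    ntot = N[j, 0, s, t] + N[j, 1, s, t] + N[j, 2, s, t]
    if ntot <= 0.0:
        return NEG
    r = ylog[j, s, t] - math.log(ntot)
    return -ylog[j, s, t] - math.log(tau[s]) - 0.5 * LOG2PI - 0.5 * (r / tau[s]) ** 2


@njit(cache=True)
def _count_sex_site(ylog, yobs, N, tau, j, s):
    T = N.shape[3]
    ll = 0.0
    for t in range(T):
        v = _count_term(ylog, yobs, N, tau, j, s, t)
        if v <= NEG:
            return NEG
        ll += v
    return ll


@njit(cache=True)
def _clutch_stage_site(bb, cc, kap, a, s):
    T = kap.shape[2]
    ll = 0.0
    for t in range(T):
        if bb[a, s, t] > 0.0:
            ll += _pois(cc[a, s, t], kap[a, s, t] * bb[a, s, t])
    return ll


@njit(cache=True)
def _fledge_stage_site(cc, ff, zet, a, s):
    T = zet.shape[2]
    ll = 0.0
    for t in range(T):
        if cc[a, s, t] > 0.0:
            ll += _binom(ff[a, s, t], cc[a, s, t], zet[a, s, t])
    return ll


# ---------------------------------------------------------------------------
# derived-rate maintenance
# ---------------------------------------------------------------------------


@njit(cache=True)
def _set_phi_row(phi, mu_phi, eps_phi, beff, j, a, s):
    Tm1 = phi.shape[3]
    for t in range(Tm1):
        phi[j, a, s, t] = _sigmoid(mu_phi[j, a, s] + beff[a, t] + eps_phi[j, a, s, t])


@njit(cache=True)
def _set_p_row(p, mu_p, eps_p, j, a, s):
    Tm1 = p.shape[3]
    for t in range(Tm1):
        p[j, a, s, t] = _sigmoid(mu_p[j, a, s] + eps_p[j, a, s, t])


@njit(cache=True)
def _set_kap_row(kap, mu_kap, eps_kap, a, s):
    T = kap.shape[2]
    for t in range(T):
        kap[a, s, t] = math.exp(mu_kap[a, s] + eps_kap[a, s, t])


@njit(cache=True, inline="always")
def _zeta_effect(lam3, dsc, u, a, s, t):
    # unit-lower-triangular factor rows: (1,0,0), (l21,1,0), (l31,l32,1)
    if a == 0:
        core = u[0, s, t]
    elif a == 1:
        core = lam3[0] * u[0, s, t] + u[1, s, t]
    else:
        core = lam3[1] * u[0, s, t] + lam3[2] * u[1, s, t] + u[2, s, t]
    return dsc[a] * core


@njit(cache=True)
def _set_zeta_cell(zet, mu_zet, beffz, lam3, dsc, u, a, s, t):
    zet[a, s, t] = _sigmoid(mu_zet[a, s] + beffz[a, t] + _zeta_effect(lam3, dsc, u, a, s, t))


@njit(cache=True)
def _set_zeta_all(zet, mu_zet, beffz, lam3, dsc, u):
    A, S, T = zet.shape
    for a in range(A):
        for s in range(S):
            for t in range(T):
                _set_zeta_cell(zet, mu_zet, beffz, lam3, dsc, u, a, s, t)


@njit(cache=True)
def _set_beff_phi(beff, beta_phi, Xp):
    ncp = beta_phi.shape[0]
    Tm1 = beff.shape[1]
    for a in range(2):
        for t in range(Tm1):
            acc = 0.0
            for k in range(ncp):
                acc += beta_phi[k, a] * Xp[k, t]
            beff[a, t] = acc


@njit(cache=True)
def _set_beff_zeta(beffz, beta_zet, Xz):
    ncz = beta_zet.shape[0]
    T = beffz.shape[1]
    for a in range(3):
        for t in range(T):
            acc = 0.0
            for k in range(ncz):
                acc += beta_zet[k, a] * Xz[k, t]
            beffz[a, t] = acc


# ---------------------------------------------------------------------------
# priors and total
# ---------------------------------------------------------------------------


@njit(cache=True)
def _prior_total(
    mu_phi, sig_phi, eps_phi, beta_phi,
    mu_p, sig_p, eps_p,
    mu_kap, sig_kap, eps_kap,
    mu_zet, beta_zet, lam3, dsc, u,
    lomega, tau, N, n0up,
    mu_sd, kmu_m, kmu_sd, sig_up, tau_up, beta_sd, lom_sd, exp_sd, fac_sd,
):
    S = mu_phi.shape[2]
    Tm1 = eps_phi.shape[3]
    T = eps_kap.shape[2]
    lp = 0.0
    for j in range(2):
        for a in range(2):
            for s in range(S):
                lp += _norm(mu_phi[j, a, s], 0.0, mu_sd)
                lp += _norm(mu_p[j, a, s], 0.0, mu_sd)
                if sig_phi[j, a, s] <= 0.0 or sig_phi[j, a, s] >= sig_up:
                    return NEG
                if sig_p[j, a, s] <= 0.0 or sig_p[j, a, s] >= sig_up:
                    return NEG
                lp += -2.0 * math.log(sig_up)
                for t in range(Tm1):
                    lp += _norm(eps_phi[j, a, s, t], 0.0, sig_phi[j, a, s])
                    lp += _norm(eps_p[j, a, s, t], 0.0, sig_p[j, a, s])
    for a in range(3):
        for s in range(S):
            lp += _norm(mu_kap[a, s], kmu_m, kmu_sd)
            lp += _norm(mu_zet[a, s], 0.0, mu_sd)
            if sig_kap[a, s] <= 0.0 or sig_kap[a, s] >= sig_up:
                return NEG
            lp += -math.log(sig_up)
            for t in range(T):
                lp += _norm(eps_kap[a, s, t], 0.0, sig_kap[a, s])
                lp += _norm(u[a, s, t], 0.0, 1.0)
    for k in range(beta_phi.shape[0]):
        for a in range(2):
            lp += _norm(beta_phi[k, a], 0.0, beta_sd)
    for k in range(beta_zet.shape[0]):
        for a in range(3):
            lp += _norm(beta_zet[k, a], 0.0, beta_sd)
    for i in range(3):
        if dsc[i] <= 0.0:
            return NEG
        lp += _norm(dsc[i], 0.0, exp_sd) + math.log(2.0)
        lp += _norm(lam3[i], 0.0, fac_sd)
    for j in range(2):
        for s in range(S):
            lp += _norm(lomega[j, s], 0.0, lom_sd)
    for s in range(S):
        if tau[s] <= 0.0 or tau[s] >= tau_up:
            return NEG
        lp += -math.log(tau_up)
    for j in range(2):
        for a in range(3):
            for s in range(S):
                if N[j, a, s, 0] < 0.0 or N[j, a, s, 0] > n0up[j, s]:
                    return NEG
                lp += -math.log(n0up[j, s])
    return lp


@njit(cache=True)
def _total_logp(
    Mj, Ma, bb, cc, ff, ylog, yobs, n0up,
    mu_phi, sig_phi, eps_phi, beta_phi,
    mu_p, sig_p, eps_p,
    mu_kap, sig_kap, eps_kap,
    mu_zet, beta_zet, lam3, dsc, u,
    lomega, tau, N,
    phi, p, kap, zet,
    mu_sd, kmu_m, kmu_sd, sig_up, tau_up, beta_sd, lom_sd, exp_sd, fac_sd,
):
    S = mu_phi.shape[2]
    lp = _prior_total(
        mu_phi, sig_phi, eps_phi, beta_phi, mu_p, sig_p, eps_p,
        mu_kap, sig_kap, eps_kap, mu_zet, beta_zet, lam3, dsc, u,
        lomega, tau, N, n0up,
        mu_sd, kmu_m, kmu_sd, sig_up, tau_up, beta_sd, lom_sd, exp_sd, fac_sd,
    )
    if lp <= NEG:
        return NEG
    for j in range(2):
        for s in range(S):
            v = _marr_pair(Mj, Ma, phi, p, j, s)
            if v <= NEG:
                return NEG
            lp += v
            lp += _proc_sex_site(N, phi, kap, zet, lomega, j, s)
            v = _count_sex_site(ylog, yobs, N, tau, j, s)
            if v <= NEG:
                return NEG
            lp += v
    for a in range(3):
        for s in range(S):
            lp += _clutch_stage_site(bb, cc, kap, a, s)
            lp += _fledge_stage_site(cc, ff, zet, a, s)
    return lp


# ---------------------------------------------------------------------------
# the chain
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _mh_accept(delta):
    if delta >= 0.0:
        return True
    if delta <= -700.0:
        return False
    return math.log(np.random.random() + 1e-300) < delta


@njit(cache=True, inline="always")
def _adapt(val, delta, gam):
    alpha = math.exp(delta) if delta < 0.0 else 1.0
    if alpha > 1.0:
        alpha = 1.0
    out = val * math.exp(gam * (alpha - 0.44))
    if out < 1e-4:
        out = 1e-4
    if out > 50.0:
        out = 50.0
    return out


@njit(cache=True)
def _local_N_terms(N, phi, kap, zet, lomega, ylog, yobs, tau, n0up, j, a, s, t):
    """All joint-density terms involving N[j, a, s, t]."""
    T = N.shape[3]
    ll = 0.0
    if t == 0:
        if N[j, a, s, 0] < 0.0 or N[j, a, s, 0] > n0up[j, s]:
            return NEG
    else:
        if a == 0:
            ll += _rec_term(N, phi, kap, zet, j, s, t - 1)
        elif a == 1:
            ll += _ad_term(N, phi, j, s, t - 1)
        else:
            ll += _pois(N[j, 2, s, t], math.exp(lomega[j, s]))
    if t < T - 1:
        if j == 0:
            ll += _rec_term(N, phi, kap, zet, 0, s, t)
            ll += _rec_term(N, phi, kap, zet, 1, s, t)
        ll += _ad_term(N, phi, j, s, t)
    v = _count_term(ylog, yobs, N, tau, j, s, t)
    if v <= NEG:
        return NEG
    return ll + v


@njit(cache=True)
def _local_year_terms(N, phi, kap, zet, lomega, ylog, yobs, tau, n0up, j, s, t):
    """All joint-density terms involving the year-t states of sex j, site s."""
    T = N.shape[3]
    ll = 0.0
    if t == 0:
        for a in range(3):
            if N[j, a, s, 0] < 0.0 or N[j, a, s, 0] > n0up[j, s]:
                return NEG
    else:
        ll += _rec_term(N, phi, kap, zet, j, s, t - 1)
        ll += _ad_term(N, phi, j, s, t - 1)
        ll += _pois(N[j, 2, s, t], math.exp(lomega[j, s]))
    if t < T - 1:
        if j == 0:
            ll += _rec_term(N, phi, kap, zet, 0, s, t)
            ll += _rec_term(N, phi, kap, zet, 1, s, t)
        ll += _ad_term(N, phi, j, s, t)
    v = _count_term(ylog, yobs, N, tau, j, s, t)
    if v <= NEG:
        return NEG
    return ll + v


@njit(cache=True)
def run_chain(
    # data
    Mj, Ma, bb, cc, ff, ylog, yobs, n0up, Xp, Xz,
    # state (modified in place)
    mu_phi, sig_phi, eps_phi, beta_phi,
    mu_p, sig_p, eps_p,
    mu_kap, sig_kap, eps_kap,
    mu_zet, beta_zet, lam3, dsc, u,
    lomega, tau, N,
    # priors
    mu_sd, kmu_m, kmu_sd, sig_up, tau_up, beta_sd, lom_sd, exp_sd, fac_sd,
    # mcmc
    n_iter, burn, thin, seed,
    # output (n_save, nflat)
    out,
):
    np.random.seed(seed)
    S = mu_phi.shape[2]
    Tm1 = eps_phi.shape[3]
    T = eps_kap.shape[2]
    ncp = beta_phi.shape[0]
    ncz = beta_zet.shape[0]

    # derived rates
    phi = np.empty((2, 2, S, Tm1))
    p = np.empty((2, 2, S, Tm1))
    kap = np.empty((3, S, T))
    zet = np.empty((3, S, T))
    beff = np.zeros((2, Tm1))
    beffz = np.zeros((3, T))
    _set_beff_phi(beff, beta_phi, Xp)
    _set_beff_zeta(beffz, beta_zet, Xz)
    for j in range(2):
        for a in range(2):
            for s in range(S):
                _set_phi_row(phi, mu_phi, eps_phi, beff, j, a, s)
                _set_p_row(p, mu_p, eps_p, j, a, s)
    for a in range(3):
        for s in range(S):
            _set_kap_row(kap, mu_kap, eps_kap, a, s)
    _set_zeta_all(zet, mu_zet, beffz, lam3, dsc, u)

    # step sizes
    st_mu_phi = np.full((2, 2, S), 0.15)
    st_sig_phi = np.full((2, 2, S), 0.15)
    st_eps_phi = np.full((2, 2, S, Tm1), 0.3)
    st_beta_phi = np.full((ncp, 2), 0.1)
    st_mu_p = np.full((2, 2, S), 0.15)
    st_sig_p = np.full((2, 2, S), 0.15)
    st_eps_p = np.full((2, 2, S, Tm1), 0.3)
    st_mu_kap = np.full((3, S), 0.05)
    st_sig_kap = np.full((3, S), 0.05)
    st_eps_kap = np.full((3, S, T), 0.1)
    st_mu_zet = np.full((3, S), 0.15)
    st_beta_zet = np.full((ncz, 3), 0.1)
    st_lam3 = np.full(3, 0.2)
    st_dsc = np.full(3, 0.15)
    st_u = np.full((3, S, T), 0.5)
    st_lom = np.full((2, S), 0.3)
    st_tau = np.full(S, 0.05)
    st_Nsc = np.full((2, S, T), 0.1)
    st_N = np.empty((2, 3, S, T))
    for j in range(2):
        for a in range(3):
            for s in range(S):
                for t in range(T):
                    v = 0.3 + 0.15 * N[j, a, s, t]
                    st_N[j, a, s, t] = v if v < 10.0 else 10.0

    n_save = out.shape[0]
    rec = 0

    for it in range(n_iter):
        gam = 3.0 / math.sqrt(it + 10.0)
        if gam > 0.25:
            gam = 0.25
        adapting = it < burn

        # --- survival & recapture -----------------------------------------
        for j in range(2):
            for s in range(S):
                # means
                for a in range(2):
                    old = mu_phi[j, a, s]
                    old_row = phi[j, a, s].copy()
                    if a == 0:
                        o_ll = _marr_one(Mj, phi, p, j, s, True)
                        o_pr = 0.0
                        for t in range(Tm1):
                            o_pr += _rec_term(N, phi, kap, zet, j, s, t)
                    else:
                        o_ll = _marr_pair(Mj, Ma, phi, p, j, s)
                        o_pr = 0.0
                        for t in range(Tm1):
                            o_pr += _ad_term(N, phi, j, s, t)
                    mu_phi[j, a, s] = old + st_mu_phi[j, a, s] * np.random.normal()
                    _set_phi_row(phi, mu_phi, eps_phi, beff, j, a, s)
                    if a == 0:
                        n_ll = _marr_one(Mj, phi, p, j, s, True)
                        n_pr = 0.0
                        for t in range(Tm1):
                            n_pr += _rec_term(N, phi, kap, zet, j, s, t)
                    else:
                        n_ll = _marr_pair(Mj, Ma, phi, p, j, s)
                        n_pr = 0.0
                        for t in range(Tm1):
                            n_pr += _ad_term(N, phi, j, s, t)
                    delta = (
                        n_ll + n_pr - o_ll - o_pr
                        + _norm(mu_phi[j, a, s], 0.0, mu_sd) - _norm(old, 0.0, mu_sd)
                    )
                    if not _mh_accept(delta):
                        mu_phi[j, a, s] = old
                        phi[j, a, s] = old_row
                    if adapting:
                        st_mu_phi[j, a, s] = _adapt(st_mu_phi[j, a, s], delta, gam)

                    old = mu_p[j, a, s]
                    old_prow = p[j, a, s].copy()
                    o_ll = (
                        _marr_one(Mj, phi, p, j, s, True)
                        if a == 0
                        else _marr_pair(Mj, Ma, phi, p, j, s)
                    )
                    mu_p[j, a, s] = old + st_mu_p[j, a, s] * np.random.normal()
                    _set_p_row(p, mu_p, eps_p, j, a, s)
                    n_ll = (
                        _marr_one(Mj, phi, p, j, s, True)
                        if a == 0
                        else _marr_pair(Mj, Ma, phi, p, j, s)
                    )
                    delta = n_ll - o_ll + _norm(mu_p[j, a, s], 0.0, mu_sd) - _norm(old, 0.0, mu_sd)
                    if not _mh_accept(delta):
                        mu_p[j, a, s] = old
                        p[j, a, s] = old_prow
                    if adapting:
                        st_mu_p[j, a, s] = _adapt(st_mu_p[j, a, s], delta, gam)

                    # year-effect SDs: conditional is prior-only
                    for which in range(2):
                        sig = sig_phi if which == 0 else sig_p
                        eps = eps_phi if which == 0 else eps_p
                        st = st_sig_phi if which == 0 else st_sig_p
                        old = sig[j, a, s]
                        prop = old + st[j, a, s] * np.random.normal()
                        if prop <= 0.0 or prop >= sig_up:
                            delta = -1.0e10
                        else:
                            delta = 0.0
                            for t in range(Tm1):
                                delta += _norm(eps[j, a, s, t], 0.0, prop) - _norm(
                                    eps[j, a, s, t], 0.0, old
                                )
                        if _mh_accept(delta):
                            sig[j, a, s] = prop
                        if adapting:
                            st[j, a, s] = _adapt(st[j, a, s], delta, gam)

                # juvenile year effects: single m-array row + one process term
                for t in range(Tm1):
                    old = eps_phi[j, 0, s, t]
                    old_v = phi[j, 0, s, t]
                    o_ll = _marr_row(Mj, phi, p, j, s, t, True) + _rec_term(
                        N, phi, kap, zet, j, s, t
                    )
                    eps_phi[j, 0, s, t] = old + st_eps_phi[j, 0, s, t] * np.random.normal()
                    phi[j, 0, s, t] = _sigmoid(
                        mu_phi[j, 0, s] + beff[0, t] + eps_phi[j, 0, s, t]
                    )
                    n_ll = _marr_row(Mj, phi, p, j, s, t, True) + _rec_term(
                        N, phi, kap, zet, j, s, t
                    )
                    delta = (
                        n_ll - o_ll
                        + _norm(eps_phi[j, 0, s, t], 0.0, sig_phi[j, 0, s])
                        - _norm(old, 0.0, sig_phi[j, 0, s])
                    )
                    if not _mh_accept(delta):
                        eps_phi[j, 0, s, t] = old
                        phi[j, 0, s, t] = old_v
                    if adapting:
                        st_eps_phi[j, 0, s, t] = _adapt(st_eps_phi[j, 0, s, t], delta, gam
                        )

                    old = eps_p[j, 0, s, t]
                    old_v = p[j, 0, s, t]
                    o_ll = _marr_row(Mj, phi, p, j, s, t, True)
                    eps_p[j, 0, s, t] = old + st_eps_p[j, 0, s, t] * np.random.normal()
                    p[j, 0, s, t] = _sigmoid(mu_p[j, 0, s] + eps_p[j, 0, s, t])
                    n_ll = _marr_row(Mj, phi, p, j, s, t, True)
                    delta = (
                        n_ll - o_ll
                        + _norm(eps_p[j, 0, s, t], 0.0, sig_p[j, 0, s])
                        - _norm(old, 0.0, sig_p[j, 0, s])
                    )
                    if not _mh_accept(delta):
                        eps_p[j, 0, s, t] = old
                        p[j, 0, s, t] = old_v
                    if adapting:
                        st_eps_p[j, 0, s, t] = _adapt(st_eps_p[j, 0, s, t], delta, gam)

                # adult year effects: full pair, running current value
                cur = _marr_pair(Mj, Ma, phi, p, j, s)
                for t in range(Tm1):
                    old = eps_phi[j, 1, s, t]
                    old_v = phi[j, 1, s, t]
                    o_ad = _ad_term(N, phi, j, s, t)
                    eps_phi[j, 1, s, t] = old + st_eps_phi[j, 1, s, t] * np.random.normal()
                    phi[j, 1, s, t] = _sigmoid(
                        mu_phi[j, 1, s] + beff[1, t] + eps_phi[j, 1, s, t]
                    )
                    n_pair = _marr_pair(Mj, Ma, phi, p, j, s)
                    delta = (
                        n_pair - cur + _ad_term(N, phi, j, s, t) - o_ad
                        + _norm(eps_phi[j, 1, s, t], 0.0, sig_phi[j, 1, s])
                        - _norm(old, 0.0, sig_phi[j, 1, s])
                    )
                    if _mh_accept(delta):
                        cur = n_pair
                    else:
                        eps_phi[j, 1, s, t] = old
                        phi[j, 1, s, t] = old_v
                    if adapting:
                        st_eps_phi[j, 1, s, t] = _adapt(st_eps_phi[j, 1, s, t], delta, gam
                        )

                    old = eps_p[j, 1, s, t]
                    old_v = p[j, 1, s, t]
                    eps_p[j, 1, s, t] = old + st_eps_p[j, 1, s, t] * np.random.normal()
                    p[j, 1, s, t] = _sigmoid(mu_p[j, 1, s] + eps_p[j, 1, s, t])
                    n_pair = _marr_pair(Mj, Ma, phi, p, j, s)
                    delta = (
                        n_pair - cur
                        + _norm(eps_p[j, 1, s, t], 0.0, sig_p[j, 1, s])
                        - _norm(old, 0.0, sig_p[j, 1, s])
                    )
                    if _mh_accept(delta):
                        cur = n_pair
                    else:
                        eps_p[j, 1, s, t] = old
                        p[j, 1, s, t] = old_v
                    if adapting:
                        st_eps_p[j, 1, s, t] = _adapt(st_eps_p[j, 1, s, t], delta, gam)

        # --- survival covariate slopes ------------------------------------
        for k in range(ncp):
            for a in range(2):
                old = beta_phi[k, a]
                old_phi = phi.copy()
                o_ll = 0.0
                for j in range(2):
                    for s in range(S):
                        o_ll += (
                            _marr_one(Mj, phi, p, j, s, True)
                            if a == 0
                            else _marr_pair(Mj, Ma, phi, p, j, s)
                        )
                        for t in range(Tm1):
                            o_ll += (
                                _rec_term(N, phi, kap, zet, j, s, t)
                                if a == 0
                                else _ad_term(N, phi, j, s, t)
                            )
                beta_phi[k, a] = old + st_beta_phi[k, a] * np.random.normal()
                _set_beff_phi(beff, beta_phi, Xp)
                for j in range(2):
                    for s in range(S):
                        _set_phi_row(phi, mu_phi, eps_phi, beff, j, a, s)
                n_ll = 0.0
                for j in range(2):
                    for s in range(S):
                        n_ll += (
                            _marr_one(Mj, phi, p, j, s, True)
                            if a == 0
                            else _marr_pair(Mj, Ma, phi, p, j, s)
                        )
                        for t in range(Tm1):
                            n_ll += (
                                _rec_term(N, phi, kap, zet, j, s, t)
                                if a == 0
                                else _ad_term(N, phi, j, s, t)
                            )
                delta = (
                    n_ll - o_ll
                    + _norm(beta_phi[k, a], 0.0, beta_sd) - _norm(old, 0.0, beta_sd)
                )
                if not _mh_accept(delta):
                    beta_phi[k, a] = old
                    phi[:] = old_phi
                    _set_beff_phi(beff, beta_phi, Xp)
                if adapting:
                    st_beta_phi[k, a] = _adapt(st_beta_phi[k, a], delta, gam)

        # --- clutch size ----------------------------------------------------
        for a in range(3):
            for s in range(S):
                old = mu_kap[a, s]
                old_row = kap[a, s].copy()
                o_ll = _clutch_stage_site(bb, cc, kap, a, s) + _rec_terms_site(
                    N, phi, kap, zet, s
                )
                mu_kap[a, s] = old + st_mu_kap[a, s] * np.random.normal()
                _set_kap_row(kap, mu_kap, eps_kap, a, s)
                n_ll = _clutch_stage_site(bb, cc, kap, a, s) + _rec_terms_site(
                    N, phi, kap, zet, s
                )
                delta = (
                    n_ll - o_ll
                    + _norm(mu_kap[a, s], kmu_m, kmu_sd) - _norm(old, kmu_m, kmu_sd)
                )
                if not _mh_accept(delta):
                    mu_kap[a, s] = old
                    kap[a, s] = old_row
                if adapting:
                    st_mu_kap[a, s] = _adapt(st_mu_kap[a, s], delta, gam)

                old = sig_kap[a, s]
                prop = old + st_sig_kap[a, s] * np.random.normal()
                if prop <= 0.0 or prop >= sig_up:
                    delta = -1.0e10
                else:
                    delta = 0.0
                    for t in range(T):
                        delta += _norm(eps_kap[a, s, t], 0.0, prop) - _norm(
                            eps_kap[a, s, t], 0.0, old
                        )
                if _mh_accept(delta):
                    sig_kap[a, s] = prop
                if adapting:
                    st_sig_kap[a, s] = _adapt(st_sig_kap[a, s], delta, gam)

                for t in range(T):
                    old = eps_kap[a, s, t]
                    old_v = kap[a, s, t]
                    o_ll = 0.0
                    if bb[a, s, t] > 0.0:
                        o_ll += _pois(cc[a, s, t], kap[a, s, t] * bb[a, s, t])
                    if t < T - 1:
                        o_ll += _rec_term(N, phi, kap, zet, 0, s, t)
                        o_ll += _rec_term(N, phi, kap, zet, 1, s, t)
                    eps_kap[a, s, t] = old + st_eps_kap[a, s, t] * np.random.normal()
                    kap[a, s, t] = math.exp(mu_kap[a, s] + eps_kap[a, s, t])
                    n_ll = 0.0
                    if bb[a, s, t] > 0.0:
                        n_ll += _pois(cc[a, s, t], kap[a, s, t] * bb[a, s, t])
                    if t < T - 1:
                        n_ll += _rec_term(N, phi, kap, zet, 0, s, t)
                        n_ll += _rec_term(N, phi, kap, zet, 1, s, t)
                    delta = (
                        n_ll - o_ll
                        + _norm(eps_kap[a, s, t], 0.0, sig_kap[a, s])
                        - _norm(old, 0.0, sig_kap[a, s])
                    )
                    if not _mh_accept(delta):
                        eps_kap[a, s, t] = old
                        kap[a, s, t] = old_v
                    if adapting:
                        st_eps_kap[a, s, t] = _adapt(st_eps_kap[a, s, t], delta, gam
                        )

        # --- fledging -------------------------------------------------------
        for a in range(3):
            for s in range(S):
                old = mu_zet[a, s]
                old_row = zet[a, s].copy()
                o_ll = _fledge_stage_site(cc, ff, zet, a, s) + _rec_terms_site(
                    N, phi, kap, zet, s
                )
                mu_zet[a, s] = old + st_mu_zet[a, s] * np.random.normal()
                for t in range(T):
                    _set_zeta_cell(zet, mu_zet, beffz, lam3, dsc, u, a, s, t)
                n_ll = _fledge_stage_site(cc, ff, zet, a, s) + _rec_terms_site(
                    N, phi, kap, zet, s
                )
                delta = n_ll - o_ll + _norm(mu_zet[a, s], 0.0, mu_sd) - _norm(old, 0.0, mu_sd)
                if not _mh_accept(delta):
                    mu_zet[a, s] = old
                    zet[a, s] = old_row
                if adapting:
                    st_mu_zet[a, s] = _adapt(st_mu_zet[a, s], delta, gam)

        for k in range(ncz):
            for a in range(3):
                old = beta_zet[k, a]
                old_zet = zet.copy()
                o_ll = 0.0
                for s in range(S):
                    o_ll += _fledge_stage_site(cc, ff, zet, a, s) + _rec_terms_site(
                        N, phi, kap, zet, s
                    )
                beta_zet[k, a] = old + st_beta_zet[k, a] * np.random.normal()
                _set_beff_zeta(beffz, beta_zet, Xz)
                for s in range(S):
                    for t in range(T):
                        _set_zeta_cell(zet, mu_zet, beffz, lam3, dsc, u, a, s, t)
                n_ll = 0.0
                for s in range(S):
                    n_ll += _fledge_stage_site(cc, ff, zet, a, s) + _rec_terms_site(
                        N, phi, kap, zet, s
                    )
                delta = (
                    n_ll - o_ll
                    + _norm(beta_zet[k, a], 0.0, beta_sd) - _norm(old, 0.0, beta_sd)
                )
                if not _mh_accept(delta):
                    beta_zet[k, a] = old
                    zet[:] = old_zet
                    _set_beff_zeta(beffz, beta_zet, Xz)
                if adapting:
                    st_beta_zet[k, a] = _adapt(st_beta_zet[k, a], delta, gam)

        # correlation-structure parameters: global zeta recompute
        for i in range(6):
            if i < 3:
                arr, st, idx = lam3, st_lam3, i
            else:
                arr, st, idx = dsc, st_dsc, i - 3
            old = arr[idx]
            old_zet = zet.copy()
            o_ll = 0.0
            for s in range(S):
                for a in range(3):
                    o_ll += _fledge_stage_site(cc, ff, zet, a, s)
                o_ll += _rec_terms_site(N, phi, kap, zet, s)
            arr[idx] = old + st[idx] * np.random.normal()
            bad = i >= 3 and arr[idx] <= 0.0
            if bad:
                delta = -1.0e10
            else:
                _set_zeta_all(zet, mu_zet, beffz, lam3, dsc, u)
                n_ll = 0.0
                for s in range(S):
                    for a in range(3):
                        n_ll += _fledge_stage_site(cc, ff, zet, a, s)
                    n_ll += _rec_terms_site(N, phi, kap, zet, s)
                if i < 3:
                    dpri = _norm(arr[idx], 0.0, fac_sd) - _norm(old, 0.0, fac_sd)
                else:
                    dpri = _norm(arr[idx], 0.0, exp_sd) - _norm(old, 0.0, exp_sd)
                delta = n_ll - o_ll + dpri
            if not _mh_accept(delta):
                arr[idx] = old
                zet[:] = old_zet
            if adapting:
                st[idx] = _adapt(st[idx], delta, gam)

        # innovations: local cells
        for s in range(S):
            for t in range(T):
                for i in range(3):
                    old = u[i, s, t]
                    old_z0 = zet[0, s, t]
                    old_z1 = zet[1, s, t]
                    old_z2 = zet[2, s, t]
                    o_ll = 0.0
                    for a in range(i, 3):
                        if cc[a, s, t] > 0.0:
                            o_ll += _binom(ff[a, s, t], cc[a, s, t], zet[a, s, t])
                    if t < T - 1:
                        o_ll += _rec_term(N, phi, kap, zet, 0, s, t)
                        o_ll += _rec_term(N, phi, kap, zet, 1, s, t)
                    u[i, s, t] = old + st_u[i, s, t] * np.random.normal()
                    for a in range(i, 3):
                        _set_zeta_cell(zet, mu_zet, beffz, lam3, dsc, u, a, s, t)
                    n_ll = 0.0
                    for a in range(i, 3):
                        if cc[a, s, t] > 0.0:
                            n_ll += _binom(ff[a, s, t], cc[a, s, t], zet[a, s, t])
                    if t < T - 1:
                        n_ll += _rec_term(N, phi, kap, zet, 0, s, t)
                        n_ll += _rec_term(N, phi, kap, zet, 1, s, t)
                    delta = n_ll - o_ll + _norm(u[i, s, t], 0.0, 1.0) - _norm(old, 0.0, 1.0)
                    if not _mh_accept(delta):
                        u[i, s, t] = old
                        zet[0, s, t] = old_z0
                        zet[1, s, t] = old_z1
                        zet[2, s, t] = old_z2
                    if adapting:
                        st_u[i, s, t] = _adapt(st_u[i, s, t], delta, gam)

        # --- immigration and counts ----------------------------------------
        for j in range(2):
            for s in range(S):
                old = lomega[j, s]
                o_ll = _im_terms(N, lomega, j, s)
                lomega[j, s] = old + st_lom[j, s] * np.random.normal()
                n_ll = _im_terms(N, lomega, j, s)
                delta = n_ll - o_ll + _norm(lomega[j, s], 0.0, lom_sd) - _norm(old, 0.0, lom_sd)
                if not _mh_accept(delta):
                    lomega[j, s] = old
                if adapting:
                    st_lom[j, s] = _adapt(st_lom[j, s], delta, gam)

        for s in range(S):
            old = tau[s]
            prop = old + st_tau[s] * np.random.normal()
            if prop <= 0.0 or prop >= tau_up:
                delta = -1.0e10
            else:
                o_ll = _count_sex_site(ylog, yobs, N, tau, 0, s) + _count_sex_site(
                    ylog, yobs, N, tau, 1, s
                )
                tau[s] = prop
                n_ll = _count_sex_site(ylog, yobs, N, tau, 0, s) + _count_sex_site(
                    ylog, yobs, N, tau, 1, s
                )
                tau[s] = old
                delta = n_ll - o_ll
            if _mh_accept(delta):
                tau[s] = prop
            if adapting:
                st_tau[s] = _adapt(st_tau[s], delta, gam)

        # --- latent abundances ----------------------------------------------
        for j in range(2):
            for a in range(3):
                for s in range(S):
                    for t in range(T):
                        old = N[j, a, s, t]
                        o_ll = _local_N_terms(
                            N, phi, kap, zet, lomega, ylog, yobs, tau, n0up, j, a, s, t
                        )
                        prop = old + st_N[j, a, s, t] * np.random.normal()
                        if prop < 0.0:
                            delta = -1.0e10
                        else:
                            N[j, a, s, t] = prop
                            n_ll = _local_N_terms(
                                N, phi, kap, zet, lomega, ylog, yobs, tau, n0up, j, a, s, t
                            )
                            N[j, a, s, t] = old
                            delta = n_ll - o_ll
                        if _mh_accept(delta):
                            N[j, a, s, t] = prop
                        if adapting:
                            st_N[j, a, s, t] = _adapt(st_N[j, a, s, t], delta, gam)

        # joint multiplicative move on one year's states (all three stages),
        # so the trajectory can drift relative to the counts; the proposal is
        # log-scale symmetric, hence the 3 log f Jacobian term
        for j in range(2):
            for s in range(S):
                for t in range(T):
                    o_ll = _local_year_terms(
                        N, phi, kap, zet, lomega, ylog, yobs, tau, n0up, j, s, t
                    )
                    f = math.exp(st_Nsc[j, s, t] * np.random.normal())
                    o0 = N[j, 0, s, t]
                    o1 = N[j, 1, s, t]
                    o2 = N[j, 2, s, t]
                    N[j, 0, s, t] = o0 * f
                    N[j, 1, s, t] = o1 * f
                    N[j, 2, s, t] = o2 * f
                    n_ll = _local_year_terms(
                        N, phi, kap, zet, lomega, ylog, yobs, tau, n0up, j, s, t
                    )
                    delta = n_ll - o_ll + 3.0 * math.log(f)
                    if not _mh_accept(delta):
                        N[j, 0, s, t] = o0
                        N[j, 1, s, t] = o1
                        N[j, 2, s, t] = o2
                    if adapting:
                        st_Nsc[j, s, t] = _adapt(st_Nsc[j, s, t], delta, gam)

        # --- record ----------------------------------------------------------
        if it >= burn and (it - burn) % thin == 0 and rec < n_save:
            col = 0
            for arr3 in (mu_phi, sig_phi, mu_p, sig_p):
                for v in arr3.ravel():
                    out[rec, col] = v
                    col += 1
            for v in beta_phi.ravel():
                out[rec, col] = v
                col += 1
            for arr2 in (mu_kap, sig_kap, mu_zet):
                for v in arr2.ravel():
                    out[rec, col] = v
                    col += 1
            for v in beta_zet.ravel():
                out[rec, col] = v
                col += 1
            for v in lam3:
                out[rec, col] = v
                col += 1
            for v in dsc:
                out[rec, col] = v
                col += 1
            for v in lomega.ravel():
                out[rec, col] = v
                col += 1
            for v in tau:
                out[rec, col] = v
                col += 1
            for arr4 in (phi, p):
                for v in arr4.ravel():
                    out[rec, col] = v
                    col += 1
            for arr3b in (kap, zet):
                for v in arr3b.ravel():
                    out[rec, col] = v
                    col += 1
            for v in N.ravel():
                out[rec, col] = v
                col += 1
            out[rec, col] = _total_logp(
                Mj, Ma, bb, cc, ff, ylog, yobs, n0up,
                mu_phi, sig_phi, eps_phi, beta_phi, mu_p, sig_p, eps_p,
                mu_kap, sig_kap, eps_kap, mu_zet, beta_zet, lam3, dsc, u,
                lomega, tau, N, phi, p, kap, zet,
                mu_sd, kmu_m, kmu_sd, sig_up, tau_up, beta_sd, lom_sd, exp_sd, fac_sd,
            )
            rec += 1
    return rec
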