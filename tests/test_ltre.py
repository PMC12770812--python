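"""Transient LTRE: sensitivities, contributions, covariate partition."""

import numpy as np
import pytest
from scipy.special import expit, logit

from piedfly import ltre, model
from piedfly.inference import PosteriorDraws
from piedfly.ltre import COMPONENTS, decompose, normalize_sensitivities, realized_lambda


def make_draws(N, phi, kappa, zeta, meta=None, **extra):
    """Wrap state/rate arrays (no chain/draw axes) as a one-draw posterior."""
    params = {
        "N": N[None, None],
        "phi": phi[None, None],
        "kappa": kappa[None, None],
        "zeta": zeta[None, None],
    }
    for k, v in extra.items():
        params[k] = np.asarray(v)[None, None]
    meta = dict(meta or {})
    meta.setdefault("sites", [f"s{i}" for i in range(N.shape[2])])
    return PosteriorDraws(params=params, meta=meta)


def _states(T=30, S=1, n0=(5.0, 12.0, 3.0)):
    N = np.zeros((2, 3, S, T))
    for s in range(S):
        N[:, :, s, 0] = n0
    return N


def _forward(N, phi, kappa, zeta, omega, mode="expectation", rng=None):
    T = N.shape[3]
    for t in range(T - 1):
        N[:, :, :, t + 1] = model.project_population(
            N[:, :, :, t], phi[:, :, :, t], kappa[:, :, t], zeta[:, :, t],
            omega, mode=mode, rng=rng,
        )
    return N


class TestRealizedLambda:
    def test_constant_population(self):
        N = _states(T=5)
        N[:] = N[:, :, :, [0]]
        d = make_draws(N, np.zeros((2, 2, 1, 4)), np.ones((3, 1, 5)), np.ones((3, 1, 5)) / 2)
        lam = realized_lambda(d)
        assert np.allclose(lam, 1.0)

    def test_doubling_then_halving(self):
        N = _states(T=3, n0=(2.0, 6.0, 2.0))
        N[0, :, 0, 1] = (4.0, 12.0, 4.0)
        N[0, :, 0, 2] = (2.0, 6.0, 2.0)
        d = make_draws(N, np.zeros((2, 2, 1, 2)), np.ones((3, 1, 3)), np.ones((3, 1, 3)) / 2)
        lam = realized_lambda(d)[0, 0]
        assert np.allclose(lam, [2.0, 0.5])
        assert ltre.geometric_mean_lambda(lam[None, None])[0, 0] == pytest.approx(1.0)

    def test_matches_recomputation_from_states(self, dataset_small):
        truth = dataset_small.truth
        N = truth.N
        d = make_draws(
            N, truth.phi_real, truth.kappa_real, truth.zeta_real,
            meta={"sites": list(truth.sites)},
        )
        lam = realized_lambda(d)[0]
        females = N[0].sum(axis=0)
        assert np.allclose(lam, females[:, 1:] / females[:, :-1])


def _lambda_fn(nf, phi_j, phi_a, kap, zet, inflow):
    tot = nf.sum()
    return (0.5 * phi_j * (nf * kap * zet).sum() + phi_a * tot + inflow) / tot


class TestSensitivities:
    def test_worked_state(self):
        nf = np.array([10.0, 10.0, 0.0])[:, None]
        kap = np.full((3, 1), 6.0)
        zet = np.full((3, 1), 0.5)
        s = ltre.sensitivities(nf, np.array([0.2]), kap, zet)
        # 0.5 * (10*6*0.5 + 10*6*0.5) / 20
        assert s["phi_juv"][0] == pytest.approx(1.5)
        assert s["phi_ad"][0] == pytest.approx(1.0)
        assert s["kappa_rec"][0] == pytest.approx(0.5 * 0.2 * 10 * 0.5 / 20)
        assert s["immigration"][0] == pytest.approx(1 / 20)

    def test_kappa_sensitivity_vanishes_without_juvenile_survival(self):
        nf = np.array([10.0, 10.0, 5.0])[:, None]
        s = ltre.sensitivities(nf, np.array([0.0]), np.full((3, 1), 6.0), np.full((3, 1), 0.5))
        for stage in ("rec", "ad", "im"):
            assert s[f"kappa_{stage}"][0] == 0.0
            assert s[f"zeta_{stage}"][0] == 0.0

    def test_zero_abundance_signalled(self):
        with pytest.raises(ValueError, match="zero total"):
            ltre.sensitivities(np.zeros((3, 1)), np.array([0.2]),
                               np.ones((3, 1)), np.ones((3, 1)))

    def test_matches_central_finite_differences(self, rng):
        h = 1e-6
        for _ in range(100):
            nf = rng.uniform(2, 40, 3)
            phi_j, phi_a = rng.uniform(0.05, 0.6), rng.uniform(0.3, 0.9)
            kap = rng.uniform(4, 7, 3)
            zet = rng.uniform(0.3, 0.9, 3)
            inflow = rng.uniform(0, 5)
            s = ltre.sensitivities(nf[:, None], np.array([phi_j]), kap[:, None], zet[:, None])

            def fd(f, x0):
                return (f(x0 + h * max(abs(x0), 1)) - f(x0 - h * max(abs(x0), 1))) / (
                    2 * h * max(abs(x0), 1)
                )

            got = s["phi_juv"][0]
            want = fd(lambda v: _lambda_fn(nf, v, phi_a, kap, zet, inflow), phi_j)
            assert got == pytest.approx(want, rel=1e-6)
            for ai, stage in enumerate(("rec", "ad", "im")):
                want = fd(
                    lambda v, ai=ai: _lambda_fn(
                        nf, phi_j, phi_a, np.where(np.arange(3) == ai, v, kap), zet, inflow
                    ),
                    kap[ai],
                )
                assert s[f"kappa_{stage}"][0] == pytest.approx(want, rel=1e-6)
                want = fd(
                    lambda v, ai=ai: _lambda_fn(
                        nf, phi_j, phi_a, kap, np.where(np.arange(3) == ai, v, zet), inflow
                    ),
                    zet[ai],
                )
                assert s[f"zeta_{stage}"][0] == pytest.approx(want, rel=1e-6)
            want = fd(lambda v: _lambda_fn(nf, phi_j, phi_a, kap, zet, v), inflow)
            assert s["immigration"][0] == pytest.approx(want, rel=1e-4, abs=1e-9)


class TestNormalize:
    def test_sums_to_one(self, rng):
        v = rng.uniform(0.1, 2, 8)
        out = normalize_sensitivities(v)
        assert out.sum() == pytest.approx(1.0)
        assert np.allclose(out / out[0], v / v[0])  # proportionality preserved

    def test_single_nonzero_entry(self):
        out = normalize_sensitivities(np.array([0.0, 3.0, 0.0]))
        assert out.tolist() == [0.0, 1.0, 0.0]

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_sensitivities(np.zeros(4))


def _single_source_draws(T=40, seed=0, beta=None, x=None):
    """Expectation dynamics where only juvenile survival varies.

    Clutch and fledging are equal across stages and immigration is zero,
    so the annual growth rate is an exactly linear function of phi_juv.
    """
    rng = np.random.default_rng(seed)
    S = 1
    eta = logit(0.35)
    if beta is None:
        eps = 0.25 * rng.standard_normal(T - 1)
        series = expit(eta + eps)
    else:
        series = expit(eta + beta * x[: T - 1])
    phi = np.zeros((2, 2, S, T - 1))
    phi[:, 0, 0, :] = series
    phi[:, 1, 0, :] = 0.55
    kappa = np.full((3, S, T), 5.6)
    zeta = np.full((3, S, T), 0.55)
    omega = np.zeros((2, S))
    N = _forward(_states(T=T, n0=(8.0, 20.0, 4.0)), phi, kappa, zeta, omega)
    return N, phi, kappa, zeta


class TestDecompose:
    def test_single_varying_rate_takes_the_whole_share(self):
        N, phi, kappa, zeta = _single_source_draws()
        d = make_draws(N, phi, kappa, zeta)
        res = decompose(d)
        shares = dict(zip(COMPONENTS, res.shares[0, :, 0]))
        assert shares["phi_juv"] == pytest.approx(1.0, abs=1e-6)
        for comp, val in shares.items():
            if comp != "phi_juv":
                assert abs(val) < 1e-6

    def test_constant_rates_give_zero_shares(self):
        rng = np.random.default_rng(3)
        S, T = 1, 40
        phi = np.zeros((2, 2, S, T - 1))
        phi[:, 0] = 0.3
        phi[:, 1] = 0.55
        kappa = np.full((3, S, T), 5.6)
        zeta = np.full((3, S, T), 0.6)
        omega = np.full((2, S), 3.0)
        N = _forward(
            _states(T=T, n0=(8.0, 20.0, 4.0)), phi, kappa, zeta, omega,
            mode="stochastic", rng=rng,
        )
        d = make_draws(N, phi, kappa, zeta)
        res = decompose(d)
        # variation in lambda is pure demographic stochasticity: no rate
        # contributes (immigration *inflow* still varies between years)
        for ci, comp in enumerate(COMPONENTS):
            if comp != "immigration":
                assert res.shares[0, ci, 0] == pytest.approx(0.0, abs=1e-12)

    def test_covariate_driven_rate_attributes_share_to_covariate(self):
        T = 40
        rng = np.random.default_rng(9)
        x = rng.standard_normal(T)
        x = (x - x.mean()) / x.std(ddof=1)
        N, phi, kappa, zeta = _single_source_draws(T=T, beta=-0.4, x=x)
        d = make_draws(
            N, phi, kappa, zeta,
            meta={"sites": ["s0"], "survival_covariates": ["rain"]},
            beta_phi=np.array([[-0.4, 0.0]]),
        )
        res = decompose(d, covariates={"rain": x})
        ci = COMPONENTS.index("phi_juv")
        comp_share = res.shares[0, ci, 0]
        cov_share = res.cov_shares[("phi_juv", "rain")][0, 0]
        assert comp_share == pytest.approx(1.0, abs=1e-6)
        assert abs(cov_share - comp_share) < 0.05  # linearization error only
        resid = res.resid_shares[0, ci, 0]
        assert resid == pytest.approx(comp_share - cov_share, abs=1e-12)

    def test_first_order_sum_explains_most_variance_at_low_amplitude(self):
        rng = np.random.default_rng(17)
        S, T = 1, 60
        phi = np.zeros((2, 2, S, T - 1))
        phi[:, 0] = expit(logit(0.3) + 0.1 * rng.standard_normal((S, T - 1)))
        phi[:, 1] = expit(logit(0.55) + 0.08 * rng.standard_normal((S, T - 1)))
        kappa = np.exp(np.log(5.6) + 0.05 * rng.standard_normal((3, S, T)))
        zeta = expit(logit(0.6) + 0.1 * rng.standard_normal((3, S, T)))
        omega = np.zeros((2, S))
        N = _forward(_states(T=T, n0=(8.0, 20.0, 4.0)), phi, kappa, zeta, omega)
        d = make_draws(N, phi, kappa, zeta)
        res = decompose(d)
        assert res.shares[0, :, 0].sum() >= 0.9

    def test_deterministic_in_the_draws(self):
        N, phi, kappa, zeta = _single_source_draws(seed=5)
        d = make_draws(N, phi, kappa, zeta)
        a = decompose(d)
        b = decompose(d)
        assert np.array_equal(a.shares, b.shares)
        assert np.array_equal(a.sens_mean, b.sens_mean)

    def test_tables_are_well_formed(self, draws_small, data_small):
        res = decompose(draws_small, covariates=data_small.covariates)
        st = res.share_table()
        assert set(st["component"]) == set(COMPONENTS)
        sens = res.sensitivity_table()
        tot = sens.groupby("site")["sensitivity_mean"].sum()
        assert np.allclose(tot, 1.0, atol=0.02)
        hl = res.headline_split()
        assert np.allclose(hl["survival_pct"] + hl["fecundity_pct"], 100.0)
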