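"""Generator and simulator: ranges, determinism, process expectations."""

import numpy as np
import pytest

from piedfly import synthetic
from piedfly.synthetic import ConfigurationError, SyntheticConfig

from conftest import small_config


class TestMakeTruth:
    def test_means_fall_in_configured_ranges(self):
        cfg = SyntheticConfig()
        truth = synthetic.make_truth(cfg, seed=1)
        lo, hi = cfg.phi_juv_range
        assert np.all((truth.phi_mean[:, 0, :] >= lo) & (truth.phi_mean[:, 0, :] <= hi))
        lo, hi = cfg.phi_ad_range
        assert np.all((truth.phi_mean[:, 1, :] >= lo) & (truth.phi_mean[:, 1, :] <= hi))
        lo, hi = cfg.kappa_range
        assert np.all((truth.kappa_mean >= lo) & (truth.kappa_mean <= hi))
        truth.validate()

    def test_same_seed_same_truth(self):
        a = synthetic.make_truth(seed=3)
        b = synthetic.make_truth(seed=3)
        assert np.array_equal(a.phi_mean, b.phi_mean)
        assert np.array_equal(a.zeta_cov, b.zeta_cov)
        assert all(np.array_equal(a.covariates[k], b.covariates[k]) for k in a.covariates)

    def test_zero_years_rejected(self):
        with pytest.raises(ConfigurationError):
            synthetic.make_truth(SyntheticConfig(n_years=0), seed=1)

    def test_inverted_range_rejected(self):
        with pytest.raises(ConfigurationError, match="min"):
            synthetic.make_truth(SyntheticConfig(kappa_range=(6.0, 5.0)), seed=1)

    def test_degenerate_ranges_pin_values(self):
        cfg = small_config(kappa_range=(6.0, 6.0), zeta_range=(0.5, 0.5))
        truth = synthetic.make_truth(cfg, seed=2)
        assert np.allclose(truth.kappa_mean, 6.0)
        assert np.allclose(truth.zeta_mean, 0.5)

    def test_truth_yaml_roundtrip(self, tmp_path):
        truth = synthetic.make_truth(small_config(), seed=5)
        truth.to_yaml(tmp_path / "truth.yaml")
        back = synthetic.TruthBundle.from_yaml(tmp_path / "truth.yaml")
        assert np.allclose(back.phi_mean, truth.phi_mean)
        assert np.allclose(back.zeta_cov, truth.zeta_cov)
        assert np.allclose(back.covariates["init_date"], truth.covariates["init_date"])


def _dead_world_config(**over):
    # all survival/immigration shut off: the population must be absorbed at 0
    return small_config(
        phi_juv_range=(1e-9, 1e-9), phi_ad_range=(1e-9, 1e-9),
        omega_f_range=(0.0, 0.0), omega_m_range=(0.0, 0.0),
        sigma_phi_range=(0.0, 0.0), **over,
    )


class TestSimulateDataset:
    def test_absorbing_state_without_survival_or_immigration(self):
        truth = synthetic.make_truth(_dead_world_config(), seed=3)
        with pytest.warns(UserWarning, match="extinct"):
            ds = synthetic.simulate_dataset(truth, seed=4)
        assert ds.extinct
        assert truth.N[:, :, :, 2:].sum() == 0  # everything gone after year 1

    def test_certain_detection_gives_full_histories(self):
        cfg = small_config(
            p_juv_range=(1.0 - 1e-12, 1.0 - 1e-12),
            p_ad_range=(1.0 - 1e-12, 1.0 - 1e-12),
            sigma_p_range=(0.0, 0.0),
        )
        truth = synthetic.make_truth(cfg, seed=5)
        ds = synthetic.simulate_dataset(truth, seed=6)
        det = ds.captures.detections
        # with p = 1 a marked bird's detections are a contiguous block:
        # detected every year from marking until death
        for row in det:
            on = np.flatnonzero(row)
            assert np.array_equal(on, np.arange(on[0], on[-1] + 1))

    def test_first_year_survival_frequency_matches_binomial(self):
        # 10,000 juveniles at phi_juv = 0.2: realized frequency within 3 SE
        cfg = small_config(
            sites=("s",), n_years=2,
            phi_juv_range=(0.2, 0.2), sigma_phi_range=(0.0, 0.0),
            p_juv_range=(1.0 - 1e-12, 1.0 - 1e-12), p_ad_range=(1.0 - 1e-12, 1.0 - 1e-12),
            sigma_p_range=(0.0, 0.0),
            # a huge population so that >10k juveniles are marked in year one
            n0_ad_range=(3200, 3200), kappa_range=(6.0, 6.0), zeta_range=(0.7, 0.7),
        )
        truth = synthetic.make_truth(cfg, seed=9)
        ds = synthetic.simulate_dataset(truth, seed=10)
        juv = (ds.captures.stage == "juv") & (ds.captures.first_year == 2001)
        det = ds.captures.detections[juv]
        n = det.shape[0]
        assert n > 8000
        survived = det[:, 1].sum()  # p = 1: survivors of year 1 are all seen
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(survived / n - 0.2) < 3 * se

    def test_detections_never_exceed_alive_window(self, dataset_small):
        ds = dataset_small
        ds.captures.validate()
        first = ds.captures.first_year
        years = ds.captures.years
        idx = np.searchsorted(years, first)
        for row, i0 in zip(ds.captures.detections, idx):
            assert row[:i0].sum() == 0 and row[i0] == 1

    def test_zero_observation_error_counts_equal_latent_totals(self):
        cfg = small_config(tau_range=(1e-9, 1e-9))
        truth = synthetic.make_truth(cfg, seed=11)
        ds = synthetic.simulate_dataset(truth, seed=12)
        totals = truth.N.sum(axis=1)
        obs = ds.counts.observed
        assert np.allclose(ds.counts.y[obs], np.round(totals[obs]))


class TestExpectedTrajectory:
    def worked_truth(self):
        cfg = small_config(
            n_years=3,
            kappa_range=(6.0, 6.0), zeta_range=(0.5, 0.5),
            phi_juv_range=(0.2, 0.2), phi_ad_range=(0.5, 0.5),
            omega_f_range=(0.0, 0.0), omega_m_range=(0.0, 0.0),
            n0_rec_range=(10, 10), n0_ad_range=(10, 10), n0_im_range=(0, 0),
        )
        return synthetic.make_truth(cfg, seed=1)

    def test_worked_example(self):
        # N_rec=10, N_ad=10, kappa=6, zeta=0.5, phi=(0.2, 0.5), omega=0
        et = synthetic.expected_trajectory(self.worked_truth())
        assert np.allclose(et.EN[0, 0, :, 1], 6.0)   # recruits
        assert np.allclose(et.EN[0, 1, :, 1], 10.0)  # adults
        assert np.allclose(et.lam[:, 0], 0.8)

    def test_lambda_two_ways_agree(self, truth_small):
        et = synthetic.expected_trajectory(truth_small)
        females = et.EN[0].sum(axis=0)
        assert np.allclose(et.lam, females[:, 1:] / females[:, :-1])

    def test_immigration_only_population(self):
        cfg = small_config(
            phi_juv_range=(1e-12, 1e-12), phi_ad_range=(1e-12, 1e-12),
            kappa_range=(5.0, 5.0),
            omega_f_range=(3.0, 3.0), omega_m_range=(3.0, 3.0),
        )
        truth = synthetic.make_truth(cfg, seed=2)
        et = synthetic.expected_trajectory(truth)
        # from the second year on the expected population is immigrants only
        assert np.allclose(et.EN[0].sum(axis=0)[:, 1:], 3.0)

    def test_monte_carlo_mean_matches_expectation(self):
        # with year-effect SDs pinned to zero the demographic draws are
        # linear in the state, so the Monte-Carlo mean must hit E[N]
        cfg = small_config(
            sites=("s",), n_years=4,
            n0_rec_range=(3, 3), n0_ad_range=(6, 6), n0_im_range=(2, 2),
            sigma_phi_range=(0.0, 0.0), sigma_p_range=(0.0, 0.0),
            sigma_kappa_range=(0.0, 0.0), zeta_sd_range=(0.0, 0.0),
        )
        truth = synthetic.make_truth(cfg, seed=13)
        et = synthetic.expected_trajectory(truth)
        sims = np.empty((500, 2, 3, truth.n_sites, truth.n_years))
        for r in range(500):
            t = synthetic.make_truth(cfg, seed=13)
            ds = synthetic.simulate_dataset(t, seed=50_000 + r)
            sims[r] = t.N
        mean = sims.mean(axis=0)
        se = sims.std(axis=0, ddof=1) / np.sqrt(sims.shape[0])
        diff = np.abs(mean - et.EN)
        assert np.all(diff <= 3 * se + 1e-9)
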