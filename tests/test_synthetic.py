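"""Generative-model checks: cohort structure, signal laws, artifacts."""

import hashlib

import numpy as np
import pytest
from scipy import stats

from swaylearn import (
    SimulationConfig,
    corrupt_recording,
    generate_dataset,
    sample_cohort,
    simulate_recording,
)
from swaylearn.errors import ConfigurationError, DomainError
from swaylearn.synthetic import age_factor

from conftest import make_profile


class TestSampleCohort:
    def test_cohort_shape_matches_group_sizes(self):
        cfg = SimulationConfig(n_asd=39, n_td=23, rng_seed=1)
        profiles = sample_cohort(cfg)
        assert len(profiles) == 62
        assert sum(p.group == "ASD" for p in profiles) == 39
        assert all(7.0 <= p.age_years <= 18.0 for p in profiles)
        assert all(1.0 <= p.bot2_percentile <= 99.0 for p in profiles)

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_asd=5, n_td=5, rng_seed=3)
        assert sample_cohort(cfg) == sample_cohort(cfg)

    def test_covariates_monotone_in_severity(self):
        """Motor percentile decreases, symptom scores increase with severity."""
        cfg = SimulationConfig(n_asd=200, n_td=200, rng_seed=7)
        profiles = sample_cohort(cfg)
        sev = np.array([p.latent_severity for p in profiles])
        assert np.corrcoef(sev, [p.bot2_percentile for p in profiles])[0, 1] < 0
        assert np.corrcoef(sev, [p.srs2_score for p in profiles])[0, 1] > 0
        assert np.corrcoef(sev, [p.rbsr_score for p in profiles])[0, 1] > 0

    def test_severity_stochastically_larger_in_asd(self):
        cfg = SimulationConfig(n_asd=200, n_td=200, rng_seed=5)
        profiles = sample_cohort(cfg)
        asd = [p.latent_severity for p in profiles if p.group == "ASD"]
        td = [p.latent_severity for p in profiles if p.group == "TD"]
        assert np.mean(asd) > np.mean(td)

    def test_equal_severity_params_give_identical_distributions(self):
        """With matched distribution parameters the groups are exchangeable."""
        cfg = SimulationConfig(
            n_asd=400, n_td=400, rng_seed=9,
            td_severity_mean=1.0, td_severity_shape=4.0,
        )
        profiles = sample_cohort(cfg)
        asd = [p.latent_severity for p in profiles if p.group == "ASD"]
        td = [p.latent_severity for p in profiles if p.group == "TD"]
        assert stats.ks_2samp(asd, td).pvalue > 0.01

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigurationError, match="n_asd"):
            SimulationConfig(n_asd=0).validate()
        with pytest.raises(ConfigurationError, match="p_missing"):
            SimulationConfig(p_missing=1.5).validate()
        with pytest.raises(ConfigurationError, match="affected_dims"):
            SimulationConfig(affected_dims=frozenset({99})).validate()


class TestSimulateRecording:
    CFG = SimulationConfig(
        frames_min=1000, frames_max=1000, p_missing=0.0, jitter_sd=0.0,
        drift_amplitude=0.0, p_corrupt_file=0.0, rng_seed=2,
    )

    def test_shape_and_determinism(self):
        rec = simulate_recording(make_profile(), 1, 2, self.CFG)
        assert rec.data.shape == (1000, 62)
        rec2 = simulate_recording(make_profile(), 1, 2, self.CFG)
        np.testing.assert_array_equal(rec.data, rec2.data)

    def test_out_of_range_pose_or_session(self):
        with pytest.raises(DomainError):
            simulate_recording(make_profile(), 99, 2, self.CFG)
        with pytest.raises(DomainError):
            simulate_recording(make_profile(), 1, 7, self.CFG)

    def test_zero_effect_makes_groups_exchangeable(self):
        """With beta=0 and no age slope, channel variances do not separate groups."""
        cfg = self.CFG.with_(effect_size_beta=0.0, age_slope=0.0, rng_seed=21)
        var_asd, var_td = [], []
        for i in range(50):
            a = make_profile("ASD", severity=1.5, pid=f"a{i}")
            t = make_profile("TD", severity=0.1, pid=f"t{i}")
            var_asd.append(np.var(simulate_recording(a, 1, 2, cfg).data[:, 0]))
            var_td.append(np.var(simulate_recording(t, 1, 2, cfg).data[:, 0]))
        assert stats.mannwhitneyu(var_asd, var_td).pvalue > 0.01

    def test_affected_dim_sd_inflation_law(self):
        """beta=2, severity=1 on an affected dim -> SD ~ 3 * sigma_base * age_factor."""
        profile = make_profile(severity=1.0, age=13.0)
        sds = []
        for i in range(100):
            cfg = self.CFG.with_(rng_seed=100 + i)
            rec = simulate_recording(profile, 1, 2, cfg)
            sds.append(rec.data[:, 0].std())  # dim 0 (head:x) is affected
        expected = 3.0 * self.CFG.sigma_base * age_factor(13.0, "ASD", self.CFG)
        assert np.mean(sds) == pytest.approx(expected, rel=0.05)

    def test_unaffected_dim_ignores_severity(self):
        profile = make_profile(severity=1.0, age=13.0)
        # dim 12 (elbow_L:x) is not in the default affected set
        sds = [
            simulate_recording(profile, 1, 2, self.CFG.with_(rng_seed=300 + i))
            .data[:, 12].std()
            for i in range(20)
        ]
        expected = self.CFG.sigma_base * age_factor(13.0, "ASD", self.CFG)
        assert np.mean(sds) == pytest.approx(expected, rel=0.1)

    def test_missing_cell_count_binomial(self):
        cfg = self.CFG.with_(p_missing=0.001, frames_min=10_000, frames_max=10_000)
        rec = simulate_recording(make_profile(), 1, 2, cfg)
        n_missing = int(np.isnan(rec.data).sum())
        expected = 0.001 * 10_000 * 62  # 620, ~10 per channel
        assert abs(n_missing - expected) < 4 * np.sqrt(expected)


class TestCorruptRecording:
    def test_no_corruption_is_identity(self):
        cfg = SimulationConfig(p_corrupt_file=0.0)
        rec = simulate_recording(make_profile(), 1, 2, cfg)
        out, flag = corrupt_recording(rec, cfg, np.random.default_rng(0))
        assert not flag
        np.testing.assert_array_equal(out.data, rec.data)

    def test_variance_scaling_exact(self):
        cfg = SimulationConfig(p_corrupt_file=1.0, corrupt_scale=100.0, p_missing=0.0)
        rec = simulate_recording(make_profile(), 1, 2, cfg)
        out, flag = corrupt_recording(rec, cfg, np.random.default_rng(0))
        assert flag
        np.testing.assert_allclose(
            np.var(out.data, axis=0), 100.0 * np.var(rec.data, axis=0), rtol=1e-9
        )

    def test_corruption_count_near_binomial_mean(self):
        cfg = SimulationConfig(p_corrupt_file=0.05, frames_min=32, frames_max=32,
                               p_missing=0.0)
        rec = simulate_recording(make_profile(), 1, 2, cfg)
        flags = sum(
            corrupt_recording(rec, cfg, np.random.default_rng(i))[1]
            for i in range(1000)
        )
        sd = np.sqrt(1000 * 0.05 * 0.95)
        assert abs(flags - 50) <= 3 * sd


class TestGenerateDataset:
    CFG = SimulationConfig(
        n_asd=2, n_td=2, sessions=(2, 3, 4), n_poses=10,
        frames_min=64, frames_max=96, rng_seed=13,
    )

    def _checksums(self, root):
        return {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(root.glob("*.tsv"))
        }

    def test_file_count_and_label_bookkeeping(self, tmp_path):
        manifest = generate_dataset(self.CFG, tmp_path / "d")
        assert len(manifest) == 2 * 2 * 3 * 10  # participants x sessions x poses
        labels = list(manifest.labels().values())
        assert labels.count("ASD") == 2 and labels.count("TD") == 2

    def test_regeneration_is_byte_identical(self, tmp_path):
        generate_dataset(self.CFG, tmp_path / "a")
        generate_dataset(self.CFG, tmp_path / "b")
        assert self._checksums(tmp_path / "a") == self._checksums(tmp_path / "b")
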