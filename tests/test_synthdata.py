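"""Generator contracts: geometry, coupling control, projection, cohorts."""

import numpy as np
import pytest

from synchnet import connectivity, spectral, synthdata as sd


def mean_offdiag_theta_plv(signals, fs, epoch_len_s=2.0):
    """Mean pairwise theta PLV over non-overlapping epochs of node signals."""
    n, t = signals.shape
    samp = int(epoch_len_s * fs)
    epochs = signals[:, : (t // samp) * samp].reshape(n, -1, samp).transpose(1, 0, 2)
    cm = connectivity.plv_matrix(epochs, fs, "theta")
    off = ~np.eye(n, dtype=bool)
    return cm.W[off].mean()


class TestForwardModel:
    def test_shapes_and_distinct_seeds(self):
        fm = sd.make_forward_model(62, 500, 148, seed=1)
        assert fm.gain.shape == (62, 500)
        assert len(set(fm.node_seeds.tolist())) == 148

    def test_deterministic_under_seed(self):
        a = sd.make_forward_model(16, 40, 8, seed=5)
        b = sd.make_forward_model(16, 40, 8, seed=5)
        assert np.array_equal(a.gain, b.gain)
        assert np.array_equal(a.node_seeds, b.node_seeds)

    def test_depth_attenuates_column_norms(self):
        fm = sd.make_forward_model(62, 500, 148, seed=1)
        norms = np.linalg.norm(fm.gain, axis=0)
        depth = fm.source_depth
        deep = norms[depth >= np.quantile(depth, 0.9)].mean()
        shallow = norms[depth <= np.quantile(depth, 0.1)].mean()
        assert deep < shallow

    def test_too_many_nodes_rejected(self):
        with pytest.raises(ValueError):
            sd.make_forward_model(16, 10, 11, seed=0)


class TestCoupledSources:
    THETA_ONLY = {b.name: 0.0 for b in spectral.CANONICAL_BANDS} | {"theta": 1.0}

    def test_full_coupling_gives_identical_band_content(self, small_fm):
        spec = sd.CouplingSpec(coupling={"theta": 1.0}, amplitude=self.THETA_ONLY)
        x = sd.simulate_coupled_sources(small_fm, spec, 10.0, 250.0, seed=0)
        th = spectral.bandpass(x, 250.0, "theta")
        mid = slice(500, 2000)
        # theta components of all nodes are the shared driver up to amplitude
        ref = th[0, mid] / np.linalg.norm(th[0, mid])
        for row in th[1:]:
            assert abs(ref @ (row[mid] / np.linalg.norm(row[mid]))) > 0.999

    def test_uncoupled_sources_sit_at_estimator_noise_floor(self, small_fm):
        # within 2-s epochs a 4-8 Hz band carries ~8 independent phase
        # samples, so the Rayleigh resultant floor is ~ sqrt(pi/(4*8)) ~ 0.31:
        # uncoupled sources must stay near that floor, far below coupled ones
        spec = sd.CouplingSpec(coupling={b.name: 0.0 for b in spectral.CANONICAL_BANDS})
        x = sd.simulate_coupled_sources(small_fm, spec, 60.0, 250.0, seed=1)
        assert mean_offdiag_theta_plv(x, 250.0) < 0.4

    def test_coupling_monotonically_increases_plv(self, small_fm):
        means = []
        for c in [0.0, 0.25, 0.5, 0.75, 1.0]:
            spec = sd.CouplingSpec(coupling={"theta": c})
            x = sd.simulate_coupled_sources(small_fm, spec, 30.0, 250.0, seed=2)
            means.append(mean_offdiag_theta_plv(x, 250.0))
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_full_coupling_saturates_plv(self, small_fm):
        spec = sd.CouplingSpec(coupling={"theta": 1.0}, amplitude=self.THETA_ONLY)
        x = sd.simulate_coupled_sources(small_fm, spec, 30.0, 250.0, seed=2)
        assert mean_offdiag_theta_plv(x, 250.0) > 0.999

    def test_unknown_band_rejected(self):
        with pytest.raises(KeyError):
            sd.CouplingSpec(coupling={"sigma": 0.5})

    def test_coupling_range_validated(self):
        with pytest.raises(ValueError):
            sd.CouplingSpec(coupling={"theta": 1.5})


class TestProjection:
    def test_noiseless_projection_is_exact_matrix_product(self, small_fm):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((small_fm.n_nodes, 500))
        raw = sd.project_to_scalp(small_fm, x, fs=250.0, sensor_noise_sd=0.0)
        assert np.array_equal(raw.data, small_fm.gain[:, small_fm.node_seeds] @ x)

    def test_sample_count_preserved_and_eog_appended(self, small_fm):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((small_fm.n_nodes, 750))
        eog = rng.standard_normal(750)
        raw = sd.project_to_scalp(small_fm, x, fs=250.0, eog_signal=eog,
                                  eog_gain=0.5)
        assert raw.n_samples == 750
        assert raw.eog_channels == ("EOG",)
        assert np.array_equal(raw.data[-1], eog)

    def test_frontal_channels_pick_up_eog(self, small_fm):
        spec = sd.CouplingSpec(eog_gain=0.5)
        raw, _ = sd.simulate_subject(small_fm, spec, 30.0, 250.0, seed=3)
        eog = raw.data[raw.eog_picks[0]]
        frontal = np.argmax(np.exp(
            -np.linalg.norm(small_fm.sensor_pos - sd.FRONTAL_POLE, axis=1)))
        r = np.corrcoef(raw.data[frontal], eog)[0, 1]
        assert r > 0.3

    def test_dimension_mismatch_rejected(self, small_fm):
        with pytest.raises(ValueError):
            sd.project_to_scalp(small_fm, np.zeros((3, 100)), fs=250.0)


class TestCohort:
    def _small_spec(self, **kw):
        g1 = sd.GroupSpec(2, sd.CouplingSpec(label="patient",
                                             coupling={"theta": 0.4},
                                             **kw))
        g2 = sd.GroupSpec(2, sd.CouplingSpec(label="control", **kw))
        return sd.CohortSpec(groups=(g1, g2), duration_s=20.0, fs=250.0,
                             n_sensors=16, n_sources=40, n_nodes=8, seed=3)

    def test_subject_counts_match_spec(self):
        cohort = sd.simulate_cohort(self._small_spec())
        assert len(cohort.subjects) == 4
        assert list(cohort.metadata["group"]).count("patient") == 2

    def test_drowsy_fraction_yields_exact_segment_count(self):
        spec = sd.CohortSpec(
            groups=(sd.GroupSpec(1, sd.CouplingSpec(label="g",
                                                    drowsy_fraction=0.2)),),
            duration_s=300.0, fs=250.0, n_sensors=16, n_sources=40, n_nodes=8,
            seed=4)
        cohort = sd.simulate_cohort(spec)
        truth = cohort.ground_truth[cohort.subjects[0].subject]
        assert len(truth["drowsy"]) == 30  # 0.2 x 150 two-second segments

    def test_bit_identical_under_same_spec(self):
        a = sd.simulate_cohort(self._small_spec())
        b = sd.simulate_cohort(self._small_spec())
        assert np.array_equal(a.subjects[0].recording.data,
                              b.subjects[0].recording.data)
        assert a.metadata.equals(b.metadata)

    def test_theta_group_difference_propagates_through_pipeline(self):
        from synchnet import pipeline as pl

        cohort = sd.simulate_cohort(self._small_spec(eog_gain=0.3))
        cfg = pl.PipelineConfig(n_epochs=8)
        strength = {}
        for rec in cohort.subjects:
            out = pl.run_subject(cfg, rec.recording, cohort.forward_model)
            strength.setdefault(rec.group, []).append(out["theta"].strength)
        assert np.mean(strength["patient"]) > np.mean(strength["control"])

    def test_fs_must_resolve_highest_band(self):
        with pytest.raises(ValueError):
            sd.CohortSpec(groups=(sd.GroupSpec(1, sd.CouplingSpec(label="g")),),
                          fs=100.0)
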