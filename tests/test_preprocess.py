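"""Screening chain: referencing, filtering, EOG regression, epoching, rejection."""

import numpy as np
import pytest

from synchnet import preprocess as pp
from synchnet.exceptions import InsufficientEpochsError
from conftest import make_epochset

FS = 1000.0


def make_raw(data, fs=FS, eog=0, reference="original"):
    data = np.asarray(data, float)
    labels = tuple(f"ch{i}" for i in range(data.shape[0]))
    eog_channels = labels[data.shape[0] - eog:] if eog else ()
    return pp.RawRecording(data=data, fs=fs, labels=labels,
                           eog_channels=eog_channels, reference=reference)


class TestAverageReference:
    def test_two_channel_mean_subtraction(self):
        raw = make_raw([[1.0], [3.0]])
        out = pp.rereference_average(raw)
        assert np.allclose(out.data[:, 0], [-1.0, 1.0])
        assert out.reference == "average"

    def test_zero_mean_data_unchanged(self):
        rng = np.random.default_rng(0)
        d = rng.standard_normal((4, 100))
        d -= d.mean(axis=0, keepdims=True)
        out = pp.rereference_average(make_raw(d))
        assert np.allclose(out.data, d)

    def test_column_sums_vanish(self):
        rng = np.random.default_rng(1)
        out = pp.rereference_average(make_raw(rng.standard_normal((7, 500))))
        assert np.abs(out.data.sum(axis=0)).max() < 1e-9

    def test_eog_excluded_and_untouched(self):
        rng = np.random.default_rng(2)
        d = rng.standard_normal((5, 50))
        out = pp.rereference_average(make_raw(d, eog=1))
        assert np.allclose(out.data[4], d[4])  # EOG channel untouched
        assert np.abs(out.data[:4].sum(axis=0)).max() < 1e-9

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            pp.rereference_average(make_raw(np.ones((1, 10))))

    def test_double_referencing_rejected(self):
        raw = make_raw(np.random.default_rng(3).standard_normal((3, 20)))
        with pytest.raises(ValueError):
            pp.rereference_average(pp.rereference_average(raw))


class TestHighpass:
    def test_dc_removed(self):
        raw = make_raw(np.full((2, 10000), 5.0))
        out = pp.highpass(raw, 1.0)
        assert np.abs(out.data).max() < 1e-6

    def test_passband_amplitude_preserved(self):
        t = np.arange(10000) / FS
        raw = make_raw([np.sin(2 * np.pi * 10 * t)])
        out = pp.highpass(raw, 1.0)
        mid = slice(2000, 8000)
        assert np.ptp(out.data[0, mid]) / 2 == pytest.approx(1.0, rel=0.01)

    def test_zero_phase(self):
        t = np.arange(10000) / FS
        x = np.sin(2 * np.pi * 8 * t)
        out = pp.highpass(make_raw([x]), 1.0)
        lags = np.arange(-30, 31)
        xc = [np.dot(x[2000:8000], np.roll(out.data[0], k)[2000:8000]) for k in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_cutoff_beyond_nyquist_rejected(self):
        raw = make_raw(np.zeros((2, 100)), fs=100.0)
        with pytest.raises(ValueError):
            pp.highpass(raw, 60.0)


class TestEOGRegression:
    def _orthogonal_pair(self, n, seed):
        rng = np.random.default_rng(seed)
        eog = rng.standard_normal(n)
        eog -= eog.mean()
        s = rng.standard_normal(n)
        s -= s.mean()
        s -= s @ eog / (eog @ eog) * eog  # make s exactly orthogonal to EOG
        return s, eog

    def test_recovers_known_contamination(self):
        s, eog = self._orthogonal_pair(5000, 0)
        raw = make_raw([s + 0.5 * eog, eog], eog=1)
        out = pp.regress_eog(raw)
        assert np.allclose(out.data[0], s, atol=1e-10)

    def test_output_uncorrelated_with_eog(self):
        rng = np.random.default_rng(1)
        d = rng.standard_normal((4, 3000))
        d[:3] += 0.7 * d[3]
        out = pp.regress_eog(make_raw(d, eog=1))
        for ch in out.data[:3]:
            assert abs(np.corrcoef(ch, d[3])[0, 1]) < 1e-10

    def test_uncontaminated_channels_nearly_unchanged(self):
        rng = np.random.default_rng(2)
        d = rng.standard_normal((3, 5000))
        out = pp.regress_eog(make_raw(d, eog=1))
        change = (out.data[:2] - d[:2]).std()
        assert change < 0.05 * d[:2].std()

    def test_constant_zero_eog_skipped_with_warning(self):
        rng = np.random.default_rng(3)
        d = rng.standard_normal((3, 100))
        d[2] = 0.0
        with pytest.warns(UserWarning, match="constant"):
            out = pp.regress_eog(make_raw(d, eog=1))
        assert np.allclose(out.data[:2], d[:2])

    def test_missing_eog_rejected(self):
        with pytest.raises(ValueError):
            pp.regress_eog(make_raw(np.zeros((2, 100))))


class TestEpoching:
    def test_epoch_counts(self):
        raw = make_raw(np.zeros((3, int(300 * FS))))
        assert pp.epoch(raw, 2.0).n_epochs == 150

    def test_trailing_remainder_discarded(self):
        raw = make_raw(np.zeros((2, int(5 * FS))))
        es = pp.epoch(raw, 2.0)
        assert es.n_epochs == 2

    def test_concatenation_reproduces_input(self):
        rng = np.random.default_rng(0)
        d = rng.standard_normal((3, 5500))
        es = pp.epoch(make_raw(d), 2.0)
        rebuilt = np.concatenate(list(es.epochs), axis=-1)
        assert np.array_equal(rebuilt, d[:, :4000])

    def test_all_statuses_initialized_kept(self):
        es = pp.epoch(make_raw(np.zeros((2, 8000))), 2.0)
        assert es.status_counts()[pp.KEPT] == es.n_epochs


class TestAmplitudeRejection:
    def test_exceeding_sample_rejected(self):
        e = np.zeros((2, 2, 2000))
        e[1, 0, 100] = 80.0
        out = pp.reject_amplitude(make_epochset(e, FS), 75.0)
        assert list(out.status) == [pp.KEPT, pp.REJECTED_AMPLITUDE]

    def test_boundary_is_strict(self):
        e = np.zeros((1, 2, 2000))
        e[0, 0, 0] = 75.0
        out = pp.reject_amplitude(make_epochset(e, FS), 75.0)
        assert out.status[0] == pp.KEPT

    def test_eog_channel_ignored(self):
        e = np.zeros((1, 2, 2000))
        e[0, 1, 0] = 500.0  # EOG blink amplitude must not reject the epoch
        out = pp.reject_amplitude(make_epochset(e, FS, eog=1), 75.0)
        assert out.status[0] == pp.KEPT

    def test_all_zero_epochs_kept(self):
        out = pp.reject_amplitude(make_epochset(np.zeros((3, 2, 2000)), FS), 75.0)
        assert all(s == pp.KEPT for s in out.status)


class TestDrowsinessRejection:
    def _tone_epoch(self, freq, fs=256.0):
        t = np.arange(int(2 * fs)) / fs
        return np.tile(np.sin(2 * np.pi * freq * t), (1, 2, 1))

    def test_theta_dominant_epoch_rejected(self):
        es = make_epochset(self._tone_epoch(6.0), 256.0)
        assert pp.reject_drowsy(es).status[0] == pp.REJECTED_DROWSY

    def test_alpha_dominant_epoch_kept(self):
        es = make_epochset(self._tone_epoch(10.0), 256.0)
        assert pp.reject_drowsy(es).status[0] == pp.KEPT

    def test_zero_alpha_power_treated_as_drowsy(self):
        es = make_epochset(np.zeros((1, 2, 512)), 256.0)
        with pytest.warns(UserWarning, match="zero alpha"):
            out = pp.reject_drowsy(es)
        assert out.status[0] == pp.REJECTED_DROWSY


class TestSelection:
    def test_first_n_retained(self):
        es = make_epochset(np.zeros((120, 2, 500)), 250.0)
        out = pp.select_epochs(es, 30)
        assert np.array_equal(out.kept_indices, np.arange(30))
        assert out.status_counts()[pp.NOT_SELECTED] == 90

    def test_exact_fit_unchanged(self):
        es = make_epochset(np.zeros((30, 2, 500)), 250.0)
        out = pp.select_epochs(es, 30)
        assert out.status_counts()[pp.KEPT] == 30

    def test_insufficient_epochs_error_names_subject(self):
        es = make_epochset(np.zeros((29, 2, 500)), 250.0)
        with pytest.raises(InsufficientEpochsError, match="sub-099"):
            pp.select_epochs(es, 30, subject="sub-099")


class TestStatusPartition:
    def test_statuses_partition_epochs_through_chain(self, screened_subject):
        raw, _ = screened_subject
        r = pp.rereference_average(raw)
        r = pp.highpass(r)
        r = pp.regress_eog(r)
        es = pp.epoch(r, 2.0)
        es = pp.reject_amplitude(es, 75.0)
        es = pp.reject_drowsy(es)
        es = pp.select_epochs(es, 10)
        counts = es.status_counts()
        assert sum(counts.values()) == es.n_epochs
        assert counts[pp.KEPT] == 10

    def test_rejections_recover_injected_ground_truth(self, screened_subject):
        raw, truth = screened_subject
        r = pp.regress_eog(pp.highpass(pp.rereference_average(raw)))
        es = pp.reject_drowsy(pp.reject_amplitude(pp.epoch(r, 2.0), 75.0))
        amp = set(np.flatnonzero(es.status == pp.REJECTED_AMPLITUDE).tolist())
        drowsy = set(np.flatnonzero(es.status == pp.REJECTED_DROWSY).tolist())
        assert amp == set(truth["artifact"])
        assert drowsy == set(truth["drowsy"])
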