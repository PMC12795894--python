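"""Filtering, interpolation, ocular removal, epoching, rejection, mapping."""

import numpy as np
import pytest

from dyadbrain.preprocess import (
    ChannelMap,
    ConfigurationError,
    EmptyResultError,
    InvalidParameterError,
    MappingError,
    apply_bandpass,
    apply_notch,
    auto_threshold,
    epoch,
    interpolate_bads,
    map_channels,
    reject_epochs,
    remove_ocular,
    standard_1010_names,
    standard_positions,
)
from dyadbrain.types import EEGRecording

SFREQ = 250.0


def _sine(freq, duration=30.0, sfreq=SFREQ, n_channels=2):
    t = np.arange(int(duration * sfreq)) / sfreq
    data = np.tile(np.sin(2 * np.pi * freq * t), (n_channels, 1))
    return EEGRecording(data=data, sfreq=sfreq, ch_names=[f"C{i}" for i in range(n_channels)])


def _power_at(rec, freq):
    spec = np.fft.rfft(rec.data[0])
    freqs = np.fft.rfftfreq(rec.n_samples, 1 / rec.sfreq)
    i = int(np.argmin(np.abs(freqs - freq)))
    return np.abs(spec[i]) ** 2


class TestFilters:
    def test_notch_attenuates_line_frequency(self):
        rec = _sine(50.0)
        out = apply_notch(rec, 50.0)
        db = 10 * np.log10(_power_at(out, 50.0) / _power_at(rec, 50.0))
        assert db <= -20

    def test_notch_passband_untouched(self):
        rec = _sine(10.0)
        out = apply_notch(rec, 50.0)
        db = 10 * np.log10(_power_at(out, 10.0) / _power_at(rec, 10.0))
        assert db >= -1

    def test_bandpass_removes_dc(self):
        rec = _sine(10.0)
        rec = rec.copy(data=rec.data + 7.5)
        out = apply_bandpass(rec, 0.5, 48.0)
        assert abs(out.data[0].mean()) <= abs(rec.data[0].mean()) * 10 ** (-20 / 20)

    def test_bandpass_passband_untouched(self):
        rec = _sine(10.0)
        out = apply_bandpass(rec, 0.5, 48.0)
        db = 10 * np.log10(_power_at(out, 10.0) / _power_at(rec, 10.0))
        assert db >= -1

    def test_zero_in_zero_out(self):
        rec = EEGRecording(np.zeros((2, 5000)), SFREQ, ["A", "B"])
        assert np.allclose(apply_notch(rec, 50.0).data, 0)
        assert np.allclose(apply_bandpass(rec, 0.5, 48.0).data, 0)

    def test_invalid_parameters(self):
        rec = _sine(10.0)
        with pytest.raises(InvalidParameterError):
            apply_notch(rec, 200.0)  # beyond Nyquist
        with pytest.raises(InvalidParameterError):
            apply_bandpass(rec, 30.0, 10.0)

    def test_zero_phase_commutes_with_time_reversal(self):
        rng = np.random.default_rng(0)
        rec = EEGRecording(rng.standard_normal((2, 5000)), SFREQ, ["A", "B"])
        fwd = apply_notch(rec, 50.0).data
        rev = apply_notch(rec.copy(data=rec.data[:, ::-1]), 50.0).data[:, ::-1]
        assert np.linalg.norm(fwd - rev) / np.linalg.norm(fwd) < 1e-6


class TestInterpolation:
    @staticmethod
    def _recording(field):
        pos = standard_positions(standard_1010_names)
        data = np.tile(field[:, None], (1, 100))
        return EEGRecording(
            data=data, sfreq=100.0, ch_names=list(standard_1010_names), positions=pos
        )

    def test_no_bads_is_identity(self):
        rec = self._recording(np.ones(61))
        out = interpolate_bads(rec)
        assert np.array_equal(out.data, rec.data)

    def test_constant_field_reproduced(self):
        field = np.full(61, 5.0)
        field[10] = -99.0  # corrupted channel
        rec = self._recording(field)
        rec.bads = [standard_1010_names[10]]
        out = interpolate_bads(rec)
        assert out.bads == []
        assert np.allclose(out.data[10], 5.0, rtol=1e-6)

    def test_smooth_field_leave_one_out(self):
        pos = standard_positions(standard_1010_names)
        field = 2.0 + pos[:, 0] * 3.0 + pos[:, 1] * 1.5 - pos[:, 2]
        truth = field[25]
        corrupted = field.copy()
        corrupted[25] = 50.0
        rec = self._recording(corrupted)
        rec.bads = [standard_1010_names[25]]
        out = interpolate_bads(rec)
        err = abs(out.data[25, 0] - truth) / (field.max() - field.min())
        assert err < 0.05

    def test_missing_positions_error(self):
        rec = EEGRecording(np.zeros((2, 10)), 100.0, ["X1", "X2"], bads=["X1"])
        with pytest.raises(ConfigurationError):
            interpolate_bads(rec)


class TestOcularRemoval:
    @staticmethod
    def _blink_train(n, sfreq, rng):
        sig = np.zeros(n)
        for start in rng.integers(0, n - 100, size=8):
            sig[start : start + 100] += np.hanning(100)
        return sig

    def test_independent_eog_leaves_eeg_untouched(self):
        rng = np.random.default_rng(1)
        eeg = rng.standard_normal((4, 2000))
        eog = rng.standard_normal(2000)
        rec = EEGRecording(
            np.vstack([eeg, eog]), 200.0, ["C1", "C2", "C3", "C4", "EOG"]
        )
        out = remove_ocular(rec, eog_names=["EOG"])
        rel = np.abs(out.data[:4] - eeg).mean() / np.abs(eeg).mean()
        assert rel <= 0.05

    def test_blink_injection_removed(self):
        rng = np.random.default_rng(2)
        n = 2000
        blink = self._blink_train(n, 200.0, rng)
        eeg = 0.2 * rng.standard_normal((3, n))
        eeg[0] += 3.0 * blink  # frontal channel contaminated
        rec = EEGRecording(
            np.vstack([eeg, blink + 0.05 * rng.standard_normal(n)]),
            200.0,
            ["Fp1", "C3", "O1", "EOG"],
        )
        out = remove_ocular(rec, eog_names=["EOG"], threshold=0.8)
        corr = np.corrcoef(out.data[0], rec.data[3])[0, 1]
        assert abs(corr) < 0.8
        assert out.data.shape == rec.data.shape

    def test_frontal_proxy_fallback(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((3, 1000))
        rec = EEGRecording(data, 100.0, ["Fp1", "Fp2", "Cz"])
        out = remove_ocular(rec)  # no explicit EOG: bipolar Fp1-Fp2 proxy
        assert out.data.shape == data.shape

    def test_no_eog_no_frontal_errors(self):
        rec = EEGRecording(np.zeros((2, 100)), 100.0, ["C3", "C4"])
        with pytest.raises(ConfigurationError):
            remove_ocular(rec)


class TestEpoching:
    def test_501_samples_at_500hz(self):
        rec = EEGRecording(np.zeros((1, 5500)), 500.0, ["A"])
        ep = epoch(rec, 1.0)
        assert ep.n_times == 501

    def test_epoch_count_formula(self):
        rec = EEGRecording(np.zeros((1, 5001)), 500.0, ["A"])
        assert epoch(rec, 1.0).n_epochs == 10

    def test_too_short_errors(self):
        rec = EEGRecording(np.zeros((1, 500)), 500.0, ["A"])
        with pytest.raises(EmptyResultError):
            epoch(rec, 1.0)

    def test_windows_reconstruct_signal(self):
        rng = np.random.default_rng(0)
        rec = EEGRecording(rng.standard_normal((2, 1001)), 100.0, ["A", "B"])
        ep = epoch(rec, 1.0)
        parts = [ep.data[0]] + [ep.data[i][:, 1:] for i in range(1, ep.n_epochs)]
        rebuilt = np.concatenate(parts, axis=1)
        assert np.array_equal(rebuilt, rec.data[:, : rebuilt.shape[1]])
        # consecutive epochs share exactly the boundary sample
        assert np.array_equal(ep.data[0][:, -1], ep.data[1][:, 0])


class TestRejection:
    @staticmethod
    def _epochs(n=20, spike_at=None, spike_size=10.0, seed=0):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((n, 3, 101))
        if spike_at is not None:
            data[spike_at, 1, 50] += spike_size
        rec = EEGRecording(
            data.transpose(1, 0, 2).reshape(3, -1)[:, : n * 100 + 1], 100.0, ["a", "b", "c"]
        )
        from dyadbrain.types import EpochArray

        return EpochArray(data=data, sfreq=100.0, epoch_len=1.0)

    def test_zero_epochs_none_rejected(self):
        from dyadbrain.types import EpochArray

        ep = EpochArray(np.zeros((5, 2, 101)), 100.0, 1.0)
        out = reject_epochs(ep, threshold=1.0)
        assert out.n_epochs == 5

    def test_spiked_epoch_dropped_exactly(self):
        ep = self._epochs(spike_at=7, spike_size=100.0)
        thr = float(np.quantile((ep.data.max(2) - ep.data.min(2)).max(1), 0.9))
        out = reject_epochs(ep, threshold=thr)
        assert 7 not in out.kept_indices
        # survivors are bit-identical
        for row, orig in zip(out.data, ep.data[out.kept_indices]):
            assert np.array_equal(row, orig)

    def test_all_rejected_errors(self):
        ep = self._epochs()
        with pytest.raises(EmptyResultError):
            reject_epochs(ep, threshold=1e-9)

    def test_auto_matches_exhaustive_grid(self):
        ep = self._epochs(spike_at=3, spike_size=30.0)
        thr, scores = auto_threshold(ep.data)
        # independent re-scoring of every candidate
        ptp = (ep.data.max(2) - ep.data.min(2)).max(1)
        cands = np.quantile(ptp, (0.6, 0.7, 0.8, 0.9, 0.95, 1.0))
        oracle = []
        folds = np.array_split(np.arange(ep.n_epochs), 5)
        for cand in cands:
            total = 0.0
            for f in folds:
                mask = np.ones(ep.n_epochs, bool)
                mask[f] = False
                keep = mask & (ptp <= cand)
                if not keep.any():
                    total = np.inf
                    break
                total += float(
                    np.sqrt(np.mean((ep.data[keep].mean(0) - np.median(ep.data[f], 0)) ** 2))
                )
            oracle.append(total)
        assert thr == cands[int(np.argmin(oracle))]
        assert np.allclose(scores, oracle)


class TestChannelMapping:
    def test_identity_map(self):
        rec = _sine(10.0, duration=1.0, n_channels=3)
        out = map_channels(rec, ChannelMap.identity(rec.ch_names))
        assert out.ch_names == rec.ch_names
        assert np.array_equal(out.data, rec.data)

    def test_unknown_source_errors(self):
        rec = _sine(10.0, duration=1.0, n_channels=2)
        with pytest.raises(MappingError):
            map_channels(rec, ChannelMap((("nope", "X"),)))

    def test_dense_to_sparse_mapping(self, tmp_path):
        rng = np.random.default_rng(0)
        names = [f"E{i}" for i in range(128)]
        rec = EEGRecording(rng.standard_normal((128, 50)), 500.0, names)
        sources = names[: 61 * 2 : 2]
        csv = tmp_path / "map.csv"
        csv.write_text(
            "source,target\n"
            + "\n".join(f"{s},{t}" for s, t in zip(sources, standard_1010_names))
        )
        cmap = ChannelMap.from_csv(str(csv))
        out = map_channels(rec, cmap)
        assert out.ch_names == list(standard_1010_names)
        assert out.n_channels == 61
        # data rows follow map order
        idx = [names.index(s) for s in sources]
        assert np.array_equal(out.data, rec.data[idx])
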