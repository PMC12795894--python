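"""Deterministic EEG preprocessing: filters, interpolation, ocular cleanup,
epoching, artifact rejection, and montage mapping.

Filtering and spherical-spline bad-channel interpolation delegate to mne
(zero-phase Hamming-window FIR, ``firwin`` design).  Two stages that in full
clinical pipelines use heavyweight learned components are implemented here as
deliberately simple, deterministic procedures:

* ocular-artifact removal is a regression projector — any EEG channel whose
  absolute correlation with the EOG trace (or a frontal bipolar proxy)
  exceeds a threshold has the least-squares EOG contribution subtracted;
* epoch rejection is a global peak-to-peak threshold, optionally selected
  from a quantile grid by cross-validated reconstruction error (mean of the
  surviving training epochs vs the median of the held-out epochs).

Epoching uses an inclusive-endpoint convention: a 1-s epoch at 500 Hz spans
501 samples and consecutive epochs share exactly one boundary sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import EEGRecording, EpochArray

__all__ = [
    "apply_notch",
    "apply_bandpass",
    "interpolate_bads",
    "remove_ocular",
    "epoch",
    "reject_epochs",
    "map_channels",
    "ChannelMap",
    "standard_1010_names",
    "standard_positions",
    "InvalidParameterError",
    "ConfigurationError",
    "EmptyResultError",
    "MappingError",
]


class InvalidParameterError(ValueError):
    """A filter or rejection parameter is out of range."""


class ConfigurationError(ValueError):
    """The recording lacks information (positions, EOG) the step needs."""


class EmptyResultError(ValueError):
    """The operation would return no data."""


class MappingError(KeyError):
    """A channel-map source cannot be resolved in the recording."""


# A 61-channel subset of the extended 10-10 system, used as the default
# montage for synthetic data (positions resolved from mne's standard_1005).
standard_1010_names: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)


def standard_positions(ch_names: list[str] | tuple[str, ...]) -> np.ndarray:
    """Head-frame 3-D positions for 10-10 channel names (meters)."""
    import mne

    try:
        montage = mne.channels.make_standard_montage("colin27_1005")
    except ValueError:  # older mne releases use the previous montage name
        montage = mne.channels.make_standard_montage("standard_1005")
    pos_map = montage.get_positions()["ch_pos"]
    missing = [n for n in ch_names if n not in pos_map]
    if missing:
        raise ConfigurationError(f"no standard position for channels: {missing}")
    return np.array([pos_map[n] for n in ch_names])


def _nyquist(rec: EEGRecording) -> float:
    return rec.sfreq / 2.0


def apply_notch(rec: EEGRecording, freq: float = 50.0, width: float = 2.0) -> EEGRecording:
    """Zero-phase FIR band-stop around a line frequency (default 50 Hz).

    The recording's shape is preserved; ``freq`` must lie below Nyquist.
    """
    import mne

    if not 0 < freq < _nyquist(rec):
        raise InvalidParameterError(
            f"notch frequency {freq} outside (0, {_nyquist(rec)})"
        )
    data = mne.filter.notch_filter(
        rec.data,
        Fs=rec.sfreq,
        freqs=[freq],
        notch_widths=width,
        method="fir",
        fir_design="firwin",
        phase="zero",
        verbose="error",
    )
    return rec.copy(data=data)


def apply_bandpass(rec: EEGRecording, low: float = 0.1, high: float = 48.0) -> EEGRecording:
    """Zero-phase FIR band-pass (default 0.1-48 Hz), shape preserved."""
    import mne

    if not 0 < low < high < _nyquist(rec):
        raise InvalidParameterError(
            f"band ({low}, {high}) invalid for sfreq {rec.sfreq}"
        )
    data = mne.filter.filter_data(
        rec.data,
        sfreq=rec.sfreq,
        l_freq=low,
        h_freq=high,
        method="fir",
        fir_design="firwin",
        phase="zero",
        verbose="error",
    )
    return rec.copy(data=data)


def interpolate_bads(rec: EEGRecording) -> EEGRecording:
    """Replace bad channels with spherical-spline estimates from good ones.

    Requires per-channel positions (``rec.positions`` or resolvable standard
    10-10 names).  Good channels are untouched; ``bads`` is cleared in the
    output.  With no bad channels this is the identity.
    """
    import mne

    if not rec.bads:
        return rec.copy()
    if rec.positions is not None:
        positions = rec.positions
    else:
        positions = standard_positions(rec.ch_names)
    info = mne.create_info(list(rec.ch_names), rec.sfreq, ch_types="eeg")
    raw = mne.io.RawArray(rec.data.copy(), info, verbose="error")
    montage = mne.channels.make_dig_montage(
        ch_pos=dict(zip(rec.ch_names, positions)), coord_frame="head"
    )
    raw.set_montage(montage, verbose="error")
    raw.info["bads"] = list(rec.bads)
    raw.interpolate_bads(reset_bads=True, verbose="error")
    out = rec.copy(data=raw.get_data())
    out.bads = []
    return out


def _frontal_proxy(rec: EEGRecording) -> np.ndarray | None:
    """Bipolar EOG proxy from frontal sensors (Fp/AF pairs), if available."""
    frontal = [n for n in rec.ch_names if n.upper().startswith(("FP", "AF"))]
    if len(frontal) < 2:
        return None
    i = rec.ch_names.index(frontal[0])
    j = rec.ch_names.index(frontal[-1])
    return rec.data[i] - rec.data[j]


def remove_ocular(
    rec: EEGRecording,
    eog_names: list[str] | None = None,
    threshold: float = 0.8,
) -> EEGRecording:
    """Regress the ocular signal out of strongly correlated EEG channels.

    The reference trace is the mean of the named EOG channels, or a frontal
    bipolar proxy when none are given.  Channels with ``|corr| > threshold``
    against the reference have their least-squares EOG projection removed;
    all other channels (and the EOG channels themselves) pass through
    unchanged, so the channel count is preserved.
    """
    if eog_names:
        missing = [n for n in eog_names if n not in rec.ch_names]
        if missing:
            raise ConfigurationError(f"EOG channels not in recording: {missing}")
        idx = [rec.ch_names.index(n) for n in eog_names]
        eog = rec.data[idx].mean(axis=0)
        protected = set(idx)
    else:
        proxy = _frontal_proxy(rec)
        if proxy is None:
            raise ConfigurationError(
                "no EOG channels given and no frontal sensors to derive a proxy"
            )
        eog = proxy
        protected = set()
    eog_c = eog - eog.mean()
    denom = float(eog_c @ eog_c)
    if denom == 0:
        return rec.copy()
    data = rec.data.copy()
    for c in range(rec.n_channels):
        if c in protected:
            continue
        ch = data[c] - data[c].mean()
        cov = float(ch @ eog_c)
        sd = np.sqrt(float(ch @ ch) * denom)
        corr = cov / sd if sd > 0 else 0.0
        if abs(corr) > threshold:
            data[c] = data[c] - (cov / denom) * eog_c
    return rec.copy(data=data)


def epoch(rec: EEGRecording, epoch_len: float = 1.0) -> EpochArray:
    """Cut the recording into fixed epochs (inclusive-endpoint convention).

    ``T = round(epoch_len * sfreq) + 1`` samples per epoch, hop of ``T - 1``,
    so consecutive epochs share one boundary sample and concatenating windows
    (dropping each epoch's first sample after the first epoch) reconstructs
    the covered part of the signal exactly.
    """
    hop = round(epoch_len * rec.sfreq)
    t = hop + 1
    n = rec.n_samples
    if n < t:
        raise EmptyResultError(
            f"recording of {n} samples shorter than one epoch ({t} samples)"
        )
    n_epochs = (n - t) // hop + 1
    data = np.stack([rec.data[:, i * hop : i * hop + t] for i in range(n_epochs)])
    return EpochArray(data=data, sfreq=rec.sfreq, epoch_len=epoch_len)


def _ptp_per_epoch(data: np.ndarray) -> np.ndarray:
    """Max across channels of each epoch's peak-to-peak amplitude."""
    return (data.max(axis=2) - data.min(axis=2)).max(axis=1)


def auto_threshold(
    data: np.ndarray,
    quantiles: tuple[float, ...] = (0.6, 0.7, 0.8, 0.9, 0.95, 1.0),
    n_folds: int = 5,
) -> tuple[float, np.ndarray]:
    """Pick a global peak-to-peak threshold by cross-validated reconstruction.

    Candidates are quantiles of the per-epoch ptp distribution.  For each
    candidate and fold, epochs in the training folds whose ptp does not exceed
    the candidate are averaged and compared (RMS) to the median of the
    held-out fold; the candidate with the lowest summed error wins (ties go to
    the smaller threshold).  Returns ``(threshold, per-candidate scores)``.
    """
    ptp = _ptp_per_epoch(data)
    cands = np.quantile(ptp, quantiles)
    e = data.shape[0]
    n_folds = min(n_folds, e)
    folds = np.array_split(np.arange(e), n_folds)
    scores = np.zeros(len(cands))
    for ci, thr in enumerate(cands):
        total = 0.0
        for f in folds:
            train_mask = np.ones(e, dtype=bool)
            train_mask[f] = False
            keep = train_mask & (ptp <= thr)
            if not keep.any():
                total = np.inf
                break
            mean_train = data[keep].mean(axis=0)
            med_test = np.median(data[f], axis=0)
            total += float(np.sqrt(np.mean((mean_train - med_test) ** 2)))
        scores[ci] = total
    best = int(np.argmin(scores))  # argmin takes the first (smallest) on ties
    return float(cands[best]), scores


def reject_epochs(ep: EpochArray, threshold: float | str = "auto") -> EpochArray:
    """Drop epochs whose maximum peak-to-peak amplitude exceeds a threshold.

    ``threshold`` may be a number or ``"auto"`` (cross-validated quantile
    grid, see :func:`auto_threshold`).  Surviving epochs are bit-identical to
    their inputs; ``kept_indices`` records the survivors.  Raises
    :class:`EmptyResultError` when everything is rejected.
    """
    if ep.n_epochs < 1:
        raise EmptyResultError("no epochs to reject from")
    if isinstance(threshold, str):
        if threshold != "auto":
            raise InvalidParameterError(f"unknown threshold mode {threshold!r}")
        thr, _ = auto_threshold(ep.data)
    else:
        thr = float(threshold)
        if thr <= 0:
            raise InvalidParameterError("threshold must be positive")
    ptp = _ptp_per_epoch(ep.data)
    keep = ptp <= thr
    if not keep.any():
        raise EmptyResultError(
            f"all {ep.n_epochs} epochs exceed threshold {thr:.4g} "
            f"(ptp range {ptp.min():.4g}..{ptp.max():.4g})"
        )
    return EpochArray(
        data=ep.data[keep],
        sfreq=ep.sfreq,
        epoch_len=ep.epoch_len,
        kept_indices=ep.kept_indices[keep],
    )


@dataclass(frozen=True)
class ChannelMap:
    """Ordered (source, target) channel renaming/selection pairs.

    Mirrors the montage-alignment table used to map a dense montage onto a
    sparser reference montage; loaded from CSV with header ``source,target``.
    """

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        targets = [t for _, t in self.pairs]
        if len(set(targets)) != len(targets):
            raise ValueError("target channel names must be unique")

    @classmethod
    def from_csv(cls, path: str) -> "ChannelMap":
        df = pd.read_csv(path)
        if not {"source", "target"} <= set(df.columns):
            raise ValueError("channel map CSV needs 'source' and 'target' columns")
        return cls(tuple(zip(df["source"].astype(str), df["target"].astype(str))))

    @classmethod
    def identity(cls, ch_names: list[str] | tuple[str, ...]) -> "ChannelMap":
        return cls(tuple((n, n) for n in ch_names))


def map_channels(rec: EEGRecording, cmap: ChannelMap) -> EEGRecording:
    """Select and rename channels according to the map, in map order."""
    rows = []
    new_names = []
    new_pos = [] if rec.positions is not None else None
    new_bads = []
    for source, target in cmap.pairs:
        if source not in rec.ch_names:
            raise MappingError(f"channel map source {source!r} not in recording")
        i = rec.ch_names.index(source)
        rows.append(rec.data[i])
        new_names.append(target)
        if new_pos is not None:
            new_pos.append(rec.positions[i])
        if source in rec.bads:
            new_bads.append(target)
    return EEGRecording(
        data=np.array(rows),
        sfreq=rec.sfreq,
        ch_names=new_names,
        bads=new_bads,
        positions=None if new_pos is None else np.array(new_pos),
    )
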