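"""EDF (European Data Format) on-disk storage for recordings.

Reading delegates to ``mne.io.read_raw_edf``.  Writing is a minimal EDF
implementation (16-bit samples, 1-second data records, ``uV`` physical
dimension) because no EDF *writer* is part of this package's dependency set.
The two directions are cross-checked in the test suite: a file produced here
must round-trip through the mne reader within one quantization step.

Limitations (documented, not silent): recordings are padded with zeros up to a
whole number of 1-second records; ``bads`` and sensor positions are not stored
in EDF and are dropped on write.
"""

from __future__ import annotations

import math
import os

import numpy as np

from .types import EEGRecording

__all__ = ["write_edf", "read_edf", "EDFFormatError"]

_DIG_MIN, _DIG_MAX = -32768, 32767


class EDFFormatError(ValueError):
    """The file violates the EDF layout or this writer's preconditions."""


def _ascii(value: str, width: int) -> bytes:
    s = value[:width].ljust(width)
    return s.encode("ascii")


def _fit8(x: float) -> str:
    """Render a float into at most 8 ASCII characters (EDF header fields)."""
    for fmt in ("%g", "%.5g", "%.4g", "%.3g", "%.2g", "%.1g"):
        s = fmt % x
        if len(s) <= 8:
            return s
    raise EDFFormatError(f"cannot encode {x!r} in 8 characters")


def write_edf(recording: EEGRecording, path: str | os.PathLike) -> None:
    """Write a recording as 16-bit EDF with one data record per second.

    Samples are stored in microvolt physical units with per-channel physical
    ranges, so the quantization step is ``(max - min) / 65535`` per channel.
    Non-integer sampling rates are not representable in 1-s records and raise.
    """
    if len(set(recording.ch_names)) != len(recording.ch_names):
        raise EDFFormatError("duplicate channel names")
    spr = round(recording.sfreq)
    if abs(spr - recording.sfreq) > 1e-9 or spr < 1:
        raise EDFFormatError("EDF writer requires an integer sampling rate")
    data = recording.data
    c, n = data.shape
    n_records = max(1, math.ceil(n / spr))
    padded = np.zeros((c, n_records * spr))
    padded[:, :n] = data

    # physical ranges must be re-parsed from their 8-char ASCII encodings so
    # that the scaling the reader reconstructs is the one used to digitize
    pmins, pmaxs = [], []
    for ch in padded:
        lo, hi = float(ch.min()), float(ch.max())
        if hi <= lo:
            hi = lo + 1.0
        lo_s, hi_s = _fit8(lo), _fit8(hi)
        lo_p, hi_p = float(lo_s), float(hi_s)
        if hi_p <= lo_p:  # rounding collapsed the interval
            hi_p = lo_p + 1.0
            hi_s = _fit8(hi_p)
        pmins.append((lo_p, lo_s))
        pmaxs.append((hi_p, hi_s))

    header = bytearray()
    header += _ascii("0", 8)
    header += _ascii("X X X X", 80)  # local patient identification
    header += _ascii("Startdate 01-JAN-2000 X X X", 80)
    header += _ascii("01.01.00", 8)
    header += _ascii("00.00.00", 8)
    header += _ascii(str(256 * (1 + c)), 8)
    header += _ascii("", 44)
    header += _ascii(str(n_records), 8)
    header += _ascii("1", 8)  # record duration, seconds
    header += _ascii(str(c), 4)
    for name in recording.ch_names:
        header += _ascii(name, 16)
    header += _ascii("", 80) * c  # transducer
    header += _ascii("uV", 8) * c
    for lo, lo_s in pmins:
        header += _ascii(lo_s, 8)
    for hi, hi_s in pmaxs:
        header += _ascii(hi_s, 8)
    header += _ascii(str(_DIG_MIN), 8) * c
    header += _ascii(str(_DIG_MAX), 8) * c
    header += _ascii("", 80) * c  # prefiltering
    header += _ascii(str(spr), 8) * c
    header += _ascii("", 32) * c

    digital = np.empty((c, n_records * spr), dtype="<i2")
    for i, ch in enumerate(padded):
        lo, hi = pmins[i][0], pmaxs[i][0]
        gain = (_DIG_MAX - _DIG_MIN) / (hi - lo)
        dig = np.rint((np.clip(ch, lo, hi) - lo) * gain + _DIG_MIN)
        digital[i] = dig.astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            sl = digital[:, r * spr : (r + 1) * spr]
            fh.write(sl.tobytes())


def _check_unique_labels(path: str | os.PathLike) -> None:
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise EDFFormatError("truncated EDF header")
        try:
            ns = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise EDFFormatError("malformed EDF header") from exc
        labels_raw = fh.read(16 * ns)
    labels = [
        labels_raw[i * 16 : (i + 1) * 16].decode("ascii", "replace").strip()
        for i in range(ns)
    ]
    if len(set(labels)) != len(labels):
        raise EDFFormatError("duplicate channel names in EDF file")


def read_edf(path: str | os.PathLike) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (microvolt-scale units).

    Channel order and names are preserved.  Raises :class:`EDFFormatError` for
    malformed files, including duplicate channel labels.
    """
    import mne

    if not os.path.exists(path):
        raise EDFFormatError(f"no such file: {path}")
    _check_unique_labels(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on malformed input
        raise EDFFormatError(f"cannot parse EDF file {path}: {exc}") from exc
    data = raw.get_data() * 1e6  # mne scales uV channels to volts
    return EEGRecording(
        data=data, sfreq=float(raw.info["sfreq"]), ch_names=list(raw.ch_names)
    )
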