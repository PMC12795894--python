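"""Synthetic resting-state EEG and labeled hyperscanning dyads.

Real hyperscanning corpora are either very large (single-brain resting EEG for
pretraining) or not shareable (clinical dyads), so every stage of the pipeline
is exercised on synthetic data with the statistical structure the method
assumes:

* **Single-brain recordings** are sums of band-limited oscillations (alpha by
  default) whose amplitudes drift slowly under an Ornstein-Uhlenbeck (OU)
  modulation, on top of 1/f-shaped Gaussian background noise.  The slow drift
  is what makes temporal order learnable: epochs close in time share a similar
  spectral state, so a temporal-shuffling label can be predicted from epoch
  embeddings.
* **Dyads** are pairs of such recordings with two controllable group effects:
  an alpha-power asymmetry applied to one member of a mixed (ASC-TD) dyad, and
  an inter-member oscillation phase coupling that can differ between groups
  (mixed dyads default to weaker coupling, emulating reduced inter-brain
  synchrony).

Every generator is a pure function of its config, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .types import EEGRecording, InvalidConfigError

__all__ = [
    "SynthConfig",
    "DyadConfig",
    "generate_recording",
    "generate_dyad",
    "make_pretext_recordings",
    "make_dyad_recordings",
]

ALPHA_BAND = (8.0, 12.0)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic resting-state recording.

    Defaults emulate a 61-channel montage sampled at 500 Hz with a multi-
    rhythm spectrum (delta through beta, alpha dominant at 10 Hz) over 1/f
    background noise.  Oscillation amplitudes drift under independent
    Ornstein-Uhlenbeck processes per channel and oscillation (timescale
    ``drift_timescale``), giving a rich multi-coordinate spectral state whose
    distance between two epochs grows with their temporal separation — the
    structure the temporal-shuffling task relies on.
    """

    n_channels: int = 61
    sfreq: float = 500.0
    duration: float = 60.0
    osc_freqs: tuple[float, ...] = (3.0, 6.0, 10.0, 16.0, 25.0)
    osc_base_amp: float = 1.5
    drift_timescale: float = 20.0
    drift_rel_std: float = 0.6
    noise_std: float = 0.5
    noise_exponent: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels < 1:
            raise InvalidConfigError("n_channels must be >= 1")
        if self.sfreq <= 0 or self.duration <= 0:
            raise InvalidConfigError("sfreq and duration must be positive")
        if self.osc_base_amp < 0 or self.noise_std < 0 or self.drift_rel_std < 0:
            raise InvalidConfigError("amplitudes must be >= 0")
        if self.drift_timescale <= 0:
            raise InvalidConfigError("drift_timescale must be positive")
        if any(f <= 0 or f >= self.sfreq / 2 for f in self.osc_freqs):
            raise InvalidConfigError("osc_freqs must lie in (0, Nyquist)")


@dataclass(frozen=True)
class DyadConfig:
    """Parameters of one synthetic dyad.

    ``group_label`` 0 is a control (TD-TD) dyad, 1 a mixed (ASC-TD) dyad.  When
    ``group_label == 1`` exactly one member (the first) has its alpha-band
    oscillation amplitude multiplied by ``alpha_power_ratio``.  ``coupling`` in
    [0, 1] sets inter-member phase alignment of the shared oscillations: 1 is
    perfect phase locking, 0 leaves phases unrelated.
    """

    base: SynthConfig = field(default_factory=SynthConfig)
    group_label: int = 0
    alpha_power_ratio: float = 1.5
    coupling: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        self.base.validate()
        if self.group_label not in (0, 1):
            raise InvalidConfigError("group_label must be 0 or 1")
        if not self.alpha_power_ratio > 0:
            raise InvalidConfigError("alpha_power_ratio must be > 0")
        if not 0.0 <= self.coupling <= 1.0:
            raise InvalidConfigError("coupling must be in [0, 1]")


def _ou_paths(
    rng: np.random.Generator, shape: tuple[int, ...], n: int, dt: float, tau: float, sigma: float
) -> np.ndarray:
    """Stationary OU sample paths, shape ``shape + (n,)``.

    Exact AR(1) discretization: x[t] = a x[t-1] + b eps[t] with
    a = exp(-dt/tau) and stationary standard deviation ``sigma``.
    """
    a = np.exp(-dt / tau)
    b = sigma * np.sqrt(1.0 - a * a)
    eps = rng.standard_normal(shape + (n,))
    x0 = sigma * rng.standard_normal(shape)
    x = lfilter([1.0], [1.0, -a], b * eps, axis=-1)
    # fold in the stationary initial condition (decays geometrically)
    x += x0[..., None] * a ** np.arange(1, n + 1)
    return x


def _pink_noise(
    rng: np.random.Generator, n_channels: int, n: int, sfreq: float, std: float, exponent: float
) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f**exponent, unit-free std."""
    if std == 0:
        return np.zeros((n_channels, n))
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, 1.0 / sfreq)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = scale[1] if n > 1 else 1.0
    shaped = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd * std


def _synthesize(
    cfg: SynthConfig,
    rng: np.random.Generator,
    phases: np.ndarray,
    alpha_scale: float = 1.0,
) -> np.ndarray:
    """Build the (C, N) signal from explicit per-channel/oscillation phases."""
    n = round(cfg.duration * cfg.sfreq)
    t = np.arange(n) / cfg.sfreq
    n_osc = len(cfg.osc_freqs)
    data = _pink_noise(rng, cfg.n_channels, n, cfg.sfreq, cfg.noise_std, cfg.noise_exponent)
    if n_osc and cfg.osc_base_amp > 0:
        drift = _ou_paths(
            rng,
            (cfg.n_channels, n_osc),
            n,
            1.0 / cfg.sfreq,
            cfg.drift_timescale,
            cfg.drift_rel_std,
        )
        amp = cfg.osc_base_amp * np.maximum(0.0, 1.0 + drift)
        for o, f in enumerate(cfg.osc_freqs):
            scale = alpha_scale if ALPHA_BAND[0] <= f <= ALPHA_BAND[1] else 1.0
            carrier = np.sin(2 * np.pi * f * t[None, :] + phases[:, o, None])
            data += scale * amp[:, o, :] * carrier
    return data


def _ch_names(n: int) -> list[str]:
    return [f"EEG{i + 1:03d}" for i in range(n)]


def generate_recording(config: SynthConfig) -> EEGRecording:
    """Generate one synthetic single-brain recording.

    The output has ``n_channels x round(duration * sfreq)`` samples; identical
    configs (including seed) produce bit-identical arrays.
    """
    config.validate()
    min_len = round(config.sfreq) + 1  # one inclusive-endpoint 1-s epoch
    if round(config.duration * config.sfreq) < min_len:
        raise InvalidConfigError("duration too short for a single epoch")
    rng = np.random.default_rng(config.seed)
    phases = rng.uniform(0, 2 * np.pi, size=(config.n_channels, len(config.osc_freqs)))
    data = _synthesize(config, rng, phases)
    return EEGRecording(data=data, sfreq=config.sfreq, ch_names=_ch_names(config.n_channels))


def generate_dyad(config: DyadConfig) -> tuple[EEGRecording, EEGRecording, int]:
    """Generate one synthetic dyad: two equal-length recordings plus the label.

    Member 1 of a mixed dyad carries the alpha-power scaling; the phase offset
    between members shrinks as ``coupling`` grows (offset ``(1 - coupling) *
    eta`` with ``eta ~ U(-pi, pi)`` per channel and oscillation), so phase
    alignment increases monotonically with coupling.
    """
    config.validate()
    cfg = config.base
    rng = np.random.default_rng(config.seed)
    n_osc = len(cfg.osc_freqs)
    phases1 = rng.uniform(0, 2 * np.pi, size=(cfg.n_channels, n_osc))
    eta = rng.uniform(-np.pi, np.pi, size=(cfg.n_channels, n_osc))
    phases2 = phases1 + (1.0 - config.coupling) * eta
    alpha_scale = config.alpha_power_ratio if config.group_label == 1 else 1.0
    data1 = _synthesize(cfg, rng, phases1, alpha_scale=alpha_scale)
    data2 = _synthesize(cfg, rng, phases2, alpha_scale=1.0)
    rec1 = EEGRecording(data=data1, sfreq=cfg.sfreq, ch_names=_ch_names(cfg.n_channels))
    rec2 = EEGRecording(data=data2, sfreq=cfg.sfreq, ch_names=_ch_names(cfg.n_channels))
    return rec1, rec2, config.group_label


def make_pretext_recordings(
    n_recordings: int, base: SynthConfig | None = None, seed: int = 0
) -> list[EEGRecording]:
    """A set of independent single-brain recordings for pretext training."""
    base = base if base is not None else SynthConfig()
    seeds = np.random.SeedSequence(seed).generate_state(n_recordings)
    return [
        generate_recording(replace(base, seed=int(s) % (2**31 - 1))) for s in seeds
    ]


def make_dyad_recordings(
    n_per_class: int,
    base: SynthConfig | None = None,
    seed: int = 0,
    alpha_power_ratio: float = 1.5,
    coupling_control: float = 0.3,
    coupling_mixed: float = 0.1,
) -> list[tuple[EEGRecording, EEGRecording, int]]:
    """Balanced labeled dyads: ``n_per_class`` control and mixed dyads each.

    Defaults encode the two group effects (alpha asymmetry 1.5 on one member of
    mixed dyads; weaker coupling in mixed dyads).  Setting
    ``alpha_power_ratio=1`` and ``coupling_control == coupling_mixed`` makes
    the label carry no signal (the null condition).
    """
    base = base if base is not None else SynthConfig()
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_per_class)
    out: list[tuple[EEGRecording, EEGRecording, int]] = []
    for i, s in enumerate(seeds):
        label = i % 2
        cfg = DyadConfig(
            base=base,
            group_label=label,
            alpha_power_ratio=alpha_power_ratio,
            coupling=coupling_mixed if label == 1 else coupling_control,
            seed=int(s) % (2**31 - 1),
        )
        out.append(generate_dyad(cfg))
    return out
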