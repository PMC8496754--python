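"""Synthetic SSVEP sessions with the structure the classifier assumes.

Emulates a 40-target speller recording: flicker frequencies 8.0-15.8 Hz in
0.2 Hz steps with phases cycling 0, pi/2, pi, 3pi/2; harmonic responses
concentrated over occipital/parieto-occipital channels; 1/f ("pink") plus
white background noise with a spatially correlated common-mode component; a
noise-only pre-stimulation interval so selection-time accounting is exercised
end to end.  Every epoch is deterministic under its seed.

The signal placed on channel ``c`` from stimulation onset is

    g_c * sum_h A_h * sin(2*pi*h*f*t + h*phi),

with ``t = 0`` at onset, per-channel gain ``g_c`` peaked over O/PO sites, and
harmonic amplitudes ``A_h`` decaying with harmonic number.  The requested SNR
(in dB) is the ratio of signal power to noise power over the stimulation
interval averaged across the occipital channels O1/Oz/O2; the noise is scaled
globally to realize it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .signal_model import EpochData, StimulusGrid

__all__ = [
    "BENCHMARK_CHANNELS_64",
    "SyntheticConfig",
    "benchmark_grid",
    "default_spatial_gains",
    "generate_epoch",
    "generate_session",
    "estimate_snr_db",
]

#: Standard 64-channel montage (extended 10-10 order) used by public
#: 40-target SSVEP benchmark recordings; CB1/CB2 are the cerebellar sites.
BENCHMARK_CHANNELS_64: Tuple[str, ...] = (
    "FP1", "FPZ", "FP2", "AF3", "AF4", "F7", "F5", "F3", "F1", "FZ",
    "F2", "F4", "F6", "F8", "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2",
    "FC4", "FC6", "FT8", "T7", "C5", "C3", "C1", "CZ", "C2", "C4",
    "C6", "T8", "M1", "TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4",
    "CP6", "TP8", "M2", "P7", "P5", "P3", "P1", "PZ", "P2", "P4",
    "P6", "P8", "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8", "CB1",
    "O1", "OZ", "O2", "CB2",
)

_OCCIPITAL = ("O1", "OZ", "O2")


def benchmark_grid() -> StimulusGrid:
    """The 40-target grid: 8.0-15.8 Hz in 0.2 Hz steps, phases cycling
    0, pi/2, pi, 3pi/2."""
    freqs = 8.0 + 0.2 * np.arange(40)
    phases = (np.arange(40) % 4) * (np.pi / 2)
    return StimulusGrid(frequencies=freqs, phases=phases)


def default_spatial_gains(labels: Sequence[str]) -> np.ndarray:
    """SSVEP topography profile: strongest at O, fading toward parietal sites."""
    gains = np.empty(len(labels))
    for i, lab in enumerate(labels):
        key = lab.upper()
        if key.startswith("O"):
            gains[i] = 1.0
        elif key.startswith("CB"):
            gains[i] = 0.85
        elif key.startswith("PO"):
            gains[i] = 0.7
        elif key.startswith(("CP", "TP")):
            gains[i] = 0.15
        elif key.startswith("P"):
            gains[i] = 0.45
        else:
            gains[i] = 0.03
    return gains


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic recording.

    ``duration_s`` includes the ``prestim_s`` noise-only interval; at the
    defaults (3.0 s total at 250 Hz) every epoch supports the full 0.7-2.1 s
    analysis-window schedule.  ``snr_db = inf`` produces noiseless epochs.
    """

    grid: StimulusGrid = field(default_factory=benchmark_grid)
    fs: float = 250.0
    duration_s: float = 3.0
    prestim_s: float = 0.5
    n_harmonics: int = 3
    harmonic_amps: Tuple[float, ...] = (1.0, 0.5, 0.25)
    channels: Tuple[str, ...] = BENCHMARK_CHANNELS_64
    spatial_gains: Optional[np.ndarray] = None
    snr_db: float = 0.0
    noise_model: str = "mixed"  # {white, pink, mixed}
    common_mode_fraction: float = 0.5
    white_fraction: float = 0.2  # white share of noise power in "mixed"
    seed: Optional[int] = None

    def __post_init__(self):
        if len(self.harmonic_amps) != self.n_harmonics:
            raise ValueError("one amplitude per harmonic is required")
        if any(a < 0 for a in self.harmonic_amps):
            raise ValueError("harmonic amplitudes must be non-negative")
        if self.noise_model not in {"white", "pink", "mixed"}:
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.duration_s <= self.prestim_s:
            raise ValueError("duration must exceed the pre-stimulus interval")
        if self.n_harmonics * float(np.max(self.grid.frequencies)) >= self.fs / 2:
            raise ValueError("highest harmonic reaches Nyquist; lower n_harmonics")

    def gains(self) -> np.ndarray:
        if self.spatial_gains is not None:
            g = np.asarray(self.spatial_gains, dtype=float)
            if g.size != len(self.channels):
                raise ValueError("spatial_gains length must match channel count")
            return g
        return default_spatial_gains(self.channels)


def _pink_noise(rng: np.random.Generator, shape: Tuple[int, int]) -> np.ndarray:
    """1/f-amplitude Gaussian noise rows, unit variance."""
    n_sig, n = shape
    n_freq = n // 2 + 1
    f = np.fft.rfftfreq(n, d=1.0)
    scale = np.zeros(n_freq)
    scale[1:] = 1.0 / np.sqrt(f[1:])  # amplitude ~ f^-1/2 -> power ~ 1/f
    spec = (
        rng.standard_normal((n_sig, n_freq)) + 1j * rng.standard_normal((n_sig, n_freq))
    ) * scale
    spec[:, 0] = 0.0
    x = np.fft.irfft(spec, n=n, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x


def _make_noise(cfg: SyntheticConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-scale structured noise: per-channel + common-mode pink, plus white."""
    C = len(cfg.channels)
    if cfg.noise_model == "white":
        return rng.standard_normal((C, n))
    own = _pink_noise(rng, (C, n))
    common = _pink_noise(rng, (1, n))
    cm = cfg.common_mode_fraction
    pink = np.sqrt(1.0 - cm) * own + np.sqrt(cm) * common
    if cfg.noise_model == "pink":
        return pink
    wf = cfg.white_fraction
    return np.sqrt(1.0 - wf) * pink + np.sqrt(wf) * rng.standard_normal((C, n))


def generate_epoch(
    cfg: SyntheticConfig,
    target: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> EpochData:
    """One labelled synthetic trial of ``cfg.duration_s`` seconds.

    The pre-stimulus interval is noise only; from onset each channel carries
    the harmonic stack scaled by its spatial gain.  Noise amplitude is set so
    that signal power / noise power over the stimulation interval on the
    occipital channels equals ``cfg.snr_db``.
    """
    if not (0 <= target < cfg.grid.n_targets):
        raise ValueError(f"target {target} outside the {cfg.grid.n_targets}-target grid")
    if rng is None:
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_total = int(round(cfg.duration_s * cfg.fs))
    onset = int(round(cfg.prestim_s * cfg.fs))
    gains = cfg.gains()
    f = float(cfg.grid.frequencies[target])
    phi = float(cfg.grid.phases[target])
    t = np.arange(n_total - onset) / cfg.fs  # t = 0 at stimulation onset
    wave = np.zeros_like(t)
    for h, amp in zip(range(1, cfg.n_harmonics + 1), cfg.harmonic_amps):
        wave += amp * np.sin(2.0 * np.pi * h * f * t + h * phi)
    signal = np.zeros((len(cfg.channels), n_total))
    signal[:, onset:] = gains[:, None] * wave[None, :]

    occ = [i for i, c in enumerate(cfg.channels) if c.upper() in _OCCIPITAL]
    if not occ:
        occ = list(range(len(cfg.channels)))
    if np.isinf(cfg.snr_db):
        samples = signal
    else:
        noise = _make_noise(cfg, rng, n_total)
        p_sig = float(np.mean(signal[occ][:, onset:] ** 2))
        if p_sig <= 0:
            raise ValueError(
                "occipital spatial gains are zero; the requested finite SNR "
                "is unreachable"
            )
        p_noise = float(np.mean(noise[occ][:, onset:] ** 2))
        scale = np.sqrt(p_sig / (p_noise * 10.0 ** (cfg.snr_db / 10.0)))
        samples = signal + scale * noise
    return EpochData(
        samples=samples,
        fs=cfg.fs,
        channel_labels=tuple(cfg.channels),
        onset_index=onset,
        true_target=int(target),
    )


def generate_session(
    cfg: SyntheticConfig, n_blocks: int, seed: Optional[int] = None
) -> List[EpochData]:
    """``N x n_blocks`` labelled epochs, each target exactly once per block.

    Noise is independent across epochs but fully determined by the master
    seed, so two sessions with equal seeds are identical.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be at least 1")
    master = np.random.SeedSequence(cfg.seed if seed is None else seed)
    children = master.spawn(cfg.grid.n_targets * n_blocks)
    epochs = []
    k = 0
    for _ in range(n_blocks):
        for target in range(cfg.grid.n_targets):
            rng = np.random.default_rng(children[k])
            epochs.append(generate_epoch(cfg, target, rng=rng))
            k += 1
    return epochs


def estimate_snr_db(epoch: EpochData, grid: StimulusGrid, n_harmonics: int = 3) -> float:
    """Realized SNR: harmonic-subspace power over residual power, occipital
    channels, stimulation interval.

    Projects each occipital channel onto the sin/cos harmonic subspace of the
    epoch's true target and compares projected to residual energy; a check
    that the generator delivers the SNR it was asked for.
    """
    if epoch.true_target is None:
        raise ValueError("epoch must carry its true target")
    occ = [c for c in epoch.channel_labels if c.upper() in _OCCIPITAL]
    idx = epoch.channel_indices(occ if occ else epoch.channel_labels)
    Y = epoch.samples[idx, epoch.onset_index :]
    Y = Y - Y.mean(axis=1, keepdims=True)
    n = Y.shape[1]
    f = float(grid.frequencies[epoch.true_target])
    t = np.arange(n) / epoch.fs
    cols = []
    for h in range(1, n_harmonics + 1):
        cols.append(np.sin(2 * np.pi * h * f * t))
        cols.append(np.cos(2 * np.pi * h * f * t))
    X = np.column_stack(cols)
    Q, _ = np.linalg.qr(X)
    proj = Y @ Q
    p_sig = float(np.sum(proj ** 2))
    p_res = float(np.sum(Y ** 2)) - p_sig
    return 10.0 * np.log10(p_sig / max(p_res, 1e-30))
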