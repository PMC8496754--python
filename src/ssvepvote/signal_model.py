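"""Core containers and signal primitives for SSVEP analysis.

A steady-state visual evoked potential (SSVEP) trial is a multichannel EEG
epoch time-locked to the onset of a flickering stimulus.  Everything else in
this package is built on the small set of types defined here: the stimulus
grid (one frequency/phase pair per flicker target), the epoch container, the
per-target harmonic sine/cosine reference sets that frequency-recognition
scorers correlate against, and the two signal primitives every scorer
shares -- zero-phase band-pass filtering and onset-locked window extraction.

Conventions
-----------
* Signals are ``channels x samples`` arrays; time runs along the last axis.
* Window lengths in seconds convert to samples as ``round(length_s * fs)``
  and windows are half-open ``[onset, onset + n)``.
* References are phase-free sin/cos pairs: the scorers used here (CCA, MSI,
  MEC and variants) are invariant to the stimulus phase, so the phase stored
  in :class:`StimulusGrid` is used by the synthetic generator only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

__all__ = [
    "StimulusGrid",
    "BandSpec",
    "EpochData",
    "ReferenceSet",
    "build_reference_set",
    "bandpass",
    "bandpass_array",
    "extract_window",
    "FILTER_ORDER",
]

#: Order of the Butterworth band-pass used throughout (zero-phase, applied
#: forward and backward, so the effective magnitude response is order 8).
FILTER_ORDER = 4


@dataclass(frozen=True)
class StimulusGrid:
    """Flicker targets of an SSVEP interface: frequency and phase per target."""

    frequencies: np.ndarray
    phases: np.ndarray

    def __post_init__(self):
        freqs = np.asarray(self.frequencies, dtype=float)
        phases = np.mod(np.asarray(self.phases, dtype=float), 2.0 * np.pi)
        object.__setattr__(self, "frequencies", freqs)
        object.__setattr__(self, "phases", phases)
        if freqs.ndim != 1 or phases.shape != freqs.shape:
            raise ValueError("frequencies and phases must be 1-D and equal length")
        if freqs.size < 2:
            raise ValueError("a stimulus grid needs at least 2 targets")
        if np.any(freqs <= 0):
            raise ValueError("stimulus frequencies must be strictly positive")
        if np.unique(freqs).size != freqs.size:
            raise ValueError("stimulus frequencies must be unique")

    @property
    def n_targets(self) -> int:
        return int(self.frequencies.size)


@dataclass(frozen=True)
class BandSpec:
    """Pass-band corner frequencies in Hz for zero-phase band-pass filtering."""

    low: float
    high: float

    def __post_init__(self):
        if not (0 <= self.low < self.high):
            raise ValueError(f"invalid band [{self.low}, {self.high}] Hz")

    def validate_for(self, fs: float) -> None:
        if self.high >= fs / 2:
            raise ValueError(
                f"band [{self.low}, {self.high}] Hz reaches the Nyquist "
                f"frequency {fs / 2:g} Hz"
            )


@dataclass
class EpochData:
    """One EEG trial: ``channels x samples`` plus sampling metadata.

    ``onset_index`` marks the sample at which stimulation starts; analysis
    windows are extracted from that point on, so pre-stimulus samples never
    enter a scorer (they matter only for selection-time accounting).
    """

    samples: np.ndarray
    fs: float
    channel_labels: Tuple[str, ...]
    onset_index: int
    true_target: Optional[int] = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a channels x time matrix")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("one label per channel row is required")
        keys = [c.upper() for c in self.channel_labels]
        if len(set(keys)) != len(keys):
            raise ValueError("channel labels must be unique")
        if not (0 <= self.onset_index < self.samples.shape[1]):
            raise ValueError("onset_index outside the recorded samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def channel_indices(self, labels: Sequence[str]) -> np.ndarray:
        """Row indices of ``labels`` (case-insensitive); unknown label raises."""
        lookup = {c.upper(): i for i, c in enumerate(self.channel_labels)}
        idx = []
        for lab in labels:
            key = lab.upper()
            if key not in lookup:
                raise KeyError(f"channel {lab!r} not present in epoch montage")
            idx.append(lookup[key])
        return np.asarray(idx, dtype=int)

    def copy_with(self, **kw) -> "EpochData":
        return replace(self, **kw)


@dataclass(frozen=True)
class ReferenceSet:
    """Per-target harmonic reference waveforms.

    ``targets[i]`` is a ``(2*Nh) x n_samples`` matrix whose rows alternate
    ``sin(2*pi*h*f_i*t)`` and ``cos(2*pi*h*f_i*t)`` for harmonics
    ``h = 1..Nh`` with ``t = k/fs``.
    """

    targets: Tuple[np.ndarray, ...]
    n_harmonics: int
    fs: float
    frequencies: np.ndarray = field(default=None)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def n_samples(self) -> int:
        return self.targets[0].shape[1]


def build_reference_set(
    grid: StimulusGrid, Nh: int, fs: float, n_samples: int
) -> ReferenceSet:
    """Construct phase-free sin/cos harmonic references for every target.

    Raises if any harmonic ``h*f`` reaches the Nyquist frequency ``fs/2``.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    if Nh < 1:
        raise ValueError("need at least one harmonic")
    fmax = float(np.max(grid.frequencies))
    if Nh * fmax >= fs / 2:
        raise ValueError(
            f"harmonic {Nh} of {fmax:g} Hz is at or above the Nyquist "
            f"frequency {fs / 2:g} Hz; reduce Nh or raise fs"
        )
    t = np.arange(n_samples) / fs
    mats = []
    for f in grid.frequencies:
        rows = np.empty((2 * Nh, n_samples))
        for h in range(1, Nh + 1):
            arg = 2.0 * np.pi * h * f * t
            rows[2 * (h - 1)] = np.sin(arg)
            rows[2 * (h - 1) + 1] = np.cos(arg)
        mats.append(rows)
    return ReferenceSet(
        targets=tuple(mats),
        n_harmonics=Nh,
        fs=float(fs),
        frequencies=np.asarray(grid.frequencies, dtype=float),
    )


def _design_sos(band: BandSpec, fs: float) -> np.ndarray:
    band.validate_for(fs)
    return sps.butter(
        FILTER_ORDER, [band.low, band.high], btype="bandpass", fs=fs, output="sos"
    )


def bandpass_array(x: np.ndarray, band: BandSpec, fs: float) -> np.ndarray:
    """Zero-phase Butterworth band-pass of a ``channels x samples`` array."""
    sos = _design_sos(band, fs)
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def bandpass(epoch: EpochData, band: BandSpec) -> EpochData:
    """Return a zero-phase band-passed copy of the epoch (original untouched)."""
    return epoch.copy_with(samples=bandpass_array(epoch.samples, band, epoch.fs))


def extract_window(epoch: EpochData, length_s: float) -> np.ndarray:
    """Onset-locked analysis window: samples ``[onset, onset + round(L*fs))``."""
    n = int(round(length_s * epoch.fs))
    if n < 1:
        raise ValueError(f"window length {length_s} s yields no samples")
    avail = epoch.n_samples - epoch.onset_index
    if epoch.onset_index + n > epoch.n_samples:
        raise ValueError(
            f"window of {length_s} s ({n} samples) exceeds the "
            f"{avail / epoch.fs:.3f} s available after stimulation onset"
        )
    return epoch.samples[:, epoch.onset_index : epoch.onset_index + n].copy()
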