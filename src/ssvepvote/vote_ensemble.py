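"""Random channel-subset voting and the dynamic-window-length classifier.

The core idea: instead of committing to one feature-extraction method and one
electrode montage, classify the same EEG window many times -- once per
(method, channel subset) pair -- and treat each classification as a vote.
For target ``i`` and method ``Phi`` the exact vote share is

    psi_i(Phi, E) = |E_i^Phi| / (2**Ne - 1),

the fraction of the ``2**Ne - 1`` non-empty subsets of the ``Ne``-electrode
pool that select target ``i``.  Enumerating the power set of the default
21-electrode occipital/parietal pool is infeasible, so the share is estimated
from ``R`` subsets drawn uniformly from the non-empty power set.  With ``K``
methods the per-target feature is the method-averaged Euclidean norm of the
shares, ``psi_i = ||(share_i^1, ..., share_i^K)||_2 / K`` (an l1 variant is
exposed as well), and the classifier decides once ``max_i psi_i`` clears a
window-length-specific threshold.  Thresholds descend over a schedule of
window lengths; if even the longest window fails the test, the leading target
is returned anyway.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .signal_model import EpochData, StimulusGrid, extract_window
from .feature_extractors import MethodSpec, prepare_scorer

__all__ = [
    "ChannelPool",
    "DEFAULT_POOL_LABELS",
    "SubsetSample",
    "VoteMatrix",
    "ThresholdSchedule",
    "ClassificationResult",
    "sample_channel_subsets",
    "tally_votes",
    "normalize_votes",
    "compute_psi",
    "build_threshold_schedule",
    "classify_dynamic",
    "enumerate_votes_exact",
]

#: The 21 electrodes covering occipital, parieto-occipital and parietal
#: scalp in the 10-10 system; the default voting pool.
DEFAULT_POOL_LABELS: Tuple[str, ...] = (
    "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8",
    "O1", "OZ", "O2", "CB1", "CB2",
)

MAX_ENUMERATION_POOL = 12

MethodLike = Union[MethodSpec, str, Callable[[Sequence[str]], int]]


@dataclass(frozen=True)
class ChannelPool:
    """The electrode pool votes are sampled from."""

    labels: Tuple[str, ...] = DEFAULT_POOL_LABELS

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        keys = [c.upper() for c in self.labels]
        if len(set(keys)) != len(keys):
            raise ValueError("pool labels must be unique")
        if len(self.labels) < 1:
            raise ValueError("pool must contain at least one electrode")

    @property
    def size(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class SubsetSample:
    """``R`` non-empty electrode subsets drawn from a pool."""

    subsets: Tuple[Tuple[str, ...], ...]
    seed: Optional[int] = None

    @property
    def R(self) -> int:
        return len(self.subsets)

    def cardinalities(self) -> np.ndarray:
        return np.array([len(s) for s in self.subsets])


@dataclass
class VoteMatrix:
    """K methods x N targets vote counts, or shares after normalization."""

    counts: np.ndarray
    methods: Tuple[str, ...]
    normalized: bool = False

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != len(self.methods):
            raise ValueError("counts must be K x N with one row per method")
        if np.any(self.counts < 0):
            raise ValueError("vote counts must be non-negative")

    @property
    def n_targets(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class ThresholdSchedule:
    """Ascending window lengths paired with descending vote thresholds."""

    window_lengths_s: Tuple[float, ...]
    taus: Tuple[float, ...]
    tau_min: float
    tau_max: float
    W_s: float
    S_max_s: float

    def __post_init__(self):
        if len(self.window_lengths_s) != len(self.taus):
            raise ValueError("one threshold per window length is required")
        if any(np.diff(self.window_lengths_s) <= 0):
            raise ValueError("window lengths must be strictly ascending")
        if any(np.diff(self.taus) > 1e-12):
            raise ValueError("thresholds must be non-increasing")

    @property
    def n_steps(self) -> int:
        return len(self.window_lengths_s)


@dataclass
class ClassificationResult:
    """Outcome of one dynamic-window classification."""

    target: int
    window_s: float
    gamma: float
    psi_trace: List[np.ndarray]
    votes_trace: List[VoteMatrix]
    stopped_by: str  # "threshold" or "max_window"

    @property
    def psi(self) -> np.ndarray:
        return self.psi_trace[-1]


def build_threshold_schedule(
    tau_min: float,
    tau_max: float,
    start_s: float = 0.7,
    stop_s: float = 2.1,
    step_s: float = 0.1,
) -> ThresholdSchedule:
    """Equidistant descending thresholds over ascending window lengths.

    ``taus[0] = tau_max`` at the shortest window, ``taus[-1] = tau_min`` at
    the longest; ``tau_min == tau_max`` gives a constant schedule (e.g. a
    plain 50% majority at every length).
    """
    if not (0.0 <= tau_min <= tau_max <= 1.0):
        raise ValueError("require 0 <= tau_min <= tau_max <= 1")
    if step_s <= 0 or stop_s < start_s:
        raise ValueError("invalid window range")
    k = (stop_s - start_s) / step_s
    if abs(k - round(k)) > 1e-9:
        raise ValueError("step must divide (stop - start) exactly")
    t = int(round(k)) + 1
    windows = tuple(round(start_s + j * step_s, 10) for j in range(t))
    if t == 1:
        if tau_min != tau_max:
            raise ValueError("a single window length requires tau_min == tau_max")
        taus = (tau_max,)
    else:
        taus = tuple(
            tau_max - j * (tau_max - tau_min) / (t - 1) for j in range(t)
        )
    return ThresholdSchedule(
        window_lengths_s=windows,
        taus=taus,
        tau_min=tau_min,
        tau_max=tau_max,
        W_s=step_s,
        S_max_s=windows[-1],
    )


def sample_channel_subsets(
    pool: ChannelPool, R: int, seed: Optional[int] = None
) -> SubsetSample:
    """Draw ``R`` subsets uniformly from the non-empty power set of the pool.

    Each electrode is included independently with probability 1/2 and empty
    draws are rejected and redrawn, which makes every one of the
    ``2**Ne - 1`` non-empty subsets equally likely.  Draws are with
    replacement and deterministic under ``seed``.
    """
    if R < 1:
        raise ValueError("R must be at least 1")
    rng = np.random.default_rng(seed)
    n = pool.size
    masks = np.empty((R, n), dtype=bool)
    pending = np.arange(R)
    while pending.size:
        draw = rng.random((pending.size, n)) < 0.5
        masks[pending] = draw
        pending = pending[~draw.any(axis=1)]
    labels = np.asarray(pool.labels, dtype=object)
    subsets = tuple(tuple(labels[m]) for m in masks)
    return SubsetSample(subsets=subsets, seed=seed)


def _coerce_method(m: MethodLike) -> Union[MethodSpec, Callable]:
    if isinstance(m, str):
        return MethodSpec.from_name(m)
    return m


def _method_name(m: MethodLike) -> str:
    m = _coerce_method(m)
    return m.name if isinstance(m, MethodSpec) else getattr(m, "__name__", "custom")


def tally_votes(
    methods: Sequence[MethodLike],
    subsets: SubsetSample,
    window: np.ndarray,
    channel_labels: Sequence[str],
    grid: StimulusGrid,
    fs: float,
) -> VoteMatrix:
    """Cast one vote per (method, subset) pair; rows of the result sum to R.

    ``methods`` may mix :class:`MethodSpec` (or method names) with plain
    callables mapping a label tuple to a target index -- the latter supports
    exact oracles and toy classifiers in tests.
    """
    if len(methods) < 1:
        raise ValueError("need at least one method")
    methods = [_coerce_method(m) for m in methods]
    window = np.atleast_2d(np.asarray(window, dtype=float))
    lookup = {c.upper(): i for i, c in enumerate(channel_labels)}
    idx_list = []
    for s in subsets.subsets:
        try:
            idx_list.append(np.array([lookup[lab.upper()] for lab in s], dtype=int))
        except KeyError as exc:
            raise KeyError(f"subset channel {exc.args[0]!r} missing from window")
    V = np.zeros((len(methods), grid.n_targets), dtype=float)
    for k, method in enumerate(methods):
        if callable(method) and not isinstance(method, MethodSpec):
            for s in subsets.subsets:
                V[k, int(method(s))] += 1
            continue
        try:
            prep = prepare_scorer(method, window, fs, grid)
            for idx in idx_list:
                V[k, prep.classify(idx)] += 1
        except Exception as exc:
            raise RuntimeError(f"method {method.name} failed while voting: {exc}") from exc
    return VoteMatrix(counts=V, methods=tuple(_method_name(m) for m in methods))


def normalize_votes(V: VoteMatrix, R: int) -> VoteMatrix:
    """Divide counts by R, turning each row into vote shares summing to one."""
    if V.normalized:
        raise ValueError("vote matrix is already normalized")
    sums = V.counts.sum(axis=1)
    if not np.allclose(sums, R):
        raise ValueError(f"row sums {sums} do not match R = {R}")
    return VoteMatrix(counts=V.counts / R, methods=V.methods, normalized=True)


def compute_psi(V_shares: VoteMatrix, norm: str = "l2") -> np.ndarray:
    """Per-target feature from normalized vote shares.

    ``l2``: ``psi_n = ||column n||_2 / K`` (bounded by ``1/sqrt(K)``, reaching
    it only when every method is unanimous for n).  ``l1``: the mean share,
    which restores a [0, 1] range.
    """
    if not V_shares.normalized:
        raise ValueError("compute_psi expects normalized vote shares")
    K = V_shares.counts.shape[0]
    if norm == "l2":
        return np.linalg.norm(V_shares.counts, axis=0) / K
    if norm == "l1":
        return V_shares.counts.sum(axis=0) / K
    raise ValueError(f"unknown norm {norm!r} (expected 'l2' or 'l1')")


def classify_dynamic(
    epoch: EpochData,
    methods: Sequence[MethodLike],
    grid: StimulusGrid,
    pool: Optional[ChannelPool] = None,
    R: int = 512,
    schedule: Optional[ThresholdSchedule] = None,
    seed: Optional[int] = None,
    norm: str = "l2",
) -> ClassificationResult:
    """Dynamic-window voting classification of one epoch.

    One subset sample is drawn per call and reused across window extensions;
    at each scheduled length the vote matrix is re-tallied from zero, shares
    and psi recomputed, and the classifier stops as soon as
    ``max psi > tau[j]`` (strictly).  If the longest window still fails the
    threshold, the target leading at that window is returned with
    ``stopped_by = "max_window"``.  Argmax ties break to the lowest index.
    """
    pool = pool or ChannelPool()
    schedule = schedule or build_threshold_schedule(0.5, 0.5)
    pool_idx = epoch.channel_indices(pool.labels)  # raises on missing channels
    needed = epoch.onset_index + int(round(schedule.S_max_s * epoch.fs))
    if needed > epoch.n_samples:
        avail = (epoch.n_samples - epoch.onset_index) / epoch.fs
        raise ValueError(
            f"epoch provides {avail:.3f} s after onset but the schedule "
            f"needs {schedule.S_max_s:g} s"
        )
    subsets = sample_channel_subsets(pool, R, seed)
    psi_trace: List[np.ndarray] = []
    votes_trace: List[VoteMatrix] = []
    gamma = 0.0
    target = 0
    stopped_by = "max_window"
    window_s = schedule.window_lengths_s[-1]
    for j, L in enumerate(schedule.window_lengths_s):
        window = extract_window(epoch, L)[pool_idx]
        V = tally_votes(methods, subsets, window, pool.labels, grid, epoch.fs)
        shares = normalize_votes(V, subsets.R)
        psi = compute_psi(shares, norm=norm)
        psi_trace.append(psi)
        votes_trace.append(V)
        target = int(np.argmax(psi))
        gamma = float(psi[target])
        if gamma > schedule.taus[j]:
            stopped_by = "threshold"
            window_s = L
            break
    return ClassificationResult(
        target=target,
        window_s=window_s,
        gamma=gamma,
        psi_trace=psi_trace,
        votes_trace=votes_trace,
        stopped_by=stopped_by,
    )


def enumerate_votes_exact(
    pool: ChannelPool,
    method: MethodLike,
    window: np.ndarray,
    channel_labels: Sequence[str],
    grid: StimulusGrid,
    fs: float,
) -> np.ndarray:
    """Exact per-target vote share over the full non-empty power set.

    Feasible only for small pools (at most ``2**12 - 1`` subsets); the result
    sums to one and is the quantity the Monte-Carlo shares estimate.
    """
    if pool.size > MAX_ENUMERATION_POOL:
        raise ValueError(
            f"exact enumeration limited to pools of <= {MAX_ENUMERATION_POOL} "
            f"electrodes (got {pool.size})"
        )
    method = _coerce_method(method)
    counts = np.zeros(grid.n_targets)
    use_callable = callable(method) and not isinstance(method, MethodSpec)
    if not use_callable:
        window = np.atleast_2d(np.asarray(window, dtype=float))
        lookup = {c.upper(): i for i, c in enumerate(channel_labels)}
        pool_idx = {lab: lookup[lab.upper()] for lab in pool.labels}
        prep = prepare_scorer(method, window, fs, grid)
    for r in range(1, pool.size + 1):
        for combo in itertools.combinations(pool.labels, r):
            if use_callable:
                counts[int(method(combo))] += 1
            else:
                idx = np.array([pool_idx[lab] for lab in combo], dtype=int)
                counts[prep.classify(idx)] += 1
    return counts / (2 ** pool.size - 1)
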