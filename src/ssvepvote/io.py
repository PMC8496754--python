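"""Session containers on disk: benchmark-layout MAT files and run configs.

Benchmark recordings of the 40-target speller ship one MAT container per
subject holding a ``channels x samples x targets x blocks`` array (64 x 1500
x 40 x 6 at 250 Hz, with stimulation onset 0.5 s into each trial).  The
loader accepts both legacy MAT and MAT v7.3 (HDF5) containers.  The fixture
writer stores synthetic sessions in the same layout -- optionally with
explicit channel labels, sampling rate and onset, which real benchmark files
lack -- so the loader is the single read path for both.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import h5py
import numpy as np
import scipy.io

from .signal_model import EpochData
from .synthetic import BENCHMARK_CHANNELS_64
from .vote_ensemble import DEFAULT_POOL_LABELS

__all__ = [
    "RunConfig",
    "load_benchmark_subject",
    "write_session",
    "provenance",
]

_DEFAULT_FS = 250.0
_DEFAULT_ONSET_S = 0.5


@dataclass
class RunConfig:
    """Full configuration of an ensemble or baseline run; JSON round-trips."""

    methods: Tuple[str, ...] = ("MEC", "MSI", "FBCCA")
    R: int = 512
    tau_min: float = 0.5
    tau_max: float = 0.5
    win_start: float = 0.7
    win_stop: float = 2.1
    win_step: float = 0.1
    pool: Tuple[str, ...] = DEFAULT_POOL_LABELS
    seed: int = 0
    prestim: float = 0.5
    norm: str = "l2"
    mode: str = "ensemble"

    def __post_init__(self):
        self.methods = tuple(m.upper() for m in self.methods)
        self.pool = tuple(self.pool)
        if self.mode not in {"ensemble", "baseline"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.norm not in {"l2", "l1"}:
            raise ValueError(f"unknown norm {self.norm!r}")
        if self.R < 1:
            raise ValueError("R must be at least 1")
        if not (0.0 <= self.tau_min <= self.tau_max <= 1.0):
            raise ValueError("require 0 <= tau_min <= tau_max <= 1")
        if self.mode == "baseline" and len(self.methods) != 1:
            raise ValueError("baseline mode takes exactly one method")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @staticmethod
    def from_json(path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        return RunConfig(**raw)

    def schedule(self):
        from .vote_ensemble import build_threshold_schedule

        return build_threshold_schedule(
            self.tau_min, self.tau_max, self.win_start, self.win_stop, self.win_step
        )


def provenance(config: dict, seed: int) -> dict:
    """Reproducibility block stamped into every output file."""
    import scipy

    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "versions": {
            "ssvepvote": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
    }


def _decode_labels(raw) -> Optional[Tuple[str, ...]]:
    if raw is None:
        return None
    out = []
    for item in np.asarray(raw).ravel():
        if isinstance(item, bytes):
            out.append(item.decode())
        elif isinstance(item, np.ndarray):
            out.append("".join(chr(int(c)) for c in item.ravel()))
        else:
            out.append(str(item))
    return tuple(s.strip() for s in out if s.strip())


def _read_container(path: Path) -> dict:
    if h5py.is_hdf5(path):
        out = {}
        with h5py.File(path, "r") as f:
            if "data" not in f:
                raise ValueError(f"{path} has no 'data' variable")
            # MATLAB v7.3 stores arrays with reversed dimension order
            out["data"] = np.asarray(f["data"]).transpose()
            for key in ("fs", "onset"):
                if key in f:
                    out[key] = float(np.asarray(f[key]).ravel()[0])
            if "labels" in f:
                node = f["labels"]
                if node.dtype == object:  # cell array of strings
                    labs = []
                    for ref in np.asarray(node).ravel():
                        labs.append(
                            "".join(chr(int(c)) for c in np.asarray(f[ref]).ravel())
                        )
                    out["labels"] = tuple(labs)
                else:
                    out["labels"] = _decode_labels(np.asarray(node))
        return out
    mat = scipy.io.loadmat(path, squeeze_me=False)
    if "data" not in mat:
        raise ValueError(f"{path} has no 'data' variable")
    out = {"data": np.asarray(mat["data"])}
    if "fs" in mat:
        out["fs"] = float(np.asarray(mat["fs"]).ravel()[0])
    if "onset" in mat:
        out["onset"] = float(np.asarray(mat["onset"]).ravel()[0])
    if "labels" in mat:
        out["labels"] = _decode_labels(mat["labels"])
    return out


def load_benchmark_subject(path) -> List[EpochData]:
    """Load one subject container into labelled epochs.

    Expects a 4-D ``channels x samples x targets x blocks`` array.  Files
    without embedded metadata (the real benchmark) get the 64-channel
    standard montage, 250 Hz, and a 0.5 s onset; fixtures written by
    :func:`write_session` carry their metadata explicitly.  Epochs are
    ordered block-major (all targets of block 0, then block 1, ...).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = _read_container(path)
    data = raw["data"]
    if data.ndim != 4:
        raise ValueError(
            f"expected a channels x samples x targets x blocks array, got "
            f"shape {data.shape}"
        )
    n_ch, n_s, n_targets, n_blocks = data.shape
    labels = raw.get("labels")
    if labels is None:
        if n_ch != 64:
            raise ValueError(
                f"container has {n_ch} channels but no label metadata; only "
                f"64-channel files map onto the standard benchmark montage"
            )
        labels = BENCHMARK_CHANNELS_64
    if len(labels) != n_ch:
        raise ValueError(
            f"{len(labels)} labels for {n_ch} channels in {path.name}"
        )
    fs = raw.get("fs", _DEFAULT_FS)
    onset = int(round(raw.get("onset", _DEFAULT_ONSET_S * fs)))
    epochs = []
    for b in range(n_blocks):
        for t in range(n_targets):
            epochs.append(
                EpochData(
                    samples=np.ascontiguousarray(data[:, :, t, b]),
                    fs=fs,
                    channel_labels=labels,
                    onset_index=onset,
                    true_target=t,
                )
            )
    return epochs


_MAT_HEADER = b"MATLAB 5.0 MAT-file, written by ssvepvote (fixed header)"


def write_session(epochs: Sequence[EpochData], path) -> None:
    """Write labelled epochs as a benchmark-layout MAT container.

    Epochs must cover every target the same number of times (blocks); channel
    labels, sampling rate and onset are stored alongside the data array.  The
    MAT text header is overwritten with a fixed string so identical sessions
    produce byte-identical files.
    """
    if not epochs:
        raise ValueError("no epochs to write")
    fs = epochs[0].fs
    labels = epochs[0].channel_labels
    onset = epochs[0].onset_index
    targets = sorted({e.true_target for e in epochs})
    if any(t is None for t in targets):
        raise ValueError("all epochs need a true target to be written")
    n_targets = len(targets)
    if targets != list(range(n_targets)):
        raise ValueError("targets must be contiguous 0..N-1")
    counts = {t: 0 for t in targets}
    for e in epochs:
        counts[e.true_target] += 1
    n_blocks = counts[0]
    if any(c != n_blocks for c in counts.values()):
        raise ValueError("every target must appear the same number of times")
    n_ch, n_s = epochs[0].samples.shape
    data = np.zeros((n_ch, n_s, n_targets, n_blocks))
    seen = {t: 0 for t in targets}
    for e in epochs:
        if e.samples.shape != (n_ch, n_s) or e.fs != fs or e.channel_labels != labels:
            raise ValueError("epochs in one session must share shape and montage")
        t = e.true_target
        data[:, :, t, seen[t]] = e.samples
        seen[t] += 1
    path = Path(path)
    scipy.io.savemat(
        path,
        {
            "data": data,
            "fs": float(fs),
            "onset": float(onset),
            "labels": np.array(list(labels)),
        },
        do_compression=False,
    )
    # scipy stamps a creation time into bytes 0..115; make output reproducible
    with open(path, "r+b") as fh:
        header = _MAT_HEADER + b" " * (116 - len(_MAT_HEADER))
        fh.write(header[:116])
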