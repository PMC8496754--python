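"""Accuracy, information transfer rate, and evaluation summaries.

The information transfer rate (ITR) of an ``N``-target selection with
accuracy ``P`` and selection time ``T`` seconds follows the standard
Wolpaw formula,

    C = (60 / T) * [log2 N + P log2 P + (1 - P) log2((1 - P) / (N - 1))]

in bits per minute, with the convention ``0 log 0 = 0``.  Selection time
includes the pre-stimulation interval (0.5 s by default) on top of the mean
analysis-window length.

Two ITR aggregations are reported when a participant breakdown is available:
the pooled ITR (Wolpaw formula on pooled accuracy and mean window) and the
mean of per-participant ITRs.  They differ in general -- ITR is convex in
accuracy over the usual operating range -- and the per-participant mean is
the one comparable across classifiers with heterogeneous subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .feature_extractors import MethodSpec, prepare_scorer
from .signal_model import EpochData, StimulusGrid, extract_window
from .vote_ensemble import ClassificationResult

__all__ = [
    "itr_bpm",
    "EvaluationSummary",
    "evaluate",
    "trials_table",
    "baseline_fixed_window",
    "TABLE_ELECTRODES",
]

#: Fixed electrode sets used by the single-method fixed-window baselines.
TABLE_ELECTRODES: Dict[str, tuple] = {
    "MEC": ("P3", "O1", "PZ", "OZ", "P4", "O2"),
    "MSI": ("P3", "PZ", "P4", "PO7", "PO8", "O1", "OZ", "O2"),
    "FBCCA": ("PZ", "PO5", "PO3", "POZ", "PO4", "PO6", "O1", "OZ", "O2"),
}


def itr_bpm(N: int, P: float, T: float) -> float:
    """Information transfer rate in bits per minute."""
    if N < 2:
        raise ValueError("need at least two targets")
    if not (0.0 <= P <= 1.0):
        raise ValueError(f"accuracy {P} outside [0, 1]")
    if T <= 0:
        raise ValueError("selection time must be positive")
    bits = np.log2(N)
    if P > 0:
        bits += P * np.log2(P)
    if P < 1:
        bits += (1.0 - P) * np.log2((1.0 - P) / (N - 1))
    return float(60.0 / T * bits)


@dataclass
class EvaluationSummary:
    """Aggregate performance of a batch of classifications."""

    accuracy: float
    mean_window_s: float
    itr: float  # pooled Wolpaw ITR, bits/min
    n_targets: int
    prestim_s: float
    per_window_table: pd.DataFrame
    per_participant: Optional[pd.DataFrame] = None
    mean_participant_itr: Optional[float] = None

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "mean_window_s": self.mean_window_s,
            "itr_bpm": self.itr,
            "n_targets": self.n_targets,
            "prestim_s": self.prestim_s,
            "per_window_table": self.per_window_table.to_dict(orient="records"),
        }
        if self.per_participant is not None:
            d["per_participant"] = self.per_participant.to_dict(orient="records")
            d["mean_participant_itr_bpm"] = self.mean_participant_itr
        return d


def _window_table(windows: np.ndarray, correct: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame({"window_s": windows, "correct": correct})
    grouped = df.groupby("window_s", sort=True)
    out = pd.DataFrame(
        {
            "window_s": grouped.size().index.to_numpy(),
            "population_pct": grouped.size().to_numpy() / len(df) * 100.0,
            "accuracy_pct": grouped["correct"].mean().to_numpy() * 100.0,
        }
    )
    return out.reset_index(drop=True)


def evaluate(
    results: Sequence[Union[ClassificationResult, int]],
    truths: Sequence[int],
    n_targets: int,
    include_prestim_s: float = 0.5,
    participants: Optional[Sequence] = None,
    fixed_window_s: Optional[float] = None,
) -> EvaluationSummary:
    """Summarize predictions against ground truth.

    ``results`` holds :class:`ClassificationResult` objects (or bare target
    indices together with ``fixed_window_s``).  Selection time is the mean
    stopping window plus ``include_prestim_s``.  All trials count toward
    accuracy, including those classified at the maximum window.
    """
    if len(results) == 0:
        raise ValueError("no results to evaluate")
    if len(results) != len(truths):
        raise ValueError("results and truths differ in length")
    preds, windows = [], []
    for r in results:
        if isinstance(r, ClassificationResult):
            preds.append(r.target)
            windows.append(r.window_s)
        else:
            if fixed_window_s is None:
                raise ValueError("bare predictions require fixed_window_s")
            preds.append(int(r))
            windows.append(fixed_window_s)
    preds = np.asarray(preds)
    windows = np.asarray(windows, dtype=float)
    truths = np.asarray(truths)
    correct = preds == truths
    accuracy = float(correct.mean())
    mean_window = float(windows.mean())
    pooled_itr = itr_bpm(n_targets, accuracy, mean_window + include_prestim_s)
    per_part = None
    mean_part_itr = None
    if participants is not None:
        if len(participants) != len(results):
            raise ValueError("participants and results differ in length")
        df = pd.DataFrame(
            {"participant": list(participants), "correct": correct, "window_s": windows}
        )
        rows = []
        for pid, g in df.groupby("participant", sort=True):
            acc = float(g["correct"].mean())
            mw = float(g["window_s"].mean())
            rows.append(
                {
                    "participant": pid,
                    "n_trials": len(g),
                    "accuracy": acc,
                    "mean_window_s": mw,
                    "itr_bpm": itr_bpm(n_targets, acc, mw + include_prestim_s),
                }
            )
        per_part = pd.DataFrame(rows)
        mean_part_itr = float(per_part["itr_bpm"].mean())
    return EvaluationSummary(
        accuracy=accuracy,
        mean_window_s=mean_window,
        itr=pooled_itr,
        n_targets=n_targets,
        prestim_s=include_prestim_s,
        per_window_table=_window_table(windows, correct),
        per_participant=per_part,
        mean_participant_itr=mean_part_itr,
    )


def trials_table(
    results: Sequence[ClassificationResult],
    truths: Sequence[int],
    participants: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Per-trial record: participant, truth, prediction, window, max psi."""
    rows = []
    for i, (r, t) in enumerate(zip(results, truths)):
        rows.append(
            {
                "participant": participants[i] if participants is not None else 0,
                "true_target": int(t),
                "predicted_target": int(r.target),
                "window_s": float(r.window_s),
                "psi_max": float(r.gamma),
                "stopped_by": r.stopped_by,
            }
        )
    return pd.DataFrame(rows)


def baseline_fixed_window(
    epochs: Sequence[EpochData],
    method: MethodSpec,
    window_s: float,
    electrodes: Optional[Sequence[str]] = None,
    grid: Optional[StimulusGrid] = None,
    include_prestim_s: float = 0.5,
    participants: Optional[Sequence] = None,
) -> EvaluationSummary:
    """Single-method, fixed-window, fixed-electrode classification baseline.

    Every epoch is scored on the method's standard electrode set (or the one
    given) at one window length; the prediction is the score argmax.  This is
    the conventional-classifier reference the voting ensemble is compared to.
    """
    from .synthetic import benchmark_grid

    grid = grid or benchmark_grid()
    electrodes = tuple(electrodes or TABLE_ELECTRODES[method.name])
    preds, truths = [], []
    for epoch in epochs:
        idx = epoch.channel_indices(electrodes)  # raises if set missing
        window = extract_window(epoch, window_s)[idx]
        prep = prepare_scorer(method, window, epoch.fs, grid)
        preds.append(prep.classify(np.arange(len(idx))))
        truths.append(epoch.true_target)
    return evaluate(
        preds,
        truths,
        grid.n_targets,
        include_prestim_s=include_prestim_s,
        participants=participants,
        fixed_window_s=window_s,
    )
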