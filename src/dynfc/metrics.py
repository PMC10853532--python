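"""Per-subject brain-state metrics.

Given a per-volume state label sequence, compute fractional occupancy,
dwell times, Markov transition probabilities (with and without dwelling
self-transitions), and per-state KOP statistics.  States are 0-based
integers in ``0..K-1`` throughout.

A state a subject never visits yields NaN (missing) metrics — never an
imputed zero — so that the group-statistics layer can drop the subject from
that state's family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kuramoto import KOPSeries
from .phase import DataError

__all__ = [
    "StateSequence",
    "SubjectStateMetrics",
    "fractional_occupancy",
    "dwell_times",
    "transition_matrix",
    "state_kop_stats",
    "subject_metrics",
]


@dataclass
class StateSequence:
    """Per-volume state labels for one subject (0-based, no temporal gaps)."""

    labels: np.ndarray
    K: int
    tr: float
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise DataError("labels must be a non-empty 1-D sequence")
        if self.labels.min() < 0 or self.labels.max() >= self.K:
            raise DataError(f"labels outside 0..{self.K - 1}")


@dataclass
class SubjectStateMetrics:
    """Derived per-subject features; NaN marks unvisited-state entries."""

    subject_id: str | None
    K: int
    fractional_occupancy: np.ndarray      # (K,) sums to 1
    dwell_time_volumes: np.ndarray        # (K,) mean run length
    dwell_time_seconds: np.ndarray        # (K,)
    state_mean_sync: np.ndarray           # (K,)
    state_metastability: np.ndarray       # (K,)
    transition_matrix: np.ndarray         # (K, K) row-stochastic or NaN row
    transition_matrix_noself: np.ndarray  # (K, K) zero diagonal, renormalised
    mean_sync: float
    metastability: float


def fractional_occupancy(labels: np.ndarray, K: int) -> np.ndarray:
    """Proportion of volumes spent in each state; sums to 1."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise DataError("empty label sequence")
    counts = np.bincount(labels, minlength=K).astype(float)
    return counts / labels.size


def _runs(labels: np.ndarray):
    """Yield (state, run_length) for maximal contiguous runs."""
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [labels.size]))
    for a, b in zip(starts, ends):
        yield int(labels[a]), int(b - a)


def dwell_times(
    labels: np.ndarray,
    K: int,
    tr: float = 1.0,
    drop_boundary_runs: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean contiguous run length per state, in volumes and in seconds.

    Runs truncated by the recording boundary count by default
    (``drop_boundary_runs=True`` drops the first and last run instead).
    Unvisited states get NaN.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise DataError("empty label sequence")
    runs = list(_runs(labels))
    if drop_boundary_runs and len(runs) > 2:
        runs = runs[1:-1]
    sums = np.zeros(K)
    counts = np.zeros(K)
    for state, length in runs:
        sums[state] += length
        counts[state] += 1
    with np.errstate(invalid="ignore"):
        mean_volumes = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return mean_volumes, mean_volumes * tr


def transition_matrix(
    labels: np.ndarray,
    K: int,
    include_self: bool = True,
) -> np.ndarray:
    """Empirical first-order Markov transition probabilities.

    Counts consecutive ordered pairs ``(t -> t+1)`` and normalises each row.
    With ``include_self=False`` the diagonal (dwelling) counts are zeroed
    before normalisation, giving the conditional distribution of the *next
    different* state.  Rows with no observed exits are NaN (undefined), not
    zero-filled.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size < 2:
        raise DataError("need at least 2 volumes for transitions")
    counts = np.zeros((K, K))
    np.add.at(counts, (labels[:-1], labels[1:]), 1.0)
    if not include_self:
        np.fill_diagonal(counts, 0.0)
    row_sums = counts.sum(axis=1)
    out = np.full((K, K), np.nan)
    ok = row_sums > 0
    out[ok] = counts[ok] / row_sums[ok, None]
    return out


def state_kop_stats(
    labels: np.ndarray,
    kop: KOPSeries,
    K: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and population std of KOP over each state's volumes.

    The occupancy-weighted mean of the per-state means equals the global
    mean synchronisation exactly, and the within- plus between-state
    variances add up to the squared global metastability (law of total
    variance; population convention).  States with no volumes get NaN means;
    states with fewer than 2 volumes get NaN metastability.
    """
    labels = np.asarray(labels, dtype=int)
    values = kop.values
    if labels.shape[0] != values.shape[0]:
        raise DataError("labels and KOP series must be aligned")
    means = np.full(K, np.nan)
    stds = np.full(K, np.nan)
    for k in range(K):
        sel = labels == k
        n = int(sel.sum())
        if n >= 1:
            means[k] = values[sel].mean()
        if n >= 2:
            stds[k] = values[sel].std()
    return means, stds


def subject_metrics(
    seq: StateSequence,
    kop: KOPSeries,
    drop_boundary_runs: bool = False,
) -> SubjectStateMetrics:
    """All per-subject state metrics plus the global dynamics summaries."""
    fo = fractional_occupancy(seq.labels, seq.K)
    dt_vol, dt_sec = dwell_times(
        seq.labels, seq.K, tr=seq.tr, drop_boundary_runs=drop_boundary_runs
    )
    sync, meta = state_kop_stats(seq.labels, kop, seq.K)
    return SubjectStateMetrics(
        subject_id=seq.subject_id,
        K=seq.K,
        fractional_occupancy=fo,
        dwell_time_volumes=dt_vol,
        dwell_time_seconds=dt_sec,
        state_mean_sync=sync,
        state_metastability=meta,
        transition_matrix=transition_matrix(seq.labels, seq.K, include_self=True),
        transition_matrix_noself=transition_matrix(seq.labels, seq.K, include_self=False),
        mean_sync=float(kop.values.mean()),
        metastability=float(kop.values.std()),
    )


def metrics_table(all_metrics: list[SubjectStateMetrics]):
    """Tidy per-subject x state DataFrame of the four state features."""
    import pandas as pd

    rows = []
    for m in all_metrics:
        for k in range(m.K):
            rows.append(
                {
                    "subject_id": m.subject_id,
                    "state": k,
                    "fo": m.fractional_occupancy[k],
                    "dwell_s": m.dwell_time_seconds[k],
                    "mean_sync": m.state_mean_sync[k],
                    "metastability": m.state_metastability[k],
                }
            )
    return pd.DataFrame(rows)
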