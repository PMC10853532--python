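"""Kuramoto order parameter and the two global dynamics summaries.

The Kuramoto order parameter (KOP) at volume *t* is the modulus of the mean
unit phasor across parcels,

    KOP(t) = | (1/P) * sum_j exp(i * phi_j(t)) |,

so KOP = 1 means full phase synchrony and values near zero mean incoherence.
Its temporal mean is the *mean synchronisation* and its temporal standard
deviation the *metastability* of the recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phase import DataError, PhaseArray

__all__ = ["KOPSeries", "GlobalSummary", "kop_series", "global_summary"]


@dataclass
class KOPSeries:
    """Kuramoto order parameter per volume; values in [0, 1]."""

    values: np.ndarray
    tr: float
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class GlobalSummary:
    """Per-subject global dynamics: mean synchronisation and metastability."""

    mean_sync: float
    metastability: float
    subject_id: str | None = None


def kop_series(phases: PhaseArray) -> KOPSeries:
    """Kuramoto order parameter at every volume.

    Equals the length of the resultant of P unit phasors divided by P; it is
    invariant to a global phase rotation at each volume.
    """
    if phases.n_parcels < 2:
        raise DataError("KOP needs at least 2 parcels")
    if phases.n_volumes < 1:
        raise DataError("empty phase array")
    resultant = np.exp(1j * phases.phases).mean(axis=1)
    return KOPSeries(values=np.abs(resultant), tr=phases.tr, subject_id=phases.subject_id)


def global_summary(kop: KOPSeries) -> GlobalSummary:
    """Temporal mean (mean synchronisation) and population standard deviation
    (metastability) of the KOP series.

    The population (N-denominator) convention keeps the exact law-of-total-
    variance decomposition across brain states: the occupancy-weighted
    within-state variance plus the between-state variance of the state means
    equals the squared metastability.
    """
    if kop.values.size < 2:
        raise DataError("need at least 2 volumes to compute metastability")
    return GlobalSummary(
        mean_sync=float(kop.values.mean()),
        metastability=float(kop.values.std()),
        subject_id=kop.subject_id,
    )
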