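"""Band-pass filtering, instantaneous phase extraction, and motion QC.

Parcellated BOLD signals are narrow-band filtered (Butterworth, zero-phase)
and converted to instantaneous phases via the analytic signal
``z(t) = s(t) + i H[s(t)]`` where ``H`` is the Hilbert transform.  The phase
of parcel *j* at volume *t* is the four-quadrant angle of ``z_j(t)``.

Motion quality control follows the framewise-displacement (FD) outlier rule:
a volume is an outlier when its FD exceeds the subject's 75th percentile plus
1.5 times the interquartile range, and a subject is excluded when more than
10% of volumes are outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "ParcelTimeseries",
    "PhaseArray",
    "MotionQC",
    "bandpass_filter",
    "hilbert_phases",
    "fd_outlier_mask",
]


class DataError(ValueError):
    """Raised when input data violates a contract (shape, range, content)."""


@dataclass
class ParcelTimeseries:
    """A T x P matrix of parcel-averaged BOLD values.

    Parameters
    ----------
    values
        Array of shape (T, P): T volumes, P parcels.
    tr
        Repetition time in seconds.
    parcel_names
        Length-P labels; defaults to ``p000..`` if omitted.
    subject_id
        Optional subject identifier carried through the pipeline.
    """

    values: np.ndarray
    tr: float
    parcel_names: list[str] = field(default_factory=list)
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D (volumes x parcels) array")
        if not np.all(np.isfinite(self.values)):
            raise DataError("values contain NaN or infinite entries")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if self.values.shape[1] < 2:
            raise DataError("need at least 2 parcels")
        if not self.parcel_names:
            self.parcel_names = [f"p{i:03d}" for i in range(self.values.shape[1])]
        if len(self.parcel_names) != self.values.shape[1]:
            raise DataError(
                f"{len(self.parcel_names)} parcel names for "
                f"{self.values.shape[1]} data columns"
            )

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.values.shape[1]


@dataclass
class PhaseArray:
    """Instantaneous phases (radians, wrapped to (-pi, pi]) per volume/parcel.

    ``trim`` volumes were discarded from each edge of the parent timeseries,
    so ``phases`` has ``T - 2 * trim`` rows.
    """

    phases: np.ndarray
    trim: int
    tr: float
    parcel_names: list[str] = field(default_factory=list)
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.ndim != 2 or self.phases.shape[0] < 1:
            raise DataError("phases must be a non-empty 2-D array")

    @property
    def n_volumes(self) -> int:
        return self.phases.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.phases.shape[1]


@dataclass
class MotionQC:
    """Framewise-displacement outlier summary for one subject."""

    fd: np.ndarray
    threshold: float
    outlier_mask: np.ndarray
    outlier_fraction: float
    excluded: bool
    subject_id: str | None = None


def bandpass_filter(
    ts: ParcelTimeseries,
    low: float = 0.02,
    high: float = 0.10,
    order: int = 2,
) -> ParcelTimeseries:
    """Zero-phase Butterworth band-pass of every parcel timeseries.

    The filter is applied forward and backward (``filtfilt``), so the
    effective magnitude response is the squared one-pass response and the
    phase response is identically zero -- essential because everything
    downstream is phase-based.

    Parameters
    ----------
    ts
        Input timeseries.
    low, high
        Pass-band edges in Hz. Defaults are the 0.02-0.10 Hz BOLD band.
    order
        Order of the underlying one-pass Butterworth design.

    Returns
    -------
    ParcelTimeseries
        Filtered series; per-parcel mean is ~0 (DC is outside the band).
    """
    nyquist = 1.0 / (2.0 * ts.tr)
    if not (0.0 < low < high):
        raise ValueError(f"need 0 < low < high, got low={low}, high={high}")
    if high >= nyquist:
        raise ValueError(f"high={high} Hz must be below Nyquist ({nyquist:.4f} Hz)")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=1.0 / ts.tr, output="sos")
    # filtfilt pads by 3 * max(len(a), len(b)) per edge; require headroom
    padlen = 3 * (2 * order + 1)
    if ts.n_volumes <= 3 * padlen:
        raise DataError(
            f"timeseries too short for order-{order} band-pass "
            f"({ts.n_volumes} volumes, need > {3 * padlen})"
        )
    filtered = signal.sosfiltfilt(sos, ts.values, axis=0)
    return ParcelTimeseries(
        values=filtered,
        tr=ts.tr,
        parcel_names=list(ts.parcel_names),
        subject_id=ts.subject_id,
    )


def hilbert_phases(ts: ParcelTimeseries, trim: int = 10) -> PhaseArray:
    """Instantaneous phase of every parcel via the analytic signal.

    The phase is the four-quadrant angle of ``s(t) + i H[s(t)]``.  The first
    and last ``trim`` volumes are dropped to suppress the Hilbert-transform
    edge transient (the FFT-based transform implicitly periodises the
    signal).

    Raises
    ------
    DataError
        If any parcel is constant (phase undefined) or trimming would leave
        no volumes.
    """
    if trim < 0:
        raise ValueError("trim must be >= 0")
    variances = ts.values.var(axis=0)
    dead = np.flatnonzero(variances == 0.0)
    if dead.size:
        names = ", ".join(ts.parcel_names[i] for i in dead[:5])
        raise DataError(f"constant (zero-variance) parcel(s): {names}")
    if ts.n_volumes - 2 * trim < 1:
        raise DataError(
            f"trim={trim} leaves no volumes out of {ts.n_volumes}"
        )
    analytic = signal.hilbert(ts.values - ts.values.mean(axis=0), axis=0)
    phases = np.angle(analytic)
    if trim:
        phases = phases[trim:-trim]
    return PhaseArray(
        phases=phases,
        trim=trim,
        tr=ts.tr,
        parcel_names=list(ts.parcel_names),
        subject_id=ts.subject_id,
    )


def fd_outlier_mask(
    fd: np.ndarray,
    max_outlier_fraction: float = 0.10,
    subject_id: str | None = None,
    threshold: float | None = None,
) -> MotionQC:
    """Flag high-motion volumes and decide subject exclusion.

    A volume is an outlier when ``fd > Q3 + 1.5 * IQR`` where Q3 and IQR are
    computed from this subject's own FD series with linear-interpolation
    percentiles.  The subject is excluded when the outlier fraction exceeds
    ``max_outlier_fraction`` (default 10%).

    Parameters
    ----------
    fd
        Per-volume framewise displacement (mm), non-negative.
    threshold
        Optional externally supplied threshold (e.g. computed over a cohort
        rather than per subject); when given, the per-subject rule is skipped.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.ndim != 1 or fd.size == 0:
        raise DataError("fd must be a non-empty 1-D series")
    if np.any(fd < 0):
        raise DataError("fd contains negative values")
    if threshold is None:
        q1, q3 = np.percentile(fd, [25.0, 75.0])
        threshold = float(q3 + 1.5 * (q3 - q1))
    mask = fd > threshold
    fraction = float(mask.mean())
    return MotionQC(
        fd=fd,
        threshold=float(threshold),
        outlier_mask=mask,
        outlier_fraction=fraction,
        excluded=fraction > max_outlier_fraction,
        subject_id=subject_id,
    )
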