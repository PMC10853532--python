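"""Readers and writers for the pipeline's plain-text formats.

Everything is delimited text: timeseries as TSV with one header row of
parcel names, FD series as a single column, cohort tables and results as
TSV, the brain-state model as a commented-metadata block followed by the
K x P centroid matrix, and ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .leida import BrainStateModel
from .phase import ParcelTimeseries

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_fd",
    "write_fd",
    "read_cohort_table",
    "write_cohort_table",
    "read_state_model",
    "write_state_model",
    "read_state_sequence",
    "write_state_sequence",
    "write_ground_truth",
]


class ParseError(ValueError):
    """Malformed input file; message carries file, row and column context."""


def write_timeseries(ts: ParcelTimeseries, path: str | Path) -> None:
    """TSV with one header row of parcel names and T numeric rows."""
    path = Path(path)
    header = "\t".join(ts.parcel_names)
    np.savetxt(path, ts.values, delimiter="\t", header=header, comments="", fmt="%.10g")


def read_timeseries(
    path: str | Path,
    tr: float,
    subject_id: str | None = None,
) -> ParcelTimeseries:
    """Read a delimited-text timeseries (header = parcel names)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        sep = "\t" if "\t" in header else ","
        names = [c.strip() for c in header.split(sep)]
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split(sep)
            if len(cells) != len(names):
                raise ParseError(
                    f"{path}:{lineno}: {len(cells)} cells but {len(names)} header columns"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError:
                bad = next(i for i, c in enumerate(cells) if not _is_number(c))
                raise ParseError(
                    f"{path}:{lineno}: non-numeric cell in column "
                    f"{bad + 1} ({names[bad]!r}): {cells[bad]!r}"
                ) from None
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return ParcelTimeseries(
        values=np.array(rows), tr=tr, parcel_names=names, subject_id=subject_id
    )


def _is_number(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def write_fd(fd: np.ndarray, path: str | Path) -> None:
    np.savetxt(Path(path), np.asarray(fd, dtype=float), fmt="%.10g")


def read_fd(path: str | Path) -> np.ndarray:
    fd = np.loadtxt(Path(path), ndmin=1)
    if fd.ndim != 1:
        raise ParseError(f"{path}: FD file must contain a single column")
    return fd


def write_cohort_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(Path(path), sep="\t", index=False)


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t")


def write_state_model(model: BrainStateModel, path: str | Path) -> None:
    """Commented metadata block followed by the K x P centroid matrix."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# K: {model.K}\n")
        fh.write(f"# seed: {model.seed}\n")
        fh.write(f"# restarts: {model.restarts}\n")
        fh.write(f"# inertia: {model.inertia:.10g}\n")
        if model.state_order is not None:
            fh.write(f"# state_order: {','.join(map(str, model.state_order))}\n")
        if model.state_mean_kop is not None:
            fh.write(
                "# state_mean_kop: "
                + ",".join(f"{v:.10g}" for v in model.state_mean_kop)
                + "\n"
            )
        np.savetxt(fh, model.centroids, delimiter="\t", fmt="%.10g")


def read_state_model(path: str | Path) -> BrainStateModel:
    path = Path(path)
    meta: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
            elif line.strip():
                rows.append([float(c) for c in line.split()])
    model = BrainStateModel(
        K=int(meta["K"]),
        centroids=np.array(rows),
        seed=int(meta["seed"]),
        restarts=int(meta["restarts"]),
        inertia=float(meta["inertia"]),
    )
    if "state_order" in meta:
        model.state_order = np.array(
            [int(v) for v in meta["state_order"].split(",")]
        )
    if "state_mean_kop" in meta:
        model.state_mean_kop = np.array(
            [float(v) for v in meta["state_mean_kop"].split(",")]
        )
    return model


def write_state_sequence(labels: np.ndarray, path: str | Path) -> None:
    np.savetxt(Path(path), np.asarray(labels, dtype=int), fmt="%d")


def read_state_sequence(path: str | Path) -> np.ndarray:
    return np.loadtxt(Path(path), dtype=int, ndmin=1)


def export_cohort(scenario, outdir: str | Path, bold: bool = True) -> pd.DataFrame:
    """Simulate a cohort and write it to disk in pipeline-ready layout.

    Writes per-subject timeseries and FD TSVs, the cohort covariate table,
    a manifest (subject_id, timeseries, fd) and the ground-truth JSON.
    Returns the manifest DataFrame.
    """
    from .synthetic import simulate_cohort, simulate_fd

    outdir = Path(outdir)
    (outdir / "timeseries").mkdir(parents=True, exist_ok=True)
    (outdir / "fd").mkdir(exist_ok=True)
    timeseries, cohort, truth = simulate_cohort(scenario, bold=bold)
    rng = np.random.default_rng(scenario.seed + 1)
    rows = []
    for i, sid in enumerate(cohort["subject_id"]):
        ts_path = outdir / "timeseries" / f"{sid}.tsv"
        fd_path = outdir / "fd" / f"{sid}.tsv"
        if bold:
            write_timeseries(timeseries[i], ts_path)
        fd = simulate_fd(scenario.T, float(cohort["motion"].iloc[i]), rng)
        write_fd(fd, fd_path)
        rows.append(
            {"subject_id": sid, "timeseries": str(ts_path), "fd": str(fd_path)}
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    write_cohort_table(cohort, outdir / "cohort.tsv")
    write_ground_truth(truth, outdir / "ground_truth.json")
    return manifest


def write_ground_truth(truth, path: str | Path) -> None:
    """JSON sidecar with the planted parameters and state sequences."""
    payload = {
        "seed": truth.seed,
        "outcome_feature": truth.outcome_feature,
        "outcome_coef": truth.outcome_coef,
        "outcome_intercept": truth.outcome_intercept,
        "outcome_noise_sd": truth.outcome_noise_sd,
        "templates": [
            {
                "label": t.label,
                "coupling_strength": t.coupling_strength,
                "community_mask": t.community_mask.astype(int).tolist(),
            }
            for t in truth.templates
        ],
        "subject_matrices": truth.subject_matrices.tolist(),
        "true_features": truth.true_features.tolist(),
        "sequences": truth.sequences.tolist(),
    }
    with open(Path(path), "w") as fh:
        json.dump(payload, fh)
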