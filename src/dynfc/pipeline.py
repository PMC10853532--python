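"""End-to-end orchestration: QC -> filter -> phases -> KOP -> LEiDA ->
state metrics -> permutation-GLM statistics, driven by a YAML config.

The pipeline consumes a manifest (one row per subject pointing at a
timeseries file and an FD file) plus a cohort covariate table, and writes
every intermediate artifact as plain text into the output directory.  All
randomness (K-means restarts, permutations) is routed through seeds in the
config, so identical config + inputs reproduce identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .kuramoto import global_summary, kop_series
from .leida import (
    cluster_eigenvectors,
    leida_vectors,
    order_states,
    relabel_by_order,
    select_k,
)
from .metrics import StateSequence, metrics_table, subject_metrics
from .phase import bandpass_filter, fd_outlier_mask, hilbert_phases
from .stats import glm_permutation_scan

logger = logging.getLogger("dynfc")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

# named response groups expandable in stats blocks; each is one FDR family
_RESPONSE_GROUPS = ("global", "fo", "dwell", "sync", "meta", "transitions")


@dataclass
class StatsBlock:
    """One GLM design: responses (group name or explicit list), covariates,
    and the term of interest tested by permutation."""

    name: str
    responses: str | list[str]
    covariates: list[str]
    term: str
    n_perm: int = 10000
    method: str = "freedman_lane"
    alpha: float = 0.05


@dataclass
class PipelineConfig:
    manifest: str
    cohort_table: str
    output_dir: str
    tr: float = 0.392
    band_low: float = 0.02
    band_high: float = 0.10
    filter_order: int = 2
    trim: int = 10
    K: int = 6
    k_scan: list[int] = field(default_factory=list)
    restarts: int = 20
    seed: int = 0
    max_outlier_fraction: float = 0.10
    drop_boundary_runs: bool = False
    stats: list[StatsBlock] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        stats = [StatsBlock(**blk) for blk in raw.pop("stats", [])]
        return cls(stats=stats, **raw)

    def validate(self) -> None:
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if not (0 < self.band_low < self.band_high < 1 / (2 * self.tr)):
            raise ValueError("invalid band for this TR")
        for p in (self.manifest, self.cohort_table):
            if not Path(p).exists():
                raise FileNotFoundError(p)


@dataclass
class PipelineResult:
    manifest: pd.DataFrame             # per-subject QC/inclusion bookkeeping
    model: object                      # ordered BrainStateModel
    features: pd.DataFrame             # wide per-subject feature table
    metrics: pd.DataFrame              # tidy subject x state table
    stats: pd.DataFrame | None
    k_scan: pd.DataFrame | None


def _feature_row(subject_id, summary, m, K):
    row = {
        "subject_id": subject_id,
        "mean_sync": summary.mean_sync,
        "metastability": summary.metastability,
    }
    for k in range(K):
        row[f"fo_state{k + 1}"] = m.fractional_occupancy[k]
        row[f"dwell_state{k + 1}"] = m.dwell_time_seconds[k]
        row[f"sync_state{k + 1}"] = m.state_mean_sync[k]
        row[f"meta_state{k + 1}"] = m.state_metastability[k]
    for i in range(K):
        for j in range(K):
            row[f"trans_{i + 1}_{j + 1}"] = m.transition_matrix[i, j]
    return row


def _expand_responses(spec: str | list[str], K: int) -> tuple[list[str], str]:
    if isinstance(spec, list):
        return spec, "custom"
    if spec == "global":
        return ["mean_sync", "metastability"], "global"
    if spec == "fo":
        return [f"fo_state{k + 1}" for k in range(K)], "fo"
    if spec == "dwell":
        return [f"dwell_state{k + 1}" for k in range(K)], "dwell"
    if spec == "sync":
        return [f"sync_state{k + 1}" for k in range(K)], "sync"
    if spec == "meta":
        return [f"meta_state{k + 1}" for k in range(K)], "meta"
    if spec == "transitions":
        return [
            f"trans_{i + 1}_{j + 1}" for i in range(K) for j in range(K)
        ], "transitions"
    raise ValueError(f"unknown response group {spec!r}; use one of {_RESPONSE_GROUPS}")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write all artifacts under ``config.output_dir``."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "state_sequences").mkdir(exist_ok=True)

    manifest = pd.read_csv(config.manifest, sep="\t")
    cohort = dio.read_cohort_table(config.cohort_table)

    # ---- stage 1: motion QC --------------------------------------------
    qc_rows = []
    included = []
    for _, row in manifest.iterrows():
        sid = row["subject_id"]
        fd = dio.read_fd(row["fd"])
        qc = fd_outlier_mask(
            fd, max_outlier_fraction=config.max_outlier_fraction, subject_id=sid
        )
        qc_rows.append(
            {
                "subject_id": sid,
                "included": not qc.excluded,
                "reason": "" if not qc.excluded else "motion_outliers>10%",
                "outlier_fraction": qc.outlier_fraction,
                "fd_threshold": qc.threshold,
            }
        )
        if not qc.excluded:
            included.append(row)
        else:
            logger.info("excluding %s: %.1f%% motion outliers", sid, 100 * qc.outlier_fraction)
    if not included:
        raise RuntimeError("no subject passed motion QC")

    # ---- stage 2: filter, phases, KOP, LEiDA vectors --------------------
    subject_ids, kops, summaries, vec_blocks = [], [], [], []
    for row in included:
        sid = row["subject_id"]
        try:
            ts = dio.read_timeseries(row["timeseries"], tr=config.tr, subject_id=sid)
            filtered = bandpass_filter(
                ts, low=config.band_low, high=config.band_high, order=config.filter_order
            )
            phases = hilbert_phases(filtered, trim=config.trim)
            kop = kop_series(phases)
            vec_blocks.append(leida_vectors(phases))
            kops.append(kop)
            summaries.append(global_summary(kop))
            subject_ids.append(sid)
        except Exception as exc:
            raise RuntimeError(f"stage=signal subject={sid}: {exc}") from exc

    lengths = [v.shape[0] for v in vec_blocks]
    pooled_vectors = np.vstack(vec_blocks)
    pooled_kop = np.concatenate([k.values for k in kops])

    # ---- stage 3: clustering and state ordering -------------------------
    k_scan_table = None
    if config.k_scan:
        k_scan_table = select_k(
            pooled_vectors, k_range=config.k_scan, seed=config.seed,
            restarts=config.restarts,
        )
        k_scan_table.to_csv(out / "k_selection.tsv", sep="\t", index=False)
    model, pooled_labels = cluster_eigenvectors(
        pooled_vectors, K=config.K, seed=config.seed, restarts=config.restarts
    )
    model = order_states(model, pooled_kop, pooled_labels)
    ranked_labels = relabel_by_order(pooled_labels, model.state_order)
    dio.write_state_model(model, out / "state_model.txt")

    # ---- stage 4: per-subject metrics -----------------------------------
    offsets = np.cumsum([0] + lengths)
    all_metrics, feat_rows = [], []
    for i, sid in enumerate(subject_ids):
        labels = ranked_labels[offsets[i]: offsets[i + 1]]
        dio.write_state_sequence(labels, out / "state_sequences" / f"{sid}.tsv")
        seq = StateSequence(labels=labels, K=config.K, tr=config.tr, subject_id=sid)
        m = subject_metrics(seq, kops[i], drop_boundary_runs=config.drop_boundary_runs)
        all_metrics.append(m)
        feat_rows.append(_feature_row(sid, summaries[i], m, config.K))
    features = pd.DataFrame(feat_rows)
    tidy = metrics_table(all_metrics)
    features.to_csv(out / "subject_features.tsv", sep="\t", index=False)
    tidy.to_csv(out / "state_metrics.tsv", sep="\t", index=False)

    # ---- stage 5: permutation-GLM inference ------------------------------
    stats_out = None
    if config.stats:
        merged = features.merge(cohort, on="subject_id", how="inner")
        blocks = []
        for b_idx, block in enumerate(config.stats):
            responses, group = _expand_responses(block.responses, config.K)
            responses = [r for r in responses if r in merged.columns]
            res = glm_permutation_scan(
                merged,
                responses=responses,
                covariates=block.covariates,
                term=block.term,
                n_perm=block.n_perm,
                seed=config.seed + 1000 * (b_idx + 1),
                family=f"{block.name}:{group}:{block.term}",
                alpha=block.alpha,
                method=block.method,
            )
            res.insert(0, "model", block.name)
            blocks.append(res)
        stats_out = pd.concat(blocks, ignore_index=True)
        stats_out.to_csv(out / "stats_results.tsv", sep="\t", index=False)

    qc_table = pd.DataFrame(qc_rows)
    qc_table["volumes_used"] = np.nan
    qc_table.loc[qc_table["included"], "volumes_used"] = lengths
    qc_table.to_csv(out / "run_manifest.tsv", sep="\t", index=False)

    return PipelineResult(
        manifest=qc_table,
        model=model,
        features=features,
        metrics=tidy,
        stats=stats_out,
        k_scan=k_scan_table,
    )
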