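"""End-to-end staging pipeline: features -> PCA -> clustering -> annotation.

The pipeline is deterministic given its configuration: the only random
element is the tie-breaking jitter used when the Delaunay triangulation
meets degenerate geometry, and that is driven by the configured seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import annotate as annotate_mod
from . import density_cluster, features as features_mod, signal_ingest
from .annotate import AnnotationParams, Hypnogram
from .density_cluster import ClusterParams, ClusterResult
from .features import FeatureTable, PCScores
from .signal_ingest import SignalRecord
from .stages import Stage


class ConfigError(Exception):
    pass


@dataclass
class PipelineConfig:
    """All tunable parameters of the staging pipeline, with the optimized
    defaults: 8-s epochs at 100 Hz, dirty log-power thresholds (1, 2),
    4 principal components, bandwidth shrinkage 0.7, 540 scan levels per
    5400-point subset, annotation quantiles (0.5, 0.1)."""

    epoch_length_s: float = 8.0
    sampling_rate_hz: float = 100.0
    eeg_log_threshold: float = 1.0
    emg_log_threshold: float = 2.0
    pcn: int = 4
    h_mult: float = 0.7
    n_grid: int = 540
    max_subset: int = 5400
    p_emg: float = 0.5
    p_delta: float = 0.1
    quantile_scope: str = "subset"  # or "global"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.quantile_scope not in ("subset", "global"):
            raise ConfigError("quantile_scope must be 'subset' or 'global'")
        if self.epoch_length_s <= 0 or self.sampling_rate_hz <= 0:
            raise ConfigError("epoch_length_s and sampling_rate_hz must be positive")
        if self.pcn < 1:
            raise ConfigError("pcn must be >= 1")
        for name in ("h_mult", "p_emg", "p_delta"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not (0 < self.p_emg < 1 and 0 < self.p_delta < 1):
            raise ConfigError("p_emg and p_delta must be in (0, 1)")

    def cluster_params(self) -> ClusterParams:
        return ClusterParams(
            h_mult=self.h_mult,
            n_grid=self.n_grid,
            max_subset=self.max_subset,
            jitter_seed=self.seed,
        )

    def annotation_params(self) -> AnnotationParams:
        return AnnotationParams(p_emg=self.p_emg, p_delta=self.p_delta)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping of parameter names")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"{path}: unknown parameters {sorted(unknown)}")
        merged = {**overrides, **data}
        return cls(**merged)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class StagingResult:
    hypnogram: Hypnogram
    features: FeatureTable
    pcs: PCScores
    clusters: ClusterResult
    cluster_stages: list[dict[int, Stage]]  # per subset
    log: dict = field(default_factory=dict)


def stage_record(record: SignalRecord, config: PipelineConfig | None = None
                 ) -> StagingResult:
    """Stage a recording into a per-epoch NREM/REM/WAKE/DIRTY hypnogram."""
    config = config or PipelineConfig()
    grid, eeg_epochs, emg_epochs = signal_ingest.split_epochs(
        record, config.epoch_length_s
    )
    table = features_mod.extract_features(
        eeg_epochs,
        emg_epochs,
        config.sampling_rate_hz,
        eeg_log_threshold=config.eeg_log_threshold,
        emg_log_threshold=config.emg_log_threshold,
    )
    clean = table.clean_indices
    pcs = features_mod.fit_project_pca(table.spectra[clean], pcn=config.pcn)
    clusters = density_cluster.cluster_scores(pcs.scores, config.cluster_params())

    log_emg = table.log_emg_total[clean]
    log_delta = table.log_eeg_delta[clean]
    ann = config.annotation_params()

    n_subsets = len(clusters.n_clusters_per_subset)
    cluster_stages: list[dict[int, Stage]] = []
    epoch_stage_clean = np.empty(len(clean), dtype=object)
    if config.quantile_scope == "subset":
        for s in range(1, n_subsets + 1):
            mask = clusters.subset_id == s
            labels = clusters.label[mask]
            medians = annotate_mod.cluster_medians(
                log_emg[mask], log_delta[mask], labels
            )
            stages = annotate_mod.annotate_clusters(
                medians, log_emg[mask], log_delta[mask], labels, ann
            )
            cluster_stages.append(stages)
            epoch_stage_clean[mask] = [stages[int(l)] for l in labels]
    else:
        # global scope: both quantile populations span all subsets, so the
        # WAKE rule is applied everywhere before the delta population forms
        emg_threshold = float(np.quantile(log_emg, config.p_emg))
        all_medians = []
        for s in range(1, n_subsets + 1):
            mask = clusters.subset_id == s
            all_medians.append(
                annotate_mod.cluster_medians(
                    log_emg[mask], log_delta[mask], clusters.label[mask]
                )
            )
        nonwake = np.zeros(len(clean), dtype=bool)
        for s, medians in enumerate(all_medians, start=1):
            mask = clusters.subset_id == s
            for label, row in medians.iterrows():
                if not row["median_log_emg"] > emg_threshold:
                    nonwake |= mask & (clusters.label == int(label))
        delta_threshold = (
            float(np.quantile(log_delta[nonwake], config.p_delta))
            if nonwake.any()
            else None
        )
        for s, medians in enumerate(all_medians, start=1):
            mask = clusters.subset_id == s
            labels = clusters.label[mask]
            stages = annotate_mod.annotate_clusters_with_thresholds(
                medians, emg_threshold, delta_threshold
            )
            cluster_stages.append(stages)
            epoch_stage_clean[mask] = [stages[int(l)] for l in labels]

    all_stages: list[Stage] = [Stage.DIRTY] * table.n_epochs
    for pos, epoch_idx in enumerate(clean):
        all_stages[epoch_idx] = epoch_stage_clean[pos]
    hypnogram = Hypnogram(
        stages=all_stages,
        epoch_length_s=config.epoch_length_s,
        start_time_s=record.start_time_s,
    )

    counts = hypnogram.counts()
    log = {
        "config": config.to_dict(),
        "n_epochs": table.n_epochs,
        "n_dirty": int(table.dirty.sum()),
        "n_subsets": n_subsets,
        "clusters_per_subset": clusters.n_clusters_per_subset,
        "scan_stride": [d.stride for d in clusters.diagnostics],
        "stage_counts": {s.name: counts[s] for s in Stage},
        "explained_variance_pcn": float(
            pcs.explained_variance_ratio[: config.pcn].sum()
        ),
    }
    return StagingResult(
        hypnogram=hypnogram,
        features=table,
        pcs=pcs,
        clusters=clusters,
        cluster_stages=cluster_stages,
        log=log,
    )


def stage_file(path: str | Path, config: PipelineConfig | None = None,
               format: str | None = None) -> StagingResult:
    config = config or PipelineConfig()
    record = signal_ingest.read_record(
        path, format=format, sampling_rate_hz=config.sampling_rate_hz
    )
    return stage_record(record, config)


def feature_frame(result: StagingResult):
    """Per-epoch feature export: dirty flag, band log-powers, PC scores."""
    import pandas as pd

    table = result.features
    n = table.n_epochs
    df = pd.DataFrame(
        {
            "epoch_index": np.arange(n),
            "dirty": table.dirty.astype(int),
            "log_emg_total": table.log_emg_total,
            "log_eeg_delta": table.log_eeg_delta,
        }
    )
    pcn = result.pcs.pcn
    pc_cols = np.full((n, pcn), np.nan)
    pc_cols[table.clean_indices] = result.pcs.scores
    for j in range(pcn):
        df[f"pc{j + 1}"] = pc_cols[:, j]
    return df


def cluster_frame(result: StagingResult):
    """Per-epoch cluster export: subset, label, density, core flag."""
    import pandas as pd

    table = result.features
    clean = table.clean_indices
    return pd.DataFrame(
        {
            "epoch_index": clean,
            "subset_id": result.clusters.subset_id,
            "cluster": result.clusters.label,
            "density": result.clusters.density,
            "is_core": result.clusters.is_core.astype(int),
        }
    )
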