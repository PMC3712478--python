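"""Cluster annotation: map whole clusters to NREM/REM/WAKE by quantile rules.

Stages are assigned per cluster, never per epoch, from two absolute spectral
summaries: the median log10 total EMG power and the median log10 EEG
delta-band (0.5-4 Hz) power of the cluster's members.

Rules (thresholds are quantiles, strict ``>`` comparisons):
  * a cluster is WAKE iff its median log EMG power exceeds the ``p_emg``
    quantile of log EMG power over all clean epochs;
  * among the remaining clusters, one is NREM iff its median log delta power
    exceeds the ``p_delta`` quantile of log delta power over the epochs of
    non-WAKE clusters, and REM otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stages import Stage


class AnnotationError(Exception):
    pass


@dataclass
class AnnotationParams:
    p_emg: float = 0.5
    p_delta: float = 0.1
    delta_band_hz: tuple[float, float] = (0.5, 4.0)

    def __post_init__(self) -> None:
        if not 0 < self.p_emg < 1:
            raise AnnotationError("p_emg must be in (0, 1)")
        if not 0 < self.p_delta < 1:
            raise AnnotationError("p_delta must be in (0, 1)")


@dataclass
class Hypnogram:
    """One stage per epoch, in original epoch order."""

    stages: list[Stage]
    epoch_length_s: float = 8.0
    start_time_s: float = 0.0

    def __len__(self) -> int:
        return len(self.stages)

    def __iter__(self):
        return iter(self.stages)

    def counts(self) -> dict[Stage, int]:
        out = {s: 0 for s in Stage}
        for s in self.stages:
            out[s] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        n = len(self.stages)
        return pd.DataFrame(
            {
                "epoch_index": np.arange(n),
                "start_time_s": self.start_time_s
                + np.arange(n) * self.epoch_length_s,
                "stage": [s.value for s in self.stages],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Hypnogram":
        df = pd.read_csv(path)
        stages = [Stage.from_code(str(c)) for c in df["stage"]]
        if len(df) > 1 and "start_time_s" in df:
            dt = float(df["start_time_s"].iloc[1] - df["start_time_s"].iloc[0])
            t0 = float(df["start_time_s"].iloc[0])
        else:
            dt, t0 = 8.0, 0.0
        return cls(stages=stages, epoch_length_s=dt, start_time_s=t0)


def cluster_medians(
    log_emg_total: np.ndarray,
    log_eeg_delta: np.ndarray,
    labels: np.ndarray,
) -> pd.DataFrame:
    """Median log EMG power and log EEG delta power per cluster.

    Returns a frame indexed by cluster label with columns ``median_log_emg``
    and ``median_log_delta`` plus the member count.
    """
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise AnnotationError("no labeled epochs")
    if np.any(labels <= 0):
        raise AnnotationError("every clean epoch must carry a cluster label")
    df = pd.DataFrame(
        {
            "label": labels,
            "log_emg": np.asarray(log_emg_total, dtype=float),
            "log_delta": np.asarray(log_eeg_delta, dtype=float),
        }
    )
    agg = df.groupby("label").agg(
        median_log_emg=("log_emg", "median"),
        median_log_delta=("log_delta", "median"),
        n_epochs=("log_emg", "size"),
    )
    return agg


def annotate_clusters(
    medians: pd.DataFrame,
    log_emg_total: np.ndarray,
    log_eeg_delta: np.ndarray,
    labels: np.ndarray,
    params: AnnotationParams | None = None,
) -> dict[int, Stage]:
    """Assign a stage to every cluster by the two quantile rules.

    ``log_emg_total``, ``log_eeg_delta`` and ``labels`` cover all clean
    epochs of the population over which the quantiles are taken (by default
    one independently clustered subset).
    """
    params = params or AnnotationParams()
    if len(medians) == 0:
        raise AnnotationError("no clusters to annotate")
    labels = np.asarray(labels)
    log_emg_total = np.asarray(log_emg_total, dtype=float)
    log_eeg_delta = np.asarray(log_eeg_delta, dtype=float)

    emg_threshold = float(np.quantile(log_emg_total, params.p_emg))
    stages: dict[int, Stage] = {}
    for label, row in medians.iterrows():
        if row["median_log_emg"] > emg_threshold:
            stages[int(label)] = Stage.WAKE

    nonwake_labels = [int(c) for c in medians.index if int(c) not in stages]
    if nonwake_labels:
        nonwake_mask = np.isin(labels, nonwake_labels)
        delta_threshold = float(
            np.quantile(log_eeg_delta[nonwake_mask], params.p_delta)
        )
        for label in nonwake_labels:
            median_delta = float(medians.loc[label, "median_log_delta"])
            stages[label] = (
                Stage.NREM if median_delta > delta_threshold else Stage.REM
            )
    return stages


def annotate_clusters_with_thresholds(
    medians: pd.DataFrame,
    emg_threshold: float,
    delta_threshold: float | None,
) -> dict[int, Stage]:
    """Apply the two rules with precomputed thresholds.

    Used when the quantile populations span several independently clustered
    subsets.  ``delta_threshold=None`` is allowed only when every cluster
    clears the EMG rule (all WAKE).
    """
    stages: dict[int, Stage] = {}
    for label, row in medians.iterrows():
        if row["median_log_emg"] > emg_threshold:
            stages[int(label)] = Stage.WAKE
    for label in medians.index:
        if int(label) in stages:
            continue
        if delta_threshold is None:
            raise AnnotationError("non-WAKE cluster but no delta threshold given")
        median_delta = float(medians.loc[label, "median_log_delta"])
        stages[int(label)] = (
            Stage.NREM if median_delta > delta_threshold else Stage.REM
        )
    return stages


def emit_hypnogram(
    cluster_stages: dict[int, Stage],
    labels: np.ndarray,
    dirty: np.ndarray,
    clean_indices: np.ndarray,
    n_epochs: int,
    epoch_length_s: float = 8.0,
    start_time_s: float = 0.0,
) -> Hypnogram:
    """Expand cluster stages to a per-epoch hypnogram in original order.

    ``labels`` runs over clean epochs in the order given by
    ``clean_indices`` (which re-interleaves the independently processed
    subsets back into recording order); dirty epochs receive DIRTY.
    """
    dirty = np.asarray(dirty, dtype=bool)
    stages: list[Stage | None] = [None] * n_epochs
    for i in np.flatnonzero(dirty):
        stages[i] = Stage.DIRTY
    for pos, epoch_idx in enumerate(np.asarray(clean_indices)):
        label = int(np.asarray(labels)[pos])
        if label not in cluster_stages:
            raise AnnotationError(f"epoch {epoch_idx}: cluster {label} has no stage")
        stages[epoch_idx] = cluster_stages[label]
    missing = [i for i, s in enumerate(stages) if s is None]
    if missing:
        raise AnnotationError(f"unlabeled clean epochs: {missing[:5]}...")
    return Hypnogram(
        stages=stages, epoch_length_s=epoch_length_s, start_time_s=start_time_s
    )
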