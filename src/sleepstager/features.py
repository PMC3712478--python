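"""Per-epoch spectral features: combined EEG/EMG power spectra, dirty-epoch
flagging, within-epoch log normalization and PCA reduction.

Each epoch is detrended (least-squares line subtracted), Hann-windowed and
transformed by a single FFT per channel.  Powers at the positive frequencies,
excluding the DC and Nyquist bins, of both channels are concatenated
EEG-first: at 100 Hz and 8-s epochs this gives 2 x 399 = 798 features per
epoch.  Absolute band powers (total EMG power, EEG delta-band power) are kept
aside before normalization because the annotation rules need absolute scale,
which the within-epoch z-score destroys.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from sklearn.decomposition import PCA

#: floor applied to powers before log10, well below any physiological power
POWER_FLOOR = 1e-12

DELTA_BAND_HZ = (0.5, 4.0)


class FeatureError(Exception):
    pass


@dataclass
class FeatureTable:
    """Per-epoch spectral features for one recording.

    ``spectra`` rows are within-epoch z-scored log10 powers; rows flagged
    ``dirty`` are left as raw log powers and excluded downstream.
    """

    spectra: np.ndarray          # (n_epochs, n_features)
    log_emg_total: np.ndarray    # (n_epochs,) log10 summed EMG power
    log_eeg_delta: np.ndarray    # (n_epochs,) log10 summed EEG delta power
    dirty: np.ndarray            # (n_epochs,) bool
    freq_axis_hz: np.ndarray     # (n_features/2,) per-channel bin centers

    @property
    def n_epochs(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_features(self) -> int:
        return self.spectra.shape[1]

    @property
    def clean_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.dirty)


@dataclass
class PCScores:
    """Projection of clean epochs onto the top principal components."""

    scores: np.ndarray                    # (n_clean, pcn)
    eigenvectors: np.ndarray              # (n_features, pcn)
    explained_variance_ratio: np.ndarray  # full spectrum, descending
    pcn: int


def spectrum_bins(samples_per_epoch: int, sampling_rate_hz: float) -> np.ndarray:
    """Frequency-bin centers kept per channel (DC and Nyquist removed)."""
    freqs = np.fft.rfftfreq(samples_per_epoch, d=1.0 / sampling_rate_hz)
    return freqs[1:-1] if samples_per_epoch % 2 == 0 else freqs[1:]


def _channel_power(x: np.ndarray) -> np.ndarray:
    """Power spectrum of epoch rows: detrend, Hann window, FFT, drop DC+Nyquist."""
    x = sps.detrend(np.asarray(x, dtype=float), axis=-1, type="linear")
    window = sps.windows.hann(x.shape[-1], sym=False)
    coef = np.fft.rfft(x * window, axis=-1)
    power = np.abs(coef) ** 2
    if x.shape[-1] % 2 == 0:
        return power[..., 1:-1]
    return power[..., 1:]


def epoch_spectrum(
    eeg: np.ndarray, emg: np.ndarray, sampling_rate_hz: float
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Combined raw EEG+EMG power vector(s) and absolute band sums.

    Accepts a single epoch (1-D) or a stack of epochs (2-D, one per row).
    Returns the EEG-first concatenated raw power matrix and a dict with
    ``eeg_total``, ``emg_total`` and ``eeg_delta`` raw band sums.
    """
    eeg = np.atleast_2d(np.asarray(eeg, dtype=float))
    emg = np.atleast_2d(np.asarray(emg, dtype=float))
    if eeg.shape != emg.shape:
        raise FeatureError("EEG and EMG epoch stacks must have identical shape")
    p_eeg = _channel_power(eeg)
    p_emg = _channel_power(emg)
    freqs = spectrum_bins(eeg.shape[-1], sampling_rate_hz)
    lo, hi = DELTA_BAND_HZ
    delta_mask = (freqs >= lo) & (freqs <= hi)
    bands = {
        "eeg_total": p_eeg.sum(axis=-1),
        "emg_total": p_emg.sum(axis=-1),
        "eeg_delta": p_eeg[..., delta_mask].sum(axis=-1),
    }
    return np.concatenate([p_eeg, p_emg], axis=-1), bands


def flag_dirty(
    eeg_total: np.ndarray,
    emg_total: np.ndarray,
    eeg_log_threshold: float = 1.0,
    emg_log_threshold: float = 2.0,
) -> np.ndarray:
    """Flag epochs whose total EEG or EMG log-power exceeds its threshold.

    True iff log10(sum EEG power) > ``eeg_log_threshold`` or
    log10(sum EMG power) > ``emg_log_threshold``.  Zero (or negative) total
    power has no logarithm and marks the epoch dirty as a degenerate signal.
    Dirty epochs are ignored for automated staging.
    """
    eeg_total = np.atleast_1d(np.asarray(eeg_total, dtype=float))
    emg_total = np.atleast_1d(np.asarray(emg_total, dtype=float))
    degenerate = (eeg_total <= 0) | (emg_total <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        over = (np.log10(np.maximum(eeg_total, POWER_FLOOR)) > eeg_log_threshold) | (
            np.log10(np.maximum(emg_total, POWER_FLOOR)) > emg_log_threshold
        )
    return degenerate | over


def log_normalize(raw_power: np.ndarray, dirty: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Within-epoch z-score of log10 powers.

    Each non-dirty row is mapped x -> (log10 x - mean) / sd, with mean and sd
    taken over that row's features.  Rows with zero spread (constant power)
    cannot be normalized and are reclassified dirty.  Returns the normalized
    matrix and the updated dirty mask; dirty rows keep their raw log powers.
    """
    raw_power = np.asarray(raw_power, dtype=float)
    n = raw_power.shape[0]
    dirty = np.zeros(n, dtype=bool) if dirty is None else dirty.copy()
    logp = np.log10(np.maximum(raw_power, POWER_FLOOR))
    mean = logp.mean(axis=1, keepdims=True)
    sd = logp.std(axis=1, keepdims=True)
    zero_sd = sd[:, 0] == 0
    dirty |= zero_sd
    out = logp.copy()
    ok = ~dirty
    out[ok] = (logp[ok] - mean[ok]) / sd[ok]
    return out, dirty


def fit_project_pca(spectra: np.ndarray, pcn: int = 4) -> PCScores:
    """PCA on the normalized spectra of all clean epochs of a recording.

    The fit uses the covariance of the already-normalized rows with no
    further column standardization.  Eigenvector signs are fixed so that each
    eigenvector's largest-magnitude element is positive, making the scores
    reproducible across runs and row orders.
    """
    spectra = np.asarray(spectra, dtype=float)
    n, d = spectra.shape
    if pcn < 1 or pcn >= d:
        raise FeatureError(f"pcn must be in [1, {d - 1}], got {pcn}")
    if n <= pcn:
        raise FeatureError(f"need more than {pcn} clean epochs, have {n}")
    if not np.all(np.isfinite(spectra)):
        raise FeatureError("non-finite values in spectra")
    pca = PCA(n_components=min(n, d), svd_solver="full")
    pca.fit(spectra)
    components = pca.components_[:pcn]  # (pcn, d)
    signs = np.sign(components[np.arange(pcn), np.argmax(np.abs(components), axis=1)])
    signs[signs == 0] = 1.0
    components = components * signs[:, None]
    scores = (spectra - pca.mean_) @ components.T
    return PCScores(
        scores=scores,
        eigenvectors=components.T,
        explained_variance_ratio=pca.explained_variance_ratio_,
        pcn=pcn,
    )


def extract_features(
    eeg_epochs: np.ndarray,
    emg_epochs: np.ndarray,
    sampling_rate_hz: float,
    eeg_log_threshold: float = 1.0,
    emg_log_threshold: float = 2.0,
) -> FeatureTable:
    """Full feature pass over an epoch stack: spectra, dirty flags, z-scores."""
    raw, bands = epoch_spectrum(eeg_epochs, emg_epochs, sampling_rate_hz)
    dirty = flag_dirty(
        bands["eeg_total"], bands["emg_total"], eeg_log_threshold, emg_log_threshold
    )
    spectra, dirty = log_normalize(raw, dirty)
    with np.errstate(divide="ignore"):
        log_emg_total = np.log10(np.maximum(bands["emg_total"], POWER_FLOOR))
        log_eeg_delta = np.log10(np.maximum(bands["eeg_delta"], POWER_FLOOR))
    return FeatureTable(
        spectra=spectra,
        log_emg_total=log_emg_total,
        log_eeg_delta=log_eeg_delta,
        dirty=dirty,
        freq_axis_hz=spectrum_bins(eeg_epochs.shape[-1], sampling_rate_hz),
    )
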