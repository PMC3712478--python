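"""Synthetic mouse EEG/EMG generator with stage-conditioned spectral content.

Produces a ground-truth hypnogram from a first-order Markov chain and, per
epoch, signals with the spectral signature of each vigilance stage:

* NREM  — high-amplitude delta (0.5-4 Hz) EEG, low EMG;
* REM   — low-amplitude theta (6-10 Hz) EEG, very low EMG (atonia);
* WAKE  — mixed EEG, high EMG whose amplitude varies strongly across epochs.

EEG epochs are synthesized in the frequency domain: complex Gaussian
coefficients shaped by a per-stage spectral envelope (Gaussian band bumps on
a 1/f noise floor), giving broadband oscillatory activity rather than pure
tones; EMG is broadband Gaussian noise scaled by a stage-specific,
per-epoch-modulated amplitude.  Artifact epochs (amplitude
far above the physiological range, tripping the dirty rule) can be injected
at a configurable rate, and the generator records where it put them.

Everything is driven by one integer seed: identical configurations give
byte-identical signals.  Amplitudes are in arbitrary units scaled so clean
epochs sit well below the dirty-power thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .annotate import Hypnogram
from .signal_ingest import SignalRecord
from .stages import Stage


class SimulationError(Exception):
    pass


@dataclass
class StageRecipe:
    """Spectral recipe of one stage.

    eeg_bands
        List of ``(center_hz, bandwidth_hz, amplitude)`` EEG band
        components: Gaussian bumps of the given full-width-half-maximum in
        the spectral envelope that shapes the epoch's random Fourier
        coefficients.
    emg_amplitude
        Standard deviation of the broadband EMG noise.
    pink_amplitude
        Amplitude of the 1/f EEG envelope floor.
    emg_epoch_sd
        Log-normal sigma of the per-epoch EMG amplitude modulation
        ("high and varying" for wake).
    eeg_epoch_sd
        Log-normal sigma of the per-epoch EEG band-drive modulation; low for
        the stereotyped low-amplitude theta of REM sleep.
    """

    eeg_bands: list[tuple[float, float, float]]
    emg_amplitude: float
    pink_amplitude: float
    emg_epoch_sd: float = 0.1
    eeg_epoch_sd: float = 0.2


# Amplitudes in arbitrary units (think mV): with 8-s/100-Hz epochs these put
# clean log10 total powers near -2..0, far below the dirty thresholds (1, 2).
DEFAULT_RECIPES: dict[Stage, StageRecipe] = {
    Stage.NREM: StageRecipe(
        eeg_bands=[(2.25, 3.5, 6e-2), (12.5, 5.0, 1.2e-2), (8.0, 4.0, 8e-3)],
        emg_amplitude=1.2e-4,
        pink_amplitude=1.0e-2,
        emg_epoch_sd=0.15,
        eeg_epoch_sd=0.2,
    ),
    Stage.REM: StageRecipe(
        eeg_bands=[(7.5, 3.0, 4e-2), (2.25, 3.5, 6e-3)],
        emg_amplitude=3.0e-5,
        pink_amplitude=8.0e-3,
        emg_epoch_sd=0.10,
        eeg_epoch_sd=0.10,
    ),
    Stage.WAKE: StageRecipe(
        eeg_bands=[(8.5, 4.0, 1.5e-2), (2.25, 3.5, 1.0e-2), (22.0, 12.0, 1.0e-2)],
        emg_amplitude=5.0e-4,
        pink_amplitude=1.2e-2,
        emg_epoch_sd=0.35,
        eeg_epoch_sd=0.25,
    ),
}

_STAGE_ORDER = (Stage.NREM, Stage.REM, Stage.WAKE)

# Rows/columns in NREM, REM, WAKE order.  NREM-heavy dwell times with no
# direct WAKE->REM transition (physiological prior, configurable); the
# stationary distribution is roughly 52% NREM, 10% REM, 38% WAKE.
DEFAULT_TRANSITION = np.array(
    [
        [0.88, 0.06, 0.06],
        [0.25, 0.65, 0.10],
        [0.09, 0.00, 0.91],
    ]
)


@dataclass
class SimConfig:
    n_epochs: int = 5400
    epoch_length_s: float = 8.0
    sampling_rate_hz: float = 100.0
    transition: np.ndarray = field(default_factory=lambda: DEFAULT_TRANSITION.copy())
    initial_stage: Stage = Stage.NREM
    seed: int = 0
    dirty_epoch_rate: float = 0.0
    artifact_gain: float = 1000.0
    difficulty: float = 0.0
    recipes: dict[Stage, StageRecipe] = field(
        default_factory=lambda: dict(DEFAULT_RECIPES)
    )

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        if self.transition.shape != (3, 3):
            raise SimulationError("transition matrix must be 3x3 (NREM, REM, WAKE)")
        if np.any(self.transition < 0) or not np.allclose(
            self.transition.sum(axis=1), 1.0, atol=1e-9
        ):
            raise SimulationError("transition rows must be non-negative and sum to 1")
        if not 0 <= self.dirty_epoch_rate < 1:
            raise SimulationError("dirty_epoch_rate must be in [0, 1)")
        if not 0 <= self.difficulty <= 1:
            raise SimulationError("difficulty must be in [0, 1]")


@dataclass
class SimResult:
    record: SignalRecord
    truth: Hypnogram          # artifact epochs marked DIRTY
    stage_truth: Hypnogram    # underlying stages, artifacts ignored
    artifact_indices: np.ndarray


def _effective_recipes(config: SimConfig) -> dict[Stage, StageRecipe]:
    """Apply the difficulty knob: geometrically pull stage amplitudes toward
    their across-stage mean, shrinking the separation between stages."""
    if config.difficulty == 0:
        return config.recipes
    t = config.difficulty

    def pull(value: float, center: float) -> float:
        return float(np.exp((1 - t) * np.log(value) + t * np.log(center)))

    emg_center = float(
        np.exp(np.mean([np.log(r.emg_amplitude) for r in config.recipes.values()]))
    )
    eeg_center = float(
        np.exp(
            np.mean(
                [
                    np.log(a)
                    for r in config.recipes.values()
                    for _, _, a in r.eeg_bands
                ]
            )
        )
    )
    out = {}
    for stage, recipe in config.recipes.items():
        bands = [(c, w, pull(a, eeg_center)) for c, w, a in recipe.eeg_bands]
        out[stage] = replace(
            recipe, eeg_bands=bands, emg_amplitude=pull(recipe.emg_amplitude, emg_center)
        )
    return out


def simulate_hypnogram(config: SimConfig) -> Hypnogram:
    """First-order Markov stage sequence, reproducible per seed."""
    rng = np.random.default_rng(config.seed)
    idx = {s: i for i, s in enumerate(_STAGE_ORDER)}
    state = idx[config.initial_stage]
    states = np.empty(config.n_epochs, dtype=int)
    for i in range(config.n_epochs):
        states[i] = state
        state = rng.choice(3, p=config.transition[state])
    return Hypnogram(
        stages=[_STAGE_ORDER[s] for s in states],
        epoch_length_s=config.epoch_length_s,
    )


def _eeg_envelope(
    recipe: StageRecipe, n: int, sampling_rate_hz: float
) -> np.ndarray:
    """Spectral amplitude envelope of one stage over the rfft bins."""
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate_hz)
    f_floor = np.maximum(freqs, freqs[1] if n > 1 else 1.0)
    env = recipe.pink_amplitude / np.sqrt(f_floor)
    for center, width, amp in recipe.eeg_bands:
        sigma = width / 2.355  # FWHM -> sd
        env = env + amp * np.exp(-0.5 * ((freqs - center) / sigma) ** 2)
    env[0] = 0.0  # no DC drive
    return env


def _eeg_epoch(
    rng: np.random.Generator,
    envelope: np.ndarray,
    n: int,
    eeg_epoch_sd: float,
) -> np.ndarray:
    # random-phase Gaussian coefficients shaped by the stage envelope; one
    # shared per-epoch gain so epochs vary in drive, not in band composition
    coef = (rng.normal(size=len(envelope)) + 1j * rng.normal(size=len(envelope)))
    coef *= envelope / np.sqrt(2.0)
    return rng.lognormal(0.0, eeg_epoch_sd) * np.fft.irfft(coef, n=n)


def simulate_signals(truth: Hypnogram, config: SimConfig) -> SimResult:
    """Render stage-conditioned EEG/EMG for a truth hypnogram."""
    recipes = _effective_recipes(config)
    for stage in _STAGE_ORDER:
        if stage not in recipes:
            raise SimulationError(f"no recipe for stage {stage.name}")
    rng = np.random.default_rng((config.seed, 1))
    spe = int(round(config.epoch_length_s * config.sampling_rate_hz))
    n_epochs = len(truth)
    eeg = np.empty(n_epochs * spe)
    emg = np.empty(n_epochs * spe)
    envelopes = {
        stage: _eeg_envelope(recipes[stage], spe, config.sampling_rate_hz)
        for stage in _STAGE_ORDER
    }
    artifact = rng.random(n_epochs) < config.dirty_epoch_rate
    for i, stage in enumerate(truth.stages):
        recipe = recipes[stage]
        sl = slice(i * spe, (i + 1) * spe)
        eeg[sl] = _eeg_epoch(rng, envelopes[stage], spe, recipe.eeg_epoch_sd)
        emg_amp = recipe.emg_amplitude * rng.lognormal(0.0, recipe.emg_epoch_sd)
        emg[sl] = rng.normal(scale=emg_amp, size=spe)
        if artifact[i]:
            eeg[sl] *= config.artifact_gain
            emg[sl] *= config.artifact_gain
    record = SignalRecord(
        eeg=eeg, emg=emg, sampling_rate_hz=config.sampling_rate_hz
    )
    dirty_truth = Hypnogram(
        stages=[
            Stage.DIRTY if artifact[i] else s for i, s in enumerate(truth.stages)
        ],
        epoch_length_s=config.epoch_length_s,
    )
    return SimResult(
        record=record,
        truth=dirty_truth,
        stage_truth=truth,
        artifact_indices=np.flatnonzero(artifact),
    )


def simulate(config: SimConfig) -> SimResult:
    """Convenience: hypnogram then signals, both from ``config.seed``."""
    return simulate_signals(simulate_hypnogram(config), config)
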