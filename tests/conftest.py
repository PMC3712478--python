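"""Shared fixtures: one full-size staged recording and small clustering inputs."""

from __future__ import annotations

import numpy as np
import pytest

from sleepstager import PipelineConfig, SimConfig, score, simulate, stage_record


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline at the optimized defaults on the default synthetic
    recording (5400 epochs, fixed seed), shared across tests."""
    sim = simulate(SimConfig(n_epochs=5400, seed=1, dirty_epoch_rate=0.005))
    result = stage_record(sim.record, PipelineConfig(seed=1))
    metrics = score(result.hypnogram, sim.truth)
    return {"sim": sim, "result": result, "metrics": metrics}


@pytest.fixture(scope="session")
def small_sim():
    """A short synthetic recording that stages cleanly; used by CLI and
    pipeline round-trip tests."""
    return simulate(SimConfig(n_epochs=400, seed=1, dirty_epoch_rate=0.01))


def make_blob_scores(seed: int = 1, n: int = 1800) -> np.ndarray:
    """Three anisotropic Gaussian blobs in 4-D, a stand-in for PC scores."""
    rng = np.random.default_rng(seed)
    centers = np.array([[0, 0, 0, 0], [6, 0, 1, 0], [3, 5, 0, 1.0]])
    sizes = [n // 2, n // 3, n - n // 2 - n // 3]
    scales = np.array([1.2, 1.0, 0.8, 1.0])
    parts = [
        rng.normal(0, 1, (s, 4)) * scales + centers[i]
        for i, s in enumerate(sizes)
    ]
    return np.vstack(parts)


@pytest.fixture(scope="session")
def blob_scores_4d() -> np.ndarray:
    return make_blob_scores(seed=1)


@pytest.fixture(scope="session")
def two_blobs_2d():
    """Two 2-D Gaussian blobs 10 sigma apart, with generating labels."""
    rng = np.random.default_rng(0)
    pts = np.vstack(
        [rng.normal(0, 1, (200, 2)), rng.normal((10, 10), 1, (200, 2))]
    )
    truth = np.repeat([1, 2], 200)
    return pts, truth
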