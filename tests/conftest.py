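"""Shared fixtures: a tiny synthetic scenario for unit tests and the
session-scoped benchmark runs reused across validation tests."""

from __future__ import annotations

import numpy as np
import pytest

import stimsort as ss
from stimsort import benchmark as bm


def tiny_config(**overrides) -> ss.SimConfig:
    """Desk-scale-but-smaller scenario: 16 electrodes, 1.5 ms, 6 amplitudes."""
    defaults = dict(
        rows=4,
        cols=4,
        pitch_um=60.0,
        n_samples=30,
        amplitudes=np.linspace(0.3, 3.0, 6),
        breakpoints=(1.4,),
        n_trials=6,
        sigma_uv=6.0,
        neurons=None,
    )
    defaults.update(overrides)
    return ss.SimConfig(**defaults)


def easy_config(**overrides) -> ss.SimConfig:
    """A well-posed scenario where artifact and spikes are identifiable:
    no breakpoint, finely spaced amplitudes, strong well-separated neurons."""
    pos = ss.make_layout(4, 4, 60.0)
    defaults = dict(
        breakpoints=(),
        amplitudes=np.linspace(0.2, 2.4, 8),
        n_trials=30,
        sigma_uv=0.5,
        neurons=[
            ss.NeuronSpec(soma_xy=tuple(pos[6]), ei_peak_uv=100.0, mu_a=1.2, s_a=0.2),
            ss.NeuronSpec(soma_xy=tuple(pos[9]), ei_peak_uv=80.0, mu_a=1.8, s_a=0.2),
        ],
    )
    defaults.update(overrides)
    return tiny_config(**defaults)


@pytest.fixture(scope="session")
def tiny_dataset() -> ss.SimulatedDataset:
    return ss.simulate_dataset(tiny_config(), seed=7)


@pytest.fixture(scope="session")
def tiny_scan() -> ss.SimulatedScan:
    return ss.simulate_scan(tiny_config(), seed=7, n_series=5)


@pytest.fixture(scope="session")
def tiny_model(tiny_scan):
    model, manifest = ss.fit_model(tiny_scan.fit_series, seed=7)
    return model


@pytest.fixture(scope="session")
def default_benchmark():
    """One full default-scenario run (simulate scan, fit, detect, score)."""
    return bm.run_default_benchmark(seed=1)


@pytest.fixture(scope="session")
def perturbation_suite():
    """Perturbation orderings over five seeds (the expensive fixture)."""
    return bm.run_perturbation_suite(seeds=(1, 2, 3, 4, 5))


def random_psd(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric PSD matrix with a controlled spectrum."""
    q, _ = np.linalg.qr(rng.normal(size=(n, n)))
    w = rng.uniform(0.1, 3.0, size=n)
    return (q * w) @ q.T
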