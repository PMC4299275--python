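import numpy as np
import pytest

from clockorder import WaveParams, generate_sample_set


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def cosine_set_factory():
    """Noiseless pure-cosine sample sets at equally spaced, shuffled phases.

    With a flat gradient, unit wavelength and no noise, every axial column of
    the phase-sorted matrix is an offset/amplitude-varied cosine completing
    exactly one cycle over the cohort, so the true order attains the global
    minimum g ~ 0 of the periodicity objective.
    """

    def make(n_samples=24, n_positions=60, seed=0, noise_sd=0.0, shuffle=True):
        phases = np.arange(n_samples) / n_samples
        if shuffle:
            phases = np.random.default_rng(seed).permutation(phases)
        params = WaveParams(gradient_amplitude=0.0, noise_sd=noise_sd)
        sset, truth = generate_sample_set(
            n_samples, n_positions, params, rng_seed=seed, phases=phases
        )
        true_perm = np.argsort([t.phase for t in truth])
        return sset, truth, true_perm

    return make


@pytest.fixture
def noisy_set_factory():
    """Traveling-wave sets at uniform random phases with gradient and noise."""

    def make(n_samples=30, n_positions=80, noise_sd=0.1, seed=0):
        sset, truth = generate_sample_set(
            n_samples, n_positions, WaveParams(noise_sd=noise_sd), rng_seed=seed
        )
        true_perm = np.argsort([t.phase for t in truth])
        return sset, truth, true_perm

    return make
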