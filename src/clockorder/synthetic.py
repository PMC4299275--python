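"""Synthetic traveling-wave profiles with known phases.

The generator emulates the phenomenology of segmentation-clock expression in
a half-PSM snapshot: a rostro-caudal baseline gradient plus a caudally
originating pulse that travels rostrally as the clock phase advances, with
additive Gaussian measurement noise.  Because each generated sample records
its true phase separately, every downstream stage (ordering, kymograph
assembly, phase-lag estimation) can be validated against ground truth that
the inference never sees.

The functional form is

    I(x, phi) = g * u(x) + a * (1 + cos(2*pi*(u(x)/w - phi))) / 2 + noise

with u(x) the position rescaled to [0, 1] over the grid, g the gradient
amplitude, a the pulse amplitude and w the wavelength as a fraction of the
axial extent.  Profiles are clipped at zero and min-max normalized, matching
how measured profiles are processed.  Phases are drawn i.i.d. uniform on
[0, 1), mirroring a cohort of embryos fixed at arbitrary, unsynchronised
points of the clock cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InvalidGridError, TooFewSamplesError
from .profiles import AxialProfile, SampleSet, minmax_normalize

__all__ = [
    "WaveParams",
    "PhaseAssignment",
    "generate_wave_profile",
    "generate_sample_set",
    "generate_paired_set",
]


@dataclass(frozen=True)
class WaveParams:
    """Parameters of the synthetic traveling wave.

    period_minutes
        Clock period used to convert phase to wall-clock time; 120 min is the
        mouse segmentation-clock period.
    wavelength_fraction
        Fraction of the axial extent spanned by one wave, in (0, 1].
    gradient_amplitude
        Height of the rostro-caudal baseline gradient (0 disables it).
    pulse_amplitude
        Height of the traveling pulse; must be positive.
    pulse_width
        Retained for API symmetry; the cosine pulse's width is set by
        ``wavelength_fraction``.
    noise_sd
        Standard deviation of i.i.d. additive Gaussian noise per grid point.
    gradient_direction
        ``"rostral_high"`` (gradient increases rostrally) or ``"flat"``.
    caudal_origin
        Waves initiate at position 0 and travel toward increasing position.
    """

    period_minutes: float = 120.0
    wavelength_fraction: float = 1.0
    gradient_amplitude: float = 0.3
    pulse_amplitude: float = 1.0
    pulse_width: float = 1.0
    noise_sd: float = 0.0
    gradient_direction: str = "rostral_high"
    caudal_origin: bool = True

    def __post_init__(self) -> None:
        if self.period_minutes <= 0:
            raise DomainError("period_minutes must be positive")
        if not (0.0 < self.wavelength_fraction <= 1.0):
            raise DomainError("wavelength_fraction must be in (0, 1]")
        if self.gradient_amplitude < 0:
            raise DomainError("gradient_amplitude must be >= 0")
        if self.pulse_amplitude <= 0:
            raise DomainError("pulse_amplitude must be positive")
        if self.pulse_width <= 0:
            raise DomainError("pulse_width must be positive")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")
        if self.gradient_direction not in ("rostral_high", "flat"):
            raise DomainError("gradient_direction must be 'rostral_high' or 'flat'")


@dataclass(frozen=True)
class PhaseAssignment:
    """Ground-truth phase of one sample, as a fraction of the clock cycle."""

    sample_id: str
    phase: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.phase < 1.0):
            raise DomainError(f"phase must be in [0, 1), got {self.phase}")

    def time_minutes(self, period_minutes: float = 120.0) -> float:
        return self.phase * period_minutes


def generate_wave_profile(
    phase: float,
    grid: np.ndarray,
    params: WaveParams = WaveParams(),
    rng_seed: int | np.random.Generator | None = 0,
    sample_id: str = "synthetic",
) -> AxialProfile:
    """Evaluate the noisy traveling wave at one phase on an axial grid.

    With ``noise_sd = 0`` the output is a pure function of
    ``(phase, grid, params)``.  The pulse peak sits at axial fraction
    ``phase * wavelength_fraction`` (mod one wavelength), so increasing phase
    moves the peak rostrally — a caudally originating, rostrally traveling
    wave.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise InvalidGridError("grid needs at least 2 positions")
    if not np.all(np.diff(grid) > 0):
        raise InvalidGridError("grid must be strictly increasing")
    if not (0.0 <= phase < 1.0):
        raise DomainError(f"phase must be in [0, 1), got {phase}")

    frac = (grid - grid[0]) / (grid[-1] - grid[0])
    gradient = (
        params.gradient_amplitude * frac
        if params.gradient_direction == "rostral_high"
        else np.zeros_like(frac)
    )
    pulse = (
        params.pulse_amplitude
        * (1.0 + np.cos(2.0 * np.pi * (frac / params.wavelength_fraction - phase)))
        / 2.0
    )
    intensity = gradient + pulse
    if params.noise_sd > 0:
        rng = np.random.default_rng(rng_seed) if not isinstance(
            rng_seed, np.random.Generator
        ) else rng_seed
        intensity = intensity + rng.normal(0.0, params.noise_sd, size=grid.size)
    intensity = np.clip(intensity, 0.0, None)
    raw = AxialProfile(sample_id, grid, intensity, raw=True)
    return minmax_normalize(raw)


def _uniform_phases(n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(0.0, 1.0, size=n)


def generate_sample_set(
    n_samples: int,
    n_positions: int,
    params: WaveParams = WaveParams(),
    rng_seed: int = 0,
    phases: np.ndarray | None = None,
) -> tuple[SampleSet, list[PhaseAssignment]]:
    """Generate N profiles at i.i.d. uniform phases on a shared grid.

    Returns the sample set and the ground-truth phase assignments as two
    separate objects so that ordering code can be handed the set alone and
    remain blind to the truth.  Pass ``phases`` explicitly (e.g. equally
    spaced) to build deterministic constructions for validation.
    """
    if n_samples < 3:
        raise TooFewSamplesError(
            f"need at least 3 samples (autocorrelation undefined below 3 rows), got {n_samples}"
        )
    if n_positions < 4:
        raise InvalidGridError("n_positions must be >= 4")
    rng = np.random.default_rng(rng_seed)
    if phases is None:
        phases = _uniform_phases(n_samples, rng)
    else:
        phases = np.asarray(phases, dtype=float)
        if phases.shape != (n_samples,):
            raise DomainError("phases must have length n_samples")
        if np.any(phases < 0) or np.any(phases >= 1):
            raise DomainError("phases must lie in [0, 1)")
    grid = np.linspace(0.0, 1.0, n_positions)
    ids = [f"s{i:03d}" for i in range(n_samples)]
    rows = [
        generate_wave_profile(ph, grid, params, rng_seed=rng, sample_id=sid).intensities
        for sid, ph in zip(ids, phases)
    ]
    sset = SampleSet(np.vstack(rows), tuple(ids), grid)
    truth = [PhaseAssignment(sid, float(ph)) for sid, ph in zip(ids, phases)]
    return sset, truth


def generate_paired_set(
    n_samples: int,
    n_positions: int,
    params: WaveParams = WaveParams(),
    partner_lag: float = 0.0,
    rng_seed: int = 0,
    phases: np.ndarray | None = None,
) -> tuple[SampleSet, SampleSet, list[PhaseAssignment]]:
    """Generate control/partner channel pairs sharing per-sample phases.

    Emulates the contralateral half-explant design: each tail is bisected
    into two identical halves, one probed for a reference clock channel
    (control) and the other for the channel of interest (partner).  The
    partner wave lags the control by ``partner_lag`` cycles (partner peaks
    later when positive) and carries an independent noise realization.
    """
    if not (0.0 <= partner_lag < 1.0):
        raise DomainError("partner_lag must be in [0, 1)")
    if n_samples < 3:
        raise TooFewSamplesError(f"need at least 3 samples, got {n_samples}")
    if n_positions < 4:
        raise InvalidGridError("n_positions must be >= 4")
    rng = np.random.default_rng(rng_seed)
    if phases is None:
        phases = _uniform_phases(n_samples, rng)
    else:
        phases = np.asarray(phases, dtype=float)
        if phases.shape != (n_samples,):
            raise DomainError("phases must have length n_samples")
    grid = np.linspace(0.0, 1.0, n_positions)
    ids = [f"s{i:03d}" for i in range(n_samples)]
    control_rows, partner_rows = [], []
    for sid, ph in zip(ids, phases):
        control_rows.append(
            generate_wave_profile(ph, grid, params, rng_seed=rng, sample_id=sid).intensities
        )
        # The partner displays the pattern the control showed partner_lag
        # cycles ago, so its peak arrives partner_lag cycles later in the
        # reconstructed time course.
        partner_rows.append(
            generate_wave_profile(
                (ph - partner_lag) % 1.0, grid, params, rng_seed=rng, sample_id=sid
            ).intensities
        )
    control = SampleSet(np.vstack(control_rows), tuple(ids), grid)
    partner = SampleSet(np.vstack(partner_rows), tuple(ids), grid)
    truth = [PhaseAssignment(sid, float(ph)) for sid, ph in zip(ids, phases)]
    return control, partner, truth
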