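"""Kymograph assembly, smoothing, periodic extension and phase-lag analysis.

A kymograph is the space-time matrix obtained by stacking axial intensity
profiles as rows in inferred time order: columns are rostro-caudal positions
(caudal origin at column 0), rows advance through the clock cycle in proxy
time rank/N.  Because the cohort uniformly samples one cycle, the kymograph
can be tiled vertically (periodic extension) to make the oscillation visually
and analytically continuous, and the mean intensity of a caudal window per
row gives a scalar oscillation time series for each channel.

For the paired half-explant design, an ordering inferred from the control
channel is transferred to the partner channel by sample id — the partner is
never re-optimised — and the lag between the two channels' caudal series is
estimated by circular cross-correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import DomainError, PairingError, ZeroVarianceError
from .ordering import Ordering
from .profiles import SampleSet

__all__ = [
    "Kymograph",
    "CaudalSeries",
    "assemble_kymograph",
    "smooth_kymograph",
    "periodic_extend",
    "caudal_mean_series",
    "transfer_ordering",
    "phase_lag",
]


@dataclass(frozen=True)
class Kymograph:
    """Space-time matrix: rows = samples in time order, columns = positions."""

    matrix: np.ndarray
    proxy_times: np.ndarray
    positions: np.ndarray
    sample_ids: tuple[str, ...] = ()
    channel_label: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        t = np.asarray(self.proxy_times, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "proxy_times", t)
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        if m.ndim != 2:
            raise DomainError("kymograph matrix must be 2-D")
        if t.size != m.shape[0]:
            raise DomainError("proxy_times length must equal row count")
        if self.positions.size != m.shape[1]:
            raise DomainError("positions length must equal column count")
        if not np.all(np.isfinite(m)):
            raise DomainError("kymograph values must be finite")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class CaudalSeries:
    """Mean caudal-window intensity as a function of proxy time."""

    times: np.ndarray
    values: np.ndarray
    caudal_fraction: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.size != v.size:
            raise DomainError("times and values must have equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise DomainError("times must be strictly increasing")


def assemble_kymograph(
    sample_set: SampleSet, ordering: Ordering, channel_label: str = ""
) -> Kymograph:
    """Stack sample profiles into time order; pure row reindexing.

    Row k of the result is the profile of the sample at rank k; proxy times
    are rank/N cycle units.
    """
    if ordering.n != sample_set.n_samples:
        raise DomainError(
            f"ordering of size {ordering.n} does not match {sample_set.n_samples} samples"
        )
    perm = ordering.permutation
    return Kymograph(
        sample_set.matrix[perm],
        np.arange(sample_set.n_samples) / sample_set.n_samples,
        sample_set.positions,
        tuple(sample_set.sample_ids[i] for i in perm),
        channel_label,
    )


def smooth_kymograph(kymo: Kymograph, window_rows: int = 3, window_cols: int = 3) -> Kymograph:
    """Boxcar-average the kymograph for visualisation.

    The time direction wraps circularly (the cohort spans one full cycle, so
    the first and last rows are temporal neighbours); the space direction
    reflects at the tissue boundaries.  Window (1, 1) is the identity.
    """
    for w, extent, name in (
        (window_rows, kymo.n_rows, "window_rows"),
        (window_cols, kymo.n_cols, "window_cols"),
    ):
        if w < 1 or w % 2 == 0 or w > extent:
            raise DomainError(f"{name} must be odd, >= 1 and <= matrix extent, got {w}")
    out = kymo.matrix
    if window_rows > 1:
        out = uniform_filter1d(out, window_rows, axis=0, mode="wrap")
    if window_cols > 1:
        out = uniform_filter1d(out, window_cols, axis=1, mode="reflect")
    return replace(kymo, matrix=out.copy())


def periodic_extend(kymo: Kymograph, n_cycles: int = 2) -> Kymograph:
    """Tile the kymograph vertically over ``n_cycles`` clock cycles."""
    if n_cycles < 1:
        raise DomainError("n_cycles must be >= 1")
    if n_cycles == 1:
        return kymo
    matrix = np.tile(kymo.matrix, (n_cycles, 1))
    times = np.concatenate([kymo.proxy_times + c for c in range(n_cycles)])
    ids = kymo.sample_ids * n_cycles
    return replace(kymo, matrix=matrix, proxy_times=times, sample_ids=ids)


def caudal_mean_series(kymo: Kymograph, caudal_fraction: float = 0.3) -> CaudalSeries:
    """Average the caudal-most window of each row into a time series.

    The caudal window is the ceil(caudal_fraction * M) columns nearest the
    caudal origin (lowest positions).  On a periodically extended kymograph
    the series spans multiple cycles.
    """
    if not (0.0 < caudal_fraction <= 1.0):
        raise DomainError("caudal_fraction must be in (0, 1]")
    n_caudal = max(1, math.ceil(caudal_fraction * kymo.n_cols))
    return CaudalSeries(
        kymo.proxy_times.copy(), kymo.matrix[:, :n_caudal].mean(axis=1), caudal_fraction
    )


def transfer_ordering(
    control_set: SampleSet,
    partner_set: SampleSet,
    ordering_from_control: Ordering,
    channel_label: str = "partner",
) -> Kymograph:
    """Arrange the partner channel by the control-derived ordering.

    Rows are matched by sample id (contralateral halves of the same tail),
    never by row index, and the partner channel is not re-optimised — its
    spatiotemporal pattern is determined blindly by the control ordering.
    """
    if set(control_set.sample_ids) != set(partner_set.sample_ids):
        missing = set(control_set.sample_ids) ^ set(partner_set.sample_ids)
        raise PairingError(f"control/partner sample ids differ: {sorted(missing)}")
    if ordering_from_control.n != control_set.n_samples:
        raise DomainError("ordering does not match the control set")
    partner_row = {sid: k for k, sid in enumerate(partner_set.sample_ids)}
    ordered_ids = [
        control_set.sample_ids[i] for i in ordering_from_control.permutation
    ]
    rows = np.array([partner_row[sid] for sid in ordered_ids], dtype=np.intp)
    n = partner_set.n_samples
    return Kymograph(
        partner_set.matrix[rows],
        np.arange(n) / n,
        partner_set.positions,
        tuple(ordered_ids),
        channel_label,
    )


def phase_lag(series_a: CaudalSeries, series_b: CaudalSeries) -> float:
    """Lag of series_b behind series_a, in cycle fractions in [-0.5, 0.5).

    Both series must share the same time grid over an integer number of
    cycles.  The lag maximises the circular cross-correlation of the
    mean-centred series; positive means series_b peaks later.  A half-cycle
    lag is reported as -0.5 by convention.
    """
    ta, tb = series_a.times, series_b.times
    if ta.size != tb.size or not np.allclose(ta, tb):
        raise DomainError("series must be sampled at identical times")
    total = ta.size
    if total < 3:
        raise DomainError("need at least 3 samples per series")
    span = float(ta[-1] - ta[0]) + float(ta[1] - ta[0])  # closed span, in cycles
    n_cycles = round(span)
    if not math.isclose(span, n_cycles, rel_tol=0, abs_tol=1e-6) or n_cycles < 1:
        raise DomainError("series must span an integer number of cycles")
    a = series_a.values - series_a.values.mean()
    b = series_b.values - series_b.values.mean()
    if np.all(a == 0) or np.all(b == 0):
        raise ZeroVarianceError("constant series has no defined phase lag")
    # Circular cross-correlation c(s) = sum_t a(t) b(t + s); the argmax s is
    # the delay of b behind a in samples.
    fa, fb = np.fft.rfft(a), np.fft.rfft(b)
    cross = np.fft.irfft(np.conj(fa) * fb, n=total)
    shift = int(cross.argmax())
    lag = (shift / total) * n_cycles
    lag = (lag + 0.5) % 1.0 - 0.5
    if math.isclose(lag, 0.5, abs_tol=1e-12):
        lag = -0.5
    return float(lag)
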