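"""Blind time ordering of static snapshots by annealed periodicity matching.

Each of N samples is a snapshot of a periodic spatiotemporal pattern taken at
an unknown phase of the cycle; the phases are effectively uniform over the
cycle, so the rank order of the samples is a proxy for time.  The ordering is
recovered by arranging the rows of the N x M profile matrix so that every
axial column, read down the rows, looks maximally like one period of an
oscillation.  Concretely, for a candidate row order the normalised circular
autocorrelation A(tau) of each column is compared against a target
autocorrelation A_T(tau) = cos(2*pi*tau/N) — the autocorrelation of a
sinusoid completing exactly one cycle across the cohort — and the mismatch

    g = (1/M') * sum_j sum_{tau=1}^{N-1} [A_j(tau) - A_T(tau)]^2

is minimised over permutations (M' = number of non-constant columns).  A key
property of g is exact invariance under cyclic shifts and full reversal of
the row order, so orderings are only ever defined modulo that symmetry;
:func:`ordering_distance` compares permutations modulo it and
:func:`canonicalize_ordering` picks a standard representative.

Minimisation uses a Metropolis--Hastings annealer over transpositions: swap
two random rows, always accept downhill moves, accept uphill moves with
probability exp(-delta_g / T) under a geometrically cooled effective
temperature T.  An exhaustive oracle over all permutations is provided for
small N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, NoSignalError, TooFewSamplesError, ZeroVarianceError
from .profiles import SampleSet

__all__ = [
    "TargetAutocorrelation",
    "AnnealConfig",
    "Ordering",
    "circular_autocorrelation",
    "target_autocorrelation",
    "ordering_error",
    "metropolis_accept",
    "metropolis_step",
    "anneal_order",
    "exhaustive_order",
    "ordering_distance",
    "canonicalize_ordering",
]


def circular_autocorrelation(column: np.ndarray) -> np.ndarray:
    """Normalised circular autocorrelation at integer lags 0..N-1.

    A(tau) = sum_t (x_t - xbar)(x_{(t+tau) mod N} - xbar) / sum_t (x_t - xbar)^2,
    so A(0) = 1 and |A(tau)| <= 1.  Indices wrap (circular), which makes the
    downstream objective exactly invariant under cyclic shifts of the series.
    """
    x = np.asarray(column, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise TooFewSamplesError("autocorrelation needs a 1-D series of length >= 3")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        raise ZeroVarianceError("constant series has no normalised autocorrelation")
    f = np.fft.rfft(xc)
    num = np.fft.irfft(f * np.conj(f), n=x.size)
    return num / denom


@dataclass(frozen=True)
class TargetAutocorrelation:
    """Target autocorrelation enforcing temporal periodicity.

    The default, cos(2*pi*tau/N), is the exact circular autocorrelation of a
    sinusoid with one full oscillation across the N samples — the signature
    of a cohort uniformly sampling one clock cycle.  Alternative targets
    (e.g. multi-cycle cosines) can be supplied wherever a target is accepted.
    """

    values: np.ndarray
    n_cycles_assumed: int = 1

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 3:
            raise DomainError("target needs >= 3 lags")
        if abs(v[0] - 1.0) > 1e-12:
            raise DomainError("target autocorrelation must have A_T(0) = 1")

    @property
    def n(self) -> int:
        return self.values.size


def target_autocorrelation(n: int, n_cycles: int = 1) -> TargetAutocorrelation:
    """Cosine target A_T(tau) = cos(2*pi*n_cycles*tau/N) for lags 0..N-1."""
    if n < 3:
        raise DomainError(f"need N >= 3, got {n}")
    tau = np.arange(n)
    return TargetAutocorrelation(np.cos(2.0 * np.pi * n_cycles * tau / n), n_cycles)


def _as_matrix(sample_set: SampleSet | np.ndarray) -> np.ndarray:
    if isinstance(sample_set, SampleSet):
        return sample_set.matrix
    m = np.asarray(sample_set, dtype=float)
    if m.ndim != 2:
        raise DomainError("expected a 2-D sample matrix")
    return m


def _check_permutation(perm: np.ndarray, n: int) -> np.ndarray:
    p = np.asarray(perm, dtype=np.intp)
    if p.shape != (n,) or not np.array_equal(np.sort(p), np.arange(n)):
        raise DomainError(f"not a valid permutation of 0..{n - 1}")
    return p


class _GEvaluator:
    """Vectorised evaluation of the ordering error g for one sample matrix.

    Constant columns carry no periodicity information (a pure rostral
    gradient can be flat after normalisation) and are excluded from g; the
    informative-column mask is permutation-invariant so it is computed once.
    """

    def __init__(self, matrix: np.ndarray, target: TargetAutocorrelation):
        matrix = np.asarray(matrix, dtype=float)
        n = matrix.shape[0]
        if target.n != n:
            raise DomainError(f"target has {target.n} lags but sample set has {n} rows")
        informative = matrix.std(axis=0) > 0.0
        if not informative.any():
            raise NoSignalError("all columns are constant; ordering objective undefined")
        cols = matrix[:, informative]
        self.n = n
        self.n_informative = int(informative.sum())
        self.informative = informative
        self._cols = cols
        self._denom = ((cols - cols.mean(axis=0)) ** 2).sum(axis=0)
        self._target_tail = target.values[1:][:, None]

    def g(self, perm: np.ndarray) -> float:
        x = self._cols[perm]
        xc = x - x.mean(axis=0)
        f = np.fft.rfft(xc, axis=0)
        acf = np.fft.irfft(f * np.conj(f), n=self.n, axis=0) / self._denom
        diff = acf[1:] - self._target_tail
        return float((diff * diff).sum() / self.n_informative)


def ordering_error(
    sample_set: SampleSet | np.ndarray,
    ordering: np.ndarray,
    target: TargetAutocorrelation | None = None,
) -> float:
    """Mismatch g between column autocorrelations and the periodic target.

    ``ordering`` lists row indices in inferred time order.  Lag 0 is omitted
    (its contribution is identically zero) and the column sum is averaged so
    g is comparable across different numbers of axial positions.
    """
    matrix = _as_matrix(sample_set)
    n = matrix.shape[0]
    perm = _check_permutation(ordering, n)
    if target is None:
        target = target_autocorrelation(n)
    return _GEvaluator(matrix, target).g(perm)


@dataclass(frozen=True)
class Ordering:
    """An inferred time order: permutation, proxy times and its g value.

    ``permutation[k]`` is the row index of the sample placed at rank k;
    proxy times are rank/N in cycle units.  ``trace`` optionally records the
    best g per annealing sweep of the winning chain.
    """

    permutation: np.ndarray
    g_value: float
    trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.permutation, dtype=np.intp)
        object.__setattr__(self, "permutation", p)
        _check_permutation(p, p.size)

    @property
    def n(self) -> int:
        return self.permutation.size

    @property
    def proxy_times(self) -> np.ndarray:
        return np.arange(self.n) / self.n

    @property
    def ranks(self) -> np.ndarray:
        """ranks[i] = time rank of original row i (inverse permutation)."""
        inv = np.empty(self.n, dtype=np.intp)
        inv[self.permutation] = np.arange(self.n)
        return inv


@dataclass(frozen=True)
class AnnealConfig:
    """Metropolis--Hastings annealing schedule.

    One sweep proposes N transpositions.  Temperature cools geometrically,
    T_k = T0 * cooling**k per sweep, floored at ``t_final``; ``t0=None``
    scales the initial temperature to the chain's starting error (initial
    g / N).  After the schedule a zero-temperature pass applies improving
    swaps until none remains.
    """

    t0: float | None = None
    t_final: float = 0.0
    n_sweeps: int = 500
    cooling: float = 0.95
    n_restarts: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.t0 is not None and self.t0 <= 0:
            raise DomainError("t0 must be positive (or None for automatic)")
        if self.t_final < 0:
            raise DomainError("t_final must be >= 0")
        if self.t0 is not None and self.t_final > self.t0:
            raise DomainError("need t0 >= t_final")
        if self.n_sweeps < 0:
            raise DomainError("n_sweeps must be >= 0")
        if not (0.0 < self.cooling <= 1.0):
            raise DomainError("cooling must be in (0, 1]")
        if self.n_restarts < 1:
            raise DomainError("n_restarts must be >= 1")


def metropolis_accept(delta_g: float, temperature: float, rng: np.random.Generator) -> bool:
    """Metropolis acceptance rule for a proposed swap.

    Downhill or neutral moves (delta_g <= 0) are always accepted; uphill
    moves are accepted with probability exp(-delta_g / T).  At T = 0 uphill
    moves are never accepted.
    """
    if delta_g <= 0.0:
        return True
    if temperature <= 0.0:
        return False
    return bool(rng.random() < math.exp(-delta_g / temperature))


def metropolis_step(
    current: Ordering,
    sample_set: SampleSet | np.ndarray,
    target: TargetAutocorrelation | None = None,
    temperature: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> Ordering:
    """One annealing step: swap two random rows, accept or reject.

    Returns the swapped ordering when accepted, otherwise the input ordering
    unchanged.
    """
    if temperature < 0:
        raise DomainError("temperature must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    matrix = _as_matrix(sample_set)
    n = matrix.shape[0]
    if current.n != n:
        raise DomainError("ordering size does not match sample set")
    if target is None:
        target = target_autocorrelation(n)
    ev = _GEvaluator(matrix, target)
    i, j = rng.choice(n, size=2, replace=False)
    proposal = current.permutation.copy()
    proposal[i], proposal[j] = proposal[j], proposal[i]
    g_new = ev.g(proposal)
    if metropolis_accept(g_new - current.g_value, temperature, rng):
        return Ordering(proposal, g_new, trace=current.trace)
    return current


def _greedy_pass(ev: _GEvaluator, perm: np.ndarray, g: float) -> tuple[np.ndarray, float]:
    """Apply improving transpositions until none exists (local minimum)."""
    n = perm.size
    improved = True
    while improved:
        improved = False
        for i in range(n - 1):
            for j in range(i + 1, n):
                perm[i], perm[j] = perm[j], perm[i]
                g_new = ev.g(perm)
                if g_new < g - 1e-15:
                    g = g_new
                    improved = True
                else:
                    perm[i], perm[j] = perm[j], perm[i]
    return perm, g


def anneal_order(
    sample_set: SampleSet | np.ndarray,
    config: AnnealConfig = AnnealConfig(),
    target: TargetAutocorrelation | None = None,
    caudal_fraction: float = 0.3,
) -> Ordering:
    """Minimise the ordering error g over row permutations by annealing.

    Runs ``n_restarts`` independent chains from random initial orderings,
    cools geometrically over ``n_sweeps`` sweeps of N proposals each, applies
    a final zero-temperature greedy pass, and returns the best ordering found,
    canonicalized modulo the cyclic-shift/reversal symmetry of g.
    Fully reproducible under ``config.rng_seed``.
    """
    matrix = _as_matrix(sample_set)
    n = matrix.shape[0]
    if target is None:
        target = target_autocorrelation(n)
    ev = _GEvaluator(matrix, target)
    rng = np.random.default_rng(config.rng_seed)

    best_perm: np.ndarray | None = None
    best_g = np.inf
    best_trace: np.ndarray | None = None
    for _ in range(config.n_restarts):
        perm = rng.permutation(n)
        g = ev.g(perm)
        t0 = config.t0 if config.t0 is not None else max(g / n, 1e-12)
        trace = np.empty(config.n_sweeps)
        for sweep in range(config.n_sweeps):
            temperature = max(t0 * config.cooling**sweep, config.t_final)
            for _ in range(n):
                i, j = rng.choice(n, size=2, replace=False)
                perm[i], perm[j] = perm[j], perm[i]
                g_new = ev.g(perm)
                if metropolis_accept(g_new - g, temperature, rng):
                    g = g_new
                else:
                    perm[i], perm[j] = perm[j], perm[i]
            trace[sweep] = g
        if config.n_sweeps > 0:
            perm, g = _greedy_pass(ev, perm, g)
        if g < best_g:
            best_g, best_perm, best_trace = g, perm.copy(), trace
    assert best_perm is not None
    canon = canonicalize_ordering(matrix, best_perm, caudal_fraction)
    return Ordering(canon, best_g, trace=best_trace)


def exhaustive_order(
    sample_set: SampleSet | np.ndarray,
    target: TargetAutocorrelation | None = None,
    caudal_fraction: float = 0.3,
) -> Ordering:
    """Brute-force oracle: global minimum of g over all row orders.

    Because g is invariant under cyclic shift and reversal, only the
    (N-1)!/2 equivalence classes are enumerated (first row fixed, direction
    fixed by requiring the second entry to be smaller than the last).
    Guarded to N <= 9.
    """
    from itertools import permutations

    matrix = _as_matrix(sample_set)
    n = matrix.shape[0]
    if n > 9:
        raise DomainError(f"exhaustive search is limited to N <= 9, got {n}")
    if target is None:
        target = target_autocorrelation(n)
    ev = _GEvaluator(matrix, target)

    best_perm = np.arange(n)
    best_g = ev.g(best_perm)
    for rest in permutations(range(1, n)):
        if rest[0] > rest[-1]:
            continue  # reversal-equivalent class already covered
        perm = np.array((0,) + rest, dtype=np.intp)
        g = ev.g(perm)
        if g < best_g - 1e-15:
            best_g, best_perm = g, perm
    return Ordering(canonicalize_ordering(matrix, best_perm, caudal_fraction), best_g)


def ordering_distance(perm_a: np.ndarray, perm_b: np.ndarray) -> float:
    """Distance between orderings modulo cyclic shift and reversal, in [0, 1].

    1 minus the maximum, over all cyclic shifts and both directions, of the
    Spearman rank correlation between the aligned rank vectors.  Zero exactly
    when one permutation is a rotated and/or reversed copy of the other —
    the degeneracy class the periodicity objective cannot distinguish.
    """
    a = np.asarray(perm_a, dtype=np.intp)
    b = np.asarray(perm_b, dtype=np.intp)
    if a.shape != b.shape:
        raise DomainError("permutations must have equal length")
    n = a.size
    _check_permutation(a, n)
    _check_permutation(b, n)
    ranks_a = np.empty(n)
    ranks_a[a] = np.arange(n)
    ranks_b = np.empty(n)
    ranks_b[b] = np.arange(n)

    ua = ranks_a - ranks_a.mean()
    denom = float(ua @ ua)
    best = -1.0
    for direction in (1.0, -1.0):
        v = direction * ranks_b
        for shift in range(n):
            w = np.mod(v + shift, n)
            wc = w - w.mean()
            best = max(best, float(ua @ wc) / denom)
    return 1.0 - best


def canonicalize_ordering(
    matrix: np.ndarray, perm: np.ndarray, caudal_fraction: float = 0.3
) -> np.ndarray:
    """Pick the standard representative of an ordering's symmetry class.

    The objective g cannot distinguish a row order from its rotations or its
    reverse, so a convention is imposed on the ordered matrix: the direction
    is chosen so the pulse peak drifts rostrally (toward higher column index)
    with increasing rank, then the order is rotated so the caudal-region mean
    intensity peaks at the first row.
    """
    matrix = np.asarray(matrix, dtype=float)
    n, m = matrix.shape
    perm = _check_permutation(perm, n).copy()

    ordered = matrix[perm]
    peaks = ordered.argmax(axis=1).astype(float)
    # Signed circular drift of the peak between consecutive rows (wrap
    # included); a rostrally traveling wave accumulates positive drift.
    step = np.mod(np.diff(peaks, append=peaks[:1]) + m / 2.0, m) - m / 2.0
    if step.sum() < 0:
        perm = perm[::-1].copy()
        ordered = matrix[perm]

    n_caudal = max(1, math.ceil(caudal_fraction * m))
    caudal_mean = ordered[:, :n_caudal].mean(axis=1)
    shift = int(caudal_mean.argmax())
    return np.roll(perm, -shift)
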