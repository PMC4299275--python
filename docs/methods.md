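# Methods

## The problem

Oscillatory gene expression in the pre-somitic mesoderm (PSM) — the
segmentation clock — produces waves that sweep the tissue caudo-rostrally
with a period of about 120 min in mouse. Imaging a fixed embryo yields a
single static snapshot of this pattern at an unknown phase of the cycle.
Because embryos are dissected and fixed at arbitrary, unsynchronised moments,
a cohort of N snapshots effectively samples the clock phase uniformly on
[0, 1): the *rank* of a sample within the cycle is therefore a usable proxy
for time, even though absolute times are unobservable. `clockorder`
reconstructs that rank order blindly — using nothing but the axial intensity
profiles themselves — and assembles the ordered profiles into kymographs for
downstream analysis.

## Profile quantification

Each sample is reduced to a 1-D axial profile `f(i, x)`:

1. a rectangular ROI is placed with axes parallel to the rostro-caudal and
   medial-lateral axes;
2. a uniform background value is subtracted (floored at 0) and pixels below
   the no-primary-antibody control threshold are zeroed;
3. intensity is averaged across the medial-lateral extent at each
   rostro-caudal pixel;
4. the axial coordinate is rescaled so the caudal-most point of the PSM is
   at 0, increasing rostrally, in units of the last-formed somite-pair
   length (this controls for natural variation in tissue size);
5. the profile is min-max normalized onto [0, 1].

The order of steps past "subtract, threshold" is a design choice; since
averaging and axis rescaling are linear they commute with the later
normalization, so only the subtract-before-threshold order is substantive.
Thresholding sets sub-threshold pixels to 0 (not to the threshold value):
the intent is to remove background signal entirely. Constant profiles are
rejected at normalization rather than silently passed on, because a flat
profile carries no ordering information and would otherwise poison the
objective. Regridding onto a common M-point grid uses linear interpolation;
higher-order schemes ring on pulse edges.

## The ordering objective

Arrange the N profiles as rows of an N x M matrix `f` and consider each
axial column `f_j` as a time series under a candidate row order. If the
order is correct and phases are uniform, every informative column completes
exactly one oscillation across the N rows, whatever its amplitude, offset or
spatial phase. The normalised *circular* autocorrelation of such a column is
exactly `cos(2*pi*tau/N)` — this is an identity, not an approximation: for
`x_t = c + a*cos(2*pi*t/N + phi)` the circular products telescope to the
cosine regardless of `(c, a, phi)`. The objective is the mismatch against
that target,

    g(order) = (1/M') * sum_j sum_{tau=1}^{N-1} [ A(f_j)(tau) - A_T(tau) ]^2,
    A_T(tau) = cos(2*pi*tau/N),

with `M'` the number of non-constant columns. Choices embedded here:

- **Circular autocorrelation** (indices mod N). This makes g *exactly*
  invariant under cyclic shifts of the row order, which is the correct
  symmetry: a cohort uniformly sampling a cycle has no distinguished
  starting phase. Linear autocorrelation would weakly break this symmetry
  and bias the optimum.
- **Single-cycle cosine target.** The target encodes the assumption that the
  cohort spans one clock cycle (`n_cycles_assumed = 1`). It is injectable:
  `target_autocorrelation(n, n_cycles=k)` builds multi-cycle targets for
  cohorts known to span k cycles.
- **Lags 1..N-1, column average.** Lag 0 contributes identically zero;
  dividing by M' makes g comparable across grid resolutions.
- **Constant columns are skipped**, not fatal: after normalization a purely
  gradient-dominated rostral column can be flat. Only an all-constant matrix
  raises an error. Constancy of a column is permutation-invariant, so the
  informative-column mask is computed once per sample set.

g is invariant under full reversal as well (the autocorrelation of a
time-reversed circular series is unchanged), so the objective identifies an
ordering only up to rotation and direction. All comparisons between
orderings use `ordering_distance`, which is 1 minus the best circular
Spearman rank correlation over all rotations and both directions — zero
exactly on the degeneracy class.

## Minimisation

A Metropolis–Hastings annealer over transpositions:

- propose a uniform random swap of two rows (no block moves);
- accept if g decreases; accept an increase `dg` with probability
  `exp(-dg/T)`;
- geometric cooling per sweep of N proposals, `T_k = T0 * cooling^k`,
  defaults `T0 = g_initial/N`, `cooling = 0.95`, 500 sweeps, 5 independent
  restarts from random initial orders, followed by a zero-temperature pass
  that applies improving swaps until none exists. `T0 = g_initial/N` scales
  the initial acceptance rate to the data's own error magnitude, so the same
  schedule works across noise levels without tuning.

The schedule is an engineering choice (the method itself prescribes only the
proposal and acceptance rule); the defaults were fixed from the structure of
the problem — a landscape over N! permutations whose local minima under
transpositions are rare for wave-like data — and validated on the synthetic
cohorts below. Objective evaluation is vectorised (one FFT over all columns
per proposal), giving roughly 20k evaluations/s at N=30, M=80 on one core;
a full default fit at that size takes ~4 s. For N <= 9 an exhaustive oracle
enumerates the (N-1)!/2 symmetry classes and returns the certified global
minimum.

The returned ordering is canonicalized: the direction is chosen so that the
per-row intensity peak drifts rostrally with increasing rank (the biological
wave direction), then rotated so the caudal-window mean peaks at rank 0.
Ties in g are broken by first discovery; full determinism follows from the
single seeded generator per fit.

## Kymographs and paired channels

`assemble_kymograph` is pure row reindexing with proxy times rank/N (in
cycle units; multiply by the 120-min period for minutes). Smoothing is a
boxcar whose time direction wraps circularly — consistent with the
periodicity assumption that row N-1 neighbours row 0 — and whose space
direction reflects at the tissue boundaries; window (1, 1) is the exact
identity. Periodic extension tiles the matrix over k cycles for display and
for circular series analysis.

The caudal mean series averages the caudal-most `ceil(0.3*M)` columns per
row (the fraction is a parameter; 0.3 covers the caudal PSM where waves
originate while excluding the rostral gradient). For contralateral
half-explant pairs, the ordering inferred from the control channel is
applied to the partner channel *by sample id*, with no re-optimisation —
the partner pattern is determined blindly. The lag between two channels'
caudal series is the argmax of their circular cross-correlation, reported in
cycle fractions in [-0.5, 0.5), positive when the partner peaks later; its
resolution is 1/N cycles, and a half-cycle lag is reported as -0.5 by
convention.

## Synthetic data generator

The generator produces the phenomenology the method targets, with ground
truth recorded separately so ordering code stays blind:

    I(x, phi) = gradient_amplitude * x
              + pulse_amplitude * (1 + cos(2*pi*(x/wavelength_fraction - phi)))/2
              + N(0, noise_sd),   then clip at 0 and min-max normalize,

on x in [0, 1] (positions in somite units). Defaults: period 120 min (mouse
clock), wavelength_fraction 1 (one wave across the PSM — wave geometry is a
free parameter, as no quantitative wavelength is established for these
protein waves), gradient_amplitude 0.3 (a visible but non-dominant
rostro-caudal gradient, as described for Dll1/Notch1 protein),
pulse_amplitude 1, noise_sd as stated per experiment. Phases are i.i.d.
uniform on [0, 1). The pulse is a periodic cosine train rather than a
windowed solitary pulse: with the default full-cohort wavelength the two are
identical, and the cosine keeps every validation closed-form. Paired
generation gives the partner channel phase `phi - lag` (it will peak `lag`
cycles later) and an independent noise realization per channel.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: spatial wavelength changing as waves narrow
rostrally, amplitude growth along the axis, sample-to-sample variation in
tissue length or wave shape, non-Gaussian or spatially correlated imaging
noise, and deviations from exact phase uniformity. The ordering objective
itself assumes none of these specifics (only periodicity across the
cohort), but recovery rates measured here are for the idealised wave.

## Validation conditions and results computed

All validation is property-based, on generated cohorts at fixed conditions:
exact-minimum construction (N=24, M=60, noiseless equally spaced phases,
where every column is an exact cosine and the true order attains g ~ 1e-12);
oracle equivalence (N=7, M=40, noise 0.1, 10 seeds); symmetry invariance
(100 random matrices, machine precision); noisy recovery (N=30, M=80, noise
0.15, 10 replicates, median ordering distance); the Metropolis acceptance
law at dg = T over 1e5 trials; blind partner transfer (lag 0.2 cycles, N=30,
noise 0.1, 10 seeds — note the lag estimate is quantised to 1/N cycles);
image-quantification round trip; and byte-level determinism of a full
pipeline run. `scripts/acceptance.py` recomputes all of these from scratch;
`tests/test_acceptance.py` asserts them. Problem sizes were chosen so the
full suite and the script each complete in about 1.5 minutes on one core
while keeping every check at its natural scale.

## Known limitations

- The method orders samples *within* one assumed cycle; it cannot detect
  that a cohort actually spans two cycles (a two-cycle cohort fits the
  two-cycle target instead — supply one explicitly).
- Rank order is the only temporal estimate; no continuous per-sample phase
  is fitted, so time resolution is 1/N of a cycle everywhere, including the
  phase-lag estimate.
- With strong noise the annealer can land in a near-degenerate local
  minimum that transposes phase-adjacent samples; restarts make this rare
  but the per-replicate distance distribution has occasional outliers
  (medians are reported for this reason).
- Direction canonicalization relies on the per-row argmax drifting
  rostrally; for signals whose maximum sits in a static rostral gradient
  rather than the traveling pulse it may pick the opposite direction (the
  ordering itself is unaffected, only its presentation).
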