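# clockorder

Blind time-ordering and kymograph analysis of oscillatory axial expression
profiles — reconstructing segmentation-clock wave dynamics from static,
unordered snapshots.

## The problem

The segmentation clock drives periodic waves of gene and protein expression
that sweep the pre-somitic mesoderm (PSM) caudo-rostrally (period ≈ 120 min
in mouse). Fixed embryos each capture a single frame of this movie at an
unknown phase; because fixation is unsynchronised, a cohort of N embryos
samples the clock phase approximately uniformly. `clockorder` recovers the
temporal order of such a cohort *blindly* — from the intensity profiles
alone — turning a pile of static snapshots into a space-time picture
(kymograph) of the oscillation. It is aimed at developmental biologists and
quantitative biologists analysing in-situ / immunofluorescence cohorts of
PSM explants or sections, and at anyone with the analogous problem of
ordering unsynchronised snapshots of a periodic process.

## The method

Each sample is reduced to a normalized axial profile `f(i, x)` (caudal
origin at x = 0, somite-pair units, min-max normalized to [0, 1]). For a
candidate row order of the N × M profile matrix, each axial column `f_j` is
scored by its normalised circular autocorrelation `A(f_j)(τ)`, and the order
is found by minimising

```
g = (1/M') Σ_j Σ_{τ=1}^{N-1} [ A(f_j)(τ) − A_T(τ) ]²,   A_T(τ) = cos(2πτ/N)
```

— the target autocorrelation of a signal completing exactly one cycle
across the cohort. Minimisation uses a Metropolis–Hastings annealer over
row transpositions: downhill swaps are always accepted, uphill swaps with
probability `exp(−Δg/T)` under geometric cooling, plus restarts and a final
greedy pass. Since g is exactly invariant under cyclic shifts and reversal
of the order, results are reported modulo that symmetry and canonicalized so
the wave travels rostrally with the caudal signal peaking first. An
exhaustive oracle certifies global minima for N ≤ 9.

For the contralateral half-explant design, the ordering inferred from a
control channel (e.g. a known clock gene) is transferred by sample id to the
partner channel, and the phase lag between the channels' caudal mean series
is estimated by circular cross-correlation.

## Worked example

Generate a paired synthetic cohort (30 samples, traveling cosine wave on a
rostro-caudal gradient, noise SD 0.1, partner channel lagging by 0.2
cycles), order the control channel blindly, and read off the partner lag:

```python
import numpy as np
from clockorder import (TimeOrderingModel, WaveParams, generate_paired_set,
                        ordering_distance)

control, partner, truth = generate_paired_set(
    30, 80, WaveParams(noise_sd=0.1), partner_lag=0.2, rng_seed=42)

res = TimeOrderingModel(control).fit(rng_seed=42)
print(res.summary())

lag = res.partner_phase_lag(partner)
print(f"partner lag: {lag:+.3f} cycles ({lag * 120:+.0f} min)")

true_perm = np.argsort([t.phase for t in truth])
print(f"distance to ground truth: {ordering_distance(res.permutation, true_perm):.4f}")
```

Output:

```
Blind time-ordering results
===========================
samples (N):          30
axial positions (M):  80
ordering error g:     0.480195
clock period:         120 min
annealer:             5 restarts x 500 sweeps, cooling 0.95
rng seed:             42
ordered sample ids:   s028 s025 s015 s021 s010 s001 s014 s009 s026 s016 ...

partner lag: +0.200 cycles (+24 min)
distance to ground truth: 0.0018
```

`g = 0.48` is the residual periodicity mismatch of the best ordering (0
would mean every column is a perfect one-cycle cosine; noise and the uneven
random phase spacing keep it positive). The inferred order is essentially
the true phase order (distance 0.002 on a 0–1 scale, where random orders
score > 0.5), and the blindly transferred partner channel peaks 0.2 cycles —
24 minutes — after the control, exactly the lag that was simulated.
`res.kymograph(smooth=(3, 3), n_cycles=2)` and `res.plot_kymograph()` give
the space-time matrix and its heatmap; `res.caudal_series()` the caudal
oscillation trace.

The same pipeline is available from the shell:

```
clockorder simulate --n-samples 30 --noise-sd 0.1 --partner-lag 0.2 --seed 42
clockorder order profiles.csv --seed 42
clockorder kymo profiles.csv ordering.csv --partner partner_profiles.csv
clockorder run --config config.yaml        # simulate → order → kymo, one seed
```

Real images enter through `clockorder quantify` (grayscale TIFFs + an ROI
table with the caudal origin and somite-unit length per image), which writes
the same long-form profile CSV (`sample_id, position, intensity`).

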