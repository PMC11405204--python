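# Methods

## The generative well model

Spike trains are drawn from a discretized conditionally-Bernoulli
network process at Δt = 1 ms. Electrode *i* fires at step *t* with
probability

    p_i(t) = clip( r_i Δt · g(t) + Σ_j W[j,i] · 1[j fired at t−1] ,  1 − 10⁻⁶ )

where *r_i* is the baseline rate (Hz), W[j,i] ≥ 0 is directed
excitation from *j* onto *i*, and g(t) is `burst_gain` while a
well-global two-state Markov process is ON (entry rate `burst_rate`
per minute; mean ON duration `burst_duration` seconds) and 1 otherwise.
Clipped probabilities are counted and logged. This is deliberately not
a biophysical model: it is the simplest process with Poisson-like
baseline counts, graded pairwise correlation, and population bursts —
the three features the downstream analysis consumes.

The implementation is event-driven but draws from exactly this law:
baseline fires are sampled per burst-state segment from the binomial
count (positions uniform without replacement — the conditional law of a
Bernoulli process given its count), and coupling-induced fires are
drawn only at steps following actual activity, with probability
c′ = (p − p_b)/(1 − p_b) so that the union with the baseline event has
probability exactly p. A brute-force per-step reference simulator in
the test suite checks rates and induced correlations distributionally.

**Stability.** The network branching ratio — the mean outgoing coupling
weight per electrode — must stay below 1, or recurrent excitation goes
supercritical and firing saturates at the clip. Symmetric coupling
counts twice. `random_coupling` therefore couples one random direction
per pair by default.

### Treatment scenario

`default_treatment_scenario` defines the multi-well study conditions:

| parameter | default | why |
|---|---|---|
| electrodes / duration | 64 (8×8), 300 s | the targeted recording format (5-min sessions) |
| baseline rate | 2 Hz | typical mature-culture multi-unit rate |
| background coupling | 5% of pairs, one direction, w = 0.1 | weak, clearly subcritical connectivity |
| strengthenable subset | 15 reciprocal pairs, w = 0.2 | see below |
| rate multipliers | 1.0 / 1.9 / 2.5 (Days 0/1/2) | plausible chemoconvulsant MFR ratios |
| coupling boost | ×3 on the designated subset, Days ≥ 1 | produces a separated strong-edge tail |
| bursts | 4/min, 0.5 s, gain 5 | free parameters; no published statistics exist for these cultures |

Two couplings regimes are needed because the strong-edge endpoint
thresholds Fisher z at 0.80 (ρ ≈ 0.66). A directed edge can barely
reach that value before the boost pushes the whole network
supercritical; a *reciprocal* pair, however, reverberates (a spike
ping-pongs with survival w² per ms), producing within-bin co-fluctuation
with z well above 1 while each electrode's total in-weight stays below
1. Boosting only a designated subset — the `boosted_edges` field of the
design — matches the intended phenomenology: a small number of
preferentially strengthened connections riding on a weak background,
which is also what makes the day-2 FC distribution bimodal. Control
wells redraw from unchanged parameters every day; child seeds derive
from `SeedSequence(seed, spawn_key=(well, day))`, so adding wells or
days never perturbs existing draws.

## Voltage conditioning

Downsampling 12.5 → 2.5 kHz applies an 8th-order Butterworth anti-alias
low-pass at 0.4·target before integer decimation. The MUA band-pass is
an order-20 Butterworth (0.1–300 Hz) and the notches are order-4
Butterworth band-stops with ±1 Hz stop edges at 60/120/180 Hz — all
realized as second-order sections; a direct-form order-20 band-pass is
numerically explosive and is never constructed. z-scoring uses the
population SD (÷N); constant channels map to zeros with a logged
warning.

Filtering is **causal by default** with a `zero_phase` option
(forward–backward). Two numerical notes:

- Zero-phase filtering uses even padding. The default odd reflection
  can excite the 0.1 Hz high-pass corner and inject multi-second
  ringing whose amplitude depends on the channel's endpoints —
  intermittent heavy-tailed artifacts that produce spurious threshold
  crossings.
- Spike-timing work must use `zero_phase=True`: the causal order-20
  band-pass disperses a ~2 ms waveform so strongly that threshold
  detection fails outright, while the zero-phase version keeps the
  peak intact and unshifted. The round-trip validation therefore runs
  zero-phase, with a 3-ms dead time covering the band-passed waveform's
  support.

Spike detection thresholds at k = 5.5 robust noise SDs
(median(|x|)/0.6745, so detection is invariant to rescaling), both
polarities, merging events within the dead time to the larger absolute
peak. k and the dead time are conventions, not published values.

## Functional connectivity

Counts are binned into half-open 50-ms windows (a spike exactly on an
edge belongs to the later bin; a trailing partial bin is dropped).
Pearson correlation is computed per unordered pair over the
concatenated non-burst bins of the recording; ρ is clipped to
±(1 − 10⁻⁷) before atanh so identical trains stay finite
(z = 8.4056…). Pairs where either electrode has zero variance over the
used bins are *invalid* — excluded from summaries, never zero-filled,
and dropped from every row of a well's feature matrix if invalid on any
day. Pairs are unordered (k = n(n−1)/2); an ordered-pair duplication
switch exists on `FCMatrix.pair_vector` for replication attempts
against analyses that counted n² entries.

Population bursts are detected directly in bin space (population count
above mean + 3 SD *and* ≥ 25% of electrodes active), merged into
intervals. `burst_bias_check` recomputes the mean pairwise z with and
without the flagged bins: a shared multiplicative rate gain biases
count correlations upward, and the generator reproduces that direction
(gain 5: z_with ≈ 0.053 vs z_without ≈ 0.011 under the default bursty
conditions; gain 1: no detectable difference).

## Trajectory embedding

Columns of A are mean-centered only — features share Fisher-z units,
and unit-variance scaling would amplify near-constant pairs.
Decomposition is an economy SVD of the centered matrix (equivalent to
row-space PCA for m ≪ k), with a deterministic sign convention (the
largest-magnitude loading of each component is positive). Explained
variance is s²ᵢ/Σs². Distances to Day 0 are reported both in 2-PC
space and in the full feature space; for m = 3 the two coincide to
machine precision (three centered points have rank ≤ 2), which the test
suite asserts on random matrices — this is the structural fact that
makes the two-dimensional trajectory plots distance-faithful. Wells are
embedded separately: a pair feature is only comparable with itself
across days within one well.

## icEEG phase locking

Per-epoch chain: running-mean detrend (1-s window, shrinking at the
edges) → least-squares sin/cos regression at 60 and 120 Hz (exact for a
pure mains tone, near-orthogonal to off-target content over whole
epochs) → order-180 type-1 equiripple low-pass (cutoff 150 Hz, chosen
between the 90 Hz band edge and the 180 Hz harmonic; configurable) →
order-390 equiripple band-pass, 70–90 Hz, 8 Hz transitions. Filters are
applied causally; the group delay is common to both contacts of a pair
and cancels in the phase difference. PLV uses the analytic-signal
phase; it is computed per epoch and averaged within a contact pair.
Patients' SOZ–SP and SOZ–control class means enter a paired t-test.

The synthetic cohort couples SP contacts to the SOZ carrier with von
Mises concentration κ_SP = 2 (population PLV 0.70) and control contacts
with κ_ctrl = 0.5 (0.24), plus wideband noise, a mains tone and slow
drift for the preprocessing to remove. The phase-offset process maps a
unit-variance AR(1) Gaussian (correlation time 2 carrier cycles)
through Φ and the von Mises quantile, so the stationary marginal is
exactly von Mises while the offset stays slow enough for the Hilbert
phase to track; measured PLV matches I₁(κ)/I₀(κ) within Monte Carlo
error for κ ∈ [0.5, 4].

**Null PLV floor.** For two independent signals band-limited to B Hz
observed for T seconds, the PLV estimator is Rayleigh-distributed with
roughly N_eff ≈ B·T independent phasors: E[PLV] ≈ √π/(2√N_eff) and
P(PLV > x) = exp(−x²N_eff). With 10⁴ samples in the 70–90 Hz band the
longest Nyquist-feasible epoch (fs = 200 Hz, T = 50 s) gives
N_eff ≈ 1100, so E[PLV] ≈ 0.027 and roughly 6–8% of independent epochs
still exceed 0.05. A PLV near 0.05 on a single 50-s epoch is therefore
*not* evidence of coupling; thresholds for real data should be derived
from this floor (or surrogate epochs), not from a fixed constant.

## Statistics

Two-sample comparisons default to the pooled-variance Student t
(Welch optional), two-tailed, with the 95% CI of the mean difference
and Cohen's d on the pooled SD; paired comparisons use the one-sample t
on differences (df = n − 1, d_z effect size). Normality is gated by the
D'Agostino–Pearson omnibus K² (rejected below n = 8). Families of
comparisons use Holm's step-down correction (uniformly at least as
powerful as Bonferroni; property-tested). Degenerate inputs
(zero-variance groups, constant differences) return flagged results —
t = 0/p = 1 for no difference, flagged ±∞ otherwise — rather than NaNs.

## What the synthetic data does and does not show

The generator reproduces the *statistical structure* the pipeline
relies on: Poisson-like baseline counts, correlation graded by
excitation strength, well-global bursts that inflate included-bin
correlations, treatment effects expressed as rate multipliers and
strengthened couplings, and phase coupling with a known closed-form
PLV. It does not emulate biophysics (synaptic dynamics, refractoriness,
glial modulation, electrode drift, 1/f noise) or dose–response
behavior, and its burst statistics are free parameters. Passing tests
therefore demonstrate that the *analysis* recovers known ground truth
of this structure at realistic sizes — not that any biological claim
holds, and not that effect magnitudes match a particular wet-lab
system.

## Problem sizes and numerical choices

Replicate-based validations run at the full recording format
(64 electrodes, 300 s, 9 treated vs 9 control wells, 20 replicates);
the zero-effect type-I calibration runs 100 replicates at 16
electrodes/60 s, since a t-test's type-I rate does not depend on well
size and the full-size null adds nothing but runtime. The AUROC
benchmark uses the 64-electrode/300-s condition with 5% of pairs
coupled at w = 0.3. Determinism: every stochastic routine takes a seed;
experiment-level seeds spawn per-well/per-day children via
`SeedSequence` spawn keys; simulator draws happen inside a seeded numba
kernel, so identical configurations are bit-identical across runs.
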