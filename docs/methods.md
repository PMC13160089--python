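# Methods

## Loop-extrusion model

Chromatin is a 1D lattice of 250 bp sites; the default geometry is 25
replicas of 4000 sites (25 Mb total). Replicas are concatenated into a single
lattice with the barrier layout tiled identically, and extruders roam the
whole lattice — this keeps at least one extruder present even at a 10-fold
depletion, where a single 1 Mb replica would often be empty. Lattice ends are
reflecting: a leg at an end simply stops.

Each cohesin is a loop-extruding factor (LEF) with two legs. The number of
LEFs is `max(1, round(total_bp / lef_separation_bp))`; the baseline
separation of 250 kb corresponds to 4 loaded cohesins per Mb (100 on 25 Mb).
Cohesin abundance is varied through the separation: an abundance ratio *r*
divides the separation by *r*.

Each step (default duration 1 s) applies, in order:

1. **Barrier update.** Each CTCF site flips bound→unbound with probability
   1 − exp(−dt/bound_time) and unbound→bound with 1 − exp(−dt/unbound_time).
   Initial states are drawn from the stationary occupancy.
2. **Unloading.** A loaded LEF unloads with probability
   1 − exp(−dt/lifetime); `lef_stalled_lifetime` is used when either leg is
   currently stalled. Both default to 1300 s.
3. **Loading.** Each unloaded LEF loads with probability `lef_birth_rate`
   (default 0.1 per step) at a uniformly random adjacent free site pair; a
   blocked attempt is retried on a later step, so the extruder pool
   (loaded + unloaded) is conserved.
4. **Translocation.** In extruder index order, each leg moves one site
   outward unless paused (`lef_pause_rate`, default 0), blocked by a
   *currently bound* barrier at the target site (respecting barrier
   orientation; bidirectional by default), blocked by another leg, or at a
   lattice end. A leg blocked by barrier, leg or end is marked stalled;
   stall flags clear when the leg moves again.

This sub-step ordering and the interpretation of the birth rate as
per-step are choices of this implementation; with the default parameters
(where plain and stalled lifetimes coincide and the pause rate is zero) the
observables are insensitive to the distinction.

Trajectories run 4000 steps; the first 25% are discarded as burn-in so loop
sizes equilibrate, and every subsequent step is recorded (a snapshot stride
is available for speed). Recorded leg positions accumulate into a per-site
histogram, the in-silico ChIP profile. Simulated FRiP is the fraction of
recorded legs within ±`window` sites of a barrier (default window 1, i.e.
the barrier site plus both flanking sites); overlapping windows are unioned.
The window coverage of the lattice plays the role of the peak genome
fraction ρ when background-adjusting simulated scans.

The simulation kernel is compiled with numba and seeded per run; scans
derive child seeds from `numpy.random.SeedSequence([seed, ratio_index])`, so
scan tables are bit-reproducible. A pure-Python twin of the kernel walks the
identical RNG stream and is compared bitwise in the tests.

## CTCF barriers

A barrier site alternates between bound (blocking) and unbound (permissive)
states; its occupancy is bound_time/(bound_time+unbound_time). Two
parameterization modes are provided:

- **Homogeneous**: all sites at occupancy 0.625 with bound time 780 s and
  unbound time 468 s, placed until the summed occupancy reaches the target
  of 13 per Mb (21 sites/Mb). This parameter block is the default and is
  what the abundance scans and the acceptance script use.
- **Heterogeneous**: occupancies drawn with replacement from a user-supplied
  pool until the 13/Mb target is reached, anchored so that occupancy 0.65
  maps to a 9.87 min bound time. The mapping from occupancy to dwell times
  holds the unbound time fixed at the anchor's value
  (u\* = 9.87 min × 0.35/0.65) and scales the bound time as
  u\*·p/(1−p) — this preserves the site's rebinding rate while matching the
  occupancy exactly. Alternatives (fixed cycle time) would be equally
  consistent with an occupancy target; fixed unbound time was chosen because
  CTCF's search/rebinding kinetics should not depend on how strongly a
  site retains it.

The 13/Mb target derives from ~217,200 CTCF molecules per cell, ~49% bound,
over an effective genome of 3 × 2.7 Gb (average copy number 3 during the
cell cycle). `fripkit.synth.default_occupancy_pool` supplies a synthetic
heterogeneous pool — Beta(1.4, 2.6) draws, mean ≈ 0.35 — sized so that ~38
sites accumulate the 13/Mb target, matching the scale of single-molecule
footprinting measurements in mES cells; it is a stand-in, not measured data.

Barrier positions are uniform without a minimum spacing; occupancy
rescaling (for CTCF-abundance scans) caps occupancies at 1 − 10⁻⁶ so dwell
times stay finite.

## Antibody background model

Antibody A binds chromatin-bound target C (dissociation constant Kd_s) and
background proteins B (Kd_n). With the reference composition — 25 μg DNA and
5 μg IgG (150 kg/mol) in 500 μL — the antibody concentration is
6.67 × 10⁻⁸ M while loaded cohesin, converted through the count-to-molarity
constant σ = (Mb equivalents)/(N_A · volume), is ~3 × 10⁻¹⁰ M: the antibody
is in ~300-fold excess, so [A] ≈ A_total and the background-bound antibody
[AB] = A·B_total/(Kd_n + A) is independent of target abundance. Total
background reads θ are therefore constant. Both the closed-form
antibody-excess solution and an exact solver (Brent root-finding on the
antibody conservation relation, residuals < 10⁻¹⁰ relative) are provided;
they agree to 0.5% in the reference regime.

Consequences, all in read-fraction space (the proportionality constant
between concentration·volume and calibrated reads cancels):

- background fraction at baseline f₀ fixes θ = f₀/(1−f₀)·AC;
- depleting the target to γ of baseline rescales the fraction to
  f(γ) = f₀/(γ(1−f₀)+f₀) — strictly decreasing in γ, →1 as γ→0;
- observed FRiP = (1−f)·FRiP_true + f·ρ for uniform background;
- a proximal-crosslinking background instead scales *with* the target, so
  f is γ-invariant and cannot invert an abundance trend.

The inversion threshold reported by `monotonic_inversion_threshold` is the
smallest baseline fraction on a grid (default step 0.05) for which the
background-adjusted simulated FRiP is nondecreasing across the scanned
abundance ratios. A grid rather than bisection is used because the
underlying scan is stochastic; with 20+ seeds per ratio the estimate is
stable to within one grid step.

## Spike-in estimation and denoising

Given spike-in calibrated totals R_UT (unperturbed) and R_dep (depleted) and
the leftover fraction γ (an input — it must come from an orthogonal
measurement such as quantitative western or imaging; the package does not
infer it), the unperturbed background fraction is
f_UT = (R_dep/R_UT − γ)/(1−γ). The naive ratio R_dep/R_UT equals f_UT only
at γ = 0 and otherwise overestimates it. Inputs with R_dep/R_UT < γ violate
the constant-background model and raise an error rather than returning a
negative fraction. Denoised FRiP values outside [0,1] are returned with a
warning, not clipped: they diagnose an inconsistent f or ρ.

## Interval FRiP

Intervals are 0-based half-open (BED). Peaks are flattened to their coverage
union (book-ended intervals merge); a read is in-peak when it shares ≥1 bp
with the union — the common FRiP convention. The overlap test uses a
binary search against the merged, sorted peak arrays per chromosome and is
checked exactly against a quadratic brute-force oracle in the tests.
Exclusion regions (blacklist-style) remove reads from numerator and
denominator before counting. ρ is flattened peak bp over total genome bp.
Reads are intervals; converting alignments to intervals (fragment span for
paired-end, read span for single-end) is left to upstream tooling.

## Synthetic data generator

`gen_reads` draws each read as background with probability f (start uniform
over the genome) or signal otherwise (inside a uniformly chosen peak with
probability q, uniformly outside peaks with 1−q). Expected FRiP is
(1−f)·q + f·ρ up to an edge effect of order read_length/chrom_length
(a background read *overlapping* a peak is slightly more likely than a
uniform point falling inside it). Defaults used in the tests — 3 Mb genome,
80 peaks × 300 bp (ρ = 0.008, the scale of real CTCF peak sets vs. a
mammalian genome), 10⁵ reads of 50 bp — keep that edge term an order of
magnitude below the binomial sampling error. The generator deliberately
omits fragment-length variation, GC/mappability bias and hotspot-structured
background, so passing tests demonstrate correctness of the estimators under
their stated assumptions, not robustness to those real-data violations.
`gen_spikein_pair` produces noiseless or Poisson-noised count pairs from
(f, γ); `profile_to_reads` bridges simulation profiles to interval FRiP by
sampling read positions proportional to leg counts.

## Problem sizes and numerical choices

The stochastic trend tests and the acceptance script use the full baseline
lattice (25 Mb, 4000 steps) with 20 seeds per abundance ratio in the test
suite and 100 in the acceptance script; the compiled kernel makes a full
six-ratio scan a matter of seconds. Monotonicity checks on adjusted curves
use a −10⁻¹² slack so only genuine decreases count. Degenerate inputs are
errors, not silent results: empty profiles, zero retained reads, γ = 0 in
the uniform rescaling (available only through an explicit limit flag),
occupancy 1 in the dwell-time mapping.

## Known limitations

- 1D lattice only: no 3D polymer mechanics, Hi-C contact maps, or
  cofactor-specific extrusion rules.
- The biochemical model assumes equilibrium binding, antibody excess,
  background weaker than signal, and spatially uniform background targets.
- Background estimation assumes total accessible epitopes are comparable
  across samples before depletion; recovery differences between experiments
  are not corrected.
- γ must be measured externally; errors in γ propagate directly into f_UT.
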