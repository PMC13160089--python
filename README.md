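# fripkit

Loop-extrusion simulation and background-aware FRiP quantification for
cohesin ChIP-seq.

In mammalian interphase, loop-extruding cohesin complexes are positioned by
CTCF barriers, producing enrichment of cohesin ChIP-seq reads at CTCF peaks.
The fraction of cohesin reads in CTCF peaks (FRiP) is a natural quantitative
readout of that positioning — but it is confounded by non-specific antibody
background, which can even invert the apparent relationship between cohesin
abundance and FRiP. `fripkit` provides the pieces needed to reason about and
correct for this:

- **`fripkit.extrusion`** — a stochastic 1D lattice simulation of cohesin
  extruders (two "legs" per complex) blocked by dynamic CTCF barriers, giving
  in-silico ChIP profiles and simulated FRiP as a function of cohesin or CTCF
  abundance.
- **`fripkit.barrier_kinetics`** — CTCF barrier sets: occupancy p =
  b/(b+u) of bound/unbound dwell times, heterogeneous occupancy sampling to a
  per-Mb target, abundance rescaling.
- **`fripkit.biochem`** — an equilibrium model of antibody-derived
  background. Because the antibody is in vast excess over its chromatin-bound
  target, total background reads θ are constant, and depleting the target to a
  fraction γ of baseline rescales the background fraction as
  f(γ) = f₀ / (γ(1−f₀) + f₀). Observed FRiP mixes signal and uniform
  background: FRiP_obs = (1−f)·FRiP_true + f·ρ, with ρ the genome fraction in
  peaks.
- **`fripkit.spikein`** — background estimation from paired spike-in
  ChIP-seq before/after depletion, f_UT = (R_dep/R_UT − γ)/(1 − γ), and FRiP
  denoising FRiP_true = (FRiP_obs − f·ρ)/(1 − f).
- **`fripkit.intervals`** — interval FRiP from BED reads/peaks (0-based,
  half-open, ≥1 bp overlap), ρ from peaks + chromosome sizes, FRiP ratios.
- **`fripkit.synth`** — synthetic genomes, peaks, read mixtures and spike-in
  pairs with known ground truth, so everything above is testable end to end
  without downloads.

## Worked example

Simulate FRiP across cohesin abundance (baseline: 25 Mb lattice at 250 bp
resolution, 100 extruders, CTCF barriers at 13 per Mb total occupancy with
bound/unbound dwell times 780 s / 468 s), then ask what antibody background
does to the trend:

```python
import numpy as np
from fripkit import uniform_barrier_set
from fripkit.extrusion import SimParams, scan_cohesin_abundance, barrier_window_coverage
from fripkit.biochem import background_adjusted_scan, monotonic_inversion_threshold

barriers = uniform_barrier_set(0.625, 13.0, seed=1, bound_time=780.0)
params = SimParams()
scan = scan_cohesin_abundance([0.1, 0.25, 0.5, 1, 1.5, 2], params, barriers,
                              seeds=range(20))
print(scan.to_string(index=False))
```

```
 ratio  frip_mean  frip_sd  n_seeds
  0.10   0.625976 0.036089       20
  0.25   0.621668 0.026220       20
  0.50   0.587162 0.019223       20
  1.00   0.552052 0.020594       20
  1.50   0.523106 0.016918       20
  2.00   0.487678 0.016717       20
```

Without background, FRiP *falls* as cohesin abundance rises: more extruders
mean more cohesin–cohesin collisions, so fewer legs reach a barrier. Now add
a uniform antibody background of 35% at baseline (ρ is the lattice fraction
inside barrier windows):

```python
rho = barrier_window_coverage(barriers, window=1)          # 0.01575
adjusted = background_adjusted_scan(scan, f_base=0.35, rho=rho)
thr = monotonic_inversion_threshold(scan, rho, np.arange(0, 1, 0.05))
```

The adjusted FRiP column now *rises* from 0.11 (ratio 0.1) to ≈0.39
(ratio 2): depletion concentrates background, masking the collision effect.
`thr` reports the smallest baseline background fraction on a 0.05 grid that
makes the adjusted curve monotonically nondecreasing (≈0.3–0.4 depending on
simulation seeds).

Correcting experimental data goes the other way — estimate the background
from a spike-in depletion pair, then denoise:

```console
$ fripkit estimate-bg --r-ut 100 --r-dep 30 --gamma 0.1
f_UT	0.222222
f_dep	0.740741
$ fripkit denoise --frip 0.3032 --f 0.4 --rho 0.008
frip_denoised	0.5
```

With 10% of cohesin left after depletion, the naive ratio 30/100 = 0.30
would overestimate the true background fraction 0.22. The same commands
accept batch TSVs; `fripkit frip` computes interval FRiP from BED files, and
`fripkit simulate` / `scan-cohesin` / `scan-ctcf` / `adjust` / `threshold` /
`synth` drive the simulator and generators. Every file-writing command drops
a `config.resolved.yaml` beside its outputs so runs are exactly repeatable.

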