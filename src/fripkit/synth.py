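"""Synthetic genomes, peaks, reads and spike-in pairs with known ground truth.

The read generator embodies the uniform-background mixture that the
denoising model assumes: each read is background with probability ``f``
(start uniform over the genome) or signal with probability ``1 - f``
(landing inside a random peak with probability ``q``, elsewhere outside
peaks). Its expected FRiP is therefore ``(1 - f) * q + f * rho`` up to edge
effects of order read_length/chrom_length, which makes every estimator in
the package testable end to end with no external data.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .extrusion import OccupancyProfile
from .spikein import SpikeInPair

__all__ = [
    "ReadGenSpec",
    "gen_genome",
    "gen_peaks",
    "gen_reads",
    "gen_spikein_pair",
    "profile_to_reads",
    "default_occupancy_pool",
]


@dataclass(frozen=True)
class ReadGenSpec:
    """Parameters of the signal/background read mixture."""

    n_reads: int
    read_length: int = 50
    in_peak_prob_signal: float = 1.0  # q
    background_fraction: float = 0.0  # f
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0 or self.read_length <= 0:
            raise ValueError("n_reads and read_length must be positive")
        for name in ("in_peak_prob_signal", "background_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def gen_genome(n_chroms: int, chrom_length: int, seed: int = 0) -> dict[str, int]:
    """Toy genome: ``n_chroms`` chromosomes of equal ``chrom_length``."""
    if n_chroms <= 0 or chrom_length <= 0:
        raise ValueError("n_chroms and chrom_length must be positive")
    return {f"chr{i + 1}": int(chrom_length) for i in range(n_chroms)}


def gen_peaks(
    genome: dict[str, int], n_peaks: int, peak_width: int, seed: int = 0
) -> pd.DataFrame:
    """Non-overlapping fixed-width peaks placed uniformly at random.

    Peak counts are apportioned to chromosomes by length (largest remainder)
    and placed without overlap, so rho == n_peaks*peak_width/genome_bp
    exactly.
    """
    if n_peaks < 0 or peak_width <= 0:
        raise ValueError("n_peaks must be >= 0 and peak_width positive")
    if n_peaks == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    genome_bp = sum(genome.values())
    if n_peaks * peak_width > genome_bp:
        raise ValueError("peaks cannot be packed into the genome")
    rng = np.random.default_rng(seed)

    chroms = list(genome)
    quotas = np.array([genome[c] for c in chroms], dtype=float)
    quotas = quotas / quotas.sum() * n_peaks
    counts = np.floor(quotas).astype(int)
    rem = n_peaks - counts.sum()
    order = np.argsort(-(quotas - np.floor(quotas)))
    for i in range(rem):
        counts[order[i % len(chroms)]] += 1

    rows = []
    for chrom, k in zip(chroms, counts):
        if k == 0:
            continue
        L = genome[chrom]
        if k * peak_width > L:
            raise ValueError(f"cannot pack {k} peaks of {peak_width} bp on {chrom}")
        # sorted anchors in the 'compressed' coordinate, then re-expand
        anchors = np.sort(rng.integers(0, L - k * peak_width + 1, size=k))
        starts = anchors + np.arange(k) * peak_width
        for s in starts:
            rows.append((chrom, int(s), int(s + peak_width)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _uniform_read_starts(rng, genome, read_length, n):
    """Chromosome chosen by length, start uniform on [0, L - read_length]."""
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    which = rng.choice(len(chroms), size=n, p=lengths / lengths.sum())
    starts = np.empty(n, dtype=np.int64)
    for i, w in enumerate(which):
        L = genome[chroms[w]]
        if read_length > L:
            raise ValueError("read_length exceeds chromosome length")
        starts[i] = rng.integers(0, L - read_length + 1)
    return [chroms[w] for w in which], starts


def gen_reads(
    genome: dict[str, int], peaks: pd.DataFrame, spec: ReadGenSpec
) -> pd.DataFrame:
    """Sample reads from the signal/background mixture (see module docs).

    In-peak signal reads are placed fully inside a uniformly chosen peak
    (requires peak width >= read length); off-peak signal reads are rejection
    sampled to avoid any peak overlap; background reads are uniform over the
    genome regardless of peaks.
    """
    from .intervals import overlaps_any  # local import to avoid cycle

    rng = np.random.default_rng(spec.seed)
    rl = spec.read_length
    n = spec.n_reads
    have_peaks = len(peaks) > 0
    if have_peaks:
        widths = (peaks["end"] - peaks["start"]).to_numpy()
        if spec.in_peak_prob_signal > 0 and (widths < rl).any():
            raise ValueError("peak width must be >= read_length for in-peak reads")

    is_bg = rng.random(n) < spec.background_fraction
    in_peak = (~is_bg) & (rng.random(n) < spec.in_peak_prob_signal) & have_peaks

    chrom_out: list[str] = [""] * n
    start_out = np.zeros(n, dtype=np.int64)

    # background: uniform over the genome
    bg_idx = np.flatnonzero(is_bg)
    if bg_idx.size:
        chroms, starts = _uniform_read_starts(rng, genome, rl, bg_idx.size)
        for j, i in enumerate(bg_idx):
            chrom_out[i] = chroms[j]
            start_out[i] = starts[j]

    # signal inside a random peak
    pk_idx = np.flatnonzero(in_peak)
    if pk_idx.size:
        which = rng.integers(0, len(peaks), size=pk_idx.size)
        p_start = peaks["start"].to_numpy()[which]
        p_end = peaks["end"].to_numpy()[which]
        offs = rng.integers(0, p_end - p_start - rl + 1)
        p_chroms = peaks["chrom"].to_numpy()[which]
        for j, i in enumerate(pk_idx):
            chrom_out[i] = p_chroms[j]
            start_out[i] = p_start[j] + offs[j]

    # signal outside peaks: rejection sample against peak overlap
    out_idx = np.flatnonzero(~is_bg & ~in_peak)
    if out_idx.size:
        remaining = list(out_idx)
        while remaining:
            chroms, starts = _uniform_read_starts(rng, genome, rl, len(remaining))
            cand = pd.DataFrame(
                {"chrom": chroms, "start": starts, "end": starts + rl}
            )
            bad = (
                overlaps_any(cand, peaks) if have_peaks
                else np.zeros(len(cand), dtype=bool)
            )
            still = []
            for j, i in enumerate(remaining):
                if bad[j]:
                    still.append(i)
                else:
                    chrom_out[i] = chroms[j]
                    start_out[i] = starts[j]
            remaining = still

    return pd.DataFrame(
        {"chrom": chrom_out, "start": start_out, "end": start_out + rl}
    )


def gen_spikein_pair(
    R_UT_depth: float,
    true_f: float,
    gamma: float,
    noise: str = "none",
    seed: int = 0,
) -> SpikeInPair:
    """Calibrated read pair with known background fraction and depletion.

    Noiseless: ``R_dep = R_UT * (f + gamma*(1 - f))`` exactly, so the
    estimator recovers ``f`` to machine precision. With ``noise='poisson'``
    both counts are Poisson-sampled around their expectations.
    """
    if R_UT_depth <= 0:
        raise ValueError("R_UT_depth must be positive")
    if not 0.0 <= true_f < 1.0 or not 0.0 <= gamma < 1.0:
        raise ValueError("true_f and gamma must be in [0, 1)")
    r_dep_expect = R_UT_depth * (true_f + gamma * (1.0 - true_f))
    if noise == "none":
        return SpikeInPair(float(R_UT_depth), float(r_dep_expect), gamma)
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        r_ut = float(max(1, rng.poisson(R_UT_depth)))
        r_dep = float(rng.poisson(r_dep_expect))
        return SpikeInPair(r_ut, r_dep, gamma)
    raise ValueError(f"unknown noise model {noise!r}")


def profile_to_reads(
    profile: OccupancyProfile,
    bp_per_site: int = 250,
    n_reads: int = 100_000,
    read_length: int = 50,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Sample reads from an in-silico ChIP profile onto a toy genome.

    Read starts land on lattice sites with probability proportional to the
    profile's leg counts, fully inside the chosen site (requires
    read_length <= bp_per_site), so interval FRiP over barrier-window
    intervals converges to the simulated FRiP as n_reads grows. Returns
    (reads, genome).
    """
    counts = profile.leg_counts.astype(float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty profile")
    if read_length > bp_per_site:
        raise ValueError("read_length must be <= bp_per_site")
    rng = np.random.default_rng(seed)
    sites = rng.choice(profile.n_sites, size=n_reads, p=counts / total)
    offs = rng.integers(0, bp_per_site - read_length + 1, size=n_reads)
    starts = sites.astype(np.int64) * bp_per_site + offs
    genome = {"sim": profile.n_sites * bp_per_site}
    reads = pd.DataFrame(
        {"chrom": "sim", "start": starts, "end": starts + read_length}
    )
    return reads, genome


def default_occupancy_pool(n: int = 100, seed: int = 0) -> np.ndarray:
    """Synthetic stand-in for measured per-site CTCF occupancies.

    Beta(1.4, 2.6) draws (mean ~0.35) clipped to [0.02, 0.98]: heterogeneous,
    mostly sub-half occupancies so that ~38 sites accumulate a total
    occupancy of 13 per Mb, matching the scale of single-molecule footprint
    measurements in mES cells.
    """
    rng = np.random.default_rng(seed)
    pool = rng.beta(1.4, 2.6, size=n)
    return np.clip(pool, 0.02, 0.98)
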