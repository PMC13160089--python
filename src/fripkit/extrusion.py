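"""Stochastic 1D loop-extrusion simulation with dynamic CTCF barriers.

Cohesin is modeled as a loop-extruding factor (LEF) with two legs on a
lattice of 250 bp sites. Legs translocate outward one site per step unless
blocked by a currently bound CTCF barrier, another leg, or a lattice end.
Barriers stochastically bind/unbind with exponential dwell times; extruders
unload with an exponential lifetime (a distinct lifetime applies while
stalled) and reload at a random free site pair. The lattice concatenates
``n_replicas`` identical 1 Mb replicas (barrier layout tiled) so at least one
extruder remains even at strong depletion.

Aggregating leg positions over post-burn-in snapshots yields an in-silico
ChIP profile; the fraction of legs within +/- ``window`` sites of a barrier is
the simulated FRiP.

Per-step kernel order: (1) barrier state update, (2) extruder unloading,
(3) loading of unloaded extruders at rate ``lef_birth_rate`` per step,
(4) leg translocation in extruder index order. Step duration is 1 s by
default so lifetimes in seconds and step counts are commensurate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numba
import numpy as np
import pandas as pd

from .barrier_kinetics import BarrierSet, scale_barrier_occupancy

__all__ = [
    "SimParams",
    "OccupancyProfile",
    "n_lefs_from_separation",
    "simulate",
    "simulated_frip",
    "barrier_window_mask",
    "barrier_window_coverage",
    "barrier_window_intervals",
    "scan_cohesin_abundance",
    "scan_ctcf_abundance",
    "profile_to_tsv",
    "profile_from_tsv",
]


@dataclass(frozen=True)
class SimParams:
    """Kinetic and lattice parameters for one simulation.

    Defaults are the baseline block: 25 replicas of 4000 sites at 250 bp
    (25 Mb), LEF separation 250 kb (100 extruders), LEF lifetime 1300 s,
    stalled lifetime 1300 s, birth rate 0.1 per step, pause rate 0,
    4000 one-second steps with the first 25% discarded, FRiP window 1.
    """

    sites_per_replica: int = 4000
    bp_per_site: int = 250
    n_replicas: int = 25
    lef_separation_bp: float = 250_000.0
    lef_lifetime: float = 1300.0  # s
    lef_stalled_lifetime: float = 1300.0  # s
    lef_birth_rate: float = 0.1  # per step
    lef_pause_rate: float = 0.0  # per step per leg
    step_duration: float = 1.0  # s
    n_steps: int = 4000
    burn_in_fraction: float = 0.25
    snapshot_stride: int = 1
    frip_window: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must be in [0, 1)")
        if self.frip_window < 0:
            raise ValueError("frip_window must be >= 0")
        if min(self.sites_per_replica, self.n_replicas, self.n_steps,
               self.snapshot_stride) <= 0:
            raise ValueError("lattice/step counts must be positive")
        if self.lef_separation_bp <= 0 or self.bp_per_site <= 0:
            raise ValueError("lengths must be positive")
        if not 0.0 <= self.lef_birth_rate <= 1.0:
            raise ValueError("lef_birth_rate is a per-step probability")
        if not 0.0 <= self.lef_pause_rate <= 1.0:
            raise ValueError("lef_pause_rate is a per-step probability")

    @property
    def n_sites(self) -> int:
        return self.sites_per_replica * self.n_replicas

    @property
    def total_bp(self) -> int:
        return self.n_sites * self.bp_per_site

    @property
    def n_lefs(self) -> int:
        return n_lefs_from_separation(self.total_bp, self.lef_separation_bp)


@dataclass(frozen=True)
class OccupancyProfile:
    """Accumulated leg counts per lattice site (the in-silico ChIP profile)."""

    leg_counts: np.ndarray  # int64, length n_sites
    n_snapshots: int
    n_lefs: int
    loaded_leg_records: int  # == leg_counts.sum(); 2 * loaded LEFs per snapshot

    @property
    def n_sites(self) -> int:
        return int(self.leg_counts.size)


def n_lefs_from_separation(total_bp: float, lef_separation_bp: float) -> int:
    """Extruder count from the mean genomic separation; floored at one so a
    single extruder survives even extreme depletion."""
    if total_bp <= 0 or lef_separation_bp <= 0:
        raise ValueError("lengths must be positive")
    return max(1, int(round(total_bp / lef_separation_bp)))


_ORIENT_CODE = {"bidirectional": 0, "left-blocking": 1, "right-blocking": 2}


def _step_prob(dwell_time: float, dt: float) -> float:
    """Per-step transition probability for an exponential dwell time."""
    if dwell_time <= 0:
        return 1.0
    return -np.expm1(-dt / dwell_time)


def _tiled_barrier_arrays(params: SimParams, barriers: BarrierSet):
    """Tile the single-replica barrier layout across the full lattice."""
    if barriers.sites_per_replica != params.sites_per_replica:
        raise ValueError("barrier set and params disagree on sites_per_replica")
    dt = params.step_duration
    n_b = len(barriers.sites)
    pos1 = np.array([s.position for s in barriers.sites], dtype=np.int64)
    p_unbind1 = np.array(
        [_step_prob(s.bound_time, dt) for s in barriers.sites], dtype=np.float64
    )
    p_bind1 = np.array(
        [_step_prob(s.unbound_time, dt) for s in barriers.sites], dtype=np.float64
    )
    occ1 = np.array([s.occupancy for s in barriers.sites], dtype=np.float64)
    orient1 = np.array(
        [_ORIENT_CODE[s.orientation] for s in barriers.sites], dtype=np.int64
    )
    reps = params.n_replicas
    offsets = np.repeat(
        np.arange(reps, dtype=np.int64) * params.sites_per_replica, n_b
    )
    return (
        np.tile(pos1, reps) + offsets,
        np.tile(p_unbind1, reps),
        np.tile(p_bind1, reps),
        np.tile(occ1, reps),
        np.tile(orient1, reps),
    )


@numba.njit(cache=False)
def _kernel(
    seed,
    n_steps,
    burn_in_steps,
    stride,
    n_sites,
    n_lefs,
    p_death,
    p_death_stalled,
    birth_rate,
    pause_rate,
    b_pos,
    b_p_unbind,
    b_p_bind,
    b_occ,
    b_orient,
):  # pragma: no cover - exercised via simulate()
    np.random.seed(seed)
    n_b = b_pos.size

    barrier_at = np.full(n_sites, -1, dtype=np.int64)
    for j in range(n_b):
        barrier_at[b_pos[j]] = j
    bound = np.empty(n_b, dtype=np.bool_)
    for j in range(n_b):
        bound[j] = np.random.random() < b_occ[j]

    left = np.zeros(n_lefs, dtype=np.int64)
    right = np.zeros(n_lefs, dtype=np.int64)
    loaded = np.zeros(n_lefs, dtype=np.bool_)
    stalled_l = np.zeros(n_lefs, dtype=np.bool_)
    stalled_r = np.zeros(n_lefs, dtype=np.bool_)
    occ = np.zeros(n_sites, dtype=np.bool_)

    leg_counts = np.zeros(n_sites, dtype=np.int64)
    n_snapshots = 0
    loaded_leg_records = 0

    for step in range(n_steps):
        # (1) barrier binding dynamics
        for j in range(n_b):
            if bound[j]:
                if np.random.random() < b_p_unbind[j]:
                    bound[j] = False
            else:
                if np.random.random() < b_p_bind[j]:
                    bound[j] = True

        # (2) unloading
        for i in range(n_lefs):
            if loaded[i]:
                p = p_death_stalled if (stalled_l[i] or stalled_r[i]) else p_death
                if np.random.random() < p:
                    occ[left[i]] = False
                    occ[right[i]] = False
                    loaded[i] = False
                    stalled_l[i] = False
                    stalled_r[i] = False

        # (3) loading at a random free adjacent site pair; a blocked attempt
        # is simply retried on a later step
        for i in range(n_lefs):
            if not loaded[i]:
                if np.random.random() < birth_rate:
                    s = np.random.randint(0, n_sites - 1)
                    if (not occ[s]) and (not occ[s + 1]):
                        left[i] = s
                        right[i] = s + 1
                        occ[s] = True
                        occ[s + 1] = True
                        loaded[i] = True

        # (4) translocation, extruder index order, left leg then right leg
        for i in range(n_lefs):
            if not loaded[i]:
                continue
            # left leg moves to left-1
            tgt = left[i] - 1
            if tgt < 0:
                stalled_l[i] = True
            elif occ[tgt]:
                stalled_l[i] = True
            else:
                j = barrier_at[tgt]
                if j >= 0 and bound[j] and (b_orient[j] == 0 or b_orient[j] == 1):
                    stalled_l[i] = True
                else:
                    stalled_l[i] = False
                    if pause_rate > 0.0 and np.random.random() < pause_rate:
                        pass
                    else:
                        occ[left[i]] = False
                        left[i] = tgt
                        occ[tgt] = True
            # right leg moves to right+1
            tgt = right[i] + 1
            if tgt >= n_sites:
                stalled_r[i] = True
            elif occ[tgt]:
                stalled_r[i] = True
            else:
                j = barrier_at[tgt]
                if j >= 0 and bound[j] and (b_orient[j] == 0 or b_orient[j] == 2):
                    stalled_r[i] = True
                else:
                    stalled_r[i] = False
                    if pause_rate > 0.0 and np.random.random() < pause_rate:
                        pass
                    else:
                        occ[right[i]] = False
                        right[i] = tgt
                        occ[tgt] = True

        # record snapshot
        if step >= burn_in_steps and (step - burn_in_steps) % stride == 0:
            n_snapshots += 1
            for i in range(n_lefs):
                if loaded[i]:
                    leg_counts[left[i]] += 1
                    leg_counts[right[i]] += 1
                    loaded_leg_records += 2

    return leg_counts, n_snapshots, loaded_leg_records, left, right, loaded


def simulate(
    params: SimParams,
    barriers: BarrierSet,
    *,
    return_state: bool = False,
    _pure_python: bool = False,
):
    """Run one trajectory and return the accumulated :class:`OccupancyProfile`.

    Identical ``(params, barriers)`` including the seed reproduce the profile
    bit for bit. ``return_state`` additionally returns the final
    ``(left, right, loaded)`` arrays (used by invariant tests);
    ``_pure_python`` runs the uncompiled kernel (slow, for cross-checking the
    compiled path).
    """
    b_pos, b_p_unbind, b_p_bind, b_occ, b_orient = _tiled_barrier_arrays(
        params, barriers
    )
    n_sites = params.n_sites
    if b_pos.size and (b_pos.min() < 0 or b_pos.max() >= n_sites):
        raise ValueError("barrier position outside lattice")
    burn_in_steps = int(params.n_steps * params.burn_in_fraction)
    if burn_in_steps >= params.n_steps:
        raise ValueError("burn-in leaves no steps to record")
    dt = params.step_duration
    p_death = _step_prob(params.lef_lifetime, dt)
    p_death_stalled = _step_prob(params.lef_stalled_lifetime, dt)

    fn = _kernel.py_func if _pure_python else _kernel
    leg_counts, n_snapshots, loaded_leg_records, left, right, loaded = fn(
        params.seed,
        params.n_steps,
        burn_in_steps,
        params.snapshot_stride,
        n_sites,
        params.n_lefs,
        p_death,
        p_death_stalled,
        params.lef_birth_rate,
        params.lef_pause_rate,
        b_pos,
        b_p_unbind,
        b_p_bind,
        b_occ,
        b_orient,
    )
    profile = OccupancyProfile(
        leg_counts=leg_counts,
        n_snapshots=int(n_snapshots),
        n_lefs=params.n_lefs,
        loaded_leg_records=int(loaded_leg_records),
    )
    if return_state:
        return profile, (left, right, loaded)
    return profile


def barrier_window_mask(
    barriers: BarrierSet, window: int, n_sites: int
) -> np.ndarray:
    """Boolean mask of lattice sites within ``window`` of any tiled barrier.

    Overlapping windows are unioned, so no site is counted twice.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    spr = barriers.sites_per_replica
    if n_sites % spr != 0:
        raise ValueError("n_sites must be a multiple of sites_per_replica")
    n_replicas = n_sites // spr
    mask = np.zeros(n_sites, dtype=bool)
    for r in range(n_replicas):
        for s in barriers.sites:
            pos = r * spr + s.position
            mask[max(0, pos - window): min(n_sites, pos + window + 1)] = True
    return mask


def barrier_window_coverage(
    barriers: BarrierSet, window: int, n_sites: int | None = None
) -> float:
    """Fraction of the lattice inside barrier windows (the simulated rho)."""
    if n_sites is None:
        n_sites = barriers.sites_per_replica
    mask = barrier_window_mask(barriers, window, n_sites)
    return float(mask.sum()) / n_sites


def barrier_window_intervals(
    barriers: BarrierSet,
    window: int,
    n_sites: int,
    bp_per_site: int = 250,
    chrom: str = "sim",
) -> "pd.DataFrame":
    """Barrier windows as bp intervals on the toy genome used by
    :func:`fripkit.synth.profile_to_reads` (0-based, half-open)."""
    mask = barrier_window_mask(barriers, window, n_sites)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]])) + 1
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts * bp_per_site,
            "end": ends * bp_per_site,
        }
    )


def simulated_frip(
    profile: OccupancyProfile, barriers: BarrierSet, window: int = 1
) -> float:
    """Fraction of recorded legs within ``window`` sites of a barrier."""
    total = int(profile.leg_counts.sum())
    if total == 0:
        raise ValueError("empty profile: no legs were recorded")
    mask = barrier_window_mask(barriers, window, profile.n_sites)
    return float(profile.leg_counts[mask].sum()) / total


def _child_seed(seed: int, ratio_index: int) -> int:
    ss = np.random.SeedSequence([int(seed), int(ratio_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def _scan(
    abundance_ratios,
    params: SimParams,
    seeds,
    make_config,
) -> pd.DataFrame:
    rows = []
    for k, ratio in enumerate(abundance_ratios):
        p_r, b_r = make_config(float(ratio))
        frips = []
        for s in seeds:
            p_rs = replace(p_r, seed=_child_seed(s, k))
            prof = simulate(p_rs, b_r)
            frips.append(simulated_frip(prof, b_r, params.frip_window))
        frips = np.asarray(frips)
        rows.append(
            {
                "ratio": float(ratio),
                "frip_mean": float(frips.mean()),
                "frip_sd": float(frips.std(ddof=1)) if len(frips) > 1 else 0.0,
                "n_seeds": len(frips),
            }
        )
    return pd.DataFrame(rows)


def scan_cohesin_abundance(
    abundance_ratios, params: SimParams, barriers: BarrierSet, seeds
) -> pd.DataFrame:
    """Simulated FRiP versus relative cohesin abundance.

    A ratio ``r`` divides the baseline LEF separation by ``r`` (so ``r``
    multiplies extruder number); barriers are unchanged. Returns a table
    (ratio, frip_mean, frip_sd, n_seeds).
    """
    ratios = np.asarray(list(abundance_ratios), dtype=float)
    if np.any(ratios <= 0):
        raise ValueError("abundance ratios must be positive")

    def make(ratio):
        return (
            replace(params, lef_separation_bp=params.lef_separation_bp / ratio),
            barriers,
        )

    return _scan(ratios, params, seeds, make)


def scan_ctcf_abundance(
    abundance_ratios, params: SimParams, barriers: BarrierSet, seeds
) -> pd.DataFrame:
    """Simulated FRiP versus relative CTCF abundance (occupancy scaling)."""
    ratios = np.asarray(list(abundance_ratios), dtype=float)
    if np.any(ratios < 0):
        raise ValueError("abundance ratios must be nonnegative")

    def make(ratio):
        return params, scale_barrier_occupancy(barriers, ratio)

    return _scan(ratios, params, seeds, make)


def profile_to_tsv(profile: OccupancyProfile, path) -> None:
    pd.DataFrame(
        {"site": np.arange(profile.n_sites), "leg_count": profile.leg_counts}
    ).to_csv(path, sep="\t", index=False)


def profile_from_tsv(path, n_lefs: int = 0, n_snapshots: int = 0) -> OccupancyProfile:
    df = pd.read_csv(path, sep="\t")
    counts = df["leg_count"].to_numpy(dtype=np.int64)
    return OccupancyProfile(counts, n_snapshots, n_lefs, int(counts.sum()))
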