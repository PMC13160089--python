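"""CTCF barrier sets: occupancies, bound/unbound dwell times, sampling and rescaling.

A CTCF site alternates between a bound (extrusion-blocking) and an unbound
(permissive) state. At equilibrium the occupancy — the probability the site is
bound at any instant — is ``bound_time / (bound_time + unbound_time)``. The
module converts between occupancy and dwell times (holding the unbound time
fixed at an anchor condition), samples heterogeneous barrier sets until a
target total occupancy per megabase is reached, and rescales occupancies to
emulate changes in CTCF abundance.

All dwell times are in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "BarrierSite",
    "BarrierSet",
    "occupancy_from_times",
    "times_from_occupancy",
    "sample_barrier_set",
    "uniform_barrier_set",
    "scale_barrier_occupancy",
    "barriers_to_tsv",
    "barriers_from_tsv",
    "DEFAULT_ANCHOR_OCCUPANCY",
    "DEFAULT_ANCHOR_BOUND_TIME_S",
    "OCCUPANCY_CAP_EPS",
]

ORIENTATIONS = ("bidirectional", "left-blocking", "right-blocking")

#: Anchor condition: occupancy 0.65 corresponds to a 9.87 min bound time
#: (about half the extruder lifetime), which reproduces genome-folding
#: features at CTCF sites.
DEFAULT_ANCHOR_OCCUPANCY = 0.65
DEFAULT_ANCHOR_BOUND_TIME_S = 9.87 * 60.0

#: Occupancies are capped this far below 1.0 when rescaling so dwell times
#: stay finite.
OCCUPANCY_CAP_EPS = 1e-6


def occupancy_from_times(bound_time: float, unbound_time: float) -> float:
    """Equilibrium occupancy of a two-state site, ``b / (b + u)``.

    Parameters
    ----------
    bound_time, unbound_time
        Mean dwell times in the bound / unbound state (any common unit).
        Must be nonnegative and not both zero.
    """
    if bound_time < 0 or unbound_time < 0:
        raise ValueError("dwell times must be nonnegative")
    total = bound_time + unbound_time
    if total == 0:
        raise ValueError("bound_time and unbound_time cannot both be zero")
    return bound_time / total


def times_from_occupancy(
    occupancy: float,
    anchor_occupancy: float = DEFAULT_ANCHOR_OCCUPANCY,
    anchor_bound_time: float = DEFAULT_ANCHOR_BOUND_TIME_S,
) -> tuple[float, float]:
    """Dwell times realising ``occupancy`` with the anchor's unbound time.

    The unbound time is held fixed at the anchor condition's value
    ``u* = anchor_bound_time * (1 - anchor_occupancy) / anchor_occupancy``
    and the bound time is scaled to ``u* * occupancy / (1 - occupancy)``;
    this preserves the site's rebinding rate while matching the requested
    occupancy exactly.

    Returns
    -------
    (bound_time, unbound_time) in the units of ``anchor_bound_time``.
    """
    if not 0.0 <= occupancy < 1.0:
        raise ValueError(f"occupancy must be in [0, 1), got {occupancy}")
    if not 0.0 < anchor_occupancy < 1.0:
        raise ValueError("anchor_occupancy must be in (0, 1)")
    if anchor_bound_time <= 0:
        raise ValueError("anchor_bound_time must be positive")
    u_star = anchor_bound_time * (1.0 - anchor_occupancy) / anchor_occupancy
    bound = u_star * occupancy / (1.0 - occupancy)
    return bound, u_star


@dataclass(frozen=True)
class BarrierSite:
    """A single dynamic CTCF barrier on the replica lattice."""

    position: int
    occupancy: float
    bound_time: float  # seconds
    unbound_time: float  # seconds
    orientation: str = "bidirectional"

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")
        if 0.0 < self.occupancy < 1.0:
            implied = occupancy_from_times(self.bound_time, self.unbound_time)
            if abs(implied - self.occupancy) > 1e-9:
                raise ValueError(
                    f"occupancy {self.occupancy} inconsistent with dwell times "
                    f"(implied {implied})"
                )


@dataclass(frozen=True)
class BarrierSet:
    """Barriers on one lattice replica (tiled identically across replicas).

    ``anchor_occupancy``/``anchor_bound_time`` record the dwell-time anchor
    used to build the set, so occupancy rescaling can recompute times
    consistently.
    """

    sites: tuple[BarrierSite, ...]
    sites_per_replica: int
    target_occupancy_per_mb: float
    anchor_occupancy: float = DEFAULT_ANCHOR_OCCUPANCY
    anchor_bound_time: float = DEFAULT_ANCHOR_BOUND_TIME_S

    def __post_init__(self) -> None:
        positions = [s.position for s in self.sites]
        if len(set(positions)) != len(positions):
            raise ValueError("barrier positions must be unique within a replica")
        for s in self.sites:
            if not 0 <= s.position < self.sites_per_replica:
                raise ValueError(
                    f"barrier position {s.position} outside "
                    f"[0, {self.sites_per_replica})"
                )

    @property
    def total_occupancy(self) -> float:
        return float(sum(s.occupancy for s in self.sites))

    def __len__(self) -> int:
        return len(self.sites)


def sample_barrier_set(
    occupancy_pool: "list[float] | np.ndarray",
    target_occupancy_per_mb: float,
    sites_per_replica: int = 4000,
    seed: int = 0,
    *,
    anchor_occupancy: float = DEFAULT_ANCHOR_OCCUPANCY,
    anchor_bound_time: float = DEFAULT_ANCHOR_BOUND_TIME_S,
    orientation: str = "bidirectional",
) -> BarrierSet:
    """Draw barrier occupancies until their sum reaches the per-Mb target.

    Occupancies are sampled with replacement from ``occupancy_pool``; the
    sampling stops at the first draw whose cumulative occupancy reaches
    ``target_occupancy_per_mb`` (one replica represents 1 Mb). Sites are then
    placed at distinct uniformly random lattice positions and dwell times
    derived with :func:`times_from_occupancy`.
    """
    pool = np.asarray(occupancy_pool, dtype=float)
    if pool.size == 0:
        raise ValueError("occupancy_pool must be non-empty")
    if np.any((pool <= 0) | (pool > 1)):
        raise ValueError("occupancy_pool entries must be in (0, 1]")
    if target_occupancy_per_mb <= 0:
        raise ValueError("target_occupancy_per_mb must be positive")

    rng = np.random.default_rng(seed)
    occs: list[float] = []
    total = 0.0
    while total < target_occupancy_per_mb:
        occ = float(pool[rng.integers(0, pool.size)])
        occs.append(occ)
        total += occ
    n = len(occs)
    if n > sites_per_replica:
        raise ValueError("more barriers than lattice sites; lower the target")
    positions = np.sort(rng.choice(sites_per_replica, size=n, replace=False))

    sites = []
    for pos, occ in zip(positions, occs):
        occ_eff = min(occ, 1.0 - OCCUPANCY_CAP_EPS)
        b, u = times_from_occupancy(occ_eff, anchor_occupancy, anchor_bound_time)
        sites.append(BarrierSite(int(pos), occ_eff, b, u, orientation))
    return BarrierSet(
        tuple(sites), sites_per_replica, target_occupancy_per_mb,
        anchor_occupancy, anchor_bound_time,
    )


def uniform_barrier_set(
    occupancy: float,
    target_occupancy_per_mb: float,
    sites_per_replica: int = 4000,
    seed: int = 0,
    *,
    bound_time: float | None = None,
    orientation: str = "bidirectional",
) -> BarrierSet:
    """Homogeneous barriers, all at ``occupancy``, filling the per-Mb target.

    Number of sites is ``ceil(target / occupancy)``. When ``bound_time`` is
    given (seconds) it anchors the dwell times at this occupancy (e.g.
    occupancy 0.625 with bound time 780 s gives the 780 s / 468 s block);
    otherwise the default 0.65/9.87-min anchor is used.
    """
    if not 0.0 < occupancy < 1.0:
        raise ValueError("occupancy must be in (0, 1)")
    if bound_time is not None:
        anchor_occ, anchor_bt = occupancy, float(bound_time)
    else:
        anchor_occ, anchor_bt = DEFAULT_ANCHOR_OCCUPANCY, DEFAULT_ANCHOR_BOUND_TIME_S
    n = math.ceil(target_occupancy_per_mb / occupancy)
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(sites_per_replica, size=n, replace=False))
    b, u = times_from_occupancy(occupancy, anchor_occ, anchor_bt)
    sites = tuple(
        BarrierSite(int(p), occupancy, b, u, orientation) for p in positions
    )
    return BarrierSet(
        sites, sites_per_replica, target_occupancy_per_mb, anchor_occ, anchor_bt
    )


def scale_barrier_occupancy(barriers: BarrierSet, factor: float) -> BarrierSet:
    """Rescale every occupancy by ``factor`` (emulating CTCF abundance change).

    Occupancies are capped at ``1 - OCCUPANCY_CAP_EPS``; dwell times are
    recomputed from the set's anchor; positions are unchanged.
    """
    if factor < 0:
        raise ValueError("factor must be nonnegative")
    new_sites = []
    for s in barriers.sites:
        occ = min(s.occupancy * factor, 1.0 - OCCUPANCY_CAP_EPS)
        b, u = times_from_occupancy(
            occ, barriers.anchor_occupancy, barriers.anchor_bound_time
        )
        new_sites.append(BarrierSite(s.position, occ, b, u, s.orientation))
    return replace(barriers, sites=tuple(new_sites))


def barriers_to_tsv(barriers: BarrierSet, path) -> None:
    """Write the set as TSV (replica, position, occupancy, bound_time_s,
    unbound_time_s, orientation). A single replica layout is written as
    replica 0; the simulator tiles it."""
    df = pd.DataFrame(
        {
            "replica": 0,
            "position": [s.position for s in barriers.sites],
            "occupancy": [s.occupancy for s in barriers.sites],
            "bound_time_s": [s.bound_time for s in barriers.sites],
            "unbound_time_s": [s.unbound_time for s in barriers.sites],
            "orientation": [s.orientation for s in barriers.sites],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def barriers_from_tsv(
    path,
    sites_per_replica: int = 4000,
    target_occupancy_per_mb: float | None = None,
) -> BarrierSet:
    """Read a barrier set written by :func:`barriers_to_tsv`."""
    df = pd.read_csv(path, sep="\t")
    sites = tuple(
        BarrierSite(
            int(r.position), float(r.occupancy), float(r.bound_time_s),
            float(r.unbound_time_s), str(r.orientation),
        )
        for r in df.itertuples()
    )
    total = float(sum(s.occupancy for s in sites))
    return BarrierSet(
        sites,
        sites_per_replica,
        target_occupancy_per_mb if target_occupancy_per_mb is not None else total,
    )
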