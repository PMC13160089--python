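import numpy as np
import pytest
from scipy.stats import spearmanr

from fripkit.barrier_kinetics import BarrierSet, BarrierSite, uniform_barrier_set
from fripkit.extrusion import (
    OccupancyProfile,
    SimParams,
    barrier_window_coverage,
    barrier_window_intervals,
    barrier_window_mask,
    n_lefs_from_separation,
    simulate,
    simulated_frip,
)

MB = 1_000_000


def small_params(**kw):
    defaults = dict(
        sites_per_replica=20, n_replicas=1, bp_per_site=250,
        lef_separation_bp=20 * 250, lef_lifetime=1e12, lef_stalled_lifetime=1e12,
        lef_birth_rate=1.0, n_steps=200, burn_in_fraction=0.5, seed=0,
    )
    defaults.update(kw)
    return SimParams(**defaults)


def permanent_barriers(positions, sites_per_replica=20):
    sites = tuple(
        BarrierSite(p, 1.0, bound_time=1e18, unbound_time=0.0) for p in positions
    )
    return BarrierSet(sites, sites_per_replica, float(len(positions)))


def no_barriers(sites_per_replica=20):
    return BarrierSet((), sites_per_replica, 0.0)


class TestLefCount:
    @pytest.mark.parametrize(
        "total, sep, expected",
        [(25 * MB, 250_000, 100), (25 * MB, 25 * MB, 1), (25 * MB, 50 * MB, 1)],
    )
    def test_counts(self, total, sep, expected):
        assert n_lefs_from_separation(total, sep) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            n_lefs_from_separation(0, 100)


class TestSingleExtruderDynamics:
    def test_immortal_extruder_reaches_lattice_ends(self):
        """With no death and no barriers a lone extruder's legs run to the
        lattice boundaries and stay there."""
        params = small_params(n_steps=200, burn_in_fraction=0.5)
        prof, (left, right, loaded) = simulate(
            params, no_barriers(), return_state=True
        )
        assert loaded[0]
        assert left[0] == 0 and right[0] == 19
        # late snapshots all have legs at the boundaries: boundary counts
        # dominate (legs arrive within <20 steps of loading, burn-in is 100)
        assert prof.leg_counts[0] == prof.n_snapshots
        assert prof.leg_counts[19] == prof.n_snapshots

    def test_permanent_barrier_pair_traps_legs(self):
        """Permanently bound bidirectional barriers flanking the loading
        region capture both legs for every recorded snapshot."""
        barriers = permanent_barriers([3, 16])
        # seed chosen so the extruder loads strictly between the barriers
        params = small_params(n_steps=300, burn_in_fraction=0.5, seed=3)
        prof, (left, right, loaded) = simulate(params, barriers, return_state=True)
        assert loaded[0]
        # legs stop just inside the barriers (blocked entering the barrier site)
        assert left[0] == 4 and right[0] == 15
        assert prof.leg_counts[4] == prof.n_snapshots
        assert prof.leg_counts[15] == prof.n_snapshots

    def test_burn_in_one_rejected(self):
        with pytest.raises(ValueError):
            small_params(burn_in_fraction=1.0)


class TestInvariants:
    def test_leg_conservation(self):
        """Every snapshot contributes exactly two counts per loaded extruder."""
        params = small_params(
            sites_per_replica=50, n_replicas=2, lef_separation_bp=10 * 250,
            lef_lifetime=30.0, lef_stalled_lifetime=15.0, lef_birth_rate=0.3,
            n_steps=400, burn_in_fraction=0.25, seed=5,
        )
        prof = simulate(params, permanent_barriers([10, 40], 50))
        assert prof.leg_counts.sum() == prof.loaded_leg_records
        assert prof.loaded_leg_records <= 2 * prof.n_lefs * prof.n_snapshots

    def test_legs_ordered_and_disjoint_final_state(self):
        params = small_params(
            sites_per_replica=100, n_replicas=1, lef_separation_bp=5 * 250,
            lef_lifetime=50.0, lef_birth_rate=0.5, n_steps=500,
            burn_in_fraction=0.2, seed=11,
        )
        _, (left, right, loaded) = simulate(
            params, permanent_barriers([20, 70], 100), return_state=True
        )
        legs = []
        for i in range(len(left)):
            if loaded[i]:
                assert left[i] < right[i]
                legs += [left[i], right[i]]
        assert len(set(legs)) == len(legs)

    def test_compiled_matches_pure_python(self):
        """The numba kernel and its uncompiled twin walk identical RNG
        streams and produce identical profiles."""
        params = small_params(
            sites_per_replica=40, lef_separation_bp=8 * 250,
            lef_lifetime=40.0, lef_birth_rate=0.3, n_steps=150, seed=9,
        )
        barriers = uniform_barrier_set(0.5, 2.0, sites_per_replica=40, seed=2)
        fast = simulate(params, barriers)
        slow = simulate(params, barriers, _pure_python=True)
        np.testing.assert_array_equal(fast.leg_counts, slow.leg_counts)
        assert fast.n_snapshots == slow.n_snapshots

    def test_bit_reproducible(self, homogeneous_barriers):
        params = SimParams(n_steps=400, seed=123)
        a = simulate(params, homogeneous_barriers)
        b = simulate(params, homogeneous_barriers)
        np.testing.assert_array_equal(a.leg_counts, b.leg_counts)

    def test_barrier_outside_lattice_rejected(self):
        params = small_params()
        bad = BarrierSet(
            (BarrierSite(10, 0.5, 10.0, 10.0),), sites_per_replica=40,
            target_occupancy_per_mb=1.0,
        )
        with pytest.raises(ValueError):
            simulate(params, bad)


class TestSimulatedFrip:
    def test_all_legs_at_barriers(self):
        barriers = permanent_barriers([5], 20)
        counts = np.zeros(20, dtype=np.int64)
        counts[5] = 10
        prof = OccupancyProfile(counts, 5, 1, 10)
        assert simulated_frip(prof, barriers, 1) == 1.0

    def test_no_barriers_zero(self):
        prof = OccupancyProfile(np.ones(20, dtype=np.int64), 10, 1, 20)
        assert simulated_frip(prof, no_barriers(), 1) == 0.0

    def test_uniform_profile_counts_window_sites(self):
        # k non-adjacent interior barriers, window 1 -> frip = 3k/n
        n = 40
        barriers = permanent_barriers([5, 15, 30], n)
        prof = OccupancyProfile(np.ones(n, dtype=np.int64), 1, n // 2, n)
        assert simulated_frip(prof, barriers, 1) == pytest.approx(9 / 40)

    def test_overlapping_windows_unioned(self):
        n = 20
        barriers = permanent_barriers([5, 6], n)  # windows overlap
        mask = barrier_window_mask(barriers, 1, n)
        assert mask.sum() == 4  # sites 4..7, not 6
        prof = OccupancyProfile(np.ones(n, dtype=np.int64), 1, 1, n)
        assert simulated_frip(prof, barriers, 1) == pytest.approx(4 / 20)

    def test_empty_profile_rejected(self):
        prof = OccupancyProfile(np.zeros(20, dtype=np.int64), 0, 1, 0)
        with pytest.raises(ValueError):
            simulated_frip(prof, permanent_barriers([5], 20), 1)

    def test_window_intervals_match_mask(self):
        barriers = permanent_barriers([0, 7, 19], 20)
        df = barrier_window_intervals(barriers, 1, 20, bp_per_site=250)
        covered = sum(df["end"] - df["start"]) / 250
        assert covered == barrier_window_mask(barriers, 1, 20).sum()

    def test_chance_level_without_blocking(self):
        """With zero-occupancy barriers, long-run FRiP over the dummy window
        set approaches the fraction of recorded legs expected there by the
        stationary leg distribution; for a crude bound we check it stays
        within a factor-of-two band of the window coverage."""
        params = small_params(
            sites_per_replica=200, lef_separation_bp=20 * 250,
            lef_lifetime=100.0, lef_birth_rate=0.5, n_steps=3000,
            burn_in_fraction=0.2, seed=1,
        )
        dummy = uniform_barrier_set(1e-9, 4e-8, sites_per_replica=200, seed=3)
        frips = []
        for seed in range(10):
            prof = simulate(SimParams(**{**params.__dict__, "seed": seed}), dummy)
            frips.append(simulated_frip(prof, dummy, 1))
        cov = barrier_window_coverage(dummy, 1, 200)
        assert 0.3 * cov < np.mean(frips) < 3.0 * cov


class TestAbundanceScans:
    def test_cohesin_scan_monotone_decreasing(self, cohesin_scan):
        rho_s, _ = spearmanr(cohesin_scan["ratio"], cohesin_scan["frip_mean"])
        assert rho_s < 0
        assert cohesin_scan["frip_mean"].is_monotonic_decreasing

    def test_ctcf_scan_monotone_increasing(self, ctcf_scan):
        rho_s, _ = spearmanr(ctcf_scan["ratio"], ctcf_scan["frip_mean"])
        assert rho_s > 0

    def test_ctcf_zero_ratio_is_chance_level(self, ctcf_scan, homogeneous_barriers):
        cov = barrier_window_coverage(homogeneous_barriers, 1)
        row = ctcf_scan[ctcf_scan["ratio"] == 0.0].iloc[0]
        assert row["frip_mean"] == pytest.approx(cov, rel=0.5)

    def test_scan_table_schema(self, cohesin_scan):
        assert list(cohesin_scan.columns) == ["ratio", "frip_mean", "frip_sd", "n_seeds"]
        assert (cohesin_scan["n_seeds"] == 20).all()
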