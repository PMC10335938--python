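"""Engine mechanics: movement, stalling, bypass, unloading, observables."""

import numpy as np
import pytest

from hoxtimer.core import Axis, Track
from hoxtimer.extrusion import (
    BarrierField,
    SimulationParams,
    Trajectory,
    anchor_occupancy,
    background_matrix,
    barrier_field,
    contact_map,
    init_lattice,
    region_contact,
    run_extrusion,
    simulate_step,
)
from hoxtimer.locus import LatticeMap


def toy_lattice(n_bins=100, bin_size=1_000):
    axis = Axis("chrT", 0, bin_size, n_bins)
    return LatticeMap(axis=axis, gene_bins={}, cbs_bin={}, region_bins={})


def uniform_profile(n_bins, value=1.0):
    return np.full(n_bins, value)


def single_barrier(n_bins, bin_idx, p_stall=1.0, p_bypass=0.0):
    stall_left = np.zeros(n_bins)
    stall_left[bin_idx] = p_stall
    byp = np.full(n_bins, p_bypass)
    return BarrierField(stall_left, np.zeros(n_bins), byp, byp.copy())


def place_extruder(state, left, right):
    state.left = np.array([left])
    state.right = np.array([right])
    state.left_stalled = np.array([False])
    state.right_stalled = np.array([False])
    state.birth = np.array([state.time])


class TestStepMechanics:
    def test_empty_step_advances_time_only(self):
        lmap = toy_lattice()
        params = SimulationParams(load_rate=0.0)
        state = init_lattice(lmap, params)
        simulate_step(state, uniform_profile(100), params)
        assert state.n_extruders == 0
        assert state.time == pytest.approx(params.dt)

    def test_free_extrusion_separation_grows_2vk(self):
        lmap = toy_lattice()
        params = SimulationParams(load_rate=0.0, unload_prob=0.0, v=1)
        state = init_lattice(lmap, params)
        place_extruder(state, 50, 50)
        for _ in range(10):
            simulate_step(state, uniform_profile(100), params)
        assert state.right[0] - state.left[0] == 2 * params.v * 10

    def test_anchors_clamp_at_edges(self):
        lmap = toy_lattice(n_bins=11)
        params = SimulationParams(load_rate=0.0, unload_prob=0.0)
        state = init_lattice(lmap, params)
        place_extruder(state, 5, 5)
        for _ in range(30):
            simulate_step(state, uniform_profile(11), params)
        assert state.left[0] == 0 and state.right[0] == 10

    def test_zero_profile_skips_loading(self):
        lmap = toy_lattice()
        params = SimulationParams(load_rate=100.0)
        state = init_lattice(lmap, params)
        simulate_step(state, np.zeros(100), params)
        assert state.n_extruders == 0

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(unload_prob=1.5)
        with pytest.raises(ValueError):
            SimulationParams(p_stall=-0.1)

    def test_same_seed_same_rng_state(self):
        lmap = toy_lattice()
        params = SimulationParams(seed=7)
        s1, s2 = init_lattice(lmap, params), init_lattice(lmap, params)
        assert s1.rng.bit_generator.state == s2.rng.bit_generator.state

    def test_stalled_residence_matches_geometric_mean(self):
        """Residence at a barrier is geometric: mean 1/p_bypass steps."""
        p_bypass = 0.1
        n_trials = 10_000
        lmap = toy_lattice(n_bins=10)
        params = SimulationParams(load_rate=0.0, unload_prob=0.0, p_bypass=p_bypass, seed=3)
        barriers = single_barrier(10, 4, p_stall=1.0, p_bypass=p_bypass)
        state = init_lattice(lmap, params)
        # many independent single-anchor walkers released at bin 5
        state.left = np.full(n_trials, 5)
        state.right = np.full(n_trials, 9)  # parked at edge, irrelevant
        state.left_stalled = np.zeros(n_trials, bool)
        state.right_stalled = np.zeros(n_trials, bool)
        state.birth = np.zeros(n_trials)
        at_barrier_steps = np.zeros(n_trials)
        for _ in range(600):
            simulate_step(state, uniform_profile(10), params, barriers)
            at_barrier_steps += state.left == 4
        assert np.all(~state.left_stalled)  # all escaped by now
        # residence at the barrier bin: geometric number of bypass draws
        assert at_barrier_steps.mean() == pytest.approx(1.0 / p_bypass, rel=0.05)


class TestRunExtrusion:
    def test_zero_duration_has_only_initial_snapshot(self):
        lmap = toy_lattice()
        params = SimulationParams()
        traj = run_extrusion(lmap, lambda t: uniform_profile(100), params, 0.0, 0.0)
        assert traj.n_snapshots == 1

    def test_identical_seeds_identical_trajectories(self):
        lmap = toy_lattice()
        params = SimulationParams(load_rate=20.0, seed=11)
        args = (lmap, lambda t: uniform_profile(100), params, 0.0, 2.0)
        t1 = run_extrusion(*args)
        t2 = run_extrusion(*args)
        assert t1.snapshot_times == t2.snapshot_times
        for a, b in zip(t1.snapshot_left, t2.snapshot_left):
            assert np.array_equal(a, b)
        for a, b in zip(t1.snapshot_right, t2.snapshot_right):
            assert np.array_equal(a, b)

    def test_left_never_exceeds_right(self):
        lmap = toy_lattice()
        params = SimulationParams(load_rate=50.0, unload_prob=0.01, seed=5)
        traj = run_extrusion(lmap, lambda t: uniform_profile(100), params, 0.0, 5.0)
        checked = 0
        for l, r in zip(traj.snapshot_left, traj.snapshot_right):
            assert np.all(l <= r)
            checked += len(l)
        assert checked > 100

    def test_mean_separation_matches_renewal_oracle(self):
        """Population-mean anchor separation equals a brute-force renewal
        average over simulated extruder lifetimes."""
        unload = 0.02
        v = 1
        lmap = toy_lattice(n_bins=2_001)
        params = SimulationParams(
            load_rate=500.0, unload_prob=unload, v=v, seed=21, max_extruders=100_000
        )
        profile = np.zeros(2_001)
        profile[1_000] = 1.0  # central loading keeps anchors off the edges
        traj = run_extrusion(lmap, lambda t: profile, params, 0.0, 4.0, snapshot_every=0.02)
        seps = np.concatenate(
            [r - l for l, r in zip(traj.snapshot_left, traj.snapshot_right)]
        )
        # oracle: brute-force census over 10,000 simulated extruder
        # lifetimes with uniform births inside the observation window — an
        # extruder born in step b with geometric lifetime L is seen at ages
        # 1..min(L, n_steps - b + 1), separated by 2 v age bins
        rng = np.random.default_rng(99)
        n_steps = 400
        births = rng.integers(1, n_steps + 1, size=10_000)
        lifetimes = rng.geometric(unload, size=10_000)
        observed = np.minimum(lifetimes, n_steps - births + 1)
        ages = np.concatenate([np.arange(1, o + 1) for o in observed])
        expected = (2 * v * ages).mean()
        assert seps.mean() == pytest.approx(expected, rel=0.10)


class TestBarrierSemantics:
    def test_absolute_barrier_never_crossed(self, wt_locus, wt_lattice):
        import dataclasses

        params = dataclasses.replace(
            SimulationParams(seed=2), p_stall=1.0, p_bypass=0.0, p_stall_reverse=0.0,
            embedded_full_block=0.0, load_rate=5.0,
        )
        cbs1_bin = wt_lattice.cbs_bin["CBS1"]
        profile = np.zeros(wt_lattice.n_bins)
        profile[cbs1_bin + 2 : cbs1_bin + 12] = 1.0  # load 3' (above) of CBS1
        traj = run_extrusion(
            wt_lattice, lambda t: profile, params, 0.0, 10.0, locus=wt_locus,
            snapshot_every=0.01,
        )
        for lefts in traj.snapshot_left:
            assert np.all(lefts >= cbs1_bin)

    def test_first_passage_monotone_in_bypass(self):
        n_bins = 40
        lmap = toy_lattice(n_bins=n_bins)
        medians = []
        for p_byp in (0.001, 0.01, 0.1):
            params = SimulationParams(load_rate=0.0, unload_prob=0.0, p_bypass=p_byp, seed=17)
            barriers = single_barrier(n_bins, 10, p_stall=1.0, p_bypass=p_byp)
            passages = []
            n_walkers = 100
            state = init_lattice(lmap, params)
            state.left = np.full(n_walkers, 20)
            state.right = np.full(n_walkers, n_bins - 1)
            state.left_stalled = np.zeros(n_walkers, bool)
            state.right_stalled = np.zeros(n_walkers, bool)
            state.birth = np.zeros(n_walkers)
            step = 0
            first_pass = np.full(n_walkers, -1)
            while np.any(first_pass < 0) and step < 200_000:
                simulate_step(state, uniform_profile(n_bins), params, barriers)
                step += 1
                newly = (state.left < 10) & (first_pass < 0)
                first_pass[newly] = step
            medians.append(np.median(first_pass[first_pass > 0]))
        assert medians[0] > medians[1] > medians[2]

    def test_barrier_field_orientation_rule(self, wt_locus, wt_lattice):
        params = SimulationParams()
        field = barrier_field(wt_locus, wt_lattice, params)
        cbs1 = wt_lattice.cbs_bin["CBS1"]  # TOWARD_TDOM: blocks left-movers
        cbs6 = wt_lattice.cbs_bin["CBS6"]  # TOWARD_CDOM: blocks right-movers
        assert field.stall_left[cbs1] == pytest.approx(params.p_stall)
        assert field.stall_right[cbs1] == pytest.approx(params.p_stall_reverse)
        assert field.stall_right[cbs6] == pytest.approx(params.p_stall)
        # CBS3 is embedded in the convergent series: full block for left-movers
        cbs3 = wt_lattice.cbs_bin["CBS3"]
        assert field.stall_left[cbs3] == pytest.approx(
            params.embedded_full_block * params.p_stall
        )


class TestOccupancy:
    def test_empty_trajectory_rejected(self):
        axis = Axis("chrT", 0, 1_000, 10)
        with pytest.raises(ValueError):
            anchor_occupancy(Trajectory(axis=axis))

    def test_conservation_window_zero(self):
        lmap = toy_lattice()
        params = SimulationParams(load_rate=30.0, unload_prob=0.01, seed=8)
        traj = run_extrusion(lmap, lambda t: uniform_profile(100), params, 0.0, 3.0)
        occ = anchor_occupancy(traj, half_window=0)
        total_anchor_snapshots = 2 * traj.total_extruder_snapshots()
        assert occ.values.sum() * traj.n_snapshots == pytest.approx(total_anchor_snapshots)

    def test_occupancy_peaks_at_absolute_barrier(self, wt_locus, wt_lattice):
        import dataclasses

        params = dataclasses.replace(
            SimulationParams(seed=4), p_stall=1.0, p_bypass=0.0, load_rate=20.0,
            unload_prob=5e-4,
        )
        cbs1_bin = wt_lattice.cbs_bin["CBS1"]
        profile = np.zeros(wt_lattice.n_bins)
        profile[cbs1_bin + 2 : cbs1_bin + 10] = 1.0
        traj = run_extrusion(wt_lattice, lambda t: profile, params, 0.0, 15.0, locus=wt_locus)
        occ = anchor_occupancy(traj, half_window=0)
        # left anchors pile at CBS1; ignore the T-DOM side
        assert int(np.argmax(occ.values[: cbs1_bin + 2])) == cbs1_bin


class TestContactMap:
    def test_background_power_law_ratio(self):
        lmap = toy_lattice(n_bins=50)
        params = SimulationParams(alpha=1.3, c0=2.0)
        traj = Trajectory(axis=lmap.axis, snapshot_times=[0.0],
                          snapshot_left=[np.empty(0, int)], snapshot_right=[np.empty(0, int)])
        cmap = contact_map(traj, params)
        ratio = cmap.matrix[10, 12] / cmap.matrix[10, 14]
        assert ratio == pytest.approx(2.0 ** params.alpha)

    def test_symmetry(self):
        lmap = toy_lattice()
        params = SimulationParams(load_rate=30.0, seed=6)
        traj = run_extrusion(lmap, lambda t: uniform_profile(100), params, 0.0, 2.0)
        cmap = contact_map(traj, params)
        assert np.allclose(cmap.matrix, cmap.matrix.T)

    def test_permanent_loop_adds_exactly_one(self):
        axis = Axis("chrT", 0, 1_000, 30)
        l, r = 5, 20
        traj = Trajectory(
            axis=axis,
            snapshot_times=[0.0, 1.0, 2.0],
            snapshot_left=[np.array([l])] * 3,
            snapshot_right=[np.array([r])] * 3,
        )
        params = SimulationParams()
        cmap = contact_map(traj, params)
        bg = background_matrix(30, params)
        assert cmap.matrix[l, r] - bg[l, r] == pytest.approx(1.0)
        assert cmap.matrix[r, l] - bg[r, l] == pytest.approx(1.0)

    def test_equals_bruteforce_recount(self):
        """On a small lattice the map must equal a naive recount."""
        lmap = toy_lattice(n_bins=30)
        params = SimulationParams(load_rate=4.0, unload_prob=0.01, seed=13, max_extruders=2)
        traj = run_extrusion(lmap, lambda t: uniform_profile(30), params, 0.0, 1.0,
                             snapshot_every=0.05)
        cmap = contact_map(traj, params)
        brute = background_matrix(30, params)
        add = np.zeros((30, 30))
        for lefts, rights in zip(traj.snapshot_left, traj.snapshot_right):
            for l, r in zip(lefts, rights):
                if l == r:
                    add[l, r] += 1.0
                else:
                    add[l, r] += 1.0
                    add[r, l] += 1.0
        brute += add / traj.n_snapshots
        assert np.allclose(cmap.matrix, brute, atol=1e-12)

    def test_region_contact_values(self):
        axis = Axis("chrT", 0, 1_000, 10)
        from hoxtimer.core import ContactMap

        m = np.full((10, 10), 3.0)
        cmap = ContactMap(axis, m)
        assert region_contact(cmap, (0, 4), (5, 9)) == pytest.approx(3.0)
        assert region_contact(cmap, (2, 2), (7, 7)) == m[2, 7]
        assert region_contact(cmap, (0, 4), (5, 9)) == region_contact(cmap, (5, 9), (0, 4))
        with pytest.raises(ValueError):
            region_contact(cmap, (4, 2), (0, 1))
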