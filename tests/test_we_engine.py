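import dataclasses

import numpy as np
import pytest

from wepath.coords_bins import BinScheme, binding_scheme
from wepath.kinetics import RegionStateDefs
from wepath.we_engine import (
    ResamplePolicy,
    Walker,
    WESimulation,
    initialize,
    merge_pair,
    resample,
    run_iteration,
    split_walker,
)


class IdentityPropagator:
    """Keeps every state fixed; pcoord is the state itself."""

    def propagate_many(self, states, n_steps, rng):
        return np.atleast_2d(np.asarray(states, dtype=float))

    def pcoords(self, states):
        return np.atleast_2d(np.asarray(states, dtype=float))


class ScriptedPropagator:
    """Replays a scripted per-call batch of states (for arrival tests)."""

    def __init__(self, script):
        self.script = [np.atleast_2d(np.asarray(s, dtype=float)) for s in script]
        self.calls = 0

    def propagate_many(self, states, n_steps, rng):
        out = self.script[self.calls]
        self.calls += 1
        return out

    def pcoords(self, states):
        return np.atleast_2d(np.asarray(states, dtype=float))


def _walker(idx, weight, x, bin_=0):
    return Walker(
        idx=idx,
        parent_idx=-1,
        weight=weight,
        state=np.array([float(x)]),
        pcoord=np.array([float(x)]),
        bin=bin_,
    )


LINE_SCHEME = BinScheme(edges=np.array([-np.inf, 0.0, 10.0, 20.0]))


class TestInitialize:
    def test_100_states_16_copies_gives_1600_at_uniform_weight(self):
        walkers = initialize([np.array([float(i)]) for i in range(100)], 16)
        assert len(walkers) == 1600
        assert all(np.isclose(w.weight, 1 / 1600) for w in walkers)

    def test_single_walker_carries_unit_weight(self):
        (w,) = initialize([np.array([0.0])], 1)
        assert w.weight == 1.0 and w.history == "U"

    @pytest.mark.parametrize("n,c", [(3, 5), (7, 2), (1, 1)])
    def test_weights_sum_to_one(self, n, c):
        walkers = initialize([np.array([float(i)]) for i in range(n)], c)
        assert abs(sum(w.weight for w in walkers) - 1.0) < 1e-15

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            initialize([], 4)


class TestSplitMerge:
    def test_even_three_way_split(self):
        children = split_walker(_walker(0, 0.3, 1.0), 3)
        assert len(children) == 3
        assert all(np.isclose(c.weight, 0.1) for c in children)

    def test_k1_is_identity(self):
        (c,) = split_walker(_walker(0, 0.4, 1.0), 1)
        assert c.weight == 0.4

    def test_split_conserves_weight_exactly(self):
        w = _walker(0, 1 / 3, 1.0)
        assert np.isclose(sum(c.weight for c in split_walker(w, 7)), w.weight)

    def test_split_rejects_zero(self):
        with pytest.raises(ValueError):
            split_walker(_walker(0, 0.5, 1.0), 0)

    def test_merge_conserves_weight(self):
        rng = np.random.default_rng(0)
        m = merge_pair(_walker(0, 0.2, 1.0), _walker(1, 0.3, 2.0), rng)
        assert np.isclose(m.weight, 0.5)

    def test_merge_survivor_frequency_matches_weights(self):
        """P(survivor = walker 1) = 0.2/0.5 = 0.4 over many seeded merges."""
        rng = np.random.default_rng(1)
        n = 10_000
        wins = sum(
            merge_pair(_walker(0, 0.2, 1.0), _walker(1, 0.3, 2.0), rng).state[0] == 1.0
            for _ in range(n)
        )
        assert abs(wins / n - 0.4) < 0.015

    def test_merge_rejects_cross_bin_and_zero_weight(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            merge_pair(_walker(0, 0.2, 1.0, bin_=0), _walker(1, 0.3, 2.0, bin_=1), rng)
        bad = dataclasses.replace(_walker(1, 0.1, 2.0))
        bad.weight = 0.0
        with pytest.raises(ValueError):
            merge_pair(_walker(0, 0.2, 1.0), bad, rng)


class TestResample:
    def test_lone_walker_reaches_bin_target(self):
        out = resample(
            [_walker(0, 0.5, 1.0)],
            LINE_SCHEME,
            ResamplePolicy(mode="per_bin_target", target=12),
            np.random.default_rng(3),
        )
        assert len(out) == 12
        assert np.isclose(sum(w.weight for w in out), 0.5)

    def test_overfull_bin_merges_down_to_target(self):
        rng = np.random.default_rng(4)
        walkers = [_walker(i, (i + 1) / 210.0, 1.0) for i in range(20)]
        out = resample(
            walkers, LINE_SCHEME, ResamplePolicy(mode="per_bin_target", target=12), rng
        )
        assert len(out) == 12
        assert np.isclose(sum(w.weight for w in out), sum(w.weight for w in walkers))

    @staticmethod
    def _binned(xs):
        walkers = [_walker(i, 1.0 / len(xs), x) for i, x in enumerate(xs)]
        bins = LINE_SCHEME.assign(np.array([[x] for x in xs]))
        for w, b in zip(walkers, bins):
            w.bin = int(b)
        return walkers

    def test_fixed_total_count_is_exact(self):
        rng = np.random.default_rng(5)
        walkers = self._binned([1.0, 5.0, 12.0, 25.0])
        out = resample(
            walkers, LINE_SCHEME, ResamplePolicy(mode="fixed_total", target=30), rng
        )
        assert len(out) == 30
        assert abs(sum(w.weight for w in out) - 1.0) < 1e-12

    def test_fixed_total_below_occupancy_is_an_error(self):
        walkers = self._binned([1.0, 5.0, 12.0, 25.0])
        with pytest.raises(ValueError, match="occupied"):
            resample(
                walkers,
                LINE_SCHEME,
                ResamplePolicy(mode="fixed_total", target=2),
                np.random.default_rng(6),
            )

    def test_resampling_preserves_weighted_mean_observable(self):
        """Splits preserve weighted averages exactly; merges do so in
        expectation.  Averaged over many seeded resamplings the weighted
        mean of the walker coordinate must match the input within 3 SE."""
        walkers = [_walker(i, w, x) for i, (w, x) in enumerate(
            [(0.05, 1.0), (0.1, 2.0), (0.25, 3.0), (0.4, 4.0), (0.2, 5.0)]
        )]
        target_mean = sum(w.weight * w.state[0] for w in walkers)
        scheme = BinScheme(edges=np.array([0.0]))  # one bin holds everything
        policy = ResamplePolicy(mode="per_bin_target", target=3)
        rng = np.random.default_rng(7)
        means = np.array([
            sum(w.weight * w.state[0] for w in resample(walkers, scheme, policy, rng))
            for _ in range(10_000)
        ])
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - target_mean) < 3 * se


def _line_defs():
    return RegionStateDefs(
        regions={
            "unbound": lambda pc: pc[:, 0] < 5.0,
            "bound": lambda pc: pc[:, 0] >= 20.0,
        }
    )


class TestRunIteration:
    def test_identity_propagator_keeps_pcoords_and_enforces_targets(self):
        walkers = initialize([np.array([1.0]), np.array([12.0])], 2)
        for w in walkers:
            w.state_label = "none"
        out, rec = run_iteration(
            walkers,
            IdentityPropagator(),
            5,
            LINE_SCHEME,
            ResamplePolicy(mode="per_bin_target", target=4),
            np.random.default_rng(8),
        )
        assert np.allclose(rec.pcoords[:, 0], [1.0, 1.0, 12.0, 12.0])
        assert rec.arrivals == []
        assert len(out) == 8
        assert abs(rec.total_weight - 1.0) < 1e-12

    def test_weight_is_conserved_in_both_modes(self):
        defs = _line_defs()
        for recycle in (False, True):
            walkers = initialize([np.array([1.0]), np.array([3.0])], 3)
            out, rec = run_iteration(
                walkers,
                IdentityPropagator(),
                1,
                LINE_SCHEME,
                ResamplePolicy(mode="per_bin_target", target=3, recycle=recycle),
                np.random.default_rng(9),
                state_defs=defs,
                initial_pool=[np.array([1.0])],
            )
            assert abs(sum(w.weight for w in out) - 1.0) < 1e-12

    def test_bound_crossing_contributes_weight_exactly_once(self):
        """A scripted walker stepping into the bound state registers one
        arrival carrying its full weight."""
        defs = _line_defs()
        walkers = initialize([np.array([1.0])], 1)
        walkers[0].state_label = "unbound"
        prop = ScriptedPropagator([[[25.0]], [[25.0]]])
        out, rec = run_iteration(
            walkers,
            prop,
            1,
            LINE_SCHEME,
            ResamplePolicy(mode="per_bin_target", target=1),
            np.random.default_rng(10),
            state_defs=defs,
        )
        assert rec.arrivals == [(0, "bound", 1.0, "unbound", "U")]
        # second iteration: still bound, no new arrival
        out2, rec2 = run_iteration(
            out,
            prop,
            1,
            LINE_SCHEME,
            ResamplePolicy(mode="per_bin_target", target=1),
            np.random.default_rng(11),
            state_defs=defs,
        )
        assert rec2.arrivals == []

    def test_recycling_restarts_walker_from_pool_with_same_weight(self):
        defs = _line_defs()
        walkers = initialize([np.array([1.0])], 1)
        walkers[0].state_label = "unbound"
        prop = ScriptedPropagator([[[25.0]]])
        out, rec = run_iteration(
            walkers,
            prop,
            1,
            LINE_SCHEME,
            ResamplePolicy(mode="per_bin_target", target=1, recycle=True),
            np.random.default_rng(12),
            state_defs=defs,
            initial_pool=[np.array([2.0])],
        )
        assert np.isclose(rec.recycled_weight, 1.0)
        assert rec.arrivals[0][1] == "bound"
        assert out[0].state[0] == 2.0 and out[0].history == "U"
        assert np.isclose(out[0].weight, 1.0)


class TestSimulation:
    def _sim(self, seed=13, target=4):
        return WESimulation(
            IdentityPropagator(),
            LINE_SCHEME,
            ResamplePolicy(mode="per_bin_target", target=target),
            tau_steps=1,
            tau=1.0,
            seed=seed,
            initial_states=[np.array([1.0]), np.array([12.0])],
            copies_per_state=2,
        )

    def test_weight_conserved_over_many_iterations(self):
        sim = self._sim()
        sim.run(50)
        for rec in sim.records:
            assert abs(rec.total_weight - 1.0) < 1e-12

    def test_runs_are_reproducible_from_the_seed(self):
        a, b = self._sim(seed=99), self._sim(seed=99)
        a.run(10)
        b.run(10)
        for ra, rb in zip(a.records, b.records):
            assert np.array_equal(ra.weights, rb.weights)
            assert np.array_equal(ra.pcoords, rb.pcoords)
            assert np.array_equal(ra.parent_idx, rb.parent_idx)

    def test_every_lineage_traces_back_to_an_initial_walker(self):
        sim = self._sim()
        sim.run(20)
        recs = sim.records
        for final_idx in range(recs[-1].n_segments):
            t, idx = len(recs) - 1, final_idx
            while True:
                parent = int(recs[t].parent_idx[idx])
                if t == 0:
                    assert parent == -1
                    break
                assert parent >= 0
                t, idx = t - 1, parent
            assert recs[0].roots[final_idx if t == len(recs) - 1 else idx] >= 0

    def test_switch_scheme_keeps_weights_and_count(self):
        sim = WESimulation(
            IdentityPropagator(),
            binding_scheme(1),
            ResamplePolicy(mode="fixed_total", target=20),
            tau_steps=1,
            tau=1.0,
            seed=14,
            initial_states=[np.array([1.0 + i, 30.0 + i]) for i in range(10)],
            copies_per_state=2,
        )
        sim.run(2)
        before = sorted(w.weight for w in sim.walkers)
        n_before = len(sim.walkers)
        sim.switch_scheme(binding_scheme(2))
        assert sorted(w.weight for w in sim.walkers) == before
        assert len(sim.walkers) == n_before

    def test_stage_switch_shifts_effort_into_contact_region(self):
        """Collapsing the non-contact RMSD cells under a fixed total must
        strictly increase the walker count in the contact region."""
        # 2 walkers in contact cells, 18 spread over non-contact RMSD cells
        states = [np.array([1.0, 0.6]), np.array([2.0, 3.0])] + [
            np.array([8.0, 5.0 + 2 * i]) for i in range(18)
        ]
        sim = WESimulation(
            IdentityPropagator(),
            binding_scheme(1),
            ResamplePolicy(mode="fixed_total", target=20),
            tau_steps=1,
            tau=1.0,
            seed=15,
            initial_states=states,
            copies_per_state=1,
        )
        sim.run(1)
        contact_before = sum(1 for w in sim.walkers if w.pcoord[0] < 5.0)
        sim.switch_scheme(binding_scheme(2))
        sim.run(1)
        contact_after = sum(1 for w in sim.walkers if w.pcoord[0] < 5.0)
        assert contact_after > contact_before
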