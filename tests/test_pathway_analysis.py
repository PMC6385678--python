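import itertools

import numpy as np
import pytest
from scipy.spatial.distance import canberra as scipy_canberra

from conftest import make_linear_records
from wepath.pathway_analysis import (
    TransitionPath,
    build_csn,
    canberra,
    event_durations,
    extract_tpe,
    histogram_entropy,
    kcenters,
    spherical_entry_map,
    tpe_frame_weights,
    weighted_contact_probabilities,
)
from wepath.we_engine import IterationRecord


def _record(iteration, labels, parents, weights=None, arrivals=(), roots=None):
    n = len(labels)
    w = np.asarray(weights if weights is not None else np.full(n, 1.0 / n))
    return IterationRecord(
        iteration=iteration,
        weights=w,
        pcoords=np.zeros((n, 2)),
        bins=np.zeros(n, dtype=int),
        parent_idx=np.asarray(parents, dtype=int),
        state_labels=np.asarray(labels, dtype=object),
        history=np.full(n, "U", dtype=object),
        roots=np.asarray(roots if roots is not None else np.zeros(n), dtype=int),
        recycled_flags=np.zeros(n, dtype=bool),
        arrivals=list(arrivals),
        recycled_weight=0.0,
        post_weights=w,
        post_parent_idx=np.arange(n),
        dyn=None,
    )


class TestExtractTpe:
    def test_direct_path_collects_intermediate_and_bound_frames(self, binding_defs):
        recs = make_linear_records(["unbound", "encounter", "bound"])
        (path,) = extract_tpe(recs, binding_defs, tau=20.0)
        assert path.frames == [(1, 0), (2, 0)]
        assert path.encounter_flags == [True, False]
        assert path.duration == 40.0

    def test_path_starts_after_last_unbound_exit(self, binding_defs):
        recs = make_linear_records(
            ["unbound", "encounter", "unbound", "encounter", "bound"]
        )
        (path,) = extract_tpe(recs, binding_defs, tau=20.0)
        assert path.frames == [(3, 0), (4, 0)]

    def test_unproductive_lineage_contributes_nothing(self, binding_defs):
        recs = make_linear_records(["unbound", "encounter", "none", "unbound"])
        assert extract_tpe(recs, binding_defs, tau=20.0) == []

    def test_shared_ancestor_frame_sums_child_weights(self, binding_defs):
        """Two bound arrivals descending from one encounter frame give that
        frame the summed arrival weight."""
        recs = [
            _record(1, ["encounter"], [-1], [1.0]),
            _record(
                2,
                ["bound", "bound"],
                [0, 0],
                [0.3, 0.2],
                arrivals=[
                    (0, "bound", 0.3, "encounter", "U"),
                    (1, "bound", 0.2, "encounter", "U"),
                ],
            ),
        ]
        paths = extract_tpe(recs, binding_defs, tau=1.0)
        assert len(paths) == 2
        fw = tpe_frame_weights(paths)
        assert np.isclose(fw[(1, 0)], 0.5)
        assert np.isclose(fw[(2, 0)], 0.3)
        assert np.isclose(fw[(2, 1)], 0.2)


class TestEventDurations:
    def test_single_path_duration_arithmetic(self):
        p = TransitionPath(frames=[(1, 0)] * 5, weight=1.0, root=0, tau=20.0)
        stats = event_durations([p])
        assert p.duration == 100.0
        assert np.isclose(stats.hist.sum(), 1.0)

    def test_histogram_mass_equals_total_tpe_weight(self):
        paths = [
            TransitionPath(frames=[(1, 0)] * n, weight=w, root=0, tau=20.0)
            for n, w in [(2, 0.2), (2, 0.3), (5, 0.4)]
        ]
        stats = event_durations(paths)
        assert np.isclose(stats.hist.sum(), 0.9)

    def test_mode_of_hand_built_fixture(self):
        paths = [
            TransitionPath(frames=[(1, 0)] * n, weight=w, root=0, tau=20.0)
            for n, w in [(2, 0.2), (2, 0.3), (5, 0.4)]
        ]
        stats = event_durations(paths)
        # durations 40, 40, 100; mass 0.5 in [40, 60) beats 0.4 in [100, 120)
        assert stats.mode == 50.0

    def test_empty_tpe_rejected(self):
        with pytest.raises(ValueError):
            event_durations([])


class TestContactProbabilities:
    def test_always_and_never_in_contact(self):
        d = np.array([[1.0, 9.0], [2.0, 8.0], [3.0, 7.0]])
        probs = weighted_contact_probabilities(d, np.array([0.2, 0.3, 0.5]), 4.5)
        assert np.allclose(probs, [1.0, 0.0])

    def test_hand_summed_weighted_fixture(self):
        d = np.array([[1.0], [5.0], [2.0]])
        probs = weighted_contact_probabilities(d, np.array([0.2, 0.3, 0.5]), 4.5)
        assert np.isclose(probs[0], 0.7 / 1.0)

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            weighted_contact_probabilities(np.ones((2, 2)), np.ones(2), 0.0)


class TestHistogramEntropy:
    def test_single_cell_gives_zero(self):
        assert histogram_entropy(np.full(100, 1.23), n_bins=20) == 0.0

    @pytest.mark.parametrize("k", [2, 5, 16])
    def test_uniform_k_cells_give_ln_k_exactly(self, k):
        samples = np.arange(k, dtype=float)
        assert np.isclose(histogram_entropy(samples, n_bins=k), np.log(k), atol=1e-12)

    def test_two_cell_weighted_value(self):
        s = histogram_entropy(np.array([0.0, 1.0]), np.array([0.25, 0.75]), n_bins=2)
        assert np.isclose(s, 0.5623, atol=2e-4)

    def test_bin_scan_is_stable_for_smooth_distributions(self):
        from wepath.pathway_analysis import entropy_bin_scan

        rng = np.random.default_rng(9)
        x = rng.uniform(0, 1, 5000)
        df = entropy_bin_scan(x, bin_counts=range(15, 36, 5))
        # uniform data: entropy tracks ln(n_bins) closely at every resolution
        assert np.allclose(df["entropy_R"], np.log(df["n_bins"]), atol=0.05)

    def test_invariant_under_permutation_and_weight_rescaling(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 2 * np.pi, size=(500, 2))
        w = rng.random(500)
        base = histogram_entropy(x, w, n_bins=15)
        perm = rng.permutation(500)
        assert np.isclose(histogram_entropy(x[perm], w[perm], 15), base)
        assert np.isclose(histogram_entropy(x, 7.0 * w, 15), base)


class TestCanberra:
    def test_identical_vectors(self):
        assert canberra(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0

    def test_orthogonal_unit_vectors(self):
        assert canberra(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 2.0

    def test_symmetric_and_matches_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            u, v = rng.normal(size=(2, 6))
            assert np.isclose(canberra(u, v), canberra(v, u))
            assert np.isclose(canberra(u, v), scipy_canberra(u, v))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            canberra(np.ones(3), np.ones(4))


class TestKCenters:
    def test_k_equals_n_covers_exactly(self):
        X = np.random.default_rng(2).normal(size=(6, 2))
        centers, assign, radius = kcenters(X, 6, metric="euclidean")
        assert radius == 0.0
        assert sorted(centers) == list(range(6))

    def test_k1_center_is_the_seed(self):
        X = np.random.default_rng(3).normal(size=(10, 3))
        centers, assign, radius = kcenters(X, 1, metric="euclidean", seed_index=4)
        assert centers.tolist() == [4]
        d = np.linalg.norm(X - X[4], axis=1)
        assert np.isclose(radius, d.max())
        assert np.all(assign == 0)

    def test_greedy_is_within_twice_the_exhaustive_optimum(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(size=(8, 2))
        from scipy.spatial.distance import cdist

        D = cdist(X, X)
        for k in (2, 3):
            opt = min(
                D[np.ix_(range(8), subset)].min(axis=1).max()
                for subset in itertools.combinations(range(8), k)
            )
            for seed in range(8):
                _, _, radius = kcenters(X, k, metric="euclidean", seed_index=seed)
                assert radius <= 2 * opt + 1e-12

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kcenters(np.zeros((3, 2)), 4)


class TestBuildCsn:
    def test_node_weights_conserve_frame_weights(self):
        ids = np.array([0, 0, 1, 2, 1])
        w = np.array([0.1, 0.2, 0.3, 0.25, 0.15])
        g = build_csn(ids, w, sequences=[np.arange(5)])
        assert np.isclose(sum(d["weight"] for _, d in g.nodes(data=True)), w.sum())

    def test_single_cluster_has_no_edges(self):
        g = build_csn(np.zeros(4, dtype=int), np.ones(4), sequences=[np.arange(4)])
        assert g.number_of_edges() == 0

    def test_scripted_sequence_matches_hand_enumerated_edges(self):
        ids = np.array([0, 0, 1, 2])
        w = np.array([0.4, 0.1, 0.3, 0.2])
        g = build_csn(ids, w, sequences=[np.arange(4)], seq_weights=np.array([0.2]))
        assert set(g.edges()) == {(0, 1), (1, 2)}
        assert np.isclose(g[0][1]["weight"], 0.2)
        # weighted property average: cluster 0 holds frames 0, 1
        g2 = build_csn(ids, w, sequences=[np.arange(4)],
                       properties={"x": np.array([1.0, 6.0, 0.0, 0.0])})
        assert np.isclose(g2.nodes[0]["x"], (0.4 * 1.0 + 0.1 * 6.0) / 0.5)

    def test_property_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_csn(np.zeros(3, dtype=int), np.ones(3), [np.arange(3)],
                      properties={"x": np.ones(2)})


class TestSphericalEntryMap:
    def test_polar_entries_occupy_one_cell_with_unit_mass(self):
        d = np.tile([0.0, 0.0, 1.0], (50, 1))
        df = spherical_entry_map(d, n_bins=10)
        occupied = df[df["prob"] > 0]
        assert len(occupied) == 1
        assert np.isclose(occupied["prob"].iloc[0], 1.0)
        assert occupied["z_hi"].iloc[0] == 1.0

    def test_cell_masses_sum_to_one(self):
        rng = np.random.default_rng(5)
        d = rng.normal(size=(500, 3))
        df = spherical_entry_map(d, weights=rng.random(500), n_bins=30)
        assert np.isclose(df["prob"].sum(), 1.0)
        assert np.isclose(df["solid_angle"].sum(), 4 * np.pi)

    def test_uniform_directions_fill_cells_by_solid_angle(self):
        """For isotropic entries each cell's mass ~ its solid angle / 4pi,
        within 3 binomial standard errors."""
        rng = np.random.default_rng(6)
        n = 100_000
        d = rng.normal(size=(n, 3))
        df = spherical_entry_map(d, n_bins=12)
        p = df["solid_angle"].to_numpy() / (4 * np.pi)
        se = np.sqrt(p * (1 - p) / n)
        z = np.abs(df["prob"].to_numpy() - p) / se
        assert z.max() < 3.0

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            spherical_entry_map(np.array([[0.0, 0.0, 0.0]]))
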