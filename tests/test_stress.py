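"""Node-stress structuring: ranking, Pareto bins, bands, feature matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stressfeat import (
    FeatureMatrix,
    NodeStresses,
    NodeSubsetSpec,
    StressField,
    build_feature_matrix,
    pareto_bins,
    percentile_bands,
    rank_nodes,
    select_top_k,
    thin_ranks,
)
from stressfeat.errors import ValidationError
from stressfeat.stress import ranked_stresses


def _field(cond, stresses_by_bone, sample_id=0):
    bones = {
        b: NodeStresses(np.arange(len(s)), np.asarray(s, dtype=float))
        for b, s in stresses_by_bone.items()
    }
    return StressField(cond, sample_id, bones)


class TestRankNodes:
    def test_descending_input_is_identity(self):
        bone = NodeStresses(np.arange(5), np.array([9.0, 7.0, 5.0, 3.0, 1.0]))
        np.testing.assert_array_equal(rank_nodes(bone), np.arange(5))

    def test_tie_broken_by_node_id(self):
        bone = NodeStresses(np.array([7, 3]), np.array([2.0, 2.0]))
        np.testing.assert_array_equal(rank_nodes(bone), [3, 7])

    def test_matches_sort_oracle(self, rng):
        stresses = rng.lognormal(size=1000)
        bone = NodeStresses(np.arange(1000), stresses)
        oracle = [i for _, i in sorted(zip(-stresses, range(1000)))]  # brute force
        np.testing.assert_array_equal(rank_nodes(bone), oracle)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            NodeStresses(np.array([], dtype=int), np.array([]))


class TestSelectTopK:
    def test_mode_all_returns_input(self):
        f = _field("A", {"B1": [3.0, 1.0, 2.0]})
        assert select_top_k(f, NodeSubsetSpec(mode="all")) is f

    def test_top_k_definition(self, rng):
        stresses = rng.lognormal(sigma=1.4, size=3300)
        f = _field("A", {"B1": stresses})
        sub = select_top_k(f, NodeSubsetSpec("top_k", 200))
        kept = sub.bones["B1"].stresses
        assert kept.size == 200
        excluded_max = np.sort(stresses)[::-1][200:].max()
        assert kept.min() >= excluded_max

    def test_matches_sort_and_slice_oracle(self, rng):
        f = _field("A", {f"B{i}": rng.lognormal(size=500) for i in range(3)})
        sub = select_top_k(f, NodeSubsetSpec("top_k", 50))
        for b, bone in f.bones.items():
            oracle = np.sort(bone.stresses)[::-1][:50]  # brute force
            np.testing.assert_allclose(
                np.sort(sub.bones[b].stresses)[::-1], oracle
            )
            # node identity preserved
            assert set(sub.bones[b].node_ids) <= set(bone.node_ids)

    def test_subset_nesting(self, rng):
        f = _field("A", {"B1": rng.lognormal(sigma=1.4, size=3300)})
        kept = [
            set(select_top_k(f, NodeSubsetSpec("top_k", k)).bones["B1"].node_ids)
            for k in (200, 500, 1000, 2000)
        ]
        all_ids = set(f.bones["B1"].node_ids)
        assert kept[0] <= kept[1] <= kept[2] <= kept[3] <= all_ids

    def test_invalid_k_rejected(self):
        with pytest.raises(ValidationError):
            NodeSubsetSpec("top_k", 0)


class TestParetoBins:
    def test_uniform_grid_one_per_bin(self):
        dist = pareto_bins(np.arange(30.0, 0.0, -1.0), n_bins=30)
        np.testing.assert_array_equal(dist.counts, np.ones(30, dtype=int))
        assert dist.edges[0] == 30.0 and dist.edges[-1] == 1.0

    def test_constant_vector_degenerate_bin(self):
        dist = pareto_bins(np.full(17, 4.2))
        assert dist.n_bins == 1
        assert dist.counts[0] == 17
        np.testing.assert_array_equal(dist.edges, [4.2, 4.2])

    def test_matches_histogram_oracle_and_conserves(self, rng):
        values = rng.lognormal(sigma=1.4, size=1000)
        dist = pareto_bins(values, n_bins=30)
        assert dist.counts.sum() == 1000
        oracle, _ = np.histogram(values, bins=np.linspace(values.min(), values.max(), 31))
        np.testing.assert_array_equal(dist.counts, oracle[::-1])
        assert np.all(np.diff(dist.edges) < 0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            pareto_bins(np.array([]))
        with pytest.raises(ValidationError):
            pareto_bins(np.ones(5), n_bins=0)


class TestPercentileBands:
    def test_exact_grid(self):
        bands = percentile_bands(np.arange(100.0, 0.0, -1.0))
        assert bands["first_5"] == (96.0, 100.0)
        assert bands["last_50"] == (1.0, 50.0)
        assert bands["last_80"] == (1.0, 80.0)
        assert bands["last_95"] == (1.0, 95.0)

    def test_constant_vector(self):
        bands = percentile_bands(np.full(40, 3.3))
        assert all(b == (3.3, 3.3) for b in bands.values())

    def test_matches_rank_slice_oracle(self, rng):
        values = rng.lognormal(size=777)
        bands = percentile_bands(values)
        s = np.sort(values)[::-1]  # brute-force rank slices
        n = s.size
        for f in (0.5, 0.8, 0.9, 0.95):
            lo, hi = bands[f"last_{int(round(f * 100))}"]
            assert lo == s[-1]
            assert hi == s[int(np.ceil(round((1 - f) * n, 6)))]
        m = int(np.ceil(round(0.05 * n, 6)))
        assert bands["first_5"] == (s[m - 1], s[0])

    def test_band_membership_partitions_nodes(self, rng):
        """First-5% and last-95% bands jointly cover the node set."""
        values = rng.lognormal(size=200)
        bands = percentile_bands(values)
        in_first = values >= bands["first_5"][0]
        in_last95 = values <= bands["last_95"][1]
        assert np.all(in_first | in_last95)


class TestFeatureMatrix:
    def test_rank_aligned_counts(self, rng):
        fa = _field("A", {"B1": rng.lognormal(size=10), "B2": rng.lognormal(size=10)})
        fb = _field("B", {"B1": rng.lognormal(size=10), "B2": rng.lognormal(size=10)})
        fm = build_feature_matrix([fa], [fb], NodeSubsetSpec("top_k", 3),
                                  summary="rank_aligned")
        assert fm.X.shape == (6, 2)
        assert (fm.y == "A").sum() == 3 and (fm.y == "B").sum() == 3

    def test_max_summary(self, rng):
        fa = _field("A", {"B1": rng.lognormal(size=20), "B2": rng.lognormal(size=20)})
        fb = _field("B", {"B1": rng.lognormal(size=20), "B2": rng.lognormal(size=20)})
        fm = build_feature_matrix([fa], [fb], summary="max")
        assert fm.X.shape == (2, 2)
        assert fm.X.loc[0, "B1"] == fa.bones["B1"].stresses.max()
        assert fm.X.loc[1, "B2"] == fb.bones["B2"].stresses.max()

    def test_rank_aligned_cells_match_sort_oracle(self, rng):
        fa = _field("A", {f"B{i}": rng.lognormal(size=50) for i in range(3)})
        fb = _field("B", {f"B{i}": rng.lognormal(size=50) for i in range(3)})
        fm = build_feature_matrix([fa], [fb], NodeSubsetSpec("top_k", 10),
                                  summary="rank_aligned")
        for r in range(10):
            for bi, b in enumerate(fm.bone_labels):
                oracle = np.sort(fa.bones[b].stresses)[::-1][r]
                assert fm.X.iloc[r, bi] == oracle

    def test_sampled_preserves_per_bone_marginals(self, rng):
        fa = _field("A", {"B1": rng.lognormal(size=30), "B2": rng.lognormal(size=30)})
        fb = _field("B", {"B1": rng.lognormal(size=30), "B2": rng.lognormal(size=30)})
        fm = build_feature_matrix([fa], [fb], NodeSubsetSpec("top_k", 10),
                                  summary="sampled", seed=5)
        for b in ("B1", "B2"):
            top = np.sort(fa.bones[b].stresses)[::-1][:10]
            col = fm.X.loc[fm.y == "A", b].to_numpy()
            np.testing.assert_allclose(np.sort(col), np.sort(top))

    def test_input_row_order_invariance(self, rng):
        stresses = rng.lognormal(size=40)
        perm = rng.permutation(40)
        fa1 = _field("A", {"B1": stresses})
        fa1_shuffled = StressField(
            "A", 0, {"B1": NodeStresses(np.arange(40)[perm], stresses[perm])}
        )
        fb = _field("B", {"B1": rng.lognormal(size=40)})
        m1 = build_feature_matrix([fa1], [fb], NodeSubsetSpec("top_k", 10),
                                  summary="rank_aligned")
        m2 = build_feature_matrix([fa1_shuffled], [fb], NodeSubsetSpec("top_k", 10),
                                  summary="rank_aligned")
        pd.testing.assert_frame_equal(m1.X, m2.X)

    def test_mismatched_bone_sets_rejected(self, rng):
        fa = _field("A", {"B1": rng.lognormal(size=5)})
        fb = _field("B", {"B2": rng.lognormal(size=5)})
        with pytest.raises(ValidationError):
            build_feature_matrix([fa], [fb])

    def test_balanced_labels_enforced(self):
        X = pd.DataFrame({"B1": [1.0, 2.0, 3.0]})
        with pytest.raises(ValidationError):
            FeatureMatrix(X, np.array(["A", "A", "B"]))

    def test_thin_ranks_even_and_deterministic(self, rng):
        fa = _field("A", {"B1": rng.lognormal(size=100)})
        fb = _field("B", {"B1": rng.lognormal(size=100)})
        fm = build_feature_matrix([fa], [fb], summary="rank_aligned")
        thin = thin_ranks(fm, 10)
        assert thin.n_instances == 20
        assert (thin.y == "A").sum() == 10
        thin2 = thin_ranks(fm, 10)
        pd.testing.assert_frame_equal(thin.X, thin2.X)
        # small matrices pass through untouched
        assert thin_ranks(fm, 100) is fm


@given(st.integers(1, 40), st.integers(1, 10))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_pareto_conservation_property(n_values, n_bins):
    rng = np.random.default_rng(n_values * 100 + n_bins)
    values = rng.lognormal(size=n_values)
    dist = pareto_bins(values, n_bins=n_bins)
    assert dist.counts.sum() == n_values
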