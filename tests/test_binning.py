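"""Distance matrices, dendrograms, bin extraction and truth evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from mcminer import binning as B
from mcminer import composition as C
from mcminer import synthetic as S
from mcminer.composition import N_TETRA_CLASSES, TetraProfile


def toy_profile(*coords):
    """TetraProfile whose leading coordinates are set, rest zero."""
    v = np.zeros(N_TETRA_CLASSES)
    v[: len(coords)] = coords
    return TetraProfile(vector=v, n_counted=1)


def rescan_agglomerate(D0, linkage_name):
    """Independent O(n^3) oracle: re-scan all cluster pairs each step."""
    n = D0.shape[0]
    members = {i: [i] for i in range(n)}
    next_id = n
    merges = []
    while len(members) > 1:
        best = None
        for u in sorted(members):
            for v in sorted(members):
                if v <= u:
                    continue
                block = D0[np.ix_(members[u], members[v])]
                d = block.mean() if linkage_name == "average" else block.max()
                sig = (
                    min(min(members[u]), min(members[v])),
                    max(min(members[u]), min(members[v])),
                )
                if best is None or d < best[0] - 1e-15 or (
                    abs(d - best[0]) <= 1e-15 and sig < best[3]
                ):
                    best = (d, u, v, sig)
        d, u, v, _ = best
        merged = members.pop(u) + members.pop(v)
        merges.append((u, v, d, len(merged)))
        members[next_id] = merged
        next_id += 1
    return merges


class TestPairwiseDistance:
    def test_identical_profiles_have_zero_distance(self):
        p = toy_profile(0.5, 0.5)
        d = B.pairwise_distance([p, p])
        assert d.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_unit_vectors_closed_form(self):
        d = B.pairwise_distance([toy_profile(0, 1), toy_profile(1, 0)])
        assert d.matrix[0, 1] == pytest.approx(np.sqrt(2))

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(0)
        profs = [
            TetraProfile(vector=rng.random(N_TETRA_CLASSES), n_counted=1)
            for _ in range(5)
        ]
        d = B.pairwise_distance(profs)
        for i in range(5):
            for j in range(5):
                naive = np.sqrt(np.sum((profs[i].vector - profs[j].vector) ** 2))
                assert d.matrix[i, j] == pytest.approx(naive, abs=1e-10)

    def test_rejects_single_profile(self):
        with pytest.raises(ValueError):
            B.pairwise_distance([toy_profile(1)])


class TestBuildTree:
    def test_two_items_single_merge_at_their_distance(self):
        d = B.DistanceMatrix(["a", "b"], np.array([[0.0, 3.0], [3.0, 0.0]]))
        tree = B.build_tree(d)
        assert tree.merges == [(0, 1, 3.0, 2)]

    @pytest.mark.parametrize("linkage_name", ["average", "complete"])
    @pytest.mark.parametrize("n", [5, 8, 10])
    def test_merge_sequence_matches_rescan_oracle(self, linkage_name, n):
        rng = np.random.default_rng(n)
        X = rng.random((n, 4))
        D0 = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(D0, 0.0)
        tree = B.build_tree(
            B.DistanceMatrix([f"i{k}" for k in range(n)], D0), linkage=linkage_name
        )
        oracle = rescan_agglomerate(D0, linkage_name)
        assert len(tree.merges) == len(oracle)
        for got, want in zip(tree.merges, oracle):
            assert got[0] == want[0] and got[1] == want[1]
            assert got[2] == pytest.approx(want[2])
            assert got[3] == want[3]

    @pytest.mark.parametrize("linkage_name", ["average", "complete", "ward"])
    def test_heights_non_decreasing(self, linkage_name):
        rng = np.random.default_rng(1)
        X = rng.random((12, 3))
        D0 = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(D0, 0.0)
        tree = B.build_tree(
            B.DistanceMatrix([f"i{k}" for k in range(12)], D0), linkage=linkage_name
        )
        heights = [m[2] for m in tree.merges]
        assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))

    @pytest.mark.parametrize("linkage_name", ["average", "complete", "ward"])
    def test_flat_cuts_agree_with_scipy(self, linkage_name):
        """Independent cross-check: tie-free input, compare k-cut partitions."""
        rng = np.random.default_rng(7)
        X = rng.random((15, 3))
        D0 = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(D0, 0.0)
        ids = [f"i{k}" for k in range(15)]
        tree = B.build_tree(B.DistanceMatrix(ids, D0), linkage=linkage_name)
        Z = linkage(squareform(D0, checks=False), method=linkage_name)
        for k in (2, 3, 5):
            ours = {frozenset(c) for c in tree.cut(n_clusters=k)}
            labels = cut_tree(Z, n_clusters=k).ravel()
            theirs = {
                frozenset(np.array(ids)[labels == lab]) for lab in set(labels)
            }
            assert ours == theirs

    def test_rejects_asymmetric_matrix(self):
        with pytest.raises(ValueError):
            B.DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_newick_roundtrips_through_dendropy(self):
        import dendropy

        rng = np.random.default_rng(2)
        X = rng.random((6, 3))
        D0 = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(D0, 0.0)
        tree = B.build_tree(B.DistanceMatrix([f"t{k}" for k in range(6)], D0))
        t = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {leaf.taxon.label for leaf in t.leaf_node_iter()} == {
            f"t{k}" for k in range(6)
        }


class TestExtractBins:
    @pytest.fixture()
    def small_tree(self):
        rng = np.random.default_rng(3)
        X = rng.random((6, 2))
        D0 = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(D0, 0.0)
        return B.build_tree(B.DistanceMatrix([f"f{k}" for k in range(6)], D0))

    def test_k1_is_everything(self, small_tree):
        bins = B.extract_bins(small_tree, n_bins=1)
        assert len(bins) == 1
        assert sorted(bins[0].fragment_ids) == [f"f{k}" for k in range(6)]

    def test_partition_property(self, small_tree):
        for k in (2, 3, 6):
            bins = B.extract_bins(small_tree, n_bins=k)
            all_ids = [f for b in bins for f in b.fragment_ids]
            assert sorted(all_ids) == [f"f{k}" for k in range(6)]
            assert len(set(all_ids)) == len(all_ids)

    def test_manual_matches_automatic_cut(self, small_tree):
        auto = B.extract_bins(small_tree, n_bins=2)
        manual = B.extract_bins(small_tree, manual=[b.fragment_ids for b in auto])
        assert [sorted(b.fragment_ids) for b in manual] == [
            sorted(b.fragment_ids) for b in auto
        ]

    def test_manual_remainder_goes_to_unbinned(self, small_tree):
        bins = B.extract_bins(small_tree, manual=[["f0", "f1"]])
        assert bins[-1].bin_id == "unbinned"
        assert sorted(bins[-1].fragment_ids) == ["f2", "f3", "f4", "f5"]

    def test_overlapping_manual_lists_raise(self, small_tree):
        with pytest.raises(ValueError, match="overlap"):
            B.extract_bins(small_tree, manual=[["f0", "f1"], ["f1", "f2"]])


class TestBinCoherence:
    def meta(self, cov, gc=None):
        gc = gc or [0.5] * len(cov)
        return pd.DataFrame(
            {
                "contig_id": [f"c{k}" for k in range(len(cov))],
                "coverage": cov,
                "gc": gc,
                "length": [20_000] * len(cov),
            },
            index=[f"f{k}" for k in range(len(cov))],
        )

    def test_constant_coverage_cv_zero(self):
        b = B.Bin("b0", ["f0", "f1", "f2"])
        B.bin_coherence(b, self.meta([30, 30, 30]))
        assert b.coverage_cv == 0.0
        assert not b.flagged_incoherent

    def test_mixed_coverage_flagged(self):
        b = B.Bin("b0", ["f0", "f1"])
        B.bin_coherence(b, self.meta([10, 30]))
        assert b.coverage_cv == pytest.approx(np.sqrt(2) * 10 / 20)  # ~0.707
        assert b.flagged_incoherent

    def test_single_member_cv_zero(self):
        b = B.Bin("b0", ["f0"])
        B.bin_coherence(b, self.meta([42]))
        assert b.coverage_cv == 0.0

    def test_missing_metadata_raises(self):
        b = B.Bin("b0", ["f0", "zz"])
        with pytest.raises(KeyError):
            B.bin_coherence(b, self.meta([1]))


class TestEvaluateBinning:
    def test_perfect_binning(self):
        bins = [B.Bin("b0", ["f0", "f1"]), B.Bin("b1", ["f2"])]
        truth = {"f0": "A", "f1": "A", "f2": "B"}
        ev = B.evaluate_binning(bins, truth)
        assert ev.accuracy == 1.0
        assert all(v == 1.0 for v in ev.purity.values())
        assert all(v == 1.0 for v in ev.recall.values())

    def test_single_bin_two_sources_purity_half(self):
        bins = [B.Bin("b0", ["f0", "f1", "f2", "f3"])]
        truth = {"f0": "A", "f1": "A", "f2": "B", "f3": "B"}
        ev = B.evaluate_binning(bins, truth)
        assert ev.purity["b0"] == 0.5

    def test_random_assignment_near_chance(self):
        rng = np.random.default_rng(0)
        frags = [f"f{k}" for k in range(200)]
        truth = {f: f"S{k % 4}" for k, f in enumerate(frags)}
        assignment = rng.integers(0, 4, size=200)
        bins = [
            B.Bin(f"b{j}", [f for f, a in zip(frags, assignment) if a == j])
            for j in range(4)
        ]
        ev = B.evaluate_binning(bins, truth)
        assert ev.accuracy == pytest.approx(0.25, abs=0.08)


class TestPlantedRecovery:
    def test_trio_recovered_perfectly_at_k3(self, trio_fragments):
        frags, truth = trio_fragments
        assert all(
            sum(1 for f in truth.values() if f == g) >= 30 for g in set(truth.values())
        )
        profiles = [C.tetra_profile(f.sequence) for f in frags]
        dist = B.pairwise_distance(profiles, ids=[f.id for f in frags])
        tree = B.build_tree(dist, linkage="average")
        bins = B.extract_bins(tree, n_bins=3)
        ev = B.evaluate_binning(bins, truth)
        assert ev.accuracy >= 0.95
        assert all(p >= 0.95 for p in ev.purity.values())

    def test_accuracy_monotone_in_divergence(self):
        """More divergent compositions are never harder to separate."""
        accs = []
        for div in (0.1, 0.5, 1.0, 2.0):
            frags, truth = [], {}
            for i, gc in enumerate([0.45, 0.55, 0.65]):
                spec = S.GenomeSpec(
                    genome_id=f"D{i}", length_bp=200_000, gc_target=gc,
                    composition_divergence=div, seed=500 + i,
                )
                g = S.generate_genome(spec)
                for fr in C.fragment_sections(C.SequenceRecord(g.genome_id, g.sequence)):
                    frags.append(fr)
                    truth[fr.id] = g.genome_id
            profiles = [C.tetra_profile(f.sequence) for f in frags]
            dist = B.pairwise_distance(profiles, ids=[f.id for f in frags])
            bins = B.extract_bins(B.build_tree(dist), n_bins=3)
            accs.append(B.evaluate_binning(bins, truth).accuracy)
        assert all(b >= a - 0.05 for a, b in zip(accs, accs[1:]))
        assert accs[-1] >= 0.95
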