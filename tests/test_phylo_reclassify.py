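"""Profile MSA construction, NJ correctness and clade-based relabeling."""

import itertools

import dendropy
import numpy as np
import pytest

from kinominer.domain_scan import build_profile
from kinominer.phylo_reclassify import (
    MultipleAlignment,
    align_to_profile,
    bootstrap_support,
    distance_matrix,
    nj_tree,
    path_length_matrix,
    reclassify_by_clade,
    select_blocks,
    support_by_bipartition,
)

TOY = "ACDEFGHIKLMNPQR"  # 15-column toy domain


@pytest.fixture(scope="module")
def toy_profile():
    return build_profile((["a", "b"], [TOY, TOY]), calibrate=False)


class TestAlignToProfile:
    def test_identical_sequences_identical_rows(self, toy_profile):
        msa = align_to_profile([("s1", TOY), ("s2", TOY)], toy_profile)
        assert msa.rows[0] == msa.rows[1] == TOY

    def test_consensus_aligns_without_gaps(self, toy_profile):
        msa = align_to_profile([("s", TOY)], toy_profile)
        assert msa.rows[0] == TOY

    def test_internal_deletion_becomes_one_gap_column(self, toy_profile):
        deleted = TOY[:7] + TOY[8:]  # drop column 7 ('I')
        msa = align_to_profile([("s", deleted)], toy_profile)
        assert msa.rows[0] == TOY[:7] + "-" + TOY[8:]

    def test_unalignable_sequence_excluded_with_warning(self, toy_profile):
        with pytest.warns(UserWarning, match="excluded"):
            msa = align_to_profile([("good", TOY), ("bad", "WWWWWWWWWWWW")],
                                   toy_profile)
        assert msa.ids == ["good"]


class TestSelectBlocks:
    def test_occupancy_threshold(self):
        msa = MultipleAlignment(
            ids=["a", "b"], rows=["A-C", "AB-"])
        # occupancies 1.0, 0.5, 0.5
        kept = select_blocks(msa, min_occupancy=0.8)
        assert kept.rows == ["A", "A"]

    def test_example_pattern(self):
        rows = ["AAAA", "A-A-", "AA-A", "AAAA", "AAAA",
                "AAAA", "AAAA", "AAAA", "AAAA", "A--A"]
        msa = MultipleAlignment(ids=[f"s{i}" for i in range(10)], rows=rows)
        occ = msa.column_occupancy
        assert list(occ) == [1.0, 0.8, 0.8, 0.9]
        kept = select_blocks(msa, min_occupancy=0.85)
        assert kept.n_columns == 2

    def test_zero_threshold_clamps_and_drops_all_gap_columns(self):
        msa = MultipleAlignment(ids=["a", "b"], rows=["A-C", "A-C"])
        kept = select_blocks(msa, min_occupancy=0.0)
        assert kept.rows == ["AC", "AC"]

    def test_nothing_kept_raises(self):
        msa = MultipleAlignment(ids=["a", "b"], rows=["A-", "-A"])
        with pytest.raises(ValueError, match="occupancy"):
            select_blocks(msa, min_occupancy=0.9)


class TestDistanceMatrix:
    def test_identity_and_p_distance(self):
        msa = MultipleAlignment(
            ids=list("abc"),
            rows=["AAAAAAAAAA", "AAAAAAAAAA", "CAAAAAAAAA"])
        D = distance_matrix(msa, "p_distance")
        assert D[0, 1] == 0.0
        assert D[0, 2] == pytest.approx(0.1)

    def test_kimura_correction(self):
        msa = MultipleAlignment(
            ids=list("abc"),
            rows=["AAAAAAAAAA", "CAAAAAAAAA", "AAAAAAAAAA"])
        D = distance_matrix(msa, "kimura_protein")
        assert D[0, 1] == pytest.approx(-np.log(1 - 0.1 - 0.002))

    def test_saturation_capped_with_warning(self):
        msa = MultipleAlignment(
            ids=list("abc"),
            rows=["A" * 20, "C" * 20, "A" * 20])
        with pytest.warns(UserWarning, match="capping"):
            D = distance_matrix(msa, "kimura_protein", max_distance=7.0)
        assert D[0, 1] == 7.0

    def test_disjoint_rows_rejected(self):
        msa = MultipleAlignment(
            ids=list("abc"),
            rows=["AA---", "---AA", "AAAAA"])
        with pytest.raises(ValueError, match="comparable"):
            distance_matrix(msa)


def random_additive_tree(n, seed):
    """A random topology with positive branch lengths and its leaf distances."""
    rng = np.random.default_rng(seed)
    subs = [f"t{i}" for i in range(n)]
    while len(subs) > 2:
        i, j = sorted(rng.choice(len(subs), size=2, replace=False))
        li, lj = rng.uniform(0.2, 2.0, size=2)
        merged = f"({subs[i]}:{li:.6f},{subs[j]}:{lj:.6f})"
        subs = [s for k, s in enumerate(subs) if k not in (i, j)] + [merged]
    la, lb = rng.uniform(0.2, 2.0, size=2)
    newick = f"({subs[0]}:{la:.6f},{subs[1]}:{lb:.6f});"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    ids = [f"t{i}" for i in range(n)]
    pdm = tree.phylogenetic_distance_matrix()
    lookup = {t.label: t for t in tree.taxon_namespace}
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = pdm.patristic_distance(lookup[ids[i]],
                                                   lookup[ids[j]])
    return ids, D


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0.0, 5.0, 9.0],
                      [5.0, 0.0, 8.0],
                      [9.0, 8.0, 0.0]])
        tree = nj_tree(D, ["a", "b", "c"])
        lengths = {leaf.taxon.label: leaf.edge.length
                   for leaf in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx((5 + 9 - 8) / 2)
        assert lengths["b"] == pytest.approx((5 + 8 - 9) / 2)
        assert lengths["c"] == pytest.approx((9 + 8 - 5) / 2)

    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):3,(C:4,D:5)) -> additive distances
        ids = ["A", "B", "C", "D"]
        D = np.array([[0, 3, 8, 9],
                      [3, 0, 9, 10],
                      [8, 9, 0, 9],
                      [9, 10, 9, 0]], dtype=float)
        tree = nj_tree(D, ids)
        assert np.allclose(path_length_matrix(tree, ids), D, atol=1e-12)
        # A,B form a clade on one side of the internal edge
        parts = {frozenset(l.taxon.label for l in n.leaf_iter())
                 for n in tree.preorder_internal_node_iter()}
        assert frozenset("AB") in parts or frozenset("CD") in parts

    @pytest.mark.parametrize("n,seed", [(5, 1), (6, 2), (7, 3), (8, 4)])
    def test_additive_matrices_recovered_exactly(self, n, seed):
        ids, D = random_additive_tree(n, seed)
        tree = nj_tree(D, ids)
        assert np.allclose(path_length_matrix(tree, ids), D, atol=1e-9)

    def test_matches_scikit_bio_topology(self):
        # independent NJ implementation as an oracle on a noisy matrix
        import skbio
        rng = np.random.default_rng(9)
        ids, D = random_additive_tree(6, 11)
        noise = rng.uniform(0, 0.05, size=D.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0.0)
        Dn = D + noise
        mine = nj_tree(Dn, ids)
        theirs = skbio.tree.nj(skbio.DistanceMatrix(Dn, ids))
        from kinominer.phylo_reclassify import _bipartitions
        mine_parts = set(_bipartitions(mine))
        leaf_set = frozenset(ids)
        ref = min(ids)
        theirs_parts = set()
        for node in theirs.non_tips(include_self=False):
            below = frozenset(t.name for t in node.tips())
            side = below if ref not in below else leaf_set - below
            if 2 <= len(side) <= len(ids) - 2:
                theirs_parts.add(side)
        assert mine_parts == theirs_parts

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(D, list("abc"))


def saturated_msa(n_groups=4, per_group=3, length=60, seed=5, jitter=0):
    """Groups of near-identical rows with distinct group signatures.

    ``jitter`` mutates that many positions per row so all pairwise
    distances are distinct (no neighbor-joining ties).
    """
    rng = np.random.default_rng(seed)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    ids, rows = [], []
    for g in range(n_groups):
        base = "".join(rng.choice(aas, size=length))
        for v in range(per_group):
            row = list(base)
            for pos in rng.choice(length, size=jitter, replace=False):
                row[pos] = aas[rng.integers(20)]
            ids.append(f"g{g}_{v}")
            rows.append("".join(row))
    return MultipleAlignment(ids=ids, rows=rows)


class TestBootstrap:
    def test_single_replicate_supports_are_binary(self):
        msa = saturated_msa()
        tree = bootstrap_support(msa, B=1, seed=3)
        values = set(support_by_bipartition(tree).values())
        assert values <= {0.0, 100.0}

    def test_clean_signal_gives_full_support(self):
        msa = saturated_msa()
        tree = bootstrap_support(msa, B=100, seed=3)
        support = support_by_bipartition(tree)
        for g in range(4):
            clade = frozenset(f"g{g}_{v}" for v in range(3))
            if clade in support:  # canonical side may be the complement
                assert support[clade] == 100.0

    def test_fixed_seed_is_deterministic(self):
        msa = saturated_msa()
        a = support_by_bipartition(bootstrap_support(msa, B=30, seed=11))
        b = support_by_bipartition(bootstrap_support(msa, B=30, seed=11))
        assert a == b

    def test_invariant_to_leaf_order(self):
        # enough signal that bootstrap replicates never hit distance ties
        msa = saturated_msa(length=120, jitter=10)
        perm = np.random.default_rng(1).permutation(len(msa.ids))
        shuffled = MultipleAlignment(
            ids=[msa.ids[i] for i in perm],
            rows=[msa.rows[i] for i in perm])
        a = support_by_bipartition(bootstrap_support(msa, B=25, seed=7))
        b = support_by_bipartition(bootstrap_support(shuffled, B=25, seed=7))
        assert a == b


class TestReclassifyByClade:
    def _tree(self, newick):
        return dendropy.Tree.get(data=newick, schema="newick")

    def test_leaf_inside_pure_clade_inherits_label(self):
        tree = self._tree(
            "((r1:1,(r2:1,(r3:1,(r4:1,(r5:1,q:1):1):1):1):1):2,out:3);")
        labels = {f"r{i}": "RGC" for i in range(1, 6)}
        new = reclassify_by_clade(tree, labels, outgroup="out", k=3)
        assert new == {"q": "RGC"}

    def test_insufficient_labeled_leaves_stays_unlabeled(self):
        tree = self._tree("((r1:1,(r2:1,q:1):1):2,out:3);")
        new = reclassify_by_clade(tree, {"r1": "TK", "r2": "TK"},
                                  outgroup="out", k=3)
        assert new == {}

    def test_low_support_clade_is_skipped(self):
        msa = saturated_msa()
        tree = bootstrap_support(msa, B=50, seed=3)
        labels = {f"g{g}_{v}": f"GRP{g}"
                  for g in range(4) for v in range(3)
                  if not (g == 0 and v == 2)}
        # with an impossible support requirement nothing transfers
        assert reclassify_by_clade(tree, labels, outgroup="g3_0",
                                   k=2, s=101.0) == {}

    def test_planted_group_members_all_relabeled(self):
        # eight unlabeled leaves nested inside one labeled group
        inner = "q1:1"
        for i in range(2, 9):
            inner = f"(q{i}:1,{inner}):1"
        newick = (f"(((a1:1,a2:1):1,(a3:1,{inner}):1):1,"
                  f"((b1:1,b2:1):1,b3:1):2,out:5);")
        tree = self._tree(newick)
        labels = {f"a{i}": "RGC" for i in range(1, 4)}
        labels.update({f"b{i}": "TK" for i in range(1, 4)})
        new = reclassify_by_clade(tree, labels, outgroup="out", k=3)
        assert new == {f"q{i}": "RGC" for i in range(1, 9)}

    def test_missing_outgroup_rejected(self):
        tree = self._tree("((a:1,b:1):1,(c:1,d:1):1);")
        with pytest.raises(ValueError, match="outgroup"):
            reclassify_by_clade(tree, {"a": "TK", "b": "TK", "c": "TK"},
                                outgroup="zz")
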