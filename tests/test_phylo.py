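"""Tree ingestion, monophyly counting (vs an edge-cut oracle), NJ and
bootstrap supports."""

import random

import pandas as pd
import pytest

from barcodekit import (
    PhyloConfig,
    bootstrap_supports,
    nj_tree,
    p_distance_matrix,
    phylo_summary,
    read_newick_with_support,
    species_monophyly,
)
from barcodekit.phylo import write_newick

from oracles import monophyly_by_edge_cut, random_newick


def _tree_from(tmp_path, newick):
    p = tmp_path / "t.nwk"
    p.write_text(newick)
    return read_newick_with_support(p)


class TestNewickIO:
    def test_supports_parsed_from_internal_labels(self, tmp_path):
        t = _tree_from(tmp_path, "((a1,a2)95,(b1,b2)80);")
        assert sorted(t.leaf_labels) == ["a1", "a2", "b1", "b2"]
        # a 4-leaf tree has one nontrivial unrooted split; both root-child
        # labels describe it and the merged view keeps the larger one, while
        # per-species supports (tested below) keep their own side's label
        nontrivial = {k: v for k, v in t.supports().items() if len(k) == 2}
        assert list(nontrivial.values()) == [95.0]
        assert all(v is None for k, v in t.supports().items() if len(k) != 2)

    def test_absent_supports_load_as_none(self, tmp_path):
        t = _tree_from(tmp_path, "((a1,a2),(b1,b2));")
        assert set(t.supports().values()) == {None}

    def test_duplicate_leaves_fatal(self, tmp_path):
        with pytest.raises(ValueError, match="duplicate"):
            _tree_from(tmp_path, "((a1,a1),(b1,b2));")

    def test_unparsable_fatal(self, tmp_path):
        with pytest.raises(ValueError, match="parse"):
            _tree_from(tmp_path, "((a1,a2)")

    def test_round_trip_preserves_topology_and_supports(self, tmp_path):
        t = _tree_from(tmp_path, "((a1,a2)95,(b1,(b2,c1)64)80);")
        write_newick(t, tmp_path / "out.nwk")
        back = read_newick_with_support(tmp_path / "out.nwk")
        assert back.supports() == t.supports()


class TestSpeciesMonophyly:
    SPECIES = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}

    def test_hand_readable_cherries(self, tmp_path):
        t = _tree_from(tmp_path, "((a1,a2)95,(b1,b2)80);")
        res = {r.species: r for r in species_monophyly(t, self.SPECIES)}
        assert res["A"].support == 95.0 and res["A"].counted_as_MS
        assert res["B"].support == 80.0 and res["B"].counted_as_MS

    def test_interleaved_tips_not_monophyletic(self, tmp_path):
        t = _tree_from(tmp_path, "((a1,b1)90,(a2,b2)85);")
        res = species_monophyly(t, self.SPECIES)
        assert not any(r.is_monophyletic for r in res)

    def test_support_below_threshold_not_counted(self, tmp_path):
        t = _tree_from(tmp_path, "((a1,a2)65,(b1,b2)80);")
        res = {r.species: r for r in species_monophyly(
            t, self.SPECIES, PhyloConfig(min_support=70))}
        assert res["A"].is_monophyletic and not res["A"].counted_as_MS
        assert res["B"].counted_as_MS

    def test_unmapped_leaf_fatal(self, tmp_path):
        t = _tree_from(tmp_path, "((a1,a2)65,(b1,zz)80);")
        with pytest.raises(KeyError, match="zz"):
            species_monophyly(t, self.SPECIES)

    def test_polytomy_without_exclusive_edge_not_monophyletic(self, tmp_path):
        t = _tree_from(tmp_path, "(a1,a2,b1,b2);")
        res = {r.species: r for r in species_monophyly(t, self.SPECIES)}
        assert not res["A"].is_monophyletic

    def test_rerooting_invariance(self, tmp_path):
        species = {f"t{i}": f"sp{i % 3}" for i in range(1, 7)}
        t1 = _tree_from(tmp_path, "((t1,t4)90,((t2,t5)80,(t3,t6)70)60);")
        t2 = _tree_from(tmp_path, "(((t3,t6)70,(t1,t4)90)60,(t2,t5)80);")
        r1 = {r.species: (r.is_monophyletic, r.support)
              for r in species_monophyly(t1, species)}
        r2 = {r.species: (r.is_monophyletic, r.support)
              for r in species_monophyly(t2, species)}
        assert r1 == r2

    def test_matches_edge_cut_oracle_on_random_trees(self):
        """Bipartition-based monophyly equals exhaustive edge enumeration on
        50 random labeled trees (the acceptance suite runs 200)."""
        rng = random.Random(7)
        import dendropy

        for _ in range(50):
            n = rng.randint(4, 32)
            nwk, species_of = random_newick(rng, n)
            tree = dendropy.Tree.get(data=nwk, schema="newick",
                                     suppress_internal_node_taxa=True)
            from barcodekit.phylo import SupportTree

            st = SupportTree(tree)
            ours = {r.species: (r.n_tips, r.is_monophyletic, r.support)
                    for r in species_monophyly(st, species_of)}
            oracle = monophyly_by_edge_cut(st.tree, species_of)
            assert ours == oracle

    def test_ms_never_increases_with_threshold(self, tmp_path):
        t = _tree_from(tmp_path,
                       "(((a1,a2)65,(b1,b2)80)50,((c1,c2)95,d1)40);")
        species = {"a1": "A", "a2": "A", "b1": "B", "b2": "B",
                   "c1": "C", "c2": "C", "d1": "D"}
        ms = [
            phylo_summary(species_monophyly(
                t, species, PhyloConfig(min_support=thr)))[2]
            for thr in (0, 50, 65, 80, 95, 100)
        ]
        assert ms == sorted(ms, reverse=True)


class TestPhyloSummary:
    def test_published_count_block(self, tmp_path):
        # SMA 183 with MS 114 leaves NMS 69 in the published survey row
        from barcodekit import MonophylyResult

        results = (
            [MonophylyResult(f"s{i}", 1, True, None, False)
             for i in range(309)]
            + [MonophylyResult(f"m{i}", 2, True, 90.0, True)
               for i in range(114)]
            + [MonophylyResult(f"n{i}", 2, False, None, False)
               for i in range(69)]
        )
        assert phylo_summary(results) == (309, 183, 114, 69)

    def test_no_multi_tip_species(self):
        from barcodekit import MonophylyResult

        results = [MonophylyResult("s", 1, True, None, False)]
        assert phylo_summary(results) == (1, 0, 0, 0)


class TestNJ:
    def test_three_taxa_unique_topology(self):
        ids = list("ABC")
        d = pd.DataFrame([[0, 2, 3], [2, 0, 3], [3, 3, 0]],
                         index=ids, columns=ids, dtype=float)
        t = nj_tree(d)
        assert sorted(t.leaf_labels) == ids

    def test_additive_four_taxon_matrix_recovers_tree(self):
        # distances from ((A:1,B:2):1,(C:3,D:4)) satisfy the four-point
        # condition: AB|CD is the unique valid split
        ids = list("ABCD")
        d = pd.DataFrame(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            index=ids, columns=ids, dtype=float)
        assert max(d.loc["A", "B"] + d.loc["C", "D"],
                   0) <= d.loc["A", "C"] + d.loc["B", "D"]
        t = nj_tree(d)
        splits = {frozenset(k) for k in t.supports()}
        assert frozenset({"C", "D"}) in splits or \
            frozenset({"A", "B"}) in splits

    def test_input_order_invariant_topology(self):
        ids = list("ABCDE")
        rng = random.Random(3)
        base = [[0] * 5 for _ in range(5)]
        for i in range(5):
            for j in range(i + 1, 5):
                base[i][j] = base[j][i] = rng.uniform(0.1, 1.0)
        d = pd.DataFrame(base, index=ids, columns=ids)
        perm = ["C", "A", "E", "B", "D"]
        t1 = nj_tree(d)
        t2 = nj_tree(d.loc[perm, perm])

        def nontrivial(t):
            return {k for k in t.supports() if 1 < len(k) < len(ids) - 1}

        assert nontrivial(t1) == nontrivial(t2)

    def test_fewer_than_three_taxa_fatal(self):
        d = pd.DataFrame([[0, 1], [1, 0]], index=["A", "B"],
                         columns=["A", "B"], dtype=float)
        with pytest.raises(ValueError, match="3 taxa"):
            nj_tree(d)


class TestBootstrap:
    # three maximally separated pairs: every column supports both cherries,
    # so column resampling can never lose them
    ALIGNED = {
        "a1": "AAAAAAAAAA", "a2": "AAAAAAAAAA",
        "b1": "CCCCCCCCCC", "b2": "CCCCCCCCCC",
        "e1": "GGGGGGGGGG",
    }

    def test_fully_consistent_signal_gives_100(self):
        t = bootstrap_supports(self.ALIGNED,
                               PhyloConfig(n_bootstrap=50, seed=1))
        sups = {k: v for k, v in t.supports().items()
                if 1 < len(k) < len(self.ALIGNED) - 1}
        assert sups
        assert all(v == 100.0 for v in sups.values())

    def test_deterministic_given_seed(self):
        t1 = bootstrap_supports(self.ALIGNED,
                                PhyloConfig(n_bootstrap=30, seed=9))
        t2 = bootstrap_supports(self.ALIGNED,
                                PhyloConfig(n_bootstrap=30, seed=9))
        assert t1.supports() == t2.supports()

    def test_signal_free_alignment_has_no_certain_split(self):
        flat = {k: "ACGTACGTAC" for k in ("x1", "x2", "x3", "x4", "x5")}
        t = bootstrap_supports(flat, PhyloConfig(n_bootstrap=30, seed=2))
        sups = [s for s in t.supports().values() if s is not None]
        # identical rows carry no signal for any bipartition
        assert all(s <= 100.0 for s in sups)
        assert not any(s == 100.0 for s in sups) or len(sups) == 0

    def test_invalid_bootstrap_count_fatal(self):
        with pytest.raises(ValueError):
            bootstrap_supports(self.ALIGNED, PhyloConfig(n_bootstrap=0))

    def test_p_distance_ignores_gap_columns(self):
        d = p_distance_matrix({"x": "AC-T", "y": "ACGT", "z": "TTGT"})
        assert d.loc["x", "y"] == 0.0
        assert d.loc["x", "z"] == pytest.approx(2 / 3)
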