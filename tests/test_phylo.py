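"""Alignments, Fitch scoring, parsimony search and branch lengths."""

import itertools

import numpy as np
import pytest

from clonaltracer import (
    CellAlignment,
    build_alignment,
    enumerate_topologies,
    fitch_score,
    search_mp_tree,
)
from clonaltracer.phylo import _MASK, _edge_changes
from clonaltracer.simdata import (
    SimulationConfig,
    sample_cells,
    simulate_clone_tree,
)

from conftest import make_matrix


def align(seqs, cells=None):
    cells = cells or [f"c{i}" for i in range(len(seqs))]
    return CellAlignment(
        cells=cells,
        sequences=list(seqs),
        site_order=[f"S{j}" for j in range(len(seqs[0]))],
    )


def sankoff_score(edges, seqs):
    """Unit-cost Sankoff dynamic program (independent oracle)."""
    n = len(seqs)
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    INF = 10**6
    total = 0
    for col in range(len(seqs[0])):
        def cost(node, parent):
            if node < n:
                mask = _MASK[seqs[node][col]]
                return [0 if (mask >> s) & 1 else INF for s in range(4)]
            out = [0] * 4
            for w in adj[node]:
                if w == parent:
                    continue
                c = cost(w, node)
                for s in range(4):
                    out[s] += min(c[sp] + (0 if sp == s else 1) for sp in range(4))
            return out

        p = adj[0][0]
        c = cost(p, 0)
        leafc = [0 if (_MASK[seqs[0][col]] >> s) & 1 else INF for s in range(4)]
        total += min(
            min(c[sp] + (0 if sp == s else 1) for sp in range(4)) + leafc[s]
            for s in range(4)
        )
    return total


class TestBuildAlignment:
    def test_direct_mapping_of_calls_to_bases(self, matrix_factory):
        m = matrix_factory(
            [[1, 0, np.nan]],
            cells=["c0"],
            refs=["T", "C", "G"],
            alts=["A", "G", "T"],
        )
        m2 = make3cells(m)
        al = build_alignment(m2)
        assert al.sequences[0] == "ACN"

    def test_all_reference_cell_is_concatenated_refs(self):
        m = make_matrix(
            np.zeros((3, 4)), refs=["A", "C", "G", "T"], alts=["T", "A", "C", "A"]
        )
        al = build_alignment(m)
        assert al.sequences[0] == "ACGT"

    def test_indel_sites_excluded_from_alignment(self):
        m = make_matrix(
            [[1, 1], [0, 0], [0, 1]], variant_class=["SNV", "INDEL"]
        )
        al = build_alignment(m)
        assert al.site_order == ["S0"]
        assert all(len(s) == 1 for s in al.sequences)

    def test_column_differences_equal_genotype_differences(self):
        rng = np.random.default_rng(1)
        calls = rng.choice([0.0, 1.0, np.nan], size=(8, 12), p=[0.45, 0.45, 0.1])
        refs = list(rng.choice(list("ACGT"), 12))
        alts = [
            {"A": "C", "C": "G", "G": "T", "T": "A"}[r] for r in refs
        ]
        m = make_matrix(calls, refs=refs, alts=alts)
        al = build_alignment(m)
        for i, j in itertools.combinations(range(8), 2):
            seq_diff = sum(
                a != b
                for a, b in zip(al.sequences[i], al.sequences[j])
                if a != "N" and b != "N"
            )
            geno_diff = int(
                np.nansum(
                    (calls[i] != calls[j])
                    & ~np.isnan(calls[i])
                    & ~np.isnan(calls[j])
                )
            )
            assert seq_diff == geno_diff

    def test_high_missing_cells_are_excluded_and_logged(self):
        calls = np.zeros((4, 4))
        calls[0, :] = np.nan
        m = make_matrix(calls)
        al = build_alignment(m, max_missing_fraction=0.8)
        assert "c0" not in al.cells
        assert al.excluded[0][0] == "c0"

    def test_zero_snv_sites_errors(self):
        m = make_matrix([[1], [0], [1]], variant_class=["INDEL"])
        with pytest.raises(ValueError, match="SNV"):
            build_alignment(m)


def make3cells(m):
    """Pad a 1-cell matrix to the 3-cell minimum with all-ref rows."""
    calls = np.vstack([m.calls, np.zeros((2, m.n_sites))])
    return make_matrix(
        calls,
        cells=list(m.cells) + ["p1", "p2"],
        sites=list(m.sites),
        refs=list(m.site_meta["ref"]),
        alts=list(m.site_meta["alt"]),
        variant_class=list(m.site_meta["variant_class"]),
    )


class TestFitchScore:
    def test_identical_sequences_score_zero(self):
        al = align(["ACGT"] * 4)
        topo = next(enumerate_topologies(4))
        assert fitch_score(topo, al) == 0

    def test_textbook_four_taxon_single_column(self):
        al = align(["A", "A", "T", "T"])
        # split-matching topology ((0,1),(2,3)) costs exactly 1
        topo = [(0, 4), (1, 4), (2, 5), (3, 5), (4, 5)]
        assert fitch_score(topo, al) == 1
        # the conflicting split ((0,2),(1,3)) costs 2
        topo2 = [(0, 4), (2, 4), (1, 5), (3, 5), (4, 5)]
        assert fitch_score(topo2, al) == 2

    def test_equals_sankoff_oracle_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            seqs = [
                "".join(rng.choice(list("ACGTN"), 20, p=[0.22] * 4 + [0.12]))
                for _ in range(6)
            ]
            al = align(seqs)
            for topo in itertools.islice(enumerate_topologies(6), 0, 105, 10):
                assert fitch_score(topo, al) == sankoff_score(topo, seqs)

    def test_invariant_to_column_order(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("ACGT"), 15)) for _ in range(6)]
        perm = rng.permutation(15)
        shuffled = ["".join(s[j] for j in perm) for s in seqs]
        for topo in itertools.islice(enumerate_topologies(6), 0, 105, 20):
            assert fitch_score(topo, align(seqs)) == fitch_score(
                topo, align(shuffled)
            )

    def test_all_n_column_never_changes_score(self):
        rng = np.random.default_rng(4)
        seqs = ["".join(rng.choice(list("ACGT"), 10)) for _ in range(5)]
        padded = [s + "N" for s in seqs]
        for topo in enumerate_topologies(5):
            assert fitch_score(topo, align(seqs)) == fitch_score(
                topo, align(padded)
            )

    def test_leaf_mismatch_errors(self):
        al = align(["A", "A", "T", "T"])
        with pytest.raises(ValueError, match="leaf"):
            fitch_score([(0, 3), (1, 3), (2, 3)], al)


class TestSearchMPTree:
    def test_four_taxa_exhaustive_over_three_topologies(self):
        al = align(["AATT", "AAAA", "TTAA", "TTTT"])
        tree = search_mp_tree(al)
        scores = [fitch_score(t, al) for t in enumerate_topologies(4)]
        assert len(scores) == 3
        assert tree.score == min(scores)

    def test_noiseless_clones_form_monophyletic_groups(self):
        cfg = SimulationConfig(
            n_clones=4, tree_shape="bifurcating", trunk_size=6,
            private_size_range=(4, 4), cells_per_clone=3, n_paratumor_cells=0,
            panel_size=40, ado_rate=0.0, fp_rate=0.0, missing_rate=0.0,
            indel_fraction=0.0, seed=5,
        )
        tree, sites = simulate_clone_tree(cfg)
        truth = sample_cells(tree, sites, cfg)
        al = build_alignment(truth.true_matrix)
        ct = search_mp_tree(al, mode="nni", seed=0)
        # identical within-clone sequences collapse onto one representative
        for rep, dups in ct.duplicates.items():
            group = {truth.cell_labels[c] for c in [rep] + dups}
            assert len(group) == 1
        assert len(ct.leaf_names) == 4

    def test_heuristic_never_beats_exhaustive_and_usually_matches(self):
        rng = np.random.default_rng(6)
        match = 0
        n_trials = 25
        for t in range(n_trials):
            seqs = ["".join(rng.choice(list("ACGT"), 15)) for _ in range(8)]
            al = align(seqs)
            ex = search_mp_tree(al, mode="exhaustive").score
            nn = search_mp_tree(al, mode="nni", seed=t).score
            assert nn >= ex
            match += nn == ex
        assert match >= 0.9 * n_trials

    def test_duplicates_reattached_as_zero_length_children(self):
        al = align(["AAAA", "AAAA", "CCCC", "GGGG", "TTTT"],
                   cells=["a1", "a2", "c", "g", "t"])
        ct = search_mp_tree(al)
        assert ct.duplicates == {"a1": ["a2"]}
        assert sorted(ct.all_cells()) == ["a1", "a2", "c", "g", "t"]
        nwk = ct.to_newick()
        assert "a2:0.0" in nwk

    def test_newick_round_trips_through_dendropy(self):
        rng = np.random.default_rng(7)
        seqs = ["".join(rng.choice(list("ACGT"), 10)) for _ in range(6)]
        ct = search_mp_tree(align(seqs))
        import dendropy

        t = dendropy.Tree.get(data=ct.to_newick(), schema="newick")
        assert {l.taxon.label for l in t.leaf_nodes()} == set(ct.leaf_names)


class TestBranchLengths:
    def test_zero_score_tree_has_all_zero_lengths(self):
        with pytest.warns(UserWarning, match="degenerate"):
            ct = search_mp_tree(align(["ACGT", "ACGT", "ACGT", "ACGT"]))
        assert ct.score == 0
        assert all(v == 0.0 for v in ct.edge_lengths().values())

    def test_lengths_times_columns_sum_to_parsimony_score(self):
        rng = np.random.default_rng(8)
        seqs = ["".join(rng.choice(list("ACGTN"), 25, p=[0.22] * 4 + [0.12]))
                for _ in range(7)]
        ct = search_mp_tree(align(seqs))
        total = sum(ct.edge_lengths().values()) * ct.n_columns
        assert total == pytest.approx(ct.score)

    def test_edge_changes_match_per_column_enumeration_oracle(self):
        # 4-taxon, 5-column instance; oracle enumerates all internal labelings
        seqs = ["AATCA", "AAGCA", "TAGGA", "TTGGA"]
        topo = [(0, 4), (1, 4), (2, 5), (3, 5), (4, 5)]
        al = align(seqs)
        changes, total = _edge_changes(topo, al.masks())
        assert total == fitch_score(topo, al)
        best = None
        for col in range(5):
            per_col_best = None
            for s4 in "ACGT":
                for s5 in "ACGT":
                    states = {0: seqs[0][col], 1: seqs[1][col],
                              2: seqs[2][col], 3: seqs[3][col], 4: s4, 5: s5}
                    cost = sum(states[u] != states[v] for u, v in topo)
                    if per_col_best is None or cost < per_col_best:
                        per_col_best = cost
            best = (best or 0) + per_col_best
        assert total == best
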