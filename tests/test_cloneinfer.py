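"""Clone calling, conflict resolution, clone-tree building, classification."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from clonaltracer import (
    Clone,
    ConflictError,
    build_clone_tree,
    call_clones,
    classify_mutations,
    conflict_test,
    pairwise_distance,
    resolve_conflicts,
)
from clonaltracer.simdata import (
    SimulationConfig,
    apply_noise,
    bifurcating_recovery_config,
    sample_cells,
    simulate_clone_tree,
    simulate_dataset,
)

from conftest import make_matrix


def clone(cid, sites, tissue="tumor", n_cells=5):
    return Clone(
        clone_id=cid,
        member_cells=[f"{cid}_c{i}" for i in range(n_cells)],
        consensus=frozenset(sites),
        tissue_composition={tissue: n_cells},
    )


class TestPairwiseDistance:
    def test_identical_rows_are_distance_zero(self):
        m = make_matrix([[1, 0, 1], [1, 0, 1]])
        d, _ = pairwise_distance(m, min_overlap=1)
        assert d[0, 1] == 0.0

    def test_pairwise_deletion_arithmetic(self):
        m = make_matrix([[1, 0, np.nan], [1, 1, 0]])
        d, _ = pairwise_distance(m, min_overlap=1)
        assert d[0, 1] == pytest.approx(1 / 2)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(0)
        calls = rng.choice([0.0, 1.0, np.nan], size=(20, 30), p=[0.45, 0.45, 0.1])
        m = make_matrix(calls)
        d, flagged = pairwise_distance(m, min_overlap=5)
        for i in range(20):
            for j in range(20):
                co = diff = 0
                for k in range(30):
                    a, b = calls[i, k], calls[j, k]
                    if not np.isnan(a) and not np.isnan(b):
                        co += 1
                        diff += a != b
                if i == j:
                    assert d[i, j] == 0.0
                elif co < 5:
                    assert flagged[i, j] and d[i, j] == 1.0
                else:
                    assert d[i, j] == pytest.approx(diff / co)


class TestCallClones:
    def test_noiseless_two_clones_recovered_exactly(self):
        cfg = SimulationConfig(
            n_clones=2, tree_shape="linear", cells_per_clone=10,
            private_size_range=(4, 4), n_paratumor_cells=0,
            ado_rate=0.0, fp_rate=0.0, missing_rate=0.0, seed=1,
        )
        tree, sites = simulate_clone_tree(cfg)
        truth = sample_cells(tree, sites, cfg)
        clones, unassigned = call_clones(truth.true_matrix, tau=0.05, min_cells=5)
        assert len(clones) == 2 and not unassigned
        called = {frozenset(c.member_cells) for c in clones}
        true_groups = {
            frozenset(c for c, lab in truth.cell_labels.items() if lab == cl)
            for cl in set(truth.cell_labels.values())
        }
        assert called == true_groups
        for c in clones:
            true_clone = truth.cell_labels[c.member_cells[0]]
            assert c.consensus == tree.nodes[true_clone].cumulative

    def test_noisy_four_clones_high_ari(self):
        ds = simulate_dataset(bifurcating_recovery_config(seed=42))
        clones, unassigned = call_clones(ds.matrix, tau=0.1)
        labels = {}
        for c in clones:
            for cell in c.member_cells:
                labels[cell] = c.clone_id
        cells = sorted(ds.truth.cell_labels)
        ari = adjusted_rand_score(
            [ds.truth.cell_labels[c] for c in cells],
            [labels.get(c, f"un_{c}") for c in cells],
        )
        assert ari >= 0.9

    def test_tau_zero_on_noisy_data_leaves_most_cells_unassigned(self):
        ds = simulate_dataset(bifurcating_recovery_config(seed=2))
        with pytest.warns(UserWarning, match="unassigned"):
            clones, unassigned = call_clones(ds.matrix, tau=0.0, min_cells=5)
        n_tumor = len(ds.truth.cell_labels)
        assert len(unassigned) > n_tumor / 2


class TestConflictTest:
    def test_nested_sets_are_conflict_free(self):
        clones = [clone("c1", {"A"}), clone("c2", {"A", "B"})]
        assert conflict_test(clones) == []

    def test_three_pattern_pair_is_conflicted(self):
        clones = [clone("c1", {"A"}), clone("c2", {"B"}), clone("c3", {"A", "B"})]
        assert conflict_test(clones) == [("A", "B")]

    def test_matches_brute_force_pattern_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            M = rng.integers(0, 2, size=(6, 12))
            sites = [f"S{j}" for j in range(12)]
            clones = [
                clone(f"c{i}", {s for j, s in enumerate(sites) if M[i, j]})
                for i in range(6)
            ]
            expected = set()
            for a, b in itertools.combinations(range(12), 2):
                pats = {(M[i, a], M[i, b]) for i in range(6)}
                if {(1, 0), (0, 1), (1, 1)} <= pats:
                    expected.add(frozenset((sites[a], sites[b])))
            got = {frozenset(p) for p in conflict_test(clones)}
            assert got == expected


class TestResolveConflicts:
    def test_conflict_free_input_unchanged(self):
        clones = [clone("c1", {"A"}), clone("c2", {"A", "B"})]
        out, log = resolve_conflicts(clones)
        assert log == []
        assert [c.consensus for c in out] == [c.consensus for c in clones]

    def test_single_conflicting_pair_removes_one_site(self):
        clones = [clone("c1", {"A"}), clone("c2", {"B"}), clone("c3", {"A", "B"})]
        out, log = resolve_conflicts(clones, fractions={"A": 0.6, "B": 0.2})
        assert len(log) == 1
        assert log[0]["site_id"] == "B"  # tie on count -> lower fraction goes
        assert conflict_test(out) == []

    def test_random_conflicted_instances_end_conflict_free(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            M = rng.integers(0, 2, size=(5, 10))
            clones = [
                clone(f"c{i}", {f"S{j}" for j in range(10) if M[i, j]})
                for i in range(5)
            ]
            out, _ = resolve_conflicts(clones)
            assert conflict_test(out) == []


def random_true_clone_family(rng, max_clones=8, max_sites=30):
    """Random perfect-phylogeny clone family via a random planted tree."""
    n_clones = int(rng.integers(2, max_clones + 1))
    edges = []
    for i in range(1, n_clones + 1):
        parent = "root" if i == 1 else f"n{int(rng.integers(1, i))}"
        edges.append((parent, f"n{i}", int(rng.integers(1, 4))))
    total = sum(k for _, _, k in edges)
    if total > max_sites:
        edges = [(p, c, 1) for p, c, _ in edges]
    cfg = SimulationConfig(
        tree_shape="custom", custom_edges=edges, panel_size=max_sites,
        cells_per_clone=3, n_paratumor_cells=0, seed=int(rng.integers(2**31)),
    )
    tree, _ = simulate_clone_tree(cfg)
    return tree


class TestBuildCloneTree:
    def test_shared_trunk_with_two_divergent_children(self):
        trunk = {f"T{i}" for i in range(10)}
        clones = [
            clone("c1", trunk),
            clone("c2", trunk | {"x"}),
            clone("c3", trunk | {"y"}),
        ]
        tree = build_clone_tree(clones)
        assert tree.edge("root", "c1").acquired == frozenset(trunk)
        assert tree.edge("c1", "c2").acquired == frozenset({"x"})
        assert tree.edge("c1", "c3").acquired == frozenset({"y"})

    def test_virtual_ancestor_inserted_for_shared_unobserved_prefix(self):
        trunk = {f"T{i}" for i in range(10)}
        shared = {"a", "b", "c"}
        clones = [
            clone("c1", trunk),
            clone("c2", trunk | shared | {"p"}),
            clone("c3", trunk | shared | {"q"}),
        ]
        tree = build_clone_tree(clones)
        virtual = tree.virtual_nodes()
        assert len(virtual) == 1
        (v,) = virtual
        assert v.cumulative == frozenset(trunk | shared)
        incoming = tree.edge(tree.parent_of(v.node_id), v.node_id)
        assert incoming.acquired == frozenset(shared)
        assert sorted(tree.children_of(v.node_id)) == ["c2", "c3"]

    def test_single_clone_gives_root_plus_one_node(self):
        tree = build_clone_tree([clone("c1", {"A", "B"})])
        assert set(tree.nodes) == {"root", "c1"}
        assert tree.edge("root", "c1").acquired == frozenset({"A", "B"})

    def test_conflicted_input_raises(self):
        clones = [clone("c1", {"A"}), clone("c2", {"B"}), clone("c3", {"A", "B"})]
        with pytest.raises(ConflictError, match="resolve_conflicts"):
            build_clone_tree(clones)

    def test_invariant_to_clone_input_order(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            tree = random_true_clone_family(rng)
            clones = [
                clone(n.node_id, n.cumulative)
                for n in tree.observed_nodes()
            ]
            t1 = build_clone_tree(clones)
            t2 = build_clone_tree(clones[::-1])
            assert t1.to_dict() == t2.to_dict()

    def test_cumulative_sets_match_path_union_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            planted = random_true_clone_family(rng)
            clones = [clone(n.node_id, n.cumulative) for n in planted.observed_nodes()]
            tree = build_clone_tree(clones)
            tree.validate()
            for node_id, node in tree.nodes.items():
                path = tree.root_path(node_id)
                union = set()
                for a, b in zip(path, path[1:]):
                    union |= tree.edge(a, b).acquired
                assert union == set(node.cumulative)
            # every observed clone keeps its consensus as cumulative set
            for c in clones:
                assert tree.nodes[c.clone_id].cumulative == c.consensus


class TestClassifyMutations:
    def test_two_tissue_structure_recovers_trunk_and_private_classes(self):
        trunk = {f"T{i}" for i in range(10)}
        met_shared = {"M1", "M2", "M3"}
        clones = [
            clone("c1", trunk, tissue="tumor"),
            clone("c2", trunk | {"p1", "p2"}, tissue="tumor"),
            clone("c3", trunk | met_shared | {"q"}, tissue="metastasis"),
            clone("c4", trunk | met_shared | {"r"}, tissue="metastasis"),
        ]
        tree = build_clone_tree(clones)
        cls = classify_mutations(tree)
        assert set(cls.sites_in("trunk")) == trunk
        assert set(cls.sites_in("tissue-private-clonal")) == met_shared
        assert set(cls.sites_in("subclonal")) == {"p1", "p2", "q", "r"}

    def test_single_clone_single_tissue_all_trunk(self):
        tree = build_clone_tree([clone("c1", {"A", "B"})])
        cls = classify_mutations(tree)
        assert set(cls.sites_in("trunk")) == {"A", "B"}

    def test_matches_brute_force_set_definitions(self):
        rng = np.random.default_rng(9)
        tissues = ["tumor", "metastasis"]
        for _ in range(20):
            planted = random_true_clone_family(rng)
            obs = planted.observed_nodes()
            assign = {n.node_id: tissues[int(rng.integers(2))] for n in obs}
            clones = [
                clone(n.node_id, n.cumulative, tissue=assign[n.node_id])
                for n in obs
            ]
            tree = build_clone_tree(clones)
            cls = classify_mutations(tree)
            all_ids = {c.clone_id for c in clones}
            by_tissue = {
                t: {c.clone_id for c in clones if assign[c.clone_id] == t}
                for t in tissues
            }
            present_tissues = {t for t, s in by_tissue.items() if s}
            for site in {s for c in clones for s in c.consensus}:
                carriers = {c.clone_id for c in clones if site in c.consensus}
                carrier_t = {assign[c] for c in carriers}
                if carriers == all_ids:
                    want = "trunk"
                elif len(carrier_t) == 1 and carriers == by_tissue[next(iter(carrier_t))] \
                        and len(present_tissues) > 1:
                    want = "tissue-private-clonal"
                elif len(carrier_t) > 1:
                    want = "tissue-shared"
                else:
                    want = "subclonal"
                assert cls.category[site] == want, site

    def test_unseen_sites_are_unassigned(self):
        tree = build_clone_tree([clone("c1", {"A"})])
        cls = classify_mutations(tree, all_sites=["A", "Z"])
        assert cls.category["Z"] == "unassigned"
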