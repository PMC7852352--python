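"""Clone calling, clone-tree reconstruction and mutation classification.

Single cells are grouped into clones by their mutation combinations using a
dropout-tolerant normalized Hamming distance (pairwise deletion of missing
calls) and average-linkage hierarchical clustering.  Clone consensus
genotypes are then placed on a perfect phylogeny rooted at an all-reference
normal ancestor: each mutation arises once and never reverts.  Where two or
more sibling lineages share mutations that no observed clone explains, an
unobserved "virtual ancestor" node is inserted — the dashed-circle clone of
a metastasis whose founder was never sampled.  Finally every site is
classified as trunk (carried by all tumor clones), tissue-private clonal
(all clones of exactly one tissue), tissue-shared, or subclonal.
"""

from __future__ import annotations

import itertools
import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .genomatrix import TUMOR_TISSUES, GenotypeMatrix

MUTATION_CATEGORIES = (
    "trunk",
    "tissue-shared",
    "tissue-private-clonal",
    "subclonal",
    "unassigned",
)


class ConflictError(ValueError):
    """Clone consensus sets violate the perfect-phylogeny condition."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Clone:
    """A group of cells with a consensus binary mutation set."""

    clone_id: str
    member_cells: list[str]
    consensus: frozenset[str]  # site ids called mutant in the consensus
    tissue_composition: dict[str, int] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.member_cells)

    def dominant_tissue(self) -> str:
        """Majority tissue of member cells (ties broken alphabetically)."""
        if not self.tissue_composition:
            raise ValueError(f"clone {self.clone_id} has no tissue composition")
        best = max(self.tissue_composition.items(), key=lambda kv: (kv[1], kv[0]))
        top = sorted(
            t for t, n in self.tissue_composition.items() if n == best[1]
        )
        return top[0]


@dataclass
class CloneNode:
    node_id: str
    cumulative: frozenset[str]
    observed: bool
    tissue_counts: dict[str, int] = field(default_factory=dict)
    member_cells: list[str] = field(default_factory=list)


@dataclass
class CloneEdge:
    parent: str
    child: str
    acquired: frozenset[str]


@dataclass
class CloneTree:
    """Rooted clone tree from an all-reference virtual normal root.

    Each node carries its cumulative mutation set (the union of acquired
    sets along its root path); each edge carries the mutations newly
    acquired on it.  Nodes are flagged observed (a called clone) or virtual
    (inferred unobserved ancestor, including the root).
    """

    nodes: dict[str, CloneNode]
    edges: list[CloneEdge]
    root: str = "root"

    def parent_of(self, node_id: str) -> str | None:
        for e in self.edges:
            if e.child == node_id:
                return e.parent
        return None

    def children_of(self, node_id: str) -> list[str]:
        return [e.child for e in self.edges if e.parent == node_id]

    def edge(self, parent: str, child: str) -> CloneEdge:
        for e in self.edges:
            if e.parent == parent and e.child == child:
                return e
        raise KeyError((parent, child))

    def observed_nodes(self) -> list[CloneNode]:
        return [n for n in self.nodes.values() if n.observed]

    def virtual_nodes(self) -> list[CloneNode]:
        return [
            n for n in self.nodes.values() if not n.observed and n.node_id != self.root
        ]

    def root_path(self, node_id: str) -> list[str]:
        path = [node_id]
        while path[-1] != self.root:
            parent = self.parent_of(path[-1])
            if parent is None:
                raise ValueError(f"node {node_id!r} is disconnected from the root")
            path.append(parent)
        return path[::-1]

    def validate(self) -> None:
        """Check tree shape and the cumulative-set / disjointness invariants."""
        if self.root not in self.nodes:
            raise ValueError("root node missing")
        if self.nodes[self.root].cumulative:
            raise ValueError("root must carry an empty mutation set")
        children = Counter(e.child for e in self.edges)
        if any(v > 1 for v in children.values()):
            raise ValueError("a node has multiple parents")
        if set(children) != set(self.nodes) - {self.root}:
            raise ValueError("edges do not span all non-root nodes exactly once")
        for node_id in self.nodes:
            path = self.root_path(node_id)  # also detects cycles/disconnection
            acquired = [self.edge(a, b).acquired for a, b in zip(path, path[1:])]
            union: set[str] = set()
            total = 0
            for a in acquired:
                union |= a
                total += len(a)
            if total != len(union):
                raise ValueError(f"acquired sets on the path to {node_id!r} overlap")
            if union != set(self.nodes[node_id].cumulative):
                raise ValueError(
                    f"cumulative set of {node_id!r} differs from its root-path union"
                )
        for n in self.virtual_nodes():
            if len(self.children_of(n.node_id)) < 2:
                raise ValueError(f"virtual node {n.node_id!r} has fewer than 2 children")

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "root": self.root,
            "nodes": [
                {
                    "id": n.node_id,
                    "observed": n.observed,
                    "cumulative": sorted(n.cumulative),
                    "tissue_counts": dict(sorted(n.tissue_counts.items())),
                    "member_cells": list(n.member_cells),
                }
                for n in sorted(self.nodes.values(), key=lambda n: n.node_id)
            ],
            "edges": [
                {"parent": e.parent, "child": e.child, "acquired": sorted(e.acquired)}
                for e in sorted(self.edges, key=lambda e: (e.parent, e.child))
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CloneTree":
        nodes = {
            n["id"]: CloneNode(
                node_id=n["id"],
                cumulative=frozenset(n["cumulative"]),
                observed=bool(n["observed"]),
                tissue_counts=dict(n.get("tissue_counts", {})),
                member_cells=list(n.get("member_cells", [])),
            )
            for n in d["nodes"]
        }
        edges = [
            CloneEdge(e["parent"], e["child"], frozenset(e["acquired"]))
            for e in d["edges"]
        ]
        return cls(nodes=nodes, edges=edges, root=d["root"])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CloneTree":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class MutationClassification:
    """Per-site clonality category and carrying clones."""

    category: dict[str, str]
    carrying_clones: dict[str, frozenset[str]]

    def sites_in(self, category: str) -> list[str]:
        return sorted(s for s, c in self.category.items() if c == category)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": sorted(self.category),
                "category": [self.category[s] for s in sorted(self.category)],
                "carrying_clones": [
                    ",".join(sorted(self.carrying_clones.get(s, frozenset())))
                    for s in sorted(self.category)
                ],
            }
        )


# ---------------------------------------------------------------------------
# Pairwise distance and clone calling
# ---------------------------------------------------------------------------

def pairwise_distance(
    matrix: GenotypeMatrix,
    min_overlap: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized Hamming distance between cells with pairwise deletion.

    distance(i, j) = (# co-observed sites with different calls) /
    (# co-observed sites).  Pairs with fewer than *min_overlap* co-observed
    sites are unreliable: their distance is set to the maximum (1.0) and
    flagged in the returned boolean matrix.
    """
    X = matrix.calls
    if X.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    obs = (~np.isnan(X)).astype(float)
    A = np.nan_to_num(X)
    co = obs @ obs.T
    both1 = A @ A.T
    both0 = (obs - A) @ (obs - A).T
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(co > 0, (co - both1 - both0) / np.maximum(co, 1), 1.0)
    unreliable = co < min_overlap
    dist = np.where(unreliable, 1.0, dist)
    np.fill_diagonal(dist, 0.0)
    np.fill_diagonal(unreliable, False)
    return dist, unreliable


def _consensus(
    sub: np.ndarray, sites: list[str], min_site_coverage: float
) -> frozenset[str]:
    """Majority-vote consensus; ties and low coverage break to reference."""
    n_obs = np.sum(~np.isnan(sub), axis=0)
    n_mut = np.nansum(sub, axis=0)
    covered = n_obs >= min_site_coverage * sub.shape[0]
    mutant = covered & (n_mut > n_obs - n_mut)
    return frozenset(s for s, m in zip(sites, mutant) if m)


def call_clones(
    matrix: GenotypeMatrix,
    tau: float = 0.1,
    min_cells: int = 5,
    min_overlap: int = 5,
    min_site_coverage: float = 0.5,
    tissues: tuple[str, ...] = TUMOR_TISSUES,
) -> tuple[list[Clone], list[str]]:
    """Group cells into clones by mutation combination.

    Average-linkage hierarchical clustering on the pairwise distance, cut so
    that clusters merge only at linkage height strictly below *tau* (tau=0
    therefore yields singletons, and two clones separated by exactly tau
    stay apart); clusters with at least *min_cells* members become clones,
    smaller clusters' cells are returned unassigned.  Consensus genotype per
    site is the majority of non-missing member calls, requiring at least a
    *min_site_coverage* fraction of members observed; ties and low coverage
    call reference (conservative against false positives).
    """
    idx = matrix.cell_indices(list(tissues))
    cells = [matrix.cells[i] for i in idx]
    if len(cells) < min_cells:
        warnings.warn("fewer tumor cells than min_cells: no clones called")
        return [], cells
    sub = matrix.subset(cells=cells)
    dist, _ = pairwise_distance(sub, min_overlap=min_overlap)
    if len(cells) == 1:
        labels = np.array([1])
    else:
        Z = linkage(squareform(dist, checks=False), method="average")
        # fcluster's cut is inclusive; shave an epsilon for a strict cut
        labels = fcluster(Z, t=tau - 1e-9, criterion="distance")

    clones: list[Clone] = []
    unassigned: list[str] = []
    groups = sorted(
        ((lab, np.flatnonzero(labels == lab)) for lab in np.unique(labels)),
        key=lambda kv: (-kv[1].size, kv[1][0]),
    )
    k = 0
    for _, rows in groups:
        members = [cells[i] for i in rows]
        if rows.size < min_cells:
            unassigned.extend(members)
            continue
        k += 1
        consensus = _consensus(sub.calls[rows], sub.sites, min_site_coverage)
        clones.append(
            Clone(
                clone_id=f"clone_{k}",
                member_cells=members,
                consensus=consensus,
                tissue_composition=dict(
                    Counter(sub.tissue_of(c) for c in members)
                ),
            )
        )
    if not clones:
        warnings.warn("all cells unassigned: no cluster reached min_cells")
    return clones, unassigned


# ---------------------------------------------------------------------------
# Perfect-phylogeny machinery
# ---------------------------------------------------------------------------

def conflict_test(clones: list[Clone]) -> list[tuple[str, str]]:
    """Pairs of sites violating the two-character compatibility condition.

    With the ancestral state fixed at reference, sites a and b conflict iff
    the clone consensus vectors exhibit all three patterns (1,0), (0,1)
    and (1,1) — i.e. their carrier sets properly intersect, which no tree
    with single-origin mutations can realize.
    """
    if not clones:
        raise ValueError("need at least one clone")
    sites = sorted(set().union(*(c.consensus for c in clones)))
    if not sites:
        return []
    M = np.array(
        [[1 if s in c.consensus else 0 for s in sites] for c in clones], dtype=int
    )
    n1 = M.sum(axis=0)
    both = M.T @ M
    conflicts = []
    for i, j in itertools.combinations(range(len(sites)), 2):
        c11 = both[i, j]
        if c11 > 0 and n1[i] - c11 > 0 and n1[j] - c11 > 0:
            conflicts.append((sites[i], sites[j]))
    return conflicts


def resolve_conflicts(
    clones: list[Clone],
    fractions: dict[str, float] | pd.Series | None = None,
) -> tuple[list[Clone], list[dict]]:
    """Greedy site removal until the clone set is conflict-free.

    Repeatedly removes the site in the most conflicting pairs; ties break
    toward the lower mutated-cell fraction (less supported site), then the
    lexicographically smaller site id.  All removals are logged.
    """
    if fractions is None:
        fractions = {}
    elif isinstance(fractions, pd.Series):
        fractions = fractions.to_dict()
    current = [
        Clone(c.clone_id, list(c.member_cells), frozenset(c.consensus),
              dict(c.tissue_composition))
        for c in clones
    ]
    log: list[dict] = []
    while True:
        conflicts = conflict_test(current)
        if not conflicts:
            return current, log
        count: Counter[str] = Counter()
        for a, b in conflicts:
            count[a] += 1
            count[b] += 1
        def frac_of(s: str) -> float:
            v = fractions.get(s)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return np.inf
            return float(v)

        victim = min(count, key=lambda s: (-count[s], frac_of(s), s))
        log.append(
            {
                "site_id": victim,
                "reason": "perfect-phylogeny-conflict",
                "n_conflicts": count[victim],
            }
        )
        current = [
            Clone(c.clone_id, c.member_cells, c.consensus - {victim},
                  c.tissue_composition)
            for c in current
        ]


class _TrieNode:
    __slots__ = ("children", "clone", "cumulative")

    def __init__(self, cumulative: frozenset[str]):
        self.children: dict[str, _TrieNode] = {}
        self.clone: Clone | None = None
        self.cumulative = cumulative


def build_clone_tree(clones: list[Clone]) -> CloneTree:
    """Perfect-phylogeny clone tree with virtual ancestors.

    Mutations are ordered by carrying-clone-set containment (carrier count
    descending, site id for determinism) and each clone's consensus is
    threaded through a prefix trie from the all-reference root; chains of
    unobserved single-child nodes collapse into multi-mutation edges, so
    the unobserved nodes that survive are exactly the shared-ancestor
    intersections of >= 2 sibling subtrees — the virtual ancestor clones.
    """
    if not clones:
        raise ValueError("need at least one clone")
    if conflict_test(clones):
        raise ConflictError(
            "clone consensus sets are conflicted; run resolve_conflicts first"
        )
    carriers: dict[str, frozenset[str]] = {}
    for site in set().union(*(c.consensus for c in clones)):
        carriers[site] = frozenset(
            c.clone_id for c in clones if site in c.consensus
        )

    root = _TrieNode(frozenset())
    for clone in sorted(clones, key=lambda c: c.clone_id):
        ordered = sorted(clone.consensus, key=lambda s: (-len(carriers[s]), s))
        node = root
        for site in ordered:
            if site not in node.children:
                node.children[site] = _TrieNode(node.cumulative | {site})
            node = node.children[site]
        if node.clone is not None or node is root:
            # a second clone with the same consensus (or an empty one):
            # attach as a child over an empty acquired set
            extra = _TrieNode(node.cumulative)
            extra.clone = clone
            node.children[f"__dup__{clone.clone_id}"] = extra
        else:
            node.clone = clone

    nodes: dict[str, CloneNode] = {
        "root": CloneNode("root", frozenset(), observed=False)
    }
    edges: list[CloneEdge] = []
    counter = itertools.count(1)

    def emit(trie: _TrieNode, parent_id: str, acquired: set[str]) -> None:
        # collapse unobserved single-child chains into one edge
        while trie.clone is None and len(trie.children) == 1:
            (site, child), = trie.children.items()
            if not site.startswith("__dup__"):
                acquired.add(site)
            trie = child
        if trie.clone is not None:
            node_id = trie.clone.clone_id
            nodes[node_id] = CloneNode(
                node_id,
                trie.cumulative,
                observed=True,
                tissue_counts=dict(trie.clone.tissue_composition),
                member_cells=list(trie.clone.member_cells),
            )
        else:
            node_id = f"virtual_{next(counter)}"
            nodes[node_id] = CloneNode(node_id, trie.cumulative, observed=False)
        edges.append(CloneEdge(parent_id, node_id, frozenset(acquired)))
        for site in sorted(trie.children):
            nxt = {site} if not site.startswith("__dup__") else set()
            emit(trie.children[site], node_id, nxt)

    for site in sorted(root.children):
        nxt = {site} if not site.startswith("__dup__") else set()
        emit(root.children[site], "root", nxt)

    tree = CloneTree(nodes=nodes, edges=edges)
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# Mutation classification
# ---------------------------------------------------------------------------

def classify_mutations(
    tree: CloneTree,
    all_sites: list[str] | None = None,
) -> MutationClassification:
    """Classify sites by clonality across tissues.

    trunk: carried by every observed tumor clone. tissue-private-clonal:
    carried by all clones of exactly one tissue and no clone of any other.
    tissue-shared: carried by clones of >= 2 tissues but not all clones.
    subclonal: carried by a proper subset of a single tissue's clones.
    Sites in *all_sites* absent from the tree (e.g. filtered) → unassigned.
    """
    observed = tree.observed_nodes()
    if not observed:
        raise ValueError("clone tree has no observed clones")
    clone_tissue = {}
    for n in observed:
        clone = Clone(
            n.node_id, n.member_cells or ["_"], n.cumulative,
            n.tissue_counts or {"tumor": 1},
        )
        clone_tissue[n.node_id] = clone.dominant_tissue()
    tissues = sorted(set(clone_tissue.values()))
    clones_by_tissue = {
        t: {cid for cid, ct in clone_tissue.items() if ct == t} for t in tissues
    }
    all_clone_ids = set(clone_tissue)

    tree_sites = set().union(*(n.cumulative for n in observed)) | set().union(
        *(e.acquired for e in tree.edges)
    )
    category: dict[str, str] = {}
    carrying: dict[str, frozenset[str]] = {}
    for site in tree_sites:
        carriers = frozenset(
            n.node_id for n in observed if site in n.cumulative
        )
        carrying[site] = carriers
        if not carriers:
            category[site] = "unassigned"
            continue
        if carriers == all_clone_ids:
            category[site] = "trunk"
            continue
        carrier_tissues = {clone_tissue[c] for c in carriers}
        if len(carrier_tissues) == 1:
            (t,) = carrier_tissues
            # all-of-the-only-tissue would already be trunk, so len>1 here
            if carriers == clones_by_tissue[t] and len(tissues) > 1:
                category[site] = "tissue-private-clonal"
            else:
                category[site] = "subclonal"
        else:
            category[site] = "tissue-shared"
    if all_sites is not None:
        for site in all_sites:
            if site not in category:
                category[site] = "unassigned"
                carrying[site] = frozenset()
    return MutationClassification(category=category, carrying_clones=carrying)
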