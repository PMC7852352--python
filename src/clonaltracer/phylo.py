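"""Maximum-parsimony trees of single cells from target-site pseudo-sequences.

Each cell's ternary genotype row is turned into a nucleotide pseudo-sequence
over the panel's SNV sites (mutant call -> alt base, reference -> ref base,
missing or INDEL -> N).  Tree search minimizes the Fitch small-parsimony
score, with N as the full {A,C,G,T} wildcard so missing data never forces a
change.  Small inputs (<= 9 unique sequences) are solved exactly by
enumerating every unrooted binary topology; larger inputs use
nearest-neighbor-interchange hill climbing from a neighbor-joining start
tree on p-distances.  Branch lengths are substitutions per site from one
deterministic most-parsimonious ancestral reconstruction, so the paper-style
scale bar (nucleotide substitution rate) is reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genomatrix import GenotypeMatrix

# nucleotide state sets as bitmasks; N = any state
_MASK = {"A": 1, "C": 2, "G": 4, "T": 8, "N": 15}
_BASE = {v: k for k, v in _MASK.items()}
_LOWBIT = np.array([x & -x for x in range(16)], dtype=np.uint8)

Edge = tuple[int, int]


@dataclass
class CellAlignment:
    """Nucleotide pseudo-sequences of cells over the panel's SNV sites."""

    cells: list[str]
    sequences: list[str]
    site_order: list[str]
    excluded: list[tuple[str, float]] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(self.site_order)

    def masks(self) -> np.ndarray:
        """(n_cells, n_columns) uint8 state-set bitmasks."""
        return np.array(
            [[_MASK[b] for b in seq] for seq in self.sequences], dtype=np.uint8
        )

    def to_fasta(self, path: str | Path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(seq), id=cell, description="")
            for cell, seq in zip(self.cells, self.sequences)
        ]
        seqio_write(records, str(path), "fasta")


@dataclass
class CellTree:
    """Unrooted parsimony tree over unique cell sequences.

    ``leaf_names[i]`` labels leaf id ``i``; internal node ids follow the
    leaves.  ``duplicates`` maps a representative leaf to cells with an
    identical sequence, re-attached as zero-length polytomy children in the
    Newick output.  ``edge_changes`` holds inferred substitutions per edge
    under one most-parsimonious reconstruction; lengths are changes per
    alignment column.
    """

    edges: list[Edge]
    leaf_names: list[str]
    score: int
    n_columns: int
    edge_changes: dict[Edge, int] = field(default_factory=dict)
    duplicates: dict[str, list[str]] = field(default_factory=dict)

    def edge_lengths(self) -> dict[Edge, float]:
        if self.n_columns == 0:
            return {e: 0.0 for e in self.edges}
        return {e: c / self.n_columns for e, c in self.edge_changes.items()}

    def all_cells(self) -> list[str]:
        out = list(self.leaf_names)
        for rep in self.leaf_names:
            out.extend(self.duplicates.get(rep, []))
        return out

    def to_newick(self) -> str:
        lengths = self.edge_lengths()

        def elen(u: int, v: int) -> float:
            return lengths.get((min(u, v), max(u, v)), 0.0)

        adj: dict[int, list[int]] = {}
        for u, v in self.edges:
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)

        def label(leaf: int) -> str:
            name = self.leaf_names[leaf]
            dups = self.duplicates.get(name, [])
            if not dups:
                return name
            inner = ",".join(
                f"{c}:0.0" for c in [name] + list(dups)
            )
            return f"({inner})"

        def render(node: int, parent: int) -> str:
            kids = [w for w in adj[node] if w != parent]
            if not kids:
                return label(node)
            inner = ",".join(
                f"{render(w, node)}:{elen(node, w):.6f}" for w in kids
            )
            return f"({inner})"

        n = len(self.leaf_names)
        if n == 1:
            return f"{label(0)};"
        if n == 2:
            return f"({label(0)}:{elen(0, 1):.6f},{label(1)}:0.0);"
        root = max(max(u, v) for u, v in self.edges)  # an internal node
        return render(root, -1) + ";"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Alignment construction
# ---------------------------------------------------------------------------

def build_alignment(
    matrix: GenotypeMatrix, max_missing_fraction: float = 0.8
) -> CellAlignment:
    """Map genotype calls to pseudo-sequences over the SNV sites.

    Cells whose fraction of N exceeds *max_missing_fraction* are excluded
    and logged in ``excluded``.
    """
    snv_sites = [
        s for s in matrix.sites if matrix.site_meta.loc[s, "variant_class"] == "SNV"
    ]
    if not snv_sites:
        raise ValueError("no SNV sites: cannot build a nucleotide alignment")
    if matrix.n_cells < 3:
        raise ValueError("need at least 3 cells")
    ref = matrix.site_meta.loc[snv_sites, "ref"].tolist()
    alt = matrix.site_meta.loc[snv_sites, "alt"].tolist()
    cols = [matrix.sites.index(s) for s in snv_sites]
    cells, seqs, excluded = [], [], []
    for i, cell in enumerate(matrix.cells):
        row = matrix.calls[i, cols]
        seq = "".join(
            "N" if np.isnan(v) else (alt[j] if v == 1 else ref[j])
            for j, v in enumerate(row)
        )
        n_frac = seq.count("N") / len(seq)
        if n_frac > max_missing_fraction:
            excluded.append((cell, n_frac))
        else:
            cells.append(cell)
            seqs.append(seq)
    return CellAlignment(
        cells=cells, sequences=seqs, site_order=snv_sites, excluded=excluded
    )


# ---------------------------------------------------------------------------
# Fitch scoring
# ---------------------------------------------------------------------------

def _adjacency(edges: list[Edge]) -> dict[int, list[int]]:
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    return adj


def _rooted_order(edges: list[Edge]) -> list[tuple[int, int]]:
    """Postorder (node, parent) pairs rooting the tree on the edge at leaf 0."""
    adj = _adjacency(edges)
    p = adj[0][0]
    order: list[tuple[int, int]] = []
    stack = [(p, 0)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for w in adj[node]:
            if w != parent:
                stack.append((w, node))
    return order[::-1]  # children before parents


def _fitch_sets(
    edges: list[Edge], masks: np.ndarray
) -> tuple[dict[int, np.ndarray], np.ndarray, int]:
    """First-pass Fitch state sets; returns (sets, per-column score, top node)."""
    n_leaves = masks.shape[0]
    order = _rooted_order(edges)
    children: dict[int, list[int]] = {}
    for node, parent in order:
        children.setdefault(parent, []).append(node)
    sets: dict[int, np.ndarray] = {}
    changes = np.zeros(masks.shape[1], dtype=np.int64)
    for node, parent in order:
        if node < n_leaves:
            sets[node] = masks[node]
            continue
        kids = children.get(node, [])
        s = None
        for w in kids:
            if s is None:
                s = sets[w]
                continue
            inter = s & sets[w]
            union = s | sets[w]
            empty = inter == 0
            changes += empty
            s = np.where(empty, union, inter)
        sets[node] = s
    top = order[-1][0]
    # virtual root joining leaf 0 with its neighbor
    inter = sets[top] & masks[0]
    empty = inter == 0
    changes += empty
    sets[-1] = np.where(empty, sets[top] | masks[0], inter)
    return sets, changes, top


def fitch_score(edges: list[Edge], alignment_or_masks) -> int:
    """Fitch small-parsimony score of a topology on an alignment.

    N (the full state set) never forces a change.  *edges* is the unrooted
    topology over leaf ids 0..n-1 (matching alignment order) and internal
    ids n..2n-3.
    """
    masks = (
        alignment_or_masks.masks()
        if isinstance(alignment_or_masks, CellAlignment)
        else np.asarray(alignment_or_masks, dtype=np.uint8)
    )
    degree: dict[int, int] = {}
    for u, v in edges:
        degree[u] = degree.get(u, 0) + 1
        degree[v] = degree.get(v, 0) + 1
    tree_leaves = {u for u, d in degree.items() if d == 1}
    if tree_leaves != set(range(masks.shape[0])):
        raise ValueError("topology leaf set does not match alignment cells")
    if len(edges) == 1:  # two-leaf tree
        return int(((masks[0] & masks[1]) == 0).sum())
    _, changes, _ = _fitch_sets(edges, masks)
    return int(changes.sum())


def _edge_changes(edges: list[Edge], masks: np.ndarray) -> tuple[dict[Edge, int], int]:
    """Substitutions per edge under one most-parsimonious reconstruction.

    Deterministic first-state (lowest-bit) tie-break in the Fitch traceback.
    """
    key = lambda u, v: (min(u, v), max(u, v))
    if len(edges) == 1:
        ch = int(((masks[0] & masks[1]) == 0).sum())
        return {key(*edges[0]): ch}, ch
    sets, changes, top = _fitch_sets(edges, masks)
    order = _rooted_order(edges)
    children: dict[int, list[int]] = {}
    for node, parent in order:
        children.setdefault(parent, []).append(node)
    counts = {key(u, v): np.zeros(masks.shape[1], dtype=np.int64) for u, v in edges}

    state: dict[int, np.ndarray] = {-1: _LOWBIT[sets[-1]]}
    # assign leaf 0 and the top node from the virtual root, charging any
    # change to the rooted edge (0, top)
    for child in (0, top):
        s = masks[0] if child == 0 else sets[child]
        keep = (state[-1] & s) > 0
        st = np.where(keep, state[-1], _LOWBIT[s])
        counts[key(0, top)] += ~keep
        state[child] = st.astype(np.uint8)
    stack = [top]
    while stack:
        node = stack.pop()
        for child in children.get(node, []):
            if child == 0 and node == top:
                continue
            s = sets[child]
            keep = (state[node] & s) > 0
            state[child] = np.where(keep, state[node], _LOWBIT[s]).astype(np.uint8)
            counts[key(node, child)] += ~keep
            stack.append(child)
    out = {e: int(c.sum()) for e, c in counts.items()}
    return out, sum(out.values())


# ---------------------------------------------------------------------------
# Topology enumeration and NNI search
# ---------------------------------------------------------------------------

def enumerate_topologies(n_leaves: int):
    """Yield every unrooted binary topology over leaves 0..n-1.

    Stepwise addition: leaf k attaches into each edge of each (k-1)-leaf
    topology, giving (2k-5)!! trees; internal ids are n..2n-3.
    """
    if n_leaves < 3:
        yield [(0, 1)] if n_leaves == 2 else []
        return
    n = n_leaves

    def grow(edges: list[Edge], k: int):
        if k == n:
            yield edges
            return
        w = n + (k - 2)  # next internal node id
        for i, (u, v) in enumerate(edges):
            new = edges[:i] + edges[i + 1:] + [(u, w), (v, w), (k, w)]
            yield from grow(new, k + 1)

    yield from grow([(0, n), (1, n), (2, n)], 3)


def _star_score(masks: np.ndarray) -> int:
    """Unit-cost parsimony score of a star tree (single internal node)."""
    per_state = [
        ((masks & s) == 0).sum(axis=0) for s in (1, 2, 4, 8)
    ]
    return int(np.minimum.reduce(per_state).sum())


def _p_distance(masks: np.ndarray) -> np.ndarray:
    """Pairwise p-distance with pairwise deletion of N positions."""
    n = masks.shape[0]
    valid = masks != 15
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            co = int(both.sum())
            if co == 0:
                d = 0.75  # no co-observed site: maximally uninformative
            else:
                d = float((masks[i][both] != masks[j][both]).sum()) / co
            D[i, j] = D[j, i] = d
    return D


def _nj_topology(D: np.ndarray) -> list[Edge]:
    """Neighbor-joining start topology via scikit-bio, as an edge list."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    n = D.shape[0]
    ids = [f"L{i}" for i in range(n)]
    tree = nj(DistanceMatrix(D, ids))
    counter = [n - 1]
    edges: list[Edge] = []

    def walk(node) -> int:
        if node.is_tip():
            return int(node.name[1:])
        counter[0] += 1
        my_id = counter[0]
        for child in node.children:
            edges.append((walk(child), my_id))
        return my_id

    root = tree.root()
    kids = list(root.children)
    if len(kids) == 2:
        # rooted output: suppress the root by joining its two children
        left, right = kids
        if left.is_tip() and right.is_tip():
            return [(int(left.name[1:]), int(right.name[1:]))]
        if left.is_tip():
            left, right = right, left
        # treat 'left' (internal) as the junction absorbing the root
        counter[0] += 1
        my_id = counter[0]
        for child in list(left.children) + [right]:
            edges.append((walk(child), my_id))
    else:
        counter[0] += 1
        my_id = counter[0]
        for child in kids:
            edges.append((walk(child), my_id))
    return edges


def _nni_neighbors(edges: list[Edge], n_leaves: int, edge: Edge):
    """The two NNI rearrangements across an internal edge."""
    u, v = edge
    adj = _adjacency(edges)
    if u < n_leaves or v < n_leaves:
        return
    a, b = [w for w in adj[u] if w != v]
    c, d = [w for w in adj[v] if w != u]
    others = [e for e in edges if set(e) not in ({a, u}, {b, u}, {c, v}, {d, v}, {u, v})]
    # swap b <-> c and b <-> d
    yield others + [(a, u), (c, u), (b, v), (d, v), (u, v)]
    yield others + [(a, u), (d, u), (c, v), (b, v), (u, v)]


def _nni_search(
    edges: list[Edge], masks: np.ndarray, seed: int
) -> tuple[list[Edge], int]:
    """Steepest-descent NNI hill climbing with a seeded sweep order."""
    n_leaves = masks.shape[0]
    rng = np.random.default_rng(seed)
    best = list(edges)
    best_score = fitch_score(best, masks)
    improved = True
    while improved:
        improved = False
        internal = [
            (min(u, v), max(u, v))
            for u, v in best
            if u >= n_leaves and v >= n_leaves
        ]
        order = rng.permutation(len(internal))
        sweep_best, sweep_score = None, best_score
        for idx in order:
            for cand in _nni_neighbors(best, n_leaves, internal[idx]):
                s = fitch_score(cand, masks)
                if s < sweep_score:
                    sweep_best, sweep_score = cand, s
        if sweep_best is not None:
            best, best_score = sweep_best, sweep_score
            improved = True
    return best, best_score


def _greedy_addition(masks: np.ndarray, order: np.ndarray) -> list[Edge]:
    """Stepwise addition: insert each leaf at the Fitch-cheapest edge.

    *order* permutes leaves 1..n-1 (leaf 0 always enters first so scoring
    can root on its pendant edge); ties break on the first-found edge.
    """
    n = masks.shape[0]
    leaves = [0] + [int(x) for x in order if x != 0]
    edges: list[Edge] = [(leaves[0], n), (leaves[1], n), (leaves[2], n)]
    for k in range(3, n):
        leaf = leaves[k]
        w = n + (k - 2)
        best_cand, best_s = None, None
        for i, (u, v) in enumerate(edges):
            cand = edges[:i] + edges[i + 1:] + [(u, w), (v, w), (leaf, w)]
            s = _partial_score(cand, masks)
            if best_s is None or s < best_s:
                best_cand, best_s = cand, s
        edges = best_cand
    return edges


def _partial_score(edges: list[Edge], masks: np.ndarray) -> int:
    """Fitch score of a (possibly partial) tree containing leaf 0."""
    if len(edges) == 1:
        u, v = edges[0]
        return int(((masks[u] & masks[v]) == 0).sum())
    _, changes, _ = _fitch_sets(edges, masks)
    return int(changes.sum())


def search_mp_tree(
    alignment: CellAlignment,
    mode: str = "auto",
    seed: int = 0,
    exhaustive_limit: int = 9,
) -> CellTree:
    """Maximum-parsimony tree over the alignment's unique sequences.

    Identical sequences are collapsed before the search and re-attached to
    their representative as zero-length polytomy children.  With <=
    *exhaustive_limit* unique sequences (mode ``auto`` or ``exhaustive``)
    all unrooted binary topologies are enumerated and a global optimum is
    returned (first-found tie-break); otherwise NNI hill climbing from a
    neighbor-joining start tree on p-distances.
    """
    if mode not in ("auto", "exhaustive", "nni"):
        raise ValueError(f"unknown search mode {mode!r}")
    seen: dict[str, str] = {}
    reps: list[str] = []
    rep_seqs: list[str] = []
    duplicates: dict[str, list[str]] = {}
    for cell, seq in zip(alignment.cells, alignment.sequences):
        if seq in seen:
            duplicates.setdefault(seen[seq], []).append(cell)
        else:
            seen[seq] = cell
            reps.append(cell)
            rep_seqs.append(seq)
    masks = np.array([[_MASK[b] for b in s] for s in rep_seqs], dtype=np.uint8)
    n = len(reps)

    if n < 4:
        warnings.warn(
            f"only {n} unique sequences: returning a degenerate tree", stacklevel=2
        )
        if n == 1:
            edges, score = [], 0
        elif n == 2:
            edges = [(0, 1)]
            score = int(((masks[0] & masks[1]) == 0).sum())
        else:
            edges = [(0, 3), (1, 3), (2, 3)]
            score = _star_score(masks)
        changes, _ = (_edge_changes(edges, masks) if n == 2 else ({}, 0))
        if n == 3:
            changes = {  # charge each leaf edge by a 3-leaf reconstruction
                (i, 3): 0 for i in range(3)
            }
            st = None
            for s_state in (1, 2, 4, 8):
                cost = [((masks[i] & s_state) == 0) for i in range(3)]
                tot = sum(c.sum() for c in cost)
                if st is None or tot < st[0]:
                    st = (tot, cost)
            for i in range(3):
                changes[(i, 3)] = int(st[1][i].sum())
        return CellTree(
            edges=edges,
            leaf_names=reps,
            score=score,
            n_columns=alignment.n_columns,
            edge_changes=changes,
            duplicates=duplicates,
        )

    if mode == "exhaustive" or (mode == "auto" and n <= exhaustive_limit):
        best, best_score = None, None
        for topo in enumerate_topologies(n):
            s = fitch_score(topo, masks)
            if best_score is None or s < best_score:
                best, best_score = topo, s
    else:
        # NJ start plus, at small n where tree signal is weak, a few seeded
        # greedy stepwise-addition restarts; NNI hill-climb from each
        rng = np.random.default_rng(seed)
        starts = [_nj_topology(_p_distance(masks))]
        n_restarts = 20 if n <= 16 else (2 if n <= 40 else 0)
        for _ in range(n_restarts):
            starts.append(_greedy_addition(masks, rng.permutation(n)))
        best, best_score = None, None
        for start in starts:
            topo, s = _nni_search(start, masks, int(rng.integers(2**31)))
            if best_score is None or s < best_score:
                best, best_score = topo, s

    changes, total = _edge_changes(best, masks)
    assert total == best_score, "traceback changes must sum to the Fitch score"
    return CellTree(
        edges=best,
        leaf_names=reps,
        score=best_score,
        n_columns=alignment.n_columns,
        edge_changes=changes,
        duplicates=duplicates,
    )


def branch_lengths(tree: CellTree, alignment: CellAlignment | None = None) -> dict[Edge, float]:
    """Per-edge substitutions per site from the stored reconstruction."""
    return tree.edge_lengths()
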