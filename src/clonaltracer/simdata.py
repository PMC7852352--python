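"""Synthetic single-cell targeted-genotyping datasets with known truth.

Emulates a tumor targeted-sequencing panel of ~60 mutation sites genotyped
across single cells from normal (paratumor) and tumor tissues: a clone tree
is planted with a shared trunk and private branches, cells are sampled from
observed clones, and the true genotypes are corrupted by an explicit noise
model — per-allele dropout at rate ``d`` (so a het mutant is seen as
reference with probability d(1-d) and missing with d^2), false-positive
mutant calls at rate ``f`` on reference genotypes, and site-level
missingness ``m`` applied after dropout.  Paired pseudo-bulk VAFs and a
control heterozygous-germline matrix for dropout estimation are generated
alongside.  Everything is deterministic given the config seed; independent
sub-streams per stage keep stages individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cloneinfer import CloneEdge, CloneNode, CloneTree
from .genomatrix import SITE_COLUMNS, GenotypeMatrix
from .spectrum import SUBSTITUTION_CLASSES, classify_substitution

#: default substitution bias: T>A-dominant, as under aristolochic-acid-like
#: carcinogen exposure reported for liver tumors (order matches
#: SUBSTITUTION_CLASSES: C>A, C>G, C>T, T>A, T>C, T>G)
DEFAULT_SIGNATURE_BIAS = (0.08, 0.04, 0.14, 0.60, 0.08, 0.06)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class SimulationConfigError(ValueError):
    """Invalid simulation parameterization."""


@dataclass
class SimulationConfig:
    """Full parameterization of the generative model."""

    n_clones: int = 4
    tree_shape: str = "bifurcating"  # linear | star | bifurcating | custom
    trunk_size: int = 10
    private_size_range: tuple[int, int] = (3, 5)
    cells_per_clone: int | dict[str, int] = 50
    n_paratumor_cells: int = 10
    tissue_assignment: dict[str, str] | None = None
    panel_size: int = 60
    ado_rate: float = 0.1
    fp_rate: float = 0.005
    missing_rate: float = 0.05
    signature_bias: Sequence[float] = DEFAULT_SIGNATURE_BIAS
    indel_fraction: float = 0.1
    seed: int = 0
    # only for tree_shape == "custom": (parent, child, n_mutations) triples;
    # node names starting with "anc" are unobserved ancestors
    custom_edges: list[tuple[str, str, int]] | None = None

    def validate(self) -> None:
        if self.n_clones < 1:
            raise SimulationConfigError("n_clones must be positive")
        if self.tree_shape not in ("linear", "star", "bifurcating", "custom"):
            raise SimulationConfigError(f"unknown tree_shape {self.tree_shape!r}")
        if self.tree_shape == "custom" and not self.custom_edges:
            raise SimulationConfigError("custom tree_shape requires custom_edges")
        if self.trunk_size < 0 or self.n_paratumor_cells < 0:
            raise SimulationConfigError("sizes must be non-negative")
        lo, hi = self.private_size_range
        if lo < 0 or hi < lo:
            raise SimulationConfigError("invalid private_size_range")
        for name in ("ado_rate", "fp_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise SimulationConfigError(f"{name} must be in [0, 1)")
        if not 0 <= self.indel_fraction <= 1:
            raise SimulationConfigError("indel_fraction must be in [0, 1]")
        bias = np.asarray(self.signature_bias, dtype=float)
        if bias.shape != (6,) or (bias < 0).any() or abs(bias.sum() - 1) > 1e-9:
            raise SimulationConfigError(
                "signature_bias must be 6 non-negative probabilities summing to 1"
            )

    def rng_streams(self) -> dict[str, np.random.Generator]:
        """Named independent generators derived from the single seed."""
        ss = np.random.SeedSequence(self.seed)
        names = ("tree", "cells", "noise", "control", "bulk")
        return dict(zip(names, map(np.random.default_rng, ss.spawn(len(names)))))


@dataclass
class GroundTruth:
    """Simulated truth: tree, cell-to-clone labels, noiseless matrix."""

    true_tree: CloneTree
    cell_labels: dict[str, str]
    true_matrix: GenotypeMatrix
    clone_fractions: dict[str, float]


@dataclass
class SimulatedDataset:
    """Bundle of everything one simulation run produces."""

    config: SimulationConfig
    tree: CloneTree
    sites: pd.DataFrame
    truth: GroundTruth
    matrix: GenotypeMatrix  # noise-applied observed matrix
    bulk_vaf: dict[str, float]
    control: pd.DataFrame


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def _tree_edges(config: SimulationConfig, rng: np.random.Generator) -> list[tuple[str, str, int]]:
    """(parent, child, n_mutations) triples for the configured shape."""
    lo, hi = config.private_size_range
    draw = lambda: int(rng.integers(lo, hi + 1))
    n = config.n_clones
    if config.tree_shape == "custom":
        return [(p, c, int(k)) for p, c, k in config.custom_edges]
    if config.tree_shape == "linear":
        edges = [("root", "clone_1", config.trunk_size)]
        for i in range(2, n + 1):
            edges.append((f"clone_{i - 1}", f"clone_{i}", draw()))
        return edges
    if config.tree_shape == "star":
        if config.trunk_size == 0:
            return [("root", f"clone_{i}", draw()) for i in range(1, n + 1)]
        # observed founder hub carrying the trunk, other clones derived
        edges = [("root", "clone_1", config.trunk_size)]
        edges += [("clone_1", f"clone_{i}", draw()) for i in range(2, n + 1)]
        return edges
    # bifurcating: clones are leaves of a balanced binary tree whose
    # internal nodes are unobserved ancestors
    edges: list[tuple[str, str, int]] = []
    counter = [0]

    def split(parent: str, leaves: list[str], n_mut: int) -> None:
        if len(leaves) == 1:
            edges.append((parent, leaves[0], n_mut))
            return
        counter[0] += 1
        anc = f"anc_{counter[0]}"
        edges.append((parent, anc, n_mut))
        half = (len(leaves) + 1) // 2
        split(anc, leaves[:half], draw())
        split(anc, leaves[half:], draw())

    split("root", [f"clone_{i}" for i in range(1, n + 1)], config.trunk_size)
    return edges


def _random_site_meta(
    site_ids: list[str],
    n_snv_needed: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw per-site coordinates, alleles and gene symbols.

    n_snv_needed flags sites forced to be SNVs (planted sites decide
    SNV/INDEL by indel_fraction upstream; this receives the resolved flag).
    """
    rows = []
    positions = set()
    for i, site in enumerate(site_ids):
        chrom = str(int(rng.integers(1, 23)))
        while True:
            pos = int(rng.integers(1, 250_000_000))
            if (chrom, pos) not in positions:
                positions.add((chrom, pos))
                break
        if n_snv_needed[i]:
            cls = SUBSTITUTION_CLASSES[
                rng.choice(6, p=np.asarray(config.signature_bias, float))
            ]
            ref, alt = cls.split(">")
            if rng.random() < 0.5:  # report on the opposite strand
                ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
            vclass = "SNV"
        else:
            base = "ACGT"[int(rng.integers(4))]
            ins = "ACGT"[int(rng.integers(4))]
            if rng.random() < 0.5:
                ref, alt = base, base + ins  # insertion
            else:
                ref, alt = base + ins, base  # deletion
            vclass = "INDEL"
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "gene": f"G{i + 1:03d}",
                "variant_class": vclass,
                "vaf": np.nan,
            }
        )
    return pd.DataFrame(rows, index=site_ids)[SITE_COLUMNS]


def simulate_clone_tree(config: SimulationConfig) -> tuple[CloneTree, pd.DataFrame]:
    """Plant a clone tree and the target-site panel it mutates.

    Returns the truth tree (root carries an empty set; every node's
    cumulative set is the union along its root path) and the panel site
    table.  Mutations are assigned disjoint site ids edge by edge; panel
    sites left over are invariant reference columns.  Each planted SNV's
    ref/alt pair is drawn from ``signature_bias``; a fraction
    ``indel_fraction`` of planted mutations are INDELs instead.
    """
    config.validate()
    rng = config.rng_streams()["tree"]
    edges = _tree_edges(config, rng)
    total = sum(k for _, _, k in edges)
    if total > config.panel_size:
        raise SimulationConfigError(
            f"{total} planted mutations exceed panel_size={config.panel_size}"
        )
    width = max(3, len(str(config.panel_size)))
    site_ids = [f"S{i + 1:0{width}d}" for i in range(config.panel_size)]
    # planted sites choose SNV vs INDEL; invariant leftovers are SNVs
    is_snv = np.ones(config.panel_size, dtype=bool)
    is_snv[:total] = rng.random(total) >= config.indel_fraction
    sites = _random_site_meta(site_ids, is_snv, config, rng)

    observed = _observed_set(config, edges)
    nodes: dict[str, CloneNode] = {
        "root": CloneNode("root", frozenset(), observed=False)
    }
    tree_edges: list[CloneEdge] = []
    cursor = 0
    cumulative = {"root": frozenset()}
    for parent, child, k in edges:
        if parent not in cumulative:
            raise SimulationConfigError(
                f"edge parent {parent!r} appears before being created"
            )
        acquired = frozenset(site_ids[cursor:cursor + k])
        cursor += k
        cumulative[child] = cumulative[parent] | acquired
        nodes[child] = CloneNode(
            child, cumulative[child], observed=child in observed
        )
        tree_edges.append(CloneEdge(parent, child, acquired))
    tree = CloneTree(nodes=nodes, edges=tree_edges)
    tree.validate()
    return tree, sites


def _observed_set(
    config: SimulationConfig, edges: list[tuple[str, str, int]]
) -> set[str]:
    """Which planted nodes receive cells (are observed clones)."""
    children = [c for _, c, _ in edges]
    if isinstance(config.cells_per_clone, dict):
        unknown = set(config.cells_per_clone) - set(children)
        if unknown:
            raise SimulationConfigError(f"cells_per_clone names unknown clones {unknown}")
        return {c for c, n in config.cells_per_clone.items() if n > 0}
    return {c for c in children if not c.startswith("anc")}


# ---------------------------------------------------------------------------
# Cell sampling and noise
# ---------------------------------------------------------------------------

def sample_cells(
    tree: CloneTree, sites: pd.DataFrame, config: SimulationConfig
) -> GroundTruth:
    """Draw cells from observed clones plus all-reference paratumor cells."""
    config.validate()
    observed = sorted(n.node_id for n in tree.observed_nodes())
    if isinstance(config.cells_per_clone, dict):
        counts = {c: int(config.cells_per_clone.get(c, 0)) for c in observed}
    else:
        counts = {c: int(config.cells_per_clone) for c in observed}
    tissue = config.tissue_assignment or {c: "tumor" for c in observed}
    missing = [c for c in observed if counts[c] > 0 and c not in tissue]
    if missing:
        raise SimulationConfigError(
            f"tissue_assignment missing observed clones {missing}"
        )

    site_ids = list(sites.index)
    cells: list[str] = []
    tissues: list[str] = []
    labels: dict[str, str] = {}
    rows: list[np.ndarray] = []
    for i in range(config.n_paratumor_cells):
        cells.append(f"para_c{i + 1:03d}")
        tissues.append("paratumor")
        rows.append(np.zeros(len(site_ids)))
    for clone in observed:
        profile = np.array(
            [1.0 if s in tree.nodes[clone].cumulative else 0.0 for s in site_ids]
        )
        for i in range(counts[clone]):
            cell = f"{clone}_c{i + 1:03d}"
            cells.append(cell)
            tissues.append(tissue[clone])
            labels[cell] = clone
            rows.append(profile.copy())
        tree.nodes[clone].tissue_counts = {tissue[clone]: counts[clone]}
        tree.nodes[clone].member_cells = [
            f"{clone}_c{i + 1:03d}" for i in range(counts[clone])
        ]

    n_tumor = sum(counts.values())
    fractions = {
        c: (counts[c] / n_tumor if n_tumor else 0.0) for c in observed
    }
    matrix = GenotypeMatrix(
        cells=cells,
        sites=site_ids,
        calls=np.vstack(rows) if rows else np.zeros((0, len(site_ids))),
        site_meta=sites.copy(),
        cell_meta=pd.DataFrame({"tissue": tissues}, index=cells),
    )
    return GroundTruth(
        true_tree=tree,
        cell_labels=labels,
        true_matrix=matrix,
        clone_fractions=fractions,
    )


def apply_noise(truth: GroundTruth, config: SimulationConfig) -> GenotypeMatrix:
    """Corrupt the true matrix with dropout, false positives and missingness.

    Heterozygous mutant (1) entries: both alleles drop with probability d^2
    (missing), the mutant allele alone drops with d(1-d) (observed 0),
    otherwise observed 1.  Reference (0) entries flip to 1 with probability
    f.  Finally every non-missing entry is masked missing with probability
    m.  Deterministic given the config seed.
    """
    config.validate()
    rng = config.rng_streams()["noise"]
    d, f, m = config.ado_rate, config.fp_rate, config.missing_rate
    G = truth.true_matrix.calls.copy()
    u = rng.random(G.shape)
    mut = G == 1
    G[mut & (u < d * d)] = np.nan
    G[mut & (u >= d * d) & (u < d * d + d * (1 - d))] = 0.0
    ref = truth.true_matrix.calls == 0
    G[ref & (u < f)] = 1.0
    mask = rng.random(G.shape) < m
    G[mask & ~np.isnan(G)] = np.nan
    out = truth.true_matrix
    return GenotypeMatrix(
        cells=list(out.cells),
        sites=list(out.sites),
        calls=G,
        site_meta=out.site_meta.copy(),
        cell_meta=out.cell_meta.copy(),
    )


def simulate_bulk_vaf(truth: GroundTruth, purity: float = 1.0) -> dict[str, float]:
    """Pseudo-bulk VAF per site under a heterozygous diploid model.

    VAF(site) = purity * (sum of fractions of clones carrying the site) / 2;
    invariant reference sites get 0.
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    tree = truth.true_tree
    vaf = {}
    for site in truth.true_matrix.sites:
        carried = sum(
            frac
            for clone, frac in truth.clone_fractions.items()
            if site in tree.nodes[clone].cumulative
        )
        vaf[site] = purity * carried / 2.0
    return vaf


def simulate_control_matrix(
    config: SimulationConfig, n_cells: int = 100, n_sites: int = 100
) -> pd.DataFrame:
    """Allele-presence calls at heterozygous germline control sites.

    Each cell x site observation reflects per-allele dropout at rate d:
    both alleles present with (1-d)^2, exactly one (``ref-only`` or
    ``alt-only``, equally likely) with 2d(1-d), and missing with d^2;
    site-level missingness m is applied on top.
    """
    config.validate()
    rng = config.rng_streams()["control"]
    d, m = config.ado_rate, config.missing_rate
    u = rng.random((n_cells, n_sites))
    side = rng.random((n_cells, n_sites)) < 0.5
    out = np.full((n_cells, n_sites), "both", dtype=object)
    single = (u >= d * d) & (u < d * d + 2 * d * (1 - d))
    out[single & side] = "ref-only"
    out[single & ~side] = "alt-only"
    out[u < d * d] = "NA"
    out[rng.random((n_cells, n_sites)) < m] = "NA"
    return pd.DataFrame(
        out,
        index=[f"ctrl_c{i + 1:03d}" for i in range(n_cells)],
        columns=[f"H{j + 1:03d}" for j in range(n_sites)],
    )


def simulate_dataset(
    config: SimulationConfig, purity: float = 1.0, control_observations: int = 10_000
) -> SimulatedDataset:
    """Run the full generative model and annotate bulk VAFs on the matrix."""
    tree, sites = simulate_clone_tree(config)
    truth = sample_cells(tree, sites, config)
    noisy = apply_noise(truth, config)
    vaf = simulate_bulk_vaf(truth, purity=purity)
    for gm in (truth.true_matrix, noisy):
        gm.site_meta["vaf"] = [vaf[s] for s in gm.sites]
    n_ctrl_sites = 100
    n_ctrl_cells = max(1, control_observations // n_ctrl_sites)
    control = simulate_control_matrix(config, n_ctrl_cells, n_ctrl_sites)
    return SimulatedDataset(
        config=config,
        tree=tree,
        sites=sites,
        truth=truth,
        matrix=noisy,
        bulk_vaf=vaf,
        control=control,
    )


# ---------------------------------------------------------------------------
# Canned study-like scenarios
# ---------------------------------------------------------------------------

def bifurcating_recovery_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Four observed leaf clones under two unobserved ancestors.

    The default recovery benchmark: trunk of 10 mutations, 3-5 per other
    edge, 50 cells per clone, d=0.1, f=0.005, m=0.05 on a 60-site panel.
    """
    cfg = SimulationConfig(
        n_clones=4,
        tree_shape="bifurcating",
        trunk_size=10,
        private_size_range=(3, 5),
        cells_per_clone=50,
        n_paratumor_cells=10,
        panel_size=60,
        ado_rate=0.1,
        fp_rate=0.005,
        missing_rate=0.05,
        seed=seed,
    )
    return replace(cfg, **overrides)


def two_tissue_metastasis_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Two-tissue scenario: shared trunk, unobserved metastasis ancestor.

    An observed founder clone carries a 10-mutation trunk shared by primary
    tumor and metastasis; a second primary clone adds private mutations; two
    metastatic clones descend from an unobserved ancestor that acquired 3
    metastasis-private clonal mutations — the "common origin, independent
    evolution" structure with a virtual ancestor in the metastasis.
    """
    cfg = SimulationConfig(
        n_clones=4,
        tree_shape="custom",
        custom_edges=[
            ("root", "clone_1", 10),      # founder: the shared trunk
            ("clone_1", "clone_2", 7),    # primary-private branch
            ("clone_1", "anc_met", 3),    # unobserved metastasis ancestor
            ("anc_met", "clone_3", 5),
            ("anc_met", "clone_4", 6),
        ],
        cells_per_clone=25,
        n_paratumor_cells=30,
        tissue_assignment={
            "clone_1": "tumor",
            "clone_2": "tumor",
            "clone_3": "metastasis",
            "clone_4": "metastasis",
        },
        panel_size=60,
        seed=seed,
    )
    return replace(cfg, **overrides)
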