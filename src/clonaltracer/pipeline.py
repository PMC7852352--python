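"""End-to-end orchestration: QC -> filter -> clones -> tree -> spectra -> phylo.

A run is fully described by a :class:`RunConfig` (YAML-loadable): either
paths to an observed genotype-matrix triplet or a simulate block with a
:class:`~clonaltracer.simdata.SimulationConfig`.  Every stage's artifacts
are written to the output directory together with a manifest recording all
parameters (defaults included) and machine-readable warnings, so any run is
replayable; identical configs produce byte-identical outputs.  A recovery
benchmark sweeps noise grids and scores clone-assignment ARI, trunk-set
recovery, topology recovery and ADO-estimator bias against simulated truth.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import __version__
from .cloneinfer import (
    CloneTree,
    build_clone_tree,
    call_clones,
    classify_mutations,
    resolve_conflicts,
)
from .genomatrix import (
    GenotypeMatrix,
    estimate_ado,
    mutated_cell_fraction,
    qc_report,
    read_control_matrix,
    read_genotype_matrix,
    write_control_matrix,
    write_genotype_matrix,
    write_vcf_lite,
)
from .phylo import build_alignment, search_mp_tree
from .simdata import (
    SimulatedDataset,
    SimulationConfig,
    bifurcating_recovery_config,
    simulate_dataset,
)
from .spectrum import branch_spectra, spectra_table


@dataclass
class StageParams:
    """Tunable analysis parameters shared across stages."""

    tau: float = 0.1
    min_cells: int = 5
    min_overlap: int = 5
    min_site_coverage: float = 0.5
    max_paratumor_fraction: float = 0.1
    max_missing_fraction: float = 0.8
    phylo_mode: str = "auto"
    correlation: str = "pearson"
    purity: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.tau <= 1:
            raise ValueError("tau must be in [0, 1]")
        if self.min_cells < 1 or self.min_overlap < 0:
            raise ValueError("invalid min_cells/min_overlap")
        for name in ("min_site_coverage", "max_paratumor_fraction",
                     "max_missing_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.phylo_mode not in ("auto", "exhaustive", "nni"):
            raise ValueError(f"unknown phylo_mode {self.phylo_mode!r}")
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")


@dataclass
class RunConfig:
    """Exactly one of *inputs* (file paths) or *simulate* must be present."""

    outdir: str
    inputs: dict[str, str] | None = None
    simulate: SimulationConfig | None = None
    params: StageParams = field(default_factory=StageParams)

    def validate(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError(
                "config must contain exactly one of 'inputs' and 'simulate'"
            )
        if self.inputs is not None:
            missing = {"matrix", "sites", "cells"} - set(self.inputs)
            if missing:
                raise ValueError(f"inputs block missing paths: {sorted(missing)}")
        else:
            self.simulate.validate()
        self.params.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.get("simulate")
        if sim is not None:
            if "private_size_range" in sim:
                sim["private_size_range"] = tuple(sim["private_size_range"])
            if "custom_edges" in sim and sim["custom_edges"] is not None:
                sim["custom_edges"] = [tuple(e) for e in sim["custom_edges"]]
            if "signature_bias" in sim:
                sim["signature_bias"] = tuple(sim["signature_bias"])
            sim = SimulationConfig(**sim)
        params = StageParams(**raw.get("params", {}))
        cfg = cls(
            outdir=raw.get("outdir", "clonal-tracer-out"),
            inputs=raw.get("inputs"),
            simulate=sim,
            params=params,
        )
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        sim = dataclasses.asdict(self.simulate) if self.simulate else None
        if sim is not None:
            sim["signature_bias"] = list(sim["signature_bias"])
            sim["private_size_range"] = list(sim["private_size_range"])
        return {
            "outdir": self.outdir,
            "inputs": self.inputs,
            "simulate": sim,
            "params": dataclasses.asdict(self.params),
        }


@dataclass
class RunResult:
    """In-memory handles on everything a run produced."""

    config: RunConfig
    matrix: GenotypeMatrix
    qc: dict
    clones: list
    unassigned: list[str]
    clone_tree: CloneTree
    classification: object
    spectra: pd.DataFrame
    cell_tree: object
    manifest: dict
    dataset: SimulatedDataset | None = None


def run_all(config: RunConfig) -> RunResult:
    """Execute the full analysis and write every artifact plus a manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = config.params
    log: list[dict] = []
    dataset = None

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        if config.simulate is not None:
            dataset = simulate_dataset(config.simulate, purity=p.purity)
            matrix = dataset.matrix
            control = dataset.control
            write_genotype_matrix(
                matrix,
                outdir / "matrix.tsv",
                outdir / "sites.tsv",
                outdir / "cells.tsv",
            )
            write_vcf_lite(matrix, outdir / "sites.vcf")
            write_control_matrix(control, outdir / "controls.tsv")
            dataset.tree.to_json(outdir / "true_tree.json")
            pd.DataFrame(
                {
                    "cell_id": sorted(dataset.truth.cell_labels),
                    "clone_id": [
                        dataset.truth.cell_labels[c]
                        for c in sorted(dataset.truth.cell_labels)
                    ],
                }
            ).to_csv(outdir / "true_cell_labels.tsv", sep="\t", index=False)
        else:
            matrix = read_genotype_matrix(
                config.inputs["matrix"], config.inputs["sites"], config.inputs["cells"]
            )
            control = (
                read_control_matrix(config.inputs["controls"])
                if config.inputs.get("controls")
                else None
            )

        # --- QC and germline/artifact filtering -------------------------
        qc = qc_report(
            matrix,
            control_matrix=control,
            max_paratumor_fraction=p.max_paratumor_fraction,
            correlation=p.correlation,
        )
        (outdir / "qc.json").write_text(
            json.dumps(qc.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        keep = [
            s
            for s in matrix.sites
            if s not in {r["site_id"] for r in qc.filtered_sites}
        ]
        filtered = matrix.subset(sites=keep)

        # --- clone calling ----------------------------------------------
        clones, unassigned = call_clones(
            filtered,
            tau=p.tau,
            min_cells=p.min_cells,
            min_overlap=p.min_overlap,
            min_site_coverage=p.min_site_coverage,
        )
        if not clones:
            raise RuntimeError(
                "clone calling produced no clones; lower min_cells or raise tau"
            )
        pd.DataFrame(
            [(c, cl.clone_id) for cl in clones for c in cl.member_cells]
            + [(c, "unassigned") for c in unassigned],
            columns=["cell_id", "clone_id"],
        ).to_csv(outdir / "clone_assignments.tsv", sep="\t", index=False)

        # --- tree, classification, spectra ------------------------------
        fractions = mutated_cell_fraction(filtered, ("tumor", "metastasis"))
        clones, removal_log = resolve_conflicts(clones, fractions)
        tree = build_clone_tree(clones)
        tree.to_json(outdir / "clone_tree.json")
        classification = classify_mutations(tree, all_sites=list(matrix.sites))
        classification.to_frame().to_csv(
            outdir / "classification.tsv", sep="\t", index=False
        )
        spectra = branch_spectra(tree, matrix.site_meta)
        stable = spectra_table(spectra)
        stable.to_csv(outdir / "spectra.tsv", sep="\t", index=False)

        # --- cell-level parsimony tree ----------------------------------
        alignment = build_alignment(
            filtered, max_missing_fraction=p.max_missing_fraction
        )
        alignment.to_fasta(outdir / "alignment.fasta")
        cell_tree = search_mp_tree(alignment, mode=p.phylo_mode, seed=p.seed)
        cell_tree.write_newick(outdir / "cell_tree.nwk")

        for w in caught:
            log.append({"warning": str(w.message)})

    manifest = {
        "tool": "clonal-tracer",
        "version": __version__,
        "config": config.to_dict(),
        "stages": {
            "qc": {
                "ado_estimate": qc.ado_estimate,
                "vaf_concordance_r": qc.vaf_concordance_r,
                "n_filtered_sites": len(qc.filtered_sites),
            },
            "clones": {
                "n_clones": len(clones),
                "n_unassigned_cells": len(unassigned),
                "conflict_removals": removal_log,
            },
            "tree": {
                "n_virtual_ancestors": len(tree.virtual_nodes()),
                "n_observed_clones": len(tree.observed_nodes()),
            },
            "classification": {
                cat: len(classification.sites_in(cat))
                for cat in sorted(set(classification.category.values()))
            },
            "phylo": {
                "parsimony_score": cell_tree.score,
                "n_unique_sequences": len(cell_tree.leaf_names),
                "n_excluded_cells": len(alignment.excluded),
            },
        },
        "warnings": log,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    _write_report(outdir / "report.md", manifest, clones, tree, classification)
    return RunResult(
        config=config,
        matrix=matrix,
        qc=qc.to_dict(),
        clones=clones,
        unassigned=unassigned,
        clone_tree=tree,
        classification=classification,
        spectra=stable,
        cell_tree=cell_tree,
        manifest=manifest,
        dataset=dataset,
    )


def _write_report(path: Path, manifest: dict, clones, tree, classification) -> None:
    lines = ["# clonal-tracer run report", ""]
    qc = manifest["stages"]["qc"]
    lines += [
        "## QC",
        "",
        f"- ADO estimate: {qc['ado_estimate']}",
        f"- VAF concordance r: {qc['vaf_concordance_r']}",
        f"- sites filtered as germline/artifact: {qc['n_filtered_sites']}",
        "",
        "## Clones",
        "",
        "| clone | cells | tissues | consensus mutations |",
        "|-------|-------|---------|---------------------|",
    ]
    for c in clones:
        tiss = ",".join(f"{t}:{n}" for t, n in sorted(c.tissue_composition.items()))
        lines.append(
            f"| {c.clone_id} | {c.n_cells} | {tiss} | {len(c.consensus)} |"
        )
    lines += ["", "## Clone tree", ""]
    for e in sorted(tree.edges, key=lambda e: (e.parent, e.child)):
        flag = "" if tree.nodes[e.child].observed else " (virtual ancestor)"
        lines.append(
            f"- {e.parent} -> {e.child}{flag}: acquires {len(e.acquired)} "
            f"mutation(s) [{', '.join(sorted(e.acquired))}]"
        )
    lines += ["", "## Mutation classification", ""]
    for cat, n in sorted(manifest["stages"]["classification"].items()):
        lines.append(f"- {cat}: {n} site(s)")
    ph = manifest["stages"]["phylo"]
    lines += [
        "",
        "## Cell phylogeny",
        "",
        f"- parsimony score: {ph['parsimony_score']}",
        f"- unique sequences: {ph['n_unique_sequences']}",
        "",
    ]
    path.write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# Recovery benchmarking against simulated truth
# ---------------------------------------------------------------------------

def evaluate_recovery(
    sim_config: SimulationConfig, params: StageParams | None = None
) -> dict:
    """Run inference on one simulated dataset and score it against truth.

    Returns clone-assignment ARI (unassigned cells count as singletons),
    exact trunk-set recovery, virtual-ancestor and full-topology recovery,
    and the ADO-estimator error on the paired control matrix.
    """
    p = params or StageParams()
    ds = simulate_dataset(sim_config, purity=p.purity)
    truth = ds.truth

    clones, unassigned = call_clones(
        ds.matrix,
        tau=p.tau,
        min_cells=p.min_cells,
        min_overlap=p.min_overlap,
        min_site_coverage=p.min_site_coverage,
    )
    tumor_cells = sorted(truth.cell_labels)
    inferred = {}
    for cl in clones:
        for c in cl.member_cells:
            inferred[c] = cl.clone_id
    for i, c in enumerate(unassigned):
        inferred[c] = f"unassigned_{i}"
    true_lab = [truth.cell_labels[c] for c in tumor_cells]
    inf_lab = [inferred.get(c, "none") for c in tumor_cells]
    ari = adjusted_rand_score(true_lab, inf_lab) if clones else 0.0

    trunk_truth = frozenset.intersection(
        *(n.cumulative for n in truth.true_tree.observed_nodes())
    )
    trunk_ok = False
    virtual_ok = False
    topology_ok = False
    if clones:
        fractions = mutated_cell_fraction(ds.matrix, ("tumor", "metastasis"))
        resolved, _ = resolve_conflicts(clones, fractions)
        tree = build_clone_tree(resolved)
        classification = classify_mutations(tree)
        trunk_ok = frozenset(classification.sites_in("trunk")) == trunk_truth
        true_virtual = {
            n.cumulative for n in truth.true_tree.virtual_nodes()
        }
        got_virtual = {n.cumulative for n in tree.virtual_nodes()}
        virtual_ok = got_virtual == true_virtual
        true_family = {
            n.cumulative
            for n in truth.true_tree.nodes.values()
            if n.node_id != truth.true_tree.root
        }
        got_family = {
            n.cumulative for n in tree.nodes.values() if n.node_id != tree.root
        }
        topology_ok = got_family == true_family

    ado_err = estimate_ado(ds.control) - sim_config.ado_rate
    return {
        "ari": float(ari),
        "trunk_recovered": bool(trunk_ok),
        "virtual_ancestors_recovered": bool(virtual_ok),
        "topology_recovered": bool(topology_ok),
        "ado_error": float(ado_err),
        "n_clones_called": len(clones),
        "n_unassigned": len(unassigned),
    }


def recovery_benchmark(
    grid: list[dict],
    n_seeds: int = 50,
    params: StageParams | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Sweep (d, f, m, cells_per_clone) grid points over seeded replicates.

    Each grid point is a dict with any of the keys ``d, f, m,
    cells_per_clone``; unspecified values take the default recovery-scenario
    settings.  Returns one row per grid point with metric means.
    """
    rows = []
    for point in grid:
        metrics = []
        for s in range(n_seeds):
            cfg = bifurcating_recovery_config(
                seed=base_seed + s,
                ado_rate=point.get("d", 0.1),
                fp_rate=point.get("f", 0.005),
                missing_rate=point.get("m", 0.05),
                cells_per_clone=point.get("cells_per_clone", 50),
            )
            metrics.append(evaluate_recovery(cfg, params))
        df = pd.DataFrame(metrics)
        rows.append(
            {
                "d": point.get("d", 0.1),
                "f": point.get("f", 0.005),
                "m": point.get("m", 0.05),
                "cells_per_clone": point.get("cells_per_clone", 50),
                "n_seeds": n_seeds,
                "mean_ari": df["ari"].mean(),
                "trunk_recovery_rate": df["trunk_recovered"].mean(),
                "virtual_recovery_rate": df["virtual_ancestors_recovered"].mean(),
                "topology_recovery_rate": df["topology_recovered"].mean(),
                "ado_bias": df["ado_error"].mean(),
            }
        )
    return pd.DataFrame(rows)
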