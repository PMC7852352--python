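"""Single-cell genotype matrix: data model, TSV/VCF-lite I/O and QC.

The central container is :class:`GenotypeMatrix`, a cells x target-sites
ternary call matrix (0 = reference, 1 = mutant, NA = missing) with per-site
metadata (coordinates, alleles, gene, SNV/INDEL class, optional bulk VAF)
and per-cell tissue labels.  QC covers allele-dropout (ADO) estimation from
control heterozygous germline sites, per-site mutated cell fractions, their
concordance with bulk variant allele frequencies, and filtering of
germline/artifact sites against paratumor (normal) cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MISSING_TOKEN = "NA"
TISSUES = ("paratumor", "tumor", "metastasis", "other")
#: tissue labels counted as malignant when computing tumor-only statistics
TUMOR_TISSUES = ("tumor", "metastasis")
SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "variant_class", "vaf"]

#: allele-presence categories of a control heterozygous-germline call
CONTROL_TOKENS = ("both", "ref-only", "alt-only", MISSING_TOKEN)


class GenotypeParseError(ValueError):
    """Raised when a genotype/site/cell table violates the file dialect."""


@dataclass
class GenotypeMatrix:
    """Ternary single-cell genotype calls plus site and cell metadata.

    Parameters
    ----------
    cells, sites
        Ordered unique identifiers.
    calls
        float array of shape (n_cells, n_sites); entries 0.0, 1.0 or NaN.
    site_meta
        DataFrame indexed by site id with columns
        ``chrom, pos, ref, alt, gene, variant_class, vaf`` (vaf may be NaN).
    cell_meta
        DataFrame indexed by cell id with a ``tissue`` column.
    """

    cells: list[str]
    sites: list[str]
    calls: np.ndarray
    site_meta: pd.DataFrame
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.cells), len(self.sites)):
            raise GenotypeParseError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.cells)} cells x {len(self.sites)} sites"
            )
        if len(set(self.cells)) != len(self.cells):
            raise GenotypeParseError("duplicate cell ids")
        if len(set(self.sites)) != len(self.sites):
            raise GenotypeParseError("duplicate site ids")
        valid = np.isnan(self.calls) | (self.calls == 0) | (self.calls == 1)
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise GenotypeParseError(
                f"invalid genotype value {self.calls[i, j]!r} at "
                f"cell {self.cells[i]!r}, site {self.sites[j]!r}"
            )
        self.site_meta = self.site_meta.reindex(self.sites)
        self.cell_meta = self.cell_meta.reindex(self.cells)
        if self.site_meta[["chrom", "pos", "ref", "alt"]].isna().any().any():
            raise GenotypeParseError("site metadata missing for some sites")
        if self.cell_meta["tissue"].isna().any():
            raise GenotypeParseError("cell metadata missing for some cells")
        bad = ~self.cell_meta["tissue"].isin(TISSUES)
        if bad.any():
            raise GenotypeParseError(
                f"unknown tissue label {self.cell_meta['tissue'][bad].iloc[0]!r}"
            )
        snv = self.site_meta["variant_class"] == "SNV"
        ref = self.site_meta.loc[snv, "ref"]
        alt = self.site_meta.loc[snv, "alt"]
        ok = ref.str.fullmatch("[ACGT]") & alt.str.fullmatch("[ACGT]") & (ref != alt)
        if not ok.all():
            bad_site = ok[~ok].index[0]
            raise GenotypeParseError(
                f"SNV site {bad_site!r} must have distinct single-base "
                "A/C/G/T ref and alt alleles"
            )

    # -- convenience accessors -------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def tissue_of(self, cell: str) -> str:
        return str(self.cell_meta.loc[cell, "tissue"])

    def cell_indices(self, tissues: Sequence[str] | None) -> np.ndarray:
        """Row indices of cells whose tissue is in *tissues* (None = all)."""
        if tissues is None:
            return np.arange(self.n_cells)
        mask = self.cell_meta["tissue"].isin(list(tissues)).to_numpy()
        return np.flatnonzero(mask)

    def subset(
        self,
        cells: Iterable[str] | None = None,
        sites: Iterable[str] | None = None,
    ) -> "GenotypeMatrix":
        cells = list(cells) if cells is not None else list(self.cells)
        sites = list(sites) if sites is not None else list(self.sites)
        ci = [self.cells.index(c) for c in cells]
        si = [self.sites.index(s) for s in sites]
        return GenotypeMatrix(
            cells=cells,
            sites=sites,
            calls=self.calls[np.ix_(ci, si)].copy(),
            site_meta=self.site_meta.loc[sites].copy(),
            cell_meta=self.cell_meta.loc[cells].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.cells, columns=self.sites)


@dataclass
class QCReport:
    """Bundle of matrix-level QC quantities."""

    ado_estimate: float | None
    vaf_concordance_r: float | None
    mutated_cell_fraction: dict[str, float]
    filtered_sites: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "ado_estimate": self.ado_estimate,
            "vaf_concordance_r": self.vaf_concordance_r,
            "mutated_cell_fraction": {
                k: (None if v is None or (isinstance(v, float) and np.isnan(v)) else v)
                for k, v in self.mutated_cell_fraction.items()
            },
            "filtered_sites": self.filtered_sites,
        }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_genotype_matrix(
    matrix_path: str | Path,
    site_path: str | Path,
    cell_path: str | Path,
) -> GenotypeMatrix:
    """Read the three-table TSV representation of a genotype matrix.

    The matrix TSV has a ``cell_id`` first column and one column per site;
    genotype tokens are ``0``/``1`` with missing as ``NA``.  The site table
    has columns ``site_id, chrom, pos, ref, alt, gene, variant_class, vaf``
    and the cell table ``cell_id, tissue``.
    """
    raw = pd.read_csv(matrix_path, sep="\t", dtype=str, keep_default_na=False)
    if raw.columns[0] != "cell_id":
        raise GenotypeParseError("matrix TSV must start with a cell_id column")
    cells = raw["cell_id"].tolist()
    sites = [str(c) for c in raw.columns[1:]]
    calls = np.empty((len(cells), len(sites)))
    for j, site in enumerate(sites):
        col = raw[site]
        for i, tok in enumerate(col):
            if tok == MISSING_TOKEN:
                calls[i, j] = np.nan
            elif tok == "0":
                calls[i, j] = 0.0
            elif tok == "1":
                calls[i, j] = 1.0
            else:
                raise GenotypeParseError(
                    f"invalid genotype token {tok!r} at cell {cells[i]!r}, "
                    f"site {site!r}"
                )
    site_meta = pd.read_csv(
        site_path, sep="\t", dtype={"site_id": str, "chrom": str}
    ).set_index("site_id")
    missing_cols = [c for c in SITE_COLUMNS if c not in site_meta.columns and c != "vaf"]
    if missing_cols:
        raise GenotypeParseError(f"site table missing columns {missing_cols}")
    if "vaf" not in site_meta.columns:
        site_meta["vaf"] = np.nan
    unknown = set(sites) - set(site_meta.index)
    if unknown:
        raise GenotypeParseError(f"sites absent from site table: {sorted(unknown)}")
    cell_meta = pd.read_csv(cell_path, sep="\t", dtype=str).set_index("cell_id")
    unknown = set(cells) - set(cell_meta.index)
    if unknown:
        raise GenotypeParseError(f"cells absent from cell table: {sorted(unknown)}")
    return GenotypeMatrix(
        cells=cells,
        sites=sites,
        calls=calls,
        site_meta=site_meta.loc[sites, SITE_COLUMNS],
        cell_meta=cell_meta.loc[cells, ["tissue"]],
    )


def write_genotype_matrix(
    matrix: GenotypeMatrix,
    matrix_path: str | Path,
    site_path: str | Path,
    cell_path: str | Path,
) -> None:
    """Write the three TSV tables; round-trips with :func:`read_genotype_matrix`."""
    toks = np.where(
        np.isnan(matrix.calls), MISSING_TOKEN,
        np.where(matrix.calls == 1, "1", "0"),
    )
    df = pd.DataFrame(toks, columns=matrix.sites)
    df.insert(0, "cell_id", matrix.cells)
    df.to_csv(matrix_path, sep="\t", index=False)

    site = matrix.site_meta.copy()
    site.insert(0, "site_id", site.index)
    site["pos"] = site["pos"].astype(int)
    site.to_csv(site_path, sep="\t", index=False, na_rep=MISSING_TOKEN)

    cell = matrix.cell_meta.copy()
    cell.insert(0, "cell_id", cell.index)
    cell.to_csv(cell_path, sep="\t", index=False)


def write_vcf_lite(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write site metadata as a minimal VCF 4.2 with GENE/VAF INFO keys."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=VAF,Number=1,Type=Float,Description="Bulk VAF">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for site_id, row in matrix.site_meta.iterrows():
            info = f"GENE={row['gene']}"
            if pd.notna(row["vaf"]):
                info += f";VAF={row['vaf']:.6g}"
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{site_id}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t{info}\n"
            )


def read_vcf_lite(path: str | Path) -> pd.DataFrame:
    """Read a VCF 4.x site table (columns as in ``GenotypeMatrix.site_meta``)."""
    rows = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                raise GenotypeParseError(f"malformed VCF line: {line!r}")
            info = dict(
                kv.split("=", 1) if "=" in kv else (kv, "")
                for kv in f[7].split(";") if kv and kv != "."
            )
            ref, alt = f[3], f[4]
            rows[f[2]] = {
                "chrom": f[0],
                "pos": int(f[1]),
                "ref": ref,
                "alt": alt,
                "gene": info.get("GENE", ""),
                "variant_class": "SNV" if len(ref) == 1 and len(alt) == 1 else "INDEL",
                "vaf": float(info["VAF"]) if "VAF" in info else np.nan,
            }
    return pd.DataFrame.from_dict(rows, orient="index")[SITE_COLUMNS]


def read_control_matrix(path: str | Path) -> pd.DataFrame:
    """Read a control het-germline allele-presence matrix TSV.

    Cells x sites with tokens ``both``/``ref-only``/``alt-only``/``NA``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False).set_index(
        "cell_id"
    )
    bad = ~df.isin(CONTROL_TOKENS)
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise GenotypeParseError(
            f"invalid control token {df.iat[i, j]!r} at cell "
            f"{df.index[i]!r}, site {df.columns[j]!r}"
        )
    return df


def write_control_matrix(control: pd.DataFrame, path: str | Path) -> None:
    out = control.copy()
    out.insert(0, "cell_id", out.index)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC operations
# ---------------------------------------------------------------------------

def mutated_cell_fraction(
    matrix: GenotypeMatrix,
    tissue_filter: Sequence[str] | Callable[[str], bool] | None = None,
) -> pd.Series:
    """Per-site fraction of mutant calls among non-missing calls.

    *tissue_filter* selects cells: a sequence of tissue labels, a predicate
    on the label, or None for all cells.  Sites with no non-missing call
    among the selected cells are NaN (undefined).
    """
    if callable(tissue_filter):
        idx = np.flatnonzero(
            matrix.cell_meta["tissue"].map(tissue_filter).to_numpy()
        )
    else:
        idx = matrix.cell_indices(tissue_filter)
    if idx.size == 0:
        raise ValueError("tissue filter selects no cells")
    sub = matrix.calls[idx]
    n_obs = np.sum(~np.isnan(sub), axis=0)
    n_mut = np.nansum(sub, axis=0)
    with np.errstate(invalid="ignore"):
        frac = np.where(n_obs > 0, n_mut / np.maximum(n_obs, 1), np.nan)
    return pd.Series(frac, index=matrix.sites)


def estimate_ado(control_matrix: pd.DataFrame) -> float:
    """Allele-dropout rate from heterozygous-germline control sites.

    Under per-allele independent dropout at rate ``d``, a het site is seen
    single-allele (``ref-only`` or ``alt-only``) with probability
    ``h = 2d(1-d)/(1-d^2) = 2d/(1+d)`` among non-missing observations;
    inverting gives ``d = h/(2-h)``.
    """
    vals = control_matrix.to_numpy().ravel()
    obs = vals != MISSING_TOKEN
    n_obs = int(obs.sum())
    if n_obs == 0:
        raise ValueError("no non-missing control observations")
    n_single = int(np.isin(vals, ("ref-only", "alt-only")).sum())
    h = n_single / n_obs
    return h / (2.0 - h)


def vaf_concordance(
    matrix: GenotypeMatrix,
    method: str = "pearson",
    tissues: Sequence[str] = TUMOR_TISSUES,
) -> float | None:
    """Correlation of tumor-cell mutated fractions with bulk VAF.

    Requires >= 3 sites annotated with a bulk VAF.  Returns None when either
    vector has zero variance (correlation undefined).
    """
    frac = mutated_cell_fraction(matrix, tissues)
    vaf = matrix.site_meta["vaf"]
    ok = vaf.notna() & frac.notna()
    if int(vaf.notna().sum()) < 3:
        raise ValueError("need >= 3 sites with bulk VAF annotation")
    x = frac[ok].to_numpy(float)
    y = vaf[ok].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def filter_germline_artifacts(
    matrix: GenotypeMatrix,
    max_paratumor_fraction: float = 0.1,
) -> tuple[GenotypeMatrix, list[dict]]:
    """Drop sites mutated in too many paratumor (normal) cells.

    Paratumor cells act as negative controls: a genuinely somatic site
    should be reference in them, so a high paratumor mutated-cell fraction
    flags a germline variant or recurrent artifact.  No-op with a warning
    when the matrix has no paratumor cells.
    """
    idx = matrix.cell_indices(["paratumor"])
    if idx.size == 0:
        warnings.warn(
            "no paratumor cells: germline/artifact filter skipped", stacklevel=2
        )
        return matrix, []
    frac = mutated_cell_fraction(matrix, ["paratumor"])
    removed = [
        {
            "site_id": s,
            "reason": "paratumor-positive",
            "paratumor_fraction": float(frac[s]),
        }
        for s in matrix.sites
        if not np.isnan(frac[s]) and frac[s] > max_paratumor_fraction
    ]
    keep = [s for s in matrix.sites if s not in {r["site_id"] for r in removed}]
    return matrix.subset(sites=keep), removed


def qc_report(
    matrix: GenotypeMatrix,
    control_matrix: pd.DataFrame | None = None,
    max_paratumor_fraction: float = 0.1,
    correlation: str = "pearson",
) -> QCReport:
    """Assemble the standard QC bundle for a genotype matrix."""
    ado = estimate_ado(control_matrix) if control_matrix is not None else None
    try:
        r = vaf_concordance(matrix, method=correlation)
    except ValueError:
        r = None
    frac = mutated_cell_fraction(matrix, TUMOR_TISSUES)
    _, removed = filter_germline_artifacts(matrix, max_paratumor_fraction)
    return QCReport(
        ado_estimate=ado,
        vaf_concordance_r=r,
        mutated_cell_fraction={
            s: (float(v) if not np.isnan(v) else None) for s, v in frac.items()
        },
        filtered_sites=removed,
    )
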