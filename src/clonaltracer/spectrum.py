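"""Six-class substitution spectra of newly acquired mutations.

Single-nucleotide variants are collapsed onto the six pyrimidine-reference
substitution classes (C>A, C>G, C>T, T>A, T>C, T>G); a purine-reference
change is reported as its reverse complement, so e.g. A>T counts as T>A.
Per branch of a clone tree, the spectrum is tabulated over the mutations
acquired on that branch only, i.e. those new relative to the most recent
ancestor clone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SubstitutionSpectrum:
    """Counts over the six pyrimidine-reference classes for a mutation set."""

    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in SUBSTITUTION_CLASSES}
    )
    n_snv: int = 0
    n_excluded: int = 0

    def add(self, ref: str, alt: str) -> None:
        cls = classify_substitution(ref, alt)
        if cls is None:
            self.n_excluded += 1
        else:
            self.counts[cls] += 1
            self.n_snv += 1

    def fractions(self) -> dict[str, float]:
        if self.n_snv == 0:
            return {c: 0.0 for c in SUBSTITUTION_CLASSES}
        return {c: n / self.n_snv for c, n in self.counts.items()}

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "n_snv": self.n_snv,
            "n_excluded": self.n_excluded,
        }


def classify_substitution(ref: str, alt: str) -> str | None:
    """Map a ref/alt allele pair to its pyrimidine-reference class.

    Returns None (excluded) for multi-base alleles (INDELs), non-ACGT
    bases, or identical ref and alt.
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1:
        return None
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT or ref == alt:
        return None
    if ref in ("A", "G"):  # purine reference: fold onto the complement strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def spectrum_of(site_ids, site_meta: pd.DataFrame) -> SubstitutionSpectrum:
    """Spectrum of an arbitrary mutation set, given site metadata."""
    spec = SubstitutionSpectrum()
    for s in site_ids:
        if s not in site_meta.index:
            raise KeyError(f"site {s!r} not present in site metadata")
        spec.add(str(site_meta.loc[s, "ref"]), str(site_meta.loc[s, "alt"]))
    return spec


def branch_spectra(tree, site_meta: pd.DataFrame) -> dict[tuple[str, str], SubstitutionSpectrum]:
    """One spectrum per clone-tree edge over that edge's acquired mutations.

    Keys are (parent, child) node-id pairs.  INDELs and undefined pairs
    count into ``n_excluded``.
    """
    out: dict[tuple[str, str], SubstitutionSpectrum] = {}
    for edge in tree.edges:
        out[(edge.parent, edge.child)] = spectrum_of(
            sorted(edge.acquired), site_meta
        )
    return out


def spectra_table(spectra: dict[tuple[str, str], SubstitutionSpectrum]) -> pd.DataFrame:
    """Long-format ``edge, class, count`` table for TSV export."""
    rows = []
    for (parent, child), spec in sorted(spectra.items()):
        for cls in SUBSTITUTION_CLASSES:
            rows.append(
                {"edge": f"{parent}->{child}", "class": cls, "count": spec.counts[cls]}
            )
        rows.append(
            {"edge": f"{parent}->{child}", "class": "excluded", "count": spec.n_excluded}
        )
    return pd.DataFrame(rows, columns=["edge", "class", "count"])
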