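"""Gene sets: GWAS-catalog derived reference set and set algebra.

The reference set collects the mapped genes of catalog SNPs listed under a
trait of interest with association p <= 5e-6 (inclusive); trait matching is
exact but case-insensitive, and gene symbols are matched as exact strings
(no alias resolution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .io_formats import GwasCatalogRecord, ValidationError

logger = logging.getLogger("varfunnel")

CODING = "coding"
NCRNA = "ncRNA"


@dataclass
class GeneSet:
    name: str
    symbols: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("gene set name must be non-empty")
        self.symbols = frozenset(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols


def build_gwas_geneset(
    records: Iterable[GwasCatalogRecord],
    trait: str,
    p_threshold: float = 5e-6,
) -> GeneSet:
    """Union of mapped genes over catalog SNPs matching ``trait`` at p <= threshold."""
    trait_lower = trait.lower()
    snps = [
        r for r in records
        if r.trait.lower() == trait_lower and r.assoc_p <= p_threshold
    ]
    symbols = frozenset(g for r in snps for g in r.mapped_genes)
    if not snps:
        logger.warning("build_gwas_geneset: no SNPs matched trait %r at p <= %g",
                       trait, p_threshold)
    logger.info(
        "build_gwas_geneset: %d SNPs under %r at p <= %g -> %d genes",
        len(snps), trait, p_threshold, len(symbols),
    )
    return GeneSet(
        name=f"gwas:{trait}",
        symbols=symbols,
        provenance=f"{len(snps)} catalog SNPs, trait={trait!r}, p<={p_threshold:g}",
    )


def intersect(a: GeneSet, b: GeneSet) -> GeneSet:
    return GeneSet(
        name=f"({a.name})&({b.name})",
        symbols=a.symbols & b.symbols,
        provenance=f"{a.provenance} | {b.provenance}",
    )


def partition_by_class(
    s: GeneSet, class_map: Mapping[str, str]
) -> tuple[GeneSet, GeneSet]:
    """Split a gene set into (coding, ncRNA) by an explicit class map."""
    unmapped = sorted(sym for sym in s.symbols if sym not in class_map)
    if unmapped:
        raise ValidationError(f"symbols missing from class map: {', '.join(unmapped)}")
    bad = sorted({class_map[sym] for sym in s.symbols} - {CODING, NCRNA})
    if bad:
        raise ValidationError(f"unknown gene classes: {bad}")
    coding = frozenset(sym for sym in s.symbols if class_map[sym] == CODING)
    ncrna = s.symbols - coding
    return (
        GeneSet(f"{s.name}:coding", coding, s.provenance),
        GeneSet(f"{s.name}:ncRNA", ncrna, s.provenance),
    )


def write_geneset(s: GeneSet, path: str | Path) -> None:
    """One symbol per line, provenance in leading '#' comments."""
    with Path(path).open("w") as fh:
        fh.write(f"# name: {s.name}\n")
        if s.provenance:
            fh.write(f"# provenance: {s.provenance}\n")
        for sym in sorted(s.symbols):
            fh.write(sym + "\n")


def read_geneset(path: str | Path) -> GeneSet:
    name = Path(path).stem
    provenance = ""
    symbols = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if line.startswith("# name:"):
                    name = line.split(":", 1)[1].strip()
                elif line.startswith("# provenance:"):
                    provenance = line.split(":", 1)[1].strip()
            elif line:
                symbols.append(line)
    return GeneSet(name, frozenset(symbols), provenance)
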