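"""Readers and writers for the external formats the pipeline touches.

Formats handled
---------------
* expression matrix — TSV, one header row of sample ids, a second ``group``
  row of case/control labels, then one row per gene of log2 intensities;
* GWAS-catalog export — TSV with ``snp_id``, ``trait``, ``assoc_p`` and
  ``mapped_genes`` columns;
* multi-sample VCF v4.2 (plain text, GT genotypes) plus PLINK 6-column PED;
* population allele-frequency tables — TSV with ``variant``, ``population``,
  ``allele_count``, ``allele_number`` (``freq`` optional, recomputed);
* transcript models — BED-like TSV of exon blocks/CDS bounds/strand plus a
  FASTA of spliced sequences;
* per-variant annotation tables (CADD scores, eQTL target genes).

All readers validate strictly: malformed rows raise rather than being
coerced, and every dropped or split record is counted and logged.
Coordinates are 1-based throughout (VCF convention); internal intervals are
1-based inclusive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger("varfunnel")

MISSING = -1  # sentinel for a missing diploid alt-allele count

CASE = "case"
CONTROL = "control"

AFFECTED = "affected"
UNAFFECTED = "unaffected"
UNKNOWN = "unknown"


class VarFunnelError(Exception):
    """Base class for all package errors."""


class ValidationError(VarFunnelError):
    """Input violated a documented invariant."""


class ParseError(ValidationError):
    """Input file could not be parsed; message carries row/column context."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Log2 expression values, genes x samples, with case/control labels."""

    gene_ids: list[str]
    sample_ids: list[str]
    group_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.group_labels) != len(self.sample_ids):
            raise ValidationError("every sample needs a group label")
        dupes = _duplicates(self.gene_ids)
        if dupes:
            raise ValidationError(f"duplicate gene ids: {', '.join(sorted(dupes))}")
        bad = set(self.group_labels) - {CASE, CONTROL}
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        for grp in (CASE, CONTROL):
            n = self.group_labels.count(grp)
            if n < 2:
                raise ValidationError(f"group '{grp}' has {n} samples; need >= 2")
        if not np.isfinite(self.values).all():
            raise ValidationError("expression values must all be finite")

    def group_columns(self, group: str) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.group_labels) if g == group])


@dataclass(frozen=True)
class GwasCatalogRecord:
    snp_id: str
    trait: str
    assoc_p: float
    mapped_genes: tuple[str, ...]


@dataclass(frozen=True)
class PedigreeMember:
    family_id: str
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "1", "2" or "unknown"
    affection: str  # affected / unaffected / unknown

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class Pedigree:
    """Roster of :class:`PedigreeMember` grouped by family."""

    def __init__(self, members: Sequence[PedigreeMember]):
        self.members = list(members)
        seen: set[tuple[str, str]] = set()
        for m in self.members:
            key = (m.family_id, m.individual_id)
            if key in seen:
                raise ValidationError(
                    f"duplicate individual {m.individual_id} in family {m.family_id}"
                )
            seen.add(key)
        for m in self.members:
            ids = {x.individual_id for x in self.members if x.family_id == m.family_id}
            for parent in (m.father_id, m.mother_id):
                if parent is not None and parent not in ids:
                    raise ValidationError(
                        f"member {m.individual_id} (family {m.family_id}) refers to "
                        f"unknown parent {parent}"
                    )

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    @property
    def sample_ids(self) -> list[str]:
        return [m.individual_id for m in self.members]

    def families(self) -> dict[str, list[PedigreeMember]]:
        fams: dict[str, list[PedigreeMember]] = {}
        for m in self.members:
            fams.setdefault(m.family_id, []).append(m)
        return fams

    def n_affected(self) -> int:
        return sum(m.affection == AFFECTED for m in self.members)


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    snp_id: str | None = None

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class VariantTable:
    """Biallelic variants with per-sample diploid alt-allele counts.

    ``genotypes`` is an (n_variants, n_samples) int8 array holding 0/1/2 or
    :data:`MISSING`.
    """

    variants: list[Variant]
    samples: list[str]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.variants), len(self.samples)):
            raise ValidationError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        valid = np.isin(self.genotypes, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValidationError("genotypes must be 0, 1, 2 or missing")

    def __len__(self) -> int:
        return len(self.variants)

    def subset(self, indices: Sequence[int]) -> "VariantTable":
        idx = list(indices)
        return VariantTable(
            [self.variants[i] for i in idx], list(self.samples), self.genotypes[idx]
        )

    def sample_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.samples)}


@dataclass(frozen=True)
class FrequencyRecord:
    variant: str
    population: str
    allele_count: int
    allele_number: int

    @property
    def freq(self) -> float:
        return self.allele_count / self.allele_number


class FrequencyTable:
    """Per-(variant, population) allele counts for the designated tested allele."""

    def __init__(self, records: Iterable[FrequencyRecord]):
        self._records: dict[tuple[str, str], FrequencyRecord] = {}
        for rec in records:
            if rec.allele_number <= 0:
                raise ValidationError(
                    f"{rec.variant}/{rec.population}: allele_number must be positive"
                )
            if not 0 <= rec.allele_count <= rec.allele_number:
                raise ValidationError(
                    f"{rec.variant}/{rec.population}: allele_count "
                    f"{rec.allele_count} outside [0, {rec.allele_number}]"
                )
            self._records[(rec.variant, rec.population)] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def get(self, variant: str, population: str) -> FrequencyRecord | None:
        return self._records.get((variant, population))

    def populations(self) -> list[str]:
        return sorted({p for _, p in self._records})

    def freq(self, variant: str, population: str) -> float | None:
        rec = self.get(variant, population)
        return None if rec is None else rec.freq


@dataclass(frozen=True)
class AnnotationRecord:
    variant: str
    cadd_phred: float | None = None
    eqtl_targets: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValidationError(
                f"{self.variant}: CADD phred score must be >= 0"
            )


# ---------------------------------------------------------------------------
# Expression matrix I/O
# ---------------------------------------------------------------------------

GROUP_ROW_LABEL = "group"


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a log2 expression TSV.

    Layout: header row ``gene_id<TAB>sample...``, second row
    ``group<TAB>case/control...``, then one row per gene.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path}: expected a tab-separated sample header")
        sample_ids = header[1:]
        group_row = fh.readline().rstrip("\n").split("\t")
        if not group_row or group_row[0] != GROUP_ROW_LABEL:
            raise ParseError(
                f"{path}: second row must be the '{GROUP_ROW_LABEL}' label row"
            )
        if len(group_row) != len(header):
            raise ParseError(f"{path}: group row width does not match header")
        group_labels = group_row[1:]
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=3):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}"
                )
            gene = fields[0]
            if gene in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene row '{gene}'")
            seen.add(gene)
            values = []
            for col, cell in enumerate(fields[1:], start=2):
                try:
                    values.append(float(cell))
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric cell in column {col}: {cell!r}"
                    ) from exc
            gene_ids.append(gene)
            rows.append(values)
    return ExpressionMatrix(gene_ids, sample_ids, group_labels, np.array(rows))


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        fh.write(GROUP_ROW_LABEL + "\t" + "\t".join(matrix.group_labels) + "\n")
        for gene, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# GWAS catalog
# ---------------------------------------------------------------------------

#: separators accepted between mapped gene symbols; the spaced hyphen form is
#: split while hyphenated symbols like ``NKX2-1`` are kept intact.
_GENE_SEPARATORS = (",", ";", " - ")


def split_mapped_genes(cell: str) -> tuple[str, ...]:
    parts = [cell]
    for sep in _GENE_SEPARATORS:
        parts = [piece for chunk in parts for piece in chunk.split(sep)]
    out: list[str] = []
    for p in parts:
        p = p.strip()
        if p and p not in out:
            out.append(p)
    return tuple(out)


def read_gwas_catalog(path: str | Path) -> list[GwasCatalogRecord]:
    """Read a GWAS-catalog export TSV (snp_id, trait, assoc_p, mapped_genes).

    Records with no mapped gene after parsing are dropped with a logged count.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"snp_id", "trait", "assoc_p", "mapped_genes"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    records: list[GwasCatalogRecord] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        try:
            p = float(row.assoc_p)
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"{path}: non-numeric assoc_p for {row.snp_id}: {row.assoc_p!r}"
            ) from exc
        if not 0 < p <= 1:
            raise ValidationError(f"{path}: assoc_p for {row.snp_id} outside (0, 1]")
        genes = split_mapped_genes("" if pd.isna(row.mapped_genes) else row.mapped_genes)
        if not genes:
            n_dropped += 1
            continue
        records.append(GwasCatalogRecord(row.snp_id, row.trait, p, genes))
    if n_dropped:
        logger.info("read_gwas_catalog: dropped %d records with no mapped gene", n_dropped)
    return records


def write_gwas_catalog(records: Sequence[GwasCatalogRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("snp_id\ttrait\tassoc_p\tmapped_genes\n")
        for rec in records:
            fh.write(
                f"{rec.snp_id}\t{rec.trait}\t{rec.assoc_p!r}\t"
                + ", ".join(rec.mapped_genes)
                + "\n"
            )


# ---------------------------------------------------------------------------
# PED pedigree
# ---------------------------------------------------------------------------


def read_ped(path: str | Path) -> Pedigree:
    """Read a PLINK 6-column PED: family, id, father, mother, sex, affection.

    Affection codes: 2 -> affected, 1 -> unaffected, 0/-9 -> unknown.
    A parent id of ``0`` marks a founder.
    """
    members: list[PedigreeMember] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            fam, iid, father, mother, sex, pheno = fields
            members.append(
                PedigreeMember(
                    family_id=fam,
                    individual_id=iid,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=sex if sex in ("1", "2") else UNKNOWN,
                    affection={"2": AFFECTED, "1": UNAFFECTED}.get(pheno, UNKNOWN),
                )
            )
    return Pedigree(members)


def write_ped(pedigree: Pedigree, path: str | Path) -> None:
    code = {AFFECTED: "2", UNAFFECTED: "1", UNKNOWN: "0"}
    with Path(path).open("w") as fh:
        for m in pedigree:
            fh.write(
                f"{m.family_id} {m.individual_id} {m.father_id or '0'} "
                f"{m.mother_id or '0'} {m.sex if m.sex in ('1', '2') else '0'} "
                f"{code[m.affection]}\n"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _parse_gt(gt: str, alt_index: int) -> int:
    """Map one GT string to the alt-count of allele ``alt_index``.

    Any half-call or missing allele yields :data:`MISSING` (conservative).
    In a multiallelic split, alleles other than ``alt_index`` count as
    non-carriers of this alt.
    """
    alleles = gt.replace("|", "/").split("/")
    counts = 0
    for a in alleles:
        if a in (".", ""):
            return MISSING
        counts += int(a) == alt_index
    if len(alleles) != 2:
        return MISSING
    return counts


def read_vcf(path: str | Path, pedigree: Pedigree | None = None) -> VariantTable:
    """Read a plain-text VCF v4.2 into a biallelic :class:`VariantTable`.

    Multiallelic sites are split into one record per alt allele (logged).
    ``./.`` and half-calls map to missing; phased separators are accepted.
    When a pedigree is given, the sample columns must match its roster
    exactly and are reordered to the pedigree order.
    """
    path = Path(path)
    samples: list[str] | None = None
    variants: list[Variant] = []
    rows: list[list[int]] = []
    n_split = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10:
                    raise ParseError(f"{path}:{lineno}: VCF has no sample columns")
                samples = cols[9:]
                continue
            if samples is None:
                raise ParseError(f"{path}: missing #CHROM header line")
            fields = line.split("\t")
            if len(fields) != 9 + len(samples):
                raise ParseError(
                    f"{path}:{lineno}: expected {9 + len(samples)} columns, "
                    f"got {len(fields)}"
                )
            chrom, pos, vid, ref, alts, _qual, _filt, _info, fmt = fields[:9]
            fmt_keys = fmt.split(":")
            if "GT" not in fmt_keys:
                raise ParseError(f"{path}:{lineno}: record has no GT in FORMAT")
            gt_i = fmt_keys.index("GT")
            gts = [f.split(":")[gt_i] for f in fields[9:]]
            alt_list = alts.split(",")
            if len(alt_list) > 1:
                n_split += 1
            for k, alt in enumerate(alt_list, start=1):
                variants.append(
                    Variant(chrom, int(pos), ref, alt, None if vid == "." else vid)
                )
                rows.append([_parse_gt(g, k) for g in gts])
    if samples is None:
        raise ParseError(f"{path}: missing #CHROM header line")
    if n_split:
        logger.info("read_vcf: split %d multiallelic sites into biallelic records", n_split)
    table = VariantTable(variants, samples, np.array(rows, dtype=np.int8).reshape(
        len(variants), len(samples)))
    if pedigree is not None:
        table = _align_to_pedigree(table, pedigree, path)
    return table


def _align_to_pedigree(table: VariantTable, pedigree: Pedigree, path: Path) -> VariantTable:
    roster = pedigree.sample_ids
    missing = sorted(set(roster) - set(table.samples))
    extra = sorted(set(table.samples) - set(roster))
    if missing or extra:
        raise ValidationError(
            f"{path}: VCF samples do not match pedigree; "
            f"missing from VCF: {missing or 'none'}; not in pedigree: {extra or 'none'}"
        )
    order = [table.samples.index(s) for s in roster]
    return VariantTable(table.variants, roster, table.genotypes[:, order])


def write_vcf(table: VariantTable, path: str | Path) -> None:
    """Write a minimal plain-text VCF v4.2 (GT only, unphased)."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    contigs = sorted({v.chrom for v in table.variants})
    with Path(path).open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for variant, row in zip(table.variants, table.genotypes):
            fh.write(
                f"{variant.chrom}\t{variant.pos}\t{variant.snp_id or '.'}\t"
                f"{variant.ref}\t{variant.alt}\t.\t.\t.\tGT\t"
                + "\t".join(gt_str[int(g)] for g in row)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Population frequencies
# ---------------------------------------------------------------------------


def read_frequencies(path: str | Path) -> FrequencyTable:
    """Read a TSV of per-population allele counts.

    Columns: ``variant``, ``population``, ``allele_number`` and either
    ``allele_count`` or ``freq`` (or both).  When both are present the
    frequency is recomputed from counts and a mismatch beyond 1e-6 is
    logged as a warning; a ``freq``-only column without ``allele_number``
    is an error because counts cannot be reconstructed.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "variant" not in df.columns or "population" not in df.columns:
        raise ParseError(f"{path}: need 'variant' and 'population' columns")
    if "allele_number" not in df.columns:
        raise ParseError(
            f"{path}: 'allele_number' column required (frequencies alone are ambiguous)"
        )
    has_count = "allele_count" in df.columns
    has_freq = "freq" in df.columns
    if not has_count and not has_freq:
        raise ParseError(f"{path}: need 'allele_count' or 'freq'")
    records = []
    for row in df.itertuples(index=False):
        an = int(row.allele_number)
        if has_count:
            ac = int(row.allele_count)
        else:
            ac = int(round(float(row.freq) * an))
            logger.debug(
                "read_frequencies: %s/%s count reconstructed from freq (residual %g)",
                row.variant, row.population, abs(float(row.freq) - ac / an),
            )
        if ac > an:
            raise ValidationError(
                f"{path}: {row.variant}/{row.population}: allele_count {ac} > "
                f"allele_number {an}"
            )
        if has_count and has_freq and not math.isnan(float(row.freq)):
            if abs(float(row.freq) - ac / an) > 1e-6:
                logger.warning(
                    "read_frequencies: %s/%s stated freq %g != %g from counts",
                    row.variant, row.population, float(row.freq), ac / an,
                )
        records.append(FrequencyRecord(str(row.variant), str(row.population), ac, an))
    return FrequencyTable(records)


def write_frequencies(table: FrequencyTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("variant\tpopulation\tallele_count\tallele_number\tfreq\n")
        for rec in table:
            fh.write(
                f"{rec.variant}\t{rec.population}\t{rec.allele_count}\t"
                f"{rec.allele_number}\t{rec.freq:.6g}\n"
            )


# ---------------------------------------------------------------------------
# Annotations (CADD / eQTL), consumed as pre-computed tables
# ---------------------------------------------------------------------------


def read_annotations(path: str | Path) -> dict[str, AnnotationRecord]:
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    if "variant" not in df.columns:
        raise ParseError(f"{path}: need a 'variant' column")
    out: dict[str, AnnotationRecord] = {}
    for row in df.itertuples(index=False):
        cadd = None
        if "cadd_phred" in df.columns and not pd.isna(row.cadd_phred):
            cadd = float(row.cadd_phred)
        targets: tuple[str, ...] = ()
        if "eqtl_targets" in df.columns and not pd.isna(row.eqtl_targets):
            targets = tuple(t.strip() for t in str(row.eqtl_targets).split(",") if t.strip())
        out[str(row.variant)] = AnnotationRecord(str(row.variant), cadd, targets)
    return out


# ---------------------------------------------------------------------------
# Transcript models
# ---------------------------------------------------------------------------


@dataclass
class TranscriptModel:
    """Strand-aware exon/CDS geometry plus the spliced transcript sequence.

    Exons are 1-based inclusive genomic intervals sorted by genomic
    coordinate; ``sequence`` runs 5'->3' in transcript orientation (i.e. it
    is the reverse complement of the genomic splice for minus-strand genes).
    ``cds_start``/``cds_end`` are genomic coordinates with
    ``cds_start <= cds_end`` regardless of strand.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise ValidationError(f"{self.gene_id}: exon interval {start}-{end} inverted")
            if start <= prev_end:
                raise ValidationError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = end
        if self.cds_start > self.cds_end:
            raise ValidationError(f"{self.gene_id}: CDS bounds inverted")
        for bound in (self.cds_start, self.cds_end):
            if self.genomic_to_transcript(bound) is None:
                raise ValidationError(f"{self.gene_id}: CDS bound {bound} not in any exon")
        total = sum(e - s + 1 for s, e in self.exons)
        if len(self.sequence) != total:
            raise ValidationError(
                f"{self.gene_id}: spliced sequence length {len(self.sequence)} != "
                f"total exon length {total}"
            )
        lo, hi = self.cds_transcript_bounds()
        if (hi - lo + 1) % 3 != 0:
            raise ValidationError(f"{self.gene_id}: CDS length not divisible by 3")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def length(self) -> int:
        return len(self.sequence)

    def contains(self, pos: int) -> bool:
        lo, hi = self.span
        return lo <= pos <= hi

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def genomic_to_transcript(self, pos: int) -> int | None:
        """0-based index in ``sequence`` of genomic position ``pos``."""
        offset = 0
        for start, end in self.exons:
            if start <= pos <= end:
                fwd = offset + (pos - start)
                return fwd if self.strand == "+" else self.length - 1 - fwd
            offset += end - start + 1
        return None

    def cds_transcript_bounds(self) -> tuple[int, int]:
        a = self.genomic_to_transcript(self.cds_start)
        b = self.genomic_to_transcript(self.cds_end)
        assert a is not None and b is not None
        return (a, b) if a <= b else (b, a)

    def cds_sequence(self) -> str:
        lo, hi = self.cds_transcript_bounds()
        return self.sequence[lo : hi + 1]

    def protein(self) -> str:
        return str(Seq(self.cds_sequence()).translate())


def read_transcripts(tsv_path: str | Path, fasta_path: str | Path) -> dict[str, TranscriptModel]:
    """Read transcript models: BED-like TSV plus FASTA of spliced sequences."""
    tsv_path = Path(tsv_path)
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    required = {"gene_id", "chrom", "strand", "exon_starts", "exon_ends", "cds_start", "cds_end"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{tsv_path}: missing columns {sorted(missing)}")
    models: dict[str, TranscriptModel] = {}
    for row in df.itertuples(index=False):
        gene = str(row.gene_id)
        if gene not in seqs:
            raise ValidationError(f"{tsv_path}: no FASTA sequence for {gene}")
        starts = [int(x) for x in str(row.exon_starts).split(",") if x]
        ends = [int(x) for x in str(row.exon_ends).split(",") if x]
        if len(starts) != len(ends):
            raise ParseError(f"{tsv_path}: {gene}: exon_starts/ends length mismatch")
        models[gene] = TranscriptModel(
            gene_id=gene,
            chrom=str(row.chrom),
            strand=str(row.strand),
            exons=list(zip(starts, ends)),
            cds_start=int(row.cds_start),
            cds_end=int(row.cds_end),
            sequence=seqs[gene],
        )
    return models


def write_transcripts(
    models: dict[str, TranscriptModel], tsv_path: str | Path, fasta_path: str | Path
) -> None:
    with Path(tsv_path).open("w") as fh:
        fh.write("gene_id\tchrom\tstrand\texon_starts\texon_ends\tcds_start\tcds_end\n")
        for m in models.values():
            fh.write(
                f"{m.gene_id}\t{m.chrom}\t{m.strand}\t"
                + ",".join(str(s) for s, _ in m.exons)
                + "\t"
                + ",".join(str(e) for _, e in m.exons)
                + f"\t{m.cds_start}\t{m.cds_end}\n"
            )
    with Path(fasta_path).open("w") as fh:
        for m in models.values():
            fh.write(f">{m.gene_id}\n")
            for i in range(0, len(m.sequence), 70):
                fh.write(m.sequence[i : i + 70] + "\n")


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup
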