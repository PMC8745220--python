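"""Variant consequence calling against transcript models.

Single-nucleotide substitutions are mapped into transcript space
(reverse-complemented for minus-strand genes) and classified into the
intronic / synonymous / missense / stop-gained / 5'-UTR / 3'-UTR /
intergenic vocabulary with strand-aware codon arithmetic on the standard
nuclear genetic code.  Splice-region classes are deliberately not modelled:
a variant inside an exon is exonic, inside an intron intronic.

Codon-change strings mirror the conventional compact notation: unchanged
bases lowercase, the substituted base uppercase (e.g. ``Ggt/Agt`` for the
first-base G>A of a glycine codon).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .io_formats import (
    AnnotationRecord,
    FrequencyTable,
    TranscriptModel,
    ValidationError,
    Variant,
)

logger = logging.getLogger("varfunnel")

INTRONIC = "intronic"
SYNONYMOUS = "synonymous"
MISSENSE = "missense"
STOP_GAINED = "stop_gained"
UTR5 = "utr5"
UTR3 = "utr3"
INTERGENIC = "intergenic"

NONINTRONIC_CLASSES = frozenset({SYNONYMOUS, MISSENSE, STOP_GAINED, UTR5, UTR3})

MS_GWAS = "ms_gwas"
FUNCTIONAL_PARTNER = "functional_partner"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class ReferenceMismatchError(ValidationError):
    """The VCF ref allele disagrees with the transcript model sequence."""


@dataclass(frozen=True)
class Consequence:
    klass: str
    hgvs_c: str = ""
    hgvs_p: str = ""
    codon_change: str = ""

    @property
    def nonintronic(self) -> bool:
        return self.klass in NONINTRONIC_CLASSES


@dataclass
class PrioritizedVariant:
    """A funnel-surviving variant with its annotations and test results."""

    variant: Variant
    gene_id: str
    consequence: Consequence
    geneset_origin: str = MS_GWAS  # ms_gwas or functional_partner
    cadd_phred: float | None = None
    eqtl_targets: tuple[str, ...] = ()
    test_results: list = field(default_factory=list)

    @property
    def key(self) -> str:
        return self.variant.key


def _aa3(aa: str) -> str:
    return "Ter" if aa == "*" else seq3(aa)


def _mark_codon(codon: str, idx: int) -> str:
    low = codon.lower()
    return low[:idx] + low[idx].upper() + low[idx + 1 :]


def classify(variant: Variant, model: TranscriptModel) -> Consequence:
    """Consequence of a single-nucleotide substitution on one transcript.

    Raises :class:`ReferenceMismatchError` when the VCF ref allele does not
    match the model sequence at the mapped position.
    """
    if not variant.is_snv:
        raise ValidationError(f"{variant.key}: only single-nucleotide substitutions")
    if variant.chrom != model.chrom or not model.contains(variant.pos):
        return Consequence(INTERGENIC)
    t = model.genomic_to_transcript(variant.pos)
    if t is None:
        return Consequence(INTRONIC)

    # transcript-orientation alleles
    if model.strand == "+":
        ref_t, alt_t = variant.ref.upper(), variant.alt.upper()
    else:
        ref_t = variant.ref.upper().translate(_COMPLEMENT)
        alt_t = variant.alt.upper().translate(_COMPLEMENT)
    if model.sequence[t].upper() != ref_t:
        raise ReferenceMismatchError(
            f"{variant.key}: ref {variant.ref} (transcript {ref_t}) disagrees with "
            f"{model.gene_id} sequence base {model.sequence[t]} at transcript "
            f"position {t + 1}"
        )

    cds_lo, cds_hi = model.cds_transcript_bounds()
    if t < cds_lo:
        return Consequence(UTR5, hgvs_c=f"c.-{cds_lo - t}{ref_t} > {alt_t}")
    if t > cds_hi:
        return Consequence(UTR3, hgvs_c=f"c.*{t - cds_hi}{ref_t} > {alt_t}")

    offset = t - cds_lo
    codon_idx = offset // 3
    within = offset % 3
    ref_codon = model.sequence[cds_lo + 3 * codon_idx : cds_lo + 3 * codon_idx + 3].upper()
    alt_codon = ref_codon[:within] + alt_t + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    codon_change = f"{_mark_codon(ref_codon, within)}/{_mark_codon(alt_codon, within)}"
    hgvs_c = f"c.{offset + 1}{ref_t}>{alt_t}"
    hgvs_p = f"p.{_aa3(ref_aa)}{codon_idx + 1}{_aa3(alt_aa)}"
    if alt_aa == ref_aa:
        klass = SYNONYMOUS
    elif alt_aa == "*":
        klass = STOP_GAINED
    else:
        klass = MISSENSE
    return Consequence(klass, hgvs_c=hgvs_c, hgvs_p=hgvs_p, codon_change=codon_change)


def annotate_variants(
    variants,
    gene_map,
    models: dict[str, TranscriptModel],
    origin_map=None,
    annotations: dict[str, AnnotationRecord] | None = None,
) -> list[PrioritizedVariant]:
    """Classify a list of :class:`Variant` against their genes' transcripts."""
    out: list[PrioritizedVariant] = []
    for variant in variants:
        gene = gene_map[variant.key]
        model = models.get(gene)
        if model is None:
            raise ValidationError(f"{variant.key}: no transcript model for gene {gene}")
        ann = (annotations or {}).get(variant.key)
        out.append(
            PrioritizedVariant(
                variant=variant,
                gene_id=gene,
                consequence=classify(variant, model),
                geneset_origin=(origin_map or {}).get(variant.key, MS_GWAS),
                cadd_phred=ann.cadd_phred if ann else None,
                eqtl_targets=ann.eqtl_targets if ann else (),
            )
        )
    return out


def low_frequency_filter(
    variants: list[PrioritizedVariant],
    freqs: FrequencyTable,
    maf_max: float = 0.04,
    source_populations: list[str] | None = None,
) -> list[PrioritizedVariant]:
    """Retain variants whose maximum frequency across the source populations
    is <= ``maf_max`` (inclusive).

    Variants with no frequency in any source population are dropped with a
    logged count.
    """
    if source_populations is None:
        source_populations = freqs.populations()
    kept: list[PrioritizedVariant] = []
    n_nofreq = 0
    for pv in variants:
        values = [
            f for pop in source_populations
            if (f := freqs.freq(pv.key, pop)) is not None
        ]
        if not values:
            n_nofreq += 1
            continue
        if max(values) <= maf_max:
            kept.append(pv)
    if n_nofreq:
        logger.warning(
            "low_frequency_filter: dropped %d variants with no frequency in %s",
            n_nofreq, source_populations,
        )
    return kept


def split_intronic(
    variants: list[PrioritizedVariant],
) -> tuple[list[PrioritizedVariant], list[PrioritizedVariant]]:
    """Disjoint (intronic, nonintronic) partition by the consequence class."""
    intronic = [v for v in variants if not v.consequence.nonintronic]
    nonintronic = [v for v in variants if v.consequence.nonintronic]
    return intronic, nonintronic
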