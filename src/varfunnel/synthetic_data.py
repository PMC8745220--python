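"""Synthetic inputs with planted, parameterized signal for every stage.

One integer seed drives independent sub-streams (expression, catalog,
transcripts, families, frequencies) so each generator can be re-run on its
own and still produce byte-identical output for the same seed.

The default configuration emulates the study design the pipeline targets:

* a log2 expression matrix (10 cases vs 10 controls) with 923 planted
  differentially expressed genes out of 20,000, gene variances drawn from a
  scaled inverse-chi-square prior;
* a GWAS-catalog export whose qualifying records (matching trait,
  p <= 5e-6) map to 543 genes, 18 of them shared with the planted DE set
  (2 ncRNA, 16 coding);
* three nuclear families totalling 11 members (7 affected, 4 unaffected)
  genotyped at planted co-segregating variants (127 in 15 of the shared
  genes plus 57 in 7 functional-partner genes, 39 of those intronic) and at
  background variants rejection-sampled to violate the transmission rule;
* per-population allele counts for an affected cohort (2 x 1098 alleles)
  and two control populations, with optional planted frequency differences;
* strand-aware multi-exon transcript models with valid CDS for every gene
  carrying planted variants, plus two hand-crafted minus-strand fixtures
  reproducing a Gly482Ser missense codon and a c.-54 5'-UTR geometry.

Truth tables record every planted feature so each stage's recall and
false-positive count can be scored exactly.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .consequence import (
    INTRONIC,
    MISSENSE,
    STOP_GAINED,
    SYNONYMOUS,
    UTR3,
    UTR5,
    classify,
)
from .gene_sets import CODING, NCRNA
from .io_formats import (
    AFFECTED,
    MISSING,
    UNAFFECTED,
    ExpressionMatrix,
    FrequencyRecord,
    FrequencyTable,
    GwasCatalogRecord,
    Pedigree,
    PedigreeMember,
    TranscriptModel,
    ValidationError,
    Variant,
    VariantTable,
)
from .segregation import TransmissionRule, evaluate_variant

logger = logging.getLogger("varfunnel")

# sub-stream ids, fixed so stages regenerate independently
_STREAM_EXPRESSION = 0
_STREAM_CATALOG = 1
_STREAM_TRANSCRIPTS = 2
_STREAM_FAMILIES = 3
_STREAM_FREQUENCIES = 4

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [
    "".join(c) for c in itertools.product(_BASES, repeat=3) if "".join(c) not in _STOPS
]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

GWAS_LOWFREQ = "gwas_lowfreq"  # low-frequency nonintronic in a shared gene
GWAS_COMMON = "gwas_common"  # nonintronic but common in controls
GWAS_INTRONIC = "gwas_intronic"
PARTNER_NONINTRONIC = "partner_nonintronic"
PARTNER_INTRONIC = "partner_intronic"
BACKGROUND = "background"


@dataclass(frozen=True)
class SimulationConfig:
    """Every knob of the synthetic study, with defaults at study scale."""

    seed: int = 0
    # expression matrix
    n_genes: int = 20_000
    n_case_samples: int = 10
    n_control_samples: int = 10
    n_de_genes: int = 923
    effect_low: float = 1.5  # planted |log2 shift| range
    effect_high: float = 3.2
    prior_d0: float = 10.0  # inverse-chi-square prior for gene variances
    prior_s0_sq: float = 0.04
    baseline_low: float = 2.0
    baseline_high: float = 14.0
    # GWAS catalog
    trait: str = "multiple sclerosis"
    catalog_snps: int = 805
    catalog_genes: int = 543
    n_overlap_genes: int = 18  # catalog genes also planted DE
    n_overlap_ncrna: int = 2
    n_decoy_trait_snps: int = 100  # other trait, any p
    n_decoy_p_snps: int = 100  # right trait, p above threshold
    gwas_p_threshold: float = 5e-6
    # functional-partner genes (DE, not in the catalog)
    n_partner_genes: int = 7
    # family variants
    n_funnel_genes: int = 15  # shared genes that carry transmitted variants
    n_funnel_variants: int = 127
    n_gwas_prioritized: int = 7  # low-frequency nonintronic among the 127
    n_gwas_common_nonintronic: int = 20
    n_partner_variants: int = 57
    n_partner_nonintronic: int = 18
    n_background_variants: int = 950
    background_maf_low: float = 0.05
    background_maf_high: float = 0.40
    background_missing_rate: float = 0.01
    max_rejection_attempts: int = 1000
    # population frequencies
    affected_population: str = "NIG-IT"
    affected_allele_number: int = 2196  # 2 x 1098 exomes
    control_populations: tuple[tuple[str, int], ...] = (
        ("1000G-TSI", 214),
        ("gnomAD-nfe", 68_000),
    )
    lowfreq_low: float = 0.002
    lowfreq_high: float = 0.025
    common_low: float = 0.08
    common_high: float = 0.45
    maf_max: float = 0.04
    n_gwas_true_diff: int = 3
    n_partner_true_diff: int = 5
    # sized so the analytic power of the pooled z-test at the Bonferroni
    # threshold is ~1 even at the smallest low-frequency baseline (0.002 vs
    # the 2196-allele cohort): |z| ~ 7 at the worst case
    planted_log_odds: float = 2.6
    # transcript models
    n_exons_low: int = 3
    n_exons_high: int = 8
    n_codons_low: int = 250
    n_codons_high: int = 500
    utr5_low: int = 60
    utr5_high: int = 200
    utr3_low: int = 100
    utr3_high: int = 300
    intron_low: int = 100
    intron_high: int = 1000

    def __post_init__(self) -> None:
        if self.n_funnel_genes > self.n_overlap_genes - self.n_overlap_ncrna:
            raise ValidationError("funnel genes must fit within the coding shared genes")
        if self.n_gwas_prioritized + self.n_gwas_common_nonintronic > self.n_funnel_variants:
            raise ValidationError("nonintronic shared-gene variants exceed the funnel total")
        if self.n_partner_nonintronic > self.n_partner_variants:
            raise ValidationError("partner nonintronic count exceeds partner total")
        if self.n_gwas_true_diff > self.n_gwas_prioritized:
            raise ValidationError("true-difference count exceeds prioritized variants")
        if self.n_partner_true_diff > self.n_partner_nonintronic:
            raise ValidationError("true-difference count exceeds partner nonintronic variants")


def null_config(seed: int = 0) -> SimulationConfig:
    """Configuration with zero planted signal at every stage."""
    return SimulationConfig(
        seed=seed,
        n_de_genes=0,
        n_funnel_variants=0,
        n_gwas_prioritized=0,
        n_gwas_common_nonintronic=0,
        n_partner_variants=0,
        n_partner_nonintronic=0,
        n_gwas_true_diff=0,
        n_partner_true_diff=0,
    )


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


# ---------------------------------------------------------------------------
# Gene naming (shared across generators so stages agree)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneNames:
    overlap: tuple[str, ...]  # catalog genes also DE; last n_overlap_ncrna are ncRNA
    partners: tuple[str, ...]
    de_filler: tuple[str, ...]
    gwas_only: tuple[str, ...]
    others: tuple[str, ...]

    @property
    def funnel(self) -> tuple[str, ...]:
        return self.overlap  # restricted further by cfg.n_funnel_genes

    def de_genes(self, n_de: int) -> tuple[str, ...]:
        pool = self.overlap + self.partners + self.de_filler
        return pool[:n_de]

    def catalog(self) -> tuple[str, ...]:
        return self.overlap + self.gwas_only


def gene_names(cfg: SimulationConfig) -> GeneNames:
    overlap = tuple(f"OLG{i + 1:02d}" for i in range(cfg.n_overlap_genes))
    partners = tuple(f"PTG{i + 1}" for i in range(cfg.n_partner_genes))
    n_filler = max(0, cfg.n_de_genes - len(overlap) - len(partners))
    de_filler = tuple(f"DEG{i + 1:04d}" for i in range(n_filler))
    gwas_only = tuple(f"GWG{i + 1:04d}" for i in range(cfg.catalog_genes - len(overlap)))
    n_named = len(overlap) + len(partners) + len(de_filler) + len(gwas_only)
    if cfg.n_genes < n_named:
        raise ValidationError(
            f"n_genes={cfg.n_genes} too small for {n_named} structured genes"
        )
    others = tuple(f"GEN{i + 1:05d}" for i in range(cfg.n_genes - n_named))
    return GeneNames(overlap, partners, de_filler, gwas_only, others)


def gene_class_map(cfg: SimulationConfig) -> dict[str, str]:
    """Coding/ncRNA class for every structured gene; the last
    ``n_overlap_ncrna`` shared genes are the planted ncRNAs."""
    names = gene_names(cfg)
    out = {g: CODING for g in names.overlap + names.partners + names.de_filler + names.gwas_only}
    for g in names.overlap[len(names.overlap) - cfg.n_overlap_ncrna :]:
        out[g] = NCRNA
    return out


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def simulate_expression(cfg: SimulationConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Log2 matrix with planted case shifts; returns (matrix, truth table).

    Gene variances are scaled inverse-chi-square with the configured
    (d0, s0^2); planted genes are shifted in cases by a uniform |effect|
    in [effect_low, effect_high] log2 units with random sign.
    """
    rng = _rng(cfg, _STREAM_EXPRESSION)
    names = gene_names(cfg)
    genes = list(names.overlap + names.partners + names.de_filler
                 + names.gwas_only + names.others)
    n = len(genes)
    de_set = set(names.de_genes(cfg.n_de_genes))
    sigma2 = cfg.prior_d0 * cfg.prior_s0_sq / rng.chisquare(cfg.prior_d0, size=n)
    sigma = np.sqrt(sigma2)
    baseline = rng.uniform(cfg.baseline_low, cfg.baseline_high, size=n)
    effects = np.zeros(n)
    is_de = np.array([g in de_set for g in genes])
    magnitudes = rng.uniform(cfg.effect_low, cfg.effect_high, size=n)
    signs = rng.choice([-1.0, 1.0], size=n)
    effects[is_de] = (magnitudes * signs)[is_de]
    n1, n0 = cfg.n_case_samples, cfg.n_control_samples
    noise = rng.normal(size=(n, n1 + n0)) * sigma[:, None]
    values = baseline[:, None] + noise
    values[:, :n1] += effects[:, None]
    matrix = ExpressionMatrix(
        gene_ids=genes,
        sample_ids=[f"MS{i + 1:02d}" for i in range(n1)]
        + [f"C{i + 1:02d}" for i in range(n0)],
        group_labels=["case"] * n1 + ["control"] * n0,
        values=values,
    )
    truth = pd.DataFrame(
        {"gene_id": genes, "is_de": is_de, "effect_log2": effects, "sigma": sigma}
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# GWAS catalog
# ---------------------------------------------------------------------------


def simulate_catalog(
    cfg: SimulationConfig,
) -> tuple[list[GwasCatalogRecord], frozenset[str]]:
    """Catalog export with the configured number of qualifying SNPs mapping
    onto exactly ``catalog_genes`` genes, plus trait and p-value decoys.

    Returns (records, expected gene set under the trait/p filter).
    """
    rng = _rng(cfg, _STREAM_CATALOG)
    names = gene_names(cfg)
    catalog_genes = list(names.catalog())
    if cfg.catalog_snps < len(catalog_genes):
        raise ValidationError("catalog_snps must cover every catalog gene at least once")
    log_hi = math.log10(cfg.gwas_p_threshold)
    records: list[GwasCatalogRecord] = []
    # every gene gets one qualifying SNP; the surplus SNPs land on random
    # genes, occasionally mapped to two symbols to exercise separator parsing
    assignments: list[tuple[str, ...]] = [(g,) for g in catalog_genes]
    for _ in range(cfg.catalog_snps - len(catalog_genes)):
        if rng.random() < 0.1:
            pair = tuple(rng.choice(catalog_genes, size=2, replace=False))
            assignments.append(pair)
        else:
            assignments.append((str(rng.choice(catalog_genes)),))
    for i, genes in enumerate(assignments):
        p = 10.0 ** rng.uniform(-12.0, log_hi)
        records.append(GwasCatalogRecord(f"rsQ{i + 1:05d}", cfg.trait, min(p, cfg.gwas_p_threshold), genes))
    for i in range(cfg.n_decoy_trait_snps):
        gene = str(rng.choice(catalog_genes))
        records.append(
            GwasCatalogRecord(
                f"rsT{i + 1:05d}", "alzheimer disease", 10.0 ** rng.uniform(-12, -2), (gene,)
            )
        )
    for i in range(cfg.n_decoy_p_snps):
        p = 10.0 ** rng.uniform(log_hi, -2.0)
        p = max(p, math.nextafter(cfg.gwas_p_threshold, 1.0))
        records.append(GwasCatalogRecord(f"rsP{i + 1:05d}", cfg.trait, p, (f"DCY{i + 1:04d}",)))
    order = rng.permutation(len(records))
    return [records[i] for i in order], frozenset(catalog_genes)


# ---------------------------------------------------------------------------
# Transcript models
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def _transcript_to_genomic(
    exons: list[tuple[int, int]], strand: str, length: int, t: int
) -> int:
    fwd = t if strand == "+" else length - 1 - t
    offset = 0
    for start, end in exons:
        span = end - start + 1
        if fwd < offset + span:
            return start + (fwd - offset)
        offset += span
    raise ValidationError(f"transcript index {t} outside exons")


def _layout_transcript(
    gene: str,
    chrom: str,
    strand: str,
    tseq: str,
    n_exons: int,
    intron_lengths: list[int],
    genome_start: int,
    cds_lo_t: int,
    cds_hi_t: int,
    rng: np.random.Generator,
) -> TranscriptModel:
    """Split a transcript sequence into exons and lay it onto the genome."""
    L = len(tseq)
    if n_exons > 1:
        cuts = sorted(rng.choice(np.arange(1, L), size=n_exons - 1, replace=False))
    else:
        cuts = []
    bounds = [0, *cuts, L]
    chunk_lengths = [bounds[i + 1] - bounds[i] for i in range(n_exons)]  # transcript order
    genomic_lengths = chunk_lengths if strand == "+" else chunk_lengths[::-1]
    exons: list[tuple[int, int]] = []
    pos = genome_start
    for i, span in enumerate(genomic_lengths):
        exons.append((pos, pos + span - 1))
        pos += span + (intron_lengths[i] if i < len(intron_lengths) else 0)
    g1 = _transcript_to_genomic(exons, strand, L, cds_lo_t)
    g2 = _transcript_to_genomic(exons, strand, L, cds_hi_t)
    return TranscriptModel(
        gene_id=gene,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_start=min(g1, g2),
        cds_end=max(g1, g2),
        sequence=tseq,
    )


def _random_transcript(
    gene: str, chrom: str, cfg: SimulationConfig, rng: np.random.Generator
) -> TranscriptModel:
    n_codons = int(rng.integers(cfg.n_codons_low, cfg.n_codons_high + 1))
    cds = (
        "ATG"
        + "".join(rng.choice(_SENSE_CODONS, size=n_codons - 2))
        + str(rng.choice(_STOPS))
    )
    u5 = _random_seq(rng, int(rng.integers(cfg.utr5_low, cfg.utr5_high + 1)))
    u3 = _random_seq(rng, int(rng.integers(cfg.utr3_low, cfg.utr3_high + 1)))
    tseq = u5 + cds + u3
    n_exons = int(rng.integers(cfg.n_exons_low, cfg.n_exons_high + 1))
    introns = [int(x) for x in rng.integers(cfg.intron_low, cfg.intron_high + 1, size=n_exons - 1)]
    strand = str(rng.choice(["+", "-"]))
    return _layout_transcript(
        gene, chrom, strand, tseq, n_exons, introns, 10_001,
        len(u5), len(u5) + len(cds) - 1, rng,
    )


def _shift_model(model: TranscriptModel, delta: int) -> TranscriptModel:
    return TranscriptModel(
        gene_id=model.gene_id,
        chrom=model.chrom,
        strand=model.strand,
        exons=[(s + delta, e + delta) for s, e in model.exons],
        cds_start=model.cds_start + delta,
        cds_end=model.cds_end + delta,
        sequence=model.sequence,
    )


def _craft_gly482(rng: np.random.Generator) -> tuple[TranscriptModel, Variant]:
    """Minus-strand transcript whose codon 482 is GGT, anchored so a
    genomic C>T at chr4:23814039 yields Ggt/Agt p.Gly482Ser."""
    n_codons = 500
    codons = ["ATG"] + [str(rng.choice(_SENSE_CODONS)) for _ in range(n_codons - 2)]
    codons.append(str(rng.choice(_STOPS)))
    codons[481] = "GGT"  # codon number 482
    cds = "".join(codons)
    u5 = _random_seq(rng, 120)
    u3 = _random_seq(rng, 180)
    tseq = u5 + cds + u3
    introns = [int(x) for x in rng.integers(200, 800, size=4)]
    model = _layout_transcript(
        "DEMO_GLY482", "chr4", "-", tseq, 5, introns, 10_001,
        len(u5), len(u5) + len(cds) - 1, rng,
    )
    t_target = len(u5) + 481 * 3  # first base of codon 482
    pos0 = _transcript_to_genomic(model.exons, "-", len(tseq), t_target)
    model = _shift_model(model, 23_814_039 - pos0)
    # transcript G>A on the minus strand is genomic C>T
    variant = Variant("chr4", 23_814_039, "C", "T", "rsDEMO482")
    return model, variant


def _craft_utr5_minus(rng: np.random.Generator) -> tuple[TranscriptModel, Variant]:
    """Minus-strand transcript with a C at c.-54, anchored so a genomic G>A
    at chr17:40100148 yields the 5'-UTR call c.-54C > T."""
    n_codons = 300
    cds = (
        "ATG"
        + "".join(rng.choice(_SENSE_CODONS, size=n_codons - 2))
        + str(rng.choice(_STOPS))
    )
    u5 = list(_random_seq(rng, 90))
    t_target = len(u5) - 54  # 54 bases upstream of the first CDS base
    u5[t_target] = "C"
    tseq = "".join(u5) + cds + _random_seq(rng, 150)
    introns = [int(x) for x in rng.integers(200, 800, size=3)]
    model = _layout_transcript(
        "DEMO_UTR5", "chr17", "-", tseq, 4, introns, 10_001,
        len(u5), len(u5) + len(cds) - 1, rng,
    )
    pos0 = _transcript_to_genomic(model.exons, "-", len(tseq), t_target)
    model = _shift_model(model, 40_100_148 - pos0)
    variant = Variant("chr17", 40_100_148, "G", "A", "rsDEMOUTR5")
    return model, variant


def simulate_transcripts(
    cfg: SimulationConfig,
) -> tuple[dict[str, TranscriptModel], list[tuple[Variant, str]]]:
    """Transcript models for every gene that carries planted variants, plus
    the two hand-crafted minus-strand fixtures.

    Returns (models by gene, crafted (variant, gene) fixtures).
    """
    rng = _rng(cfg, _STREAM_TRANSCRIPTS)
    names = gene_names(cfg)
    models: dict[str, TranscriptModel] = {}
    carriers = list(names.overlap[: cfg.n_funnel_genes]) + list(names.partners)
    for i, gene in enumerate(carriers):
        models[gene] = _random_transcript(gene, f"chr_{gene}", cfg, rng)
    gly_model, gly_variant = _craft_gly482(rng)
    utr_model, utr_variant = _craft_utr5_minus(rng)
    models[gly_model.gene_id] = gly_model
    models[utr_model.gene_id] = utr_model
    crafted = [(gly_variant, gly_model.gene_id), (utr_variant, utr_model.gene_id)]
    return models, crafted


# ---------------------------------------------------------------------------
# Variant planting within transcripts
# ---------------------------------------------------------------------------


def _plant_variant(
    model: TranscriptModel,
    klass: str,
    rng: np.random.Generator,
    used: set[int],
    max_attempts: int = 2000,
) -> Variant:
    """Place a single-nucleotide substitution of the requested consequence
    class inside a transcript; verified against :func:`classify`."""
    L = model.length
    cds_lo, cds_hi = model.cds_transcript_bounds()
    for _ in range(max_attempts):
        if klass == INTRONIC:
            gaps = [
                (model.exons[i][1] + 1, model.exons[i + 1][0] - 1)
                for i in range(len(model.exons) - 1)
                if model.exons[i + 1][0] - model.exons[i][1] > 1
            ]
            if not gaps:
                raise ValidationError(f"{model.gene_id}: no intron to place a variant in")
            lo, hi = gaps[int(rng.integers(len(gaps)))]
            pos = int(rng.integers(lo, hi + 1))
            if pos in used:
                continue
            ref = str(rng.choice(list(_BASES)))
            alt = str(rng.choice([b for b in _BASES if b != ref]))
            variant = Variant(model.chrom, pos, ref, alt)
        else:
            if klass == UTR5:
                if cds_lo == 0:
                    raise ValidationError(f"{model.gene_id}: no 5'-UTR")
                t = int(rng.integers(0, cds_lo))
            elif klass == UTR3:
                if cds_hi == L - 1:
                    raise ValidationError(f"{model.gene_id}: no 3'-UTR")
                t = int(rng.integers(cds_hi + 1, L))
            else:
                # keep clear of the start and stop codons
                t = int(rng.integers(cds_lo + 3, cds_hi - 2))
            ref_t = model.sequence[t].upper()
            alt_choices = [b for b in _BASES if b != ref_t]
            rng.shuffle(alt_choices)
            alt_t = None
            if klass in (UTR5, UTR3):
                alt_t = alt_choices[0]
            else:
                offset = t - cds_lo
                codon_idx, within = divmod(offset, 3)
                start = cds_lo + 3 * codon_idx
                ref_codon = model.sequence[start : start + 3].upper()
                for cand in alt_choices:
                    alt_codon = ref_codon[:within] + cand + ref_codon[within + 1 :]
                    ref_aa = _translate_codon(ref_codon)
                    alt_aa = _translate_codon(alt_codon)
                    got = (
                        SYNONYMOUS if alt_aa == ref_aa
                        else STOP_GAINED if alt_aa == "*"
                        else MISSENSE
                    )
                    if got == klass:
                        alt_t = cand
                        break
                if alt_t is None:
                    continue
            pos = _transcript_to_genomic(model.exons, model.strand, L, t)
            if pos in used:
                continue
            if model.strand == "+":
                ref, alt = ref_t, alt_t
            else:
                ref = ref_t.translate(_COMPLEMENT)
                alt = alt_t.translate(_COMPLEMENT)
            variant = Variant(model.chrom, pos, ref, alt)
        result = classify(variant, model)
        if result.klass == klass:
            used.add(variant.pos)
            return variant
    raise ValidationError(
        f"{model.gene_id}: could not plant a {klass} variant in {max_attempts} attempts"
    )


_CODON_TABLE: dict[str, str] = {}


def _translate_codon(codon: str) -> str:
    if not _CODON_TABLE:
        from Bio.Seq import Seq

        for c in ("".join(x) for x in itertools.product(_BASES, repeat=3)):
            _CODON_TABLE[c] = str(Seq(c).translate())
    return _CODON_TABLE[codon]


# ---------------------------------------------------------------------------
# Families: pedigree, genotypes, VCF truth
# ---------------------------------------------------------------------------


def default_pedigree() -> Pedigree:
    """Three nuclear families, 11 members, 7 affected / 4 unaffected."""
    rows = [
        # family, id, father, mother, sex, affection
        ("F1", "F1_I1", None, None, "1", AFFECTED),
        ("F1", "F1_I2", None, None, "2", UNAFFECTED),
        ("F1", "F1_II1", "F1_I1", "F1_I2", "2", AFFECTED),
        ("F1", "F1_II2", "F1_I1", "F1_I2", "1", AFFECTED),
        ("F2", "F2_I1", None, None, "1", UNAFFECTED),
        ("F2", "F2_I2", None, None, "2", AFFECTED),
        ("F2", "F2_II1", "F2_I1", "F2_I2", "2", AFFECTED),
        ("F2", "F2_II2", "F2_I1", "F2_I2", "1", UNAFFECTED),
        ("F3", "F3_I1", None, None, "1", AFFECTED),
        ("F3", "F3_I2", None, None, "2", UNAFFECTED),
        ("F3", "F3_II1", "F3_I1", "F3_I2", "2", AFFECTED),
    ]
    return Pedigree(
        [PedigreeMember(f, i, fa, mo, s, a) for f, i, fa, mo, s, a in rows]
    )


@dataclass
class FamilySim:
    pedigree: Pedigree
    variants: VariantTable
    gene_map: dict[str, str]
    origin_map: dict[str, str]
    subgroup: dict[str, str]  # variant key -> planting subgroup
    planted_keys: frozenset[str]  # all transmission-passing planted variants
    models: dict[str, TranscriptModel]
    crafted: list[tuple[Variant, str]]

    def keys_in(self, *subgroups: str) -> frozenset[str]:
        return frozenset(k for k, s in self.subgroup.items() if s in subgroups)


def _planted_genotypes(
    pedigree: Pedigree, rng: np.random.Generator
) -> dict[str, int]:
    """Genotypes that satisfy the default transmission rule in one random
    family: affected members het, unaffected members ref."""
    families = list(pedigree.families().items())
    fam_id, _ = families[int(rng.integers(len(families)))]
    out: dict[str, int] = {}
    for m in pedigree:
        if m.family_id == fam_id and m.affection == AFFECTED:
            out[m.individual_id] = 1
        else:
            out[m.individual_id] = 0
    return out


def _background_genotypes(
    pedigree: Pedigree,
    rule: TransmissionRule,
    rng: np.random.Generator,
    cfg: SimulationConfig,
) -> dict[str, int]:
    """Hardy-Weinberg founders with Mendelian transmission, rejection-sampled
    until the variant violates the transmission rule."""
    for _ in range(cfg.max_rejection_attempts):
        maf = rng.uniform(cfg.background_maf_low, cfg.background_maf_high)
        out: dict[str, int] = {}
        for fam in pedigree.families().values():
            by_id = {m.individual_id: m for m in fam}
            for m in fam:
                if m.is_founder:
                    out[m.individual_id] = int(rng.binomial(2, maf))
            for m in fam:
                if not m.is_founder:
                    gf = out[m.father_id]
                    gm = out[m.mother_id]
                    a = int(rng.random() < gf / 2.0) + int(rng.random() < gm / 2.0)
                    out[m.individual_id] = a
        for key in out:
            if rng.random() < cfg.background_missing_rate:
                out[key] = MISSING
        if not evaluate_variant(out, pedigree, rule).overall_pass:
            return out
    raise ValidationError(
        "could not sample a rule-violating background variant within "
        f"{cfg.max_rejection_attempts} attempts"
    )


def _distribute(n: int, bins: int, rng: np.random.Generator) -> list[int]:
    """Split n items over bins, each bin getting at least one while n >= bins."""
    if bins == 0 or n <= 0:
        return [0] * bins
    if n <= bins:
        return [1] * n + [0] * (bins - n)
    extra = rng.multinomial(n - bins, [1.0 / bins] * bins)
    return [1 + int(e) for e in extra]


_NONINTRONIC_MIX = ([SYNONYMOUS, MISSENSE, STOP_GAINED, UTR5, UTR3],
                    [0.40, 0.40, 0.05, 0.08, 0.07])


def simulate_families(
    cfg: SimulationConfig, rule: TransmissionRule | None = None
) -> FamilySim:
    """Pedigree plus a variant table with planted co-segregating variants.

    Planted variants pass the transmission rule by construction (affected
    carriers in one family, including a transmitting parent-child pair);
    background variants are rejection-sampled to violate it.
    """
    rule = rule or TransmissionRule()
    rng = _rng(cfg, _STREAM_FAMILIES)
    pedigree = default_pedigree()
    models, crafted = simulate_transcripts(cfg)
    names = gene_names(cfg)
    classes, weights = _NONINTRONIC_MIX

    records: list[tuple[Variant, str, str, dict[str, int]]] = []
    used: dict[str, set[int]] = {}

    def plant(gene: str, klass: str, subgroup: str) -> None:
        model = models[gene]
        variant = _plant_variant(model, klass, rng, used.setdefault(model.chrom, set()))
        records.append((variant, gene, subgroup, _planted_genotypes(pedigree, rng)))

    # shared-gene (MS-GWAS arm) variants: 7 low-frequency nonintronic, some
    # common nonintronic, the rest intronic, spread over the funnel genes
    funnel_genes = list(names.overlap[: cfg.n_funnel_genes])
    specs: list[str] = (
        [GWAS_LOWFREQ] * cfg.n_gwas_prioritized
        + [GWAS_COMMON] * cfg.n_gwas_common_nonintronic
        + [GWAS_INTRONIC]
        * (cfg.n_funnel_variants - cfg.n_gwas_prioritized - cfg.n_gwas_common_nonintronic)
    )
    rng.shuffle(specs)
    if funnel_genes:
        counts = _distribute(len(specs), len(funnel_genes), rng)
        spec_iter = iter(specs)
        for gene, k in zip(funnel_genes, counts):
            for _ in range(k):
                sub = next(spec_iter)
                klass = (
                    INTRONIC if sub == GWAS_INTRONIC
                    else str(rng.choice(classes, p=weights))
                )
                plant(gene, klass, sub)

    # functional-partner arm: intronic/nonintronic split only
    partner_specs = (
        [PARTNER_NONINTRONIC] * cfg.n_partner_nonintronic
        + [PARTNER_INTRONIC] * (cfg.n_partner_variants - cfg.n_partner_nonintronic)
    )
    rng.shuffle(partner_specs)
    if names.partners:
        counts = _distribute(len(partner_specs), len(names.partners), rng)
        spec_iter = iter(partner_specs)
        for gene, k in zip(names.partners, counts):
            for _ in range(k):
                sub = next(spec_iter)
                klass = (
                    INTRONIC if sub == PARTNER_INTRONIC
                    else str(rng.choice(classes, p=weights))
                )
                plant(gene, klass, sub)

    # background variants violating the rule, one synthetic gene each
    for i in range(cfg.n_background_variants):
        ref = str(rng.choice(list(_BASES)))
        alt = str(rng.choice([b for b in _BASES if b != ref]))
        variant = Variant("chrB", 1_000 + 50 * i, ref, alt)
        genotypes = _background_genotypes(pedigree, rule, rng, cfg)
        records.append((variant, f"BGG{i + 1:04d}", BACKGROUND, genotypes))

    records.sort(key=lambda r: (r[0].chrom, r[0].pos))
    roster = pedigree.sample_ids
    table = VariantTable(
        [r[0] for r in records],
        roster,
        np.array([[r[3][s] for s in roster] for r in records], dtype=np.int8).reshape(
            len(records), len(roster)
        ),
    )
    gene_map = {r[0].key: r[1] for r in records}
    subgroup = {r[0].key: r[2] for r in records}
    origin_map = {
        r[0].key: ("functional_partner" if r[2].startswith("partner") else "ms_gwas")
        for r in records
        if r[2] != BACKGROUND
    }
    planted = frozenset(k for k, s in subgroup.items() if s != BACKGROUND)
    return FamilySim(
        pedigree=pedigree,
        variants=table,
        gene_map=gene_map,
        origin_map=origin_map,
        subgroup=subgroup,
        planted_keys=planted,
        models=models,
        crafted=crafted,
    )


# ---------------------------------------------------------------------------
# Population frequencies
# ---------------------------------------------------------------------------


def _logit_shift(p: float, delta: float) -> float:
    return 1.0 / (1.0 + math.exp(-(math.log(p / (1.0 - p)) + delta)))


def _truncated_binomial(
    rng: np.random.Generator,
    n: int,
    p: float,
    freq_max: float | None = None,
    freq_min: float | None = None,
    attempts: int = 200,
) -> int:
    for _ in range(attempts):
        x = int(rng.binomial(n, p))
        if freq_max is not None and x / n > freq_max:
            continue
        if freq_min is not None and x / n <= freq_min:
            continue
        return x
    if freq_max is not None:
        return int(math.floor(freq_max * n))
    return int(math.ceil((freq_min or 0.0) * n)) + 1


def simulate_frequencies(
    cfg: SimulationConfig, family_sim: FamilySim | None = None
) -> tuple[FrequencyTable, pd.DataFrame]:
    """Allele counts per population for every planted family variant.

    Counts are Binomial(allele_number, p); planted true-difference variants
    shift the affected cohort's p by ``planted_log_odds`` on the logit
    scale.  Low-frequency shared-gene variants are guaranteed to realize
    control frequencies <= maf_max (and the planted common ones > maf_max),
    so the MAF filter sees its planted truth exactly.
    """
    fam = family_sim if family_sim is not None else simulate_families(cfg)
    rng = _rng(cfg, _STREAM_FREQUENCIES)
    lowfreq = sorted(fam.keys_in(GWAS_LOWFREQ))
    common_gwas = sorted(fam.keys_in(GWAS_COMMON, GWAS_INTRONIC))
    partner_keys = sorted(fam.keys_in(PARTNER_NONINTRONIC, PARTNER_INTRONIC))
    partner_nonint = sorted(fam.keys_in(PARTNER_NONINTRONIC))

    diff_keys: set[str] = set()
    if cfg.n_gwas_true_diff and lowfreq:
        diff_keys |= set(rng.choice(lowfreq, size=cfg.n_gwas_true_diff, replace=False))
    if cfg.n_partner_true_diff and partner_nonint:
        diff_keys |= set(
            rng.choice(partner_nonint, size=cfg.n_partner_true_diff, replace=False)
        )

    records: list[FrequencyRecord] = []
    truth_rows = []
    for key in lowfreq + common_gwas + partner_keys:
        if key in lowfreq:
            base = float(rng.uniform(cfg.lowfreq_low, cfg.lowfreq_high))
            fmax, fmin = cfg.maf_max, None
        elif key in common_gwas:
            base = float(rng.uniform(cfg.common_low, cfg.common_high))
            fmax, fmin = None, cfg.maf_max
        else:
            base = float(rng.uniform(cfg.common_low, cfg.common_high))
            fmax = fmin = None
        p_aff = _logit_shift(base, cfg.planted_log_odds) if key in diff_keys else base
        x_aff = int(rng.binomial(cfg.affected_allele_number, p_aff))
        records.append(
            FrequencyRecord(key, cfg.affected_population, x_aff, cfg.affected_allele_number)
        )
        for pop, an in cfg.control_populations:
            x = _truncated_binomial(rng, an, base, freq_max=fmax, freq_min=fmin)
            records.append(FrequencyRecord(key, pop, x, an))
        truth_rows.append(
            {
                "variant": key,
                "subgroup": fam.subgroup[key],
                "p_control": base,
                "p_affected": p_aff,
                "true_diff": key in diff_keys,
            }
        )
    return FrequencyTable(records), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Whole-dataset bundle
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    cfg: SimulationConfig
    expression: ExpressionMatrix
    expression_truth: pd.DataFrame
    catalog: list[GwasCatalogRecord]
    catalog_genes: frozenset[str]
    family: FamilySim
    frequencies: FrequencyTable
    frequency_truth: pd.DataFrame
    class_map: dict[str, str]
    partner_genes: tuple[str, ...]


def simulate_all(cfg: SimulationConfig) -> SyntheticDataset:
    expression, expr_truth = simulate_expression(cfg)
    catalog, catalog_genes = simulate_catalog(cfg)
    fam = simulate_families(cfg)
    freqs, freq_truth = simulate_frequencies(cfg, fam)
    return SyntheticDataset(
        cfg=cfg,
        expression=expression,
        expression_truth=expr_truth,
        catalog=catalog,
        catalog_genes=catalog_genes,
        family=fam,
        frequencies=freqs,
        frequency_truth=freq_truth,
        class_map=gene_class_map(cfg),
        partner_genes=gene_names(cfg).partners,
    )
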