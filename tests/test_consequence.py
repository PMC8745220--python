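"""Consequence calling: crafted fixtures, translation oracle, filters."""

import numpy as np
import pytest
from Bio.Seq import Seq

from varfunnel.consequence import (
    INTRONIC,
    MISSENSE,
    STOP_GAINED,
    SYNONYMOUS,
    UTR3,
    UTR5,
    PrioritizedVariant,
    Consequence,
    ReferenceMismatchError,
    classify,
    low_frequency_filter,
    split_intronic,
)
from varfunnel.io_formats import (
    FrequencyRecord,
    FrequencyTable,
    TranscriptModel,
    Variant,
)
from varfunnel.synthetic_data import (
    SimulationConfig,
    _plant_variant,
    _random_transcript,
    simulate_families,
    simulate_transcripts,
)

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(COMP)[::-1]


# ---------------------------------------------------------------------------
# crafted minus-strand fixtures
# ---------------------------------------------------------------------------


class TestCraftedFixtures:
    def test_gly482ser_missense(self):
        """Minus-strand G>A in codon 482 (GGT): Ggt/Agt, p.Gly482Ser."""
        models, crafted = simulate_transcripts(SimulationConfig(seed=0))
        variant, gene = crafted[0]
        assert (variant.chrom, variant.pos) == ("chr4", 23814039)
        assert (variant.ref, variant.alt) == ("C", "T")
        c = classify(variant, models[gene])
        assert c.klass == MISSENSE
        assert c.codon_change == "Ggt/Agt"
        assert c.hgvs_p == "p.Gly482Ser"

    def test_utr5_c54(self):
        """Minus-strand G>A 54 bases upstream of the CDS: c.-54C > T, 5'-UTR."""
        models, crafted = simulate_transcripts(SimulationConfig(seed=0))
        variant, gene = crafted[1]
        assert (variant.chrom, variant.pos) == ("chr17", 40100148)
        c = classify(variant, models[gene])
        assert c.klass == UTR5
        assert c.hgvs_c == "c.-54C > T"


# ---------------------------------------------------------------------------
# brute-force full-translation oracle
# ---------------------------------------------------------------------------


def genome_for(model: TranscriptModel, rng) -> tuple[int, str]:
    """Genomic sequence over the gene span consistent with the model."""
    start, end = model.span
    genome = list("".join(rng.choice(list("ACGT"), size=end - start + 1)))
    exonic = model.sequence if model.strand == "+" else revcomp(model.sequence)
    i = 0
    for s, e in model.exons:
        for pos in range(s, e + 1):
            genome[pos - start] = exonic[i]
            i += 1
    return start, "".join(genome)


def oracle_classify(variant: Variant, model: TranscriptModel, genome_start: int, genome: str):
    """Re-splice and fully retranslate the edited gene, independently of the
    production code's coordinate arithmetic."""
    span_lo, span_hi = model.span
    if variant.chrom != model.chrom or not span_lo <= variant.pos <= span_hi:
        return "intergenic"
    idx = variant.pos - genome_start
    assert genome[idx] != variant.alt
    edited = genome[:idx] + variant.alt + genome[idx + 1 :]

    def splice(g: str) -> str:
        parts = [g[s - genome_start : e - genome_start + 1] for s, e in model.exons]
        joined = "".join(parts)
        return joined if model.strand == "+" else revcomp(joined)

    before, after = splice(genome), splice(edited)
    if before == after:
        return INTRONIC
    # transcript coordinate of each genomic position, by explicit enumeration
    coords = [p for s, e in model.exons for p in range(s, e + 1)]
    if model.strand == "-":
        coords = coords[::-1]
    cds_lo = min(coords.index(model.cds_start), coords.index(model.cds_end))
    cds_hi = max(coords.index(model.cds_start), coords.index(model.cds_end))
    t = next(i for i in range(len(before)) if before[i] != after[i])
    if t < cds_lo:
        return UTR5
    if t > cds_hi:
        return UTR3
    prot_before = str(Seq(before[cds_lo : cds_hi + 1]).translate())
    prot_after = str(Seq(after[cds_lo : cds_hi + 1]).translate())
    changed = [i for i in range(len(prot_before)) if prot_before[i] != prot_after[i]]
    if not changed:
        return SYNONYMOUS
    if prot_after[changed[0]] == "*":
        return STOP_GAINED
    return MISSENSE


def test_classify_agrees_with_full_translation_oracle():
    """>= 1,000 random SNVs on random transcripts, both strands."""
    rng = np.random.default_rng(99)
    cfg = SimulationConfig(seed=0)
    n_checked = 0
    for k in range(25):
        model = _random_transcript(f"T{k}", f"chrT{k}", cfg, rng)
        genome_start, genome = genome_for(model, rng)
        span_lo, span_hi = model.span
        positions = rng.integers(span_lo, span_hi + 1, size=40)
        for pos in positions:
            ref = genome[pos - genome_start]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            variant = Variant(model.chrom, int(pos), ref, alt)
            expected = oracle_classify(variant, model, genome_start, genome)
            got = classify(variant, model)
            assert got.klass == expected, (variant.key, model.gene_id)
            n_checked += 1
    assert n_checked >= 1000


def test_strand_mirror_consistency():
    """A transcript and its reverse-complemented mirror give identical classes."""
    rng = np.random.default_rng(7)
    cfg = SimulationConfig(seed=0)
    model = _random_transcript("FWD", "chrM", cfg, rng)
    if model.strand == "-":  # force a + model for the mirror construction
        model = TranscriptModel(
            "FWD", "chrM", "+", model.exons, model.cds_start, model.cds_end,
            revcomp(model.sequence),
        )
    genome_start, genome = genome_for(model, rng)
    span_lo, span_hi = model.span
    width = span_hi - span_lo

    def mirror_pos(pos: int) -> int:
        return span_lo + (span_hi - pos)

    mirrored = TranscriptModel(
        "REV", "chrM", "-",
        sorted(((mirror_pos(e), mirror_pos(s)) for s, e in model.exons)),
        mirror_pos(model.cds_end), mirror_pos(model.cds_start),
        model.sequence,  # same transcript, mirrored genome
    )
    for pos in rng.integers(span_lo, span_hi + 1, size=200):
        ref = genome[pos - genome_start]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        fwd = classify(Variant("chrM", int(pos), ref, alt), model)
        rev = classify(
            Variant("chrM", mirror_pos(int(pos)), ref.translate(COMP), alt.translate(COMP)),
            mirrored,
        )
        assert fwd.klass == rev.klass
        assert fwd.hgvs_p == rev.hgvs_p


def test_reference_mismatch_raises():
    rng = np.random.default_rng(3)
    cfg = SimulationConfig(seed=0)
    model = _random_transcript("G", "chr1", cfg, rng)
    used: set[int] = set()
    planted = _plant_variant(model, MISSENSE, rng, used)
    wrong_ref = next(b for b in "ACGT" if b != planted.ref and b != planted.alt)
    with pytest.raises(ReferenceMismatchError):
        classify(Variant("chr1", planted.pos, wrong_ref, planted.alt), model)


def test_generated_cds_translate_cleanly(default_dataset):
    """Every generated transcript has a valid CDS: start codon, no internal
    stop, one terminal stop."""
    for model in default_dataset.family.models.values():
        protein = model.protein()
        assert model.cds_sequence().startswith("ATG")
        assert protein.endswith("*")
        assert "*" not in protein[:-1]


# ---------------------------------------------------------------------------
# low-frequency filter and intronic split
# ---------------------------------------------------------------------------


def _pv(key: str, klass: str = MISSENSE) -> PrioritizedVariant:
    chrom, pos, ref, alt = key.rsplit(":", 3)
    return PrioritizedVariant(
        variant=Variant(chrom, int(pos), ref, alt),
        gene_id="G",
        consequence=Consequence(klass),
    )


class TestLowFrequencyFilter:
    def _freqs(self, entries):
        return FrequencyTable(
            FrequencyRecord(v, pop, int(round(f * 10000)), 10000)
            for v, pop, f in entries
        )

    def test_published_maf_examples(self):
        """0.0224 passes the 0.04 ceiling, 0.3215 does not."""
        freqs = self._freqs([("chr2:1:G:A", "ctrl", 0.0224), ("chr12:1:G:A", "ctrl", 0.3215)])
        kept = low_frequency_filter(
            [_pv("chr2:1:G:A"), _pv("chr12:1:G:A")], freqs, source_populations=["ctrl"]
        )
        assert [p.key for p in kept] == ["chr2:1:G:A"]

    def test_boundary_inclusive(self):
        freqs = self._freqs([("chr1:1:A:T", "ctrl", 0.04)])
        assert len(low_frequency_filter([_pv("chr1:1:A:T")], freqs, source_populations=["ctrl"])) == 1

    def test_max_across_source_populations(self):
        freqs = self._freqs([("chr1:1:A:T", "a", 0.01), ("chr1:1:A:T", "b", 0.10)])
        assert low_frequency_filter([_pv("chr1:1:A:T")], freqs, source_populations=["a", "b"]) == []
        assert len(low_frequency_filter([_pv("chr1:1:A:T")], freqs, source_populations=["a"])) == 1

    def test_no_frequency_dropped_with_warning(self, caplog):
        freqs = self._freqs([("chr9:9:A:T", "ctrl", 0.01)])
        with caplog.at_level("WARNING", logger="varfunnel"):
            kept = low_frequency_filter([_pv("chr1:1:A:T")], freqs, source_populations=["ctrl"])
        assert kept == []
        assert "no frequency" in caplog.text


class TestSplitIntronic:
    def test_planted_partner_split(self, default_dataset):
        """The partner-arm fixture splits 57 variants into 39 intronic and
        18 nonintronic."""
        fam = default_dataset.family
        partner_keys = fam.keys_in("partner_nonintronic", "partner_intronic")
        pvs = []
        for key in sorted(partner_keys):
            gene = fam.gene_map[key]
            chrom, pos, ref, alt = key.rsplit(":", 3)
            variant = Variant(chrom, int(pos), ref, alt)
            pvs.append(
                PrioritizedVariant(
                    variant=variant, gene_id=gene,
                    consequence=classify(variant, fam.models[gene]),
                )
            )
        intronic, nonintronic = split_intronic(pvs)
        assert (len(pvs), len(intronic), len(nonintronic)) == (57, 39, 18)

    def test_empty(self):
        assert split_intronic([]) == ([], [])

    def test_partition_sizes_sum(self, rng):
        classes = [INTRONIC, SYNONYMOUS, MISSENSE, UTR5, UTR3, STOP_GAINED]
        pvs = [
            _pv(f"chr1:{i + 1}:A:T", str(rng.choice(classes))) for i in range(60)
        ]
        intronic, nonintronic = split_intronic(pvs)
        assert len(intronic) + len(nonintronic) == len(pvs)
        assert not {p.key for p in intronic} & {p.key for p in nonintronic}


def test_intron_placed_variant_is_intronic():
    rng = np.random.default_rng(11)
    model = _random_transcript("G", "chr5", SimulationConfig(seed=0), rng)
    planted = _plant_variant(model, INTRONIC, rng, set())
    assert classify(planted, model).klass == INTRONIC
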