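"""End-to-end funnel orchestration.

Runs the stages in method order — differential expression, GWAS gene set,
family transmission filter, gene-set restriction, consequence annotation
with the low-frequency/nonintronic prioritization, and the case-control
allele-frequency tests — each stage reading and writing plain-text files in
an output directory, so that running the stages one by one produces exactly
the same files as the monolithic run.

The funnel has two arms: shared-gene variants (transmission-filtered
variants in genes that are both GWAS-listed and differentially expressed)
go through the low-frequency + nonintronic prioritization; variants in the
configured functional-partner genes (differentially expressed interactors
not in the GWAS catalog) are restricted to nonintronic consequences only.
The union of both arms forms the tested family for the Bonferroni-tiered
z-tests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import af_stats, consequence, de_expression, gene_sets, io_formats, segregation
from .io_formats import ValidationError
from .synthetic_data import SimulationConfig, gene_class_map, gene_names, simulate_all

logger = logging.getLogger("varfunnel")

INPUT_FILES = {
    "expression": "expression.tsv",
    "catalog": "catalog.tsv",
    "vcf": "families.vcf",
    "ped": "families.ped",
    "transcripts_tsv": "transcripts.tsv",
    "transcripts_fasta": "transcripts.fa",
    "frequencies": "frequencies.tsv",
    "gene_map": "gene_map.tsv",
    "class_map": "class_map.tsv",
    "annotations": "annotations.tsv",
}

MAF_FROM_CONTROLS = "controls"
MAF_FROM_AFFECTED = "affected"

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}


@dataclass
class PipelineConfig:
    """Declarative configuration; defaults mirror the method's thresholds."""

    seed: int = 0
    simulate: bool = True
    sim: dict = field(default_factory=dict)  # SimulationConfig overrides
    inputs: dict = field(default_factory=dict)  # explicit input paths
    trait: str = "multiple sclerosis"
    gwas_p_threshold: float = 5e-6
    fc_min: float = 2.0
    p_max: float = 0.05
    use_adjusted: bool = True
    use_shrinkage: bool = True
    rule: dict = field(default_factory=dict)  # TransmissionRule overrides
    maf_max: float = 0.04
    maf_source: str = MAF_FROM_CONTROLS
    alpha: float = 0.05
    borderline_mult: float = 5.0
    nominal_level: float = 0.05
    m_convention: str = af_stats.M_DISTINCT_VARIANTS
    affected_population: str = "NIG-IT"
    control_populations: list = field(default_factory=lambda: ["1000G-TSI", "gnomAD-nfe"])
    partner_genes: list = field(default_factory=list)

    _FIELD_TYPES = {
        "seed": int,
        "simulate": bool,
        "sim": dict,
        "inputs": dict,
        "trait": str,
        "gwas_p_threshold": (int, float),
        "fc_min": (int, float),
        "p_max": (int, float),
        "use_adjusted": bool,
        "use_shrinkage": bool,
        "rule": dict,
        "maf_max": (int, float),
        "maf_source": str,
        "alpha": (int, float),
        "borderline_mult": (int, float),
        "nominal_level": (int, float),
        "m_convention": str,
        "affected_population": str,
        "control_populations": list,
        "partner_genes": list,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        if not isinstance(data, dict):
            raise ValidationError("config: expected a mapping at the top level")
        unknown = set(data) - set(cls._FIELD_TYPES)
        if unknown:
            raise ValidationError(f"config: unknown fields {sorted(unknown)}")
        for key, value in data.items():
            expected = cls._FIELD_TYPES[key]
            if isinstance(value, bool) and expected in ((int, float),):
                raise ValidationError(f"config: {key}: expected a number, got a boolean")
            if not isinstance(value, expected):
                name = getattr(expected, "__name__", "number")
                raise ValidationError(
                    f"config: {key}: expected {name}, got {type(value).__name__}"
                )
        cfg = cls(**data)
        if cfg.maf_source not in (MAF_FROM_CONTROLS, MAF_FROM_AFFECTED):
            raise ValidationError("config: maf_source: must be 'controls' or 'affected'")
        bad_sim = set(cfg.sim) - _SIM_FIELDS
        if bad_sim:
            raise ValidationError(f"config: sim: unknown fields {sorted(bad_sim)}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def sim_config(self) -> SimulationConfig:
        overrides = dict(self.sim)
        overrides.setdefault("seed", self.seed)
        overrides.setdefault("trait", self.trait)
        overrides.setdefault("gwas_p_threshold", self.gwas_p_threshold)
        overrides.setdefault("maf_max", self.maf_max)
        return SimulationConfig(**overrides)

    def transmission_rule(self) -> segregation.TransmissionRule:
        return segregation.TransmissionRule(**self.rule)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class FunnelReport:
    """Stage counts of the prioritization funnel plus provenance."""

    config_hash: str
    seed: int
    n_input_variants: int
    n_input_genes: int
    n_transmitted: int
    n_shared_genes: int
    n_shared_coding: int | None
    n_shared_ncrna: int | None
    n_geneset_variants: int
    n_geneset_genes: int
    n_gwas_nonintronic: int
    n_prioritized: int  # low-frequency nonintronic, shared-gene arm
    n_partner_variants: int
    n_partner_intronic: int
    n_partner_nonintronic: int
    n_tested: int
    bonferroni_m: int
    threshold: float
    tier_counts: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Input plumbing
# ---------------------------------------------------------------------------


def _input_path(config: PipelineConfig, outdir: Path, key: str) -> Path:
    if key in config.inputs:
        return Path(config.inputs[key])
    return outdir / "inputs" / INPUT_FILES[key]


def write_gene_map(gene_map: dict[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("variant\tgene\n")
        for key in sorted(gene_map):
            fh.write(f"{key}\t{gene_map[key]}\n")


def read_gene_map(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with Path(path).open() as fh:
        header = fh.readline()
        if not header.startswith("variant"):
            raise io_formats.ParseError(f"{path}: expected a variant/gene header")
        for line in fh:
            variant, gene = line.rstrip("\n").split("\t")
            out[variant] = gene
    return out


def write_class_map(class_map: dict[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene\tclass\n")
        for gene in sorted(class_map):
            fh.write(f"{gene}\t{class_map[gene]}\n")


def read_class_map(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with Path(path).open() as fh:
        fh.readline()
        for line in fh:
            gene, klass = line.rstrip("\n").split("\t")
            out[gene] = klass
    return out


def stage_simulate(config: PipelineConfig, outdir: str | Path) -> SimulationConfig:
    """Generate every pipeline input (plus truth tables) under outdir/inputs."""
    outdir = Path(outdir)
    indir = outdir / "inputs"
    indir.mkdir(parents=True, exist_ok=True)
    sim_cfg = config.sim_config()
    data = simulate_all(sim_cfg)
    io_formats.write_expression(data.expression, indir / INPUT_FILES["expression"])
    io_formats.write_gwas_catalog(data.catalog, indir / INPUT_FILES["catalog"])
    io_formats.write_vcf(data.family.variants, indir / INPUT_FILES["vcf"])
    io_formats.write_ped(data.family.pedigree, indir / INPUT_FILES["ped"])
    io_formats.write_transcripts(
        data.family.models,
        indir / INPUT_FILES["transcripts_tsv"],
        indir / INPUT_FILES["transcripts_fasta"],
    )
    io_formats.write_frequencies(data.frequencies, indir / INPUT_FILES["frequencies"])
    write_gene_map(data.family.gene_map, indir / INPUT_FILES["gene_map"])
    write_class_map(data.class_map, indir / INPUT_FILES["class_map"])
    with (indir / "partner_genes.txt").open("w") as fh:
        for gene in data.partner_genes:
            fh.write(gene + "\n")
    data.expression_truth.to_csv(indir / "truth_expression.tsv", sep="\t", index=False)
    truth_variants = sorted(
        (key, sub) for key, sub in data.family.subgroup.items()
    )
    with (indir / "truth_variants.tsv").open("w") as fh:
        fh.write("variant\tsubgroup\n")
        for key, sub in truth_variants:
            fh.write(f"{key}\t{sub}\n")
    data.frequency_truth.to_csv(indir / "truth_frequencies.tsv", sep="\t", index=False)
    if not config.partner_genes:
        config.partner_genes = list(data.partner_genes)
    return sim_cfg


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _counts_dir(outdir: Path) -> Path:
    d = outdir / "counts"
    d.mkdir(parents=True, exist_ok=True)
    return d


def _write_counts(outdir: Path, stage: str, counts: dict) -> None:
    with (_counts_dir(outdir) / f"{stage}.json").open("w") as fh:
        json.dump(counts, fh, sort_keys=True, indent=1)


def _read_counts(outdir: Path, stage: str) -> dict:
    path = Path(outdir) / "counts" / f"{stage}.json"
    if not path.exists():
        raise ValidationError(f"stage '{stage}' has not been run (missing {path})")
    with path.open() as fh:
        return json.load(fh)


def stage_de(config: PipelineConfig, outdir: str | Path) -> dict:
    """Differential expression: moderated t, BH, FC/p selection."""
    outdir = Path(outdir)
    matrix = io_formats.read_expression(_input_path(config, outdir, "expression"))
    shrink = None
    if config.use_shrinkage:
        case_idx = matrix.group_columns(io_formats.CASE)
        ctrl_idx = matrix.group_columns(io_formats.CONTROL)
        x1 = matrix.values[:, case_idx]
        x0 = matrix.values[:, ctrl_idx]
        n1, n0 = len(case_idx), len(ctrl_idx)
        pooled = ((n1 - 1) * x1.var(axis=1, ddof=1) + (n0 - 1) * x0.var(axis=1, ddof=1)) / (
            n1 + n0 - 2
        )
        shrink = de_expression.fit_shrinkage(pooled, n1 + n0 - 2)
    records = de_expression.moderated_t(matrix, shrink)
    de_genes = de_expression.select_de(
        records, fc_min=config.fc_min, p_max=config.p_max, use_adjusted=config.use_adjusted
    )
    de_expression.write_de_table(records, outdir / "de_table.tsv")
    de_set = gene_sets.GeneSet(
        "de",
        frozenset(de_genes),
        provenance=f"FC>={config.fc_min:g}, p<={config.p_max:g}, "
        f"{'adjusted' if config.use_adjusted else 'raw'}",
    )
    gene_sets.write_geneset(de_set, outdir / "geneset_de.txt")
    counts = {"n_genes": len(matrix.gene_ids), "n_de_genes": len(de_set)}
    _write_counts(outdir, "de", counts)
    return counts


def stage_geneset(config: PipelineConfig, outdir: str | Path) -> dict:
    """GWAS-catalog reference gene set under the trait/p filter."""
    outdir = Path(outdir)
    records = io_formats.read_gwas_catalog(_input_path(config, outdir, "catalog"))
    qualifying = [
        r for r in records
        if r.trait.lower() == config.trait.lower() and r.assoc_p <= config.gwas_p_threshold
    ]
    gwas_set = gene_sets.build_gwas_geneset(records, config.trait, config.gwas_p_threshold)
    gene_sets.write_geneset(gwas_set, outdir / "geneset_gwas.txt")
    counts = {
        "n_catalog_records": len(records),
        "n_qualifying_snps": len(qualifying),
        "n_gwas_genes": len(gwas_set),
    }
    _write_counts(outdir, "geneset", counts)
    return counts


def stage_segregate(config: PipelineConfig, outdir: str | Path) -> dict:
    """Vertical-transmission filter on the family VCF."""
    outdir = Path(outdir)
    pedigree = io_formats.read_ped(_input_path(config, outdir, "ped"))
    table = io_formats.read_vcf(_input_path(config, outdir, "vcf"), pedigree)
    rule = config.transmission_rule()
    transmitted, reports = segregation.transmission_filter(table, pedigree, rule)
    io_formats.write_vcf(transmitted, outdir / "transmitted.vcf")
    segregation.write_segregation_report(reports, outdir / "segregation_report.tsv")
    gene_map = read_gene_map(_input_path(config, outdir, "gene_map"))
    input_genes = {gene_map[v.key] for v in table.variants if v.key in gene_map}
    counts = {
        "n_input_variants": len(table),
        "n_input_genes": len(input_genes),
        "n_transmitted": len(transmitted),
    }
    _write_counts(outdir, "segregate", counts)
    return counts


def stage_annotate(config: PipelineConfig, outdir: str | Path) -> dict:
    """Gene-set restriction, consequence calling and prioritization filters."""
    outdir = Path(outdir)
    transmitted = io_formats.read_vcf(outdir / "transmitted.vcf")
    gene_map = read_gene_map(_input_path(config, outdir, "gene_map"))
    gwas_set = gene_sets.read_geneset(outdir / "geneset_gwas.txt")
    de_set = gene_sets.read_geneset(outdir / "geneset_de.txt")
    shared = gene_sets.intersect(gwas_set, de_set)
    gene_sets.write_geneset(shared, outdir / "geneset_shared.txt")

    class_path = _input_path(config, outdir, "class_map")
    n_coding = n_ncrna = None
    if class_path.exists():
        class_map = read_class_map(class_path)
        coding, ncrna = gene_sets.partition_by_class(shared, class_map)
        n_coding, n_ncrna = len(coding), len(ncrna)

    models = io_formats.read_transcripts(
        _input_path(config, outdir, "transcripts_tsv"),
        _input_path(config, outdir, "transcripts_fasta"),
    )
    ann_path = _input_path(config, outdir, "annotations")
    annotations = io_formats.read_annotations(ann_path) if ann_path.exists() else {}
    freqs = io_formats.read_frequencies(_input_path(config, outdir, "frequencies"))

    partner_de = frozenset(config.partner_genes) & de_set.symbols
    arm_gwas, arm_partner = [], []
    n_unmapped = 0
    for variant in transmitted.variants:
        gene = gene_map.get(variant.key)
        if gene is None:
            n_unmapped += 1
        elif gene in shared:
            arm_gwas.append(variant)
        elif gene in partner_de:
            arm_partner.append(variant)
    annotated = consequence.annotate_variants(
        arm_gwas, gene_map, models,
        origin_map={v.key: consequence.MS_GWAS for v in arm_gwas},
        annotations=annotations,
    ) + consequence.annotate_variants(
        arm_partner, gene_map, models,
        origin_map={v.key: consequence.FUNCTIONAL_PARTNER for v in arm_partner},
        annotations=annotations,
    )
    gwas_pv = [p for p in annotated if p.geneset_origin == consequence.MS_GWAS]
    partner_pv = [p for p in annotated if p.geneset_origin == consequence.FUNCTIONAL_PARTNER]
    _, gwas_nonintronic = consequence.split_intronic(gwas_pv)
    if config.maf_source == MAF_FROM_CONTROLS:
        source_pops = list(config.control_populations)
    else:
        source_pops = [config.affected_population]
    prioritized = consequence.low_frequency_filter(
        gwas_nonintronic, freqs, maf_max=config.maf_max, source_populations=source_pops
    )
    partner_intronic, partner_nonintronic = consequence.split_intronic(partner_pv)
    tested_keys = {p.key for p in prioritized} | {p.key for p in partner_nonintronic}

    with (outdir / "annotated.tsv").open("w") as fh:
        fh.write(
            "variant\tsnp_id\tgene\torigin\tclass\thgvs_c\thgvs_p\tcodon_change\t"
            "cadd_phred\ttested\n"
        )
        for p in sorted(annotated, key=lambda p: (p.gene_id, p.key)):
            c = p.consequence
            fh.write(
                f"{p.key}\t{p.variant.snp_id or '.'}\t{p.gene_id}\t{p.geneset_origin}\t"
                f"{c.klass}\t{c.hgvs_c}\t{c.hgvs_p}\t{c.codon_change}\t"
                f"{'' if p.cadd_phred is None else p.cadd_phred}\t"
                f"{'yes' if p.key in tested_keys else 'no'}\n"
            )
    counts = {
        "n_shared_genes": len(shared),
        "n_shared_coding": n_coding,
        "n_shared_ncrna": n_ncrna,
        "n_geneset_variants": len(gwas_pv),
        "n_geneset_genes": len({p.gene_id for p in gwas_pv}),
        "n_gwas_nonintronic": len(gwas_nonintronic),
        "n_prioritized": len(prioritized),
        "n_partner_variants": len(partner_pv),
        "n_partner_intronic": len(partner_intronic),
        "n_partner_nonintronic": len(partner_nonintronic),
        "n_tested": len(tested_keys),
        "n_unmapped_dropped": n_unmapped,
    }
    _write_counts(outdir, "annotate", counts)
    return counts


def stage_aftest(config: PipelineConfig, outdir: str | Path) -> dict:
    """Two-proportion z-tests with Bonferroni tiering; writes the result
    table and assembles the funnel report from all stage counts."""
    outdir = Path(outdir)
    freqs = io_formats.read_frequencies(_input_path(config, outdir, "frequencies"))
    tested: list[consequence.PrioritizedVariant] = []
    with (outdir / "annotated.tsv").open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if fields[idx["tested"]] != "yes":
                continue
            chrom, pos, ref, alt = fields[idx["variant"]].rsplit(":", 3)
            snp_id = fields[idx["snp_id"]]
            tested.append(
                consequence.PrioritizedVariant(
                    variant=io_formats.Variant(
                        chrom, int(pos), ref, alt, None if snp_id == "." else snp_id
                    ),
                    gene_id=fields[idx["gene"]],
                    consequence=consequence.Consequence(
                        klass=fields[idx["class"]],
                        hgvs_c=fields[idx["hgvs_c"]],
                        hgvs_p=fields[idx["hgvs_p"]],
                        codon_change=fields[idx["codon_change"]],
                    ),
                    geneset_origin=fields[idx["origin"]],
                    cadd_phred=float(fields[idx["cadd_phred"]])
                    if fields[idx["cadd_phred"]]
                    else None,
                )
            )
    tested.sort(key=lambda p: (p.gene_id, p.key))
    comparisons = [
        (config.affected_population, pop) for pop in config.control_populations
    ]
    results, test_cfg = af_stats.run_family(
        tested,
        freqs,
        comparisons,
        alpha=config.alpha,
        borderline_mult=config.borderline_mult,
        nominal_level=config.nominal_level,
        m_convention=config.m_convention,
    )
    # headline tier per variant: the tier of its most significant comparison
    tier_counts = {t: 0 for t in (af_stats.SIGNIFICANT, af_stats.BORDERLINE,
                                  af_stats.NOMINAL, af_stats.NS)}
    headline: dict[str, str] = {}
    for p in tested:
        ps = [r.p_two_sided for r in p.test_results if r.tier != af_stats.NOT_EVALUABLE]
        label = af_stats.tier(min(ps), test_cfg) if ps else af_stats.NS
        headline[p.key] = label
        tier_counts[label] += 1

    with (outdir / "results.tsv").open("w") as fh:
        cols = ["variant", "snp_id", "gene", "origin", "class", "codon_change", "hgvs_p"]
        cols.append(f"maf_{config.affected_population}")
        for pop in config.control_populations:
            cols.append(f"maf_{pop}")
        for pop in config.control_populations:
            cols.append(f"p_{config.affected_population}_vs_{pop}")
        cols.append("tier")
        fh.write("\t".join(cols) + "\n")
        for p in tested:
            row = [
                p.key, p.variant.snp_id or ".", p.gene_id, p.geneset_origin,
                p.consequence.klass, p.consequence.codon_change, p.consequence.hgvs_p,
            ]
            f_aff = freqs.freq(p.key, config.affected_population)
            row.append("" if f_aff is None else f"{f_aff:.4g}")
            for pop in config.control_populations:
                f = freqs.freq(p.key, pop)
                row.append("" if f is None else f"{f:.4g}")
            by_pop = {r.comparison[1]: r for r in p.test_results}
            for pop in config.control_populations:
                r = by_pop.get(pop)
                row.append(
                    "" if r is None or r.tier == af_stats.NOT_EVALUABLE
                    else f"{r.p_two_sided:.3g}"
                )
            row.append(headline[p.key])
            fh.write("\t".join(row) + "\n")

    counts = {
        "n_tested": len(tested),
        "bonferroni_m": test_cfg.m,
        "threshold": test_cfg.threshold,
        "tier_counts": tier_counts,
    }
    _write_counts(outdir, "aftest", counts)

    seg = _read_counts(outdir, "segregate")
    ann = _read_counts(outdir, "annotate")
    report = FunnelReport(
        config_hash=config.digest(),
        seed=config.seed,
        n_input_variants=seg["n_input_variants"],
        n_input_genes=seg["n_input_genes"],
        n_transmitted=seg["n_transmitted"],
        n_shared_genes=ann["n_shared_genes"],
        n_shared_coding=ann["n_shared_coding"],
        n_shared_ncrna=ann["n_shared_ncrna"],
        n_geneset_variants=ann["n_geneset_variants"],
        n_geneset_genes=ann["n_geneset_genes"],
        n_gwas_nonintronic=ann["n_gwas_nonintronic"],
        n_prioritized=ann["n_prioritized"],
        n_partner_variants=ann["n_partner_variants"],
        n_partner_intronic=ann["n_partner_intronic"],
        n_partner_nonintronic=ann["n_partner_nonintronic"],
        n_tested=counts["n_tested"],
        bonferroni_m=counts["bonferroni_m"],
        threshold=counts["threshold"],
        tier_counts=tier_counts,
    )
    with (outdir / "funnel_report.json").open("w") as fh:
        json.dump(report.to_dict(), fh, sort_keys=True, indent=1)
    return counts


STAGES = ("de", "geneset", "segregate", "annotate", "aftest")

_STAGE_FUNCS = {
    "de": stage_de,
    "geneset": stage_geneset,
    "segregate": stage_segregate,
    "annotate": stage_annotate,
    "aftest": stage_aftest,
}


def run_stage(name: str, config: PipelineConfig, outdir: str | Path) -> dict:
    if name == "simulate":
        stage_simulate(config, outdir)
        return {}
    if name not in _STAGE_FUNCS:
        raise ValidationError(f"unknown stage: {name}; choose from {STAGES}")
    return _STAGE_FUNCS[name](config, outdir)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> FunnelReport:
    """The whole funnel: (optional simulation then) all stages in order.

    Deterministic given config + seed; returns the assembled
    :class:`FunnelReport` (also written to ``funnel_report.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.simulate:
        stage_simulate(config, outdir)
    for name in STAGES:
        try:
            _STAGE_FUNCS[name](config, outdir)
        except ValidationError as exc:
            raise ValidationError(f"stage {name}: {exc}") from exc
    with (outdir / "funnel_report.json").open() as fh:
        data = json.load(fh)
    return FunnelReport(**data)
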