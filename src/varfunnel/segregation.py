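"""Family co-segregation filter: vertical transmission of disease.

A variant passes in a family, under the default dominant-carrier rule, when
every affected member carries at least one alternate allele and at least one
affected parent-affected child pair both carry (the vertical-transmission
signature).  Unaffected carriers are tolerated by default (incomplete
penetrance) and can be excluded by flag.  A variant passes overall when it
passes in at least ``min_families_passing`` families.

Missing genotypes are resolved by policy: for affected members the default
is to fail the variant in that family (conservative); for unaffected
members a missing call is treated as non-carrier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .gene_sets import GeneSet, intersect
from .io_formats import (
    AFFECTED,
    MISSING,
    UNAFFECTED,
    Pedigree,
    PedigreeMember,
    ValidationError,
    VariantTable,
)

logger = logging.getLogger("varfunnel")

PASS = "pass"
FAIL = "fail"
NOT_EVALUABLE = "not_evaluable"

FAIL_IN_FAMILY = "fail_variant_in_family"
AS_NONCARRIER = "treat_as_noncarrier"


@dataclass(frozen=True)
class TransmissionRule:
    model: str = "dominant"
    require_all_affected_carriers: bool = True
    require_parent_child_transmission: bool = True
    exclude_if_unaffected_carrier: bool = False
    min_families_passing: int = 1
    missing_policy_affected: str = FAIL_IN_FAMILY
    missing_policy_unaffected: str = AS_NONCARRIER

    def __post_init__(self) -> None:
        if self.model != "dominant":
            raise ValidationError(f"unsupported genetic model: {self.model}")
        if self.min_families_passing < 1:
            raise ValidationError("min_families_passing must be >= 1")
        for policy in (self.missing_policy_affected, self.missing_policy_unaffected):
            if policy not in (FAIL_IN_FAMILY, AS_NONCARRIER):
                raise ValidationError(f"unknown missing policy: {policy}")


@dataclass
class FamilyVerdict:
    family_id: str
    verdict: str  # pass / fail / not_evaluable
    reason: str


@dataclass
class SegregationReport:
    variant_key: str
    family_verdicts: list[FamilyVerdict]
    overall_pass: bool


def evaluate_family(
    genotypes: Mapping[str, int],
    family: Sequence[PedigreeMember],
    rule: TransmissionRule,
) -> FamilyVerdict:
    """Verdict for one variant in one family.

    ``genotypes`` maps individual_id -> diploid alt count (or MISSING);
    every family member must have an entry.
    """
    family_id = family[0].family_id if family else "?"
    missing_members = [m.individual_id for m in family if m.individual_id not in genotypes]
    if missing_members:
        raise ValidationError(
            f"family {family_id}: no genotype for {', '.join(missing_members)}"
        )
    affected = [m for m in family if m.affection == AFFECTED]
    if not affected:
        return FamilyVerdict(family_id, NOT_EVALUABLE, "no affected members")

    def carrier(member: PedigreeMember) -> bool | None:
        """True/False carrier status; None when missing fails the family."""
        g = genotypes[member.individual_id]
        if g == MISSING:
            if member.affection == AFFECTED:
                policy = rule.missing_policy_affected
            else:
                policy = rule.missing_policy_unaffected
            return None if policy == FAIL_IN_FAMILY else False
        return g >= 1

    status: dict[str, bool | None] = {m.individual_id: carrier(m) for m in family}

    if rule.require_all_affected_carriers:
        for m in affected:
            if status[m.individual_id] is None:
                return FamilyVerdict(
                    family_id, FAIL, f"missing genotype for affected {m.individual_id}"
                )
            if status[m.individual_id] is False:
                return FamilyVerdict(
                    family_id, FAIL, f"affected non-carrier {m.individual_id}"
                )

    if rule.require_parent_child_transmission:
        by_id = {m.individual_id: m for m in family}
        found = False
        for child in affected:
            if status[child.individual_id] is not True:
                continue
            for pid in (child.father_id, child.mother_id):
                parent = by_id.get(pid) if pid else None
                if (
                    parent is not None
                    and parent.affection == AFFECTED
                    and status[parent.individual_id] is True
                ):
                    found = True
        if not found:
            return FamilyVerdict(
                family_id, FAIL, "no affected parent-child carrier pair"
            )

    if rule.exclude_if_unaffected_carrier:
        for m in family:
            if m.affection == UNAFFECTED and status[m.individual_id] is True:
                return FamilyVerdict(
                    family_id, FAIL, f"unaffected carrier {m.individual_id}"
                )

    return FamilyVerdict(family_id, PASS, "vertical transmission")


def evaluate_variant(
    genotypes: Mapping[str, int], pedigree: Pedigree, rule: TransmissionRule
) -> SegregationReport:
    verdicts = [
        evaluate_family(genotypes, members, rule)
        for members in pedigree.families().values()
    ]
    n_pass = sum(v.verdict == PASS for v in verdicts)
    return SegregationReport(
        variant_key="",
        family_verdicts=verdicts,
        overall_pass=n_pass >= rule.min_families_passing,
    )


def transmission_filter(
    variants: VariantTable, pedigree: Pedigree, rule: TransmissionRule
) -> tuple[VariantTable, list[SegregationReport]]:
    """Retain variants whose overall transmission verdict is pass.

    Emits a :class:`SegregationReport` for every input variant, in input
    order; the filter is deterministic and order-independent.
    """
    roster = pedigree.sample_ids
    missing = sorted(set(roster) - set(variants.samples))
    if missing:
        raise ValidationError(f"variant table lacks pedigree samples: {missing}")
    col = variants.sample_index()
    order = [col[s] for s in roster]
    reports: list[SegregationReport] = []
    keep: list[int] = []
    for i, variant in enumerate(variants.variants):
        row = variants.genotypes[i]
        genotypes = {s: int(row[j]) for s, j in zip(roster, order)}
        report = evaluate_variant(genotypes, pedigree, rule)
        report.variant_key = variant.key
        reports.append(report)
        if report.overall_pass:
            keep.append(i)
    logger.info(
        "transmission_filter: %d of %d variants show vertical transmission",
        len(keep), len(variants),
    )
    return variants.subset(keep), reports


@dataclass
class FunnelStageCounts:
    n_input: int
    n_transmitted: int
    n_in_geneset: int
    n_genes: int
    n_unmapped_dropped: int


def funnel(
    variants: VariantTable,
    pedigree: Pedigree,
    rule: TransmissionRule,
    gwas_set: GeneSet,
    de_set: GeneSet,
    gene_map: Mapping[str, str],
) -> tuple[VariantTable, dict[str, str], FunnelStageCounts]:
    """Transmission filter, then restriction to the GWAS x DE gene intersection.

    ``gene_map`` maps variant keys to gene symbols; retained variants with no
    mapping are dropped with a count.  Returns the restricted table, the
    variant->gene map of the survivors, and per-stage counts.
    """
    transmitted, _reports = transmission_filter(variants, pedigree, rule)
    shared = intersect(gwas_set, de_set)
    keep: list[int] = []
    kept_genes: dict[str, str] = {}
    n_unmapped = 0
    for i, variant in enumerate(transmitted.variants):
        gene = gene_map.get(variant.key)
        if gene is None:
            n_unmapped += 1
            continue
        if gene in shared:
            keep.append(i)
            kept_genes[variant.key] = gene
    if n_unmapped:
        logger.info("funnel: dropped %d transmitted variants with no gene mapping",
                    n_unmapped)
    counts = FunnelStageCounts(
        n_input=len(variants),
        n_transmitted=len(transmitted),
        n_in_geneset=len(keep),
        n_genes=len(set(kept_genes.values())),
        n_unmapped_dropped=n_unmapped,
    )
    logger.info(
        "funnel: %d input -> %d transmitted -> %d variants in %d shared genes",
        counts.n_input, counts.n_transmitted, counts.n_in_geneset, counts.n_genes,
    )
    return transmitted.subset(keep), kept_genes, counts


def write_segregation_report(
    reports: Sequence[SegregationReport], path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        fh.write("variant\tfamily\tverdict\treason\toverall\n")
        for rep in reports:
            for v in rep.family_verdicts:
                fh.write(
                    f"{rep.variant_key}\t{v.family_id}\t{v.verdict}\t{v.reason}\t"
                    f"{'pass' if rep.overall_pass else 'fail'}\n"
                )
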