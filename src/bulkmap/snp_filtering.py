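"""Six-rule SNP filtration cascade for an EMS mutant bulked-segregant cross.

The cascade reduces a raw three-sample variant set to candidate induced
mutations that are homozygous-divergent between the two parents and show the
G:C->A:T transition signature of EMS mutagenesis:

  (i)   read depth out of range (parents <3 or >100, bulk <5 or >150),
  (ii)  genotyping quality below 20 in any sample,
  (iii) heterozygous (or uncalled) in the wild-type parent,
  (iv)  bulk heterogeneous with both alleles foreign to the cross,
  (v)   parents not homozygous for different alleles,
  (vi)  substitution outside the EMS spectrum (not C->T or G->A).

Boundary semantics are strict inequalities — a depth of exactly 3, 100, 5 or
150 and a GQ of exactly 20 pass. Depth is the sum of the AD fields, not DP,
so the depth filter and the SNP index see the same reads. Rule (iv) is kept
as an explicit predicate although it is provably vacuous on biallelic
records: a heterogeneous bulk then shows exactly {ref, alt}, which always
intersects a non-missing parent genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .variant_io import Genotype, SampleRole, VariantRecord

RULE_IDS = ("i", "ii", "iii", "iv", "v", "vi")

#: EMS produces G:C -> A:T transitions; on the reference strand these read
#: as G->A or C->T, oriented wild-type-allele -> mutant-allele.
EMS_SUBSTITUTIONS = frozenset({("G", "A"), ("C", "T")})


@dataclass
class FilterConfig:
    parent_depth_min: int = 3
    parent_depth_max: int = 100
    bulk_depth_min: int = 5
    bulk_depth_max: int = 150
    gq_min: int = 20
    ems_only: bool = True

    def __post_init__(self) -> None:
        if self.parent_depth_min > self.parent_depth_max:
            raise ValueError("parent depth min > max")
        if self.bulk_depth_min > self.bulk_depth_max:
            raise ValueError("bulk depth min > max")
        if self.gq_min < 0:
            raise ValueError("gq_min must be >= 0")


@dataclass
class FilterReport:
    """Partition of the input: every record is either kept or attributed to
    the first rule it fails."""

    input_count: int
    removed_by_rule: dict[str, int]
    kept_count: int

    def __post_init__(self) -> None:
        if self.input_count != self.kept_count + sum(self.removed_by_rule.values()):
            raise ValueError("FilterReport counts do not partition the input")

    def to_dict(self) -> dict:
        return {
            "input": self.input_count,
            "kept": self.kept_count,
            "removed": dict(self.removed_by_rule),
        }


def rule_depth(record: VariantRecord, config: FilterConfig) -> bool:
    """Rule (i): summed-AD depth within range for every role."""
    for role in (SampleRole.WT_PARENT, SampleRole.MUT_PARENT):
        d = record.depth(role)
        if d < config.parent_depth_min or d > config.parent_depth_max:
            return False
    d = record.depth(SampleRole.BULK)
    return config.bulk_depth_min <= d <= config.bulk_depth_max


def rule_gq(record: VariantRecord, config: FilterConfig) -> bool:
    """Rule (ii): genotype quality at or above the minimum in every role."""
    return all(record.gq(role) >= config.gq_min for role in SampleRole)


def rule_parent_het(record: VariantRecord, config: FilterConfig | None = None) -> bool:
    """Rule (iii): the wild-type parent must be a called homozygote."""
    return record.genotype(SampleRole.WT_PARENT) in (Genotype.HOM_REF, Genotype.HOM_ALT)


def rule_bulk_foreign_allele(record: VariantRecord, config: FilterConfig | None = None) -> bool:
    """Rule (iv): fail a heterogeneous bulk whose alleles are all foreign to
    the cross (none matches any allele carried by either parent).

    Vacuous on biallelic records (see module docstring); meaningful only for
    inputs decomposed from multiallelic sites.
    """
    observed = record.observed_alleles(SampleRole.BULK)
    if len(observed) < 2:
        return True
    allowed = record.genotype_alleles(SampleRole.WT_PARENT) | record.genotype_alleles(
        SampleRole.MUT_PARENT
    )
    if not allowed:
        return True  # both parents uncalled: cannot assess foreignness
    return bool(observed & allowed)


def rule_parents_identical(record: VariantRecord, config: FilterConfig | None = None) -> bool:
    """Rule (v): keep only sites where the parents are homozygous for
    different alleles (hom_ref vs hom_alt, either orientation)."""
    wt = record.genotype(SampleRole.WT_PARENT)
    mut = record.genotype(SampleRole.MUT_PARENT)
    return {wt, mut} == {Genotype.HOM_REF, Genotype.HOM_ALT}


def rule_ems_spectrum(record: VariantRecord, config: FilterConfig | None = None) -> bool:
    """Rule (vi): the wild-type-allele -> mutant-allele substitution must be
    an EMS transition (C->T or G->A)."""
    if config is not None and not config.ems_only:
        return True
    wt = record.homozygous_allele(SampleRole.WT_PARENT)
    mut = record.homozygous_allele(SampleRole.MUT_PARENT)
    if wt is None or mut is None:
        return False  # orientation undefined without homozygous parents
    return (wt, mut) in EMS_SUBSTITUTIONS


RULES = (
    ("i", rule_depth),
    ("ii", rule_gq),
    ("iii", rule_parent_het),
    ("iv", rule_bulk_foreign_allele),
    ("v", rule_parents_identical),
    ("vi", rule_ems_spectrum),
)


def first_failing_rule(record: VariantRecord, config: FilterConfig) -> str | None:
    """Rule id of the first failed rule in order (i)..(vi), or None if the
    record passes the whole cascade."""
    for rule_id, rule in RULES:
        if not rule(record, config):
            return rule_id
    return None


def filter_pipeline(
    records: list[VariantRecord], config: FilterConfig | None = None
) -> tuple[list[VariantRecord], FilterReport]:
    """Apply rules (i)..(vi) with first-failing-rule attribution."""
    if config is None:
        config = FilterConfig()
    removed = {rule_id: 0 for rule_id in RULE_IDS}
    kept: list[VariantRecord] = []
    for record in records:
        failed = first_failing_rule(record, config)
        if failed is None:
            kept.append(record)
        else:
            removed[failed] += 1
    report = FilterReport(
        input_count=len(records), removed_by_rule=removed, kept_count=len(kept)
    )
    return kept, report
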