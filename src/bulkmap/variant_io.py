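"""Readers and writers for the formats the mapping pipeline touches.

All domain types use 1-based inclusive genomic coordinates. Conversions to
half-open or 0-based systems are internal to the readers; nothing outside this
module should need to think about coordinate conventions.

The pipeline operates on exactly three sequenced entities: the wild-type
parent line, the mutant parent, and the pooled DNA of recessive-phenotype F2
plants (the bulk). Every VCF consumed or produced carries these three roles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO

log = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")

#: FORMAT layout of every VCF this package writes.
VCF_FORMAT = "GT:AD:DP:GQ"

#: GQ assumed when the field is absent from a record. Absence of an annotation
#: should not silently delete data, so missing GQ passes the quality filter.
DEFAULT_GQ = 99


class SampleRole(str, Enum):
    """The three sequenced entities of a bulked-segregant mutant cross."""

    WT_PARENT = "wt_parent"
    MUT_PARENT = "mut_parent"
    BULK = "bulk"


#: Canonical sample-column order for written VCFs.
ROLE_ORDER: tuple[SampleRole, ...] = (
    SampleRole.WT_PARENT,
    SampleRole.MUT_PARENT,
    SampleRole.BULK,
)


class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


_GT_STRINGS = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


@dataclass(frozen=True)
class SampleCall:
    """Genotype call for one role at one site.

    ``allele_depths`` is the (ref_count, alt_count) read support; depth used by
    the filters is their sum (not the DP field), keeping the depth filter
    consistent with what the SNP index later consumes.
    """

    genotype: Genotype
    allele_depths: tuple[int, int]
    gq: int = DEFAULT_GQ

    def __post_init__(self) -> None:
        r, a = self.allele_depths
        if r < 0 or a < 0:
            raise ValueError(f"negative allele depth: {self.allele_depths}")
        if self.gq < 0:
            raise ValueError(f"negative GQ: {self.gq}")

    @property
    def depth(self) -> int:
        return self.allele_depths[0] + self.allele_depths[1]


@dataclass
class VariantRecord:
    """One biallelic SNP site with calls for all three sample roles."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    calls: dict[SampleRole, SampleCall]

    def __post_init__(self) -> None:
        if self.ref_allele not in NUCLEOTIDES or self.alt_allele not in NUCLEOTIDES:
            raise ValueError(
                f"only single-nucleotide alleles are representable: "
                f"{self.ref_allele!r}>{self.alt_allele!r} at {self.chrom}:{self.pos}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        missing = [r for r in ROLE_ORDER if r not in self.calls]
        if missing:
            raise ValueError(f"record {self.chrom}:{self.pos} lacks roles {missing}")

    def call(self, role: SampleRole) -> SampleCall:
        return self.calls[role]

    def genotype(self, role: SampleRole) -> Genotype:
        return self.calls[role].genotype

    def depth(self, role: SampleRole) -> int:
        return self.calls[role].depth

    def gq(self, role: SampleRole) -> int:
        return self.calls[role].gq

    def genotype_alleles(self, role: SampleRole) -> frozenset[str]:
        """Bases carried by the role's called genotype (empty if missing)."""
        gt = self.genotype(role)
        if gt is Genotype.HOM_REF:
            return frozenset({self.ref_allele})
        if gt is Genotype.HOM_ALT:
            return frozenset({self.alt_allele})
        if gt is Genotype.HET:
            return frozenset({self.ref_allele, self.alt_allele})
        return frozenset()

    def observed_alleles(self, role: SampleRole) -> frozenset[str]:
        """Bases with read support (depth > 0) in the role."""
        r, a = self.calls[role].allele_depths
        out = set()
        if r > 0:
            out.add(self.ref_allele)
        if a > 0:
            out.add(self.alt_allele)
        return frozenset(out)

    def homozygous_allele(self, role: SampleRole) -> str | None:
        gt = self.genotype(role)
        if gt is Genotype.HOM_REF:
            return self.ref_allele
        if gt is Genotype.HOM_ALT:
            return self.alt_allele
        return None

    def mutant_allele(self) -> str | None:
        """The mutant-parent's homozygous allele; orientation anchor for the
        SNP index (robust to reference polarity)."""
        return self.homozygous_allele(SampleRole.MUT_PARENT)


def _normalise_role_map(role_map: Mapping[str, SampleRole | str]) -> dict[str, SampleRole]:
    out = {name: SampleRole(role) for name, role in role_map.items()}
    roles = list(out.values())
    for role in ROLE_ORDER:
        if roles.count(role) != 1:
            raise ValueError(f"role_map must map exactly one sample to {role.value!r}")
    return out


def _classify_gt(gt: tuple | None) -> Genotype:
    if gt is None or any(a is None for a in gt):
        return Genotype.MISSING
    alleles = set(gt)
    if alleles == {0}:
        return Genotype.HOM_REF
    if alleles == {1}:
        return Genotype.HOM_ALT
    if alleles == {0, 1}:
        return Genotype.HET
    raise ValueError(f"unexpected allele indices in GT {gt} for a biallelic site")


def read_vcf(
    path: str | Path,
    role_map: Mapping[str, SampleRole | str],
    on_non_snp: str = "drop",
) -> list[VariantRecord]:
    """Read a three-sample VCF into :class:`VariantRecord` objects.

    Parameters
    ----------
    role_map
        sample name -> role; must cover wt_parent, mut_parent and bulk exactly.
    on_non_snp
        ``"drop"`` (default) skips indel/multiallelic lines with a logged
        count; ``"error"`` raises on the first such line.
    """
    if on_non_snp not in ("drop", "error"):
        raise ValueError("on_non_snp must be 'drop' or 'error'")
    roles = _normalise_role_map(role_map)
    records: list[VariantRecord] = []
    n_non_snp = 0
    with pysam.VariantFile(str(path)) as vf:
        header_samples = set(vf.header.samples)
        absent = [s for s in roles if s not in header_samples]
        if absent:
            raise ValueError(f"samples {absent} not present in VCF header of {path}")
        for rec in vf:
            alts = rec.alts or ()
            if (
                len(alts) != 1
                or len(rec.ref) != 1
                or len(alts[0]) != 1
                or rec.ref.upper() not in NUCLEOTIDES
                or alts[0].upper() not in NUCLEOTIDES
            ):
                if on_non_snp == "error":
                    raise ValueError(
                        f"non-biallelic-SNP line at {rec.chrom}:{rec.pos} "
                        f"(REF={rec.ref} ALT={','.join(alts) or '.'})"
                    )
                n_non_snp += 1
                continue
            calls: dict[SampleRole, SampleCall] = {}
            for sample_name, role in roles.items():
                s = rec.samples[sample_name]
                genotype = _classify_gt(s.get("GT"))
                ad = s.get("AD")
                if ad is None or any(x is None for x in ad):
                    if genotype is Genotype.MISSING:
                        ad = (0, 0)
                    else:
                        raise ValueError(
                            f"malformed AD for sample {sample_name!r} at "
                            f"{rec.chrom}:{rec.pos}"
                        )
                if len(ad) != 2:
                    raise ValueError(
                        f"AD must have two values at {rec.chrom}:{rec.pos}, got {ad}"
                    )
                gq = s.get("GQ")
                calls[role] = SampleCall(
                    genotype=genotype,
                    allele_depths=(int(ad[0]), int(ad[1])),
                    gq=DEFAULT_GQ if gq is None else int(gq),
                )
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,  # pysam .pos is 1-based
                    ref_allele=rec.ref.upper(),
                    alt_allele=alts[0].upper(),
                    calls=calls,
                )
            )
    if n_non_snp:
        log.info("read_vcf: dropped %d non-biallelic-SNP lines from %s", n_non_snp, path)
    return records


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    sample_names: Mapping[SampleRole, str] | None = None,
) -> dict[str, SampleRole]:
    """Write records as a plain-text VCF v4.2 (FORMAT GT:AD:DP:GQ).

    Sample columns appear in the order wt_parent, mut_parent, bulk. Returns
    the role map needed to re-read the file with :func:`read_vcf`.
    """
    if sample_names is None:
        sample_names = {r: r.value for r in ROLE_ORDER}
    contigs: list[str] = []
    for rec in records:
        if rec.chrom not in contigs:
            contigs.append(rec.chrom)
    lines = ["##fileformat=VCFv4.2", "##source=bulkmap"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth (sum of AD)">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    ]
    header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header_cols += [sample_names[r] for r in ROLE_ORDER]
    lines.append("\t".join(header_cols))
    for rec in records:
        row = [rec.chrom, str(rec.pos), ".", rec.ref_allele, rec.alt_allele, ".", ".", ".", VCF_FORMAT]
        for role in ROLE_ORDER:
            c = rec.calls[role]
            r, a = c.allele_depths
            row.append(f"{_GT_STRINGS[c.genotype]}:{r},{a}:{r + a}:{c.gq}")
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
    return {name: role for role, name in sample_names.items()}


@dataclass
class GeneModel:
    """Exon/intron structure of a single-transcript protein-coding gene.

    ``exons`` are 1-based inclusive genomic intervals sorted by genomic
    position (ascending); transcription order is derived from ``strand``.
    ``cds_start``/``cds_end`` are the genomic bounds of the coding sequence.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene has no exons")
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon interval ({s},{e}) inverted")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
        if not (self._within_exon(self.cds_start) and self._within_exon(self.cds_end)):
            raise ValueError(f"{self.gene_id}: CDS boundaries must fall inside exons")
        n = self.spliced_cds_length
        if n <= 0 or n % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: spliced CDS length {n} is not a positive multiple of 3"
            )

    def _within_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, genomic order."""
        return tuple(
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )

    def exon_ordinal(self, genomic_index: int) -> int:
        """1-based exon number in transcription order."""
        if self.strand == "+":
            return genomic_index + 1
        return self.n_exons - genomic_index

    def intron_ordinal(self, genomic_index: int) -> int:
        n_introns = self.n_exons - 1
        if self.strand == "+":
            return genomic_index + 1
        return n_introns - genomic_index

    def cds_intervals(self) -> tuple[tuple[int, int], ...]:
        """Exon intervals clipped to the CDS bounds, genomic order."""
        out = []
        for s, e in self.exons:
            s2, e2 = max(s, self.cds_start), min(e, self.cds_end)
            if s2 <= e2:
                out.append((s2, e2))
        return tuple(out)

    @property
    def spliced_cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals())

    @property
    def transcript_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


def read_gene_models(
    gff3_path: str | Path, fasta_path: str | Path
) -> tuple[list[GeneModel], dict[str, str]]:
    """Parse GFF3 gene models and their genome, returning models plus a
    chrom -> uppercase-sequence mapping.

    GFF3 phase fields are ignored; reading frame is derived from the CDS
    start, which is sufficient for single-transcript models.
    """
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exons = sorted(
            (f.start, f.end) for f in db.children(gene, featuretype="exon")
        )
        cds = [(f.start, f.end) for f in db.children(gene, featuretype="CDS")]
        if not exons or not cds:
            raise ValueError(f"gene {gene.id} lacks exon or CDS features")
        model = GeneModel(
            gene_id=gene.id,
            chrom=gene.seqid,
            strand=gene.strand,
            exons=tuple(exons),
            cds_start=min(s for s, _ in cds),
            cds_end=max(e for _, e in cds),
        )
        if model.chrom not in genome:
            raise ValueError(f"gene {gene.id}: contig {model.chrom} missing from FASTA")
        if model.end > len(genome[model.chrom]):
            raise ValueError(f"gene {gene.id}: exon beyond end of contig {model.chrom}")
        models.append(model)
    return models, genome


PHENOTYPE_VALUES = ("wild_type", "mutant")


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns plant_id, phenotype in {wild_type, mutant}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ("plant_id", "phenotype"), path)
    bad = set(df["phenotype"]) - set(PHENOTYPE_VALUES)
    if bad:
        raise ValueError(f"{path}: unknown phenotype values {sorted(bad)}")
    return df


def read_genotype_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns plant_id, genotype formatted ``X:Y`` (KASP style)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ("plant_id", "genotype"), path)
    for g in df["genotype"]:
        parts = g.split(":")
        if len(parts) != 2 or not all(parts):
            raise ValueError(f"{path}: malformed genotype {g!r} (expected 'X:Y')")
    return df


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
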