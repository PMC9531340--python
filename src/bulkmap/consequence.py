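"""Gene-model-aware consequence classification for single-nucleotide changes.

Beyond the usual exonic classes (stop_gained / missense / synonymous /
start_lost), this module models the splice-junction failure mode that EMS
transitions commonly produce: a substitution inside the 2-nt donor (GT) or
acceptor (AG) window of an intron abolishes splicing of that intron only.
The retained intron is left in the mature transcript, the coding sequence is
re-translated through it, and the (usually frameshifted, prematurely
terminated) mutant protein length is reported alongside the wild-type one.

Exon skipping and multi-intron effects are deliberately not modelled; a
splice-window hit retains exactly its own intron.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping

from Bio.Seq import Seq

from .variant_io import GeneModel, NUCLEOTIDES

#: Substitutions this close (nt) to an intron end hit the donor/acceptor motif.
SPLICE_WINDOW_NT = 2

START_CODON = "ATG"


class EffectClass(str, Enum):
    SPLICE_DISRUPTION_INTRON_RETENTION = "splice_disruption_intron_retention"
    STOP_GAINED = "stop_gained"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    START_LOST = "start_lost"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"


@dataclass(frozen=True)
class FeatureLocus:
    """Position of a SNP relative to a gene model, in transcription order.

    ``kind`` is one of exon / intron / splice / intergenic; for ``splice``,
    ``splice_end`` says whether the donor or acceptor window was hit (the
    ordinal is the affected intron's).
    """

    kind: str
    ordinal: int | None = None
    splice_end: str | None = None


@dataclass
class VariantEffect:
    gene_id: str
    effect_class: EffectClass
    affected_feature: FeatureLocus
    wt_protein_length: int
    mut_protein_length: int
    wt_transcript_length: int
    mut_transcript_length: int
    frameshift: bool

    def to_dict(self) -> dict:
        f = self.affected_feature
        feature = f.kind if f.ordinal is None else f"{f.kind}_{f.ordinal}"
        return {
            "gene_id": self.gene_id,
            "effect_class": self.effect_class.value,
            "feature": feature,
            "wt_protein_length": self.wt_protein_length,
            "mut_protein_length": self.mut_protein_length,
            "wt_transcript_length": self.wt_transcript_length,
            "mut_transcript_length": self.mut_transcript_length,
            "frameshift": self.frameshift,
        }


class StartCodonError(ValueError):
    """Raised when a coding sequence does not begin with ATG."""


@dataclass(frozen=True)
class TranslationResult:
    protein: str  # residues up to (excluding) the first in-frame stop
    stop_found: bool  # False flags a non-stop transcript

    @property
    def length(self) -> int:
        return len(self.protein)


def translate(cds: str) -> TranslationResult:
    """Translate from an ATG start to the first in-frame stop.

    Trailing bases short of a full codon (as arise after a frameshifting
    intron retention) are ignored. A sequence without an in-frame stop is
    returned with ``stop_found=False``.
    """
    cds = cds.upper()
    if cds[:3] != START_CODON:
        raise StartCodonError(f"coding sequence starts with {cds[:3]!r}, not ATG")
    trimmed = cds[: len(cds) - len(cds) % 3]
    aa = str(Seq(trimmed).translate())
    stop = aa.find("*")
    if stop == -1:
        return TranslationResult(protein=aa, stop_found=False)
    return TranslationResult(protein=aa[:stop], stop_found=True)


def locate_snp(gene: GeneModel, chrom: str, pos: int) -> FeatureLocus:
    """Assign a genomic position to an exon, intron interior, splice window,
    or intergenic space, with ordinals in transcription order."""
    if chrom != gene.chrom or not (gene.start <= pos <= gene.end):
        return FeatureLocus(kind="intergenic")
    for i, (s, e) in enumerate(gene.exons):
        if s <= pos <= e:
            return FeatureLocus(kind="exon", ordinal=gene.exon_ordinal(i))
    for j, (s, e) in enumerate(gene.introns):
        if s <= pos <= e:
            ordinal = gene.intron_ordinal(j)
            in_left = pos - s < SPLICE_WINDOW_NT  # genomic-left edge
            in_right = e - pos < SPLICE_WINDOW_NT
            if in_left or in_right:
                if gene.strand == "+":
                    splice_end = "donor" if in_left else "acceptor"
                else:
                    splice_end = "donor" if in_right else "acceptor"
                return FeatureLocus(kind="splice", ordinal=ordinal, splice_end=splice_end)
            return FeatureLocus(kind="intron", ordinal=ordinal)
    # pos falls in the gene span but outside every exon/intron: impossible for
    # contiguous models, kept defensive.
    return FeatureLocus(kind="intergenic")


def _contig(genome: Mapping[str, str] | str, chrom: str) -> str:
    if isinstance(genome, str):
        return genome
    return genome[chrom]


def _extract(seq: str, intervals, strand: str) -> str:
    parts = [seq[s - 1 : e] for s, e in sorted(intervals)]
    joined = "".join(parts)
    if strand == "-":
        return str(Seq(joined).reverse_complement())
    return joined


def _retained_genomic(gene: GeneModel, retained_introns: set[int]) -> list[tuple[int, int]]:
    out = []
    for j, iv in enumerate(gene.introns):
        if gene.intron_ordinal(j) in retained_introns:
            out.append(iv)
    found = {gene.intron_ordinal(j) for j, _ in enumerate(gene.introns)}
    bad = set(retained_introns) - found
    if bad:
        raise ValueError(f"{gene.gene_id}: no intron with ordinal(s) {sorted(bad)}")
    return out


def splice_transcript(
    gene: GeneModel,
    retained_introns: set[int],
    genome: Mapping[str, str] | str,
) -> str:
    """Mature mRNA with the given introns (transcription-order ordinals)
    retained; minus-strand genes are reverse-complemented."""
    seq = _contig(genome, gene.chrom)
    intervals = list(gene.exons) + _retained_genomic(gene, retained_introns)
    return _extract(seq, intervals, gene.strand)


def _coding_sequence(
    gene: GeneModel,
    contig: str,
    retained_introns: set[int] = frozenset(),
    substitution: tuple[int, str] | None = None,
) -> str:
    """Spliced CDS, optionally with retained introns (those inside the CDS
    genomic span) and a single-base substitution applied on the forward
    strand before extraction."""
    if substitution is not None:
        pos, alt = substitution
        if alt not in NUCLEOTIDES:
            raise ValueError(f"substitution base {alt!r} is not a nucleotide")
        contig = contig[: pos - 1] + alt + contig[pos:]
    intervals = list(gene.cds_intervals())
    for s, e in _retained_genomic(gene, set(retained_introns)):
        if gene.cds_start <= s and e <= gene.cds_end:
            intervals.append((s, e))
    return _extract(contig, intervals, gene.strand)


def classify_effect(
    gene: GeneModel,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    genome: Mapping[str, str] | str,
) -> VariantEffect:
    """Classify a single-nucleotide substitution against one gene model.

    Splice-window hits retain their intron and re-translate; exonic hits
    substitute the base and re-translate; intron-interior and intergenic
    positions leave the product untouched.
    """
    contig = _contig(genome, gene.chrom)
    if chrom == gene.chrom:
        found = contig[pos - 1].upper()
        if found != ref.upper():
            raise ValueError(
                f"reference mismatch at {chrom}:{pos}: expected {ref}, contig has {found}"
            )
    locus = locate_snp(gene, chrom, pos)
    wt_cds = _coding_sequence(gene, contig)
    wt_prot = translate(wt_cds)
    wt_tlen = gene.transcript_length

    def effect(cls, mut_len, mut_tlen, frameshift=False):
        return VariantEffect(
            gene_id=gene.gene_id,
            effect_class=cls,
            affected_feature=locus,
            wt_protein_length=wt_prot.length,
            mut_protein_length=mut_len,
            wt_transcript_length=wt_tlen,
            mut_transcript_length=mut_tlen,
            frameshift=frameshift,
        )

    if locus.kind == "intergenic":
        return effect(EffectClass.INTERGENIC, wt_prot.length, wt_tlen)
    if locus.kind == "intron":
        return effect(EffectClass.INTRONIC, wt_prot.length, wt_tlen)
    if locus.kind == "splice":
        k = locus.ordinal
        assert k is not None
        j = next(j for j in range(len(gene.introns)) if gene.intron_ordinal(j) == k)
        intron_len = gene.introns[j][1] - gene.introns[j][0] + 1
        mut_cds = _coding_sequence(gene, contig, retained_introns={k}, substitution=(pos, alt))
        mut_prot = translate(mut_cds)
        return effect(
            EffectClass.SPLICE_DISRUPTION_INTRON_RETENTION,
            mut_prot.length,
            wt_tlen + intron_len,
            frameshift=intron_len % 3 != 0,
        )
    # exonic substitution
    mut_cds = _coding_sequence(gene, contig, substitution=(pos, alt))
    try:
        mut_prot = translate(mut_cds)
    except StartCodonError:
        return effect(EffectClass.START_LOST, 0, wt_tlen)
    if mut_prot.protein == wt_prot.protein:
        return effect(EffectClass.SYNONYMOUS, mut_prot.length, wt_tlen)
    if mut_prot.length < wt_prot.length:
        return effect(EffectClass.STOP_GAINED, mut_prot.length, wt_tlen)
    return effect(EffectClass.MISSENSE, mut_prot.length, wt_tlen)
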