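"""Feature location, intron-retention splicing, translation, and effect
classification, including strand symmetry."""

from __future__ import annotations

import numpy as np
import pytest

from bulkmap.consequence import (
    EffectClass,
    StartCodonError,
    classify_effect,
    locate_snp,
    splice_transcript,
    translate,
)
from bulkmap.variant_io import GeneModel

from conftest import mirror_gene, mirror_snp

# --- independent translation oracle -----------------------------------------

_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
CODON_TABLE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def oracle_translate(cds: str) -> str:
    out = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = CODON_TABLE[cds[i : i + 3]]
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


class TestTranslate:
    def test_short_orf(self):
        result = translate("ATGAAATAA")
        assert result.protein == "MK"
        assert result.stop_found

    def test_non_stop_transcript_flagged(self):
        result = translate("ATGAAACCC")
        assert result.protein == "MKP"
        assert not result.stop_found

    def test_non_atg_start_raises(self):
        with pytest.raises(StartCodonError):
            translate("ATAAAATAA")

    def test_matches_codon_table_oracle_on_random_orfs(self):
        rng = np.random.default_rng(17)
        sense = [c for c, aa in CODON_TABLE.items() if aa != "*"]
        for _ in range(50):
            n = int(rng.integers(2, 200))
            body = [sense[i] for i in rng.integers(0, len(sense), size=n)]
            # sprinkle a stop in half the cases
            if rng.random() < 0.5:
                body[int(rng.integers(0, n))] = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
            cds = "ATG" + "".join(body)
            assert translate(cds).protein == oracle_translate(cds)


class TestLocateSnp:
    @pytest.mark.parametrize(
        "pos,kind,ordinal,splice_end",
        [
            (50, "exon", 1, None),
            (101, "splice", 1, "donor"),
            (102, "splice", 1, "donor"),
            (103, "intron", 1, None),
            (125, "intron", 1, None),
            (149, "splice", 1, "acceptor"),
            (150, "splice", 1, "acceptor"),
            (151, "exon", 2, None),
            (400, "intergenic", None, None),
        ],
    )
    def test_plus_strand_assignment(self, toy_gene, pos, kind, ordinal, splice_end):
        locus = locate_snp(toy_gene, "chr1", pos)
        assert (locus.kind, locus.ordinal, locus.splice_end) == (kind, ordinal, splice_end)

    def test_other_chromosome_is_intergenic(self, toy_gene):
        assert locate_snp(toy_gene, "chr2", 50).kind == "intergenic"

    @pytest.mark.parametrize(
        "pos,kind,ordinal,splice_end",
        [
            (150, "splice", 1, "donor"),  # genomic-right edge is the donor on -
            (101, "splice", 1, "acceptor"),
            (125, "intron", 1, None),
            (151, "exon", 1, None),  # genomic-last exon is exon 1 on -
            (50, "exon", 2, None),
        ],
    )
    def test_minus_strand_ordinals_flip(self, pos, kind, ordinal, splice_end):
        gene = GeneModel("toy-", "chr1", "-", ((1, 100), (151, 300)), 2, 300)
        locus = locate_snp(gene, "chr1", pos)
        assert (locus.kind, locus.ordinal, locus.splice_end) == (kind, ordinal, splice_end)


class TestSpliceTranscript:
    def test_no_retention_equals_exon_total(self, synthetic_gene):
        seq = splice_transcript(synthetic_gene.model, set(), synthetic_gene.genome)
        assert len(seq) == synthetic_gene.model.transcript_length == 1896

    def test_retaining_intron_two_gives_published_cdna_length(self, synthetic_gene):
        seq = splice_transcript(synthetic_gene.model, {2}, synthetic_gene.genome)
        assert len(seq) == 1994

    def test_retaining_all_introns_recovers_genomic_span(self, synthetic_gene):
        model = synthetic_gene.model
        retained = set(range(1, model.n_exons))
        seq = splice_transcript(model, retained, synthetic_gene.genome)
        assert len(seq) == model.end - model.start + 1 == 2517

    def test_unknown_intron_ordinal_rejected(self, synthetic_gene):
        with pytest.raises(ValueError, match="no intron"):
            splice_transcript(synthetic_gene.model, {99}, synthetic_gene.genome)

    def test_minus_strand_is_reverse_complement(self, synthetic_gene):
        mirrored, rc = mirror_gene(synthetic_gene.model, synthetic_gene.contig)
        plus = splice_transcript(synthetic_gene.model, {2}, synthetic_gene.genome)
        minus = splice_transcript(mirrored, {2}, {mirrored.chrom: rc})
        assert minus == plus


def _find_codon_pos(gene, codons: tuple[str, ...], max_spliced_nt: int) -> int:
    """Genomic position of the third base of the first codon-aligned match
    within the first `max_spliced_nt` nt of the spliced CDS (all inside
    exon 1, so spliced offset k maps to genomic exon1_start + k)."""
    from bulkmap.consequence import _coding_sequence

    cds = _coding_sequence(gene.model, gene.contig)
    for k in range(0, max_spliced_nt - 2, 3):
        if cds[k : k + 3] in codons:
            return gene.model.exons[0][0] + k + 2
    raise AssertionError(f"no {codons} codon found in search window")


#: codons where a third-base G->A change preserves the amino acid
WOBBLE_G_CODONS = ("CTG", "GTG", "TCG", "CCG", "ACG", "GCG", "CGG", "GGG")


class TestClassifyEffect:
    def test_splice_donor_hit_retains_intron_and_truncates(self, synthetic_gene):
        eff = classify_effect(synthetic_gene.model, *synthetic_gene.splice_snp,
                              synthetic_gene.genome)
        assert eff.effect_class is EffectClass.SPLICE_DISRUPTION_INTRON_RETENTION
        assert (eff.affected_feature.kind, eff.affected_feature.ordinal) == ("splice", 2)
        assert eff.frameshift  # 98 % 3 != 0
        assert eff.wt_protein_length == 631
        assert eff.mut_protein_length < eff.wt_protein_length
        assert eff.mut_transcript_length == 1994
        assert eff.mut_transcript_length - eff.wt_transcript_length == 98

    def test_exonic_tgg_to_tga_is_stop_gained(self, synthetic_gene):
        eff = classify_effect(synthetic_gene.model, *synthetic_gene.stop_snp,
                              synthetic_gene.genome)
        assert eff.effect_class is EffectClass.STOP_GAINED
        assert eff.affected_feature.kind == "exon"
        assert eff.mut_protein_length == 300  # stop at codon 301
        assert eff.mut_protein_length < eff.wt_protein_length
        assert not eff.frameshift

    def test_wobble_substitution_is_synonymous(self, synthetic_gene):
        # e.g. CTG->CTA keeps leucine; search exon 1 for a wobble-G codon
        pos = _find_codon_pos(synthetic_gene, WOBBLE_G_CODONS, 270)
        eff = classify_effect(synthetic_gene.model, synthetic_gene.contig_name,
                              pos, "G", "A", synthetic_gene.genome)
        assert eff.effect_class is EffectClass.SYNONYMOUS
        assert eff.mut_protein_length == eff.wt_protein_length

    def test_first_base_substitution_is_missense(self, synthetic_gene):
        # GAG (Glu) -> AAG (Lys) or GAC (Asp) -> AAC (Asn)
        pos = _find_codon_pos(synthetic_gene, ("GAG", "GAC"), 270) - 2
        eff = classify_effect(synthetic_gene.model, synthetic_gene.contig_name,
                              pos, "G", "A", synthetic_gene.genome)
        assert eff.effect_class is EffectClass.MISSENSE
        assert eff.mut_protein_length == eff.wt_protein_length

    def test_start_codon_hit_is_start_lost(self, synthetic_gene):
        pos = synthetic_gene.model.cds_start + 2  # third base of ATG
        eff = classify_effect(synthetic_gene.model, synthetic_gene.contig_name,
                              pos, "G", "A", synthetic_gene.genome)
        assert eff.effect_class is EffectClass.START_LOST
        assert eff.mut_protein_length == 0

    def test_intron_interior_and_flank(self, synthetic_gene):
        model = synthetic_gene.model
        intron1 = model.introns[0]
        mid = (intron1[0] + intron1[1]) // 2
        base = synthetic_gene.contig[mid - 1]
        alt = "A" if base != "A" else "G"
        eff = classify_effect(model, synthetic_gene.contig_name, mid, base, alt,
                              synthetic_gene.genome)
        assert eff.effect_class is EffectClass.INTRONIC
        flank_base = synthetic_gene.contig[9]
        eff = classify_effect(model, synthetic_gene.contig_name, 10, flank_base,
                              "A" if flank_base != "A" else "G", synthetic_gene.genome)
        assert eff.effect_class is EffectClass.INTERGENIC

    def test_reference_mismatch_detected(self, synthetic_gene):
        chrom, pos, ref, alt = synthetic_gene.splice_snp
        wrong_ref = "T" if ref != "T" else "C"
        with pytest.raises(ValueError, match="reference mismatch"):
            classify_effect(synthetic_gene.model, chrom, pos, wrong_ref, alt,
                            synthetic_gene.genome)


def _in_frame_retention_gene():
    """Two-exon gene whose 99-nt stop-free intron preserves frame and adds
    33 residues when retained."""
    rng = np.random.default_rng(23)
    sense = [c for c, aa in CODON_TABLE.items() if aa != "*"]
    exon1 = "ATG" + "".join(sense[i] for i in rng.integers(0, len(sense), size=49))
    exon2 = "".join(sense[i] for i in rng.integers(0, len(sense), size=49)) + "TAA"
    intron = "GT" + "C" * 95 + "AG"  # codons GTC, CCC..., CAG: no stops
    contig = "A" * 100 + exon1 + intron + exon2 + "A" * 100
    e1 = (101, 100 + len(exon1))
    i1 = (e1[1] + 1, e1[1] + len(intron))
    e2 = (i1[1] + 1, i1[1] + len(exon2))
    model = GeneModel("inframe", "chrX", "+", (e1, e2), e1[0], e2[1])
    return model, contig


class TestRetentionFrameInvariants:
    def test_in_frame_stop_free_retention_extends_protein(self):
        model, contig = _in_frame_retention_gene()
        snp_pos = model.introns[0][0]  # donor G->A
        eff = classify_effect(model, "chrX", snp_pos, "G", "A", contig)
        assert eff.effect_class is EffectClass.SPLICE_DISRUPTION_INTRON_RETENTION
        assert not eff.frameshift  # 99 % 3 == 0
        assert eff.mut_protein_length == eff.wt_protein_length + 33
        assert eff.mut_transcript_length - eff.wt_transcript_length == 99

    def test_transcript_delta_equals_intron_length(self, synthetic_gene):
        for k, (s, e) in enumerate(synthetic_gene.model.introns, start=1):
            seq = splice_transcript(synthetic_gene.model, {k}, synthetic_gene.genome)
            assert len(seq) - 1896 == e - s + 1


class TestStrandSymmetry:
    @pytest.mark.parametrize("which", ["splice_snp", "stop_snp"])
    def test_mirrored_gene_gives_identical_effect(self, synthetic_gene, which):
        snp = getattr(synthetic_gene, which)
        fwd = classify_effect(synthetic_gene.model, *snp, synthetic_gene.genome)
        mirrored, rc = mirror_gene(synthetic_gene.model, synthetic_gene.contig)
        rsnp = mirror_snp(snp, len(synthetic_gene.contig))
        rev = classify_effect(mirrored, *rsnp, {mirrored.chrom: rc})
        assert rev.effect_class is fwd.effect_class
        assert rev.mut_protein_length == fwd.mut_protein_length
        assert rev.wt_protein_length == fwd.wt_protein_length
        assert rev.mut_transcript_length == fwd.mut_transcript_length
        assert rev.frameshift is fwd.frameshift
        assert rev.affected_feature.ordinal == fwd.affected_feature.ordinal
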