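"""Shared fixtures: record builders, toy gene models, strand mirroring."""

from __future__ import annotations

import pytest
from Bio.Seq import Seq

from bulkmap.simulate import make_causal_gene
from bulkmap.variant_io import (
    GeneModel,
    Genotype,
    SampleCall,
    SampleRole,
    VariantRecord,
)

ROLES = (SampleRole.WT_PARENT, SampleRole.MUT_PARENT, SampleRole.BULK)


def build_record(
    chrom="A01",
    pos=100,
    ref="G",
    alt="A",
    wt=("hom_ref", (30, 0), 99),
    mut=("hom_alt", (0, 30), 99),
    bulk=("hom_alt", (5, 45), 99),
):
    """A valid EMS-candidate record by default; override per-role triples
    (genotype, (ref_depth, alt_depth), gq) to break individual rules."""
    calls = {
        role: SampleCall(genotype=Genotype(gt), allele_depths=tuple(ad), gq=gq)
        for role, (gt, ad, gq) in zip(ROLES, (wt, mut, bulk))
    }
    return VariantRecord(chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt, calls=calls)


@pytest.fixture
def record_factory():
    return build_record


@pytest.fixture(scope="session")
def synthetic_gene():
    """The deterministic synthetic causal gene (1896-nt CDS, 98-nt intron 2)."""
    return make_causal_gene()


@pytest.fixture
def toy_gene():
    """Two-exon plus-strand model, exons (1,100) and (151,300), CDS (2,300)
    so the spliced CDS is 249 nt; intron spans (101,150)."""
    return GeneModel(
        gene_id="toy",
        chrom="chr1",
        strand="+",
        exons=((1, 100), (151, 300)),
        cds_start=2,
        cds_end=300,
    )


COMPLEMENT = str.maketrans("ACGT", "TGCA")


def mirror_gene(model: GeneModel, contig: str):
    """Reverse-complement mirror of a gene and its contig: same transcript,
    opposite strand. Used to check strand symmetry of annotation."""
    n = len(contig)
    rc = str(Seq(contig).reverse_complement())
    exons = tuple(sorted((n - e + 1, n - s + 1) for s, e in model.exons))
    mirrored = GeneModel(
        gene_id=model.gene_id + "_rc",
        chrom=model.chrom,
        strand="-" if model.strand == "+" else "+",
        exons=exons,
        cds_start=n - model.cds_end + 1,
        cds_end=n - model.cds_start + 1,
    )
    return mirrored, rc


def mirror_snp(snp: tuple[str, int, str, str], contig_len: int):
    chrom, pos, ref, alt = snp
    return (chrom, contig_len - pos + 1, ref.translate(COMPLEMENT), alt.translate(COMPLEMENT))
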