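"""Synthetic data generator for the full mapping workflow.

Emulates the study design end to end: EMS mutagenesis of an inbred parent
(G:C -> A:T transitions scattered over the genome), an F2 cross between the
mutant and its wild-type progenitor, selection of a recessive-phenotype bulk
of 30 plants, and finite-depth pooled short-read sampling of the three
sequenced entities. Ground truth (site positions, recombination fractions to
the causal locus, realised bulk allele frequencies) is returned alongside
the VCF-ready records so every pipeline stage can be verified.

Meiosis uses the Haldane model (crossovers as a Poisson process along the
chromosome, no interference), so the recombination fraction at map distance
d Morgans is r = (1 - e^(-2d)) / 2.

A small proportion of non-EMS background sites (parent-shared variants,
residual wild-type heterozygosity, non-transition substitutions) is mixed in
so the filter cascade has realistic work to do; see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .variant_io import (
    Genotype,
    GeneModel,
    SampleCall,
    SampleRole,
    VariantRecord,
)

#: Minor-allele read fraction at or below which the simulator's genotype
#: caller reports a homozygote (a simulator convention, not a claim about
#: any production caller).
HET_CALL_FRACTION = 0.20

EMS_PAIRS = (("G", "A"), ("C", "T"))
ALL_SUBSTITUTIONS = tuple(
    (r, a) for r in "ACGT" for a in "ACGT" if r != a
)
NON_EMS_SUBSTITUTIONS = tuple(s for s in ALL_SUBSTITUTIONS if s not in EMS_PAIRS)

#: Background-site classes: both parents carry the variant ("shared"),
#: residual heterozygosity in the wild-type parent ("wt_het"), or a
#: mutant-specific non-transition change ("non_ems").
BACKGROUND_CATEGORIES = ("shared", "wt_het", "non_ems")
_BACKGROUND_PROBS = (0.4, 0.4, 0.2)

#: Categories carried on the mutant-parent haplotype and therefore subject
#: to linkage with the causal locus.
MUTANT_HAPLOTYPE_CATEGORIES = ("causal", "ems", "non_ems")


def haldane_r(d_morgans: float) -> float:
    """Map distance (Morgans) -> recombination fraction, no interference."""
    if d_morgans < 0:
        raise ValueError("map distance must be non-negative")
    return 0.5 * (1.0 - math.exp(-2.0 * d_morgans))


def haldane_d(r: float) -> float:
    """Recombination fraction -> map distance (Morgans); r=0.5 is infinite."""
    if not 0.0 <= r < 0.5:
        raise ValueError("recombination fraction must be in [0, 0.5)")
    return -0.5 * math.log(1.0 - 2.0 * r)


@dataclass
class SimConfig:
    """Study-scale defaults: a 2 x 10 Mb genome, ~100 EMS sites, a 30-plant
    recessive bulk at 50x pooled depth, parents at 30x."""

    n_chromosomes: int = 2
    chrom_length_bp: int = 10_000_000
    ems_rate: float = 5e-6  # EMS mutations per bp
    causal: tuple[str, int] = ("A02", 5_000_000)
    bulk_size: int = 30
    mean_depth: float = 50.0
    parent_depth: float = 30.0
    seq_error: float = 0.001  # per-base miscall probability
    cm_per_mb: float = 4.0
    background_rate: float = 1.5e-6  # non-EMS noise sites per bp
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length_bp < 1:
            raise ValueError("genome dimensions must be positive")
        for rate in (self.ems_rate, self.seq_error, self.background_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.bulk_size < 1:
            raise ValueError("bulk_size must be >= 1")
        chrom, pos = self.causal
        if chrom not in self.chrom_names or not (1 <= pos <= self.chrom_length_bp):
            raise ValueError(f"causal position {self.causal} outside the genome")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(f"A{i + 1:02d}" for i in range(self.n_chromosomes))

    @property
    def morgans_per_bp(self) -> float:
        return self.cm_per_mb / 100.0 / 1e6


@dataclass(frozen=True)
class TrueSite:
    chrom: str
    pos: int
    ref: str
    alt: str
    r_to_causal: float
    category: str  # causal | ems | shared | wt_het | non_ems

    @property
    def on_mutant_haplotype(self) -> bool:
        return self.category in MUTANT_HAPLOTYPE_CATEGORIES


@dataclass
class SimTruth:
    sites: list[TrueSite]
    causal_index: int
    bulk_freqs: np.ndarray | None = None  # realised mutant-allele bulk frequency

    @property
    def causal(self) -> TrueSite:
        return self.sites[self.causal_index]


def _recomb_fraction(config: SimConfig, chrom: str, pos: int) -> float:
    c_chrom, c_pos = config.causal
    if chrom != c_chrom:
        return 0.5
    return haldane_r(abs(pos - c_pos) * config.morgans_per_bp)


def simulate_ems_sites(config: SimConfig, rng: np.random.Generator | None = None) -> SimTruth:
    """Scatter EMS transitions (and background noise sites) over the genome.

    Site counts are Poisson with mean rate x genome size; positions are
    uniform. The causal site is always present, G->A at ``config.causal``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genome_size = config.n_chromosomes * config.chrom_length_bp
    taken: set[tuple[str, int]] = {config.causal}
    sites: list[TrueSite] = []

    def _place(n: int) -> list[tuple[str, int]]:
        placed = []
        chroms = rng.integers(0, config.n_chromosomes, size=n)
        positions = rng.integers(1, config.chrom_length_bp + 1, size=n)
        for ci, pos in zip(chroms, positions):
            key = (config.chrom_names[ci], int(pos))
            if key in taken:
                continue  # collisions are vanishingly rare; drop duplicates
            taken.add(key)
            placed.append(key)
        return placed

    n_ems = rng.poisson(config.ems_rate * genome_size)
    for chrom, pos in _place(int(n_ems)):
        ref, alt = EMS_PAIRS[rng.integers(0, 2)]
        sites.append(
            TrueSite(chrom, pos, ref, alt, _recomb_fraction(config, chrom, pos), "ems")
        )
    n_bg = rng.poisson(config.background_rate * genome_size)
    for chrom, pos in _place(int(n_bg)):
        category = BACKGROUND_CATEGORIES[
            rng.choice(len(BACKGROUND_CATEGORIES), p=_BACKGROUND_PROBS)
        ]
        if category == "non_ems":
            ref, alt = NON_EMS_SUBSTITUTIONS[rng.integers(0, len(NON_EMS_SUBSTITUTIONS))]
        else:
            ref, alt = ALL_SUBSTITUTIONS[rng.integers(0, len(ALL_SUBSTITUTIONS))]
        sites.append(
            TrueSite(chrom, pos, ref, alt, _recomb_fraction(config, chrom, pos), category)
        )
    c_chrom, c_pos = config.causal
    sites.append(TrueSite(c_chrom, c_pos, "G", "A", 0.0, "causal"))
    sites.sort(key=lambda s: (s.chrom, s.pos))
    causal_index = next(i for i, s in enumerate(sites) if s.category == "causal")
    return SimTruth(sites=sites, causal_index=causal_index)


def _draw_gamete(
    positions_by_chrom: dict[str, np.ndarray],
    config: SimConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """One F1 gamete: per chromosome, a boolean vector over site positions
    that is True where the gamete carries the mutant-parent haplotype.

    Crossovers form a Poisson process along the chromosome (Haldane model);
    the haplotype flips at each crossover, starting from a fair coin.
    """
    out = {}
    lam = config.chrom_length_bp * config.morgans_per_bp
    for chrom, pos in positions_by_chrom.items():
        n_x = rng.poisson(lam)
        if n_x:
            xs = np.sort(rng.uniform(0, config.chrom_length_bp, size=n_x))
            parity = np.searchsorted(xs, pos) % 2
        else:
            parity = np.zeros(len(pos), dtype=int)
        start = rng.integers(0, 2)
        out[chrom] = (start + parity) % 2 == 0
    return out


def simulate_f2_bulk(
    truth: SimTruth, config: SimConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Realised mutant-allele bulk frequency at every site in ``truth``.

    Each bulk plant is two independent F1 gametes; plants are kept only if
    homozygous for the mutant allele at the causal site, until ``bulk_size``
    plants are accepted. Sites on the mutant haplotype get frequency
    (mutant alleles) / (2 x bulk_size); parent-shared sites are fixed at 1;
    wt-heterozygosity sites segregate independently at expectation 0.5.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    positions_by_chrom: dict[str, list[int]] = {}
    index_by_chrom: dict[str, list[int]] = {}
    for i, s in enumerate(truth.sites):
        if s.on_mutant_haplotype:
            positions_by_chrom.setdefault(s.chrom, []).append(s.pos)
            index_by_chrom.setdefault(s.chrom, []).append(i)
    pos_arrays = {c: np.array(v, dtype=float) for c, v in positions_by_chrom.items()}
    causal = truth.causal
    causal_chrom_idx = positions_by_chrom[causal.chrom].index(causal.pos)

    counts = np.zeros(len(truth.sites))
    accepted = 0
    while accepted < config.bulk_size:
        g1 = _draw_gamete(pos_arrays, config, rng)
        g2 = _draw_gamete(pos_arrays, config, rng)
        if not (g1[causal.chrom][causal_chrom_idx] and g2[causal.chrom][causal_chrom_idx]):
            continue
        for chrom, indices in index_by_chrom.items():
            # note: + on numpy bool arrays is logical OR, so cast first
            counts[indices] += g1[chrom].astype(np.int64) + g2[chrom].astype(np.int64)
        accepted += 1
    freqs = counts / (2 * config.bulk_size)
    for i, s in enumerate(truth.sites):
        if s.category == "shared":
            freqs[i] = 1.0
        elif s.category == "wt_het":
            freqs[i] = rng.binomial(2 * config.bulk_size, 0.5) / (2 * config.bulk_size)
    truth.bulk_freqs = freqs
    return freqs


def _call_genotype(ref_n: int, alt_n: int) -> Genotype:
    total = ref_n + alt_n
    if total == 0:
        return Genotype.MISSING
    frac_alt = alt_n / total
    if frac_alt >= 1.0 - HET_CALL_FRACTION:
        return Genotype.HOM_ALT
    if frac_alt <= HET_CALL_FRACTION:
        return Genotype.HOM_REF
    return Genotype.HET


def sample_read_depths(
    truth: SimTruth,
    freqs: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[VariantRecord]:
    """Pooled short-read sampling: Poisson depth per site and sample, binomial
    allele counts with symmetric per-base error, majority-rule genotype calls
    with a 20% minor-read het threshold, and a uniformly high synthetic GQ."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    e = config.seq_error
    records: list[VariantRecord] = []
    for site, f in zip(truth.sites, freqs):
        # true alt-carriage probability per sampled read, before error
        if site.category == "shared":
            wt_p, mut_p = 1.0 - e, 1.0 - e
        elif site.category == "wt_het":
            wt_p, mut_p = 0.5, e
        else:  # causal / ems / non_ems: wt parent is reference, mut parent alt
            wt_p, mut_p = e, 1.0 - e
        bulk_p = f * (1.0 - e) + (1.0 - f) * e
        calls = {}
        for role, depth_mean, p in (
            (SampleRole.WT_PARENT, config.parent_depth, wt_p),
            (SampleRole.MUT_PARENT, config.parent_depth, mut_p),
            (SampleRole.BULK, config.mean_depth, bulk_p),
        ):
            d = int(rng.poisson(depth_mean))
            alt_n = int(rng.binomial(d, p)) if d else 0
            ref_n = d - alt_n
            calls[role] = SampleCall(
                genotype=_call_genotype(ref_n, alt_n),
                allele_depths=(ref_n, alt_n),
                gq=99,
            )
        records.append(
            VariantRecord(
                chrom=site.chrom,
                pos=site.pos,
                ref_allele=site.ref,
                alt_allele=site.alt,
                calls=calls,
            )
        )
    return records


def simulate_phenotype_tables(
    truth: SimTruth,
    n_f2: int = 93,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mendelian F2 draw at the causal SNP: genotype ~ 1:2:1, phenotype
    mutant iff homozygous mutant (expected 3:1 wild-type:mutant). Returns
    (phenotypes, KASP-style genotypes) keyed by plant_id."""
    if n_f2 <= 0:
        raise ValueError("n_f2 must be positive")
    if rng is None:
        rng = np.random.default_rng(0)
    causal = truth.causal
    dosages = rng.choice([0, 1, 2], size=n_f2, p=[0.25, 0.5, 0.25])
    geno_strings = {
        0: f"{causal.ref}:{causal.ref}",
        1: f"{causal.ref}:{causal.alt}",
        2: f"{causal.alt}:{causal.alt}",
    }
    ids = [f"P{i + 1:04d}" for i in range(n_f2)]
    phenotypes = pd.DataFrame(
        {
            "plant_id": ids,
            "phenotype": ["mutant" if d == 2 else "wild_type" for d in dosages],
        }
    )
    genotypes = pd.DataFrame(
        {"plant_id": ids, "genotype": [geno_strings[int(d)] for d in dosages]}
    )
    return phenotypes, genotypes


@dataclass
class SimDataset:
    """Everything one seeded simulation produces."""

    config: SimConfig
    truth: SimTruth
    records: list[VariantRecord]
    phenotypes: pd.DataFrame
    genotypes: pd.DataFrame


def simulate_dataset(config: SimConfig, n_f2: int = 93) -> SimDataset:
    """Run the full generative chain under one seed."""
    rng = np.random.default_rng(config.seed)
    truth = simulate_ems_sites(config, rng)
    freqs = simulate_f2_bulk(truth, config, rng)
    records = sample_read_depths(truth, freqs, config, rng)
    phenotypes, genotypes = simulate_phenotype_tables(truth, n_f2=n_f2, rng=rng)
    return SimDataset(
        config=config,
        truth=truth,
        records=records,
        phenotypes=phenotypes,
        genotypes=genotypes,
    )


def write_truth_tsv(truth: SimTruth, path: str | Path) -> None:
    rows = []
    freqs = truth.bulk_freqs
    for i, s in enumerate(truth.sites):
        rows.append(
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "ref": s.ref,
                "alt": s.alt,
                "r_to_causal": s.r_to_causal,
                "category": s.category,
                "bulk_freq": None if freqs is None else float(freqs[i]),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Synthetic causal gene
# ---------------------------------------------------------------------------

#: Spliced-CDS exon lengths (nt) of the synthetic gene: 7 exons totalling
#: 1896 nt (631 residues + stop), with 6 introns totalling 621 nt for a
#: 2517-bp genomic span. Intron 2 is 98 nt so its retention yields a
#: 1994-nt transcript and a frameshifted, prematurely terminated product.
SYNTH_EXON_LENGTHS = (270, 282, 270, 276, 270, 264, 264)
SYNTH_INTRON_LENGTHS = (101, 98, 95, 92, 104, 131)
SYNTH_FLANK = 200
#: 1-based middle-codon index forced to TGG so a G->A third-base change
#: creates TGA; codon 301 occupies spliced CDS nt 901-903 inside exon 4.
_TGG_CODON = 301

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class SyntheticGene:
    """Synthetic stand-in gene with the published coding arithmetic of the
    mapped locus (1896-nt CDS / 631 aa / 98-nt second intron); the real gene
    sequence is unpublished, so the sequence content here is seeded-random."""

    model: GeneModel
    contig_name: str
    contig: str
    splice_snp: tuple[str, int, str, str]  # donor +1 of intron 2, G->A
    stop_snp: tuple[str, int, str, str]  # exon 4, TGG -> TGA
    wt_protein_length: int
    wt_cdna_length: int
    retained_intron_length: int
    retained_cdna_length: int

    @property
    def genome(self) -> dict[str, str]:
        return {self.contig_name: self.contig}


def make_causal_gene(
    rng: np.random.Generator | None = None, contig_name: str = "synthAN"
) -> SyntheticGene:
    """Build the synthetic causal gene plus its contig and the two mutation
    fixtures (splice-donor G->A, exon TGG->TGA)."""
    if rng is None:
        rng = np.random.default_rng(20220727)
    n_codons = sum(SYNTH_EXON_LENGTHS) // 3  # 632 incl. stop
    sense = [c for c in ("".join(p) for p in _all_codons()) if c not in STOP_CODONS]
    codons = ["ATG"] + [sense[rng.integers(0, len(sense))] for _ in range(n_codons - 2)]
    codons.append("TAA")
    codons[_TGG_CODON - 1] = "TGG"
    cds = "".join(codons)
    assert len(cds) == sum(SYNTH_EXON_LENGTHS)

    bases = "ACGT"

    def random_seq(n: int) -> str:
        return "".join(bases[i] for i in rng.integers(0, 4, size=n))

    introns = []
    for j, ilen in enumerate(SYNTH_INTRON_LENGTHS):
        if j == 1:
            # retained-frame stop right after the donor: GTC TAA ... AG.
            # Exons 1+2 span 552 CDS nt (phase 0), so retention reads the
            # intron in frame and terminates at its second codon.
            introns.append("GT" + "C" + "TAA" + random_seq(ilen - 8) + "AG")
        else:
            introns.append("GT" + random_seq(ilen - 4) + "AG")
        assert len(introns[j]) == ilen

    pieces = [random_seq(SYNTH_FLANK)]
    exons: list[tuple[int, int]] = []
    cursor = SYNTH_FLANK + 1
    offset = 0
    for i, elen in enumerate(SYNTH_EXON_LENGTHS):
        pieces.append(cds[offset : offset + elen])
        exons.append((cursor, cursor + elen - 1))
        cursor += elen
        offset += elen
        if i < len(introns):
            pieces.append(introns[i])
            cursor += len(introns[i])
    pieces.append(random_seq(SYNTH_FLANK))
    contig = "".join(pieces)

    model = GeneModel(
        gene_id="synthAN.1",
        chrom=contig_name,
        strand="+",
        exons=tuple(exons),
        cds_start=exons[0][0],
        cds_end=exons[-1][1],
    )
    intron2_start = exons[1][1] + 1
    assert contig[intron2_start - 1] == "G"
    # genomic position of the TGG codon's third base (spliced CDS nt 903)
    tgg_third_spliced = _TGG_CODON * 3
    prefix = 0
    stop_pos = None
    for (s, e), elen in zip(exons, SYNTH_EXON_LENGTHS):
        if prefix < tgg_third_spliced <= prefix + elen:
            stop_pos = s + (tgg_third_spliced - prefix) - 1
            break
        prefix += elen
    assert stop_pos is not None and contig[stop_pos - 1] == "G"
    return SyntheticGene(
        model=model,
        contig_name=contig_name,
        contig=contig,
        splice_snp=(contig_name, intron2_start, "G", "A"),
        stop_snp=(contig_name, stop_pos, "G", "A"),
        wt_protein_length=n_codons - 1,
        wt_cdna_length=sum(SYNTH_EXON_LENGTHS),
        retained_intron_length=SYNTH_INTRON_LENGTHS[1],
        retained_cdna_length=sum(SYNTH_EXON_LENGTHS) + SYNTH_INTRON_LENGTHS[1],
    )


def _all_codons():
    for a in "ACGT":
        for b in "ACGT":
            for c in "ACGT":
                yield a, b, c


def write_gene_gff3(model: GeneModel, path: str | Path) -> None:
    lines = ["##gff-version 3"]
    attrs = f"ID={model.gene_id}"
    lines.append(
        "\t".join(
            [model.chrom, "bulkmap", "gene", str(model.start), str(model.end), ".",
             model.strand, ".", attrs]
        )
    )
    mrna_id = f"{model.gene_id}.mRNA"
    lines.append(
        "\t".join(
            [model.chrom, "bulkmap", "mRNA", str(model.start), str(model.end), ".",
             model.strand, ".", f"ID={mrna_id};Parent={model.gene_id}"]
        )
    )
    for k, (s, e) in enumerate(model.exons, 1):
        lines.append(
            "\t".join(
                [model.chrom, "bulkmap", "exon", str(s), str(e), ".", model.strand,
                 ".", f"ID={mrna_id}.exon{k};Parent={mrna_id}"]
            )
        )
    for k, (s, e) in enumerate(model.cds_intervals(), 1):
        lines.append(
            "\t".join(
                [model.chrom, "bulkmap", "CDS", str(s), str(e), ".", model.strand,
                 ".", f"ID={mrna_id}.cds{k};Parent={mrna_id}"]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(name: str, seq: str, path: str | Path, width: int = 80) -> None:
    chunks = [seq[i : i + width] for i in range(0, len(seq), width)]
    Path(path).write_text(f">{name}\n" + "\n".join(chunks) + "\n")
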