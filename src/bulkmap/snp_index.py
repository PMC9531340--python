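"""SNP-index computation, sliding-window smoothing, and candidate-region calls.

The SNP index of a site is the fraction of bulk reads carrying the mutant
allele, where "mutant allele" means the mutant parent's homozygous allele
(not the VCF ALT — this makes the index robust to reference polarity). In a
perfectly selected recessive bulk the index is 1.0 at the causal locus,
0.5 at unlinked sites, and 1 - r at a marker with recombination fraction r.

Raw per-SNP indices are smoothed with a sliding window (arithmetic mean of
the indices of the SNPs inside each window); maximal runs of windows at or
above a fixed threshold become candidate regions whose bounds are snapped to
the first and last contributing raw SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .variant_io import SampleRole, VariantRecord

log = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 2_000_000
DEFAULT_STEP_BP = 10_000
DEFAULT_MIN_SNPS = 3
DEFAULT_THRESHOLD = 0.80


@dataclass(frozen=True)
class SnpIndexPoint:
    chrom: str
    pos: int
    index: float
    bulk_depth: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.index <= 1.0:
            raise ValueError(f"SNP index {self.index} outside [0,1]")


def compute_snp_index(record: VariantRecord) -> SnpIndexPoint:
    """Mutant-allele read fraction in the bulk at one filtered site.

    Raises ``ValueError`` when the bulk has zero depth or the mutant allele
    cannot be oriented (mutant parent not homozygous); batch callers exclude
    such sites with a logged count via :func:`compute_snp_indices`.
    """
    mut = record.mutant_allele()
    if mut is None:
        raise ValueError(
            f"{record.chrom}:{record.pos}: mutant parent is not homozygous; "
            "mutant allele undefined"
        )
    ref_n, alt_n = record.call(SampleRole.BULK).allele_depths
    total = ref_n + alt_n
    if total == 0:
        raise ValueError(f"{record.chrom}:{record.pos}: zero bulk depth")
    mut_n = alt_n if mut == record.alt_allele else ref_n
    return SnpIndexPoint(
        chrom=record.chrom, pos=record.pos, index=mut_n / total, bulk_depth=total
    )


def compute_snp_indices(records: Iterable[VariantRecord]) -> list[SnpIndexPoint]:
    """Per-site indices for a filtered record set, excluding (with a logged
    count) sites with zero bulk depth or an unorientable mutant allele."""
    points: list[SnpIndexPoint] = []
    n_excluded = 0
    for record in records:
        try:
            points.append(compute_snp_index(record))
        except ValueError:
            n_excluded += 1
    if n_excluded:
        log.info("compute_snp_indices: excluded %d sites", n_excluded)
    points.sort(key=lambda p: (p.chrom, p.pos))
    return points


@dataclass
class WindowTrack:
    """Window-smoothed SNP-index track for one chromosome.

    ``values[i]`` is the mean raw index of the SNPs inside the window
    centred at ``centers[i]``; windows with fewer than ``min_snps`` SNPs are
    masked (``mask[i]`` True).
    """

    chrom: str
    centers: np.ndarray
    values: np.ndarray
    n_snps: np.ndarray
    mask: np.ndarray
    window_bp: int
    step_bp: int
    min_snps: int


def sliding_window(
    points: Sequence[SnpIndexPoint],
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
    min_snps: int = DEFAULT_MIN_SNPS,
) -> list[WindowTrack]:
    """Smooth raw indices with windows of ``window_bp`` centred every
    ``step_bp`` along each chromosome (windows are inclusive intervals
    ``[c - w/2, c + w/2]``)."""
    if not (window_bp >= step_bp > 0):
        raise ValueError("require window_bp >= step_bp > 0")
    if min_snps < 1:
        raise ValueError("min_snps must be >= 1")
    by_chrom: dict[str, list[SnpIndexPoint]] = {}
    for p in points:
        by_chrom.setdefault(p.chrom, []).append(p)
    tracks: list[WindowTrack] = []
    half = window_bp / 2.0
    for chrom in sorted(by_chrom):
        pts = sorted(by_chrom[chrom], key=lambda p: p.pos)
        pos = np.array([p.pos for p in pts], dtype=float)
        idx = np.array([p.index for p in pts], dtype=float)
        csum = np.concatenate([[0.0], np.cumsum(idx)])
        centers = np.arange(step_bp, pos[-1] + step_bp, step_bp, dtype=float)
        lo = np.searchsorted(pos, centers - half, side="left")
        hi = np.searchsorted(pos, centers + half, side="right")
        n = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1), np.nan)
        mask = n < min_snps
        tracks.append(
            WindowTrack(
                chrom=chrom,
                centers=centers,
                values=values,
                n_snps=n.astype(int),
                mask=mask,
                window_bp=window_bp,
                step_bp=step_bp,
                min_snps=min_snps,
            )
        )
    return tracks


@dataclass
class CandidateRegion:
    """High-index interval; bounds are positions of the first and last
    contributing raw SNP, length reported in Mb to two decimals."""

    chrom: str
    start: int
    end: int
    peak_index: float
    n_snps: int
    length_mb: float = field(init=False)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start > end")
        self.length_mb = round((self.end - self.start) / 1e6, 2)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "start": self.start,
            "end": self.end,
            "length_mb": self.length_mb,
            "peak_index": self.peak_index,
            "n_snps": self.n_snps,
        }


def call_candidate_regions(
    tracks: Sequence[WindowTrack],
    points: Sequence[SnpIndexPoint],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[CandidateRegion]:
    """Maximal runs of consecutive unmasked windows with smoothed index at or
    above ``threshold``, snapped to the raw SNPs inside the run's span.

    Regions from all chromosomes are returned sorted by peak index
    (descending), so the first element is the top mapping signal.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    pos_lists: dict[str, list[int]] = {}
    for p in points:
        pos_lists.setdefault(p.chrom, []).append(p.pos)
    pos_by_chrom = {c: np.array(sorted(v), dtype=float) for c, v in pos_lists.items()}
    regions: list[CandidateRegion] = []
    for track in tracks:
        above = (~track.mask) & (np.nan_to_num(track.values, nan=-1.0) >= threshold)
        if not above.any():
            continue
        raw = pos_by_chrom.get(track.chrom)
        if raw is None or raw.size == 0:
            continue
        half = track.window_bp / 2.0
        # run boundaries over the boolean vector
        edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
        for run_start, run_end in zip(edges[::2], edges[1::2] - 1):
            span_lo = track.centers[run_start] - half
            span_hi = track.centers[run_end] + half
            lo = np.searchsorted(raw, span_lo, side="left")
            hi = np.searchsorted(raw, span_hi, side="right")
            if hi <= lo:
                continue
            peak = float(np.nanmax(track.values[run_start : run_end + 1]))
            regions.append(
                CandidateRegion(
                    chrom=track.chrom,
                    start=int(raw[lo]),
                    end=int(raw[hi - 1]),
                    peak_index=peak,
                    n_snps=int(hi - lo),
                )
            )
    regions.sort(key=lambda r: (-r.peak_index, -(r.end - r.start), r.chrom, r.start))
    return regions


def call_regions_from_raw(
    points: Sequence[SnpIndexPoint], threshold: float = DEFAULT_THRESHOLD
) -> list[CandidateRegion]:
    """Threshold applied directly to raw per-SNP indices (no smoothing):
    maximal runs of consecutive above-threshold SNPs per chromosome."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    regions: list[CandidateRegion] = []
    by_chrom: dict[str, list[SnpIndexPoint]] = {}
    for p in sorted(points, key=lambda p: (p.chrom, p.pos)):
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom, pts in by_chrom.items():
        run: list[SnpIndexPoint] = []
        for p in pts + [None]:  # type: ignore[list-item]
            if p is not None and p.index >= threshold:
                run.append(p)
                continue
            if run:
                regions.append(
                    CandidateRegion(
                        chrom=chrom,
                        start=run[0].pos,
                        end=run[-1].pos,
                        peak_index=max(q.index for q in run),
                        n_snps=len(run),
                    )
                )
                run = []
    regions.sort(key=lambda r: (-r.peak_index, -(r.end - r.start), r.chrom, r.start))
    return regions


def expected_index_at_linked_marker(r: float) -> float:
    """Expected bulk mutant-allele frequency at a marker with recombination
    fraction ``r`` to the causal locus, among F2 plants homozygous recessive
    at that locus.

    Each selected plant contributes two F1 gametes that carry the causal
    mutant allele; a gamete is non-recombinant between marker and causal
    locus with probability 1 - r, so the marker carries the mutant allele
    with probability 1 - r.
    """
    if not 0.0 <= r <= 0.5:
        raise ValueError("recombination fraction must be in [0, 0.5]")
    return 1.0 - r


def plot_snp_index(
    tracks: Sequence[WindowTrack],
    points: Sequence[SnpIndexPoint],
    path,
    threshold: float = DEFAULT_THRESHOLD,
) -> None:
    """Per-chromosome index plot: raw points, smoothed track, threshold line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = [t.chrom for t in tracks]
    fig, axes = plt.subplots(
        1, max(len(chroms), 1), figsize=(4 * max(len(chroms), 1), 3), squeeze=False
    )
    for ax, track in zip(axes[0], tracks):
        pts = [p for p in points if p.chrom == track.chrom]
        ax.plot([p.pos / 1e6 for p in pts], [p.index for p in pts], ".", ms=3, alpha=0.5)
        ok = ~track.mask
        ax.plot(track.centers[ok] / 1e6, track.values[ok], "-", lw=1.5)
        ax.axhline(threshold, ls=":", color="deeppink")
        ax.set_ylim(-0.05, 1.05)
        ax.set_xlabel(f"{track.chrom} (Mb)")
        ax.set_ylabel("SNP index")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
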