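"""Sequence- and methylation-derived profiles around anchor sites.

GC-content metaprofiles, DNA-methylation metaprofiles, the nucleosome
occupancy vs GC curve and the window-GC two-sample test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genomic_io import (
    GenomeSequence,
    GenomicSite,
    MethylationTrack,
    Profile,
    ProfileNormalization,
    TagSet,
    make_offsets,
)
from .tag_profiling import NUCLEOSOME_FOOTPRINT, _interval_index, extend_tags

logger = logging.getLogger(__name__)

_GC_CODES = (ord("G"), ord("C"))
_ACGT_CODES = (ord("A"), ord("C"), ord("G"), ord("T"))


def _gc_valid_cumsums(genome: GenomeSequence, chrom: str) -> tuple[np.ndarray, np.ndarray]:
    arr = genome.base_array(chrom)
    is_gc = (arr == _GC_CODES[0]) | (arr == _GC_CODES[1])
    is_valid = np.isin(arr, np.array(_ACGT_CODES, dtype=np.uint8))
    gc_cum = np.concatenate(([0], np.cumsum(is_gc, dtype=np.int64)))
    valid_cum = np.concatenate(([0], np.cumsum(is_valid, dtype=np.int64)))
    return gc_cum, valid_cum


def gc_profile(
    genome: GenomeSequence, anchors: list[GenomicSite], half_window: int
) -> Profile:
    """Per-offset fraction of anchors with G or C at ``pos + offset``.

    Ns (and positions beyond chromosome ends) are excluded from both the
    numerator and the denominator; offsets with no valid base at all get 0.
    """
    W = half_window
    if not anchors:
        raise ValueError("no anchors given")
    gc_counts = np.zeros(2 * W + 1)
    valid_counts = np.zeros(2 * W + 1)
    arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for anchor in anchors:
        chrom = anchor.chrom
        if chrom not in genome.sequences:
            continue
        if chrom not in arrays:
            arr = genome.base_array(chrom)
            arrays[chrom] = (
                (arr == _GC_CODES[0]) | (arr == _GC_CODES[1]),
                np.isin(arr, np.array(_ACGT_CODES, dtype=np.uint8)),
            )
        is_gc, is_valid = arrays[chrom]
        length = len(is_gc)
        lo = anchor.pos - W
        hi = anchor.pos + W + 1
        src_lo, src_hi = max(lo, 0), min(hi, length)
        if src_hi <= src_lo:
            continue
        dst_lo = src_lo - lo
        dst_hi = dst_lo + (src_hi - src_lo)
        gc_counts[dst_lo:dst_hi] += is_gc[src_lo:src_hi]
        valid_counts[dst_lo:dst_hi] += is_valid[src_lo:src_hi]
    values = np.divide(
        gc_counts, valid_counts, out=np.zeros_like(gc_counts), where=valid_counts > 0
    )
    return Profile(
        offsets=make_offsets(W),
        values=values,
        n_anchors=len(anchors),
        normalization=ProfileNormalization(1.0, True, 0),
    )


def methylation_profile(
    track: MethylationTrack,
    anchors: list[GenomicSite],
    half_window: int,
    mode: str = "all",
) -> Profile:
    """Sum methylation percentages at each offset, averaged over anchors.

    ``mode="all"`` divides by the number of anchors, treating unmeasured
    positions as zero contribution; ``mode="observed"`` divides by the number
    of anchors with a measurement at that offset.
    """
    W = half_window
    if not anchors:
        raise ValueError("no anchors given")
    if mode not in ("all", "observed"):
        raise ValueError("mode must be 'all' or 'observed'")
    sums = np.zeros(2 * W + 1)
    counts = np.zeros(2 * W + 1)
    by_chrom = track.by_chrom()
    for anchor in anchors:
        entry = by_chrom.get(anchor.chrom)
        if entry is None:
            continue
        positions, levels = entry
        lo = np.searchsorted(positions, anchor.pos - W)
        hi = np.searchsorted(positions, anchor.pos + W, side="right")
        if hi > lo:
            offs = positions[lo:hi] - (anchor.pos - W)
            np.add.at(sums, offs, levels[lo:hi])
            np.add.at(counts, offs, 1.0)
    if mode == "all":
        values = sums / len(anchors)
    else:
        values = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    return Profile(
        offsets=make_offsets(W),
        values=values,
        n_anchors=len(anchors),
        normalization=ProfileNormalization(1.0, True, 0),
    )


@dataclass
class GcOccupancyCurve:
    """Mean nucleosome occupancy binned by local GC fraction."""

    bin_edges: np.ndarray  # length n_bins + 1, partitioning [0, 1]
    mean_occupancy: np.ndarray  # NaN for empty bins
    n_snps: np.ndarray
    low_confidence: np.ndarray  # bins with fewer than the minimum count

    def argmax_bin(self, min_n: int = 1) -> tuple[float, float]:
        """(lo, hi) edges of the highest-occupancy bin with >= min_n SNPs."""
        masked = np.where(self.n_snps >= min_n, self.mean_occupancy, np.nan)
        if np.all(np.isnan(masked)):
            raise ValueError("no bin satisfies the minimum count")
        idx = int(np.nanargmax(masked))
        return float(self.bin_edges[idx]), float(self.bin_edges[idx + 1])


def occupancy_vs_gc(
    genome: GenomeSequence,
    tags: TagSet,
    anchors: list[GenomicSite],
    gc_window: int = 600,
    occ_window: int = 200,
    bin_width: float = 0.02,
    genome_length: int | None = None,
    min_bin_count: int = 20,
) -> GcOccupancyCurve:
    """Bin per-SNP nucleosome occupancy by the SNP's local GC content.

    GC is the fraction of G/C bases in the symmetric ``gc_window`` around
    each SNP (Ns excluded); occupancy is the mean per-base coverage of
    146-bp-extended nucleosome tags in the symmetric ``occ_window``, divided
    by genome-average coverage.  SNPs whose window leaves the chromosome are
    skipped.
    """
    if genome_length is None or genome_length <= 0:
        raise ValueError("genome_length must be a positive integer")
    gc_half = gc_window // 2
    occ_half = occ_window // 2
    extended = extend_tags(tags, NUCLEOSOME_FOOTPRINT)
    footprint = sum(len(iv) for iv in extended.intervals)
    coverage_divisor = footprint / genome_length
    index = _interval_index(extended)
    cumsums: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    n_bins = int(np.ceil(1.0 / bin_width))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 1.0)
    occ_sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    for anchor in anchors:
        chrom = anchor.chrom
        if chrom not in genome.sequences:
            continue
        length = len(genome.sequences[chrom])
        if anchor.pos - gc_half < 0 or anchor.pos + gc_half > length:
            continue
        if chrom not in cumsums:
            cumsums[chrom] = _gc_valid_cumsums(genome, chrom)
        gc_cum, valid_cum = cumsums[chrom]
        lo, hi = anchor.pos - gc_half, anchor.pos + gc_half
        n_valid = valid_cum[hi] - valid_cum[lo]
        if n_valid == 0:
            continue
        gc = (gc_cum[hi] - gc_cum[lo]) / n_valid

        win_lo, win_hi = anchor.pos - occ_half, anchor.pos + occ_half
        total_cov = 0.0
        by_strand = index.get(chrom)
        if by_strand is not None:
            for strand in ("+", "-"):
                starts, ends, max_len = by_strand[strand]
                if len(starts) == 0:
                    continue
                i = np.searchsorted(starts, win_lo - max_len)
                j = np.searchsorted(starts, win_hi)
                if j > i:
                    a = np.maximum(starts[i:j], win_lo)
                    b = np.minimum(ends[i:j], win_hi)
                    total_cov += float(np.clip(b - a, 0, None).sum())
        occupancy = total_cov / occ_window
        if coverage_divisor > 0:
            occupancy /= coverage_divisor
        bin_idx = min(int(gc / bin_width), n_bins - 1)
        occ_sums[bin_idx] += occupancy
        counts[bin_idx] += 1

    mean_occ = np.divide(
        occ_sums, counts, out=np.full(n_bins, np.nan), where=counts > 0
    )
    return GcOccupancyCurve(
        bin_edges=edges,
        mean_occupancy=mean_occ,
        n_snps=counts,
        low_confidence=counts < min_bin_count,
    )


def window_gc_fractions(
    genome: GenomeSequence, anchors: list[GenomicSite], window: int = 600
) -> np.ndarray:
    """Per-anchor GC fraction in a symmetric window (Ns excluded)."""
    half = window // 2
    cumsums: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    out = []
    for anchor in anchors:
        chrom = anchor.chrom
        if chrom not in genome.sequences:
            continue
        length = len(genome.sequences[chrom])
        if anchor.pos - half < 0 or anchor.pos + half > length:
            continue
        if chrom not in cumsums:
            cumsums[chrom] = _gc_valid_cumsums(genome, chrom)
        gc_cum, valid_cum = cumsums[chrom]
        lo, hi = anchor.pos - half, anchor.pos + half
        n_valid = valid_cum[hi] - valid_cum[lo]
        if n_valid == 0:
            continue
        out.append((gc_cum[hi] - gc_cum[lo]) / n_valid)
    return np.array(out, dtype=float)


def window_gc_ttest(
    genome: GenomeSequence,
    anchors_a: list[GenomicSite],
    anchors_b: list[GenomicSite],
    window: int = 600,
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sample t-test on per-anchor window GC between two anchor sets.

    Welch by default (``equal_var=False``); two-sided p-value.
    """
    a = window_gc_fractions(genome, anchors_a, window)
    b = window_gc_fractions(genome, anchors_b, window)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each anchor set needs at least two usable windows")
    result = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(result.statistic), float(result.pvalue)
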