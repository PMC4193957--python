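"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately written with plain Python loops and stdlib
helpers (no shared code with the package) so the tests cross-check two
independent routes to the same quantity.
"""

from __future__ import annotations

import statistics
from statistics import StatisticsError

NUC_LEN = 146


def pearson(x, y):
    return statistics.correlation(list(x), list(y))


def five_prime(start, end, strand):
    return end - 1 if strand == "-" else start


def brute_strand_counts(tags, anchors, half_window):
    """(plus, minus) 5'-end count profiles as plain lists."""
    W = half_window
    plus = [0.0] * (2 * W + 1)
    minus = [0.0] * (2 * W + 1)
    for anchor in anchors:
        for iv in tags.intervals:
            if iv.chrom != anchor.chrom:
                continue
            fp = five_prime(iv.start, iv.end, iv.strand)
            d = fp - anchor.pos
            if -W <= d <= W:
                target = minus if iv.strand == "-" else plus
                target[d + W] += 1.0
    return plus, minus


def brute_strand_coverage(tags, anchors, half_window):
    """(plus, minus) per-base coverage profiles as plain lists."""
    W = half_window
    plus = [0.0] * (2 * W + 1)
    minus = [0.0] * (2 * W + 1)
    for anchor in anchors:
        for iv in tags.intervals:
            if iv.chrom != anchor.chrom:
                continue
            target = minus if iv.strand == "-" else plus
            for pos in range(iv.start, iv.end):
                d = pos - anchor.pos
                if -W <= d <= W:
                    target[d + W] += 1.0
    return plus, minus


def brute_extend(tags_intervals, length=NUC_LEN):
    """[(chrom, start, end, strand)] extended 3'-wards, clipped at 0."""
    out = []
    for iv in tags_intervals:
        if iv.strand == "-":
            out.append((iv.chrom, max(0, iv.end - length), iv.end, iv.strand))
        else:
            out.append((iv.chrom, iv.start, iv.start + length, iv.strand))
    return out


def brute_best_shift(plus, minus, max_shift):
    """Exhaustive search for the correlation-maximising symmetric shift.

    Each candidate shift moves the profiles toward each other; the better of
    the two movement directions is used so the answer is order-invariant.
    """
    L = len(plus)
    best_s, best_r = 0, None
    for s in range(0, min(max_shift, (L - 2) // 2) + 1):
        rs = []
        for x, y in ((plus[: L - 2 * s], minus[2 * s:]),
                     (minus[: L - 2 * s], plus[2 * s:])):
            try:
                rs.append(pearson(x, y))
            except StatisticsError:
                continue
        if not rs:
            continue
        r = max(rs)
        if best_r is None or r > best_r:
            best_s, best_r = s, r
    return best_s


def brute_shift_sum(plus, minus, shift):
    L = len(plus)
    out = [0.0] * L
    for i in range(L):
        if 0 <= i - shift < L:
            out[i] += plus[i - shift]
        if 0 <= i + shift < L:
            out[i] += minus[i + shift]
    return out


def brute_aggregate_profile(tags, anchors, half_window, mode, genome_length,
                            max_shift=None):
    """Full pipeline by loops: usable anchors assume pos - W >= 0 already."""
    from snpchrom.genomic_io import GenomicInterval, TagSet

    if mode == "nucleosome":
        extended = TagSet(
            [GenomicInterval(*t) for t in brute_extend(tags.intervals)],
            tags.source_label,
        )
        plus, minus = brute_strand_coverage(extended, anchors, half_window)
        footprint = sum(iv.end - iv.start for iv in extended.intervals)
        cap = 73 if max_shift is None else max_shift
    else:
        plus, minus = brute_strand_counts(tags, anchors, half_window)
        footprint = len(tags.intervals)
        cap = 100 if max_shift is None else max_shift
    shift = brute_best_shift(plus, minus, cap)
    summed = brute_shift_sum(plus, minus, shift)
    c = footprint / genome_length
    return [v / (c * len(anchors)) for v in summed], shift


def brute_region_profile(intervals, anchors, half_window):
    W = half_window
    values = [0.0] * (2 * W + 1)
    for anchor in anchors:
        for d in range(-W, W + 1):
            pos = anchor.pos + d
            for iv in intervals:
                if iv.chrom == anchor.chrom and iv.start <= pos < iv.end:
                    values[d + W] += 1.0
                    break
    return [v / len(anchors) for v in values]


def brute_density_profile(snp_sites, mutation_sites, half_window):
    W = half_window
    counts = [0] * (2 * W + 1)
    for m in mutation_sites:
        for v in snp_sites:
            if v.chrom != m.chrom:
                continue
            d = v.pos - m.pos
            if -W <= d <= W:
                counts[d + W] += 1
    return [c / len(mutation_sites) for c in counts]


def brute_gc_profile(genome, anchors, half_window):
    W = half_window
    gc = [0] * (2 * W + 1)
    valid = [0] * (2 * W + 1)
    for anchor in anchors:
        seq = genome.sequences.get(anchor.chrom)
        if seq is None:
            continue
        for d in range(-W, W + 1):
            pos = anchor.pos + d
            if 0 <= pos < len(seq):
                base = seq[pos]
                if base in "ACGT":
                    valid[d + W] += 1
                    if base in "GC":
                        gc[d + W] += 1
    return [g / v if v else 0.0 for g, v in zip(gc, valid)]


def brute_methylation_profile(track, anchors, half_window):
    W = half_window
    sums = [0.0] * (2 * W + 1)
    for anchor in anchors:
        for site, level in track.sites:
            if site.chrom != anchor.chrom:
                continue
            d = site.pos - anchor.pos
            if -W <= d <= W:
                sums[d + W] += level
    return [s / len(anchors) for s in sums]


def brute_hm_level(tags, snp_pos, chrom, window, genome_length, shift=0):
    half = window // 2
    count = 0
    for iv in tags.intervals:
        if iv.chrom != chrom:
            continue
        fp = five_prime(iv.start, iv.end, iv.strand)
        eff = fp - shift if iv.strand == "-" else fp + shift
        if snp_pos - half <= eff < snp_pos + half:
            count += 1
    coverage = len(tags.intervals) / genome_length
    return count / coverage if coverage else 0.0


def mann_whitney_auc(scores, labels):
    """AUC as the mean over all (positive, negative) pairs, ties count 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == "risk"]
    neg = [s for s, l in zip(scores, labels) if l == "neutral"]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def normal_sf(x):
    """High-precision standard normal survival function via erfc."""
    import math

    return 0.5 * math.erfc(x / math.sqrt(2.0))
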