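from __future__ import annotations

import numpy as np
import pytest

from snpchrom.genomic_io import GenomicInterval, GenomicSite, SnpRecord, TagSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_instance(rng, n_anchors=None, n_tags=None, half_window=None,
                    chrom="chr1", genome_length=2000):
    """A small random (tags, anchors, W) instance for oracle comparisons."""
    W = int(rng.integers(5, 50)) if half_window is None else half_window
    n_anchors = int(rng.integers(1, 11)) if n_anchors is None else n_anchors
    n_tags = int(rng.integers(1, 101)) if n_tags is None else n_tags
    anchors = [
        GenomicSite(chrom, int(p))
        for p in rng.integers(W, genome_length - W - 1, size=n_anchors)
    ]
    intervals = []
    for _ in range(n_tags):
        start = int(rng.integers(0, genome_length - 200))
        length = int(rng.integers(1, 60))
        strand = ["+", "-", "."][int(rng.integers(0, 3))]
        intervals.append(GenomicInterval(chrom, start, start + length, strand))
    return TagSet(intervals, "test"), anchors, W


def make_snp(pos, alleles=("A", "G"), chrom="chr1", variant_class="single",
             func="intron", validated=True, risk_label="other"):
    return SnpRecord(
        site=GenomicSite(chrom, pos),
        observed_alleles=alleles,
        variant_class=variant_class,
        func_category=func,
        validated=validated,
        risk_label=risk_label,
    )
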