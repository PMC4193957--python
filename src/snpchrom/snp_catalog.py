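"""SNP categorisation, filtering, risk/neutral labelling and random controls.

SNPs fall into nine functional categories taken from the input table's
``func`` vocabulary (a configurable alias map translates dialects).
Coding-synonymous SNPs not matching a risk site are the neutral comparator;
risk sites split into coding and non-coding risk SNPs by category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genomic_io import GenomicInterval, GenomicSite, SnpRecord

logger = logging.getLogger(__name__)

NINE_CATEGORIES: tuple[str, ...] = (
    "coding_synonymous",
    "coding_nonsynonymous",
    "exon_other",
    "intron",
    "utr5",
    "utr3",
    "near_gene_5",
    "near_gene_3",
    "intergenic_other",
)

CODING_CATEGORIES = frozenset(
    {"coding_synonymous", "coding_nonsynonymous", "exon_other"}
)

#: UCSC-style func values mapped onto the internal vocabulary.
DEFAULT_CATEGORY_ALIASES: dict[str, str] = {
    "coding-synon": "coding_synonymous",
    "coding_synonymous": "coding_synonymous",
    "coding-nonsynon": "coding_nonsynonymous",
    "coding_nonsynonymous": "coding_nonsynonymous",
    "missense": "coding_nonsynonymous",
    "nonsense": "coding_nonsynonymous",
    "frameshift": "coding_nonsynonymous",
    "exon": "exon_other",
    "exon_other": "exon_other",
    "cds-reference": "exon_other",
    "intron": "intron",
    "untranslated-5": "utr5",
    "utr5": "utr5",
    "untranslated-3": "utr3",
    "utr3": "utr3",
    "near-gene-5": "near_gene_5",
    "near_gene_5": "near_gene_5",
    "near-gene-3": "near_gene_3",
    "near_gene_3": "near_gene_3",
    "intergenic": "intergenic_other",
    "intergenic_other": "intergenic_other",
    "unknown": "intergenic_other",
}

#: Multi-annotation precedence: coding > UTR > intron > near-gene > intergenic.
DEFAULT_PRECEDENCE: tuple[str, ...] = (
    "coding_nonsynonymous",
    "coding_synonymous",
    "exon_other",
    "utr5",
    "utr3",
    "intron",
    "near_gene_5",
    "near_gene_3",
    "intergenic_other",
)

#: Region class (as named in a GeneAnnotation) used to sample random controls
#: for each SNP category.
CATEGORY_REGION_CLASS: dict[str, str] = {
    "coding_synonymous": "exon",
    "coding_nonsynonymous": "exon",
    "exon_other": "exon",
    "intron": "intron",
    "utr5": "utr5",
    "utr3": "utr3",
    "near_gene_5": "near_gene_5",
    "near_gene_3": "near_gene_3",
    "intergenic_other": "intergenic",
}


@dataclass
class GeneAnnotation:
    """Per-region-class interval lists used for random-locus sampling."""

    regions: dict[str, list[GenomicInterval]] = field(default_factory=dict)

    def total_length(self, region_class: str) -> int:
        return sum(len(iv) for iv in self.regions.get(region_class, []))


def normalize_category(
    func: str,
    aliases: Mapping[str, str] | None = None,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> str | None:
    """Map a raw ``func`` annotation to one of the nine categories.

    Comma-separated multi-annotations are resolved by ``precedence``.
    Returns ``None`` when no token is recognised.
    """
    aliases = DEFAULT_CATEGORY_ALIASES if aliases is None else aliases
    mapped = [
        aliases[token.strip().lower()]
        for token in str(func).split(",")
        if token.strip().lower() in aliases
    ]
    if not mapped:
        return None
    rank = {cat: i for i, cat in enumerate(precedence)}
    return min(mapped, key=lambda c: rank.get(c, len(rank)))


def filter_snps(
    records: Iterable[SnpRecord],
    aliases: Mapping[str, str] | None = None,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> list[SnpRecord]:
    """Apply the analysis filters: single-base class, validated, valid alleles.

    Retained records have their ``func_category`` normalised to the internal
    nine-category vocabulary; records whose category cannot be mapped are
    dropped.
    """
    kept = []
    for rec in records:
        if rec.variant_class != "single" or not rec.validated:
            continue
        if not rec.has_valid_alleles:
            continue
        category = normalize_category(rec.func_category, aliases, precedence)
        if category is None:
            continue
        kept.append(replace(rec, func_category=category))
    return kept


def assign_labels(
    records: Iterable[SnpRecord], risk_sites: Iterable[GenomicSite]
) -> tuple[list[SnpRecord], int]:
    """Assign risk/neutral/other labels by exact coordinate match.

    A record at a risk site becomes ``risk_coding`` or ``risk_noncoding``
    depending on its category; non-risk coding-synonymous records become
    ``neutral``; everything else is ``other``.  Returns the relabelled
    records and the number of risk sites matching no record.
    """
    risk_keys = {(s.chrom, s.pos) for s in risk_sites}
    matched: set[tuple[str, int]] = set()
    out = []
    for rec in records:
        key = (rec.site.chrom, rec.site.pos)
        if key in risk_keys:
            matched.add(key)
            label = (
                "risk_coding"
                if rec.func_category in CODING_CATEGORIES
                else "risk_noncoding"
            )
        elif rec.func_category == "coding_synonymous":
            label = "neutral"
        else:
            label = "other"
        out.append(replace(rec, risk_label=label))
    n_unmatched = len(risk_keys - matched)
    if n_unmatched:
        logger.warning("%d risk sites matched no SNP record", n_unmatched)
    return out, n_unmatched


def sample_random_loci(
    annotation: GeneAnnotation,
    category_counts: Mapping[str, int],
    rng: np.random.Generator | int,
) -> dict[str, list[GenomicSite]]:
    """Sample category-matched random control loci, uniform per region class.

    For every category ``c``, ``category_counts[c]`` sites are drawn uniformly
    from the bases of the corresponding region class.  Deterministic for a
    fixed seed.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out: dict[str, list[GenomicSite]] = {}
    for category, n in category_counts.items():
        region_class = CATEGORY_REGION_CLASS.get(category, category)
        intervals = annotation.regions.get(region_class, [])
        total = sum(len(iv) for iv in intervals)
        if total == 0:
            raise ValueError(
                f"region class {region_class!r} for category {category!r} "
                "has zero total length"
            )
        lengths = np.array([len(iv) for iv in intervals], dtype=np.int64)
        bounds = np.cumsum(lengths)
        draws = rng.integers(0, total, size=int(n))
        sites = []
        for d in draws:
            idx = int(np.searchsorted(bounds, d, side="right"))
            iv = intervals[idx]
            offset = int(d) - (int(bounds[idx]) - len(iv))
            sites.append(GenomicSite(iv.chrom, iv.start + offset))
        out[category] = sites
    return out
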