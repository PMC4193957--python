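"""Synthetic inputs with plantable effect sizes.

Every generator is a pure function of :class:`SimulationConfig` (including
its master seed), and every planted effect has a closed-form expectation so
downstream recovery tolerances can be derived analytically:

* nucleosome tags with dyads positioned at (or offset from) anchor classes,
* histone-mark tags with class-dependent window intensities,
* a substitution spectrum with configurable type probabilities (3:1 Ts:Tv
  by default),
* mutation neighbourhoods with SNP enrichment at +/-1 and depletion at 0,
* class-dependent methylation levels around SNPs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .genomic_io import (
    GenomeSequence,
    GenomicInterval,
    GenomicSite,
    MethylationTrack,
    SnpRecord,
    TagSet,
    write_genome_fasta,
    write_methylation_table,
    write_site_table,
    write_snp_table,
    write_tag_bed,
)
from .snp_catalog import GeneAnnotation, assign_labels, filter_snps

logger = logging.getLogger(__name__)

#: region class -> SNP category for non-exon regions
_REGION_CATEGORY = {
    "intron": "intron",
    "utr5": "utr5",
    "utr3": "utr3",
    "near_gene_5": "near_gene_5",
    "near_gene_3": "near_gene_3",
    "intergenic": "intergenic_other",
}


def _default_gc_by_class() -> dict[str, float]:
    return {
        "exon": 0.55,
        "utr5": 0.52,
        "utr3": 0.45,
        "intron": 0.40,
        "near_gene_5": 0.45,
        "near_gene_3": 0.42,
        "intergenic": 0.40,
    }


def _default_snp_density() -> dict[str, float]:
    return {
        "exon": 0.004,
        "utr5": 0.004,
        "utr3": 0.004,
        "intron": 0.004,
        "near_gene_5": 0.004,
        "near_gene_3": 0.004,
        "intergenic": 0.004,
    }


def _default_substitution_probs() -> dict[str, float]:
    return {
        "A/G": 0.375,
        "C/T": 0.375,
        "A/C": 0.0625,
        "A/T": 0.0625,
        "C/G": 0.0625,
        "G/T": 0.0625,
    }


def _default_hm_effects() -> dict[str, dict[str, float]]:
    return {
        "H3K4me3": {"risk": 1.5, "neutral": 1.0, "other": 1.0},
        "H3K9me3": {"risk": 1.4, "neutral": 1.0, "other": 1.0},
        "H3K27me3": {"risk": 0.7, "neutral": 1.0, "other": 1.0},
        "H3K36me3": {"risk": 1.3, "neutral": 1.0, "other": 1.0},
    }


@dataclass
class SimulationConfig:
    """All knobs of the synthetic dataset; a pure function of this object."""

    genome_length: int = 2_000_000
    chrom: str = "chrS"
    master_seed: int = 0

    # region layout: alternating intergenic and gene blocks
    intergenic_length: int = 6000
    near_gene_length: int = 1000
    utr5_length: int = 300
    utr3_length: int = 500
    exon_length: int = 300
    intron_length: int = 1500
    n_exons_per_gene: int = 3

    gc_by_class: dict[str, float] = field(default_factory=_default_gc_by_class)
    #: optional (mean, amplitude, period): GC varies sinusoidally with position
    gc_sinusoid: tuple[float, float, float] | None = None

    # SNP planting
    snp_density: dict[str, float] = field(default_factory=_default_snp_density)
    exon_category_probs: dict[str, float] = field(
        default_factory=lambda: {
            "coding_synonymous": 0.4,
            "coding_nonsynonymous": 0.4,
            "exon_other": 0.2,
        }
    )
    substitution_probs: dict[str, float] = field(
        default_factory=_default_substitution_probs
    )
    risk_fraction: float = 0.02
    unvalidated_fraction: float = 0.05
    nonsingle_fraction: float = 0.02

    # nucleosome tag model
    # every class is either positioned or depleted so the cross-anchor tag
    # pedestal is homogeneous and only the coherent central dyad (or linker)
    # distinguishes the classes
    positioned_classes: tuple[str, ...] = (
        "coding_synonymous",
        "coding_nonsynonymous",
        "exon_other",
        "utr5",
        "near_gene_5",
    )
    depleted_classes: tuple[str, ...] = (
        "intron",
        "utr3",
        "near_gene_3",
        "intergenic_other",
    )
    dyad_spacing: int = 200
    dyad_jitter_sd: float = 20.0
    #: extra jitter sd per dyad index |k| (phasing decays away from the anchor,
    #: making the central peak the unambiguous profile maximum)
    dyad_jitter_growth: float = 40.0
    dyads_per_side: int = 5
    coverage_per_dyad: float = 5.0
    #: multiplicative coverage decay per dyad index |k| (array strength fades
    #: with distance from the anchor)
    coverage_decay: float = 0.7
    tag_length: int = 25
    tag_start_sd: float = 10.0
    nucleosome_background_rate: float = 0.02  # tags per bp

    # histone-mark tag model
    hm_types: tuple[str, ...] = ("H3K4me3", "H3K9me3", "H3K27me3", "H3K36me3")
    hm_baseline: float = 5.0  # expected tags in a SNP window
    hm_effects: dict[str, dict[str, float]] = field(default_factory=_default_hm_effects)
    hm_window: int = 200
    hm_background_rate: float = 0.002  # tags per bp

    # mutation neighbourhood model
    mutation_n_sites: int = 10_000
    mutation_snp_density: float = 0.004
    mutation_p_enrich: float = 0.8 * 0.004  # gives fold 1.4 at each of +/-1
    mutation_p_deplete: float = 0.5  # gives fold 0.5 at 0
    mutation_half_window: int = 5000

    # methylation model
    meth_class_means: dict[str, float] = field(
        default_factory=lambda: {"neutral": 80.0, "risk": 40.0}
    )
    meth_sd: float = 10.0
    meth_window: int = 200

    def __post_init__(self) -> None:
        total = sum(self.substitution_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"substitution probabilities must sum to 1, got {total}")
        for name, value in (
            ("risk_fraction", self.risk_fraction),
            ("mutation_p_enrich", self.mutation_p_enrich),
            ("mutation_p_deplete", self.mutation_p_deplete),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        coerced = dict(data)
        for key in ("positioned_classes", "depleted_classes", "hm_types", "gc_sinusoid"):
            if key in coerced and coerced[key] is not None:
                coerced[key] = tuple(coerced[key])
        return cls(**coerced)

    @property
    def expected_fold_flank(self) -> float:
        """Closed-form planted fold at offsets -1/+1."""
        rho = self.mutation_snp_density
        return (rho + self.mutation_p_enrich / 2.0) / rho

    @property
    def expected_fold_center(self) -> float:
        """Closed-form planted fold at offset 0."""
        return 1.0 - self.mutation_p_deplete


# ---------------------------------------------------------------------------
# Genome and annotation
# ---------------------------------------------------------------------------

def _region_layout(config: SimulationConfig) -> list[tuple[str, int, int]]:
    """(region_class, start, end) blocks tiling [0, genome_length)."""
    L = config.genome_length
    blocks: list[tuple[str, int, int]] = []
    pos = 0

    def push(region_class: str, length: int) -> None:
        nonlocal pos
        if pos >= L or length <= 0:
            return
        end = min(pos + length, L)
        blocks.append((region_class, pos, end))
        pos = end

    while pos < L:
        push("intergenic", config.intergenic_length)
        push("near_gene_5", config.near_gene_length)
        push("utr5", config.utr5_length)
        for i in range(config.n_exons_per_gene):
            push("exon", config.exon_length)
            if i < config.n_exons_per_gene - 1:
                push("intron", config.intron_length)
        push("utr3", config.utr3_length)
        push("near_gene_3", config.near_gene_length)
    return blocks


def make_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeSequence, GeneAnnotation]:
    """Draw a genome with per-region (or sinusoidal) GC and its annotation."""
    rng = rng or np.random.default_rng(config.master_seed)
    L = config.genome_length
    blocks = _region_layout(config)
    p_gc = np.empty(L)
    for region_class, start, end in blocks:
        p_gc[start:end] = config.gc_by_class.get(region_class, 0.4)
    if config.gc_sinusoid is not None:
        mean, amp, period = config.gc_sinusoid
        x = np.arange(L)
        p_gc = mean + amp * np.sin(2.0 * np.pi * x / period)
        p_gc = np.clip(p_gc, 0.0, 1.0)
    is_gc = rng.random(L) < p_gc
    coin = rng.integers(0, 2, size=L).astype(bool)
    codes = np.where(
        is_gc,
        np.where(coin, ord("G"), ord("C")),
        np.where(coin, ord("A"), ord("T")),
    ).astype(np.uint8)
    genome = GenomeSequence({config.chrom: codes.tobytes().decode("ascii")})
    regions: dict[str, list[GenomicInterval]] = {}
    for region_class, start, end in blocks:
        regions.setdefault(region_class, []).append(
            GenomicInterval(config.chrom, start, end)
        )
    return genome, GeneAnnotation(regions)


# ---------------------------------------------------------------------------
# SNP planting
# ---------------------------------------------------------------------------

def _conditional_partner_table(
    substitution_probs: Mapping[str, float],
) -> dict[str, tuple[list[str], np.ndarray]]:
    """For each reference base, the partner bases and normalised probabilities."""
    table: dict[str, tuple[list[str], np.ndarray]] = {}
    for base in "ACGT":
        partners, probs = [], []
        for pair, prob in substitution_probs.items():
            b1, b2 = pair.split("/")
            if base == b1:
                partners.append(b2)
                probs.append(prob)
            elif base == b2:
                partners.append(b1)
                probs.append(prob)
        probs_arr = np.array(probs)
        table[base] = (partners, probs_arr / probs_arr.sum())
    return table


def plant_snps(
    config: SimulationConfig,
    genome: GenomeSequence,
    annotation: GeneAnnotation,
    rng: np.random.Generator,
) -> tuple[list[SnpRecord], list[GenomicSite]]:
    """Plant SNPs per region class; returns (records, risk sites).

    One allele always equals the reference base; the other is drawn from the
    substitution-type distribution conditioned on the reference.  A small
    configurable fraction of records is unvalidated or non-single to
    exercise the filters.  Risk sites are a random subset of filter-passing
    records.
    """
    seq = genome.sequences[config.chrom]
    partner_table = _conditional_partner_table(config.substitution_probs)
    records: list[SnpRecord] = []
    for region_class in sorted(annotation.regions):
        density = config.snp_density.get(region_class, 0.0)
        if density <= 0.0:
            continue
        exon_cats = list(config.exon_category_probs)
        exon_probs = np.array([config.exon_category_probs[c] for c in exon_cats])
        exon_probs = exon_probs / exon_probs.sum()
        for iv in annotation.regions[region_class]:
            hits = np.flatnonzero(rng.random(len(iv)) < density)
            for offset in hits:
                pos = iv.start + int(offset)
                ref = seq[pos]
                if ref not in "ACGT":
                    continue
                partners, probs = partner_table[ref]
                alt = partners[rng.choice(len(partners), p=probs)]
                if region_class == "exon":
                    category = exon_cats[rng.choice(len(exon_cats), p=exon_probs)]
                else:
                    category = _REGION_CATEGORY[region_class]
                if rng.random() < config.nonsingle_fraction:
                    variant_class, alleles = "insertion", None
                else:
                    variant_class, alleles = "single", (ref, alt)
                records.append(
                    SnpRecord(
                        site=GenomicSite(config.chrom, pos),
                        observed_alleles=alleles,
                        variant_class=variant_class,
                        func_category=category,
                        validated=rng.random() >= config.unvalidated_fraction,
                    )
                )
    records.sort(key=lambda r: r.site.pos)
    risk_sites = [
        rec.site
        for rec in records
        if rec.variant_class == "single"
        and rec.validated
        and rec.has_valid_alleles
        and rng.random() < config.risk_fraction
    ]
    return records, risk_sites


# ---------------------------------------------------------------------------
# Nucleosome tags
# ---------------------------------------------------------------------------

def _intervals_from_arrays(
    chrom: str, starts: np.ndarray, ends: np.ndarray, strands: np.ndarray
) -> list[GenomicInterval]:
    return [
        GenomicInterval(chrom, int(s), int(e), "+" if plus else "-")
        for s, e, plus in zip(starts, ends, strands)
    ]


def simulate_nucleosome_tags(
    config: SimulationConfig,
    genome: GenomeSequence,
    snps: list[SnpRecord],
    rng: np.random.Generator,
) -> TagSet:
    """Paired-strand tags from jittered dyads around anchor classes.

    Positioned classes get dyads at ``anchor + spacing*k``; depleted classes
    at ``anchor + spacing/2 + spacing*k`` (linker over the anchor), for
    ``k = -K..K`` with Gaussian jitter.  Each dyad emits a Poisson number of
    tag pairs: plus tags starting at ``dyad - 73 + noise`` and minus tags
    ending at ``dyad + 74 - noise``.  Background tags are uniform.
    """
    L = len(genome.sequences[config.chrom])
    K = config.dyads_per_side
    offsets = np.arange(-K, K + 1) * config.dyad_spacing
    jitter_sd = config.dyad_jitter_sd + config.dyad_jitter_growth * np.abs(
        np.arange(-K, K + 1)
    )
    centers_list = []
    for rec in snps:
        if rec.func_category in config.positioned_classes:
            base = rec.site.pos
        elif rec.func_category in config.depleted_classes:
            base = rec.site.pos + config.dyad_spacing // 2
        else:
            continue
        centers_list.append(base + offsets)
    tl = config.tag_length
    starts_all, ends_all, strands_all = [], [], []
    if centers_list:
        dyads = np.concatenate(centers_list).astype(float)
        sds = np.tile(jitter_sd, len(centers_list))
        dyads = dyads + rng.normal(0.0, 1.0, size=len(dyads)) * sds
        coverage = config.coverage_per_dyad * config.coverage_decay ** np.abs(
            np.arange(-K, K + 1)
        )
        n_pairs = rng.poisson(np.tile(coverage, len(centers_list)))
        centers = np.repeat(dyads, n_pairs)
        if len(centers):
            plus_starts = np.rint(
                centers - 73 + rng.normal(0.0, config.tag_start_sd, len(centers))
            ).astype(np.int64)
            minus_ends = np.rint(
                centers + 74 - rng.normal(0.0, config.tag_start_sd, len(centers))
            ).astype(np.int64)
            keep_p = (plus_starts >= 0) & (plus_starts + tl <= L)
            keep_m = (minus_ends - tl >= 0) & (minus_ends <= L)
            starts_all.append(plus_starts[keep_p])
            ends_all.append(plus_starts[keep_p] + tl)
            strands_all.append(np.ones(int(keep_p.sum()), dtype=bool))
            starts_all.append(minus_ends[keep_m] - tl)
            ends_all.append(minus_ends[keep_m])
            strands_all.append(np.zeros(int(keep_m.sum()), dtype=bool))
    n_bg = rng.poisson(config.nucleosome_background_rate * L)
    if n_bg:
        bg_starts = rng.integers(0, L - tl, size=n_bg)
        bg_strands = rng.integers(0, 2, size=n_bg).astype(bool)
        starts_all.append(bg_starts)
        ends_all.append(bg_starts + tl)
        strands_all.append(bg_strands)
    if not starts_all:
        return TagSet([], "nucleosome")
    starts = np.concatenate(starts_all)
    ends = np.concatenate(ends_all)
    strands = np.concatenate(strands_all)
    return TagSet(_intervals_from_arrays(config.chrom, starts, ends, strands), "nucleosome")


def simulate_gc_biased_tags(
    genome: GenomeSequence,
    chrom: str,
    rng: np.random.Generator,
    n_tags: int,
    gc_window: int = 600,
    peak_gc: float = 0.54,
    width: float = 0.08,
    tag_length: int = 25,
) -> TagSet:
    """Paired-strand tags whose local density is unimodal in window GC.

    Dyad centres are drawn with probability proportional to a Gaussian kernel
    of the rolling ``gc_window`` GC fraction around ``peak_gc``; each dyad
    emits one plus tag starting at ``dyad - 73`` and one minus tag ending at
    ``dyad + 74``.  Exercises the occupancy-vs-GC curve with a known optimum.
    """
    arr = genome.base_array(chrom)
    is_gc = ((arr == ord("G")) | (arr == ord("C"))).astype(float)
    kernel = np.ones(gc_window) / gc_window
    rolling = np.convolve(is_gc, kernel, mode="same")
    weight = np.exp(-((rolling - peak_gc) ** 2) / (2.0 * width**2))
    margin = 73 + tag_length
    weight[:margin] = 0.0
    weight[-margin:] = 0.0
    prob = weight / weight.sum()
    centers = rng.choice(len(arr), size=n_tags, p=prob)
    intervals = []
    for c in centers:
        intervals.append(GenomicInterval(chrom, int(c) - 73, int(c) - 73 + tag_length, "+"))
        intervals.append(
            GenomicInterval(chrom, int(c) + 74 - tag_length, int(c) + 74, "-")
        )
    return TagSet(intervals, "gc_biased")


# ---------------------------------------------------------------------------
# Histone-mark tags
# ---------------------------------------------------------------------------

def _risk_group(record: SnpRecord) -> str:
    if record.risk_label in ("risk_coding", "risk_noncoding", "risk"):
        return "risk"
    if record.risk_label == "neutral":
        return "neutral"
    return "other"


def simulate_hm_tags(
    config: SimulationConfig,
    snps: list[SnpRecord],
    rng: np.random.Generator,
) -> dict[str, TagSet]:
    """Per-mark tags: Poisson window counts scaled by the class effect,
    plus a uniform genome-wide background."""
    L = config.genome_length
    half = config.hm_window // 2
    tl = config.tag_length
    groups = np.array([_risk_group(rec) for rec in snps])
    positions = np.array([rec.site.pos for rec in snps], dtype=np.int64)
    out: dict[str, TagSet] = {}
    for hm in config.hm_types:
        effects = config.hm_effects.get(hm, {})
        lam = config.hm_baseline * np.array(
            [effects.get(g, 1.0) for g in groups]
        )
        counts = rng.poisson(lam) if len(lam) else np.zeros(0, dtype=int)
        anchor_pos = np.repeat(positions, counts)
        five_primes = anchor_pos + rng.integers(-half, half, size=len(anchor_pos))
        n_bg = rng.poisson(config.hm_background_rate * L)
        bg = rng.integers(tl, L - tl, size=n_bg)
        five_primes = np.concatenate([five_primes, bg])
        strands = rng.integers(0, 2, size=len(five_primes)).astype(bool)
        starts = np.where(strands, five_primes, five_primes - tl + 1)
        ends = np.where(strands, five_primes + tl, five_primes + 1)
        keep = (starts >= 0) & (ends <= L)
        out[hm] = TagSet(
            _intervals_from_arrays(
                config.chrom, starts[keep], ends[keep], strands[keep]
            ),
            hm,
        )
    return out


# ---------------------------------------------------------------------------
# Mutation neighbourhoods
# ---------------------------------------------------------------------------

def uniform_snp_positions(
    config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Background SNP positions: each base carries probability rho."""
    return np.flatnonzero(
        rng.random(config.genome_length) < config.mutation_snp_density
    ).astype(np.int64)


def plant_mutation_sites(
    config: SimulationConfig,
    snp_positions: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw mutation sites and plant the +/-1 enrichment and 0 depletion.

    Per site, independently: with probability ``mutation_p_enrich`` an extra
    SNP is added at site-1 or site+1 (fair coin); with probability
    ``mutation_p_deplete`` any SNP at the site itself is removed.  Expected
    density: rho + p_enrich/2 at each of +/-1, rho*(1 - p_deplete) at 0, rho
    elsewhere.  Returns (mutation sites, adjusted SNP positions), both sorted.
    """
    L = config.genome_length
    W = config.mutation_half_window
    n = config.mutation_n_sites
    if L <= 2 * W:
        raise ValueError("genome too short for the mutation window")
    sites = rng.integers(W, L - W, size=n)
    deplete = rng.random(n) < config.mutation_p_deplete
    enrich = rng.random(n) < config.mutation_p_enrich
    side = rng.choice(np.array([-1, 1]), size=n)
    kept = snp_positions[~np.isin(snp_positions, sites[deplete])]
    extra = sites[enrich] + side[enrich]
    out = np.sort(np.concatenate([kept, extra])).astype(np.int64)
    return np.sort(sites).astype(np.int64), out


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

def simulate_methylation(
    config: SimulationConfig,
    snps: list[SnpRecord],
    rng: np.random.Generator,
) -> MethylationTrack:
    """Clipped-normal methylation levels in windows around labelled SNPs.

    Only SNPs whose risk group has a configured class mean contribute
    (sparse elsewhere).  Where windows overlap, the first write wins.
    """
    half = config.meth_window // 2
    pos_parts, level_parts = [], []
    for rec in snps:
        group = _risk_group(rec)
        if group not in config.meth_class_means:
            continue
        mean = config.meth_class_means[group]
        lo = max(0, rec.site.pos - half)
        hi = min(config.genome_length, rec.site.pos + half)
        if hi <= lo:
            continue
        pos_parts.append(np.arange(lo, hi, dtype=np.int64))
        level_parts.append(
            np.clip(rng.normal(mean, config.meth_sd, size=hi - lo), 0.0, 100.0)
        )
    if not pos_parts:
        return MethylationTrack([])
    positions = np.concatenate(pos_parts)
    levels = np.concatenate(level_parts)
    unique_pos, first_idx = np.unique(positions, return_index=True)
    chrom = config.chrom
    sites = [
        (GenomicSite(chrom, int(p)), float(levels[i]))
        for p, i in zip(unique_pos, first_idx)
    ]
    return MethylationTrack(sites)


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: GenomeSequence
    annotation: GeneAnnotation
    snps: list[SnpRecord]  # raw planted records (pre-filter)
    labeled_snps: list[SnpRecord]  # filtered + risk/neutral labelled
    risk_sites: list[GenomicSite]
    nucleosome_tags: TagSet
    hm_tags: dict[str, TagSet]
    mutation_sites: np.ndarray
    mutation_snp_positions: np.ndarray
    methylation: MethylationTrack
    ground_truth: dict


def simulate_dataset(
    config: SimulationConfig, outdir: str | Path | None = None
) -> SimulatedDataset:
    """Generate all inputs deterministically from the config's master seed.

    When ``outdir`` is given, writes FASTA, SNP TSV, tag BEDs, methylation
    and mutation TSVs and a ground-truth JSON of the planted parameters.
    """
    streams = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(config.master_seed).spawn(6)
    ]
    r_genome, r_snp, r_nuc, r_hm, r_mut, r_meth = streams
    genome, annotation = make_genome(config, r_genome)
    records, risk_sites = plant_snps(config, genome, annotation, r_snp)
    labeled, _ = assign_labels(filter_snps(records), risk_sites)
    nuc_tags = simulate_nucleosome_tags(config, genome, labeled, r_nuc)
    hm_tags = simulate_hm_tags(config, labeled, r_hm)
    background = uniform_snp_positions(config, r_mut)
    mut_sites, mut_snps = plant_mutation_sites(config, background, r_mut)
    methylation = simulate_methylation(config, labeled, r_meth)
    ts_probability = sum(
        p for t, p in config.substitution_probs.items() if t in ("A/G", "C/T")
    )
    ground_truth = {
        "master_seed": config.master_seed,
        "ts_probability": ts_probability,
        "positioned_classes": list(config.positioned_classes),
        "depleted_classes": list(config.depleted_classes),
        "hm_effects": config.hm_effects,
        "expected_fold_flank": config.expected_fold_flank,
        "expected_fold_center": config.expected_fold_center,
        "meth_class_means": config.meth_class_means,
    }
    dataset = SimulatedDataset(
        config=config,
        genome=genome,
        annotation=annotation,
        snps=records,
        labeled_snps=labeled,
        risk_sites=risk_sites,
        nucleosome_tags=nuc_tags,
        hm_tags=hm_tags,
        mutation_sites=mut_sites,
        mutation_snp_positions=mut_snps,
        methylation=methylation,
        ground_truth=ground_truth,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genome_fasta(genome, outdir / "genome.fa")
        write_snp_table(records, outdir / "snps.tsv")
        write_site_table(risk_sites, outdir / "risk_sites.tsv")
        write_tag_bed(nuc_tags, outdir / "nucleosome_tags.bed")
        for hm, tags in hm_tags.items():
            write_tag_bed(tags, outdir / f"hm_{hm}.bed")
        write_methylation_table(methylation, outdir / "methylation.tsv")
        write_site_table(
            [GenomicSite(config.chrom, int(p)) for p in mut_sites],
            outdir / "mutation_sites.tsv",
        )
        write_site_table(
            [GenomicSite(config.chrom, int(p)) for p in mut_snps],
            outdir / "mutation_snp_positions.tsv",
        )
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(ground_truth, fh, indent=2)
    return dataset
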