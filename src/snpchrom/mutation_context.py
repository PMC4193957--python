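"""SNP-density profiles around somatic mutation sites with positional Z-tests.

The density at offset d is the number of (mutation, SNP) pairs separated by
exactly d bases, averaged over mutation sites.  A flank-based null (mean and
standard deviation of the density outside a small exclusion radius) feeds a
per-offset Z-test and fold-change calls at the -1/0/+1 positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .genomic_io import GenomicSite, make_offsets

logger = logging.getLogger(__name__)

DEFAULT_HALF_WINDOW = 5000
DEFAULT_EXCLUSION_RADIUS = 10


@dataclass
class PositionalDensity:
    """SNP density per offset around mutation sites."""

    offsets: np.ndarray
    density: np.ndarray  # SNPs per mutation site
    n_mutations: int

    def __post_init__(self) -> None:
        if len(self.offsets) != len(self.density):
            raise ValueError("offsets and density must have equal length")

    @property
    def half_window(self) -> int:
        return (len(self.offsets) - 1) // 2

    def at(self, offset: int) -> float:
        return float(self.density[offset + self.half_window])


@dataclass
class PositionalTest:
    """Per-offset Z statistics against a flank-derived null."""

    z: np.ndarray
    p: np.ndarray
    enriched_offsets: np.ndarray  # offsets flagged significantly above the null
    depleted_offsets: np.ndarray
    alpha: float
    alpha_per_test: float


#: Site collections may be GenomicSite lists or {chrom: position-array} dicts.
SiteCollection = "list[GenomicSite] | dict[str, np.ndarray]"


def _sites_by_chrom(sites) -> dict[str, np.ndarray]:
    if isinstance(sites, dict):
        return {
            c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in sites.items()
        }
    grouped: dict[str, list[int]] = {}
    for s in sites:
        grouped.setdefault(s.chrom, []).append(s.pos)
    return {c: np.sort(np.array(p, dtype=np.int64)) for c, p in grouped.items()}


def snp_density_profile(
    snp_sites,
    mutation_sites,
    half_window: int = DEFAULT_HALF_WINDOW,
    chrom_sizes: dict[str, int] | None = None,
) -> PositionalDensity:
    """SNP counts at every offset in a window around mutation sites.

    Both site collections may be ``GenomicSite`` lists or
    ``{chrom: position-array}`` dicts.  Mutations whose window leaves the
    chromosome are dropped (and counted in the log).  A mutation coinciding
    with a SNP contributes at offset 0.
    """
    W = half_window
    snp_index = _sites_by_chrom(snp_sites)
    muts_raw = _sites_by_chrom(mutation_sites)
    n_input = sum(len(v) for v in muts_raw.values())
    muts_by_chrom: dict[str, np.ndarray] = {}
    n_usable = 0
    for chrom, positions in muts_raw.items():
        keep = positions - W >= 0
        if chrom_sizes is not None and chrom in chrom_sizes:
            keep &= positions + W < chrom_sizes[chrom]
        muts_by_chrom[chrom] = positions[keep]
        n_usable += int(keep.sum())
    if n_input - n_usable:
        logger.warning("dropped %d window-clipped mutation sites", n_input - n_usable)
    if not n_usable:
        raise ValueError("no usable mutation sites")
    counts = np.zeros(2 * W + 1, dtype=np.int64)
    for chrom, muts in muts_by_chrom.items():
        snps = snp_index.get(chrom)
        if snps is None or len(snps) == 0:
            continue
        lo = np.searchsorted(snps, muts - W)
        hi = np.searchsorted(snps, muts + W, side="right")
        lengths = hi - lo
        total = int(lengths.sum())
        if total == 0:
            continue
        starts = np.repeat(lo, lengths)
        cum = np.concatenate(([0], np.cumsum(lengths)[:-1]))
        within = np.arange(total) - np.repeat(cum, lengths)
        offs = snps[starts + within] - np.repeat(muts, lengths) + W
        counts += np.bincount(offs, minlength=2 * W + 1)
    return PositionalDensity(
        offsets=make_offsets(W),
        density=counts / n_usable,
        n_mutations=n_usable,
    )


def positional_null(
    density: PositionalDensity,
    exclusion_radius: int = DEFAULT_EXCLUSION_RADIUS,
) -> tuple[float, float]:
    """Null mean and standard deviation from flank offsets |d| > radius."""
    flank = density.density[np.abs(density.offsets) > exclusion_radius]
    if len(flank) < 2:
        raise ValueError("exclusion radius leaves fewer than two flank offsets")
    return float(np.mean(flank)), float(np.std(flank, ddof=1))


def positional_z_test(
    density: PositionalDensity,
    u: float,
    s: float,
    alpha: float = 0.05,
    bonferroni: bool = True,
) -> PositionalTest:
    """Per-offset z = (density - u)/s with two-sided normal p-values.

    With ``bonferroni=True`` the significance threshold is alpha divided by
    the number of offsets tested.
    """
    if s <= 0:
        raise ValueError(
            "null standard deviation must be positive; widen the null region"
        )
    z = (density.density - u) / s
    p = 2.0 * norm.sf(np.abs(z))
    n_tests = len(density.offsets)
    alpha_per_test = alpha / n_tests if bonferroni else alpha
    significant = p < alpha_per_test
    return PositionalTest(
        z=z,
        p=p,
        enriched_offsets=density.offsets[significant & (z > 0)],
        depleted_offsets=density.offsets[significant & (z < 0)],
        alpha=alpha,
        alpha_per_test=alpha_per_test,
    )


def fold_report(
    density: PositionalDensity,
    u: float,
    positions: tuple[int, ...] = (-1, 0, 1),
) -> dict[int, float]:
    """Fold change density/u at the requested offsets."""
    if u <= 0:
        raise ValueError("null mean must be positive for fold changes")
    return {d: density.at(d) / u for d in positions}
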