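"""Substitution spectra and between-set comparison.

The six unordered substitution types are A/G and C/T (transitions) and
G/T, A/C, C/G, A/T (transversions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from scipy.stats import norm

from .genomic_io import BASES, SnpRecord

SUBSTITUTION_TYPES: tuple[str, ...] = ("A/G", "C/T", "A/C", "A/T", "C/G", "G/T")
TRANSITION_TYPES = frozenset({"A/G", "C/T"})


def classify_substitution(a1: str, a2: str) -> tuple[str, bool]:
    """Canonical unordered substitution type and whether it is a transition."""
    a1, a2 = str(a1).upper(), str(a2).upper()
    if a1 not in BASES or a2 not in BASES:
        raise ValueError(f"alleles must be in {sorted(BASES)}, got ({a1!r}, {a2!r})")
    if a1 == a2:
        raise ValueError(f"alleles must differ, got ({a1!r}, {a2!r})")
    subst = "/".join(sorted((a1, a2)))
    return subst, subst in TRANSITION_TYPES


@dataclass
class SubstitutionSpectrum:
    counts: dict[str, int]
    n_total: int
    n_excluded: int

    @property
    def fractions(self) -> dict[str, float]:
        return {t: self.counts[t] / self.n_total for t in SUBSTITUTION_TYPES}

    @property
    def ts_fraction(self) -> float:
        return sum(self.counts[t] for t in TRANSITION_TYPES) / self.n_total

    @property
    def tv_fraction(self) -> float:
        return 1.0 - self.ts_fraction

    @property
    def ts_tv_ratio(self) -> float:
        n_ts = sum(self.counts[t] for t in TRANSITION_TYPES)
        n_tv = self.n_total - n_ts
        return math.inf if n_tv == 0 else n_ts / n_tv


def substitution_spectrum(snps: Iterable[SnpRecord]) -> SubstitutionSpectrum:
    """Count the six substitution types over records with valid allele pairs.

    Records without a valid distinct-base allele pair are excluded and
    counted in ``n_excluded``.  An empty valid set is an error.
    """
    counts = {t: 0 for t in SUBSTITUTION_TYPES}
    n_excluded = 0
    for rec in snps:
        if not rec.has_valid_alleles:
            n_excluded += 1
            continue
        subst, _ = classify_substitution(*rec.observed_alleles)
        counts[subst] += 1
    n_total = sum(counts.values())
    if n_total == 0:
        raise ValueError("no records with valid allele pairs; cannot form a spectrum")
    return SubstitutionSpectrum(counts, n_total, n_excluded)


def compare_spectra(
    spec_a: SubstitutionSpectrum, spec_b: SubstitutionSpectrum
) -> dict[str, tuple[float, float]]:
    """Pooled two-proportion Z-test per substitution type, two-sided.

    Returns ``{type: (z, p)}`` with ``z = (f_a - f_b) / se`` where the
    standard error uses the pooled proportion.  Degenerate pooled
    proportions (0 or 1) give ``z = 0, p = 1``.
    """
    n_a, n_b = spec_a.n_total, spec_b.n_total
    if n_a == 0 or n_b == 0:
        raise ValueError("both spectra must have a positive total count")
    out: dict[str, tuple[float, float]] = {}
    for subst in SUBSTITUTION_TYPES:
        c_a, c_b = spec_a.counts[subst], spec_b.counts[subst]
        pooled = (c_a + c_b) / (n_a + n_b)
        se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n_a + 1.0 / n_b))
        if se == 0.0:
            out[subst] = (0.0, 1.0)
            continue
        z = (c_a / n_a - c_b / n_b) / se
        p = 2.0 * float(norm.sf(abs(z)))
        out[subst] = (z, min(p, 1.0))
    return out
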