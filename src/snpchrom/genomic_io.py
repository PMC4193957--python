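"""Readers and writers for the on-disk formats used throughout the package.

All genomic coordinates are 0-based and half-open internally.  Conversions
from 1-based dialects happen in the readers and nowhere else.  A SNP or
mutation site occupies the single base at index ``pos``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

BASES = frozenset("ACGT")
STRANDS = ("+", "-", ".")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class GenomicSite:
    """A single genomic base position (0-based)."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if self.pos < 0:
            raise ValueError(f"pos must be >= 0, got {self.pos}")


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A stranded interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Position of the 5' end: ``start`` for +/unstranded, ``end - 1`` for -."""
        return self.end - 1 if self.strand == "-" else self.start


@dataclass(frozen=True, slots=True)
class SnpRecord:
    """One SNP site with alleles, functional category and labels.

    ``observed_alleles`` is ``None`` when the allele string could not be
    parsed into two single bases; such records are flagged for exclusion by
    :attr:`has_valid_alleles` rather than raising at parse time.
    """

    site: GenomicSite
    observed_alleles: tuple[str, str] | None
    variant_class: str = "single"
    func_category: str = ""
    validated: bool = False
    risk_label: str = "other"

    @property
    def has_valid_alleles(self) -> bool:
        a = self.observed_alleles
        return (
            a is not None
            and len(a) == 2
            and a[0] in BASES
            and a[1] in BASES
            and a[0] != a[1]
        )


@dataclass
class TagSet:
    """A collection of stranded intervals from a sequencing experiment."""

    intervals: list[GenomicInterval]
    source_label: str = ""

    @property
    def total_tag_count(self) -> int:
        return len(self.intervals)


@dataclass
class MethylationTrack:
    """Per-position mean methylation percentages in [0, 100]."""

    sites: list[tuple[GenomicSite, float]]

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Sorted ``{chrom: (positions, levels)}`` arrays for fast lookup."""
        grouped: dict[str, list[tuple[int, float]]] = {}
        for site, level in self.sites:
            grouped.setdefault(site.chrom, []).append((site.pos, level))
        out = {}
        for chrom, pairs in grouped.items():
            pairs.sort()
            pos = np.array([p for p, _ in pairs], dtype=np.int64)
            lev = np.array([v for _, v in pairs], dtype=float)
            out[chrom] = (pos, lev)
        return out


@dataclass
class GenomeSequence:
    """Per-chromosome base strings over {A, C, G, T, N}."""

    sequences: dict[str, str]
    _arrays: dict[str, np.ndarray] = field(
        default_factory=dict, repr=False, compare=False
    )

    @property
    def lengths(self) -> dict[str, int]:
        return {chrom: len(seq) for chrom, seq in self.sequences.items()}

    def base_array(self, chrom: str) -> np.ndarray:
        """The chromosome as a uint8 array of ASCII codes (cached)."""
        if chrom not in self._arrays:
            self._arrays[chrom] = np.frombuffer(
                self.sequences[chrom].encode("ascii"), dtype=np.uint8
            )
        return self._arrays[chrom]


@dataclass(frozen=True, slots=True)
class ProfileNormalization:
    """How a profile's raw counts were scaled."""

    genome_coverage_divisor: float = 1.0
    per_anchor_averaged: bool = False
    shift_used: int = 0


@dataclass(eq=False)
class Profile:
    """A position-indexed vector over offsets -W..+W relative to anchors."""

    offsets: np.ndarray
    values: np.ndarray
    n_anchors: int
    normalization: ProfileNormalization = ProfileNormalization()

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.offsets) != len(self.values):
            raise ValueError("offsets and values must have equal length")
        if len(self.offsets) % 2 != 1:
            raise ValueError("profile must span -W..+W (odd length)")

    @property
    def half_window(self) -> int:
        return (len(self.offsets) - 1) // 2

    def value_at(self, offset: int) -> float:
        return float(self.values[offset + self.half_window])

    def equals(self, other: "Profile") -> bool:
        return (
            np.array_equal(self.offsets, other.offsets)
            and np.array_equal(self.values, other.values)
            and self.n_anchors == other.n_anchors
            and self.normalization == other.normalization
        )


def make_offsets(half_window: int) -> np.ndarray:
    return np.arange(-half_window, half_window + 1, dtype=np.int64)


# ---------------------------------------------------------------------------
# SNP tables
# ---------------------------------------------------------------------------

_SNP_COLUMN_SYNONYMS: dict[str, tuple[str, ...]] = {
    "chrom": ("chrom", "chr", "chromosome"),
    "pos": ("chromStart", "pos", "position", "start"),
    "alleles": ("observed", "alleles", "allele"),
    "class": ("class", "variant_class", "varClass"),
    "func": ("func", "func_category", "function"),
    "valid": ("valid", "validated", "validation", "valid_status"),
}

_FALSY_VALIDATION = {"", "unknown", "nan", "none", "0", "false", "no"}


def parse_alleles(text: str) -> tuple[str, str] | None:
    """Parse a slash-separated allele pair like ``"A/G"``.

    Returns ``None`` for anything that is not exactly two single-character
    fields (multi-base alleles, indel notation, missing data).  Validity of
    the bases themselves is checked by :attr:`SnpRecord.has_valid_alleles`.
    """
    parts = [p.strip().upper() for p in str(text).split("/")]
    if len(parts) != 2 or any(len(p) != 1 for p in parts):
        return None
    return (parts[0], parts[1])


def _parse_validated(text: str) -> bool:
    return str(text).strip().lower() not in _FALSY_VALIDATION


def _resolve_column(columns: Sequence[str], key: str) -> str:
    for candidate in _SNP_COLUMN_SYNONYMS[key]:
        if candidate in columns:
            return candidate
    raise ValueError(
        f"SNP table is missing a required column for {key!r}; "
        f"expected one of {_SNP_COLUMN_SYNONYMS[key]}"
    )


def read_snp_table(path: str | Path, one_based: bool = False) -> list[SnpRecord]:
    """Read a UCSC-dump-style SNP TSV into :class:`SnpRecord` objects.

    The table must have a header with columns for chromosome, position,
    observed alleles (``A/G``), variant class, functional category and
    validation status (synonym lists accepted).  Positions are 0-based by
    default; pass ``one_based=True`` for 1-based dialects.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    cols = {key: _resolve_column(list(df.columns), key) for key in _SNP_COLUMN_SYNONYMS}
    shift = 1 if one_based else 0
    records = []
    for row in df.itertuples(index=False):
        row_d = dict(zip(df.columns, row))
        records.append(
            SnpRecord(
                site=GenomicSite(str(row_d[cols["chrom"]]), int(row_d[cols["pos"]]) - shift),
                observed_alleles=parse_alleles(row_d[cols["alleles"]]),
                variant_class=str(row_d[cols["class"]]).strip(),
                func_category=str(row_d[cols["func"]]).strip(),
                validated=_parse_validated(row_d[cols["valid"]]),
            )
        )
    return records


def write_snp_table(records: Iterable[SnpRecord], path: str | Path) -> None:
    """Write SNP records as a TSV readable by :func:`read_snp_table`."""
    rows = []
    for rec in records:
        alleles = "/".join(rec.observed_alleles) if rec.observed_alleles else "-"
        rows.append(
            {
                "chrom": rec.site.chrom,
                "chromStart": rec.site.pos,
                "chromEnd": rec.site.pos + 1,
                "observed": alleles,
                "class": rec.variant_class,
                "func": rec.func_category,
                "valid": "by-cluster" if rec.validated else "unknown",
                "risk_label": rec.risk_label,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED-like tag and interval files
# ---------------------------------------------------------------------------

def _iter_bed_rows(path: Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split()


def read_tag_bed(path: str | Path, source_label: str | None = None) -> TagSet:
    """Read sequencing tags from a BED3/BED6 file.

    Rows with ``start >= end`` are rejected with a logged warning; strand is
    taken from column 6 when present, else ``"."``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    intervals = []
    for lineno, fields in _iter_bed_rows(path):
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        if start >= end:
            logger.warning("%s:%d: rejected row with start >= end", path, lineno)
            continue
        strand = fields[5] if len(fields) >= 6 and fields[5] in STRANDS else "."
        intervals.append(GenomicInterval(chrom, start, end, strand))
    return TagSet(intervals, source_label or path.stem)


def write_tag_bed(tags: TagSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in tags.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\ttag\t0\t{iv.strand}\n")


def read_interval_bed(path: str | Path) -> list[GenomicInterval]:
    """Read bound regions (BED3+) as a plain interval list."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    intervals = []
    for lineno, fields in _iter_bed_rows(path):
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        if start >= end:
            logger.warning("%s:%d: rejected row with start >= end", path, lineno)
            continue
        strand = fields[5] if len(fields) >= 6 and fields[5] in STRANDS else "."
        intervals.append(GenomicInterval(chrom, start, end, strand))
    return intervals


# ---------------------------------------------------------------------------
# Site lists and methylation
# ---------------------------------------------------------------------------

def read_site_table(path: str | Path, one_based: bool = False) -> list[GenomicSite]:
    """Read a plain ``chrom<TAB>pos`` site list (mutations, risk sites).

    A single header line is tolerated if its second field is non-numeric.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    shift = 1 if one_based else 0
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                pos = int(fields[1])
            except (IndexError, ValueError):
                if lineno == 1:
                    continue  # header
                raise ValueError(f"{path}:{lineno}: malformed site row {line!r}")
            sites.append(GenomicSite(fields[0], pos - shift))
    return sites


read_mutation_sites = read_site_table


def write_site_table(sites: Iterable[GenomicSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\n")
        for site in sites:
            fh.write(f"{site.chrom}\t{site.pos}\n")


def read_methylation_table(path: str | Path) -> MethylationTrack:
    """Read a ``chrom pos level`` table; levels outside [0, 100] are rejected."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                pos, level = int(fields[1]), float(fields[2])
            except (IndexError, ValueError):
                if lineno == 1:
                    continue  # header
                raise ValueError(f"{path}:{lineno}: malformed methylation row")
            if not 0.0 <= level <= 100.0:
                logger.warning(
                    "%s:%d: rejected methylation level %s outside [0, 100]",
                    path, lineno, level,
                )
                continue
            sites.append((GenomicSite(fields[0], pos), level))
    return MethylationTrack(sites)


def write_methylation_table(track: MethylationTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tlevel\n")
        for site, level in track.sites:
            fh.write(f"{site.chrom}\t{site.pos}\t{float(level)!r}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome_fasta(path: str | Path) -> GenomeSequence:
    """Read a genome FASTA; bases are upper-cased, N is accepted."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sequences = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    return GenomeSequence(sequences)


def write_genome_fasta(genome: GenomeSequence, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in genome.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Profile TSVs
# ---------------------------------------------------------------------------

def write_profile_tsv(profile: Profile, path: str | Path) -> None:
    """Write a profile as offset/value TSV with a metadata comment header.

    Floats are written with ``repr`` so the write -> read round trip is the
    identity.
    """
    norm = profile.normalization
    with open(path, "w") as fh:
        fh.write(f"# n_anchors={profile.n_anchors}\n")
        fh.write(f"# genome_coverage_divisor={norm.genome_coverage_divisor!r}\n")
        fh.write(f"# per_anchor_averaged={norm.per_anchor_averaged}\n")
        fh.write(f"# shift_used={norm.shift_used}\n")
        fh.write("offset\tvalue\n")
        for off, val in zip(profile.offsets, profile.values):
            fh.write(f"{int(off)}\t{float(val)!r}\n")


def read_profile_tsv(path: str | Path) -> Profile:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict[str, str] = {}
    offsets, values = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
                continue
            if line.startswith("offset"):
                continue
            off, val = line.split("\t")
            offsets.append(int(off))
            values.append(float(val))
    norm = ProfileNormalization(
        genome_coverage_divisor=float(meta.get("genome_coverage_divisor", 1.0)),
        per_anchor_averaged=meta.get("per_anchor_averaged", "False") == "True",
        shift_used=int(meta.get("shift_used", 0)),
    )
    return Profile(
        offsets=np.array(offsets, dtype=np.int64),
        values=np.array(values, dtype=float),
        n_anchors=int(meta.get("n_anchors", 0)),
        normalization=norm,
    )
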