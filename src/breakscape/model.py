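"""Shared genomic data model.

Coordinates are 0-based, half-open (BED convention) throughout. Positions
quoted from 1-based sources must be converted on ingestion (subtract 1 from
starts). Strand is stored but never interpreted by distance computations.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

STRANDS = ("+", "-", ".")
GENOTYPES = ("WT", "RAD21-", "SMC1A_Pdef", "ATMi", "LIG4-")
DAMAGE_STATES = ("NT", "DSB")

#: AsiSI recognition site; palindromic, so one scan of the forward strand
#: reports every cuttable position exactly once.
ASISI_MOTIF = "GCGATCGC"

CHIP_FACTORS = ("MRE11", "RAD21", "CTCF", "GH2AX")


class ValidationError(ValueError):
    """Raised when a domain-model invariant is violated."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start {self.start}")
        if self.start >= self.end:
            raise ValidationError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GenomeLayout:
    """Chromosome naming, lengths and (optionally) sequence."""

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValidationError("duplicate chromosome names")
        for name in self.chrom_names:
            if name not in self.chrom_lengths:
                raise ValidationError(f"no length for chromosome {name}")
            if self.chrom_lengths[name] <= 0:
                raise ValidationError(f"non-positive length for {name}")
        if self.sequences is not None:
            for name, seq in self.sequences.items():
                if len(seq) != self.chrom_lengths[name]:
                    raise ValidationError(
                        f"sequence length {len(seq)} != chromosome length "
                        f"{self.chrom_lengths[name]} for {name}"
                    )

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return math.ceil(self.chrom_lengths[chrom] / bin_size)

    def check_interval(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self.chrom_lengths:
            raise ValidationError(f"unknown chromosome {iv.chrom}")
        if iv.end > self.chrom_lengths[iv.chrom]:
            raise ValidationError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self.chrom_lengths[iv.chrom]}"
            )


@dataclass(frozen=True)
class DSBSite:
    """An (inducible) double-strand break site.

    ``cut`` has width 8 for a genuine AsiSI motif occurrence, or width 1 for
    an abstract break position.
    """

    id: str
    cut: GenomicInterval
    is_bait: bool = False

    @property
    def chrom(self) -> str:
        return self.cut.chrom

    @property
    def midpoint(self) -> int:
        return self.cut.midpoint


@dataclass(frozen=True)
class SignalPeak:
    """A called ChIP peak (summit plus spanning interval)."""

    interval: GenomicInterval
    summit: int
    signal: float

    def __post_init__(self) -> None:
        if not self.interval.start <= self.summit < self.interval.end:
            raise ValidationError("summit outside peak interval")
        if self.signal < 0:
            raise ValidationError("negative peak signal")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class CoverageTrack:
    """Binned per-chromosome signal in rpkm-like density units."""

    bin_size: int
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValidationError("bin_size must be positive")
        for chrom, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if (arr < 0).any():
                raise ValidationError(f"negative coverage on {chrom}")
            self.values[chrom] = arr

    def chroms(self) -> list[str]:
        return list(self.values)

    def mean_over(self, iv: GenomicInterval) -> float:
        """Per-bp mean signal over an interval (bins weighted by overlap)."""
        v = self.values[iv.chrom]
        bs = self.bin_size
        end = min(iv.end, len(v) * bs)
        if end <= iv.start:
            raise ValidationError("interval outside track")
        idx = np.arange(iv.start // bs, (end - 1) // bs + 1)
        lo = np.maximum(iv.start, idx * bs)
        hi = np.minimum(end, (idx + 1) * bs)
        return float((v[idx] * (hi - lo)).sum() / (end - iv.start))


@dataclass(frozen=True)
class DamageDomain:
    """A TAD or γH2AX interval, flagged damaged when it holds >=1 DSB."""

    interval: GenomicInterval
    kind: str  # "TAD" or "GH2AX"
    damaged: bool

    def __post_init__(self) -> None:
        if self.kind not in ("TAD", "GH2AX"):
            raise ValidationError(f"unknown domain kind {self.kind!r}")

    @property
    def id(self) -> str:
        return (
            f"{self.kind}:{self.interval.chrom}:"
            f"{self.interval.start}-{self.interval.end}"
        )


@dataclass
class ContactMatrix:
    """Binned ligation-frequency matrix for one chromosome (pair).

    Counts are floats: normalized matrices are fractional, and O/E matrices
    may carry NaN where the expected value is zero (masked entries).
    """

    chrom_a: str
    chrom_b: str
    resolution: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if self.resolution <= 0:
            raise ValidationError("resolution must be positive")
        if np.nanmin(self.counts, initial=0.0) < 0:
            raise ValidationError("negative contact count")
        if self.is_intra and self.counts.shape[0] != self.counts.shape[1]:
            raise ValidationError("intra-chromosomal matrix must be square")

    @property
    def is_intra(self) -> bool:
        return self.chrom_a == self.chrom_b

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def bin_of(self, pos: int) -> int:
        return pos // self.resolution


@dataclass(frozen=True)
class JunctionRecord:
    """One HTGTS bait->prey junction with junction-flanking sequence."""

    read_id: str
    bait_chrom: str
    bait_pos: int
    bait_strand: str
    prey_chrom: str
    prey_pos: int
    prey_strand: str
    bait_flank: str  # ends at the junction point
    prey_flank: str  # starts at the junction point
    label: str | None = None

    def __post_init__(self) -> None:
        for strand in (self.bait_strand, self.prey_strand):
            if strand not in ("+", "-"):
                raise ValidationError(f"invalid junction strand {strand!r}")
        for flank in (self.bait_flank, self.prey_flank):
            if set(flank) - set("ACGTN"):
                raise ValidationError(f"invalid flank sequence {flank!r}")


@dataclass(frozen=True)
class ConditionLabel:
    """Experimental condition: damage state x genotype."""

    damage: str
    genotype: str

    def __post_init__(self) -> None:
        if self.damage not in DAMAGE_STATES:
            raise ValidationError(f"unknown damage state {self.damage!r}")
        if self.genotype not in GENOTYPES:
            raise ValidationError(f"unknown genotype {self.genotype!r}")


def min_distance(point: int, sites: list[DSBSite]) -> int:
    """Minimum distance (bp) from ``point`` to any site's cut midpoint.

    A point lying inside a cut interval is at distance 0. The caller is
    responsible for restricting ``sites`` to the relevant chromosome.
    """
    if not sites:
        raise ValidationError("min_distance over an empty site list")
    best = None
    for site in sites:
        if site.cut.contains(point):
            return 0
        d = abs(point - site.midpoint)
        if best is None or d < best:
            best = d
    return best


def find_asisi_sites(layout: GenomeLayout) -> list[DSBSite]:
    """All AsiSI motif occurrences in the layout's sequence, sorted.

    The motif is its own reverse complement, so forward-strand occurrences
    enumerate every site once. 'N' never matches.
    """
    if layout.sequences is None:
        raise ValidationError("layout carries no sequence")
    sites: list[DSBSite] = []
    for chrom in layout.chrom_names:
        seq = layout.sequences.get(chrom, "")
        pos = seq.find(ASISI_MOTIF)
        while pos != -1:
            sites.append(
                DSBSite(
                    id=f"asisi_{chrom}_{pos}",
                    cut=GenomicInterval(chrom, pos, pos + len(ASISI_MOTIF)),
                )
            )
            pos = seq.find(ASISI_MOTIF, pos + 1)
    return sites


def rpkm_normalize(read_count: float, window_bp: int, library_size: float) -> float:
    """Reads per kb of window per million mapped reads."""
    if read_count < 0:
        raise ValidationError("negative read count")
    if window_bp <= 0 or library_size <= 0:
        raise ValidationError("window and library size must be positive")
    return read_count / ((window_bp / 1000.0) * (library_size / 1e6))
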