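"""Readers and writers for the plain-text formats the pipeline touches.

Formats: BED3/BED6, grid-aligned bedGraph, contact triplets (straw-dump
style with a ``#resolution=<bp>`` header line), a junction TSV and FASTA.
All readers validate eagerly and name the offending line in errors; all
reader/writer pairs are mutual inverses on canonical forms.
"""
from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    ContactMatrix,
    CoverageTrack,
    GenomeLayout,
    GenomicInterval,
    JunctionRecord,
    ValidationError,
)


class ParseError(ValueError):
    """Raised on malformed input, naming the file and line number."""


JUNCTION_COLUMNS = [
    "read_id",
    "bait_chrom",
    "bait_pos",
    "bait_strand",
    "prey_chrom",
    "prey_pos",
    "prey_strand",
    "bait_flank",
    "prey_flank",
]

_FLANK_RE = re.compile(r"^[ACGTN]+$")


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """BED3/BED6 (tab-separated) -> intervals, preserving name/score."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}, line {lineno}: expected >=3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from None
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError:
                    raise ParseError(
                        f"{path}, line {lineno}: bad score {fields[4]!r}"
                    ) from None
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, strand, name, score)
                )
            except ValidationError as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from None
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                fields += [
                    iv.name if iv.name is not None else ".",
                    repr(iv.score) if iv.score is not None else ".",
                    iv.strand,
                ]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# bedGraph

def read_bedgraph(
    path: str | Path, bin_size: int, layout: GenomeLayout
) -> CoverageTrack:
    """Grid-aligned bedGraph -> CoverageTrack; unlisted bins are zero."""
    values = {
        chrom: np.zeros(layout.n_bins(chrom, bin_size))
        for chrom in layout.chrom_names
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}, line {lineno}: expected 4 fields")
            chrom = fields[0]
            if chrom not in layout.chrom_lengths:
                raise ParseError(f"{path}, line {lineno}: unknown chromosome {chrom}")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from None
            chrom_len = layout.chrom_lengths[chrom]
            expected_end = min(start + bin_size, chrom_len)
            if start % bin_size != 0 or end != expected_end:
                raise ParseError(
                    f"{path}, line {lineno}: record {start}-{end} not aligned "
                    f"to the {bin_size} bp bin grid"
                )
            if value < 0:
                raise ParseError(f"{path}, line {lineno}: negative value")
            values[chrom][start // bin_size] = value
    return CoverageTrack(bin_size=bin_size, values=values)


def write_bedgraph(
    track: CoverageTrack, path: str | Path, layout: GenomeLayout
) -> None:
    """Non-zero bins only; values formatted for exact float round-trip."""
    bs = track.bin_size
    with open(path, "w") as fh:
        for chrom in layout.chrom_names:
            if chrom not in track.values:
                continue
            v = track.values[chrom]
            chrom_len = layout.chrom_lengths[chrom]
            for b in np.nonzero(v)[0]:
                start = int(b) * bs
                end = min(start + bs, chrom_len)
                fh.write(f"{chrom}\t{start}\t{end}\t{float(v[b])!r}\n")


# ---------------------------------------------------------------------------
# contact triplets

def read_contacts(
    path: str | Path,
    resolution: int | None,
    layout: GenomeLayout,
) -> dict[tuple[str, str], ContactMatrix]:
    """Dump-style triplets -> matrices keyed by (chrom_a, chrom_b).

    Intra-chromosomal entries are symmetrized (each listed count is
    assigned to both (i, j) and (j, i)); unlisted pairs are zero.
    """
    header_res = None
    entries: list[tuple[str, int, str, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*resolution\s*=\s*(\d+)", line)
                if m:
                    header_res = int(m.group(1))
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(f"{path}, line {lineno}: expected 5 fields")
            ca, cb = fields[0], fields[2]
            for chrom in (ca, cb):
                if chrom not in layout.chrom_lengths:
                    raise ParseError(
                        f"{path}, line {lineno}: unknown chromosome {chrom}"
                    )
            try:
                sa, sb, count = int(fields[1]), int(fields[3]), float(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from None
            if count < 0:
                raise ParseError(f"{path}, line {lineno}: negative count")
            entries.append((ca, sa, cb, sb, count))

    if header_res is None and resolution is None:
        raise ParseError(f"{path}: no #resolution header and none supplied")
    if header_res is not None and resolution is not None and header_res != resolution:
        raise ParseError(
            f"{path}: header resolution {header_res} != requested {resolution}"
        )
    res = header_res if header_res is not None else resolution

    order = {c: i for i, c in enumerate(layout.chrom_names)}
    matrices: dict[tuple[str, str], ContactMatrix] = {}
    for ca, sa, cb, sb, count in entries:
        if sa % res != 0 or sb % res != 0:
            raise ParseError(f"{path}: start {sa} or {sb} not on the {res} bp grid")
        if order[ca] > order[cb]:
            ca, sa, cb, sb = cb, sb, ca, sa
        key = (ca, cb)
        if key not in matrices:
            matrices[key] = ContactMatrix(
                ca,
                cb,
                res,
                np.zeros((layout.n_bins(ca, res), layout.n_bins(cb, res))),
            )
        m = matrices[key]
        i, j = sa // res, sb // res
        if i >= m.shape[0] or j >= m.shape[1]:
            raise ParseError(f"{path}: bin start {sa}/{sb} beyond chromosome end")
        m.counts[i, j] = count
        if m.is_intra:
            m.counts[j, i] = count
    return matrices


def write_contacts(
    matrices: Iterable[ContactMatrix], path: str | Path
) -> None:
    """Canonical triplet dump: upper triangle for intra, sorted, no zeros."""
    matrices = list(matrices)
    resolutions = {m.resolution for m in matrices}
    if len(resolutions) != 1:
        raise ValidationError(f"mixed resolutions {sorted(resolutions)}")
    res = resolutions.pop()
    with open(path, "w") as fh:
        fh.write(f"#resolution={res}\n")
        for m in sorted(matrices, key=lambda m: (m.chrom_a, m.chrom_b)):
            if m.is_intra:
                ii, jj = np.triu_indices(m.shape[0])
            else:
                ii, jj = np.indices(m.shape).reshape(2, -1)
            vals = m.counts[ii, jj]
            keep = vals != 0
            for i, j, v in zip(ii[keep], jj[keep], vals[keep]):
                fh.write(
                    f"{m.chrom_a}\t{int(i) * res}\t{m.chrom_b}\t{int(j) * res}\t{float(v)!r}\n"
                )


# ---------------------------------------------------------------------------
# junction TSV

def read_junctions(path: str | Path) -> list[JunctionRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in JUNCTION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing junction columns {missing}")
    records: list[JunctionRecord] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                JunctionRecord(
                    read_id=row.read_id,
                    bait_chrom=row.bait_chrom,
                    bait_pos=int(row.bait_pos),
                    bait_strand=row.bait_strand,
                    prey_chrom=row.prey_chrom,
                    prey_pos=int(row.prey_pos),
                    prey_strand=row.prey_strand,
                    bait_flank=row.bait_flank,
                    prey_flank=row.prey_flank,
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ParseError(f"{path}, line {lineno}: {exc}") from None
        if not _FLANK_RE.match(records[-1].bait_flank) or not _FLANK_RE.match(
            records[-1].prey_flank
        ):
            raise ParseError(f"{path}, line {lineno}: invalid flank sequence")
    return records


def write_junctions(records: Iterable[JunctionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(JUNCTION_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.read_id}\t{r.bait_chrom}\t{r.bait_pos}\t{r.bait_strand}\t"
                f"{r.prey_chrom}\t{r.prey_pos}\t{r.prey_strand}\t"
                f"{r.bait_flank}\t{r.prey_flank}\n"
            )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# plain-text manifest (ground truth, run parameters)

def write_manifest(items: dict[str, object], path: str | Path) -> None:
    with open(path, "w") as fh:
        for key in items:
            fh.write(f"{key}={items[key]}\n")


def read_manifest(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            out[key] = value
    return out
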