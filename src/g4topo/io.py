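"""Readers and writers for the standard formats the pipeline touches.

FASTA via Biopython, VCF via pysam, MAF via Bio.AlignIO; BED is parsed
directly because the methylation dialect (a designated level column) and
per-line rejection with logged counts need finer control than a table
reader gives.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import pysam
from Bio import SeqIO

from .intervals import GenomicInterval

log = logging.getLogger("g4topo")

_ALPHABET = set("ACGTN")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def load_genome(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into ``{chrom: uppercase sequence}``.

    Sequences are uppercased and restricted to the A/C/G/T/N alphabet
    (other IUPAC codes are mapped to N). Record order is preserved.
    """
    genome: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            if set(seq) - _ALPHABET:
                seq = "".join(c if c in _ALPHABET else "N" for c in seq)
            genome[rec.id] = seq
    if not genome:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


def write_genome(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class MethylCall:
    """A per-site methylation call: a position and a level in [0, 1]."""

    position: GenomicInterval
    level: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.level <= 1.0):
            raise ValueError(f"methylation level {self.level} outside [0, 1]")


def load_intervals(
    path: str | Path, min_cols: int = 3
) -> list[GenomicInterval]:
    """Load a BED file into sorted GenomicIntervals (0-based half-open).

    Lines with ``start >= end`` are rejected with a logged warning; a
    non-numeric coordinate is a parse error.
    """
    out: list[GenomicInterval] = []
    rejected = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < min_cols:
                raise ValueError(f"{path}:{lineno}: expected >= {min_cols} columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinate") from exc
            if start >= end:
                rejected += 1
                log.warning("%s:%d: rejected empty/inverted interval [%d, %d)", path, lineno, start, end)
                continue
            strand = cols[5] if len(cols) >= 6 and cols[5] in "+-." else "."
            out.append(GenomicInterval(cols[0], start, end, strand))
    log.info("loaded %d intervals from %s (%d rejected)", len(out), path, rejected)
    return sorted(out, key=lambda iv: (iv.chrom, iv.start, iv.end))


def load_methylation(
    path: str | Path, level_col: int = 3
) -> list[MethylCall]:
    """Load per-CpG methylation from a BED dialect.

    ``level_col`` is the 0-based column carrying the methylation fraction
    (the dialect varies between callers, hence the override). Values given
    as percentages (> 1) are divided by 100.
    """
    calls: list[MethylCall] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            start, end = int(cols[1]), int(cols[2])
            if start >= end:
                log.warning("%s:%d: rejected empty interval", path, lineno)
                continue
            level = float(cols[level_col])
            if level > 1.0:
                level /= 100.0
            calls.append(MethylCall(GenomicInterval(cols[0], start, end), level))
    return sorted(calls, key=lambda c: (c.position.chrom, c.position.start))


def write_intervals(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """Write BED3 (or BED6 when names/scores given; score col x100, rounded)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if names is None and scores is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = names[i] if names is not None else "."
                score = round(scores[i] * 100) if scores is not None else 0
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


@dataclass
class RawVariant:
    """One VCF record before multi-allelic splitting (1-based pos converted)."""

    chrom: str
    pos: int  # 0-based position of the first REF base
    ref: str
    alts: tuple[str, ...]
    afs: tuple[float | None, ...]  # per-ALT allele frequency, None if absent


def load_variants(path: str | Path) -> Iterator[RawVariant]:
    """Stream raw records from a VCF 4.x file (multi-allelic preserved).

    No chromosome filtering happens here: exclusion (e.g. chrY) is a
    downstream decision. Records lacking REF or ALT are skipped with a
    warning.
    """
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.ref is None or not rec.alts:
                log.warning("skipping VCF record at %s:%s with missing REF/ALT", rec.chrom, rec.pos)
                continue
            af = rec.info.get("AF")
            if af is None:
                afs: tuple[float | None, ...] = (None,) * len(rec.alts)
            else:
                if not isinstance(af, tuple):
                    af = (af,)
                afs = tuple(float(x) if x is not None else None for x in af)
                if len(afs) != len(rec.alts):
                    afs = (afs + (None,) * len(rec.alts))[: len(rec.alts)]
            yield RawVariant(rec.chrom, rec.pos - 1, rec.ref, tuple(rec.alts), afs)
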