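"""Detection of potential G4-forming sequences.

Two detectors are provided, mirroring the two standard approaches:

* a consensus-motif scan for ``G{>=3}(N{1-7}G{>=3}){>=3}`` (loops may
  contain G — a long G-run may be split into run/loop/run by regex
  backtracking, which is what lets e.g. a 7-G run serve as the junction of
  two quartet runs), with the complementary C-pattern reported on the
  minus strand;
* G4Hunter window scoring: each base in a G-run of length n scores
  +min(n, 4), each base in a C-run scores -min(n, 4), A/T/N score 0, and
  width-w windows whose mean absolute score reaches the threshold are
  merged into candidate regions.

Overlapping calls are merged strand-agnostically into a MergedG4Set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .intervals import GenomicInterval, merge_intervals

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class G4Motif:
    """A detected G4 candidate: interval, sequence, detection method, score."""

    interval: GenomicInterval
    sequence: str  # plus-strand genomic sequence of the interval
    method: str  # {"consensus", "g4hunter"}
    score: float | None  # G4Hunter mean base score; None for consensus
    strand: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.interval):
            raise ValueError("sequence length does not match interval length")


@dataclass
class MergedG4Set:
    """Sorted, non-overlapping union of G4 calls with per-interval provenance."""

    intervals: list[GenomicInterval]
    provenance: list[frozenset[str]] = field(default_factory=list)

    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)


def _consensus_pattern(base: str, min_run: int, loop_min: int, loop_max: int) -> re.Pattern:
    run = f"{base}{{{min_run},}}"
    loop = f"[ACGTN]{{{loop_min},{loop_max}}}"
    return re.compile(f"{run}(?:{loop}{run}){{3,}}")


def _scan_one_strand(
    seq: str, chrom: str, base: str, strand: str,
    min_run: int, loop_min: int, loop_max: int,
) -> list[tuple[int, int]]:
    """Return merged maximal-match spans of the run pattern anchored at every
    run start (not just the non-overlapping leftmost matches)."""
    pat = _consensus_pattern(base, min_run, loop_min, loop_max)
    spans: list[tuple[int, int]] = []
    # candidate anchors: starts of maximal base-runs of length >= min_run
    for m in re.finditer(f"{base}{{{min_run},}}", seq):
        a = m.start()
        hit = pat.match(seq, a)
        if hit:
            spans.append((a, hit.end()))
    # collapse overlapping spans to maximal extents
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def scan_consensus(
    seq: str,
    chrom: str = "seq",
    min_run: int = 3,
    loop_min: int = 1,
    loop_max: int = 7,
) -> list[G4Motif]:
    """Scan for consensus G4 motifs on both strands.

    Returns maximal matches of G{>=min_run}(N{loop_min-loop_max}G{>=min_run}){>=3}
    on the plus strand and of the complementary C-pattern reported on the
    minus strand. Loop characters may be any base including G.
    """
    out: list[G4Motif] = []
    for base, strand in (("G", "+"), ("C", "-")):
        for s, e in _scan_one_strand(seq, chrom, base, strand, min_run, loop_min, loop_max):
            out.append(
                G4Motif(GenomicInterval(chrom, s, e, strand), seq[s:e], "consensus", None, strand)
            )
    return sorted(out, key=lambda m: (m.interval.start, m.interval.end, m.strand))


def g4hunter_base_scores(seq: str) -> np.ndarray:
    """Per-base G4Hunter scores: +min(n,4) in an n-G run, -min(n,4) in a C run."""
    scores = np.zeros(len(seq), dtype=np.int8)
    for m in re.finditer("G+", seq):
        scores[m.start() : m.end()] = min(m.end() - m.start(), 4)
    for m in re.finditer("C+", seq):
        scores[m.start() : m.end()] = -min(m.end() - m.start(), 4)
    return scores


def g4hunter_detect(
    seq: str,
    chrom: str = "seq",
    window: int = 25,
    threshold: float = 1.5,
    refine: str = "none",
) -> list[G4Motif]:
    """G4Hunter sliding-window detection.

    Width-``window`` windows (step 1) whose mean base score has absolute
    value >= ``threshold`` are retained; runs of consecutive qualifying
    windows merge into one region from the first window's start to the last
    window's end. The region score is the mean base score over the region
    and the strand is the sign of that score. Sequences shorter than the
    window are scored as a single full-length window.
    """
    if window <= 0 or threshold <= 0:
        raise ValueError("window and threshold must be strictly positive")
    n = len(seq)
    if n == 0:
        return []
    scores = g4hunter_base_scores(seq)
    w = min(window, n)
    csum = np.concatenate([[0], np.cumsum(scores, dtype=np.int64)])
    means = (csum[w:] - csum[:-w]) / w  # means[i] = mean over [i, i+w)
    qualifying = np.abs(means) >= threshold
    out: list[G4Motif] = []
    i = 0
    while i < len(qualifying):
        if not qualifying[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(qualifying) and qualifying[j + 1]:
            j += 1
        s, e = i, j + w  # region spans first window start .. last window end
        if refine == "trim-to-runs":
            sign = 1 if means[i] > 0 else -1
            while s < e and np.sign(scores[s]) != sign:
                s += 1
            while e > s and np.sign(scores[e - 1]) != sign:
                e -= 1
        region_score = float((csum[e] - csum[s]) / (e - s))
        strand = "+" if region_score > 0 else "-"
        out.append(
            G4Motif(GenomicInterval(chrom, s, e, strand), seq[s:e], "g4hunter", region_score, strand)
        )
        i = j + 1
    return out


def g4hunter_mean_score(seq: str) -> float:
    """Mean G4Hunter base score over a whole sequence (one full-length window)."""
    if not seq:
        raise ValueError("empty sequence")
    return float(np.mean(g4hunter_base_scores(seq)))


def merge_motifs(motifs: Iterable[G4Motif]) -> MergedG4Set:
    """Merge overlapping/bookended motif intervals, strand-agnostic.

    Total bp is conserved: the merged union covers exactly the union of the
    input motif bp. Provenance records which detection methods contributed
    to each merged interval.
    """
    motifs = list(motifs)
    if not motifs:
        return MergedG4Set([], [])
    chroms = {m.interval.chrom for m in motifs}
    if len(chroms) > 1:
        raise ValueError(f"merge_motifs expects one chromosome, got {sorted(chroms)}")
    ivs = sorted(motifs, key=lambda m: (m.interval.start, m.interval.end))
    merged: list[GenomicInterval] = []
    prov: list[set[str]] = []
    for m in ivs:
        iv = m.interval
        if merged and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
            prov[-1].add(m.method)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
            prov.append({m.method})
    return MergedG4Set(merged, [frozenset(p) for p in prov])


def detect_genome(
    genome: dict[str, str],
    method: str = "both",
    min_run: int = 3,
    loop_min: int = 1,
    loop_max: int = 7,
    window: int = 25,
    threshold: float = 1.5,
    refine: str = "none",
) -> dict[str, MergedG4Set]:
    """Run one or both detectors over a genome and merge per chromosome."""
    if method not in ("consensus", "g4hunter", "both"):
        raise ValueError(f"unknown method {method!r}")
    out: dict[str, MergedG4Set] = {}
    for chrom, seq in genome.items():
        motifs: list[G4Motif] = []
        if method in ("consensus", "both"):
            motifs += scan_consensus(seq, chrom, min_run, loop_min, loop_max)
        if method in ("g4hunter", "both"):
            motifs += g4hunter_detect(seq, chrom, window, threshold, refine)
        out[chrom] = merge_motifs(motifs) if motifs else MergedG4Set([], [])
    return out


def merged_sets_union(per_chrom: dict[str, MergedG4Set]) -> list[GenomicInterval]:
    """Flatten per-chromosome merged sets into one sorted interval list."""
    ivs = [iv for s in per_chrom.values() for iv in s.intervals]
    return merge_intervals(ivs)
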