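"""Matched genomic controls for G4 sequences.

For each G4 the search picks a uniformly random anchor on the same
chromosome, tests the window of identical length there, then shifts the
window alternately +1/-1 bp outward until a segment matches the G4's GC
fraction and CpG/GpC dinucleotide counts within a reciprocal tolerance, or
the attempt budget runs out. Accepted controls overlapping any G4 from
either detection method are discarded afterwards.

Window metrics are evaluated in O(1) per shift from per-chromosome prefix
sums, so the bidirectional scan is cheap even with large attempt budgets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval, intersect, merge_intervals

log = logging.getLogger("g4topo")


@dataclass(frozen=True)
class SequenceMetrics:
    """Length, GC fraction and CpG/GpC dinucleotide counts of a sequence."""

    length: int
    gc: float
    cpg: int
    gpc: int


def sequence_metrics(seq: str) -> SequenceMetrics:
    """Metrics on the given strand; N excluded from the GC denominator."""
    if not seq:
        raise ValueError("empty sequence")
    denom = len(seq) - seq.count("N")
    gc = (seq.count("G") + seq.count("C")) / denom if denom else 0.0
    return SequenceMetrics(len(seq), gc, seq.count("CG"), seq.count("GC"))


def within_tolerance(a: SequenceMetrics, b: SequenceMetrics, tol: float = 0.10) -> bool:
    """Reciprocal tolerance: |a - b| <= tol * max(a, b) for gc, cpg, gpc.

    Lengths must match exactly; zero-vs-zero counts pass, zero-vs-nonzero
    fail (tol * max = tol * nonzero < difference).
    """
    if a.length != b.length:
        return False
    for x, y in ((a.gc, b.gc), (a.cpg, b.cpg), (a.gpc, b.gpc)):
        if x == y == 0:
            continue
        if abs(x - y) > tol * max(x, y):
            return False
    return True


class _ChromIndex:
    """Prefix sums for O(1) window metrics on one chromosome."""

    def __init__(self, seq: str) -> None:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        self.n = len(seq)
        G, C, N = ord("G"), ord("C"), ord("N")
        is_gc = (arr == G) | (arr == C)
        is_n = arr == N
        self.gc_sum = np.concatenate([[0], np.cumsum(is_gc, dtype=np.int64)])
        self.n_sum = np.concatenate([[0], np.cumsum(is_n, dtype=np.int64)])
        cpg = (arr[:-1] == C) & (arr[1:] == G) if self.n > 1 else np.zeros(0, bool)
        gpc = (arr[:-1] == G) & (arr[1:] == C) if self.n > 1 else np.zeros(0, bool)
        self.cpg_sum = np.concatenate([[0], np.cumsum(cpg, dtype=np.int64)])
        self.gpc_sum = np.concatenate([[0], np.cumsum(gpc, dtype=np.int64)])

    def metrics(self, start: int, end: int) -> SequenceMetrics:
        L = end - start
        denom = L - int(self.n_sum[end] - self.n_sum[start])
        gc = (self.gc_sum[end] - self.gc_sum[start]) / denom if denom else 0.0
        # dinucleotide start positions lie in [start, end-1)
        cpg = int(self.cpg_sum[end - 1] - self.cpg_sum[start]) if L > 1 else 0
        gpc = int(self.gpc_sum[end - 1] - self.gpc_sum[start]) if L > 1 else 0
        return SequenceMetrics(L, float(gc), cpg, gpc)


@dataclass
class ControlSet:
    """Up to k control intervals per source G4, none overlapping any G4."""

    pairs: dict[int, list[GenomicInterval]] = field(default_factory=dict)
    success_counts: dict[int, int] = field(default_factory=dict)

    def all_intervals(self) -> list[GenomicInterval]:
        out = [iv for ivs in self.pairs.values() for iv in ivs]
        return sorted(out, key=lambda iv: (iv.chrom, iv.start, iv.end))


def generate_controls(
    genome: dict[str, str],
    g4s: list[GenomicInterval],
    g4_exclusion_union: list[GenomicInterval] | None = None,
    per_g4: int = 2,
    tol: float = 0.10,
    max_attempts: int = 10_000,
    anchors_per_g4: int = 5,
    seed: int = 0,
    disjoint_controls: bool = False,
) -> ControlSet:
    """Bidirectional shifting search for matched controls.

    ``g4_exclusion_union`` is the union of G4 intervals from both detection
    methods; accepted candidates overlapping it are filtered out at the
    end. Controls may overlap each other unless ``disjoint_controls``.
    """
    rng = np.random.default_rng(seed)
    idx: dict[str, _ChromIndex] = {}
    exclusion = merge_intervals(g4_exclusion_union if g4_exclusion_union is not None else g4s)
    out = ControlSet()
    taken: list[GenomicInterval] = []
    for gid, g4 in enumerate(g4s):
        chrom = g4.chrom
        if chrom not in idx:
            idx[chrom] = _ChromIndex(genome[chrom])
        ci = idx[chrom]
        L = len(g4)
        target = ci.metrics(g4.start, g4.end)
        found: list[GenomicInterval] = []
        for _anchor in range(anchors_per_g4):
            if len(found) >= per_g4:
                break
            if ci.n < L:
                break
            anchor = int(rng.integers(0, ci.n - L + 1))
            for k in range(max_attempts):
                # shift sequence 0, +1, -1, +2, -2, ...
                shift = (k + 1) // 2 if k % 2 == 1 else -(k // 2)
                s = anchor + shift
                if s < 0 or s + L > ci.n:
                    continue
                cand = GenomicInterval(chrom, s, s + L)
                if within_tolerance(target, ci.metrics(s, s + L), tol):
                    if disjoint_controls and any(cand.overlap(t) for t in taken):
                        continue
                    found.append(cand)
                    taken.append(cand)
                    break
        out.pairs[gid] = found
        out.success_counts[gid] = len(found)
        if not found:
            log.info("no control found for G4 #%d (%s:%d-%d)", gid, chrom, g4.start, g4.end)
    # drop any control overlapping the G4 exclusion union
    for gid, ivs in out.pairs.items():
        kept = []
        for iv in ivs:
            srt = sorted([iv], key=lambda x: (x.chrom, x.start))
            if not intersect(srt, exclusion, mode="any"):
                kept.append(iv)
        out.pairs[gid] = kept
        out.success_counts[gid] = len(kept)
    n_ok = sum(out.success_counts.values())
    log.info("controls: %d accepted for %d G4s", n_ok, len(g4s))
    return out
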