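"""Germline variant classification and G4 enrichment around mutations.

Variants are classified by a strictly sequential length-based rule table:
equal-length unit alleles are substitutions; equal-length multi-base
alleles are MNPs; a unit reference with a longer alternate is an insertion
(small if the inserted length is <= 50 bp); a reference longer than the
alternate is a deletion (small if <= 50 bp); the remaining case
(multi-base reference, longer alternate) falls through the rule table and
is labelled complex. Multi-allelic records are split one alternate per
record first.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .controls import ControlSet
from .detect import MergedG4Set
from .enrichment import GCEnrichmentModel, gc_fraction, residual_pvalue, adjust_pvalues
from .intervals import GenomicInterval, merge_intervals, total_overlap_bp
from .io import RawVariant

log = logging.getLogger("g4topo")

CLASSES = (
    "substitution", "MNP", "small_insertion", "insertion",
    "small_deletion", "deletion", "complex",
)


@dataclass(frozen=True)
class MutationRecord:
    chrom: str
    pos: int  # 0-based position of the first REF base
    ref: str
    alt: str
    mut_class: str
    indel_len: int
    af: float | None


def classify_mutation(ref: str, alt: str, small_max: int = 50) -> str:
    """Sequential classification rules; see module docstring."""
    if not ref or not alt:
        raise ValueError("empty allele")
    lr, la = len(ref), len(alt)
    if lr == la:
        return "substitution" if lr == 1 else "MNP"
    if lr == 1 and la > 1:
        return "small_insertion" if la - lr <= small_max else "insertion"
    if lr > la:
        return "small_deletion" if lr - la <= small_max else "deletion"
    return "complex"  # multi-base ref with a longer alt: outside the rule table


def split_multiallelic(record: RawVariant, small_max: int = 50) -> list[MutationRecord]:
    """One MutationRecord per ALT allele, carrying the per-allele AF."""
    out = []
    for alt, af in zip(record.alts, record.afs):
        cls = classify_mutation(record.ref, alt, small_max)
        out.append(
            MutationRecord(
                record.chrom, record.pos, record.ref, alt, cls,
                abs(len(alt) - len(record.ref)), af,
            )
        )
    return out


def classify_variants(
    records, small_max: int = 50, exclude_chroms: tuple[str, ...] = ()
) -> list[MutationRecord]:
    out: list[MutationRecord] = []
    skipped = 0
    for rec in records:
        if rec.chrom in exclude_chroms:
            skipped += 1
            continue
        out.extend(split_multiallelic(rec, small_max))
    log.info("classified %d mutation records (%d records on excluded chromosomes)",
             len(out), skipped)
    return out


def class_counts(mutations: list[MutationRecord]) -> Counter:
    return Counter(m.mut_class for m in mutations)


def mutation_midpoint(m: MutationRecord) -> int:
    """Midpoint of the reference span (floor tie-break)."""
    return m.pos + len(m.ref) // 2


def mutation_windows(
    mutations: list[MutationRecord],
    chrom_sizes: dict[str, int],
    half_width: int = 50,
) -> list[GenomicInterval]:
    """Midpoint +/- half_width windows, clipped at chromosome ends."""
    out = []
    for m in mutations:
        mid = mutation_midpoint(m)
        s = max(0, mid - half_width)
        e = min(chrom_sizes[m.chrom], mid + half_width)
        if s < e:
            out.append(GenomicInterval(m.chrom, s, e))
    return sorted(out, key=lambda iv: (iv.chrom, iv.start, iv.end))


@dataclass
class ClassEnrichment:
    mut_class: str
    n_mutations: int
    window_bp: int
    g4_bp: int
    fold: float
    control_fold: float | None
    pooled_gc: float
    residual: float
    p: float
    p_adj: float = float("nan")


def _window_density(
    windows: list[GenomicInterval], merged: list[GenomicInterval]
) -> tuple[int, int]:
    wm = merge_intervals(windows)
    bp = total_overlap_bp(wm, merged)
    return bp, sum(len(w) for w in wm)


def g4_enrichment_at_mutations(
    mutations: list[MutationRecord],
    g4_union: list[GenomicInterval],
    genome: dict[str, str],
    model: GCEnrichmentModel,
    controls: ControlSet | None = None,
    half_width: int = 50,
    exclude_classes: tuple[str, ...] = ("complex",),
    adjust: str = "BH",
) -> list[ClassEnrichment]:
    """Per-class G4 fold enrichment in windows centred on mutation midpoints.

    fold = (G4 bp density within the merged class windows) divided by the
    genome-wide G4 density; significance is the GC-adjusted residual test
    at the pooled window GC. The control fold repeats the computation with
    the matched-control intervals in place of the G4s.
    """
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    genome_bp = sum(chrom_sizes.values())
    g4_density = sum(len(iv) for iv in g4_union) / genome_bp
    ctrl_union = merge_intervals(controls.all_intervals()) if controls else None
    ctrl_density = (
        sum(len(iv) for iv in ctrl_union) / genome_bp if ctrl_union else None
    )
    out: list[ClassEnrichment] = []
    by_class: dict[str, list[MutationRecord]] = {}
    for m in mutations:
        if m.mut_class not in exclude_classes:
            by_class.setdefault(m.mut_class, []).append(m)
    for cls in CLASSES:
        if cls in exclude_classes:
            continue
        muts = by_class.get(cls, [])
        if not muts:
            log.warning("class %s: zero mutations, skipped", cls)
            continue
        windows = mutation_windows(muts, chrom_sizes, half_width)
        g4_bp, win_bp = _window_density(windows, merge_intervals(g4_union))
        fold = (g4_bp / win_bp) / g4_density
        pooled = "".join(genome[w.chrom][w.start : w.end] for w in merge_intervals(windows))
        gc = gc_fraction(pooled)
        r, p = residual_pvalue(model, gc, fold)
        cfold = None
        if ctrl_union and ctrl_density:
            cbp, cwin = _window_density(windows, ctrl_union)
            cfold = (cbp / cwin) / ctrl_density
        out.append(ClassEnrichment(cls, len(muts), win_bp, g4_bp, fold, cfold, gc, r, p))
    if out:
        adj = adjust_pvalues([c.p for c in out], method=adjust)
        for c, pa in zip(out, adj):
            c.p_adj = float(pa)
    return out


def positional_mutation_profile(
    mutations: list[MutationRecord],
    g4_union: list[GenomicInterval],
    chrom_sizes: dict[str, int],
    half: int = 1000,
) -> np.ndarray:
    """Per-offset G4 coverage count across +/-half around mutation midpoints."""
    prof = np.zeros(2 * half, dtype=np.int64)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merge_intervals(g4_union):
        by_chrom.setdefault(iv.chrom, []).append(iv)
    starts = {c: np.array([iv.start for iv in ivs]) for c, ivs in by_chrom.items()}
    ends = {c: np.array([iv.end for iv in ivs]) for c, ivs in by_chrom.items()}
    for m in mutations:
        mid = mutation_midpoint(m)
        if m.chrom not in starts:
            continue
        s, e = starts[m.chrom], ends[m.chrom]
        lo, hi = mid - half, mid + half
        sel = (e > lo) & (s < hi)
        for a, b in zip(s[sel], e[sel]):
            prof[max(a, lo) - lo : min(b, hi) - lo] += 1
    return prof


def mutation_rate_enrichment(
    mutations: list[MutationRecord],
    g4_union: list[GenomicInterval],
    chrom_sizes: dict[str, int],
    half_width: int = 50,
    by_class: bool = False,
) -> dict[str, float] | float:
    """Mutation rate in G4-proximal regions relative to the background rate.

    The proximal stratum is the merged union of G4 intervals expanded by
    ``half_width`` on each side; the estimator is (mutations per bp inside
    the stratum) / (mutations per bp outside). Optionally per class.
    """
    prox = merge_intervals(
        GenomicInterval(iv.chrom, max(0, iv.start - half_width),
                        min(chrom_sizes[iv.chrom], iv.end + half_width))
        for iv in g4_union
    )
    prox_bp = sum(len(iv) for iv in prox)
    total_bp = sum(chrom_sizes.values())
    rest_bp = total_bp - prox_bp
    if prox_bp == 0 or rest_bp == 0:
        raise ValueError("degenerate proximal stratum")
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for iv in prox:
        starts.setdefault(iv.chrom, []).append(iv.start)  # type: ignore[arg-type]
        ends.setdefault(iv.chrom, []).append(iv.end)  # type: ignore[arg-type]
    starts = {c: np.array(v) for c, v in starts.items()}
    ends = {c: np.array(v) for c, v in ends.items()}

    def _inside(m: MutationRecord) -> bool:
        if m.chrom not in starts:
            return False
        i = int(np.searchsorted(starts[m.chrom], m.pos, side="right")) - 1
        return i >= 0 and m.pos < ends[m.chrom][i]

    def _ratio(muts: list[MutationRecord]) -> float:
        n_in = sum(_inside(m) for m in muts)
        n_out = len(muts) - n_in
        if n_out == 0:
            return float("inf")
        return (n_in / prox_bp) / (n_out / rest_bp)

    if not by_class:
        return _ratio(mutations)
    out: dict[str, float] = {}
    for cls in CLASSES:
        muts = [m for m in mutations if m.mut_class == cls]
        if muts:
            out[cls] = _ratio(muts)
    return out


def mutation_ratio(
    g4_union: list[GenomicInterval],
    mutations: list[MutationRecord],
    compartments: dict[str, list[GenomicInterval]] | None = None,
) -> dict[str, float | None]:
    """Fraction of G4 bp overlapping mutation reference spans, per compartment.

    A compartment with zero G4 bp yields None (undefined, flagged).
    """
    spans = sorted(
        (GenomicInterval(m.chrom, m.pos, m.pos + len(m.ref)) for m in mutations),
        key=lambda iv: (iv.chrom, iv.start, iv.end),
    )
    span_union = merge_intervals(spans)
    g4m = merge_intervals(g4_union)
    comps = {"genome": None, **(compartments or {})}
    out: dict[str, float | None] = {}
    for name, comp in comps.items():
        if comp is None:
            g4_here = g4m
        else:
            compm = merge_intervals(comp)
            g4_here = []
            for iv in g4m:
                for c in compm:
                    ov = iv.overlap(c)
                    if ov:
                        g4_here.append(
                            GenomicInterval(iv.chrom, max(iv.start, c.start), min(iv.end, c.end))
                        )
            g4_here = merge_intervals(g4_here)
        total = sum(len(iv) for iv in g4_here)
        if total == 0:
            log.warning("compartment %s: zero G4 bp, mutation ratio undefined", name)
            out[name] = None
            continue
        out[name] = total_overlap_bp(g4_here, span_union) / total
    return out
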