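"""G4 microstructure: G-run/loop decomposition, the binned substitution
profile, and the trinucleotide mutability model.

Canonical G4s (exactly four G-runs of >= 3 G) are decomposed into runs and
loops; substitution positions are projected onto a fixed-length vector of
500 upstream flank positions + 4 runs x 20 bins + 3 loops x 30 bins + 500
downstream flank positions = 1,170 entries. A substitution inside a run or
loop spreads its unit mass over the bins its base overlaps (fractional,
mass-conserving); flank substitutions land in their single 1-bp position.

The trinucleotide model collapses the 64 trinucleotides into 32 canonical
classes (lexicographic minimum of a trinucleotide and its reverse
complement), estimates per-class mutability as observed substitutions over
genome-wide occurrences, and tests per-class G4 enrichment with a
two-tailed binomial test.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import stats

from .detect import revcomp
from .enrichment import adjust_pvalues
from .intervals import GenomicInterval, merge_intervals
from .variants import MutationRecord

log = logging.getLogger("g4topo")

PROFILE_LEN = 500 + 4 * 20 + 3 * 30 + 500  # 1170


@dataclass
class G4Decomposition:
    """Four G-runs, three loops and the two 500-bp flanks of a canonical G4."""

    interval: GenomicInterval  # the motif span
    g_runs: list[GenomicInterval]  # genomic coordinates, length 4
    loops: list[GenomicInterval]  # genomic coordinates, length 3
    strand: str
    flank: int = 500


def decompose_g4(
    sequence: str, interval: GenomicInterval, strand: str = "+",
    min_run: int = 3, flank: int = 500,
) -> G4Decomposition | None:
    """Decompose a consensus motif into runs/loops; None unless exactly 4 runs.

    ``sequence`` is the motif-strand sequence (reverse-complemented for a
    minus-strand motif); run/loop coordinates are reported on the genome.
    """
    base = "G"
    runs = [(m.start(), m.end()) for m in re.finditer(f"{base}{{{min_run},}}", sequence)]
    if len(runs) != 4:
        return None
    if strand == "-":
        L = len(sequence)
        runs = [(L - e, L - s) for s, e in reversed(runs)]
    g_runs = [GenomicInterval(interval.chrom, interval.start + s, interval.start + e, strand)
              for s, e in runs]
    loops = [
        GenomicInterval(interval.chrom, g_runs[i].end, g_runs[i + 1].start, strand)
        for i in range(3)
        if g_runs[i].end < g_runs[i + 1].start
    ]
    if len(loops) != 3:
        return None  # adjacent runs leave no loop; not a canonical 4-run motif
    return G4Decomposition(interval, g_runs, loops, strand, flank)


def _segment_layout(flank: int, run_bins: int, loop_bins: int) -> list[tuple[str, int]]:
    """(label, width-in-vector-positions) in 5'->3' order."""
    return (
        [("flank5", flank)]
        + [x for i in range(3) for x in ((f"run{i}", run_bins), (f"loop{i}", loop_bins))]
        + [("run3", run_bins), ("flank3", flank)]
    )


def profile_segment_labels(flank: int = 500, run_bins: int = 20, loop_bins: int = 30) -> list[str]:
    labels: list[str] = []
    for label, width in _segment_layout(flank, run_bins, loop_bins):
        labels.extend([label] * width)
    return labels


@dataclass
class SubstitutionProfile:
    """Mutation mass over the fixed G4 coordinate vector.

    ``fold`` divides each position's mass by the window-average mass (its
    mean is exactly 1). Vector positions differ in genomic width — a flank
    position is 1 bp while a run bin covers L/20 bp of an L-bp run — so
    ``density_fold`` additionally corrects by the accumulated bp width per
    position; under uniformly placed substitutions it is flat at 1.
    """

    mass: np.ndarray
    fold: np.ndarray
    density_fold: np.ndarray
    widths: np.ndarray
    counted: int


def binned_substitution_profile(
    decompositions: list[G4Decomposition],
    substitutions: list[MutationRecord],
    af_min: float = 0.05,
    run_bins: int = 20,
    loop_bins: int = 30,
    flank: int = 500,
) -> SubstitutionProfile:
    """Project substitutions onto the fixed G4 coordinate vector.

    Substitutions are filtered to allele frequency >= ``af_min`` (records
    with absent AF are dropped by the filter). Mass is conserved: the
    vector total equals the number of substitutions counted.
    """
    if not decompositions:
        raise ValueError("no canonical decompositions supplied")
    subs = [
        m for m in substitutions
        if m.mut_class == "substitution" and m.af is not None and m.af >= af_min
    ]
    # index substitution positions per chromosome
    by_chrom: dict[str, np.ndarray] = {}
    for chrom in {d.interval.chrom for d in decompositions}:
        pos = sorted(m.pos for m in subs if m.chrom == chrom)
        by_chrom[chrom] = np.array(pos, dtype=np.int64)
    n_pos = 2 * flank + 4 * run_bins + 3 * loop_bins
    mass = np.zeros(n_pos)
    widths = np.zeros(n_pos)
    counted = 0
    for d in decompositions:
        _accumulate_widths(widths, d, flank, run_bins, loop_bins)
        positions = by_chrom.get(d.interval.chrom)
        if positions is None or len(positions) == 0:
            continue
        lo = d.interval.start - flank
        hi = d.interval.end + flank
        sel = positions[(positions >= max(0, lo)) & (positions < hi)]
        if len(sel) == 0:
            continue
        counted += _allocate(
            mass, sel, d, flank, run_bins, loop_bins
        )
    if mass.sum() > 0:
        fold = mass / mass.mean()
        density = mass / widths
        density_fold = density / (mass.sum() / widths.sum())
    else:
        fold = np.full_like(mass, np.nan)
        density_fold = np.full_like(mass, np.nan)
    return SubstitutionProfile(mass, fold, density_fold, widths, counted)


def _accumulate_widths(
    widths: np.ndarray, d: G4Decomposition, flank: int, run_bins: int, loop_bins: int
) -> None:
    run_order = [0, 1, 2, 3] if d.strand != "-" else [3, 2, 1, 0]
    loop_order = [0, 1, 2] if d.strand != "-" else [2, 1, 0]
    v = 0
    widths[v : v + flank] += 1.0
    v += flank
    for i in range(3):
        widths[v : v + run_bins] += len(d.g_runs[run_order[i]]) / run_bins
        v += run_bins
        widths[v : v + loop_bins] += len(d.loops[loop_order[i]]) / loop_bins
        v += loop_bins
    widths[v : v + run_bins] += len(d.g_runs[run_order[3]]) / run_bins
    v += run_bins
    widths[v : v + flank] += 1.0


def _allocate(
    mass: np.ndarray,
    positions: np.ndarray,
    d: G4Decomposition,
    flank: int,
    run_bins: int,
    loop_bins: int,
) -> int:
    """Add unit mass per substitution into the profile vector; returns count."""
    # segment genomic spans in 5'->3' order on the motif strand's genome
    # orientation; minus-strand motifs are mirrored so position 0 is the
    # motif 5' flank on the motif strand
    motif = d.interval
    layout: list[tuple[str, GenomicInterval | None, int]] = []
    layout.append(("flank5", None, flank))
    for i in range(3):
        layout.append((f"run{i}", d.g_runs[i], run_bins))
        layout.append((f"loop{i}", d.loops[i], loop_bins))
    layout.append(("run3", d.g_runs[3], run_bins))
    layout.append(("flank3", None, flank))
    counted = 0
    minus = d.strand == "-"
    if minus:
        # mirror: 5' flank of the motif strand is genomically downstream
        layout = [
            ("flank5", None, flank),
            ("run3", d.g_runs[3], run_bins),
            ("loop2", d.loops[2], loop_bins),
            ("run2", d.g_runs[2], run_bins),
            ("loop1", d.loops[1], loop_bins),
            ("run1", d.g_runs[1], run_bins),
            ("loop0", d.loops[0], loop_bins),
            ("run0", d.g_runs[0], run_bins),
            ("flank3", None, flank),
        ]
    for p in positions:
        v = 0
        placed = False
        for label, seg, width in layout:
            if label == "flank5":
                g_lo, g_hi = (motif.end, motif.end + flank) if minus else (motif.start - flank, motif.start)
            elif label == "flank3":
                g_lo, g_hi = (motif.start - flank, motif.start) if minus else (motif.end, motif.end + flank)
            else:
                g_lo, g_hi = seg.start, seg.end
            if g_lo <= p < g_hi:
                if label.startswith("flank"):
                    off = p - g_lo
                    idx = v + ((g_hi - g_lo - 1 - off) if minus else off)
                    mass[idx] += 1.0
                else:
                    L = g_hi - g_lo
                    off = p - g_lo
                    if minus:
                        off = L - 1 - off
                    # base occupies [off, off+1) of a segment of length L,
                    # mapped to [off*width/L, (off+1)*width/L) in bin space
                    lo_b = off * width / L
                    hi_b = (off + 1) * width / L
                    b0 = int(np.floor(lo_b))
                    b1 = min(int(np.ceil(hi_b)), width)
                    span = hi_b - lo_b
                    for b in range(b0, b1):
                        ov = min(hi_b, b + 1) - max(lo_b, b)
                        if ov > 0:
                            mass[v + b] += ov / span
                placed = True
                break
            v += width
        if placed:
            counted += 1
    return counted


# ---------------------------------------------------------------------------
# trinucleotide mutability model

_BASES = "ACGT"
_TRINUCS = ["".join(t) for t in product(_BASES, repeat=3)]
CANONICAL_CLASSES = sorted({min(t, revcomp(t)) for t in _TRINUCS})  # 32 classes


def canonical_trinuc(t: str) -> str:
    """Lexicographic minimum of a trinucleotide and its reverse complement."""
    return min(t, revcomp(t))


def trinucleotide_counts(genome: dict[str, str]) -> dict[str, int]:
    """Genome-wide canonical trinucleotide occurrence counts.

    Width-3 windows at step 1; windows containing N are skipped.
    """
    counts = {c: 0 for c in CANONICAL_CLASSES}
    code = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(_BASES):
        code[ord(b)] = i
    canon_of = np.array(
        [CANONICAL_CLASSES.index(canonical_trinuc(t)) for t in _TRINUCS], dtype=np.int64
    )
    for seq in genome.values():
        if len(seq) < 3:
            continue
        enc = code[np.frombuffer(seq.encode(), dtype=np.uint8)]
        tri = 16 * enc[:-2] + 4 * enc[1:-1] + enc[2:]
        valid = (enc[:-2] >= 0) & (enc[1:-1] >= 0) & (enc[2:] >= 0)
        binc = np.bincount(canon_of[tri[valid]], minlength=len(CANONICAL_CLASSES))
        for i, c in enumerate(CANONICAL_CLASSES):
            counts[c] += int(binc[i])
    return counts


def substitution_trinuc_counts(
    substitutions: list[MutationRecord], genome: dict[str, str]
) -> tuple[dict[str, int], int]:
    """Canonical-class counts of substitution reference contexts.

    Each substitution locus is expanded by one base each side; loci at
    chromosome edges (no context) or with N in context are skipped and
    counted.
    """
    counts = {c: 0 for c in CANONICAL_CLASSES}
    skipped = 0
    for m in substitutions:
        if m.mut_class != "substitution":
            continue
        seq = genome[m.chrom]
        if m.pos < 1 or m.pos + 2 > len(seq):
            skipped += 1
            continue
        tri = seq[m.pos - 1 : m.pos + 2]
        if "N" in tri:
            skipped += 1
            continue
        counts[canonical_trinuc(tri)] += 1
    if skipped:
        log.info("trinucleotide model: %d substitutions without full context skipped", skipped)
    return counts, skipped


def trinucleotide_mutability(
    substitutions: list[MutationRecord], genome: dict[str, str]
) -> dict[str, float]:
    """Per-class mutability: observed substitutions / genome occurrences."""
    genome_counts = trinucleotide_counts(genome)
    sub_counts, _ = substitution_trinuc_counts(substitutions, genome)
    out: dict[str, float] = {}
    for c in CANONICAL_CLASSES:
        if genome_counts[c] == 0:
            if sub_counts[c] > 0:
                raise ValueError(f"class {c} mutated but absent from the genome")
            out[c] = 0.0
        else:
            out[c] = sub_counts[c] / genome_counts[c]
    return out


@dataclass
class TrinucEnrichment:
    trinuc: str
    genome_count: int
    genome_mut: int
    g4_count: int
    g4_mut: int
    genome_ratio: float
    g4_ratio: float
    fold: float
    p: float
    p_adj: float = float("nan")


def _region_trinuc_counts(
    genome: dict[str, str], regions: list[GenomicInterval]
) -> dict[str, int]:
    sub = {
        iv: genome[iv.chrom][iv.start : iv.end]
        for iv in regions
    }
    return trinucleotide_counts({f"{iv.chrom}:{iv.start}": s for iv, s in sub.items()})


def g4_trinuc_enrichment(
    g4_union: list[GenomicInterval],
    substitutions: list[MutationRecord],
    genome: dict[str, str],
    adjust: str = "BH",
) -> list[TrinucEnrichment]:
    """Per-class fold enrichment of mutability inside (expanded) G4 regions.

    Merged G4 loci are expanded 1 bp each side. fold = G4 mutability /
    genome-wide mutability; the two-tailed binomial test compares the
    observed G4 substitution count for a class against its expectation
    (genome-wide per-occurrence rate x G4 occurrences of the class).
    """
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    expanded = merge_intervals(
        GenomicInterval(iv.chrom, max(0, iv.start - 1), min(chrom_sizes[iv.chrom], iv.end + 1))
        for iv in g4_union
    )
    genome_counts = trinucleotide_counts(genome)
    genome_mut, _ = substitution_trinuc_counts(substitutions, genome)
    g4_counts = _region_trinuc_counts(genome, expanded)
    # substitutions falling inside the expanded regions
    subs_in: list[MutationRecord] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in expanded:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    starts = {c: np.array([iv.start for iv in v]) for c, v in by_chrom.items()}
    ends = {c: np.array([iv.end for iv in v]) for c, v in by_chrom.items()}
    for m in substitutions:
        if m.mut_class != "substitution" or m.chrom not in starts:
            continue
        i = np.searchsorted(starts[m.chrom], m.pos - 1, side="right") - 1
        # the substitution's trinucleotide occurrence [pos-1, pos+2) must lie
        # inside the region so numerator and denominator count the same windows
        if i >= 0 and m.pos - 1 >= starts[m.chrom][i] and m.pos + 2 <= ends[m.chrom][i]:
            subs_in.append(m)
    g4_mut, _ = substitution_trinuc_counts(subs_in, genome)
    out: list[TrinucEnrichment] = []
    for c in CANONICAL_CLASSES:
        if g4_counts[c] == 0:
            continue  # class absent in G4 regions
        if genome_counts[c] == 0:
            continue
        genome_ratio = genome_mut[c] / genome_counts[c]
        g4_ratio = g4_mut[c] / g4_counts[c]
        fold = g4_ratio / genome_ratio if genome_ratio > 0 else float("inf")
        p_rate = min(genome_ratio, 1.0)
        if p_rate == 0.0:
            p = 1.0
        else:
            p = float(
                stats.binomtest(g4_mut[c], g4_counts[c], p_rate, alternative="two-sided").pvalue
            )
        out.append(
            TrinucEnrichment(c, genome_counts[c], genome_mut[c], g4_counts[c], g4_mut[c],
                             genome_ratio, g4_ratio, fold, p)
        )
    if out:
        adj = adjust_pvalues([max(t.p, 1e-300) for t in out], method=adjust)
        for t, pa in zip(out, adj):
            t.p_adj = float(pa)
    return out
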