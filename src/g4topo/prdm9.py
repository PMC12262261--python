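"""G4 enrichment at PRDM9 ChIP-seq binding sites.

PRDM9 positions meiotic recombination hotspots; its binding peaks (one set
per genotype, e.g. A/A or C/L4) are centred and a fixed window built
around each midpoint. Three read-outs are produced: the fraction of peak
windows overlapping at least one merged G4, the GC-adjusted fold
enrichment of G4 bp inside the windows, and a per-offset positional
profile of G4 occurrence (normalised to mean 1) with bootstrap confidence
bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .enrichment import GCEnrichmentModel, adjust_pvalues, gc_fraction, residual_pvalue
from .intervals import GenomicInterval, merge_intervals

log = logging.getLogger("g4topo")


@dataclass
class PeakSet:
    genotype: str
    peaks: list[GenomicInterval]

    def midpoints(self) -> list[tuple[str, int]]:
        return [(p.chrom, (p.start + p.end) // 2) for p in self.peaks]


@dataclass
class PositionalProfile:
    offsets: np.ndarray  # -half .. half-1
    counts: np.ndarray  # per-offset window count with G4 coverage
    enrichment: np.ndarray  # counts / mean(counts)
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None


def _coverage_matrix(
    midpoints: list[tuple[str, int]],
    g4_union: list[GenomicInterval],
    chrom_sizes: dict[str, int],
    half: int,
) -> np.ndarray:
    """Boolean (n_peaks, 2*half) matrix: window offset covered by a G4."""
    merged = merge_intervals(g4_union)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {c for c, _ in midpoints}:
        ivs = [iv for iv in merged if iv.chrom == chrom]
        by_chrom[chrom] = (
            np.array([iv.start for iv in ivs], dtype=np.int64),
            np.array([iv.end for iv in ivs], dtype=np.int64),
        )
    M = np.zeros((len(midpoints), 2 * half), dtype=bool)
    for i, (chrom, mid) in enumerate(midpoints):
        starts, ends = by_chrom.get(chrom, (np.zeros(0, np.int64),) * 2)
        lo, hi = mid - half, mid + half
        sel = np.flatnonzero((ends > lo) & (starts < hi))
        for j in sel:
            a = max(int(starts[j]), lo) - lo
            b = min(int(ends[j]), hi) - lo
            M[i, a:b] = True
    return M


def peak_overlap_fraction(
    peak_set: PeakSet,
    g4_union: list[GenomicInterval],
    chrom_sizes: dict[str, int],
    half: int = 1000,
) -> float:
    """Percentage of peak windows intersecting >= 1 merged G4."""
    if not peak_set.peaks:
        raise ValueError("empty peak set")
    M = _coverage_matrix(peak_set.midpoints(), g4_union, chrom_sizes, half)
    return 100.0 * float(M.any(axis=1).mean())


@dataclass
class PeakEnrichment:
    genotype: str
    n_peaks: int
    overlap_pct: float
    fold: float
    pooled_gc: float
    residual: float
    p: float
    p_adj: float = float("nan")


def peak_enrichment(
    peak_sets: list[PeakSet],
    g4_union: list[GenomicInterval],
    genome: dict[str, str],
    model: GCEnrichmentModel,
    half: int = 1000,
    adjust: str = "BH",
) -> list[PeakEnrichment]:
    """GC-adjusted G4 fold enrichment per genotype, BH across genotypes."""
    if not model.fitted:
        raise ValueError("model not fitted")
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    genome_bp = sum(chrom_sizes.values())
    merged = merge_intervals(g4_union)
    density = sum(len(iv) for iv in merged) / genome_bp
    out: list[PeakEnrichment] = []
    for ps in peak_sets:
        windows = merge_intervals(
            GenomicInterval(c, max(0, m - half), min(chrom_sizes[c], m + half))
            for c, m in ps.midpoints()
        )
        win_bp = sum(len(w) for w in windows)
        g4_bp = 0
        for w in windows:
            g4_bp += sum(w.overlap(iv) for iv in merged if iv.chrom == w.chrom)
        fold = (g4_bp / win_bp) / density
        pooled = "".join(genome[w.chrom][w.start : w.end] for w in windows)
        gc = gc_fraction(pooled)
        r, p = residual_pvalue(model, gc, fold)
        ov = peak_overlap_fraction(ps, g4_union, chrom_sizes, half)
        out.append(PeakEnrichment(ps.genotype, len(ps.peaks), ov, fold, gc, r, p))
    if out:
        adj = adjust_pvalues([e.p for e in out], method=adjust)
        for e, pa in zip(out, adj):
            e.p_adj = float(pa)
    return out


def positional_profile(
    peak_set: PeakSet,
    g4_union: list[GenomicInterval],
    chrom_sizes: dict[str, int],
    half: int = 1000,
    boot_n: int = 1000,
    seed: int = 0,
) -> PositionalProfile:
    """Per-offset G4 occurrence profile with bootstrap 95% bands.

    Occurrence is window-level presence: a window whose G4 coverage
    includes an offset contributes one count there. The profile is
    normalised by its mean across offsets. Bootstrap resamples peaks with
    replacement; fewer than 10 peaks refuses the bootstrap and emits the
    point profile only.
    """
    if boot_n < 100:
        raise ValueError("boot_n must be >= 100")
    M = _coverage_matrix(peak_set.midpoints(), g4_union, chrom_sizes, half)
    counts = M.sum(axis=0).astype(float)
    mean = counts.mean()
    enrich = counts / mean if mean > 0 else np.full_like(counts, np.nan)
    offsets = np.arange(-half, half)
    if len(peak_set.peaks) < 10:
        log.warning("fewer than 10 peaks: bootstrap refused, point profile only")
        return PositionalProfile(offsets, counts, enrich)
    rng = np.random.default_rng(seed)
    n = M.shape[0]
    boots = np.empty((boot_n, 2 * half))
    Mf = M.astype(float)
    for b in range(boot_n):
        w = np.bincount(rng.integers(0, n, size=n), minlength=n).astype(float)
        c = w @ Mf
        m = c.mean()
        boots[b] = c / m if m > 0 else np.nan
    lo, hi = np.nanpercentile(boots, [2.5, 97.5], axis=0)
    return PositionalProfile(offsets, counts, enrich, lo, hi)


def proximal_peak_summary(
    profile: PositionalProfile, radius: int = 250
) -> tuple[float, bool]:
    """Maximum normalised enrichment and whether its argmax is within
    +/-radius of offset 0 (ties broken toward the offset closest to 0)."""
    e = profile.enrichment
    best = np.flatnonzero(e == np.nanmax(e))
    # tie-break toward 0
    arg = best[np.argmin(np.abs(profile.offsets[best]))]
    return float(e[arg]), bool(abs(int(profile.offsets[arg])) <= radius)


def profile_ks_test(a: PositionalProfile, b: PositionalProfile) -> tuple[float, float]:
    """Two-sided KS test between two normalised profiles (e.g. G4 vs control)."""
    res = stats.ks_2samp(a.enrichment, b.enrichment)
    return float(res.statistic), float(res.pvalue)
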