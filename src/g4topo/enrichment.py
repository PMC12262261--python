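"""G4 density, fold enrichment, and the GC-adjusted residual test.

Fold enrichment of a region is its G4 bp density divided by the genome-wide
density. Because G4 density is strongly confounded by GC content, observed
folds are compared against a degree-2 polynomial of fold on GC fraction,
fitted on non-overlapping training windows; significance of a region is the
empirical two-tailed percentile of its residual (observed - predicted fold)
within the training residual distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval


@dataclass
class GenomicBin:
    interval: GenomicInterval
    gc: float = float("nan")
    g4_bp: int = 0
    density: float = float("nan")
    fold: float = float("nan")
    residual: float = float("nan")
    p: float = float("nan")
    p_adj: float = float("nan")


@dataclass
class GCEnrichmentModel:
    """Quadratic fold-vs-GC model with an empirical residual distribution."""

    coefficients: np.ndarray | None = None  # (beta0, beta1, beta2)
    residuals: np.ndarray | None = None
    bin_size: int | None = None
    cv_errors: dict[int, float] = field(default_factory=dict)

    @property
    def fitted(self) -> bool:
        return self.coefficients is not None

    def predict(self, gc: float | np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise ValueError("model not fitted")
        b0, b1, b2 = self.coefficients
        g = np.asarray(gc, dtype=float)
        return b0 + b1 * g + b2 * g * g


def bin_genome(chrom_sizes: dict[str, int], bin_size: int = 100_000) -> list[GenomicBin]:
    """Tile each chromosome with disjoint bins; the last bin is truncated."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    bins: list[GenomicBin] = []
    for chrom, size in chrom_sizes.items():
        for start in range(0, size, bin_size):
            bins.append(GenomicBin(GenomicInterval(chrom, start, min(start + bin_size, size))))
    return bins


def gc_fraction(seq: str) -> float:
    """GC fraction with N bases excluded from the denominator."""
    n_gc = seq.count("G") + seq.count("C")
    denom = len(seq) - seq.count("N")
    return n_gc / denom if denom else float("nan")


def _coverage_per_bin(
    bins: list[GenomicBin], merged_g4: list[GenomicInterval]
) -> None:
    """Fill bin.g4_bp from a merged interval list (two-pointer sweep)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged_g4:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda iv: iv.start)
    for b in bins:
        ivs = by_chrom.get(b.interval.chrom, [])
        starts = [iv.start for iv in ivs]
        # bins are processed independently; bisect keeps this near-linear
        import bisect

        i = bisect.bisect_left(starts, b.interval.start)
        if i > 0 and ivs[i - 1].end > b.interval.start:
            i -= 1
        bp = 0
        while i < len(ivs) and ivs[i].start < b.interval.end:
            bp += b.interval.overlap(ivs[i])
            i += 1
        b.g4_bp = bp


def density_and_fold(
    g4_union: list[GenomicInterval],
    bins: list[GenomicBin],
    background: float,
    genome: dict[str, str] | None = None,
) -> list[GenomicBin]:
    """Fill density (g4 bp / bin length) and fold (density / background).

    When the genome is given, each bin's GC fraction is filled too.
    """
    if background <= 0:
        raise ValueError("background density must be positive (no G4s detected?)")
    _coverage_per_bin(bins, g4_union)
    for b in bins:
        b.density = b.g4_bp / len(b.interval)
        b.fold = b.density / background
        if genome is not None:
            b.gc = gc_fraction(genome[b.interval.chrom][b.interval.start : b.interval.end])
    return bins


def genome_g4_density(g4_union: list[GenomicInterval], chrom_sizes: dict[str, int]) -> float:
    total = sum(chrom_sizes.values())
    return sum(len(iv) for iv in g4_union) / total


def _polyfit_gc(gc: np.ndarray, fold: np.ndarray) -> np.ndarray:
    # returns (b0, b1, b2) for fold ~ b0 + b1*g + b2*g^2
    X = np.column_stack([np.ones_like(gc), gc, gc * gc])
    beta, *_ = np.linalg.lstsq(X, fold, rcond=None)
    return beta


def fit_gc_model(
    genome: dict[str, str],
    g4_union: list[GenomicInterval],
    candidate_bin_sizes: tuple[int, ...] = (500_000, 1_000_000, 2_000_000, 4_000_000),
    folds: int = 10,
    seed: int = 0,
    min_windows: int = 30,
) -> GCEnrichmentModel:
    """Fit the quadratic fold-vs-GC model, selecting bin size by 10-fold CV.

    For each candidate size the genome is tiled, fold enrichment and GC are
    computed per window, and a degree-2 polynomial is fitted by least
    squares; the size minimising mean CV squared error is kept and its
    training residuals stored for the empirical test.
    """
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    background = genome_g4_density(g4_union, chrom_sizes)
    rng = np.random.default_rng(seed)
    model = GCEnrichmentModel()
    best = None
    for size in candidate_bin_sizes:
        bins = bin_genome(chrom_sizes, size)
        if len(bins) < min_windows:
            continue
        density_and_fold(g4_union, bins, background, genome)
        gc = np.array([b.gc for b in bins])
        fold = np.array([b.fold for b in bins])
        ok = np.isfinite(gc)
        gc, fold = gc[ok], fold[ok]
        if len(gc) < min_windows or np.ptp(gc) == 0:
            continue
        idx = rng.permutation(len(gc))
        k = min(folds, len(gc))
        cv_err = 0.0
        for part in np.array_split(idx, k):
            train = np.setdiff1d(idx, part)
            beta = _polyfit_gc(gc[train], fold[train])
            pred = beta[0] + beta[1] * gc[part] + beta[2] * gc[part] ** 2
            cv_err += float(np.sum((fold[part] - pred) ** 2))
        cv_err /= len(gc)
        model.cv_errors[size] = cv_err
        if best is None or cv_err < best[0]:
            beta = _polyfit_gc(gc, fold)
            resid = fold - (beta[0] + beta[1] * gc + beta[2] * gc * gc)
            best = (cv_err, size, beta, resid)
    if best is None:
        raise ValueError("no candidate bin size yields enough non-degenerate windows")
    _, model.bin_size, model.coefficients, model.residuals = best
    return model


def fit_gc_model_from_bins(gc: np.ndarray, fold: np.ndarray, bin_size: int = 0) -> GCEnrichmentModel:
    """Fit directly from precomputed (gc, fold) pairs — no CV, no tiling."""
    beta = _polyfit_gc(np.asarray(gc, float), np.asarray(fold, float))
    resid = np.asarray(fold, float) - (
        beta[0] + beta[1] * np.asarray(gc, float) + beta[2] * np.asarray(gc, float) ** 2
    )
    return GCEnrichmentModel(coefficients=beta, residuals=resid, bin_size=bin_size)


def residual_pvalue(model: GCEnrichmentModel, gc: float, fold_observed: float) -> tuple[float, float]:
    """Two-tailed empirical p-value for an observed fold at GC fraction g.

    r = observed - predicted; p = 2 * min(pct, 1 - pct) where pct is r's
    percentile among training residuals, floored at 1/(n+1) (a raw
    percentile of 0 or 1 would give p = 0) and capped at 1.
    """
    if not model.fitted:
        raise ValueError("model not fitted")
    r = float(fold_observed - model.predict(gc))
    n = len(model.residuals)
    pct = stats.percentileofscore(model.residuals, r, kind="mean") / 100.0
    p = 2.0 * min(pct, 1.0 - pct)
    p = max(p, 1.0 / (n + 1))
    return r, min(p, 1.0)


def adjust_pvalues(
    ps,
    method: str = "BH",
    grouping=None,
) -> np.ndarray:
    """Multiple-testing adjustment (BH step-up or Bonferroni), optionally
    within groups (e.g. per chromosome)."""
    ps = np.asarray(ps, dtype=float)
    if np.any((ps <= 0) | (ps > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    sm_method = {"BH": "fdr_bh", "bonferroni": "bonferroni"}[method]
    out = np.empty_like(ps)
    if grouping is None:
        out[:] = multipletests(ps, method=sm_method)[1]
    else:
        grouping = np.asarray(grouping)
        for g in np.unique(grouping):
            m = grouping == g
            out[m] = multipletests(ps[m], method=sm_method)[1]
    return out


def score_bins(
    bins: list[GenomicBin], model: GCEnrichmentModel, adjust: str = "BH"
) -> list[GenomicBin]:
    """Residual test per bin with BH adjustment within each chromosome."""
    for b in bins:
        b.residual, b.p = residual_pvalue(model, b.gc, b.fold)
    ps = [b.p for b in bins]
    chroms = [b.interval.chrom for b in bins]
    adj = adjust_pvalues(ps, method=adjust, grouping=chroms)
    for b, pa in zip(bins, adj):
        b.p_adj = float(pa)
    return bins
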