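"""Region methylation: averaging, three-state classification, Dirichlet
profiles and group comparisons.

A region's methylation is the unweighted mean of the per-CpG call levels it
covers; regions with no calls are flagged uncovered and excluded. Means are
classified hypo (< 0.2), methylated ([0.2, 0.8)) or hyper (>= 0.8). Per
compartment, the three-state composition is modelled as Dirichlet with a
uniform prior; the posterior is approached by iterative multinomial
resampling at the MLE proportions, one draw per step with a Bayes update,
until the posterior mean is stable. The closed-form posterior mean
(alpha + n)/(sum alpha + sum n) is what the resampler converges to and is
used as an oracle in tests.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval
from .io import MethylCall

log = logging.getLogger("g4topo")

STATES = ("hypo", "meth", "hyper")


@dataclass
class RegionMethylation:
    region_id: int
    covered_sites: int
    mean_level: float | None
    state: str | None  # None when uncovered


def classify_methylation(mean_level: float, hypo_cut: float = 0.2, hyper_cut: float = 0.8) -> str:
    """[0, hypo) -> hypo; [hypo, hyper) -> meth; [hyper, 1] -> hyper."""
    if not (0.0 <= mean_level <= 1.0):
        raise ValueError(f"mean methylation {mean_level} outside [0, 1]")
    if mean_level < hypo_cut:
        return "hypo"
    if mean_level < hyper_cut:
        return "meth"
    return "hyper"


def mean_methylation(
    regions: list[GenomicInterval],
    calls: list[MethylCall],
    hypo_cut: float = 0.2,
    hyper_cut: float = 0.8,
) -> list[RegionMethylation]:
    """Unweighted mean call level per region; zero-call regions uncovered."""
    by_chrom: dict[str, tuple[list[int], list[float]]] = {}
    for c in calls:
        starts, levels = by_chrom.setdefault(c.position.chrom, ([], []))
        starts.append(c.position.start)
        levels.append(c.level)
    for chrom, (starts, levels) in by_chrom.items():
        order = np.argsort(starts, kind="stable")
        by_chrom[chrom] = ([starts[i] for i in order], [levels[i] for i in order])
    out: list[RegionMethylation] = []
    for rid, region in enumerate(regions):
        starts, levels = by_chrom.get(region.chrom, ([], []))
        lo = bisect_left(starts, region.start)
        hi = bisect_left(starts, region.end)
        inside = levels[lo:hi]
        if not inside:
            out.append(RegionMethylation(rid, 0, None, None))
        else:
            m = float(np.mean(inside))
            out.append(
                RegionMethylation(rid, len(inside), m, classify_methylation(m, hypo_cut, hyper_cut))
            )
    n_cov = sum(1 for r in out if r.covered_sites)
    log.info("methylation: %d/%d regions covered", n_cov, len(regions))
    return out


def state_counts(region_meth: list[RegionMethylation]) -> np.ndarray:
    counts = np.zeros(3, dtype=np.int64)
    for r in region_meth:
        if r.state is not None:
            counts[STATES.index(r.state)] += 1
    return counts


@dataclass
class MethylationProfile:
    counts: np.ndarray
    prior: np.ndarray
    posterior_alpha: np.ndarray
    posterior_mean: np.ndarray
    trace: np.ndarray = field(repr=False, default=None)
    steps: int = 0


def dirichlet_profile(
    counts,
    prior=(1.0, 1.0, 1.0),
    tol: float = 1e-4,
    window: int = 100,
    max_steps: int = 200_000,
    seed: int = 0,
) -> MethylationProfile:
    """Dirichlet posterior over (hypo, meth, hyper) by multinomial resampling.

    One multinomial(1, q) draw per step at the MLE q = n / sum(n); the draw
    is added to the running counts and the posterior alpha updated.
    Stops when the posterior mean has moved less than ``tol`` (max absolute
    component change) over the last ``window`` steps.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.sum() < 1:
        raise ValueError("need at least one classified region")
    prior = np.asarray(prior, dtype=float)
    q = counts / counts.sum()
    rng = np.random.default_rng(seed)
    # the observed counts define the sampling proportions q; the posterior
    # is built from the prior plus the resampled draws, so its mean after m
    # steps is (prior + drawn)/(sum(prior) + m) -> q as m grows
    alpha = prior.copy()
    trace = [alpha / alpha.sum()]
    step = 0
    while step < max_steps:
        draw = rng.multinomial(1, q)
        alpha = alpha + draw
        trace.append(alpha / alpha.sum())
        step += 1
        if step >= window:
            # stable only when every point of the trailing window is within
            # tol of the current mean (endpoints alone can agree by chance)
            recent = np.array(trace[-window - 1 :])
            if np.max(np.abs(recent - recent[-1])) < tol:
                break
    mean = alpha / alpha.sum()
    return MethylationProfile(
        counts=counts, prior=prior, posterior_alpha=alpha,
        posterior_mean=mean, trace=np.array(trace), steps=step,
    )


@dataclass
class GroupComparison:
    label: str
    n_a: int
    n_b: int
    mwu_stat: float
    mwu_p: float
    ks_stat: float
    ks_p: float
    mwu_p_adj: float = float("nan")
    ks_p_adj: float = float("nan")


def compare_methylation(
    groups: dict[str, tuple[np.ndarray, np.ndarray]],
    adjust: str = "bonferroni",
) -> list[GroupComparison]:
    """Two-sided Mann-Whitney U and Kolmogorov-Smirnov per labelled pair.

    ``groups`` maps a compartment label to the two level vectors to compare
    (e.g. conserved vs non-conserved, or G4 vs control). P-values are
    Bonferroni-adjusted across compartments by default.
    """
    out: list[GroupComparison] = []
    for label, (a, b) in groups.items():
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"group {label!r}: need n >= 2 on both sides")
        ks = stats.ks_2samp(a, b, method="auto")
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            log.warning("group %r: both samples constant and equal; MWU p set to 1", label)
            mwu_stat, mwu_p = len(a) * len(b) / 2.0, 1.0
        else:
            mwu = stats.mannwhitneyu(a, b, alternative="two-sided")
            mwu_stat, mwu_p = float(mwu.statistic), float(mwu.pvalue)
        out.append(
            GroupComparison(label, len(a), len(b), mwu_stat, mwu_p,
                            float(ks.statistic), float(ks.pvalue))
        )
    method = {"bonferroni": "bonferroni", "BH": "fdr_bh"}[adjust]
    if out:
        for attr in ("mwu", "ks"):
            ps = np.clip([getattr(r, f"{attr}_p") for r in out], np.nextafter(0, 1), 1.0)
            adj = multipletests(ps, method=method)[1]
            for r, pa in zip(out, adj):
                setattr(r, f"{attr}_p_adj", float(pa))
    return out
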