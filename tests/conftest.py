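"""Shared fixtures: a small synthetic bundle and brute-force oracles."""

from __future__ import annotations

import re

import numpy as np
import pytest

import g4topo as g


@pytest.fixture(scope="session")
def bundle():
    """One deterministic desk-scale bundle reused across test modules."""
    spec = g.SimulationSpec(
        seed=7,
        chrom_lengths={"chr1": 400_000, "chr2": 300_000},
        n_g4=140,
        n_variants=4000,
    )
    genome, truth = g.simulate_genome(spec)
    return spec, genome, truth


@pytest.fixture(scope="session")
def detected(bundle):
    spec, genome, truth = bundle
    per_chrom = g.detect_genome(genome, method="both")
    return g.merged_sets_union(per_chrom)


# ---------------------------------------------------------------------------
# brute-force oracles (kept independent of the implementation's internals)


def brute_consensus_spans(
    seq: str, base: str = "G", min_run: int = 3, loop_min: int = 1, loop_max: int = 7
) -> list[tuple[int, int]]:
    """All maximal consensus-motif spans by breadth-first parse enumeration.

    States (position, runs completed); transitions consume a run of any
    admissible length then a loop of 1-7 bases. Every reachable end with
    >= 4 runs from every start is collected and overlapping spans merged.
    """
    n = len(seq)
    run_at = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        run_at[i] = run_at[i + 1] + 1 if seq[i] == base else 0
    spans = []
    for start in range(n):
        if run_at[start] < min_run:
            continue
        # BFS over (pos, runs)
        seen = set()
        frontier = set()
        best_end = -1
        for r in range(min_run, run_at[start] + 1):
            frontier.add((start + r, 1))
        while frontier:
            nxt = set()
            for pos, k in frontier:
                if (pos, k) in seen:
                    continue
                seen.add((pos, k))
                if k >= 4:
                    best_end = max(best_end, pos)
                for l in range(loop_min, loop_max + 1):
                    j = pos + l
                    if j >= n or run_at[j] < min_run:
                        continue
                    for r in range(min_run, run_at[j] + 1):
                        nxt.add((j + r, k + 1))
            frontier = nxt - seen
        if best_end > 0:
            spans.append((start, best_end))
    merged: list[tuple[int, int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def brute_g4hunter_regions(seq: str, w: int = 25, s: float = 1.5) -> list[tuple[int, int]]:
    """Direct window-by-window G4Hunter scan (no cumulative sums)."""

    def base_score(i: int) -> int:
        c = seq[i]
        if c not in "GC":
            return 0
        j = i
        while j > 0 and seq[j - 1] == c:
            j -= 1
        k = i
        while k + 1 < len(seq) and seq[k + 1] == c:
            k += 1
        run = k - j + 1
        return min(run, 4) * (1 if c == "G" else -1)

    scores = [base_score(i) for i in range(len(seq))]
    w = min(w, len(seq))
    qual = [
        abs(sum(scores[i : i + w]) / w) >= s for i in range(len(seq) - w + 1)
    ]
    regions = []
    i = 0
    while i < len(qual):
        if qual[i]:
            j = i
            while j + 1 < len(qual) and qual[j + 1]:
                j += 1
            regions.append((i, j + w))
            i = j + 1
        else:
            i += 1
    return regions


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
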