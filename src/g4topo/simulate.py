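"""Synthetic pipeline inputs with known ground truth.

Every input the analysis consumes can be generated here at desk scale: a
genome with planted canonical G4 motifs at recorded coordinates, germline
variants with a known class mixture and a controllable G4-proximal
enrichment factor, per-CpG methylation drawn from a known three-state
mixture, multiple-alignment blocks from simulated haplotypes at a tunable
divergence, and ChIP-seq-like peaks with a tunable G4 co-localisation
fraction. A single global seed fans out deterministically to per-stage
seeds so stages can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval
from .io import MethylCall

_STAGES = ("genome", "variants", "methylation", "maf", "peaks")


@dataclass
class SimulationSpec:
    """Ground-truth parameters of one synthetic bundle."""

    # genome
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    base_gc: float = 0.41
    n_g4: int = 200
    run_len_range: tuple[int, int] = (3, 5)
    loop_len_range: tuple[int, int] = (1, 7)
    # optional enriched region: (chrom, start, end, density fold rho_bin)
    enriched_region: tuple[str, int, int, float] | None = None
    # variants
    n_variants: int = 2000
    class_mixture: dict[str, float] = field(
        default_factory=lambda: {
            "substitution": 0.70, "MNP": 0.05,
            "small_insertion": 0.10, "insertion": 0.025,
            "small_deletion": 0.10, "deletion": 0.025,
        }
    )
    rho_mut: float = 1.0  # rate multiplier within +/- mut_half of a planted G4
    mut_half: int = 50
    af_beta: tuple[float, float] = (2.0, 5.0)
    # methylation
    meth_mixture: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    calls_per_region: tuple[int, int] = (1, 20)
    # pangenome
    n_haplotypes: int = 10
    divergence: float = 0.02
    indel_rate: float = 0.0
    block_len_range: tuple[int, int] = (10_000, 50_000)
    # peaks
    n_peaks: int = 200
    peak_width: int = 200
    colocalization_q: float = 0.5
    peak_jitter: int = 200
    seed: int = 0

    def rng(self, stage: str) -> np.random.Generator:
        """Per-stage generator derived from the global seed."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(_STAGES.index(stage),))
        return np.random.default_rng(ss)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _draw_motif(rng: np.random.Generator, spec: SimulationSpec) -> str:
    runs = rng.integers(spec.run_len_range[0], spec.run_len_range[1] + 1, size=4)
    loops = rng.integers(spec.loop_len_range[0], spec.loop_len_range[1] + 1, size=3)
    loop_alphabet = "ACT"  # G-free loops keep the planted run structure exact
    parts = []
    for i in range(4):
        parts.append("G" * int(runs[i]))
        if i < 3:
            parts.append("".join(rng.choice(list(loop_alphabet), size=int(loops[i]))))
    return "".join(parts)


def simulate_genome(spec: SimulationSpec) -> tuple[dict[str, str], list[GenomicInterval]]:
    """Background at the target GC with planted, non-overlapping G4 motifs.

    Motifs are flanked by a forced A on both sides so the planted interval
    is the maximal consensus match locally; an optional enriched region
    receives rho_bin-fold the baseline planting density. Returns the
    genome and the truth intervals (sorted).
    """
    rng = spec.rng("genome")
    mean_len = (
        4 * np.mean(spec.run_len_range) + 3 * np.mean(spec.loop_len_range) + 2
    )
    total = sum(spec.chrom_lengths.values())
    if total < 2 * (mean_len + 2) * max(spec.n_g4, 1):
        raise ValueError("genome too short for the requested G4 packing")
    genome: dict[str, str] = {}
    truth: list[GenomicInterval] = []
    # distribute motif count over chromosomes by length; route extras into
    # the enriched region at rho_bin-fold density
    for chrom, L in spec.chrom_lengths.items():
        arr = _random_background(rng, L, spec.base_gc)
        n_here = int(round(spec.n_g4 * L / total))
        regions = [(0, L, 1.0)]
        if spec.enriched_region and spec.enriched_region[0] == chrom:
            _, s, e, rho = spec.enriched_region
            regions = [(0, s, 1.0), (s, e, rho), (e, L, 1.0)]
        weights = np.array([max(e - s, 0) * w for s, e, w in regions], dtype=float)
        if weights.sum() == 0:
            genome[chrom] = arr.tobytes().decode()
            continue
        weights /= weights.sum()
        occupied: list[tuple[int, int]] = []
        attempts = 0
        placed = 0
        while placed < n_here and attempts < 50 * n_here + 100:
            attempts += 1
            ridx = rng.choice(len(regions), p=weights)
            s, e, _ = regions[ridx]
            motif = _draw_motif(rng, spec)
            m = len(motif)
            if e - s < m + 2:
                continue
            pos = int(rng.integers(s + 1, e - m - 1 + 1))
            if any(pos - 2 < oe and pos + m + 2 > os for os, oe in occupied):
                continue
            arr[pos : pos + m] = np.frombuffer(motif.encode(), dtype=np.uint8)
            arr[pos - 1] = ord("A")
            arr[pos + m] = ord("A")
            occupied.append((pos, pos + m))
            truth.append(GenomicInterval(chrom, pos, pos + m, "+"))
            placed += 1
        if placed < n_here:
            raise ValueError(f"could not pack {n_here} motifs into {chrom}")
        genome[chrom] = arr.tobytes().decode()
    truth.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return genome, truth


_CLASS_ORDER = (
    "substitution", "MNP", "small_insertion", "insertion", "small_deletion", "deletion"
)


def _alt_for_class(rng: np.random.Generator, cls: str, ref_base: str) -> tuple[int, str]:
    """Return (ref_len, alt_template_len) semantics via (ref_len, alt string rule).

    The caller slices the true REF from the genome; here we only decide
    lengths and, for substitutions/MNPs, how to mutate bases.
    """
    if cls == "substitution":
        return 1, "sub"
    if cls == "MNP":
        return int(rng.integers(2, 4)), "sub"
    if cls == "small_insertion":
        return 1, f"ins{int(rng.integers(1, 51))}"
    if cls == "insertion":
        return 1, f"ins{int(rng.integers(51, 120))}"
    if cls == "small_deletion":
        return 1 + int(rng.integers(1, 51)), "del"
    if cls == "deletion":
        return 1 + int(rng.integers(51, 120)), "del"
    raise ValueError(cls)


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


def simulate_variants(
    spec: SimulationSpec,
    genome: dict[str, str],
    truth_g4s: list[GenomicInterval],
) -> list[dict]:
    """Variants with a known class mixture and G4-proximal enrichment.

    Positions are uniform over the genome except that the G4-proximal
    stratum (planted G4s +/- mut_half) receives rho_mut times the baseline
    per-bp rate. Class counts are an exact multinomial draw from the
    mixture. Returns VCF-ready dicts (chrom, pos0, ref, alt, af, class).
    """
    rng = spec.rng("variants")
    chroms = list(genome)
    sizes = np.array([len(genome[c]) for c in chroms], dtype=float)
    # proximal stratum per chromosome
    prox: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for iv in truth_g4s:
        prox[iv.chrom].append(
            (max(0, iv.start - spec.mut_half), min(len(genome[iv.chrom]), iv.end + spec.mut_half))
        )
    prox_flat: list[tuple[str, int, int]] = []
    for c in chroms:
        merged: list[tuple[int, int]] = []
        for s, e in sorted(prox[c]):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        prox_flat += [(c, s, e) for s, e in merged]
    prox_bp = sum(e - s for _, s, e in prox_flat)
    rest_bp = sizes.sum() - prox_bp
    w_prox = spec.rho_mut * prox_bp
    p_prox = w_prox / (w_prox + rest_bp)
    classes = list(spec.class_mixture)
    probs = np.array([spec.class_mixture[c] for c in classes], dtype=float)
    probs /= probs.sum()
    counts = rng.multinomial(spec.n_variants, probs)
    out: list[dict] = []
    prox_lens = np.array([e - s for _, s, e in prox_flat], dtype=float)
    prox_by_chrom = {
        c: sorted((s, e) for cc, s, e in prox_flat if cc == c) for c in chroms
    }

    def _in_prox(c: str, pos: int) -> bool:
        from bisect import bisect_right

        ivs = prox_by_chrom[c]
        i = bisect_right(ivs, (pos, np.inf)) - 1
        return i >= 0 and ivs[i][0] <= pos < ivs[i][1]

    for cls, n in zip(classes, counts):
        for _ in range(int(n)):
            ref_len, rule = _alt_for_class(rng, cls, "")
            for _try in range(200):
                if prox_bp > 0 and rng.random() < p_prox:
                    i = rng.choice(len(prox_flat), p=prox_lens / prox_lens.sum())
                    c, s, e = prox_flat[i]
                    pos = int(rng.integers(s, e))
                else:
                    # background stratum: uniform over the complement of the
                    # proximal regions (rejection keeps the strata disjoint)
                    ci = rng.choice(len(chroms), p=sizes / sizes.sum())
                    c = chroms[ci]
                    pos = int(rng.integers(0, sizes[ci]))
                    if _in_prox(c, pos):
                        continue
                seq = genome[c]
                if pos + ref_len > len(seq):
                    continue
                ref = seq[pos : pos + ref_len]
                if "N" in ref:
                    continue
                break
            else:
                continue
            if rule == "sub":
                alt = "".join(_other_base(rng, b) for b in ref)
            elif rule.startswith("ins"):
                k = int(rule[3:])
                alt = ref + "".join(rng.choice(list("ACGT"), size=k))
            else:  # deletion: keep the anchor base
                alt = ref[0]
            af = float(rng.beta(*spec.af_beta))
            out.append(
                {"chrom": c, "pos": pos, "ref": ref, "alt": alt, "af": af, "class": cls}
            )
    out.sort(key=lambda v: (v["chrom"], v["pos"]))
    return out


def write_vcf(variants: list[dict], genome: dict[str, str], path) -> None:
    """Write simulated variants as uncompressed VCF 4.2 with per-ALT AF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        for chrom, seq in genome.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(
                f"{v['chrom']}\t{v['pos'] + 1}\t.\t{v['ref']}\t{v['alt']}\t.\t.\tAF={v['af']:.6f}\n"
            )


_META_BETA = {"hypo": (1.0, 9.0), "meth": (5.0, 5.0), "hyper": (9.0, 1.0)}
_META_STATES = ("hypo", "meth", "hyper")


def simulate_methylation(
    spec: SimulationSpec, regions: list[GenomicInterval]
) -> tuple[list[MethylCall], list[str]]:
    """Per-region methylation from the three-state mixture.

    Each region draws a state from the mixture, then 1-20 CpG calls with
    levels from the state's Beta component: Beta(1,9) hypo, Beta(5,5)
    methylated, Beta(9,1) hyper. Returns the calls and the per-region true
    states.
    """
    rng = spec.rng("methylation")
    calls: list[MethylCall] = []
    states: list[str] = []
    pis = np.asarray(spec.meth_mixture, dtype=float)
    pis = pis / pis.sum()
    for region in regions:
        state = _META_STATES[int(rng.choice(3, p=pis))]
        states.append(state)
        a, b = _META_BETA[state]
        n_calls = int(rng.integers(spec.calls_per_region[0], spec.calls_per_region[1] + 1))
        n_calls = min(n_calls, len(region))
        pos = rng.choice(len(region), size=n_calls, replace=False)
        for p in sorted(int(x) for x in pos):
            level = float(np.clip(rng.beta(a, b), 0.0, 1.0))
            calls.append(MethylCall(GenomicInterval(region.chrom, region.start + p, region.start + p + 1), level))
    calls.sort(key=lambda c: (c.position.chrom, c.position.start))
    return calls, states


def write_methylation_bed(calls: list[MethylCall], path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.position.chrom}\t{c.position.start}\t{c.position.end}\t{c.level:.4f}\n")


def simulate_maf(spec: SimulationSpec, genome: dict[str, str], ref_name: str = "ref"):
    """Haplotypes diverged from the reference, emitted as MAF blocks.

    Blocks of 10-50 kb tile each chromosome disjointly. Each haplotype row
    substitutes bases independently at the divergence rate and (optionally)
    deletes short segments at ``indel_rate``; the reference row stays
    ungapped. Returns a list of block dicts ready for writing.
    """
    rng = spec.rng("maf")
    blocks = []
    for chrom, seq in genome.items():
        pos = 0
        L = len(seq)
        while pos < L:
            size = int(rng.integers(spec.block_len_range[0], spec.block_len_range[1] + 1))
            size = min(size, L - pos)
            ref_text = seq[pos : pos + size]
            rows = {}
            ref_arr = np.frombuffer(ref_text.encode(), dtype=np.uint8)
            for h in range(spec.n_haplotypes):
                arr = ref_arr.copy()
                mut = rng.random(size) < spec.divergence
                if mut.any():
                    idx = np.flatnonzero(mut)
                    for i in idx:
                        arr[i] = ord(_other_base(rng, chr(arr[i])))
                if spec.indel_rate > 0:
                    dele = rng.random(size) < spec.indel_rate
                    for i in np.flatnonzero(dele):
                        dlen = int(rng.integers(1, 4))
                        arr[i : i + dlen] = ord("-")
                rows[f"hap{h}.{chrom}"] = arr.tobytes().decode()
            blocks.append(
                {
                    "ref_src": f"{ref_name}.{chrom}",
                    "chrom": chrom,
                    "start": pos,
                    "size": size,
                    "src_size": L,
                    "ref_text": ref_text,
                    "rows": rows,
                }
            )
            pos += size
    return blocks


def write_maf(blocks, path) -> None:
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for b in blocks:
            fh.write("\na score=0.0\n")
            fh.write(
                f"s {b['ref_src']} {b['start']} {b['size']} + {b['src_size']} {b['ref_text']}\n"
            )
            for src, text in b["rows"].items():
                ungapped = len(text) - text.count("-")
                fh.write(f"s {src} 0 {ungapped} + {ungapped} {text}\n")


def simulate_peaks(
    spec: SimulationSpec,
    truth_g4s: list[GenomicInterval],
    chrom_sizes: dict[str, int],
) -> list[GenomicInterval]:
    """Peaks co-localised with planted G4s at fraction q, rest uniform.

    A co-localised peak is centred within +/- peak_jitter of a planted G4
    midpoint.
    """
    rng = spec.rng("peaks")
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    half = spec.peak_width // 2
    peaks: list[GenomicInterval] = []
    for _ in range(spec.n_peaks):
        if truth_g4s and rng.random() < spec.colocalization_q:
            g4 = truth_g4s[int(rng.integers(0, len(truth_g4s)))]
            mid = (g4.start + g4.end) // 2 + int(
                rng.integers(-spec.peak_jitter, spec.peak_jitter + 1)
            )
            chrom = g4.chrom
        else:
            ci = int(rng.choice(len(chroms), p=sizes / sizes.sum()))
            chrom = chroms[ci]
            mid = int(rng.integers(half, chrom_sizes[chrom] - half))
        s = max(0, mid - half)
        e = min(chrom_sizes[chrom], mid + half)
        if s < e:
            peaks.append(GenomicInterval(chrom, s, e))
    peaks.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return peaks
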