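"""Conservation of reference G4s across pangenome haplotypes from MAF.

Each reference G4 is located inside the multiple-alignment block covering
it (reference gaps skipped when mapping interval offsets to alignment
columns); per-haplotype identity is the percentage of columns where the
haplotype base matches the reference base (gaps count as mismatch). A G4
is conserved when it was found in a block and its alignment identity
reaches the threshold (50% by default) under the chosen rule: identity of
the best haplotype ("any", default), the mean across haplotypes, or all
haplotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO

from .intervals import GenomicInterval

log = logging.getLogger("g4topo")


@dataclass
class AlignmentBlock:
    ref_chrom: str
    ref_start: int  # 0-based on the reference
    ref_text: str  # aligned reference row (with gaps)
    haplotypes: dict[str, str]  # sample id -> aligned text

    def __post_init__(self) -> None:
        for sid, text in self.haplotypes.items():
            if len(text) != len(self.ref_text):
                raise ValueError(f"row {sid} length differs from reference row")
        self.ref_end = self.ref_start + sum(1 for c in self.ref_text if c != "-")


def read_maf(path, ref_prefix: str | None = None) -> list[AlignmentBlock]:
    """Read MAF blocks, taking the first row of each block as the reference.

    With ``ref_prefix`` the reference row is the one whose source name
    starts with the prefix (e.g. the reference assembly name).
    """
    blocks: list[AlignmentBlock] = []
    for aln in AlignIO.parse(str(path), "maf"):
        recs = list(aln)
        if not recs:
            continue
        ref = None
        if ref_prefix is not None:
            for r in recs:
                if r.id.startswith(ref_prefix):
                    ref = r
                    break
        if ref is None:
            ref = recs[0]
        haps = {r.id: str(r.seq).upper() for r in recs if r is not ref}
        chrom = ref.id.split(".", 1)[-1] if "." in ref.id else ref.id
        blocks.append(
            AlignmentBlock(chrom, int(ref.annotations["start"]), str(ref.seq).upper(), haps)
        )
    blocks.sort(key=lambda b: (b.ref_chrom, b.ref_start))
    for a, b in zip(blocks, blocks[1:]):
        if a.ref_chrom == b.ref_chrom and b.ref_start < a.ref_end:
            raise ValueError(
                f"overlapping MAF blocks on {a.ref_chrom}: "
                f"[{a.ref_start},{a.ref_end}) and [{b.ref_start},{b.ref_end})"
            )
    return blocks


@dataclass
class ConservationRecord:
    g4_id: int
    found: bool
    identities: dict[str, float] = field(default_factory=dict)  # percent, per haplotype
    haplotypes_present: int = 0
    conserved: bool = False
    interval: GenomicInterval | None = None


def locate_in_maf(
    g4s: list[GenomicInterval], blocks: list[AlignmentBlock]
) -> list[tuple[GenomicInterval, AlignmentBlock | None, tuple[int, int] | None]]:
    """Map each G4 reference interval to alignment columns of its block.

    A G4 covered by no single block (outside all blocks, or split across a
    block boundary) is returned with (None, None): not found.
    """
    by_chrom: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.ref_chrom, []).append(b)
    out = []
    for g4 in g4s:
        hit = None
        for b in by_chrom.get(g4.chrom, []):
            if b.ref_start <= g4.start and g4.end <= b.ref_end:
                hit = b
                break
        if hit is None:
            out.append((g4, None, None))
            continue
        # map reference offsets to columns, skipping reference gaps
        ref_positions = np.flatnonzero(np.frombuffer(hit.ref_text.encode(), np.uint8) != ord("-"))
        c0 = int(ref_positions[g4.start - hit.ref_start])
        c1 = int(ref_positions[g4.end - 1 - hit.ref_start]) + 1
        out.append((g4, hit, (c0, c1)))
    return out


def conservation_score(
    g4_id: int,
    g4: GenomicInterval,
    block: AlignmentBlock | None,
    span: tuple[int, int] | None,
    threshold: float = 50.0,
    rule: str = "any",
    exclude_chroms: tuple[str, ...] = ("chrY",),
) -> ConservationRecord:
    """Per-haplotype identity over a located span and the conserved call."""
    rec = ConservationRecord(g4_id, found=False, interval=g4)
    if g4.chrom in exclude_chroms:
        return rec
    if block is None or span is None or not block.haplotypes:
        return rec
    c0, c1 = span
    ref = block.ref_text[c0:c1]
    rec.found = True
    rec.haplotypes_present = len(block.haplotypes)
    for sid, text in block.haplotypes.items():
        seg = text[c0:c1]
        matches = sum(
            1 for r, h in zip(ref, seg) if r != "-" and h != "-" and r == h
        )
        rec.identities[sid] = 100.0 * matches / (c1 - c0)
    vals = list(rec.identities.values())
    if rule == "any":
        score = max(vals)
    elif rule == "mean":
        score = float(np.mean(vals))
    elif rule == "all":
        score = min(vals)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    rec.conserved = score >= threshold
    return rec


def score_conservation(
    g4s: list[GenomicInterval],
    blocks: list[AlignmentBlock],
    threshold: float = 50.0,
    rule: str = "any",
    exclude_chroms: tuple[str, ...] = ("chrY",),
) -> list[ConservationRecord]:
    located = locate_in_maf(g4s, blocks)
    return [
        conservation_score(i, g4, blk, span, threshold, rule, exclude_chroms)
        for i, (g4, blk, span) in enumerate(located)
    ]


def bin_index(x: int, chrom_size: int, n_bins: int = 2000) -> int:
    """bin(x) = 1 + floor(B * x / S); positions at x = S clamp to bin B."""
    if n_bins <= 0:
        raise ValueError("n_bins must be positive")
    return min(1 + (n_bins * x) // chrom_size, n_bins)


def bin_share(
    records: list[ConservationRecord],
    chrom_sizes: dict[str, int],
    n_bins: int = 2000,
    haplotype_total: int = 88,
) -> pd.DataFrame:
    """Mean haplotype share per genomic bin: sum_i H_i / (H_total * N).

    Each aligned G4 contributes to the bin of its start and of its end (a
    G4 straddling two bins counts in both). Empty bins are omitted.
    """
    acc: dict[tuple[str, int], list[int]] = {}
    for rec in records:
        if not rec.found or rec.interval is None:
            continue
        S = chrom_sizes[rec.interval.chrom]
        bins = {
            bin_index(rec.interval.start, S, n_bins),
            bin_index(rec.interval.end, S, n_bins),
        }
        for b in bins:
            acc.setdefault((rec.interval.chrom, b), []).append(rec.haplotypes_present)
    rows = [
        {
            "chrom": chrom,
            "bin": b,
            "n_g4": len(h),
            "mean_share": sum(h) / (haplotype_total * len(h)),
        }
        for (chrom, b), h in sorted(acc.items())
    ]
    return pd.DataFrame(rows, columns=["chrom", "bin", "n_g4", "mean_share"])


def sharing_statistics(
    haplotype_motifs: dict[str, set[str]]
) -> tuple[pd.Series, dict[str, int], pd.DataFrame, pd.DataFrame]:
    """Sharing spectrum, unique counts, pairwise sharing matrix, length table.

    ``haplotype_motifs`` maps haplotype id to its set of distinct motif
    sequences. Returns (spectrum, unique_counts, pairwise, length_table):
    spectrum[k] = number of motifs present in exactly k haplotypes;
    pairwise[i, j] = Jaccard shared proportion |A & B| / |A | B|;
    length_table lists mean motif length per sharing level k.
    """
    haps = sorted(haplotype_motifs)
    if len(haps) < 2:
        raise ValueError("need >= 2 haplotypes")
    presence: dict[str, int] = {}
    for h in haps:
        for m in haplotype_motifs[h]:
            presence[m] = presence.get(m, 0) + 1
    ks = pd.Series(presence.values())
    spectrum = ks.value_counts().sort_index()
    spectrum.index.name = "n_haplotypes"
    unique_counts = {
        h: sum(1 for m in haplotype_motifs[h] if presence[m] == 1) for h in haps
    }
    mat = pd.DataFrame(np.eye(len(haps)), index=haps, columns=haps)
    for i, a in enumerate(haps):
        for b in haps[i + 1 :]:
            A, B = haplotype_motifs[a], haplotype_motifs[b]
            j = len(A & B) / len(A | B) if A | B else 1.0
            mat.loc[a, b] = mat.loc[b, a] = j
    length_rows = [
        {"n_haplotypes": k, "mean_length": float(np.mean([len(m) for m, c in presence.items() if c == k]))}
        for k in sorted(set(presence.values()))
    ]
    return spectrum, unique_counts, mat, pd.DataFrame(length_rows)
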