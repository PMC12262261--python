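"""G-run/loop decomposition, binned profiles, trinucleotide model."""

import numpy as np
import pytest

import g4topo as g
from g4topo.microstructure import (
    CANONICAL_CLASSES,
    PROFILE_LEN,
    profile_segment_labels,
    substitution_trinuc_counts,
)
from g4topo.intervals import GenomicInterval as GI


class TestDecompose:
    def test_hand_parse_of_telomeric_motif(self):
        seq = "GGGTTAGGGTTAGGGTTAGGG"
        d = g.decompose_g4(seq, GI("c1", 100, 121), "+")
        assert [(r.start, r.end) for r in d.g_runs] == [
            (100, 103), (106, 109), (112, 115), (118, 121)
        ]
        assert all(len(l) == 3 for l in d.loops)

    def test_five_runs_rejected(self):
        seq = "GGGAGGGAGGGAGGGAGGG"
        assert g.decompose_g4(seq, GI("c1", 0, 19), "+") is None

    def test_runs_and_loops_tile_the_motif(self):
        seq = "GGGGTAGGGCCAGGGTTTTGGG"
        d = g.decompose_g4(seq, GI("c1", 0, len(seq)), "+")
        segs = sorted([(x.start, x.end) for x in d.g_runs + d.loops])
        assert segs[0][0] == 0 and segs[-1][1] == len(seq)
        assert all(a[1] == b[0] for a, b in zip(segs, segs[1:]))

    def test_minus_strand_coordinates_mirrored(self):
        plus = "GGGTTAGGGTTAGGGTTAGGG"
        minus = g.revcomp(plus)  # CCCTAA... on the genome
        d = g.decompose_g4(plus, GI("c1", 0, 21), "-")
        # genomic coordinates still tile [0, 21)
        segs = sorted([(x.start, x.end) for x in d.g_runs + d.loops])
        assert segs[0][0] == 0 and segs[-1][1] == 21


class TestBinnedProfile:
    def _decomp(self, start=10_000):
        seq = "GGGTTAGGGTTAGGGTTAGGG"
        return g.decompose_g4(seq, GI("c1", start, start + 21), "+")

    def _sub(self, pos, af=0.5):
        return g.MutationRecord("c1", pos, "A", "G", "substitution", 0, af)

    def test_vector_length(self):
        assert PROFILE_LEN == 1170
        assert len(profile_segment_labels()) == 1170

    def test_mass_conservation(self):
        d = self._decomp()
        subs = [self._sub(p) for p in range(9_600, 10_500, 7)]
        prof = g.binned_substitution_profile([d], subs)
        assert prof.mass.sum() == pytest.approx(prof.counted, rel=1e-9)
        assert prof.fold.mean() == pytest.approx(1.0, rel=1e-9)

    def test_af_filter_applied(self):
        d = self._decomp()
        subs = [self._sub(10_005, af=0.04), self._sub(10_005, af=0.05)]
        assert g.binned_substitution_profile([d], subs).counted == 1

    def test_loop_only_substitutions_leave_runs_empty(self):
        d = self._decomp()
        labels = np.array(profile_segment_labels())
        # loop positions of the motif: offsets 3-5, 9-11, 15-17
        subs = [self._sub(10_000 + off) for off in (3, 4, 5, 9, 10, 16)]
        prof = g.binned_substitution_profile([d], subs)
        assert prof.counted == 6
        run_mass = prof.mass[np.char.startswith(labels, "run")].sum()
        loop_mass = prof.mass[np.char.startswith(labels, "loop")].sum()
        assert run_mass == 0 and loop_mass == pytest.approx(6.0)

    def test_flank_substitution_single_position(self):
        d = self._decomp()
        subs = [self._sub(10_000 - 42)]
        prof = g.binned_substitution_profile([d], subs)
        assert (prof.mass > 0).sum() == 1
        assert prof.mass[500 - 42] == pytest.approx(1.0)

    def test_flat_null_profile_is_flat(self):
        """Uniform substitutions over many identical motifs give fold ~ 1
        in every run/loop bin (flank positions are single-bp and noisier)."""
        rng = np.random.default_rng(0)
        decomps = [self._decomp(start=20_000 * (i + 1)) for i in range(200)]
        subs = []
        for d in decomps:
            lo, hi = d.interval.start - 50, d.interval.end + 50
            for p in rng.integers(lo, hi, size=1000):
                subs.append(self._sub(int(p)))
        prof = g.binned_substitution_profile(decomps, subs)
        labels = np.array(profile_segment_labels())
        inner = ~np.char.startswith(labels, "flank")
        # only motif +/- 50 bp carries events here, so flatness is judged
        # against the mean density of the covered positions
        density = prof.mass / prof.widths
        inner_rel = density[inner] / density[inner].mean()
        assert np.max(np.abs(inner_rel - 1)) < 0.1
        covered_flank = ~inner & (prof.mass > 0)
        assert abs(density[covered_flank].mean() / density[inner].mean() - 1) < 0.1

    def test_empty_decompositions_rejected(self):
        with pytest.raises(ValueError):
            g.binned_substitution_profile([], [])


class TestTrinucCounts:
    def test_window_count_is_length_minus_two(self):
        counts = g.trinucleotide_counts({"c1": "ACGTA"})
        assert sum(counts.values()) == 3

    def test_n_windows_skipped(self):
        counts = g.trinucleotide_counts({"c1": "ACNGT"})
        assert sum(counts.values()) == 0

    def test_canonicalization_collapses_revcomp(self):
        assert g.canonical_trinuc("GAA") == g.canonical_trinuc("TTC")
        a = g.trinucleotide_counts({"c1": "GAA"})
        b = g.trinucleotide_counts({"c1": "TTC"})
        assert a == b

    def test_32_classes_closed_under_revcomp(self):
        assert len(CANONICAL_CLASSES) == 32
        from itertools import product
        seen = set()
        for t in ("".join(p) for p in product("ACGT", repeat=3)):
            seen.add(g.canonical_trinuc(t))
            assert g.canonical_trinuc(t) == g.canonical_trinuc(g.revcomp(t))
        assert seen == set(CANONICAL_CLASSES)

    def test_counts_invariant_under_genome_revcomp(self, bundle):
        _, genome, _ = bundle
        fwd = g.trinucleotide_counts({"chr1": genome["chr1"][:50_000]})
        rev = g.trinucleotide_counts({"chr1": g.revcomp(genome["chr1"][:50_000])})
        assert fwd == rev


class TestMutability:
    def test_no_substitutions_all_zero(self, bundle):
        _, genome, _ = bundle
        small = {"c": genome["chr1"][:1000]}
        ratios = g.trinucleotide_mutability([], small)
        assert all(v == 0 for v in ratios.values())

    def test_every_site_of_one_class_mutated(self):
        seq = "TTGAATTGAATTGAA"  # GAA at 2, 7, 12
        genome = {"c1": seq}
        subs = [g.MutationRecord("c1", p + 1, "A", "G", "substitution", 0, 0.5) for p in (2, 7, 12)]
        ratios = g.trinucleotide_mutability(subs, genome)
        assert ratios[g.canonical_trinuc("AAT")] >= 0  # sanity on other classes
        # the mutated central base at p+1 has context seq[p:p+3] = GAA
        assert ratios[g.canonical_trinuc("GAA")] == pytest.approx(
            3 / g.trinucleotide_counts(genome)[g.canonical_trinuc("GAA")]
        )

    def test_edge_substitutions_skipped(self):
        genome = {"c1": "ACGT"}
        subs = [g.MutationRecord("c1", 0, "A", "G", "substitution", 0, 0.5)]
        counts, skipped = substitution_trinuc_counts(subs, genome)
        assert skipped == 1 and sum(counts.values()) == 0

    def test_known_rate_recovery(self):
        """Substitutions planted at a fixed per-occurrence rate are recovered."""
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=200_000))
        genome = {"c1": seq}
        rate = 0.05
        subs = []
        for p in range(1, len(seq) - 2):
            if seq[p - 1 : p + 2] == "GAA" and rng.random() < rate:
                subs.append(g.MutationRecord("c1", p, seq[p], "G", "substitution", 0, 0.5))
        ratios = g.trinucleotide_mutability(subs, genome)
        n = g.trinucleotide_counts(genome)[g.canonical_trinuc("GAA")]
        se = np.sqrt(rate * (1 - rate) / n)
        # GAA class counts GAA+TTC occurrences; only GAA sites were mutated
        n_gaa = sum(
            1 for p in range(1, len(seq) - 2) if seq[p - 1 : p + 2] == "GAA"
        )
        expected = rate * n_gaa / n
        assert ratios[g.canonical_trinuc("GAA")] == pytest.approx(expected, abs=3 * se)


class TestG4TrinucEnrichment:
    def test_planted_gaa_enrichment(self):
        """Substitutions planted only at GAA sites near G4s show a large
        GAA-class fold."""
        spec = g.SimulationSpec(seed=41, chrom_lengths={"chr1": 300_000}, n_g4=100)
        genome, truth = g.simulate_genome(spec)
        seq = genome["chr1"]
        subs = []
        in_g4 = np.zeros(len(seq), bool)
        for iv in truth:
            in_g4[max(0, iv.start - 1) : iv.end + 1] = True
        for p in range(1, len(seq) - 2):
            if in_g4[p] and seq[p - 1 : p + 2] in ("GAA", "TTC"):
                subs.append(g.MutationRecord("chr1", p, seq[p], "C", "substitution", 0, 0.5))
        if not subs:
            pytest.skip("no GAA context inside planted G4s for this seed")
        out = g.g4_trinuc_enrichment(truth, subs, genome)
        gaa = next(t for t in out if t.trinuc == g.canonical_trinuc("GAA"))
        assert gaa.fold > 10
        assert gaa.p_adj < 1e-3
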