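"""Pangenome conservation from MAF blocks."""

import numpy as np
import pytest

import g4topo as g
from g4topo.conservation import AlignmentBlock
from g4topo.intervals import GenomicInterval as GI


def block(chrom, start, ref_text, haps):
    return AlignmentBlock(chrom, start, ref_text, haps)


class TestLocate:
    def test_gapless_block_columns_are_offsets(self):
        b = block("c1", 100, "ACGTACGTAC", {"h1": "ACGTACGTAC"})
        out = g.locate_in_maf([GI("c1", 102, 106)], [b])
        (_, blk, span) = out[0]
        assert blk is b and span == (2, 6)

    def test_reference_gap_stretches_column_span(self):
        # reference offset: A=0 C=1 G=2 (gap) T=3 A=4
        b = block("c1", 0, "ACG--TA", {"h1": "ACGGGTA"})
        out = g.locate_in_maf([GI("c1", 1, 4)], [b])
        _, _, span = out[0]
        assert span == (1, 6)  # columns include the reference gap

    def test_outside_all_blocks_not_found(self):
        b = block("c1", 0, "ACGT", {"h1": "ACGT"})
        recs = g.score_conservation([GI("c1", 100, 110)], [b], exclude_chroms=())
        assert not recs[0].found

    def test_overlapping_blocks_rejected(self, tmp_path):
        p = tmp_path / "bad.maf"
        p.write_text(
            "##maf version=1\n\n"
            "a score=0\n"
            "s ref.c1 0 10 + 100 ACGTACGTAC\n"
            "s hap0.c1 0 10 + 10 ACGTACGTAC\n\n"
            "a score=0\n"
            "s ref.c1 5 10 + 100 ACGTACGTAC\n"
            "s hap0.c1 0 10 + 10 ACGTACGTAC\n"
        )
        with pytest.raises(ValueError, match="overlapping"):
            g.read_maf(p, ref_prefix="ref.")


class TestConservationScore:
    def test_identical_haplotypes_fully_conserved(self):
        b = block("c1", 0, "GGGTTAGGGT", {"h1": "GGGTTAGGGT", "h2": "GGGTTAGGGT"})
        rec = g.score_conservation([GI("c1", 0, 10)], [b], exclude_chroms=())[0]
        assert rec.found and rec.conserved
        assert all(v == 100.0 for v in rec.identities.values())
        assert rec.haplotypes_present == 2

    def test_all_gap_haplotype_identity_zero(self):
        b = block("c1", 0, "GGGTTAGGGT", {"h1": "-" * 10})
        rec = g.score_conservation([GI("c1", 0, 10)], [b], exclude_chroms=())[0]
        assert rec.identities["h1"] == 0.0
        assert not rec.conserved

    def test_fifty_percent_boundary_is_conserved(self):
        # 10 of 20 columns match: score exactly 50% -> conserved
        ref = "A" * 20
        hap = "A" * 10 + "C" * 10
        b = block("c1", 0, ref, {"h1": hap})
        rec = g.score_conservation([GI("c1", 0, 20)], [b], exclude_chroms=())[0]
        assert rec.identities["h1"] == pytest.approx(50.0)
        assert rec.conserved

    def test_chry_excluded(self):
        b = block("chrY", 0, "GGGG", {"h1": "GGGG"})
        rec = g.score_conservation([GI("chrY", 0, 4)], [b])[0]
        assert not rec.found and not rec.conserved

    def test_rules_any_mean_all(self):
        b = block("c1", 0, "A" * 10, {"good": "A" * 10, "bad": "C" * 10})
        g4 = [GI("c1", 0, 10)]
        assert g.score_conservation(g4, [b], rule="any", exclude_chroms=())[0].conserved
        assert g.score_conservation(g4, [b], rule="mean", exclude_chroms=())[0].conserved
        assert not g.score_conservation(g4, [b], rule="all", exclude_chroms=())[0].conserved


class TestBinShare:
    def test_bin_formula(self):
        assert g.bin_index(0, 1000, 2000) == 1
        assert g.bin_index(500, 1000, 2000) == 1001
        assert g.bin_index(1000, 1000, 2000) == 2000  # end position clamps

    def test_all_haplotypes_share_gives_one(self):
        recs = []
        for i in range(5):
            r = g.ConservationRecord(i, True, {}, haplotypes_present=88,
                                     conserved=True, interval=GI("c1", i * 100, i * 100 + 20))
            recs.append(r)
        df = g.bin_share(recs, {"c1": 1_000_000}, haplotype_total=88)
        assert (df["mean_share"] == 1.0).all()

    def test_straddling_g4_counted_in_both_bins(self):
        S = 2000  # with B=2000, each position is its own bin
        rec = g.ConservationRecord(0, True, {}, haplotypes_present=44,
                                   conserved=True, interval=GI("c1", 999, 1001))
        df = g.bin_share([rec], {"c1": S}, haplotype_total=88)
        assert len(df) == 2
        assert (df["mean_share"] == 0.5).all()


class TestSharing:
    def test_identical_sets_all_mass_at_h(self):
        sets = {f"h{i}": {"GGGA", "GGGC"} for i in range(4)}
        spectrum, unique, mat, _ = g.sharing_statistics(sets)
        assert spectrum.to_dict() == {4: 2}
        assert all(v == 0 for v in unique.values())
        assert np.allclose(mat.values, 1.0)

    def test_disjoint_sets_all_unique(self):
        sets = {"h1": {"AAA"}, "h2": {"CCC"}}
        spectrum, unique, mat, _ = g.sharing_statistics(sets)
        assert spectrum.to_dict() == {1: 2}
        assert unique == {"h1": 1, "h2": 1}
        assert mat.loc["h1", "h2"] == 0.0

    def test_spectrum_matches_set_algebra(self):
        sets = {
            "h1": {"A", "B", "C"},
            "h2": {"B", "C", "D"},
            "h3": {"C", "E"},
        }
        spectrum, unique, mat, lengths = g.sharing_statistics(sets)
        # A:1 B:2 C:3 D:1 E:1
        assert spectrum.to_dict() == {1: 3, 2: 1, 3: 1}
        assert sum(spectrum) == 5  # distinct motifs in the union
        assert mat.equals(mat.T) and np.allclose(np.diag(mat.values), 1.0)
        assert mat.loc["h1", "h2"] == pytest.approx(2 / 4)

    def test_single_haplotype_rejected(self):
        with pytest.raises(ValueError):
            g.sharing_statistics({"h1": {"A"}})


class TestSimulatedMaf:
    def test_zero_divergence_full_identity(self, bundle):
        spec, genome, truth = bundle
        spec0 = g.SimulationSpec(seed=spec.seed, chrom_lengths=spec.chrom_lengths,
                                 n_haplotypes=4, divergence=0.0)
        blocks = [
            AlignmentBlock(b["chrom"], b["start"], b["ref_text"], b["rows"])
            for b in g.simulate_maf(spec0, genome)
        ]
        recs = g.score_conservation(truth[:30], blocks, exclude_chroms=())
        assert all(r.found for r in recs)
        assert all(v == 100.0 for r in recs for v in r.identities.values())

    def test_divergence_identity_matches_binomial(self, bundle):
        """Mean per-column identity at divergence d matches 1 - d."""
        spec, genome, truth = bundle
        d = 0.3
        spec_d = g.SimulationSpec(seed=5, chrom_lengths=spec.chrom_lengths,
                                  n_haplotypes=6, divergence=d)
        blocks = [
            AlignmentBlock(b["chrom"], b["start"], b["ref_text"], b["rows"])
            for b in g.simulate_maf(spec_d, genome)
        ]
        recs = g.score_conservation(truth, blocks, exclude_chroms=())
        ids = np.array([v for r in recs if r.found for v in r.identities.values()])
        n_cols = sum(len(r.interval) for r in recs if r.found) * 6
        se = 100 * np.sqrt(d * (1 - d) / n_cols)
        assert ids.mean() == pytest.approx(100 * (1 - d), abs=3 * se)

    def test_identity_decreases_with_divergence(self, bundle):
        spec, genome, truth = bundle
        means = []
        for d in (0.0, 0.1, 0.3):
            sp = g.SimulationSpec(seed=6, chrom_lengths=spec.chrom_lengths,
                                  n_haplotypes=3, divergence=d)
            blocks = [
                AlignmentBlock(b["chrom"], b["start"], b["ref_text"], b["rows"])
                for b in g.simulate_maf(sp, genome)
            ]
            recs = g.score_conservation(truth[:50], blocks, exclude_chroms=())
            means.append(np.mean([v for r in recs if r.found for v in r.identities.values()]))
        assert means[0] > means[1] > means[2]

    def test_maf_round_trip_through_file(self, bundle, tmp_path):
        spec, genome, truth = bundle
        sp = g.SimulationSpec(seed=8, chrom_lengths={"chr1": 60_000},
                              n_haplotypes=3, divergence=0.05,
                              block_len_range=(10_000, 20_000))
        sub_genome = {"chr1": genome["chr1"][:60_000]}
        raw = g.simulate_maf(sp, sub_genome)
        path = tmp_path / "x.maf"
        g.write_maf(raw, path)
        blocks = g.read_maf(path, ref_prefix="ref.")
        assert len(blocks) == len(raw)
        # blocks tile the reference disjointly
        spans = sorted((b.ref_start, b.ref_end) for b in blocks)
        assert spans[0][0] == 0 and spans[-1][1] == 60_000
        assert all(a[1] == b[0] for a, b in zip(spans, spans[1:]))
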