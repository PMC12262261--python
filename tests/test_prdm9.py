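"""G4 enrichment at binding-site peaks: overlap, folds, profiles."""

import numpy as np
import pytest

import g4topo as g
from g4topo.intervals import GenomicInterval as GI


def flat_model():
    return g.GCEnrichmentModel(
        coefficients=np.array([1.0, 0.0, 0.0]),
        residuals=np.linspace(-0.5, 0.5, 99),
        bin_size=1,
    )


class TestOverlapFraction:
    def test_g4s_everywhere_is_100(self):
        peaks = g.PeakSet("A/A", [GI("c1", 1000 * i, 1000 * i + 200) for i in range(1, 5)])
        g4 = [GI("c1", 0, 10_000)]
        assert g.peak_overlap_fraction(peaks, g4, {"c1": 10_000}) == 100.0

    def test_no_g4s_is_0(self):
        peaks = g.PeakSet("A/A", [GI("c1", 2000, 2200)])
        assert g.peak_overlap_fraction(peaks, [], {"c1": 10_000}) == 0.0

    def test_empty_peaks_rejected(self):
        with pytest.raises(ValueError):
            g.peak_overlap_fraction(g.PeakSet("A/A", []), [], {})

    def test_colocalization_recovery(self):
        """Planted co-localization q in {0, 0.5, 1} recovered after
        correcting for chance overlap (brute-force chance estimate)."""
        spec0 = g.SimulationSpec(seed=51, chrom_lengths={"chr1": 800_000}, n_g4=120,
                                 n_peaks=400)
        genome, truth = g.simulate_genome(spec0)
        sizes = {c: len(s) for c, s in genome.items()}
        half = 1000
        # chance term: fraction of all possible windows hitting any G4
        hit = np.zeros(sizes["chr1"], bool)
        for iv in truth:
            hit[max(0, iv.start - half) : iv.end + half] = True
        chance = hit.mean()
        for q in (0.0, 0.5, 1.0):
            spec = g.SimulationSpec(seed=51, chrom_lengths={"chr1": 800_000},
                                    n_g4=120, n_peaks=400, colocalization_q=q)
            peaks = g.simulate_peaks(spec, truth, sizes)
            frac = g.peak_overlap_fraction(g.PeakSet("x", peaks), truth, sizes, half) / 100
            q_est = (frac - chance) / (1 - chance) if chance < 1 else 1.0
            assert q_est == pytest.approx(q, abs=0.08)


class TestPeakEnrichment:
    def test_genome_as_one_window_fold_one(self):
        genome = {"c1": "A" * 4000}
        g4 = [GI("c1", 100, 300), GI("c1", 2000, 2100)]
        peaks = [GI("c1", 1900, 2100)]  # midpoint 2000, window [1000, 3000)
        # make the window the whole genome: half = 2000 covers [0, 4000)
        out = g.peak_enrichment([g.PeakSet("A/A", peaks)], g4, genome, flat_model(), half=2000)
        assert out[0].fold == pytest.approx(1.0)

    def test_fold_matches_planted_density_ratio(self):
        """Windows centred on a G4 cluster recover the density ratio."""
        rng = np.random.default_rng(0)
        L = 200_000
        seq = "A" * L
        # cluster: every 500 bp in [50k, 70k) a 50 bp G4; background none
        g4 = [GI("c1", s, s + 50) for s in range(50_000, 70_000, 500)]
        genome = {"c1": seq}
        peaks = [GI("c1", m - 100, m + 100) for m in range(52_000, 68_000, 2000)]
        out = g.peak_enrichment([g.PeakSet("A/A", peaks)], g4, genome, flat_model())
        density_windows = 0.1  # 50 bp per 500 bp
        density_genome = sum(len(iv) for iv in g4) / L
        assert out[0].fold == pytest.approx(density_windows / density_genome, rel=0.05)

    def test_bh_across_genotypes(self):
        genome = {"c1": "A" * 50_000}
        g4 = [GI("c1", s, s + 30) for s in range(0, 50_000, 1000)]
        sets = [
            g.PeakSet(lab, [GI("c1", 10_000 * (i + 1), 10_000 * (i + 1) + 100)])
            for i, lab in enumerate(("A/A", "A/B", "C/L4"))
        ]
        out = g.peak_enrichment(sets, g4, genome, flat_model())
        assert len(out) == 3
        assert all(np.isfinite(e.p_adj) and e.p_adj >= e.p for e in out)


class TestPositionalProfile:
    def _uniform_setup(self, seed=0, n_peaks=150):
        spec = g.SimulationSpec(seed=seed, chrom_lengths={"chr1": 600_000},
                                n_g4=100, n_peaks=n_peaks, colocalization_q=0.0)
        genome, truth = g.simulate_genome(spec)
        sizes = {c: len(s) for c, s in genome.items()}
        peaks = g.simulate_peaks(spec, truth, sizes)
        return truth, sizes, peaks

    def test_mean_normalized_to_one(self):
        truth, sizes, peaks = self._uniform_setup()
        prof = g.positional_profile(g.PeakSet("x", peaks), truth, sizes, boot_n=100, seed=0)
        assert prof.enrichment.mean() == pytest.approx(1.0, abs=1e-9)
        assert np.all(prof.ci_lower <= prof.ci_upper)

    def test_identical_windows_zero_width_ci(self):
        g4 = [GI("c1", 5000 * i + 2400, 5000 * i + 2600) for i in range(1, 13)]
        peaks = [GI("c1", 5000 * i + 2450, 5000 * i + 2550) for i in range(1, 13)]
        prof = g.positional_profile(g.PeakSet("x", peaks), g4, {"c1": 100_000},
                                    boot_n=100, seed=0)
        assert np.allclose(prof.ci_lower, prof.ci_upper)

    def test_fewer_than_ten_peaks_point_profile_only(self):
        g4 = [GI("c1", 100, 200)]
        peaks = [GI("c1", 100, 200)] * 5
        prof = g.positional_profile(g.PeakSet("x", peaks), g4, {"c1": 100_000},
                                    boot_n=100, seed=0)
        assert prof.ci_lower is None

    def test_planted_central_g4s_peak_in_middle(self):
        """G4s planted near midpoints produce a central bump distinguishable
        from a control profile (two-sided KS)."""
        spec = g.SimulationSpec(seed=52, chrom_lengths={"chr1": 600_000},
                                n_g4=150, n_peaks=200, colocalization_q=1.0,
                                peak_jitter=100)
        genome, truth = g.simulate_genome(spec)
        sizes = {c: len(s) for c, s in genome.items()}
        peaks = g.simulate_peaks(spec, truth, sizes)
        prof = g.positional_profile(g.PeakSet("x", peaks), truth, sizes, boot_n=100, seed=0)
        centre = prof.enrichment[900:1100].mean()
        flanks = np.r_[prof.enrichment[:200], prof.enrichment[-200:]].mean()
        assert centre > 3 * flanks
        # null control: same peaks against shifted G4s
        shifted = sorted(
            (GI(iv.chrom, iv.start + 3000, iv.end + 3000) for iv in truth),
            key=lambda iv: (iv.chrom, iv.start),
        )
        ctrl = g.positional_profile(g.PeakSet("x", peaks), shifted, sizes, boot_n=100, seed=0)
        _, p = g.profile_ks_test(prof, ctrl)
        assert p < 1e-3

    def test_ks_symmetric_under_label_swap(self):
        truth, sizes, peaks = self._uniform_setup(seed=1)
        a = g.positional_profile(g.PeakSet("x", peaks[:70]), truth, sizes, boot_n=100, seed=0)
        b = g.positional_profile(g.PeakSet("y", peaks[70:]), truth, sizes, boot_n=100, seed=0)
        s1, p1 = g.profile_ks_test(a, b)
        s2, p2 = g.profile_ks_test(b, a)
        assert s1 == s2 and p1 == p2

    def test_ci_width_shrinks_with_peak_count(self):
        """Bootstrap band width ~ 1/sqrt(n peaks) on homogeneous data."""
        truth, sizes, peaks = self._uniform_setup(seed=2, n_peaks=400)
        small = g.positional_profile(g.PeakSet("x", peaks[:100]), truth, sizes,
                                     boot_n=200, seed=0)
        large = g.positional_profile(g.PeakSet("x", peaks), truth, sizes,
                                     boot_n=200, seed=0)
        w_small = np.nanmean(small.ci_upper - small.ci_lower)
        w_large = np.nanmean(large.ci_upper - large.ci_lower)
        assert w_large < w_small


class TestProximalSummary:
    def _profile(self, enrich):
        e = np.asarray(enrich, float)
        return g.PositionalProfile(np.arange(-len(e) // 2, len(e) // 2), e, e)

    def test_central_spike_flagged(self):
        e = np.ones(2000)
        e[1000] = 5.0
        mx, prox = g.proximal_peak_summary(self._profile(e))
        assert mx == 5.0 and prox

    def test_edge_maximum_not_proximal(self):
        e = np.linspace(0.5, 1.5, 2000)
        _, prox = g.proximal_peak_summary(self._profile(e))
        assert not prox

    def test_tie_broken_toward_centre(self):
        e = np.ones(2000)
        e[1010] = 3.0  # offset +10
        e[30] = 3.0  # offset -970
        mx, prox = g.proximal_peak_summary(self._profile(e))
        assert mx == 3.0 and prox
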