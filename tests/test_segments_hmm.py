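"""Tract HMM: binning, emissions, decoding, segment calling, recovery."""

import numpy as np
import pandas as pd
import pytest

from ntracts import segments_hmm as hmm, synthetic_data as sd
from ntracts.formats_io import GeneticMap


def tiny_panel(gmap, snps_per_cm=40, seed=0):
    return sd.archaic_panel(gmap, snps_per_cm=snps_per_cm, seed=seed)


def decode_genome(gmap, truth, coverage=2.0, c=0.05, seed=0, snps_per_cm=50):
    panel, freqs = sd.archaic_panel(gmap, snps_per_cm=snps_per_cm,
                                    seed=seed + 1)
    frags, _ = sd.simulate_reads(
        truth, panel, freqs,
        sd.ReadSimSpec(coverage=coverage, contamination=c, seed=seed + 2))
    track = hmm.bin_genome(gmap, panel)
    hmm.add_read_counts(track, frags, {"nea": freqs["nea"],
                                       "afr": freqs["modern"],
                                       "contaminant": freqs["contaminant"]})
    return hmm.decode(track, F=0.03, tau=0.2, c=c, e=0.001)


class TestBinGenome:
    def test_bin_count_and_span(self):
        gmap = GeneticMap({"1": (np.array([0.0, 1e6]), np.array([0.0, 1.0]))})
        panel = pd.DataFrame({"chrom": ["1"], "pos_bp": [500_000],
                              "cm": [0.5]})
        track = hmm.bin_genome(gmap, panel, bin_cm=0.05)
        assert track.n_bins["1"] == 20
        edges = track.edges_cm["1"]
        assert edges[0] == 0.0 and edges[-1] == pytest.approx(1.0)

    def test_boundary_snp_in_right_open_bin(self):
        gmap = GeneticMap({"1": (np.array([0.0, 1e6]), np.array([0.0, 1.0]))})
        panel = pd.DataFrame({"chrom": ["1", "1"], "pos_bp": [100_000, 150_000],
                              "cm": [0.10, 0.15]})
        track = hmm.bin_genome(gmap, panel, bin_cm=0.05)
        assert track.snp["bin"].tolist() == [2, 3]

    def test_unmapped_chromosome_raises(self):
        gmap = GeneticMap({"1": (np.array([0.0, 1e6]), np.array([0.0, 1.0]))})
        panel = pd.DataFrame({"chrom": ["7"], "pos_bp": [5], "cm": [0.0]})
        with pytest.raises(KeyError):
            hmm.bin_genome(gmap, panel)


class TestEmissions:
    def test_uninformative_site_equal_likelihoods(self):
        ll = hmm.site_emission_loglik(
            np.array([3]), np.array([2]), np.array([0.4]), np.array([0.4]),
            np.array([0.4]), c=0.1, e=0.01)
        assert ll[0, 0] == pytest.approx(ll[0, 1]) == pytest.approx(ll[0, 2])

    def test_perfectly_informative_clean_read(self):
        ll = hmm.site_emission_loglik(
            np.array([1]), np.array([0]), np.array([1.0]), np.array([0.0]),
            np.array([0.5]), c=0.0, e=0.0)
        assert ll[0, 2] == pytest.approx(0.0, abs=1e-9)
        assert ll[0, 0] < -20  # clipped -inf

    def test_matches_exhaustive_read_source_enumeration(self):
        # 3 reads at one site: brute force over (contaminant, haplotype,
        # error) configurations for k = 1 Neanderthal copy
        p_nea, p_afr, p_cont, c, e = 0.9, 0.1, 0.3, 0.2, 0.01
        n_der, n_anc = 2, 1

        def p_derived_one_read():
            # k=1: endogenous read picks the archaic haplotype w.p. 1/2
            q = 0.5 * p_nea + 0.5 * p_afr
            p_endo = (1 - e) * q + e * (1 - q)
            return c * p_cont + (1 - c) * p_endo

        p1 = p_derived_one_read()
        want = n_der * np.log(p1) + n_anc * np.log(1 - p1)
        got = hmm.site_emission_loglik(
            np.array([n_der]), np.array([n_anc]), np.array([p_nea]),
            np.array([p_afr]), np.array([p_cont]), c=c, e=e)[0, 1]
        assert got == pytest.approx(want, abs=1e-12)

    def test_smoothing_keeps_frequencies_interior(self):
        p = hmm.smooth_freq(np.array([0.0, 1.0]), n=100)
        assert 0 < p[0] < p[1] < 1


class TestDecode:
    def test_zero_reads_posterior_is_stationary(self):
        gmap = GeneticMap({"1": (np.array([0.0, 2e6]), np.array([0.0, 2.0]))})
        panel = pd.DataFrame({"chrom": ["1"], "pos_bp": [1_000_000],
                              "cm": [1.0]})
        track = hmm.bin_genome(gmap, panel, bin_cm=0.1)
        track.snp[["n_der", "n_anc"]] = 0
        track.snp["p_nea"] = 0.9
        track.snp["p_afr"] = 0.1
        track.snp["p_cont"] = 0.1
        F = 0.07
        dec = hmm.decode(track, F=F, tau=0.5, recompute_emissions=True)
        stat = np.array([(1 - F) ** 2, 2 * F * (1 - F), F ** 2])
        np.testing.assert_allclose(dec.posteriors["1"],
                                   np.tile(stat, (20, 1)), atol=1e-9)

    def test_saturated_signal_posterior_two_copies(self, small_map):
        # every bin strongly favours two archaic copies
        panel, _ = tiny_panel(small_map)
        track = hmm.bin_genome(small_map, panel)
        track.emissions = {}
        for chrom, nb in track.n_bins.items():
            E = np.full((nb, 3), -50.0)
            E[:, 2] = 0.0
            track.emissions[chrom] = E
        dec = hmm.decode(track, F=0.03, tau=0.2,
                         recompute_emissions=False)
        for chrom in dec.posteriors:
            assert (dec.posteriors[chrom][:, 2] > 0.99).all()

    def test_posteriors_normalised(self, small_map, empty_truth):
        dec = decode_genome(small_map, empty_truth, seed=10)
        for post in dec.posteriors.values():
            np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_forward_backward_loglik_agreement(self, small_map):
        truth = sd.simulate_pedigree_tracts(
            sd.PedigreeSimSpec(g=3, map=small_map, seed=5))
        dec = decode_genome(small_map, truth, seed=6)
        ll_b = hmm.backward_loglik(dec.track, F=0.03, tau=0.2)
        assert dec.loglik == pytest.approx(ll_b, abs=1e-6)

    def test_decode_deterministic(self, small_map, empty_truth):
        a = decode_genome(small_map, empty_truth, seed=20)
        b = decode_genome(small_map, empty_truth, seed=20)
        assert a.loglik == b.loglik
        for chrom in a.posteriors:
            np.testing.assert_array_equal(a.posteriors[chrom],
                                          b.posteriors[chrom])

    def test_invalid_parameters_raise(self, small_map, empty_truth):
        panel, freqs = tiny_panel(small_map)
        track = hmm.bin_genome(small_map, panel)
        with pytest.raises(ValueError):
            hmm.decode(track, F=0.0, tau=0.2)
        with pytest.raises(ValueError):
            hmm.decode(track, F=0.1, tau=-1.0)


class TestCallSegments:
    def _decoded_with_pany(self, pany, bin_cm=0.05):
        n = len(pany)
        gmap = GeneticMap({"1": (np.array([0.0, n * bin_cm * 1e6]),
                                 np.array([0.0, n * bin_cm]))})
        panel = pd.DataFrame({"chrom": ["1"], "pos_bp": [1], "cm": [0.0]})
        track = hmm.bin_genome(gmap, panel, bin_cm=bin_cm)
        post = np.zeros((n, 3))
        post[:, 1] = pany
        post[:, 0] = 1 - pany
        return hmm.DecodedTrack(track=track, posteriors={"1": post},
                                loglik=0.0, params={})

    def test_no_bins_above_threshold(self):
        dec = self._decoded_with_pany(np.full(40, 0.5))
        segs, summary = hmm.call_segments(dec)
        assert segs == [] and summary.total_cm == 0.0

    def test_run_of_ten_bins_is_half_cm(self):
        pany = np.zeros(40)
        pany[10:20] = 0.95
        dec = self._decoded_with_pany(pany)
        segs, summary = hmm.call_segments(dec, min_cm=0.2)
        assert len(segs) == 1
        assert segs[0].length_cm == pytest.approx(0.5)
        assert segs[0].start_cm == pytest.approx(0.5)
        assert summary.total_cm == pytest.approx(0.5)

    def test_short_segments_dropped(self):
        pany = np.zeros(40)
        pany[5:7] = 0.95  # 0.1 cM < 0.2 cM cutoff
        dec = self._decoded_with_pany(pany)
        segs, _ = hmm.call_segments(dec, min_cm=0.2)
        assert segs == []

    def test_summary_counts_long_segments(self):
        pany = np.zeros(300)
        pany[:120] = 0.95   # 6 cM
        pany[200:260] = 0.95  # 3 cM
        dec = self._decoded_with_pany(pany)
        segs, summary = hmm.call_segments(dec)
        assert summary.n_segments_gt5cm == 1
        assert summary.longest_cm == pytest.approx(6.0)
        assert summary.total_cm == pytest.approx(9.0)


class TestRecovery:
    def test_planted_tract_recovered_with_boundaries(self, small_map):
        truth = sd.TruthSet(
            map=small_map,
            hap_intervals=[{"1": [(20.0, 40.0, "recent")], "2": []},
                           {"1": [], "2": []}],
            params={})
        dec = decode_genome(small_map, truth, coverage=2.0, c=0.05, seed=30)
        segs, _ = hmm.call_segments(dec)
        big = [s for s in segs if s.length_cm >= 5]
        assert len(big) == 1
        assert big[0].start_cm == pytest.approx(20.0, abs=0.5)
        assert big[0].end_cm == pytest.approx(40.0, abs=0.5)

    def test_recall_does_not_drop_with_coverage(self, small_map):
        truth = sd.TruthSet(
            map=small_map,
            hap_intervals=[{"1": [(10.0, 30.0, "recent"),
                                  (45.0, 55.0, "recent")],
                            "2": [(5.0, 20.0, "recent")]},
                           {"1": [], "2": []}],
            params={})
        truth_cm = 45.0
        recalls = []
        for cov in (0.5, 2.0, 5.0):
            meds = []
            for s in range(3):
                dec = decode_genome(small_map, truth, coverage=cov,
                                    c=0.05, seed=100 + s)
                segs, _ = hmm.call_segments(dec)
                got = 0.0
                for seg in segs:
                    for a, b, _ in truth.hap_intervals[0].get(seg.chrom, []):
                        got += max(0.0, min(seg.end_cm, b)
                                   - max(seg.start_cm, a))
                meds.append(got / truth_cm)
            recalls.append(np.median(meds))
        assert recalls[1] >= recalls[0] - 1e-9
        assert recalls[2] >= recalls[1] - 1e-9


class TestFitParams:
    def test_refit_improves_or_keeps_loglik(self, small_map):
        truth = sd.simulate_pedigree_tracts(
            sd.PedigreeSimSpec(g=3, map=small_map, seed=40))
        panel, freqs = sd.archaic_panel(small_map, snps_per_cm=20, seed=41)
        frags, _ = sd.simulate_reads(
            truth, panel, freqs,
            sd.ReadSimSpec(coverage=1.0, contamination=0.0, seed=42))
        track = hmm.bin_genome(small_map, panel)
        hmm.add_read_counts(track, frags, {"nea": freqs["nea"],
                                           "afr": freqs["modern"]})
        base = hmm.decode(track, F=0.1, tau=1.0, c=0.0, e=0.001)
        refit = hmm.fit_params(track, F0=0.1, tau0=1.0, e0=0.001,
                               max_iter=40)
        assert refit.loglik >= base.loglik - 1e-6
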