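"""Deamination filtering, pseudo-haploid calling, contamination, sex, PMR."""

import numpy as np
import pandas as pd
import pytest

from ntracts import adna_qc as qc
from ntracts import synthetic_data as sd
from ntracts.formats_io import MISSING, GeneticMap, empty_fragment_table


def make_frags(rows):
    """Fragment table from minimal dicts; unset fields get neutral values."""
    defaults = {
        "specimen_id": "s", "chrom": "1", "start_bp": 0, "length_bp": 50,
        "strand": "+", "mapq": 37, "ct_5p": False, "ct_3p": False,
        "ref_c_5p_mask": 0, "ct_5p_mask": 0, "ref_c_3p_mask": 0,
        "ct_3p_mask": 0, "snp_index": -1, "allele": -1, "base_quality": 40,
        "pos_5p": 25, "pos_3p": 26,
    }
    recs = []
    for i, row in enumerate(rows):
        r = dict(defaults, fragment_id=i)
        r.update(row)
        recs.append(r)
    base = empty_fragment_table()
    return pd.concat([base, pd.DataFrame(recs)], ignore_index=True)[
        base.columns].astype(base.dtypes.to_dict())


class TestFilterDeaminated:
    def test_inclusive_or_of_ends(self):
        frags = make_frags([
            {"ct_5p": True, "ct_3p": False},
            {"ct_5p": False, "ct_3p": True},
            {"ct_5p": True, "ct_3p": True},
            {"ct_5p": False, "ct_3p": False},
        ])
        kept = qc.filter_deaminated(frags)
        assert kept["fragment_id"].tolist() == [0, 1, 2]

    def test_counting_and_idempotence(self):
        frags = make_frags([{"ct_5p": i < 4} for i in range(10)])
        once = qc.filter_deaminated(frags)
        assert len(once) == 4
        pd.testing.assert_frame_equal(qc.filter_deaminated(once), once)

    def test_invalid_k_raises(self):
        with pytest.raises(ValueError):
            qc.filter_deaminated(make_frags([{}]), k=0)


class TestPseudohaploidCall:
    panel = pd.DataFrame({
        "snp_id": ["s0", "s1"], "chrom": ["1", "1"],
        "pos_bp": [100, 200], "cm": [0.1, 0.2],
        "ref_allele": ["A", "C"], "alt_allele": ["T", "G"],
    })

    def test_low_base_quality_missing(self):
        frags = make_frags([{"snp_index": 0, "allele": 0, "base_quality": 29}])
        calls = qc.pseudohaploid_call(frags, self.panel)
        assert calls[0] == MISSING

    def test_damage_consistent_allele_masked(self):
        # + strand read carrying a T at distance 3 from the 5' end
        frags = make_frags([{"snp_index": 0, "allele": 1, "strand": "+",
                             "pos_5p": 3, "pos_3p": 48}])
        calls = qc.pseudohaploid_call(frags, self.panel, mask_k=5)
        assert calls[0] == MISSING
        # same allele away from the ends is kept
        frags2 = make_frags([{"snp_index": 0, "allele": 1, "strand": "+",
                              "pos_5p": 20, "pos_3p": 31}])
        assert qc.pseudohaploid_call(frags2, self.panel, mask_k=5)[0] == 1

    def test_minus_strand_a_masked(self):
        # panel s1 has ref A? no: s0 ref A. A on - strand near end -> masked
        frags = make_frags([{"snp_index": 0, "allele": 0, "strand": "-",
                             "pos_5p": 2, "pos_3p": 49}])
        assert qc.pseudohaploid_call(frags, self.panel)[0] == MISSING

    def test_empty_input_all_missing(self):
        calls = qc.pseudohaploid_call(empty_fragment_table(), self.panel)
        assert (calls == MISSING).all()

    def test_deterministic_given_seed(self):
        frags = make_frags([{"snp_index": 1, "allele": a, "pos_5p": 20,
                             "pos_3p": 31} for a in (0, 1, 0, 1, 1)])
        a = qc.pseudohaploid_call(frags, self.panel, seed=42)
        b = qc.pseudohaploid_call(frags, self.panel, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_clean_simulation_calls_match_haplotypes(self, small_map,
                                                     small_panel):
        panel, freqs = small_panel
        truth = sd.simulate_pedigree_tracts(
            sd.PedigreeSimSpec(g=3, map=small_map, seed=1))
        frags, haps = sd.simulate_reads(
            truth, panel, freqs,
            sd.ReadSimSpec(coverage=1.0, contamination=0.0, error=0.0,
                           deamination=0.0, seed=2))
        calls = qc.pseudohaploid_call(frags, panel, seed=3)
        called = calls != MISSING
        ok = (calls[called] == haps[0, called]) | \
             (calls[called] == haps[1, called])
        assert ok.all()


class TestContaminationDeam:
    def test_fully_endogenous_gives_zero(self):
        # every fragment deaminated at both terminal positions
        frags = make_frags([{"ct_5p": True, "ct_3p": True,
                             "ref_c_5p_mask": 1, "ct_5p_mask": 1,
                             "ref_c_3p_mask": 1, "ct_3p_mask": 1}
                            for _ in range(200)])
        est = qc.estimate_contamination_deam(frags)
        assert est.c_hat == pytest.approx(0.0, abs=1e-3)

    def test_no_informative_fragments_flagged(self):
        est = qc.estimate_contamination_deam(make_frags([{}] * 10))
        assert est.flagged and np.isnan(est.c_hat)

    @pytest.mark.parametrize("c_true", [0.0, 0.42])
    def test_simulation_recovery(self, small_panel, empty_truth, c_true):
        panel, freqs = small_panel
        frags, _ = sd.simulate_reads(
            empty_truth, panel, freqs,
            sd.ReadSimSpec(coverage=5.0, contamination=c_true,
                           deamination=0.3, seed=13))
        est = qc.estimate_contamination_deam(frags)
        assert est.c_hat == pytest.approx(c_true, abs=0.05)

    def test_consistency_with_fragment_count(self, small_panel, empty_truth):
        # |bias| shrinks as the fragment count grows (three sizes)
        panel, freqs = small_panel
        errs = []
        for cov in (0.3, 2.0, 12.0):
            ests = []
            for s in range(4):
                frags, _ = sd.simulate_reads(
                    empty_truth, panel, freqs,
                    sd.ReadSimSpec(coverage=cov, contamination=0.3,
                                   deamination=0.3, seed=100 + s))
                ests.append(qc.estimate_contamination_deam(frags).c_hat)
            errs.append(np.mean(np.abs(np.array(ests) - 0.3)))
        assert errs[2] < errs[0]
        assert errs[2] < 0.03


class TestContaminationX:
    def _x_setup(self, seed=0, n=1500):
        gmap = GeneticMap({"X": (np.array([0.0, 100e6]),
                                 np.array([0.0, 100.0]))})
        truth = sd.TruthSet(map=gmap, hap_intervals=[{"X": []}, {"X": []}],
                            params={})
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(np.arange(1, 100_000_000), n, replace=False))
        panel = pd.DataFrame({
            "snp_id": [f"x{i}" for i in range(n)], "chrom": "X",
            "pos_bp": pos, "cm": pos / 1e6,
            "ref_allele": "A", "alt_allele": "G"})
        pmod = rng.uniform(0.1, 0.9, n)
        freqs = {"nea": pmod, "modern": pmod,
                 "contaminant": np.clip(pmod + rng.normal(0, 0.1, n),
                                        0.05, 0.95)}
        return truth, panel, freqs

    def test_all_consensus_matches_give_zero(self):
        truth, panel, freqs = self._x_setup()
        frags, _ = sd.simulate_reads(
            truth, panel, freqs,
            sd.ReadSimSpec(coverage=3.0, contamination=0.0, error=0.0,
                           sex="male", seed=1))
        est = qc.estimate_contamination_x(frags, panel, freqs["contaminant"])
        assert est.c_hat == pytest.approx(0.0, abs=0.005)

    def test_recovery_at_three_percent(self):
        truth, panel, freqs = self._x_setup(seed=2, n=2500)
        frags, _ = sd.simulate_reads(
            truth, panel, freqs,
            sd.ReadSimSpec(coverage=2.5, contamination=0.03, sex="male",
                           seed=3))
        est = qc.estimate_contamination_x(frags, panel, freqs["contaminant"])
        assert 0.01 <= est.c_hat <= 0.05

    def test_female_refused(self):
        truth, panel, freqs = self._x_setup()
        frags, _ = sd.simulate_reads(
            truth, panel, freqs, sd.ReadSimSpec(coverage=1.0, seed=4))
        with pytest.raises(ValueError, match="male"):
            qc.estimate_contamination_x(frags, panel, freqs["contaminant"],
                                        sex="female")

    def test_few_sites_flagged(self):
        truth, panel, freqs = self._x_setup(n=60)
        frags, _ = sd.simulate_reads(
            truth, panel, freqs,
            sd.ReadSimSpec(coverage=0.3, sex="male", seed=5))
        est = qc.estimate_contamination_x(frags, panel, freqs["contaminant"])
        assert est.flagged


def _sex_genome(seed=0, x_sites=4000, auto_sites=8000):
    gmap = GeneticMap({
        "1": (np.array([0.0, 200e6]), np.array([0.0, 200.0])),
        "X": (np.array([0.0, 100e6]), np.array([0.0, 100.0])),
    })
    truth = sd.TruthSet(map=gmap,
                        hap_intervals=[{"1": [], "X": []}, {"1": [], "X": []}],
                        params={})
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, size, k in (("1", 200_000_000, auto_sites),
                           ("X", 100_000_000, x_sites)):
        pos = np.sort(rng.choice(np.arange(1, size), k, replace=False))
        rows.append(pd.DataFrame({
            "snp_id": [f"{chrom}_{i}" for i in range(k)], "chrom": chrom,
            "pos_bp": pos, "cm": pos / 1e6,
            "ref_allele": "A", "alt_allele": "G"}))
    panel = pd.concat(rows, ignore_index=True)
    p = rng.uniform(0.1, 0.9, len(panel))
    freqs = {"nea": p, "modern": p, "contaminant": p}
    return truth, panel, freqs


class TestDetermineSex:
    def test_simulated_male_and_female(self):
        truth, panel, freqs = _sex_genome()
        nx = int((panel["chrom"] == "X").sum())
        na = len(panel) - nx
        for sex, expect_rho in (("male", 0.5), ("female", 1.0)):
            frags, _ = sd.simulate_reads(
                truth, panel, freqs,
                sd.ReadSimSpec(coverage=1.0, deamination=0.3, sex=sex,
                               seed=6))
            call = qc.determine_sex(frags, n_x_sites=nx, n_auto_sites=na)
            assert call.call == sex
            assert call.x_auto_ratio == pytest.approx(expect_rho, abs=0.12)

    def test_tiny_sample_unresolved(self):
        frags = make_frags(
            [{"chrom": "X" if i < 3 else "1", "ct_5p": True}
             for i in range(10)])
        call = qc.determine_sex(frags, n_x_sites=100, n_auto_sites=200)
        assert call.call == "unresolved"

    def test_no_autosomal_fragments_raises(self):
        frags = make_frags([{"chrom": "X", "ct_5p": True}])
        with pytest.raises(ValueError):
            qc.determine_sex(frags, n_x_sites=10, n_auto_sites=10)


class TestPairwiseMismatch:
    def test_identical_calls(self):
        calls = np.array([0, 1, 1, 0] * 200)
        res = qc.pairwise_mismatch_rate(calls, calls)
        assert res.pmr == 0.0 and res.verdict == "same_individual"

    def test_small_overlap_inconclusive(self):
        a = np.full(100, 0)
        b = np.full(100, 0)
        b[:13] = 1
        res = qc.pairwise_mismatch_rate(a, b)
        assert res.pmr == pytest.approx(0.13)
        assert res.verdict == "inconclusive"

    def test_zero_overlap_raises(self):
        a = np.full(10, MISSING)
        with pytest.raises(ValueError):
            qc.pairwise_mismatch_rate(a, a)

    def test_self_lower_than_unrelated(self, small_map, small_panel):
        panel, freqs = small_panel
        truth = sd.simulate_pedigree_tracts(
            sd.PedigreeSimSpec(g=4, map=small_map, seed=0))
        wins = 0
        n_rep = 20
        for rep in range(n_rep):
            spec0 = sd.ReadSimSpec(coverage=1.0, seed=1000 + rep)
            frags0, haps = sd.simulate_reads(truth, panel, freqs, spec0)
            frags1, _ = sd.simulate_reads(
                truth, panel, freqs,
                sd.ReadSimSpec(coverage=1.0, seed=2000 + rep),
                hap_alleles=haps)
            frags2, _ = sd.simulate_reads(
                truth, panel, freqs,
                sd.ReadSimSpec(coverage=1.0, seed=3000 + rep))
            ca = qc.pseudohaploid_call(frags0, panel, seed=rep)
            cb = qc.pseudohaploid_call(frags1, panel, seed=rep + 1)
            cu = qc.pseudohaploid_call(frags2, panel, seed=rep + 2)
            pmr_self = qc.pairwise_mismatch_rate(ca, cb).pmr
            pmr_unrel = qc.pairwise_mismatch_rate(ca, cu).pmr
            wins += pmr_self < pmr_unrel
        assert wins == n_rep
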