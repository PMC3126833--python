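"""Diversity estimators, Ne calibration, Fst and site classification."""

import itertools
import math

import numpy as np
import pytest

from pansort.popgen import (PAN_RATES, EvolutionaryRateParams,
                            classify_shared_sites, effective_size,
                            fst_between, fst_matrix, fu_li_dstar,
                            fu_li_dstar_from_counts, harmonic,
                            locus_summary, mean_coalescent_time,
                            nucleotide_diversity, pairwise_fst,
                            pooled_summary, round_ne, tajimas_d,
                            tajimas_d_from_counts, watterson_theta)
from pansort.simulate import (CoalescentParams, HaplotypeAlignment,
                              SplitModelParams, simulate_locus,
                              simulate_split)


class TestHarmonic:
    def test_stable_and_monotone_to_1e4(self):
        prev = 0.0
        for n in (2, 10, 100, 1000, 10_000):
            a = harmonic(n - 1)
            assert math.isfinite(a) and a > prev
            prev = a
        # asymptotics: a_n ~ ln(n) + gamma
        assert harmonic(9999) == pytest.approx(math.log(9999) + 0.5772157,
                                               abs=1e-4)


class TestWattersonAndNe:
    """Worked examples with published-scale inputs: (n, length, S) triples
    reproduce the reported per-site percentages and Ne after rounding."""

    @pytest.mark.parametrize("S,n,L,pct", [
        (611, 40, 144055, 0.10),    # bonobo autosomal
        (1908, 40, 140718, 0.32),   # central chimpanzee autosomal
        (1239, 40, 138916, 0.21),   # eastern chimpanzee autosomal
        (746, 8, 142544, 0.20),     # Nigerian-Cameroonian autosomal
        (279, 20, 16552, 0.48),     # bonobo mtDNA
    ])
    def test_watterson_percent(self, S, n, L, pct):
        assert round(100 * watterson_theta(S, n, L), 2) == pct

    @pytest.mark.parametrize("S,n,L,ne", [
        (611, 40, 144055, 11_100),
        (1908, 40, 140718, 35_400),
        (746, 8, 142544, 22_400),
    ])
    def test_effective_size(self, S, n, L, ne):
        tw = watterson_theta(S, n, L)
        assert round_ne(effective_size(tw, PAN_RATES)) == ne

    def test_zero_sites_zero_theta_zero_ne(self):
        assert watterson_theta(0, 40, 10_000) == 0.0
        assert effective_size(0.0, PAN_RATES) == 0.0

    def test_mu_calibration(self):
        assert PAN_RATES.mu == pytest.approx((0.0135 / (2 * 6e6)) * 20)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            watterson_theta(10, 1, 100)
        with pytest.raises(ValueError):
            EvolutionaryRateParams(d=0.0, t=6e6, g=20)


class TestCoalescentTime:
    @pytest.mark.parametrize("ne,g,years", [
        (35_000, 20, 2.8e6),
        (11_000, 20, 880_000),
        (0, 20, 0.0),
    ])
    def test_four_ne_generations(self, ne, g, years):
        assert mean_coalescent_time(ne, g) == years


class TestDiversity:
    def test_single_difference(self):
        seqs = ["A" * 100, "A" * 50 + "G" + "A" * 49]
        assert nucleotide_diversity(seqs) == pytest.approx(0.01)

    def test_identical_sequences(self):
        assert nucleotide_diversity(["ACGT" * 10] * 4) == 0.0

    def test_matches_exhaustive_pairwise_oracle(self):
        seqs = ["ACGTACGTAC", "ACGTACGTAA", "ACGAACGTAC", "TCGTACGTAC"]
        pairs = itertools.combinations(range(4), 2)
        oracle = np.mean([sum(a != b for a, b in zip(seqs[i], seqs[j]))
                          for i, j in pairs]) / 10
        assert nucleotide_diversity(seqs) == pytest.approx(oracle)

    def test_gapped_columns_excluded(self):
        seqs = ["AC-TA", "ACGTA", "ACGTG"]
        # column 2 dropped entirely; 1 difference over 4 columns
        assert nucleotide_diversity(seqs) == pytest.approx(
            (2 / 3) / 4)


class TestDStatistics:
    """Frozen oracle values computed independently with exact fraction
    arithmetic from the published formulas."""

    @pytest.mark.parametrize("n,counts,expect_d,expect_dstar", [
        (5, [1, 2, 1, 3], 0.27344976645587904, 0.27344976645587904),
        (6, [1, 1, 1, 2, 3, 5], -0.3508405479905108, -0.41638722303760123),
        (8, [4, 4, 3, 5], 1.8991819477134189, 1.312509838027499),
    ])
    def test_frozen_hand_computed_values(self, n, counts, expect_d,
                                         expect_dstar):
        S = len(counts)
        pi_total = sum(c * (n - c) for c in counts) / (n * (n - 1) / 2)
        singles = sum(1 for c in counts if min(c, n - c) == 1)
        assert tajimas_d_from_counts(S, pi_total, n) == \
            pytest.approx(expect_d)
        assert fu_li_dstar_from_counts(S, singles, n) == \
            pytest.approx(expect_dstar)

    def test_alignment_route_agrees_with_count_route(self):
        anc = "A" * 10
        seqs = [list(anc) for _ in range(5)]
        for site, k in [(2, 1), (4, 2), (6, 1), (8, 3)]:
            for i in range(k):
                seqs[i][site] = "G"
        seqs = ["".join(s) for s in seqs]
        assert tajimas_d(seqs) == pytest.approx(0.27344976645587904)
        assert fu_li_dstar(seqs) == pytest.approx(0.27344976645587904)

    def test_sign_conventions(self):
        # intermediate-frequency variants push D positive, an excess of
        # singletons pushes it negative
        assert tajimas_d_from_counts(4, 4 * 4 * 4 / 28.0, 8) > 0
        assert tajimas_d_from_counts(6, 6 * 1 * 5 / 15.0, 6) < 0

    def test_undefined_when_no_variation(self):
        assert math.isnan(tajimas_d_from_counts(0, 0.0, 10))
        assert math.isnan(fu_li_dstar_from_counts(0, 0, 10))

    def test_neutral_simulation_mean_near_zero(self):
        rng_seed = 77
        vals = []
        p = CoalescentParams(12, 1000, 4.0)
        for r in range(2000):
            aln = simulate_locus(p, seed=rng_seed + r)
            d = tajimas_d(aln)
            if not math.isnan(d):
                vals.append(d)
        se = np.std(vals) / math.sqrt(len(vals))
        assert abs(np.mean(vals)) < max(3 * se, 0.1)


class TestEstimatorBias:
    def test_theta_estimators_unbiased(self):
        theta, L, n, reps = 5.0, 2000, 10, 5000
        tw, pi = [], []
        p = CoalescentParams(n, L, theta)
        rng = np.random.default_rng(123)
        from pansort.simulate import _simulate_counts
        for _ in range(reps):
            c = _simulate_counts(p, rng)
            tw.append(len(c) / harmonic(n - 1))
            pi.append(np.sum(c * (n - c)) / (n * (n - 1) / 2))
        assert abs(np.mean(tw) - theta) / theta < 0.02
        assert abs(np.mean(pi) - theta) / theta < 0.02


class TestFst:
    def test_identical_frequencies_zero(self):
        c = np.array([3, 5, 7])
        n = np.array([10, 10, 10])
        assert pairwise_fst(c, n, c, n) == pytest.approx(0.0)

    def test_fixed_differences_one(self):
        assert pairwise_fst([10, 0], 10, [0, 10], 10) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        c1 = rng.integers(0, 11, size=30)
        c2 = rng.integers(0, 11, size=30)
        f_ab = pairwise_fst(c1, 10, c2, 10)
        f_ba = pairwise_fst(c2, 10, c1, 10)
        assert f_ab == pytest.approx(f_ba)

    def test_matches_independent_per_site_oracle(self, rng):
        c1 = rng.integers(0, 13, size=50)
        c2 = rng.integers(0, 9, size=50)
        n1, n2 = 12, 8
        # brute-force ratio of averages, written from the definition
        hw_sum = hb_sum = 0.0
        for a, b in zip(c1, c2):
            p, q = a / n1, b / n2
            hb = p * (1 - q) + q * (1 - p)
            if hb == 0:
                continue
            hw_sum += (2 * p * (1 - p) + 2 * q * (1 - q)) / 2
            hb_sum += hb
        oracle = 1 - hw_sum / hb_sum
        assert pairwise_fst(c1, n1, c2, n2) == pytest.approx(oracle,
                                                             abs=1e-12)

    def test_split_population_fst_increases_with_divergence(self):
        def fst_at(t):
            alns = [simulate_split(SplitModelParams((10, 10), t), theta=5.0,
                                   seed=500 + t_i * 100 + r, locus_length=800)
                    for t_i, r in [(int(t * 10), k) for k in range(8)]]
            return fst_between(alns, "pop1", "pop2")
        assert fst_at(0.1) < fst_at(2.0)

    def test_weir_cockerham_option(self, rng):
        c1 = rng.integers(1, 10, size=40)
        c2 = rng.integers(1, 8, size=40)
        wc = pairwise_fst(c1, 10, c2, 8, method="weir-cockerham")
        assert -1.0 <= wc <= 1.0
        with pytest.raises(ValueError):
            pairwise_fst(c1, 10, c2, 8, method="nope")

    def test_no_sites_raises(self):
        with pytest.raises(ValueError):
            pairwise_fst([], 10, [], 10)


def _toy_split_alignment():
    #            0123456789
    seqs = {
        "a_0": "AAAAACGTAA",
        "a_1": "AAGAACGTAA",   # site 2 poly in a
        "a_2": "AAAAACGTCA",   # site 8 poly in a
        "b_0": "ATAAACGGAA",   # site 1 derived fixed in b, site 7 poly b
        "b_1": "ATAAACGTAA",
        "out": "AAAAACGTAA",
    }
    pop = {k: ("A" if k.startswith("a") else "B")
           for k in seqs if k != "out"}
    return HaplotypeAlignment(sequences=list(seqs.values()),
                              labels=list(seqs),
                              pop_map=pop, outgroup_label="out",
                              locus_length=10)


class TestSiteClassification:
    def test_definition_cases(self):
        aln = _toy_split_alignment()
        cls = classify_shared_sites(aln, "A", "B")
        # site 1: A fixed ancestral, B fixed derived -> category 5
        assert cls.b_fixed_derived_a_ancestral == 1
        # sites 2, 8: A polymorphic, B fixed ancestral -> skipped
        # site 7: B polymorphic, A fixed ancestral -> skipped
        assert cls.total == 1

    def test_both_polymorphic_case(self):
        seqs = ["AAT", "AAG", "AAT", "AAG", "AAT"]
        aln = HaplotypeAlignment(
            sequences=seqs + ["AAT"],
            labels=["a_0", "a_1", "b_0", "b_1", "b_2", "out"],
            pop_map={"a_0": "A", "a_1": "A", "b_0": "B", "b_1": "B",
                     "b_2": "B"},
            outgroup_label="out", locus_length=3)
        cls = classify_shared_sites(aln, "A", "B")
        assert cls.both_poly == 1 and cls.total == 1

    def test_counts_match_bruteforce_on_simulated_split(self):
        aln = simulate_split(SplitModelParams((8, 8), 0.6), theta=8.0,
                             seed=42, locus_length=2000)
        cls = classify_shared_sites(aln, "pop1", "pop2")
        # independent per-site re-classification
        a = aln.sequences_for("pop1")
        b = aln.sequences_for("pop2")
        out = aln.outgroup_sequence
        tally = dict(c1=0, c2=0, c3=0, c4=0, c5=0)
        polarized = 0
        for j in range(2000):
            ca = {s[j] for s in a}
            cb = {s[j] for s in b}
            allc = ca | cb
            if len(allc) > 2 or out[j] not in allc | {out[j]}:
                continue
            if len(allc) == 2 and out[j] not in allc:
                continue
            if len(allc) == 1:
                continue
            polarized += 1
            anc = out[j]
            if len(ca) > 1 and len(cb) > 1:
                tally["c3"] += 1
            elif len(ca) > 1 and cb == {anc}:
                pass  # private polymorphism, skipped by design
            elif len(ca) > 1:
                tally["c1"] += 1
            elif len(cb) > 1 and ca == {anc}:
                pass
            elif len(cb) > 1:
                tally["c2"] += 1
            elif ca != {anc} and cb == {anc}:
                tally["c4"] += 1
            elif cb != {anc} and ca == {anc}:
                tally["c5"] += 1
        assert cls.a_poly_b_fixed_derived == tally["c1"]
        assert cls.b_poly_a_fixed_derived == tally["c2"]
        assert cls.both_poly == tally["c3"]
        assert cls.a_fixed_derived_b_ancestral == tally["c4"]
        assert cls.b_fixed_derived_a_ancestral == tally["c5"]
        assert cls.total <= polarized

    def test_missing_outgroup_raises(self):
        aln = simulate_locus(CoalescentParams(4, 100, 1.0), seed=0)
        aln.outgroup_label = None
        with pytest.raises(ValueError):
            classify_shared_sites(aln, "pop1", "pop1")


class TestPooling:
    def test_pooled_equals_concatenated(self):
        alns = [simulate_locus(CoalescentParams(8, 500, 2.0), seed=s)
                for s in (1, 2, 3)]
        per_locus = [locus_summary(a, "pop1") for a in alns]
        pooled = pooled_summary(per_locus)
        concat = ["".join(a.sequences_for("pop1")[i] for a in alns)
                  for i in range(8)]
        direct = locus_summary(concat)
        assert pooled.S == direct.S
        assert pooled.pi == pytest.approx(direct.pi)
        assert pooled.tajima_d == pytest.approx(direct.tajima_d)
        assert pooled.fu_li_dstar == pytest.approx(direct.fu_li_dstar)

    def test_pooled_requires_common_n(self):
        a = locus_summary(simulate_locus(CoalescentParams(4, 200, 1.0), 1),
                          "pop1")
        b = locus_summary(simulate_locus(CoalescentParams(6, 200, 1.0), 2),
                          "pop1")
        with pytest.raises(ValueError):
            pooled_summary([a, b])
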