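"""Tajima's D, simulated nulls, MK/G tests, Ka/Ks and HKA."""

import numpy as np
import pytest
from scipy.special import comb
from scipy.stats import chi2

from conftest import make_aln, make_dataset
from sundapop import coalsim
from sundapop.neutrality import (
    hka_test,
    ka_ks,
    mk_counts,
    mk_test,
    multilocus_d_test,
    neutral_interval,
    tajima_constants,
    tajima_d,
    tajima_test,
)
from sundapop.sumstats import harmonic, summary_stats


class TestTajimaD:
    def test_hand_derived_positive_case(self):
        s = summary_stats(make_aln(["AAAA", "AAAT", "AATT", "ATTT"]))
        assert tajima_d(s.mean_pairwise, s.S, s.n) == pytest.approx(0.168, abs=0.001)

    def test_hand_derived_negative_case(self):
        # three singleton-lineage mutations: mean pairwise 1.5
        s = summary_stats(make_aln(["AAA", "AAA", "AAA", "TTT"]))
        assert s.mean_pairwise == pytest.approx(1.5)
        assert tajima_d(s.mean_pairwise, s.S, s.n) == pytest.approx(-0.754, abs=0.001)

    def test_monomorphic_is_missing(self):
        assert tajima_d(0.0, 0, 10) is None

    def test_equals_theta_estimator_route_on_random_alignments(self):
        # independent re-derivation: D = (theta_pi - theta_W) / sd with
        # per-locus (not per-site) estimators
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(2, 6)) * 2  # builder pairs haplotypes per individual
            L = int(rng.integers(4, 20))
            seqs = ["".join(rng.choice(list("ACGT"), p=[0.7, 0.1, 0.1, 0.1], size=L)) for _ in range(n)]
            s = summary_stats(make_aln(seqs))
            if s.S == 0:
                continue
            c = tajima_constants(n)
            theta_pi = s.mean_pairwise
            theta_w = s.S / c["a1"]
            sd = np.sqrt(c["e1"] * s.S + c["e2"] * s.S * (s.S - 1))
            assert tajima_d(s.mean_pairwise, s.S, s.n) == pytest.approx(
                (theta_pi - theta_w) / sd, abs=1e-12
            )


class TestNeutralInterval:
    def test_same_seed_identical(self):
        r1 = neutral_interval(12, 8, reps=500, seed=3)
        r2 = neutral_interval(12, 8, reps=500, seed=3)
        assert r1[:2] == r2[:2]
        assert (r1[3] == r2[3]).all()

    def test_interval_brackets_zero_and_mean_slightly_negative(self):
        lo1, hi1, _, sims1 = neutral_interval(24, 20, reps=4000, seed=1)
        lo2, hi2, _, sims2 = neutral_interval(24, 20, reps=4000, seed=2)
        for lo, hi, sims in ((lo1, hi1, sims1), (lo2, hi2, sims2)):
            assert lo < 0 < hi
            assert -0.15 < sims.mean() < 0.05  # fixed-S D mean is mildly negative
        assert abs(sims1.mean() - sims2.mean()) < 0.05

    def test_median_observation_gives_p_near_one(self):
        _, _, p, sims = neutral_interval(12, 10, reps=2000, seed=5, d_obs=None)
        med = float(np.median(sims))
        _, _, p, _ = neutral_interval(12, 10, reps=2000, seed=5, d_obs=med)
        assert p > 0.9

    def test_fixed_s_with_two_haplotypes_is_degenerate(self):
        # every mutation separates the pair: mean pairwise == S exactly
        for seed in range(20):
            sam = coalsim.sim_neutral(2, S=5, seed=seed)
            assert sam.matrix.shape == (2, 5)
            assert (sam.matrix.sum(axis=0) == 1).all()

    def test_rejection_rate_near_nominal_under_own_null(self):
        # simulate data under the fixed-S null and test it against the same
        # null: rejection at the 2.5/97.5 interval should be ~5%
        n, S, reps = 20, 25, 6000
        lo, hi, _, sims = neutral_interval(n, S, reps=reps, seed=9)
        rng = np.random.default_rng(10)
        data = coalsim.simulate_fixed_s_pi(n, S, 4000, rng)
        c = tajima_constants(n)
        sd = np.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))
        d = (data - S / c["a1"]) / sd
        rate = float(((d < lo) | (d > hi)).mean())
        assert 0.03 < rate < 0.07


class TestMultilocusD:
    def test_identical_loci_preserve_observed_average(self):
        # two identical loci: the observed average equals the per-locus D and
        # the averaged null is narrower, so the multilocus p cannot exceed
        # the single-locus p by more than Monte-Carlo error
        seqs = ["AAAA", "AAAT", "AATT", "ATTT"] * 3
        ds = make_dataset({"L1": seqs, "L2": seqs})
        res = multilocus_d_test(ds, reps=3000, seed=4)
        single = tajima_test(ds.locus("L1"), reps=3000, seed=4)
        assert res["observed_average_D"] == pytest.approx(single.D)
        assert res["p_two_sided"] <= single.p_two_sided + 0.05

    def test_same_seed_reproducible(self):
        seqs = ["AAAA", "AAAT", "AATT", "ATTT"] * 2
        ds = make_dataset({"L1": seqs, "L2": seqs})
        r1 = multilocus_d_test(ds, reps=500, seed=7)
        r2 = multilocus_d_test(ds, reps=500, seed=7)
        assert r1["p_two_sided"] == r2["p_two_sided"]

    def test_strongly_negative_average_d_rejected(self):
        # singleton-heavy loci (expansion-like site pattern) at n=20
        rng = np.random.default_rng(0)
        loci = {}
        for l in range(4):
            base = ["A" * 30 for _ in range(20)]
            # 12 singleton mutations at distinct sites and haplotypes
            for k in range(12):
                i = int(rng.integers(20))
                s = list(base[i])
                s[k + l] = "T" if s[k + l] == "A" else "A"
                base[i] = "".join(s)
            loci[f"L{l}"] = base
        ds = make_dataset(loci)
        res = multilocus_d_test(ds, reps=2000, seed=1)
        assert res["observed_average_D"] < -1.0
        assert res["p_two_sided"] < 0.05


def fisher_two_tailed_oracle(a, b, c, d):
    """Point-probability rule by full hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2
    def pt(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(N, c1)
    p_obs = pt(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = pt(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


class TestMKTest:
    # printed two-tailed Fisher and uncorrected G p-values for the five loci
    PRINTED = [
        ("GapC", 3, 4, 10, 2, 0.12874, 0.06825),
        ("GBSSI", 12, 1, 23, 29, 0.00181, 0.00078),
        ("PgiC", 2, 1, 13, 9, 1.00000, 0.79974),
        ("SBE2", 1, 2, 4, 2, 0.52381, 0.34063),
        ("SODH", 1, 3, 7, 2, 0.21678, 0.06971),
    ]

    @pytest.mark.parametrize("locus,fs,fr,ps,pr,fisher,g", PRINTED)
    def test_published_tables_reproduce_to_all_decimals(self, locus, fs, fr, ps, pr, fisher, g):
        res = mk_test(fs, fr, ps, pr)
        assert round(res.fisher_p, 5) == fisher
        assert round(res.g_p, 5) == g

    def test_fisher_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            a, b, c, d = rng.integers(0, 21, size=4)
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            res = mk_test(int(a), int(c), int(b), int(d))
            oracle = fisher_two_tailed_oracle(int(a), int(b), int(c), int(d))
            assert res.fisher_p == pytest.approx(oracle, abs=1e-9)

    try:
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=60, deadline=None, derandomize=True)
        @given(st.tuples(*[st.integers(0, 25)] * 4))
        def test_fisher_oracle_property(self, counts):
            """Point-probability Fisher equals enumeration for any 2x2 table."""
            a, b, c, d = counts
            if min(a + b, c + d, a + c, b + d) == 0:
                return
            res = mk_test(a, c, b, d)
            assert res.fisher_p == pytest.approx(
                fisher_two_tailed_oracle(a, b, c, d), abs=1e-9
            )
    except ImportError:  # pragma: no cover - hypothesis is a test extra
        pass

    def test_zero_margin_degenerates(self):
        res = mk_test(0, 0, 5, 3)
        assert res.fisher_p == 1.0
        assert res.g_stat is None

    def test_counts_from_alignment_standard_convention(self):
        # polymorphic-and-divergent counts as polymorphic only
        aln = make_aln(["TTTAAA", "TTTAAA", "TTCAAA", "TTCAAA"], exons=[(0, 6, 0)])
        og = np.array(list("TTGGAA"), dtype="U1")
        counts = mk_counts(aln, og)
        # col2: focal polymorphic T/C (syn), outgroup G ignored as divergence
        # col3: fixed A vs G -> AAA->GAA replacement (Lys->Glu)
        assert counts["poly_syn"] == 1
        assert counts["fixed_rep"] == 1
        assert counts["fixed_syn"] == 0


class TestKaKs:
    def test_identical_sequences_zero(self):
        aln = make_aln(["TTTAAA", "TTTAAA"], exons=[(0, 6, 0)])
        ka, ks, ratio = ka_ks(aln, np.array(list("TTTAAA"), dtype="U1"))
        assert ka == 0 and ks == 0 and ratio is None

    def test_single_synonymous_difference(self):
        codons = "TTT" * 100
        aln = make_aln([codons, codons], exons=[(0, 300, 0)])
        og = list(codons)
        og[2] = "C"  # TTT->TTC synonymous
        ka, ks, _ = ka_ks(aln, np.array(og, dtype="U1"))
        assert ks > 0
        assert ka == 0

    def test_invariant_to_identical_outgroup_haplotype_choice(self):
        codons = "TTTAAA" * 50
        aln = make_aln([codons, codons], exons=[(0, 300, 0)])
        og = list(codons)
        og[2] = "C"
        og1 = np.array(og, dtype="U1")
        assert ka_ks(aln, og1) == ka_ks(aln, og1.copy())


class TestHKA:
    def test_proportional_loci_give_chi2_near_zero(self):
        S = np.array([10.0, 20.0, 30.0])
        D = np.array([5.0, 10.0, 15.0])
        n = np.array([10, 10, 10])
        res = hka_test(S, D, n)
        assert res.chi2_total == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0)
        assert res.df == 2

    def test_totals_conserved(self):
        res = hka_test(np.array([12.0, 30.0]), np.array([6.0, 7.0]), np.array([8, 12]))
        assert res.exp_poly.sum() + res.exp_div.sum() == pytest.approx(
            res.obs_poly.sum() + res.obs_div.sum(), abs=1e-6
        )
        assert res.exp_div.sum() == pytest.approx(res.obs_div.sum(), abs=1e-6)

    def test_two_locus_toy_matches_straight_line_oracle(self):
        # oracle: same estimating equations solved by brute-force grid search
        S = np.array([20.0, 10.0])
        D = np.array([8.0, 9.0])
        n = np.array([10, 10])
        a = np.array([harmonic(10)] * 2)
        b = np.array([harmonic(10, 2)] * 2)
        best = None
        for T in np.linspace(0.01, 20, 40001):
            theta = (S + D) / (a + T + 1)
            resid = abs((theta * (T + 1)).sum() - D.sum())
            if best is None or resid < best[0]:
                best = (resid, T, theta)
        _, T, theta = best
        exp_p, exp_d = theta * a, theta * (T + 1)
        x2 = (((S - exp_p) ** 2) / (exp_p + theta**2 * b)).sum() + (
            ((D - exp_d) ** 2) / (exp_d + theta**2)
        ).sum()
        res = hka_test(S, D, n)
        assert res.t_hat == pytest.approx(T, abs=1e-3)
        assert res.chi2_total == pytest.approx(x2, rel=1e-3)
        assert res.p == pytest.approx(float(chi2.sf(x2, 1)), rel=1e-3)

    def test_locus_order_invariance(self):
        S = np.array([20.0, 10.0, 4.0])
        D = np.array([8.0, 9.0, 2.0])
        n = np.array([10, 12, 8])
        r1 = hka_test(S, D, n)
        r2 = hka_test(S[::-1].copy(), D[::-1].copy(), n[::-1].copy())
        assert r1.chi2_total == pytest.approx(r2.chi2_total, abs=1e-9)

    def test_no_divergence_is_an_error(self):
        with pytest.raises(ValueError, match="divergence"):
            hka_test(np.array([5.0, 6.0]), np.array([0.0, 0.0]), np.array([6, 6]))
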