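"""Coverage equalization, hard filtering, discordance, F, and Wilcoxon tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fecalrad import concordance_stats as cs
from fecalrad import synth_community as sc
from fecalrad.synth_community import MISSING


class TestEqualizeCoverage:
    def test_already_equal_unchanged(self):
        a, b = np.array([500, 500]), np.array([250, 750])
        out_a, out_b = cs.equalize_coverage(a, b, seed=0)
        assert np.array_equal(out_a, a) and np.array_equal(out_b, b)

    def test_larger_downsampled_to_smaller_total(self):
        a, b = np.array([1500, 500]), np.array([600, 400])
        out_a, out_b = cs.equalize_coverage(a, b, seed=0)
        assert out_a.sum() == out_b.sum() == 1000
        assert np.array_equal(out_b, b), "smaller member preserved bit-exactly"
        assert np.all(out_a <= a)

    def test_hypergeometric_expectation(self):
        a = np.array([10, 10, 0])
        b = np.array([10])
        means = np.mean(
            [cs.equalize_coverage(a, b, seed=s)[0] for s in range(400)], axis=0
        )
        se = np.sqrt(10 * 0.5 * 0.5 * (10 / 19)) / np.sqrt(400)
        assert abs(means[0] - 5) <= 4 * se and abs(means[1] - 5) <= 4 * se
        assert means[2] == 0

    def test_empty_member_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cs.equalize_coverage(np.array([0, 0]), np.array([5]), seed=0)


def _records(**overrides):
    base = {
        "QD": 20.0, "MQ": 50.0, "FS": 10.0, "HaplotypeScore": 5.0,
        "MQRankSum": 0.0, "ReadPosRankSum": 0.0, "is_indel": False,
    }
    base.update(overrides)
    return pd.DataFrame([base])


class TestHardFilter:
    def test_low_qd_fails(self):
        assert not cs.apply_hard_filter(_records(QD=1.9)).iloc[0]

    def test_qd_boundary_is_strict(self):
        assert cs.apply_hard_filter(_records(QD=2.0)).iloc[0]

    @pytest.mark.parametrize(
        "col,bad",
        [("MQ", 39.9), ("FS", 60.1), ("HaplotypeScore", 13.1),
         ("MQRankSum", -12.6), ("ReadPosRankSum", -8.1)],
    )
    def test_each_condition_fails_alone(self, col, bad):
        assert not cs.apply_hard_filter(_records(**{col: bad})).iloc[0]

    @pytest.mark.parametrize(
        "col,boundary",
        [("MQ", 40.0), ("FS", 60.0), ("HaplotypeScore", 13.0),
         ("MQRankSum", -12.5), ("ReadPosRankSum", -8.0)],
    )
    def test_boundaries_pass(self, col, boundary):
        assert cs.apply_hard_filter(_records(**{col: boundary})).iloc[0]

    def test_indel_always_excluded(self):
        assert not cs.apply_hard_filter(_records(is_indel=True)).iloc[0]

    def test_missing_annotation_passes_subcondition(self):
        assert cs.apply_hard_filter(_records(MQRankSum=np.nan)).iloc[0]

    def test_idempotent(self):
        df = pd.concat(
            [_records(), _records(QD=1.0), _records(FS=100.0)], ignore_index=True
        )
        passed = df[cs.apply_hard_filter(df).to_numpy()]
        assert cs.apply_hard_filter(passed).all()


def _matrix(calls: np.ndarray) -> sc.GenotypeMatrix:
    n_samples, n_sites = calls.shape
    sites = pd.DataFrame(
        {
            "contig": "chr1", "pos": np.arange(n_sites), "ref": "A", "alt": "G",
            "p": np.full(n_sites, 0.5),
        }
    )
    return sc.GenotypeMatrix(
        [f"s{i}" for i in range(n_samples)], sites, calls.astype(np.int8)
    )


class TestGenotypeRateFilter:
    def test_site_boundary_90_percent(self):
        calls = np.zeros((10, 2), dtype=np.int8)
        calls[0, 0] = MISSING  # site 0 called in 9/10 -> kept
        calls[:2, 1] = MISSING  # site 1 called in 8/10 -> removed
        out, info = cs.genotype_rate_filter(_matrix(calls))
        assert out.n_sites == 1 and info["n_sites_removed"] == 1

    def test_toy_hand_enumeration(self):
        # 10 samples x 5 sites. Sample 3 is missing everywhere: sites 0-3
        # stay at call rate 9/10 = 0.9 (kept), while site 4 with a second
        # missing call drops to 8/10 (removed). Sample 3 is then genotyped
        # at 0 of the 4 retained sites (< 10%) and is removed.
        calls = np.zeros((10, 5), dtype=np.int8)
        calls[3, :] = MISSING
        calls[0, 4] = MISSING
        out, info = cs.genotype_rate_filter(_matrix(calls))
        assert out.n_sites == 4
        assert out.n_samples == 9
        assert info["n_samples_removed"] == 1 and info["n_sites_removed"] == 1

    def test_output_satisfies_both_rules(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(20, 50)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.2] = MISSING
        out, info = cs.genotype_rate_filter(_matrix(calls))
        if not info["empty"]:
            assert np.all(out.site_call_rates() >= 0.9)
            assert np.all(out.sample_call_rates() >= 0.1)

    def test_empty_result_flagged(self):
        calls = np.full((4, 3), MISSING, dtype=np.int8)
        out, info = cs.genotype_rate_filter(_matrix(calls))
        assert info["empty"]


class TestUniqueAlleles:
    def test_identical_callsets(self):
        a = np.array([0, 1, 2, 1])
        assert cs.unique_allele_proportion(a, a) == (0.0, 0.0)

    def test_het_versus_hom(self):
        # A = ref/alt, B = ref/ref: alt unique to A; A observed 2 alleles
        prop_a, prop_b = cs.unique_allele_proportion(np.array([1]), np.array([0]))
        assert prop_a == 0.5 and prop_b == 0.0

    def test_opposite_homozygotes(self):
        assert cs.unique_allele_proportion(np.array([0]), np.array([2])) == (1.0, 1.0)

    def test_missing_sites_excluded(self):
        a = np.array([1, MISSING, 0])
        b = np.array([0, 1, MISSING])
        # only site 0 jointly called
        assert cs.unique_allele_proportion(a, b) == (0.5, 0.0)

    def test_no_joint_sites_undefined(self):
        a = np.array([MISSING, 1])
        b = np.array([1, MISSING])
        res = cs.unique_allele_proportion(a, b)
        assert np.isnan(res[0]) and np.isnan(res[1])

    def test_symmetric_at_zero_dropout(self):
        truth = sc.simulate_genotypes(6, 5000, seed=0)
        blood, feces = sc.make_paired_callsets(
            truth, sc.DropoutModel(feces_extra_missing_rate=0.1), seed=1
        )
        props = [
            cs.unique_allele_proportion(blood.calls[i], feces.calls[i])
            for i in range(6)
        ]
        mean_b = np.mean([p[0] for p in props])
        mean_f = np.mean([p[1] for p in props])
        # calls are truthful, so nothing is unique to either member
        assert mean_b == 0.0 and mean_f == 0.0


class TestInbreedingF:
    def test_all_heterozygous_is_minus_one(self):
        calls = np.ones(10, dtype=np.int8)
        p = np.full(10, 0.5)
        assert cs.inbreeding_F(calls, p) == pytest.approx(-1.0)

    def test_all_homozygous_is_plus_one(self):
        calls = np.zeros(10, dtype=np.int8)
        p = np.full(10, 0.5)
        assert cs.inbreeding_F(calls, p) == pytest.approx(1.0)

    def test_four_site_hand_computation(self):
        calls = np.array([0, 1, 2, 0], dtype=np.int8)
        p = np.array([0.5, 0.5, 0.1, 0.9])
        # E_hom = 0.5 + 0.5 + 0.82 + 0.82 = 2.64; O_hom = 3
        assert cs.inbreeding_F(calls, p) == pytest.approx(0.36 / 1.36)

    def test_denominator_zero_is_nan(self):
        calls = np.array([0], dtype=np.int8)
        p = np.array([1.0])  # E_hom = 1 = N
        assert np.isnan(cs.inbreeding_F(calls, p))

    def test_missing_calls_excluded(self):
        calls = np.array([0, 1, 2, 0, MISSING], dtype=np.int8)
        p = np.array([0.5, 0.5, 0.1, 0.9, 0.5])
        assert cs.inbreeding_F(calls, p) == pytest.approx(0.36 / 1.36)

    def test_small_sample_correction_shrinks_e_hom(self):
        calls = np.array([0, 1, 2, 0], dtype=np.int8)
        p = np.array([0.5, 0.5, 0.1, 0.9])
        f_known = cs.inbreeding_F(calls, p)
        f_corr = cs.inbreeding_F(calls, p, n_chromosomes=12)
        # c > 1 lowers E_hom, so corrected F moves toward O_hom/N
        assert f_corr != f_known
        c = 12 / 11
        e_hom = float(np.sum(1 - 2 * p * (1 - p) * c))
        assert f_corr == pytest.approx((3 - e_hom) / (4 - e_hom))


def _signed_rank_enumeration(diffs: np.ndarray) -> float:
    """Independent oracle: literal enumeration of every sign assignment."""
    d = diffs[diffs != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        np.sum(ranks[np.array(signs, dtype=bool)])
        for signs in itertools.product([0, 1], repeat=len(d))
    ]
    ws = np.asarray(ws)
    eps = 1e-9
    p_le = np.mean(ws <= w_obs + eps)
    p_ge = np.mean(ws >= w_obs - eps)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestSignedRank:
    def test_identical_pairs_p_one(self):
        assert cs.signed_rank_test([0.0, 0.0, 0.0]).p_value == 1.0

    def test_six_positive_differences(self):
        res = cs.signed_rank_test([1, 2, 3, 4, 5, 6])
        assert res.p_value == pytest.approx(2 / 64)
        assert res.method == "exact"

    def test_symmetric_differences_centered(self):
        res = cs.signed_rank_test([1, -1, 2, -2, 3, -3])
        assert res.statistic == pytest.approx(10.5)
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        d = rng.normal(size=n).round(1)  # rounding creates occasional ties
        assert cs.signed_rank_test(d).p_value == pytest.approx(
            _signed_rank_enumeration(d)
        )

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(42)
        d = rng.normal(size=10)
        ours = cs.signed_rank_test(d)
        ref = stats.wilcoxon(d, zero_method="wilcox", method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_large_n_uses_approximation(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.5, 1.0, size=40)
        res = cs.signed_rank_test(d)
        assert res.method == "approx" and 0 <= res.p_value <= 1


def _rank_sum_enumeration(a: np.ndarray, b: np.ndarray) -> float:
    """Independent oracle: every distinct labeling via permutations."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n = len(a)
    w_obs = ranks[:n].sum()
    ws = [
        np.sum(ranks[list(perm)][:n])
        for perm in itertools.permutations(range(len(pooled)))
    ]
    ws = np.asarray(ws)
    eps = 1e-9
    p_le = np.mean(ws <= w_obs + eps)
    p_ge = np.mean(ws >= w_obs - eps)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestRankSum:
    def test_identical_groups(self):
        res = cs.rank_sum_test([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0

    def test_fully_separated_groups(self):
        res = cs.rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_permutation_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(2, 4)), int(rng.integers(2, 5))
        a = rng.normal(size=n).round(1)
        b = rng.normal(size=m).round(1)
        assert cs.rank_sum_test(a, b).p_value == pytest.approx(
            _rank_sum_enumeration(a, b)
        )

    def test_p_decreases_with_shift(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=30)
        ps = [
            cs.rank_sum_test(a, a + shift).p_value for shift in (0.0, 0.5, 1.0, 2.0)
        ]
        assert all(x >= y for x, y in zip(ps, ps[1:]))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            cs.rank_sum_test([], [1.0])


class TestPairedConcordance:
    def test_null_simulation_reports_symmetry(self):
        truth = sc.simulate_genotypes(6, 3000, seed=3)
        blood, feces = sc.make_paired_callsets(
            truth, sc.DropoutModel(feces_extra_missing_rate=0.05), seed=4
        )
        rep = cs.paired_concordance(blood, feces)
        assert rep["n_pairs"] == 6
        assert rep["mean_unique_blood"] == rep["mean_unique_feces"] == 0.0
        assert abs(rep["mean_F_feces"] - rep["mean_F_blood"]) < 0.05
        assert rep["inbreeding_test"].p_value > 0.05

    def test_dropout_inflates_f_monotonically(self):
        means = []
        for d in (0.0, 0.2, 0.4):
            truth = sc.simulate_genotypes(6, 4000, seed=10)
            blood, feces = sc.make_paired_callsets(
                truth, sc.DropoutModel(feces_allelic_dropout_rate=d), seed=11
            )
            rep = cs.paired_concordance(blood, feces)
            means.append(rep["mean_F_feces"] - rep["mean_F_blood"])
        assert means[0] < means[1] < means[2]
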