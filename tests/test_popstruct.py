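"""LD pruning, IBS, classical MDS, and per-site sample-type tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from fecalrad import popstruct as ps
from fecalrad import synth_community as sc
from fecalrad.synth_community import MISSING


def _matrix(calls: np.ndarray, types=None) -> sc.GenotypeMatrix:
    n_samples, n_sites = calls.shape
    sites = pd.DataFrame(
        {
            "contig": "chr1", "pos": np.arange(n_sites) * 10, "ref": "A", "alt": "G",
            "p": np.full(n_sites, 0.5),
        }
    )
    return sc.GenotypeMatrix(
        [f"s{i}" for i in range(n_samples)], sites, calls.astype(np.int8),
        sample_types=types,
    )


class TestLdR2:
    def test_identical_dosages(self):
        g = np.array([0, 1, 2, 1, 0])
        assert ps.ld_r2(g, g) == pytest.approx(1.0)

    def test_constant_site_undefined(self):
        assert np.isnan(ps.ld_r2(np.array([0, 1, 2]), np.array([1, 1, 1])))

    def test_orthogonal_dosages(self):
        a = np.array([0, 0, 2, 2])
        b = np.array([0, 2, 0, 2])
        assert ps.ld_r2(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_joint_calls_only(self):
        a = np.array([0, 1, 2, MISSING, 0, 2])
        b = np.array([0, 1, 2, 2, MISSING, 2])
        assert ps.ld_r2(a, b) == pytest.approx(1.0)


class TestLdPrune:
    def test_uncorrelated_sites_unchanged(self):
        rng = np.random.default_rng(0)
        gm = _matrix(rng.integers(0, 3, size=(30, 40)))
        kept = ps.ld_prune(gm, seed=1)
        assert kept.size == 40

    def test_duplicated_column_one_removed(self):
        rng = np.random.default_rng(1)
        base = rng.integers(0, 3, size=(20, 10))
        base[:, 7] = base[:, 3]
        kept = ps.ld_prune(_matrix(base), seed=2)
        assert kept.size == 9
        assert (3 in kept) != (7 in kept)

    def test_five_identical_columns_one_survivor(self):
        rng = np.random.default_rng(2)
        base = rng.integers(0, 3, size=(20, 12))
        for j in (2, 4, 6, 8):
            base[:, j] = base[:, 0]
        kept = ps.ld_prune(_matrix(base), seed=3)
        survivors = [j for j in (0, 2, 4, 6, 8) if j in kept]
        assert len(survivors) == 1
        assert kept.size == 8

    def test_no_offending_pair_remains(self):
        rng = np.random.default_rng(3)
        base = rng.integers(0, 3, size=(15, 60))
        # plant correlated blocks
        for j in range(0, 60, 7):
            base[:, j] = base[:, (j + 3) % 60]
        gm = _matrix(base)
        kept = ps.ld_prune(gm, window=10, seed=4)
        for w0 in range(kept.size):
            widx = kept[w0 : w0 + 10]
            for x in range(widx.size):
                for y in range(x + 1, widx.size):
                    r2 = ps.ld_r2(gm.calls[:, widx[x]], gm.calls[:, widx[y]])
                    assert not (r2 > 0.5)


class TestIBS:
    def test_duplicate_samples_ibs_one(self):
        calls = np.array([[0, 1, 2, 1], [0, 1, 2, 1]])
        ibs = ps.ibs_matrix(_matrix(calls))
        assert ibs.values[0, 1] == 1.0

    def test_opposite_homozygotes_ibs_zero(self):
        calls = np.array([[0, 0, 0], [2, 2, 2]])
        ibs = ps.ibs_matrix(_matrix(calls))
        assert ibs.values[0, 1] == 0.0

    def test_het_versus_hom_half(self):
        calls = np.array([[1], [0]])
        ibs = ps.ibs_matrix(_matrix(calls))
        assert ibs.values[0, 1] == 0.5

    def test_zero_joint_sites_nan(self):
        calls = np.array([[0, MISSING], [MISSING, 2]])
        ibs = ps.ibs_matrix(_matrix(calls))
        assert np.isnan(ibs.values[0, 1])
        assert ibs.joint_counts[0, 1] == 0


class TestMDS:
    def test_equilateral_triangle(self):
        d = np.ones((3, 3)) - np.eye(3)
        coords, eigvals = ps.mds(d, k=2)
        recovered = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.allclose(recovered, d, atol=1e-9)
        assert eigvals[0] == pytest.approx(eigvals[1])
        assert eigvals[0] > 0

    def test_duplicate_points_coincide(self):
        d = np.array(
            [[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]]
        )
        coords, _ = ps.mds(d, k=2)
        # the second eigenvalue is ~0; its eigenvector contributes only noise
        assert np.linalg.norm(coords[0] - coords[1]) < 1e-7

    def test_planted_two_dimensional_recovery(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(12, 2))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        coords, _ = ps.mds(d, k=2)
        recovered = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.abs(recovered - d).max() < 1e-9

    def test_undefined_entries_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError, match="undefined"):
            ps.mds(d)


class TestAssociation:
    def test_identical_allele_counts_p_one(self):
        # both groups: one hom-ref, one het, one hom-alt
        calls = np.array([[0, 0], [1, 1], [2, 2], [0, 0], [1, 1], [2, 2]])
        gm = _matrix(calls, types=["blood"] * 3 + ["feces"] * 3)
        res = ps.sample_type_association(gm)
        assert np.allclose(res["chi2"], 0.0)
        assert np.allclose(res["p"], 1.0)

    def test_hand_computed_table(self):
        # blood: 10 ref alleles; feces: 10 alt alleles -> chi2 = 20
        calls = np.array([[0]] * 5 + [[2]] * 5)
        gm = _matrix(calls, types=["blood"] * 5 + ["feces"] * 5)
        res = ps.sample_type_association(gm)
        assert res["chi2"].iloc[0] == pytest.approx(20.0)

    def test_monomorphic_site_skipped(self):
        calls = np.zeros((6, 1), dtype=np.int8)
        gm = _matrix(calls, types=["blood"] * 3 + ["feces"] * 3)
        res = ps.sample_type_association(gm)
        assert np.isnan(res["p"].iloc[0])

    def test_matches_scipy_contingency(self):
        rng = np.random.default_rng(7)
        calls = rng.integers(0, 3, size=(20, 30))
        gm = _matrix(calls, types=["blood"] * 10 + ["feces"] * 10)
        res = ps.sample_type_association(gm)
        for j in range(30):
            ref1 = int((2 - calls[:10, j]).sum())
            alt1 = int(calls[:10, j].sum())
            ref2 = int((2 - calls[10:, j]).sum())
            alt2 = int(calls[10:, j].sum())
            table = np.array([[ref1, alt1], [ref2, alt2]])
            if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
                assert np.isnan(res["p"].iloc[j])
                continue
            chi2, p, _, _ = chi2_contingency(table, correction=False)
            assert res["chi2"].iloc[j] == pytest.approx(chi2)
            assert res["p"].iloc[j] == pytest.approx(p)

    def test_one_group_empty_rejected(self):
        gm = _matrix(np.zeros((3, 2), dtype=np.int8), types=["blood"] * 3)
        with pytest.raises(ValueError, match="two sample types"):
            ps.sample_type_association(gm)


class TestMissingness:
    def test_equal_missingness_p_one(self):
        calls = np.array([[0, MISSING], [0, 0], [0, MISSING], [0, 0]])
        gm = _matrix(calls, types=["blood", "blood", "feces", "feces"])
        res = ps.missingness_test(gm)
        assert res["p"].iloc[1] == pytest.approx(1.0)

    def test_hand_computed_twelve(self):
        # 6 blood all called, 6 feces all missing -> chi2 = 12
        calls = np.concatenate(
            [np.zeros((6, 1)), np.full((6, 1), MISSING)]
        )
        gm = _matrix(calls, types=["blood"] * 6 + ["feces"] * 6)
        res = ps.missingness_test(gm)
        assert res["chi2"].iloc[0] == pytest.approx(12.0)

    def test_fully_called_site_skipped(self):
        calls = np.zeros((6, 1), dtype=np.int8)
        gm = _matrix(calls, types=["blood"] * 3 + ["feces"] * 3)
        res = ps.missingness_test(gm)
        assert np.isnan(res["p"].iloc[0])


class TestSameIndividual:
    def _ibs(self, values, ids):
        return ps.IBSMatrix(np.asarray(values, dtype=float), ids,
                            np.full((len(ids), len(ids)), 100))

    def test_identical_members_distance_zero(self):
        ibs = self._ibs([[1.0, 1.0], [1.0, 1.0]], ["i1_B", "i1_F"])
        out = ps.same_individual_distance(ibs, {"i1": ("i1_B", "i1_F")})
        assert out["within_distance"] == [0.0]
        assert out["test"] is None  # single pair: test skipped

    def test_planted_clusters_within_below_between(self):
        truth, labels = sc.simulate_structured_genotypes(
            [3, 3], 2000, divergence=0.3, seed=8
        )
        blood, feces = sc.make_paired_callsets(truth, sc.DropoutModel(), seed=9)
        merged = sc.merge_matrices(blood, feces)
        ibs = ps.ibs_matrix(merged)
        pairs = {ind: (f"{ind}_B", f"{ind}_F") for ind in truth.individuals}
        out = ps.same_individual_distance(ibs, pairs)
        within = np.array(out["within_distance"])
        between = np.array(out["between_distance"])
        assert np.all(within < between)
        assert out["test"].p_value < 0.05

    def test_missing_member_skipped_with_warning(self):
        ibs = self._ibs([[1.0, 0.9], [0.9, 1.0]], ["i1_B", "i1_F"])
        with pytest.warns(UserWarning, match="missing member"):
            out = ps.same_individual_distance(
                ibs, {"i1": ("i1_B", "i1_F"), "i2": ("i2_B", "i2_F")}
            )
        assert out["individuals"] == ["i1"]


def test_structured_populations_separate_on_mds():
    """Two diverged populations split on component 1; same-individual
    blood/feces pairs sit closer than any cross-individual pair."""
    truth, labels = sc.simulate_structured_genotypes(
        [4, 4], 3000, divergence=0.25, seed=21
    )
    blood, feces = sc.make_paired_callsets(
        truth, sc.DropoutModel(feces_extra_missing_rate=0.05), seed=22
    )
    merged = sc.merge_matrices(blood, feces)
    ibs = ps.ibs_matrix(merged)
    coords, _ = ps.mds(ibs.distance(), k=2)
    pop = np.array(labels + labels)
    c1 = coords[:, 0]
    # silhouette on component 1 > 0: within-population spread below separation
    mu0, mu1 = c1[pop == 0].mean(), c1[pop == 1].mean()
    sil = []
    for i in range(c1.size):
        own = np.abs(c1[i] - c1[(pop == pop[i])]).sum() / max(1, (pop == pop[i]).sum() - 1)
        other = np.abs(c1[i] - c1[(pop != pop[i])]).mean()
        sil.append((other - own) / max(own, other))
    assert np.mean(sil) > 0
    assert abs(mu0 - mu1) > 0
    # mutual nearest neighbours: each blood sample's closest other sample is
    # its own feces twin
    d = ibs.distance()
    np.fill_diagonal(d, np.inf)
    n = truth.n_samples
    for i in range(n):
        assert np.argmin(d[i]) == n + i
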