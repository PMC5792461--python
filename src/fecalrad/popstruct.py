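"""Stringent SNP-set construction and population-structure statistics.

Covers the post-filter analyses of a paired blood/feces study: linkage-
disequilibrium pruning by pairwise dosage r-squared in sliding SNP
windows, pairwise identity-by-state (IBS), classical (Torgerson)
multidimensional scaling of 1 - IBS distances, per-site chi-square tests
for allele-frequency or missingness association with sample type, and the
same-individual blood/feces distance comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .concordance_stats import TestResult, signed_rank_test
from .synth_community import MISSING, GenotypeMatrix

# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def ld_r2(genotypes_i: np.ndarray, genotypes_j: np.ndarray) -> float:
    """Squared Pearson correlation of alt-allele dosages over joint calls.

    Returns NaN when fewer than 2 samples are jointly called or either
    site has zero dosage variance (pruning treats NaN as 0).
    """
    gi = np.asarray(genotypes_i, dtype=float)
    gj = np.asarray(genotypes_j, dtype=float)
    joint = (gi != MISSING) & (gj != MISSING)
    if joint.sum() < 2:
        return float("nan")
    x, y = gi[joint], gj[joint]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _window_r2(calls: np.ndarray) -> np.ndarray:
    """Pairwise r^2 for a (samples x sites) dosage block with missing data."""
    g = calls.astype(float)
    g[g == MISSING] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pairwise-complete corr emits noise
        r = pd.DataFrame(g).corr(min_periods=2).to_numpy()
    return r * r


def ld_prune(
    matrix: GenotypeMatrix,
    window: int = 50,
    r2_threshold: float = 0.5,
    seed=None,
) -> np.ndarray:
    """Indices of sites retained after sliding-window LD pruning.

    A window of ``window`` SNPs slides one retained SNP at a time along the
    site order; within a window, each pair with r^2 above the threshold
    loses one member chosen uniformly at random. Passes repeat until no
    offending pair remains in any window. Output preserves site order.
    """
    rng = np.random.default_rng(seed)
    keep = np.ones(matrix.n_sites, dtype=bool)
    changed = True
    while changed:
        changed = False
        idx = np.flatnonzero(keep)
        for w0 in range(0, max(1, idx.size - 1)):
            widx = idx[w0 : w0 + window]
            widx = widx[keep[widx]]
            if widx.size < 2:
                continue
            r2 = _window_r2(matrix.calls[:, widx])
            iu, ju = np.triu_indices(widx.size, k=1)
            offending = np.flatnonzero(np.nan_to_num(r2[iu, ju]) > r2_threshold)
            for k in offending:
                a, b = widx[iu[k]], widx[ju[k]]
                if keep[a] and keep[b]:
                    victim = a if rng.random() < 0.5 else b
                    keep[victim] = False
                    changed = True
    return np.flatnonzero(keep)


# ---------------------------------------------------------------------------
# IBS and MDS
# ---------------------------------------------------------------------------


@dataclass
class IBSMatrix:
    """Pairwise identity-by-state with per-pair joint-call counts."""

    values: np.ndarray
    sample_ids: list[str]
    joint_counts: np.ndarray

    def distance(self) -> np.ndarray:
        return 1.0 - self.values


def ibs_matrix(matrix: GenotypeMatrix) -> IBSMatrix:
    """Mean per-site allele sharing between every pair of samples.

    For biallelic dosages the shared-allele fraction at one site is
    ``1 - |d_i - d_j| / 2`` (identical genotypes 1, het vs hom 0.5,
    opposite homozygotes 0); entries with zero jointly-called sites are
    NaN.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    g = matrix.calls.astype(float)
    g[g == MISSING] = np.nan
    n = matrix.n_samples
    vals = np.ones((n, n))
    counts = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(counts, matrix.called().sum(axis=1))
    for i in range(n):
        for j in range(i + 1, n):
            diff = np.abs(g[i] - g[j])
            joint = ~np.isnan(diff)
            counts[i, j] = counts[j, i] = int(joint.sum())
            if counts[i, j] == 0:
                vals[i, j] = vals[j, i] = np.nan
            else:
                ibs = float(np.mean(1.0 - diff[joint] / 2.0))
                vals[i, j] = vals[j, i] = ibs
    return IBSMatrix(vals, list(matrix.sample_ids), counts)


def mds(distance: np.ndarray, k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers ``-D^2 / 2``, eigendecomposes, and returns the top-k
    coordinates (eigenvectors scaled by sqrt eigenvalue) plus the full
    eigenvalue spectrum in descending order. Negative eigenvalues (non-
    Euclidean distances) are truncated to zero with a warning. Distances
    are reproduced exactly when D embeds in k Euclidean dimensions.
    """
    d = np.asarray(distance, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance must be a square matrix")
    if np.isnan(d).any():
        raise ValueError(
            "distance matrix has undefined entries; filter samples with no "
            "jointly-called sites first"
        )
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if np.any(eigval[:k] < -1e-10 * max(1.0, abs(eigval[0]))):
        warnings.warn("negative eigenvalues truncated: distances are non-Euclidean")
    lam = np.clip(eigval[:k], 0.0, None)
    coords = eigvec[:, :k] * np.sqrt(lam)
    return coords, eigval


# ---------------------------------------------------------------------------
# per-site chi-square tests
# ---------------------------------------------------------------------------


def _two_group_masks(sample_types: list[str]) -> tuple[np.ndarray, np.ndarray]:
    types = np.asarray(sample_types)
    groups = sorted(set(types))
    if len(groups) != 2:
        raise ValueError(f"need exactly two sample types, got {groups}")
    return types == groups[0], types == groups[1]


def _chi2_2x2(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray):
    """Vectorized 2x2 chi-square without continuity correction.

    Rows (a, b) and (c, d) per table; returns (chi2, p, min expected),
    NaN where a margin is empty.
    """
    a, b, c, d = (x.astype(float) for x in (a, b, c, d))
    total = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    valid = (r1 > 0) & (r2 > 0) & (c1 > 0) & (c2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.stack([r1 * c1, r1 * c2, r2 * c1, r2 * c2]) / total
        o = np.stack([a, b, c, d])
        chi2 = np.where(valid, np.nansum((o - e) ** 2 / e, axis=0), np.nan)
        p = np.where(valid, stats.chi2.sf(chi2, df=1), np.nan)
        min_expected = np.where(valid, e.min(axis=0), np.nan)
    return chi2, p, min_expected


def sample_type_association(
    matrix: GenotypeMatrix, sample_types: list[str] | None = None
) -> pd.DataFrame:
    """Per-site chi-square of allele counts against sample type.

    Builds the 2x2 table of (ref, alt) allele counts by type from called
    genotypes (2 alleles per call) and applies the chi-square test without
    continuity correction. Monomorphic sites and empty margins yield NaN;
    tables with any expected count below 5 are flagged, not switched to a
    different test.
    """
    types = sample_types if sample_types is not None else matrix.sample_types
    if types is None:
        raise ValueError("sample types required")
    g1, g2 = _two_group_masks(types)
    called = matrix.called()
    dose = matrix.calls.astype(np.int64)
    dose_called = np.where(called, dose, 0)
    alt1 = dose_called[g1].sum(axis=0)
    alt2 = dose_called[g2].sum(axis=0)
    tot1 = 2 * called[g1].sum(axis=0)
    tot2 = 2 * called[g2].sum(axis=0)
    chi2, p, min_e = _chi2_2x2(tot1 - alt1, alt1, tot2 - alt2, alt2)
    return pd.DataFrame(
        {
            "contig": matrix.sites["contig"],
            "pos": matrix.sites["pos"],
            "chi2": chi2,
            "p": p,
            "low_expected": min_e < 5,
        }
    )


def missingness_test(
    matrix: GenotypeMatrix, sample_types: list[str] | None = None
) -> pd.DataFrame:
    """Per-site chi-square of called/missing counts against sample type."""
    types = sample_types if sample_types is not None else matrix.sample_types
    if types is None:
        raise ValueError("sample types required")
    g1, g2 = _two_group_masks(types)
    called = matrix.called()
    c1 = called[g1].sum(axis=0)
    c2 = called[g2].sum(axis=0)
    m1 = int(g1.sum()) - c1
    m2 = int(g2.sum()) - c2
    chi2, p, min_e = _chi2_2x2(c1, m1, c2, m2)
    return pd.DataFrame(
        {
            "contig": matrix.sites["contig"],
            "pos": matrix.sites["pos"],
            "chi2": chi2,
            "p": p,
            "low_expected": min_e < 5,
        }
    )


def count_significant(results: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Number and proportion of testable sites with p below alpha."""
    tested = results["p"].notna()
    n_tested = int(tested.sum())
    n_sig = int((results.loc[tested, "p"] < alpha).sum())
    return {
        "alpha": alpha,
        "n_tested": n_tested,
        "n_significant": n_sig,
        "proportion": n_sig / n_tested if n_tested else float("nan"),
    }


def significant_site_percentage(n_significant: int, n_total: int) -> float:
    """Percentage of significant sites from a numerator/denominator pair."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_significant <= n_total:
        raise ValueError("n_significant must lie in [0, n_total]")
    return 100.0 * n_significant / n_total


# ---------------------------------------------------------------------------
# same-individual distances
# ---------------------------------------------------------------------------


def same_individual_distance(
    ibs: IBSMatrix, pairs: dict[str, tuple[str, str]]
) -> dict:
    """Within-individual cross-type distances versus between-individual ones.

    ``pairs`` maps individual id to its (blood sample id, feces sample id).
    For each pair the within distance is 1 - IBS between its two members;
    the between distance is the mean 1 - IBS from the blood member to the
    feces members of all *other* individuals. Reports both plus a
    signed-rank test of within - between (skipped when fewer than 2 usable
    pairs).
    """
    index = {s: i for i, s in enumerate(ibs.sample_ids)}
    d = ibs.distance()
    within, between, used = [], [], []
    feces_members = {ind: f for ind, (_, f) in pairs.items()}
    for ind, (s_blood, s_feces) in pairs.items():
        if s_blood not in index or s_feces not in index:
            warnings.warn(f"pair {ind}: missing member, skipped")
            continue
        i, j = index[s_blood], index[s_feces]
        within.append(float(d[i, j]))
        others = [
            float(d[i, index[f]])
            for other, f in feces_members.items()
            if other != ind and f in index
        ]
        between.append(float(np.mean(others)) if others else float("nan"))
        used.append(ind)
    result: TestResult | None = None
    diffs = [w - b for w, b in zip(within, between) if not np.isnan(b)]
    if len(diffs) >= 2:
        result = signed_rank_test(diffs)
    return {
        "individuals": used,
        "within_distance": within,
        "between_distance": between,
        "test": result,
    }
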