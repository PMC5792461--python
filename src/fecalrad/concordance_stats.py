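"""Paired blood/feces genotype-concordance statistics.

The validation logic for methylation-based fecal enrichment: if capture
biased genotyping, feces-derived call sets would show (i) an excess of
alleles unique to blood, and (ii) inflated method-of-moments inbreeding
coefficients F from lost heterozygotes. This module implements the
machinery those comparisons need — coverage equalization between paired
samples, GATK-style hard filtering of variant records, site/sample
genotyping-rate filtering, unique-allele discordance, F, and Wilcoxon
signed-rank / rank-sum tests with exact small-sample null distributions.

The method-of-moments inbreeding coefficient for one sample over N called
biallelic sites with reference-allele frequencies p is::

    F = (O_hom - E_hom) / (N - E_hom),
    E_hom = sum over sites of 1 - 2 p q c

with c = n_chrom / (n_chrom - 1) the small-sample correction when the
frequencies were estimated from n_chrom chromosomes, and c = 1 when they
are known. Allelic dropout converts heterozygotes to homozygotes, raising
O_hom and hence F by (approximately) the dropout rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synth_community import MISSING, GenotypeMatrix

# ---------------------------------------------------------------------------
# coverage equalization
# ---------------------------------------------------------------------------


def equalize_coverage(
    counts_a: np.ndarray, counts_b: np.ndarray, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Downsample the deeper member of a pair to the shallower one's total.

    Works on per-locus read-count vectors: the larger vector is subsampled
    without replacement (multivariate hypergeometric) to the smaller
    vector's total. The smaller member is returned unchanged.
    """
    a = np.asarray(counts_a, dtype=np.int64)
    b = np.asarray(counts_b, dtype=np.int64)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("read counts must be nonnegative")
    ta, tb = int(a.sum()), int(b.sum())
    if min(ta, tb) == 0:
        raise ValueError("cannot equalize against an empty read set")
    if ta == tb:
        return a.copy(), b.copy()
    rng = np.random.default_rng(seed)
    if ta > tb:
        return rng.multivariate_hypergeometric(a, tb).astype(np.int64), b.copy()
    return a.copy(), rng.multivariate_hypergeometric(b, ta).astype(np.int64)


# ---------------------------------------------------------------------------
# variant hard filtering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HardFilterThresholds:
    """Standard short-variant hard-filter thresholds (all overridable)."""

    qd_min: float = 2.0
    mq_min: float = 40.0
    fs_max: float = 60.0
    haplotype_score_max: float = 13.0
    mq_rank_sum_min: float = -12.5
    read_pos_rank_sum_min: float = -8.0


#: Annotation column, threshold attribute, and failing direction.
_FILTER_RULES = (
    ("QD", "qd_min", "lt"),
    ("MQ", "mq_min", "lt"),
    ("FS", "fs_max", "gt"),
    ("HaplotypeScore", "haplotype_score_max", "gt"),
    ("MQRankSum", "mq_rank_sum_min", "lt"),
    ("ReadPosRankSum", "read_pos_rank_sum_min", "lt"),
)


def apply_hard_filter(
    records: pd.DataFrame,
    thresholds: HardFilterThresholds = HardFilterThresholds(),
) -> pd.Series:
    """PASS/fail per variant record under the hard-filter thresholds.

    ``records`` carries the INFO annotations as columns (NaN where the
    caller did not emit one — an absent annotation cannot fail its
    sub-condition) plus a boolean ``is_indel`` column; indels always fail.
    Conditions are strict inequalities: a record fails iff QD < 2.0,
    MQ < 40.0, FS > 60.0, HaplotypeScore > 13.0, MQRankSum < -12.5 or
    ReadPosRankSum < -8.0 (defaults). Returns a boolean Series, True = PASS.
    """
    n = len(records)
    fail = np.zeros(n, dtype=bool)
    for col, attr, direction in _FILTER_RULES:
        if col not in records.columns:
            continue
        vals = pd.to_numeric(records[col], errors="coerce")
        thr = getattr(thresholds, attr)
        this = (vals < thr) if direction == "lt" else (vals > thr)
        fail |= this.fillna(False).to_numpy()
    if "is_indel" in records.columns:
        fail |= records["is_indel"].fillna(False).astype(bool).to_numpy()
    return pd.Series(~fail, index=records.index, name="pass")


# ---------------------------------------------------------------------------
# genotyping-rate filtering
# ---------------------------------------------------------------------------


def genotype_rate_filter(
    matrix: GenotypeMatrix,
    site_rate_min: float = 0.9,
    sample_rate_min: float = 0.1,
) -> tuple[GenotypeMatrix, dict]:
    """Stringent genotyping-rate filter: sites first, then samples.

    Sites are kept when called in at least ``site_rate_min`` of samples;
    samples are then kept when genotyped at at least ``sample_rate_min`` of
    the *retained* sites (both boundaries inclusive).
    """
    if matrix.n_sites == 0 or matrix.n_samples == 0:
        raise ValueError("matrix must be nonempty")
    site_keep = matrix.site_call_rates() >= site_rate_min
    trimmed = matrix.subset(site_idx=np.flatnonzero(site_keep))
    if trimmed.n_sites == 0:
        return trimmed, {"empty": True, "n_sites_kept": 0, "n_samples_kept": 0}
    sample_keep = trimmed.sample_call_rates() >= sample_rate_min
    out = trimmed.subset(sample_idx=np.flatnonzero(sample_keep))
    info = {
        "empty": out.n_sites == 0 or out.n_samples == 0,
        "n_sites_kept": out.n_sites,
        "n_samples_kept": out.n_samples,
        "n_sites_removed": int((~site_keep).sum()),
        "n_samples_removed": int((~sample_keep).sum()),
    }
    return out, info


# ---------------------------------------------------------------------------
# unique-allele discordance
# ---------------------------------------------------------------------------


def unique_allele_proportion(
    calls_a: np.ndarray, calls_b: np.ndarray
) -> tuple[float, float]:
    """Proportion of alleles unique to each member over jointly-called sites.

    Genotypes are compared as allele *sets* (dosage 0 -> {ref}, 1 ->
    {ref, alt}, 2 -> {alt}). An allele is unique to A at a site when it is
    present in A's genotype and absent from B's. The proportion for A is
    unique-to-A alleles over all distinct alleles observed in A, summed
    over sites called in both members; symmetric for B. Returns (nan, nan)
    when no site is jointly called.
    """
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    if a.shape != b.shape:
        raise ValueError("call vectors must have equal length")
    joint = (a != MISSING) & (b != MISSING)
    if not joint.any():
        return float("nan"), float("nan")
    a, b = a[joint], b[joint]
    ref_a, alt_a = a <= 1, a >= 1
    ref_b, alt_b = b <= 1, b >= 1
    unique_a = int((ref_a & ~ref_b).sum() + (alt_a & ~alt_b).sum())
    unique_b = int((ref_b & ~ref_a).sum() + (alt_b & ~alt_a).sum())
    total_a = int(ref_a.sum() + alt_a.sum())
    total_b = int(ref_b.sum() + alt_b.sum())
    return unique_a / total_a, unique_b / total_b


# ---------------------------------------------------------------------------
# inbreeding coefficient
# ---------------------------------------------------------------------------


def inbreeding_F(
    calls: np.ndarray,
    site_freqs: np.ndarray,
    n_chromosomes: int | None = None,
) -> float:
    """Method-of-moments F for one sample; see module docstring.

    ``n_chromosomes`` enables the small-sample correction
    ``c = n/(n-1)`` when ``site_freqs`` were estimated from n chromosomes;
    leave ``None`` for known frequencies (c = 1). Returns NaN when the
    denominator ``N - E_hom`` vanishes.
    """
    g = np.asarray(calls)
    p = np.asarray(site_freqs, dtype=float)
    if g.shape != p.shape:
        raise ValueError("calls and site_freqs must have equal length")
    called = g != MISSING
    g, p = g[called], p[called]
    n = g.size
    if n == 0:
        return float("nan")
    c = 1.0
    if n_chromosomes is not None:
        if n_chromosomes < 2:
            raise ValueError("n_chromosomes must be >= 2 for the correction")
        c = n_chromosomes / (n_chromosomes - 1.0)
    e_hom = float(np.sum(1.0 - 2.0 * p * (1.0 - p) * c))
    o_hom = int(np.sum((g == 0) | (g == 2)))
    denom = n - e_hom
    if denom == 0:
        return float("nan")
    return (o_hom - e_hom) / denom


def inbreeding_F_matrix(
    matrix: GenotypeMatrix, n_chromosomes: int | None = None
) -> pd.Series:
    """Per-sample F using the site frequencies carried by the matrix."""
    p = matrix.sites["p"].to_numpy()
    vals = [inbreeding_F(matrix.calls[i], p, n_chromosomes)
            for i in range(matrix.n_samples)]
    return pd.Series(vals, index=matrix.sample_ids, name="F")


# ---------------------------------------------------------------------------
# Wilcoxon tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str  # "exact" | "approx" | "degenerate"

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "p": self.p_value,
                "n": self.n, "method": self.method}


SIGNED_RANK_EXACT_MAX_N = 15


def signed_rank_test(differences: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped before ranking. For n <= 15 the exact
    null distribution of W+ is built over all 2^n sign assignments of the
    observed (possibly tied) ranks; larger n uses the tie-corrected normal
    approximation. All-zero differences give p = 1.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, 0, "degenerate")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= SIGNED_RANK_EXACT_MAX_N:
        # doubled ranks are integers even under ties; DP over subset sums
        # enumerates the 2^n equiprobable sign assignments exactly
        r2 = np.round(2 * ranks).astype(np.int64)
        dist = np.zeros(int(r2.sum()) + 1, dtype=np.float64)
        dist[0] = 1.0
        for r in r2:
            dist[r:] += dist[:-r].copy() if r else dist.copy()
        dist /= 2.0**n
        w2 = int(round(2 * w_plus))
        p_le = float(dist[: w2 + 1].sum())
        p_ge = float(dist[w2:].sum())
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(w_plus, p, n, "exact")
    res = stats.wilcoxon(d, zero_method="wilcox", correction=False,
                         alternative="two-sided", method="approx")
    return TestResult(float(res.statistic), float(res.pvalue), n, "approx")


RANK_SUM_EXACT_MAX_TOTAL = 12


def rank_sum_test(values_a: Sequence[float], values_b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    For combined sample sizes <= 12 the exact null is enumerated over all
    C(n+m, n) assignments of the pooled (possibly tied) ranks to group A;
    larger samples use the tie-corrected normal approximation with
    continuity correction. The statistic reported is the rank sum of A.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n, m = a.size, b.size
    pooled_ranks = stats.rankdata(np.concatenate([a, b]))
    w = float(pooled_ranks[:n].sum())
    if n + m <= RANK_SUM_EXACT_MAX_TOTAL:
        sums = np.array(
            [pooled_ranks[list(idx)].sum()
             for idx in combinations(range(n + m), n)]
        )
        eps = 1e-9
        p_le = float(np.mean(sums <= w + eps))
        p_ge = float(np.mean(sums >= w - eps))
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(w, p, n + m, "exact")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return TestResult(w, float(res.pvalue), n + m, "approx")


# ---------------------------------------------------------------------------
# paired summaries
# ---------------------------------------------------------------------------


@dataclass
class PairedStat:
    individual: str
    stat_blood: float
    stat_feces: float

    @property
    def difference(self) -> float:
        return self.stat_feces - self.stat_blood


def paired_concordance(
    blood: GenotypeMatrix,
    feces: GenotypeMatrix,
    n_chromosomes: int | None = None,
) -> dict:
    """Full paired validation: unique alleles, F, and signed-rank tests.

    Pairs samples by individual id (order preserved from the blood
    matrix). Returns per-individual statistics and the two paired tests:
    feces-vs-blood unique-allele proportions and inbreeding coefficients.
    """
    if blood.individuals is None or feces.individuals is None:
        raise ValueError("matrices must carry individual ids for pairing")
    feces_by_ind = {ind: i for i, ind in enumerate(feces.individuals)}
    p = blood.sites["p"].to_numpy()
    unique_pairs: list[PairedStat] = []
    f_pairs: list[PairedStat] = []
    for i, ind in enumerate(blood.individuals):
        if ind not in feces_by_ind:
            continue
        j = feces_by_ind[ind]
        ua_b, ua_f = unique_allele_proportion(blood.calls[i], feces.calls[j])
        unique_pairs.append(PairedStat(ind, ua_b, ua_f))
        f_b = inbreeding_F(blood.calls[i], p, n_chromosomes)
        f_f = inbreeding_F(feces.calls[j], p, n_chromosomes)
        f_pairs.append(PairedStat(ind, f_b, f_f))
    ua_test = signed_rank_test([s.difference for s in unique_pairs])
    f_test = signed_rank_test([s.difference for s in f_pairs])
    return {
        "n_pairs": len(unique_pairs),
        "unique_alleles": unique_pairs,
        "inbreeding": f_pairs,
        "mean_unique_blood": float(np.mean([s.stat_blood for s in unique_pairs])),
        "mean_unique_feces": float(np.mean([s.stat_feces for s in unique_pairs])),
        "mean_F_blood": float(np.mean([s.stat_blood for s in f_pairs])),
        "mean_F_feces": float(np.mean([s.stat_feces for s in f_pairs])),
        "unique_allele_test": ua_test,
        "inbreeding_test": f_test,
    }
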