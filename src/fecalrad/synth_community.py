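"""Synthetic host/bacterial community and paired genotype generator.

Generates every input the downstream stages consume, at desk scale:

* a CpG-methylated "host" genome and unmethylated "bacterial" genomes;
* fecal fragment pools mixing the two at a controlled host fraction
  (real fecal extracts are typically < 5% host DNA, often < 1%);
* diploid genotype matrices under Hardy-Weinberg equilibrium;
* paired blood/feces call sets in which the feces member carries extra
  missingness and heterozygote allelic dropout — the two error modes the
  concordance statistics are designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .genome import ReferenceSequence
from .mbd_capture import FragmentPool

MISSING = -1  # dosage code for a missing diploid call

BLOOD = "blood"
FECES = "feces"


@dataclass(frozen=True)
class MethylationModel:
    """Per-CpG methylation probabilities by origin.

    Vertebrate genomes methylate the large majority of their CpGs; the
    default 0.75 sits in the typical somatic range. Bacterial genomes lack
    CpG methylation, hence 0.0.
    """

    host_cpg_methylated_prob: float = 0.75
    bacterial_cpg_methylated_prob: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.host_cpg_methylated_prob, self.bacterial_cpg_methylated_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("methylation probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class DropoutModel:
    """Feces-specific genotyping error rates for paired call sets."""

    feces_allelic_dropout_rate: float = 0.0
    feces_extra_missing_rate: float = 0.0
    blood_missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for r in (self.feces_allelic_dropout_rate, self.feces_extra_missing_rate,
                  self.blood_missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class GenotypeMatrix:
    """Samples x biallelic sites, diploid calls coded as alt-allele dosage.

    ``calls[i, j]`` is 0/1/2 or :data:`MISSING`. ``sites`` carries contig,
    0-based position, ref/alt alleles and the population reference-allele
    frequency ``p`` each site was simulated with (or estimated from data).
    """

    sample_ids: list[str]
    sites: pd.DataFrame  # columns: contig, pos, ref, alt, p
    calls: np.ndarray  # int8, shape (n_samples, n_sites)
    sample_types: list[str] | None = None  # blood / feces
    individuals: list[str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError("calls shape must be (n_samples, n_sites)")
        if "p" in self.sites and (
            (self.sites["p"] < 0).any() or (self.sites["p"] > 1).any()
        ):
            raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.calls != MISSING

    def site_call_rates(self) -> np.ndarray:
        return self.called().mean(axis=0)

    def sample_call_rates(self) -> np.ndarray:
        return self.called().mean(axis=1)

    def subset(self, sample_idx=None, site_idx=None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        ti = np.arange(self.n_sites) if site_idx is None else np.asarray(site_idx)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in si],
            self.sites.iloc[ti].reset_index(drop=True),
            self.calls[np.ix_(si, ti)].copy(),
            None if self.sample_types is None else [self.sample_types[i] for i in si],
            None if self.individuals is None else [self.individuals[i] for i in si],
        )

    def copy(self) -> "GenotypeMatrix":
        return self.subset()


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

def simulate_genome(
    length: int,
    gc_content: float = 0.40,
    cpg_enrichment: float = 1.0,
    seed=None,
    cpg_methylated_prob: float = 0.75,
    name: str = "chr1",
) -> ReferenceSequence:
    """Simulate one contig with controlled GC, CpG rate and methylation.

    Bases are drawn i.i.d. with P(G) = P(C) = gc/2; the CpG dinucleotide
    count is then adjusted toward ``cpg_enrichment`` times the i.i.d.
    expectation by planting or destroying CG pairs at random positions
    (an approximation that leaves base composition essentially intact).
    Each resulting CpG is methylated independently with
    ``cpg_methylated_prob``.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc_content <= 1.0:
        raise ValueError("gc_content must lie in [0, 1]")
    if cpg_enrichment < 0:
        raise ValueError("cpg_enrichment must be nonnegative")
    if not 0.0 <= cpg_methylated_prob <= 1.0:
        raise ValueError("cpg_methylated_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seq = rng.choice(bases, size=length, p=probs).copy()

    if cpg_enrichment != 1.0 and length >= 2:
        is_c = seq[:-1] == b"C"
        is_g = seq[1:] == b"G"
        cg_pos = np.flatnonzero(is_c & is_g)
        target = int(round((gc_content / 2) ** 2 * cpg_enrichment * (length - 1)))
        if target > cg_pos.size:
            # plant CG pairs at positions not already starting a CpG
            candidates = np.setdiff1d(np.arange(0, length - 1, 2), cg_pos)
            extra = min(target - cg_pos.size, candidates.size)
            chosen = rng.choice(candidates, size=extra, replace=False)
            seq[chosen] = b"C"
            seq[chosen + 1] = b"G"
        elif target < cg_pos.size:
            drop = rng.choice(cg_pos, size=cg_pos.size - target, replace=False)
            seq[drop + 1] = b"A"  # destroy the pair, keep it simple

    sequence = seq.tobytes().decode("ascii")
    genome = ReferenceSequence({name: sequence})
    cpg = genome.cpg_positions(name)
    meth = cpg[rng.random(cpg.size) < cpg_methylated_prob] if cpg.size else cpg
    genome.methylated_cpg[name] = meth
    return genome


def simulate_community(
    host_length: int = 200_000,
    n_bacteria: int = 3,
    bacterial_length: int = 100_000,
    host_gc: float = 0.40,
    bacterial_gc: float = 0.50,
    methylation: MethylationModel = MethylationModel(),
    seed=None,
) -> tuple[ReferenceSequence, list[ReferenceSequence]]:
    """Host genome plus a small panel of bacterial genomes.

    Bacterial genomes are simulated without CpG depletion and with the
    bacterial methylation probability (default zero).
    """
    entropy = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss = entropy.spawn(n_bacteria + 1)
    host = simulate_genome(
        host_length, host_gc, seed=ss[0],
        cpg_methylated_prob=methylation.host_cpg_methylated_prob, name="host_chr1",
    )
    bacteria = [
        simulate_genome(
            bacterial_length, bacterial_gc, seed=ss[i + 1],
            cpg_methylated_prob=methylation.bacterial_cpg_methylated_prob,
            name=f"bact{i + 1}",
        )
        for i in range(n_bacteria)
    ]
    return host, bacteria


def simulate_fecal_pool(
    host_genome: ReferenceSequence,
    bacterial_genomes: Sequence[ReferenceSequence],
    host_fraction: float,
    n_fragments: int,
    fragment_length_mean: float = 250.0,
    fragment_length_sd: float = 80.0,
    min_fragment_length: int = 50,
    seed=None,
) -> FragmentPool:
    """Mix host and bacterial fragments at a target host fraction.

    Each fragment's origin is Bernoulli(``host_fraction``); its source
    contig is chosen proportional to contig length, its start uniform, and
    its length normal (truncated below at ``min_fragment_length``). The
    fragment's methylated-CpG count is the number of methylated CpGs its
    interval covers on the source genome.
    """
    if not 0.0 <= host_fraction <= 1.0:
        raise ValueError("host_fraction must lie in [0, 1]")
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    rng = np.random.default_rng(seed)
    is_host = rng.random(n_fragments) < host_fraction
    lengths = rng.normal(fragment_length_mean, fragment_length_sd, n_fragments)
    lengths = np.maximum(lengths, min_fragment_length).astype(np.int64)

    m = np.zeros(n_fragments, dtype=np.int64)
    for host_flag in (True, False):
        idx = np.flatnonzero(is_host == host_flag)
        if idx.size == 0:
            continue
        if host_flag:
            genomes = [host_genome]
            which = np.zeros(idx.size, dtype=np.int64)
        else:
            genomes = list(bacterial_genomes)
            if not genomes:
                raise ValueError("need at least one bacterial genome when host_fraction < 1")
            sizes = np.array([g.total_length() for g in genomes], dtype=float)
            which = rng.choice(len(genomes), size=idx.size, p=sizes / sizes.sum())
        for gi, g in enumerate(genomes):
            sub = idx[which == gi]
            if sub.size == 0:
                continue
            names = g.names
            contig_lens = np.array([g.length(n) for n in names], dtype=float)
            ci = rng.choice(len(names), size=sub.size, p=contig_lens / contig_lens.sum())
            for k, contig in enumerate(names):
                sub_c = sub[ci == k]
                if sub_c.size == 0:
                    continue
                clen = g.length(contig)
                flen = np.minimum(lengths[sub_c], clen)
                starts = rng.integers(0, clen - flen + 1)
                pos = g.methylated_cpg.get(contig)
                if pos is not None and pos.size:
                    m[sub_c] = (
                        np.searchsorted(pos, starts + flen)
                        - np.searchsorted(pos, starts)
                    )
    return FragmentPool(is_host, m)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def uniform_freq_sampler(low: float = 0.05, high: float = 0.95) -> Callable:
    """Reference-allele frequency sampler avoiding monomorphic extremes."""

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(low, high, n)

    return sample


def simulate_genotypes(
    n_individuals: int,
    n_sites: int,
    freq_sampler: Callable | None = None,
    seed=None,
    contig: str = "chr1",
    spacing: int = 100,
) -> GenotypeMatrix:
    """Truth genotypes under Hardy-Weinberg equilibrium.

    Site reference-allele frequencies ``p`` come from ``freq_sampler``
    (default uniform on [0.05, 0.95]); alt-allele dosages are
    Binomial(2, 1 - p) per individual, i.e. genotype probabilities
    (p^2, 2pq, q^2). Sites are unlinked.
    """
    if n_individuals < 1 or n_sites < 1:
        raise ValueError("need at least one individual and one site")
    rng = np.random.default_rng(seed)
    sampler = freq_sampler or uniform_freq_sampler()
    p = np.asarray(sampler(rng, n_sites), dtype=float)
    calls = rng.binomial(2, 1.0 - p, size=(n_individuals, n_sites)).astype(np.int8)
    sites = pd.DataFrame(
        {
            "contig": contig,
            "pos": np.arange(n_sites, dtype=np.int64) * spacing,
            "ref": "A",
            "alt": "G",
            "p": p,
        }
    )
    ids = [f"ind{i + 1:03d}" for i in range(n_individuals)]
    return GenotypeMatrix(ids, sites, calls, individuals=list(ids))


def simulate_structured_genotypes(
    n_per_pop: Sequence[int],
    n_sites: int,
    divergence: float = 0.2,
    seed=None,
) -> tuple[GenotypeMatrix, list[int]]:
    """Two-or-more population truth matrix with diverged allele frequencies.

    Population frequencies are drawn around a shared ancestral frequency,
    jittered by ``divergence``; used for population-structure checks.
    Returns the matrix and the per-sample population labels.
    """
    rng = np.random.default_rng(seed)
    anc = rng.uniform(0.1, 0.9, n_sites)
    pops = []
    calls = []
    labels: list[int] = []
    for k, n in enumerate(n_per_pop):
        pk = np.clip(anc + rng.uniform(-divergence, divergence, n_sites), 0.02, 0.98)
        pops.append(pk)
        calls.append(rng.binomial(2, 1.0 - pk, size=(n, n_sites)).astype(np.int8))
        labels.extend([k] * n)
    all_calls = np.vstack(calls)
    # record the pooled frequency as the site annotation
    p_pooled = np.average(np.vstack(pops), axis=0,
                          weights=np.asarray(n_per_pop, dtype=float))
    sites = pd.DataFrame(
        {
            "contig": "chr1",
            "pos": np.arange(n_sites, dtype=np.int64) * 100,
            "ref": "A",
            "alt": "G",
            "p": p_pooled,
        }
    )
    ids = [f"ind{i + 1:03d}" for i in range(all_calls.shape[0])]
    gm = GenotypeMatrix(ids, sites, all_calls, individuals=list(ids))
    return gm, labels


def make_paired_callsets(
    truth: GenotypeMatrix,
    dropout: DropoutModel,
    seed=None,
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Derive paired blood/feces call sets from truth genotypes.

    Blood calls go missing at ``blood_missing_rate`` and are otherwise
    truthful. Feces calls go missing at ``blood_missing_rate +
    feces_extra_missing_rate`` (capped at 1); each *surviving heterozygous*
    feces call collapses to a homozygote with probability
    ``feces_allelic_dropout_rate``, the lost allele chosen uniformly.
    Homozygous calls are unaffected by dropout.
    """
    if np.any(truth.calls == MISSING):
        raise ValueError("truth matrix must have no missing calls")
    rng = np.random.default_rng(seed)
    shape = truth.calls.shape

    blood = truth.calls.copy()
    blood[rng.random(shape) < dropout.blood_missing_rate] = MISSING

    feces = truth.calls.copy()
    miss_rate = min(1.0, dropout.blood_missing_rate + dropout.feces_extra_missing_rate)
    feces[rng.random(shape) < miss_rate] = MISSING
    het = feces == 1
    drop = het & (rng.random(shape) < dropout.feces_allelic_dropout_rate)
    # the surviving allele is chosen uniformly: dosage 0 or 2 with prob 1/2
    feces[drop] = np.where(rng.random(shape)[drop] < 0.5, 0, 2).astype(np.int8)

    inds = truth.individuals or truth.sample_ids
    gm_blood = GenotypeMatrix(
        [f"{s}_B" for s in truth.sample_ids], truth.sites.copy(), blood,
        sample_types=[BLOOD] * truth.n_samples, individuals=list(inds),
    )
    gm_feces = GenotypeMatrix(
        [f"{s}_F" for s in truth.sample_ids], truth.sites.copy(), feces,
        sample_types=[FECES] * truth.n_samples, individuals=list(inds),
    )
    return gm_blood, gm_feces


def merge_matrices(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Stack two call sets sharing an identical site table."""
    if not a.sites[["contig", "pos", "ref", "alt"]].equals(
        b.sites[["contig", "pos", "ref", "alt"]]
    ):
        raise ValueError("matrices must share the same site list")
    return GenotypeMatrix(
        a.sample_ids + b.sample_ids,
        a.sites.copy(),
        np.vstack([a.calls, b.calls]),
        (a.sample_types or ["?"] * a.n_samples) + (b.sample_types or ["?"] * b.n_samples),
        (a.individuals or a.sample_ids) + (b.individuals or b.sample_ids),
    )
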