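# Methods

This note documents the models behind `fecalrad`, the parameters that
matter, the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## In-silico ddRAD locus prediction (`digestsim`)

Digestion is modelled on the top strand only: every motif occurrence of
either enzyme contributes a cut at `site_start + cut_offset`, overlapping
occurrences included (physical digestion cuts every site). Sticky-end
overhangs are ignored for fragment length; the ≤ 4 bp they contribute is
absorbed into the configurable `adapter_total_bp`. Fragments tile each
contig exactly (length conservation and re-digestion idempotence are
tested properties). Coordinates are 0-based half-open throughout; BED is
written natively and VCF positions are converted at the boundary.

A fragment is ddRAD-sequenceable when its two ends come from *distinct*
enzymes — only those molecules receive one P1 and one P2 adapter. Size
selection keeps fragments whose adapter-inclusive length lies in
`target ± half_width`, boundaries inclusive (defaults 300 ± 39 bp, the
"tight" automated gel collection). The combined adapter contribution is
not a measurable property of the gel window, so it is a parameter:
`adapter_total_bp = 76` by default (two ligated ddRAD adapters of typical
design), overridable. Both the opposite-end restriction and the
adapter-inclusive interpretation of the window are parameters precisely
because neither is forced by the chemistry alone.

Annotations: GC fraction over the tag sequence only; CpG dinucleotides
counted in `[start − 5000, end + 5000)` clipped at contig edges *without*
rescaling (a caveat for contigs shorter than the window); N counts as
non-GC and interrupts motif and CpG matches.

Read weighting encodes the empirical behaviour that a locus is sequenced
at a frequency that falls off with the deviation of its total length from
the selection target. A unit-height Gaussian kernel
`exp(−(L_total − target)² / (2·sd²))` with `kernel_sd_bp = 39` (matching
the collection half-width) is the simplest smooth, symmetric,
strictly-decreasing choice; only relative weights matter downstream.

## MBD capture model (`mbd_capture`)

No quantitative binding model is available for MBD2-Fc capture, so the
simulator uses the simplest form that reproduces three qualitative
observations about the chemistry: methylation selectivity, nonspecific
carryover of unmethylated DNA, and gains from serial enrichment. Capture
probability saturates in the fragment's methylated-CpG count *m*:

    p(m) = p_bg + (p_max − p_bg) · m / (m + k_half)

with defaults `p_max = 0.8`, `p_bg = 0.05`, `k_half = 5`. `p_bg` is the
background binding probability of unmethylated DNA; a bead surplus
relative to total DNA maps onto a larger `p_bg` (the bead:DNA ratio is not
modelled explicitly because its effect is known only directionally).
Fragments are independent Bernoulli trials — no bead competition or
saturation — which is a stated limitation, as is the assumption that
serial rounds are independent per fragment. An empty post-round pool is a
flagged (`depleted`) result, not an exception.

The closed-form companion
`f′ = f·E[p_host] / (f·E[p_host] + (1 − f)·E[p_bact])` is the exact
expectation ratio for one round; the simulator is tested against it within
3 delta-method standard errors across a grid of host fractions
(10⁻⁴–0.2) and 1–2 rounds at 10⁵ fragments. Fold enrichment `f′/f` is
maximal as `f → 0` and approaches 1 as `f → 1` — low-start samples gain
the most, which the demo pipeline reproduces.

## Synthetic community and genotypes (`synth_community`)

Host genomes are i.i.d. base draws at a configurable GC (default 0.40, in
the vertebrate range); a `cpg_enrichment` factor adjusts the CpG
dinucleotide count toward a multiple of the i.i.d. expectation by planting
or destroying CG pairs (an approximation that leaves overall composition
essentially intact). Each CpG is methylated independently — 75% for the
host by default (typical somatic methylation), 0% for bacteria. Fecal
pools draw fragment origins Bernoulli(host fraction), positions uniform,
lengths normal (mean 250 bp, sd 80, floor 50 — degraded fecal DNA scale);
a fragment's `m` is the number of methylated CpGs it covers.

Genotypes: site reference-allele frequencies default to uniform(0.05,
0.95) (avoiding monomorphic edges), diploid calls are Binomial(2, q)
under Hardy–Weinberg, sites unlinked. Paired call sets derive from truth
by (i) missingness — blood at `blood_missing_rate`, feces at
`blood + feces_extra` capped at 1; and (ii) heterozygote allelic dropout
in feces at rate *d*, the surviving allele chosen uniformly (no basis for
reference bias). Dropout is modelled per genotype, not per read: the
mechanism (too few intact target molecules before amplification) acts
upstream of sequencing, so a per-genotype Bernoulli is the minimal
faithful abstraction. With known site frequencies, dropout inflates the
inbreeding coefficient by E[F_feces] ≈ d, which is the basis of the
recovery check. The simulator deliberately exposes dropout and
missingness as separate knobs so the statistics' power to separate the
two error modes can be studied.

What the generator does *not* emulate: linkage and haplotype structure
(except planted duplicate columns for pruning tests), coalescent
ancestry, indels, multi-allelic sites, sequencing error, reference bias,
and PCR duplicates. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated generative model, not
robustness to every artefact of real fecal libraries.

## qPCR quantification (`enrich_quant`)

The standard curve is an ordinary least-squares fit of Ct on
log₁₀(quantity) over ≥ 3 distinct positive standards; a slope ≥ 0 rejects
the curve. Efficiency `10^(−1/b) − 1` is reported alongside (−3.3219 ↔
100%). The limit of quantification is the lowest standard; unknowns
inverting below it are flagged and excluded from cohort summaries rather
than extrapolated. Replicate wells are averaged before inversion, with a
spread above 0.5 cycles flagging unreliable duplicates (a reconciliation
rule the assay itself does not dictate). Host/total proportions above 1 —
possible because qPCR and fluorometric totals have independent errors —
clamp to 1 with a warning, never an error. The cohort fold statistic is
the mean of per-sample folds, not the ratio of mean proportions.

## Concordance statistics (`concordance_stats`)

*Coverage equalization* subsamples the deeper member of a pair to the
shallower one's total without replacement (multivariate hypergeometric on
per-locus counts), leaving the shallower member bit-exact. It operates on
count vectors pre-genotyping; re-calling variants is out of scope.

*Hard filtering*: a record fails iff any strict inequality holds (QD <
2.0, MQ < 40.0, FS > 60.0, HaplotypeScore > 13.0, MQRankSum < −12.5,
ReadPosRankSum < −8.0); indels always fail. A record missing an
annotation passes that sub-condition — an absent annotation cannot fail
it, matching how callers emit these fields. Filtering is idempotent.

*Genotyping-rate filter*: sites (≥ 90% called) are filtered before
samples (≥ 10% of retained sites); the two rules do not commute, and the
site-first order matches standard toolkit behaviour.

*Unique alleles*: genotypes are compared as allele sets over sites called
in both members; the proportion for one member is its unique alleles over
all distinct alleles it shows at those sites. Sites called in only one
member are excluded from numerator and denominator — differential
missingness is the missingness chi-square's job, not this statistic's.

*Inbreeding coefficient*: `F = (O_hom − E_hom)/(N − E_hom)` with
`E_hom = Σ (1 − 2pq·c)`; `c = n_chrom/(n_chrom − 1)` when frequencies are
estimated from `n_chrom` chromosomes, `c = 1` when known. A zero
denominator yields NaN, flagged.

*Wilcoxon tests*: zero differences are dropped before signed-rank ranking
(relevant because paired designs here are small, n = 6). For n ≤ 15 the
exact two-sided null is built over all 2ⁿ sign assignments of the
observed, possibly tied, ranks via a subset-sum convolution on doubled
ranks; the rank-sum test enumerates all C(n+m, n) labelings for combined
sizes ≤ 12. Two-sided p = min(1, 2·min(lower tail, upper tail)). Larger
samples use scipy's tie-corrected normal approximations. The exact
branches are cross-checked in tests against literal enumeration and
scipy's exact methods.

## Population structure (`popstruct`)

LD r² is the squared Pearson correlation of alt-dosage vectors over
jointly-called samples; undefined values (constant sites, < 2 joint
calls) count as 0 for pruning. Pruning slides a 50-SNP window one
retained SNP at a time, removes one uniformly-chosen member of each pair
with r² > 0.5, and repeats to a fixpoint, so the output provably contains
no offending pair in any window; window, threshold and step are
parameters because the procedure is conventionally stated without a step.

IBS between two samples is the mean per-site shared-allele fraction
`1 − |dᵢ − dⱼ|/2`; MDS is classical Torgerson scaling of `1 − IBS` (the
conventional distance for genotype MDS): double-center `−D²/2`,
eigendecompose, scale the top-k eigenvectors by √λ, truncating negative
eigenvalues with a warning. Planted Euclidean configurations are
recovered to 1e−9.

Per-site association (2×2 allele counts × sample type) and missingness
(called/missing × type) use the chi-square without continuity correction,
df = 1; empty margins skip the site, and tables with any expected count
below 5 are flagged rather than silently switched to another test. The
significance threshold for counting "significant" sites defaults to an
unadjusted α = 0.05 and is always an explicit, logged parameter. The
asymptotic chi-square is visibly anticonservative for allele-count tables
from small cohorts (~6 per type), so the type-I calibration checks run at
40 samples per type × 10⁴ sites, where the observed rate sits within 3
binomial SE of nominal.

Same-individual distances report `1 − IBS` for each blood–feces pair and
compare each pair's within-individual distance against the mean distance
from its blood member to all other individuals' feces members via the
paired signed-rank test (skipped below 2 usable pairs).

## Pipeline and determinism

Every stochastic stage draws from a named child of one master
`SeedSequence`, so stages are individually reproducible and the demo
summary JSON is byte-identical across reruns of the same configuration.
The demo runs a 200 kb host genome, two 60 kb bacterial genomes, 2×10⁴
fragments at 1% host, 6 individuals (two populations) × 1,500 sites —
sizes chosen so the full pipeline completes in seconds on a laptop while
every statistic remains well-resolved; all are configuration fields.
Validation suites use larger, purpose-chosen sizes (e.g. 20 pairs × 10⁴
sites for dropout recovery, 10⁵-fragment pools for capture agreement).

## Known limitations

- Capture ignores bead saturation and between-round correlation; the
  saturating curve is a model, not an inference from binding data.
- The genome simulator's CpG adjustment perturbs composition slightly and
  produces no CpG islands or methylation domains.
- Unique-allele proportions ignore half-missing genotypes (not
  representable in the dosage encoding).
- The association/missingness chi-squares are asymptotic; at
  six-per-group cohort sizes their null rate runs low, which is flagged
  per site (`low_expected`) rather than corrected.
- VCF ingestion is biallelic-SNP only; multi-allelic records are skipped
  with a logged count.
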