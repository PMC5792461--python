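"""Format readers/writers, run configuration, and pipeline orchestration.

Conventions: internal coordinates are 0-based half-open everywhere; BED is
written natively, VCF positions are converted on read/write (pysam handles
the 1-based representation). FASTA wraps at 60 columns. The end-to-end
demo pipeline chains community simulation -> MBD capture -> in-silico
digest -> qPCR quantification -> paired concordance -> population
structure, and emits one machine-readable JSON summary that is a pure
function of (config, seeds).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import concordance_stats as cs
from . import digestsim, enrich_quant, mbd_capture, popstruct
from . import synth_community as synth
from .genome import ReferenceSequence
from .synth_community import MISSING, GenotypeMatrix

INFO_FIELDS = ("QD", "MQ", "FS", "HaplotypeScore", "MQRankSum", "ReadPosRankSum")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> ReferenceSequence:
    """Read a FASTA file; bases are uppercased, duplicate names rejected."""
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig name {rec.id!r}")
        contigs[rec.id] = str(rec.seq).upper()
    if not contigs:
        warnings.warn(f"no sequences found in {path}; returning empty genome")
    return ReferenceSequence(contigs)


def write_fasta(genome: ReferenceSequence, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")  # wraps at 60 columns


def write_methylation_track(genome: ReferenceSequence, path) -> None:
    """TSV of methylated-CpG positions (contig, 0-based position)."""
    rows = [
        {"contig": name, "position": int(p)}
        for name, arr in genome.methylated_cpg.items()
        for p in arr
    ]
    pd.DataFrame(rows, columns=["contig", "position"]).to_csv(path, sep="\t", index=False)


def read_methylation_track(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return {
        str(name): np.sort(grp["position"].to_numpy(dtype=np.int64))
        for name, grp in df.groupby("contig")
    }


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read (contig, start, end) intervals from a BED3+ file."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_radtag_bed(tags, path) -> None:
    """BED6 of predicted loci: name = tag id, score = read_weight x 1000."""
    with open(path, "w") as fh:
        for tag in tags:
            score = int(round(tag.read_weight * 1000))
            fh.write(
                f"{tag.contig}\t{tag.start}\t{tag.end}\t{tag.tag_id}\t{score}\t+\n"
            )


def write_radtag_table(tags, counts, path) -> None:
    """TSV sidecar: tag id, length, gc_fraction, cpg_flank_count, read_count."""
    rows = [
        {
            "tag_id": t.tag_id,
            "length": t.length,
            "gc_fraction": t.gc_fraction,
            "cpg_flank_count": t.cpg_flank_count,
            "read_weight": t.read_weight,
            "read_count": 0 if counts is None else counts.get(t.tag_id, 0),
        }
        for t in tags
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(
    matrix: GenotypeMatrix,
    path,
    info: pd.DataFrame | None = None,
    filter_status: list[str] | None = None,
) -> None:
    """Write a biallelic-SNP VCF (uncompressed) from a genotype matrix.

    Internal 0-based positions are converted to the 1-based VCF
    convention. INFO column ``AF`` carries the alt-allele frequency
    (1 - p); extra per-site annotations come from ``info`` columns named
    after the standard caller fields. ``filter_status`` supplies per-site
    FILTER strings (default PASS).
    """
    header = pysam.VariantHeader()
    contig_max = matrix.sites.groupby("contig", sort=False)["pos"].max()
    for contig, mx in contig_max.items():
        header.contigs.add(str(contig), length=int(mx) + 2)
    header.info.add("AF", "A", "Float", "Alternate allele frequency")
    for name in INFO_FIELDS:
        header.info.add(name, "1", "Float", f"{name} annotation")
    header.formats.add("GT", "1", "String", "Genotype")
    if filter_status is not None:
        for status in sorted(set(filter_status) - {"PASS", "."}):
            header.filters.add(status, None, None, "failed hard filter")
    for s in matrix.sample_ids:
        header.add_sample(s)
    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j in range(matrix.n_sites):
            site = matrix.sites.iloc[j]
            rec = vcf.new_record(
                contig=str(site["contig"]),
                start=int(site["pos"]),
                stop=int(site["pos"]) + len(str(site["ref"])),
                alleles=(str(site["ref"]), str(site["alt"])),
            )
            if "p" in site:
                rec.info["AF"] = float(1.0 - site["p"])
            if info is not None:
                for name in INFO_FIELDS:
                    if name in info.columns and pd.notna(info.iloc[j][name]):
                        rec.info[name] = float(info.iloc[j][name])
            if filter_status is not None:
                rec.filter.add(filter_status[j])
            for i, s in enumerate(matrix.sample_ids):
                rec.samples[s]["GT"] = gt_map[int(matrix.calls[i, j])]
            vcf.write(rec)


def read_vcf(path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a VCF into a genotype matrix plus an annotation frame.

    Biallelic records are ingested (multi-allelic ones skipped with a
    logged count); positions become 0-based. The annotation frame carries
    the hard-filter INFO fields (NaN when absent), an ``is_indel`` flag
    and the FILTER string. ``./.`` genotypes become missing. Site ``p`` is
    1 - AF when the record carries AF, else the ref-allele frequency
    estimated from the called genotypes.
    """
    sites = []
    annos = []
    calls_rows = []
    n_multi = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                n_multi += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            dosages = np.full(len(samples), MISSING, dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                dosages[i] = sum(1 for a in gt if a != 0)
            if "AF" in rec.info:
                af = rec.info["AF"]
                p = 1.0 - float(af[0] if isinstance(af, tuple) else af)
            else:
                called = dosages != MISSING
                p = (
                    1.0 - float(dosages[called].sum()) / (2.0 * called.sum())
                    if called.any()
                    else np.nan
                )
            sites.append(
                {"contig": rec.contig, "pos": rec.start, "ref": ref, "alt": alt, "p": p}
            )
            anno = {
                name: float(rec.info[name]) if name in rec.info else np.nan
                for name in INFO_FIELDS
            }
            anno["is_indel"] = len(ref) != 1 or len(alt) != 1
            anno["filter"] = ";".join(rec.filter.keys()) or "."
            annos.append(anno)
            calls_rows.append(dosages)
    if n_multi:
        warnings.warn(f"skipped {n_multi} multi-allelic record(s) in {path}")
    if not sites:
        raise ValueError(f"no usable biallelic records in {path}")
    site_df = pd.DataFrame(sites)
    calls = np.vstack(calls_rows).T  # samples x sites
    return GenotypeMatrix(list(samples), site_df, calls), pd.DataFrame(annos)


def write_sample_types(matrix: GenotypeMatrix, path) -> None:
    """Sidecar TSV carrying sample type and individual pairing metadata."""
    pd.DataFrame(
        {
            "sample": matrix.sample_ids,
            "type": matrix.sample_types or ["?"] * matrix.n_samples,
            "individual": matrix.individuals or matrix.sample_ids,
        }
    ).to_csv(path, sep="\t", index=False)


def read_sample_types(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Parameters of the end-to-end demo pipeline (one seed drives all stages)."""

    seed: int = 0
    # community
    host_length: int = 200_000
    n_bacteria: int = 2
    bacterial_length: int = 60_000
    host_gc: float = 0.40
    bacterial_gc: float = 0.50
    host_cpg_methylated_prob: float = 0.75
    # fecal pool + capture
    host_fraction: float = 0.01
    n_fragments: int = 20_000
    p_max: float = 0.8
    p_bg: float = 0.05
    k_half: float = 5.0
    rounds: int = 2
    # digest / size selection
    target_total_bp: int = 300
    half_width_bp: int = 39
    adapter_total_bp: int = 76
    kernel_sd_bp: float = 39.0
    mean_depth: float = 30.0
    # qPCR
    qpcr_intercept: float = 35.0
    qpcr_slope: float = -3.3219
    qpcr_noise_sd: float = 0.05
    total_conc_ng: float = 10.0
    # genotypes
    n_individuals: int = 6
    n_populations: int = 2
    n_sites: int = 1_500
    feces_allelic_dropout_rate: float = 0.10
    feces_extra_missing_rate: float = 0.10
    blood_missing_rate: float = 0.02
    # popstruct
    ld_window: int = 50
    r2_threshold: float = 0.5
    alpha: float = 0.05
    mds_k: int = 2

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


STAGE_NAMES = (
    "community", "pool", "capture", "reads", "qpcr", "genotypes",
    "callsets", "equalize", "prune",
)


def stage_seeds(seed: int) -> dict[str, np.random.SeedSequence]:
    """Independent, named seed streams for every stochastic stage."""
    children = np.random.SeedSequence(seed).spawn(len(STAGE_NAMES))
    return dict(zip(STAGE_NAMES, children))


# ---------------------------------------------------------------------------
# JSON helpers
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, cs.TestResult):
        return _jsonable(obj.to_dict())
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def write_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(summary), fh, sort_keys=True, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _simulate_reads(tags, genome, mean_depth, rng) -> list[tuple[str, int, int]]:
    """Per-tag read sets: Poisson(depth x weight) reads inside each locus,
    plus a 5% background of off-target reads."""
    reads: list[tuple[str, int, int]] = []
    for tag in tags:
        n = rng.poisson(mean_depth * tag.read_weight)
        for _ in range(n):
            reads.append((tag.contig, tag.start, tag.end))
    n_bg = rng.poisson(0.05 * max(1, len(reads)))
    names = genome.names
    for _ in range(n_bg):
        contig = names[int(rng.integers(0, len(names)))]
        start = int(rng.integers(0, max(1, genome.length(contig) - 100)))
        reads.append((contig, start, start + 100))
    return reads


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full demo pipeline and write artifacts plus summary JSON.

    Returns the summary dict; identical (config, seed) produce a
    byte-identical ``summary.json``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    summary: dict = {"config": dataclasses.asdict(config)}

    # --- stage 1: synthetic community -------------------------------------
    meth = synth.MethylationModel(host_cpg_methylated_prob=config.host_cpg_methylated_prob)
    host, bacteria = synth.simulate_community(
        host_length=config.host_length,
        n_bacteria=config.n_bacteria,
        bacterial_length=config.bacterial_length,
        host_gc=config.host_gc,
        bacterial_gc=config.bacterial_gc,
        methylation=meth,
        seed=seeds["community"],
    )
    write_fasta(host, out / "host.fa")
    write_methylation_track(host, out / "host_methylation.tsv")

    # --- stage 2: fecal pool + MBD capture ---------------------------------
    pool = synth.simulate_fecal_pool(
        host, bacteria, config.host_fraction, config.n_fragments, seed=seeds["pool"]
    )
    params = mbd_capture.CaptureParams(
        p_max=config.p_max, p_bg=config.p_bg, k_half=config.k_half, rounds=config.rounds
    )
    enriched = mbd_capture.serial_enrich(pool, params, seeds["capture"])
    pool.to_tsv(out / "pool_pre.tsv")
    enriched.to_tsv(out / "pool_post.tsv")
    capture_report = mbd_capture.enrichment_report(pool, enriched, params)
    summary["capture"] = capture_report

    # --- stage 3: in-silico digest + read tally ----------------------------
    selection = digestsim.SizeSelection(
        target_total_bp=config.target_total_bp,
        half_width_bp=config.half_width_bp,
        adapter_total_bp=config.adapter_total_bp,
        kernel_sd_bp=config.kernel_sd_bp,
    )
    tags = digestsim.predict_radtags(host, selection=selection)
    reads_rng = np.random.default_rng(seeds["reads"])
    reads = _simulate_reads(tags, host, config.mean_depth, reads_rng)
    counts = digestsim.tally_reads(reads, tags)
    write_radtag_bed(tags, out / "radtags.bed")
    write_radtag_table(tags, counts, out / "radtags.tsv")
    summary["digest"] = {
        "n_radtags": len(tags),
        "n_reads": len(reads),
        "n_unassigned": counts[digestsim.UNASSIGNED],
        "mean_length": float(np.mean([t.length for t in tags])) if tags else None,
        "mean_gc": float(np.mean([t.gc_fraction for t in tags])) if tags else None,
    }

    # --- stage 4: qPCR quantification + fold enrichment --------------------
    qpcr_rng = np.random.default_rng(seeds["qpcr"])
    sheet_rows = []
    for q in (1e-4, 1e-3, 1e-2, 1e-1, 1.0):  # ng, 10-fold series in duplicate
        for rep in (1, 2):
            ct = (
                config.qpcr_intercept
                + config.qpcr_slope * np.log10(q)
                + qpcr_rng.normal(0, config.qpcr_noise_sd)
            )
            sheet_rows.append(
                {
                    "well": f"S{q:g}_{rep}", "sample": f"std_{q:g}", "role": "standard",
                    "known_quantity": q, "Ct": ct, "total_conc": np.nan,
                }
            )
    host_conc = capture_report["pre_host_fraction"] * config.total_conc_ng
    for rep in (1, 2):
        ct = (
            config.qpcr_intercept
            + config.qpcr_slope * np.log10(host_conc)
            + qpcr_rng.normal(0, config.qpcr_noise_sd)
        )
        sheet_rows.append(
            {
                "well": f"U1_{rep}", "sample": "sample1", "role": "unknown",
                "known_quantity": np.nan, "Ct": ct, "total_conc": config.total_conc_ng,
            }
        )
    sheet = pd.DataFrame(sheet_rows)
    sheet.to_csv(out / "qpcr_plate.tsv", sep="\t", index=False)
    curve, unknowns, records = enrich_quant.process_qpcr_sheet(
        sheet, post_props={"sample1": capture_report["post_host_fraction"]}
    )
    unknowns.to_csv(out / "qpcr_unknowns.tsv", sep="\t", index=False)
    summary["quantify"] = {
        "curve": {
            "slope": curve.slope, "intercept": curve.intercept,
            "r_squared": curve.r_squared, "efficiency": curve.efficiency,
            "loq": curve.limit_of_quantification,
        },
        "records": [dataclasses.asdict(r) for r in records],
        "summary": enrich_quant.summarize_folds(records),
    }

    # --- stage 5: paired genotypes + concordance ---------------------------
    per_pop = [
        config.n_individuals // config.n_populations
        + (1 if k < config.n_individuals % config.n_populations else 0)
        for k in range(config.n_populations)
    ]
    truth, pop_labels = synth.simulate_structured_genotypes(
        per_pop, config.n_sites, seed=seeds["genotypes"]
    )
    dropout = synth.DropoutModel(
        feces_allelic_dropout_rate=config.feces_allelic_dropout_rate,
        feces_extra_missing_rate=config.feces_extra_missing_rate,
        blood_missing_rate=config.blood_missing_rate,
    )
    blood, feces = synth.make_paired_callsets(truth, dropout, seed=seeds["callsets"])
    write_vcf(blood, out / "blood.vcf")
    write_vcf(feces, out / "feces.vcf")
    concord = cs.paired_concordance(blood, feces)
    summary["concordance"] = {
        "n_pairs": concord["n_pairs"],
        "mean_unique_blood": concord["mean_unique_blood"],
        "mean_unique_feces": concord["mean_unique_feces"],
        "mean_F_blood": concord["mean_F_blood"],
        "mean_F_feces": concord["mean_F_feces"],
        "unique_allele_test": concord["unique_allele_test"],
        "inbreeding_test": concord["inbreeding_test"],
    }

    # --- stage 6: population structure -------------------------------------
    merged = synth.merge_matrices(blood, feces)
    write_sample_types(merged, out / "sample_types.tsv")
    filtered, filt_info = cs.genotype_rate_filter(merged)
    kept = popstruct.ld_prune(
        filtered, window=config.ld_window, r2_threshold=config.r2_threshold,
        seed=seeds["prune"],
    )
    pruned = filtered.subset(site_idx=kept)
    ibs = popstruct.ibs_matrix(pruned)
    coords, eigvals = popstruct.mds(ibs.distance(), k=config.mds_k)
    coord_df = pd.DataFrame(
        coords, columns=[f"C{i + 1}" for i in range(config.mds_k)]
    )
    coord_df.insert(0, "sample", pruned.sample_ids)
    coord_df.insert(1, "type", pruned.sample_types)
    coord_df.to_csv(out / "mds_coordinates.tsv", sep="\t", index=False)

    assoc = popstruct.sample_type_association(pruned)
    missing = popstruct.missingness_test(pruned)
    assoc.to_csv(out / "association_tests.tsv", sep="\t", index=False)
    missing.to_csv(out / "missingness_tests.tsv", sep="\t", index=False)

    pairs = {
        ind: (f"{ind}_B", f"{ind}_F")
        for ind in (truth.individuals or truth.sample_ids)
    }
    same_ind = popstruct.same_individual_distance(ibs, pairs)

    summary["popstruct"] = {
        "filter": filt_info,
        "n_sites_pruned": int(len(kept)),
        "mds_eigenvalues": eigvals[: config.mds_k],
        "mds_coordinates": {
            s: coords[i].tolist() for i, s in enumerate(pruned.sample_ids)
        },
        "population_labels": {
            s: int(dict(zip(truth.individuals, pop_labels))[ind])
            for s, ind in zip(pruned.sample_ids, pruned.individuals)
        },
        "association": popstruct.count_significant(assoc, config.alpha),
        "missingness": popstruct.count_significant(missing, config.alpha),
        "same_individual": {
            "within_mean": float(np.mean(same_ind["within_distance"]))
            if same_ind["within_distance"] else None,
            "between_mean": float(np.nanmean(same_ind["between_distance"]))
            if same_ind["between_distance"] else None,
            "test": same_ind["test"],
        },
    }

    write_summary(summary, out / "summary.json")
    return summary
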