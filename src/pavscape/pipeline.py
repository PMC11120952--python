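"""End-to-end orchestration: simulate -> merge -> filter -> landscape ->
association scan -> haplotype comparison, with every intermediate written to
disk in a standard text format and a deterministic JSON run report."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gwas as gwas_mod
from . import haplotype as hap_mod
from . import landscape as land_mod
from .core import GenotypeMatrix, PAVRecord, PavscapeError
from .io import (
    read_phenotype_table,
    read_sv_vcf,
    write_bed,
    write_gff3,
    write_phenotype_table,
    write_sv_vcf,
)
from .merge import FilterParams, MergeParams, apply_variant_filters, merge_callsets
from .simulate import (
    CALLER_NAMES,
    SimulationConfig,
    TraitSpec,
    simulate_caller_callsets,
    simulate_gene_annotation,
    simulate_pav_truth,
    simulate_phenotypes,
)


class PipelineStageError(PavscapeError):
    """An error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    merge: MergeParams = field(default_factory=MergeParams)
    filters: FilterParams = field(default_factory=FilterParams)
    window_size: int = 1_000_000
    step: int = 500_000
    top_frac: float = 0.10
    flank_bp: int = 3000
    n_pcs: int = 3
    n_permutations: int = 1000
    alpha: float = 0.05
    #: optional external phenotype TSV; defaults to the simulated table.
    phenotype_path: str | None = None
    #: permutation seed; defaults to simulation seed + 1000.
    perm_seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("simulation", {})
        if "traits" in sim_raw:
            sim_raw["traits"] = tuple(TraitSpec(*t) for t in sim_raw["traits"])
        for key in ("hotspot_regions", "causal_pavs"):
            if key in sim_raw:
                sim_raw[key] = tuple(tuple(x) for x in sim_raw[key])
        cfg = cls(
            simulation=SimulationConfig(**sim_raw),
            merge=MergeParams(**raw.pop("merge", {})),
            filters=FilterParams(**raw.pop("filters", {})),
            **raw,
        )
        return cfg


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise PipelineStageError(name, exc) from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages, write intermediates under ``outdir`` and return
    the run report (also written as ``report.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": _echo_params(config), "stages": {}}

    sim = _stage_simulate(config, outdir, report)
    matrix_all = _stage_merge(config, outdir, report)
    matrix = _stage_filter(config, outdir, report, matrix_all)
    _stage_landscape(config, outdir, report, matrix)
    assoc = _stage_gwas(config, outdir, report, matrix, sim)
    _stage_haplotest(config, outdir, report, matrix, assoc)

    report["summary"] = summarize_counts(report)
    (outdir / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=1, default=_jsonable))
    return report


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def _echo_params(config: RunConfig) -> dict:
    d = asdict(config)
    sim = d["simulation"]
    sim["traits"] = [list(dataclasses.astuple(t)) if dataclasses.is_dataclass(t)
                     else list(t) for t in config.simulation.traits]
    sim["hotspot_regions"] = [list(h) for h in sim["hotspot_regions"]]
    sim["causal_pavs"] = [list(c) for c in sim["causal_pavs"]]
    return d


@_stage("simulate")
def _stage_simulate(config, outdir, report):
    ann = simulate_gene_annotation(config.simulation)
    truth = simulate_pav_truth(config.simulation, ann)
    cs_a, cs_b = simulate_caller_callsets(truth, config.simulation)
    phenos = simulate_phenotypes(truth, config.simulation)
    write_gff3(ann, outdir / "genes.gff3")
    for cs in (cs_a, cs_b):
        write_sv_vcf(cs.records, cs.samples, outdir / f"{cs.caller}.vcf")
    write_phenotype_table(phenos, outdir / "phenotypes.tsv")
    truth.to_json(outdir / "truth.json")
    report["stages"]["simulate"] = {
        "n_true_pavs": int(truth.n_loci),
        "n_samples": len(truth.samples),
        "caller_records": {cs.caller: len(cs) for cs in (cs_a, cs_b)},
    }
    return {"annotation": ann, "truth": truth}


@_stage("merge")
def _stage_merge(config, outdir, report):
    callsets = [read_sv_vcf(outdir / f"{name}.vcf", caller=name)
                for name in CALLER_NAMES]
    matrix = merge_callsets(callsets, config.merge)
    merged_records = _matrix_to_records(matrix)
    write_sv_vcf(merged_records, matrix.samples, outdir / "merged.vcf")
    report["stages"]["merge"] = {
        "input_records": {cs.caller: len(cs) for cs in callsets},
        "n_merged_loci": int(matrix.n_loci),
    }
    return matrix


def _matrix_to_records(matrix: GenotypeMatrix) -> list[PAVRecord]:
    records = []
    for j, row in enumerate(matrix.loci.itertuples()):
        svlen = -int(row.size) if row.svtype == "DEL" else int(row.size)
        records.append(PAVRecord(
            chrom=row.chrom, start=int(row.start), end=int(row.end),
            svtype=row.svtype, svlen=svlen, caller="merged", filter="PASS",
            genotypes=matrix.genotypes[:, j], record_id=row.locus_id))
    return records


@_stage("filter")
def _stage_filter(config, outdir, report, matrix_all):
    matrix = apply_variant_filters(matrix_all, config.filters)
    matrix.to_tsv(outdir / "matrix.tsv", outdir / "loci.tsv")
    report["stages"]["filter"] = {
        "n_loci_in": int(matrix_all.n_loci),
        "n_loci_kept": int(matrix.n_loci),
    }
    return matrix


@_stage("landscape")
def _stage_landscape(config, outdir, report, matrix):
    from .io import read_gff3

    ann = read_gff3(outdir / "genes.gff3")
    spectrum = land_mod.size_spectrum(matrix.loci["size"])
    pd.DataFrame({
        "bin_lo": spectrum["bin_edges"][:-1],
        "bin_hi": spectrum["bin_edges"][1:],
        "count": spectrum["counts"],
    }).to_csv(outdir / "size_spectrum.tsv", sep="\t", index=False)
    context = land_mod.summarize_context(matrix, ann, config.flank_bp)
    pd.DataFrame([context]).to_csv(outdir / "context_summary.tsv", sep="\t",
                                   index=False)
    lengths = config.simulation.chromosome_lengths()
    counts = land_mod.count_breakpoints_in_windows(
        matrix.loci, lengths, config.window_size, config.step)
    counts.flatten().to_csv(outdir / "window_counts.tsv", sep="\t", index=False)
    hotspots = land_mod.detect_hotspots(counts, config.top_frac)
    write_bed(((h.chrom, h.start, h.end, f"hotspot{i + 1}", h.total_breakpoints)
               for i, h in enumerate(hotspots)), outdir / "hotspots.bed")
    chrom_counts = land_mod.per_chromosome_counts(matrix)
    report["stages"]["landscape"] = {
        "short_fraction": spectrum["short_fraction"],
        "context": context,
        "n_hotspot_regions": len(hotspots),
        "per_chromosome": {k: int(v) for k, v in chrom_counts.items()},
    }
    return hotspots


@_stage("gwas")
def _stage_gwas(config, outdir, report, matrix, sim):
    from .io import read_gff3

    pheno_path = config.phenotype_path or outdir / "phenotypes.tsv"
    table = read_phenotype_table(pheno_path)
    annotation = read_gff3(outdir / "genes.gff3")
    table = table.reindex(matrix.samples)
    X, usable = gwas_mod.encode_genotypes(matrix)
    basis = gwas_mod.compute_pcs(X[:, usable], k=config.n_pcs)
    base_seed = (config.perm_seed if config.perm_seed is not None
                 else config.simulation.seed + 1000)
    results = {}
    thresholds = {}
    stage = {"traits": {}}
    for ti, trait in enumerate(table.columns):
        y = table[trait].to_numpy(dtype=float)
        spec = gwas_mod.PermutationSpec(
            n_permutations=config.n_permutations, alpha=config.alpha,
            seed=base_seed + ti)
        thr = gwas_mod.permutation_threshold(
            X[:, usable], y, basis.scores, spec)
        res = gwas_mod.association_scan(
            X[:, usable], y, basis.scores,
            locus_ids=matrix.loci.loc[usable, "locus_id"])
        res["significant"] = res["minus_log10_p"] >= thr
        res.to_csv(outdir / f"assoc_{trait}.tsv", sep="\t", index=False,
                   float_format="%.6g")
        sig = gwas_mod.call_significant(res, thr)
        genes = gwas_mod.map_to_genes(sig, matrix.loci, annotation,
                                      config.flank_bp)
        genes.to_csv(outdir / f"genes_{trait}.tsv", sep="\t", index=False)
        results[trait] = res
        thresholds[trait] = thr
        stage["traits"][trait] = {
            "threshold": thr,
            "n_significant": int(res["significant"].sum()),
        }
    (outdir / "thresholds.json").write_text(
        json.dumps(thresholds, sort_keys=True, indent=1))
    report["stages"]["gwas"] = stage
    return {"results": results, "thresholds": thresholds, "table": table}


@_stage("haplotest")
def _stage_haplotest(config, outdir, report, matrix, assoc):
    rows = []
    for trait, res in assoc["results"].items():
        sig = res[res["significant"]].sort_values(["p", "locus_id"])
        if sig.empty:
            continue
        locus = sig.iloc[0]["locus_id"]
        pheno = assoc["table"][trait]
        groups = hap_mod.split_haplotypes(matrix, locus, pheno)
        try:
            cmp = hap_mod.compare_groups(groups, pheno)
        except ValueError:
            continue  # a near-fixed locus can leave a group under-sized
        rows.append({"trait": trait, "locus_id": locus,
                     "group1_mean": cmp.group1_mean,
                     "group2_mean": cmp.group2_mean,
                     "n1": cmp.n1, "n2": cmp.n2, "t": cmp.t, "df": cmp.df,
                     "p": cmp.p, "significant": cmp.significant})
    pd.DataFrame(rows, columns=["trait", "locus_id", "group1_mean",
                                "group2_mean", "n1", "n2", "t", "df", "p",
                                "significant"]).to_csv(
        outdir / "haplotype_tests.tsv", sep="\t", index=False,
        float_format="%.6g")
    report["stages"]["haplotest"] = {"n_tests": len(rows)}
    return rows


def summarize_counts(report: dict) -> dict:
    """Internal-consistency tallies: per-trait significant counts with their
    total, per-chromosome PAV counts with the rounded integer mean."""
    gwas_stage = report["stages"].get("gwas", {}).get("traits", {})
    per_trait = {t: v["n_significant"] for t, v in gwas_stage.items()}
    per_chrom = report["stages"].get("landscape", {}).get("per_chromosome", {})
    total_pavs = sum(per_chrom.values())
    return {
        "significant_per_trait": per_trait,
        "total_significant": sum(per_trait.values()),
        "pavs_per_chromosome": per_chrom,
        "total_pavs": total_pavs,
        "mean_pavs_per_chromosome": (
            land_mod.mean_per_chromosome(total_pavs, len(per_chrom))
            if per_chrom else 0),
    }
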