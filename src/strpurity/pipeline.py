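"""End-to-end orchestration: filters -> purity/coding audits -> models.

A pipeline run is a pure function of (inputs, config, seed).  Every stage
logs rows in and out, excluded loci are tallied by their first exclusion
reason, and the effective config is serialized into the output directory
alongside the result tables so any model can be refit standalone.

Exit codes used by the CLI: 0 success, 2 config error, 3 input error,
4 model non-convergence (partial outputs kept).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as strio
from .annotate import GenomicInterval, classify_chromhmm, intersect_loci
from .coding import CodingLocus, summarize_coding_allele
from .filters import filter_table
from .glm import GLMResult, ModelSpec, compare_aic, fit_glm, joint_consequence_model
from .nonb import NonBConfig, predict_structures
from .repeats import IMPURITY_CAP, Motif, score_allele_table
from .simulate import coding_long_format

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ConfigError", "InputError", "run_coding", "run_noncoding"]


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class InputError(ValueError):
    """Missing or malformed input (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    bundle_dir: str
    out_dir: str
    missingness_cap: float = 0.25
    hwe_p_threshold: float = 1e-6
    impurity_cap: float = IMPURITY_CAP
    seed: int = 0
    bonferroni_binding: int = 10
    bonferroni_nonb: int = 12
    run_nonb: bool = False
    nonb_config: NonBConfig = field(default_factory=NonBConfig)

    def __post_init__(self) -> None:
        if not 0 < self.missingness_cap < 1 or not 0 < self.impurity_cap < 1:
            raise ConfigError("caps must be in (0, 1)")
        if not 0 < self.hwe_p_threshold < 1:
            raise ConfigError("hwe_p_threshold must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        try:
            raw = yaml.safe_load(Path(path).read_text())
        except FileNotFoundError as exc:
            raise ConfigError(f"config file not found: {path}") from exc
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise InputError(f"required input missing: {what} ({path})")
    return path


class _Manifest:
    """Machine-readable run log: per-stage row counts and wall times."""

    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.stages: list[dict] = []
        self._t0 = time.time()

    def stage(self, name: str, rows_in: int, rows_out: int, **extra) -> None:
        entry = {"stage": name, "rows_in": rows_in, "rows_out": rows_out,
                 "elapsed_s": round(time.time() - self._t0, 3), **extra}
        self.stages.append(entry)
        logger.info("stage %s: %d -> %d rows", name, rows_in, rows_out)

    def write(self, config: PipelineConfig, **extra) -> None:
        payload = {"config": _config_dict(config), "stages": self.stages, **extra}
        (self.out_dir / "run_manifest.json").write_text(json.dumps(payload, indent=1))


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return d


def _glm_tsv(results: dict[str, GLMResult], path: Path,
             bonferroni_m: dict[str, int] | None = None) -> None:
    """Coefficient tables for a set of fits; ``bonferroni_m`` maps model
    names to their multiple-testing family size (applied to every term)."""
    frames = []
    for name, res in results.items():
        f = res.to_frame().reset_index(names="term")
        f.insert(0, "model", name)
        if bonferroni_m and name in bonferroni_m:
            f["p_bonferroni"] = np.minimum(1.0, f["p"] * bonferroni_m[name])
        f["converged"] = res.converged
        frames.append(f)
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def _filtered_major_alleles(config: PipelineConfig, manifest: _Manifest) -> pd.DataFrame:
    """Shared front end: filter cascade, then the major-allele table."""
    bundle = Path(config.bundle_dir)
    gt_path = bundle / "genotypes.vcf"
    if not gt_path.exists():
        gt_path = _require(bundle / "genotypes.tsv", "genotype table")
        loci = strio.read_genotypes_tsv(gt_path)
    else:
        loci = strio.read_genotypes_vcf(gt_path)
    segdup_path = bundle / "segdups.bed"
    segdup_ids: set[str] = set()
    if segdup_path.exists():
        segdups = strio.read_bed(segdup_path)
        locus_ivs = [GenomicInterval(g.chrom, g.start, g.end, g.locus_id) for g in loci]
        hits = intersect_loci(locus_ivs, segdups)
        segdup_ids = {g.locus_id for g, h in zip(loci, hits) if h}
    reports = filter_table(loci, segdup_loci=segdup_ids)
    strio.write_tsv(reports, manifest.out_dir / "filter_report.tsv")
    tally = reports.loc[~reports["passed"], "fail_reasons"].str.split(",").str[0]
    manifest.stage("filter_cascade", len(reports), int(reports["passed"].sum()),
                   exclusions=tally.value_counts().to_dict())
    passing = reports[reports["passed"]]
    by_id = {g.locus_id: g for g in loci}
    rows = []
    for _, rep in passing.iterrows():
        g = by_id[rep["locus_id"]]
        rows.append({
            "locus_id": g.locus_id, "chrom": g.chrom, "start": g.start, "end": g.end,
            "motif": g.motif, "allele_seq": rep["major_allele"],
            "major_freq": rep["major_freq"],
        })
    return pd.DataFrame(rows)


def run_noncoding(config: PipelineConfig) -> dict[str, GLMResult]:
    """Noncoding analysis: purity scoring, annotation joins, purity models."""
    bundle = Path(config.bundle_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)

    table = _filtered_major_alleles(config, manifest)
    loci_tsv = bundle / "loci.tsv"
    ann = strio.read_tsv(_require(loci_tsv, "annotated locus table"))
    # coding loci are excluded from all noncoding analyses
    if "is_coding" in ann.columns:
        n0 = len(ann)
        ann = ann[ann["is_coding"] == 0]
        manifest.stage("drop_coding", n0, len(ann))
    table = table.merge(
        ann.drop(columns=[c for c in ("allele_seq", "chrom", "start", "end", "motif")
                          if c in ann.columns]),
        on="locus_id", how="inner",
    )
    table = score_allele_table(table)
    n0 = len(table)
    table = table[table["fraction_interrupted"] <= config.impurity_cap]
    manifest.stage("impurity_cap", n0, len(table))

    # chromatin classification from the chromHMM track, when provided
    hmm_path = bundle / "chromhmm.bed"
    if hmm_path.exists():
        track = strio.read_bed(hmm_path)
        locus_ivs = [GenomicInterval(r.chrom, int(r.start), int(r.end), r.locus_id)
                     for r in table.itertuples()]
        states = intersect_loci(locus_ivs, track)
        table["chrom_class"] = [
            classify_chromhmm(int(s) for s in hit) for hit in states
        ]
    if "chrom_class" not in table.columns:
        raise InputError("no chromatin annotation available (chromhmm.bed or chrom_class)")

    table["log_allele_len"] = np.log(table["allele_seq"].str.len())
    table["pure"] = (table["edit_distance"] == 0).astype(int)
    strio.write_tsv(table, out / "purity_table.tsv")

    if config.run_nonb:
        flags = [predict_structures(seq, (0, len(seq)), config.nonb_config)
                 for seq in table["allele_seq"]]
        nonb = pd.DataFrame(flags, index=table.index)
        table = pd.concat([table, nonb.astype(int)], axis=1)
        strio.write_tsv(table[["locus_id", *nonb.columns]], out / "nonb_flags.tsv")

    results: dict[str, GLMResult] = {}
    enh_het = table[table["chrom_class"].isin(
        ["weak_enhancer", "strong_enhancer", "heterochromatin"])].copy()
    if enh_het["chrom_class"].nunique() > 1:
        enh_het["enhancer"] = enh_het["chrom_class"].str.contains("enhancer").astype(int)
        results["enhancer_vs_heterochromatin"] = fit_glm(enh_het, ModelSpec(
            response="edit_distance",
            covariates=("gc_fraction", "motif_len", "enhancer"),
            offset="log_allele_len", name="enhancer_vs_heterochromatin"))
        results["purity_logistic"] = fit_glm(enh_het, ModelSpec(
            response="pure",
            covariates=("gc_fraction", "motif_len", "log_allele_len", "enhancer"),
            offset=None, family="binomial_logit", name="purity_logistic"))
    else:
        manifest.stage("enhancer_models_skipped", len(enh_het), 0,
                       note="single chromatin class; enhancer terms absent")

    both_enh = table[table["chrom_class"].str.contains("enhancer")].copy()
    if both_enh["chrom_class"].nunique() > 1:
        both_enh["strong"] = (both_enh["chrom_class"] == "strong_enhancer").astype(int)
        results["strong_vs_weak_enhancer"] = fit_glm(both_enh, ModelSpec(
            response="edit_distance",
            covariates=("gc_fraction", "motif_len", "strong"),
            offset="log_allele_len", name="strong_vs_weak_enhancer"))
    if "atac_peak" in both_enh.columns and both_enh["atac_peak"].nunique() > 1:
        results["enhancer_atac"] = fit_glm(both_enh, ModelSpec(
            response="edit_distance",
            covariates=("gc_fraction", "motif_len", "atac_peak"),
            offset="log_allele_len", name="enhancer_atac"))

    # longest-pure-stretch models, with and without the purity covariate
    if "enhancer_vs_heterochromatin" in results:
        base = ModelSpec(response="longest_pure_bp",
                         covariates=("gc_fraction", "motif_len", "enhancer"),
                         offset="log_allele_len", name="longest_pure")
        results["longest_pure"] = fit_glm(enh_het, base)
        with_dist = ModelSpec(response="longest_pure_bp",
                              covariates=("gc_fraction", "motif_len", "enhancer",
                                          "edit_distance"),
                              offset="log_allele_len", name="longest_pure_given_purity")
        results["longest_pure_given_purity"] = fit_glm(enh_het, with_dist)

    # SISTR / SNV model when companion files exist
    sistr_path, snv_path = bundle / "sistr.tsv", bundle / "snvs.vcf"
    if sistr_path.exists() and snv_path.exists():
        scores = strio.read_sistr_scores(sistr_path)
        snvs = strio.read_snvs_vcf(snv_path)
        sub = table[table["motif_len"].between(2, 4)].copy()
        sub = sub[sub["locus_id"].map(lambda x: x in scores and scores[x].reliable)]
        if len(sub):
            sub["constrained"] = sub["locus_id"].map(
                lambda x: int(scores[x].constrained))
            ivs = [GenomicInterval(r.chrom, int(r.start), int(r.end))
                   for r in sub.itertuples()]
            from .annotate import count_interrupting_snvs

            sub["n_snvs"] = [count_interrupting_snvs(iv, snvs) for iv in ivs]
            results["sistr_snv"] = fit_glm(sub, ModelSpec(
                response="n_snvs",
                covariates=("gc_fraction", "motif_len", "constrained"),
                offset="log_allele_len", name="sistr_snv"))
            manifest.stage("sistr_locus_set", len(table), len(sub))

    # AG vs AC dinucleotides near DNA-binding sites (interaction model)
    if "near_binding_site" in table.columns:
        dinucs = table[table["motif"].isin(["AG", "AC"])].copy()
        dinucs["motif_is_AG"] = (dinucs["motif"] == "AG").astype(int)
        if (dinucs["motif_is_AG"].nunique() > 1
                and dinucs["near_binding_site"].nunique() > 1):
            results["ag_binding_interaction"] = fit_glm(dinucs, ModelSpec(
                response="edit_distance",
                covariates=("motif_is_AG", "near_binding_site"),
                interactions=(("motif_is_AG", "near_binding_site"),),
                offset="log_allele_len", name="ag_binding_interaction"))
        else:
            manifest.stage("ag_binding_skipped", len(dinucs), 0,
                           note="no AG/AC contrast or binding-site variation")

    # non-B structure x regulatory-element interaction models
    if config.run_nonb and "enhancer_vs_heterochromatin" in results:
        from .nonb import STRUCTURES

        for element in ("strong_enhancer", "promoter"):
            sub = table[table["chrom_class"].isin([element, "heterochromatin"])].copy()
            sub["in_element"] = (sub["chrom_class"] == element).astype(int)
            for structure in STRUCTURES:
                if structure not in sub.columns or sub[structure].nunique() < 2:
                    continue
                if sub["in_element"].nunique() < 2:
                    continue
                name = f"nonb_{structure}_x_{element}"
                results[name] = fit_glm(sub, ModelSpec(
                    response="edit_distance",
                    covariates=("gc_fraction", "motif_len", "in_element", structure),
                    interactions=(("in_element", structure),),
                    offset="log_allele_len", name=name))

    families = {"ag_binding_interaction": config.bonferroni_binding}
    families.update({name: config.bonferroni_nonb for name in results
                     if name.startswith("nonb_")})
    _glm_tsv(results, out / "noncoding_models.tsv", bonferroni_m=families)
    aic_delta = None
    if {"longest_pure", "longest_pure_given_purity"} <= results.keys():
        aic_delta = compare_aic(results["longest_pure_given_purity"],
                                results["longest_pure"])
    manifest.write(config, n_models=len(results), longest_pure_delta_aic=aic_delta)
    if any(not r.converged for r in results.values()):
        logger.warning("one or more models did not converge")
    return results


def run_coding(config: PipelineConfig) -> dict[str, GLMResult]:
    """Coding analysis: codon audits, exposures, consequence-specific models."""
    bundle = Path(config.bundle_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    table = strio.read_tsv(_require(bundle / "coding_loci.tsv", "coding locus table"))

    summaries = []
    for row in table.itertuples():
        locus = CodingLocus(row.locus_id, Motif(row.motif),
                            int(row.frame_offset), row.strand, loeuf=row.loeuf)
        s = summarize_coding_allele(locus, row.allele_seq)
        summaries.append({
            "locus_id": s.locus_id, "n_codons": s.n_codons,
            "n_silent_interruptions": s.n_silent_interruptions,
            "n_missense_interruptions": s.n_missense_interruptions,
            "silent_exposure": s.silent_exposure,
            "missense_exposure": s.missense_exposure, "usable": s.usable,
        })
    meta_cols = ["locus_id", "motif", "motif_len", "gc_fraction", "loeuf"]
    meta_cols += [c for c in ("ad_gene", "pfam_domain") if c in table.columns]
    summary = pd.DataFrame(summaries).merge(table[meta_cols], on="locus_id")
    n0 = len(summary)
    summary = summary[summary["usable"]]
    # the 25% impurity cap, counted on interrupted codon bases
    frac = (summary["n_silent_interruptions"] + summary["n_missense_interruptions"]) / (
        3 * summary["n_codons"])
    summary = summary[frac <= config.impurity_cap]
    manifest.stage("coding_audit", n0, len(summary))
    strio.write_tsv(summary, out / "coding_summary.tsv")
    if summary.empty:
        logger.warning("no usable coding loci after filters; writing empty outputs")
        manifest.write(config, n_models=0)
        return {}

    long = coding_long_format(summary)
    strio.write_tsv(long, out / "coding_long.tsv")
    long["log_exposure"] = np.log(long["exposure"])

    results: dict[str, GLMResult] = {}
    sil = long[long["consequence"] == "silent"]
    mis = long[long["consequence"] == "missense"]
    spec = ModelSpec(response="n_interruptions",
                     covariates=("gc_fraction", "motif_len", "loeuf"),
                     offset="log_exposure", name="silent_vs_loeuf")
    results["silent_vs_loeuf"] = fit_glm(sil, spec)
    results["missense_vs_loeuf"] = fit_glm(
        mis, ModelSpec(response="n_interruptions",
                       covariates=("gc_fraction", "motif_len", "loeuf"),
                       offset="log_exposure", name="missense_vs_loeuf"))
    results["joint_interaction"] = joint_consequence_model(long)
    # alternate constraint annotations, fitted on silent counts when present
    for col, name in (("ad_gene", "silent_vs_ad_gene"),
                      ("pfam_domain", "silent_vs_pfam_domain")):
        if col in summary.columns and summary[col].nunique() > 1:
            with_flag = sil.merge(summary[["locus_id", col]], on="locus_id")
            results[name] = fit_glm(with_flag, ModelSpec(
                response="n_interruptions",
                covariates=("gc_fraction", "motif_len", col),
                offset="log_exposure", name=name))
    _glm_tsv(results, out / "coding_models.tsv")
    manifest.write(config, n_models=len(results))
    return results
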