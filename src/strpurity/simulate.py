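"""Synthetic data generation for every pipeline input.

The generator emulates the statistical structure of population-scale STR
genotype tables and their companion annotation files so the full analysis
is exercisable without any download:

* loci carry 2-6 bp motifs drawn from a realistic pool, allele lengths in
  the short-read-spannable range, and annotation columns (chromatin class,
  enhancer peaks, LOEUF, SISTR class, binding-site proximity);
* each major allele's interruption count is drawn Poisson with log rate
  equal to a planted linear predictor (GC fraction and motif length as
  covariates, log allele length as offset, plus configurable annotation
  effects), and an allele sequence realizing exactly that count is built
  by substituting well-separated bases of a pure repeat;
* diploid genotype tables are drawn at Hardy-Weinberg proportions around
  the major allele;
* ground truth (planted coefficients and per-locus counts) is emitted
  alongside for parameter-recovery testing.

All outputs are a deterministic function of the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import GenomicInterval, SNVRecord
from .coding import mutational_space
from .filters import LocusGenotypes
from .repeats import Motif, pure_allele
from . import io as strio

__all__ = [
    "DEFAULT_MOTIF_POOL",
    "SimParams",
    "plant_substitutions",
    "generate_locus_table",
    "generate_genotypes",
    "write_bundle",
]

#: Motif pool loosely matching the genome-wide motif spectrum of
#: non-homopolymer STRs (dinucleotides dominate; AT-rich motifs common).
DEFAULT_MOTIF_POOL: dict[str, float] = {
    "AC": 0.25,
    "AT": 0.18,
    "AG": 0.12,
    "AAT": 0.10,
    "AAC": 0.06,
    "CAG": 0.05,
    "AGG": 0.04,
    "AAAT": 0.08,
    "AAAG": 0.05,
    "AATG": 0.03,
    "AAAAT": 0.04,
    "AAAAC": 0.03,
    "AATGGC": 0.04,
    "CCGGAA": 0.03,
}

_CHROM_CLASS_PROBS = {
    "heterochromatin": 0.78,
    "transcribed": 0.12,
    "weak_enhancer": 0.05,
    "other": 0.035,
    "promoter": 0.008,
    "strong_enhancer": 0.007,
}


@dataclass
class SimParams:
    """Study conditions for the synthetic cohort.

    ``gain_rate`` is the probability that a nucleotide added by slippage
    is erroneous (an interruption), in the empirically supported 1e-3 to
    1e-2 per-base range.  ``base_rate`` sets the baseline interruption
    density per bp of allele so that typical alleles carry 0-3
    interruptions.  ``planted_effects`` maps annotation column names to
    log-scale Poisson coefficients.
    """

    n_loci: int = 2500
    motif_pool: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MOTIF_POOL))
    min_copies: int = 8
    max_copies: int = 25
    mu_slip: float = 5e-3
    gain_rate: float = 5e-3
    base_rate: float = 8e-3
    beta_gc: float = -0.5
    beta_motif_len: float = -0.1
    planted_effects: dict[str, float] = field(default_factory=dict)
    n_samples: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.gain_rate <= 1 or not 0 <= self.mu_slip <= 1:
            raise ValueError("rates must be in [0, 1]")
        if self.n_loci < 1:
            raise ValueError("n_loci must be positive")
        total = sum(self.motif_pool.values())
        if not np.isclose(total, 1.0):
            self.motif_pool = {m: p / total for m, p in self.motif_pool.items()}


def plant_substitutions(
    motif: str, length_bp: int, k: int, rng: np.random.Generator
) -> str:
    """Pure allele with exactly k substitution interruptions.

    Positions are chosen pairwise non-adjacent (spacing >= 2) and at least
    one base away from either allele end, and each substituted base
    differs from the template base.  Occasionally a draw still admits a
    cheaper alignment (substitutions across consecutive copies of a
    run-containing motif can mimic a phase shift), so the arrangement is
    verified against the purity metric and redrawn until the realized
    fitting-alignment distance equals k.
    """
    from .repeats import purity_distance

    m = Motif(motif)
    pure = pure_allele(m, length_bp)
    for _ in range(50):
        seq = list(pure)
        candidates = list(range(1, length_bp - 1))
        positions: list[int] = []
        rng.shuffle(candidates)
        for pos in candidates:
            if len(positions) == k:
                break
            if all(abs(pos - q) >= 2 for q in positions):
                positions.append(pos)
        if len(positions) < k:
            raise ValueError(f"cannot place {k} spaced substitutions in {length_bp} bp")
        for pos in positions:
            seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
        planted = "".join(seq)
        if purity_distance(planted, m) == k:
            return planted
    raise ValueError(f"could not realize distance {k} in {length_bp} bp of {motif}")


def _draw_annotations(n: int, rng: np.random.Generator) -> pd.DataFrame:
    classes = rng.choice(
        list(_CHROM_CLASS_PROBS), size=n, p=list(_CHROM_CLASS_PROBS.values())
    )
    ann = pd.DataFrame({"chrom_class": classes})
    is_enh = np.isin(classes, ["weak_enhancer", "strong_enhancer"])
    ann["enhancer"] = is_enh.astype(int)
    ann["strong_enhancer"] = (classes == "strong_enhancer").astype(int)
    ann["promoter"] = (classes == "promoter").astype(int)
    # open chromatin overlaps enhancers preferentially
    ann["atac_peak"] = (rng.random(n) < np.where(is_enh, 0.4, 0.05)).astype(int)
    # gene-level constraint: LOEUF roughly lognormal, clipped to observed range
    ann["loeuf"] = np.clip(rng.lognormal(-0.2, 0.45, n), 0.05, 2.0)
    ann["sistr_constrained"] = (rng.random(n) < 0.6).astype(int)
    ann["near_binding_site"] = (rng.random(n) < 0.1).astype(int)
    return ann


def generate_locus_table(params: SimParams, sequences: bool = True) -> tuple[pd.DataFrame, dict]:
    """Annotated locus table with planted Poisson interruption counts.

    Returns ``(table, truth)`` where truth records the planted
    coefficients and the realized per-locus counts.  The table carries
    the measured-covariate columns the regression layer expects
    (``gc_fraction``, ``motif_len``, ``log_allele_len``) plus the allele
    sequence whose purity metrics realize the planted count.
    """
    rng = np.random.default_rng(params.seed)
    motifs = rng.choice(list(params.motif_pool), size=params.n_loci,
                        p=list(params.motif_pool.values()))
    rows = []
    for i, motif in enumerate(motifs):
        copies = int(rng.integers(params.min_copies, params.max_copies + 1))
        length = copies * len(motif)
        m = Motif(motif)
        rows.append({
            "locus_id": f"STR{i:06d}",
            "chrom": f"chr{1 + i % 22}",
            "start": 10_000 + 2_000 * (i // 22),
            "motif": motif,
            "motif_len": len(motif),
            "gc_fraction": m.gc_fraction,
            "allele_len": length,
        })
    table = pd.DataFrame(rows)
    table["end"] = table["start"] + table["allele_len"]
    table = pd.concat([table, _draw_annotations(params.n_loci, rng)], axis=1)
    table["log_allele_len"] = np.log(table["allele_len"])

    eta = (
        np.log(params.base_rate)
        + params.beta_gc * table["gc_fraction"].to_numpy()
        + params.beta_motif_len * table["motif_len"].to_numpy()
        + table["log_allele_len"].to_numpy()
    )
    for col, beta in params.planted_effects.items():
        eta = eta + beta * pd.to_numeric(table[col]).to_numpy()
    lam = np.exp(eta)
    counts = rng.poisson(lam)
    # respect the impurity cap and the spacing the planting scheme needs
    cap = np.minimum(table["allele_len"] // 4, (table["allele_len"] - 2 + 1) // 2)
    counts = np.minimum(counts, cap.to_numpy())
    if sequences:
        table["allele_seq"] = [
            plant_substitutions(m, int(l), int(k), rng)
            for m, l, k in zip(table["motif"], table["allele_len"], counts)
        ]
    table["n_interruptions"] = counts
    truth = {
        "beta0": float(np.log(params.base_rate)),
        "beta_gc": params.beta_gc,
        "beta_motif_len": params.beta_motif_len,
        "planted_effects": dict(params.planted_effects),
        "counts": counts.tolist(),
    }
    return table, truth


def generate_genotypes(
    table: pd.DataFrame, params: SimParams, rng: np.random.Generator | None = None
) -> list[LocusGenotypes]:
    """Diploid genotypes at Hardy-Weinberg proportions around the major allele.

    Each locus segregates its planted major allele at frequency 0.55-0.95
    against a one-motif expansion of it; a small fraction of calls are
    missing to exercise the missingness filter without tripping it.
    """
    rng = rng or np.random.default_rng(params.seed + 1)
    loci = []
    for _, row in table.iterrows():
        major = row["allele_seq"]
        minor = major + row["motif"]  # one-motif expansion
        p = rng.uniform(0.55, 0.95)
        calls: list[tuple[str, str] | None] = []
        for _ in range(params.n_samples):
            if rng.random() < 0.03:
                calls.append(None)
                continue
            a1 = major if rng.random() < p else minor
            a2 = major if rng.random() < p else minor
            calls.append((a1, a2))
        loci.append(LocusGenotypes(row["locus_id"], row["motif"], calls,
                                   row["chrom"], int(row["start"]), int(row["end"])))
    return loci


def _companion_tracks(table: pd.DataFrame, rng: np.random.Generator):
    """BED tracks, score tables and SNVs consistent with the locus table."""
    chromhmm, atac, segdups = [], [], []
    state_for_class = {
        "transcribed": 6, "promoter": 3, "strong_enhancer": 14,
        "weak_enhancer": 11, "other": 20, "heterochromatin": 24,
    }
    snvs: list[SNVRecord] = []
    for _, row in table.iterrows():
        s, e = int(row["start"]), int(row["end"])
        chromhmm.append(GenomicInterval(row["chrom"], s - 50, e + 50,
                                        str(state_for_class[row["chrom_class"]])))
        if row["atac_peak"]:
            atac.append(GenomicInterval(row["chrom"], s - 20, e + 20, "peak"))
        n_snv = rng.poisson(0.5 if row["sistr_constrained"] else 0.9)
        for _ in range(n_snv):
            pos = int(rng.integers(s, e))
            snvs.append(SNVRecord(row["chrom"], pos, "A", "G",
                                  allele_count=int(rng.integers(2, 50)),
                                  filter_pass=True))
    loeuf = table[["locus_id", "loeuf"]].copy()
    loeuf["gene_id"] = ["GENE" + lid[3:] for lid in table["locus_id"]]
    sistr = pd.DataFrame({
        "locus_id": table["locus_id"],
        "s_median": np.where(table["sistr_constrained"] == 1,
                             rng.uniform(0.001, 0.1, len(table)), 0.0),
        "ci_width": rng.uniform(0.01, 0.25, len(table)),
    })
    return chromhmm, atac, segdups, loeuf, sistr, snvs


def write_bundle(out_dir: str | Path, params: SimParams) -> dict[str, Path]:
    """Write the full synthetic fixture bundle to a directory.

    Emits the annotated locus table, a genotype VCF and TSV, chromHMM and
    ATAC BED tracks, LOEUF and SISTR score tables, an SNV VCF, and a
    ground-truth JSON with the planted coefficients.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed + 2)
    table, truth = generate_locus_table(params)
    loci = generate_genotypes(table, params)
    chromhmm, atac, _, loeuf, sistr, snvs = _companion_tracks(table, rng)

    paths = {
        "loci": out / "loci.tsv",
        "genotypes_vcf": out / "genotypes.vcf",
        "genotypes_tsv": out / "genotypes.tsv",
        "chromhmm_bed": out / "chromhmm.bed",
        "atac_bed": out / "atac.bed",
        "loeuf_tsv": out / "loeuf.tsv",
        "sistr_tsv": out / "sistr.tsv",
        "snvs_vcf": out / "snvs.vcf",
        "coding_loci": out / "coding_loci.tsv",
        "truth_json": out / "ground_truth.json",
        "params_json": out / "sim_params.json",
    }
    coding_table, coding_truth = generate_coding_table(
        n_loci=min(params.n_loci, 2500), seed=params.seed + 3)
    strio.write_tsv(coding_table, paths["coding_loci"])
    truth = {**truth, "coding": coding_truth}
    strio.write_tsv(table, paths["loci"])
    strio.write_genotypes_vcf(loci, paths["genotypes_vcf"])
    strio.write_genotypes_tsv(loci, paths["genotypes_tsv"])
    strio.write_bed(chromhmm, paths["chromhmm_bed"])
    strio.write_bed(atac, paths["atac_bed"])
    strio.write_tsv(loeuf, paths["loeuf_tsv"])
    strio.write_tsv(sistr, paths["sistr_tsv"])
    strio.write_snvs_vcf(snvs, paths["snvs_vcf"])
    paths["truth_json"].write_text(json.dumps(truth, indent=1))
    paths["params_json"].write_text(json.dumps(
        {k: v for k, v in asdict(params).items()}, indent=1))
    return paths


#: Coding motifs (3- and 6-mers) whose in-frame tilings contain no stop codon
#: in any rotation, so every pure-ancestor candidate is admissible.
CODING_MOTIF_POOL = ("CAG", "AAG", "ACC", "AGC", "CCG", "AAC", "GCC", "AGG",
                     "AATGGC", "ACCGGA")


def _mutant_codons(codon: str, status: str) -> list[str]:
    """Single-substitution mutants of a codon with the given consequence."""
    from .coding import GENETIC_CODE

    out = []
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            aa, ref_aa = GENETIC_CODE[mut], GENETIC_CODE[codon]
            if status == "silent" and aa == ref_aa:
                out.append(mut)
            elif status == "missense" and aa not in ("*", ref_aa):
                out.append(mut)
    return out


def plant_codon_interruptions(
    motif: str, n_codons: int, k_silent: int, k_missense: int, rng: np.random.Generator
) -> str:
    """Pure in-frame tiling of the motif with planted interrupted codons.

    The allele is ``n_codons`` codons of the motif's frame-0 tiling (the
    motif length must divide ``3 * n_codons``).  ``k_silent`` codons
    receive a single silent substitution and ``k_missense`` a single
    missense substitution, all in distinct codons that admit the required
    consequence, so a codon audit against the pure ancestor recovers the
    counts exactly.
    """
    length = 3 * n_codons
    if length % len(motif):
        raise ValueError("allele length must be a whole number of motif copies")
    allele = pure_allele(Motif(motif), length)
    codons = [allele[i : i + 3] for i in range(0, length, 3)]
    order = list(rng.permutation(n_codons))
    planted = 0
    for status, k in (("silent", k_silent), ("missense", k_missense)):
        placed = 0
        for idx in order:
            if placed == k:
                break
            options = _mutant_codons(codons[idx], status)
            if codons[idx] == allele[3 * idx : 3 * idx + 3] and options:
                codons[idx] = options[rng.integers(len(options))]
                placed += 1
                planted += 1
        if placed < k:
            raise ValueError(f"could not place {k} {status} substitutions in {motif} allele")
    return "".join(codons)


def generate_coding_table(
    n_loci: int = 2500,
    beta_silent_loeuf: float = -0.25,
    beta_missense_loeuf: float = 0.1,
    base_silent_rate: float = 0.05,
    base_missense_rate: float = 0.05,
    min_codons: int = 8,
    max_codons: int = 30,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Coding STR cohort with planted consequence-specific constraint effects.

    Silent and missense interrupted-codon counts are drawn Poisson with
    rates ``base_rate * exp(beta * LOEUF)`` per unit of the class's
    mutational-space exposure, then realized as codon substitutions in
    the allele sequence.  Returns a per-locus wide table (with the allele
    sequence) and the planted truth.
    """
    rng = np.random.default_rng(seed)
    from .coding import mutational_space as mspace

    rows = []
    for i in range(n_loci):
        motif = CODING_MOTIF_POOL[rng.integers(len(CODING_MOTIF_POOL))]
        codons_per_copy = len(motif) // 3
        copies = int(rng.integers(max(min_codons // codons_per_copy, 2),
                                  max_codons // codons_per_copy + 1))
        n_codons = copies * codons_per_copy
        loeuf = float(np.clip(rng.lognormal(-0.2, 0.45), 0.05, 2.0))
        tiling = pure_allele(Motif(motif), 3 * n_codons)
        spaces = [mspace(tiling[j : j + 3]) for j in range(0, 3 * n_codons, 3)]
        sil_subs = sum(s[0] for s in spaces)
        mis_subs = sum(s[1] for s in spaces)
        silent_exposure = float(n_codons)
        missense_exposure = n_codons * (mis_subs / sil_subs) if sil_subs else np.nan
        lam_s = base_silent_rate * np.exp(beta_silent_loeuf * loeuf) * silent_exposure
        lam_m = base_missense_rate * np.exp(beta_missense_loeuf * loeuf) * missense_exposure
        k_s = int(rng.poisson(lam_s))
        k_m = int(rng.poisson(lam_m))
        cap = max(n_codons // 4, 1)  # keep within the 25% impurity cap
        k_s, k_m = min(k_s, cap), min(k_m, max(cap - k_s, 0))
        seq = plant_codon_interruptions(motif, n_codons, k_s, k_m, rng)
        m = Motif(motif)
        rows.append({
            "locus_id": f"CSTR{i:05d}",
            # alternate constraint annotations: dominant-disease gene
            # membership and protein-domain overlap, no planted effect
            "ad_gene": int(rng.random() < 0.06),
            "pfam_domain": int(rng.random() < 0.12),
            "motif": motif,
            "motif_len": len(motif),
            "gc_fraction": m.gc_fraction,
            "n_codons": n_codons,
            "allele_len": 3 * n_codons,
            "loeuf": loeuf,
            "strand": "+",
            "frame_offset": 0,
            "allele_seq": seq,
            "k_silent": k_s,
            "k_missense": k_m,
            "silent_exposure": silent_exposure,
            "missense_exposure": missense_exposure,
        })
    truth = {
        "beta_silent_loeuf": beta_silent_loeuf,
        "beta_missense_loeuf": beta_missense_loeuf,
        "base_silent_rate": base_silent_rate,
        "base_missense_rate": base_missense_rate,
    }
    return pd.DataFrame(rows), truth


def coding_long_format(table: pd.DataFrame) -> pd.DataFrame:
    """Wide coding table to long format: one row per (locus, consequence)."""
    common = ["locus_id", "motif", "motif_len", "gc_fraction", "loeuf"]
    sil = table[common].copy()
    sil["consequence"] = "silent"
    sil["n_interruptions"] = table["n_silent_interruptions"].to_numpy()
    sil["exposure"] = table["silent_exposure"].to_numpy()
    mis = table[common].copy()
    mis["consequence"] = "missense"
    mis["n_interruptions"] = table["n_missense_interruptions"].to_numpy()
    mis["exposure"] = table["missense_exposure"].to_numpy()
    return pd.concat([sil, mis], ignore_index=True)


# --- headline regression designs (count-level parameter planting) --------
#
# Each design plants known coefficients in the exact model shape the
# analysis fits (response, covariates, offset, interactions) and draws the
# response Poisson from the implied rate, so fitted estimates can be
# checked for nominal +/-2 SE coverage.  The slower sequence-level
# generators realize the same counts as actual alleles; their agreement is
# tested separately, so these tables isolate the statistical behaviour of
# the regression layer.

HEADLINE_DESIGNS = (
    "silent_loeuf",
    "missense_loeuf",
    "joint_interaction",
    "enhancer_purity",
    "longest_pure",
    "ag_binding_interaction",
    "sistr_snv",
)


def generate_design_table(
    design: str, n_loci: int, seed: int, null: bool = False
) -> tuple[pd.DataFrame, dict, dict[str, float]]:
    """Synthetic table + model description + planted truth for one design.

    Returns ``(table, spec_kwargs, truth)`` where ``spec_kwargs`` can be
    passed to ``glm.ModelSpec`` (or marks the joint model) and ``truth``
    maps fitted term names to the planted coefficients.  ``null=True``
    zeroes the design's headline effect (for type-I calibration).
    """
    rng = np.random.default_rng(seed)
    gc = rng.uniform(0.0, 1.0, n_loci)
    motif_len = rng.integers(2, 7, n_loci).astype(float)
    allele_len = (motif_len * rng.integers(8, 26, n_loci)).astype(float)
    log_len = np.log(allele_len)
    base = dict(gc_fraction=gc, motif_len=motif_len, log_allele_len=log_len)

    def poisson(eta: np.ndarray) -> np.ndarray:
        return rng.poisson(np.exp(eta))

    if design in ("silent_loeuf", "missense_loeuf"):
        beta = 0.0 if null else (-0.25 if design == "silent_loeuf" else 0.1)
        loeuf = np.clip(rng.lognormal(-0.2, 0.45, n_loci), 0.05, 2.0)
        n_codons = rng.integers(8, 31, n_loci).astype(float)
        exposure = n_codons if design == "silent_loeuf" else n_codons * rng.uniform(2, 8, n_loci)
        eta = np.log(0.05) - 0.3 * gc + beta * loeuf + np.log(exposure)
        table = pd.DataFrame({"gc_fraction": gc, "loeuf": loeuf,
                              "log_exposure": np.log(exposure),
                              "n_interruptions": poisson(eta)})
        spec = dict(response="n_interruptions", covariates=("gc_fraction", "loeuf"),
                    offset="log_exposure", name=design)
        return table, spec, {"loeuf": beta, "gc_fraction": -0.3}

    if design == "joint_interaction":
        b_mis, b_loeuf, b_int = -1.0, -0.25, (0.0 if null else -0.4)
        loeuf = np.clip(rng.lognormal(-0.2, 0.45, n_loci), 0.05, 2.0)
        n_codons = rng.integers(8, 31, n_loci).astype(float)
        rows = []
        for is_mis in (0.0, 1.0):
            exposure = n_codons * (rng.uniform(2, 8, n_loci) if is_mis else 1.0)
            eta = (np.log(0.08) - 0.3 * gc + b_mis * is_mis + b_loeuf * loeuf
                   + b_int * is_mis * loeuf + np.log(exposure))
            rows.append(pd.DataFrame({
                "gc_fraction": gc, "motif_len": motif_len, "loeuf": loeuf,
                "consequence": "missense" if is_mis else "silent",
                "exposure": exposure, "n_interruptions": poisson(eta)}))
        table = pd.concat(rows, ignore_index=True)
        return table, {"joint": True}, {"is_missense:loeuf": b_int,
                                        "is_missense": b_mis, "loeuf": b_loeuf}

    if design == "enhancer_purity":
        beta = 0.0 if null else -0.05
        enh = (rng.random(n_loci) < 0.05).astype(float)
        eta = np.log(0.02) - 0.5 * gc - 0.05 * motif_len + beta * enh + log_len
        table = pd.DataFrame({**base, "enhancer": enh, "edit_distance": poisson(eta)})
        spec = dict(response="edit_distance",
                    covariates=("gc_fraction", "motif_len", "enhancer"),
                    offset="log_allele_len", name=design)
        return table, spec, {"enhancer": beta}

    if design == "longest_pure":
        beta = 0.0 if null else 0.012
        enh = (rng.random(n_loci) < 0.05).astype(float)
        dist = rng.poisson(1.0, n_loci).astype(float)
        eta = (np.log(0.6) + 0.02 * gc - 0.01 * motif_len + beta * enh
               - 0.05 * dist + log_len)
        table = pd.DataFrame({**base, "enhancer": enh, "edit_distance": dist,
                              "longest_pure_bp": poisson(eta)})
        spec = dict(response="longest_pure_bp",
                    covariates=("gc_fraction", "motif_len", "enhancer", "edit_distance"),
                    offset="log_allele_len", name=design)
        return table, spec, {"enhancer": beta, "edit_distance": -0.05}

    if design == "ag_binding_interaction":
        b_ag, b_site, b_int = 0.22, 0.05, (0.0 if null else -0.35)
        n = n_loci
        is_ag = (rng.random(n) < 0.5).astype(float)
        site = (rng.random(n) < 0.3).astype(float)
        length = rng.integers(16, 51, n) * 2.0
        eta = (np.log(0.02) + b_ag * is_ag + b_site * site
               + b_int * is_ag * site + np.log(length))
        table = pd.DataFrame({"motif_is_AG": is_ag, "near_binding_site": site,
                              "log_allele_len": np.log(length),
                              "edit_distance": rng.poisson(np.exp(eta))})
        spec = dict(response="edit_distance",
                    covariates=("motif_is_AG", "near_binding_site"),
                    interactions=(("motif_is_AG", "near_binding_site"),),
                    offset="log_allele_len", name=design)
        return table, spec, {"motif_is_AG:near_binding_site": b_int}

    if design == "sistr_snv":
        beta = 0.0 if null else -0.25
        constrained = (rng.random(n_loci) < 0.6).astype(float)
        eta = np.log(0.02) - 0.3 * gc - 0.02 * motif_len + beta * constrained + log_len
        table = pd.DataFrame({**base, "constrained": constrained,
                              "n_snvs": poisson(eta)})
        spec = dict(response="n_snvs",
                    covariates=("gc_fraction", "motif_len", "constrained"),
                    offset="log_allele_len", name=design)
        return table, spec, {"constrained": beta}

    raise ValueError(f"unknown design {design!r}")


def interruption_consequence_probs(motif: str) -> tuple[float, float]:
    """(P silent, P missense) for a new interruption, from mutational space.

    Uses the motif's codon content (trinucleotide motifs map directly to a
    codon; longer motifs average over their in-frame codons), restricted
    to non-nonsense substitutions.
    """
    m = Motif(motif).sequence
    tiled = (m * 3)[: max(3, (len(m) // 3) * 3)] if len(m) % 3 == 0 else (m * 3)[:3]
    sil = mis = 0
    for i in range(0, len(tiled) - 2, 3):
        codon = tiled[i : i + 3]
        try:
            s, mm, _ = mutational_space(codon)
        except ValueError:  # stop codon in this frame: skip
            continue
        sil, mis = sil + s, mis + mm
    if sil + mis == 0:
        return 0.5, 0.5
    return sil / (sil + mis), mis / (sil + mis)
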