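"""Locus/sample filter cascade and major-allele extraction.

Population STR genotype tables are filtered before purity analysis:

* loci missing genotypes for more than 25% of individuals are dropped;
* loci failing a Hardy-Weinberg equilibrium test at P < 1e-6 are dropped;
* loci overlapping a known segmental duplication are dropped;
* only the major (most frequent) allele is analyzed, with frequencies
  recalculated after sample-level exclusions;
* major alleles more than 25% interrupted are dropped downstream.

HWE for multiallelic STR loci is tested with a chi-square goodness of fit
on the full diploid genotype table against Hardy-Weinberg expectations,
pooling genotype classes with expected count below 5 (exact multi-allele
tests are impractical at high allele counts).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .repeats import IMPURITY_CAP, Motif, purity_distance

__all__ = [
    "MISSINGNESS_CAP",
    "HWE_P_THRESHOLD",
    "LocusGenotypes",
    "FilterReport",
    "major_allele",
    "hwe_test",
    "filter_locus",
    "filter_table",
]

MISSINGNESS_CAP = 0.25
HWE_P_THRESHOLD = 1e-6


@dataclass
class LocusGenotypes:
    """Diploid allele calls for one locus; ``None`` marks a missing call."""

    locus_id: str
    motif: str
    calls: list[tuple[str, str] | None]
    chrom: str = "chr1"
    start: int = 0
    end: int = 0

    @property
    def n_samples(self) -> int:
        return len(self.calls)

    @property
    def call_rate(self) -> float:
        called = sum(c is not None for c in self.calls)
        return called / len(self.calls) if self.calls else 0.0

    def allele_counts(self) -> Counter[str]:
        counts: Counter[str] = Counter()
        for call in self.calls:
            if call is not None:
                counts.update(call)
        return counts

    def genotype_counts(self) -> Counter[tuple[str, str]]:
        counts: Counter[tuple[str, str]] = Counter()
        for call in self.calls:
            if call is not None:
                counts[tuple(sorted(call))] += 1
        return counts


@dataclass
class FilterReport:
    locus_id: str
    pass_missingness: bool
    hwe_p: float
    pass_hwe: bool
    in_segdup: bool
    major_allele: str | None
    major_freq: float
    pass_impurity_cap: bool
    fail_reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.fail_reasons


def major_allele(genotypes: LocusGenotypes) -> tuple[str, float] | None:
    """Most frequent allele among passing calls; ties break lexicographically.

    Returns None when the locus has no called genotypes (dropped upstream).
    """
    counts = genotypes.allele_counts()
    if not counts:
        return None
    total = sum(counts.values())
    best = min(counts, key=lambda a: (-counts[a], a))
    return best, counts[best] / total


def hwe_test(genotype_counts: dict[tuple[str, str], int],
             mode: str = "full") -> float:
    """Chi-square Hardy-Weinberg goodness-of-fit p-value.

    ``mode="full"``: observed diploid genotype counts are compared to
    expectations from the allele frequencies; genotype classes with
    expected count < 5 are pooled into a single class.  Degrees of
    freedom: classes - 1 - (n_alleles - 1), floored at 1.

    ``mode="allele_vs_rest"``: each allele is collapsed to a biallelic
    (allele vs rest) table tested at 1 df; the minimum p-value is
    Bonferroni-corrected by the number of alleles.  Useful at very high
    allele counts where the full table is sparse.

    Monomorphic loci return 1 by convention.
    """
    if mode == "allele_vs_rest":
        return _hwe_allele_vs_rest(genotype_counts)
    if mode != "full":
        raise ValueError(f"unknown HWE mode {mode!r}")
    n = sum(genotype_counts.values())
    if n == 0:
        raise ValueError("no called genotypes")
    allele_counts: Counter[str] = Counter()
    for (a1, a2), c in genotype_counts.items():
        allele_counts[a1] += c
        allele_counts[a2] += c
    alleles = sorted(allele_counts)
    if len(alleles) < 2:
        return 1.0
    freqs = {a: allele_counts[a] / (2 * n) for a in alleles}
    obs, exp = [], []
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            e = n * (freqs[a] ** 2 if a == b else 2 * freqs[a] * freqs[b])
            obs.append(genotype_counts.get((a, b), 0))
            exp.append(e)
    obs_arr, exp_arr = np.array(obs, float), np.array(exp, float)
    keep = exp_arr >= 5
    if (~keep).any():
        obs_arr = np.append(obs_arr[keep], obs_arr[~keep].sum())
        exp_arr = np.append(exp_arr[keep], exp_arr[~keep].sum())
    if len(obs_arr) < 2:
        return 1.0
    stat = ((obs_arr - exp_arr) ** 2 / exp_arr).sum()
    df = max(len(obs_arr) - 1 - (len(alleles) - 1), 1)
    return float(stats.chi2.sf(stat, df))


def _hwe_allele_vs_rest(genotype_counts: dict[tuple[str, str], int]) -> float:
    n = sum(genotype_counts.values())
    if n == 0:
        raise ValueError("no called genotypes")
    alleles = sorted({a for pair in genotype_counts for a in pair})
    if len(alleles) < 2:
        return 1.0
    p_min = 1.0
    for a in alleles:
        hom = het = 0
        for (x, y), c in genotype_counts.items():
            k = (x == a) + (y == a)
            if k == 2:
                hom += c
            elif k == 1:
                het += c
        other = n - hom - het
        p = (2 * hom + het) / (2 * n)
        exp = np.array([n * p * p, n * 2 * p * (1 - p), n * (1 - p) ** 2])
        obs = np.array([hom, het, other], float)
        keep = exp >= 5
        if keep.sum() < 2:
            continue
        stat = ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum() + (
            ((obs[~keep].sum() - exp[~keep].sum()) ** 2 / exp[~keep].sum())
            if (~keep).any() and exp[~keep].sum() > 0 else 0.0
        )
        df = max(int(keep.sum() + ((~keep).any() and 1)) - 2, 1)
        p_min = min(p_min, float(stats.chi2.sf(stat, df)))
    return min(1.0, p_min * len(alleles))


def filter_locus(
    genotypes: LocusGenotypes,
    in_segdup: bool = False,
    excluded_samples: set[int] | None = None,
) -> FilterReport:
    """Apply the locus filter cascade and extract the major allele.

    ``excluded_samples`` are indices into the call list (e.g. related
    individuals); their calls are treated as missing before frequency
    calculations, mirroring sample-level exclusion upstream.
    """
    if excluded_samples:
        calls = [
            None if i in excluded_samples else c for i, c in enumerate(genotypes.calls)
        ]
        genotypes = LocusGenotypes(
            genotypes.locus_id, genotypes.motif, calls,
            genotypes.chrom, genotypes.start, genotypes.end,
        )
    reasons: list[str] = []
    pass_missing = genotypes.call_rate >= 1 - MISSINGNESS_CAP
    if not pass_missing:
        reasons.append("missingness")
    gcounts = genotypes.genotype_counts()
    if gcounts:
        hwe_p = hwe_test(dict(gcounts))
    else:
        hwe_p = float("nan")
        reasons.append("no_calls")
    pass_hwe = bool(hwe_p >= HWE_P_THRESHOLD) if gcounts else False
    if gcounts and not pass_hwe:
        reasons.append("hwe")
    if in_segdup:
        reasons.append("segdup")
    maj = major_allele(genotypes)
    if maj is None:
        major, freq = None, float("nan")
        pass_impurity = False
    else:
        major, freq = maj
        frac = purity_distance(major, Motif(genotypes.motif)) / len(major)
        pass_impurity = frac <= IMPURITY_CAP
        if not pass_impurity:
            reasons.append("impurity")
    return FilterReport(
        locus_id=genotypes.locus_id,
        pass_missingness=pass_missing,
        hwe_p=hwe_p,
        pass_hwe=pass_hwe,
        in_segdup=in_segdup,
        major_allele=major,
        major_freq=freq,
        pass_impurity_cap=pass_impurity,
        fail_reasons=reasons,
    )


def filter_table(
    loci: list[LocusGenotypes],
    segdup_loci: set[str] | None = None,
    excluded_samples: set[int] | None = None,
) -> pd.DataFrame:
    """Run the cascade over many loci; one FilterReport row per locus."""
    segdup_loci = segdup_loci or set()
    rows = []
    for g in loci:
        rep = filter_locus(g, in_segdup=g.locus_id in segdup_loci,
                           excluded_samples=excluded_samples)
        rows.append({
            "locus_id": rep.locus_id,
            "pass_missingness": rep.pass_missingness,
            "hwe_p": rep.hwe_p,
            "pass_hwe": rep.pass_hwe,
            "in_segdup": rep.in_segdup,
            "major_allele": rep.major_allele,
            "major_freq": rep.major_freq,
            "pass_impurity_cap": rep.pass_impurity_cap,
            "fail_reasons": ",".join(rep.fail_reasons),
            "passed": rep.passed,
        })
    return pd.DataFrame(rows)
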