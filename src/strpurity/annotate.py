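"""Annotation joins: chromatin states, interval tracks, constraint scores, SNVs.

Coordinates are BED-convention throughout: 0-based, half-open.  Readers
tolerate both ``chr``-prefixed and bare chromosome names through a
normalization option.

The chromatin classifier collapses 25-state chromHMM annotations to six
classes with a fixed sequential precedence: transcribed (states 1, 5-9),
promoter (2-4), strong enhancer (13-15), weak enhancer (10-12, 16-18),
other (19, 20, 22, 23), and heterochromatin for everything else.  States
21, 24 and 25 are not named by any rule and fall through to the
heterochromatin class.  A locus overlapping several chromHMM intervals
contributes the union of their states before classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "CHROM_CLASSES",
    "GenomicInterval",
    "SistrScore",
    "SNVRecord",
    "normalize_chrom",
    "classify_chromhmm",
    "intersect_loci",
    "min_loeuf_of_element",
    "count_interrupting_snvs",
    "sistr_locus_set",
]

CHROM_CLASSES = (
    "transcribed",
    "promoter",
    "strong_enhancer",
    "weak_enhancer",
    "other",
    "heterochromatin",
)

# Sequential precedence: first rule whose state set intersects the locus wins.
_CHROMHMM_RULES: tuple[tuple[str, frozenset[int]], ...] = (
    ("transcribed", frozenset({1, 5, 6, 7, 8, 9})),
    ("promoter", frozenset({2, 3, 4})),
    ("strong_enhancer", frozenset({13, 14, 15})),
    ("weak_enhancer", frozenset({10, 11, 12, 16, 17, 18})),
    ("other", frozenset({19, 20, 22, 23})),
)


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    payload: Any = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class SistrScore:
    """Per-locus selection coefficient against one-motif length changes."""

    locus_id: str
    s_median: float
    ci_width: float

    @property
    def constrained(self) -> bool:
        return self.s_median > 0

    @property
    def reliable(self) -> bool:
        return self.ci_width < 0.3


@dataclass(frozen=True)
class SNVRecord:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    allele_count: int
    filter_pass: bool


def normalize_chrom(chrom: str, style: str = "chr") -> str:
    """Normalize chromosome naming; ``style`` is 'chr' or 'bare'."""
    bare = chrom[3:] if chrom.startswith("chr") else chrom
    return f"chr{bare}" if style == "chr" else bare


def classify_chromhmm(overlapping_states: Iterable[int]) -> str:
    """Collapse the set of overlapping chromHMM states to one class."""
    states = set(overlapping_states)
    if states - set(range(1, 26)):
        raise ValueError(f"chromHMM states must be in 1..25, got {sorted(states)}")
    for cls, rule_states in _CHROMHMM_RULES:
        if states & rule_states:
            return cls
    return "heterochromatin"


def _build_trees(track: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in track:
        trees.setdefault(normalize_chrom(iv.chrom), IntervalTree()).addi(
            iv.start, iv.end, iv.payload
        )
    return trees


def intersect_loci(
    loci: list[GenomicInterval],
    track: list[GenomicInterval],
    min_overlap_bp: int = 1,
) -> list[set]:
    """Payloads of track intervals overlapping each locus by >= min_overlap_bp."""
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    trees = _build_trees(track)
    out: list[set] = []
    for locus in loci:
        tree = trees.get(normalize_chrom(locus.chrom))
        hits: set = set()
        if tree is not None:
            for iv in tree.overlap(locus.start, locus.end):
                overlap = min(locus.end, iv.end) - max(locus.start, iv.begin)
                if overlap >= min_overlap_bp:
                    hits.add(iv.data)
        out.append(hits)
    return out


def min_loeuf_of_element(
    linked_genes: Iterable[str], gene_scores: dict[str, float]
) -> float | None:
    """Minimum LOEUF over an element's linked genes; None if none scored."""
    scores = [gene_scores[g] for g in linked_genes if g in gene_scores]
    return min(scores) if scores else None


def genehancer_min_loeuf(
    links: pd.DataFrame,
    gene_scores: dict[str, float],
    elite_only: bool = True,
) -> dict[str, float]:
    """Per-element minimum LOEUF over its (optionally elite) gene links.

    ``links`` needs columns ``element_id``, ``gene_id`` and a boolean
    ``elite``; elements whose links are all unscored are absent from the
    result (missing, not zero).
    """
    use = links[links["elite"].astype(bool)] if elite_only else links
    out: dict[str, float] = {}
    for element_id, grp in use.groupby("element_id"):
        score = min_loeuf_of_element(grp["gene_id"], gene_scores)
        if score is not None:
            out[element_id] = score
    return out


def count_interrupting_snvs(locus: GenomicInterval, snvs: Iterable[SNVRecord]) -> int:
    """Nonsingleton, filter-passing SNVs inside the locus footprint.

    Positions are 0-based; the half-open locus interval excludes ``end``.
    Singletons (allele_count < 2) and filter failures are excluded.
    """
    chrom = normalize_chrom(locus.chrom)
    return sum(
        1
        for v in snvs
        if v.filter_pass
        and v.allele_count >= 2
        and normalize_chrom(v.chrom) == chrom
        and locus.start <= v.pos < locus.end
    )


def sistr_locus_set(
    loci: pd.DataFrame, scores: dict[str, SistrScore], coding_locus_ids: set[str]
) -> pd.DataFrame:
    """Construct the SISTR analysis locus set.

    Keeps noncoding 2-4-mer loci with a reliable score (95% CI width below
    0.3) and attaches the neutral/constrained classification (median s = 0
    versus > 0).  Expects ``locus_id`` and ``motif`` columns.
    """
    keep = []
    for _, row in loci.iterrows():
        sc = scores.get(row["locus_id"])
        if sc is None or not sc.reliable:
            continue
        if not 2 <= len(row["motif"]) <= 4:
            continue
        if row["locus_id"] in coding_locus_ids:
            continue
        keep.append({**row, "s_median": sc.s_median, "constrained": sc.constrained})
    return pd.DataFrame(keep)
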