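"""Codon-level interruption analysis for coding STRs.

Coding STRs (trinucleotide and hexanucleotide motifs, fully contained in
an exon) are audited codon by codon against a hypothetical pure ancestral
allele: the motif rotation, tiled to the observed allele length, that
minimizes the number of amino-acid changes versus the observed allele
while implying no nonsense change in either direction.  Each interrupted
codon is classified as silent (same amino acid) or missense.

Because codons differ in their "mutational space" — how many of the nine
possible single-base substitutions are silent versus missense — raw
interruption counts are not comparable across consequence classes.  The
module therefore computes per-class *exposures*: the silent exposure is
the codon count, and the missense exposure is the codon count scaled by
the ratio of missense to silent substitution opportunities summed over
the ancestral codons, so that a neutral mutational process produces equal
interruption rates per unit exposure in the two classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .repeats import Motif, pure_allele

__all__ = [
    "GENETIC_CODE",
    "STOP_CODONS",
    "CodingLocus",
    "CodonAudit",
    "CodingInterruptionSummary",
    "reverse_complement",
    "mutational_space",
    "infer_pure_ancestor",
    "audit_codons",
    "exposures",
    "summarize_coding_allele",
]

_BASES = "ACGT"

# Standard genetic code (NCBI table 1), codons enumerated in TCAG order.
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
GENETIC_CODE: dict[str, str] = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate("TCAG")
    for j, b in enumerate("TCAG")
    for k, c in enumerate("TCAG")
}
STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(codon: str) -> str:
    return GENETIC_CODE[codon]


def mutational_space(codon: str) -> tuple[int, int, int]:
    """Counts of (silent, missense, nonsense) among the 9 single-base substitutions."""
    if codon not in GENETIC_CODE:
        raise ValueError(f"not a valid codon: {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no defined mutational space")
    aa = GENETIC_CODE[codon]
    n_silent = n_missense = n_nonsense = 0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            maa = GENETIC_CODE[mutant]
            if maa == "*":
                n_nonsense += 1
            elif maa == aa:
                n_silent += 1
            else:
                n_missense += 1
    return n_silent, n_missense, n_nonsense


@dataclass(frozen=True)
class CodingLocus:
    """A coding STR locus: 3- or 6-bp motif fully contained in one exon."""

    locus_id: str
    motif: Motif
    frame_offset: int  # codon phase of the allele's first base (0, 1 or 2)
    strand: str = "+"
    gene_id: str | None = None
    loeuf: float | None = None

    def __post_init__(self) -> None:
        if len(self.motif) not in (3, 6):
            raise ValueError("coding loci require a 3- or 6-bp motif")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class CodonAudit:
    codon_index: int
    observed_codon: str
    ancestral_codon: str
    status: Literal["pure", "silent", "missense"]
    n_silent_subs: int
    n_missense_subs: int
    n_nonsense_subs: int


@dataclass(frozen=True)
class CodingInterruptionSummary:
    locus_id: str
    n_codons: int
    n_silent_interruptions: int
    n_missense_interruptions: int
    silent_exposure: float
    missense_exposure: float
    usable: bool = True


def _codon_starts(n: int, frame_offset: int) -> range:
    """Starts of complete codons fully inside an allele of length n.

    ``frame_offset`` is the phase of the first base within its codon, so the
    first complete codon begins at ``(3 - frame_offset) % 3``; a trailing
    partial codon is skipped.
    """
    first = (3 - frame_offset) % 3
    last = first + ((n - first) // 3) * 3
    return range(first, last, 3) if last > first else range(0)


def infer_pure_ancestor(
    allele_seq: str, motif: Motif | str, frame_offset: int = 0
) -> tuple[str, str] | None:
    """Infer the hypothetical pure ancestral allele.

    Enumerates every rotation of the motif tiled to the allele length and
    returns ``(ancestor_seq, rotation)`` for the candidate minimizing the
    number of amino-acid changes versus the observed allele, discarding any
    candidate whose comparison implies a nonsense change in either
    direction.  Ties break to the lexicographically smallest rotation.
    Returns None when every candidate implies a nonsense change (the locus
    is unusable, not an error).
    """
    m = motif if isinstance(motif, Motif) else Motif(motif)
    starts = _codon_starts(len(allele_seq), frame_offset)
    candidates: list[tuple[int, str, str]] = []
    for rot in sorted(m.rotations):
        cand = pure_allele(Motif(rot), len(allele_seq))
        aa_changes = 0
        nonsense = False
        for s in starts:
            obs, anc = allele_seq[s : s + 3], cand[s : s + 3]
            if GENETIC_CODE[obs] == "*" or GENETIC_CODE[anc] == "*":
                nonsense = obs != anc or GENETIC_CODE[obs] == "*"
                if nonsense:
                    break
            if GENETIC_CODE[obs] != GENETIC_CODE[anc]:
                aa_changes += 1
        if not nonsense:
            candidates.append((aa_changes, rot, cand))
    if not candidates:
        return None
    _, rot, cand = min(candidates)
    return cand, rot


def audit_codons(allele_seq: str, ancestor: str, frame_offset: int = 0) -> list[CodonAudit]:
    """Per-codon comparison of the observed allele to its pure ancestor.

    Only complete codons fully inside the allele are audited; the
    mutational-space counts are computed on the ancestral codon.
    """
    if len(allele_seq) != len(ancestor):
        raise ValueError("allele and ancestor must have equal length")
    audits: list[CodonAudit] = []
    for idx, s in enumerate(_codon_starts(len(allele_seq), frame_offset)):
        obs, anc = allele_seq[s : s + 3], ancestor[s : s + 3]
        if obs == anc:
            status = "pure"
        elif GENETIC_CODE[obs] == GENETIC_CODE[anc]:
            status = "silent"
        else:
            status = "missense"
        sil, mis, non = mutational_space(anc)
        audits.append(CodonAudit(idx, obs, anc, status, sil, mis, non))
    return audits


def exposures(
    audits: list[CodonAudit],
    ratio_orientation: Literal["missense_to_silent", "silent_to_missense"] = "missense_to_silent",
) -> tuple[float, float] | None:
    """Per-class mutational-opportunity exposures for an audited allele.

    silent_exposure is the codon count; missense_exposure is the codon
    count times the ratio of total missense to total silent substitution
    opportunities over the ancestral codons, so a neutral mutational
    process yields equal rates per exposure in both classes.  Passing
    ``ratio_orientation="silent_to_missense"`` instead multiplies by the
    inverted ratio.  Returns None when the allele offers no silent
    opportunity at all (the locus is excluded from the joint model).
    """
    if not audits:
        raise ValueError("audits must be non-empty")
    n = len(audits)
    tot_sil = sum(a.n_silent_subs for a in audits)
    tot_mis = sum(a.n_missense_subs for a in audits)
    if tot_sil == 0:
        return None
    if ratio_orientation == "missense_to_silent":
        ratio = tot_mis / tot_sil
    elif ratio_orientation == "silent_to_missense":
        ratio = tot_sil / tot_mis
    else:
        raise ValueError(f"unknown ratio_orientation {ratio_orientation!r}")
    return float(n), n * ratio


def summarize_coding_allele(
    locus: CodingLocus,
    allele_seq: str,
    ratio_orientation: Literal["missense_to_silent", "silent_to_missense"] = "missense_to_silent",
) -> CodingInterruptionSummary:
    """Run the full coding audit for one major allele.

    Minus-strand loci are reverse-complemented to transcript orientation
    before codon logic.  Loci where every ancestor candidate implies a
    nonsense change, or with no silent mutational opportunity, come back
    with ``usable=False``.
    """
    seq = reverse_complement(allele_seq) if locus.strand == "-" else allele_seq
    unusable = CodingInterruptionSummary(locus.locus_id, 0, 0, 0, 0.0, 0.0, usable=False)
    res = infer_pure_ancestor(seq, locus.motif, locus.frame_offset)
    if res is None:
        return unusable
    ancestor, _ = res
    audits = audit_codons(seq, ancestor, locus.frame_offset)
    if not audits:
        return unusable
    exp = exposures(audits, ratio_orientation)
    if exp is None:
        return unusable
    sil_exp, mis_exp = exp
    return CodingInterruptionSummary(
        locus_id=locus.locus_id,
        n_codons=len(audits),
        n_silent_interruptions=sum(a.status == "silent" for a in audits),
        n_missense_interruptions=sum(a.status == "missense" for a in audits),
        silent_exposure=sil_exp,
        missense_exposure=mis_exp,
    )
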