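"""Canonical repeat motifs and allele purity metrics.

A short tandem repeat (STR) allele is scored against a hypothetical pure
allele built from the locus motif.  Purity is quantified three ways:

* ``purity_distance`` — the minimum Levenshtein distance between the
  observed allele and a pure repeat template, using a *fitting* alignment
  (free leading/trailing gaps on the template side only) so that the
  observed allele is compared against the best-matching window of an
  arbitrarily long pure repeat, in any motif phase.
* ``longest_pure_stretch`` — the longest run of bases whose period equals
  the motif length and whose repeating unit is a rotation of the motif
  (partial trailing motif copies count, since slippage rates scale per
  base of pure repeat, not per complete motif copy).
* ``fraction_interrupted`` — distance divided by allele length; alleles
  with more than 25% of bases classified as interruptions are flagged for
  exclusion (such alleles are likely mis-genotyped or compound repeats).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import pandas as pd

__all__ = [
    "Motif",
    "ObservedAllele",
    "IMPURITY_CAP",
    "pure_allele",
    "purity_distance",
    "best_rotation",
    "longest_pure_stretch",
    "fraction_interrupted",
    "score_allele",
    "score_allele_table",
]

#: Alleles with fraction_interrupted strictly above this are excluded.
IMPURITY_CAP = 0.25

_DNA = set("ACGT")


def _smallest_period(s: str) -> int:
    for p in range(1, len(s) + 1):
        if len(s) % p == 0 and s == s[:p] * (len(s) // p):
            return p
    return len(s)


@dataclass(frozen=True)
class Motif:
    """A canonical STR repeat unit of 2-6 bases.

    Motifs are canonicalized to their smallest period on construction
    (``ATAT`` becomes ``AT``); homopolymer motifs are rejected because
    single-base runs have no meaningful interruption structure under the
    rotation-based purity metrics.
    """

    sequence: str
    rotations: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq or set(seq) - _DNA:
            raise ValueError(f"motif must be a non-empty ACGT string, got {self.sequence!r}")
        p = _smallest_period(seq)
        if p == 1:
            raise ValueError(f"homopolymer motif {seq!r} is not allowed")
        seq = seq[:p]  # canonicalize degenerate motifs (e.g. ATAT -> AT)
        if not 2 <= len(seq) <= 6:
            raise ValueError(f"motif length must be 2-6 after canonicalization, got {seq!r}")
        object.__setattr__(self, "sequence", seq)
        rots = frozenset(seq[i:] + seq[:i] for i in range(len(seq)))
        object.__setattr__(self, "rotations", rots)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> float:
        return sum(b in "GC" for b in self.sequence) / len(self.sequence)


def _as_motif(motif: Motif | str) -> Motif:
    return motif if isinstance(motif, Motif) else Motif(motif)


def pure_allele(motif: Motif | str, length_bp: int) -> str:
    """Tile the motif and truncate to exactly ``length_bp`` bases."""
    if length_bp < 1:
        raise ValueError(f"length_bp must be >= 1, got {length_bp}")
    m = _as_motif(motif).sequence
    return (m * (length_bp // len(m) + 1))[:length_bp]


def purity_distance(allele_seq: str, motif: Motif | str) -> int:
    """Minimum fitting-alignment edit distance to a pure repeat.

    The observed allele is aligned end-to-end against a pure template of
    length ``len(allele) + 2*len(motif)`` with free gaps at both template
    ends, minimized over all motif rotations.  The template overhang
    guarantees that a longer template can never reduce the distance for
    any allele within the impurity cap.
    """
    if not allele_seq:
        raise ValueError("allele_seq must be non-empty")
    m = _as_motif(motif)
    tmpl_len = len(allele_seq) + 2 * len(m)
    best = len(allele_seq)
    for rot in sorted(m.rotations):
        template = pure_allele(Motif(rot), tmpl_len)
        d = edlib.align(allele_seq, template, mode="HW", task="distance")["editDistance"]
        if d < best:
            best = d
    return best


def best_rotation(allele_seq: str, motif: Motif | str) -> str:
    """Lexicographically smallest rotation achieving the minimum distance."""
    m = _as_motif(motif)
    tmpl_len = len(allele_seq) + 2 * len(m)
    scored = []
    for rot in sorted(m.rotations):
        template = pure_allele(Motif(rot), tmpl_len)
        d = edlib.align(allele_seq, template, mode="HW", task="distance")["editDistance"]
        scored.append((d, rot))
    return min(scored)[1]


def longest_pure_stretch(allele_seq: str, motif: Motif | str) -> int:
    """Length (bp) of the longest substring that is a pure run of the motif.

    A substring qualifies if its repeating unit (period = motif length) is a
    rotation of the motif; partial trailing copies count toward the length.
    Computed by decomposing the allele into maximal period-p agreement runs
    and checking each run's leading window against the motif's rotation set.
    """
    if not allele_seq:
        raise ValueError("allele_seq must be non-empty")
    m = _as_motif(motif)
    p = len(m)
    n = len(allele_seq)
    if n < p:
        # partial single copy: longest substring of any doubled rotation
        best = 0
        doubled = m.sequence * 2
        for i in range(n):
            for j in range(i + 1, n + 1):
                if allele_seq[i:j] in doubled and j - i > best:
                    best = j - i
        return best
    best = 0
    i = 0
    while i + p <= n:
        if allele_seq[i : i + p] not in m.rotations:
            i += 1
            continue
        # extend while period-p agreement holds
        j = i + p
        while j < n and allele_seq[j] == allele_seq[j - p]:
            j += 1
        if j - i > best:
            best = j - i
        # next candidate start: the run [i, j) is maximal at its right end,
        # but an overlapping run in a different phase can begin inside it
        i += 1
    return best


def fraction_interrupted(edit_distance: int, length_bp: int) -> float:
    """Interrupted fraction = edit distance / allele length in bp."""
    return edit_distance / length_bp


@dataclass(frozen=True)
class ObservedAllele:
    """One observed allele at a locus, with derived purity metrics."""

    locus_id: str
    sequence: str
    motif: Motif
    edit_distance: int
    longest_pure_bp: int

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    @property
    def fraction_interrupted(self) -> float:
        return self.edit_distance / self.length_bp

    @property
    def excluded(self) -> bool:
        return self.fraction_interrupted > IMPURITY_CAP


def score_allele(locus_id: str, sequence: str, motif: Motif | str) -> ObservedAllele:
    m = _as_motif(motif)
    return ObservedAllele(
        locus_id=locus_id,
        sequence=sequence,
        motif=m,
        edit_distance=purity_distance(sequence, m),
        longest_pure_bp=longest_pure_stretch(sequence, m),
    )


def score_allele_table(table: pd.DataFrame) -> pd.DataFrame:
    """Append purity columns to an allele table.

    Expects columns ``locus_id``, ``motif``, ``allele_seq``; appends
    ``edit_distance``, ``longest_pure_bp``, ``fraction_interrupted`` and
    ``excluded_flag`` (impurity over 25%).
    """
    out = table.copy()
    dists, stretches = [], []
    for motif, seq in zip(out["motif"], out["allele_seq"]):
        m = Motif(motif)
        dists.append(purity_distance(seq, m))
        stretches.append(longest_pure_stretch(seq, m))
    out["edit_distance"] = dists
    out["longest_pure_bp"] = stretches
    out["fraction_interrupted"] = out["edit_distance"] / out["allele_seq"].str.len()
    out["excluded_flag"] = out["fraction_interrupted"] > IMPURITY_CAP
    return out
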