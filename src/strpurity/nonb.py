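"""Pattern-based prediction of six non-B DNA structure classes.

Each major allele is padded with up to 150 bp of flanking sequence on
either side and scanned for sequence patterns capable of forming:

* slipped-strand structures (direct repeats),
* triple helices (mirror repeats in purine- or pyrimidine-rich context),
* cruciforms (inverted repeats),
* bent DNA (phased A-tracts),
* Z-DNA (alternating purine-pyrimidine runs of GC/CA/GT steps),
* G-quadruplexes (four G3+ tracts with short loops, either strand).

A structure is called for the allele only if at least one predicted span
overlaps the allele interval by >= 1 bp; predictions confined entirely to
the flanking margins are ignored.  Overlapping spans of the same
structure are merged before binning, and any N breaks every pattern.

Thresholds (arm lengths, spacers, loop sizes) follow published
pattern-level definitions of these motif classes and live in a single
config object so they can be overridden wholesale.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "STRUCTURES",
    "NonBConfig",
    "NonBCall",
    "pad_allele",
    "find_structure_spans",
    "predict_structures",
]

STRUCTURES = (
    "slipped_strand",
    "triple_helix",
    "cruciform",
    "bent_DNA",
    "Z_DNA",
    "G_quadruplex",
)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class NonBConfig:
    direct_min_arm: int = 10
    direct_max_spacer: int = 10
    mirror_min_arm: int = 10
    mirror_max_spacer: int = 8
    mirror_min_skew: float = 0.9  # purine (or pyrimidine) fraction of the span
    inverted_min_arm: int = 6
    inverted_max_spacer: int = 3
    apr_min_tract: int = 3
    apr_max_tract: int = 6
    apr_min_tracts: int = 3
    apr_phase: int = 10
    apr_phase_tol: int = 1
    z_min_run: int = 10
    g4_min_tract: int = 3
    g4_min_loop: int = 1
    g4_max_loop: int = 7
    g4_n_tracts: int = 4


@dataclass(frozen=True)
class NonBCall:
    structure: str
    start: int
    end: int
    overlaps_repeat: bool


def pad_allele(
    allele_seq: str, left_flank: str = "", right_flank: str = ""
) -> tuple[str, tuple[int, int]]:
    """Concatenate flanks around the allele; returns (padded, allele interval)."""
    start = len(left_flank)
    return left_flank + allele_seq + right_flank, (start, start + len(allele_seq))


def _merge(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not spans:
        return []
    spans = sorted(spans)
    merged = [spans[0]]
    for s, e in spans[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _segments(seq: str) -> list[tuple[int, str]]:
    """Maximal N-free segments as (offset, subsequence)."""
    segs, start = [], None
    for i, b in enumerate(seq):
        if b in "ACGT":
            if start is None:
                start = i
        elif start is not None:
            segs.append((start, seq[start:i]))
            start = None
    if start is not None:
        segs.append((start, seq[start:]))
    return segs


def _direct_repeats(seq: str, cfg: NonBConfig) -> list[tuple[int, int]]:
    """Two identical arms of >= min_arm bp separated by <= max_spacer bp.

    A direct repeat with arm length a and spacer g appears as a run of
    positions where seq[k] == seq[k + d] with d = a + g; a maximal
    agreement run of length r at shift d yields arms of min(r, d).
    """
    n, spans = len(seq), []
    for d in range(cfg.direct_min_arm, n):
        k = 0
        while k + d < n:
            if seq[k] != seq[k + d]:
                k += 1
                continue
            j = k
            while j + d < n and seq[j] == seq[j + d]:
                j += 1
            r = j - k
            arm = min(r, d)
            if arm >= cfg.direct_min_arm and d - arm <= cfg.direct_max_spacer:
                spans.append((k, k + r + d))
            k = j + 1
    return spans


def _mirror_arms(
    seq: str, min_arm: int, max_spacer: int, inverted: bool
) -> list[tuple[int, int, int]]:
    """Maximal mirror (seq[c-1-k] == seq[c+g+k]) or inverted (== complement)
    repeats, as (center, spacer, arm) triples."""
    n, arms = len(seq), []
    for center in range(1, n):
        for g in range(max_spacer + 1):
            arm = 0
            while (
                center - 1 - arm >= 0
                and center + g + arm < n
                and (
                    seq[center - 1 - arm] == _COMPLEMENT[seq[center + g + arm]]
                    if inverted
                    else seq[center - 1 - arm] == seq[center + g + arm]
                )
            ):
                arm += 1
            if arm >= min_arm:
                arms.append((center, g, arm))
    return arms


def _cruciform(seq: str, cfg: NonBConfig) -> list[tuple[int, int]]:
    return [
        (c - arm, c + g + arm)
        for c, g, arm in _mirror_arms(seq, cfg.inverted_min_arm,
                                      cfg.inverted_max_spacer, inverted=True)
    ]


def _triple_helix(seq: str, cfg: NonBConfig) -> list[tuple[int, int]]:
    """Mirror repeats whose span is purine- or pyrimidine-skewed.

    A maximal arm can over-extend through chance matches that dilute the
    skew, so arms are trimmed down to the minimum length until the skew
    condition is met.
    """
    spans = []
    for c, g, max_arm in _mirror_arms(seq, cfg.mirror_min_arm,
                                      cfg.mirror_max_spacer, inverted=False):
        for arm in range(max_arm, cfg.mirror_min_arm - 1, -1):
            sub = seq[c - arm : c + g + arm]
            pur = sum(b in PURINES for b in sub) / len(sub)
            if pur >= cfg.mirror_min_skew or pur <= 1 - cfg.mirror_min_skew:
                spans.append((c - arm, c + g + arm))
                break
    return spans


def _bent_dna(seq: str, cfg: NonBConfig) -> list[tuple[int, int]]:
    """>= 3 A-tracts (A3-6 or T3-6) with starts phased ~10 +/- 1 bp apart."""
    tracts = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] in "AT":
            j = i
            while j < n and seq[j] == seq[i]:
                j += 1
            if cfg.apr_min_tract <= j - i <= cfg.apr_max_tract:
                tracts.append((i, j))
            i = j
        else:
            i += 1
    spans = []
    lo = cfg.apr_phase - cfg.apr_phase_tol
    hi = cfg.apr_phase + cfg.apr_phase_tol
    center = lambda t: (t[0] + t[1]) / 2  # tracts are phased center-to-center
    for a in range(len(tracts)):
        chain = [tracts[a]]
        for b in range(a + 1, len(tracts)):
            gap = center(tracts[b]) - center(chain[-1])
            if lo <= gap <= hi:
                chain.append(tracts[b])
            elif gap > hi:
                break
        if len(chain) >= cfg.apr_min_tracts:
            spans.append((chain[0][0], chain[-1][1]))
    return spans


_Z_STEPS = frozenset({frozenset("GC"), frozenset("CA"), frozenset("TG")})


def _z_dna(seq: str, cfg: NonBConfig) -> list[tuple[int, int]]:
    """Alternating purine-pyrimidine runs made of GC/CA/GT dinucleotide steps."""
    n, spans = len(seq), []
    i = 0
    while i < n - 1:
        j = i
        while j + 1 < n and frozenset((seq[j], seq[j + 1])) in _Z_STEPS:
            j += 1
        if j - i + 1 >= cfg.z_min_run:
            spans.append((i, j + 1))
        i = max(j, i + 1)
    return spans


def _g_quadruplex(seq: str, cfg: NonBConfig) -> list[tuple[int, int]]:
    spans = []
    for base in "GC":  # G-strand motif and its C-strand mirror
        tracts = []
        i, n = 0, len(seq)
        while i < n:
            if seq[i] == base:
                j = i
                while j < n and seq[j] == base:
                    j += 1
                if j - i >= cfg.g4_min_tract:
                    tracts.append((i, j))
                i = j
            else:
                i += 1
        # chain 4 tracts with loops in [min_loop, max_loop]
        for a in range(len(tracts)):
            chain = [tracts[a]]
            k = a
            while len(chain) < cfg.g4_n_tracts:
                nxt = None
                for b in range(k + 1, len(tracts)):
                    loop = tracts[b][0] - chain[-1][1]
                    if cfg.g4_min_loop <= loop <= cfg.g4_max_loop:
                        nxt = b
                        break
                    if loop > cfg.g4_max_loop:
                        break
                if nxt is None:
                    break
                chain.append(tracts[nxt])
                k = nxt
            if len(chain) >= cfg.g4_n_tracts:
                spans.append((chain[0][0], chain[-1][1]))
    return spans


_DETECTORS = {
    "slipped_strand": _direct_repeats,
    "triple_helix": _triple_helix,
    "cruciform": _cruciform,
    "bent_DNA": _bent_dna,
    "Z_DNA": _z_dna,
    "G_quadruplex": _g_quadruplex,
}


def find_structure_spans(
    padded_seq: str, config: NonBConfig | None = None
) -> dict[str, list[tuple[int, int]]]:
    """Merged predicted spans per structure over the full padded sequence."""
    cfg = config or NonBConfig()
    seq = padded_seq.upper()
    out: dict[str, list[tuple[int, int]]] = {s: [] for s in STRUCTURES}
    for offset, seg in _segments(seq):  # N breaks every pattern
        for name, det in _DETECTORS.items():
            out[name].extend((offset + s, offset + e) for s, e in det(seg, cfg))
    return {name: _merge(spans) for name, spans in out.items()}


def predict_structures(
    padded_seq: str,
    allele_interval: tuple[int, int],
    config: NonBConfig | None = None,
) -> dict[str, bool]:
    """Per-structure flag: does any predicted span overlap the allele by >= 1 bp?"""
    a0, a1 = allele_interval
    spans = find_structure_spans(padded_seq, config)
    return {
        name: any(s < a1 and e > a0 for s, e in span_list)
        for name, span_list in spans.items()
    }
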