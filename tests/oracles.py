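"""Independent brute-force oracles used across the test suite.

These deliberately avoid the implementation's code paths (edlib, run
decomposition, rule precedence tables) so each check is dual-route.
"""

from __future__ import annotations

import numpy as np


def global_levenshtein(a: str, b: str) -> list[int]:
    """Last DP row: edit distance of ``a`` against every prefix of ``b``."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev


def brute_purity_distance(allele: str, motif: str) -> int:
    """Min global edit distance to a pure template of any phase and length.

    Every substring of an infinite pure repeat is a prefix of some
    rotation's tiling, so minimizing over rotations and template prefix
    lengths (up to a generous 2*len(allele) + 2 motif copies) equals the
    fitting-alignment distance.
    """
    L = len(allele)
    best = L
    for i in range(len(motif)):
        rot = motif[i:] + motif[:i]
        template = (rot * (2 * L // len(rot) + 3))[: 2 * L + 2 * len(motif)]
        row = global_levenshtein(allele, template)
        best = min(best, min(row[1:]))
    return best


def brute_longest_pure(allele: str, motif: str) -> int:
    """Longest substring with period == |motif| whose unit is a motif rotation."""
    p = len(motif)
    rotations = {motif[i:] + motif[:i] for i in range(p)}
    best = 0
    n = len(allele)
    for i in range(n):
        for j in range(i + p, n + 1):
            sub = allele[i:j]
            if sub[:p] not in rotations:
                continue
            if all(sub[k] == sub[k - p] for k in range(p, len(sub))):
                best = max(best, len(sub))
    return best


def brute_mutational_space(codon: str, translate) -> tuple[int, int, int]:
    """Consequence counts via a caller-supplied independent translator."""
    sil = mis = non = 0
    ref = translate(codon)
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            aa = translate(codon[:pos] + base + codon[pos + 1 :])
            if aa == "*":
                non += 1
            elif aa == ref:
                sil += 1
            else:
                mis += 1
    return sil, mis, non


# chromHMM oracle: an explicit state -> (priority, class) table, resolved by
# taking the class of the highest-priority state present (priority 0 wins).
_STATE_TABLE: dict[int, tuple[int, str]] = {}
for s in (1, 5, 6, 7, 8, 9):
    _STATE_TABLE[s] = (0, "transcribed")
for s in (2, 3, 4):
    _STATE_TABLE[s] = (1, "promoter")
for s in (13, 14, 15):
    _STATE_TABLE[s] = (2, "strong_enhancer")
for s in (10, 11, 12, 16, 17, 18):
    _STATE_TABLE[s] = (3, "weak_enhancer")
for s in (19, 20, 22, 23):
    _STATE_TABLE[s] = (4, "other")
for s in (21, 24, 25):
    _STATE_TABLE[s] = (5, "heterochromatin")


def chromhmm_oracle(states: set[int]) -> str:
    if not states:
        return "heterochromatin"
    return min(_STATE_TABLE[s] for s in states)[1]


def allpairs_intersect(loci, track, min_overlap: int = 1) -> list[set]:
    out = []
    for locus in loci:
        hits = set()
        for iv in track:
            lc = locus.chrom.removeprefix("chr")
            tc = iv.chrom.removeprefix("chr")
            if lc == tc and min(locus.end, iv.end) - max(locus.start, iv.start) >= min_overlap:
                hits.add(iv.payload)
        out.append(hits)
    return out


# --- brute-force non-B pattern oracles -----------------------------------
# Independent re-derivations of the six pattern definitions (naive scans,
# no run decomposition or arm extension logic shared with the package).

_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _spans_overlap(spans, a0, a1):
    return any(s < a1 and e > a0 for s, e in spans)


def oracle_direct(seq, min_arm=10, max_spacer=10):
    # any longer direct repeat contains a min_arm instance, so scanning
    # minimal arms suffices for the existence/overlap question
    n = len(seq)
    spans = []
    for i in range(n):
        for arm in (min_arm,):
            for g in range(max_spacer + 1):
                j = i + arm + g
                if j + arm <= n and seq[i : i + arm] == seq[j : j + arm]:
                    spans.append((i, j + arm))
    return spans


def oracle_mirror(seq, min_arm=10, max_spacer=8, min_skew=0.9):
    n = len(seq)
    spans = []
    for i in range(n):
        for arm in range(min_arm, min_arm + 16):
            for g in range(max_spacer + 1):
                end = i + 2 * arm + g
                if end > n:
                    break
                left, right = seq[i : i + arm], seq[i + arm + g : end]
                if left != right[::-1]:
                    continue
                span = seq[i:end]
                pur = sum(b in "AG" for b in span) / len(span)
                if pur >= min_skew or pur <= 1 - min_skew:
                    spans.append((i, end))
    return spans


def oracle_inverted(seq, min_arm=6, max_spacer=3):
    n = len(seq)
    spans = []
    for i in range(n):
        for arm in (min_arm,):  # minimal arms suffice for existence
            for g in range(max_spacer + 1):
                end = i + 2 * arm + g
                if end > n:
                    break
                left, right = seq[i : i + arm], seq[i + arm + g : end]
                if left == "".join(_RC.get(b, "N") for b in right)[::-1]:
                    spans.append((i, end))
    return spans


def oracle_bent(seq, min_tract=3, max_tract=6, min_tracts=3, phase=10, tol=1):
    import re

    tracts = []
    for m in re.finditer(r"A+|T+", seq):
        if min_tract <= len(m.group()) <= max_tract:
            tracts.append((m.start(), m.end()))
    spans = []
    for combo_start in range(len(tracts)):
        chain = [tracts[combo_start]]
        for t in tracts[combo_start + 1 :]:
            gap = (t[0] + t[1]) / 2 - (chain[-1][0] + chain[-1][1]) / 2
            if phase - tol <= gap <= phase + tol:
                chain.append(t)
            elif gap > phase + tol:
                break
        if len(chain) >= min_tracts:
            spans.append((chain[0][0], chain[-1][1]))
    return spans


def oracle_z(seq, min_run=10):
    steps = {"GC", "CG", "CA", "AC", "GT", "TG"}
    spans = []
    for i in range(len(seq) - min_run + 1):
        sub = seq[i : i + min_run]  # a longer run contains a min_run window
        if all(sub[k : k + 2] in steps for k in range(len(sub) - 1)):
            spans.append((i, i + min_run))
    return spans


def oracle_g4(seq, min_tract=3, min_loop=1, max_loop=7):
    import re

    spans = []
    for base in "GC":
        pat = f"{base}{{{min_tract},}}"
        loop = f"[ACGT]{{{min_loop},{max_loop}}}"
        rx = re.compile(f"(?=({pat}(?:{loop}{pat}){{3}}))")
        for m in rx.finditer(seq):
            spans.append((m.start(), m.start() + len(m.group(1))))
    return spans


NONB_ORACLES = {
    "slipped_strand": oracle_direct,
    "triple_helix": oracle_mirror,
    "cruciform": oracle_inverted,
    "bent_DNA": oracle_bent,
    "Z_DNA": oracle_z,
    "G_quadruplex": oracle_g4,
}


def oracle_nonb_flag(structure: str, padded: str, interval) -> bool:
    """Does the padded sequence contain the pattern overlapping the allele?"""
    a0, a1 = interval
    # restrict the scan window for tractability; a pattern overlapping the
    # allele has a minimal instance starting within ~60 bp of it
    w0, w1 = max(0, a0 - 60), min(len(padded), a1 + 60)
    spans = NONB_ORACLES[structure](padded[w0:w1])
    return _spans_overlap([(s + w0, e + w0) for s, e in spans], a0, a1)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Random sequence preserving the exact dinucleotide composition.

    Altschul-Erickson Eulerian shuffle: pick a "last edge" for every
    non-terminal vertex so the last edges form an in-tree to the terminal
    character, permute the remaining edges, then walk the Eulerian path.
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    terminal = seq[-1]
    vertices = [v for v in edges if v != terminal]
    for _ in range(200):
        last = {v: edges[v][rng.integers(len(edges[v]))] for v in vertices}
        # every vertex must reach the terminal by following last-edges
        ok = True
        for v in vertices:
            seen, cur = set(), v
            while cur != terminal and cur in last and cur not in seen:
                seen.add(cur)
                cur = last[cur]
            if cur != terminal:
                ok = False
                break
        if not ok:
            continue
        order: dict[str, list[str]] = {}
        for v, out in edges.items():
            rest = list(out)
            if v in last:
                rest.remove(last[v])
            perm = rng.permutation(len(rest))
            order[v] = [rest[i] for i in perm] + ([last[v]] if v in last else [])
        walk = [seq[0]]
        cur = seq[0]
        counters = {v: 0 for v in order}
        while counters.get(cur, len(order.get(cur, []))) < len(order.get(cur, [])):
            nxt = order[cur][counters[cur]]
            counters[cur] += 1
            walk.append(nxt)
            cur = nxt
        if len(walk) == len(seq):
            return "".join(walk)
    raise RuntimeError("dinucleotide shuffle failed to find an Eulerian walk")
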