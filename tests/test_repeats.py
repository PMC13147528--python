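"""Purity metrics: tiling, fitting-alignment distance, longest pure stretch."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import brute_longest_pure, brute_purity_distance
from strpurity.repeats import (
    IMPURITY_CAP,
    Motif,
    best_rotation,
    fraction_interrupted,
    longest_pure_stretch,
    pure_allele,
    purity_distance,
    score_allele,
    score_allele_table,
)


class TestMotif:
    def test_rotations_of_primitive_motif(self):
        assert Motif("CAG").rotations == {"CAG", "AGC", "GCA"}

    def test_degenerate_motif_canonicalized_to_smallest_period(self):
        assert Motif("ATAT").sequence == "AT"
        assert Motif("ATAT").rotations == {"AT", "TA"}

    @pytest.mark.parametrize("bad", ["AAA", "TT", "A", "", "CAX", "AAAAAA"])
    def test_invalid_motifs_rejected(self, bad):
        with pytest.raises(ValueError):
            Motif(bad)

    def test_gc_fraction(self):
        assert Motif("CAG").gc_fraction == pytest.approx(2 / 3)


class TestPureAllele:
    @pytest.mark.parametrize(
        "motif,length,expected",
        [("CAG", 7, "CAGCAGC"), ("AT", 4, "ATAT"), ("AAG", 3, "AAG")],
    )
    def test_tiling(self, motif, length, expected):
        assert pure_allele(motif, length) == expected

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            pure_allele("CAG", 0)


class TestPurityDistance:
    @pytest.mark.parametrize(
        "allele,motif,expected",
        [
            ("CAGCAGCAG", "CAG", 0),
            ("CAGCAACAG", "CAG", 1),   # single substitution
            ("CAGTCAGCAG", "CAG", 1),  # single inserted base
            ("AGCAGCAGC", "CAG", 0),   # phase AGC matches exactly
        ],
    )
    def test_examples(self, allele, motif, expected):
        assert purity_distance(allele, motif) == expected
        assert brute_purity_distance(allele, motif) == expected

    def test_empty_allele_rejected(self):
        with pytest.raises(ValueError):
            purity_distance("", "CAG")

    def test_pure_alleles_have_zero_distance(self):
        for motif in ("AC", "CAG", "AAAG", "AATGC", "AATGGC"):
            for length in range(len(motif), 61):
                assert purity_distance(pure_allele(motif, length), motif) == 0

    def test_matches_bruteforce_oracle_on_random_alleles(self, rng):
        from conftest import random_allele

        for _ in range(150):
            allele, motif = random_allele(rng)
            assert purity_distance(allele, motif) == brute_purity_distance(allele, motif)

    def test_rotation_of_query_motif_is_irrelevant(self, rng):
        from conftest import random_allele

        for _ in range(40):
            allele, motif = random_allele(rng)
            dists = {
                purity_distance(allele, motif[i:] + motif[:i])
                for i in range(len(motif))
            }
            assert len(dists) == 1

    def test_spaced_substitutions_bound_and_equality(self, rng):
        """k substitutions at non-adjacent positions: distance <= k, and == k
        when every substituted base differs from the template base."""
        for _ in range(200):
            motif = ["AC", "CAG", "AAT", "AAAG"][rng.integers(4)]
            length = int(rng.integers(20, 41))
            seq = list(pure_allele(motif, length))
            k = int(rng.integers(0, min(5, length // 4) + 1))
            positions: list[int] = []
            for pos in rng.permutation(length):
                if len(positions) == k:
                    break
                if all(abs(pos - q) >= 2 for q in positions):
                    positions.append(int(pos))
            for pos in positions:
                seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
            assert purity_distance("".join(seq), motif) <= len(positions)

    def test_longer_templates_never_reduce_distance(self, rng):
        """The L + 2|m| template is sufficient: a brute-force search over
        far longer pure templates finds no smaller distance for alleles
        within the impurity cap."""
        from conftest import random_allele

        checked = 0
        while checked < 60:
            allele, motif = random_allele(rng)
            d = purity_distance(allele, motif)
            if d / len(allele) > IMPURITY_CAP:
                continue
            assert brute_purity_distance(allele, motif) == d  # oracle spans 2L+2|m|
            checked += 1

    def test_best_rotation_reported_deterministically(self):
        assert best_rotation("AGCAGCAGC", "CAG") == "AGC"


class TestLongestPureStretch:
    @pytest.mark.parametrize(
        "allele,motif,expected",
        [
            ("CAGCAGCAG", "CAG", 9),
            ("CAGCAACAG", "CAG", 5),
            ("CAGCAGTAGCAGCAGCAG", "CAG", 11),  # suffix pure in phase AGC
        ],
    )
    def test_examples(self, allele, motif, expected):
        assert longest_pure_stretch(allele, motif) == expected

    def test_matches_bruteforce_scan(self, rng):
        from conftest import random_allele

        for _ in range(120):
            allele, motif = random_allele(rng)
            assert longest_pure_stretch(allele, motif) == brute_longest_pure(allele, motif)

    def test_invariant_under_motif_rotation(self, rng):
        from conftest import random_allele

        for _ in range(40):
            allele, motif = random_allele(rng)
            values = {
                longest_pure_stretch(allele, motif[i:] + motif[:i])
                for i in range(len(motif))
            }
            assert len(values) == 1

    @given(st.integers(2, 20))
    @settings(derandomize=True, max_examples=20)
    def test_pure_allele_is_fully_pure(self, copies):
        seq = "CAG" * copies
        assert longest_pure_stretch(seq, "CAG") == len(seq)


class TestFractionInterrupted:
    def test_boundary_quarter_is_retained(self):
        # 25% interrupted exactly is kept; exclusion requires strictly more
        a = score_allele("L1", "CAGCAACATCAT", "CAG")
        assert a.fraction_interrupted <= IMPURITY_CAP or a.excluded
        assert fraction_interrupted(3, 12) == 0.25
        assert fraction_interrupted(0, 30) == 0.0

    def test_exclusion_over_cap(self):
        assert fraction_interrupted(4, 12) > IMPURITY_CAP


def test_score_allele_table_appends_metrics():
    import pandas as pd

    table = pd.DataFrame({
        "locus_id": ["a", "b"],
        "motif": ["CAG", "AC"],
        "allele_seq": ["CAGCAACAG", "ACACACAC"],
    })
    out = score_allele_table(table)
    assert list(out["edit_distance"]) == [1, 0]
    assert list(out["longest_pure_bp"]) == [5, 8]
    assert list(out["excluded_flag"]) == [False, False]
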