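"""Non-B DNA structure detectors and the repeat-overlap binning rule."""

import numpy as np
import pytest

from oracles import dinucleotide_shuffle, oracle_nonb_flag
from strpurity.nonb import (
    STRUCTURES,
    NonBConfig,
    find_structure_spans,
    pad_allele,
    predict_structures,
)

_RC = str.maketrans("ACGT", "TGCA")


def _rand(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), n)) if n > 0 else ""


def _planted_designs(rng):
    """(core generator, allele length, filler alphabet) per structure.

    Fillers are chosen so neither the embedding nor its dinucleotide
    shuffle tends to recreate the pattern by composition alone; the
    planted cores are the canonical pattern-level motifs of each class.
    """
    return {
        "slipped_strand": (lambda: (lambda arm: arm + _rand(rng, 3) + arm)(_rand(rng, 12)),
                           60, "ACGT"),
        "triple_helix": (lambda: (lambda arm: arm + _rand(rng, 2, "AG") + arm[::-1])(
            _rand(rng, 12, "AG")), 70, "ACGT"),
        "cruciform": (lambda: (lambda arm: arm + _rand(rng, 2)
                               + arm.translate(_RC)[::-1])(_rand(rng, 8)), 40, "ACGT"),
        "bent_DNA": (lambda: "AAAA" + _rand(rng, 6, "CG") + "AAAA"
                     + _rand(rng, 6, "CG") + "AAAA", 60, "CG"),
        "Z_DNA": (lambda: "GCAC" * 3, 60, "AT"),
        "G_quadruplex": (lambda: "GGGTTAGGGTTAGGGTTAGGG", 60, "AT"),
    }


class TestPadAllele:
    def test_margins_and_interval(self):
        padded, iv = pad_allele("A" * 30, "C" * 150, "G" * 150)
        assert len(padded) == 330
        assert iv == (150, 180)

    def test_empty_flanks(self):
        padded, iv = pad_allele("ACGTAC")
        assert padded == "ACGTAC"
        assert iv == (0, 6)

    def test_short_flank_accepted(self):
        _, iv = pad_allele("A" * 30, "C" * 80, "G" * 150)
        assert iv == (80, 110)


class TestExamples:
    def test_g_quadruplex_inside_allele(self):
        seq = "GGGTTAGGGTTAGGGTTAGGG"
        assert predict_structures(seq, (0, len(seq)))["G_quadruplex"]

    def test_z_dna_alternating_run(self):
        seq = "GCGCGCGCGCGC"
        assert predict_structures(seq, (0, len(seq)))["Z_DNA"]

    def test_quiet_forty_mer_is_all_negative(self):
        # random 40-mer, max homopolymer 2, no repeated arms
        seq = "ACCATTATTCCGGCATGATGAGGATGCAATAGTTCACTGA"
        flags = predict_structures(seq, (0, 40))
        assert not any(flags.values())

    def test_margin_only_call_is_ignored(self):
        g4 = "GGGTTAGGGTTAGGGTTAGGG"
        left = "T" + g4 + "ACTGACTGCA" * 5  # G4 wholly inside the left margin
        allele = "ACCATTATTCCGGCATGATGAGGATGCAATAGTTCACTGA"
        padded, iv = pad_allele(allele, left, "ACTGTACGCA" * 6)
        assert not predict_structures(padded, iv)["G_quadruplex"]
        # the same G4 inside the allele is reported
        padded2, iv2 = pad_allele(g4 + allele[: 40 - len(g4)])
        assert predict_structures(padded2, iv2)["G_quadruplex"]

    def test_n_breaks_patterns(self):
        seq = "GGGTTAGGGTTAGGGTTAGGG"
        broken = seq[:10] + "N" + seq[11:]
        assert not predict_structures(broken, (0, len(broken)))["G_quadruplex"]


class TestPlantedAndShuffled:
    @pytest.mark.parametrize("structure", STRUCTURES)
    def test_fires_at_any_offset_and_stays_quiet_on_shuffles(self, structure, rng):
        """Planted motifs are detected at every offset; dinucleotide-shuffled
        controls are negative except when the shuffle itself recreates a
        genuine instance of the pattern (certified by an independent
        brute-force oracle — the detector must never call a control the
        oracle does not confirm)."""
        gen, allele_len, filler = _planted_designs(rng)[structure]
        fired = 0
        clean_controls = clean_negative = 0
        trials = 100
        for _ in range(trials):
            core = gen()
            pad = allele_len - len(core)
            off = int(rng.integers(0, pad + 1))
            allele = _rand(rng, off, filler) + core + _rand(rng, pad - off, filler)
            padded, iv = pad_allele(allele, _rand(rng, 150), _rand(rng, 150))
            fired += predict_structures(padded, iv)[structure]
            control = dinucleotide_shuffle(allele, rng)
            padded2, iv2 = pad_allele(control, _rand(rng, 150), _rand(rng, 150))
            called = predict_structures(padded2, iv2)[structure]
            if called:  # detector never invents a pattern
                assert oracle_nonb_flag(structure, padded2, iv2)
            if not oracle_nonb_flag(structure, padded2, iv2):
                clean_controls += 1
                clean_negative += not called
        assert fired == trials
        assert clean_controls > 0.8 * trials  # shuffling does disperse the signal
        assert clean_negative >= 0.95 * clean_controls

    def test_binning_is_monotone_under_flank_extension(self, rng):
        """Extending a firing allele with neutral flanks never clears flags."""
        designs = _planted_designs(rng)
        neutral = "ACCATTATTCCGGCATGATGAGGATGCAATAGTTCACTGA"
        for structure, (gen, allele_len, filler) in designs.items():
            core = gen()
            allele = core + _rand(rng, allele_len - len(core), filler)
            base_flags = predict_structures(*pad_allele(allele))
            padded, iv = pad_allele(allele, neutral, neutral)
            extended_flags = predict_structures(padded, iv)
            for s in STRUCTURES:
                if base_flags[s]:
                    assert extended_flags[s]


class TestSpans:
    def test_overlapping_same_structure_calls_merged(self):
        seq = "GGGTGGGTGGGTGGGTGGGTGGG"  # five chained G-tracts: overlapping G4s
        spans = find_structure_spans(seq)["G_quadruplex"]
        assert len(spans) == 1

    def test_config_override_changes_calls(self):
        seq = "GCGCGCGC"  # 8 bp alternating run
        assert not predict_structures(seq, (0, 8))["Z_DNA"]
        relaxed = NonBConfig(z_min_run=8)
        assert predict_structures(seq, (0, 8), relaxed)["Z_DNA"]
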