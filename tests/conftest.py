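import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from strpurity.simulate import SimParams, write_bundle


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory) -> Path:
    """A small synthetic fixture bundle shared across pipeline tests."""
    out = tmp_path_factory.mktemp("bundle")
    write_bundle(out, SimParams(n_loci=200, n_samples=50, seed=11,
                                planted_effects={"enhancer": -0.3}))
    return out


def random_allele(rng: np.random.Generator, max_len: int = 24) -> tuple[str, str]:
    """(allele, motif) pair mixing fully random and mutated-pure alleles."""
    from strpurity.repeats import Motif, pure_allele

    motifs = ["AC", "AT", "AG", "CAG", "AAT", "AAAG", "AATGC", "AATGGC"]
    motif = motifs[rng.integers(len(motifs))]
    length = int(rng.integers(len(motif), max_len + 1))
    if rng.random() < 0.5:
        return "".join(rng.choice(list("ACGT"), length)), motif
    seq = list(pure_allele(Motif(motif), length))
    for _ in range(int(rng.integers(0, 4))):
        pos = int(rng.integers(length))
        seq[pos] = rng.choice(list("ACGT"))
    return "".join(seq), motif
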