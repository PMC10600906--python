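import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from m6apred.fixtures import FixtureConfig, generate_benchmark
from m6apred.seqio import SequenceRecord


@pytest.fixture
def random_records():
    """Factory for equal-length random canonical records."""

    def make(n=10, length=41, seed=0, label=None, alphabet="DNA"):
        rng = np.random.default_rng(seed)
        bases = "ACGU" if alphabet == "RNA" else "ACGT"
        out = []
        for i in range(n):
            seq = "".join(bases[j] for j in rng.integers(0, 4, size=length))
            lab = label if label is not None else int(i % 2)
            out.append(
                SequenceRecord(
                    id=f"r{i}", sequence=seq, label=lab, alphabet=alphabet
                )
            )
        return out

    return make


@pytest.fixture
def small_benchmark():
    """A small, clearly separable synthetic dataset (shared across tests)."""
    return generate_benchmark(
        FixtureConfig(n_pos=40, n_neg=40, length=41, signal=0.9, seed=11)
    )


@pytest.fixture
def fasta_pair(tmp_path, small_benchmark):
    """The small benchmark written as a (positive, negative) FASTA pair."""
    from m6apred.seqio import write_fasta

    pos = tmp_path / "pos.fasta"
    neg = tmp_path / "neg.fasta"
    write_fasta([r for r in small_benchmark if r.label == 1], pos)
    write_fasta([r for r in small_benchmark if r.label == 0], neg)
    return pos, neg
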