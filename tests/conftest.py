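import numpy as np
import pandas as pd
import pytest

from binref import build_feature_matrix
from binref.synthetic import CommunitySpec, simulate_community


@pytest.fixture(scope="session")
def small_community():
    """Three planted genomes, 10 contigs each, 7 samples — shared fixture."""
    spec = CommunitySpec(
        n_genomes=3,
        contigs_per_genome=10,
        n_samples=7,
        length_range=(1000, 2000),
        random_seed=11,
    )
    return simulate_community(spec)


@pytest.fixture(scope="session")
def small_features(small_community):
    return build_feature_matrix(
        small_community.contigs,
        small_community.coverage,
        include=("abundance", "gc"),
    )


@pytest.fixture
def write_fasta(tmp_path):
    def _write(text, name="contigs.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture
def write_csv(tmp_path):
    def _write(text, name="table.csv"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture
def random_sequences():
    def _make(n, rng=None, min_len=50, max_len=400, with_ambiguity=False):
        rng = rng or np.random.default_rng(0)
        alphabet = list("ACGT") + (["N"] if with_ambiguity else [])
        seqs = []
        for _ in range(n):
            length = int(rng.integers(min_len, max_len + 1))
            seqs.append("".join(rng.choice(alphabet, size=length)))
        return seqs

    return _make
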