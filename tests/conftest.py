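import random
from pathlib import Path

import numpy as np
import pytest

from karyon import features, synthetic
from karyon.types import ContigAnnotation, GeneRecord


@pytest.fixture
def worked_example() -> ContigAnnotation:
    """The fully hand-derived example: 10 kb contig, three genes."""
    return ContigAnnotation(
        contig_id="c1",
        length=10000,
        genes=[
            GeneRecord("c1", 1, 1000, "+", has_rbs=True),
            GeneRecord("c1", 2001, 3000, "+", has_rbs=False),
            GeneRecord("c1", 5001, 6000, "-", has_rbs=False),
        ],
    )


@pytest.fixture(scope="session")
def default_dataset() -> synthetic.SyntheticDataset:
    """The shipped default study conditions: 10 organisms/class x 20 contigs."""
    return synthetic.generate_dataset(seed=11)


@pytest.fixture(scope="session")
def default_features(default_dataset):
    frame, excluded = features.build_feature_matrix(default_dataset.contigs)
    assert not excluded
    return frame


@pytest.fixture
def rnd() -> random.Random:
    return random.Random(1234)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def write_fasta(path: Path, lengths: dict[str, int], seed: int = 0) -> None:
    """Random-sequence FASTA with the given record lengths."""
    gen = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    with path.open("w") as fh:
        for cid, n in lengths.items():
            fh.write(f">{cid}\n")
            seq = "".join(bases[gen.integers(0, 4, size=n)])
            for i in range(0, n, 70):
                fh.write(seq[i : i + 70] + "\n")
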