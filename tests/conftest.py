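"""Shared fixtures: small synthetic genomes and models, generated at test
time (no stored data files)."""

from __future__ import annotations

import numpy as np
import pytest

from spliceworks.model import SpliceModel, build_config
from spliceworks.synthetic import SyntheticSpec, generate_genome


@pytest.fixture(scope="session")
def tiny_genome(tmp_path_factory):
    """A 2-chromosome toy genome with 6 genes, written to disk."""
    out = tmp_path_factory.mktemp("tiny_genome")
    spec = SyntheticSpec(
        n_chromosomes=2,
        chromosome_length=60_000,
        genes_per_chromosome=3,
        noncanonical_fraction=0.15,
        seed=3,
    )
    chroms, truth = generate_genome(spec, output_dir=out)
    return {
        "dir": out,
        "fasta": out / "genome.fa",
        "gff": out / "annotation.gff3",
        "chroms": chroms,
        "truth": truth,
        "spec": spec,
    }


@pytest.fixture(scope="session")
def small_model():
    """An untrained flank-80 model with few channels (fast forward)."""
    return SpliceModel(build_config(80, channels=8), seed=2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
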