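import numpy as np
import pytest

import mitescan as ms


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_fasta(tmp_path):
    path = tmp_path / "toy.fasta"
    path.write_text(">chr1 test chromosome\nacgt\nACGT\n>chr2\nGGGGCCCCAA\n")
    return path


@pytest.fixture
def implanted_genome():
    """A 60 kb genome with four perfect implants of known coordinates."""
    genome = ms.random_genome(60000, seed=77)
    specs = [
        ms.ImplantSpec(tir_length=12, total_length=300, tsd="TA"),
        ms.ImplantSpec(tir_length=11, total_length=150, tsd="TAA"),
        ms.ImplantSpec(tir_length=14, total_length=420, tsd="GATCCA"),
        ms.ImplantSpec(tir_length=10, total_length=80, tsd="GAT"),
    ]
    mutated, truth = ms.implant(genome, specs, seed=78)
    return mutated, truth
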