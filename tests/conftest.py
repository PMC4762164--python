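import numpy as np
import pandas as pd
import pytest
from pyfaidx import Fasta

from sigrefit.contexts import CONTEXT_ORDER
from sigrefit.signatures import SignatureSet
from sigrefit.simulate import random_genome, synthetic_signature_set


@pytest.fixture(scope="session")
def genome_dict() -> dict[str, str]:
    """Two random chromosomes, long enough that every trinucleotide occurs."""
    return random_genome({"chr1": 4000, "chr2": 3000}, seed=11)


@pytest.fixture(scope="session")
def genome_fasta(tmp_path_factory, genome_dict) -> Fasta:
    path = tmp_path_factory.mktemp("genome") / "synthetic_genome.fa"
    with open(path, "w") as fh:
        for name, seq in genome_dict.items():
            fh.write(f">{name}\n{seq}\n")
    return Fasta(str(path))


@pytest.fixture(scope="session")
def sig_set() -> SignatureSet:
    """Small realistic synthetic reference set."""
    return synthetic_signature_set(k=8, seed=5)


@pytest.fixture(scope="session")
def disjoint_sigs() -> SignatureSet:
    """Two signatures with disjoint support (first vs last 48 contexts)."""
    a = np.zeros(96)
    a[:48] = 1 / 48
    b = np.zeros(96)
    b[48:] = 1 / 48
    return SignatureSet(
        pd.DataFrame([a, b], index=["SigA", "SigB"], columns=list(CONTEXT_ORDER))
    )
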