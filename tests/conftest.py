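import numpy as np
import pytest

from seqrex import ExactKmerIndex, write_fasta

# The four-bin nucleotide worked example: R occurs in bins 2 and 3 (ACCCA,
# AGGCTA) and bin 4 shares all 3-mers of the word AGCCA.
EXAMPLE1_BINS = ["ACCTTA", "ACCCAAGCC", "ACCAGGCTA", "AAGCCA"]
EXAMPLE1_REGEX = "A(A|C|G)(C|G)C(T)*A"


@pytest.fixture
def example1_index():
    return ExactKmerIndex.from_sequences(EXAMPLE1_BINS, 3)


@pytest.fixture
def example1_paths(tmp_path):
    paths = []
    for j, seq in enumerate(EXAMPLE1_BINS):
        p = tmp_path / f"UB{j + 1}.fa"
        write_fasta(p, [(f"UB{j + 1}", seq)])
        paths.append(p)
    return paths


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
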