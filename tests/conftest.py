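import numpy as np
import pytest

from saaspred.records import Msa
from saaspred.synthetic import (
    aaindex_fixture_text,
    make_annotated_library,
    make_labeled_table,
    make_protein_family,
)


@pytest.fixture(scope="session")
def aaindex_file(tmp_path_factory):
    path = tmp_path_factory.mktemp("aaindex") / "aaindex_synthetic.txt"
    path.write_text(aaindex_fixture_text(seed=0))
    return path


@pytest.fixture(scope="session")
def aaindex_entries(aaindex_file):
    from saaspred.io import read_aaindex

    return read_aaindex(aaindex_file)


@pytest.fixture
def tiny_msa():
    """Three rows, one isolated substitution F5G on the first hit."""
    return Msa(ids=["q", "h1", "h2"], rows=["ACDEF", "ACDEG", "ACDEF"])


@pytest.fixture(scope="session")
def planted_table():
    """n=2000, 3 informative of 20 features, |coef| = 2."""
    return make_labeled_table(n=2000, n_features=20,
                              informative_idx=(0, 1, 2), seed=42)


@pytest.fixture(scope="session")
def annotated_library():
    return make_annotated_library(n_proteins=4, length=80, seed=5)


@pytest.fixture(scope="session")
def family():
    return make_protein_family(length=40, n_seqs=12, conserved_cols=(5, 6),
                               coupled_col_pairs=((10, 13),),
                               substitution_rate=0.08, seed=9)
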