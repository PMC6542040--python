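import numpy as np
import pandas as pd
import pytest

from peptidome import simulate
from peptidome.simulate import bundled_substrate_fasta


@pytest.fixture(scope="session")
def substrate_fasta():
    return bundled_substrate_fasta()


@pytest.fixture(scope="session")
def design6():
    return simulate.generate_design(n_per_group=6, doses=(0, 10, 40), seed=0)


@pytest.fixture(scope="session")
def small_truth(substrate_fasta, design6):
    return simulate.generate_feature_truth(
        substrate_fasta, design6, n_features=400, seed=11
    )


@pytest.fixture(scope="session")
def small_events(small_truth, design6):
    return simulate.emit_ion_events(small_truth, design6, lod=4096.0, seed=12)


@pytest.fixture
def tiny_fasta(tmp_path):
    """Five short proteins for brute-force candidate-oracle comparisons."""
    path = tmp_path / "tiny.fasta"
    records = [
        ("P00001|ProtA|MEROPS toy protein A", "MKVLAGTSERFNDQWPHYLC"),
        ("P00002|ProtB|SignalP toy protein B", "GASPVTLNDEQKRHFYWMCI"),
        ("P00003|ProtC|MEROPS toy protein C", "LPFKNLAGAGSTVR"),
        ("P00004|ProtD|MEROPS+SignalP toy protein D", "QWERTYPASDFGHKLCVNM"),
        ("P00005|ProtE|SignalP toy protein E", "AAAAGGGGSSSSPPPPVVVV"),
    ]
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n{seq}\n")
    return path
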