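import numpy as np
import pandas as pd
import pytest

from crypticseq.models import ExonBin, GeneModel, make_sample_table


@pytest.fixture
def two_bin_gene() -> GeneModel:
    return GeneModel(
        "g1",
        (
            ExonBin("g1", 1, "chr1", 100, 200, "+"),
            ExonBin("g1", 2, "chr1", 300, 400, "+"),
        ),
    )


@pytest.fixture
def small_samples() -> pd.DataFrame:
    return make_sample_table(
        ["c1", "c2", "c3", "t1", "t2", "t3"],
        ["control"] * 3 + ["treatment"] * 3,
    )


def make_results_frame(sig_up, expressed=None, gene_id="g1", p_sig=0.001, p_null=0.9):
    """Exon-results table for one gene from a significance pattern.

    ``sig_up`` is a boolean sequence over bins 1..E; ``expressed`` likewise
    (default all True).
    """
    E = len(sig_up)
    if expressed is None:
        expressed = [True] * E
    return pd.DataFrame(
        {
            "gene_id": gene_id,
            "bin_index": np.arange(1, E + 1),
            "log2fc": [1.0 if s else 0.1 for s in sig_up],
            "p": [p_sig if s else p_null for s in sig_up],
            "direction": ["up"] * E,
            "expressed": list(expressed),
            "source": "native",
        }
    )
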