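import numpy as np
import pandas as pd
import pytest

from pimnet import (
    EvidenceChannel,
    ExpressionMatrix,
    ReferenceSets,
    SimConfig,
    make_pair,
)


@pytest.fixture
def tiny_refs():
    """|PRS| = 4, |NRS| = 8 on a 7-protein universe."""
    prs = frozenset(
        {make_pair("A", "B"), make_pair("A", "C"), make_pair("B", "C"), make_pair("C", "D")}
    )
    nrs = frozenset(
        {
            make_pair("A", "E"), make_pair("A", "F"), make_pair("B", "E"),
            make_pair("B", "F"), make_pair("C", "E"), make_pair("C", "F"),
            make_pair("D", "E"), make_pair("D", "F"),
        }
    )
    return ReferenceSets(prs, nrs, "Ran")


def binary_channel(name, pairs):
    return EvidenceChannel(name=name, values={p: 1 for p in pairs}, kind="binary")


@pytest.fixture
def small_matrix():
    """4 features x 4 samples with one clean up and one clean down feature."""
    values = pd.DataFrame(
        {
            "T1": [4.0, 1.0, 2.0, 2.0],
            "T2": [5.0, 2.0, 2.0, 2.1],
            "N1": [1.0, 4.0, 2.0, 1.9],
            "N2": [2.0, 5.0, 2.0, 2.0],
        },
        index=["up1", "down1", "flat", "noisy"],
    )
    labels = pd.Series(
        ["treated", "treated", "normal", "normal"],
        index=["T1", "T2", "N1", "N2"],
        name="class",
    )
    return ExpressionMatrix(values=values, class_labels=labels)


@pytest.fixture
def default_config():
    return SimConfig(seed=0)


def rng(seed=0):
    return np.random.default_rng(seed)
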