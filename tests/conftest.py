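import dataclasses

import numpy as np
import pandas as pd
import pytest

from glims.core_io import GeneNetwork, LabelSet, OmicsMatrix, PSIMatrix
from glims.synthetic import PRESETS, SyntheticConfig, generate_dataset


@pytest.fixture
def path3():
    """3-node path a-b-c."""
    return GeneNetwork(["a", "b", "c"], [("a", "b"), ("b", "c")])


@pytest.fixture
def small_psi():
    """Tiny paired tumor/normal PSI tables exercising every filter rule.

    Event tumor/normal means: e1 0.05/0.5 (tumor mean too low), e2 0.4/0.1
    (kept), e3 0.4/0.4 (no fold change), e4 0.6/0.1 (kept), e5 0.3/absent
    from normal.
    """
    samples = [f"T{i}" for i in range(4)]
    tumor_rows = {
        "GA;SE;chr1:1-2": [0.05] * 4,
        "GB;SE;chr1:3-4": [0.4] * 4,
        "GC;A5;chr1:5-6": [0.4] * 4,
        "GD;RI;chr1:7-8": [0.6] * 4,
        "GE;MX;chr1:9-10": [0.3] * 4,
    }
    normal_rows = {
        "GA;SE;chr1:1-2": [0.5] * 3,
        "GB;SE;chr1:3-4": [0.1] * 3,
        "GC;A5;chr1:5-6": [0.4] * 3,
        "GD;RI;chr1:7-8": [0.1] * 3,
    }

    def build(rows, cols, cond):
        df = pd.DataFrame(rows, index=cols).T
        host = pd.Series([e.split(";")[0] for e in df.index], index=df.index)
        cls = pd.Series([e.split(";")[1] for e in df.index], index=df.index)
        return PSIMatrix(df, host, cls, condition=cond)

    return (build(tumor_rows, samples, "tumor"),
            build(normal_rows, [f"N{i}" for i in range(3)], "normal"))


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small planted dataset shared by training-oriented tests."""
    cfg = dataclasses.replace(
        PRESETS["easy"], n_genes=150, n_samples_tumor=40, n_samples_normal=30,
        n_communities=5, n_events=60, seed=321)
    return generate_dataset(cfg)


def random_scores_and_labels(rng, n_pos=8, n_neg=12):
    genes = [f"g{i:02d}" for i in range(n_pos + n_neg)]
    scores = pd.Series(rng.random(len(genes)), index=genes)
    labels = LabelSet(frozenset(genes[:n_pos]), frozenset(genes[n_pos:]))
    return scores, labels
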