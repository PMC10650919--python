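"""Shared fixtures: a small clean cohort turned into normalized window splits."""

import numpy as np
import pytest

from doapred import preprocess as pp
from doapred import synthcase as sc
from doapred import tdc


@pytest.fixture(scope="session")
def small_cohort():
    cases, metas = sc.generate_cohort(10, rng_seed=101)
    return cases, metas


@pytest.fixture(scope="session")
def window_splits(small_cohort):
    """(train, val, normalizer, segmentation) from an 8/2 split, K=3."""
    cases, _ = small_cohort
    cleans_tr = [pp.clean_case(c, "train") for c in cases[:8]]
    cleans_va = [pp.clean_case(c, "validation") for c in cases[8:]]
    train_ws = pp.WindowSet.concatenate([pp.make_windows(c) for c in cleans_tr])
    val_ws = pp.WindowSet.concatenate([pp.make_windows(c) for c in cleans_va])
    norm = pp.Normalizer.fit(train_ws)
    seg = tdc.segment_windows(train_ws, K=3)
    return norm.transform(train_ws), norm.transform(val_ws), norm, seg
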