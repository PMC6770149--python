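"""Shared fixtures: small hand-built record sets and session-scope
synthetic datasets reused across test modules (generation is deterministic,
so sharing them is safe and keeps the suite fast)."""

import numpy as np
import pytest

from epitope_ptqsar.pt_features import AssayRecord
from epitope_ptqsar.synthetic_data import (
    generate_dataset,
    nonlinear_spec,
)


def make_record(
    query="ACDE",
    ref="ACDF",
    e_ref=1,
    e_q=0,
    org="orgA",
    host="hostA",
    proc="procA",
    tech="techA",
    adju="adjuA",
):
    return AssayRecord(
        query_seq=query,
        ref_seq=ref,
        ref_activity=e_ref,
        query_activity=e_q,
        conditions={"org": org, "host": host, "proc": proc, "tech": tech, "adju": adju},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def nonlinear_20k():
    """Interaction-driven synthetic dataset at the benchmark scale."""
    return generate_dataset(nonlinear_spec(20000, seed=42))


@pytest.fixture(scope="session")
def synth_10k():
    """Mid-size synthetic dataset for feature-algebra and ratio checks."""
    return generate_dataset(nonlinear_spec(10000, seed=7))
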