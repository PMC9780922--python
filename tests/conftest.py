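import numpy as np
import pandas as pd
import pytest

from oralresponder import load_table1_fixture


def make_counts(rows):
    """Build a long-format count table from (participant, phase, rep, group, cfu, limit) tuples."""
    return pd.DataFrame(
        rows,
        columns=["participant_id", "phase", "replicate", "group",
                 "cfu_per_ml", "detection_limit"],
    )


def make_delta(values, participants=None, phases=None, groups=None):
    """Wide change matrix from an (I, P, B) array."""
    arr = np.asarray(values, dtype=float)
    I, P, B = arr.shape
    participants = participants or [f"P{i+1}" for i in range(I)]
    phases = phases or [f"ph{p+1}" for p in range(P)]
    groups = groups or [f"B{b+1}" for b in range(B)]
    idx = pd.MultiIndex.from_product([participants, phases],
                                     names=["participant_id", "phase"])
    return pd.DataFrame(arr.reshape(I * P, B), index=idx, columns=groups)


@pytest.fixture(scope="session")
def table1():
    """Published τ table, phases × participants."""
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table1_tau(table1):
    """Published τ table in the participant × phase layout the stats use."""
    return table1.T


@pytest.fixture
def simple_counts():
    """Two participants, two phases, two groups, two replicates, no censoring."""
    rows = []
    for pid, base in (("A", 4.0), ("B", 5.0)):
        for phase, shift in (("I", 0.0), ("II", 0.5)):
            for rep in (1, 2):
                for g, extra in (("g1", 0.0), ("g2", 1.0)):
                    rows.append((pid, phase, rep, g,
                                 10 ** (base + shift + extra), 100.0))
    return make_counts(rows)
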