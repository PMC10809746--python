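import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import anchorclust as ac

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

BASES = "ACGT"


def random_junctions(rng: np.random.Generator, n: int, length: int) -> list[str]:
    mat = rng.integers(0, 4, size=(n, length))
    return ["".join(BASES[b] for b in row) for row in mat]


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_table():
    """30 clones of up to 8 members over two junction lengths."""
    params = ac.SimulationParams(
        n_clones=30, clone_size=8, junction_lengths=(21, 24)
    )
    return ac.simulate_repertoire(params, np.random.default_rng(11))


def make_table(rows):
    """Build a SequenceTable from (id, junction, v, j, label, clone) tuples;
    missing trailing fields default to empty/None."""
    full = []
    for row in rows:
        row = tuple(row) + ("", "", None, None)[len(row) - 2 :]
        full.append(row[:6])
    frame = pd.DataFrame(
        full,
        columns=["sequence_id", "junction", "v", "j", "label", "true_clone_id"],
    )
    frame["v_calls"] = [
        frozenset(x for x in str(v).split(",") if x) for v in frame.pop("v")
    ]
    frame["j_calls"] = [
        frozenset(x for x in str(j).split(",") if x) for j in frame.pop("j")
    ]
    return ac.table_from_frame(
        frame[
            ["sequence_id", "junction", "v_calls", "j_calls", "label", "true_clone_id"]
        ],
        dedup="vj_context",
    )
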