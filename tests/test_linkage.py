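import numpy as np
import pytest

import anchorclust as ac
from anchorclust import (
    ClusterConfig,
    PackingParams,
    PartitionConfig,
    encode_sequences,
    single_linkage_clusters,
)
from anchorclust.linkage import _blocked_components

from conftest import random_junctions

FAST = ClusterConfig(
    partition=PartitionConfig(
        size_threshold=1000,
        packing=PackingParams(population_size=10, generations=10),
    )
)


def as_partition(labels):
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(i)
    return frozenset(frozenset(g) for g in groups.values())


def test_single_linkage_worked_example():
    labels = single_linkage_clusters(["AAAA", "AAAT", "TTTT"], 0.30)
    assert as_partition(labels) == {frozenset({0, 1}), frozenset({2})}


def test_cutoff_zero_groups_identical_sequences():
    labels = single_linkage_clusters(["AAAA", "TTTT", "AAAA"], 0.0)
    assert as_partition(labels) == {frozenset({0, 2}), frozenset({1})}


def test_cutoff_one_single_cluster(rng):
    labels = single_linkage_clusters(random_junctions(rng, 10, 8), 1.0)
    assert len(set(labels)) == 1


def test_cutoff_is_inclusive():
    # distance exactly 0.25 merges at cutoff 0.25
    labels = single_linkage_clusters(["AAAA", "AAAT"], 0.25)
    assert labels[0] == labels[1]


def test_cutoff_monotonicity(rng):
    seqs = random_junctions(rng, 60, 12)
    counts = [
        len(set(single_linkage_clusters(seqs, c)))
        for c in np.linspace(0, 1, 11)
    ]
    assert counts == sorted(counts, reverse=True)


@pytest.mark.parametrize("seed", range(5))
def test_blocked_components_match_scipy_path(seed):
    rng = np.random.default_rng(seed)
    seqs = random_junctions(rng, 150, 10)
    enc = encode_sequences(seqs)
    cutoff = float(rng.uniform(0.1, 0.6))
    direct = single_linkage_clusters(enc, cutoff)
    blocked = _blocked_components(enc, cutoff)
    assert as_partition(direct) == as_partition(blocked)


def test_no_cluster_spans_junction_lengths(small_table):
    res = ac.cluster_repertoire(small_table, FAST)
    length_of = dict(
        zip(small_table.df["sequence_id"], small_table.df["junction_length"])
    )
    for members in res.clusters.values():
        assert len({length_of[m] for m in members}) == 1


def test_perfect_recovery_of_separated_clones(small_table):
    res = ac.cluster_repertoire(small_table, FAST)
    truth = {r.sequence_id: r.true_clone_id for r in small_table.records()}
    q = ac.pairwise_quality(truth, {k: res.assignment[k] for k in truth})
    assert q.f_measure == 1.0


def test_oracle_equivalence_when_partitioner_is_noop(small_table):
    """With every length group under the size threshold the pipeline must
    equal direct single linkage per length group, exactly."""
    res = ac.cluster_repertoire(small_table, FAST)
    df = small_table.df
    for length in df["junction_length"].unique():
        sub = df[df["junction_length"] == length]
        labels = single_linkage_clusters(list(sub["junction"]), FAST.hd_cutoff)
        direct = as_partition(labels)
        ids = list(sub["sequence_id"])
        got = {}
        for i, sid in enumerate(ids):
            got.setdefault(res.assignment[sid], set()).add(i)
        assert frozenset(frozenset(g) for g in got.values()) == direct


def test_deterministic_given_seed(small_table):
    cfg = ClusterConfig(
        seed=9,
        partition=PartitionConfig(
            size_threshold=60,
            packing=PackingParams(population_size=10, generations=10),
        ),
    )
    a = ac.cluster_repertoire(small_table, cfg)
    b = ac.cluster_repertoire(small_table, cfg)
    assert a.assignment == b.assignment


def test_workers_do_not_change_results(small_table):
    cfg = ClusterConfig(
        seed=4,
        partition=PartitionConfig(
            size_threshold=60,
            packing=PackingParams(population_size=8, generations=8),
        ),
    )
    serial = ac.cluster_repertoire(small_table, cfg, n_workers=1)
    parallel = ac.cluster_repertoire(small_table, cfg, n_workers=2)
    assert serial.assignment == parallel.assignment


def test_empty_table_gives_empty_result():
    import pandas as pd

    table = ac.SequenceTable(
        df=pd.DataFrame(
            columns=[
                "sequence_id", "junction", "junction_length",
                "v_calls", "j_calls", "label", "true_clone_id",
            ]
        )
    )
    res = ac.cluster_repertoire(table, FAST)
    assert res.assignment == {}
    assert res.clusters == {}


def test_duplicates_reattached_to_representative_cluster(tmp_path):
    path = tmp_path / "r.tsv"
    path.write_text(
        "sequence_id\tjunction\nid1\tAAAAAA\nid2\tAAAAAA\nid3\tTTTTTT\n"
    )
    table = ac.read_repertoire(path)
    res = ac.cluster_repertoire(table, FAST)
    assert res.assignment["id2"] == res.assignment["id1"]
    assert res.assignment["id3"] != res.assignment["id1"]
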