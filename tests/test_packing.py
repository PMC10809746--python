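import numpy as np
import pytest

from anchorclust import (
    PackingParams,
    conway_lexicode,
    conway_variation,
    d_min_for,
    encode_sequences,
    evolve_packing,
    hamming,
)

from conftest import random_junctions


def brute_force_lexicode(points: list[str], d_min: int) -> list[str]:
    """Naive reference: scan in order, accept iff >= d_min from all accepted."""
    accepted: list[str] = []
    for p in points:
        if all(hamming(p, a) >= d_min for a in accepted):
            accepted.append(p)
    return accepted


def assert_valid_packing(anchors: list[str], d_min: int):
    for i in range(len(anchors)):
        for j in range(i + 1, len(anchors)):
            assert hamming(anchors[i], anchors[j]) >= d_min


def test_lexicode_worked_example():
    pk = conway_lexicode(["AAAA", "AAAT", "AATT", "TTTT"], d_min=2)
    assert pk.to_strings() == ["AAAA", "AATT", "TTTT"]


def test_lexicode_unsatisfiable_beyond_first_point():
    pk = conway_lexicode(["AAAA", "TTTT"], d_min=5)
    assert pk.to_strings() == ["AAAA"]


def test_lexicode_empty_input():
    assert conway_lexicode([], d_min=2).size == 0


@pytest.mark.parametrize("seed", range(10))
def test_lexicode_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 51))
    L = int(rng.integers(4, 16))
    d_min = int(rng.integers(1, L + 1))
    points = random_junctions(rng, n, L)
    got = conway_lexicode(points, d_min).to_strings()
    assert got == brute_force_lexicode(points, d_min)
    assert_valid_packing(got, d_min)


def test_lexicode_monotone_in_d_min(rng):
    points = random_junctions(rng, 60, 12)
    sizes = [conway_lexicode(points, d).size for d in range(1, 13)]
    assert sizes == sorted(sizes, reverse=True)


def test_variation_idempotent_union(rng):
    a = conway_lexicode(["AAAA"], 2)
    pool = encode_sequences(["AAAA"])
    child = conway_variation(a, a, pool, rate=0, rng=rng)
    assert child.to_strings() == ["AAAA"]


def test_variation_keeps_distant_parents(rng):
    a = conway_lexicode(["AAAA"], 2)
    b = conway_lexicode(["TTTT"], 2)
    child = conway_variation(a, b, encode_sequences(["AAAA"]), rate=0, rng=rng)
    assert sorted(child.to_strings()) == ["AAAA", "TTTT"]


@pytest.mark.parametrize("seed", range(8))
def test_variation_output_satisfies_constraint(seed):
    rng = np.random.default_rng(seed)
    pool = encode_sequences(random_junctions(rng, 40, 10))
    d_min = 4
    a = conway_lexicode(pool[rng.permutation(40)], d_min)
    b = conway_lexicode(pool[rng.permutation(40)], d_min)
    child = conway_variation(a, b, pool, rate=5, rng=rng)
    assert_valid_packing(child.to_strings(), d_min)


def test_evolve_single_point_any_params():
    pk = evolve_packing(
        ["ACGTACGT"], PackingParams(population_size=3, generations=2), np.random.default_rng(0)
    )
    assert pk.to_strings() == ["ACGTACGT"]


def test_evolve_close_pair_yields_singleton():
    # ratio 0.75 on length 4 -> d_min 3; the only pair has HD 1
    pk = evolve_packing(
        ["AAAA", "AAAT"],
        PackingParams(min_distance_ratio=0.75, population_size=5, generations=5),
        np.random.default_rng(0),
    )
    assert pk.size == 1
    assert pk.d_min == 3


def test_evolve_empty_points():
    pk = evolve_packing([], PackingParams(population_size=2, generations=1), np.random.default_rng(0))
    assert pk.size == 0


@pytest.mark.parametrize("seed", range(5))
def test_evolve_respects_constraint_and_anchors_are_input_points(seed):
    rng = np.random.default_rng(seed)
    points = random_junctions(rng, 80, 12)
    params = PackingParams(
        min_distance_ratio=0.5, population_size=10, generations=10,
        random_material_rate=5,
    )
    pk = evolve_packing(points, params, rng)
    anchors = pk.to_strings()
    assert_valid_packing(anchors, pk.d_min)
    assert set(anchors) <= set(points)
    assert pk.d_min == d_min_for(0.5, 12)


def test_evolve_never_below_best_initial_member(rng):
    """Steady-state replacement never shrinks the best packing, so the
    result is at least as large as every initial population member."""
    points = random_junctions(rng, 200, 12)
    params = PackingParams(
        min_distance_ratio=0.5, population_size=8, generations=20,
        random_material_rate=10,
    )
    seed_rng = np.random.default_rng(77)
    # record the initial population with an identical generator state
    replay = np.random.default_rng(77)
    enc = encode_sequences(points)
    init_sizes = [
        conway_lexicode(enc[replay.permutation(len(points))], d_min_for(0.5, 12)).size
        for _ in range(params.population_size)
    ]
    pk = evolve_packing(points, params, seed_rng)
    assert pk.size >= max(init_sizes)


def test_evolve_deterministic_under_fixed_seed(rng):
    points = random_junctions(rng, 100, 12)
    params = PackingParams(min_distance_ratio=0.5, population_size=6, generations=10)
    a = evolve_packing(points, params, np.random.default_rng(5))
    b = evolve_packing(points, params, np.random.default_rng(5))
    assert a.to_strings() == b.to_strings()
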