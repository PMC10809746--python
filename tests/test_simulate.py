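import itertools

import numpy as np
import pytest

import anchorclust as ac
from anchorclust import SimulationParams, simulate_labelled_mixture, simulate_repertoire


def test_zero_mutation_collapses_each_clone():
    params = SimulationParams(
        n_clones=5, clone_size=5, per_site_mutation_rate=0.0,
        junction_lengths=(12,), collapse_duplicates=True,
    )
    t = simulate_repertoire(params, np.random.default_rng(0))
    # 5 identical copies per clone collapse to one unique junction each
    assert t.n_retained == 5
    assert t.df["true_clone_id"].nunique() == 5


def test_zero_mutation_without_collapse_keeps_copies():
    params = SimulationParams(
        n_clones=3, clone_size=4, per_site_mutation_rate=0.0,
        junction_lengths=(12,), collapse_duplicates=False,
    )
    t = simulate_repertoire(params, np.random.default_rng(0))
    # identical copies stay in the table as collapsed duplicates of their
    # retained representative rather than being silently dropped
    assert t.n_input == 12
    assert t.n_retained == 3
    assert t.n_duplicates == 9


def test_clone_members_share_one_length():
    params = SimulationParams(n_clones=20, clone_size=6, junction_lengths=(15, 18, 21))
    t = simulate_repertoire(params, np.random.default_rng(1))
    for _, grp in t.df.groupby("true_clone_id"):
        assert grp["junction_length"].nunique() == 1


def test_reproducible_output(tmp_path):
    params = SimulationParams(n_clones=10, clone_size=6, junction_lengths=(18,))
    a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
    ac.write_airr(simulate_repertoire(params, np.random.default_rng(5)), a)
    ac.write_airr(simulate_repertoire(params, np.random.default_rng(5)), b)
    assert a.read_bytes() == b.read_bytes()


def test_between_clone_distance_matches_uniform_expectation():
    """Uniform random germlines mismatch at each site with probability 3/4;
    the mean between-clone normalized HD over many seeds must sit within
    three standard errors of 0.75."""
    L = 30
    dists = []
    for seed in range(40):
        params = SimulationParams(
            n_clones=2, clone_size=1, per_site_mutation_rate=0.0,
            junction_lengths=(L,),
        )
        t = simulate_repertoire(params, np.random.default_rng(seed))
        a, b = list(t.df["junction"])
        dists.append(ac.normalized_hamming(a, b))
    mean = np.mean(dists)
    se = np.sqrt(0.75 * 0.25 / L / len(dists))
    assert abs(mean - 0.75) <= 3 * se


def test_within_clone_below_between_clone():
    params = SimulationParams(
        n_clones=10, clone_size=8, per_site_mutation_rate=0.02,
        lineage_depth=3, junction_lengths=(30,),
    )
    t = simulate_repertoire(params, np.random.default_rng(9))
    df = t.df
    within, between = [], []
    for (i, a), (j, b) in itertools.combinations(df.iterrows(), 2):
        d = ac.normalized_hamming(a["junction"], b["junction"])
        (within if a["true_clone_id"] == b["true_clone_id"] else between).append(d)
    from scipy.stats import mannwhitneyu

    stat, p = mannwhitneyu(within, between, alternative="less")
    assert p < 1e-10
    assert max(within) < min(between)


def test_within_clone_divergence_union_bound():
    r, d = 0.02, 3
    bound = 1 - (1 - r) ** (2 * d)
    params = SimulationParams(
        n_clones=12, clone_size=10, per_site_mutation_rate=r,
        lineage_depth=d, junction_lengths=(45,), collapse_duplicates=False,
    )
    t = simulate_repertoire(params, np.random.default_rng(21))
    within = []
    for _, grp in t.df.groupby("true_clone_id"):
        seqs = list(grp["junction"])
        within += [
            ac.normalized_hamming(a, b) for a, b in itertools.combinations(seqs, 2)
        ]
    assert np.mean(within) <= bound


def test_clone_size_distributions():
    geo = SimulationParams(n_clones=50, clone_size=("geometric", 0.3),
                           junction_lengths=(12,), collapse_duplicates=False)
    t = simulate_repertoire(geo, np.random.default_rng(2))
    sizes = t.df.groupby("true_clone_id").size()
    assert len(sizes) == 50 and sizes.min() >= 1
    power = SimulationParams(n_clones=50, clone_size=("powerlaw", 2.0),
                             junction_lengths=(12,), collapse_duplicates=False)
    t2 = simulate_repertoire(power, np.random.default_rng(2))
    assert t2.df.groupby("true_clone_id").size().min() >= 1


def test_invalid_params_rejected():
    with pytest.raises(ac.ContractError):
        SimulationParams(n_clones=0)
    with pytest.raises(ac.ContractError):
        SimulationParams(clone_size=0)


def test_labelled_mixture_counts_and_purity():
    base = dict(n_clones=8, clone_size=4, junction_lengths=(15,),
                per_site_mutation_rate=0.01)
    t = simulate_labelled_mixture(
        {
            "disease": SimulationParams(**base),
            "healthy": SimulationParams(**base),
        },
        np.random.default_rng(4),
    )
    counts = t.df.groupby("label").size()
    assert set(counts.index) == {"disease", "healthy"}
    # clones never span labels
    for _, grp in t.df.groupby("true_clone_id"):
        assert grp["label"].nunique() == 1


def test_gene_call_simulation_exercises_vj():
    params = SimulationParams(
        n_clones=10, clone_size=4, junction_lengths=(15,),
        with_gene_calls=True, multi_annotation_prob=1.0,
    )
    t = simulate_repertoire(params, np.random.default_rng(6))
    assert all(len(r.v_calls) >= 1 and len(r.j_calls) == 1 for r in t.records())
    assert any(len(r.v_calls) > 1 for r in t.records())
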