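#!/usr/bin/env python
"""Smoke benchmark: cluster a large synthetic repertoire end to end.

Simulates ~100K junction sequences (5,000 clones over five junction
lengths), runs the full pipeline at default parameters, and prints wall
time, peak group sizes and the pairwise F-measure against the simulated
truth.  Intended as a completion check on a single desktop CPU, not a
performance claim.

Usage:  python scripts/benchmark.py [--n-clones 5000] [--seed 1]
"""

from __future__ import annotations

import argparse
import time

import numpy as np

from anchorclust import (
    ClusterConfig,
    SimulationParams,
    cluster_repertoire,
    pairwise_quality,
    simulate_repertoire,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--n-clones", type=int, default=5000)
    parser.add_argument("--clone-size", type=int, default=28)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    params = SimulationParams(
        n_clones=args.n_clones,
        clone_size=args.clone_size,
        junction_lengths=(48, 51, 54, 57, 60),
    )
    t0 = time.perf_counter()
    table = simulate_repertoire(params, np.random.default_rng(args.seed))
    t_sim = time.perf_counter() - t0
    sizes = table.df.groupby("junction_length").size()
    print(f"simulated {table.n_retained} unique sequences in {t_sim:.1f}s")
    print("group sizes:", dict(sizes))

    config = ClusterConfig(seed=args.seed)
    t0 = time.perf_counter()
    result = cluster_repertoire(table, config)
    t_run = time.perf_counter() - t0
    truth = dict(zip(table.df["sequence_id"], table.df["true_clone_id"]))
    q = pairwise_quality(truth, {k: result.assignment[k] for k in truth})
    print(
        f"clustered into {len(result.clusters)} clusters in {t_run:.1f}s; "
        f"F = {100 * q.f_measure:.2f}%"
    )


if __name__ == "__main__":
    main()
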