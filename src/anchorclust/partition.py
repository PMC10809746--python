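"""Recursive anchor-distance partitioning with a BIRCH clusterer.

Each length-stratified group that exceeds the size threshold is embedded as
normalized Hamming-distance vectors to a freshly packed anchor set, split by
BIRCH (clustering-feature tree, merge-radius threshold, global agglomeration
into as many clusters as anchors), and the parts are recursed until every
leaf is small enough for all-pairs comparison.

Degenerate rounds (too few anchors, or a split that returns a single part)
fall back by relaxing the minimum-distance ratio in steps of 0.1; below a
floor of 0.3 — or at the recursion depth bound — the group becomes a forced
leaf, which downstream clustering handles in memory-bounded blocks.  Leaves
always partition the input exactly; sequences are never lost.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.cluster import Birch

from .distances import batch_distance
from .errors import ContractError
from .packing import PackingParams, d_min_for, evolve_packing

RATIO_STEP = 0.1
RATIO_FLOOR = 0.3
# Above this group size the BIRCH tree is fitted on a 10% sample by default.
AUTO_FIT_LIMIT = 10_000


@dataclass(frozen=True)
class PartitionConfig:
    """Parameters of the recursive partitioner.

    radius_threshold
        BIRCH merge radius on Euclidean distance between normalized-HD
        vectors (vectors live in [0,1]^k).
    size_threshold
        Largest group handed to all-pairs single linkage.
    fit_fraction
        Fraction of rows used to fit the BIRCH tree before assigning all
        rows; ``None`` selects 1.0 for groups up to 10,000 rows and 0.10
        beyond that.
    """

    radius_threshold: float = 0.5
    size_threshold: int = 1000
    fit_fraction: float | None = None
    branching_factor: int = 50
    max_depth: int = 30
    packing: PackingParams = field(default_factory=PackingParams)

    def __post_init__(self) -> None:
        if self.size_threshold < 2:
            raise ContractError("size_threshold must be >= 2")
        if self.fit_fraction is not None and not 0.0 < self.fit_fraction <= 1.0:
            raise ContractError("fit_fraction must lie in (0, 1]")
        if self.max_depth < 1:
            raise ContractError("max_depth must be positive")

    def resolve_fit_fraction(self, n: int) -> float:
        if self.fit_fraction is not None:
            return self.fit_fraction
        return 1.0 if n <= AUTO_FIT_LIMIT else 0.10


@dataclass
class LeafCluster:
    """A subcluster ready for all-pairs comparison.

    ``members`` indexes into the length group's sequence list.  ``forced``
    marks leaves emitted by the fallback path, which may exceed the size
    threshold.
    """

    members: np.ndarray
    depth: int
    forced: bool = False


def birch_partition(
    vectors: np.ndarray,
    n_clusters: int,
    radius: float,
    fit_fraction: float,
    rng: np.random.Generator,
    *,
    branching_factor: int = 50,
) -> np.ndarray:
    """Split distance vectors with BIRCH; returns one label per row.

    The clustering-feature tree is built on a uniform random sample of
    ``ceil(fit_fraction * n)`` rows, frozen, and every row is then assigned
    to the nearest final subcluster centroid.  The number of distinct labels
    never exceeds ``n_clusters`` (clamped to the sample size with a warning).
    """
    n = vectors.shape[0]
    if n == 0:
        raise ContractError("cannot partition an empty vector set")
    if n_clusters < 1:
        raise ContractError("n_clusters must be >= 1")
    sample_size = max(1, math.ceil(fit_fraction * n))
    if n_clusters > sample_size:
        warnings.warn(
            f"n_clusters={n_clusters} exceeds the fitting sample ({sample_size}); "
            "clamping",
            stacklevel=2,
        )
        n_clusters = sample_size
    idx = rng.choice(n, size=sample_size, replace=False) if sample_size < n else np.arange(n)
    model = Birch(
        threshold=radius,
        branching_factor=branching_factor,
        n_clusters=n_clusters,
    )
    with warnings.catch_warnings():
        # sklearn warns when the CF tree yields fewer subclusters than
        # n_clusters; fewer parts are acceptable here.
        warnings.simplefilter("ignore")
        model.fit(vectors[idx])
        labels = model.predict(vectors)
    return labels


def recursive_partition(
    group: np.ndarray,
    config: PartitionConfig,
    rng: np.random.Generator,
) -> list[LeafCluster]:
    """Partition an encoded length group into leaves of bounded size.

    Returns leaves whose ``members`` arrays are pairwise disjoint and union
    to ``range(len(group))``.
    """
    if group.ndim != 2:
        raise ContractError("group must be an encoded sequence matrix")
    n, L = group.shape
    if n == 0:
        return []
    leaves: list[LeafCluster] = []
    _split(group, np.arange(n), 0, config, rng, leaves)
    return leaves


def _split(
    group: np.ndarray,
    indices: np.ndarray,
    depth: int,
    config: PartitionConfig,
    rng: np.random.Generator,
    leaves: list[LeafCluster],
) -> None:
    n = indices.size
    if n <= config.size_threshold:
        leaves.append(LeafCluster(members=indices, depth=depth))
        return
    if depth >= config.max_depth:
        warnings.warn(
            f"recursion depth limit reached for a group of {n} sequences; "
            "emitting a forced leaf",
            stacklevel=2,
        )
        leaves.append(LeafCluster(members=indices, depth=depth, forced=True))
        return

    rows = group[indices]
    L = rows.shape[1]
    pool = np.unique(rows, axis=0)
    ratio = config.packing.min_distance_ratio
    while ratio >= RATIO_FLOOR - 1e-9:
        params = replace(config.packing, min_distance_ratio=ratio)
        packing = evolve_packing(pool, params, rng, d_min=d_min_for(ratio, L))
        if packing.size < 2:
            ratio -= RATIO_STEP
            continue
        vectors = batch_distance(rows, packing.anchors)
        labels = birch_partition(
            vectors,
            n_clusters=packing.size,
            radius=config.radius_threshold,
            fit_fraction=config.resolve_fit_fraction(n),
            rng=rng,
            branching_factor=config.branching_factor,
        )
        parts = [indices[labels == lab] for lab in np.unique(labels)]
        parts = [p for p in parts if p.size]
        if len(parts) < 2:
            ratio -= RATIO_STEP
            continue
        for part in parts:
            _split(group, part, depth + 1, config, rng, leaves)
        return
    warnings.warn(
        f"no usable anchor packing for a group of {n} sequences; "
        "emitting a forced leaf",
        stacklevel=2,
    )
    leaves.append(LeafCluster(members=indices, depth=depth, forced=True))
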