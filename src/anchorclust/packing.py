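"""Point packing: selection of maximally spaced anchor sequences.

Anchors are junction sequences whose pairwise Hamming distances all satisfy a
minimum-distance constraint.  A greedy lexicode scan (Conway's Lexicode
Algorithm, CLA) filters an ordered point list down to a valid packing; a
recombination operator (Conway's Variation Operator, CVO) unions two parent
packings with freshly sampled points and re-filters through CLA.  A small
steady-state evolutionary loop maximises packing size.

The minimum distance is specified as a ratio of the junction length so it is
comparable across length strata: ``d_min = ceil(ratio * L)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .distances import (
    decode_sequences,
    encode_sequences,
    pack_bits,
    packed_distances_to_point,
)
from .errors import ContractError


@dataclass(frozen=True)
class PackingParams:
    """Hyperparameters of the point-packing search.

    min_distance_ratio
        Minimum anchor-pair Hamming distance divided by junction length.
    population_size
        Number of candidate packings kept by the evolutionary loop.
    random_material_rate
        Number of points sampled from the pool and injected per variation.
    generations
        Number of offspring produced before stopping.
    stagnation
        Stop early after this many offspring without improving the best size.
    """

    min_distance_ratio: float = 0.6
    population_size: int = 1000
    random_material_rate: int = 50
    generations: int = 50
    stagnation: int = 20

    def __post_init__(self) -> None:
        if not 0.0 < self.min_distance_ratio <= 1.0:
            raise ContractError("min_distance_ratio must lie in (0, 1]")
        if self.population_size < 1 or self.generations < 1:
            raise ContractError("population_size and generations must be positive")
        if self.random_material_rate < 0:
            raise ContractError("random_material_rate must be non-negative")


@dataclass(frozen=True)
class Packing:
    """A set of anchors (encoded rows) with all pairwise distances >= d_min."""

    anchors: np.ndarray  # (k, L) uint8, in acceptance order
    d_min: int

    @property
    def size(self) -> int:
        return int(self.anchors.shape[0])

    def to_strings(self) -> list[str]:
        return decode_sequences(self.anchors)


def d_min_for(ratio: float, length: int) -> int:
    """Effective minimum distance: ceil(ratio * L), at least 1."""
    return max(1, math.ceil(ratio * length))


def _as_matrix(points) -> np.ndarray:
    if isinstance(points, np.ndarray):
        return points
    return encode_sequences(list(points))


def conway_lexicode(points, d_min: int) -> Packing:
    """Greedy lexicode scan: accept each point iff it is >= d_min from all
    previously accepted points.  Deterministic given the input order.

    Implemented as k vectorised passes (k = packing size): a running
    minimum-distance array over all points is updated each time a point is
    accepted, which is equivalent to the naive per-point scan.
    """
    pts = _as_matrix(points)
    if d_min < 1:
        raise ContractError("d_min must be >= 1")
    n = pts.shape[0]
    if n == 0:
        return Packing(anchors=np.empty((0, 0), dtype=np.uint8), d_min=d_min)
    accepted = _cla_indices(pack_bits(pts), d_min)
    return Packing(anchors=pts[accepted], d_min=d_min)


def _cla_indices_numpy(packed: np.ndarray, d_min: int) -> np.ndarray:
    """Greedy lexicode scan over pre-packed rows; returns accepted indices.

    Maintains a running minimum distance of every row to the accepted set,
    which makes the scan k vectorised passes instead of n scalar ones.
    """
    n = packed.shape[0]
    mind = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    accepted: list[int] = []
    ptr = 0
    while ptr < n:
        ok = np.nonzero(mind[ptr:] >= d_min)[0]
        if ok.size == 0:
            break
        j = ptr + int(ok[0])
        accepted.append(j)
        np.minimum(mind, packed_distances_to_point(packed, packed[j]), out=mind)
        ptr = j + 1
    return np.asarray(accepted, dtype=np.int64)


try:  # compiled scan; rows already within d_min of an anchor are skipped
    import numba

    @numba.njit(cache=True)
    def _cla_indices_jit(packed, d_min):  # pragma: no cover - exercised via wrapper
        n, w = packed.shape
        big = np.int64(1) << np.int64(60)
        mind = np.full(n, big, dtype=np.int64)
        accepted = np.empty(n, dtype=np.int64)
        mask = np.uint64(0x5555555555555555)
        one = np.uint64(1)
        k = 0
        ptr = 0
        while ptr < n:
            j = -1
            for i in range(ptr, n):
                if mind[i] >= d_min:
                    j = i
                    break
            if j < 0:
                break
            accepted[k] = j
            k += 1
            for i in range(n):
                if mind[i] < d_min:
                    continue  # permanently rejected; no need to track
                d = np.int64(0)
                for c in range(w):
                    z = packed[i, c] ^ packed[j, c]
                    x = (z | (z >> one)) & mask
                    # SWAR popcount
                    x = x - ((x >> np.uint64(1)) & np.uint64(0x5555555555555555))
                    x = (x & np.uint64(0x3333333333333333)) + (
                        (x >> np.uint64(2)) & np.uint64(0x3333333333333333)
                    )
                    x = (x + (x >> np.uint64(4))) & np.uint64(0x0F0F0F0F0F0F0F0F)
                    d += np.int64((x * np.uint64(0x0101010101010101)) >> np.uint64(56))
                if d < mind[i]:
                    mind[i] = d
            ptr = j + 1
        return accepted[:k]

    def _cla_indices(packed: np.ndarray, d_min: int) -> np.ndarray:
        return _cla_indices_jit(np.ascontiguousarray(packed), np.int64(d_min))

except ImportError:  # pragma: no cover
    _cla_indices = _cla_indices_numpy


def conway_variation(
    parent_a: Packing,
    parent_b: Packing,
    pool: np.ndarray,
    rate: int,
    rng: np.random.Generator,
) -> Packing:
    """Recombine two packings: union the parents, inject `rate` random points
    drawn from the pool without replacement, shuffle, and re-filter with CLA.
    """
    if parent_a.d_min != parent_b.d_min:
        raise ContractError("parents must share d_min")
    parts = [p.anchors for p in (parent_a, parent_b) if p.size]
    if rate > 0 and pool.shape[0] > 0:
        k = min(rate, pool.shape[0])
        parts.append(pool[rng.choice(pool.shape[0], size=k, replace=False)])
    if not parts:
        return Packing(anchors=np.empty((0, 0), dtype=np.uint8), d_min=parent_a.d_min)
    union = np.concatenate(parts, axis=0)
    union = union[rng.permutation(union.shape[0])]
    return conway_lexicode(union, parent_a.d_min)


def evolve_packing(
    points,
    params: PackingParams,
    rng: np.random.Generator,
    *,
    d_min: int | None = None,
) -> Packing:
    """Steady-state evolutionary search for a large packing.

    Initialises ``population_size`` packings by running CLA on independent
    random shuffles of the points, then repeatedly recombines two
    uniform-randomly chosen parents through CVO; the offspring replaces the
    smallest population member if it is strictly larger.  Fitness is packing
    cardinality.  Returns the largest packing after ``generations`` offspring
    (or earlier on stagnation).  Reproducible under a fixed generator state.
    """
    pts = _as_matrix(points)
    n = pts.shape[0]
    if n == 0:
        return Packing(anchors=np.empty((0, 0), dtype=np.uint8), d_min=d_min or 1)
    if d_min is None:
        d_min = d_min_for(params.min_distance_ratio, pts.shape[1])
    if n == 1:
        return Packing(anchors=pts.copy(), d_min=d_min)

    packed_all = pack_bits(pts)
    population = []
    for _ in range(params.population_size):
        perm = rng.permutation(n)
        idx = _cla_indices(packed_all[perm], d_min)
        population.append(Packing(anchors=pts[perm[idx]], d_min=d_min))
    sizes = np.array([p.size for p in population])
    best = int(sizes.max())
    stagnant = 0
    for _ in range(params.generations):
        ia, ib = rng.integers(0, len(population), size=2)
        child = conway_variation(
            population[ia], population[ib], pts, params.random_material_rate, rng
        )
        worst = int(sizes.argmin())
        if child.size > sizes[worst]:
            population[worst] = child
            sizes[worst] = child.size
        if child.size > best:
            best = child.size
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= params.stagnation:
                break
    return population[int(sizes.argmax())]
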