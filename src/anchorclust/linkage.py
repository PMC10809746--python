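"""Single-linkage clonal clustering of leaves and pipeline orchestration.

Within each leaf all pairwise normalized Hamming distances are computed and
sequences are merged by single linkage, cut (inclusively) at the clonal
cutoff — equivalently, connected components of the graph joining pairs at
distance <= cutoff.  ``cluster_repertoire`` runs the whole workflow:
stratify by junction length (optionally by V/J usage first), recursively
partition each group, single-link every leaf, and assemble globally unique
cluster ids.
"""

from __future__ import annotations

import dataclasses
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .distances import batch_distance, encode_sequences
from .errors import ContractError
from .io import SequenceTable
from .partition import PartitionConfig, recursive_partition
from . import vj as _vj

# Largest leaf for the direct condensed-distance path; bigger (forced) leaves
# fall back to blocked union-find over the same threshold graph.
DIRECT_LINKAGE_LIMIT = 8000
_BLOCK = 1024


@dataclass(frozen=True)
class ClusterConfig:
    """Resolved parameters of a clustering run."""

    hd_cutoff: float = 0.12
    vj_mode: str = "none"  # {"pre", "post", "none"}
    strip_alleles: bool = True
    partition: PartitionConfig = field(default_factory=PartitionConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hd_cutoff <= 1.0:
            raise ContractError("hd_cutoff must lie in [0, 1]")
        if self.vj_mode not in ("pre", "post", "none"):
            raise ContractError(f"unknown vj_mode: {self.vj_mode!r}")


@dataclass
class ClusterResult:
    """Final sequence -> cluster assignment with provenance."""

    assignment: dict[str, int]
    clusters: dict[int, list[str]]
    params_used: dict
    per_length_stats: dict

    @classmethod
    def from_assignment(
        cls, assignment: Mapping[str, int], params_used: dict, per_length_stats: dict
    ) -> "ClusterResult":
        clusters: dict[int, list[str]] = {}
        for sid, cid in assignment.items():
            clusters.setdefault(cid, []).append(sid)
        return cls(dict(assignment), clusters, params_used, per_length_stats)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = np.arange(n)

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel to 0..m-1 in order of first occurrence."""
    _, first = np.unique(raw, return_index=True)
    order = {raw[i]: rank for rank, i in enumerate(sorted(first))}
    return np.array([order[v] for v in raw], dtype=np.int64)


def single_linkage_clusters(members, cutoff: float) -> np.ndarray:
    """Cluster equal-length sequences by single linkage at ``cutoff``.

    ``members`` is a list of strings or an encoded matrix.  Returns integer
    labels (0..m-1, numbered by first occurrence).  Merges at distance equal
    to the cutoff are included.
    """
    enc = members if isinstance(members, np.ndarray) else encode_sequences(list(members))
    n = enc.shape[0]
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    if n <= DIRECT_LINKAGE_LIMIT:
        condensed = pdist(enc, metric="hamming")
        tree = linkage(condensed, method="single")
        raw = fcluster(tree, t=cutoff, criterion="distance")
        return _canonical_labels(raw)
    return _blocked_components(enc, cutoff)


def _blocked_components(enc: np.ndarray, cutoff: float) -> np.ndarray:
    """Connected components of the threshold graph, built block-by-block so
    memory stays ~(block x n) rather than n^2/2."""
    n = enc.shape[0]
    uf = _UnionFind(n)
    for start in range(0, n, _BLOCK):
        stop = min(start + _BLOCK, n)
        dist = batch_distance(enc[start:stop], enc[start:])
        rows, cols = np.nonzero(dist <= cutoff + 1e-12)
        for r, c in zip(rows, cols):
            i, j = start + int(r), start + int(c)
            if i < j:
                uf.union(i, j)
    roots = np.array([uf.find(i) for i in range(n)])
    return _canonical_labels(roots)


def _cluster_group(args) -> tuple[np.ndarray, dict]:
    """Partition one (VJ group, junction length) stratum and single-link its
    leaves.  Top-level so it can run in a worker process."""
    junctions, config, seed_key = args
    enc = encode_sequences(junctions)
    rng = np.random.default_rng(list(seed_key))
    leaves = recursive_partition(enc, config.partition, rng)
    labels = np.full(enc.shape[0], -1, dtype=np.int64)
    offset = 0
    for leaf in sorted(leaves, key=lambda lf: int(lf.members.min())):
        sub = single_linkage_clusters(enc[leaf.members], config.hd_cutoff)
        labels[leaf.members] = sub + offset
        offset += int(sub.max()) + 1 if sub.size else 0
    stats = {
        "n_sequences": int(enc.shape[0]),
        "n_leaves": len(leaves),
        "max_depth": max((lf.depth for lf in leaves), default=0),
        "n_forced_leaves": sum(lf.forced for lf in leaves),
    }
    return labels, stats


def cluster_repertoire(
    table: SequenceTable, config: ClusterConfig, n_workers: int = 1
) -> ClusterResult:
    """Run the full anchor-clustering workflow on a validated table.

    Sequences are grouped by junction length (and by shared V/J usage first
    when ``vj_mode == "pre"``) and processed independently; each group gets
    a random substream derived from the global seed and its own identity, so
    results do not depend on scheduling or worker count.  Collapsed
    duplicates are re-attached to their representative's cluster.
    """
    df = table.df
    params_used = dataclasses.asdict(config)
    if df.empty:
        return ClusterResult.from_assignment({}, params_used, {})

    if config.vj_mode == "pre":
        groups = _vj.vj_components(table, strip_alleles=config.strip_alleles)
    else:
        groups = [np.arange(len(df))]

    lengths_all = df["junction_length"].to_numpy()
    junctions_all = df["junction"].to_numpy()
    tasks = []
    for gidx, rows in enumerate(groups):
        glens = lengths_all[rows]
        for length in np.unique(glens):
            sel = rows[glens == length]
            seed_key = (config.seed, gidx, int(length))
            tasks.append(((gidx, int(length)), sel, seed_key))

    payloads = [
        (list(junctions_all[sel]), config, seed_key) for _, sel, seed_key in tasks
    ]
    if n_workers > 1 and len(tasks) > 1:
        with ProcessPoolExecutor(max_workers=n_workers) as pool:
            outputs = list(pool.map(_cluster_group, payloads))
    else:
        outputs = [_cluster_group(p) for p in payloads]

    assignment: dict[str, int] = {}
    per_length_stats: dict[str, dict] = {}
    offset = 0
    ids_all = df["sequence_id"].to_numpy()
    for ((gidx, length), sel, _), (labels, stats) in zip(tasks, outputs):
        for sid, lab in zip(ids_all[sel], labels):
            assignment[str(sid)] = int(lab) + offset
        offset += int(labels.max()) + 1 if labels.size else 0
        per_length_stats[f"group{gidx}_len{length}"] = stats

    result = ClusterResult.from_assignment(assignment, params_used, per_length_stats)
    if config.vj_mode == "post":
        result = _vj.vj_refine_post(result, table, strip_alleles=config.strip_alleles)
        result.params_used = params_used
        result.per_length_stats = per_length_stats

    # re-attach collapsed duplicates to their representative's cluster
    for rep_id, dup_ids in table.duplicate_map.items():
        cid = result.assignment[rep_id]
        for dup in dup_ids:
            result.assignment[dup] = cid
            result.clusters[cid].append(dup)
    return result


def audit_cross_leaf_pairs(
    enc: np.ndarray,
    leaves,
    cutoff: float,
    rng: np.random.Generator,
    max_rows: int = 500,
) -> int:
    """Diagnostic: count sampled cross-leaf pairs within the cutoff.

    The pipeline never merges clusters across leaf boundaries; this audits
    how many within-cutoff pairs that approximation severs, on a row sample.
    """
    leaf_of = np.empty(enc.shape[0], dtype=np.int64)
    for li, leaf in enumerate(leaves):
        leaf_of[leaf.members] = li
    n = enc.shape[0]
    rows = rng.choice(n, size=min(max_rows, n), replace=False)
    dist = batch_distance(enc[rows], enc)
    count = 0
    for r, i in enumerate(rows):
        close = np.nonzero(dist[r] <= cutoff + 1e-12)[0]
        count += int(np.sum((leaf_of[close] != leaf_of[i]) & (close != i)))
    return count // 2
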