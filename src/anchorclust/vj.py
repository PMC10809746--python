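"""Grouping by V/J gene usage, before (VJ-Pre) or after (VJ-Post) clustering.

Two sequences belong together when they share at least one V gene AND at
least one J gene; multi-annotated sequences chain groups greedily, so the
groups are the connected components of that shared-gene graph.  Gene names
are compared at the allele-stripped level (text before ``*``) by default.
Sequences lacking V or J calls bypass the grouping into one catch-all group
(simulated repertoires carry no gene calls and must still cluster).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SequenceTable


@dataclass
class VJGroup:
    """One shared-V/J component: the union of its members' gene names."""

    v_genes: frozenset[str]
    j_genes: frozenset[str]
    member_ids: list[str]


def _strip(genes: frozenset[str], strip_alleles: bool) -> frozenset[str]:
    if not strip_alleles:
        return genes
    return frozenset(g.split("*")[0] for g in genes)


def _component_labels(
    v_sets: list[frozenset[str]],
    j_sets: list[frozenset[str]],
    *,
    match: str = "vj",
) -> np.ndarray:
    """Connected-component label per record under the shared-gene relation.

    ``match`` selects the linking rule: "vj" (share >=1 V and >=1 J), "v" or
    "j" (one side only).  Records with an empty required set get label -1
    (caller places them in a catch-all group).
    """
    n = len(v_sets)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    first_holder: dict[tuple, int] = {}
    labels = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        if match == "vj":
            if not v_sets[i] or not j_sets[i]:
                continue
            keys = [(v, j) for v in v_sets[i] for j in j_sets[i]]
        elif match == "v":
            if not v_sets[i]:
                continue
            keys = [(v,) for v in v_sets[i]]
        else:
            if not j_sets[i]:
                continue
            keys = [(j,) for j in j_sets[i]]
        for key in keys:
            holder = first_holder.setdefault(key, i)
            if holder != i:
                union(holder, i)
    comp_id: dict[int, int] = {}
    for i in range(n):
        if match == "vj" and (not v_sets[i] or not j_sets[i]):
            continue
        if match == "v" and not v_sets[i]:
            continue
        if match == "j" and not j_sets[i]:
            continue
        root = find(i)
        labels[i] = comp_id.setdefault(root, len(comp_id))
    return labels


def vj_components(
    table: SequenceTable, *, strip_alleles: bool = True, match: str = "vj"
) -> list[np.ndarray]:
    """Row-position groups for VJ-Pre: one array per component, plus one
    catch-all array for records bypassing the grouping.  The arrays
    partition ``range(len(table.df))``."""
    v_sets = [_strip(v, strip_alleles) for v in table.df["v_calls"]]
    j_sets = [_strip(j, strip_alleles) for j in table.df["j_calls"]]
    labels = _component_labels(v_sets, j_sets, match=match)
    groups = [
        np.nonzero(labels == lab)[0] for lab in np.unique(labels) if lab >= 0
    ]
    bypass = np.nonzero(labels < 0)[0]
    if bypass.size:
        groups.append(bypass)
    return groups


def vj_partition_pre(
    table: SequenceTable, *, strip_alleles: bool = True, match: str = "vj"
) -> list[VJGroup]:
    """Partition a table into shared-V/J groups (the VJ-Pre strategy)."""
    ids = table.df["sequence_id"].to_numpy()
    out = []
    for rows in vj_components(table, strip_alleles=strip_alleles, match=match):
        v_union: set[str] = set()
        j_union: set[str] = set()
        for r in rows:
            v_union |= _strip(table.df["v_calls"].iloc[r], strip_alleles)
            j_union |= _strip(table.df["j_calls"].iloc[r], strip_alleles)
        out.append(
            VJGroup(
                v_genes=frozenset(v_union),
                j_genes=frozenset(j_union),
                member_ids=[str(s) for s in ids[rows]],
            )
        )
    return out


def vj_refine_post(result, table: SequenceTable, *, strip_alleles: bool = True, match: str = "vj"):
    """Re-split every distance-based cluster into shared-V/J components
    (the VJ-Post strategy).  Never merges clusters; idempotent."""
    from .linkage import ClusterResult  # local import to avoid a cycle

    by_id = {
        str(row.sequence_id): (
            _strip(row.v_calls, strip_alleles),
            _strip(row.j_calls, strip_alleles),
        )
        for row in table.df.itertuples(index=False)
    }
    assignment: dict[str, int] = {}
    next_id = 0
    for cid in sorted(result.clusters):
        members = [m for m in result.clusters[cid] if m in by_id]
        v_sets = [by_id[m][0] for m in members]
        j_sets = [by_id[m][1] for m in members]
        labels = _component_labels(v_sets, j_sets, match=match)
        # bypass records (label -1) stay together in their own component
        local: dict[int, int] = {}
        for m, lab in zip(members, labels):
            key = int(lab)
            if key not in local:
                local[key] = next_id
                next_id += 1
            assignment[m] = local[key]
    # collapsed duplicates (present in the result but not in the retained
    # table) follow their representative
    for rep_id, dup_ids in table.duplicate_map.items():
        if rep_id in assignment:
            for dup in dup_ids:
                if dup in result.assignment:
                    assignment[dup] = assignment[rep_id]
    return ClusterResult.from_assignment(
        assignment, result.params_used, result.per_length_stats
    )
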