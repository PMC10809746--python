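"""Synthetic clonal repertoires with known clone membership.

Each clone is a uniform-random germline junction plus descendants generated
along a random lineage tree: every new member picks a random existing node
(germline or earlier descendant) whose depth is below ``lineage_depth`` as
its parent and mutates each site independently at ``per_site_mutation_rate``
(uniform substitution to a different base).  Within-clone divergence is thus
bounded in expectation by ``1 - (1 - r)^(2d)`` per site, while germlines of
different clones mismatch at ~75% of sites, giving tunable separation
between within- and between-clone distances.

Germlines are drawn uniformly over {A,C,G,T}^L rather than from germline
gene databases: the goal is controlled ground-truth separation, not
immunogenetic realism (a hook accepts user-supplied germlines).  Labelled
mixtures concatenate independently simulated repertoires, so clones never
span labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError
from .io import SequenceTable, table_from_frame

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of one simulated repertoire.

    clone_size
        Either a fixed integer, ("geometric", p) or ("powerlaw", alpha);
        sizes are clamped to >= 1.
    junction_lengths / length_weights
        Candidate junction lengths (nucleotides; in-frame multiples of 3 by
        default) and their sampling weights (uniform when omitted).  Each
        clone draws one length.
    per_site_mutation_rate
        Per-site substitution probability on each lineage edge.
    lineage_depth
        Maximum number of lineage edges from the germline to any member.
    """

    n_clones: int = 250
    clone_size: int | tuple = 20
    junction_lengths: Sequence[int] = (48, 51, 54, 57, 60)
    length_weights: Sequence[float] | None = None
    per_site_mutation_rate: float = 0.015
    lineage_depth: int = 3
    label: str | None = None
    collapse_duplicates: bool = True
    with_gene_calls: bool = False
    multi_annotation_prob: float = 0.1
    n_v_genes: int = 30
    n_j_genes: int = 6
    germlines: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ContractError("n_clones must be positive")
        if isinstance(self.clone_size, int) and self.clone_size < 1:
            raise ContractError("fixed clone size must be >= 1")
        if not 0.0 <= self.per_site_mutation_rate <= 1.0:
            raise ContractError("per_site_mutation_rate must lie in [0, 1]")
        if self.lineage_depth < 1:
            raise ContractError("lineage_depth must be >= 1")
        if not self.junction_lengths:
            raise ContractError("junction_lengths must be non-empty")


def _draw_clone_size(spec, rng: np.random.Generator) -> int:
    if isinstance(spec, int):
        return spec
    kind, param = spec
    if kind == "geometric":
        return int(rng.geometric(param))
    if kind == "powerlaw":
        # discrete power law via inverse transform on a Pareto draw
        return max(1, int(rng.pareto(param)) + 1)
    raise ContractError(f"unknown clone_size distribution: {spec!r}")


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    child = seq.copy()
    if rate <= 0:
        return child
    hits = np.nonzero(rng.random(seq.size) < rate)[0]
    if hits.size:
        # substitute with one of the three other bases, uniformly
        child[hits] = (child[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return child


def _decode(row: np.ndarray) -> str:
    return bytes(_BASES[row]).decode("ascii")


def simulate_repertoire(
    params: SimulationParams, rng: np.random.Generator | int
) -> SequenceTable:
    """Simulate one clonally structured repertoire with ground truth.

    Returns a validated SequenceTable whose ``true_clone_id`` column records
    clone membership; fixed seed and params give identical output.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    lengths = np.asarray(params.junction_lengths)
    weights = None
    if params.length_weights is not None:
        w = np.asarray(params.length_weights, dtype=float)
        weights = w / w.sum()

    ids, junctions, clone_ids = [], [], []
    v_calls, j_calls = [], []
    for ci in range(params.n_clones):
        L = int(rng.choice(lengths, p=weights))
        if params.germlines is not None:
            g = params.germlines[ci % len(params.germlines)].upper()
            lut = np.zeros(256, dtype=np.uint8)
            for code, b in enumerate(_BASES):
                lut[b] = code
            germline = lut[np.frombuffer(g.encode(), dtype=np.uint8)]
            L = germline.size
        else:
            germline = rng.integers(0, 4, size=L, dtype=np.uint8)
        size = _draw_clone_size(params.clone_size, rng)

        # random lineage: nodes[(depth, sequence)]; each member attaches to a
        # random node of depth < lineage_depth
        nodes: list[tuple[int, np.ndarray]] = [(0, germline)]
        members: list[np.ndarray] = []
        eligible = [0]  # node indices with depth < lineage_depth
        while len(members) < size:
            pidx = int(rng.choice(eligible)) if len(eligible) > 1 else eligible[0]
            pdepth, pseq = nodes[pidx]
            child = _mutate(pseq, params.per_site_mutation_rate, rng)
            nodes.append((pdepth + 1, child))
            if pdepth + 1 < params.lineage_depth:
                eligible.append(len(nodes) - 1)
            members.append(child)

        if params.with_gene_calls:
            v = {f"IGHV{rng.integers(1, params.n_v_genes + 1)}-1"}
            j = {f"IGHJ{rng.integers(1, params.n_j_genes + 1)}"}
            if rng.random() < params.multi_annotation_prob:
                v.add(f"IGHV{rng.integers(1, params.n_v_genes + 1)}-1")
        else:
            v, j = set(), set()
        clone_name = f"clone{ci + 1}"
        for mi, member in enumerate(members):
            ids.append(f"{clone_name}_seq{mi + 1}")
            junctions.append(_decode(member))
            clone_ids.append(clone_name)
            v_calls.append(frozenset(v))
            j_calls.append(frozenset(j))

    frame = pd.DataFrame(
        {
            "sequence_id": ids,
            "junction": junctions,
            "v_calls": v_calls,
            "j_calls": j_calls,
            "label": pd.Series([params.label] * len(ids), dtype=object),
            "true_clone_id": clone_ids,
        }
    )
    if params.collapse_duplicates:
        # duplicates are dropped at generation time (first occurrence kept)
        # so the table is unique on junctions and the truth stays unambiguous
        frame = frame[~frame["junction"].duplicated()].reset_index(drop=True)
    return table_from_frame(frame, dedup="junction")


def simulate_labelled_mixture(
    params_per_label: Mapping[str, SimulationParams],
    rng: np.random.Generator | int,
) -> SequenceTable:
    """Concatenate independently simulated repertoires, one per label class,
    shuffling record order.  Every true clone is label-pure by construction."""
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    if len(params_per_label) < 2:
        raise ContractError("a labelled mixture needs at least two label classes")
    frames = []
    for label in sorted(params_per_label):
        p = params_per_label[label]
        sub = simulate_repertoire(
            SimulationParams(**{**p.__dict__, "label": label}), rng
        )
        df = sub.df.copy()
        df["sequence_id"] = [f"{label}_{s}" for s in df["sequence_id"]]
        df["true_clone_id"] = [f"{label}_{c}" for c in df["true_clone_id"]]
        frames.append(df)
    merged = pd.concat(frames, ignore_index=True)
    merged = merged.iloc[rng.permutation(len(merged))].reset_index(drop=True)
    merged = merged.drop(columns=["junction_length"])
    return table_from_frame(merged, dedup="junction")
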