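"""Clustering-quality metrics.

Against ground-truth clones: pairwise sensitivity, precision and F-measure
over all unordered sequence pairs.  Against categorical labels (no ground
truth): singleton / non-singleton retention and fraction, where a cluster is
"pure" if all members carry one label and a singleton counts as pure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping

import numpy as np
import pandas as pd

from .errors import ContractError


@dataclass(frozen=True)
class ConfusionCounts:
    """Pair-level confusion counts over unordered sequence pairs.

    TP: clonally related pairs co-clustered; FN: related pairs separated;
    FP: unrelated pairs co-clustered.
    """

    TP: int
    FP: int
    FN: int


@dataclass(frozen=True)
class QualityMetrics:
    sensitivity: float
    precision: float
    f_measure: float


@dataclass(frozen=True)
class PurityMetrics:
    """Label-purity summary, all values percentages in [0, 100]."""

    singleton_retention: float
    singleton_fraction: float
    non_singleton_retention: float
    non_singleton_fraction: float


def _pairs(counts: np.ndarray) -> int:
    counts = counts.astype(np.int64)
    return int((counts * (counts - 1) // 2).sum())


def pair_confusion(
    truth: Mapping[Hashable, Hashable], predicted: Mapping[Hashable, Hashable]
) -> ConfusionCounts:
    """Pair confusion counts via contingency-table algebra.

    TP is the sum of C(n_ij, 2) over the truth x predicted contingency
    table; related pairs and co-clustered pairs come from the marginals.
    Equal to the naive enumeration over all C(n, 2) pairs.
    """
    if set(truth) != set(predicted):
        raise ContractError("truth and predicted assignments cover different ids")
    ids = list(truth)
    t = pd.factorize(np.array([truth[i] for i in ids], dtype=object))[0]
    p = pd.factorize(np.array([predicted[i] for i in ids], dtype=object))[0]
    joint = pd.crosstab(t, p).to_numpy()
    tp = _pairs(joint.ravel())
    related = _pairs(joint.sum(axis=1))
    co_clustered = _pairs(joint.sum(axis=0))
    return ConfusionCounts(TP=tp, FP=co_clustered - tp, FN=related - tp)


def quality_metrics(counts: ConfusionCounts) -> QualityMetrics:
    """Sensitivity = TP/(TP+FN); precision = TP/(TP+FP); F = harmonic mean.

    Degenerate denominators use bounded conventions: sensitivity 1 when no
    related pairs exist, precision 1 when nothing is co-clustered, F 0 when
    sensitivity + precision is 0.
    """
    sens = counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN else 1.0
    prec = counts.TP / (counts.TP + counts.FP) if counts.TP + counts.FP else 1.0
    fm = 2 * sens * prec / (sens + prec) if sens + prec else 0.0
    return QualityMetrics(sensitivity=sens, precision=prec, f_measure=fm)


def pairwise_quality(
    truth: Mapping[Hashable, Hashable], predicted: Mapping[Hashable, Hashable]
) -> QualityMetrics:
    """Convenience: confusion counts then quality metrics, pairs pooled."""
    return quality_metrics(pair_confusion(truth, predicted))


def lengthwise_average_f(
    truth: Mapping[Hashable, Hashable],
    predicted: Mapping[Hashable, Hashable],
    length_of: Mapping[Hashable, int],
) -> float:
    """F-measure computed per junction-length group, averaged across groups
    (unweighted).  Used where per-length performance is summarised."""
    by_len: dict[int, list] = {}
    for sid in truth:
        by_len.setdefault(length_of[sid], []).append(sid)
    fs = []
    for ids in by_len.values():
        q = pairwise_quality(
            {i: truth[i] for i in ids}, {i: predicted[i] for i in ids}
        )
        fs.append(q.f_measure)
    return float(np.mean(fs))


def purity_metrics(
    predicted: Mapping[Hashable, Hashable], labels: Mapping[Hashable, Hashable]
) -> PurityMetrics:
    """Retention and fraction metrics against categorical labels.

    Singleton retention = singletons / total sequences; singleton fraction =
    singletons / total clusters; non-singleton retention = sequences in
    non-singleton pure clusters / total sequences; non-singleton fraction =
    non-singleton pure clusters / total clusters.  All as percentages.
    """
    missing = [i for i in predicted if i not in labels]
    if missing:
        raise ContractError(f"{len(missing)} clustered ids lack labels")
    members: dict[Hashable, list] = {}
    for sid, cid in predicted.items():
        members.setdefault(cid, []).append(sid)
    total_seqs = len(predicted)
    total_clusters = len(members)
    singletons = sum(1 for m in members.values() if len(m) == 1)
    pure_non_singleton = [
        m
        for m in members.values()
        if len(m) > 1 and len({labels[i] for i in m}) == 1
    ]
    seqs_in_pure_ns = sum(len(m) for m in pure_non_singleton)
    pct = lambda num, den: 100.0 * num / den if den else 0.0
    return PurityMetrics(
        singleton_retention=pct(singletons, total_seqs),
        singleton_fraction=pct(singletons, total_clusters),
        non_singleton_retention=pct(seqs_in_pure_ns, total_seqs),
        non_singleton_fraction=pct(len(pure_non_singleton), total_clusters),
    )
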