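"""Reading, validating and writing junction-sequence tables.

Input is either an AIRR Rearrangement TSV (default column names ``junction``,
``v_call``, ``j_call`` per the AIRR standard, overridable) or a plain FASTA of
junction sequences.  Validation uppercases sequences, drops records containing
ambiguous characters (anything outside A/C/G/T) with a count, and collapses
exact duplicates into a ``duplicate_map`` so they can be re-expanded when
cluster assignments are written.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, NamedTuple

import pandas as pd
from Bio import SeqIO

from .errors import ConfigurationError, ContractError, EmptyInputError

DEFAULT_COLUMNS: Mapping[str, str] = {
    "sequence_id": "sequence_id",
    "junction": "junction",
    "v_call": "v_call",
    "j_call": "j_call",
    "label": "label",
    "true_clone_id": "true_clone_id",
}

_VALID_JUNCTION = re.compile(r"^[ACGT]+$")


class SequenceRecord(NamedTuple):
    """One validated junction sequence with its annotations."""

    sequence_id: str
    junction: str
    v_calls: frozenset[str]
    j_calls: frozenset[str]
    label: str | None
    true_clone_id: str | None


@dataclass
class SequenceTable:
    """Validated, de-duplicated collection of junction sequences.

    ``df`` holds the retained records (columns: sequence_id, junction,
    junction_length, v_calls, j_calls, label, true_clone_id).
    ``duplicate_map`` maps each retained record's sequence_id to the ids of
    the exact duplicates collapsed into it.
    """

    df: pd.DataFrame
    duplicate_map: dict[str, list[str]] = field(default_factory=dict)
    n_input: int = 0
    n_ambiguous: int = 0

    @property
    def n_retained(self) -> int:
        return len(self.df)

    @property
    def n_duplicates(self) -> int:
        return sum(len(v) for v in self.duplicate_map.values())

    def records(self) -> Iterator[SequenceRecord]:
        for row in self.df.itertuples(index=False):
            yield SequenceRecord(
                row.sequence_id,
                row.junction,
                row.v_calls,
                row.j_calls,
                row.label,
                row.true_clone_id,
            )

    def check_conservation(self) -> None:
        """Input rows = retained + dropped ambiguous + collapsed duplicates."""
        if self.n_input != self.n_retained + self.n_ambiguous + self.n_duplicates:
            raise ContractError(
                "sequence accounting mismatch: "
                f"{self.n_input} != {self.n_retained} + {self.n_ambiguous} "
                f"+ {self.n_duplicates}"
            )


def _parse_calls(value) -> frozenset[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return frozenset()
    text = str(value).strip()
    if not text or text.lower() == "nan":
        return frozenset()
    return frozenset(part.strip() for part in text.split(",") if part.strip())


def table_from_frame(
    frame: pd.DataFrame, *, dedup: str = "vj_context"
) -> SequenceTable:
    """Validate a raw frame (columns as in ``SequenceTable.df`` but junction
    unvalidated) into a SequenceTable.

    ``dedup`` is either ``"vj_context"`` (duplicate = identical junction AND
    identical V/J call sets; lossless for VJ grouping) or ``"junction"``
    (junction only; matches data without gene annotations).
    """
    if dedup not in ("vj_context", "junction"):
        raise ConfigurationError(f"unknown dedup mode: {dedup!r}")
    n_input = len(frame)
    if n_input == 0:
        raise EmptyInputError("input contains no sequences")
    if frame["sequence_id"].duplicated().any():
        dupes = frame["sequence_id"][frame["sequence_id"].duplicated()].iloc[0]
        raise ContractError(f"duplicate sequence_id in input: {dupes!r}")

    frame = frame.copy()
    frame["junction"] = frame["junction"].astype(str).str.upper()
    valid = frame["junction"].str.fullmatch(_VALID_JUNCTION.pattern)
    n_ambiguous = int((~valid).sum())
    frame = frame[valid]
    if frame.empty:
        raise EmptyInputError("no sequences remain after removing ambiguous records")

    if dedup == "vj_context":
        key = [
            f"{j}|{'|'.join(sorted(v))}|{'|'.join(sorted(jj))}"
            for j, v, jj in zip(frame["junction"], frame["v_calls"], frame["j_calls"])
        ]
    else:
        key = list(frame["junction"])
    frame = frame.assign(_key=key)
    keep = ~frame["_key"].duplicated()
    duplicate_map: dict[str, list[str]] = {}
    if not keep.all():
        rep_of_key = dict(zip(frame.loc[keep, "_key"], frame.loc[keep, "sequence_id"]))
        for sid, k in zip(frame.loc[~keep, "sequence_id"], frame.loc[~keep, "_key"]):
            duplicate_map.setdefault(rep_of_key[k], []).append(sid)
    frame = frame[keep].drop(columns="_key")
    frame = frame.assign(junction_length=frame["junction"].str.len())
    frame = frame[
        [
            "sequence_id",
            "junction",
            "junction_length",
            "v_calls",
            "j_calls",
            "label",
            "true_clone_id",
        ]
    ].reset_index(drop=True)

    table = SequenceTable(
        df=frame,
        duplicate_map=duplicate_map,
        n_input=n_input,
        n_ambiguous=n_ambiguous,
    )
    table.check_conservation()
    return table


def read_repertoire(
    path: str | Path,
    format: str = "airr_tsv",
    column_map: Mapping[str, str] | None = None,
    *,
    dedup: str = "vj_context",
) -> SequenceTable:
    """Read and validate a repertoire from AIRR TSV or FASTA.

    Records with ambiguous characters (N or anything outside A/C/G/T) are
    dropped and counted; exact duplicates are collapsed into the table's
    ``duplicate_map``; comma-separated multi-valued gene calls are parsed
    into sets.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file does not exist: {path}")
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)

    if format == "airr_tsv":
        try:
            raw = pd.read_csv(path, sep="\t", dtype=str)
        except pd.errors.EmptyDataError:
            raise EmptyInputError(f"input file is empty: {path}") from None
        if cols["junction"] not in raw.columns:
            raise ConfigurationError(
                f"required junction column {cols['junction']!r} not found in {path}"
            )
        frame = pd.DataFrame(
            {
                "sequence_id": (
                    raw[cols["sequence_id"]].astype(str)
                    if cols["sequence_id"] in raw.columns
                    else [f"seq{i + 1}" for i in range(len(raw))]
                ),
                "junction": raw[cols["junction"]],
                "v_calls": [
                    _parse_calls(v)
                    for v in (
                        raw[cols["v_call"]]
                        if cols["v_call"] in raw.columns
                        else [None] * len(raw)
                    )
                ],
                "j_calls": [
                    _parse_calls(v)
                    for v in (
                        raw[cols["j_call"]]
                        if cols["j_call"] in raw.columns
                        else [None] * len(raw)
                    )
                ],
                "label": (
                    raw[cols["label"]]
                    if cols["label"] in raw.columns
                    else pd.Series([None] * len(raw), dtype=object)
                ),
                "true_clone_id": (
                    raw[cols["true_clone_id"]]
                    if cols["true_clone_id"] in raw.columns
                    else pd.Series([None] * len(raw), dtype=object)
                ),
            }
        )
    elif format == "fasta":
        ids, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.description or rec.id)
            seqs.append(str(rec.seq))
        frame = pd.DataFrame(
            {
                "sequence_id": ids,
                "junction": seqs,
                "v_calls": [frozenset()] * len(ids),
                "j_calls": [frozenset()] * len(ids),
                "label": pd.Series([None] * len(ids), dtype=object),
                "true_clone_id": pd.Series([None] * len(ids), dtype=object),
            }
        )
    else:
        raise ConfigurationError(f"unknown input format: {format!r}")

    if frame.empty:
        raise EmptyInputError(f"input file contains no sequences: {path}")
    return table_from_frame(frame, dedup=dedup)


def _calls_to_text(calls: frozenset[str]) -> str:
    return ",".join(sorted(calls))


def write_clusters(table: SequenceTable, result, path: str | Path) -> None:
    """Write per-sequence cluster assignments as TSV.

    Collapsed duplicates are re-expanded with the cluster id of their
    retained representative.  Raises ContractError if any retained sequence
    is unassigned.
    """
    assignment = result.assignment
    rows = []
    for rec in table.records():
        if rec.sequence_id not in assignment:
            raise ContractError(f"sequence {rec.sequence_id!r} has no cluster")
        cluster = assignment[rec.sequence_id]
        base = (
            rec.junction,
            len(rec.junction),
            _calls_to_text(rec.v_calls),
            _calls_to_text(rec.j_calls),
            cluster,
        )
        rows.append((rec.sequence_id, *base))
        for dup_id in table.duplicate_map.get(rec.sequence_id, ()):
            rows.append((dup_id, *base))
    out = pd.DataFrame(
        rows,
        columns=[
            "sequence_id",
            "junction",
            "junction_length",
            "v_calls",
            "j_calls",
            "cluster_id",
        ],
    )
    out.to_csv(path, sep="\t", index=False)


def write_airr(table: SequenceTable, path: str | Path) -> None:
    """Write a SequenceTable back to AIRR-style TSV (retained records only)."""
    out = pd.DataFrame(
        {
            "sequence_id": table.df["sequence_id"],
            "junction": table.df["junction"],
            "v_call": [_calls_to_text(v) for v in table.df["v_calls"]],
            "j_call": [_calls_to_text(v) for v in table.df["j_calls"]],
            "label": table.df["label"],
            "true_clone_id": table.df["true_clone_id"],
        }
    )
    out.to_csv(path, sep="\t", index=False)
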