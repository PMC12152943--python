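"""Readers and writers for the package's plain-text formats.

All tabular formats are CSV/TSV (delimiter inferred from the extension):
activity records ``compound_id,target_id,pchembl,standard_type``; binary
matrices with the compound id in the first column and 0/1 feature columns;
interactome edges and pathway membership as 2-column TSV; expression
filters as one id per line; transporter votes in long format
``compound_id,transporter,algorithm,prediction``; labels as
``compound_id,label``.  Matrix round-trips are lossless.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DataError
from .matrices import (
    ActivityRecord,
    BinaryMatrix,
    InteractomeMap,
    PathwayMembership,
    TransporterVoteTable,
)


def _sep(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_activity_records(path) -> list[ActivityRecord]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    required = {"compound_id", "target_id", "pchembl", "standard_type"}
    if not required <= set(df.columns):
        raise DataError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    return [
        ActivityRecord(
            str(r.compound_id), str(r.target_id), float(r.pchembl), str(r.standard_type)
        )
        for r in df.itertuples(index=False)
    ]


def write_activity_records(records: Iterable[ActivityRecord], path) -> None:
    path = Path(path)
    pd.DataFrame(
        [
            (r.compound_id, r.target_id, r.pchembl, r.standard_type)
            for r in records
        ],
        columns=["compound_id", "target_id", "pchembl", "standard_type"],
    ).to_csv(path, sep=_sep(path), index=False)


def read_binary_matrix(path, block_label: str) -> BinaryMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    df.index = df.index.astype(str)
    return BinaryMatrix(df, block_label)


def write_binary_matrix(m: BinaryMatrix, path) -> None:
    path = Path(path)
    out = m.frame.copy()
    out.index.name = "compound_id"
    out.to_csv(path, sep=_sep(path))


def read_interactome(path) -> InteractomeMap:
    edges: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise DataError(f"{path}: expected 2 tab-separated columns, got {line!r}")
        edges.setdefault(parts[0], set()).add(parts[1])
    return InteractomeMap(edges)


def write_interactome(im: InteractomeMap, path) -> None:
    lines = [
        f"{t}\t{i}" for t in sorted(im.edges) for i in sorted(im.edges[t])
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_membership(path) -> PathwayMembership:
    assignments: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise DataError(f"{path}: expected 2 tab-separated columns, got {line!r}")
        assignments.setdefault(parts[0], set()).add(parts[1])
    return PathwayMembership(assignments)


def write_membership(pm: PathwayMembership, path) -> None:
    lines = [
        f"{p}\t{pw}"
        for p in sorted(pm.assignments)
        for pw in sorted(pm.assignments[p])
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_id_list(path) -> set[str]:
    return {
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }


def write_id_list(ids: Iterable[str], path) -> None:
    ids = sorted(set(ids))
    Path(path).write_text("\n".join(ids) + ("\n" if ids else ""))


def read_transporter_votes(path) -> TransporterVoteTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    required = {"compound_id", "transporter", "algorithm", "prediction"}
    if not required <= set(df.columns):
        raise DataError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    votes: dict[tuple[str, str], list[int]] = {}
    for r in df.itertuples(index=False):
        votes.setdefault((str(r.compound_id), str(r.transporter)), []).append(
            int(r.prediction)
        )
    compounds = list(dict.fromkeys(str(c) for c in df["compound_id"]))
    transporters = list(dict.fromkeys(str(t) for t in df["transporter"]))
    return TransporterVoteTable(
        compound_ids=compounds, transporter_ids=transporters, votes=votes
    )


def write_transporter_votes(v: TransporterVoteTable, path) -> None:
    path = Path(path)
    rows = []
    for c in v.compound_ids:
        for t in v.transporter_ids:
            for i, vote in enumerate(v.votes[(c, t)]):
                rows.append((c, t, f"alg{i}", vote))
    pd.DataFrame(
        rows, columns=["compound_id", "transporter", "algorithm", "prediction"]
    ).to_csv(path, sep=_sep(path), index=False)


def read_labels(path) -> pd.Series:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    if not {"compound_id", "label"} <= set(df.columns):
        raise DataError(f"{path}: expected columns compound_id,label")
    s = pd.Series(
        df["label"].to_numpy(), index=df["compound_id"].astype(str), name="label"
    )
    if not set(np.unique(s)) <= {0, 1}:
        raise DataError(f"{path}: labels must be binary 0/1")
    return s.astype(int)


def write_labels(labels: pd.Series, path) -> None:
    path = Path(path)
    out = labels.rename("label").to_frame()
    out.index.name = "compound_id"
    out.to_csv(path, sep=_sep(path))
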