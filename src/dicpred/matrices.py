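"""Binary fingerprint matrices for compound bioactivity profiles.

A compound is described by binary blocks: which liver-expressed protein
targets it is active on, which pathways those targets (and their first-degree
interactome neighbours) belong to, which chemical substructure keys it
contains, and which hepatic transporters it is predicted to inhibit.  This
module builds, merges, deduplicates and characterises those blocks.

All matrices are pandas-backed: rows are compounds, columns are features,
cells are 0/1.  Feature provenance is carried by a ``block_label``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)

#: Valid fingerprint block labels; "combined" marks a concatenation of blocks.
BLOCK_LABELS = ("target", "pathway", "substructure", "transporter", "combined")

#: Activity standard types whose pChEMBL values are accepted.
STANDARD_TYPES = ("IC50", "EC50", "Ki", "Kd", "AC50", "Potency")

#: Hepatic transporters covered by the inhibition-prediction panel.
TRANSPORTERS = (
    "BCRP", "BSEP", "MATE1", "MDR1", "MRP3",
    "OATP1B1", "OATP1B3", "OCT1", "OCT2",
)


@dataclass(frozen=True)
class ActivityRecord:
    """One bioactivity measurement: compound vs target with a pChEMBL value.

    pChEMBL is -log10 of a molar potency (IC50, EC50, Ki, Kd, AC50 or
    Potency); 5.0 corresponds to 10 uM.
    """

    compound_id: str
    target_id: str
    pchembl: float
    standard_type: str = "IC50"

    def __post_init__(self) -> None:
        if not self.compound_id or not self.target_id:
            raise DataError("ActivityRecord ids must be non-empty")
        if self.standard_type not in STANDARD_TYPES:
            raise DataError(
                f"unknown standard_type {self.standard_type!r}; "
                f"expected one of {STANDARD_TYPES}"
            )


class BinaryMatrix:
    """Compounds x features 0/1 matrix with a block label.

    Parameters
    ----------
    frame
        DataFrame with compound ids as index, feature ids as columns and
        values in {0, 1}.  Ids must be unique along each axis.
    block_label
        One of :data:`BLOCK_LABELS`.
    """

    def __init__(self, frame: pd.DataFrame, block_label: str) -> None:
        if block_label not in BLOCK_LABELS:
            raise ParameterError(
                f"block_label {block_label!r} not in {BLOCK_LABELS}"
            )
        if frame.index.has_duplicates:
            raise DataError("duplicate compound ids in matrix")
        if frame.columns.has_duplicates:
            raise DataError("duplicate feature ids in matrix")
        values = frame.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            raise DataError("matrix values must be 0 or 1")
        self._frame = frame.astype(np.int8, copy=True)
        self._frame.index = frame.index.astype(str)
        self._frame.columns = frame.columns.astype(str)
        self._frame.index.name = "compound_id"
        self.block_label = block_label

    # -- container protocol -------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def compound_ids(self) -> list[str]:
        return list(self._frame.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self._frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self._frame.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._frame.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        r, c = self.shape
        return f"<BinaryMatrix[{self.block_label}] {r} compounds x {c} features>"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMatrix):
            return NotImplemented
        return (
            self.block_label == other.block_label
            and self._frame.equals(other._frame)
        )

    def subset(self, compound_ids: Sequence[str]) -> "BinaryMatrix":
        """Row-restrict to ``compound_ids``, preserving the given order."""
        missing = [c for c in compound_ids if c not in self._frame.index]
        if missing:
            raise DataError(f"compounds absent from matrix: {missing[:5]}")
        return BinaryMatrix(self._frame.loc[list(compound_ids)], self.block_label)


@dataclass
class InteractomeMap:
    """First-degree protein-protein interaction neighbours per target."""

    edges: dict[str, set[str]] = field(default_factory=dict)

    def interactors(self, target_id: str) -> set[str]:
        return self.edges.get(target_id, set())


@dataclass
class PathwayMembership:
    """Protein -> pathway assignments (e.g. Reactome membership)."""

    assignments: dict[str, set[str]] = field(default_factory=dict)

    def pathways(self, protein_id: str) -> set[str]:
        return self.assignments.get(protein_id, set())


@dataclass
class ExpressionFilter:
    """Liver-expressed gene and pathway id sets used as tissue filters."""

    liver_genes: set[str] = field(default_factory=set)
    liver_pathways: set[str] = field(default_factory=set)


@dataclass
class TransporterVoteTable:
    """Per-algorithm binary inhibition predictions per compound/transporter.

    ``votes[(compound_id, transporter)]`` is the list of per-algorithm
    predictions — five algorithms per transporter, four for OATP1B1 (the
    support-vector model is dropped there).
    """

    compound_ids: list[str]
    transporter_ids: list[str]
    votes: dict[tuple[str, str], list[int]]

    def __post_init__(self) -> None:
        for key, vlist in self.votes.items():
            if len(vlist) not in (4, 5):
                raise DataError(
                    f"vote list for {key} has length {len(vlist)}; expected 4 or 5"
                )
            if any(v not in (0, 1) for v in vlist):
                raise DataError(f"non-binary vote for {key}: {vlist}")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def binarize_activities(
    records: Iterable[ActivityRecord], threshold: float = 5.0
) -> BinaryMatrix:
    """Collapse bioactivity records into a binary compound-target matrix.

    For each compound-target pair the maximum reported pChEMBL value is
    taken (highest reported potency); the bit is set iff that maximum is
    at or above ``threshold`` (default 5.0, i.e. activity <= 10 uM).
    Pairs without any record are 0.
    """
    records = list(records)
    if not records:
        raise DataError("no activity records supplied")
    if not np.isfinite(threshold):
        raise ParameterError("threshold must be finite")
    for i, rec in enumerate(records):
        if not np.isfinite(rec.pchembl):
            raise DataError(
                f"non-finite pChEMBL in record {i} "
                f"({rec.compound_id}, {rec.target_id})"
            )
    compounds = list(dict.fromkeys(r.compound_id for r in records))
    targets = list(dict.fromkeys(r.target_id for r in records))
    best: dict[tuple[str, str], float] = {}
    for rec in records:
        key = (rec.compound_id, rec.target_id)
        prev = best.get(key)
        if prev is None or rec.pchembl > prev:
            best[key] = rec.pchembl
    frame = pd.DataFrame(0, index=compounds, columns=targets, dtype=np.int8)
    for (cid, tid), value in best.items():
        if value >= threshold:
            frame.loc[cid, tid] = 1
    return BinaryMatrix(frame, "target")


def filter_targets_by_tissue(
    m: BinaryMatrix, f: ExpressionFilter
) -> BinaryMatrix:
    """Restrict target columns to liver-expressed genes; rows are kept."""
    keep = [t for t in m.feature_ids if t in f.liver_genes]
    if not keep:
        warnings.warn(
            "tissue filter removed every target column", stacklevel=2
        )
    return BinaryMatrix(m.frame[keep], m.block_label)


def merge_predicted_targets(
    known: BinaryMatrix,
    tool_predictions: Sequence[BinaryMatrix],
    min_tools: int,
) -> BinaryMatrix:
    """OR known targets with tool predictions supported by >= ``min_tools``.

    ``min_tools=1`` is the "+all" setting (any tool suffices), 2 and 3 the
    two- and three-tool consensus settings.  Known interactions are always
    kept; the feature axis is the union of all target ids, the compound axis
    the union of all compound ids (outer alignment).
    """
    if not 1 <= min_tools <= len(tool_predictions):
        raise ParameterError(
            f"min_tools={min_tools} outside [1, {len(tool_predictions)}]"
        )
    compounds = list(known.compound_ids)
    targets = list(known.feature_ids)
    for tool in tool_predictions:
        compounds += [c for c in tool.compound_ids if c not in set(compounds)]
        targets += [t for t in tool.feature_ids if t not in set(targets)]
    known_a = known.frame.reindex(index=compounds, columns=targets, fill_value=0)
    support = sum(
        tool.frame.reindex(index=compounds, columns=targets, fill_value=0).astype(int)
        for tool in tool_predictions
    )
    merged = ((known_a == 1) | (support >= min_tools)).astype(np.int8)
    return BinaryMatrix(merged, "target")


def derive_pathway_matrix(
    m: BinaryMatrix,
    im: InteractomeMap,
    pm: PathwayMembership,
    f: ExpressionFilter,
    include_direct: bool = True,
) -> BinaryMatrix:
    """Expand a compound-target matrix into a compound-pathway matrix.

    For each compound the relevant protein set is its active targets plus
    all first-degree interactome neighbours of those targets; the compound
    hits a pathway iff any protein in that set is assigned to it and the
    pathway passes the liver-expression filter.

    ``include_direct=False`` drops the direct targets' own pathway
    assignments and propagates through interactors only.
    """
    pathway_universe = sorted(
        {p for ps in pm.assignments.values() for p in ps} & f.liver_pathways
    )
    frame = pd.DataFrame(
        0, index=m.compound_ids, columns=pathway_universe, dtype=np.int8
    )
    values = m.values
    targets = m.feature_ids
    for i, cid in enumerate(m.compound_ids):
        active = [targets[j] for j in np.flatnonzero(values[i])]
        proteins: set[str] = set()
        for t in active:
            proteins |= im.interactors(t)
            if include_direct:
                proteins.add(t)
        hit: set[str] = set()
        for p in proteins:
            hit |= pm.pathways(p)
        for pathway in hit & f.liver_pathways:
            frame.loc[cid, pathway] = 1
    return BinaryMatrix(frame, "pathway")


def transporter_consensus(
    v: TransporterVoteTable, min_votes: int = 3
) -> BinaryMatrix:
    """Per-transporter inhibition call: active iff >= ``min_votes`` of the
    per-algorithm predictions vote active (default 3)."""
    frame = pd.DataFrame(
        0, index=v.compound_ids, columns=v.transporter_ids, dtype=np.int8
    )
    for cid in v.compound_ids:
        for tid in v.transporter_ids:
            vlist = v.votes.get((cid, tid))
            if not vlist:
                raise DataError(f"empty vote list for ({cid}, {tid})")
            if sum(vlist) >= min_votes:
                frame.loc[cid, tid] = 1
    return BinaryMatrix(frame, "transporter")


def concat_blocks(blocks: Sequence[BinaryMatrix]) -> BinaryMatrix:
    """Column-concatenate fingerprint blocks over their common compounds.

    Compounds are the intersection of all block compound sets in the first
    block's order; feature ids are prefixed with their block label so a
    protein id reused as a pathway key cannot collide.
    """
    if not blocks:
        raise ParameterError("no blocks to concatenate")
    common = set(blocks[0].compound_ids)
    for b in blocks[1:]:
        common &= set(b.compound_ids)
    if not common:
        raise DataError("blocks share no compounds")
    dropped = len(set().union(*(b.compound_ids for b in blocks))) - len(common)
    if dropped:
        logger.info("concat_blocks dropped %d compounds absent from some block", dropped)
    order = [c for c in blocks[0].compound_ids if c in common]
    pieces = []
    for b in blocks:
        piece = b.frame.loc[order]
        piece = piece.rename(columns=lambda f, lb=b.block_label: f"{lb}:{f}")
        pieces.append(piece)
    merged = pd.concat(pieces, axis=1)
    label = blocks[0].block_label if len(blocks) == 1 else "combined"
    return BinaryMatrix(merged, label)


def _duplicated_compounds(m: BinaryMatrix) -> set[str]:
    dup = m.frame.duplicated(keep=False)
    return set(m.frame.index[dup])


def unique_across(
    target_m: BinaryMatrix,
    pathway_m: BinaryMatrix,
    substructure_m: BinaryMatrix,
) -> set[str]:
    """Compounds whose fingerprint row is unique in all three descriptor
    spaces (target, pathway, substructure), checked per space.

    A duplicate row in any single space disqualifies both members of the
    duplicate pair; the nine-bit transporter block is never consulted.
    """
    common = (
        set(target_m.compound_ids)
        & set(pathway_m.compound_ids)
        & set(substructure_m.compound_ids)
    )
    excluded: set[str] = set()
    for m in (target_m, pathway_m, substructure_m):
        excluded |= _duplicated_compounds(m)
    return common - excluded


def coverage(m: BinaryMatrix) -> float:
    """Matrix coverage: set bits over total possible interactions
    (compounds x features), as a fraction in [0, 1]."""
    rows, cols = m.shape
    if rows == 0 or cols == 0:
        raise DataError("coverage undefined for a degenerate matrix")
    return float(m.values.sum()) / (rows * cols)
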