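"""Seeded synthetic fixtures with the statistical structure the method assumes.

The generators emulate what the real cholestasis data looks like to the
pipeline: an imbalanced two-class compound set (~3.3 negatives per
positive), sparse binary fingerprint blocks whose background densities
mirror the observed block coverages, a handful of class-informative bits
with presence-rate gaps like 0.40 vs 0.22, toy interactome/pathway maps and
per-algorithm transporter votes.  Every generator is a pure function of its
spec and seed, and where an operation needs an oracle the generator also
returns the expected output computed by independent brute force.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .matrices import (
    TRANSPORTERS,
    ActivityRecord,
    BinaryMatrix,
    ExpressionFilter,
    InteractomeMap,
    PathwayMembership,
    TransporterVoteTable,
)
from .resampling import LabeledDataset

#: Default class sizes: the study's 3.26:1 imbalance at quarter scale.
DEFAULT_N_POS = 53
DEFAULT_N_NEG = 172

#: Default block sizes: quarter-scale versions of the real fingerprint
#: lengths (targets 1079, pathways 2051, substructure keys 881,
#: transporters 9), with background bit rates matching the observed
#: per-block coverages.
DEFAULT_BLOCKS = (
    ("target", 270, 0.01),
    ("pathway", 512, 0.114),
    ("substructure", 220, 0.145),
    ("transporter", 9, 0.07),
)

#: Default class-informative bits: presence-rate pairs copied from the
#: top-ranked real descriptors (two pathways, two targets).
DEFAULT_INFORMATIVE = (
    ("pathway", 0.69, 0.47, 1),
    ("pathway", 0.55, 0.33, 1),
    ("target", 0.40, 0.22, 1),
    ("target", 0.21, 0.08, 1),
)


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the binary-fingerprint dataset generator.

    ``blocks`` lists (block_label, n_features, background_rate);
    ``informative`` lists (block_label, rate_pos, rate_neg, count) — those
    features are drawn with class-conditional Bernoulli rates and replace
    the first ``count`` background features of their block.
    """

    n_pos: int = DEFAULT_N_POS
    n_neg: int = DEFAULT_N_NEG
    blocks: tuple = DEFAULT_BLOCKS
    informative: tuple = DEFAULT_INFORMATIVE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ParameterError("need at least one compound per class")
        for label, n, rate in self.blocks:
            if not 0.0 <= rate <= 1.0:
                raise ParameterError(f"background rate {rate} outside [0, 1]")
            if n < 1:
                raise ParameterError(f"block {label!r} must have >= 1 feature")
        counts: dict[str, int] = {}
        sizes = {label: n for label, n, _ in self.blocks}
        for label, rp, rn, count in self.informative:
            if not (0.0 <= rp <= 1.0 and 0.0 <= rn <= 1.0):
                raise ParameterError("informative rates must lie in [0, 1]")
            if label not in sizes:
                raise ParameterError(f"informative block {label!r} not declared")
            counts[label] = counts.get(label, 0) + count
        for label, c in counts.items():
            if c > sizes[label]:
                raise ParameterError(
                    f"block {label!r} has {sizes[label]} features but "
                    f"{c} informative bits requested"
                )

    def informative_feature_ids(self) -> list[str]:
        """Ids of the planted class-informative features, in order."""
        ids = []
        next_slot: dict[str, int] = {}
        for label, _rp, _rn, count in self.informative:
            start = next_slot.get(label, 0)
            ids += [f"{label}:inf{start + i}" for i in range(count)]
            next_slot[label] = start + count
        return ids


def make_binary_dataset(spec: GeneratorSpec) -> LabeledDataset:
    """Draw an imbalanced labelled binary dataset from ``spec``.

    Every bit is an independent Bernoulli draw: class-conditional rates for
    the informative features, the block background rate otherwise.
    Compound order interleaves the classes deterministically.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    y = np.array([1] * spec.n_pos + [0] * spec.n_neg)
    perm = rng.permutation(n)
    y = y[perm]
    compound_ids = [f"c{i:04d}" for i in range(n)]

    inf_per_block: dict[str, list[tuple[float, float]]] = {}
    for label, rp, rn, count in spec.informative:
        inf_per_block.setdefault(label, []).extend([(rp, rn)] * count)

    columns: list[str] = []
    pieces: list[np.ndarray] = []
    for label, n_features, background in spec.blocks:
        planted = inf_per_block.get(label, [])
        for i, (rp, rn) in enumerate(planted):
            rates = np.where(y == 1, rp, rn)
            pieces.append((rng.random(n) < rates).astype(np.int8)[:, None])
            columns.append(f"{label}:inf{i}")
        n_noise = n_features - len(planted)
        if n_noise:
            pieces.append(
                (rng.random((n, n_noise)) < background).astype(np.int8)
            )
            columns += [f"{label}:f{i}" for i in range(n_noise)]
    X = pd.DataFrame(
        np.hstack(pieces), index=compound_ids, columns=columns, dtype=np.int8
    )
    labels = pd.Series(y, index=compound_ids, dtype=int)
    return LabeledDataset(
        X.astype(float), labels, provenance=f"synthetic(seed={spec.seed})"
    )


def make_activity_records(
    n_compounds: int = 20,
    n_targets: int = 10,
    density: float = 0.3,
    pchembl_range: tuple[float, float] = (3.0, 9.0),
    seed: int = 0,
) -> tuple[list[ActivityRecord], BinaryMatrix]:
    """Random bioactivity records plus their expected binarization.

    Roughly ``density`` of the compound-target pairs receive a record with
    a uniform pChEMBL value; a third of those pairs get a second record
    with a different value, so max-aggregation is exercised.  The expected
    matrix (bit = 1 iff the pair's maximum pChEMBL >= 5) is computed here
    by direct enumeration and returned for oracle tests.
    """
    if not 0.0 < density <= 1.0:
        raise ParameterError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    lo, hi = pchembl_range
    records: list[ActivityRecord] = []
    best: dict[tuple[str, str], float] = {}
    stypes = ("IC50", "EC50", "Ki", "Kd", "AC50", "Potency")
    for i in range(n_compounds):
        cid = f"c{i:03d}"
        for j in range(n_targets):
            tid = f"T{j:03d}"
            if rng.random() >= density:
                continue
            n_rec = 2 if rng.random() < 1 / 3 else 1
            for _ in range(n_rec):
                val = float(rng.uniform(lo, hi))
                records.append(
                    ActivityRecord(cid, tid, val, stypes[int(rng.integers(6))])
                )
                key = (cid, tid)
                if key not in best or val > best[key]:
                    best[key] = val
    compounds = list(dict.fromkeys(r.compound_id for r in records))
    targets = list(dict.fromkeys(r.target_id for r in records))
    frame = pd.DataFrame(0, index=compounds, columns=targets, dtype=np.int8)
    for (cid, tid), val in best.items():
        if val >= 5.0:
            frame.loc[cid, tid] = 1
    return records, BinaryMatrix(frame, "target")


@dataclass
class InteractomeFixture:
    target_matrix: BinaryMatrix
    interactome: InteractomeMap
    membership: PathwayMembership
    expression: ExpressionFilter
    expected_pathways: BinaryMatrix


def make_interactome_fixture(
    n_targets: int = 6,
    n_interactors: int = 8,
    n_pathways: int = 5,
    n_compounds: int = 8,
    seed: int = 0,
    liver_fraction: float = 0.8,
) -> InteractomeFixture:
    """Small random target matrix + interactome/pathway maps + expected
    pathway matrix computed by brute-force set expansion.

    The brute force walks, for every compound, its active targets, adds
    every first-degree interactor, collects all pathway assignments of the
    resulting protein set and keeps the liver-expressed ones.
    """
    if min(n_targets, n_interactors, n_pathways, n_compounds) < 1:
        raise ParameterError("fixture sizes must be >= 1")
    rng = np.random.default_rng(seed)
    targets = [f"T{i}" for i in range(n_targets)]
    interactors = [f"I{i}" for i in range(n_interactors)]
    pathways = [f"P{i}" for i in range(n_pathways)]
    compounds = [f"c{i}" for i in range(n_compounds)]

    tm = pd.DataFrame(
        (rng.random((n_compounds, n_targets)) < 0.4).astype(np.int8),
        index=compounds, columns=targets,
    )
    target_matrix = BinaryMatrix(tm, "target")

    edges = {
        t: {i for i in interactors if rng.random() < 0.3} for t in targets
    }
    proteins = targets + interactors
    assignments = {
        p: {pw for pw in pathways if rng.random() < 0.4} for p in proteins
    }
    liver_pathways = {pw for pw in pathways if rng.random() < liver_fraction}
    expression = ExpressionFilter(
        liver_genes=set(targets), liver_pathways=liver_pathways
    )

    # brute-force expected matrix
    pathway_universe = sorted(
        {p for ps in assignments.values() for p in ps} & liver_pathways
    )
    expected = pd.DataFrame(
        0, index=compounds, columns=pathway_universe, dtype=np.int8
    )
    for c in compounds:
        protein_set: set[str] = set()
        for t in targets:
            if tm.loc[c, t] == 1:
                protein_set.add(t)
                protein_set |= edges[t]
        for p in protein_set:
            for pw in assignments.get(p, set()):
                if pw in liver_pathways:
                    expected.loc[c, pw] = 1
    return InteractomeFixture(
        target_matrix=target_matrix,
        interactome=InteractomeMap(edges),
        membership=PathwayMembership(assignments),
        expression=expression,
        expected_pathways=BinaryMatrix(expected, "pathway"),
    )


def make_transporter_votes(
    n_compounds: int = 10, seed: int = 0, active_rate: float = 0.3
) -> tuple[TransporterVoteTable, BinaryMatrix]:
    """Random per-algorithm transporter votes plus expected >=3-vote
    consensus bits.

    Nine transporters with five algorithm votes each, except OATP1B1 which
    has four (its support-vector model is dropped).
    """
    if n_compounds < 1:
        raise ParameterError("need at least one compound")
    rng = np.random.default_rng(seed)
    compounds = [f"c{i:03d}" for i in range(n_compounds)]
    votes: dict[tuple[str, str], list[int]] = {}
    expected = pd.DataFrame(0, index=compounds, columns=list(TRANSPORTERS), dtype=np.int8)
    for c in compounds:
        for t in TRANSPORTERS:
            n_alg = 4 if t == "OATP1B1" else 5
            vlist = [int(rng.random() < active_rate) for _ in range(n_alg)]
            votes[(c, t)] = vlist
            if vlist.count(1) >= 3:
                expected.loc[c, t] = 1
    table = TransporterVoteTable(
        compound_ids=compounds, transporter_ids=list(TRANSPORTERS), votes=votes
    )
    return table, BinaryMatrix(expected, "transporter")
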