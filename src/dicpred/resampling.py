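"""Stratified splitting and class balancing for imbalanced compound sets.

Cholestasis data is dominated by negatives (roughly 3.3:1).  Two balancing
strategies are provided, both applied to training data only:

* SMOTE oversampling — synthetic minority compounds interpolated between a
  minority row and one of its k nearest minority neighbours (Euclidean),
  until the classes are 1:1.
* Undersampling into subsets — the majority class is partitioned uniformly
  at random into ``n_subsets`` disjoint near-equal parts, each paired with
  the full minority class; one submodel is later trained per part.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .errors import DataError, ParameterError
from .matrices import BinaryMatrix

POSITIVE, NEGATIVE = 1, 0


@dataclass
class LabeledDataset:
    """Feature matrix plus binary cholestasis labels (1 = positive).

    ``X`` may contain fractional values after SMOTE; labels are aligned to
    ``X.index``.  ``provenance`` is a free-text audit tag.
    """

    X: pd.DataFrame
    y: pd.Series
    provenance: str = ""

    def __post_init__(self) -> None:
        self.y = self.y.reindex(self.X.index)
        if self.y.isna().any():
            raise DataError("labels missing for some compounds")
        if not set(self.y.unique()) <= {0, 1}:
            raise DataError("labels must be binary 0/1")
        self.y = self.y.astype(int)

    @classmethod
    def from_matrix(
        cls, m: BinaryMatrix, labels: pd.Series, provenance: str = ""
    ) -> "LabeledDataset":
        return cls(m.frame.astype(float), labels, provenance)

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.X.index)

    def class_ids(self, label: int) -> list[str]:
        return list(self.X.index[self.y == label])

    @property
    def n_positive(self) -> int:
        return int((self.y == POSITIVE).sum())

    @property
    def n_negative(self) -> int:
        return int((self.y == NEGATIVE).sum())

    def subset(self, ids: list[str], provenance: Optional[str] = None) -> "LabeledDataset":
        return LabeledDataset(
            self.X.loc[ids], self.y.loc[ids],
            self.provenance if provenance is None else provenance,
        )


@dataclass
class SplitResult:
    train: LabeledDataset
    test: LabeledDataset
    seed: int

    def manifest(self) -> pd.DataFrame:
        """Two-column table ``compound_id,partition`` for reproducibility."""
        rows = [(c, "train") for c in self.train.compound_ids]
        rows += [(c, "test") for c in self.test.compound_ids]
        return pd.DataFrame(rows, columns=["compound_id", "partition"])


def _train_quota(class_sizes: dict[int, int], train_fraction: float) -> dict[int, int]:
    """Largest-remainder apportionment of the per-class train counts.

    Total train size is floor(fraction * N); each class gets floor of its
    quota and the leftover seats go to the largest fractional remainders
    (ties to the larger class, then to the positive class, for determinism).
    """
    total = int(np.floor(train_fraction * sum(class_sizes.values())))
    quotas = {c: train_fraction * n for c, n in class_sizes.items()}
    alloc = {c: int(np.floor(q)) for c, q in quotas.items()}
    leftover = total - sum(alloc.values())
    order = sorted(
        class_sizes,
        key=lambda c: (quotas[c] - alloc[c], class_sizes[c], c),
        reverse=True,
    )
    for c in order[:leftover]:
        alloc[c] += 1
    return alloc


def stratified_split(
    d: LabeledDataset, train_fraction: float = 0.8, seed: int = 0
) -> SplitResult:
    """Stratified train/test split on the cholestasis classes.

    The train set holds floor(fraction * N) compounds, apportioned to the
    classes by largest remainder so per-class counts never deviate from
    fraction * class_size by more than one; membership within a class is
    random under ``seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ParameterError("train_fraction must lie in (0, 1)")
    sizes = {POSITIVE: d.n_positive, NEGATIVE: d.n_negative}
    if min(sizes.values()) == 0:
        raise DataError("both classes must be present for a stratified split")
    alloc = _train_quota(sizes, train_fraction)
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for label in (NEGATIVE, POSITIVE):
        ids = np.array(d.class_ids(label))
        rng.shuffle(ids)
        train_ids += list(ids[: alloc[label]])
        test_ids += list(ids[alloc[label]:])
    # keep original dataset order for readability of manifests
    order = {c: i for i, c in enumerate(d.compound_ids)}
    train_ids.sort(key=order.__getitem__)
    test_ids.sort(key=order.__getitem__)
    return SplitResult(
        train=d.subset(train_ids, provenance=f"{d.provenance}|train"),
        test=d.subset(test_ids, provenance=f"{d.provenance}|test"),
        seed=seed,
    )


def smote_oversample(
    d: LabeledDataset, k_neighbors: int = 5, seed: int = 0
) -> LabeledDataset:
    """Oversample the minority class to parity with synthetic interpolants.

    Each synthetic compound lies on the segment between a randomly chosen
    minority row and one of its ``k_neighbors`` nearest minority neighbours
    (Euclidean distance); coordinates may therefore be fractional.
    Originals are preserved unchanged.  Returns the input untouched when the
    classes are already balanced.
    """
    n_pos, n_neg = d.n_positive, d.n_negative
    if n_pos == n_neg:
        return d
    minority = POSITIVE if n_pos < n_neg else NEGATIVE
    n_min, n_maj = min(n_pos, n_neg), max(n_pos, n_neg)
    if n_min <= k_neighbors:
        raise DataError(
            f"minority class has {n_min} members, not enough for "
            f"k_neighbors={k_neighbors}; reduce k"
        )
    Xmin = d.X.loc[d.y == minority].to_numpy(dtype=float)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xmin)
    # first neighbour is the point itself
    neigh = nn.kneighbors(Xmin, return_distance=False)[:, 1:]
    rng = np.random.default_rng(seed)
    n_new = n_maj - n_min
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k_neighbors, size=n_new)
    gap = rng.uniform(0.0, 1.0, size=n_new)
    synthetic = Xmin[base] + gap[:, None] * (Xmin[neigh[base, pick]] - Xmin[base])
    syn_ids = [f"smote_{i}" for i in range(n_new)]
    X_out = pd.concat(
        [d.X.astype(float), pd.DataFrame(synthetic, index=syn_ids, columns=d.X.columns)]
    )
    y_out = pd.concat(
        [d.y, pd.Series(minority, index=syn_ids, dtype=int)]
    )
    return LabeledDataset(X_out, y_out, provenance=f"{d.provenance}|smote(k={k_neighbors},seed={seed})")


def undersample_subsets(
    d: LabeledDataset, n_subsets: int = 4, seed: int = 0
) -> list[LabeledDataset]:
    """Partition the majority class into disjoint near-equal random subsets,
    each paired with the full minority class.

    Subset sizes differ by at most one and their union recovers the
    majority class exactly.  When majority/n_subsets is smaller than the
    minority class the per-subset imbalance inverts; no correction is made.
    """
    if n_subsets < 1:
        raise ParameterError("n_subsets must be >= 1")
    majority = NEGATIVE if d.n_negative >= d.n_positive else POSITIVE
    maj_ids = np.array(d.class_ids(majority))
    min_ids = d.class_ids(1 - majority)
    if len(maj_ids) < n_subsets:
        raise DataError(
            f"majority class ({len(maj_ids)}) smaller than n_subsets={n_subsets}"
        )
    rng = np.random.default_rng(seed)
    rng.shuffle(maj_ids)
    parts = np.array_split(maj_ids, n_subsets)
    order = {c: i for i, c in enumerate(d.compound_ids)}
    out = []
    for i, part in enumerate(parts):
        ids = sorted(list(part) + min_ids, key=order.__getitem__)
        out.append(d.subset(ids, provenance=f"{d.provenance}|us{i}(seed={seed})"))
    return out
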