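"""Consensus classifiers over balanced training subsets.

Three decision rules are implemented:

* 4-submodel undersampling consensus — one probabilistic classifier per
  majority-class subset; a compound is active when 3 or 4 submodels vote
  active at the 0.5 threshold, inactive at 0 or 1 votes, and a 2-2 tie is
  resolved by the mean of the four probabilities (>= 0.5 -> active).
* 9-model expanded consensus — the 4 gradient-boosting and 4 random-forest
  undersampling submodels plus the better of the two SMOTE-trained models;
  active iff at least 5 of the 9 vote active.
* Probability-range filtering — predictions whose mean probability falls in
  [0.35, 0.65] (inclusive) are set aside as uncertain; retained labels are
  re-derived from the mean probability alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier

from .errors import DataError, ParameterError
from .resampling import (
    LabeledDataset,
    smote_oversample,
    undersample_subsets,
)

ALGORITHMS = ("random_forest", "gradient_boosting")

#: Probability at or above which a single model votes "active".
VOTE_THRESHOLD = 0.5


@dataclass(frozen=True)
class LearnerSpec:
    """Algorithm choice plus hyperparameters and seed for one base learner."""

    algorithm: str = "gradient_boosting"
    hyperparameters: tuple = ()  # tuple of (key, value) pairs; hashable
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ParameterError(
                f"algorithm {self.algorithm!r} not in {ALGORITHMS}"
            )

    @property
    def params(self) -> dict:
        return dict(self.hyperparameters)

    def build(self, seed: Optional[int] = None):
        """Instantiate an unfitted sklearn estimator for this spec."""
        rs = (self.seed if seed is None else seed) % (2**31)
        if self.algorithm == "random_forest":
            return RandomForestClassifier(random_state=rs, **self.params)
        return GradientBoostingClassifier(random_state=rs, **self.params)


@dataclass
class PredictionSet:
    """Per-compound consensus output.

    ``frame`` columns: ``mean_probability`` (mean of member probabilities,
    always stored), ``active_votes`` (members voting active at 0.5),
    ``label`` (1 active / 0 inactive) and ``excluded`` (set by the
    probability-range filter).
    """

    frame: pd.DataFrame
    n_members: int

    @property
    def compound_ids(self) -> list[str]:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.insert(2, "label_name", np.where(out["label"] == 1, "active", "inactive"))
        out.index.name = "compound_id"
        out.to_csv(path)


def _positive_probabilities(estimator, X: pd.DataFrame) -> np.ndarray:
    proba = estimator.predict_proba(X.to_numpy(dtype=float))
    classes = list(estimator.classes_)
    if 1 not in classes:
        return np.zeros(len(X))
    return proba[:, classes.index(1)]


def _check_features(feature_ids: Sequence[str], X: pd.DataFrame) -> pd.DataFrame:
    missing = [f for f in feature_ids if f not in X.columns]
    extra = [f for f in X.columns if f not in set(feature_ids)]
    if missing or extra:
        raise DataError(
            f"feature space mismatch: missing={missing[:5]} extra={extra[:5]}"
        )
    return X[list(feature_ids)]


@dataclass
class SubsetEnsemble:
    """Four classifiers, one per majority-class undersampling subset."""

    submodels: list
    spec: LearnerSpec
    feature_ids: list[str]
    subset_manifest: list[list[str]]  # compound ids per training subset

    def __post_init__(self) -> None:
        if len(self.submodels) != 4:
            raise DataError(f"subset ensemble needs 4 submodels, got {len(self.submodels)}")

    def member_probabilities(self, X: pd.DataFrame) -> np.ndarray:
        """(n_compounds, 4) positive-class probabilities."""
        X = _check_features(self.feature_ids, X)
        return np.column_stack(
            [_positive_probabilities(m, X) for m in self.submodels]
        )


@dataclass
class ExpandedConsensus:
    """Nine members: 4 US-GB + 4 US-RF + the best SMOTE-trained model."""

    members: list
    feature_ids: list[str]
    member_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.members) != 9:
            raise DataError(f"expanded consensus needs 9 members, got {len(self.members)}")

    def member_probabilities(self, X: pd.DataFrame) -> np.ndarray:
        X = _check_features(self.feature_ids, X)
        return np.column_stack(
            [_positive_probabilities(m, X) for m in self.members]
        )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _fit_one(spec: LearnerSpec, subset: LabeledDataset, seed: int):
    if subset.n_positive == 0 or subset.n_negative == 0:
        raise DataError(
            f"training subset {subset.provenance!r} contains a single class"
        )
    est = spec.build(seed=seed)
    est.fit(subset.X.to_numpy(dtype=float), subset.y.to_numpy())
    return est


def fit_subset_ensemble(
    subsets: Sequence[LabeledDataset], spec: LearnerSpec
) -> SubsetEnsemble:
    """Train one classifier per undersampling subset (exactly four)."""
    subsets = list(subsets)
    if len(subsets) != 4:
        raise ParameterError(f"expected 4 subsets, got {len(subsets)}")
    feature_ids = list(subsets[0].X.columns)
    submodels = [
        _fit_one(spec, s, (spec.seed * 131 + i) % (2**31))
        for i, s in enumerate(subsets)
    ]
    return SubsetEnsemble(
        submodels=submodels,
        spec=spec,
        feature_ids=feature_ids,
        subset_manifest=[s.compound_ids for s in subsets],
    )


def _consensus_from_probabilities(
    probs: np.ndarray, rule: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply a vote rule to an (n, members) probability matrix.

    Returns (mean_probability, active_votes, label).  ``rule`` is "us4"
    (>=3 active, <=1 inactive, 2-2 tie by mean probability) or "majority5of9".
    """
    votes = (probs >= VOTE_THRESHOLD).sum(axis=1)
    mean = probs.mean(axis=1)
    if rule == "us4":
        label = np.where(
            votes >= 3, 1, np.where(votes <= 1, 0, (mean >= VOTE_THRESHOLD).astype(int))
        )
    elif rule == "majority5of9":
        label = (votes >= 5).astype(int)
    else:  # pragma: no cover - internal
        raise ParameterError(f"unknown rule {rule!r}")
    return mean, votes, label


def predict_us_consensus(e: SubsetEnsemble, X: pd.DataFrame) -> PredictionSet:
    """4-submodel consensus: active at 3-4 votes, inactive at 0-1, and the
    2-2 tie decided by the mean of all four probabilities (>= 0.5)."""
    probs = e.member_probabilities(X)
    mean, votes, label = _consensus_from_probabilities(probs, "us4")
    frame = pd.DataFrame(
        {
            "mean_probability": mean,
            "active_votes": votes,
            "label": label,
            "excluded": False,
        },
        index=X.index,
    )
    return PredictionSet(frame=frame, n_members=4)


def fit_expanded_consensus(
    train: LabeledDataset,
    gb_spec: LearnerSpec = LearnerSpec("gradient_boosting"),
    rf_spec: LearnerSpec = LearnerSpec("random_forest"),
    smote_spec: Optional[LearnerSpec] = None,
    seed: int = 0,
    n_subsets: int = 4,
    smote_k: int = 5,
    shared_partition: bool = True,
    smote_selection_folds: int = 5,
) -> ExpandedConsensus:
    """Build the 9-member consensus on one training set.

    The majority class is partitioned once (shared between the GB and RF
    families by default), giving 4 GB and 4 RF submodels; the ninth member
    is the SMOTE-trained model — GB or RF, whichever scores the higher
    pooled balanced accuracy in an internal stratified CV on the
    (unbalanced) training set with SMOTE applied inside each fold.
    """
    if train.n_positive == 0 or train.n_negative == 0:
        raise DataError("training set must contain both classes")
    subsets = undersample_subsets(train, n_subsets=n_subsets, seed=seed)
    gb = fit_subset_ensemble(subsets, LearnerSpec("gradient_boosting", gb_spec.hyperparameters, seed=gb_spec.seed))
    if not shared_partition:
        subsets = undersample_subsets(train, n_subsets=n_subsets, seed=seed + 1)
    rf = fit_subset_ensemble(subsets, LearnerSpec("random_forest", rf_spec.hyperparameters, seed=rf_spec.seed))

    smote_member, smote_name = _best_smote_model(
        train, seed=seed, k_neighbors=smote_k,
        hyperparameters=() if smote_spec is None else smote_spec.hyperparameters,
        n_folds=smote_selection_folds,
    )
    members = gb.submodels + rf.submodels + [smote_member]
    names = [f"US_GB_{i}" for i in range(4)] + [f"US_RF_{i}" for i in range(4)]
    names.append(smote_name)
    return ExpandedConsensus(
        members=members, feature_ids=gb.feature_ids, member_names=names
    )


def _best_smote_model(
    train: LabeledDataset,
    seed: int,
    k_neighbors: int,
    hyperparameters: tuple,
    n_folds: int = 5,
):
    """Train GB and RF on the SMOTE-balanced set; keep the one with the
    higher CV balanced accuracy (computed with SMOTE inside each fold)."""
    from .evaluation import compute_metrics, confusion
    from sklearn.model_selection import StratifiedKFold

    scores = {}
    n_folds = min(n_folds, train.n_positive, train.n_negative)
    for alg in ("gradient_boosting", "random_forest"):
        spec = LearnerSpec(alg, hyperparameters, seed=seed)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
        ids = np.array(train.compound_ids)
        y = train.y.to_numpy()
        y_true, y_pred = [], []
        for fold, (tr, te) in enumerate(skf.split(ids, y)):
            fold_train = smote_oversample(
                train.subset(list(ids[tr])), k_neighbors=k_neighbors,
                seed=(seed * 7919 + fold) % (2**31),
            )
            est = _fit_one(spec, fold_train, (seed * 104729 + fold) % (2**31))
            p = _positive_probabilities(est, train.X.loc[ids[te]])
            y_true += list(y[te])
            y_pred += list((p >= VOTE_THRESHOLD).astype(int))
        m = compute_metrics(confusion(y_true, y_pred))
        scores[alg] = m.balanced_accuracy
    best = max(scores, key=lambda a: (scores[a], a))
    balanced = smote_oversample(train, k_neighbors=k_neighbors, seed=seed)
    spec = LearnerSpec(best, hyperparameters, seed=seed)
    return _fit_one(spec, balanced, (seed * 15485863) % (2**31)), f"SMOTE_{'GB' if best == 'gradient_boosting' else 'RF'}"


def predict_expanded_consensus(
    c: ExpandedConsensus, X: pd.DataFrame
) -> PredictionSet:
    """9-member majority vote: active iff at least five members vote active
    at the 0.5 threshold; mean probability over all nine is stored."""
    probs = c.member_probabilities(X)
    mean, votes, label = _consensus_from_probabilities(probs, "majority5of9")
    frame = pd.DataFrame(
        {
            "mean_probability": mean,
            "active_votes": votes,
            "label": label,
            "excluded": False,
        },
        index=X.index,
    )
    return PredictionSet(frame=frame, n_members=9)


# ---------------------------------------------------------------------------
# probability-range filtering
# ---------------------------------------------------------------------------

def probability_range_filter(
    p: PredictionSet, low: float = 0.35, high: float = 0.65
) -> tuple[PredictionSet, PredictionSet]:
    """Split predictions into confident (retained) and uncertain (excluded).

    Compounds with mean probability in [low, high] (boundaries inclusive)
    are excluded; retained labels are re-derived from the mean probability:
    below ``low`` -> inactive, above ``high`` -> active.
    """
    if not low < high:
        raise ParameterError("filter bounds must satisfy low < high")
    frame = p.frame.copy()
    mp = frame["mean_probability"]
    uncertain = (mp >= low) & (mp <= high)
    retained = frame.loc[~uncertain].copy()
    retained["label"] = (retained["mean_probability"] > high).astype(int)
    retained["excluded"] = False
    excluded = frame.loc[uncertain].copy()
    excluded["excluded"] = True
    return (
        PredictionSet(frame=retained, n_members=p.n_members),
        PredictionSet(frame=excluded, n_members=p.n_members),
    )
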