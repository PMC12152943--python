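"""Model / Results objects for the cholestasis consensus classifiers.

Follows the two-object convention of statistical modelling libraries: a
Model is constructed from data and configuration, ``fit()`` returns a
Results object that carries the trained ensemble, prediction methods,
feature importances and a ``summary()`` table; cross-validation hangs off
the Model (it refits), evaluation and filtering off the Results.

>>> model = UndersampledConsensus(dataset, algorithm="gradient_boosting")
>>> res = model.fit(seed=1)
>>> pred = res.predict(test.X)
>>> retained, excluded = res.predict_filtered(test.X)
>>> print(res.summary())
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import joblib
import pandas as pd

from . import __version__ as _pkg_version
from .consensus import (
    ExpandedConsensus,
    LearnerSpec,
    PredictionSet,
    SubsetEnsemble,
    fit_expanded_consensus,
    fit_subset_ensemble,
    predict_expanded_consensus,
    predict_us_consensus,
    probability_range_filter,
)
from .errors import ConfigError, ParameterError
from .evaluation import (
    CrossValidationResult,
    ImportanceRanking,
    MetricsReport,
    band_table,
    compute_metrics,
    confusion,
    cross_validate,
    mean_scaled_importance,
)
from .resampling import LabeledDataset, undersample_subsets


def _summary_block(title: str, rows: list[tuple[str, object]]) -> str:
    width = max(len(k) for k, _ in rows) + 2
    lines = [title, "=" * 58]
    lines += [f"{k + ':':<{width}}{v}" for k, v in rows]
    return "\n".join(lines)


class _ConsensusModelBase:
    """Shared construction/CV plumbing for the two consensus models."""

    def __init__(
        self,
        dataset: LabeledDataset,
        n_subsets: int = 4,
        filter_bounds: tuple[float, float] = (0.35, 0.65),
    ) -> None:
        self.dataset = dataset
        self.n_subsets = n_subsets
        self.filter_bounds = filter_bounds

    @classmethod
    def from_dataframe(cls, X: pd.DataFrame, y: pd.Series, **kwargs):
        """Build the model from a feature frame and binary label series."""
        return cls(LabeledDataset(X, y, provenance="from_dataframe"), **kwargs)

    def _fit_for_cv(self, train: LabeledDataset, seed: int):
        raise NotImplementedError

    def cross_validate(self, k: int = 10, seed: int = 0) -> CrossValidationResult:
        """Stratified k-fold CV with balancing inside each training fold and
        pooled out-of-fold predictions."""
        return cross_validate(
            self.dataset,
            self._fit_for_cv,
            k=k,
            seed=seed,
            boundaries=self.filter_bounds,
        )


class _ConsensusResultsBase:
    """Shared prediction/evaluation surface of fitted consensus models."""

    filter_bounds: tuple[float, float]

    def _predict_raw(self, X: pd.DataFrame) -> PredictionSet:
        raise NotImplementedError

    def predict(self, X: pd.DataFrame) -> PredictionSet:
        """Consensus predictions (no probability-range filtering)."""
        return self._predict_raw(X)

    def predict_filtered(
        self, X: pd.DataFrame, low: Optional[float] = None, high: Optional[float] = None
    ) -> tuple[PredictionSet, PredictionSet]:
        """Predictions split into (retained, excluded) by the probability
        band; defaults to the model's configured bounds."""
        lo = self.filter_bounds[0] if low is None else low
        hi = self.filter_bounds[1] if high is None else high
        return probability_range_filter(self._predict_raw(X), lo, hi)

    def evaluate(self, test: LabeledDataset, filtered: bool = False):
        """Metrics on a labelled test set.

        With ``filtered=True`` returns (MetricsReport on retained compounds,
        BandTable); otherwise just the MetricsReport on all compounds.
        """
        pred = self._predict_raw(test.X)
        if not filtered:
            return compute_metrics(
                confusion(test.y.loc[pred.compound_ids], pred.frame["label"])
            )
        from .evaluation import metrics_from_bands

        bands = band_table(
            pred.frame["mean_probability"],
            test.y.loc[pred.compound_ids],
            self.filter_bounds,
        )
        return metrics_from_bands(bands), bands


@dataclass
class UndersampledConsensusResults(_ConsensusResultsBase):
    """Fitted 4-submodel undersampling consensus."""

    model: "UndersampledConsensus"
    ensemble: SubsetEnsemble
    seed: int

    def __post_init__(self) -> None:
        self.filter_bounds = self.model.filter_bounds

    def _predict_raw(self, X: pd.DataFrame) -> PredictionSet:
        return predict_us_consensus(self.ensemble, X)

    def feature_importances(self) -> ImportanceRanking:
        """Mean scaled influence across the four submodels, ranked."""
        return mean_scaled_importance(self.ensemble)

    def summary(self) -> str:
        d = self.model.dataset
        sizes = [len(s) for s in self.ensemble.subset_manifest]
        top = self.feature_importances().top(5)
        return _summary_block(
            "Undersampling consensus (4 submodels)",
            [
                ("algorithm", self.ensemble.spec.algorithm),
                ("decision rule", ">=3/4 votes active; <=1 inactive; 2-2 tie by mean prob"),
                ("training compounds", f"{d.n} ({d.n_negative} neg / {d.n_positive} pos)"),
                ("subset sizes", sizes),
                ("features", len(self.ensemble.feature_ids)),
                ("filter band", list(self.filter_bounds)),
                ("seed", self.seed),
                ("top features", ", ".join(top)),
            ],
        )

    def save(self, directory) -> None:
        _save_bundle(directory, self, kind="us4")


class UndersampledConsensus(_ConsensusModelBase):
    """4-submodel undersampling consensus model.

    The majority class of ``dataset`` is partitioned into ``n_subsets``
    random disjoint subsets; one probabilistic classifier (random forest or
    gradient-boosted trees) is trained per subset paired with the full
    minority class.  Prediction uses the 3-of-4 vote rule with the 2-2 tie
    broken by the mean probability.
    """

    def __init__(
        self,
        dataset: LabeledDataset,
        algorithm: str = "gradient_boosting",
        hyperparameters: tuple = (),
        n_subsets: int = 4,
        filter_bounds: tuple[float, float] = (0.35, 0.65),
    ) -> None:
        super().__init__(dataset, n_subsets=n_subsets, filter_bounds=filter_bounds)
        self.algorithm = algorithm
        self.hyperparameters = hyperparameters

    def fit(self, seed: int = 0) -> UndersampledConsensusResults:
        subsets = undersample_subsets(self.dataset, n_subsets=self.n_subsets, seed=seed)
        spec = LearnerSpec(self.algorithm, self.hyperparameters, seed=seed)
        ensemble = fit_subset_ensemble(subsets, spec)
        return UndersampledConsensusResults(model=self, ensemble=ensemble, seed=seed)

    def _fit_for_cv(self, train: LabeledDataset, seed: int):
        return UndersampledConsensus(
            train,
            algorithm=self.algorithm,
            hyperparameters=self.hyperparameters,
            n_subsets=self.n_subsets,
            filter_bounds=self.filter_bounds,
        ).fit(seed=seed)

    def predict(self, X: pd.DataFrame) -> PredictionSet:  # CV factory contract
        raise ParameterError("call fit() first; predict lives on the Results object")


@dataclass
class ExpandedConsensusResults(_ConsensusResultsBase):
    """Fitted 9-member expanded consensus."""

    model: "ExpandedConsensusModel"
    consensus: ExpandedConsensus
    seed: int

    def __post_init__(self) -> None:
        self.filter_bounds = self.model.filter_bounds

    def _predict_raw(self, X: pd.DataFrame) -> PredictionSet:
        return predict_expanded_consensus(self.consensus, X)

    def summary(self) -> str:
        d = self.model.dataset
        return _summary_block(
            "Expanded consensus (9 members)",
            [
                ("members", ", ".join(self.consensus.member_names)),
                ("decision rule", "active iff >=5 of 9 members vote active at p>=0.5"),
                ("training compounds", f"{d.n} ({d.n_negative} neg / {d.n_positive} pos)"),
                ("features", len(self.consensus.feature_ids)),
                ("filter band", list(self.filter_bounds)),
                ("seed", self.seed),
            ],
        )

    def save(self, directory) -> None:
        _save_bundle(directory, self, kind="expanded9")


class ExpandedConsensusModel(_ConsensusModelBase):
    """9-member expanded consensus: 4 US-GB + 4 US-RF + best SMOTE model,
    majority vote at >=5 of 9."""

    def __init__(
        self,
        dataset: LabeledDataset,
        gb_hyperparameters: tuple = (),
        rf_hyperparameters: tuple = (),
        n_subsets: int = 4,
        smote_k: int = 5,
        shared_partition: bool = True,
        filter_bounds: tuple[float, float] = (0.35, 0.65),
    ) -> None:
        super().__init__(dataset, n_subsets=n_subsets, filter_bounds=filter_bounds)
        self.gb_hyperparameters = gb_hyperparameters
        self.rf_hyperparameters = rf_hyperparameters
        self.smote_k = smote_k
        self.shared_partition = shared_partition

    def fit(self, seed: int = 0) -> ExpandedConsensusResults:
        consensus = fit_expanded_consensus(
            self.dataset,
            gb_spec=LearnerSpec("gradient_boosting", self.gb_hyperparameters, seed=seed),
            rf_spec=LearnerSpec("random_forest", self.rf_hyperparameters, seed=seed + 1),
            seed=seed,
            n_subsets=self.n_subsets,
            smote_k=self.smote_k,
            shared_partition=self.shared_partition,
        )
        return ExpandedConsensusResults(model=self, consensus=consensus, seed=seed)

    def _fit_for_cv(self, train: LabeledDataset, seed: int):
        return ExpandedConsensusModel(
            train,
            gb_hyperparameters=self.gb_hyperparameters,
            rf_hyperparameters=self.rf_hyperparameters,
            n_subsets=self.n_subsets,
            smote_k=self.smote_k,
            shared_partition=self.shared_partition,
            filter_bounds=self.filter_bounds,
        ).fit(seed=seed)


# ---------------------------------------------------------------------------
# serialization: directory bundle with JSON manifest + joblib payload
# ---------------------------------------------------------------------------

def _save_bundle(directory, results, kind: str) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if kind == "us4":
        feature_ids = results.ensemble.feature_ids
        manifest = {
            "kind": kind,
            "version": _pkg_version,
            "algorithm": results.ensemble.spec.algorithm,
            "hyperparameters": dict(results.ensemble.spec.hyperparameters),
            "seed": results.seed,
            "filter_bounds": list(results.filter_bounds),
            "feature_ids": feature_ids,
            "subset_manifest": results.ensemble.subset_manifest,
        }
        payload = results.ensemble
    else:
        feature_ids = results.consensus.feature_ids
        manifest = {
            "kind": kind,
            "version": _pkg_version,
            "member_names": results.consensus.member_names,
            "seed": results.seed,
            "filter_bounds": list(results.filter_bounds),
            "feature_ids": feature_ids,
        }
        payload = results.consensus
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    joblib.dump(payload, directory / "model.joblib")


def load_bundle(directory):
    """Load a saved ensemble bundle; returns an object with ``predict(X)``
    and ``predict_filtered(X)``."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise ConfigError(f"no manifest.json in {directory}")
    manifest = json.loads(manifest_path.read_text())
    payload = joblib.load(directory / "model.joblib")
    bounds = tuple(manifest.get("filter_bounds", (0.35, 0.65)))

    class _Loaded(_ConsensusResultsBase):
        filter_bounds = bounds
        kind = manifest["kind"]
        feature_ids = manifest["feature_ids"]

        def _predict_raw(self, X: pd.DataFrame) -> PredictionSet:
            if self.kind == "us4":
                return predict_us_consensus(payload, X)
            return predict_expanded_consensus(payload, X)

    return _Loaded()
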