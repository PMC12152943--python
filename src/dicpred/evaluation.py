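"""Performance metrics, probability-band tabulation and model selection.

The positive class throughout is cholestasis-positive.  Metrics with a zero
denominator are reported as NaN (an explicit undefined marker) rather than
silently as 0, so degenerate folds cannot inflate averages.  Matthews
correlation (MCC) is the headline robustness metric under class imbalance;
balanced accuracy — the mean of sensitivity and specificity — drives model
selection because it rewards sensitivity, which matters most for a toxicity
alert.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .resampling import LabeledDataset

UNDEFINED = float("nan")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise DataError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    mcc: float
    sensitivity: float
    specificity: float
    precision: float
    balanced_accuracy: float

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "accuracy": self.accuracy,
                "MCC": self.mcc,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "precision": self.precision,
                "balanced accuracy": self.balanced_accuracy,
            }
        )

    def rounded(self, ndigits: int = 2) -> pd.Series:
        """Reporting-layer rounding; internal comparisons stay full precision."""
        return self.as_series().round(ndigits)


BAND_NAMES = ("low", "middle", "high")


@dataclass
class BandTable:
    """Per-class compound counts in probability bands.

    Bands partition [0, 1] as [0, low), [low, high], (high, 1] — the
    middle (uncertain) band is closed on both sides, matching the filtering
    rule that excludes boundary probabilities.
    """

    boundaries: tuple[float, float] = (0.35, 0.65)
    counts: pd.DataFrame = field(default_factory=pd.DataFrame)

    def class_counts(self, label: int) -> tuple[int, int, int]:
        col = self.counts[label]
        return tuple(int(col[b]) for b in BAND_NAMES)


# ---------------------------------------------------------------------------
# metric arithmetic
# ---------------------------------------------------------------------------

def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise DataError(f"length mismatch: {yt.shape} vs {yp.shape}")
    if yt.size and (not np.isin(yt, (0, 1)).all() or not np.isin(yp, (0, 1)).all()):
        raise DataError("labels must be binary 0/1")
    return ConfusionCounts(
        TP=int(((yt == 1) & (yp == 1)).sum()),
        FP=int(((yt == 0) & (yp == 1)).sum()),
        TN=int(((yt == 0) & (yp == 0)).sum()),
        FN=int(((yt == 1) & (yp == 0)).sum()),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else UNDEFINED


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """All six metrics from a confusion table.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); any metric
    whose denominator is zero comes back NaN.
    """
    if c.total == 0:
        raise DataError("cannot compute metrics from all-zero counts")
    tp, fp, tn, fn = float(c.TP), float(c.FP), float(c.TN), float(c.FN)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else UNDEFINED
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    bal = (sens + spec) / 2.0 if not (math.isnan(sens) or math.isnan(spec)) else UNDEFINED
    return MetricsReport(
        accuracy=_ratio(tp + tn, c.total),
        mcc=mcc,
        sensitivity=sens,
        specificity=spec,
        precision=_ratio(tp, tp + fp),
        balanced_accuracy=bal,
    )


# ---------------------------------------------------------------------------
# probability bands
# ---------------------------------------------------------------------------

def band_table(
    mean_probabilities: Sequence[float],
    y_true: Sequence[int],
    boundaries: tuple[float, float] = (0.35, 0.65),
) -> BandTable:
    """Tally compounds per class into low/middle/high probability bands."""
    low, high = boundaries
    if not low < high:
        raise ParameterError("boundaries must satisfy low < high")
    p = np.asarray(mean_probabilities, dtype=float)
    y = np.asarray(y_true, dtype=int)
    if p.shape != y.shape:
        raise DataError("probabilities and labels differ in length")
    if p.size and (p.min() < 0 or p.max() > 1):
        raise DataError("probabilities must lie in [0, 1]")
    counts = pd.DataFrame(0, index=list(BAND_NAMES), columns=[0, 1], dtype=int)
    for label in (0, 1):
        pc = p[y == label]
        counts.loc["low", label] = int((pc < low).sum())
        counts.loc["middle", label] = int(((pc >= low) & (pc <= high)).sum())
        counts.loc["high", label] = int((pc > high).sum())
    return BandTable(boundaries=(low, high), counts=counts)


def metrics_from_bands(t: BandTable) -> MetricsReport:
    """Metrics on the confident predictions only: the middle (uncertain)
    band is dropped, low-band compounds count as predicted-negative and
    high-band compounds as predicted-positive."""
    if list(t.counts.index) != list(BAND_NAMES):
        raise DataError("band table must have exactly the low/middle/high bands")
    neg = t.class_counts(0)
    pos = t.class_counts(1)
    c = ConfusionCounts(TP=pos[2], FP=neg[2], TN=neg[0], FN=pos[0])
    if c.total == 0:
        raise DataError("no compounds retained outside the uncertain band")
    return compute_metrics(c)


def excluded_summary(t: BandTable) -> tuple[int, int, int, float]:
    """Middle-band bookkeeping: (total excluded, negatives, positives,
    negative:positive ratio).  Ratio is NaN when no positives are excluded."""
    neg = t.class_counts(0)[1]
    pos = t.class_counts(1)[1]
    ratio = neg / pos if pos > 0 else UNDEFINED
    return neg + pos, neg, pos, ratio


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CrossValidationResult:
    pooled: MetricsReport
    band: BandTable
    per_fold: list[MetricsReport]
    predictions: pd.DataFrame  # compound_id index; mean_probability, label, y_true


def cross_validate(
    d: LabeledDataset,
    model_factory: Callable[[LabeledDataset, int], object],
    k: int = 10,
    seed: int = 0,
    boundaries: tuple[float, float] = (0.35, 0.65),
) -> CrossValidationResult:
    """Stratified k-fold CV with pooled out-of-fold predictions.

    ``model_factory(train_fold, fold_seed)`` must return a fitted object with
    ``predict(X) -> PredictionSet``; any class balancing belongs inside the
    factory so the held-out fold is never altered.  Each compound is
    predicted exactly once out-of-fold; metrics and the probability-band
    table are computed on the pooled predictions, so the band-table class
    totals equal the full training-set class sizes.
    """
    from sklearn.model_selection import StratifiedKFold

    counts = (d.n_positive, d.n_negative)
    if min(counts) < k:
        raise DataError(f"smallest class ({min(counts)}) has fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    ids = np.array(d.compound_ids)
    y = d.y.to_numpy()
    rows = []
    per_fold = []
    for fold, (tr, te) in enumerate(skf.split(ids, y)):
        train_ds = d.subset(list(ids[tr]), provenance=f"{d.provenance}|cv{fold}")
        fitted = model_factory(train_ds, (seed * 1009 + fold) % (2**31))
        pred = fitted.predict(d.X.loc[ids[te]])
        frame = pred.frame[["mean_probability", "label"]].copy()
        frame["y_true"] = d.y.loc[frame.index]
        frame["fold"] = fold
        rows.append(frame)
        per_fold.append(
            compute_metrics(confusion(frame["y_true"], frame["label"]))
        )
    pooled = pd.concat(rows)
    pooled = pooled.loc[[c for c in d.compound_ids if c in pooled.index]]
    if len(pooled) != d.n:
        raise DataError("pooled out-of-fold predictions do not cover the dataset")
    metrics = compute_metrics(confusion(pooled["y_true"], pooled["label"]))
    band = band_table(pooled["mean_probability"], pooled["y_true"], boundaries)
    return CrossValidationResult(
        pooled=metrics, band=band, per_fold=per_fold, predictions=pooled
    )


# ---------------------------------------------------------------------------
# selection, importance, bookkeeping
# ---------------------------------------------------------------------------

def select_best(results: Iterable[tuple[str, MetricsReport]]) -> str:
    """Pick the model with the highest balanced accuracy, compared at three
    decimal places; ties go to higher sensitivity, then higher MCC, then
    the lexicographically first name."""
    results = list(results)
    if not results:
        raise ParameterError("no candidates to select from")

    def nz(x: float) -> float:
        return -math.inf if math.isnan(x) else x

    def key(item: tuple[str, MetricsReport]):
        name, m = item
        return (
            -round(nz(m.balanced_accuracy), 3),
            -nz(m.sensitivity),
            -nz(m.mcc),
            name,
        )

    return min(results, key=key)[0]


@dataclass
class ImportanceRanking:
    """Features ranked by mean scaled influence, descending in [0, 1]."""

    table: pd.DataFrame  # columns: feature_id, mean_scaled_influence

    def rank_of(self, feature_id: str) -> int:
        """1-based rank of a feature."""
        pos = self.table.index[self.table["feature_id"] == feature_id]
        if len(pos) == 0:
            raise DataError(f"feature {feature_id!r} not in ranking")
        return int(pos[0]) + 1

    def top(self, n: int) -> list[str]:
        return list(self.table["feature_id"].head(n))

    def __len__(self) -> int:
        return len(self.table)


def mean_scaled_importance(ensemble) -> ImportanceRanking:
    """Aggregate per-submodel feature importances into one ranking.

    Each submodel's raw importance vector is scaled by its own maximum (the
    top feature maps to 1.0), the scaled vectors are averaged across
    submodels, and features are sorted by descending mean scaled influence
    (ties broken by feature id for determinism).  A submodel whose
    importances are all zero contributes zeros, with a warning.
    """
    feature_ids = ensemble.feature_ids
    scaled = []
    for sub in ensemble.submodels:
        raw = np.asarray(sub.feature_importances_, dtype=float)
        top = raw.max()
        if top <= 0:
            warnings.warn("submodel has all-zero feature importances", stacklevel=2)
            scaled.append(np.zeros_like(raw))
        else:
            scaled.append(raw / top)
    mean = np.mean(scaled, axis=0)
    table = pd.DataFrame(
        {"feature_id": feature_ids, "mean_scaled_influence": mean}
    ).sort_values(
        ["mean_scaled_influence", "feature_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return ImportanceRanking(table)


def class_balance(labels: Sequence[int]) -> float:
    """Negative:positive ratio (the R of "R:1"); NaN with no positives."""
    y = np.asarray(labels, dtype=int)
    pos = int((y == 1).sum())
    neg = int((y == 0).sum())
    if pos == 0:
        return UNDEFINED
    return neg / pos


def format_ratio(r: float) -> str:
    return "undefined" if math.isnan(r) else f"{r:.2f}:1"
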