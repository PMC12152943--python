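"""End-to-end pipeline orchestration with provenance.

``run_pipeline`` drives the full flow on files: read fingerprint blocks,
concatenate, split, train the chosen consensus, cross-validate, predict the
test set, apply probability-range filtering and write every artifact plus a
JSON provenance record.  Output is atomic: everything is written into a
temporary sibling directory that is renamed into place only on success.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__ as _pkg_version
from . import io
from .errors import ConfigError
from .evaluation import excluded_summary, format_ratio
from .matrices import concat_blocks
from .model import ExpandedConsensusModel, UndersampledConsensus
from .resampling import LabeledDataset, stratified_split

logger = logging.getLogger(__name__)

_BLOCK_KEYS = ("target", "pathway", "substructure", "transporter")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``blocks`` maps block label -> path of that block's binary-matrix CSV;
    ``labels`` is the compound_id,label CSV.  ``consensus_mode`` is
    ``"us4"`` (4-submodel undersampling consensus) or ``"expanded9"``.
    """

    blocks: dict[str, str]
    labels: str
    out_dir: str
    consensus_mode: str = "us4"
    algorithm: str = "gradient_boosting"
    train_fraction: float = 0.8
    n_subsets: int = 4
    filter_low: float = 0.35
    filter_high: float = 0.65
    cv_folds: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.consensus_mode not in ("us4", "expanded9"):
            raise ConfigError(f"unknown consensus_mode {self.consensus_mode!r}")
        if not 0.0 <= self.filter_low < self.filter_high <= 1.0:
            raise ConfigError("filter bounds must satisfy 0 <= low < high <= 1")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        unknown = set(self.blocks) - set(_BLOCK_KEYS)
        if unknown:
            raise ConfigError(f"unknown block labels {sorted(unknown)}")
        if not self.blocks:
            raise ConfigError("at least one fingerprint block is required")
        for label, path in self.blocks.items():
            if not Path(path).exists():
                raise ConfigError(f"block file for {label!r} not found: {path}")
        if not Path(self.labels).exists():
            raise ConfigError(f"labels file not found: {self.labels}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a mapping")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"bad config key: {exc}") from exc

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _metrics_row(name: str, report) -> dict:
    row = {"model": name}
    row.update(report.as_series().round(2).to_dict())
    return row


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full modelling pipeline described by ``cfg``.

    Returns the output directory.  Artifacts: combined matrix, split
    manifest, trained model bundle, prediction CSVs (raw/retained/excluded),
    metrics CSV (CV pooled + test, unfiltered and filtered), band-table CSV,
    excluded-compound summary, feature-importance CSV (us4 mode) and
    ``provenance.json``.
    """
    cfg.validate()
    blocks = [
        io.read_binary_matrix(cfg.blocks[label], label)
        for label in _BLOCK_KEYS
        if label in cfg.blocks
    ]
    combined = concat_blocks(blocks) if len(blocks) > 1 else blocks[0]
    labels = io.read_labels(cfg.labels)
    missing = [c for c in combined.compound_ids if c not in labels.index]
    if missing:
        raise ConfigError(f"labels missing for {len(missing)} compounds, e.g. {missing[:3]}")
    if len(blocks) == 1:
        # single block: still block-qualify so trained models are portable
        combined = concat_blocks([combined])
    dataset = LabeledDataset.from_matrix(
        combined, labels, provenance=f"pipeline(seed={cfg.seed})"
    )

    out_dir = Path(cfg.out_dir)
    tmp = Path(tempfile.mkdtemp(prefix=".dicpred_", dir=out_dir.parent or "."))
    try:
        _run_into(cfg, dataset, combined, tmp)
        if out_dir.exists():
            shutil.rmtree(out_dir)
        tmp.rename(out_dir)
    except Exception:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    logger.info("pipeline artifacts written to %s", out_dir)
    return out_dir


def _run_into(cfg: RunConfig, dataset: LabeledDataset, combined, tmp: Path) -> None:
    io.write_binary_matrix(combined, tmp / "combined_matrix.csv")
    split = stratified_split(dataset, train_fraction=cfg.train_fraction, seed=cfg.seed)
    split.manifest().to_csv(tmp / "split_manifest.csv", index=False)

    if cfg.consensus_mode == "us4":
        model = UndersampledConsensus(
            split.train,
            algorithm=cfg.algorithm,
            n_subsets=cfg.n_subsets,
            filter_bounds=(cfg.filter_low, cfg.filter_high),
        )
    else:
        model = ExpandedConsensusModel(
            split.train,
            n_subsets=cfg.n_subsets,
            filter_bounds=(cfg.filter_low, cfg.filter_high),
        )
    cv = model.cross_validate(k=cfg.cv_folds, seed=cfg.seed)
    results = model.fit(seed=cfg.seed)
    results.save(tmp / "model_bundle")

    pred = results.predict(split.test.X)
    pred.to_csv(tmp / "predictions_test.csv")
    retained, excluded = results.predict_filtered(split.test.X)
    retained.to_csv(tmp / "predictions_retained.csv")
    excluded.to_csv(tmp / "predictions_excluded.csv")

    from .evaluation import metrics_from_bands

    test_metrics = results.evaluate(split.test)
    test_filtered, test_bands = results.evaluate(split.test, filtered=True)
    cv_filtered = metrics_from_bands(cv.band)
    pd.DataFrame(
        [
            _metrics_row("cv_pooled", cv.pooled),
            _metrics_row("cv_pooled_filtered", cv_filtered),
            _metrics_row("test", test_metrics),
            _metrics_row("test_filtered", test_filtered),
        ]
    ).to_csv(tmp / "metrics.csv", index=False)

    bands = pd.concat(
        {
            "train": cv.band.counts.rename(columns={0: "Chol-", 1: "Chol+"}),
            "test": test_bands.counts.rename(columns={0: "Chol-", 1: "Chol+"}),
        },
        axis=1,
    )
    bands.index.name = "band"
    bands.to_csv(tmp / "band_table.csv")

    rows = []
    for name, bt in (("train", cv.band), ("test", test_bands)):
        count, neg, pos, ratio = excluded_summary(bt)
        rows.append(
            {"partition": name, "excluded": count, "Chol-": neg,
             "Chol+": pos, "class_balance": format_ratio(ratio)}
        )
    pd.DataFrame(rows).to_csv(tmp / "excluded_summary.csv", index=False)

    if cfg.consensus_mode == "us4":
        ranking = results.feature_importances()
        out = ranking.table.copy()
        out.insert(0, "rank", range(1, len(out) + 1))
        out.to_csv(tmp / "feature_importance.csv", index=False)

    provenance = {
        "package_version": _pkg_version,
        "config": cfg.__dict__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_compounds": dataset.n,
        "n_features": combined.shape[1],
        "train_size": split.train.n,
        "test_size": split.test.n,
    }
    (tmp / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
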