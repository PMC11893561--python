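"""Experiment orchestration: splits, cross-validation, grids, artifacts.

The protocol mirrors how the method is evaluated on real slide archives:

1. a stratified test set is held out once per dataset (default 20%);
2. the remaining bags are split into stratified folds (default 5);
3. within each fold, the anomaly detector is trained **only on the
   normal (label-0) bags of that fold's training split** — positive bags
   never touch the detector;
4. every training bag is scored, top-k selected, and the fusion
   classifier is trained on the kept instances;
5. fold models are evaluated on the fold's validation bags and on the
   fixed test set; metrics are reported as mean +/- sd over folds.

Everything is seeded; rerunning a config yields identical metrics files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import StratifiedKFold, train_test_split

from .anomaly import ADTrainConfig, GMVAEModel, reconstruct, train_ad
from .bags import BagDataset, read_bag_store
from .fusion import (FusionModel, TrainConfig, predict_bag, train_classifier)
from .metrics import MetricsReport, accuracy_metric, auc, recall_metric
from .selection import SelectionConfig, apply_selection, select
from .synthetic import GeneratorConfig, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class FoldSplit:
    """One cross-validation fold plus the fixed standalone test set."""

    fold: int
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]


def stratified_kfold(labels, n_folds: int = 5, seed: int = 0):
    """Stratified fold assignment; returns (train_idx, val_idx) pairs.

    Per-class counts differ by at most one across folds; errors if any
    class has fewer members than folds.
    """
    labels = np.asarray(labels, dtype=int)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} bags; need >= {n_folds} for "
            f"{n_folds}-fold stratified CV"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(train.tolist(), val.tolist())
            for train, val in skf.split(np.zeros(len(labels)), labels)]


def stratified_holdout(labels, test_fraction: float = 0.2, seed: int = 0):
    """Single stratified train/test split; returns (train_idx, test_idx)."""
    idx = np.arange(len(labels))
    train, test = train_test_split(idx, test_size=test_fraction,
                                   random_state=seed, stratify=labels)
    return train.tolist(), test.tolist()


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed to reproduce a run, loadable from YAML."""

    data_path: Optional[str] = None          # bag store; if None, simulate
    n_bags: int = 200
    class_proportions: tuple[float, float] = (0.5, 0.5)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    # anomaly scoring wants a strong information bottleneck (beta-VAE style):
    # a narrow latent plus heavy KL keeps normal reconstructions sharp enough
    # while refusing to extrapolate off the normal manifold
    ad: ADTrainConfig = field(default_factory=lambda: ADTrainConfig(
        latent_dim=8, kl_weight=100.0, epochs=120))
    train: TrainConfig = field(default_factory=TrainConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    modalities: tuple[str, ...] = ("p", "c", "t", "r")
    mode: str = "multimodal"
    n_folds: int = 5
    test_fraction: float = 0.2
    seed: int = 0
    output_dir: Optional[str] = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (("generator", GeneratorConfig), ("ad", ADTrainConfig),
                         ("train", TrainConfig), ("selection", SelectionConfig)):
            if key in d and isinstance(d[key], dict):
                sub_d = dict(d[key])
                if key == "train" and "selection" in sub_d and isinstance(
                        sub_d["selection"], dict):
                    sub_d["selection"] = SelectionConfig(**sub_d["selection"])
                d[key] = sub(**_tupled(sub_d))
        for key in ("class_proportions", "modalities"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def resolved(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj
        d = {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}
        # fixed linear maps are keyed by map_seed; don't serialize the matrices
        for key in ("modality_maps", "component_means", "component_scales",
                    "mixture_weights", "abnormal_direction"):
            d["generator"].pop(key, None)
        d["train"].pop("class_weights", None)
        return d


def _tupled(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


# ---------------------------------------------------------------------------
# Core train/evaluate unit
# ---------------------------------------------------------------------------

def _fold_seed(base: int, fold: int) -> int:
    return (base * 10007 + fold) % (2**31)


def score_dataset(dataset: BagDataset, ad_model: GMVAEModel) -> BagDataset:
    """Attach reconstruction embeddings and errors to every bag."""
    scored = []
    for bag in dataset:
        rec = reconstruct(ad_model, bag.F_p)
        scored.append(bag.with_(F_r=rec.F_r, errors=rec.errors))
    return BagDataset(scored, manifest=dict(dataset.manifest))


def train_fold(train_bags: BagDataset, config: RunConfig, seed: int):
    """Train AD on the normal bags, then the fusion classifier on selected bags."""
    normals = train_bags.filter_label(0)
    ad_cfg = dataclasses.replace(config.ad, seed=seed)
    ad_model = train_ad(normals, ad_cfg)
    scored = score_dataset(train_bags, ad_model)
    selected = BagDataset(
        [apply_selection(b, select(b.errors, config.selection)) for b in scored],
        manifest=dict(train_bags.manifest))
    dims = {name: mat.shape[1] for name, mat in selected[0].modalities().items()}
    fusion = FusionModel(modalities=config.modalities, mode=config.mode,
                         d_model=config.train.d_model,
                         n_classes=config.train.n_classes,
                         n_latents=config.train.n_latents, seed=seed,
                         dims=dims)
    train_cfg = dataclasses.replace(config.train, seed=seed,
                                    selection=config.selection)
    train_classifier(selected, fusion, train_cfg)
    return ad_model, fusion


def evaluate(bags: BagDataset, ad_model: GMVAEModel, fusion: FusionModel,
             selection: SelectionConfig) -> pd.DataFrame:
    """Predict every bag; returns a tidy frame of probabilities and labels."""
    rows = []
    for bag in bags:
        pred = predict_bag(bag, ad_model, fusion, selection)
        rows.append({"bag_id": bag.bag_id,
                     "prob_class_1": float(pred.probabilities[1]),
                     "pred_label": pred.label, "true_label": bag.label})
    return pd.DataFrame(rows)


def metrics_from_predictions(preds: pd.DataFrame) -> dict:
    return {
        "auc": auc(preds["prob_class_1"].to_numpy(),
                   preds["true_label"].to_numpy()),
        "accuracy": accuracy_metric(preds["pred_label"].to_numpy(),
                                    preds["true_label"].to_numpy()),
        "recall": recall_metric(preds["pred_label"].to_numpy(),
                                preds["true_label"].to_numpy()),
    }


def instance_error_auc(bags: BagDataset, ad_model: GMVAEModel) -> float:
    """Instance-level ROC of reconstruction errors against hidden labels.

    Only meaningful on synthetic bags, where ground-truth instance labels
    exist; measures how well the detector separates abnormal instances.
    """
    errors, labels = [], []
    for bag in bags:
        if bag.instance_labels is None:
            continue
        rec = reconstruct(ad_model, bag.F_p)
        errors.append(rec.errors)
        labels.append(np.asarray(bag.instance_labels, dtype=int))
    if not errors:
        raise ValueError("no bags with instance labels")
    return auc(np.concatenate(errors), np.concatenate(labels))


def load_or_simulate(config: RunConfig) -> BagDataset:
    if config.data_path is not None:
        return read_bag_store(config.data_path)
    return generate_dataset(config.n_bags, config.class_proportions,
                            config.generator, seed=config.generator.seed)


def run_single_split(dataset: BagDataset, config: RunConfig) -> dict:
    """One stratified train/test split: train the pipeline, evaluate held out.

    Returns bag-level metrics on the held-out bags, the instance-level
    reconstruction-error AUC (when hidden instance labels exist), the
    trained models and the prediction frame.
    """
    labels = dataset.labels
    train_idx, test_idx = stratified_holdout(labels, config.test_fraction,
                                             config.seed)
    train_bags = dataset.subset(train_idx)
    test_bags = dataset.subset(test_idx)
    ad_model, fusion = train_fold(train_bags, config, _fold_seed(config.seed, 0))
    preds = evaluate(test_bags, ad_model, fusion, config.selection)
    out = metrics_from_predictions(preds)
    try:
        out["instance_auc"] = instance_error_auc(test_bags, ad_model)
    except ValueError:
        pass
    out["predictions"] = preds
    out["ad_model"] = ad_model
    out["fusion_model"] = fusion
    return out


def run_experiment(config: RunConfig,
                   dataset: Optional[BagDataset] = None) -> MetricsReport:
    """Full protocol: fixed test set, stratified k-fold CV, artifacts on disk."""
    dataset = dataset if dataset is not None else load_or_simulate(config)
    labels = dataset.labels
    train_idx, test_idx = stratified_holdout(labels, config.test_fraction,
                                             config.seed)
    trainval = dataset.subset(train_idx)
    test_bags = dataset.subset(test_idx)
    folds = stratified_kfold(trainval.labels, config.n_folds, config.seed)
    report = MetricsReport()
    all_preds = []
    log_lines = [f"seed={config.seed} n_bags={len(dataset)} "
                 f"test_bags={len(test_bags)} folds={config.n_folds}"]
    test_ids = [b.bag_id for b in test_bags]
    for fold, (tr, va) in enumerate(folds):
        split = FoldSplit(fold=fold,
                          train_ids=[trainval[i].bag_id for i in tr],
                          val_ids=[trainval[i].bag_id for i in va],
                          test_ids=test_ids)
        seed = _fold_seed(config.seed, fold)
        logger.info("fold %d: %d train / %d val bags (seed %d)",
                    fold, len(split.train_ids), len(split.val_ids), seed)
        log_lines.append(
            f"fold={fold} seed={seed} train={len(split.train_ids)} "
            f"val={len(split.val_ids)} val_ids={','.join(split.val_ids)}")
        ad_model, fusion = train_fold(trainval.subset(tr), config, seed)
        fold_metrics = {}
        for split_name, bags in (("val", trainval.subset(va)),
                                 ("test", test_bags)):
            preds = evaluate(bags, ad_model, fusion, config.selection)
            preds.insert(0, "fold", fold)
            preds.insert(1, "split", split_name)
            all_preds.append(preds)
            for name, value in metrics_from_predictions(preds).items():
                fold_metrics[f"{split_name}_{name}"] = value
        report.add_fold(**fold_metrics)
        logger.info("fold %d metrics: %s", fold, fold_metrics)
        log_lines.append(f"fold={fold} " + " ".join(
            f"{k}={v:.6f}" for k, v in fold_metrics.items()))
    if config.output_dir is not None:
        _write_artifacts(config, report, pd.concat(all_preds, ignore_index=True),
                         log_lines)
    return report


def _write_artifacts(config: RunConfig, report: MetricsReport,
                     preds: pd.DataFrame, log_lines: list[str]) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "metrics.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True))
    rows = []
    for name in report.metric_names:
        rows.append({"metric": name, "mean": report.mean(name),
                     "sd": report.sd(name)})
    pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)
    preds.to_csv(out / "preds.csv", index=False)
    (out / "config.json").write_text(
        json.dumps(config.resolved(), indent=2, sort_keys=True))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")


# ---------------------------------------------------------------------------
# Ablation grids
# ---------------------------------------------------------------------------

def selection_grid(config: RunConfig, strategies: Sequence[str] = ("max", "minmax"),
                   k_grid: Sequence[float] = (0.1, 0.2, 0.3, 0.4),
                   dataset: Optional[BagDataset] = None) -> pd.DataFrame:
    """Strategy x k grid: one row of test metrics per combination."""
    dataset = dataset if dataset is not None else load_or_simulate(config)
    rows = []
    for strategy in strategies:
        for k in k_grid:
            cfg = dataclasses.replace(
                config, selection=SelectionConfig(k=k, strategy=strategy))
            res = run_single_split(dataset, cfg)
            rows.append({"strategy": strategy, "k": k, "auc": res["auc"],
                         "accuracy": res["accuracy"], "recall": res["recall"]})
    return pd.DataFrame(rows)


FEATURE_COMBOS = (("p", "c"), ("p", "c", "r"), ("p", "t"), ("p", "t", "r"),
                  ("p", "c", "t"), ("p", "c", "t", "r"))


def feature_ablation(config: RunConfig,
                     combos: Sequence[tuple] = FEATURE_COMBOS,
                     dataset: Optional[BagDataset] = None) -> pd.DataFrame:
    """Feature-combination ablation: one row of test metrics per combo."""
    dataset = dataset if dataset is not None else load_or_simulate(config)
    rows = []
    for combo in combos:
        cfg = dataclasses.replace(config, modalities=tuple(combo))
        res = run_single_split(dataset, cfg)
        rows.append({"features": "+".join(combo), "auc": res["auc"],
                     "accuracy": res["accuracy"], "recall": res["recall"]})
    return pd.DataFrame(rows)
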