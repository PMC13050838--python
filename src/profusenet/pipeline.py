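"""End-to-end orchestration: prepare -> featurize -> train -> evaluate -> ablate.

All randomness descends from a single root seed; every run produces a
manifest sufficient to reproduce it bit-compatibly on the same backend.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, training
from .evaluation import EvalReport, evaluate_predictions, paired_ttest
from .features import FeatureConfig, fit_feature_pipeline
from .model import ModelSpec, build_model
from .redundancy import AlignmentParams, filter_redundant
from .sequence_io import LabeledDataset, SplitSpec, read_fasta, stratified_split
from .synthetic_data import GeneratorConfig, generate_dataset
from .training import TrainConfig, train

# Each ablation variant maps to exactly one (architecture, feature) setting.
VARIANTS: dict[str, dict] = {
    "full": {"use_conv": True, "dual_branch": True, "use_bilstm": True,
             "components": ("embedding", "pseaac", "dpc")},
    "cnn_only": {"use_conv": True, "dual_branch": True, "use_bilstm": False,
                 "components": ("embedding", "pseaac", "dpc")},
    "bilstm_only": {"use_conv": False, "dual_branch": False, "use_bilstm": True,
                    "components": ("embedding", "pseaac", "dpc")},
    "single_cnn_bilstm": {"use_conv": True, "dual_branch": False, "use_bilstm": True,
                          "components": ("embedding", "pseaac", "dpc")},
    "dual_no_handcrafted": {"use_conv": True, "dual_branch": True, "use_bilstm": True,
                            "components": ("embedding",)},
    "dual_pseaac_only": {"use_conv": True, "dual_branch": True, "use_bilstm": True,
                         "components": ("embedding", "pseaac")},
    "dual_dpc_only": {"use_conv": True, "dual_branch": True, "use_bilstm": True,
                      "components": ("embedding", "dpc")},
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything a run needs; nested stage configs share the root seed."""

    generator: GeneratorConfig | None = field(default_factory=GeneratorConfig)
    fasta: str | None = None
    label_manifest: str | None = None
    dedupe: bool = False
    dedupe_threshold: float = 0.90
    split: SplitSpec = field(default_factory=SplitSpec)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    variant: str = "full"
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0
    bootstrap_B: int = 1000

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise KeyError(
                f"unknown variant {self.variant!r}; choose from {sorted(VARIANTS)}"
            )
        if self.generator is None and self.fasta is None:
            raise ValueError("either a generator config or an input FASTA is required")


@dataclass
class RunManifest:
    config: dict
    seeds: dict[str, int]
    input_hash: str
    stage_outputs: dict = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    environment: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _dataset_hash(ds: LabeledDataset) -> str:
    h = hashlib.sha256()
    for s in ds.sequences:
        h.update(f"{s.id}\t{s.label}\t{s.residues}\n".encode())
    return h.hexdigest()


def _resolve_configs(cfg: ExperimentConfig) -> tuple[FeatureConfig, ModelSpec]:
    toggles = VARIANTS[cfg.variant]
    feat = replace(cfg.features, components=toggles["components"])
    spec = ModelSpec(
        embed_dim=feat.token_dim,
        use_conv=toggles["use_conv"],
        dual_branch=toggles["dual_branch"],
        use_bilstm=toggles["use_bilstm"],
        use_late_fusion=True,
        fusion_dim=feat.fusion_dim,
    )
    return feat, spec


def load_input(cfg: ExperimentConfig) -> LabeledDataset:
    if cfg.fasta is not None:
        return read_fasta(cfg.fasta, manifest=cfg.label_manifest)
    generator = replace(cfg.generator, seed=cfg.generator.seed + cfg.seed)
    ds, _ = generate_dataset(generator)
    return ds


def run_experiment(cfg: ExperimentConfig) -> tuple[RunManifest, EvalReport]:
    """Execute dedupe -> split -> featurize -> train -> evaluate."""
    seeds = {
        "root": cfg.seed,
        "split": cfg.seed + 1,
        "train": cfg.seed + 2,
        "model_init": cfg.seed + 3,
        "bootstrap": cfg.seed + 4,
    }
    manifest = RunManifest(config=_config_dict(cfg), seeds=seeds, input_hash="")
    timer = time.perf_counter

    t0 = timer()
    ds = load_input(cfg)
    manifest.input_hash = _dataset_hash(ds)
    manifest.timings["load"] = timer() - t0

    if cfg.dedupe:
        t0 = timer()
        ds, cluster_report = filter_redundant(
            ds, threshold=cfg.dedupe_threshold, params=AlignmentParams()
        )
        manifest.stage_outputs["dedupe"] = {
            "retained": len(ds),
            "removed": len(cluster_report.removed),
        }
        manifest.timings["dedupe"] = timer() - t0

    t0 = timer()
    split_spec = replace(cfg.split, seed=seeds["split"])
    train_ds, val_ds, test_ds = stratified_split(ds, split_spec)
    manifest.stage_outputs["split"] = {
        "train": len(train_ds), "validation": len(val_ds), "test": len(test_ds),
        "train_class_counts": train_ds.class_counts,
        "ids": {"train": train_ds.ids, "validation": val_ds.ids, "test": test_ds.ids},
    }
    manifest.timings["split"] = timer() - t0

    t0 = timer()
    feat_cfg, spec = _resolve_configs(cfg)
    pipeline = fit_feature_pipeline(train_ds, feat_cfg)
    splits = {
        "train": pipeline.featurize(train_ds),
        "validation": pipeline.featurize(val_ds),
        "test": pipeline.featurize(test_ds),
    }
    manifest.stage_outputs["featurize"] = {
        "fusion_dim": feat_cfg.fusion_dim,
        "components": list(feat_cfg.components),
        "fit_ids": pipeline.fit_ids,
    }
    manifest.timings["featurize"] = timer() - t0

    t0 = timer()
    model = build_model(spec, seed=seeds["model_init"])
    train_cfg = replace(cfg.train, seed=seeds["train"])
    history = train(model, splits["train"], splits["validation"], train_cfg)
    manifest.stage_outputs["train"] = history.to_dict()
    manifest.timings["train"] = timer() - t0

    t0 = timer()
    test = splits["test"]
    scores = _predict_scores(model, test)
    report = evaluate_predictions(
        test.labels, scores, B=cfg.bootstrap_B, seed=seeds["bootstrap"]
    )
    manifest.stage_outputs["evaluate"] = report.to_dict()
    manifest.timings["evaluate"] = timer() - t0
    manifest.environment = {"backend": "numpy", "spec": spec.to_dict()}
    manifest.stage_outputs["model"] = {
        "parameters": int(sum(p.data.size for p in model.params.values()))
    }
    # stash live objects for callers that need them (not serialized)
    manifest.artifacts = {  # type: ignore[attr-defined]
        "model": model, "pipeline": pipeline, "splits": splits, "history": history,
    }
    return manifest, report


def _predict_scores(model, split, batch_size: int = 64) -> np.ndarray:
    scores = np.empty(len(split))
    for start in range(0, len(split), batch_size):
        rows = np.arange(start, min(start + batch_size, len(split)))
        probs = model.forward(
            split.token_matrix(rows), split.mask[rows],
            split.fused[rows] if model.spec.use_late_fusion else None,
        )
        scores[rows] = probs[:, 1]
    return scores


def _config_dict(cfg: ExperimentConfig) -> dict:
    d = asdict(cfg)
    feat = d.get("features", {})
    if "pseaac" in feat and isinstance(feat["pseaac"], dict):
        feat["pseaac"].pop("properties", None)  # ndarray; implied by defaults
    return d


def run_ablation(
    cfg: ExperimentConfig,
    variants: list[str],
    n_repeats: int = 10,
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Per-variant mean +/- bootstrap 95% CI over seeded repeats, plus paired
    t-tests of every variant against the full model."""
    if len(variants) < 2:
        raise ValueError("need at least 2 variants to ablate")
    for v in variants:
        if v not in VARIANTS:
            raise KeyError(f"unknown variant {v!r}")

    results: dict[str, dict[str, list[float]]] = {}
    for variant in variants:
        accs, aucs = [], []
        for rep in range(n_repeats):
            run_cfg = replace(cfg, variant=variant, seed=cfg.seed + rep)
            _, report = run_experiment(run_cfg)
            accs.append(report.metrics.accuracy)
            aucs.append(report.roc_auc)
        results[variant] = {"accuracy": accs, "roc_auc": aucs}

    rows = []
    rng = np.random.default_rng(cfg.seed)
    for variant in variants:
        row = {"variant": variant}
        for metric in ("accuracy", "roc_auc"):
            vals = np.array(results[variant][metric])
            boots = np.array([
                vals[rng.integers(0, len(vals), len(vals))].mean()
                for _ in range(1000)
            ])
            row[f"{metric}_mean"] = vals.mean()
            row[f"{metric}_ci_lower"] = np.percentile(boots, 2.5)
            row[f"{metric}_ci_upper"] = np.percentile(boots, 97.5)
        rows.append(row)
    table = pd.DataFrame(rows)

    reference = "full" if "full" in variants else variants[0]
    tests: dict[str, dict] = {}
    for variant in variants:
        if variant == reference:
            continue
        tests[variant] = {
            metric: asdict(paired_ttest(
                results[reference][metric], results[variant][metric]
            ))
            for metric in ("accuracy", "roc_auc")
        }
    return table, tests
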