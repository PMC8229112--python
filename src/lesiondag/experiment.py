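"""End-to-end experiment driver at desk scale.

One call wires the whole workflow together: synthesize a labeled lesion image
set, standardize the images, split into train / test with repeated
stratified validation folds, train the one-vs-one classifier bank, sweep the
DDAG root and select it from validation scores, evaluate on the held-out
test set, and compare against the classical probability-fusion rules applied
to a small ensemble of multiclass heads.  Every artifact is written under
one experiment directory and the whole run is reproducible from (config,
seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data import SplitPlan, make_validation_repeats, stratified_split
from .ensemble import (
    AGGREGATION_METHODS,
    PairwiseScoreSet,
    aggregate,
    select_root,
)
from .evaluation import (
    bacc,
    confusion,
    kruskal_dunn,
    metrics_report,
    paired_t,
    root_sweep,
)
from .pairwise import (
    LinearSoftmaxBackbone,
    TrainingConfig,
    enumerate_tasks,
    plateau_trigger,
    poly_decay,
    train_pairwise,
)
from .preprocess import PipelineConfig, preprocess_image
from .synthetic import LabeledImageSet, SyntheticImageSpec, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "run_experiment"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Resolved settings of one experiment run."""

    class_names: tuple[str, ...] = ("MEL", "NEV", "SEK")
    image_spec: SyntheticImageSpec = field(default_factory=SyntheticImageSpec)
    split: SplitPlan = field(default_factory=SplitPlan)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    aggregation_methods: tuple[str, ...] = AGGREGATION_METHODS
    n_members: int = 3
    input_size: tuple[int, int] = (32, 32)
    color_constancy: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_names) != self.image_spec.n_classes:
            raise ValueError("class_names must match the image spec's class count")
        unknown = set(self.aggregation_methods) - set(AGGREGATION_METHODS)
        if unknown:
            raise ValueError(f"unknown aggregation methods: {sorted(unknown)}")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")


def _sub_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=key).generate_state(1)[0])


def _preprocess_set(dataset: LabeledImageSet, config: ExperimentConfig) -> LabeledImageSet:
    pipeline = PipelineConfig(
        crop_size=None,
        resize_size=config.input_size,
        mean_rgb=None,
        color_constancy=config.color_constancy,
    )
    return LabeledImageSet(
        images=[preprocess_image(im, pipeline) for im in dataset.images],
        labels=dataset.labels,
        class_names=dataset.class_names,
        provenance={**dataset.provenance, "preprocessed": True},
    )


def _train_multiclass_member(
    data: LabeledImageSet,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    config: TrainingConfig,
    seed: int,
) -> LinearSoftmaxBackbone:
    """Train one multiclass (K-node head) ensemble member with the same
    schedule as the pairwise loop: plateau-triggered polynomial LR decay and
    best validation-BACC checkpoint selection."""
    K = data.n_classes
    backbone = LinearSoftmaxBackbone()
    train_images = [data.images[i] for i in train_idx]
    val_images = [data.images[i] for i in val_idx]
    y_train = data.labels[train_idx]
    y_val = data.labels[val_idx]
    counts = {c: int((y_train == c).sum()) for c in range(K)}
    from .data import class_weights  # local import avoids cycle at module load

    w = class_weights(counts, mode="total").as_array(K)
    sample_w = w[y_train]
    backbone.initialize(train_images, n_classes=K, seed=seed)
    rng = np.random.default_rng(_sub_seed(seed, 7))
    best = (-np.inf, backbone.snapshot())
    val_losses: list[float] = []
    lr = config.lr0
    for epoch in range(config.total_epochs):
        backbone.train_epoch(train_images, y_train, sample_w, lr, config.batch_size, rng)
        p_val = backbone.predict_confidences(val_images)
        q = np.clip(p_val[np.arange(len(y_val)), y_val], 1e-7, 1.0)
        val_losses.append(float(np.mean(-np.log(q))))
        score = bacc(confusion(y_val, p_val.argmax(axis=1), K))
        if score > best[0]:
            best = (score, backbone.snapshot())
        if plateau_trigger(val_losses, config.plateau_patience):
            lr = poly_decay(config.lr0, epoch + 1, config.total_epochs)
            if lr <= 0.0:
                break
    backbone.restore(best[1])
    return backbone


def _score_sets_from_bank(
    bank: dict[tuple[int, int], LinearSoftmaxBackbone], images: list[np.ndarray]
) -> list[PairwiseScoreSet]:
    per_pair = {pair: model.predict_confidences(images) for pair, model in bank.items()}
    n = len(images)
    return [
        PairwiseScoreSet(
            scores={pair: (float(conf[s, 0]), float(conf[s, 1])) for pair, conf in per_pair.items()}
        )
        for s in range(n)
    ]


def _ddag_probability_surrogate(score_sets: list[PairwiseScoreSet], K: int) -> np.ndarray:
    """Per-class mean of pairwise confidences, renormalized per sample.

    The DDAG emits a decision, not a probability vector; this surrogate makes
    its confidence comparable to the fusion rules in the statistical tests.
    """
    out = np.zeros((len(score_sets), K))
    for s, scores in enumerate(score_sets):
        for c in range(K):
            others = [scores.confidence(c, o) for o in range(K) if o != c]
            out[s, c] = float(np.mean(others))
    return out / out.sum(axis=1, keepdims=True)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> Path:
    """Run the full workflow and write all artifacts under ``out_dir``.

    Outputs: ``config_resolved.json``, ``split_manifest.csv``, per-task
    training traces, ``root_sweep.json``, per-method metrics, the statistical
    comparison, and ``summary.json``.  Returns the experiment directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "experiment.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t_start = time.perf_counter()
    try:
        spec = replace(config.image_spec, seed=_sub_seed(config.seed, 0))
        _json_dump(_config_to_dict(replace(config, image_spec=spec)), out / "config_resolved.json")

        logger.info("stage=simulate seed=%d n=%s", spec.seed, spec.n_per_class)
        dataset = generate_dataset(spec, class_names=config.class_names)
        dataset = _preprocess_set(dataset, config)
        K = dataset.n_classes

        logger.info("stage=split plan=%s", config.split)
        split_seed = _sub_seed(config.seed, 1)
        pool_idx, test_idx = stratified_split(dataset.labels, config.split.test_fraction, split_seed)
        repeats_local = make_validation_repeats(
            dataset.labels[pool_idx], replace(config.split, seed=_sub_seed(config.seed, 2))
        )
        repeats = [(pool_idx[tr], pool_idx[va]) for tr, va in repeats_local]
        _write_manifest(dataset, pool_idx, test_idx, repeats, out / "split_manifest.csv")

        tasks = enumerate_tasks(K)
        banks: list[dict[tuple[int, int], LinearSoftmaxBackbone]] = []
        val_bacc: dict[tuple[int, int], list[float]] = {t.pair: [] for t in tasks}
        for r, (tr_idx, va_idx) in enumerate(repeats):
            bank: dict[tuple[int, int], LinearSoftmaxBackbone] = {}
            for t in tasks:
                t0 = time.perf_counter()
                cfg = replace(config.training, seed=_sub_seed(config.seed, 3, r, t.i, t.j))
                model, trace = train_pairwise(
                    dataset, t, LinearSoftmaxBackbone(), cfg, (tr_idx, va_idx)
                )
                bank[t.pair] = model
                val_bacc[t.pair].append(trace.val_bacc[trace.best_epoch])
                pd.DataFrame(
                    {
                        "train_loss": trace.train_loss,
                        "val_loss": trace.val_loss,
                        "train_acc": trace.train_acc,
                        "val_bacc": trace.val_bacc,
                        "lr_used": trace.lr_used,
                    }
                ).to_csv(out / f"trace_r{r}_pair{t.i}{t.j}.csv", index_label="epoch")
                logger.info(
                    "stage=train repeat=%d pair=%s best_val_bacc=%.4f elapsed=%.2fs",
                    r, t.pair, trace.val_bacc[trace.best_epoch], time.perf_counter() - t0,
                )
            banks.append(bank)

        mean_val = {pair: float(np.mean(v)) for pair, v in val_bacc.items()}
        structure = select_root(mean_val)
        best_repeat = int(
            np.argmax([np.mean([val_bacc[t.pair][r] for t in tasks]) for r in range(len(repeats))])
        )
        bank = banks[best_repeat]
        logger.info("stage=select_root root=%s repeat=%d", structure.root_pair, best_repeat)

        test_images = [dataset.images[i] for i in test_idx]
        y_test = dataset.labels[test_idx]
        score_sets = _score_sets_from_bank(bank, test_images)
        sweep = root_sweep(score_sets, y_test, K)
        _json_dump({f"{i},{j}": v for (i, j), v in sorted(sweep.items())}, out / "root_sweep.json")

        ddag_probs = _ddag_probability_surrogate(score_sets, K)
        from .ensemble import ddag_predict_batch

        y_ddag, _ = ddag_predict_batch(score_sets, structure)
        ddag_cm = confusion(y_test, y_ddag, K)
        ddag_bacc = bacc(ddag_cm)

        method_metrics: dict[str, dict] = {
            "ddag": {
                "bacc": ddag_bacc,
                "confusion": ddag_cm.tolist(),
                "root_pair": list(structure.root_pair),
            }
        }
        method_true_probs: dict[str, np.ndarray] = {
            "ddag": ddag_probs[np.arange(len(y_test)), y_test]
        }

        if config.aggregation_methods:
            tr_idx, va_idx = repeats[best_repeat]
            members = [
                _train_multiclass_member(
                    dataset, tr_idx, va_idx, config.training, _sub_seed(config.seed, 4, m)
                )
                for m in range(config.n_members)
            ]
            stack = np.stack([m.predict_confidences(test_images) for m in members])
            for method in config.aggregation_methods:
                fused = aggregate(stack, method)
                report = metrics_report(y_test, fused)
                method_metrics[method] = report.to_dict()
                method_true_probs[method] = fused[np.arange(len(y_test)), y_test]

        comparison = None
        if len(method_true_probs) >= 3:
            names = sorted(method_true_probs)
            result = kruskal_dunn(
                [method_true_probs[nm] for nm in names], alpha=0.05, names=names
            )
            comparison = {
                "statistic": result.statistic,
                "omnibus_p": result.omnibus_p,
                "group_ranks": result.group_ranks,
                "worse_than": {k: sorted(v) for k, v in result.worse_than.items()},
            }
        paired = {}
        for nm, probs in method_true_probs.items():
            if nm == "ddag":
                continue
            try:
                t_stat, p = paired_t(method_true_probs["ddag"], probs)
                paired[nm] = {"t": t_stat, "p": p}
            except ValueError:
                paired[nm] = {"t": None, "p": None}

        summary = {
            "seed": config.seed,
            "class_names": list(config.class_names),
            "selected_root": list(structure.root_pair),
            "mean_val_bacc": {f"{i},{j}": v for (i, j), v in sorted(mean_val.items())},
            "root_sweep_test_bacc": {f"{i},{j}": v for (i, j), v in sorted(sweep.items())},
            "ddag_test_bacc": ddag_bacc,
            "methods": method_metrics,
            "comparison": comparison,
            "paired_t_vs_ddag": paired,
        }
        _json_dump(summary, out / "summary.json")
        logger.info("stage=done elapsed=%.2fs", time.perf_counter() - t_start)
        return out
    except Exception:
        logger.exception("experiment stage failed")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _config_to_dict(config: ExperimentConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [convert(v) for v in obj]
        if isinstance(obj, dict):
            return {str(k): convert(v) for k, v in obj.items()}
        return obj

    return convert(config)


def _write_manifest(
    dataset: LabeledImageSet,
    pool_idx: np.ndarray,
    test_idx: np.ndarray,
    repeats: list[tuple[np.ndarray, np.ndarray]],
    path: Path,
) -> None:
    subset = np.full(len(dataset), "pool", dtype=object)
    subset[test_idx] = "test"
    rows = {
        "index": np.arange(len(dataset)),
        "label": dataset.labels,
        "class_name": [dataset.class_names[c] for c in dataset.labels],
        "subset": subset,
    }
    for r, (tr, va) in enumerate(repeats):
        col = np.full(len(dataset), "", dtype=object)
        col[tr] = "train"
        col[va] = "val"
        rows[f"repeat{r}"] = col
    pd.DataFrame(rows).to_csv(path, index=False)
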