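"""Metrics, statistical comparison and experiment orchestration.

Per-class recall, precision and F1 (the classification analogue of the
Dice coefficient), rank-statistic one-vs-rest AUC, descriptive recall
statistics (population sd), paired sign-flip permutation tests with
Cohen's d and bootstrap confidence intervals, and a seeded end-to-end
experiment driver covering the simulate -> preprocess -> encode ->
select -> train -> evaluate chain with an ablation grid over encoders,
selector and classifier.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cube import BandGrid, default_grid
from . import simkit, encoders, egpo, cssnet

__all__ = [
    "ConfusionMatrix", "MetricReport", "ComparisonStat", "ExperimentConfig",
    "confusion_and_metrics", "recall_stats", "auc_rank", "compare_models",
    "run_experiment",
]

logger = logging.getLogger(__name__)

D_CAP = 1e3   # sentinel for Cohen's d with zero-variance differences


@dataclass
class ConfusionMatrix:
    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_names,
                            columns=self.class_names)


@dataclass
class MetricReport:
    recall: np.ndarray
    precision: np.ndarray
    f1: np.ndarray            # classification Dice
    auc: np.ndarray | None
    macro_recall: float
    macro_precision: float
    macro_f1: float
    macro_auc: float | None
    recall_descriptives: dict[str, float]


@dataclass
class ComparisonStat:
    difference: np.ndarray
    mean_difference: float
    p_value: float
    cohens_d: float
    ci95: tuple[float, float]
    n_permutations: int


def auc_rank(scores: np.ndarray, is_positive: np.ndarray) -> float:
    """One-vs-rest AUC via the rank statistic (Mann-Whitney U).

    Equals the tie-corrected fraction of (positive, negative) pairs where
    the positive sample scores higher.
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(is_positive, dtype=bool)
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("need both positive and negative samples")
    order = scores.argsort(kind="mergesort")
    ranks = np.empty(scores.size)
    ranks[order] = np.arange(1, scores.size + 1)
    # average ranks over ties
    for value in np.unique(scores):
        sel = scores == value
        ranks[sel] = ranks[sel].mean()
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def confusion_and_metrics(truth: np.ndarray, predicted: np.ndarray,
                          scores: np.ndarray | None = None,
                          class_names: list[str] | None = None
                          ) -> tuple[ConfusionMatrix, MetricReport]:
    """Confusion matrix plus the standard per-class metric suite.

    ``scores`` (n_samples x n_classes), when given, yields one-vs-rest
    rank AUC per class. F1 is reported as the classification Dice score.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    classes = np.unique(np.concatenate([truth, predicted]))
    k = classes.size
    lookup = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((k, k), dtype=int)
    for t, p in zip(truth, predicted):
        counts[lookup[t], lookup[p]] += 1
    names = class_names or [str(c) for c in classes]

    tp = np.diag(counts).astype(float)
    row = counts.sum(axis=1).astype(float)
    col = counts.sum(axis=0).astype(float)
    recall = np.divide(tp, row, out=np.zeros(k), where=row > 0)
    precision = np.divide(tp, col, out=np.zeros(k), where=col > 0)
    denom = precision + recall
    f1 = np.divide(2 * precision * recall, denom, out=np.zeros(k),
                   where=denom > 0)
    auc = None
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        auc = np.array([auc_rank(scores[:, i], truth == c)
                        for i, c in enumerate(classes)])
    return (ConfusionMatrix(counts=counts, class_names=names),
            MetricReport(recall=recall, precision=precision, f1=f1, auc=auc,
                         macro_recall=float(recall.mean()),
                         macro_precision=float(precision.mean()),
                         macro_f1=float(f1.mean()),
                         macro_auc=None if auc is None else float(auc.mean()),
                         recall_descriptives=recall_stats(recall)))


def recall_stats(per_class_recalls: np.ndarray) -> dict[str, float]:
    """Descriptive row in percent: mean, population sd (ddof 0), min, max."""
    r = 100.0 * np.asarray(per_class_recalls, dtype=float)
    return {"mean": float(r.mean()), "sd": float(r.std(ddof=0)),
            "min": float(r.min()), "max": float(r.max())}


def compare_models(recalls_a: np.ndarray, recalls_b: np.ndarray,
                   seed: int = 0, n_permutations: int = 10_000,
                   n_bootstrap: int = 2_000) -> ComparisonStat:
    """Paired comparison of per-fold recalls of two models.

    The p-value comes from the two-sided sign-flip permutation
    distribution of the mean paired difference (exhaustively enumerated
    for up to 12 folds, otherwise ``n_permutations`` seeded draws);
    Cohen's d is mean/sd of the differences (zero-variance differences
    hit a capped sentinel); the 95% CI is a percentile bootstrap of the
    mean difference.
    """
    a = np.asarray(recalls_a, dtype=float)
    b = np.asarray(recalls_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must share a shape")
    diff = a - b
    n = diff.size
    obs = diff.mean()
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0x9E12]))

    if n <= 12:
        signs = np.array(np.meshgrid(*[[-1, 1]] * n)).T.reshape(-1, n)
        n_perm = signs.shape[0]
    else:
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
        n_perm = n_permutations
    null = (signs * diff).mean(axis=1)
    p = float(np.mean(np.abs(null) >= abs(obs) - 1e-15))

    sd = diff.std(ddof=1) if n > 1 else 0.0
    if sd < 1e-15:
        d = 0.0 if abs(obs) < 1e-15 else float(np.sign(obs) * D_CAP)
    else:
        d = float(np.clip(obs / sd, -D_CAP, D_CAP))

    boots = np.empty(n_bootstrap)
    for i in range(n_bootstrap):
        boots[i] = diff[rng.integers(0, n, size=n)].mean()
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return ComparisonStat(difference=diff, mean_difference=float(obs),
                          p_value=p, cohens_d=d, ci95=ci,
                          n_permutations=n_perm)


# ---------------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Seeded configuration for one end-to-end synthetic experiment."""

    seed: int = 0
    train_per_class: int = 40
    test_per_class: int = 10
    height: int = 64
    width: int = 64
    band_step_nm: float = 10.0
    encoder_names: tuple[str, ...] = ("vit", "swin", "pvt", "detr")
    selector: str = "egpo"            # "egpo" | "none"
    classifier: str = "cssnet"        # "cssnet" | "reference"
    egpo_iterations: int = 100
    cssnet_epochs: int = 30
    class_indices: tuple[int, ...] | None = None   # subset of the 16 classes
    outdir: str | None = None

    def specs(self) -> list[simkit.ClassSpec]:
        rows = simkit.table2_specs()
        if self.class_indices is not None:
            rows = [rows[i] for i in self.class_indices]
        return [simkit.ClassSpec(
            crop=s.crop, disease=s.disease, key_windows=s.key_windows,
            reflectance_delta=s.reflectance_delta,
            lesion_density=s.lesion_density,
            counts=(self.train_per_class, 0, self.test_per_class))
            for s in rows]

    def grid(self) -> BandGrid:
        return BandGrid(np.arange(400.0, 1000.0 + 1e-9, self.band_step_nm))


def run_experiment(config: ExperimentConfig) -> dict:
    """Simulate, featurize, select, train and evaluate one configuration.

    Returns a bundle with the metric report, confusion matrix, selection
    history and stage wall times; when ``config.outdir`` is set, writes
    metrics.json, confusion.csv, convergence.csv, roc.csv and PNG figures
    (confusion heatmap, one-vs-rest ROC curves, selector convergence).
    """
    t_start = time.time()
    grid = config.grid()
    specs = config.specs()
    names = [s.name for s in specs]
    timings: dict[str, float] = {}

    t0 = time.time()
    plan = simkit.plan_dataset(specs, grid, config.seed,
                               height=config.height, width=config.width)
    Xtr = np.stack([s.cube.data for s in plan["train"]])
    ytr = np.array([s.label for s in plan["train"]])
    Xte = np.stack([s.cube.data for s in plan["test"]])
    yte = np.array([s.label for s in plan["test"]])
    timings["simulate"] = time.time() - t0
    logger.info("stage=simulate seed=%d n_train=%d n_test=%d t=%.1fs",
                config.seed, len(ytr), len(yte), timings["simulate"])

    t0 = time.time()
    enc_cfg = encoders.EncoderConfig(seed=config.seed)
    Ftr, gmap = encoders.build_feature_matrix(
        Xtr, grid, enc_cfg, encoder_names=config.encoder_names)
    Fte, _ = encoders.build_feature_matrix(
        Xte, grid, enc_cfg, encoder_names=config.encoder_names)
    timings["encode"] = time.time() - t0

    history: list[float] = []
    if config.selector == "egpo":
        t0 = time.time()
        sel_cfg = egpo.EGPOConfig(seed=config.seed,
                                  iterations=config.egpo_iterations)
        sel = egpo.run_egpo(Ftr, ytr, sel_cfg, group_map=gmap)
        mask = sel.best_mask
        history = sel.history
        timings["select"] = time.time() - t0
    elif config.selector == "none":
        mask = np.ones(Ftr.shape[1], dtype=bool)
    else:
        raise ValueError(f"unknown selector '{config.selector}'")

    mu, sd = Ftr.mean(axis=0), Ftr.std(axis=0)
    sd[sd < 1e-9] = 1.0
    Ztr, Zte = (Ftr - mu) / sd, (Fte - mu) / sd

    t0 = time.time()
    if config.classifier == "cssnet":
        net_cfg = cssnet.CSSNetConfig(
            in_channels=Ftr.shape[1], n_classes=len(specs),
            epochs=config.cssnet_epochs, seed=config.seed,
            n_capsules=8, capsule_dim=8)
        model = cssnet.CSSNet(net_cfg)
        cssnet.train(model, cssnet.features_to_input(Ztr), ytr,
                     cfg=net_cfg, selection_mask=mask)
        preds = cssnet.predict(model, cssnet.features_to_input(Zte),
                               selection_mask=mask)
        yhat = np.array([p.label for p in preds])
        scores = np.stack([p.class_probs for p in preds])
    elif config.classifier == "reference":
        Zs, Zts = Ztr[:, mask], Zte[:, mask]
        centroids = np.stack([Zs[ytr == c].mean(axis=0)
                              for c in range(len(specs))])
        d2 = ((Zts[:, None, :] - centroids[None]) ** 2).sum(axis=2)
        yhat = np.argmin(d2, axis=1)
        scores = -d2
    else:
        raise ValueError(f"unknown classifier '{config.classifier}'")
    timings["train_eval"] = time.time() - t0

    cm, report = confusion_and_metrics(yte, yhat, scores=scores,
                                       class_names=names)
    bundle = {
        "config": asdict(config),
        "selected_features": int(mask.sum()),
        "n_features": int(mask.size),
        "macro_recall": report.macro_recall,
        "macro_f1": report.macro_f1,
        "macro_auc": report.macro_auc,
        "recall_descriptives": report.recall_descriptives,
        "per_class_recall": report.recall.tolist(),
        "timings": {k: round(v, 2) for k, v in timings.items()},
        "wall_time": round(time.time() - t_start, 2),
    }
    if config.outdir:
        _write_bundle(Path(config.outdir), bundle, cm, report, history,
                      yte, scores, names)
    return bundle


def _write_bundle(outdir: Path, bundle: dict, cm: ConfusionMatrix,
                  report: MetricReport, history: list[float],
                  yte: np.ndarray, scores: np.ndarray, names: list[str]):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "metrics.json").write_text(json.dumps(bundle, indent=2))
    cm.to_frame().to_csv(outdir / "confusion.csv")
    if history:
        pd.DataFrame({"iteration": range(len(history)),
                      "best_fitness": history}).to_csv(
            outdir / "convergence.csv", index=False)
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(history)
        ax.set_xlabel("iteration")
        ax.set_ylabel("best fitness")
        ax.set_title("selector convergence")
        fig.tight_layout()
        fig.savefig(outdir / "convergence.png", dpi=120)
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(cm.counts, cmap="Blues")
    ax.set_xlabel("predicted")
    ax.set_ylabel("truth")
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(outdir / "confusion.png", dpi=120)
    plt.close(fig)

    # one-vs-rest ROC curves
    roc_rows = []
    fig, ax = plt.subplots(figsize=(5, 5))
    for i, name in enumerate(names):
        pos = yte == i
        order = np.argsort(-scores[:, i])
        tp = np.cumsum(pos[order])
        fp = np.cumsum(~pos[order])
        tpr = tp / max(pos.sum(), 1)
        fpr = fp / max((~pos).sum(), 1)
        ax.plot(fpr, tpr, lw=0.8)
        roc_rows.append(pd.DataFrame({"class": name, "fpr": fpr, "tpr": tpr}))
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    fig.tight_layout()
    fig.savefig(outdir / "roc.png", dpi=120)
    plt.close(fig)
    pd.concat(roc_rows).to_csv(outdir / "roc.csv", index=False)
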