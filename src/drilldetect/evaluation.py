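"""Grouped 5-fold cross-validation and sensitivity reporting.

The evaluation protocol mirrors the acquisition unit: recordings (one
per drill hole) are partitioned into folds by ``source_id`` so that
windows of the same hole never appear in both a training and a test
split.  Per fold, the pipeline

1. cuts every training recording into overlap-labeled sliding analysis
   windows (step = L/4, a window is *breakthrough* when it overlaps an
   annotated event by at least half its length); cortical windows are
   decimated to a non-overlapping grid since overlapping windows of a
   stationary texture are near-duplicates,
2. balances the window counts by augmenting the breakthrough windows
   (gain / time-stretch / pitch-shift, training split only),
3. extracts log-mel features and fits the scalar normalization on the
   training pool only,
4. trains the classifier with focal loss, monitoring the held-out
   fold's loss for best-weight selection and LR-on-plateau,
5. scores every held-out window on the full sliding grid.

The report aggregates per-fold confusion matrices and per-class
sensitivity (recall) mean +- std, the primary metric being breakthrough
sensitivity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .audio_io import AudioClip, CLASSES, Window, window_labels
from .augment import AugmentationSpec, balance_training_set
from .features import (
    LogMelExtractor,
    NormalizationStats,
    StftConfig,
    fit_normalization,
    frame_signal,
)
from .model import (
    BreakthroughClassifier,
    FocalLossParams,
    ModelSpec,
    TrainingConfig,
    TrainingResult,
)
from .simulate import LabeledRecording

__all__ = [
    "EvalReport",
    "FoldResult",
    "make_folds",
    "train_fold",
    "confusion_and_sensitivity",
    "cross_validate",
    "compare_window_lengths",
    "compare_positions",
]


class EvaluationError(ValueError):
    pass


def make_folds(items, k: int = 5, seed: int = 0, grouping=None) -> np.ndarray:
    """Assign each item to one of ``k`` folds, grouped by source_id.

    Every group (drill hole) lands in exactly one fold and fold sizes are
    balanced within one group.  Returns an integer fold index per item.
    """
    if grouping is None:
        grouping = lambda it: getattr(it, "source_id", str(it))
    groups = [grouping(it) for it in items]
    unique = sorted(set(groups))
    if len(unique) < k:
        raise EvaluationError(f"need at least {k} groups, got {len(unique)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    fold_of_group = {unique[g]: i % k for i, g in enumerate(order)}
    return np.array([fold_of_group[g] for g in groups], dtype=int)


def confusion_and_sensitivity(predictions, labels) -> dict:
    """2x2 confusion matrix (rows = true class) and per-class recall.

    ``predictions``/``labels`` are class-name sequences or binary arrays
    (1 = breakthrough).  Raises when a class has no support.
    """
    def _to_idx(seq):
        arr = np.asarray(seq)
        if arr.dtype.kind in "if":
            return arr.astype(int)
        return np.array([CLASSES.index(v) for v in arr])

    y_true = _to_idx(labels)
    y_pred = _to_idx(predictions)
    cm = np.zeros((2, 2), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[t, p] += 1
    support = cm.sum(axis=1)
    if np.any(support == 0):
        missing = [CLASSES[i] for i in np.flatnonzero(support == 0)]
        raise EvaluationError(f"no support for class(es): {missing}")
    sens = cm.diagonal() / support
    return {
        "confusion": cm,
        "normalized": cm / support[:, None],
        "sensitivity": {CLASSES[i]: float(sens[i]) for i in range(2)},
        "accuracy": float(cm.diagonal().sum() / cm.sum()),
    }


@dataclass
class FoldResult:
    fold: int
    confusion: np.ndarray
    sensitivity: dict
    test_accuracy: float
    train_accuracy: float
    lr_events: list
    n_train: int
    n_test: int


@dataclass
class EvalReport:
    """Cross-validated detection performance for one configuration."""

    window_ms: float
    position: str
    folds: list[FoldResult]
    seed: int

    def sensitivity_stats(self, label: str = "breakthrough") -> tuple[float, float]:
        vals = np.array([f.sensitivity[label] for f in self.folds])
        return float(vals.mean()), float(vals.std(ddof=1) if len(vals) > 1 else 0.0)

    @property
    def mean_test_accuracy(self) -> float:
        return float(np.mean([f.test_accuracy for f in self.folds]))

    @property
    def mean_train_accuracy(self) -> float:
        return float(np.mean([f.train_accuracy for f in self.folds]))

    def summary(self) -> str:
        bt = self.sensitivity_stats("breakthrough")
        ct = self.sensitivity_stats("cortical")
        lines = [
            f"Breakthrough detection — {self.window_ms:.0f} ms window, "
            f"position: {self.position}",
            "=" * 60,
            f"folds:                     {len(self.folds)}",
            f"sensitivity breakthrough:  {100*bt[0]:.2f} +- {100*bt[1]:.2f} %",
            f"sensitivity cortical:      {100*ct[0]:.2f} +- {100*ct[1]:.2f} %",
            f"mean accuracy (train):     {100*self.mean_train_accuracy:.2f} %",
            f"mean accuracy (test):      {100*self.mean_test_accuracy:.2f} %",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "window_ms": self.window_ms,
            "position": self.position,
            "seed": self.seed,
            "sensitivity_breakthrough": self.sensitivity_stats("breakthrough"),
            "sensitivity_cortical": self.sensitivity_stats("cortical"),
            "mean_train_accuracy": self.mean_train_accuracy,
            "mean_test_accuracy": self.mean_test_accuracy,
            "folds": [
                {
                    "fold": f.fold,
                    "confusion": f.confusion.tolist(),
                    "sensitivity": f.sensitivity,
                    "test_accuracy": f.test_accuracy,
                    "train_accuracy": f.train_accuracy,
                    "lr_events": f.lr_events,
                    "n_train": f.n_train,
                    "n_test": f.n_test,
                }
                for f in self.folds
            ],
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def confusion_table(self) -> pd.DataFrame:
        rows = []
        for f in self.folds:
            for i, true in enumerate(CLASSES):
                for j, pred in enumerate(CLASSES):
                    rows.append(
                        {"fold": f.fold, "true": true, "predicted": pred,
                         "count": int(f.confusion[i, j])}
                    )
        return pd.DataFrame(rows)

    def plot_confusion(self, ax=None):
        """Mean row-normalized confusion matrix as a heatmap."""
        import matplotlib.pyplot as plt

        norm = np.mean(
            [f.confusion / f.confusion.sum(axis=1, keepdims=True) for f in self.folds],
            axis=0,
        )
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(norm, cmap="Blues", vmin=0, vmax=1)
        ax.set_xticks([0, 1], CLASSES)
        ax.set_yticks([0, 1], CLASSES)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        for i in range(2):
            for j in range(2):
                ax.text(j, i, f"{norm[i, j]:.2f}", ha="center", va="center",
                        color="white" if norm[i, j] > 0.5 else "black")
        ax.figure.colorbar(im, ax=ax, fraction=0.046)
        return ax


# --- per-fold training pipeline ---------------------------------------------

#: decimation of cortical training windows relative to the L/4 grid
CORTICAL_TRAIN_DECIMATION = 4


def _grid_windows(rec: LabeledRecording, cfg: StftConfig) -> list[Window]:
    return window_labels(rec.as_clip(), rec.events, cfg)


def _training_clips(recs, cfg: StftConfig):
    """Overlap-labeled windows of the training recordings, as clips.

    Breakthrough windows keep the dense L/4 grid; cortical windows are
    decimated to a non-overlapping grid.
    """
    cortical, breakthrough = [], []
    for rec in recs:
        for i, w in enumerate(_grid_windows(rec, cfg)):
            clip = AudioClip(
                samples=w.samples,
                sample_rate=rec.sample_rate,
                label=w.label,
                source_id=rec.source_id,
                position=rec.position,
            )
            if w.label == "breakthrough":
                breakthrough.append(clip)
            elif i % CORTICAL_TRAIN_DECIMATION == 0:
                cortical.append(clip)
    return cortical, breakthrough


def _clip_window_count(clip: AudioClip, cfg: StftConfig) -> float:
    n = len(clip.samples)
    if n < cfg.window_length:
        return 0.0
    return 1.0 + (n - cfg.window_length) // cfg.step


def _clips_to_features(clips, extractor: LogMelExtractor, label: int):
    cfg = extractor.cfg
    windows = []
    for clip in clips:
        for w in frame_signal(clip.samples, cfg):
            windows.append(w)
    if not windows:
        return np.empty((0, cfg.n_mels, cfg.n_frames), np.float32), np.empty(0, np.int8)
    X = extractor.batch(np.asarray(windows))
    y = np.full(len(windows), label, dtype=np.int8)
    return X, y


def train_fold(
    train_recs,
    test_recs,
    stft_cfg: StftConfig,
    model_spec: ModelSpec,
    train_cfg: TrainingConfig,
    aug_spec: AugmentationSpec | None = None,
    loss_params: FocalLossParams | None = None,
    fold_seed: int = 0,
):
    """Train on one fold's training recordings, score its held-out windows.

    Returns ``(result, fold_metrics)`` where ``result`` is the
    :class:`~drilldetect.model.TrainingResult` and ``fold_metrics`` holds
    the held-out confusion matrix and sensitivities.  Normalization and
    augmentation derive from the training split only; held-out recordings
    are scored on the full L/4 sliding grid.
    """
    aug_spec = aug_spec or AugmentationSpec()
    extractor = LogMelExtractor(stft_cfg)

    cortical, breakthrough = _training_clips(train_recs, stft_cfg)
    if not cortical or not breakthrough:
        raise EvaluationError("training split lacks one of the classes")

    balanced = balance_training_set(
        {"cortical": cortical, "breakthrough": breakthrough},
        aug_spec,
        count_fn=lambda c: _clip_window_count(c, stft_cfg),
        seed=fold_seed,
    )

    X_c, y_c = _clips_to_features(balanced["cortical"], extractor, 0)
    X_b, y_b = _clips_to_features(balanced["breakthrough"], extractor, 1)
    X_train = np.concatenate([X_c, X_b])
    y_train = np.concatenate([y_c, y_b])

    stats = fit_normalization([X_train])
    X_train = (X_train - np.float32(stats.mu)) / np.float32(stats.sigma)

    test_windows: list[Window] = []
    test_of_rec: list[int] = []
    for ri, rec in enumerate(test_recs):
        ws = _grid_windows(rec, stft_cfg)
        test_windows.extend(ws)
        test_of_rec.extend([ri] * len(ws))
    X_test = extractor.batch(np.asarray([w.samples for w in test_windows]), stats=stats)
    y_test = np.array([1 if w.label == "breakthrough" else 0 for w in test_windows], np.int8)

    clf = BreakthroughClassifier(model_spec, loss_params, train_cfg)
    result = clf.fit(X_train, y_train, X_test, y_test, seed=fold_seed)

    pred_test = result.predict(X_test)
    pred_train = result.predict(X_train)
    metrics = confusion_and_sensitivity(pred_test, y_test)
    metrics["train_accuracy"] = float((pred_train == y_train).mean())
    metrics["n_train"] = len(y_train)
    metrics["n_test"] = len(y_test)
    metrics["stats"] = stats
    return result, metrics


def cross_validate(
    recordings,
    stft_cfg: StftConfig | None = None,
    model_spec: ModelSpec | None = None,
    train_cfg: TrainingConfig | None = None,
    aug_spec: AugmentationSpec | None = None,
    loss_params: FocalLossParams | None = None,
    position: str | None = None,
) -> EvalReport:
    """Grouped k-fold cross-validation over labeled recordings."""
    stft_cfg = stft_cfg or StftConfig()
    model_spec = model_spec or ModelSpec.reduced()
    train_cfg = train_cfg or TrainingConfig()
    folds = make_folds(recordings, k=train_cfg.folds, seed=train_cfg.seed)
    results = []
    for fold in range(train_cfg.folds):
        train_recs = [r for r, f in zip(recordings, folds) if f != fold]
        test_recs = [r for r, f in zip(recordings, folds) if f == fold]
        result, metrics = train_fold(
            train_recs,
            test_recs,
            stft_cfg,
            model_spec,
            train_cfg,
            aug_spec,
            loss_params,
            fold_seed=(train_cfg.seed * 1000 + fold) % (2**31),
        )
        results.append(
            FoldResult(
                fold=fold,
                confusion=metrics["confusion"],
                sensitivity=metrics["sensitivity"],
                test_accuracy=metrics["accuracy"],
                train_accuracy=metrics["train_accuracy"],
                lr_events=result.lr_events,
                n_train=metrics["n_train"],
                n_test=metrics["n_test"],
            )
        )
    pos = position or (recordings[0].position if recordings else "synthetic")
    return EvalReport(
        window_ms=stft_cfg.window_ms, position=pos, folds=results, seed=train_cfg.seed
    )


def compare_window_lengths(
    recordings,
    window_ms_list=(100, 50, 25),
    model_spec: ModelSpec | None = None,
    train_cfg: TrainingConfig | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Re-run cross-validation for each window length; tabulate sensitivity.

    All three standard configurations produce identically-shaped 256x69
    features, so the same architecture is trained throughout.
    """
    rows = []
    reports = {}
    for wms in window_ms_list:
        cfg = StftConfig.for_window_ms(wms)
        rep = cross_validate(recordings, cfg, model_spec, train_cfg, **kwargs)
        reports[wms] = rep
        bt, ct = rep.sensitivity_stats("breakthrough"), rep.sensitivity_stats("cortical")
        rows.append(
            {
                "window_ms": wms,
                "sensitivity_breakthrough_mean": bt[0],
                "sensitivity_breakthrough_std": bt[1],
                "sensitivity_cortical_mean": ct[0],
                "sensitivity_cortical_std": ct[1],
            }
        )
    table = pd.DataFrame(rows).set_index("window_ms")
    table.attrs["reports"] = reports
    return table


def compare_positions(
    corpus_a,
    corpus_b,
    stft_cfg: StftConfig | None = None,
    model_spec: ModelSpec | None = None,
    train_cfg: TrainingConfig | None = None,
    **kwargs,
) -> tuple[EvalReport, EvalReport]:
    """Treat two sensor positions as independent datasets, evaluate both."""
    stft_cfg = stft_cfg or StftConfig()
    sr_a = {r.sample_rate for r in corpus_a}
    sr_b = {r.sample_rate for r in corpus_b}
    if sr_a != sr_b:
        raise EvaluationError("corpora must share the window configuration")
    rep_a = cross_validate(corpus_a, stft_cfg, model_spec, train_cfg, **kwargs)
    rep_b = cross_validate(corpus_b, stft_cfg, model_spec, train_cfg, **kwargs)
    return rep_a, rep_b
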