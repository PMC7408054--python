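"""CNN B-scan tumor classifier with leakage-free, sample-aware evaluation.

B-scans are resized to 128 x 128 and min-max normalized to [0, 1] per
image, then classified tumor (1) vs. non-neoplastic brain parenchyma (0) by
a small sequential conv-net (conv / max-pool blocks, dense, dropout 0.5,
softmax) trained with Adam on categorical cross-entropy.

Cross-validation is *sample-aware*: folds partition sample IDs, never
individual B-scans, so scans of one biopsy cannot appear on both sides of a
split; final evaluation additionally enforces patient-disjoint test data.
A "nonsense" test on out-of-distribution images with balanced arbitrary
labels checks that reported accuracy honestly falls to chance (~50%) when
the input carries no class signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.transform import resize
from sklearn.metrics import auc, roc_curve

from fioct._nn import SequentialCNN
from fioct.errors import InvalidParameterError, LeakageError
from fioct.synthetic_data import LabeledBScanSet

__all__ = [
    "ModelConfig",
    "MetricsReport",
    "TrainedClassifier",
    "preprocess_bscan",
    "preprocess_set",
    "make_folds",
    "train_model",
    "cross_validate",
    "evaluate",
    "nonsense_test",
]

INPUT_SIZE = (128, 128)


@dataclass
class ModelConfig:
    """Hyperparameters of the sequential CNN.

    Defaults follow the emulated training protocol (Adam, dropout 0.5,
    100 epochs); filter counts are a package choice sized for CPU training.
    """

    conv_channels: tuple[int, ...] = (8, 16, 32)
    kernel_size: int = 3
    dense_units: int = 64
    dropout: float = 0.5
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 16
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise InvalidParameterError("dropout must be in [0, 1)")
        if self.epochs < 1:
            raise InvalidParameterError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise InvalidParameterError("only the adam optimizer is supported")


#: Reduced-epoch configuration used by the package's own evaluation runs on
#: synthetic data (the textures separate quickly; see docs/methods.md).
EVAL_EPOCHS = 8


def evaluation_config(seed: int = 0, epochs: int = EVAL_EPOCHS) -> ModelConfig:
    """Default-architecture config at the package's evaluation epoch budget."""
    return ModelConfig(epochs=epochs, seed=seed)


@dataclass
class MetricsReport:
    """Contingency table plus derived classification metrics and ROC/AUC."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float

    @staticmethod
    def from_scores(
        y_true: np.ndarray, tumor_score: np.ndarray, threshold: float = 0.5
    ) -> "MetricsReport":
        """Build the report from true labels and continuous tumor scores.

        Hard predictions use ``score > threshold`` (default 0.5); the ROC
        curve and AUC use the continuous score.  Undefined ratios (empty
        denominator) are reported as NaN.
        """
        y_true = np.asarray(y_true, dtype=int)
        score = np.asarray(tumor_score, dtype=float)
        pred = (score > threshold).astype(int)
        tp = int(np.sum((pred == 1) & (y_true == 1)))
        fp = int(np.sum((pred == 1) & (y_true == 0)))
        tn = int(np.sum((pred == 0) & (y_true == 0)))
        fn = int(np.sum((pred == 0) & (y_true == 1)))

        def ratio(a: int, b: int) -> float:
            return a / b if b else float("nan")

        if len(np.unique(y_true)) == 2:
            fpr, tpr, _ = roc_curve(y_true, score)
            roc_auc = float(auc(fpr, tpr))
        else:
            fpr = tpr = np.array([])
            roc_auc = float("nan")
        return MetricsReport(
            tp=tp, fp=fp, tn=tn, fn=fn,
            accuracy=ratio(tp + tn, tp + tn + fp + fn),
            sensitivity=ratio(tp, tp + fn),
            specificity=ratio(tn, tn + fp),
            ppv=ratio(tp, tp + fp),
            npv=ratio(tn, tn + fn),
            roc_fpr=fpr, roc_tpr=tpr, auc=roc_auc,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["roc_fpr"] = np.asarray(self.roc_fpr).tolist()
        d["roc_tpr"] = np.asarray(self.roc_tpr).tolist()
        return d


@dataclass
class TrainedClassifier:
    """A fitted CNN plus the sample/patient identity of its training data."""

    net: SequentialCNN
    config: ModelConfig
    train_sample_ids: np.ndarray
    train_patient_ids: np.ndarray
    history: dict = field(default_factory=dict)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Per-class probabilities (columns: [non-tumor, tumor]) summing to 1."""
        return self.net.predict_proba(preprocess_set(images))

    def tumor_score(self, images: np.ndarray) -> np.ndarray:
        return self.predict_proba(images)[:, 1]

    def save(self, path) -> None:
        path = Path(path)
        weights = self.net.get_weights()
        np.savez(
            path,
            *weights,
            config=json.dumps(asdict(self.config)),
            train_sample_ids=self.train_sample_ids,
            train_patient_ids=self.train_patient_ids,
        )

    @staticmethod
    def load(path) -> "TrainedClassifier":
        data = np.load(Path(path), allow_pickle=False)
        cfg_dict = json.loads(str(data["config"]))
        cfg_dict["conv_channels"] = tuple(cfg_dict["conv_channels"])
        config = ModelConfig(**cfg_dict)
        net = _build_net(config)
        weights = [data[k] for k in data.files if k.startswith("arr_")]
        net.set_weights(weights)
        return TrainedClassifier(
            net=net,
            config=config,
            train_sample_ids=data["train_sample_ids"],
            train_patient_ids=data["train_patient_ids"],
        )


def preprocess_bscan(bscan: np.ndarray) -> np.ndarray:
    """Resize a grayscale B-scan to 128 x 128 and min-max scale to [0, 1].

    Bilinear interpolation; a constant input maps to all zeros (the min-max
    denominator would vanish).
    """
    img = np.asarray(bscan, dtype=float)
    if img.size == 0 or img.ndim != 2:
        raise InvalidParameterError("B-scan must be a non-empty 2D image")
    if img.shape != INPUT_SIZE:
        img = resize(img, INPUT_SIZE, order=1, preserve_range=True,
                     anti_aliasing=False)
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.zeros(INPUT_SIZE, dtype=np.float32)
    return ((img - lo) / (hi - lo)).astype(np.float32)


def preprocess_set(images: np.ndarray) -> np.ndarray:
    return np.stack([preprocess_bscan(im) for im in images])


def make_folds(
    dataset: LabeledBScanSet, k: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Sample-aware k-fold partitions: folds split *sample IDs*, not scans.

    Unique sample IDs are shuffled and split into k validation groups;
    every sample appears in exactly one validation fold, and no fold shares
    a sample between its train and validation side.  Returns per-fold
    (train_indices, val_indices) into the dataset.
    """
    samples = np.unique(dataset.sample_ids)
    if len(samples) < k:
        raise InvalidParameterError(
            f"{len(samples)} samples cannot form {k} sample-disjoint folds"
        )
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(samples)
    folds = []
    for val_samples in np.array_split(shuffled, k):
        val_mask = np.isin(dataset.sample_ids, val_samples)
        train_idx = np.flatnonzero(~val_mask)
        val_idx = np.flatnonzero(val_mask)
        assert not set(dataset.sample_ids[train_idx]) & set(dataset.sample_ids[val_idx])
        folds.append((train_idx, val_idx))
    return folds


def _build_net(config: ModelConfig) -> SequentialCNN:
    return SequentialCNN(
        input_shape=INPUT_SIZE,
        n_classes=config.n_classes,
        conv_channels=config.conv_channels,
        kernel_size=config.kernel_size,
        dense_units=config.dense_units,
        dropout=config.dropout,
        learning_rate=config.learning_rate,
        seed=config.seed,
    )


def train_model(train_set: LabeledBScanSet, config: ModelConfig) -> TrainedClassifier:
    """Fit the CNN on a labeled B-scan set.

    Raises on a single-class training set.  Training curves (per-epoch loss
    and accuracy) are kept on the returned classifier.
    """
    if len(np.unique(train_set.labels)) < 2:
        raise InvalidParameterError("training set must contain both classes")
    net = _build_net(config)
    x = preprocess_set(train_set.images)
    history = net.fit(x, train_set.labels, epochs=config.epochs,
                      batch_size=config.batch_size)
    return TrainedClassifier(
        net=net,
        config=config,
        train_sample_ids=np.unique(train_set.sample_ids),
        train_patient_ids=np.unique(train_set.patient_ids),
        history=history,
    )


def cross_validate(
    dataset: LabeledBScanSet, config: ModelConfig, k: int = 10, seed: int = 0
) -> dict:
    """Sample-aware k-fold cross-validation; returns per-fold accuracies."""
    accuracies = []
    for fold, (train_idx, val_idx) in enumerate(make_folds(dataset, k=k, seed=seed)):
        fold_cfg = ModelConfig(**{**asdict(config), "seed": config.seed + fold})
        fold_cfg.conv_channels = tuple(fold_cfg.conv_channels)
        clf = train_model(dataset.subset(train_idx), fold_cfg)
        val = dataset.subset(val_idx)
        pred = clf.tumor_score(val.images) > 0.5
        accuracies.append(float(np.mean(pred.astype(int) == val.labels)))
    return {
        "fold_accuracy": accuracies,
        "mean_accuracy": float(np.mean(accuracies)),
        "k": k,
    }


def evaluate(clf: TrainedClassifier, test_set: LabeledBScanSet) -> MetricsReport:
    """Contingency table, accuracy/sensitivity/specificity/PPV/NPV, ROC/AUC.

    Refuses to score a test set sharing any sample or patient with the
    training data (information leakage).
    """
    shared_p = set(clf.train_patient_ids) & set(np.unique(test_set.patient_ids))
    shared_s = set(clf.train_sample_ids) & set(np.unique(test_set.sample_ids))
    if shared_p or shared_s:
        raise LeakageError(
            f"test set shares patients {sorted(shared_p)} / samples "
            f"{sorted(shared_s)} with training data"
        )
    scores = clf.tumor_score(test_set.images)
    return MetricsReport.from_scores(test_set.labels, scores)


def nonsense_test(
    clf: TrainedClassifier, images: np.ndarray, labels: np.ndarray
) -> float:
    """Accuracy on out-of-distribution images with balanced arbitrary labels.

    Because the labels are independent of anything the model can extract,
    expected accuracy is chance level (0.5 for a balanced binary set).
    """
    labels = np.asarray(labels, dtype=int)
    pred = (clf.tumor_score(images) > 0.5).astype(int)
    return float(np.mean(pred == labels))
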