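"""The three maturity-stage classifiers: RBF-SVM, 1D-CNN and SAE.

All three expose the same fit/predict surface over a calibration matrix
(samples x channels) and 0-based stage labels, so the pipeline can swap
them by configuration.  The SVM delegates to scikit-learn (RBF kernel,
one-vs-one, randomized log-uniform search over C and gamma in
[1e-4, 1e3] scored by stratified 5-fold CV).  The two deep models run on
the package's numpy backprop core: the CNN follows the published layer
table (64 then 32 stride-2 kernels of size 2, a size-3 stride-1 max
pool, dense 512/64 heads — 128/32 when the input is the CARS-selected
channel subset — batch norm throughout, dropout 0.5, softmax over the
five stages); the SAE greedily pretrains two autoencoder layers and then
fine-tunes encoders plus a softmax head end-to-end.

Inputs to the deep models are standardized per channel with calibration
statistics frozen at fit time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import loguniform
from sklearn.model_selection import RandomizedSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import nn

__all__ = [
    "SvmSearchConfig",
    "TrainConfig",
    "CnnArchitecture",
    "SaeArchitecture",
    "cnn_feature_lengths",
    "build_cnn",
    "SvmStageClassifier",
    "CnnStageClassifier",
    "SaeStageClassifier",
    "train_svm",
    "train_cnn",
    "train_sae",
    "make_classifier",
]

N_STAGES = 5


@dataclass
class SvmSearchConfig:
    """Randomized-search box for the RBF-SVM hyperparameters."""

    c_low: float = 1e-4
    c_high: float = 1e3
    gamma_low: float = 1e-4
    gamma_high: float = 1e3
    n_candidates: int = 50
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.c_low, self.gamma_low) <= 0:
            raise ValueError("search bounds must be positive")


@dataclass
class TrainConfig:
    """Gradient-training settings shared by the CNN and the SAE head.

    Defaults are the published ones (batch 10, learning rate 1e-4,
    1000 epochs, weight decay); tests run a shorter-epoch profile.
    """

    batch_size: int = 10
    learning_rate: float = 1e-4
    epochs: int = 1000
    weight_decay: float = 1e-4
    dropout: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs/batch_size/learning_rate must be positive")


def cnn_feature_lengths(input_length: int) -> tuple[int, int, int, int]:
    """Lengths after conv1 / pool / conv2, plus the flattened width.

    Valid convolutions: L -> floor((L - k) / s) + 1.
    """

    def out(l: int, k: int, s: int, name: str) -> int:
        if l < k:
            raise ValueError(f"input too short at layer {name!r} (length {l}, kernel {k})")
        return (l - k) // s + 1

    l1 = out(input_length, 2, 2, "conv1")
    l2 = out(l1, 3, 1, "maxpool")
    l3 = out(l2, 2, 2, "conv2")
    return l1, l2, l3, l3 * 32


@dataclass
class CnnArchitecture:
    """Published 1D-CNN layer table; dense widths switch with input mode."""

    input_length: int
    mode: str = "full"  # "full" spectra or CARS-"selected" channels
    conv1_kernels: int = 64
    conv2_kernels: int = 32
    kernel_size: int = 2
    conv_stride: int = 2
    pool_size: int = 3
    pool_stride: int = 1
    dropout: float = 0.5
    n_classes: int = N_STAGES

    def __post_init__(self) -> None:
        if self.mode not in ("full", "selected"):
            raise ValueError("mode must be 'full' or 'selected'")
        if self.input_length < 8:
            raise ValueError("input_length must be >= 8")

    @property
    def dense_sizes(self) -> tuple[int, int]:
        return (512, 64) if self.mode == "full" else (128, 32)

    @property
    def feature_lengths(self) -> tuple[int, int, int, int]:
        return cnn_feature_lengths(self.input_length)


def build_cnn(arch: CnnArchitecture, rng: np.random.Generator) -> nn.Sequential:
    """Materialise the layer stack (conv -> BN -> ReLU ordering)."""
    _, _, _, flat = arch.feature_lengths
    d1, d2 = arch.dense_sizes
    layers = [
        nn.Conv1d(1, arch.conv1_kernels, arch.kernel_size, arch.conv_stride, rng),
        nn.BatchNorm(arch.conv1_kernels),
        nn.ReLU(),
        nn.MaxPool1d(arch.pool_size, arch.pool_stride),
        nn.Conv1d(
            arch.conv1_kernels, arch.conv2_kernels, arch.kernel_size, arch.conv_stride, rng
        ),
        nn.BatchNorm(arch.conv2_kernels),
        nn.ReLU(),
        nn.Flatten(),
        nn.Dense(flat, d1, rng),
        nn.BatchNorm(d1),
        nn.ReLU(),
        nn.Dropout(arch.dropout, rng),
        nn.Dense(d1, d2, rng),
        nn.BatchNorm(d2),
        nn.ReLU(),
        nn.Dropout(arch.dropout, rng),
        nn.Dense(d2, arch.n_classes, rng),
    ]
    return nn.Sequential(layers)


@dataclass
class SaeArchitecture:
    """Stacked-autoencoder shape: strictly decreasing encoder widths."""

    encoder_sizes: tuple[int, int] = (256, 64)
    pretrain_epochs: int = 200
    n_classes: int = N_STAGES

    def __post_init__(self) -> None:
        if not all(a > b for a, b in zip(self.encoder_sizes, self.encoder_sizes[1:])):
            raise ValueError("encoder sizes must be strictly decreasing")

    @classmethod
    def for_input(cls, input_length: int, pretrain_epochs: int = 200) -> "SaeArchitecture":
        """Default widths: 256/64 for full spectra, 64/16 for selected subsets."""
        sizes = (256, 64) if input_length >= 512 else (64, 16)
        return cls(sizes, pretrain_epochs)


class _Standardizer:
    """Per-channel z-scoring with calibration statistics frozen at fit."""

    def fit(self, x: np.ndarray) -> "_Standardizer":
        self.mean_ = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        self.sd_ = sd
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.mean_.size:
            raise ValueError(
                f"channel mismatch: got {x.shape[1]}, trained on {self.mean_.size}"
            )
        return (x - self.mean_) / self.sd_


class SvmStageClassifier:
    """RBF-SVM with randomized (C, gamma) search, one-vs-one multiclass."""

    def __init__(self, config: SvmSearchConfig | None = None) -> None:
        self.config = config or SvmSearchConfig()

    def fit(self, x: np.ndarray, labels: np.ndarray) -> "SvmStageClassifier":
        labels = np.asarray(labels, dtype=int)
        classes, counts = np.unique(labels, return_counts=True)
        if classes.size < 2:
            raise ValueError("SVM training needs at least two classes")
        if counts.min() < self.config.cv_folds:
            warnings.warn(
                "fewer samples than CV folds in some class; folds reduced",
                stacklevel=2,
            )
        folds = min(self.config.cv_folds, int(counts.min()))
        cv = StratifiedKFold(n_splits=max(folds, 2), shuffle=True, random_state=self.config.seed)
        pipe = Pipeline(
            [
                ("scale", StandardScaler()),
                ("svc", SVC(kernel="rbf", decision_function_shape="ovo")),
            ]
        )
        search = RandomizedSearchCV(
            pipe,
            param_distributions={
                "svc__C": loguniform(self.config.c_low, self.config.c_high),
                "svc__gamma": loguniform(self.config.gamma_low, self.config.gamma_high),
            },
            n_iter=self.config.n_candidates,
            cv=cv,
            scoring="accuracy",
            random_state=self.config.seed,
            refit=True,
        )
        search.fit(x, labels)
        self.search_ = search
        self.best_params_ = (
            float(search.best_params_["svc__C"]),
            float(search.best_params_["svc__gamma"]),
        )
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.search_.predict(x)


class CnnStageClassifier:
    """Table-1 1D-CNN trained with AdamW cross-entropy."""

    def __init__(
        self, mode: str = "full", train_config: TrainConfig | None = None
    ) -> None:
        self.mode = mode
        self.train_config = train_config or TrainConfig()

    def fit(self, x: np.ndarray, labels: np.ndarray) -> "CnnStageClassifier":
        cfg = self.train_config
        labels = np.asarray(labels, dtype=int)
        self.scaler_ = _Standardizer().fit(x)
        xs = self.scaler_.transform(x)[:, None, :]  # (N, 1, L)
        rng = np.random.default_rng(cfg.seed)
        self.arch_ = CnnArchitecture(
            input_length=x.shape[1], mode=self.mode, dropout=cfg.dropout
        )
        self.net_ = build_cnn(self.arch_, rng)
        self.loss_history_ = nn.train_classifier(
            self.net_,
            xs,
            labels,
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            lr=cfg.learning_rate,
            weight_decay=cfg.weight_decay,
            rng=rng,
        )
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        xs = self.scaler_.transform(x)[:, None, :]
        return nn.softmax(self.net_.forward(xs, train=False))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)


class SaeStageClassifier:
    """Greedy layer-wise pretrained stacked autoencoder + softmax head."""

    def __init__(
        self,
        arch: SaeArchitecture | None = None,
        train_config: TrainConfig | None = None,
    ) -> None:
        self.arch = arch
        self.train_config = train_config or TrainConfig()

    def fit(self, x: np.ndarray, labels: np.ndarray) -> "SaeStageClassifier":
        cfg = self.train_config
        labels = np.asarray(labels, dtype=int)
        arch = self.arch or SaeArchitecture.for_input(x.shape[1])
        self.arch_ = arch
        self.scaler_ = _Standardizer().fit(x)
        xs = self.scaler_.transform(x)
        rng = np.random.default_rng(cfg.seed)

        # greedy pretraining: each AE reconstructs its own input
        self.pretrain_losses_ = []
        encoders = []
        current = xs
        for width in arch.encoder_sizes:
            enc = nn.Dense(current.shape[1], width, rng)
            ae = nn.Sequential([enc, nn.ReLU(), nn.Dense(width, current.shape[1], rng)])
            losses = nn.train_autoencoder(
                ae,
                current,
                current,
                epochs=arch.pretrain_epochs,
                batch_size=cfg.batch_size,
                lr=1e-3,
                weight_decay=0.0,
                rng=rng,
            )
            self.pretrain_losses_.append(losses)
            encoders.append(enc)
            current = nn.Sequential([enc, nn.ReLU()]).forward(current, train=False)

        # fine-tune: pretrained encoders + fresh softmax head, end to end
        stack: list[nn.Layer] = []
        for enc in encoders:
            stack += [enc, nn.ReLU()]
        stack.append(nn.Dense(arch.encoder_sizes[-1], arch.n_classes, rng))
        self.net_ = nn.Sequential(stack)
        self.finetune_losses_ = nn.train_classifier(
            self.net_,
            xs,
            labels,
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            lr=cfg.learning_rate,
            weight_decay=cfg.weight_decay,
            rng=rng,
        )
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.net_.forward(self.scaler_.transform(x), train=False))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)


# Functional wrappers matching the operation-style interface


def train_svm(
    x: np.ndarray, labels: np.ndarray, config: SvmSearchConfig | None = None
) -> tuple[SvmStageClassifier, tuple[float, float]]:
    clf = SvmStageClassifier(config).fit(x, labels)
    return clf, clf.best_params_


def train_cnn(
    x: np.ndarray,
    labels: np.ndarray,
    mode: str = "full",
    config: TrainConfig | None = None,
) -> tuple[CnnStageClassifier, list[float]]:
    clf = CnnStageClassifier(mode, config).fit(x, labels)
    return clf, clf.loss_history_


def train_sae(
    x: np.ndarray,
    labels: np.ndarray,
    arch: SaeArchitecture | None = None,
    config: TrainConfig | None = None,
) -> tuple[SaeStageClassifier, list[list[float]]]:
    clf = SaeStageClassifier(arch, config).fit(x, labels)
    return clf, clf.pretrain_losses_


def make_classifier(name: str, input_mode: str, train_config: TrainConfig | None = None,
                    svm_config: SvmSearchConfig | None = None):
    """Factory keyed by classifier name: 'svm', 'cnn' or 'sae'."""
    if name == "svm":
        return SvmStageClassifier(svm_config)
    if name == "cnn":
        return CnnStageClassifier(input_mode, train_config)
    if name == "sae":
        return SaeStageClassifier(None, train_config)
    raise ValueError(f"unknown classifier {name!r}")
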