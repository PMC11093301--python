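"""CNN feature extraction from FC matrices, exposed as sklearn-style estimators.

Two branches exist.  The *static* branch consumes the R x R Pearson matrix;
its kernels span whole rows (1 x R), then whole columns (R x 1), then 1 x 1,
so each first-layer filter weight addresses one ROI's connectivity profile.
The *dynamic* branch consumes the R x R x Q coherence tensor and prepends a
single-filter 1 x 1 convolution that compresses the Q frequency channels —
its Q weights rank frequency bands by discriminative value.

Each branch carries an auxiliary two-class head trained with Adam on softmax
cross-entropy; the head exists only to fit parameters.  The extracted feature
vector is the attention-gated 16-vector of the last convolutional block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._nn import BranchNet, train_branch
from .io_core import DimensionError, PipelineConfig, ValidationError

__all__ = [
    "BranchArchitecture",
    "TrainedExtractor",
    "DeepFeatures",
    "CnnBranchExtractor",
    "build_branch",
    "train_extractor",
    "extract_features",
]


@dataclass(frozen=True)
class BranchArchitecture:
    """Declarative description of one branch.

    ``conv_specs`` lists (filters, in_channels, kernel_h, kernel_w) in order;
    the dynamic branch's first entry is the channel compression.
    """

    kind: str
    n_roi: int
    in_channels: int
    conv_specs: tuple[tuple[int, int, int, int], ...]
    attention_hidden: int = 8
    attention_out: int = 16
    dropout: float = 0.5
    leaky_slope: float = 0.01

    @property
    def n_features(self) -> int:
        return self.conv_specs[-1][0]


def build_branch(kind: str, config: PipelineConfig) -> BranchArchitecture:
    """Architecture for ``kind`` in {'static', 'dynamic'} at the configured R, Q."""
    r = config.n_roi
    if r < 2:
        raise ValidationError("n_roi must be >= 2")
    if kind == "static":
        specs = ((32, 1, 1, r), (64, 32, r, 1), (16, 64, 1, 1))
        in_ch = 1
    elif kind == "dynamic":
        q = config.n_bands
        specs = ((1, q, 1, 1), (32, 1, 1, r), (64, 32, r, 1), (16, 64, 1, 1))
        in_ch = q
    else:
        raise ValidationError(f"unknown branch kind {kind!r}")
    return BranchArchitecture(
        kind=kind,
        n_roi=r,
        in_channels=in_ch,
        conv_specs=specs,
        dropout=config.dropout,
        leaky_slope=config.leaky_slope,
    )


class CnnBranchExtractor(BaseEstimator, TransformerMixin):
    """Fit one CNN branch on labelled FC inputs; transform to 16-d deep features.

    Parameters
    ----------
    kind : {'static', 'dynamic'}
        Which branch architecture to build.
    learning_rate, max_epochs, batch_size, dropout, leaky_slope :
        Training hyperparameters of the auxiliary head (defaults follow the
        published regime: Adam at 1e-4 for at most 50 epochs, dropout 0.5,
        LeakyReLU slope 0.01).
    random_state : int
        Seeds weight initialization, shuffling and dropout; identical seeds and
        data give identical fitted weights.
    """

    def __init__(
        self,
        kind: str = "static",
        *,
        learning_rate: float = 1e-4,
        max_epochs: int = 50,
        batch_size: int = 8,
        dropout: float = 0.5,
        leaky_slope: float = 0.01,
        random_state: int = 0,
    ):
        self.kind = kind
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.dropout = dropout
        self.leaky_slope = leaky_slope
        self.random_state = random_state

    def _coerce(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        expected_ndim = 3 if self.kind == "static" else 4
        if X.ndim != expected_ndim:
            raise DimensionError(
                f"{self.kind} branch expects {expected_ndim}-D input "
                f"(n_subjects first), got shape {X.shape}"
            )
        if not np.isfinite(X).all():
            raise ValidationError("FC input contains non-finite values")
        return X

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CnnBranchExtractor":
        X = self._coerce(X)
        y = np.asarray(y, dtype=int)
        if X.shape[0] != y.shape[0]:
            raise DimensionError("X and y disagree on the number of subjects")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2 or counts.min() < 2:
            raise ValidationError("need at least 2 subjects in each class")
        n_roi = X.shape[-1]
        n_channels = 1 if self.kind == "static" else X.shape[1]
        ss = np.random.SeedSequence(self.random_state).spawn(2)
        net = BranchNet(
            self.kind,
            n_roi,
            n_channels,
            dropout=self.dropout,
            leaky_slope=self.leaky_slope,
            rng=np.random.default_rng(ss[0]),
        )
        self.loss_trace_ = train_branch(
            net,
            X,
            y,
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            batch_size=self.batch_size,
            seed=ss[1],
        )
        self.net_ = net
        self.n_roi_ = n_roi
        self.n_channels_ = n_channels
        self.classes_ = classes
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Attention-weighted 16-d deep features, inference mode (deterministic)."""
        check_is_fitted(self, "net_")
        X = self._coerce(X)
        return self.net_.forward(X, train=False)["features"]

    def attention_weights(self, X: np.ndarray) -> np.ndarray:
        """Sigmoid gate values in (0, 1), one 16-vector per subject."""
        check_is_fitted(self, "net_")
        X = self._coerce(X)
        return self.net_.forward(X, train=False)["gate"]

    def head_predict(self, X: np.ndarray) -> np.ndarray:
        """Labels from the auxiliary head (used only to monitor training)."""
        check_is_fitted(self, "net_")
        X = self._coerce(X)
        logits = self.net_.forward(X, train=False)["logits"]
        return logits.argmax(axis=1)

    def head_accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.head_predict(X) == np.asarray(y, dtype=int)))

    @property
    def architecture_(self) -> BranchArchitecture:
        check_is_fitted(self, "net_")
        config = PipelineConfig(
            n_roi=self.n_roi_,
            n_bands=max(self.n_channels_, 2),
            dropout=self.dropout,
            leaky_slope=self.leaky_slope,
        )
        arch = build_branch(self.kind, config)
        if self.kind == "dynamic" and self.n_channels_ != config.n_bands:
            # n_bands floor of 2 in the config; rebuild specs with the true Q
            specs = ((1, self.n_channels_, 1, 1),) + arch.conv_specs[1:]
            arch = BranchArchitecture(
                kind="dynamic",
                n_roi=self.n_roi_,
                in_channels=self.n_channels_,
                conv_specs=specs,
                dropout=self.dropout,
                leaky_slope=self.leaky_slope,
            )
        return arch


@dataclass
class TrainedExtractor:
    """A fitted branch: architecture, weights, training trace and seed."""

    architecture: BranchArchitecture
    state: dict[str, np.ndarray]
    loss_trace: list[float]
    seed: int

    def to_net(self) -> BranchNet:
        net = BranchNet(
            self.architecture.kind,
            self.architecture.n_roi,
            self.architecture.in_channels,
            dropout=self.architecture.dropout,
            leaky_slope=self.architecture.leaky_slope,
            rng=0,
        )
        net.load_state_dict(self.state)
        return net

    def save(self, path: str | Path) -> None:
        """Checkpoint as .npz with a JSON sidecar describing the architecture."""
        path = Path(path)
        np.savez(path, **self.state)
        sidecar = path.with_suffix(path.suffix + ".json")
        with open(sidecar, "w") as fh:
            json.dump(
                {
                    "kind": self.architecture.kind,
                    "n_roi": self.architecture.n_roi,
                    "in_channels": self.architecture.in_channels,
                    "conv_specs": [list(s) for s in self.architecture.conv_specs],
                    "dropout": self.architecture.dropout,
                    "leaky_slope": self.architecture.leaky_slope,
                    "seed": self.seed,
                    "loss_trace": self.loss_trace,
                },
                fh,
            )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedExtractor":
        path = Path(path)
        with open(path.with_suffix(path.suffix + ".json")) as fh:
            meta = json.load(fh)
        with np.load(path if path.suffix == ".npz" else str(path)) as npz:
            state = {k: npz[k] for k in npz.files}
        arch = BranchArchitecture(
            kind=meta["kind"],
            n_roi=meta["n_roi"],
            in_channels=meta["in_channels"],
            conv_specs=tuple(tuple(s) for s in meta["conv_specs"]),
            dropout=meta["dropout"],
            leaky_slope=meta["leaky_slope"],
        )
        return cls(architecture=arch, state=state,
                   loss_trace=meta["loss_trace"], seed=meta["seed"])


@dataclass(frozen=True)
class DeepFeatures:
    """Per-subject attention-weighted features plus the gate values."""

    vector: np.ndarray
    attention_weights: np.ndarray


def train_extractor(
    arch: BranchArchitecture,
    inputs: list[tuple[np.ndarray, int]],
    config: PipelineConfig,
    seed: int,
) -> TrainedExtractor:
    """Train one branch on (FC tensor, label) pairs; functional wrapper."""
    X = np.stack([fc for fc, _ in inputs])
    y = np.array([label for _, label in inputs], dtype=int)
    est = CnnBranchExtractor(
        kind=arch.kind,
        learning_rate=config.learning_rate,
        max_epochs=config.max_epochs,
        batch_size=config.batch_size,
        dropout=arch.dropout,
        leaky_slope=arch.leaky_slope,
        random_state=seed,
    ).fit(X, y)
    return TrainedExtractor(
        architecture=est.architecture_,
        state=est.net_.state_dict(),
        loss_trace=est.loss_trace_,
        seed=seed,
    )


def extract_features(model: TrainedExtractor, fc_input: np.ndarray) -> DeepFeatures:
    """Inference-mode features for a single subject's FC input."""
    net = model.to_net()
    out = net.forward(np.asarray(fc_input, dtype=float)[None], train=False)
    return DeepFeatures(vector=out["features"][0], attention_weights=out["gate"][0])
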