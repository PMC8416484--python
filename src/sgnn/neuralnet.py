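"""Feed-forward neural network classifier with gdx training.

The classifier is a small multilayer perceptron — 3 inputs, a 9-unit and a
6-unit hidden layer, 1 output — with hyperbolic-tangent activations
throughout. Class targets are encoded as -1 (negative) / +1 (positive) and
the decision threshold sits at 0 on the output activation.

Training uses batch gradient descent with momentum and an adaptive
learning rate (the "gdx" scheme): after every epoch the learning rate
grows by ``lr_inc`` when the sum-of-squared-errors decreased, while an
epoch whose error exceeds the previous one by more than ``max_perf_inc``
is rejected outright and the learning rate shrinks by ``lr_dec``.

A trained predictor is packaged as a :class:`PredictorBundle` that also
carries the feature configuration and the Na4vSS normalization bounds
derived from its training data, so prediction is fully self-contained and
serializable to a single JSON document.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateTrainingError,
    DivergenceError,
    ModelLoadError,
)
from .features import (
    FeatureConfig,
    FeatureVector,
    NormalizationBounds,
    PKaEntry,
    PKaTable,
    PropensityScale,
    bounds_from_records,
    featurize,
)
from .sequence_io import NEGATIVE, POSITIVE, LabeledDataset, SequenceRecord

BUNDLE_FORMAT_VERSION = 1

DEFAULT_LAYER_SIZES = (3, 9, 6, 1)
INIT_RANGE = 0.5  # weights drawn uniform in [-INIT_RANGE, INIT_RANGE]


@dataclass
class MLPModel:
    """Multilayer perceptron with tanh activations and input scaling.

    ``input_scaling`` holds per-feature ``(offset, gain)`` pairs mapping raw
    features to roughly [-1, 1]: ``scaled = (x - offset) * gain``.
    """

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]  # weights[k]: (layer_sizes[k], layer_sizes[k+1])
    biases: list[np.ndarray]  # biases[k]: (layer_sizes[k+1],)
    activation: str = "tanh"
    input_offset: np.ndarray = field(
        default_factory=lambda: np.zeros(DEFAULT_LAYER_SIZES[0])
    )
    input_gain: np.ndarray = field(
        default_factory=lambda: np.ones(DEFAULT_LAYER_SIZES[0])
    )
    decision_threshold: float = 0.0

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.layer_sizes) - 1:
            raise ConfigurationError("one weight matrix per layer transition required")
        for k, (w, b) in enumerate(zip(self.weights, self.biases)):
            expect = (self.layer_sizes[k], self.layer_sizes[k + 1])
            if w.shape != expect:
                raise ConfigurationError(f"weights[{k}] shape {w.shape} != {expect}")
            if b.shape != (self.layer_sizes[k + 1],):
                raise ConfigurationError(f"biases[{k}] shape {b.shape} mismatch")
        if self.input_offset.shape != (self.layer_sizes[0],):
            raise ConfigurationError("input_offset must have one entry per input")
        if self.input_gain.shape != (self.layer_sizes[0],):
            raise ConfigurationError("input_gain must have one entry per input")
        if self.activation != "tanh":
            raise ConfigurationError(f"unsupported activation {self.activation!r}")

    def copy(self) -> "MLPModel":
        return MLPModel(
            layer_sizes=self.layer_sizes,
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            activation=self.activation,
            input_offset=self.input_offset.copy(),
            input_gain=self.input_gain.copy(),
            decision_threshold=self.decision_threshold,
        )


@dataclass(frozen=True)
class TrainConfig:
    """gdx hyperparameters; defaults follow the scheme's canonical settings."""

    epochs: int = 500
    goal: float = 0.01  # target sum of squared errors
    lr0: float = 0.01
    lr_inc: float = 1.05
    lr_dec: float = 0.7
    max_perf_inc: float = 1.04
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.lr_dec < 1.0 < self.lr_inc):
            raise ConfigurationError("require lr_dec < 1 < lr_inc")
        if self.max_perf_inc <= 1.0:
            raise ConfigurationError("max_perf_inc must exceed 1")
        if not 0.0 <= self.momentum < 1.0:
            raise ConfigurationError("momentum must lie in [0, 1)")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be positive")


@dataclass
class TrainReport:
    """Per-epoch record of an accepted-step training run."""

    error_trace: list[float]
    final_epoch: int
    final_lr: float
    stop_reason: str  # "goal reached" | "epochs exhausted"


def init_model(
    seed: int, layer_sizes: Sequence[int] = DEFAULT_LAYER_SIZES
) -> MLPModel:
    """Seeded random model: weights/biases uniform in [-0.5, 0.5]."""
    rng = np.random.default_rng(seed)
    sizes = tuple(int(s) for s in layer_sizes)
    weights = [
        rng.uniform(-INIT_RANGE, INIT_RANGE, size=(sizes[k], sizes[k + 1]))
        for k in range(len(sizes) - 1)
    ]
    biases = [
        rng.uniform(-INIT_RANGE, INIT_RANGE, size=sizes[k + 1])
        for k in range(len(sizes) - 1)
    ]
    return MLPModel(
        layer_sizes=sizes,
        weights=weights,
        biases=biases,
        input_offset=np.zeros(sizes[0]),
        input_gain=np.ones(sizes[0]),
    )


def _forward_batch(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Raw network outputs for an (n, n_inputs) matrix of raw features."""
    a = (X - model.input_offset) * model.input_gain
    for w, b in zip(model.weights, model.biases):
        a = np.tanh(a @ w + b)
    return a[:, 0]


def forward(model: MLPModel, features: FeatureVector | np.ndarray) -> float:
    """Network score for one feature vector; in (-1, 1) for tanh output."""
    x = features.as_array() if isinstance(features, FeatureVector) else np.asarray(features, dtype=float)
    if x.shape != (model.layer_sizes[0],):
        raise ConfigurationError(
            f"expected {model.layer_sizes[0]} features, got shape {x.shape}"
        )
    return float(_forward_batch(model, x[None, :])[0])


def classify(model: MLPModel, features: FeatureVector | np.ndarray) -> tuple[str, float]:
    """Binary decision plus raw score; ties at the threshold are positive."""
    score = forward(model, features)
    label = POSITIVE if score >= model.decision_threshold else NEGATIVE
    return label, score


def _sse_and_gradient(
    model: MLPModel, X: np.ndarray, t: np.ndarray
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """Sum-of-squared-errors and its gradient by backpropagation.

    X is raw features (n, n_in); t is the +-1 target vector (n,).
    """
    a = (X - model.input_offset) * model.input_gain
    activations = [a]
    for w, b in zip(model.weights, model.biases):
        a = np.tanh(a @ w + b)
        activations.append(a)
    out = activations[-1][:, 0]
    err = out - t
    sse = float(np.sum(err**2))

    # dE/d(out) = 2*err; tanh'(z) = 1 - a^2
    delta = (2.0 * err)[:, None] * (1.0 - activations[-1] ** 2)
    grads_w: list[np.ndarray] = [np.empty(0)] * len(model.weights)
    grads_b: list[np.ndarray] = [np.empty(0)] * len(model.biases)
    for k in range(len(model.weights) - 1, -1, -1):
        grads_w[k] = activations[k].T @ delta
        grads_b[k] = delta.sum(axis=0)
        if k > 0:
            delta = (delta @ model.weights[k].T) * (1.0 - activations[k] ** 2)
    return sse, grads_w, grads_b


def _targets(labels: Sequence[str]) -> np.ndarray:
    return np.array([1.0 if lab == POSITIVE else -1.0 for lab in labels])


def train_gdx(
    model: MLPModel,
    X: Sequence[FeatureVector] | np.ndarray,
    y: Sequence[str],
    config: TrainConfig,
) -> tuple[MLPModel, TrainReport]:
    """Batch gdx training on sum-of-squared-errors.

    Per epoch the candidate update is
    ``dw(t) = momentum * dw(t-1) - (1 - momentum) * lr * grad``.
    If the new error exceeds the old one by more than ``max_perf_inc`` the
    step is rejected (weights restored, momentum memory cleared) and the
    learning rate is multiplied by ``lr_dec``; otherwise the step is
    accepted and, when the error strictly decreased, the learning rate is
    multiplied by ``lr_inc``. Training stops when the error reaches
    ``goal`` or the epoch budget is exhausted. Deterministic for a fixed
    model and config.
    """
    if isinstance(X, np.ndarray):
        Xmat = np.asarray(X, dtype=float)
    else:
        Xmat = np.stack([fv.as_array() for fv in X])
    if Xmat.shape[0] != len(y):
        raise ConfigurationError(f"{Xmat.shape[0]} samples but {len(y)} labels")
    if Xmat.shape[0] < 2 or len(set(y)) < 2:
        raise DegenerateTrainingError(
            "training requires at least two samples covering both classes"
        )
    t = _targets(y)

    model = model.copy()
    lr = config.lr0
    vel_w = [np.zeros_like(w) for w in model.weights]
    vel_b = [np.zeros_like(b) for b in model.biases]

    error, grads_w, grads_b = _sse_and_gradient(model, Xmat, t)
    trace: list[float] = []
    stop_reason = "epochs exhausted"
    epoch = 0
    for epoch in range(1, config.epochs + 1):
        if error <= config.goal:
            stop_reason = "goal reached"
            epoch -= 1
            break
        prev_w = [w.copy() for w in model.weights]
        prev_b = [b.copy() for b in model.biases]
        for k in range(len(model.weights)):
            vel_w[k] = config.momentum * vel_w[k] - (1.0 - config.momentum) * lr * grads_w[k]
            vel_b[k] = config.momentum * vel_b[k] - (1.0 - config.momentum) * lr * grads_b[k]
            model.weights[k] += vel_w[k]
            model.biases[k] += vel_b[k]
        new_error, new_gw, new_gb = _sse_and_gradient(model, Xmat, t)
        if not np.isfinite(new_error):
            raise DivergenceError(f"non-finite training error at epoch {epoch}")
        if new_error > error * config.max_perf_inc:
            # reject: restore weights, clear momentum memory, shrink lr
            model.weights = prev_w
            model.biases = prev_b
            vel_w = [np.zeros_like(w) for w in model.weights]
            vel_b = [np.zeros_like(b) for b in model.biases]
            lr *= config.lr_dec
            trace.append(error)
        else:
            if new_error < error:
                lr *= config.lr_inc
            error, grads_w, grads_b = new_error, new_gw, new_gb
            trace.append(error)
    else:
        if error <= config.goal:
            stop_reason = "goal reached"

    return model, TrainReport(
        error_trace=trace,
        final_epoch=epoch,
        final_lr=lr,
        stop_reason=stop_reason,
    )


# ---------------------------------------------------------------------------
# end-to-end predictor bundle

@dataclass
class PredictorBundle:
    """Self-contained predictor: trained model + feature configuration."""

    model: MLPModel
    feature_config: FeatureConfig
    train_config: TrainConfig | None = None

    def featurize(self, record: SequenceRecord) -> FeatureVector:
        return featurize(record, self.feature_config)

    def predict_record(self, record: SequenceRecord) -> tuple[FeatureVector, str, float]:
        fv = self.featurize(record)
        label, score = classify(self.model, fv)
        return fv, label, score


def _input_scaling(F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature min-max scaling to [-1, 1]; constant features map to 0."""
    lo, hi = F.min(axis=0), F.max(axis=0)
    offset = (lo + hi) / 2.0
    span = hi - lo
    gain = np.where(span > 0, 2.0 / np.where(span > 0, span, 1.0), 0.0)
    return offset, gain


def fit_pipeline(
    train: LabeledDataset,
    feature_config: FeatureConfig,
    train_config: TrainConfig | None = None,
) -> tuple[PredictorBundle, TrainReport]:
    """Fit the full predictor on a labeled training set.

    Normalization bounds (min/max Na4vSS) and the network's input scaling
    are derived from the training data only, then frozen into the bundle.
    """
    if train_config is None:
        train_config = TrainConfig()
    if train.n_positive == 0 or train.n_negative == 0:
        raise DegenerateTrainingError("training set must contain both classes")

    bounds = bounds_from_records(train.records, feature_config)
    fitted_config = feature_config.with_bounds(bounds)
    fvs = [featurize(rec, fitted_config) for rec in train.records]
    F = np.stack([fv.as_array() for fv in fvs])

    model = init_model(train_config.seed)
    model.input_offset, model.input_gain = _input_scaling(F)
    model, report = train_gdx(model, F, train.labels, train_config)
    bundle = PredictorBundle(
        model=model, feature_config=fitted_config, train_config=train_config
    )
    return bundle, report


# ---------------------------------------------------------------------------
# serialization

def save_model(bundle: PredictorBundle) -> str:
    """Serialize a bundle to a versioned JSON document (round-trip safe)."""
    fc = bundle.feature_config
    if fc.bounds is None:
        raise ConfigurationError("cannot serialize a bundle without fitted bounds")
    m = bundle.model
    doc = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "model": {
            "layer_sizes": list(m.layer_sizes),
            "weights": [w.tolist() for w in m.weights],
            "biases": [b.tolist() for b in m.biases],
            "activation": m.activation,
            "input_offset": m.input_offset.tolist(),
            "input_gain": m.input_gain.tolist(),
            "decision_threshold": m.decision_threshold,
        },
        "features": {
            "scale_name": fc.scale.name,
            "scale_values": dict(sorted(fc.scale.values.items())),
            "pka_entries": {
                res: {"pka": e.pka, "polarity": e.polarity}
                for res, e in sorted(fc.pka_table.entries.items())
            },
            "include_termini": fc.pka_table.include_termini,
            "nterm_pka": fc.pka_table.nterm_pka,
            "cterm_pka": fc.pka_table.cterm_pka,
            "ph": fc.ph,
            "window_bands": [list(b) for b in fc.window_bands],
            "na4vss_min": fc.bounds.na4vss_min,
            "na4vss_max": fc.bounds.na4vss_max,
        },
        "train_config": (
            None
            if bundle.train_config is None
            else {
                "epochs": bundle.train_config.epochs,
                "goal": bundle.train_config.goal,
                "lr0": bundle.train_config.lr0,
                "lr_inc": bundle.train_config.lr_inc,
                "lr_dec": bundle.train_config.lr_dec,
                "max_perf_inc": bundle.train_config.max_perf_inc,
                "momentum": bundle.train_config.momentum,
                "seed": bundle.train_config.seed,
            }
        ),
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def load_model(text: str) -> PredictorBundle:
    """Inverse of :func:`save_model`; validates version and structure."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelLoadError(f"model bundle is not valid JSON: {exc}") from exc
    try:
        if doc["format_version"] != BUNDLE_FORMAT_VERSION:
            raise ModelLoadError(
                f"unsupported bundle format version {doc['format_version']!r}"
            )
        md = doc["model"]
        model = MLPModel(
            layer_sizes=tuple(md["layer_sizes"]),
            weights=[np.array(w, dtype=float) for w in md["weights"]],
            biases=[np.array(b, dtype=float) for b in md["biases"]],
            activation=md["activation"],
            input_offset=np.array(md["input_offset"], dtype=float),
            input_gain=np.array(md["input_gain"], dtype=float),
            decision_threshold=float(md["decision_threshold"]),
        )
        fd = doc["features"]
        scale = PropensityScale(name=fd["scale_name"], values=fd["scale_values"])
        pka = PKaTable(
            entries={
                res: PKaEntry(pka=e["pka"], polarity=e["polarity"])
                for res, e in fd["pka_entries"].items()
            },
            include_termini=fd["include_termini"],
            nterm_pka=fd["nterm_pka"],
            cterm_pka=fd["cterm_pka"],
        )
        fc = FeatureConfig(
            scale=scale,
            pka_table=pka,
            ph=fd["ph"],
            window_bands=tuple(tuple(b) for b in fd["window_bands"]),
            bounds=NormalizationBounds(
                na4vss_min=fd["na4vss_min"], na4vss_max=fd["na4vss_max"]
            ),
        )
        tc = doc.get("train_config")
        train_config = TrainConfig(**tc) if tc else None
    except (KeyError, TypeError, ValueError, ConfigurationError) as exc:
        raise ModelLoadError(f"corrupted model bundle: {exc}") from exc
    return PredictorBundle(model=model, feature_config=fc, train_config=train_config)
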