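"""Declarative model specifications and the scikit-learn style regressor.

The default architecture feeds two parallel encoders from one stacked input
row ``[drug_first | drug_second | ccl]``: a *pair* encoder over the two drug
blocks (widths 1024, 2048) and a *triple* encoder over the whole row (widths
2048, 4096). Their concatenated embeddings enter a multitask predictor
(widths 4096, 1024) that regresses the synergy score together with the two
single-drug responses. Ablation variants rearrange the encoder set or reduce
the predictor to a single task.

At the reference input dimensions (per-drug feature 1956, CCL feature 4639)
the default network has 61,381,635 trainable parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .nn import DenseStack, MultiEncoderNet, TrainingDiverged, fit_network

__all__ = [
    "SpecError",
    "EncoderSpec",
    "PredictorSpec",
    "ModelSpec",
    "TrainConfig",
    "ENCODER_KINDS",
    "ABLATION_VARIANTS",
    "marsy_spec",
    "make_ablation_spec",
    "build_model",
    "count_parameters",
    "spec_parameter_count",
    "predict_synergy_symmetric",
    "extract_embeddings",
    "SynergyRegressor",
    "save_checkpoint",
    "load_checkpoint",
]


class SpecError(ValueError):
    """A model specification violates its invariants."""


ENCODER_KINDS = ("pair", "triple", "ccl", "drug_first", "drug_second")


@dataclass(frozen=True)
class EncoderSpec:
    """One encoder: which input slice it reads and its hidden layers."""

    kind: str
    hidden_widths: tuple[int, ...]
    activations: tuple[str, ...]
    dropout: float = 0.2

    def __post_init__(self) -> None:
        if self.kind not in ENCODER_KINDS:
            raise SpecError(f"unknown encoder kind {self.kind!r}; options: {ENCODER_KINDS}")
        if len(self.hidden_widths) != len(self.activations):
            raise SpecError("hidden_widths and activations must have equal lengths")
        if not self.hidden_widths or any(w < 1 for w in self.hidden_widths):
            raise SpecError("hidden_widths must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise SpecError("dropout must lie in [0, 1)")


@dataclass(frozen=True)
class PredictorSpec:
    """The multitask head: hidden layers plus a linear output layer."""

    hidden_widths: tuple[int, ...] = (4096, 1024)
    activations: tuple[str, ...] = ("relu", "relu")
    output_dim: int = 3
    output_activation: str = "linear"
    dropout: float = 0.5

    def __post_init__(self) -> None:
        if len(self.hidden_widths) != len(self.activations):
            raise SpecError("hidden_widths and activations must have equal lengths")
        if self.output_dim < 1:
            raise SpecError("output_dim must be at least 1")
        if not (0.0 <= self.dropout < 1.0):
            raise SpecError("dropout must lie in [0, 1)")


@dataclass(frozen=True)
class ModelSpec:
    """Full architecture description from which a network is built."""

    encoders: tuple[EncoderSpec, ...]
    predictor: PredictorSpec = field(default_factory=PredictorSpec)
    tasks: tuple[str, ...] = ("synergy", "ri_first", "ri_second")
    drug_dim: int = 1956
    ccl_dim: int = 4639

    def __post_init__(self) -> None:
        if not self.encoders:
            raise SpecError("at least one encoder is required")
        if not self.tasks:
            raise SpecError("tasks must be non-empty")
        if len(self.tasks) != self.predictor.output_dim:
            raise SpecError(
                f"{len(self.tasks)} tasks but predictor output_dim={self.predictor.output_dim}"
            )
        kinds = [e.kind for e in self.encoders]
        if len(set(kinds)) != len(kinds):
            raise SpecError(f"duplicate encoder kinds: {kinds}")
        if self.drug_dim < 1 or self.ccl_dim < 1:
            raise SpecError("drug_dim and ccl_dim must be positive")

    @property
    def pair_dim(self) -> int:
        return 2 * self.drug_dim

    @property
    def triple_dim(self) -> int:
        return self.pair_dim + self.ccl_dim

    def input_dims(self) -> dict[str, int]:
        return {
            "drug": self.drug_dim,
            "ccl": self.ccl_dim,
            "pair": self.pair_dim,
            "triple": self.triple_dim,
        }

    def encoder_slice(self, kind: str) -> slice:
        m, g = self.drug_dim, self.ccl_dim
        table = {
            "drug_first": slice(0, m),
            "drug_second": slice(m, 2 * m),
            "pair": slice(0, 2 * m),
            "ccl": slice(2 * m, 2 * m + g),
            "triple": slice(0, 2 * m + g),
        }
        return table[kind]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for network training.

    ``learning_rate`` may be zero (a null update, useful for diagnostics).
    ``validation_fraction`` is the carve-out monitored for early stopping.
    """

    optimizer: str = "adamax"
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 200
    patience: int = 10
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer not in ("adamax", "adam"):
            raise SpecError(f"unknown optimizer {self.optimizer!r}")
        if self.learning_rate < 0:
            raise SpecError("learning_rate must be non-negative")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise SpecError("batch_size and max_epochs must be positive")
        if not (0.0 < self.validation_fraction <= 0.5):
            raise SpecError("validation_fraction must lie in (0, 0.5]")


# ---------------------------------------------------------------------------
# spec builders
# ---------------------------------------------------------------------------

#: default hidden widths per encoder kind (before width scaling)
_DEFAULT_WIDTHS: dict[str, tuple[int, ...]] = {
    "pair": (1024, 2048),
    "triple": (2048, 4096),
    "ccl": (1024, 2048),
    "drug_first": (1024, 2048),
    "drug_second": (1024, 2048),
}

#: encoder sets of the ablation variants
ABLATION_VARIANTS: dict[str, tuple[str, ...]] = {
    "marsy": ("pair", "triple"),
    "model1_v1": ("triple",),
    "model1_v2": ("triple",),
    "model1_v3": ("triple",),
    "model2": ("ccl", "pair"),
    "model3": ("ccl", "triple"),
    "model4": ("drug_first", "drug_second", "ccl"),
    "model5": ("drug_first", "drug_second", "triple"),
    "model6": ("drug_first", "drug_second", "ccl", "pair"),
    "single_task": ("pair", "triple"),
}

#: variant-specific triple-encoder widths (documented defaults; configurable)
_VARIANT_WIDTH_OVERRIDES: dict[str, dict[str, tuple[int, ...]]] = {
    "model1_v2": {"triple": (3072, 4096)},
    "model1_v3": {"triple": (2048, 4096, 2048, 4096)},
}


def _scale(widths: Sequence[int], factor: float) -> tuple[int, ...]:
    return tuple(max(1, int(round(w * factor))) for w in widths)


def _encoder(
    kind: str,
    widths: Sequence[int],
    input_activation: str,
    dropout: float,
    depth: int,
) -> EncoderSpec:
    widths = tuple(widths)
    if depth > len(widths):
        widths = widths + (widths[-1],) * (depth - len(widths))
    acts = (input_activation,) + ("relu",) * (len(widths) - 1)
    return EncoderSpec(kind=kind, hidden_widths=widths, activations=acts, dropout=dropout)


def make_ablation_spec(
    variant: str,
    *,
    drug_dim: int = 1956,
    ccl_dim: int = 4639,
    width_scale: float = 1.0,
    input_activation: str = "linear",
    encoder_dropout: float = 0.2,
    predictor_dropout: float = 0.5,
    encoder_depth: int = 2,
    predictor_depth: int = 2,
    tasks: tuple[str, ...] | None = None,
) -> ModelSpec:
    """ModelSpec for the default architecture or one of its ablation variants."""
    if variant not in ABLATION_VARIANTS:
        raise SpecError(
            f"unknown variant {variant!r}; valid names: {sorted(ABLATION_VARIANTS)}"
        )
    overrides = _VARIANT_WIDTH_OVERRIDES.get(variant, {})
    encoders = []
    for kind in ABLATION_VARIANTS[variant]:
        widths = overrides.get(kind, _DEFAULT_WIDTHS[kind])
        depth = len(widths) if kind in overrides else encoder_depth
        encoders.append(
            _encoder(kind, _scale(widths, width_scale), input_activation, encoder_dropout, depth)
        )
    if tasks is None:
        tasks = ("synergy",) if variant == "single_task" else ("synergy", "ri_first", "ri_second")
    pred_widths = _scale((4096, 1024), width_scale)
    if predictor_depth > 2:
        pred_widths = pred_widths + (pred_widths[-1],) * (predictor_depth - 2)
    predictor = PredictorSpec(
        hidden_widths=pred_widths,
        activations=("relu",) * len(pred_widths),
        output_dim=len(tasks),
        dropout=predictor_dropout,
    )
    return ModelSpec(
        encoders=tuple(encoders),
        predictor=predictor,
        tasks=tuple(tasks),
        drug_dim=drug_dim,
        ccl_dim=ccl_dim,
    )


def marsy_spec(**kwargs) -> ModelSpec:
    """The default two-encoder multitask specification."""
    return make_ablation_spec("marsy", **kwargs)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------


def build_model(spec: ModelSpec, seed: int = 0) -> MultiEncoderNet:
    """Instantiate a trainable network from a specification."""
    rng = np.random.default_rng(seed)
    encoders = []
    for es in spec.encoders:
        sl = spec.encoder_slice(es.kind)
        in_dim = sl.stop - sl.start
        stack = DenseStack(
            in_dim,
            es.hidden_widths,
            es.activations,
            [es.dropout] * len(es.hidden_widths),
            rng,
        )
        encoders.append((es.kind, sl, stack))
    ps = spec.predictor
    pred_in = sum(stack.out_dim for _, _, stack in encoders)
    predictor = DenseStack(
        pred_in,
        [*ps.hidden_widths, ps.output_dim],
        [*ps.activations, ps.output_activation],
        [*([ps.dropout] * len(ps.hidden_widths)), 0.0],
        rng,
    )
    return MultiEncoderNet(encoders, predictor)


def count_parameters(model: MultiEncoderNet | ModelSpec) -> int:
    """Total count of trainable scalars (weights and biases)."""
    if isinstance(model, ModelSpec):
        return spec_parameter_count(model)
    return model.n_parameters()


def spec_parameter_count(spec: ModelSpec) -> int:
    """Closed-form parameter count: sum over layers of fan_in*fan_out + fan_out."""
    total = 0
    pred_in = 0
    for es in spec.encoders:
        sl = spec.encoder_slice(es.kind)
        fan_in = sl.stop - sl.start
        for w in es.hidden_widths:
            total += fan_in * w + w
            fan_in = w
        pred_in += es.hidden_widths[-1]
    fan_in = pred_in
    for w in (*spec.predictor.hidden_widths, spec.predictor.output_dim):
        total += fan_in * w + w
        fan_in = w
    return total


def extract_embeddings(
    model: "MultiEncoderNet | SynergyRegressor", X: np.ndarray, encoder: str | None = None
) -> dict[str, np.ndarray]:
    """Final-layer encoder activations for each sample.

    Returns a mapping from encoder kind to an (n_samples, width) array. With
    ``encoder`` given, only that encoder is computed; an absent encoder
    raises ``KeyError``.
    """
    net = model.network_ if isinstance(model, SynergyRegressor) else model
    outputs = net.encoder_outputs(np.asarray(X, dtype=float))
    if encoder is not None:
        if encoder not in outputs:
            raise KeyError(
                f"encoder {encoder!r} absent from this model (has {sorted(outputs)})"
            )
        return {encoder: outputs[encoder]}
    return outputs


def _swap_drug_blocks(X: np.ndarray, drug_dim: int) -> np.ndarray:
    m = drug_dim
    Xs = X.copy()
    Xs[:, :m], Xs[:, m : 2 * m] = X[:, m : 2 * m], X[:, :m]
    return Xs


def predict_synergy_symmetric(
    model: "MultiEncoderNet | SynergyRegressor",
    X: np.ndarray,
    drug_dim: int | None = None,
) -> np.ndarray:
    """Order-invariant synergy prediction: mean over both drug orderings.

    ``X`` holds stacked rows ``[drug_a | drug_b | ccl]``; the result equals
    the value obtained with the two drug blocks swapped, exactly.
    """
    if isinstance(model, SynergyRegressor):
        check_is_fitted(model, "network_")
        if drug_dim is None:
            drug_dim = model.drug_dim_
        net = model.network_
    else:
        net = model
        if drug_dim is None:
            raise ValueError("drug_dim is required when passing a bare network")
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    forward = net.predict(X)[:, 0]
    backward = net.predict(_swap_drug_blocks(X, drug_dim))[:, 0]
    out = 0.5 * (forward + backward)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------


class SynergyRegressor(RegressorMixin, BaseEstimator):
    """Multitask neural regressor for drug-pair synergy and single-drug response.

    Rows of ``X`` are triple feature vectors ``[drug_first | drug_second |
    ccl]``; ``drug_dim`` tells the estimator where the blocks split. ``y``
    is either a length-n vector of synergy scores or an (n, 3) array of
    (synergy, RI_first, RI_second) targets.

    Parameters
    ----------
    variant
        Architecture name: ``"marsy"`` (two encoders, multitask) or one of
        the ablation variants (``model1_v1`` ... ``model6``,
        ``single_task``).
    drug_dim
        Length of one per-drug feature block. Required.
    width_scale
        Multiplies every hidden width; ``1/8`` gives the scaled-down model
        used in desk-scale experiments.
    random_state
        Seeds weight initialization, batch shuffling, dropout masks and the
        validation carve-out.

    Attributes
    ----------
    network_ : MultiEncoderNet
        The trained network.
    spec_ : ModelSpec
        The resolved architecture specification.
    history_ : dict
        Per-epoch train/validation losses and the best epoch.
    n_parameters_ : int
        Trainable parameter count.
    """

    def __init__(
        self,
        variant: str = "marsy",
        drug_dim: int | None = None,
        width_scale: float = 1.0,
        encoder_depth: int = 2,
        predictor_depth: int = 2,
        input_activation: str = "linear",
        encoder_dropout: float = 0.2,
        predictor_dropout: float = 0.5,
        optimizer: str = "adamax",
        learning_rate: float = 1e-3,
        batch_size: int = 128,
        max_epochs: int = 200,
        patience: int = 10,
        validation_fraction: float = 0.1,
        random_state: int | None = None,
    ) -> None:
        self.variant = variant
        self.drug_dim = drug_dim
        self.width_scale = width_scale
        self.encoder_depth = encoder_depth
        self.predictor_depth = predictor_depth
        self.input_activation = input_activation
        self.encoder_dropout = encoder_dropout
        self.predictor_dropout = predictor_dropout
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- internal -----------------------------------------------------------

    def _resolve_spec(self, n_features: int, n_tasks: int) -> ModelSpec:
        if self.drug_dim is None:
            raise SpecError("drug_dim must be set so the input row can be sliced")
        ccl_dim = n_features - 2 * self.drug_dim
        if ccl_dim < 1:
            raise SpecError(
                f"n_features={n_features} leaves no CCL block for drug_dim={self.drug_dim}"
            )
        tasks: tuple[str, ...]
        if self.variant == "single_task" or n_tasks == 1:
            tasks = ("synergy",)
        else:
            tasks = ("synergy", "ri_first", "ri_second")[:n_tasks]
        return make_ablation_spec(
            self.variant,
            drug_dim=self.drug_dim,
            ccl_dim=ccl_dim,
            width_scale=self.width_scale,
            input_activation=self.input_activation,
            encoder_dropout=self.encoder_dropout,
            predictor_dropout=self.predictor_dropout,
            encoder_depth=self.encoder_depth,
            predictor_depth=self.predictor_depth,
            tasks=tasks,
        )

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y) -> "SynergyRegressor":
        X = check_array(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self._y_was_1d = y.ndim == 1
        Y = y[:, None] if y.ndim == 1 else y
        if Y.shape[0] != X.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        n_tasks = 1 if self.variant == "single_task" else Y.shape[1]
        if self.variant == "single_task" and Y.shape[1] > 1:
            Y = Y[:, :1]
        self.spec_ = self._resolve_spec(X.shape[1], n_tasks)
        seed = 0 if self.random_state is None else int(self.random_state)
        self.network_ = build_model(self.spec_, seed=seed)
        self.n_parameters_ = self.network_.n_parameters()
        rng = np.random.default_rng(seed + 1)
        self.history_ = fit_network(
            self.network_,
            X,
            Y,
            optimizer=self.optimizer,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            validation_fraction=self.validation_fraction,
            rng=rng,
        )
        self.n_features_in_ = X.shape[1]
        self.drug_dim_ = self.spec_.drug_dim
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        out = self.network_.predict(X)
        if self._y_was_1d or out.shape[1] == 1:
            return out[:, 0] if out.shape[1] == 1 else out
        return out

    def predict_symmetric(self, X) -> np.ndarray:
        """Order-invariant synergy prediction (see predict_synergy_symmetric)."""
        return predict_synergy_symmetric(self, X)

    def score(self, X, y) -> float:  # R^2 on the synergy task
        pred = self.predict(X)
        pred_syn = pred if pred.ndim == 1 else pred[:, 0]
        y = np.asarray(y, dtype=float)
        y_syn = y if y.ndim == 1 else y[:, 0]
        ss_res = float(np.sum((y_syn - pred_syn) ** 2))
        ss_tot = float(np.sum((y_syn - y_syn.mean()) ** 2))
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(est: SynergyRegressor, directory: str | Path) -> None:
    """Serialize a fitted estimator: spec + params JSON, weights npz."""
    check_is_fitted(est, "network_")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "params": est.get_params(),
        "spec": asdict(est.spec_),
        "history": est.history_,
        "y_was_1d": est._y_was_1d,
        "n_features_in": est.n_features_in_,
    }
    (directory / "checkpoint.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    weights = {f"p{i}": p for i, p in enumerate(est.network_.parameters())}
    np.savez(directory / "weights.npz", **weights)


def _spec_from_dict(d: Mapping) -> ModelSpec:
    encoders = tuple(
        EncoderSpec(
            kind=e["kind"],
            hidden_widths=tuple(e["hidden_widths"]),
            activations=tuple(e["activations"]),
            dropout=e["dropout"],
        )
        for e in d["encoders"]
    )
    p = d["predictor"]
    predictor = PredictorSpec(
        hidden_widths=tuple(p["hidden_widths"]),
        activations=tuple(p["activations"]),
        output_dim=p["output_dim"],
        output_activation=p["output_activation"],
        dropout=p["dropout"],
    )
    return ModelSpec(
        encoders=encoders,
        predictor=predictor,
        tasks=tuple(d["tasks"]),
        drug_dim=d["drug_dim"],
        ccl_dim=d["ccl_dim"],
    )


def load_checkpoint(directory: str | Path) -> SynergyRegressor:
    """Reconstruct an equivalent fitted estimator from a checkpoint directory."""
    directory = Path(directory)
    meta = json.loads((directory / "checkpoint.json").read_text())
    est = SynergyRegressor(**meta["params"])
    est.spec_ = _spec_from_dict(meta["spec"])
    est.network_ = build_model(est.spec_, seed=0)
    with np.load(directory / "weights.npz") as arrays:
        state = [arrays[f"p{i}"] for i in range(len(arrays.files))]
    est.network_.set_state(state)
    est.history_ = meta["history"]
    est._y_was_1d = meta["y_was_1d"]
    est.n_features_in_ = meta["n_features_in"]
    est.n_parameters_ = est.network_.n_parameters()
    est.drug_dim_ = est.spec_.drug_dim
    return est
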