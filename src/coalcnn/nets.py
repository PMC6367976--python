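"""Per-task network architectures and the training loop.

Architectures are described declaratively (:class:`NetworkSpec`) and
compiled against concrete input shapes into a two-branch model: an image
branch of convolution/pooling layers, an optional positional branch of
dense layers, a merge (concatenation), head layers, and an output layer.
1D convolutional filters slide along the site axis with stride 1 and span
the entire chromosome dimension; 2D filters are square.

``spec_introgression``, ``spec_rho_haploid``, ``spec_rho_tetraploid``,
``spec_sweep`` and ``spec_demography`` reproduce the published per-task
architectures; their ``filters`` argument can shrink every layer
proportionally for small-compute runs without changing the topology.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from . import _engine as eng

__all__ = [
    "LayerSpec", "NetworkSpec", "TrainingConfig", "TrainedModel", "Model",
    "spec_introgression", "spec_rho_haploid", "spec_rho_tetraploid",
    "spec_sweep", "spec_demography", "spec_theta_toy",
    "build_model", "train", "predict", "predict_classes", "class_probabilities",
]


@dataclass
class LayerSpec:
    kind: str  # conv1d | conv2d | avgpool | maxpool | dense | dropout | flatten
    filters: int = 0
    kernel: int = 0
    units: int = 0
    activation: str = "relu"
    rate: float = 0.0
    l2: float = 0.0
    pool_size: int = 2
    padding: str = "valid"  # convolutions only; "same" preserves width


@dataclass
class NetworkSpec:
    """Declarative description of a (possibly two-branch) architecture."""

    image_branch: list[LayerSpec]
    position_branch: list[LayerSpec] = field(default_factory=list)
    head: list[LayerSpec] = field(default_factory=list)
    output_units: int = 1
    output_activation: str = "linear"
    name: str = ""

    @property
    def has_position_branch(self) -> bool:
        return bool(self.position_branch)


@dataclass
class TrainingConfig:
    loss: str = "mse"  # mse | rmse | categorical_crossentropy
    batch_size: int = 32
    max_epochs: int = 10
    seed: int = 0
    learning_rate: float = 1e-3
    optimizer: str = "adam"

    def __post_init__(self):
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


def _conv_block(filters, kernel, dropout, l2, pool="avg", pool_size=2):
    layers = [
        LayerSpec("conv1d", filters=filters, kernel=kernel, l2=l2),
        LayerSpec("avgpool" if pool == "avg" else "maxpool", pool_size=pool_size),
    ]
    if dropout:
        layers.append(LayerSpec("dropout", rate=dropout))
    return layers


def spec_introgression(filters: tuple[int, int, int] = (256, 128, 128),
                       dense: tuple[int, int] = (128, 128)) -> NetworkSpec:
    """Three-class introgression classifier.

    Three kernel-2 1D conv layers (256/128/128 filters) each followed by
    average pooling with 25% dropout between them, then two dense layers
    of 128 units with 50% dropout, and a 3-unit sigmoid output (trained
    with renormalized categorical cross-entropy).
    """
    image = []
    for f in filters:
        image += _conv_block(f, 2, 0.25, 0.0)
    head = []
    for u in dense:
        head += [LayerSpec("dense", units=u), LayerSpec("dropout", rate=0.5)]
    return NetworkSpec(image_branch=image, head=head, output_units=3,
                       output_activation="sigmoid", name="introgression")


def spec_rho_haploid(filters: tuple[int, int, int] = (1250, 256, 256),
                     merge_units: int = 256) -> NetworkSpec:
    """Recombination-rate regressor for phased haplotype images.

    Image branch: kernel-2 1D convs of 1,250/256/256 filters, average
    pooling, 25% dropout and L2 1e-4 after each. Position branch: one
    64-unit dense layer with 10% dropout. Merged into a 256-unit dense
    layer; single linear output on the log-centred rho scale.
    """
    image = []
    for f in filters:
        image += _conv_block(f, 2, 0.25, 1e-4)
    pos = [LayerSpec("dense", units=64, l2=1e-4), LayerSpec("dropout", rate=0.10)]
    head = [LayerSpec("dense", units=merge_units, l2=1e-4)]
    return NetworkSpec(image_branch=image, position_branch=pos, head=head,
                       output_units=1, output_activation="linear", name="rho_haploid")


def spec_rho_tetraploid(filters: tuple[int, int, int] = (256, 256, 256),
                        merge_units: int = 256) -> NetworkSpec:
    """As :func:`spec_rho_haploid` but with the first conv layer reduced to
    256 filters, matching the narrower 12-individual read-fraction input."""
    s = spec_rho_haploid(filters=filters, merge_units=merge_units)
    return replace(s, name="rho_tetraploid")


def spec_sweep(filters: int = 256, n_conv: int = 5, merge_units: int = 256) -> NetworkSpec:
    """Five-class selective-sweep classifier.

    Five kernel-2 1D conv layers of 256 filters with average pooling and
    20% dropout; position branch dense 64 with 10% dropout; merged dense
    256 with 25% dropout; L2 1e-4 on hidden layers; 5-way softmax output.
    """
    image = []
    for _ in range(n_conv):
        image += _conv_block(filters, 2, 0.20, 1e-4)
    pos = [LayerSpec("dense", units=64, l2=1e-4), LayerSpec("dropout", rate=0.10)]
    head = [LayerSpec("dense", units=merge_units, l2=1e-4), LayerSpec("dropout", rate=0.25)]
    return NetworkSpec(image_branch=image, position_branch=pos, head=head,
                       output_units=5, output_activation="softmax", name="sweep")


def spec_demography(conv_dim: int = 1, kernel: int = 2, dropout: bool = False,
                    filters: int = 128, pos_units: int = 32,
                    merge_units: int = 256) -> NetworkSpec:
    """Five-parameter demographic regressor (one hyperparameter grid point).

    Four conv layers (1D or 2D) of 128 filters each followed by size-2 max
    pooling; a 32-unit dense layer on the distance vector; concatenation
    into a 256-unit dense layer and 5 linear outputs. Optional 25% dropout
    after each pooling step, the distance dense layer and the final dense
    layer.
    """
    kind = "conv1d" if conv_dim == 1 else "conv2d"
    image = []
    for _ in range(4):
        # same-padding keeps large kernels viable along the narrow
        # chromosome axis after repeated pooling
        image += [LayerSpec(kind, filters=filters, kernel=kernel, padding="same"),
                  LayerSpec("maxpool", pool_size=2)]
        if dropout:
            image.append(LayerSpec("dropout", rate=0.25))
    pos = [LayerSpec("dense", units=pos_units)]
    if dropout:
        pos.append(LayerSpec("dropout", rate=0.25))
    head = [LayerSpec("dense", units=merge_units)]
    if dropout:
        head.append(LayerSpec("dropout", rate=0.25))
    return NetworkSpec(image_branch=image, position_branch=pos, head=head,
                       output_units=5, output_activation="linear",
                       name=f"demography_{conv_dim}d_k{kernel}")


def spec_theta_toy(filters: tuple[int, int] = (32, 32), dense: int = 64) -> NetworkSpec:
    """Small 1D CNN used for the input-reorganization experiment:
    two kernel-2 conv+avg-pool blocks, a dense layer, one linear output."""
    image = []
    for f in filters:
        image += _conv_block(f, 2, 0.0, 0.0)
    head = [LayerSpec("dense", units=dense)]
    return NetworkSpec(image_branch=image, head=head, output_units=1,
                       output_activation="linear", name="theta_toy")


# ---------------------------------------------------------------------------
# compilation


class Model:
    """A compiled two-branch network with explicit forward/backward passes."""

    def __init__(self, spec: NetworkSpec, input_shapes, rng: np.random.Generator):
        """``input_shapes``: list of per-example shapes, image branch first,
        e.g. ``[(418, 50), (418,)]`` or ``[(H, W, 1), (P,)]`` for 2D convs."""
        self.spec = spec
        self.rng = rng
        self.branches: list[list[eng.Layer]] = []
        self.branch_widths: list[int] = []
        branch_specs = [spec.image_branch]
        if spec.has_position_branch:
            branch_specs.append(spec.position_branch)
        if len(input_shapes) != len(branch_specs):
            raise ValueError(
                f"{len(input_shapes)} inputs supplied for {len(branch_specs)} branches")
        for layers_spec, shape in zip(branch_specs, input_shapes):
            layers, width = self._compile(layers_spec, shape, terminal_flatten=True)
            self.branches.append(layers)
            self.branch_widths.append(width)
        head_in = sum(self.branch_widths)
        self.head, width = self._compile(spec.head, (head_in,), terminal_flatten=False)
        self.head.append(eng.Dense(width, spec.output_units, rng=self.rng))
        self.head.append(eng.Activation(spec.output_activation))

    def _compile(self, layer_specs, shape, terminal_flatten):
        shape = tuple(shape)
        layers: list[eng.Layer] = []
        for ls in layer_specs:
            if ls.kind == "conv1d":
                if len(shape) != 2:
                    raise ValueError(f"conv1d expects (W, C) input, got {shape}")
                W, C = shape
                same = ls.padding == "same"
                if not same and W < ls.kernel:
                    raise ValueError(f"input width {W} smaller than kernel {ls.kernel}")
                layers.append(eng.Conv1D(C, ls.filters, ls.kernel, ls.l2,
                                         rng=self.rng, padding=ls.padding))
                layers.append(eng.Activation(ls.activation))
                shape = (W if same else W - ls.kernel + 1, ls.filters)
            elif ls.kind == "conv2d":
                if len(shape) != 3:
                    raise ValueError(f"conv2d expects (H, W, C) input, got {shape}")
                H, W, C = shape
                same = ls.padding == "same"
                if not same and min(H, W) < ls.kernel:
                    raise ValueError(f"input {shape} smaller than kernel {ls.kernel}")
                layers.append(eng.Conv2D(C, ls.filters, ls.kernel, ls.l2,
                                         rng=self.rng, padding=ls.padding))
                layers.append(eng.Activation(ls.activation))
                shape = ((H, W, ls.filters) if same
                         else (H - ls.kernel + 1, W - ls.kernel + 1, ls.filters))
            elif ls.kind in ("avgpool", "maxpool"):
                s = ls.pool_size
                if len(shape) == 2:
                    layers.append(eng.AvgPool1D(s) if ls.kind == "avgpool" else eng.MaxPool1D(s))
                    shape = (shape[0] // s, shape[1])
                    if shape[0] == 0:
                        raise ValueError("pooled width reached zero")
                else:
                    layers.append(eng.AvgPool2D(s) if ls.kind == "avgpool" else eng.MaxPool2D(s))
                    shape = (shape[0] // s, shape[1] // s, shape[2])
                    if min(shape[:2]) == 0:
                        raise ValueError("pooled size reached zero")
            elif ls.kind == "dense":
                if len(shape) > 1:
                    layers.append(eng.Flatten())
                    shape = (int(np.prod(shape)),)
                layers.append(eng.Dense(shape[0], ls.units, ls.l2, rng=self.rng))
                layers.append(eng.Activation(ls.activation))
                shape = (ls.units,)
            elif ls.kind == "dropout":
                layers.append(eng.Dropout(ls.rate, rng=self.rng))
            elif ls.kind == "flatten":
                layers.append(eng.Flatten())
                shape = (int(np.prod(shape)),)
            else:
                raise ValueError(f"unknown layer kind {ls.kind!r}")
        if terminal_flatten and len(shape) > 1:
            layers.append(eng.Flatten())
            shape = (int(np.prod(shape)),)
        return layers, int(np.prod(shape))

    # forward/backward ----------------------------------------------------
    def forward(self, inputs: list[np.ndarray], train: bool = False) -> np.ndarray:
        outs = []
        for layers, x in zip(self.branches, inputs):
            h = x
            for layer in layers:
                h = layer.forward(h, train)
            outs.append(h)
        h = outs[0] if len(outs) == 1 else np.concatenate(outs, axis=1)
        self._concat_widths = [o.shape[1] for o in outs]
        for layer in self.head:
            h = layer.forward(h, train)
        return h

    def backward(self, dY: np.ndarray) -> None:
        g = dY
        for layer in reversed(self.head):
            g = layer.backward(g)
        offset = 0
        for layers, width in zip(self.branches, self._concat_widths):
            gb = g[:, offset : offset + width]
            offset += width
            for layer in reversed(layers):
                gb = layer.backward(gb)

    def all_layers(self):
        for layers in self.branches:
            yield from layers
        yield from self.head

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.all_layers() for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.all_layers() for g in layer.grads()]

    def reg_loss(self) -> float:
        return sum(layer.reg_loss() for layer in self.all_layers())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights):
            p[...] = w


@dataclass
class TrainedModel:
    spec: NetworkSpec
    model: Model
    config: TrainingConfig
    history: dict
    selected_epoch: int  # 1-based epoch whose validation loss was minimal


def build_model(spec: NetworkSpec, input_shapes, seed: int = 0) -> Model:
    return Model(spec, input_shapes, np.random.default_rng(seed))


def _as_inputs(data) -> tuple[list[np.ndarray], np.ndarray]:
    """``data`` is (inputs, y) where inputs is an array or list of arrays."""
    inputs, y = data
    if isinstance(inputs, np.ndarray):
        inputs = [inputs]
    return [np.asarray(x, dtype=np.float32) for x in inputs], np.asarray(y)


def _batched_loss(model: Model, inputs, y, loss, batch_size=256) -> float:
    n = y.shape[0]
    total = 0.0
    for i in range(0, n, batch_size):
        sl = slice(i, min(i + batch_size, n))
        pred = model.forward([x[sl] for x in inputs], train=False)
        total += loss.value(pred, y[sl]) * (sl.stop - sl.start)
    return total / n


def train(spec: NetworkSpec, train_data, val_data, cfg: TrainingConfig,
          input_shapes=None, verbose: bool = False) -> TrainedModel:
    """Mini-batch training with Adam and best-on-validation model selection.

    ``train_data``/``val_data`` are ``(inputs, y)`` pairs where ``inputs``
    is the image array or ``[image, positions]`` list; classification
    labels must already be one-hot. Runs up to ``cfg.max_epochs`` full
    passes, records per-epoch train/validation loss, and returns the
    parameters of the epoch with minimal validation loss. Deterministic
    given ``cfg.seed`` and fixed data order.
    """
    Xtr, ytr = _as_inputs(train_data)
    Xval, yval = _as_inputs(val_data)
    if spec.output_units != (ytr.shape[1] if ytr.ndim > 1 else 1):
        raise ValueError(
            f"network has {spec.output_units} outputs but labels have "
            f"{ytr.shape[1] if ytr.ndim > 1 else 1} dimensions")
    if ytr.ndim == 1:
        ytr, yval = ytr[:, None], yval[:, None]
    ytr = ytr.astype(np.float32)
    yval = yval.astype(np.float32)
    if input_shapes is None:
        input_shapes = [x.shape[1:] for x in Xtr]
    rng = np.random.default_rng(cfg.seed)
    model = Model(spec, input_shapes, rng)
    loss = eng.LOSSES[cfg.loss]()
    opt = eng.Adam(model.params(), lr=cfg.learning_rate)
    n = ytr.shape[0]
    history = {"train_loss": [], "val_loss": []}
    best_val, best_weights, best_epoch = np.inf, model.get_weights(), 0
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        running = 0.0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb = [x[idx] for x in Xtr]
            yb = ytr[idx]
            pred = model.forward(xb, train=True)
            lval = loss.value(pred, yb)
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {i // cfg.batch_size}: "
                    f"{lval}; consider lowering the learning rate")
            running += lval * len(idx)
            model.backward(loss.grad(pred, yb))
            opt.step(model.grads())
        val_loss = _batched_loss(model, Xval, yval, loss)
        history["train_loss"].append(running / n)
        history["val_loss"].append(val_loss)
        if verbose:
            print(f"epoch {epoch}: train {running / n:.4f}  val {val_loss:.4f}")
        if val_loss < best_val:
            best_val, best_weights, best_epoch = val_loss, model.get_weights(), epoch
    model.set_weights(best_weights)
    return TrainedModel(spec=spec, model=model, config=cfg, history=history,
                        selected_epoch=best_epoch)


def predict(trained: TrainedModel | Model, inputs, batch_size: int = 256,
            transform=None) -> np.ndarray:
    """Evaluation-mode predictions (dropout off); deterministic.

    ``transform`` (a fitted :class:`~coalcnn.imageprep.TargetTransform`)
    back-transforms regression outputs to the natural scale.
    """
    model = trained.model if isinstance(trained, TrainedModel) else trained
    if isinstance(inputs, np.ndarray):
        inputs = [inputs]
    inputs = [np.asarray(x, dtype=np.float32) for x in inputs]
    n = inputs[0].shape[0]
    chunks = []
    for i in range(0, n, batch_size):
        sl = slice(i, min(i + batch_size, n))
        chunks.append(model.forward([x[sl] for x in inputs], train=False))
    out = np.concatenate(chunks, axis=0)
    if transform is not None:
        out = transform.invert(out.astype(np.float64))
    return out


def class_probabilities(trained, inputs, batch_size: int = 256) -> np.ndarray:
    """Per-class probabilities; sigmoid outputs are renormalized to sum to 1."""
    out = predict(trained, inputs, batch_size=batch_size)
    s = out.sum(axis=1, keepdims=True)
    return out / np.where(s == 0, 1.0, s)


def predict_classes(trained, inputs, batch_size: int = 256) -> np.ndarray:
    return np.argmax(class_probabilities(trained, inputs, batch_size), axis=1)
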