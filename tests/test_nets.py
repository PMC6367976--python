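"""Network construction, gradients, training loop behaviour."""

import numpy as np
import pytest

from coalcnn import nets
from coalcnn._engine import LOSSES
from coalcnn.nets import LayerSpec, NetworkSpec, TrainingConfig


# --- published architecture fidelity -------------------------------------------


def _conv_filters(spec):
    return [ls.filters for ls in spec.image_branch if ls.kind.startswith("conv")]


def _dense_units(layer_specs):
    return [ls.units for ls in layer_specs if ls.kind == "dense"]


def test_introgression_spec_layer_widths():
    s = nets.spec_introgression()
    assert _conv_filters(s) == [256, 128, 128]
    assert _dense_units(s.head) == [128, 128]
    assert s.output_units == 3 and s.output_activation == "sigmoid"
    assert all(ls.kernel == 2 for ls in s.image_branch if ls.kind == "conv1d")


def test_rho_specs():
    h = nets.spec_rho_haploid()
    assert _conv_filters(h) == [1250, 256, 256]
    assert _dense_units(h.position_branch) == [64]
    assert _dense_units(h.head) == [256]
    assert h.output_units == 1 and h.output_activation == "linear"
    t = nets.spec_rho_tetraploid()
    assert _conv_filters(t) == [256, 256, 256]
    # tetraploid input is 460 sites x 12 read-fraction individuals
    model = nets.build_model(t, [(460, 12), (460,)], seed=0)
    assert model.branches[0][0].in_ch == 12


def test_sweep_spec():
    s = nets.spec_sweep()
    assert _conv_filters(s) == [256] * 5
    assert s.output_units == 5 and s.output_activation == "softmax"
    merged = [ls for ls in s.head if ls.kind == "dense"]
    assert merged[0].units == 256
    drops = [ls.rate for ls in s.head if ls.kind == "dropout"]
    assert drops == [0.25]


def test_demography_spec():
    s = nets.spec_demography(conv_dim=2, kernel=4, dropout=True)
    convs = [ls for ls in s.image_branch if ls.kind == "conv2d"]
    assert len(convs) == 4 and all(ls.filters == 128 for ls in convs)
    assert _dense_units(s.position_branch) == [32]
    assert _dense_units(s.head) == [256]
    assert s.output_units == 5 and s.output_activation == "linear"


# --- gradient correctness --------------------------------------------------------


def _numeric_grad(f, p, eps=1e-3):
    g = np.zeros_like(p, dtype=np.float64)
    it = np.nditer(p, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = p[i]
        p[i] = old + eps
        f1 = f()
        p[i] = old - eps
        f2 = f()
        p[i] = old
        g[i] = (f1 - f2) / (2 * eps)
    return g


@pytest.mark.parametrize("loss_name,output_act,out_units", [
    ("mse", "linear", 2),
    ("rmse", "linear", 2),
    ("categorical_crossentropy", "softmax", 3),
    ("categorical_crossentropy", "sigmoid", 3),
])
def test_backprop_matches_finite_differences(loss_name, output_act, out_units):
    """Analytic gradients of a two-branch conv/pool/dense net agree with
    central finite differences for every loss/output pairing used."""
    rng = np.random.default_rng(0)
    spec = NetworkSpec(
        image_branch=[LayerSpec("conv1d", filters=3, kernel=2, l2=1e-3),
                      LayerSpec("avgpool"),
                      LayerSpec("conv1d", filters=2, kernel=3, padding="same"),
                      LayerSpec("maxpool")],
        position_branch=[LayerSpec("dense", units=4, l2=1e-3)],
        head=[LayerSpec("dense", units=5)],
        output_units=out_units, output_activation=output_act)
    X = [rng.normal(size=(4, 12, 3)), rng.normal(size=(4, 6))]
    if output_act == "linear":
        y = rng.normal(size=(4, out_units))
    else:
        y = np.eye(out_units)[rng.integers(0, out_units, 4)]
    model = nets.build_model(spec, [(12, 3), (6,)], seed=1)
    loss = LOSSES[loss_name]()

    def total():
        return loss.value(model.forward(X, train=False), y) + model.reg_loss()

    model.backward(loss.grad(model.forward(X, train=False), y))
    for p, g in zip(model.params(), model.grads()):
        ng = _numeric_grad(total, p)
        rel = np.abs(ng - g) / np.maximum(np.abs(ng) + np.abs(g), 1e-6)
        assert rel.max() < 1e-3


def test_conv2d_gradients():
    rng = np.random.default_rng(2)
    spec = NetworkSpec(
        image_branch=[LayerSpec("conv2d", filters=2, kernel=3, padding="same"),
                      LayerSpec("avgpool"),
                      LayerSpec("conv2d", filters=2, kernel=2)],
        head=[LayerSpec("dense", units=3)], output_units=2,
        output_activation="linear")
    X = [rng.normal(size=(3, 8, 6, 1))]
    y = rng.normal(size=(3, 2))
    model = nets.build_model(spec, [(8, 6, 1)], seed=3)
    loss = LOSSES["mse"]()

    def total():
        return loss.value(model.forward(X, train=False), y)

    model.backward(loss.grad(model.forward(X, train=False), y))
    for p, g in zip(model.params(), model.grads()):
        ng = _numeric_grad(total, p)
        rel = np.abs(ng - g) / np.maximum(np.abs(ng) + np.abs(g), 1e-6)
        assert rel.max() < 1e-3


# --- training loop ----------------------------------------------------------------


def _toy_regression(n=64, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.random((n, 16, 3)).astype(np.float32)
    y = X[:, :4, 0].sum(axis=1, keepdims=True)
    return [X], y


def test_training_on_constant_labels_converges_to_constant():
    X, _ = _toy_regression()
    y = np.full((64, 1), 7.0, dtype=np.float32)
    spec = nets.spec_theta_toy(filters=(8, 8), dense=8)
    cfg = TrainingConfig(loss="mse", batch_size=16, max_epochs=40, seed=0)
    tm = nets.train(spec, (X, y), (X, y), cfg)
    pred = nets.predict(tm, X)
    assert np.abs(pred - 7.0).mean() < 0.5
    assert tm.history["val_loss"][-1] < 0.5


def test_training_is_deterministic_given_seed():
    X, y = _toy_regression()
    spec = nets.spec_theta_toy(filters=(8, 8), dense=8)
    cfg = TrainingConfig(loss="rmse", batch_size=16, max_epochs=3, seed=5)
    a = nets.train(spec, (X, y), (X, y), cfg)
    b = nets.train(spec, (X, y), (X, y), cfg)
    assert a.history["val_loss"] == b.history["val_loss"]
    assert a.selected_epoch == b.selected_epoch


def test_selected_epoch_minimizes_validation_loss():
    X, y = _toy_regression()
    spec = nets.spec_theta_toy(filters=(8, 8), dense=8)
    cfg = TrainingConfig(loss="mse", batch_size=16, max_epochs=6, seed=2)
    tm = nets.train(spec, (X, y), (X, y), cfg)
    assert tm.selected_epoch == int(np.argmin(tm.history["val_loss"])) + 1


def test_dropout_only_active_in_training_mode():
    rng = np.random.default_rng(1)
    spec = NetworkSpec(
        image_branch=[LayerSpec("conv1d", filters=4, kernel=2),
                      LayerSpec("dropout", rate=0.5)],
        head=[], output_units=1, output_activation="linear")
    model = nets.build_model(spec, [(10, 2)], seed=0)
    X = [rng.normal(size=(5, 10, 2)).astype(np.float32)]
    e1 = model.forward(X, train=False)
    e2 = model.forward(X, train=False)
    assert (e1 == e2).all()  # evaluation mode is deterministic
    t1 = model.forward(X, train=True)
    t2 = model.forward(X, train=True)
    assert not np.allclose(t1, t2)  # dropout masks differ across passes


def test_shape_mismatch_raises_before_training():
    X, y = _toy_regression()
    spec = nets.spec_theta_toy(filters=(8, 8), dense=8)
    cfg = TrainingConfig(loss="mse", batch_size=16, max_epochs=1, seed=0)
    with pytest.raises(ValueError):
        nets.train(spec, (X, np.hstack([y, y])), (X, y), cfg)


def test_softmax_probabilities_and_argmax():
    rng = np.random.default_rng(4)
    spec = NetworkSpec(image_branch=[LayerSpec("conv1d", filters=4, kernel=2)],
                       head=[LayerSpec("dense", units=6)],
                       output_units=4, output_activation="softmax")
    model = nets.build_model(spec, [(8, 2)], seed=0)
    X = [rng.normal(size=(10, 8, 2)).astype(np.float32)]
    out = nets.predict(model, X)
    assert np.allclose(out.sum(axis=1), 1.0, atol=1e-6)
    assert (nets.predict_classes(model, X) == out.argmax(axis=1)).all()


def test_sigmoid_probabilities_renormalized():
    spec = NetworkSpec(image_branch=[LayerSpec("conv1d", filters=4, kernel=2)],
                       head=[], output_units=3, output_activation="sigmoid")
    model = nets.build_model(spec, [(8, 2)], seed=0)
    X = [np.random.default_rng(0).normal(size=(6, 8, 2)).astype(np.float32)]
    probs = nets.class_probabilities(model, X)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_backtransformed_rho_predictions_positive():
    from coalcnn.imageprep import fit_target_transform

    rng = np.random.default_rng(6)
    tf = fit_target_transform(rng.uniform(1e-4, 1e-1, 50), log_flag=True)
    spec = NetworkSpec(image_branch=[LayerSpec("conv1d", filters=3, kernel=2)],
                       head=[], output_units=1, output_activation="linear")
    model = nets.build_model(spec, [(8, 2)], seed=0)
    X = [rng.normal(size=(20, 8, 2)).astype(np.float32)]
    pred = nets.predict(model, X, transform=tf)
    assert (pred > 0).all()


def test_config_validation():
    with pytest.raises(ValueError):
        TrainingConfig(batch_size=0)
    with pytest.raises(ValueError):
        TrainingConfig(max_epochs=0)
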