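"""End-to-end presets wiring simulation -> image prep -> training -> metrics.

Each task ships in two profiles: ``paper`` reproduces the published scale
(hundreds of thousands of simulated alignments; hours of compute) and
``desk`` is a reduced-size profile with the same scenario distributions,
class compositions and preprocessing, sized to finish on a single CPU in
minutes. Desk networks keep the published topology but shrink layer
widths. Transforms are always fitted on the training split, model
selection is on the validation split, and metrics are computed once on the
previously unseen test split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nets, simgen
from .evalmetrics import EvalReport, accuracy_ci, confusion, r_squared, rmse, spearman_rho
from .imageprep import fit_target_transform
from .simgen import LabeledDataset

__all__ = ["ExperimentPreset", "PRESETS", "get_preset", "run_experiment",
           "run_fig3_ablation", "theta_baseline_rmse"]

TASKS = ("theta_toy", "introgression", "rho_haploid", "rho_interpolation",
         "rho_tetraploid", "sweeps", "demography", "demography_grid")


@dataclass
class ExperimentPreset:
    task: str
    scale: str  # "paper" | "desk"
    data: dict = field(default_factory=dict)  # dataset-builder arguments
    net: dict = field(default_factory=dict)  # architecture arguments
    training: dict = field(default_factory=dict)  # TrainingConfig arguments
    transform: dict = field(default_factory=dict)  # target-transform flags


def _presets() -> dict:
    p = {}
    # --- theta toy: published protocol is already desk-sized -------------
    for scale in ("paper", "desk"):
        p[("theta_toy", scale)] = ExperimentPreset(
            "theta_toy", scale,
            data=dict(n_train=4000, n_val=500, n_test=1000),
            net=dict(filters=(32, 32), dense=64),
            training=dict(loss="rmse", batch_size=64, max_epochs=8),
            transform=dict(log_flag=False, zscore_flag=False, none=True))
    # --- recombination, phased haplotypes --------------------------------
    p[("rho_haploid", "paper")] = ExperimentPreset(
        "rho_haploid", "paper",
        data=dict(n_train=143_775, n_val=6_250, n_test=6_250),
        net=dict(filters=(1250, 256, 256), merge_units=256),
        training=dict(loss="mse", batch_size=32, max_epochs=16),
        transform=dict(log_flag=True, zscore_flag=False))
    p[("rho_haploid", "desk")] = ExperimentPreset(
        "rho_haploid", "desk",
        data=dict(n_train=2500, n_val=400, n_test=600),
        net=dict(filters=(64, 64, 64), merge_units=128),
        training=dict(loss="mse", batch_size=32, max_epochs=10),
        transform=dict(log_flag=True, zscore_flag=False))
    for scale in ("paper", "desk"):
        base = p[("rho_haploid", scale)]
        p[("rho_interpolation", scale)] = ExperimentPreset(
            "rho_interpolation", scale,
            data=dict(base.data, interpolation_test=True,
                      n_test=5000 if scale == "paper" else base.data["n_test"]),
            net=dict(base.net), training=dict(base.training),
            transform=dict(base.transform))
    p[("rho_tetraploid", "paper")] = ExperimentPreset(
        "rho_tetraploid", "paper",
        data=dict(n_train=200_000, n_val=10_000, n_test=7_500, tetraploid=True),
        net=dict(filters=(256, 256, 256), merge_units=256),
        training=dict(loss="mse", batch_size=32, max_epochs=9),
        transform=dict(log_flag=True, zscore_flag=False))
    p[("rho_tetraploid", "desk")] = ExperimentPreset(
        "rho_tetraploid", "desk",
        data=dict(n_train=1500, n_val=250, n_test=400, tetraploid=True),
        net=dict(filters=(64, 64, 64), merge_units=128),
        training=dict(loss="mse", batch_size=32, max_epochs=8),
        transform=dict(log_flag=True, zscore_flag=False))
    # --- introgression ----------------------------------------------------
    p[("introgression", "paper")] = ExperimentPreset(
        "introgression", "paper",
        data=dict(n_train=(107_500, 107_500, 7_500), n_val_per_class=2_500,
                  n_test_per_class=2_500),
        net=dict(filters=(256, 128, 128), dense=(128, 128)),
        training=dict(loss="categorical_crossentropy", batch_size=256, max_epochs=19))
    p[("introgression", "desk")] = ExperimentPreset(
        "introgression", "desk",
        # 1/100 of the published counts, composition preserved
        data=dict(n_train=(1075, 1075, 75), n_val_per_class=150,
                  n_test_per_class=200),
        net=dict(filters=(64, 32, 32), dense=(64, 64)),
        training=dict(loss="categorical_crossentropy", batch_size=32, max_epochs=15))
    # --- sweeps -----------------------------------------------------------
    p[("sweeps", "paper")] = ExperimentPreset(
        "sweeps", "paper",
        data=dict(n_train_total=233_655, n_val_per_class=400, n_test_per_class=600),
        net=dict(filters=256, n_conv=5, merge_units=256),
        training=dict(loss="categorical_crossentropy", batch_size=32, max_epochs=3))
    p[("sweeps", "desk")] = ExperimentPreset(
        "sweeps", "desk",
        data=dict(n_train_total=1500, n_val_per_class=60, n_test_per_class=100),
        net=dict(filters=48, n_conv=5, merge_units=128),
        training=dict(loss="categorical_crossentropy", batch_size=32, max_epochs=6))
    # --- demography -------------------------------------------------------
    p[("demography", "paper")] = ExperimentPreset(
        "demography", "paper",
        data=dict(n_train=80_000, n_val=10_000, n_test=10_000),
        net=dict(conv_dim=1, kernel=2, dropout=False, filters=128),
        training=dict(loss="rmse", batch_size=200, max_epochs=10),
        transform=dict(log_flag=True, zscore_flag=True))
    p[("demography", "desk")] = ExperimentPreset(
        "demography", "desk",
        # unit-scale pixels converge far faster than 0/255 at this data size
        data=dict(n_train=1500, n_val=250, n_test=300, ranges=DESK_DEMOGRAPHY_RANGES,
                  L_bp=300_000, encoding="zero_one"),
        net=dict(conv_dim=1, kernel=2, dropout=False, filters=32, pos_units=16,
                 merge_units=64),
        training=dict(loss="rmse", batch_size=25, max_epochs=25),
        transform=dict(log_flag=True, zscore_flag=True))
    # --- demography hyperparameter grid ------------------------------------
    p[("demography_grid", "paper")] = ExperimentPreset(
        "demography_grid", "paper",
        data=dict(p[("demography", "paper")].data),
        net=dict(filters=128, pos_units=32, merge_units=256),
        training=dict(batch_size=200, max_epochs=10))
    p[("demography_grid", "desk")] = ExperimentPreset(
        "demography_grid", "desk",
        data=dict(n_train=200, n_val=60, n_test=80, ranges=DESK_DEMOGRAPHY_RANGES,
                  L_bp=300_000),
        net=dict(filters=16, pos_units=8, merge_units=32),
        training=dict(batch_size=50, max_epochs=4, n_points=8))
    return p


DESK_DEMOGRAPHY_RANGES = {
    # narrower-than-default ranges keep desk simulations quick while
    # spanning an order of magnitude in size and time
    "N0": (500.0, 20_000.0),
    "N1": (500.0, 20_000.0),
    "N2": (500.0, 20_000.0),
    "T1": (100.0, 4_000.0),
    "T2": (100.0, 8_000.0),
}

PRESETS = _presets()


def get_preset(task: str, scale: str = "desk") -> ExperimentPreset:
    try:
        return PRESETS[(task, scale)]
    except KeyError:
        raise KeyError(f"no preset for task={task!r}, scale={scale!r}; "
                       f"tasks: {TASKS}") from None


def theta_baseline_rmse(lo: float = 10.0, hi: float = 50.0) -> float:
    """RMSE of the constant-mean predictor for U(lo, hi) targets:
    the standard deviation (hi - lo) / sqrt(12), ~11.5 for U(10, 50)."""
    return (hi - lo) / np.sqrt(12.0)


def _regression_report(task, truth, pred, extra=None) -> EvalReport:
    metrics = {"rmse": rmse(truth, pred), "r2": r_squared(truth, pred)}
    sp = spearman_rho(truth, pred)
    if np.ndim(sp) == 0:
        metrics["spearman"] = float(sp)
    else:
        metrics["spearman"] = [float(v) for v in sp]
    metrics.update(extra or {})
    return EvalReport(task=task, n_test=len(truth), metrics=metrics)


def _classification_report(task, truth, pred_classes, k, class_names) -> EvalReport:
    matrix, acc = confusion(truth, pred_classes, k)
    ci = accuracy_ci(int((truth == pred_classes).sum()), len(truth))
    return EvalReport(task=task, n_test=len(truth), metrics={"accuracy": acc},
                      confusion_matrix=matrix, accuracy_ci95=ci,
                      class_names=class_names)


def _save_run(outdir, preset, seed, report, trained):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.json", "w") as fh:
        json.dump({"task": preset.task, "scale": preset.scale, "seed": seed,
                   "data": {k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in preset.data.items() if k != "ranges"},
                   "net": preset.net, "training": preset.training,
                   "transform": preset.transform}, fh, indent=2)
    report.to_json(outdir / "report.json")
    if trained is not None:
        with open(outdir / "history.json", "w") as fh:
            json.dump({"history": trained.history,
                       "selected_epoch": trained.selected_epoch}, fh, indent=2)


def run_experiment(preset: ExperimentPreset | tuple[str, str], seed: int = 0,
                   outdir=None, datasets: dict[str, LabeledDataset] | None = None,
                   verbose: bool = False):
    """Run one preset end to end; returns ``(EvalReport, TrainedModel, splits)``.

    Builds the three splits (unless pre-built ``datasets`` with a matching
    task are supplied), fits any response transform on the training split,
    trains with best-on-validation selection, and evaluates once on the
    test split. ``seed`` drives both simulation and training.
    """
    if isinstance(preset, tuple):
        preset = get_preset(*preset)
    rng = np.random.default_rng(seed)
    task = preset.task

    if task == "demography_grid":
        from . import hypersearch

        raw = {}
        d = dict(preset.data)
        n_points = preset.training.get("n_points")
        for split, n in (("train", d.pop("n_train")), ("val", d.pop("n_val")),
                         ("test", d.pop("n_test"))):
            raw[split] = simgen.simulate_demography(rng, n, **d)
        points = hypersearch.enumerate_grid()
        if n_points:
            points = points[:: max(len(points) // n_points, 1)][:n_points]
        results = hypersearch.run_grid(
            raw, points=points, max_epochs=preset.training["max_epochs"],
            seed=seed, batch_size=preset.training["batch_size"], **preset.net)
        summary = hypersearch.compare_axes(results)
        report = EvalReport(task=task, n_test=len(raw["test"][0]),
                            metrics={"n_points": len(points),
                                     "median_best_val_rmse":
                                         float(results["best_val_rmse"].median())})
        if outdir:
            Path(outdir).mkdir(parents=True, exist_ok=True)
            results.to_csv(Path(outdir) / "grid_results.csv", index=False)
            with open(Path(outdir) / "axis_summary.json", "w") as fh:
                json.dump(summary, fh, indent=2, default=str)
            report.to_json(Path(outdir) / "report.json")
        return report, (results, summary), raw

    if datasets is None:
        datasets = _build_datasets(task, preset, rng)
    train_ds, val_ds, test_ds = datasets["train"], datasets["val"], datasets["test"]

    classification = task in ("introgression", "sweeps")
    if classification:
        transform = None
        ytr, yval = train_ds.one_hot(), val_ds.one_hot()
    else:
        tf_kwargs = {k: v for k, v in preset.transform.items() if k != "none"}
        transform = (None if preset.transform.get("none")
                     else fit_target_transform(train_ds.labels, **tf_kwargs))
        ytr = transform.apply(train_ds.labels) if transform else train_ds.labels
        yval = transform.apply(val_ds.labels) if transform else val_ds.labels
        if ytr.ndim == 1:
            ytr, yval = ytr[:, None], yval[:, None]

    spec = _build_spec(task, preset)
    cfg = nets.TrainingConfig(seed=seed, **preset.training)
    trained = nets.train(spec, (train_ds.inputs(), ytr), (val_ds.inputs(), yval),
                         cfg, verbose=verbose)

    if classification:
        pred = nets.predict_classes(trained, test_ds.inputs())
        report = _classification_report(task, test_ds.labels, pred,
                                        len(test_ds.class_names), test_ds.class_names)
    else:
        pred_nat = nets.predict(trained, test_ds.inputs(), transform=transform)
        truth = test_ds.labels
        if truth.ndim == 1:
            pred_nat = pred_nat.ravel()
        extra = {}
        if transform is not None:
            pred_t = nets.predict(trained, test_ds.inputs())
            truth_t = transform.apply(truth)
            if truth_t.ndim == 1:
                pred_t = pred_t.ravel()
            extra["rmse_transformed"] = rmse(truth_t, pred_t)
        report = _regression_report(task, truth, pred_nat, extra)
    report.metrics["selected_epoch"] = trained.selected_epoch
    if outdir:
        _save_run(outdir, preset, seed, report, trained)
    return report, trained, datasets


def _build_datasets(task, preset, rng):
    d = dict(preset.data)
    if task == "theta_toy":
        return simgen.build_theta_toy_dataset(rng, **d)
    if task in ("rho_haploid", "rho_interpolation", "rho_tetraploid"):
        return simgen.build_rho_dataset(rng, **d)
    if task == "introgression":
        return simgen.build_introgression_dataset(rng, **d)
    if task == "sweeps":
        return simgen.build_sweep_dataset(rng, **d)
    if task == "demography":
        return simgen.build_demography_dataset(rng, **d)
    raise ValueError(f"unknown task {task!r}")


def _build_spec(task, preset):
    if task == "theta_toy":
        return nets.spec_theta_toy(**preset.net)
    if task in ("rho_haploid", "rho_interpolation"):
        return nets.spec_rho_haploid(**preset.net)
    if task == "rho_tetraploid":
        return nets.spec_rho_tetraploid(**preset.net)
    if task == "introgression":
        return nets.spec_introgression(**preset.net)
    if task == "sweeps":
        return nets.spec_sweep(**preset.net)
    if task == "demography":
        return nets.spec_demography(**preset.net)
    raise ValueError(f"unknown task {task!r}")


TREATMENTS = ("raw", "transposed", "transposed_sorted")


def run_fig3_ablation(n_seeds: int = 5, n_train: int = 1500, n_val: int = 800,
                      max_epochs: int = 4, net=None, batch_size: int = 64,
                      base_seed: int = 0) -> pd.DataFrame:
    """Input-reorganization experiment on the theta toy task.

    For each seed, fresh alignments are simulated once and prepared three
    ways — raw orientation (chromosomes x sites), transposed (sites x
    chromosomes), and transposed plus similarity-sorted — and the same
    small network is trained on each. The held-out RMSE after every epoch
    is recorded, giving three RMSE-vs-epoch curves whose expected final
    ordering is transposed+sorted <= transposed <= raw.
    """
    if n_seeds < 2:
        raise ValueError("need at least 2 seeds to average over")
    net = net or dict(filters=(32, 32), dense=64)
    rows = []
    for si in range(n_seeds):
        seed = base_seed * 1000 + si
        rng = np.random.default_rng(seed)
        raw_tr = simgen.simulate_theta_toy(rng, n_train)
        raw_val = simgen.simulate_theta_toy(rng, n_val)
        width = max(a.n_sites for alns in (raw_tr[0], raw_val[0]) for a in alns)
        for treatment in TREATMENTS:
            sort = treatment == "transposed_sorted"
            transpose = treatment != "raw"
            splits = {}
            for name, (alns, th) in (("train", raw_tr), ("val", raw_val)):
                splits[name] = simgen._prepare(
                    alns, th, width, sort=sort, transpose=transpose,
                    encoding="zero_one", position_mode=None, split=name)
            spec = nets.spec_theta_toy(**net)
            cfg = nets.TrainingConfig(loss="rmse", batch_size=batch_size,
                                      max_epochs=max_epochs, seed=seed)
            trained = nets.train(
                spec, (splits["train"].inputs(), splits["train"].labels[:, None]),
                (splits["val"].inputs(), splits["val"].labels[:, None]), cfg)
            for epoch, v in enumerate(trained.history["val_loss"], start=1):
                rows.append({"treatment": treatment, "seed": si, "epoch": epoch,
                             "rmse": v})
    return pd.DataFrame(rows)
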