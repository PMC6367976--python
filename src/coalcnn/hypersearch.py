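"""Factorial hyperparameter search for the demographic-inference network.

The grid crosses six axes: convolution dimensionality (1D/2D), kernel size
(2, 4, 6, 8, 10), dropout (on/off), similarity sorting of chromosomes
(on/off), log-scaling of the response parameters (on/off), and pixel
encoding (-1/1 vs 0/255) — 160 points in total. Each point is trained for
up to a fixed number of epochs, keeping the epoch with minimal validation
RMSE, and the axes are compared by per-level medians, Mann-Whitney U
tests, and (for kernel size) a Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from . import nets
from .evalmetrics import rmse, spearman_rho
from .imageprep import Encoding, fit_target_transform
from .simgen import LabeledDataset, simulate_demography, _prepare
from .imageprep import PositionFeature

__all__ = ["HyperPoint", "enumerate_grid", "run_grid", "compare_axes",
           "prepare_grid_data"]

KERNEL_SIZES = (2, 4, 6, 8, 10)
PARAM_NAMES = ("N0", "N1", "N2", "T1", "T2")


@dataclass(frozen=True)
class HyperPoint:
    conv_dim: int  # 1 | 2
    kernel: int  # in {2, 4, 6, 8, 10}
    dropout: bool
    sort_rows: bool
    log_targets: bool
    encoding: str  # Encoding.NEG_POS | Encoding.ZERO_255

    def __post_init__(self):
        if self.conv_dim not in (1, 2):
            raise ValueError("conv_dim must be 1 or 2")
        if self.kernel not in KERNEL_SIZES:
            raise ValueError(f"kernel must be one of {KERNEL_SIZES}")
        if self.encoding not in (Encoding.NEG_POS, Encoding.ZERO_255):
            raise ValueError("encoding must be NEG_POS or ZERO_255")


def enumerate_grid() -> list[HyperPoint]:
    """Full factorial product, lexicographic over the axes as listed (160 points)."""
    return [
        HyperPoint(conv_dim=c, kernel=k, dropout=d, sort_rows=s,
                   log_targets=lg, encoding=e)
        for c, k, d, s, lg, e in product(
            (1, 2), KERNEL_SIZES, (False, True), (False, True), (False, True),
            (Encoding.NEG_POS, Encoding.ZERO_255))
    ]


def prepare_grid_data(raw_splits: dict, point: HyperPoint) -> dict[str, LabeledDataset]:
    """Re-encode/sort the raw simulated splits per grid point."""
    width = max(a.n_sites for alns, _ in raw_splits.values() for a in alns)
    out = {}
    for split, (alns, labels) in raw_splits.items():
        out[split] = _prepare(alns, labels, width, sort=point.sort_rows,
                              transpose=True, encoding=point.encoding,
                              position_mode=PositionFeature.DISTANCES,
                              split=split, config={"task": "demography"})
    return out


def _point_inputs(ds: LabeledDataset, point: HyperPoint):
    imgs = ds.images
    if point.conv_dim == 2:
        imgs = imgs[..., None]  # (N, W, C, 1): one-channel 2D image
    return [imgs, ds.positions]


def run_grid(raw_splits: dict, points: list[HyperPoint] | None = None,
             max_epochs: int = 10, seed: int = 0, filters: int = 128,
             pos_units: int = 32, merge_units: int = 256,
             batch_size: int = 200) -> pd.DataFrame:
    """Train one network per grid point and tabulate its scores.

    ``raw_splits`` maps split name to ``(alignments, label_matrix)`` as
    produced by :func:`coalcnn.simgen.simulate_demography`. Per-point RMSEs
    are on the z-scored response scale (the training loss scale); the best
    validation RMSE is the minimum over that point's epoch history. One
    derived seed per point keeps the grid deterministic; a training
    failure at a point is recorded as NaN rather than aborting the grid.
    """
    points = enumerate_grid() if points is None else points
    rows = []
    for idx, pt in enumerate(points):
        row = {"conv_dim": pt.conv_dim, "kernel": pt.kernel, "dropout": pt.dropout,
               "sort_rows": pt.sort_rows, "log_targets": pt.log_targets,
               "encoding": pt.encoding}
        try:
            data = prepare_grid_data(raw_splits, pt)
            tf = fit_target_transform(data["train"].labels, log_flag=pt.log_targets,
                                      zscore_flag=True)
            spec = nets.spec_demography(conv_dim=pt.conv_dim, kernel=pt.kernel,
                                        dropout=pt.dropout, filters=filters,
                                        pos_units=pos_units, merge_units=merge_units)
            cfg = nets.TrainingConfig(loss="rmse", batch_size=batch_size,
                                      max_epochs=max_epochs,
                                      seed=seed * 100_003 + idx)
            trained = nets.train(
                spec,
                (_point_inputs(data["train"], pt), tf.apply(data["train"].labels)),
                (_point_inputs(data["val"], pt), tf.apply(data["val"].labels)),
                cfg)
            pred = nets.predict(trained, _point_inputs(data["test"], pt))
            truth_z = tf.apply(data["test"].labels)
            row.update(
                best_val_rmse=float(min(trained.history["val_loss"])),
                selected_epoch=trained.selected_epoch,
                test_rmse=rmse(truth_z, pred),
            )
            rho = spearman_rho(data["test"].labels, pred)
            row.update({f"spearman_{p}": float(r) for p, r in zip(PARAM_NAMES, rho)})
        except Exception as exc:  # record, do not kill the grid
            row.update(best_val_rmse=np.nan, selected_epoch=-1, test_rmse=np.nan,
                       error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)


BINARY_AXES = {
    "conv_dim": (1, 2),
    "dropout": (False, True),
    "sort_rows": (False, True),
    "log_targets": (False, True),
    "encoding": (Encoding.NEG_POS, Encoding.ZERO_255),
}


def compare_axes(results: pd.DataFrame, metric: str = "best_val_rmse") -> dict:
    """Per-axis summaries of the grid results.

    For each two-level axis: the median RMSE at each level and a two-sided
    Mann-Whitney U p-value. For kernel size: the Spearman correlation of
    kernel with RMSE (and its p-value), plus a Mann-Whitney comparison of
    the smallest vs largest kernels.
    """
    df = results.dropna(subset=[metric])
    out = {}
    for axis, (lo, hi) in BINARY_AXES.items():
        a = df.loc[df[axis] == lo, metric].to_numpy()
        b = df.loc[df[axis] == hi, metric].to_numpy()
        entry = {"levels": (lo, hi),
                 "median": (float(np.median(a)) if a.size else np.nan,
                            float(np.median(b)) if b.size else np.nan)}
        if a.size and b.size:
            entry["mannwhitney_p"] = float(
                stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        out[axis] = entry
    sp = stats.spearmanr(df["kernel"], df[metric])
    kern = {"spearman_rho": float(sp.statistic), "spearman_p": float(sp.pvalue),
            "median_by_kernel": {int(k): float(np.median(df.loc[df.kernel == k, metric]))
                                 for k in sorted(df.kernel.unique())}}
    small = df.loc[df.kernel == df.kernel.min(), metric].to_numpy()
    large = df.loc[df.kernel == df.kernel.max(), metric].to_numpy()
    if small.size and large.size:
        kern["mannwhitney_p_small_vs_large"] = float(
            stats.mannwhitneyu(small, large, alternative="two-sided").pvalue)
    out["kernel"] = kern
    return out
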