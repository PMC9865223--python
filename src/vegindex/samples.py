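"""Labelled sample plots and the train/verify partition.

Field plots are small blocks of pixels (3 x 3 by default, i.e. 30 x 30 m on a
10 m grid) that share one vegetation label.  Splitting into training and
verification sets is done at plot level, stratified by class, so that the nine
pixels of one plot never straddle the partition (spatial leakage guard).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DataError
from .stack import MultiTemporalStack


@dataclass(frozen=True)
class SamplePlot:
    """A contiguous block of same-label pixels."""

    plot_id: str
    class_label: str
    pixels: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.pixels:
            raise DataError(f"plot {self.plot_id} has no pixels")

    @property
    def size(self) -> int:
        return len(self.pixels)


@dataclass
class SampleSet:
    """Plots plus an optional plot-level train/verify partition."""

    plots: list[SamplePlot]
    partition: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.plot_id for p in self.plots]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate plot ids in sample set")

    @property
    def classes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for p in self.plots:
            seen.setdefault(p.class_label, None)
        return tuple(seen)

    def subset(self, which: str) -> "SampleSet":
        """Plots assigned to one side of the partition ('train' or 'verify')."""
        if which not in {"train", "verify"}:
            raise DataError(f"unknown partition side {which!r}")
        if not self.partition:
            raise DataError("sample set has no partition; call split_train_verify")
        kept = [p for p in self.plots if self.partition.get(p.plot_id) == which]
        return SampleSet(plots=kept, partition={p.plot_id: which for p in kept})

    @property
    def n_pixels(self) -> int:
        return sum(p.size for p in self.plots)


def square_plot(plot_id: str, class_label: str, top: int, left: int,
                size: int = 3) -> SamplePlot:
    """A ``size x size`` plot with top-left pixel (top, left)."""
    px = tuple((top + r, left + c) for r in range(size) for c in range(size))
    return SamplePlot(plot_id=plot_id, class_label=class_label, pixels=px)


def plots_from_csv(path: "str | Path") -> SampleSet:
    """Read plots from a CSV with columns plot_id, class, row, col."""
    df = pd.read_csv(path)
    required = {"plot_id", "class", "row", "col"}
    if not required.issubset(df.columns):
        raise DataError(f"plot CSV must have columns {sorted(required)}")
    plots = []
    for pid, grp in df.groupby("plot_id", sort=False):
        labels = grp["class"].unique()
        if len(labels) != 1:
            raise DataError(f"plot {pid} has multiple class labels: {list(labels)}")
        px = tuple(zip(grp["row"].astype(int), grp["col"].astype(int)))
        plots.append(SamplePlot(str(pid), str(labels[0]), px))
    return SampleSet(plots=plots)


def plots_to_csv(samples: SampleSet, path: "str | Path") -> Path:
    rows = [
        {"plot_id": p.plot_id, "class": p.class_label, "row": r, "col": c}
        for p in samples.plots for (r, c) in p.pixels
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def plots_from_label_raster(labels: np.ndarray,
                            class_names: Sequence[str]) -> SampleSet:
    """Build plots from an integer label raster (0 = unlabelled, 1..k = class).

    Each 4-connected component of same-label pixels becomes one plot.
    """
    labels = np.asarray(labels)
    plots: list[SamplePlot] = []
    for value, name in enumerate(class_names, start=1):
        comp, n = ndimage.label(labels == value)
        for i in range(1, n + 1):
            rows, cols = np.nonzero(comp == i)
            px = tuple(zip(rows.tolist(), cols.tolist()))
            plots.append(SamplePlot(f"{name}_{i:03d}", name, px))
    return SampleSet(plots=plots)


def split_train_verify(samples: SampleSet, train_fraction: float = 0.6,
                       seed: int = 0) -> SampleSet:
    """Stratified plot-level split; per class, round(fraction * n) plots train.

    Deterministic under a fixed seed.  Classes with fewer than two plots
    cannot be stratified and raise.
    """
    if not 0.0 < train_fraction < 1.0:
        raise DataError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    partition: dict[str, str] = {}
    by_class: dict[str, list[SamplePlot]] = {}
    for p in samples.plots:
        by_class.setdefault(p.class_label, []).append(p)
    for label, plots in by_class.items():
        if len(plots) < 2:
            raise DataError(
                f"class {label!r} has {len(plots)} plot(s); need >= 2 to split")
        n_train = int(round(train_fraction * len(plots)))
        n_train = min(max(n_train, 1), len(plots) - 1)
        order = rng.permutation(len(plots))
        for rank, idx in enumerate(order):
            partition[plots[idx].plot_id] = "train" if rank < n_train else "verify"
    return SampleSet(plots=list(samples.plots), partition=partition)


def extract_samples(stack: MultiTemporalStack,
                    plots: "SampleSet | Iterable[SamplePlot]") -> pd.DataFrame:
    """Long table of reflectance: one row per (pixel, phase, band).

    Columns: plot_id, class, row, col, phase, band, reflectance.  Every plot
    pixel must be inside the grid and unmasked; offenders are reported by plot.
    """
    plot_list = plots.plots if isinstance(plots, SampleSet) else list(plots)
    nrows, ncols = stack.nrows, stack.ncols
    bad: list[str] = []
    for p in plot_list:
        for (r, c) in p.pixels:
            if not (0 <= r < nrows and 0 <= c < ncols):
                bad.append(p.plot_id)
                break
            if stack.data.mask is not np.ma.nomask and stack.data.mask[:, :, r, c].any():
                bad.append(p.plot_id)
                break
    if bad:
        raise DataError(f"plots with out-of-bounds or masked pixels: {sorted(set(bad))}")

    if not plot_list:
        return pd.DataFrame(columns=["plot_id", "class", "row", "col",
                                     "phase", "band", "reflectance"])

    rows = np.array([rc[0] for p in plot_list for rc in p.pixels])
    cols = np.array([rc[1] for p in plot_list for rc in p.pixels])
    pids = np.array([p.plot_id for p in plot_list for _ in p.pixels])
    labs = np.array([p.class_label for p in plot_list for _ in p.pixels])

    cube = np.ma.getdata(stack.data)[:, :, rows, cols]  # (P, B, Npix)
    n_px = len(rows)
    frames = []
    for i, ph in enumerate(stack.phases):
        for j, bd in enumerate(stack.bands):
            frames.append(pd.DataFrame({
                "plot_id": pids, "class": labs, "row": rows, "col": cols,
                "phase": ph.name, "band": bd.name,
                "reflectance": cube[i, j],
            }))
    out = pd.concat(frames, ignore_index=True)
    assert len(out) == n_px * len(stack.phases) * len(stack.bands)
    return out
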