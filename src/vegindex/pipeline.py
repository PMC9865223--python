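"""Stage orchestration: validated configs, reproducible runs, manifests.

A run executes an ordered subset of the stages

    simulate -> indices -> screen -> train -> classify -> evaluate

against one shared state.  Each stage writes its outputs under the run
directory; the manifest records the config, the seed, and every output file
with a SHA-256 checksum, so that re-running a deterministic config reproduces
the artefacts bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .classes import CLASS_ORDER, DISPLAY_NAMES
from .classify import DEFAULT_HIERARCHY, build_knowledge_tree, classify_tree
from .development import select_combination, standard_candidates
from .errors import ConfigError, DataError
from .evaluate import accuracy_report, confusion_matrix
from .indices import optimal_feature_set
from .samples import extract_samples, plots_to_csv, split_train_verify
from .simulate import SceneConfig, default_profiles, simulate_scene
from .stack import read_stack, write_raster, write_stack

STAGES = ("simulate", "indices", "screen", "train", "classify", "evaluate")

#: Which earlier stage each stage depends on.
_DEPENDS = {
    "indices": "simulate",
    "screen": "simulate",
    "train": "indices",
    "classify": "train",
    "evaluate": "classify",
}


@dataclass
class RunConfig:
    """Everything a pipeline run needs; validated before any stage executes."""

    out_dir: str = "run"
    seed: int = 0
    # scene generation
    shape: tuple[int, int] = (120, 120)
    plots_per_class: "int | Sequence[int] | str" = 10
    plot_size: int = 3
    noise_multiplier: float = 1.0
    noise_sd: float = 0.005
    # input rasters (alternative to the simulate stage)
    paths_by_phase: dict[str, str] = field(default_factory=dict)
    band_map: dict[str, int] = field(default_factory=dict)
    scale: float = 1.0
    # sampling / training
    train_fraction: float = 0.6
    screening_scope: str = "classes_to_identify"
    n_trees: int = 250

    def validate(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ConfigError(
                f"train_fraction: expected a value in (0, 1), got "
                f"{self.train_fraction}")
        if self.noise_multiplier < 0:
            raise ConfigError("noise_multiplier: must be >= 0")
        if self.plot_size < 1:
            raise ConfigError("plot_size: must be >= 1")
        if self.n_trees < 1:
            raise ConfigError("n_trees: must be >= 1")
        if self.screening_scope not in {"classes_to_identify", "target"}:
            raise ConfigError(
                f"screening_scope: unknown value {self.screening_scope!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        if not isinstance(d["plots_per_class"], (int, str)):
            d["plots_per_class"] = list(d["plots_per_class"])
        return d

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = sorted(set(raw) - known)
        if bad:
            raise ConfigError(f"unknown config fields: {bad}")
        if "shape" in raw:
            raw["shape"] = tuple(raw["shape"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig,
                 stages: Sequence[str] = STAGES) -> dict:
    """Execute the requested stages in order; return (and write) the manifest."""
    config.validate()
    stages = list(stages)
    for s in stages:
        if s not in STAGES:
            raise ConfigError(f"unknown stage {s!r}; choose from {STAGES}")
    stages.sort(key=STAGES.index)
    done: set[str] = set()
    for s in stages:
        dep = _DEPENDS.get(s)
        if dep and dep not in stages[:stages.index(s)]:
            raise ConfigError(f"stage {s!r} requires stage {dep!r} to run first")
        done.add(s)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    manifest: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
        "stages": {},
    }
    for s in stages:
        t0 = time.perf_counter()
        outputs = _STAGE_FN[s](config, out, state)
        manifest["stages"][s] = {
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
            "wall_time_s": round(time.perf_counter() - t0, 3),
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _stage_simulate(config: RunConfig, out: Path, state: dict) -> list[Path]:
    profiles = default_profiles(noise_sd=config.noise_sd)
    scene_cfg = SceneConfig(shape=config.shape,
                            plots_per_class=config.plots_per_class,
                            plot_size=config.plot_size, seed=config.seed,
                            noise_multiplier=config.noise_multiplier)
    stack, labels, samples = simulate_scene(profiles, scene_cfg)
    state.update(stack=stack, labels=labels, samples=samples)
    paths = list(write_stack(stack, out, prefix="scene").values())
    paths.append(write_raster(out / "labels.tif", labels, grid=stack.grid))
    paths.append(plots_to_csv(samples, out / "plots.csv"))
    return paths


def _load_input_stack(config: RunConfig, state: dict) -> None:
    if "stack" not in state:
        if not config.paths_by_phase:
            raise DataError("no stack available: run the simulate stage or "
                            "provide paths_by_phase in the config")
        state["stack"] = read_stack(config.paths_by_phase,
                                    config.band_map or None,
                                    scale=config.scale)


def _stage_indices(config: RunConfig, out: Path, state: dict) -> list[Path]:
    _load_input_stack(config, state)
    features = optimal_feature_set(state["stack"])
    state["features"] = features
    p = out / "optimal_features.tif"
    features.write(p)
    paths = [p]
    if "samples" in state:
        table = features.sample_table(state["samples"])
        fp = out / "feature_samples.csv"
        table.to_csv(fp, index=False)
        paths.append(fp)
    return paths


def _stage_screen(config: RunConfig, out: Path, state: dict) -> list[Path]:
    _load_input_stack(config, state)
    if "samples" not in state:
        raise DataError("screening needs labelled plots from the simulate stage")
    long = extract_samples(state["stack"], state["samples"])
    paths = []
    for target, cands in standard_candidates().items():
        report = select_combination(cands, long, scope=config.screening_scope)
        p = out / f"screening_{target}.csv"
        report.to_frame().to_csv(p, index=False)
        paths.append(p)
    return paths


def _stage_train(config: RunConfig, out: Path, state: dict) -> list[Path]:
    if "samples" not in state:
        raise DataError("training needs labelled plots from the simulate stage")
    samples = split_train_verify(state["samples"],
                                 train_fraction=config.train_fraction,
                                 seed=config.seed)
    state["samples"] = samples
    tree = build_knowledge_tree(state["features"], samples.subset("train"),
                                hierarchy=DEFAULT_HIERARCHY)
    state["tree"] = tree
    p = out / "knowledge_tree.json"
    tree.to_json(p)
    sp = plots_to_csv(samples.subset("train"), out / "train_plots.csv")
    vp = plots_to_csv(samples.subset("verify"), out / "verify_plots.csv")
    return [p, sp, vp]


def _stage_classify(config: RunConfig, out: Path, state: dict) -> list[Path]:
    labels, classes = classify_tree(state["tree"], state["features"])
    state["predicted"] = labels
    state["pred_classes"] = classes
    p = out / "classified.tif"
    write_raster(p, labels, grid=state["stack"].grid)
    legend = out / "classified_legend.json"
    legend.write_text(json.dumps(
        {i: c for i, c in enumerate(classes)} | {-1: "nodata"}, indent=2))
    return [p, legend]


def _stage_evaluate(config: RunConfig, out: Path, state: dict) -> list[Path]:
    samples = state["samples"]
    if not samples.partition:
        raise DataError("evaluate needs a train/verify partition (train stage)")
    verify = samples.subset("verify")
    pred_map, classes = state["predicted"], state["pred_classes"]
    y_true, y_pred = [], []
    for plot in verify.plots:
        for (r, c) in plot.pixels:
            y_true.append(plot.class_label)
            idx = pred_map[r, c]
            y_pred.append(classes[idx] if idx >= 0 else "nodata")
    order = [c for c in CLASS_ORDER if c in set(y_true) | set(y_pred)]
    if "nodata" in y_pred:
        order.append("nodata")
    cm = confusion_matrix(y_pred, y_true, order)
    report = accuracy_report(cm)
    paths = []
    p = out / "confusion_matrix.csv"
    cm.to_frame().to_csv(p)
    paths.append(p)
    p = out / "accuracy_report.txt"
    p.write_text(report.format_table(DISPLAY_NAMES) + "\n")
    paths.append(p)
    p = out / "accuracy_summary.json"
    p.write_text(json.dumps({
        **report.summary(),
        "PA_pct": {c: round(report.pa[c] * 100, 2) for c in cm.classes},
        "UA_pct": {c: round(report.ua[c] * 100, 2) for c in cm.classes},
        "n_verify_pixels": cm.n,
    }, indent=2))
    paths.append(p)
    state["report"] = report
    return paths


_STAGE_FN = {
    "simulate": _stage_simulate,
    "indices": _stage_indices,
    "screen": _stage_screen,
    "train": _stage_train,
    "classify": _stage_classify,
    "evaluate": _stage_evaluate,
}
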