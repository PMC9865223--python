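"""Hierarchical knowledge-decision-tree classification and the RF comparator.

The knowledge decision tree is an ordered list of one-feature threshold rules.
Rules fire sequentially: each rule peels one class off the pixels that no
earlier rule claimed, and whatever survives every rule gets the fallback
class.  The default hierarchy follows the identification order of the study
system - December NDVI isolates the evergreen conifer, April NDVI the bare
cropland, then the four modified indices take pine-oak, Quercus, scrub grass
and finally split shaw (high MTM-RSI side) from Larix (fallback).

Published rule thresholds being experiential and unprinted, thresholds are
calibrated from training samples as the minimal-misclassification 1-D split;
user-supplied expert thresholds can override any rule.

The random-forest comparator is deliberately a stock bagged-tree ensemble
(scikit-learn) behind a thin, reproducibility-focused interface: what this
module guarantees is the contract (tree count, sqrt(p) features per split,
seed determinism), not a re-implementation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .classes import HIERARCHY_ORDER
from .errors import DataError
from .indices import FeatureSet
from .samples import SampleSet

#: (feature, class assigned when the rule fires), in firing order.  The last
#: hierarchy class is the fallback and has no rule of its own.
DEFAULT_HIERARCHY: tuple[tuple[str, str], ...] = (
    ("NDVI@DEC", "pinus"),
    ("NDVI@APR", "crops"),
    ("UTM-DMI", "pine_oak"),
    ("MTM-NDQI", "quercus"),
    ("MTM-DSI", "scrub_grass"),
    ("MTM-RSI", "shaw"),
)
DEFAULT_FALLBACK = HIERARCHY_ORDER[-1]  # larix

NODATA_LABEL = "nodata"


def calibrate_threshold(target: np.ndarray, rest: np.ndarray
                        ) -> tuple[float, str]:
    """Best 1-D split separating target-class values from the rest.

    The direction ('GE' or 'LE') points toward the target mean; candidate
    thresholds are the midpoints of adjacent distinct sorted pooled values;
    the threshold minimising training misclassifications wins, ties going to
    the smallest threshold.  Deterministic.  Raises when both vectors are one
    identical constant (inseparable).
    """
    t = np.asarray(target, dtype=float)
    r = np.asarray(rest, dtype=float)
    if t.size == 0 or r.size == 0:
        raise DataError("calibrate_threshold needs non-empty target and rest")
    pooled = np.concatenate([t, r])
    distinct = np.unique(pooled)
    if distinct.size == 1:
        raise DataError("target and rest are one identical constant; inseparable")
    direction = "GE" if t.mean() >= r.mean() else "LE"
    cuts = (distinct[:-1] + distinct[1:]) / 2.0
    if direction == "GE":
        errors = [(np.count_nonzero(t < c) + np.count_nonzero(r >= c)) for c in cuts]
    else:
        errors = [(np.count_nonzero(t > c) + np.count_nonzero(r <= c)) for c in cuts]
    best = int(np.argmin(errors))  # first minimum = smallest threshold
    return float(cuts[best]), direction


@dataclass(frozen=True)
class DecisionRule:
    feature: str
    threshold: float
    direction: str  # 'GE' or 'LE'
    assigned_class: str

    def __post_init__(self) -> None:
        if self.direction not in {"GE", "LE"}:
            raise DataError(f"rule direction must be GE or LE, got {self.direction!r}")

    def fires(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return v >= self.threshold if self.direction == "GE" else v <= self.threshold


@dataclass
class KnowledgeDecisionTree:
    """Ordered threshold rules plus the fallback class."""

    rules: list[DecisionRule]
    fallback_class: str = DEFAULT_FALLBACK

    @property
    def classes(self) -> list[str]:
        return [r.assigned_class for r in self.rules] + [self.fallback_class]

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Labels for a per-pixel feature table (one column per feature).

        Rows with a missing value at a rule that must be consulted are
        labelled ``nodata``.
        """
        for r in self.rules:
            if r.feature not in features.columns:
                raise DataError(f"feature table lacks rule feature {r.feature!r}")
        n = len(features)
        out = np.full(n, "", dtype=object)
        undecided = np.ones(n, dtype=bool)
        for r in self.rules:
            vals = features[r.feature].to_numpy(dtype=float)
            bad = undecided & ~np.isfinite(vals)
            out[bad] = NODATA_LABEL
            undecided &= ~bad
            with np.errstate(invalid="ignore"):
                hit = undecided & r.fires(vals)
            out[hit] = r.assigned_class
            undecided &= ~hit
        out[undecided] = self.fallback_class
        return out.astype(str)

    def to_dict(self) -> dict:
        return {
            "rules": [
                {"feature": r.feature, "threshold": r.threshold,
                 "direction": r.direction, "class": r.assigned_class}
                for r in self.rules
            ],
            "fallback_class": self.fallback_class,
        }

    def to_json(self, path: "str | Path | None" = None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "KnowledgeDecisionTree":
        rules = [DecisionRule(r["feature"], float(r["threshold"]),
                              r["direction"], r["class"]) for r in d["rules"]]
        return cls(rules=rules, fallback_class=d["fallback_class"])

    @classmethod
    def from_json(cls, src: "str | Path") -> "KnowledgeDecisionTree":
        p = Path(src)
        text = p.read_text() if p.exists() else str(src)
        return cls.from_dict(json.loads(text))


def build_knowledge_tree(
    features: "FeatureSet | pd.DataFrame",
    training: SampleSet | None = None,
    hierarchy: tuple[tuple[str, str], ...] = DEFAULT_HIERARCHY,
    fallback_class: str = DEFAULT_FALLBACK,
    expert_thresholds: dict[str, tuple[float, str]] | None = None,
) -> KnowledgeDecisionTree:
    """Calibrate every rule of the hierarchy from training samples.

    ``features`` is either a :class:`FeatureSet` (with ``training`` the
    labelled plots to sample it at) or a ready-made per-pixel feature table
    with a ``class`` column.  At each stage the target class is split against
    the classes not yet assigned; ``expert_thresholds`` maps a feature name to
    a (threshold, direction) pair that overrides calibration for that rule.
    """
    if isinstance(features, FeatureSet):
        if training is None:
            raise DataError("building from a FeatureSet needs training samples")
        table = features.sample_table(training)
    else:
        table = features
    if "class" not in table.columns:
        raise DataError("training table needs a 'class' column")

    needed = {cls for _, cls in hierarchy} | {fallback_class}
    present = set(table["class"].unique())
    missing = sorted(needed - present)
    if missing:
        raise DataError(f"training data lacks classes: {missing}")

    remaining = list(dict.fromkeys([cls for _, cls in hierarchy] + [fallback_class]))
    rules: list[DecisionRule] = []
    for feature, target in hierarchy:
        if feature not in table.columns:
            raise DataError(f"training table lacks feature {feature!r}")
        stage = table[table["class"].isin(remaining)]
        tvals = stage.loc[stage["class"] == target, feature].dropna().to_numpy()
        rvals = stage.loc[stage["class"] != target, feature].dropna().to_numpy()
        if expert_thresholds and feature in expert_thresholds:
            thr, direction = expert_thresholds[feature]
        else:
            thr, direction = calibrate_threshold(tvals, rvals)
        rules.append(DecisionRule(feature, float(thr), direction, target))
        remaining.remove(target)
    return KnowledgeDecisionTree(rules=rules, fallback_class=fallback_class)


def classify_tree(tree: KnowledgeDecisionTree, features: FeatureSet
                  ) -> tuple[np.ndarray, list[str]]:
    """Classify a whole feature raster by sequential masking.

    Returns an integer label raster (index into the returned class list,
    -1 = nodata where a needed feature is masked) plus the class list
    (rule classes in order, fallback last).
    """
    classes = tree.classes
    cube = features.to_array()
    nrows, ncols = cube.shape[1], cube.shape[2]
    flat = pd.DataFrame({
        l.name: np.ma.filled(l.values, np.nan).ravel() for l in features.layers
    })
    labels = tree.predict(flat)
    lut = {name: i for i, name in enumerate(classes)}
    lut[NODATA_LABEL] = -1
    out = np.array([lut[l] for l in labels], dtype=np.int16).reshape(nrows, ncols)
    return out, classes


@dataclass(frozen=True)
class EnsembleConfig:
    """Random-forest comparator settings: 250 trees, sqrt(p) features/split."""

    n_trees: int = 250
    max_features: str = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise DataError("n_trees must be >= 1")


@dataclass
class EnsembleClassifier:
    model: RandomForestClassifier
    feature_names: list[str]
    config: EnsembleConfig = field(default_factory=EnsembleConfig)


def train_ensemble(features: pd.DataFrame, labels: "pd.Series | np.ndarray",
                   config: EnsembleConfig = EnsembleConfig()
                   ) -> EnsembleClassifier:
    """Fit the bagged-tree comparator on a samples x features table."""
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels)
    if X.shape[1] < 1:
        raise DataError("need at least one feature column")
    if len(np.unique(y)) < 2:
        raise DataError("need at least two classes to train the ensemble")
    model = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        random_state=config.seed,
        n_jobs=1,
    )
    model.fit(X, y)
    return EnsembleClassifier(model=model,
                              feature_names=list(features.columns),
                              config=config)


def classify_ensemble(classifier: EnsembleClassifier,
                      features: pd.DataFrame) -> np.ndarray:
    """Majority-vote labels, one per row; columns must match training."""
    if list(features.columns) != classifier.feature_names:
        raise DataError(
            f"feature columns {list(features.columns)} do not match training "
            f"columns {classifier.feature_names}")
    if len(features) == 0:
        return np.array([], dtype=str)
    return classifier.model.predict(features.to_numpy(dtype=float))
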