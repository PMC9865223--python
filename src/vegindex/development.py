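"""Developing a modified index: statistics, screening, formula instantiation.

The development flow for a class-specific index is: (1) compute per-class mean
and standard deviation of reflectance for every (phase, band) cell; (2) from
visual spectral analysis, list candidate feature band combinations - pairs of
(band, phase) operands whose contrast isolates the target class; (3) screen
the candidates by the sum of per-class standard deviations over both operands
(the most stable combination, i.e. the smallest sum, wins); (4) bind the
winning combination to one of three formula templates patterned on the typical
indices (difference, normalized complement, relative change); and (5) confirm
separability with a distribution-overlap check.

The candidate list is explicit (supplied by the analyst or a config); the
visual spectral analysis that produces it is not an algorithm.  An exhaustive
enumeration helper over a stated band/phase subset is provided as a clearly
flagged extension beyond that workflow.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bands import Band, Phase, parse_band, parse_phase
from .errors import DataError
from . import indices as _idx
from .stack import MultiTemporalStack

#: Reporting scale for SD sums: reflectance in [0, 1] times 1e4 puts scores on
#: the integer digital-number scale the screening tables conventionally use.
DEFAULT_SCORE_SCALE = 1.0e4


@dataclass(frozen=True)
class Operand:
    band: Band
    phase: Phase

    @property
    def label(self) -> str:
        return f"{self.band.name}@{self.phase.name}"


def operand(band, phase) -> Operand:
    return Operand(parse_band(band), parse_phase(phase))


@dataclass(frozen=True)
class BandCombination:
    """A dual-band (band, phase) operand pair proposed for a target class."""

    a: Operand
    b: Operand
    target_class: str = ""
    classes_to_identify: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise DataError(f"operands must be distinct, got {self.a.label} twice")

    @property
    def label(self) -> str:
        return f"{self.a.label} and {self.b.label}"


class FormulaTemplate(enum.Enum):
    """The three formula patterns the modified indices are built from."""

    DIFFERENCE = "difference"              # a - b
    NORMALIZED_COMPLEMENT = "normalized_complement"  # (1 - a - b)/(a + b)
    RELATIVE_CHANGE = "relative_change"    # (a - b)/b


_TEMPLATE_FN = {
    FormulaTemplate.DIFFERENCE: lambda a, b: _idx._ma(a) - _idx._ma(b),
    FormulaTemplate.NORMALIZED_COMPLEMENT: _idx.mtm_ndqi,
    FormulaTemplate.RELATIVE_CHANGE: _idx.mtm_rsi,
}


@dataclass(frozen=True)
class IndexDefinition:
    """A formula template bound to a band combination; evaluatable on stacks."""

    name: str
    template: FormulaTemplate
    combination: BandCombination

    def evaluate(self, stack: MultiTemporalStack) -> np.ma.MaskedArray:
        a = stack.band(self.combination.a.phase, self.combination.a.band)
        b = stack.band(self.combination.b.phase, self.combination.b.band)
        return self.evaluate_operands(a, b)

    def evaluate_operands(self, a, b) -> np.ma.MaskedArray:
        return _TEMPLATE_FN[self.template](a, b)

    def to_dict(self) -> dict:
        c = self.combination
        return {
            "name": self.name,
            "template": self.template.value,
            "operand_a": {"band": c.a.band.name, "phase": c.a.phase.name},
            "operand_b": {"band": c.b.band.name, "phase": c.b.phase.name},
            "target_class": c.target_class,
            "classes_to_identify": list(c.classes_to_identify),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "IndexDefinition":
        comb = BandCombination(
            a=operand(d["operand_a"]["band"], d["operand_a"]["phase"]),
            b=operand(d["operand_b"]["band"], d["operand_b"]["phase"]),
            target_class=d.get("target_class", ""),
            classes_to_identify=tuple(d.get("classes_to_identify", ())),
        )
        return cls(name=d["name"], template=FormulaTemplate(d["template"]),
                   combination=comb)


def instantiate_index(combination: BandCombination, template: FormulaTemplate,
                      name: str) -> IndexDefinition:
    """Bind a screened band combination to a formula template."""
    return IndexDefinition(name=name, template=template, combination=combination)


def modified_index_definitions() -> dict[str, IndexDefinition]:
    """The four class-specific modified indices as screened definitions.

    Evaluating each on a stack reproduces the corresponding function in
    :mod:`vegindex.indices` bit-for-bit.
    """
    return {
        "UTM-DMI": instantiate_index(
            BandCombination(operand("RE4", "FEB"), operand("SWIR1", "FEB"),
                            "pine_oak",
                            ("quercus", "scrub_grass", "larix", "shaw")),
            FormulaTemplate.DIFFERENCE, "UTM-DMI"),
        "MTM-NDQI": instantiate_index(
            BandCombination(operand("RE4", "JUN"), operand("RE4", "OCT"),
                            "quercus", ("scrub_grass", "larix", "shaw")),
            FormulaTemplate.NORMALIZED_COMPLEMENT, "MTM-NDQI"),
        "MTM-DSI": instantiate_index(
            BandCombination(operand("RE2", "JUN"), operand("RE2", "AUG"),
                            "scrub_grass", ("larix", "shaw")),
            FormulaTemplate.DIFFERENCE, "MTM-DSI"),
        "MTM-RSI": instantiate_index(
            BandCombination(operand("RE2", "JUN"), operand("RE2", "OCT"),
                            "shaw", ("larix",)),
            FormulaTemplate.RELATIVE_CHANGE, "MTM-RSI"),
    }


def standard_candidates() -> dict[str, list[BandCombination]]:
    """The analyst-derived candidate lists for the four class-specific indices.

    Pine-oak contrasts RE4 against SWIR-1 within one winter date (February or
    December); Quercus pairs NIR or RE4 across June and October; scrub grass
    pairs each red-edge/NIR band across June and August; shaw pairs the same
    bands across June and October.
    """
    def combos(pairs, target, to_identify):
        return [BandCombination(operand(*a), operand(*b), target,
                                tuple(to_identify)) for a, b in pairs]

    return {
        "pine_oak": combos(
            [(("RE4", "FEB"), ("SWIR1", "FEB")),
             (("RE4", "DEC"), ("SWIR1", "DEC"))],
            "pine_oak", ("quercus", "scrub_grass", "larix", "shaw")),
        "quercus": combos(
            [(("NIR", "JUN"), ("NIR", "OCT")),
             (("RE4", "JUN"), ("RE4", "OCT"))],
            "quercus", ("scrub_grass", "larix", "shaw")),
        "scrub_grass": combos(
            [(("RE2", "JUN"), ("RE2", "AUG")),
             (("RE3", "JUN"), ("RE3", "AUG")),
             (("NIR", "JUN"), ("NIR", "AUG")),
             (("RE4", "JUN"), ("RE4", "AUG"))],
            "scrub_grass", ("larix", "shaw")),
        "shaw": combos(
            [(("RE2", "JUN"), ("RE2", "OCT")),
             (("RE3", "JUN"), ("RE3", "OCT")),
             (("NIR", "JUN"), ("NIR", "OCT")),
             (("RE4", "JUN"), ("RE4", "OCT"))],
            "shaw", ("larix",)),
    }


def class_spectral_stats(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-(class, phase, band) mean and sample standard deviation (ddof=1).

    ``samples`` is the long table produced by
    :func:`vegindex.samples.extract_samples`.
    """
    if samples.empty:
        raise DataError("sample table is empty")
    counts = samples.groupby(["class", "phase", "band"])["reflectance"].count()
    thin = counts[counts < 2]
    if not thin.empty:
        raise DataError(
            f"need >= 2 pixels per (class, phase, band); short cells: "
            f"{list(thin.index[:5])}")
    out = (samples.groupby(["class", "phase", "band"])["reflectance"]
           .agg(mean="mean", sd=lambda x: x.std(ddof=1))
           .reset_index())
    return out


def _operand_values(samples: pd.DataFrame, op: Operand,
                    class_label: str) -> np.ndarray:
    sel = samples[(samples["class"] == class_label)
                  & (samples["phase"] == op.phase.name)
                  & (samples["band"] == op.band.name)]
    if sel.empty:
        raise DataError(
            f"no samples for class {class_label!r}, operand {op.label}")
    return sel["reflectance"].to_numpy(dtype=float)


def sd_sum_score(combination: BandCombination, samples: pd.DataFrame, *,
                 scope: str = "classes_to_identify",
                 scale: float = DEFAULT_SCORE_SCALE) -> float:
    """Stability score of a candidate: summed per-class operand SDs.

    For every class in scope (default: the classes still to be identified at
    this stage of the hierarchy; ``scope='target'`` restricts to the target
    class only) the sample standard deviation of each operand's reflectance is
    accumulated; the total is reported times ``scale`` (1e4 by default, the
    digital-number scale).  Smaller is more stable.
    """
    if scope == "classes_to_identify":
        class_scope: Sequence[str] = (combination.classes_to_identify
                                      or (combination.target_class,))
    elif scope == "target":
        class_scope = (combination.target_class,)
    else:
        raise DataError(f"unknown scope {scope!r}")
    if not all(class_scope):
        raise DataError("combination lacks class labels for the requested scope")
    total = 0.0
    for label in class_scope:
        for op in (combination.a, combination.b):
            vals = _operand_values(samples, op, label)
            if len(vals) < 2:
                raise DataError(
                    f"need >= 2 samples for class {label!r}, operand {op.label}")
            total += float(np.std(vals, ddof=1))
    return total * scale


@dataclass
class ScreeningReport:
    """Scored candidates with exactly one selected (minimal-score) winner."""

    combinations: list[BandCombination]
    sd_sums: list[float]
    selected_index: int

    def __post_init__(self) -> None:
        if len(self.combinations) != len(self.sd_sums):
            raise DataError("combinations and scores differ in length")
        if not self.combinations:
            raise DataError("screening report needs at least one candidate")
        lo = min(self.sd_sums)
        if self.sd_sums[self.selected_index] != lo:
            raise DataError("selected candidate does not have the minimal score")

    @property
    def selected(self) -> BandCombination:
        return self.combinations[self.selected_index]

    @property
    def selected_score(self) -> float:
        return self.sd_sums[self.selected_index]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "combination": [c.label for c in self.combinations],
            "sd_sum": self.sd_sums,
            "selected": [i == self.selected_index
                         for i in range(len(self.combinations))],
        })


def select_from_scores(candidates: Sequence[BandCombination],
                       scores: Sequence[float]) -> ScreeningReport:
    """Pick the argmin-score candidate; ties go to the earliest-listed one."""
    if len(candidates) == 0:
        raise DataError("no candidate combinations to screen")
    scores = [float(s) for s in scores]
    best = int(np.argmin(scores))  # argmin returns the first minimum
    return ScreeningReport(list(candidates), scores, best)


def select_combination(candidates: Sequence[BandCombination],
                       samples: pd.DataFrame, *,
                       scope: str = "classes_to_identify",
                       scale: float = DEFAULT_SCORE_SCALE) -> ScreeningReport:
    """Score every candidate on the sample table and select the most stable."""
    scores = [sd_sum_score(c, samples, scope=scope, scale=scale)
              for c in candidates]
    return select_from_scores(candidates, scores)


def enumerate_combinations(bands: Iterable, phases: Iterable, target_class: str,
                           classes_to_identify: Sequence[str],
                           cross_phase_only: bool = False) -> list[BandCombination]:
    """Exhaustively enumerate same-band cross-phase and same-phase pairs.

    Extension beyond the analyst-driven workflow: generates every distinct
    operand pair over the given band/phase subset for automated screening.
    """
    ops = [operand(b, p) for b in bands for p in phases]
    out = []
    for i, a in enumerate(ops):
        for b in ops[i + 1:]:
            if cross_phase_only and a.phase == b.phase:
                continue
            out.append(BandCombination(a, b, target_class,
                                       tuple(classes_to_identify)))
    return out


def overlap_fraction(values_a: np.ndarray, values_b: np.ndarray,
                     method: str = "range") -> float:
    """Fraction of pooled samples inside the overlap of two class intervals.

    ``method='range'`` intersects the classes' min-max ranges (the box-plot
    whisker reading); ``method='iqr'`` intersects their interquartile ranges.
    Returns a proportion in [0, 1]; identical distributions give 1, disjoint
    ranges give 0.  A separability check typically flags a pair whose overlap
    exceeds 0.25.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("overlap_fraction needs two non-empty sample vectors")
    if method == "range":
        lo_a, hi_a = a.min(), a.max()
        lo_b, hi_b = b.min(), b.max()
    elif method == "iqr":
        lo_a, hi_a = np.percentile(a, [25, 75])
        lo_b, hi_b = np.percentile(b, [25, 75])
    else:
        raise DataError(f"unknown overlap method {method!r}")
    lo, hi = max(lo_a, lo_b), min(hi_a, hi_b)
    if lo > hi:
        return 0.0
    pooled = np.concatenate([a, b])
    inside = np.count_nonzero((pooled >= lo) & (pooled <= hi))
    return inside / pooled.size
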