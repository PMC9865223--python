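"""Typical and modified vegetation indices.

Three typical indices drive the easy separations (evergreen conifer in winter,
bare cropland in spring):

    RVI  = RED / NIR
    DVI  = NIR - RED
    NDVI = (NIR - RED) / (NIR + RED)

Note the RVI orientation: the ratio is printed RED/NIR in the source method
even though the classical ratio vegetation index is NIR/RED; the printed form
is the default here and ``orientation='nir_red'`` gives the conventional one.

Four modified indices amplify the red-edge/SWIR contrasts that the typical
indices cannot see, two of them across acquisition dates (multi-temporal):

    UTM-DMI  = RE4(Feb) - SWIR1(Feb)          pine-oak mixed forest
    MTM-NDQI = (1 - RE4(Jun) - RE4(Oct)) / (RE4(Jun) + RE4(Oct))   Quercus
    MTM-DSI  = RE2(Jun) - RE2(Aug)            scrub grass
    MTM-RSI  = (RE2(Jun) - RE2(Oct)) / RE2(Oct)                    shaw

All operations are pixel-wise and mask-propagating: an output pixel is masked
iff any operand pixel is masked or a denominator is zero, so whole-raster
computation never aborts on isolated degenerate pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import Band, Phase
from .errors import DataError
from .samples import SampleSet
from .stack import GridSpec, MultiTemporalStack, write_raster

__all__ = [
    "rvi", "dvi", "ndvi", "utm_dmi", "mtm_ndqi", "mtm_dsi", "mtm_rsi",
    "IndexLayer", "FeatureSet", "optimal_feature_set", "time_series_feature_set",
    "OPTIMAL_FEATURE_NAMES",
]


def _ma(x):
    return np.ma.masked_invalid(np.ma.asarray(x, dtype=float))


def _safe_divide(num, den):
    """Element-wise num/den with zero denominators masked, not raised."""
    num, den = _ma(num), _ma(den)
    den = np.ma.masked_where(den == 0, den)
    return num / den


def rvi(red, nir, orientation: str = "red_nir"):
    """Ratio vegetation index; default orientation is RED/NIR (see module doc)."""
    if orientation == "red_nir":
        return _safe_divide(red, nir)
    if orientation == "nir_red":
        return _safe_divide(nir, red)
    raise DataError(f"unknown RVI orientation {orientation!r}")


def dvi(red, nir):
    """Difference vegetation index NIR - RED."""
    return _ma(nir) - _ma(red)


def ndvi(red, nir):
    """Normalized difference vegetation index (NIR - RED)/(NIR + RED)."""
    red, nir = _ma(red), _ma(nir)
    return _safe_divide(nir - red, nir + red)


def utm_dmi(re4_feb, swir1_feb):
    """Uni-temporal difference index for pine-oak mixed forest (February).

    Pine-oak canopies keep RE4 at the SWIR-1 level in winter, so the
    difference sits near zero for them and clearly below zero for the
    deciduous classes still to be identified.
    """
    return _ma(re4_feb) - _ma(swir1_feb)


def mtm_ndqi(re4_june, re4_oct):
    """Multi-temporal normalized index for Quercus (RE4, June + October).

    With both operands below their seasonal bounds (0.54 in June, 0.34 in
    October) the operand sum stays below 1 and the index is positive; it is
    strictly decreasing in the sum, so the class with the highest June and
    October RE4 (Quercus) takes the low side.
    """
    a, b = _ma(re4_june), _ma(re4_oct)
    return _safe_divide(1.0 - a - b, a + b)


def mtm_dsi(re2_june, re2_aug):
    """Multi-temporal difference index for scrub grass (RE2, June - August).

    Scrub grass greens up between June and August while woody classes senesce,
    so its value is negative where the others are positive.
    """
    return _ma(re2_june) - _ma(re2_aug)


def mtm_rsi(re2_june, re2_oct):
    """Multi-temporal ratio index for shaw (RE2, (June - October)/October).

    Shaw loses more red-edge reflectance between June and October than Larix,
    so its relative change is larger.
    """
    a, b = _ma(re2_june), _ma(re2_oct)
    return _safe_divide(a - b, b)


@dataclass
class IndexLayer:
    """A named single-band index raster plus its (band, phase) provenance."""

    name: str
    values: np.ma.MaskedArray
    provenance: tuple[tuple[Band, Phase], ...] = ()

    def __post_init__(self) -> None:
        self.values = _ma(self.values)


@dataclass
class FeatureSet:
    """An ordered, co-registered collection of index layers."""

    layers: list[IndexLayer]
    name: str = "features"
    grid: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise DataError(f"duplicate feature names: {names}")
        shapes = {l.values.shape for l in self.layers}
        if len(shapes) > 1:
            raise DataError(f"feature layers are not co-registered: {shapes}")

    @property
    def feature_names(self) -> list[str]:
        return [l.name for l in self.layers]

    def __getitem__(self, name: str) -> IndexLayer:
        for l in self.layers:
            if l.name == name:
                return l
        raise DataError(f"feature set has no layer {name!r}")

    def sample_table(self, samples: SampleSet) -> pd.DataFrame:
        """Per-pixel feature table for labelled plots.

        Columns: plot_id, class, row, col, then one column per feature.
        """
        records = []
        for p in samples.plots:
            for (r, c) in p.pixels:
                rec = {"plot_id": p.plot_id, "class": p.class_label,
                       "row": r, "col": c}
                for l in self.layers:
                    v = l.values[r, c]
                    rec[l.name] = float(v) if v is not np.ma.masked else np.nan
                records.append(rec)
        cols = ["plot_id", "class", "row", "col"] + self.feature_names
        return pd.DataFrame.from_records(records, columns=cols)

    def to_array(self) -> np.ma.MaskedArray:
        """(feature, row, col) cube in layer order."""
        return np.ma.stack([l.values for l in self.layers])

    def write(self, path) -> None:
        """Write as a multi-band TIFF with band descriptions = feature names."""
        arr = np.ma.filled(self.to_array(), np.nan)
        write_raster(path, arr, grid=self.grid, descriptions=self.feature_names)


#: Layer order of the optimal feature set.
OPTIMAL_FEATURE_NAMES: tuple[str, ...] = (
    "NDVI@DEC", "NDVI@APR", "UTM-DMI", "MTM-NDQI", "MTM-DSI", "MTM-RSI",
)


def optimal_feature_set(stack: MultiTemporalStack,
                        rvi_orientation: str = "red_nir") -> FeatureSet:
    """The six-layer optimal feature set.

    December NDVI (evergreen conifer), April NDVI (bare cropland), then the
    four modified indices, in that fixed order.  Raises naming the first
    missing band or phase.
    """
    del rvi_orientation  # reserved; the optimal set contains no RVI layer
    stack.require([
        (Band.RED, Phase.DEC), (Band.NIR, Phase.DEC),
        (Band.RED, Phase.APR), (Band.NIR, Phase.APR),
        (Band.RE4, Phase.FEB), (Band.SWIR1, Phase.FEB),
        (Band.RE4, Phase.JUN), (Band.RE4, Phase.OCT),
        (Band.RE2, Phase.JUN), (Band.RE2, Phase.AUG), (Band.RE2, Phase.OCT),
    ])
    g = stack.band
    layers = [
        IndexLayer("NDVI@DEC", ndvi(g(Phase.DEC, Band.RED), g(Phase.DEC, Band.NIR)),
                   ((Band.RED, Phase.DEC), (Band.NIR, Phase.DEC))),
        IndexLayer("NDVI@APR", ndvi(g(Phase.APR, Band.RED), g(Phase.APR, Band.NIR)),
                   ((Band.RED, Phase.APR), (Band.NIR, Phase.APR))),
        IndexLayer("UTM-DMI", utm_dmi(g(Phase.FEB, Band.RE4), g(Phase.FEB, Band.SWIR1)),
                   ((Band.RE4, Phase.FEB), (Band.SWIR1, Phase.FEB))),
        IndexLayer("MTM-NDQI", mtm_ndqi(g(Phase.JUN, Band.RE4), g(Phase.OCT, Band.RE4)),
                   ((Band.RE4, Phase.JUN), (Band.RE4, Phase.OCT))),
        IndexLayer("MTM-DSI", mtm_dsi(g(Phase.JUN, Band.RE2), g(Phase.AUG, Band.RE2)),
                   ((Band.RE2, Phase.JUN), (Band.RE2, Phase.AUG))),
        IndexLayer("MTM-RSI", mtm_rsi(g(Phase.JUN, Band.RE2), g(Phase.OCT, Band.RE2)),
                   ((Band.RE2, Phase.JUN), (Band.RE2, Phase.OCT))),
    ]
    return FeatureSet(layers=layers, name="optimal", grid=stack.grid)


_TYPICAL = {"NDVI": ndvi, "RVI": rvi, "DVI": dvi}


def time_series_feature_set(stack: MultiTemporalStack, index: str,
                            rvi_orientation: str = "red_nir") -> FeatureSet:
    """One layer of the chosen typical index per phase, named 'INDEX@PHASE'."""
    index = index.upper()
    if index not in _TYPICAL:
        raise DataError(f"unknown typical index {index!r}; choose NDVI, RVI or DVI")
    fn = _TYPICAL[index]
    layers = []
    for ph in stack.phases:
        red, nir = stack.band(ph, Band.RED), stack.band(ph, Band.NIR)
        vals = fn(red, nir, orientation=rvi_orientation) if index == "RVI" else fn(red, nir)
        layers.append(IndexLayer(f"{index}@{ph.name}", vals,
                                 ((Band.RED, ph), (Band.NIR, ph))))
    return FeatureSet(layers=layers, name=f"time_series_{index.lower()}",
                      grid=stack.grid)
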