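"""Multi-date, multi-band reflectance stacks: reading, alignment, resampling.

A :class:`MultiTemporalStack` is the raw input to all index math: a masked
array indexed ``(phase, band, row, col)`` holding unitless surface reflectance
in [0, 1], with one shared pixel grid for every date.  Bands delivered at 20 m
are block-replicated onto the 10 m grid with nearest-neighbour interpolation;
integer digital-number inputs (the 0--10000 convention) are rescaled to [0, 1]
on read via a configurable scale factor.

Files are multi-band TIFFs (one file per acquisition date).  Basic
georeferencing (pixel size and top-left corner) travels in the standard
GeoTIFF ModelPixelScale / ModelTiepoint tags; inputs must already share a CRS,
since reprojection is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import tifffile

from .bands import BAND_ORDER, PHASE_ORDER, Band, Phase, parse_band, parse_phase
from .errors import ConfigError, DataError

_PIXEL_SCALE_TAG = 33550
_TIEPOINT_TAG = 33922


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned pixel grid: top-left corner coordinates and pixel size (m).

    Pixel centres are georeferenced; (row, col) indices are 0-based.
    """

    origin: tuple[float, float] = (0.0, 0.0)
    pixel_size: float = 10.0


@dataclass
class MultiTemporalStack:
    """Reflectance cube indexed (phase, band, row, col), values in [0, 1]."""

    data: np.ma.MaskedArray
    phases: tuple[Phase, ...] = PHASE_ORDER
    bands: tuple[Band, ...] = BAND_ORDER
    grid: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        self.data = np.ma.masked_invalid(np.ma.asarray(self.data, dtype=float))
        if self.data.ndim != 4:
            raise DataError("stack data must be 4-D (phase, band, row, col)")
        p, b, _, _ = self.data.shape
        if p != len(self.phases) or b != len(self.bands):
            raise DataError(
                f"stack shape {self.data.shape} inconsistent with "
                f"{len(self.phases)} phases x {len(self.bands)} bands")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def nrows(self) -> int:
        return self.data.shape[2]

    @property
    def ncols(self) -> int:
        return self.data.shape[3]

    def band(self, phase: "Phase | str", band: "Band | str") -> np.ma.MaskedArray:
        """One (row, col) reflectance plane for a given date and band."""
        ph, bd = parse_phase(phase), parse_band(band)
        try:
            i = self.phases.index(ph)
        except ValueError:
            raise DataError(f"stack has no phase {ph.name}") from None
        try:
            j = self.bands.index(bd)
        except ValueError:
            raise DataError(f"stack has no band {bd.name}") from None
        return self.data[i, j]

    def require(self, pairs: Iterable[tuple[Band, Phase]]) -> None:
        """Raise :class:`DataError` naming the first missing (band, phase)."""
        for bd, ph in pairs:
            if ph not in self.phases:
                raise DataError(f"stack is missing phase {ph.name}")
            if bd not in self.bands:
                raise DataError(f"stack is missing band {bd.name}")


def resample_nearest(raster: np.ndarray, factor: int) -> np.ndarray:
    """Nearest-neighbour upsampling by an integer factor (block replication).

    For integer factors nearest-neighbour interpolation of a coarse grid onto
    a grid ``factor`` times finer degenerates to replicating each input pixel
    into a ``factor x factor`` block, which this implements exactly.
    """
    if int(factor) != factor or factor < 1:
        raise DataError(f"resampling factor must be an integer >= 1, got {factor}")
    factor = int(factor)
    if factor == 1:
        return np.asanyarray(raster)
    out = np.repeat(np.repeat(raster, factor, axis=0), factor, axis=1)
    return out


def read_stack(
    paths_by_phase: Mapping["Phase | str", "str | Path"],
    band_map: Mapping["Band | str", int] | None = None,
    *,
    scale: float = 1.0,
    nodata: float | None = None,
) -> MultiTemporalStack:
    """Read one multi-band TIFF per phase into an aligned stack.

    ``band_map`` maps each of the ten bands to its 0-based page/band index in
    every file (identity order by default).  Pages at half the finest grid's
    resolution are upsampled with :func:`resample_nearest`; grids whose shapes
    are not integer multiples cannot be reconciled and raise.
    """
    if not paths_by_phase:
        raise ConfigError("paths_by_phase is empty")
    phases = tuple(sorted((parse_phase(p) for p in paths_by_phase),
                          key=lambda p: p.month))
    paths = {parse_phase(p): Path(v) for p, v in paths_by_phase.items()}
    if band_map is None:
        band_map = {b: i for i, b in enumerate(BAND_ORDER)}
    else:
        band_map = {parse_band(b): int(i) for b, i in band_map.items()}
    missing = [b.name for b in BAND_ORDER if b not in band_map]
    if missing:
        raise ConfigError(f"band map is missing bands: {', '.join(missing)}")

    arrays: dict[Phase, np.ndarray] = {}
    grids: dict[Phase, GridSpec] = {}
    for ph in phases:
        arr, grid = _read_phase(paths[ph])
        arrays[ph] = arr
        grids[ph] = grid

    nrows = max(a.shape[1] for a in arrays.values())
    ncols = max(a.shape[2] for a in arrays.values())
    fine_grid = min(grids.values(), key=lambda g: g.pixel_size)

    planes = np.empty((len(phases), len(BAND_ORDER), nrows, ncols), dtype=float)
    for i, ph in enumerate(phases):
        arr = arrays[ph]
        for j, bd in enumerate(BAND_ORDER):
            k = band_map[bd]
            if k >= arr.shape[0]:
                raise DataError(
                    f"{paths[ph]}: band {bd.name} mapped to index {k} but file "
                    f"has only {arr.shape[0]} bands")
            plane = arr[k]
            if plane.shape != (nrows, ncols):
                fr, fc = nrows / plane.shape[0], ncols / plane.shape[1]
                if fr != fc or fr != int(fr):
                    raise DataError(
                        f"{paths[ph]}: band {bd.name} grid {plane.shape} is not "
                        f"an integer-factor coarsening of ({nrows}, {ncols})")
                plane = resample_nearest(plane, int(fr))
            planes[i, j] = plane

    data = np.ma.masked_invalid(planes)
    if nodata is not None:
        data = np.ma.masked_values(data, nodata)
    if scale != 1.0:
        data = data / float(scale)
    return MultiTemporalStack(data=data, phases=phases, grid=fine_grid)


def _read_phase(path: Path) -> tuple[np.ndarray, GridSpec]:
    if not path.exists():
        raise DataError(f"raster file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        axes = tif.series[0].axes
        page = tif.pages[0]
        px = 10.0
        origin = (0.0, 0.0)
        if _PIXEL_SCALE_TAG in page.tags:
            px = float(page.tags[_PIXEL_SCALE_TAG].value[0])
        if _TIEPOINT_TAG in page.tags:
            tp = page.tags[_TIEPOINT_TAG].value
            origin = (float(tp[3]), float(tp[4]))
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise DataError(f"{path}: expected a 2-D or 3-D raster, got {arr.ndim}-D")
    # pixel-interleaved files come back (row, col, band); band-sequential stay put
    if axes.endswith("S") and not axes.startswith("S"):
        arr = np.moveaxis(arr, -1, 0)
    return arr.astype(float), GridSpec(origin=origin, pixel_size=px)


def write_raster(
    path: "str | Path",
    array: np.ndarray,
    *,
    grid: GridSpec = GridSpec(),
    descriptions: list[str] | None = None,
) -> Path:
    """Write a (band, row, col) or (row, col) array as a georeferenced TIFF."""
    path = Path(path)
    arr = np.ascontiguousarray(array)
    extratags = [
        (_PIXEL_SCALE_TAG, "d", 3, (grid.pixel_size, grid.pixel_size, 0.0)),
        (_TIEPOINT_TAG, "d", 6, (0.0, 0.0, 0.0, grid.origin[0], grid.origin[1], 0.0)),
    ]
    meta = {"axes": "SYX"} if arr.ndim == 3 else {"axes": "YX"}
    if descriptions:
        meta["band_names"] = list(descriptions)
    tifffile.imwrite(path, arr, extratags=extratags, metadata=meta)
    return path


def write_stack(stack: MultiTemporalStack, out_dir: "str | Path",
                prefix: str = "scene") -> dict[Phase, Path]:
    """Write one multi-band TIFF per phase; masked pixels become NaN."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[Phase, Path] = {}
    for i, ph in enumerate(stack.phases):
        arr = np.ma.filled(stack.data[i], np.nan)
        p = out_dir / f"{prefix}_{ph.name.lower()}.tif"
        write_raster(p, arr, grid=stack.grid,
                     descriptions=[b.name for b in stack.bands])
        paths[ph] = p
    return paths
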