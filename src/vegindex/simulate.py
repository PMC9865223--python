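"""Synthetic multi-temporal scenes with the study system's spectral phenology.

No imagery or field data is deposited for the study system, so every other
module is exercised on generated scenes.  Each of the seven classes gets a
mean spectrum per (phase, band) built as a soil/green-vegetation mixture
driven by a class-specific greenness schedule, plus targeted red-edge/SWIR
adjustments that encode the contrasts the classification method relies on:

* the evergreen conifer (Pinus) keeps high greenness - hence high NDVI - in
  December and February, when everything else is dormant;
* cropland is bare through April (lowest April NDVI) and peaks in August;
* the five remaining classes share one greenness schedule, so their red/NIR
  signal (and hence NDVI/RVI/DVI) is deliberately near-identical - the
  separations live in RE2/RE4/SWIR-1:
  - pine-oak holds February RE4 at the SWIR-1 level (difference ~ 0) while
    the other four sit clearly below it;
  - Quercus has the highest June and October NIR/RE4, with June RE4 < 0.54,
    October RE4 < 0.34 and their sum < 1 for every class;
  - scrub grass raises RE2/RE3/NIR/RE4 from June to August while the woody
    classes decline;
  - shaw exceeds Larix in those bands in June and drops below it by October.

Within-class variation is independent Gaussian noise per (pixel, phase,
band), sd 0.005 reflectance by default (scaled by a multiplier), clipped to
[0, 1].  At that noise the rule-feature class gaps span roughly 7-15 noise
standard deviations and x10^4-scaled screening sums land in the few-hundreds
range typical of screening score tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bands import BAND_ORDER, PHASE_ORDER, Band, Phase
from .classes import CLASS_ORDER
from .errors import DataError
from .samples import SamplePlot, SampleSet
from .stack import GridSpec, MultiTemporalStack

#: Bare-soil and dense-green-canopy endmember spectra (band order BLUE..SWIR2).
SOIL_SPECTRUM = np.array(
    [0.110, 0.140, 0.180, 0.210, 0.220, 0.235, 0.250, 0.270, 0.330, 0.290])
VEGETATION_SPECTRUM = np.array(
    [0.030, 0.065, 0.040, 0.110, 0.270, 0.330, 0.360, 0.380, 0.170, 0.090])

#: Greenness by phase (FEB, APR, JUN, AUG, OCT, DEC).
_GREENNESS: dict[str, tuple[float, ...]] = {
    "crops": (0.03, 0.03, 0.06, 0.85, 0.35, 0.05),
    "pinus": (0.70, 0.72, 0.78, 0.80, 0.75, 0.70),
    # the five spectrally similar classes share one schedule
    "scrub_grass": (0.25, 0.50, 0.80, 0.80, 0.45, 0.25),
    "quercus": (0.25, 0.50, 0.80, 0.80, 0.45, 0.25),
    "pine_oak": (0.25, 0.50, 0.80, 0.80, 0.45, 0.25),
    "larix": (0.25, 0.50, 0.80, 0.80, 0.45, 0.25),
    "shaw": (0.25, 0.50, 0.80, 0.80, 0.45, 0.25),
}

#: Targeted mean adjustments: (class, phase, band) -> reflectance.
_OVERRIDES: dict[tuple[str, Phase, Band], float] = {
    # February: pine-oak RE4 == SWIR-1 level; other deciduous classes well below
    ("pine_oak", Phase.FEB, Band.RE4): 0.290,
    ("quercus", Phase.FEB, Band.RE4): 0.230,
    ("scrub_grass", Phase.FEB, Band.RE4): 0.230,
    ("larix", Phase.FEB, Band.RE4): 0.230,
    ("shaw", Phase.FEB, Band.RE4): 0.230,
    # June: Quercus red-edge/NIR peak; scrub still greening; shaw above Larix
    ("quercus", Phase.JUN, Band.RE4): 0.460,
    ("quercus", Phase.JUN, Band.NIR): 0.400,
    ("scrub_grass", Phase.JUN, Band.RE2): 0.240,
    ("scrub_grass", Phase.JUN, Band.RE3): 0.290,
    ("scrub_grass", Phase.JUN, Band.NIR): 0.320,
    ("scrub_grass", Phase.JUN, Band.RE4): 0.340,
    ("larix", Phase.JUN, Band.RE2): 0.262,
    ("larix", Phase.JUN, Band.RE3): 0.315,
    ("larix", Phase.JUN, Band.NIR): 0.332,
    ("larix", Phase.JUN, Band.RE4): 0.350,
    ("shaw", Phase.JUN, Band.RE2): 0.275,
    ("shaw", Phase.JUN, Band.RE3): 0.325,
    ("shaw", Phase.JUN, Band.NIR): 0.345,
    ("shaw", Phase.JUN, Band.RE4): 0.365,
    # August: scrub rises June->August, woody classes decline
    ("scrub_grass", Phase.AUG, Band.RE2): 0.285,
    ("scrub_grass", Phase.AUG, Band.RE3): 0.320,
    ("scrub_grass", Phase.AUG, Band.NIR): 0.350,
    ("scrub_grass", Phase.AUG, Band.RE4): 0.370,
    ("larix", Phase.AUG, Band.RE2): 0.252,
    ("larix", Phase.AUG, Band.RE3): 0.308,
    ("larix", Phase.AUG, Band.NIR): 0.328,
    ("larix", Phase.AUG, Band.RE4): 0.345,
    ("shaw", Phase.AUG, Band.RE2): 0.262,
    ("shaw", Phase.AUG, Band.RE3): 0.318,
    ("shaw", Phase.AUG, Band.NIR): 0.338,
    ("shaw", Phase.AUG, Band.RE4): 0.358,
    # October: Quercus still highest NIR/RE4; shaw now below Larix; October
    # RE4 stays below 0.34 for every class
    ("quercus", Phase.OCT, Band.RE4): 0.335,
    ("quercus", Phase.OCT, Band.NIR): 0.330,
    ("larix", Phase.OCT, Band.RE2): 0.250,
    ("larix", Phase.OCT, Band.RE3): 0.280,
    ("larix", Phase.OCT, Band.NIR): 0.300,
    ("larix", Phase.OCT, Band.RE4): 0.315,
    ("shaw", Phase.OCT, Band.RE2): 0.205,
    ("shaw", Phase.OCT, Band.RE3): 0.255,
    ("shaw", Phase.OCT, Band.NIR): 0.270,
    ("shaw", Phase.OCT, Band.RE4): 0.285,
    ("pinus", Phase.OCT, Band.RE4): 0.335,
}

#: Default within-class noise sd (reflectance units) per (pixel, phase, band).
DEFAULT_NOISE_SD = 0.005


@dataclass(frozen=True)
class ClassSpectralProfile:
    """Mean reflectance and noise sd per (phase, band) for one class."""

    class_label: str
    means: np.ndarray      # (n_phases, n_bands) in [0, 1]
    noise_sd: np.ndarray   # (n_phases, n_bands) >= 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "noise_sd",
                           np.asarray(self.noise_sd, dtype=float))
        if self.means.shape != (len(PHASE_ORDER), len(BAND_ORDER)):
            raise DataError(f"profile means must be shaped "
                            f"({len(PHASE_ORDER)}, {len(BAND_ORDER)})")
        if ((self.means < 0) | (self.means > 1)).any():
            raise DataError(f"profile means for {self.class_label!r} "
                            "outside [0, 1]")
        if (self.noise_sd < 0).any():
            raise DataError("noise sd must be nonnegative")

    def mean(self, phase: Phase, band: Band) -> float:
        return float(self.means[PHASE_ORDER.index(phase),
                                BAND_ORDER.index(band)])


def default_profiles(noise_sd: float = DEFAULT_NOISE_SD
                     ) -> list[ClassSpectralProfile]:
    """The seven default class profiles (see module docstring for design)."""
    profiles = []
    for label in CLASS_ORDER:
        g = np.array(_GREENNESS[label])[:, None]
        means = SOIL_SPECTRUM[None, :] * (1 - g) + VEGETATION_SPECTRUM[None, :] * g
        for (cls, ph, bd), v in _OVERRIDES.items():
            if cls == label:
                means[PHASE_ORDER.index(ph), BAND_ORDER.index(bd)] = v
        sd = np.full_like(means, float(noise_sd))
        profiles.append(ClassSpectralProfile(label, means, sd))
    return profiles


#: Per-class plot counts mirroring the study's verification column totals
#: (x9 pixels each) and its 270-plot survey size.
PRESET_PLOTS: dict[str, tuple[int, ...]] = {
    "table_mirror": (7, 8, 13, 14, 13, 8, 7),     # 70 plots, 630 pixels
    "survey": (38, 39, 39, 39, 39, 38, 38),       # 270 plots, 2430 pixels
}


@dataclass(frozen=True)
class SceneConfig:
    """Scene geometry, sampling design, seed and noise scaling."""

    shape: tuple[int, int] = (120, 120)
    plots_per_class: "int | Sequence[int] | str" = 10
    plot_size: int = 3
    seed: int = 0
    noise_multiplier: float = 1.0
    margin: int = 1          # guard pixels between a plot and its cell edge
    pixel_size: float = 10.0

    def plot_counts(self, n_classes: int) -> tuple[int, ...]:
        p = self.plots_per_class
        if isinstance(p, str):
            if p not in PRESET_PLOTS:
                raise DataError(f"unknown plot preset {p!r}; "
                                f"choose from {sorted(PRESET_PLOTS)}")
            counts = PRESET_PLOTS[p]
        elif isinstance(p, int):
            counts = (p,) * n_classes
        else:
            counts = tuple(int(x) for x in p)
        if len(counts) != n_classes:
            raise DataError(f"need {n_classes} per-class plot counts, "
                            f"got {len(counts)}")
        return counts


def simulate_scene(profiles: Sequence[ClassSpectralProfile],
                   config: SceneConfig = SceneConfig()
                   ) -> tuple[MultiTemporalStack, np.ndarray, SampleSet]:
    """Generate (reflectance stack, label raster, sample plots).

    Plots are placed on a jittered regular grid of non-overlapping cells with
    a guard margin; unlabelled background pixels carry the bare-soil spectrum
    and label 0.  Labels are 1-based indices into the profile order.
    Deterministic under the config seed.
    """
    rng = np.random.default_rng(config.seed)
    nrows, ncols = config.shape
    counts = config.plot_counts(len(profiles))
    cell = config.plot_size + 2 * config.margin
    cells_r, cells_c = nrows // cell, ncols // cell
    n_plots = sum(counts)
    if n_plots > cells_r * cells_c:
        raise DataError(
            f"{n_plots} plots of {config.plot_size}x{config.plot_size} (+margin "
            f"{config.margin}) do not fit a {nrows}x{ncols} scene")

    cells = [(r, c) for r in range(cells_r) for c in range(cells_c)]
    chosen = rng.permutation(len(cells))[:n_plots]
    jit = config.margin
    plots: list[SamplePlot] = []
    labels = np.zeros((nrows, ncols), dtype=np.int16)
    class_map = np.zeros((nrows, ncols), dtype=np.int16)  # 0 = background
    k = 0
    for ci, prof in enumerate(profiles, start=1):
        for _ in range(counts[ci - 1]):
            cr, cc = cells[chosen[k]]
            k += 1
            top = cr * cell + int(rng.integers(0, 2 * jit + 1))
            left = cc * cell + int(rng.integers(0, 2 * jit + 1))
            top = min(top, nrows - config.plot_size)
            left = min(left, ncols - config.plot_size)
            px = tuple((top + r, left + c)
                       for r in range(config.plot_size)
                       for c in range(config.plot_size))
            pid = f"{prof.class_label}_{k:04d}"
            plots.append(SamplePlot(pid, prof.class_label, px))
            rows = [p[0] for p in px]
            cols = [p[1] for p in px]
            labels[rows, cols] = ci
            class_map[rows, cols] = ci

    means = np.stack([SOIL_SPECTRUM[None, :].repeat(len(PHASE_ORDER), 0)]
                     + [p.means for p in profiles])        # (1+k, P, B)
    sds = np.stack([np.zeros((len(PHASE_ORDER), len(BAND_ORDER)))]
                   + [p.noise_sd for p in profiles])
    cube = means[class_map]                                 # (R, C, P, B)
    sd_cube = sds[class_map] * config.noise_multiplier
    if config.noise_multiplier > 0:
        cube = cube + rng.standard_normal(cube.shape) * sd_cube
    cube = np.clip(cube, 0.0, 1.0)
    data = np.moveaxis(cube, (2, 3), (0, 1))                # (P, B, R, C)
    stack = MultiTemporalStack(
        data=np.ma.asarray(data),
        phases=PHASE_ORDER,
        grid=GridSpec(pixel_size=config.pixel_size),
    )
    return stack, labels, SampleSet(plots=plots)


def simulate_sample_table(profiles: Sequence[ClassSpectralProfile],
                          n_per_class: int, seed: int = 0,
                          noise_multiplier: float = 1.0) -> pd.DataFrame:
    """Plot-free per-pixel spectra table (class, pixel, phase, band, reflectance).

    Lightweight stand-in for extract_samples output in statistics and
    screening tests; deterministic under the seed.
    """
    if n_per_class < 2:
        raise DataError("n_per_class must be >= 2")
    rng = np.random.default_rng(seed)
    frames = []
    for prof in profiles:
        draws = (prof.means[None, :, :]
                 + rng.standard_normal((n_per_class,) + prof.means.shape)
                 * prof.noise_sd[None, :, :] * noise_multiplier)
        draws = np.clip(draws, 0.0, 1.0)
        for i, ph in enumerate(PHASE_ORDER):
            for j, bd in enumerate(BAND_ORDER):
                frames.append(pd.DataFrame({
                    "plot_id": [f"{prof.class_label}_px{n}"
                                for n in range(n_per_class)],
                    "class": prof.class_label,
                    "pixel": np.arange(n_per_class),
                    "phase": ph.name,
                    "band": bd.name,
                    "reflectance": draws[:, i, j],
                }))
    return pd.concat(frames, ignore_index=True)


def profiles_to_dict(profiles: Sequence[ClassSpectralProfile]) -> dict:
    """JSON/YAML-serialisable profile description."""
    out = {}
    for p in profiles:
        out[p.class_label] = {
            "means": {ph.name: {bd.name: float(p.means[i, j])
                                for j, bd in enumerate(BAND_ORDER)}
                      for i, ph in enumerate(PHASE_ORDER)},
            "noise_sd": {ph.name: {bd.name: float(p.noise_sd[i, j])
                                   for j, bd in enumerate(BAND_ORDER)}
                         for i, ph in enumerate(PHASE_ORDER)},
        }
    return out


def profiles_from_dict(d: Mapping) -> list[ClassSpectralProfile]:
    profiles = []
    for label, spec in d.items():
        means = np.array([[spec["means"][ph.name][bd.name]
                           for bd in BAND_ORDER] for ph in PHASE_ORDER])
        sd = np.array([[spec["noise_sd"][ph.name][bd.name]
                        for bd in BAND_ORDER] for ph in PHASE_ORDER])
        profiles.append(ClassSpectralProfile(label, means, sd))
    return profiles
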