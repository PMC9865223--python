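"""Band and acquisition-phase vocabulary.

The toolkit works with the ten Sentinel-2 surface-reflectance bands that carry
vegetation signal at 10--20 m (the three 60 m atmospheric bands are excluded),
and with an ordered set of acquisition dates ("phases") spanning one phenological
year.  Reflectance is always handled internally on the unitless [0, 1] scale.
"""

from __future__ import annotations

import enum


class Band(enum.Enum):
    """Sentinel-2-style spectral bands used for vegetation mapping.

    The value is the conventional Sentinel-2 band code; ``native_resolution``
    is the ground sampling distance (m) the band is delivered at, which decides
    whether a band needs nearest-neighbour upsampling to the 10 m grid.
    """

    BLUE = "B2"
    GREEN = "B3"
    RED = "B4"
    RE1 = "B5"
    RE2 = "B6"
    RE3 = "B7"
    NIR = "B8"
    RE4 = "B8A"
    SWIR1 = "B11"
    SWIR2 = "B12"

    @property
    def native_resolution(self) -> int:
        return 10 if self in _TEN_METRE else 20

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


_TEN_METRE = frozenset({Band.BLUE, Band.GREEN, Band.RED, Band.NIR})

#: Canonical band order used for the band axis of a reflectance stack.
BAND_ORDER: tuple[Band, ...] = tuple(Band)


class Phase(enum.Enum):
    """Acquisition date within the phenological year (month label)."""

    FEB = 2
    APR = 4
    JUN = 6
    AUG = 8
    OCT = 10
    DEC = 12

    @property
    def month(self) -> int:
        return self.value

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


#: Canonical phase order used for the phase axis of a reflectance stack.
PHASE_ORDER: tuple[Phase, ...] = tuple(Phase)


def parse_band(name: "str | Band") -> Band:
    """Accept a :class:`Band`, a member name ('RE4') or a band code ('B8A')."""
    if isinstance(name, Band):
        return name
    key = str(name).strip().upper()
    if key in Band.__members__:
        return Band[key]
    for b in Band:
        if b.value.upper() == key:
            return b
    raise KeyError(f"unknown band {name!r}; expected one of "
                   f"{[b.name for b in Band]}")


def parse_phase(name: "str | Phase") -> Phase:
    if isinstance(name, Phase):
        return name
    key = str(name).strip().upper()[:3]
    if key in Phase.__members__:
        return Phase[key]
    raise KeyError(f"unknown phase {name!r}; expected one of "
                   f"{[p.name for p in Phase]}")
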