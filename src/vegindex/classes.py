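"""The seven target vegetation classes of the Lingkong Mountain study system.

Class keys are short machine-friendly identifiers; ``DISPLAY_NAMES`` carries
the full names.  ``CLASS_ORDER`` is the canonical report order (the order the
published confusion-matrix legend uses); ``HIERARCHY_ORDER`` is the order in
which the knowledge decision tree peels classes off, from the spectrally most
distinctive to the least.
"""

from __future__ import annotations

#: Report order: crops, scrub grass, Pinus, Quercus, pine-oak, Larix, shaw.
CLASS_ORDER: tuple[str, ...] = (
    "crops",
    "scrub_grass",
    "pinus",
    "quercus",
    "pine_oak",
    "larix",
    "shaw",
)

DISPLAY_NAMES: dict[str, str] = {
    "crops": "Crops",
    "scrub_grass": "Scrub grass",
    "pinus": "Pinus tabuliformis",
    "quercus": "Quercus wutaishanica",
    "pine_oak": "Pine-oak mixed forest",
    "larix": "Larix principis-rupprechtii",
    "shaw": "Shaw",
}

#: Identification order of the hierarchical classifier; the last class is the
#: fallback left after every rule has fired.
HIERARCHY_ORDER: tuple[str, ...] = (
    "pinus",
    "crops",
    "pine_oak",
    "quercus",
    "scrub_grass",
    "shaw",
    "larix",
)
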