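"""The 12-class land-cover vocabulary shared by every module.

Four vegetation classes, five watercourse classes binned from Strahler stream
order, and three road quality classes. Class ids double as the keys of the
travel-speed lookup table.
"""

from __future__ import annotations

VEGETATION_CLASSES = {1: "Forest", 2: "Grass", 3: "Bare", 4: "Scrub"}

#: Strahler order k in 1..4 maps to 100 + k; orders >= 5 are capped into 105,
#: the class treated as never passable.
STREAM_CLASSES = {
    101: "Stream class 1",
    102: "Stream class 2",
    103: "Stream class 3",
    104: "Stream class 4",
    105: "Stream class 5",
}

ROAD_CLASSES = {201: "National road", 202: "Provincial road", 203: "Local road"}

#: GeoJSON road features carry a textual class attribute from this set.
ROAD_CLASS_IDS = {"national": 201, "provincial": 202, "local": 203}
ROAD_CLASS_NAMES = {v: k for k, v in ROAD_CLASS_IDS.items()}

ALL_CLASSES = {**VEGETATION_CLASSES, **STREAM_CLASSES, **ROAD_CLASSES}

#: Traversal-time sentinel (seconds): cells at or above this are impassable.
IMPASSABLE_SECONDS = 99_999.0
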