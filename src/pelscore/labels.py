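"""Categorical raster encodings shared across the pipeline.

Two rasters describe a slide besides the instance map: a nuclear *class*
map (what kind of cell a nucleus belongs to) and a tissue *layer* mask
(which intra-epithelial compartment a pixel lies in).  Both are stored as
small unsigned integers; the enums below are the single source of truth
for the encoding.
"""

from __future__ import annotations

from enum import IntEnum


class NucleusClass(IntEnum):
    """Nuclear classification labels (HoVer-Net-style output contract)."""

    BACKGROUND = 0
    EPITHELIAL = 1
    INFLAMMATORY = 2
    CONNECTIVE = 3
    OTHER = 4


class TissueLayer(IntEnum):
    """Intra-epithelial layer mask labels (surface to depth)."""

    BACKGROUND = 0
    KERATIN = 1
    EPITHELIAL = 2
    BASAL = 3
    CONNECTIVE_TISSUE = 4


#: Layers that together constitute "epithelium" for patch retention.
EPITHELIUM_LAYERS = (TissueLayer.KERATIN, TissueLayer.EPITHELIAL, TissueLayer.BASAL)

#: Compartment names in reporting order.
COMPARTMENTS = ("keratin", "epithelial", "basal", "connective_tissue")

LAYER_NAMES = {
    TissueLayer.BACKGROUND: "background",
    TissueLayer.KERATIN: "keratin",
    TissueLayer.EPITHELIAL: "epithelial",
    TissueLayer.BASAL: "basal",
    TissueLayer.CONNECTIVE_TISSUE: "connective_tissue",
}

CLASS_NAMES = {
    NucleusClass.BACKGROUND: "background",
    NucleusClass.EPITHELIAL: "epithelial",
    NucleusClass.INFLAMMATORY: "inflammatory",
    NucleusClass.CONNECTIVE: "connective",
    NucleusClass.OTHER: "other",
}

LAYER_BY_NAME = {v: k for k, v in LAYER_NAMES.items()}
CLASS_BY_NAME = {v: k for k, v in CLASS_NAMES.items()}
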