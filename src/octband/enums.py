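"""Controlled vocabularies shared across the pipeline.

Groups, intraretinal layers (inner to outer) and macular regions follow the
Stratus OCT macular protocol: three diagnostic groups, seven layers segmented
between the ILM and the OS/RPE junction, and four concentric macular regions.
"""

from __future__ import annotations

import enum


class GroupLabel(str, enum.Enum):
    """Diagnostic group of an eye."""

    HEALTHY = "HEALTHY"
    DM = "DM"  # type 1 diabetes mellitus, no retinopathy
    MDR = "MDR"  # mild diabetic retinopathy

    def __str__(self) -> str:  # serialize as bare upper-case string
        return self.value


class LayerName(str, enum.Enum):
    """Intraretinal layer, ordered inner (vitreous side) to outer."""

    RNFL = "RNFL"
    GCL_IPL = "GCL_IPL"
    INL = "INL"
    OPL = "OPL"
    ONL_IS = "ONL_IS"
    OS = "OS"
    RPE = "RPE"

    def __str__(self) -> str:
        return self.value


#: Layers in anatomical order, inner to outer.
LAYER_ORDER: tuple[LayerName, ...] = tuple(LayerName)

#: Layers whose thickness is depressed by the foveal pit.
INNER_LAYERS: tuple[LayerName, ...] = (
    LayerName.RNFL,
    LayerName.GCL_IPL,
    LayerName.INL,
    LayerName.OPL,
)


class RegionName(str, enum.Enum):
    """Concentric macular region (disc plus three annuli)."""

    FOVEOLA = "FOVEOLA"
    FOVEA = "FOVEA"
    PARAFOVEA = "PARAFOVEA"
    PERIFOVEA = "PERIFOVEA"

    def __str__(self) -> str:
        return self.value


#: Outer radius (mm) of each region; diameters 0.35 / 1.85 / 2.85 / 5.85 mm.
REGION_OUTER_RADIUS_MM: dict[RegionName, float] = {
    RegionName.FOVEOLA: 0.175,
    RegionName.FOVEA: 0.925,
    RegionName.PARAFOVEA: 1.425,
    RegionName.PERIFOVEA: 2.925,
}

#: Feature column names of the tabular interchange schema.
FEATURE_COLUMNS: tuple[str, ...] = (
    "eye_id",
    "subject_id",
    "group",
    "scan_index",
    "layer",
    "region",
    "TH_um",
    "TR",
    "FD",
)
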