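"""Tissue compartment labels and their display colours.

The compartments mirror the quality-control overlays of the section
segmentation: dorsal/ventral surface ectoderm, the rudiment core, periphery
and neck, the condensing mammary mesenchyme directly around the rudiment,
and a fixed window of dermal mesenchyme below it.
"""

from enum import IntEnum


class Compartment(IntEnum):
    BACKGROUND = 0
    DORSAL_ECTODERM = 1
    VENTRAL_ECTODERM = 2
    MR_CORE = 3
    MR_PERIPHERY = 4
    MR_NECK = 5
    MAMMARY_MESENCHYME = 6
    DERMAL_MESENCHYME = 7


#: Epithelial compartments that together make up the mammary rudiment.
MR_COMPARTMENTS = (Compartment.MR_CORE, Compartment.MR_PERIPHERY, Compartment.MR_NECK)

#: Surface ectoderm arms flanking the rudiment.
ECTODERM_COMPARTMENTS = (Compartment.DORSAL_ECTODERM, Compartment.VENTRAL_ECTODERM)

#: QC overlay colour key (RGB): green / yellow / orange / red / purple /
#: turquoise / blue for d.ect, v.ect, core, periphery, neck, mammary and
#: dermal mesenchyme respectively.
OVERLAY_COLORS = {
    Compartment.DORSAL_ECTODERM: (0, 170, 0),
    Compartment.VENTRAL_ECTODERM: (230, 220, 0),
    Compartment.MR_CORE: (255, 140, 0),
    Compartment.MR_PERIPHERY: (220, 30, 30),
    Compartment.MR_NECK: (150, 40, 180),
    Compartment.MAMMARY_MESENCHYME: (0, 200, 200),
    Compartment.DERMAL_MESENCHYME: (40, 70, 220),
}
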