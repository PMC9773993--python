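"""Integer tissue labels shared by the whole pipeline.

The anatomy model distinguishes 13 biological tissues (the conductivity
table rows), three electrode materials and background.  Label values are
stable across runs so that exported NIfTI volumes are comparable.
"""

from __future__ import annotations

BACKGROUND = 0
SKIN = 1
FAT = 2
MUSCLE = 3
LUNGS = 4
HEART = 5
VISCERA = 6
BONE = 7  # vertebrae + sacrum share the bone conductivity
DISK = 8
DURA = 9
CSF = 10
ROOTS = 11  # spinal roots, cauda equina and dorsal root ganglia
SPINAL_WM = 12
SPINAL_GM = 13
GEL = 14
RUBBER = 15
CONNECTOR_ANODE = 16
CONNECTOR_CATHODE = 17

LABEL_NAMES: dict[int, str] = {
    BACKGROUND: "background",
    SKIN: "skin",
    FAT: "fat",
    MUSCLE: "muscle",
    LUNGS: "lungs",
    HEART: "heart",
    VISCERA: "viscera",
    BONE: "vertebrae_bone",
    DISK: "intervertebral_disk",
    DURA: "dura_mater",
    CSF: "csf",
    ROOTS: "spinal_roots",
    SPINAL_WM: "spinal_wm",
    SPINAL_GM: "spinal_gm",
    GEL: "gel",
    RUBBER: "rubber",
    CONNECTOR_ANODE: "connector_anode",
    CONNECTOR_CATHODE: "connector_cathode",
}

NAME_TO_LABEL: dict[str, int] = {v: k for k, v in LABEL_NAMES.items()}

#: The 13 biological tissues of the conductivity table.
TISSUE_LABELS = (
    SKIN, FAT, MUSCLE, LUNGS, HEART, VISCERA, BONE, DISK, DURA, CSF,
    ROOTS, SPINAL_WM, SPINAL_GM,
)

ELECTRODE_LABELS = (GEL, RUBBER, CONNECTOR_ANODE, CONNECTOR_CATHODE)
CONNECTOR_LABELS = (CONNECTOR_ANODE, CONNECTOR_CATHODE)
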