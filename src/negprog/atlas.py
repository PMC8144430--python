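"""Desikan-Killiany surface atlas: 34 cortical regions per hemisphere.

The gyrification feature space is one scalar per region and hemisphere
(68 columns). Column names follow the FreeSurfer convention
``{lh,rh}_<region>``.
"""

from __future__ import annotations

DK_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

#: The 68 ROI column names, left hemisphere first.
ROI_COLUMNS: tuple[str, ...] = tuple(
    f"{hemi}_{region}" for hemi in ("lh", "rh") for region in DK_REGIONS
)

assert len(ROI_COLUMNS) == 68
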