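"""Fixed catalog of regional brain measures.

The analysis grid crosses genetic variants with 93 combined-hemisphere
measures: surface area and mean thickness of 34 cortical parcels
(Desikan-Killiany atlas) and the volume of 25 non-cortical structures
(subcortical, ventricular, callosal and other automatically segmented
regions).  Midline structures are carried as left/right halves in the
synthetic tables so that every region follows the same column convention.
"""

from __future__ import annotations

from typing import List, Tuple

CORTICAL_REGIONS: Tuple[str, ...] = (
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

NONCORTICAL_REGIONS: Tuple[str, ...] = (
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
    "accumbens",
    "ventral_dc",
    "cerebellum_cortex",
    "cerebellum_white_matter",
    "cerebral_white_matter",
    "lateral_ventricle",
    "inferior_lateral_ventricle",
    "third_ventricle",
    "fourth_ventricle",
    "choroid_plexus",
    "csf",
    "vessel",
    "optic_chiasm",
    "brain_stem",
    "cc_anterior",
    "cc_mid_anterior",
    "cc_central",
    "cc_mid_posterior",
    "cc_posterior",
)

MEASURE_TYPES: Tuple[str, ...] = ("area", "thickness", "volume")

#: Global covariate (column name) matched to each measure type.
GLOBAL_COVARIATE = {
    "area": "total_surface_area",
    "thickness": "global_mean_thickness",
    "volume": "icv",
}

assert len(CORTICAL_REGIONS) == 34
assert len(NONCORTICAL_REGIONS) == 25


def measure_name(region: str, measure_type: str) -> str:
    """Combined-hemisphere column name, e.g. ``hippocampus__volume``."""
    return f"{region}__{measure_type}"


def hemisphere_column(region: str, measure_type: str, hemisphere: str) -> str:
    """Per-hemisphere column name, e.g. ``hippocampus__volume__L``."""
    if hemisphere not in ("L", "R"):
        raise ValueError(f"hemisphere must be 'L' or 'R', got {hemisphere!r}")
    return f"{region}__{measure_type}__{hemisphere}"


def measure_catalog() -> List[Tuple[str, str]]:
    """All 93 (region, measure_type) pairs in deterministic order.

    Cortical area, cortical thickness, then non-cortical volume; regions in
    catalog order within each block.
    """
    pairs: List[Tuple[str, str]] = []
    pairs.extend((r, "area") for r in CORTICAL_REGIONS)
    pairs.extend((r, "thickness") for r in CORTICAL_REGIONS)
    pairs.extend((r, "volume") for r in NONCORTICAL_REGIONS)
    return pairs


def parse_measure_name(name: str) -> Tuple[str, str]:
    """Split ``region__measure_type`` back into its parts."""
    region, sep, mtype = name.rpartition("__")
    if not sep or mtype not in MEASURE_TYPES:
        raise ValueError(f"not a measure column name: {name!r}")
    return region, mtype
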