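"""Canonical parcellation and cell-type identifiers.

All analyses operate on the 34 bilateral Desikan-Killiany cortical regions
(hemisphere-averaged inputs; the table schema has no hemisphere column) and
on 8 canonical cortical cell classes.
"""

from __future__ import annotations

DK34_REGIONS: tuple[str, ...] = (
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

N_REGIONS = len(DK34_REGIONS)

CELL_TYPES: tuple[str, ...] = (
    "astro",
    "endo",
    "micro",
    "neuro-ex",
    "neuro-in",
    "oligo",
    "opc",
    "per",
)

SEXES: tuple[str, ...] = ("M", "F")

#: preterm birth is defined as birth before 37 completed weeks of gestation
PRETERM_GA_CUTOFF_WEEKS = 37.0


def hemisphere_pairs(regions_68: list[str]) -> dict[str, tuple[str | None, str | None]]:
    """Resolve left/right hemisphere column names into bilateral pairs.

    Accepts names like ``lh_bankssts`` / ``rh_bankssts`` (or ``L_...``/``R_...``).
    Returns ``{bilateral_name: (left_name_or_None, right_name_or_None)}``.
    """
    pairs: dict[str, list[str | None]] = {}
    for name in regions_68:
        base, side = _split_hemi(name)
        slot = pairs.setdefault(base, [None, None])
        slot[0 if side == "L" else 1] = name
    return {k: (v[0], v[1]) for k, v in pairs.items()}


def _split_hemi(name: str) -> tuple[str, str]:
    lowered = name.lower()
    for prefix, side in (("lh_", "L"), ("rh_", "R"), ("l_", "L"), ("r_", "R")):
        if lowered.startswith(prefix):
            return name[len(prefix):], side
    for suffix, side in (("_lh", "L"), ("_rh", "R"), ("_l", "L"), ("_r", "R")):
        if lowered.endswith(suffix):
            return name[: -len(suffix)], side
    raise ValueError(f"cannot resolve hemisphere of region name {name!r}")
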