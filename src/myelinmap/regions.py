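"""Controlled vocabulary of brain regions and published reference anchors.

The regions are the white- and deep-grey-matter landmarks conventionally
used to stage myelination: posterior/anterior limb of the internal capsule
(PLIC/ALIC), central and frontal white matter of the centrum semiovale,
genu and splenium of the corpus callosum, posterior pons, and the deep
grey nuclei (putamen, caudate, thalamus).  Bilateral structures carry a
side; the corpus callosum and pons are midline.

``REFERENCE_ANCHORS`` holds the published normative R1 values (1/s) at
birth and 12 months together with the regional myelination time constant
tau (months) and its uncertainty — enough to reconstruct the full growth
curve of each region via :func:`myelinmap.growth.params_from_anchors`.
"""

from __future__ import annotations

from dataclasses import dataclass

MIDLINE = "midline"

#: (region, side) pairs of the controlled vocabulary.
REGIONS: tuple[tuple[str, str], ...] = tuple(
    (region, side)
    for region in (
        "plic",
        "alic",
        "central_wm",
        "frontal_wm",
        "putamen",
        "caudate",
        "thalamus",
    )
    for side in ("right", "left")
) + (("genu", MIDLINE), ("splenium", MIDLINE), ("pons", MIDLINE))

REGION_NAMES = {
    "plic": "Posterior limb of the internal capsule",
    "alic": "Anterior limb of the internal capsule",
    "central_wm": "Central white matter",
    "frontal_wm": "Frontal white matter",
    "genu": "Genu of the corpus callosum",
    "splenium": "Splenium of the corpus callosum",
    "pons": "Posterior pons",
    "putamen": "Putamen",
    "caudate": "Caudate nucleus",
    "thalamus": "Thalamus",
}


def region_key(region: str, side: str = MIDLINE) -> str:
    """Canonical key, e.g. ``plic_right`` or ``genu``."""
    if (region, side) not in REGIONS:
        raise KeyError(f"unknown region/side {(region, side)!r}")
    return region if side == MIDLINE else f"{region}_{side}"


def split_key(key: str) -> tuple[str, str]:
    for region, side in REGIONS:
        if region_key(region, side) == key:
            return region, side
    raise KeyError(f"unknown region key {key!r}")


@dataclass(frozen=True)
class ReferenceAnchor:
    """Published normative curve for one region: R1 at birth and at
    12 months (1/s) plus the myelination time constant tau +- uncertainty
    (months)."""

    r1_birth: float
    r1_12mo: float
    tau: float
    tau_uncertainty: float


#: Normative anchors for the right side of bilateral structures and for the
#: midline structures (3-T MP2RAGE cohort, ages 3-72 months).
REFERENCE_ANCHORS: dict[str, ReferenceAnchor] = {
    "plic_right": ReferenceAnchor(0.76, 0.97, 16.5, 3.1),
    "alic_right": ReferenceAnchor(0.57, 0.85, 15.8, 1.9),
    "central_wm_right": ReferenceAnchor(0.64, 0.87, 18.7, 2.2),
    "frontal_wm_right": ReferenceAnchor(0.43, 0.77, 16.5, 1.2),
    "genu": ReferenceAnchor(0.37, 0.84, 13.6, 1.0),
    "splenium": ReferenceAnchor(0.44, 0.91, 12.9, 1.1),
    "pons": ReferenceAnchor(0.66, 0.81, 15.9, 3.8),
    "putamen_right": ReferenceAnchor(0.56, 0.65, 21.5, 4.0),
    "caudate_right": ReferenceAnchor(0.57, 0.63, 21.5, 6.5),
    "thalamus_right": ReferenceAnchor(0.63, 0.73, 20.1, 5.3),
}
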