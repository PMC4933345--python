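"""Stereological whole-heart retention estimate and transmural gradient.

Fluorescently labelled donor cells are counted on thin transverse
cryosections (7.5 um), giving an areal density (cells/mm^2).  Dividing by
the section thickness (mm) converts this to a volumetric density
(cells/mm^3), and multiplying by the myocardial volume — heart mass in mg
under the 1 mg == 1 mm^3 tissue-density assumption — extrapolates to the
whole-heart retained cell count:

    retained = mean areal density / thickness_mm x heart_mass_mg

The transmural analysis averages labelled-cell densities per wall layer
(epicardial / mid-myocardial / endocardial), first across section levels
within each heart and then across hearts, and reports the
endocardium:epicardium density ratio.
"""
from __future__ import annotations

import dataclasses
import logging
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SectionCount",
    "HeartStereology",
    "TransmuralGradient",
    "whole_heart_estimate",
    "transmural_gradient",
    "LAYERS",
    "LEVELS",
]

LEVELS = ("base", "mid", "apex")
LAYERS = ("epicardial", "mid-myocardial", "endocardial")
DEFAULT_SECTION_THICKNESS_MM = 0.0075  # 7.5 um cryosections


@dataclasses.dataclass(frozen=True)
class SectionCount:
    """Labelled-cell count on one section region.

    ``layer`` is one of ``epicardial``, ``mid-myocardial``, ``endocardial``
    or ``whole`` (the full cross-section, used by the whole-heart
    estimator).
    """

    heart_id: str
    level: str
    layer: str
    labeled_cells: float
    examined_area: float  # mm^2

    def __post_init__(self) -> None:
        if self.labeled_cells < 0:
            raise ValueError("labeled_cells must be non-negative")
        if self.examined_area <= 0:
            raise ValueError("examined_area must be positive")
        if self.layer not in LAYERS + ("whole",):
            raise ValueError(f"unknown wall layer {self.layer!r}")

    @property
    def density(self) -> float:
        """Areal density, cells/mm^2."""
        return self.labeled_cells / self.examined_area


@dataclasses.dataclass(frozen=True)
class HeartStereology:
    """Section counts plus the scalars needed for whole-heart extrapolation."""

    heart_id: str
    heart_mass: float  # mg; 1 mg is treated as 1 mm^3 of myocardium
    injected_dose: float
    sections: tuple[SectionCount, ...]
    section_thickness: float = DEFAULT_SECTION_THICKNESS_MM  # mm

    def __post_init__(self) -> None:
        if self.heart_mass <= 0:
            raise ValueError("heart_mass must be positive")
        if self.section_thickness <= 0:
            raise ValueError("section_thickness must be positive")
        if self.injected_dose <= 0:
            raise ValueError("injected_dose must be positive")
        object.__setattr__(self, "sections", tuple(self.sections))


@dataclasses.dataclass(frozen=True)
class TransmuralGradient:
    """Per-layer mean areal densities and the endo:epi ratio."""

    layer_densities: dict[str, float]  # cells/mm^2, averaged hearts-last
    endo_epi_ratio: float              # NaN when epicardial density is 0


def whole_heart_estimate(
    h: HeartStereology,
    area_weighted: bool = False,
) -> tuple[float, float]:
    """Whole-heart retained cell count and retention rate from sections.

    Averages the areal density over the heart's whole-section counts
    (equal weight per section by default; ``area_weighted`` pools counts
    over pooled area instead), then applies
    ``density / thickness * heart_mass``.

    Returns
    -------
    (retained_cells, retention_pct)
    """
    whole = [s for s in h.sections if s.layer == "whole"]
    if not whole:
        raise ValueError(f"heart {h.heart_id}: no whole-section counts")
    if area_weighted:
        density = sum(s.labeled_cells for s in whole) / sum(s.examined_area for s in whole)
    else:
        density = float(np.mean([s.density for s in whole]))
    retained = density / h.section_thickness * h.heart_mass
    return retained, retained / h.injected_dose * 100.0


def transmural_gradient(sections: Iterable[SectionCount]) -> TransmuralGradient:
    """Two-stage transmural averaging and the endocardium:epicardium ratio.

    Densities are averaged per layer across section levels *within* each
    heart first, then across hearts, so every heart contributes equally to
    the pooled layer means regardless of how many levels were sectioned.
    """
    per_heart: dict[str, dict[str, list[float]]] = defaultdict(lambda: defaultdict(list))
    for s in sections:
        if s.layer == "whole":
            continue
        per_heart[s.heart_id][s.layer].append(s.density)
    layers_seen = {layer for by_layer in per_heart.values() for layer in by_layer}
    if len(layers_seen) < 2:
        raise ValueError("transmural gradient needs counts for >= 2 distinct layers")

    layer_densities: dict[str, float] = {}
    for layer in LAYERS:
        heart_means = [
            float(np.mean(by_layer[layer]))
            for by_layer in per_heart.values()
            if layer in by_layer
        ]
        if heart_means:
            layer_densities[layer] = float(np.mean(heart_means))

    epi = layer_densities.get("epicardial", 0.0)
    endo = layer_densities.get("endocardial", float("nan"))
    if epi <= 0:
        logger.warning("epicardial density is zero; endo:epi ratio undefined")
        ratio = float("nan")
    else:
        ratio = endo / epi
    return TransmuralGradient(layer_densities=layer_densities, endo_epi_ratio=ratio)
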