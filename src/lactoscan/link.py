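"""Globule geometry correction and crescent-to-globule linking.

A cytoplasmic crescent is cytoplasm trapped against the surface of a milk
fat globule, so each detected crescent is attributed to the globule whose
*boundary* its centroid is closest to: the link distance is the Euclidean
centroid distance minus the globule's equivalent radius (negative when the
centroid falls inside the idealized disk).  Raw centroid distance would
systematically mis-link small crescents sitting on large globules.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.measure import perimeter_crofton

from .segment import GlobuleRecord, RnaObject

__all__ = ["LinkParams", "CrescentRecord", "correct_globule_geometry", "link_crescents"]


@dataclass
class LinkParams:
    """Linking parameters.

    ``max_link_distance`` (px) caps the centroid-to-boundary distance; a
    crescent farther than this from every globule is kept as an orphan
    (it still contributes exosomal RNA).  Ties are always broken toward the
    lowest globule id.
    """

    max_link_distance: float = 25.0

    def __post_init__(self) -> None:
        if self.max_link_distance < 0:
            raise ValueError("max_link_distance must be >= 0")


@dataclass
class CrescentRecord:
    """A crescent after linking."""

    crescent_id: int
    centroid: tuple[float, float]
    area: float
    integrated_intensity: float
    linked_globule_id: int | None
    link_distance: float | None  # px; negative if centroid inside the disk
    orphan_flag: bool
    kind: str = "crescent"


def correct_globule_geometry(
    globule_labels: np.ndarray, records: Sequence[GlobuleRecord]
) -> list[GlobuleRecord]:
    """Fill holes in each globule component and recompute its measurements.

    DIC detection can return only the bright rim of a globule; filling the
    component recovers the disk, after which area, centroid, equivalent
    radius and circularity are recomputed.  Already-solid components are
    returned unchanged, making the correction idempotent.
    """
    labels = np.asarray(globule_labels)
    slices = ndimage.find_objects(labels)
    corrected: list[GlobuleRecord] = []
    for rec in records:
        sl = slices[rec.globule_id - 1]
        if sl is None:
            corrected.append(rec)
            continue
        comp = labels[sl] == rec.globule_id
        filled = ndimage.binary_fill_holes(comp)
        # never claim pixels already owned by another globule
        filled &= (labels[sl] == rec.globule_id) | (labels[sl] == 0)
        if filled.sum() == comp.sum():
            corrected.append(rec)
            continue
        ys, xs = np.nonzero(filled)
        area = float(filled.sum())
        perim = perimeter_crofton(filled, directions=4)
        corrected.append(
            replace(
                rec,
                centroid=(
                    float(xs.mean() + sl[1].start),
                    float(ys.mean() + sl[0].start),
                ),
                area=area,
                equivalent_radius=float(np.sqrt(area / np.pi)),
                circularity=float(min(4 * np.pi * area / perim**2, 1.05))
                if perim > 0
                else rec.circularity,
            )
        )
    return corrected


def link_crescents(
    crescents: Sequence[RnaObject],
    globules: Sequence[GlobuleRecord],
    params: LinkParams | None = None,
    _chunk: int = 1024,
) -> list[CrescentRecord]:
    """Link each crescent candidate to its closest milk fat globule.

    distance(c, g) = ||centroid_c − centroid_g||₂ − equivalent_radius_g.
    The globule minimizing this distance wins; exact ties go to the lowest
    globule id.  Crescents farther than ``max_link_distance`` from every
    globule, or any crescent when no globules exist, are flagged as orphans.
    Output order preserves input order.
    """
    params = params or LinkParams()
    if not crescents:
        return []
    if not globules:
        return [
            CrescentRecord(
                crescent_id=c.object_id,
                centroid=c.centroid,
                area=c.area,
                integrated_intensity=c.integrated_intensity,
                linked_globule_id=None,
                link_distance=None,
                orphan_flag=True,
            )
            for c in crescents
        ]
    order = np.argsort([g.globule_id for g in globules], kind="stable")
    gs = [globules[i] for i in order]
    centers = np.array([g.centroid for g in gs], dtype=float)
    radii = np.array([g.equivalent_radius for g in gs], dtype=float)
    ids = np.array([g.globule_id for g in gs])

    out: list[CrescentRecord] = []
    pts = np.array([c.centroid for c in crescents], dtype=float)
    for lo in range(0, len(crescents), _chunk):
        block = pts[lo : lo + _chunk]
        d = np.linalg.norm(block[:, None, :] - centers[None, :, :], axis=2) - radii
        best = np.argmin(d, axis=1)  # first minimum == lowest globule_id on ties
        for j, c in enumerate(crescents[lo : lo + _chunk]):
            dist = float(d[j, best[j]])
            if dist > params.max_link_distance:
                out.append(
                    CrescentRecord(
                        crescent_id=c.object_id,
                        centroid=c.centroid,
                        area=c.area,
                        integrated_intensity=c.integrated_intensity,
                        linked_globule_id=None,
                        link_distance=None,
                        orphan_flag=True,
                    )
                )
            else:
                out.append(
                    CrescentRecord(
                        crescent_id=c.object_id,
                        centroid=c.centroid,
                        area=c.area,
                        integrated_intensity=c.integrated_intensity,
                        linked_globule_id=int(ids[best[j]]),
                        link_distance=dist,
                        orphan_flag=False,
                    )
                )
    return out
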