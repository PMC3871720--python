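"""Scene-level quantification and batch processing.

Two headline statistics are computed per image:

* ``pct_globules_with_crescents`` — the crescent incidence: the percentage
  of milk fat globules carrying at least one linked crescent (a globule
  with several crescents counts once).
* ``cellular_rna_pct`` / ``exosomal_rna_pct`` — the split of segmented milk
  RNA between nucleated cells and crescents.  By default the split uses
  integrated, background-subtracted fluorescence (RNA mass tracks
  fluorescence yield better than projected area); ``attribution_mode="area"``
  substitutes object areas.  The denominator covers segmented RNA objects
  only; diffuse sub-threshold skim signal is excluded.
"""

from __future__ import annotations

import logging
import math
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ChannelStack, Tile, load_channel_stack, tile_iterator
from .link import CrescentRecord, LinkParams, correct_globule_geometry, link_crescents
from .segment import (
    CellRecord,
    GlobuleRecord,
    RnaObject,
    SegmentationParams,
    classify_rna_objects,
    segment_channel_objects,
    segment_globules,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MilkSummary",
    "SceneResult",
    "summarize_scene",
    "process_stack",
    "process_stack_tiled",
    "aggregate_tiles",
    "batch_process",
]


@dataclass
class MilkSummary:
    """Headline statistics for one image (or one aggregated slide)."""

    image_id: str
    n_globules: int
    n_crescents_linked: int
    n_crescents_orphan: int
    n_cells: int
    pct_globules_with_crescents: float  # NaN when no globules
    cellular_rna_pct: float  # NaN when no RNA objects
    exosomal_rna_pct: float
    attribution_mode: str = "intensity"

    @property
    def n_crescents(self) -> int:
        return self.n_crescents_linked + self.n_crescents_orphan

    def to_row(self) -> dict:
        return {
            "image_id": self.image_id,
            "n_globules": self.n_globules,
            "n_crescents": self.n_crescents,
            "n_crescents_linked": self.n_crescents_linked,
            "n_crescents_orphan": self.n_crescents_orphan,
            "n_cells": self.n_cells,
            "pct_globules_with_crescents": self.pct_globules_with_crescents,
            "cellular_rna_pct": self.cellular_rna_pct,
            "exosomal_rna_pct": self.exosomal_rna_pct,
            "attribution_mode": self.attribution_mode,
        }


@dataclass
class SceneResult:
    """All detections for one image plus provenance."""

    image_id: str
    globules: list[GlobuleRecord]
    crescents: list[CrescentRecord]
    cells: list[CellRecord]
    summary: MilkSummary
    params: dict = field(default_factory=dict)
    globule_labels: np.ndarray | None = None
    rna_labels: np.ndarray | None = None


def summarize_scene(
    globules: Sequence[GlobuleRecord],
    crescents: Sequence[CrescentRecord],
    cells: Sequence[CellRecord],
    mode: str = "intensity",
    image_id: str = "",
) -> MilkSummary:
    """Compute the per-image summary from linked object records.

    Degenerate inputs yield NaN fields rather than errors: with no globules
    the incidence is undefined, and with no RNA objects the attribution
    split is undefined.
    """
    if mode not in ("intensity", "area"):
        raise ValueError("attribution mode must be 'intensity' or 'area'")
    n_globules = len(globules)
    linked = [c for c in crescents if not c.orphan_flag]
    orphans = [c for c in crescents if c.orphan_flag]
    if n_globules:
        bearing = len({c.linked_globule_id for c in linked})
        pct = 100.0 * bearing / n_globules
    else:
        pct = math.nan

    if mode == "intensity":
        cell_total = sum(c.integrated_rna_intensity for c in cells)
        cresc_total = sum(c.integrated_intensity for c in crescents)
    else:
        cell_total = sum(c.rna_area for c in cells)
        cresc_total = sum(c.area for c in crescents)
    denom = cell_total + cresc_total
    cellular = 100.0 * cell_total / denom if denom > 0 else math.nan
    exosomal = 100.0 - cellular if denom > 0 else math.nan

    return MilkSummary(
        image_id=image_id,
        n_globules=n_globules,
        n_crescents_linked=len(linked),
        n_crescents_orphan=len(orphans),
        n_cells=len(cells),
        pct_globules_with_crescents=pct,
        cellular_rna_pct=cellular,
        exosomal_rna_pct=exosomal,
        attribution_mode=mode,
    )


def _detect_tile(stack: ChannelStack, seg: SegmentationParams):
    """Run all per-pixel stages on one stack; linking is deferred."""
    globule_labels, globules = segment_globules(stack.dic, seg)
    globules = correct_globule_geometry(globule_labels, globules)
    rna_labels, rna_objects = segment_channel_objects(
        stack.rna, seg.min_rna_area, seg, channel="rna"
    )
    dna_labels, _ = segment_channel_objects(
        stack.dna, seg.min_dna_area, seg, channel="dna"
    )
    candidates, cells = classify_rna_objects(
        rna_labels, rna_objects, dna_labels > 0, seg
    )
    return globule_labels, globules, rna_labels, candidates, cells


def process_stack(
    stack: ChannelStack,
    seg: SegmentationParams | None = None,
    link: LinkParams | None = None,
    mode: str = "intensity",
    keep_labels: bool = False,
) -> SceneResult:
    """Full pipeline on one in-memory stack (no tiling)."""
    seg = seg or SegmentationParams()
    link = link or LinkParams()
    globule_labels, globules, rna_labels, candidates, cells = _detect_tile(stack, seg)
    crescents = link_crescents(candidates, globules, link)
    summary = summarize_scene(globules, crescents, cells, mode, stack.image_id)
    return SceneResult(
        image_id=stack.image_id,
        globules=globules,
        crescents=crescents,
        cells=cells,
        summary=summary,
        params={"segmentation": vars(seg).copy(), "linking": vars(link).copy(),
                "attribution_mode": mode},
        globule_labels=globule_labels if keep_labels else None,
        rna_labels=rna_labels if keep_labels else None,
    )


@dataclass
class _TileDetections:
    tile: Tile
    globules: list[GlobuleRecord]
    candidates: list[RnaObject]
    cells: list[CellRecord]
    image_id: str


def _offset(record, dx: float, dy: float):
    from dataclasses import replace

    x, y = record.centroid
    return replace(record, centroid=(x + dx, y + dy))


def aggregate_tiles(
    tile_results: Sequence[_TileDetections],
    link: LinkParams | None = None,
    mode: str = "intensity",
) -> SceneResult:
    """Merge per-tile detections into one slide-level result.

    An object is kept by the unique tile whose half-open core region
    contains its centroid (in parent coordinates); ids are re-issued
    globally in tile order, and crescent–globule linking is re-run over the
    full aggregated object lists so that links can cross tile boundaries.
    """
    link = link or LinkParams()
    if not tile_results:
        raise ValueError("no tile results to aggregate")
    image_ids = {t.image_id for t in tile_results}
    if len(image_ids) != 1:
        raise ValueError(f"tiles from different images: {sorted(image_ids)}")
    image_id = image_ids.pop()

    globules: list[GlobuleRecord] = []
    candidates: list[RnaObject] = []
    cells: list[CellRecord] = []
    from dataclasses import replace

    for tr in tile_results:
        dx, dy = tr.tile.origin_x, tr.tile.origin_y
        for g in tr.globules:
            g = _offset(g, dx, dy)
            if tr.tile.contains_core(*g.centroid):
                globules.append(replace(g, globule_id=len(globules) + 1))
        for c in tr.candidates:
            c = _offset(c, dx, dy)
            if tr.tile.contains_core(*c.centroid):
                candidates.append(replace(c, object_id=len(candidates) + 1))
        for c in tr.cells:
            c = _offset(c, dx, dy)
            if tr.tile.contains_core(*c.centroid):
                cells.append(replace(c, cell_id=len(cells) + 1))

    crescents = link_crescents(candidates, globules, link)
    summary = summarize_scene(globules, crescents, cells, mode, image_id)
    return SceneResult(
        image_id=image_id,
        globules=globules,
        crescents=crescents,
        cells=cells,
        summary=summary,
        params={"linking": vars(link).copy(), "attribution_mode": mode,
                "n_tiles": len(tile_results)},
    )


def process_stack_tiled(
    stack: ChannelStack,
    tile_size: int,
    overlap: int,
    seg: SegmentationParams | None = None,
    link: LinkParams | None = None,
    mode: str = "intensity",
) -> SceneResult:
    """Tile a large stack, detect per tile, and aggregate.

    ``overlap`` must be at least the largest expected object diameter so
    that the tile owning an object's centroid sees the whole object.
    """
    seg = seg or SegmentationParams()
    results = []
    for tile in tile_iterator(stack, tile_size, overlap):
        _, globules, _, candidates, cells = _detect_tile(tile.stack, seg)
        results.append(
            _TileDetections(
                tile=tile,
                globules=globules,
                candidates=candidates,
                cells=cells,
                image_id=stack.image_id,
            )
        )
    out = aggregate_tiles(results, link, mode)
    out.params["segmentation"] = vars(seg).copy()
    out.params["tiling"] = {"tile_size": tile_size, "overlap": overlap}
    return out


def batch_process(
    paths: Sequence,
    channel_map: Mapping[str, int | str] | None = None,
    seg: SegmentationParams | None = None,
    link: LinkParams | None = None,
    mode: str = "intensity",
    pixel_size: float = 1.0,
    tile_size: int | None = None,
    overlap: int = 64,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Process a batch of images; failures are isolated, never fatal.

    Returns ``(summaries, objects)``: one summary row per input (with a
    ``status`` column, ``ok`` or ``failed: <reason>``) and the concatenated
    object table for all successful images.
    """
    if not list(paths):
        raise ValueError("empty path list")
    channel_map = dict(channel_map or {"dic": 0, "rna": 1, "dna": 2})
    summary_rows: list[dict] = []
    object_rows: list[dict] = []
    for path in paths:
        try:
            stack = load_channel_stack(path, channel_map, pixel_size=pixel_size)
            if tile_size is not None:
                result = process_stack_tiled(stack, tile_size, overlap, seg, link, mode)
            else:
                result = process_stack(stack, seg, link, mode)
            row = result.summary.to_row()
            row["status"] = "ok"
            summary_rows.append(row)
            object_rows.extend(_object_rows(result, pixel_size))
            logger.info(
                "%s: %d globules, %d crescents, %d cells",
                result.image_id,
                result.summary.n_globules,
                result.summary.n_crescents,
                result.summary.n_cells,
            )
        except Exception as exc:  # noqa: BLE001 - batch isolation is the contract
            logger.error("failed on %s: %s", path, exc)
            logger.debug("%s", traceback.format_exc())
            summary_rows.append(
                {"image_id": Path(str(path)).stem, "status": f"failed: {exc}"}
            )
    summaries = pd.DataFrame(summary_rows)
    objects = pd.DataFrame(object_rows)
    return summaries, objects


def _object_rows(result: SceneResult, pixel_size: float) -> Iterable[dict]:
    from .io import OBJECT_TABLE_COLUMNS, _record_row

    for records in (result.globules, result.crescents, result.cells):
        for rec in records:
            yield dict(
                zip(OBJECT_TABLE_COLUMNS, _record_row(rec, result.image_id, pixel_size))
            )
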