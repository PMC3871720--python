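"""Image input/output: channel stacks, whole-slide tiling, object tables.

A micrograph of acridine-orange (AO) stained whole milk carries three
registered planes: a differential interference contrast (DIC) image in which
fat globules appear as gray bubbles, an AO-RNA fluorescence plane (emission
~650 nm) and an AO-DNA fluorescence plane (emission ~525 nm).  Channel
identity is always declared by the caller through a ``channel_map`` — TIFF
files carry no reliable channel metadata, so nothing is inferred from color.

Coordinates are 0-based pixel indices with ``x`` = column and ``y`` = row;
centroids are arithmetic means of member-pixel coordinates and may be
fractional.  Areas are reported in px² and, when a pixel size is known, µm².
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import tifffile

__all__ = [
    "ChannelStack",
    "Tile",
    "load_channel_stack",
    "write_channel_stack",
    "tile_iterator",
    "write_object_table",
    "OBJECT_TABLE_COLUMNS",
]

CHANNEL_ROLES = ("dic", "rna", "dna")


class ValidationError(ValueError):
    """Raised when an input image or record violates a structural contract."""


@dataclass
class ChannelStack:
    """Three registered 2-D intensity planes plus pixel-size metadata.

    Parameters
    ----------
    dic, rna, dna
        2-D float arrays of identical shape (arbitrary intensity units).
    pixel_size
        Physical edge length of one pixel in micrometres.  The default of
        1.0 makes µm² areas numerically equal to px² areas.
    image_id
        Identifier of the source image (file stem by convention).
    provenance
        Free-form metadata (original dtype, tile origin, ...).
    """

    dic: np.ndarray
    rna: np.ndarray
    dna: np.ndarray
    pixel_size: float = 1.0
    image_id: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        planes = {}
        for role in CHANNEL_ROLES:
            plane = np.asarray(getattr(self, role))
            if plane.ndim != 2:
                raise ValidationError(f"channel {role!r} is not a 2-D plane")
            planes[role] = plane
            setattr(self, role, plane)
        shapes = {role: p.shape for role, p in planes.items()}
        if len(set(shapes.values())) != 1:
            ref = planes["dic"].shape
            bad = [r for r, s in shapes.items() if s != ref]
            raise ValidationError(
                f"plane shape mismatch for channel(s) {', '.join(bad)}: {shapes}"
            )
        for role, plane in planes.items():
            if not np.all(np.isfinite(plane)):
                raise ValidationError(f"channel {role!r} contains non-finite values")
            if np.any(plane < 0):
                raise ValidationError(f"channel {role!r} contains negative intensities")
        if not self.pixel_size > 0:
            raise ValidationError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dic.shape

    def crop(self, y0: int, y1: int, x0: int, x1: int) -> "ChannelStack":
        """Return a view-backed sub-stack (no copy of pixel data)."""
        return ChannelStack(
            dic=self.dic[y0:y1, x0:x1],
            rna=self.rna[y0:y1, x0:x1],
            dna=self.dna[y0:y1, x0:x1],
            pixel_size=self.pixel_size,
            image_id=self.image_id,
            provenance=dict(self.provenance),
        )


@dataclass
class Tile:
    """One tile of a larger image.

    ``core_bounds`` is the half-open rectangle ``(y0, y1, x0, x1)`` in
    *parent* coordinates whose detections are authoritative; the union of all
    tiles' cores partitions the parent exactly.  The remainder of the tile is
    overlap margin shared with neighbours.
    """

    stack: ChannelStack
    origin_x: int
    origin_y: int
    core_bounds: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        y0, y1, x0, x1 = self.core_bounds
        h, w = self.stack.shape
        if not (self.origin_y <= y0 <= y1 <= self.origin_y + h):
            raise ValidationError("core_bounds outside tile (y)")
        if not (self.origin_x <= x0 <= x1 <= self.origin_x + w):
            raise ValidationError("core_bounds outside tile (x)")

    def contains_core(self, x: float, y: float) -> bool:
        """Half-open membership test for a centroid in parent coordinates."""
        y0, y1, x0, x1 = self.core_bounds
        return (y0 <= y < y1) and (x0 <= x < x1)


def _load_plane(source, page_index: int | None) -> np.ndarray:
    if page_index is None:
        arr = tifffile.imread(source)
    else:
        arr = tifffile.imread(source, key=page_index)
    return np.asarray(arr)


def load_channel_stack(
    path: str | Path | None,
    channel_map: Mapping[str, int | str | Path],
    pixel_size: float = 1.0,
    image_id: str | None = None,
) -> ChannelStack:
    """Load a three-channel stack from TIFF.

    ``channel_map`` maps each of the roles ``dic``, ``rna``, ``dna`` either to
    a page index within the multi-page TIFF at ``path``, or to a per-channel
    file path (in which case ``path`` may be None).

    Raises
    ------
    FileNotFoundError
        If a referenced file does not exist.
    ValidationError
        If roles are missing, pages are missing, or plane shapes disagree.
    """
    roles = set(channel_map)
    if roles != set(CHANNEL_ROLES):
        raise ValidationError(
            f"channel_map must name exactly {CHANNEL_ROLES}, got {sorted(roles)}"
        )
    planes: dict[str, np.ndarray] = {}
    dtypes: dict[str, str] = {}
    for role in CHANNEL_ROLES:
        source = channel_map[role]
        if isinstance(source, (int, np.integer)):
            if path is None:
                raise ValidationError(
                    f"channel {role!r} given as page index but no path supplied"
                )
            p = Path(path)
            if not p.exists():
                raise FileNotFoundError(p)
            with tifffile.TiffFile(p) as tf:
                n_pages = len(tf.pages)
            if source >= n_pages:
                raise ValidationError(
                    f"channel {role!r} requests page {source} but {p.name} has "
                    f"only {n_pages} page(s)"
                )
            plane = _load_plane(p, int(source))
        else:
            p = Path(source)
            if not p.exists():
                raise FileNotFoundError(p)
            plane = _load_plane(p, None)
        dtypes[role] = str(plane.dtype)
        planes[role] = plane.astype(np.float64, copy=False)

    shapes = {r: planes[r].shape for r in CHANNEL_ROLES}
    if len(set(shapes.values())) != 1:
        ref = shapes["dic"]
        bad = [r for r in ("rna", "dna") if shapes[r] != ref] or ["dic"]
        raise ValidationError(
            f"plane shape mismatch for channel(s) {', '.join(bad)}: {shapes}"
        )
    if image_id is None:
        image_id = Path(path).stem if path is not None else Path(channel_map["dic"]).stem
    return ChannelStack(
        pixel_size=pixel_size,
        image_id=image_id,
        provenance={"source_dtypes": dtypes, "path": str(path) if path else None},
        **planes,
    )


def write_channel_stack(stack: ChannelStack, path: str | Path, dtype=np.uint16) -> Path:
    """Write a stack as a 3-page TIFF (pages in dic, rna, dna order).

    Intensities are rounded and clipped to the target integer dtype; the
    synthetic generator keeps its levels inside the uint16 range so the
    write → load round trip is bit-exact.
    """
    path = Path(path)
    info = np.iinfo(dtype)
    pages = [
        np.clip(np.rint(getattr(stack, role)), info.min, info.max).astype(dtype)
        for role in CHANNEL_ROLES
    ]
    tifffile.imwrite(path, np.stack(pages, axis=0), photometric="minisblack")
    return path


def tile_iterator(
    stack: ChannelStack, tile_size: int, overlap: int
) -> Iterator[Tile]:
    """Yield overlapping tiles in row-major order.

    Consecutive tiles along an axis advance by ``tile_size - overlap`` so
    adjacent tiles share an ``overlap``-pixel band; each tile's authoritative
    core is bounded by the midlines of its overlap bands, so the cores
    partition the image exactly.  Callers are responsible for choosing
    ``overlap`` at least as large as the maximum expected object diameter so
    every object is fully contained in the tile owning its centroid.
    """
    if tile_size <= 2 * overlap:
        raise ValueError(f"tile_size ({tile_size}) must exceed 2*overlap ({2 * overlap})")
    if overlap < 0:
        raise ValueError("overlap must be non-negative")
    h, w = stack.shape

    def _starts(size: int) -> list[int]:
        starts = [0]
        while starts[-1] + tile_size < size:
            starts.append(starts[-1] + tile_size - overlap)
        return starts

    ys, xs = _starts(h), _starts(w)

    def _bounds(starts: list[int], i: int, size: int) -> tuple[int, int, int, int]:
        lo = starts[i]
        hi = min(lo + tile_size, size)
        core_lo = 0 if i == 0 else lo + overlap // 2 + overlap % 2
        core_hi = size if i == len(starts) - 1 else starts[i + 1] + overlap // 2 + overlap % 2
        return lo, hi, core_lo, core_hi

    for iy in range(len(ys)):
        y_lo, y_hi, cy0, cy1 = _bounds(ys, iy, h)
        for ix in range(len(xs)):
            x_lo, x_hi, cx0, cx1 = _bounds(xs, ix, w)
            yield Tile(
                stack=stack.crop(y_lo, y_hi, x_lo, x_hi),
                origin_x=x_lo,
                origin_y=y_lo,
                core_bounds=(cy0, cy1, cx0, cx1),
            )


OBJECT_TABLE_COLUMNS = [
    "image_id",
    "object_id",
    "kind",
    "x",
    "y",
    "area_px2",
    "area_um2",
    "linked_globule_id",
    "link_distance_px",
    "flags",
]


def write_object_table(
    records: Sequence,
    path: str | Path,
    image_id: str = "",
    pixel_size: float = 1.0,
) -> Path:
    """Write per-object records of any kind to a CSV object table.

    Accepts globule, crescent, cell and raw RNA-object records; fields a kind
    does not define are left empty.  An empty record list yields a
    header-only file.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(OBJECT_TABLE_COLUMNS)
        for rec in records:
            writer.writerow(_record_row(rec, image_id, pixel_size))
    return path


def _record_row(rec, image_id: str, pixel_size: float) -> list:
    kind = getattr(rec, "kind", None) or type(rec).__name__.removesuffix("Record").lower()
    obj_id = next(
        (
            getattr(rec, name)
            for name in ("globule_id", "crescent_id", "cell_id", "object_id")
            if hasattr(rec, name)
        ),
        "",
    )
    x, y = rec.centroid
    area = getattr(rec, "area", None)
    if area is None:
        area = getattr(rec, "rna_area", "")
    area_um2 = area * pixel_size**2 if area != "" else ""
    linked = getattr(rec, "linked_globule_id", None)
    dist = getattr(rec, "link_distance", None)
    flags = []
    if getattr(rec, "orphan_flag", False):
        flags.append("orphan")
    return [
        image_id,
        obj_id,
        kind,
        _fmt(x),
        _fmt(y),
        _fmt(area),
        _fmt(area_um2),
        "" if linked is None else linked,
        "" if dist is None else _fmt(dist),
        ";".join(flags),
    ]


def _fmt(value) -> str:
    """Format numbers with enough digits for lossless float round-trips."""
    if value == "" or value is None:
        return ""
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return repr(float(value))
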