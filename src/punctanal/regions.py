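"""Region-of-interest object model: generic regions, dendrites, categories.

Analysis is restricted to user-defined regions.  A *generic region* is a
simple polygon used for plain intensity measurements (e.g. a soma).  A
*dendrite region* is the container object of the analysis: it carries a
centerline (a polyline traced along the dendrite), an enclosing polygon
— either generated automatically as a fixed-width band around the
centerline or supplied freehand — and owns the puncta and spines found
inside it.  Objects are grouped into named categories (e.g. "transfected"
vs "non-transfected") for aggregate statistics.

ROIs are not drawn interactively; they arrive as a JSON sidecar next to
each image (see :func:`load_rois`).

Geometry conventions: vertices are ``(row, col)`` floats, pixels are
0-based, and a pixel belongs to a polygon iff its *center* lies strictly
inside (even-odd rule).  Fixed-width dendrite bands use round joins at
polyline elbows.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon

from .detection import Punctum

log = logging.getLogger(__name__)

__all__ = [
    "GenericRegion",
    "DendriteRegion",
    "CategorySet",
    "ContainmentError",
    "polyline_length",
    "buffer_centerline",
    "rasterize_region",
    "attach_puncta",
    "load_rois",
]


class ContainmentError(ValueError):
    """An object's pixels fall outside its container's mask."""


def polyline_length(centerline: Sequence[Sequence[float]], pixel_size: float = 1.0) -> float:
    """Arc length of a polyline, scaled to physical units.

    Sum of Euclidean segment lengths (in pixels) times ``pixel_size``.
    """
    pts = np.asarray(centerline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("centerline needs at least 2 (row, col) vertices")
    return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)) * pixel_size)


def buffer_centerline(
    centerline: Sequence[Sequence[float]], half_width: float
) -> list[tuple[float, float]]:
    """Outline of the fixed-width band around a centerline.

    Returns the vertex list (``(row, col)`` floats) of the set of points
    within ``half_width`` (same units as the vertices, i.e. pixels) of
    the polyline.  Elbows and end caps are round.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    pts = np.asarray(centerline, dtype=float)
    if pts.shape[0] < 2 or polyline_length(pts) == 0:
        raise ValueError("degenerate centerline")
    line = LineString([(c, r) for r, c in pts])  # shapely is (x, y) = (col, row)
    poly = line.buffer(half_width, quad_segs=16)
    return [(y, x) for x, y in poly.exterior.coords]


def rasterize_region(
    polygon: Sequence[Sequence[float]], image_shape: tuple[int, int]
) -> np.ndarray:
    """Boolean mask of pixels whose centers lie inside the polygon.

    The pixel at ``(r, c)`` has its center at exactly ``(r, c)``.
    Centers on the boundary are excluded (strict interior, even-odd
    rule).  A polygon entirely outside the image yields an empty mask
    with a warning.
    """
    verts = np.asarray(polygon, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3:
        raise ValueError("polygon needs at least 3 vertices")
    poly = Polygon([(c, r) for r, c in verts])
    if not poly.is_valid:
        raise ValueError("polygon must be simple (non-self-intersecting)")
    h, w = image_shape
    mask = np.zeros((h, w), dtype=bool)
    minx, miny, maxx, maxy = poly.bounds
    c0, c1 = max(0, math.floor(minx)), min(w - 1, math.ceil(maxx))
    r0, r1 = max(0, math.floor(miny)), min(h - 1, math.ceil(maxy))
    if c0 > c1 or r0 > r1:
        log.warning("polygon lies entirely outside the image; empty mask")
        return mask
    rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    inside = shapely.contains_xy(poly, cc.ravel(), rr.ravel()).reshape(rr.shape)
    mask[r0 : r1 + 1, c0 : c1 + 1] = inside
    if not mask.any():
        log.warning("polygon covers no pixel centers; empty mask")
    return mask


@dataclass
class GenericRegion:
    """A simple-polygon ROI for plain intensity measurement."""

    id: str
    polygon: list[tuple[float, float]]
    group: str = "default"

    def __post_init__(self) -> None:
        if len(self.polygon) < 3:
            raise ValueError(f"region {self.id}: polygon needs >= 3 vertices")
        p = Polygon([(c, r) for r, c in self.polygon])
        if not p.is_valid:
            raise ValueError(f"region {self.id}: polygon must be simple")

    def mask(self, image_shape: tuple[int, int]) -> np.ndarray:
        return rasterize_region(self.polygon, image_shape)


@dataclass
class DendriteRegion:
    """A dendrite segment: centerline + enclosing polygon + contents.

    ``mode`` is ``fixed_width`` (polygon derived by buffering the
    centerline by ``half_width`` pixels) or ``freehand`` (polygon
    supplied by the user).  The region owns the puncta and spines
    detected/placed inside it; densities are computed against the
    centerline arc length.
    """

    id: str
    centerline: list[tuple[float, float]]
    mode: str = "fixed_width"
    half_width: float | None = None  # pixels, fixed_width mode
    polygon: list[tuple[float, float]] | None = None
    group: str = "default"
    pixel_size: float = 1.0
    puncta: list[Punctum] = field(default_factory=list)
    spines: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.centerline) < 2:
            raise ValueError(f"dendrite {self.id}: centerline needs >= 2 vertices")
        if self.mode == "fixed_width":
            if self.half_width is None or self.half_width <= 0:
                raise ValueError(f"dendrite {self.id}: fixed_width mode needs half_width > 0")
            if self.polygon is None:
                self.polygon = buffer_centerline(self.centerline, self.half_width)
        elif self.mode == "freehand":
            if self.polygon is None:
                raise ValueError(f"dendrite {self.id}: freehand mode needs a polygon")
        else:
            raise ValueError(f"dendrite {self.id}: unknown mode {self.mode!r}")
        if not self.length_phys > 0:
            raise ValueError(f"dendrite {self.id}: zero-length centerline")

    @property
    def length_phys(self) -> float:
        """Centerline arc length in micrometres."""
        return polyline_length(self.centerline, self.pixel_size)

    def mask(self, image_shape: tuple[int, int]) -> np.ndarray:
        return rasterize_region(self.polygon, image_shape)


def attach_puncta(
    region: DendriteRegion,
    puncta: Iterable[Punctum],
    mask: np.ndarray,
) -> DendriteRegion:
    """Attach detected puncta to a dendrite region.

    Every punctum pixel must lie inside the region's rasterized mask
    (pass the mask that detection itself used to avoid re-rasterizing);
    otherwise a :class:`ContainmentError` is raised.
    """
    puncta = list(puncta)
    for p in puncta:
        for r, c in p.pixel_set:
            if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c]):
                raise ContainmentError(
                    f"punctum {p.label} has pixel ({r}, {c}) outside region {region.id}"
                )
    region.puncta = puncta
    return region


class CategorySet:
    """Assignment of object ids to named categories (one each).

    Objects not explicitly assigned belong to the category ``default``.
    """

    def __init__(self) -> None:
        self._cat: dict[str, str] = {}

    def assign(self, object_id: str, category: str) -> None:
        self._cat[object_id] = category

    def category_of(self, object_id: str) -> str:
        return self._cat.get(object_id, "default")

    def members(self, category: str) -> list[str]:
        return [o for o, c in self._cat.items() if c == category]

    @property
    def categories(self) -> list[str]:
        return sorted(set(self._cat.values()))


def load_rois(
    path: str | Path | dict, pixel_size: float = 1.0
) -> tuple[list[DendriteRegion], list[GenericRegion], list[dict]]:
    """Parse an ROI sidecar (JSON file or already-parsed dict).

    Schema::

        {"regions": [
          {"id": "d1", "kind": "dendrite", "mode": "fixed_width",
           "centerline": [[r,c],...], "half_width_um": 2.0, "group": "transfected"},
          {"id": "s1", "kind": "generic", "polygon": [[r,c],...], "group": "..."},
          {"id": "sp1", "kind": "spine", "dendrite": "d1",
           "landmarks": {"base": [r,c], "tip": [r,c],
                         "head": [[r,c],[r,c]], "neck": [[r,c],[r,c]]}}
        ]}

    ``half_width_um`` is physical; it is converted to pixels with the
    supplied calibration.  Returns dendrites, generic regions, and raw
    spine records (resolved into Spine objects by the caller, which owns
    the classification rules).
    """
    if isinstance(path, (str, Path)):
        text = Path(path).read_text()
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed ROI JSON {path}: line {exc.lineno}: {exc.msg}") from exc
    else:
        doc = path
    dendrites: list[DendriteRegion] = []
    generics: list[GenericRegion] = []
    spines: list[dict] = []
    for rec in doc.get("regions", []):
        kind = rec.get("kind")
        if kind == "dendrite":
            hw_um = rec.get("half_width_um")
            dendrites.append(
                DendriteRegion(
                    id=rec["id"],
                    centerline=[tuple(v) for v in rec["centerline"]],
                    mode=rec.get("mode", "fixed_width"),
                    half_width=None if hw_um is None else hw_um / pixel_size,
                    polygon=[tuple(v) for v in rec["polygon"]] if "polygon" in rec else None,
                    group=rec.get("group", "default"),
                    pixel_size=pixel_size,
                )
            )
        elif kind == "generic":
            generics.append(
                GenericRegion(
                    id=rec["id"],
                    polygon=[tuple(v) for v in rec["polygon"]],
                    group=rec.get("group", "default"),
                )
            )
        elif kind == "spine":
            spines.append(rec)
        else:
            raise ValueError(f"unknown ROI kind {kind!r} in record {rec.get('id')!r}")
    return dendrites, generics, spines
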