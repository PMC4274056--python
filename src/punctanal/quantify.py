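"""Per-dendrite and per-group aggregation, region intensity, TSV export.

The dendrite is the statistical unit: each dendrite region yields one
row of statistics (puncta count, density per µm and per 10 µm, mean
per-punctum average and integrated intensity, total puncta intensity per
length, spine counts/densities, puncta per spine), and group statistics
are unweighted mean ± SD across the dendrites of a category.  Pooled
count/length ratios differ from the mean of per-dendrite densities in
general; the exported group value is the latter (per-dendrite first),
which matches treating dendrites as replicates.

Results are written as four TSV files (``puncta.tsv``, ``dendrites.tsv``,
``spines.tsv``, ``groups.tsv``) plus a run-metadata JSON.  Floats are
written with Python's shortest-round-trip repr, so re-parsing a table
reproduces the in-memory values exactly.  When the batch is
uncalibrated (pixel_size 1.0 px) "µm" columns are really pixel units; a
warning is logged.
"""

from __future__ import annotations

import json
import logging
import math
import statistics
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .detection import Punctum
from .regions import DendriteRegion, GenericRegion
from .spines import Spine, spine_summary, SPINE_TYPES

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1

__all__ = [
    "DendriteStats",
    "GroupStats",
    "RegionIntensity",
    "dendrite_stats",
    "group_stats",
    "region_intensity",
    "export_results",
]


@dataclass
class DendriteStats:
    """One dendrite's aggregated puncta and spine measurements."""

    dendrite_id: str
    group: str
    length_um: float
    puncta_count: int
    puncta_density_per_um: float
    puncta_density_per_10um: float
    mean_avg_intensity: float | None
    mean_integrated_intensity: float | None
    total_puncta_intensity_per_length: float
    spine_count: int
    spine_density_per_um: float
    puncta_per_spine: float | None
    image: str = ""


@dataclass
class GroupStats:
    """Unweighted mean ± SD of each dendrite metric across a category.

    SD is the sample standard deviation (ddof=1); a single-dendrite
    group reports SD 0.
    """

    group: str
    n_dendrites: int
    means: dict[str, float | None]
    sds: dict[str, float | None]


@dataclass
class RegionIntensity:
    """Plain intensity measurement over a generic region's mask."""

    region_id: str
    area_px: int
    integrated_intensity: int
    average_intensity: float


_NUMERIC_FIELDS = (
    "length_um",
    "puncta_count",
    "puncta_density_per_um",
    "puncta_density_per_10um",
    "mean_avg_intensity",
    "mean_integrated_intensity",
    "total_puncta_intensity_per_length",
    "spine_count",
    "spine_density_per_um",
    "puncta_per_spine",
)


def dendrite_stats(region: DendriteRegion, image: str = "") -> DendriteStats:
    """Compute the per-dendrite statistics row from its attached objects."""
    length = region.length_phys
    if not length > 0:
        raise ValueError(f"dendrite {region.id}: zero length")
    puncta = region.puncta
    n = len(puncta)
    total_int = sum(p.integrated_intensity for p in puncta)
    n_sp = len(region.spines)
    return DendriteStats(
        dendrite_id=region.id,
        group=region.group,
        length_um=length,
        puncta_count=n,
        puncta_density_per_um=n / length,
        puncta_density_per_10um=10.0 * n / length,
        mean_avg_intensity=(sum(p.average_intensity for p in puncta) / n) if n else None,
        mean_integrated_intensity=(total_int / n) if n else None,
        total_puncta_intensity_per_length=total_int / length,
        spine_count=n_sp,
        spine_density_per_um=n_sp / length,
        puncta_per_spine=(n / n_sp) if n_sp else None,
        image=image,
    )


def group_stats(dendrites: Sequence[DendriteStats], category: str) -> GroupStats | None:
    """Mean ± SD of each metric across the dendrites of one category.

    Returns ``None`` (with a warning) for an empty category.
    """
    members = [d for d in dendrites if d.group == category]
    if not members:
        log.warning("category %r has no dendrites; skipped", category)
        return None
    means: dict[str, float | None] = {}
    sds: dict[str, float | None] = {}
    for f in _NUMERIC_FIELDS:
        vals = [getattr(d, f) for d in members if getattr(d, f) is not None]
        if not vals:
            means[f] = sds[f] = None
            continue
        means[f] = sum(vals) / len(vals)
        sds[f] = statistics.stdev(vals) if len(vals) > 1 else 0.0
    return GroupStats(group=category, n_dendrites=len(members), means=means, sds=sds)


def region_intensity(
    region: GenericRegion | DendriteRegion,
    channel: np.ndarray,
    mask: np.ndarray | None = None,
) -> RegionIntensity:
    """Integrated and average intensity of a channel over a region mask."""
    channel = np.asarray(channel)
    if mask is None:
        mask = region.mask(channel.shape)
    if mask.shape != channel.shape:
        raise ValueError("mask and channel shapes differ")
    area = int(mask.sum())
    if area == 0:
        raise ValueError(f"region {region.id} rasterizes to an empty mask")
    integ = int(channel[mask].astype(np.int64).sum())
    return RegionIntensity(
        region_id=region.id,
        area_px=area,
        integrated_intensity=integ,
        average_intensity=integ / area,
    )


def _puncta_frame(puncta: Mapping[str, Iterable[Punctum]] | None) -> pd.DataFrame:
    cols = [
        "image", "dendrite_id", "label", "area_px", "area_um2",
        "integrated_intensity", "average_intensity", "centroid_row", "centroid_col",
    ]
    rows = []
    for key, plist in (puncta or {}).items():
        image, _, dend = key.partition("::")
        for p in plist:
            rows.append({
                "image": image, "dendrite_id": dend, "label": p.label,
                "area_px": p.area_px, "area_um2": p.area_phys,
                "integrated_intensity": p.integrated_intensity,
                "average_intensity": p.average_intensity,
                "centroid_row": p.centroid[0], "centroid_col": p.centroid[1],
            })
    return pd.DataFrame(rows, columns=cols)


def _spines_frame(spines: Iterable[tuple[str, Spine]]) -> pd.DataFrame:
    cols = [
        "image", "dendrite_id", "spine_id", "length_um", "head_width_um",
        "neck_width_um", "category", "category_source",
    ]
    rows = [
        {
            "image": image, "dendrite_id": s.dendrite_id, "spine_id": s.id,
            "length_um": s.length, "head_width_um": s.head_width,
            "neck_width_um": s.neck_width, "category": s.category,
            "category_source": s.category_source,
        }
        for image, s in spines
    ]
    return pd.DataFrame(rows, columns=cols)


def _groups_frame(groups: Iterable[GroupStats]) -> pd.DataFrame:
    cols = ["group", "n_dendrites"]
    cols += [f"mean_{f}" for f in _NUMERIC_FIELDS] + [f"sd_{f}" for f in _NUMERIC_FIELDS]
    rows = []
    for g in groups:
        row = {"group": g.group, "n_dendrites": g.n_dendrites}
        row.update({f"mean_{f}": g.means[f] for f in _NUMERIC_FIELDS})
        row.update({f"sd_{f}": g.sds[f] for f in _NUMERIC_FIELDS})
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)


def export_results(
    out_dir: str | Path,
    dendrites: Sequence[DendriteStats],
    groups: Sequence[GroupStats] = (),
    puncta: Mapping[str, Iterable[Punctum]] | None = None,
    spines: Iterable[tuple[str, Spine]] = (),
    metadata: dict | None = None,
) -> dict[str, Path]:
    """Write the four TSV tables plus run metadata to ``out_dir``.

    ``puncta`` maps ``"<image>::<dendrite_id>"`` to that dendrite's
    punctum list; ``spines`` is (image, Spine) pairs.  TSV uses UTF-8,
    '.' decimal separator and shortest-round-trip float formatting.
    Returns the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dend_df = pd.DataFrame(
        [asdict(d) for d in dendrites],
        columns=["image", "dendrite_id", "group", *_NUMERIC_FIELDS],
    )
    frames = {
        "puncta.tsv": _puncta_frame(puncta),
        "dendrites.tsv": dend_df,
        "spines.tsv": _spines_frame(spines),
        "groups.tsv": _groups_frame(groups),
    }
    paths = {}
    for name, df in frames.items():
        p = out_dir / name
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    meta = {"schema_version": SCHEMA_VERSION, "software_version": __version__}
    meta.update(metadata or {})
    meta_path = out_dir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    paths["run_metadata.json"] = meta_path
    return paths
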