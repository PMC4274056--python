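"""Puncta detection by descending multi-threshold region growing.

Synaptic proteins appear as puncta — small bright clusters — in
fluorescence images.  Detecting them with a single intensity threshold
merges adjacent bright puncta into one object whenever the valley between
them still clears the threshold, which under-counts synapses and inflates
per-punctum intensity.  The detector here instead sweeps the threshold
downward from ``t_start`` (default 255) to a user-chosen floor ``t_min``:
puncta are *seeded* at high thresholds where neighbouring peaks are still
separate, then *grown* outward as the threshold drops, so two peaks whose
connecting saddle exceeds ``t_min`` remain two objects.

Per round at threshold ``t`` (inclusive — a pixel counts as signal when
its intensity is ``>= t``):

1. candidates are the unassigned in-mask pixels with intensity ``>= t``;
2. *expansion to a fixed point*: a candidate adjacent to an existing
   punctum joins it; if adjacent to several, it joins the punctum of the
   brightest adjacent member pixel (ties broken by lowest label), so
   boundaries between touching puncta follow intensity ridges; pixels
   assigned this round recruit their own neighbours within the round;
3. *formation*: the remaining candidates are grouped into connected
   components, and each isolated component of at least ``min_size``
   pixels (default 4) becomes a new punctum.  Smaller components stay
   unassigned and are reconsidered in every later round.

The final round at exactly ``t_min`` always runs, even when the step does
not land on it.  Labels are assigned in row-major discovery order and all
tie-breaks are fixed, so detection is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "DetectionParams",
    "Punctum",
    "detect_puncta",
    "single_threshold_detect",
    "filter_by_marker",
]


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of the descending-threshold sweep.

    Attributes
    ----------
    t_min
        Final (lowest) threshold of the sweep; the user-set floor that
        separates signal from background.
    t_start
        Initial threshold (default 255, the 8-bit maximum).
    step
        Per-round threshold decrement (default 1).
    min_size
        Minimum pixel count for a *new* punctum (default 4 adjacent
        pixels; expansion can grow puncta past any size).
    connectivity
        Pixel adjacency: 8 (default, includes diagonals) or 4.
    """

    t_min: int
    t_start: int = 255
    step: int = 1
    min_size: int = 4
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not (0 <= self.t_min <= self.t_start <= 255):
            raise ValueError(
                f"need 0 <= t_min <= t_start <= 255, got {self.t_min}, {self.t_start}"
            )
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class Punctum:
    """One detected punctum: a connected set of above-threshold pixels.

    ``integrated_intensity`` is the exact integer sum of channel values
    over the pixel set; ``average_intensity`` is that sum divided by the
    pixel count.
    """

    label: int
    pixel_set: frozenset[tuple[int, int]]
    area_px: int
    integrated_intensity: int
    average_intensity: float
    centroid: tuple[float, float]
    pixel_size: float = 1.0

    @property
    def area_phys(self) -> float:
        """Area in square micrometres (``area_px * pixel_size**2``)."""
        return self.area_px * self.pixel_size**2


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)


_OFFSETS_4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_OFFSETS_8 = _OFFSETS_4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def _shifted(arr: np.ndarray, dr: int, dc: int, fill) -> np.ndarray:
    """Value of the neighbour at offset (dr, dc), `fill` outside the image."""
    out = np.full_like(arr, fill)
    h, w = arr.shape
    rs_src = slice(max(dr, 0), h + min(dr, 0))
    cs_src = slice(max(dc, 0), w + min(dc, 0))
    rs_dst = slice(max(-dr, 0), h + min(-dr, 0))
    cs_dst = slice(max(-dc, 0), w + min(-dc, 0))
    out[rs_dst, cs_dst] = arr[rs_src, cs_src]
    return out


def _validate_inputs(channel: np.ndarray, region_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    channel = np.asarray(channel)
    mask = np.asarray(region_mask, dtype=bool)
    if channel.ndim != 2:
        raise ValueError(f"channel must be 2D, got shape {channel.shape}")
    if mask.shape != channel.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match channel shape {channel.shape}"
        )
    return channel.astype(np.int32, copy=False), mask


def _threshold_schedule(params: DetectionParams) -> list[int]:
    ts = list(range(params.t_start, params.t_min - 1, -params.step))
    if not ts or ts[-1] != params.t_min:
        ts.append(params.t_min)  # final round at exactly t_min always runs
    return ts


def _form_new_puncta(
    candidates: np.ndarray,
    labels: np.ndarray,
    struct: np.ndarray,
    min_size: int,
    next_label: int,
) -> int:
    """Label isolated candidate components of >= min_size pixels in place.

    New labels follow row-major order of each component's first pixel.
    """
    comp, ncomp = ndimage.label(candidates, structure=struct)
    if ncomp == 0:
        return next_label
    flat = comp.ravel()
    sizes = np.bincount(flat)
    first = np.full(ncomp + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # first occurrence (row-major) of each component id
    np.minimum.at(first, flat[nz], nz)
    order = sorted(range(1, ncomp + 1), key=lambda k: first[k])
    keep = [k for k in order if sizes[k] >= min_size]
    if keep:
        remap = np.zeros(ncomp + 1, dtype=labels.dtype)
        for k in keep:
            remap[k] = next_label
            next_label += 1
        labels += remap[comp]
    return next_label


def _expand_to_fixed_point(
    labels: np.ndarray,
    intensity: np.ndarray,
    candidates: np.ndarray,
    offsets: Sequence[tuple[int, int]],
) -> None:
    """Grow existing puncta into the candidate set until nothing changes.

    Each wave assigns, simultaneously, every candidate with an assigned
    neighbour to the punctum of its brightest assigned neighbour (ties to
    the lowest label); assignment is re-evaluated until a fixed point, so
    pixels recruited in one wave can recruit further candidates in the
    next.
    """
    big = np.iinfo(labels.dtype).max
    while candidates.any() and labels.any():
        best_int = np.full(labels.shape, -1, dtype=np.int32)
        best_lab = np.full(labels.shape, big, dtype=labels.dtype)
        for dr, dc in offsets:
            n_lab = _shifted(labels, dr, dc, 0)
            n_int = _shifted(intensity, dr, dc, -1)
            valid = n_lab > 0
            better = valid & (
                (n_int > best_int) | ((n_int == best_int) & (n_lab < best_lab))
            )
            best_int[better] = n_int[better]
            best_lab[better] = n_lab[better]
        adopt = candidates & (best_lab != big)
        if not adopt.any():
            break
        labels[adopt] = best_lab[adopt]
        candidates[adopt] = False


def _collect_puncta(
    labels: np.ndarray, intensity: np.ndarray, pixel_size: float
) -> list[Punctum]:
    n = int(labels.max(initial=0))
    if n == 0:
        return []
    idx = np.arange(1, n + 1)
    sums = ndimage.sum_labels(intensity, labels, idx)
    counts = ndimage.sum_labels(np.ones_like(intensity), labels, idx)
    centroids = ndimage.center_of_mass(np.ones_like(intensity), labels, idx)
    out = []
    rows, cols = np.nonzero(labels)
    labs = labels[rows, cols]
    order = np.argsort(labs, kind="stable")
    rows, cols, labs = rows[order], cols[order], labs[order]
    bounds = np.searchsorted(labs, np.arange(1, n + 2))
    for k in range(n):
        lo, hi = bounds[k], bounds[k + 1]
        pix = frozenset(zip(rows[lo:hi].tolist(), cols[lo:hi].tolist()))
        area = int(counts[k])
        integ = int(round(sums[k]))
        out.append(
            Punctum(
                label=k + 1,
                pixel_set=pix,
                area_px=area,
                integrated_intensity=integ,
                average_intensity=integ / area,
                centroid=(float(centroids[k][0]), float(centroids[k][1])),
                pixel_size=pixel_size,
            )
        )
    return out


def detect_puncta(
    channel: np.ndarray,
    region_mask: np.ndarray,
    params: DetectionParams,
    pixel_size: float = 1.0,
) -> tuple[list[Punctum], np.ndarray]:
    """Detect puncta in ``channel`` restricted to ``region_mask``.

    Runs the descending multi-threshold sweep described in the module
    docstring and returns the detected puncta together with the label
    map (0 = unassigned, k > 0 = punctum k).

    Rounds at thresholds where no new candidate pixel can appear are
    skipped; because each processed round runs expansion to a fixed
    point, this is an exact shortcut, not an approximation.
    """
    intensity, mask = _validate_inputs(channel, region_mask)
    labels = np.zeros(intensity.shape, dtype=np.int32)
    if not mask.any():
        return [], labels
    struct = _structure(params.connectivity)
    offsets = _OFFSETS_8 if params.connectivity == 8 else _OFFSETS_4
    in_mask_vals = np.unique(intensity[mask])

    next_label = 1
    prev_t: int | None = None
    for t in _threshold_schedule(params):
        upper = np.inf if prev_t is None else prev_t
        if not np.any((in_mask_vals >= t) & (in_mask_vals < upper)):
            continue  # no new candidates; previous fixed point still holds
        prev_t = t
        candidates = mask & (labels == 0) & (intensity >= t)
        _expand_to_fixed_point(labels, intensity, candidates, offsets)
        next_label = _form_new_puncta(
            candidates, labels, struct, params.min_size, next_label
        )
    return _collect_puncta(labels, intensity, pixel_size), labels


def single_threshold_detect(
    channel: np.ndarray,
    region_mask: np.ndarray,
    t: int,
    min_size: int = 4,
    connectivity: int = 8,
    pixel_size: float = 1.0,
) -> tuple[list[Punctum], np.ndarray]:
    """Baseline single-round detection at one threshold.

    Connected components of in-mask pixels with intensity ``>= t``;
    components of at least ``min_size`` pixels become puncta.  This is
    the classical particle-analysis baseline that merges adjacent bright
    puncta, used as comparison and oracle for :func:`detect_puncta`.
    """
    intensity, mask = _validate_inputs(channel, region_mask)
    labels = np.zeros(intensity.shape, dtype=np.int32)
    candidates = mask & (intensity >= t)
    _form_new_puncta(candidates, labels, _structure(connectivity), min_size, 1)
    return _collect_puncta(labels, intensity, pixel_size), labels


def filter_by_marker(
    puncta: Iterable[Punctum],
    marker_channel: np.ndarray,
    marker_threshold: int,
    min_overlap_fraction: float = 0.0,
) -> list[Punctum]:
    """Keep only puncta overlapping the transfection-marker channel.

    A punctum belongs to the measured (transfected) neuron when its
    pixels overlap the cell-fill marker.  A punctum is kept iff its
    overlap fraction — pixels with marker intensity ``>= marker_threshold``
    divided by its area — is positive *and* at least
    ``min_overlap_fraction``.  The default (0.0) therefore keeps any
    punctum with a single overlapping pixel.
    """
    marker = np.asarray(marker_channel)
    if not 0.0 <= min_overlap_fraction <= 1.0:
        raise ValueError("min_overlap_fraction must be in [0, 1]")
    hot = marker >= marker_threshold
    kept = []
    for p in puncta:
        rows, cols = zip(*p.pixel_set)
        try:
            frac = hot[np.array(rows), np.array(cols)].sum() / p.area_px
        except IndexError as exc:
            raise ValueError("marker channel shape does not cover puncta") from exc
        if frac > 0 and frac >= min_overlap_fraction:
            kept.append(p)
    return kept
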