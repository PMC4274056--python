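"""Dendritic spine morphometry and rule-based classification.

Spines are marked manually with landmark points: a *base* on the
dendrite shaft, a *tip* at the spine head apex, and optional point pairs
spanning the widest part of the head and the narrowest part of the neck.
From these the spine's length (base-tip), head width and neck width are
computed in micrometres and the spine is sorted into one of the four
conventional morphological classes:

* **mushroom** — bulbous head on a thin neck (high head/neck ratio);
* **thin** — long with a small head;
* **stubby** — short, no distinct neck (length comparable to width);
* **filopodia** — long headless protrusion (head/neck ratio near 1).

No consensus quantitative thresholds exist in the literature; the
defaults in :class:`SpineRules` are this package's own, are fully
configurable, and are echoed into every exported run's metadata so
results are self-describing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Spine",
    "SpineRules",
    "SPINE_TYPES",
    "spine_dims_from_landmarks",
    "classify_spine",
    "spine_summary",
]

SPINE_TYPES = ("mushroom", "thin", "stubby", "filopodia")


@dataclass(frozen=True)
class SpineRules:
    """Classification thresholds (all configurable, units noted).

    Rules are evaluated in fixed order — filopodia, mushroom, stubby,
    thin — so every measurement triple maps to exactly one class:

    1. filopodia: head/neck ratio < ``filopodia_max_head_neck_ratio``
       and length >= ``filopodia_min_length_um``;
    2. mushroom: head/neck ratio >= ``mushroom_head_neck_ratio``;
    3. stubby: length/head ratio <= ``stubby_max_length_head_ratio``;
    4. thin otherwise.

    When the neck pair is missing the head/neck ratio is unavailable;
    the mushroom rule then fires only if the head width alone is at
    least ``mushroom_head_fallback_um``, and the filopodia ratio clause
    is treated as satisfied when no head was measured at all (a headless
    protrusion).
    """

    mushroom_head_neck_ratio: float = 1.5
    filopodia_max_head_neck_ratio: float = 1.2
    filopodia_min_length_um: float = 2.0
    stubby_max_length_head_ratio: float = 1.0
    mushroom_head_fallback_um: float = 0.6

    def __post_init__(self) -> None:
        vals = asdict(self)
        if any(v <= 0 for v in vals.values()):
            raise ValueError("all spine-rule thresholds must be positive")
        if not self.filopodia_max_head_neck_ratio < self.mushroom_head_neck_ratio:
            raise ValueError(
                "filopodia_max_head_neck_ratio must be below mushroom_head_neck_ratio"
            )


@dataclass
class Spine:
    """One spine: landmark-derived dimensions plus its class.

    ``category_source`` records whether the class came from the rules
    (``auto``) or was set by the user (``manual``); manual labels are
    never overwritten by re-classification.
    """

    id: str
    dendrite_id: str
    length: float  # µm, base -> tip
    head_width: float | None = None  # µm
    neck_width: float | None = None  # µm
    category: str = "thin"
    category_source: str = "auto"
    landmarks: dict | None = None

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValueError(f"spine {self.id}: length must be positive")
        for w in (self.head_width, self.neck_width):
            if w is not None and w < 0:
                raise ValueError(f"spine {self.id}: widths must be >= 0")
        if self.category not in SPINE_TYPES:
            raise ValueError(f"spine {self.id}: unknown category {self.category!r}")
        if self.category_source not in ("auto", "manual"):
            raise ValueError("category_source must be 'auto' or 'manual'")


def _dist(a: Sequence[float], b: Sequence[float]) -> float:
    return math.hypot(a[0] - b[0], a[1] - b[1])


def spine_dims_from_landmarks(
    landmarks: Mapping, pixel_size: float = 1.0
) -> tuple[float, float | None, float | None]:
    """(length, head_width, neck_width) in µm from landmark points.

    ``landmarks`` maps ``base``/``tip`` to points and optionally
    ``head``/``neck`` to point pairs; distances are Euclidean in pixels
    times ``pixel_size``.  Missing pairs yield ``None`` widths.
    """
    base, tip = landmarks["base"], landmarks["tip"]
    length = _dist(base, tip) * pixel_size
    if length == 0:
        raise ValueError("spine base and tip coincide")

    def pair_dist(key: str) -> float | None:
        pair = landmarks.get(key)
        if pair is None:
            return None
        return _dist(pair[0], pair[1]) * pixel_size

    return length, pair_dist("head"), pair_dist("neck")


def classify_spine(
    length: float,
    head_width: float | None,
    neck_width: float | None,
    rules: SpineRules = SpineRules(),
) -> str:
    """Classify one spine; see :class:`SpineRules` for the rule order."""
    if length is None or not length > 0:
        raise ValueError("classification requires a positive length")
    ratio = None
    if head_width is not None and neck_width is not None and neck_width > 0:
        ratio = head_width / neck_width
    elif head_width is not None and neck_width == 0:
        ratio = math.inf

    # 1. filopodia: long, headless or near-uniform width
    filo_thin = (
        ratio < rules.filopodia_max_head_neck_ratio if ratio is not None else head_width is None
    )
    if filo_thin and length >= rules.filopodia_min_length_um:
        return "filopodia"
    # 2. mushroom: pronounced head
    if ratio is not None:
        if ratio >= rules.mushroom_head_neck_ratio:
            return "mushroom"
    elif head_width is not None and head_width >= rules.mushroom_head_fallback_um:
        return "mushroom"
    # 3. stubby: about as long as wide
    if head_width is not None and head_width > 0 and length / head_width <= rules.stubby_max_length_head_ratio:
        return "stubby"
    # 4. default
    return "thin"


def auto_classify(spine: Spine, rules: SpineRules = SpineRules()) -> Spine:
    """Apply the rules to a spine unless it carries a manual label."""
    if spine.category_source != "manual":
        spine.category = classify_spine(
            spine.length, spine.head_width, spine.neck_width, rules
        )
        spine.category_source = "auto"
    return spine


def spine_summary(spines: Iterable[Spine], dendrite_length: float) -> dict:
    """Per-dendrite spine statistics.

    Densities are counts per µm of dendrite; per-type densities sum to
    the total by construction.  Means are taken over present values
    (``None`` when no spine carries the measurement).
    """
    if not dendrite_length > 0:
        raise ValueError("dendrite_length must be positive")
    spines = list(spines)
    n = len(spines)

    def mean_of(vals: list[float]) -> float | None:
        return sum(vals) / len(vals) if vals else None

    by_type = {t: sum(1 for s in spines if s.category == t) for t in SPINE_TYPES}
    return {
        "spine_count": n,
        "spine_density_per_um": n / dendrite_length,
        "density_by_type_per_um": {t: k / dendrite_length for t, k in by_type.items()},
        "count_by_type": by_type,
        "mean_length_um": mean_of([s.length for s in spines]),
        "mean_head_width_um": mean_of(
            [s.head_width for s in spines if s.head_width is not None]
        ),
        "mean_neck_width_um": mean_of(
            [s.neck_width for s in spines if s.neck_width is not None]
        ),
    }
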