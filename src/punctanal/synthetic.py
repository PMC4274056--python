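"""Synthetic fluorescence images with known ground truth.

Real puncta images are not redistributable, so detection and
quantification are validated on generated ones: isotropic 2D Gaussian
blobs (the puncta) on a flat background, optionally with bounded uniform
noise and a filled marker-channel polygon standing in for the
transfection marker / cell fill.  The pixel model is

    value(y, x) = clip(background + sum_b A_b * exp(-d_b^2 / (2 sigma_b^2))
                       + noise, 0, 255)

rounded to the nearest integer (clipping at 255 is allowed and simply
saturates).  Every generator takes an explicit RNG seed and the same
spec + seed reproduces the image bit for bit.

The ground-truth record carries each blob's center and, for every blob
pair, the *saddle* — the minimum of the continuous noiseless field along
the straight line between the two peaks.  Whether two adjacent blobs
merge at a threshold t is governed by this saddle: they form one
connected component iff saddle >= t.  :func:`two_blob_merge_case` uses
this to construct images guaranteed to exhibit the merge artefact
(single-threshold detection sees 1 object where there are 2 puncta), and
well-separated controls where both detectors agree.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .image_io import ImageFrame

__all__ = [
    "Blob",
    "FixtureSpec",
    "TwoBlobCase",
    "generate_fixture",
    "two_blob_merge_case",
    "random_fixture_spec",
    "separated_fixture_spec",
]


@dataclass(frozen=True)
class Blob:
    """One planted punctum: isotropic Gaussian intensity profile."""

    center: tuple[float, float]  # (row, col)
    amplitude: float  # peak above background, 0-255
    sigma: float  # px

    def __post_init__(self) -> None:
        if not 0 < self.amplitude <= 255:
            raise ValueError("amplitude must be in (0, 255]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class FixtureSpec:
    """Full recipe for one synthetic image (JSON-serializable)."""

    shape: tuple[int, int]
    blobs: list[Blob] = field(default_factory=list)
    background: float = 0.0
    noise_model: str = "none"  # "none" | "uniform"
    noise_amplitude: int = 0  # uniform noise in [-k, k]
    seed: int = 0
    dendrite_centerlines: list[list[tuple[float, float]]] = field(default_factory=list)
    marker_polygon: list[tuple[float, float]] | None = None
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        h, w = self.shape
        if h < 1 or w < 1:
            raise ValueError("image shape must be positive")
        if self.noise_model not in ("none", "uniform"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        for b in self.blobs:
            r, c = b.center
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"blob at {b.center} lies outside {self.shape}")

    def to_json(self) -> str:
        doc = asdict(self)
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str | Path) -> "FixtureSpec":
        if isinstance(text, Path):
            text = text.read_text()
        doc = json.loads(text)
        doc["blobs"] = [
            Blob(center=tuple(b["center"]), amplitude=b["amplitude"], sigma=b["sigma"])
            for b in doc.get("blobs", [])
        ]
        doc["shape"] = tuple(doc["shape"])
        if doc.get("marker_polygon"):
            doc["marker_polygon"] = [tuple(v) for v in doc["marker_polygon"]]
        doc["dendrite_centerlines"] = [
            [tuple(v) for v in line] for line in doc.get("dendrite_centerlines", [])
        ]
        return cls(**doc)


def _field(spec: FixtureSpec) -> np.ndarray:
    """Continuous noiseless intensity field sampled at pixel centers."""
    h, w = spec.shape
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    out = np.full((h, w), float(spec.background))
    for b in spec.blobs:
        d2 = (rr - b.center[0]) ** 2 + (cc - b.center[1]) ** 2
        out += b.amplitude * np.exp(-d2 / (2.0 * b.sigma**2))
    return out


def field_at(spec: FixtureSpec, points: np.ndarray) -> np.ndarray:
    """Continuous noiseless field at arbitrary (row, col) points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.full(pts.shape[0], float(spec.background))
    for b in spec.blobs:
        d2 = (pts[:, 0] - b.center[0]) ** 2 + (pts[:, 1] - b.center[1]) ** 2
        out += b.amplitude * np.exp(-d2 / (2.0 * b.sigma**2))
    return out


def pair_saddle(spec: FixtureSpec, i: int, j: int, n_samples: int = 513) -> float:
    """Minimum of the continuous field on the segment between blob i and j."""
    a = np.asarray(spec.blobs[i].center, dtype=float)
    b = np.asarray(spec.blobs[j].center, dtype=float)
    ts = np.linspace(0.0, 1.0, n_samples)[:, None]
    return float(field_at(spec, a[None, :] * (1 - ts) + b[None, :] * ts).min())


def generate_fixture(spec: FixtureSpec) -> tuple[ImageFrame, dict]:
    """Render a spec into an image frame plus its ground-truth record.

    With a marker polygon the frame is RGB (marker filled at 255 in R,
    signal in G, B zero); otherwise single-channel GRAY.  Ground truth
    lists blob centers/amplitudes/sigmas and all pairwise saddles.
    """
    base = _field(spec)
    if spec.noise_model == "uniform" and spec.noise_amplitude > 0:
        rng = np.random.default_rng(spec.seed)
        k = int(spec.noise_amplitude)
        base = base + rng.integers(-k, k + 1, size=base.shape)
    signal = np.clip(np.round(base), 0, 255).astype(np.uint8)

    if spec.marker_polygon is not None:
        from .regions import rasterize_region

        marker = np.where(rasterize_region(spec.marker_polygon, spec.shape), 255, 0)
        pixels = np.stack(
            [marker.astype(np.uint8), signal, np.zeros_like(signal)], axis=-1
        )
        frame = ImageFrame(pixels=pixels, channels=("R", "G", "B"), pixel_size=spec.pixel_size)
    else:
        frame = ImageFrame(pixels=signal, channels=("GRAY",), pixel_size=spec.pixel_size)

    nb = len(spec.blobs)
    truth = {
        "centers": [list(b.center) for b in spec.blobs],
        "amplitudes": [b.amplitude for b in spec.blobs],
        "sigmas": [b.sigma for b in spec.blobs],
        "background": spec.background,
        "saddles": {
            f"{i}-{j}": pair_saddle(spec, i, j)
            for i in range(nb)
            for j in range(i + 1, nb)
        },
    }
    return frame, truth


@dataclass
class TwoBlobCase:
    """A two-blob spec with its analytically certified expected counts."""

    spec: FixtureSpec
    saddle: float
    expected_single: int  # puncta found by one round at t_min
    expected_multi: int  # puncta found by the descending sweep


def _discrete_components(img: np.ndarray, t: float, min_size: int) -> int:
    comp, n = ndimage.label(img >= t, structure=np.ones((3, 3), bool))
    if n == 0:
        return 0
    sizes = np.bincount(comp.ravel())[1:]
    return int((sizes >= min_size).sum())


def two_blob_merge_case(
    separation_px: float,
    peaks: tuple[float, float],
    sigma: float,
    t_min: int,
    min_size: int = 4,
) -> TwoBlobCase:
    """Construct a certified two-blob fixture for the merge artefact.

    Two Gaussian blobs at the given separation, noiseless, background 0.
    The connecting saddle is computed from the continuous Gaussian-sum
    field and the rendered image is checked with plain connected-
    component labeling (independent of the sweep detector):

    * saddle strictly above ``t_min`` (merge case): at ``t_min`` the
      blobs form one component, but at some higher threshold two
      isolated >= ``min_size`` components exist — expected counts are
      (single=1, multi=2);
    * saddle strictly below ``t_min`` (well-separated control): two
      components already at ``t_min`` — expected counts (2, 2).

    Combinations where the saddle reaches ``min(peaks)``, falls within
    one intensity unit of ``t_min`` (ambiguous after rounding), or whose
    rendering fails the component check raise ``ValueError`` reporting
    the computed saddle.
    """
    if separation_px <= 0:
        raise ValueError("separation must be positive")
    pad = int(math.ceil(4 * sigma + 4))
    h = 2 * pad + 1
    w = int(math.ceil(separation_px)) + 2 * pad + 1
    r0 = float(pad)
    c0 = float(pad)
    spec = FixtureSpec(
        shape=(h, w),
        blobs=[
            Blob(center=(r0, c0), amplitude=float(peaks[0]), sigma=sigma),
            Blob(center=(r0, c0 + separation_px), amplitude=float(peaks[1]), sigma=sigma),
        ],
        background=0.0,
        seed=0,
    )
    saddle = pair_saddle(spec, 0, 1)
    lo_peak = min(peaks)
    if saddle >= lo_peak - 1:
        raise ValueError(
            f"infeasible: saddle {saddle:.1f} reaches the lower peak {lo_peak}"
        )
    if abs(saddle - t_min) < 1:
        raise ValueError(
            f"infeasible: saddle {saddle:.1f} within one intensity unit of t_min {t_min}"
        )
    img = _field(spec)  # continuous; rounding handled by >= comparisons below
    img = np.round(img)
    if saddle > t_min:
        if _discrete_components(img, t_min, min_size) != 1:
            raise ValueError(
                f"infeasible: saddle {saddle:.1f} > t_min but blobs not merged at {t_min}"
            )
        split_ok = any(
            _discrete_components(img, t, min_size) >= 2
            for t in range(int(math.ceil(saddle)) + 1, int(math.floor(lo_peak)) + 1)
        )
        if not split_ok:
            raise ValueError(
                f"infeasible: no threshold above saddle {saddle:.1f} yields two "
                f">= {min_size}-pixel clusters"
            )
        return TwoBlobCase(spec=spec, saddle=saddle, expected_single=1, expected_multi=2)
    if _discrete_components(img, t_min, min_size) != 2:
        raise ValueError(
            f"infeasible: saddle {saddle:.1f} < t_min but blobs not separate at {t_min}"
        )
    return TwoBlobCase(spec=spec, saddle=saddle, expected_single=2, expected_multi=2)


def random_fixture_spec(
    seed: int,
    shape: tuple[int, int] = (256, 256),
    n_blobs: tuple[int, int] = (5, 30),
    amplitude: tuple[float, float] = (90.0, 250.0),
    sigma: tuple[float, float] = (1.0, 3.0),
    background: float = 0.0,
    noise_amplitude: int = 0,
    edge_margin: float = 8.0,
) -> FixtureSpec:
    """A random blob field with no separation constraint (blobs may merge)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_blobs[0], n_blobs[1] + 1))
    h, w = shape
    blobs = [
        Blob(
            center=(
                float(rng.uniform(edge_margin, h - 1 - edge_margin)),
                float(rng.uniform(edge_margin, w - 1 - edge_margin)),
            ),
            amplitude=float(rng.uniform(*amplitude)),
            sigma=float(rng.uniform(*sigma)),
        )
        for _ in range(n)
    ]
    return FixtureSpec(
        shape=shape,
        blobs=blobs,
        background=background,
        noise_model="uniform" if noise_amplitude else "none",
        noise_amplitude=noise_amplitude,
        seed=seed,
    )


def separated_fixture_spec(
    seed: int,
    t_min: int,
    shape: tuple[int, int] = (256, 256),
    n_blobs: tuple[int, int] = (5, 15),
    amplitude_margin: float = 50.0,
    sigma: tuple[float, float] = (1.2, 2.2),
    noise_amplitude: int = 4,
    max_tries: int = 500,
) -> FixtureSpec:
    """A blob field guaranteed recoverable at ``t_min``: every pairwise
    saddle sits below ``t_min`` by more than the noise amplitude, and
    every blob's four nearest neighbours of the peak clear ``t_min``
    even under worst-case noise (so each blob yields >= 4 adjacent
    above-threshold pixels).  Centers are rejection-sampled until the
    saddle condition holds.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_blobs[0], n_blobs[1] + 1))
    h, w = shape
    margin = 10.0
    lo_amp = t_min + amplitude_margin
    for _ in range(max_tries):
        sigmas = rng.uniform(*sigma, size=n)
        amps = rng.uniform(lo_amp, 250.0, size=n)
        # at distance 1 from the peak the profile must still clear t_min + noise
        ok_amp = amps * np.exp(-1.0 / (2.0 * sigmas**2)) >= t_min + noise_amplitude + 2
        if not ok_amp.all():
            continue
        min_dist = 6.0 * float(sigmas.max())
        centers = []
        for _ in range(20 * n):
            cand = (rng.uniform(margin, h - 1 - margin), rng.uniform(margin, w - 1 - margin))
            if all(math.dist(cand, c) >= min_dist for c in centers):
                centers.append(cand)
            if len(centers) == n:
                break
        if len(centers) < n:
            continue
        spec = FixtureSpec(
            shape=shape,
            blobs=[
                Blob(center=(float(r), float(c)), amplitude=float(a), sigma=float(s))
                for (r, c), a, s in zip(centers, amps, sigmas)
            ],
            background=0.0,
            noise_model="uniform" if noise_amplitude else "none",
            noise_amplitude=noise_amplitude,
            seed=seed,
        )
        saddles = [pair_saddle(spec, i, j) for i in range(n) for j in range(i + 1, n)]
        if all(s < t_min - noise_amplitude - 1 for s in saddles):
            return spec
    raise RuntimeError("could not place separated blobs; relax the parameters")
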