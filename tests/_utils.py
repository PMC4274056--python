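"""Shared test helpers: independent brute-force geometry oracle and a
builder for dendrite regions with a known number of attached puncta."""

import numpy as np

from punctanal.detection import DetectionParams, detect_puncta
from punctanal.regions import DendriteRegion, attach_puncta


def point_in_polygon_evenodd(r, c, verts):
    """Brute-force even-odd ray-crossing test (independent oracle)."""
    inside = False
    n = len(verts)
    for i in range(n):
        r1, c1 = verts[i]
        r2, c2 = verts[(i + 1) % n]
        if (r1 > r) != (r2 > r):
            c_cross = c1 + (r - r1) * (c2 - c1) / (r2 - r1)
            if c < c_cross:
                inside = not inside
    return inside


def make_dendrite(n_puncta, length_px, dend_id="d1", group="g", pixel_size=1.0):
    """Dendrite along a row with n well-separated square puncta attached."""
    h = 40
    w = int(length_px) + 10
    ch = np.zeros((h, w), dtype=np.uint8)
    assert 3 * n_puncta + 4 <= length_px + 8, "too many puncta for this length"
    for i in range(n_puncta):
        c = 6 + i * 3  # 2-px blocks separated by a 1-px gap
        ch[18:20, c : c + 2] = 100 + i
    d = DendriteRegion(
        id=dend_id,
        centerline=[(19.0, 3.0), (19.0, 3.0 + length_px)],
        half_width=6.0,
        group=group,
        pixel_size=pixel_size,
    )
    mask = d.mask(ch.shape)
    puncta, _ = detect_puncta(ch, mask, DetectionParams(t_min=70), pixel_size)
    assert len(puncta) == n_puncta
    attach_puncta(d, puncta, mask)
    return d, ch
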