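import json
from pathlib import Path

import numpy as np
import pytest

from punctanal import FixtureSpec, Blob, generate_fixture, save_image


@pytest.fixture
def full_mask():
    def make(shape):
        return np.ones(shape, dtype=bool)

    return make


@pytest.fixture
def two_blob_frame():
    """Noiseless pair of close Gaussian blobs whose saddle exceeds 70."""
    spec = FixtureSpec(
        shape=(21, 27),
        blobs=[Blob((10, 10), 200, 1.5), Blob((10, 15), 180, 1.5)],
        seed=0,
    )
    frame, truth = generate_fixture(spec)
    return frame, truth


@pytest.fixture
def batch_dir(tmp_path):
    """Two fixture images with ROI sidecars and a batch config on disk."""

    def centerline(r):
        return [[r, 20.0], [r, 235.0]]

    for i, seed in enumerate([11, 12]):
        spec = FixtureSpec(
            shape=(128, 256),
            blobs=[
                Blob((60.0 + 4 * (j % 3), 30.0 + 22 * j), 150 + 8 * j, 1.6)
                for j in range(9)
            ],
            marker_polygon=[[40.0, 5.0], [40.0, 250.0], [90.0, 250.0], [90.0, 5.0]],
            seed=seed,
        )
        frame, _ = generate_fixture(spec)
        save_image(frame, tmp_path / f"img{i}.tif")
        rois = {
            "regions": [
                {
                    "id": "d1",
                    "kind": "dendrite",
                    "mode": "fixed_width",
                    "centerline": centerline(62.0),
                    "half_width_um": 4.0,
                    "group": "transfected",
                },
                {
                    "id": "sp1",
                    "kind": "spine",
                    "dendrite": "d1",
                    "landmarks": {
                        "base": [62, 40],
                        "tip": [59, 40],
                        "head": [[59, 39], [59, 41]],
                        "neck": [[61, 39.6], [61, 40.4]],
                    },
                },
            ]
        }
        (tmp_path / f"img{i}.rois.json").write_text(json.dumps(rois))
    cfg = {
        "t_min": 70,
        "channel": "G",
        "marker_channel": "R",
        "marker_threshold": 50,
        "pixel_size_um": 1.0,
        "images": str(tmp_path / "*.tif"),
        "out_dir": str(tmp_path / "out"),
    }
    cfg_path = tmp_path / "config.json"
    cfg_path.write_text(json.dumps(cfg))
    return tmp_path, cfg_path
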