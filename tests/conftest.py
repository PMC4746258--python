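"""Shared fixtures: toy rasters, a small synthetic tissue, on-disk image sets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import hypoquant as hq
from hypoquant.synthetic_tissue import RingSpec, TissueSpec


@pytest.fixture(scope="session")
def toys():
    return hq.generate_toy_fixtures()


def small_tissue_spec(seed: int, snr: float | None = None, radius_scale: float = 1.0) -> TissueSpec:
    """Fast 3-ring, ~45-cell tissue on a 256×256 frame for pipeline tests."""
    rings = []
    for name, ri, ro, n, wt, wi, li, sw in (
        ("xylem", 0.0, 35.0, 12, 3, 70.0, 10.0, 100.0),
        ("phloem", 35.0, 60.0, 16, 2, 55.0, 12.0, 0.0),
        ("cortex", 60.0, 85.0, 16, 2, 45.0, 14.0, 0.0),
    ):
        noise = wi / snr if snr else 0.0
        rings.append(
            RingSpec(
                class_name=name,
                r_inner_um=ri * radius_scale,
                r_outer_um=ro * radius_scale,
                n_cells=n,
                wall_thickness_px=wt,
                wall_intensity=wi,
                wall_noise_sd=noise,
                lumen_intensity=li,
                lumen_noise_sd=noise,
                signal_wall=sw,
            )
        )
    return TissueSpec(
        size_px=256,
        pixel_size_um=0.7,
        center_xy=(128.0, 128.0),
        rings=tuple(rings),
        seed=seed,
        signal_background=5.0,
    )


@pytest.fixture(scope="session")
def small_tissue():
    """(image, ground truth) for the small noiseless 3-ring tissue."""
    return hq.generate_radial_tissue(small_tissue_spec(seed=3))


@pytest.fixture(scope="session")
def small_segmented(small_tissue):
    """Segmentation + frame + feature table for the small tissue."""
    image, truth = small_tissue
    seg = hq.segment_image(image.reference)
    frame = hq.TissueFrame(truth.spec.center_xy, truth.spec.pixel_size_um)
    table = hq.compute_feature_table(seg, image.reference, frame)
    return seg, frame, table


@pytest.fixture
def image_folder(tmp_path):
    """A source folder with three parseable synthetic images on disk."""
    src = tmp_path / "images"
    src.mkdir()
    names = [
        "C01R1_LM10_Col_21-day-old_Hyp_BR1.tif",
        "C01R2_LM10_Col_21-day-old_Hyp_BR2.tif",
        "C02R1_LM10_mut_21-day-old_Hyp_BR1.tif",
    ]
    for i, name in enumerate(names):
        image, _ = hq.generate_radial_tissue(small_tissue_spec(seed=20 + i))
        hq.save_two_channel_image(src / name, image)
    return src, names


def annotate_from_truth(table: pd.DataFrame, roic: np.ndarray, truth, image_id=None) -> pd.DataFrame:
    """Training annotations from ground truth via majority pixel overlap."""
    mapping = hq.majority_true_classes(roic, truth)
    rows = [
        {"cell_id": int(k), "class_label": mapping[k]}
        for k in table.index
        if mapping.get(int(k))
    ]
    ann = pd.DataFrame(rows)
    if image_id is not None:
        ann.insert(0, "image_id", image_id)
    return ann
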