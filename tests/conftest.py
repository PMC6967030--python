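import math

import numpy as np
import pytest

from infiltra import density_quant, image_quant, synthgen


@pytest.fixture(scope="session")
def noiseless_image():
    spec = synthgen.SyntheticImageSpec(
        width=512,
        height=512,
        n_cd1a=50,
        n_cd3cd8neg=10,
        n_cd3cd8pos=5,
        noise_sd=0.0,
        autofluorescence_blob_count=0,
        seed=7,
    )
    image, truth = synthgen.generate_lesion_image(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def noisy_image():
    spec = synthgen.SyntheticImageSpec(
        width=512,
        height=512,
        n_cd1a=50,
        n_cd3cd8neg=10,
        n_cd3cd8pos=5,
        noise_sd=0.02,
        bleach_factor=0.75,
        autofluorescence_blob_count=3,
        seed=11,
    )
    image, truth = synthgen.generate_lesion_image(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def image_cohort():
    """60 synthetic patients, one default-noise image each, pushed through
    the automated area pipeline and the component-count emulation.

    Returns a list of per-patient dicts with ground truth and both measured
    quantities.
    """
    rng = np.random.default_rng(20)
    thresholds = image_quant.ColorThresholds()
    rows = []
    for i in range(60):
        ratio = float(np.exp(rng.normal(math.log(0.12), 1.0)))
        n_green = 60
        n_pos = int(np.clip(round(ratio * n_green), 1, 25))
        n_neg = int(np.clip(round(2.0 * ratio * n_green), 1, 30))
        spec = synthgen.SyntheticImageSpec(
            width=256,
            height=256,
            n_cd1a=n_green,
            n_cd3cd8neg=n_neg,
            n_cd3cd8pos=n_pos,
            noise_sd=0.02,
            bleach_factor=0.8,
            autofluorescence_blob_count=2,
            seed=1000 + i,
        )
        image, truth = synthgen.generate_lesion_image(spec)
        masks = image_quant.classify_pixels(image, thresholds)
        result = image_quant.compute_area_ratios(
            image_quant.measure_cumulative_areas(masks, image_id=f"P{i:03d}")
        )
        counts = density_quant.count_cells_from_masks(masks)
        ratios = density_quant.compute_density_ratios(counts)
        rows.append(
            {
                "patient_id": f"P{i:03d}",
                "true_count_ratio": truth.true_counts["CD3CD8pos"] / truth.true_counts["CD1a"],
                "true_area_ratio": truth.true_pixel_area["CD3CD8pos"] / truth.true_pixel_area["CD1a"],
                "area_ratio": result.cd8_to_cd1a_ratio,
                "count_ratio": ratios.cd8_ratio,
            }
        )
    return rows
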