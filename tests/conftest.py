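"""Shared fixtures: the reference phantom and a compact fast phantom."""

import numpy as np
import pytest

from marrowmap import (
    BoneElement,
    PhantomSpec,
    generate_phantom,
    reference_phantom_spec,
    run_pipeline,
    sample_training_voxels,
)
from marrowmap.config import PipelineConfig


def small_phantom_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Compact two-vertebrae + long-bone phantom for fast unit tests.

    40 x 40 x 80 voxels at 3 mm; vertebrae all red marrow, the long bone
    mostly yellow. Generates in well under a second.
    """
    elements = [
        BoneElement("cylinder", (60.0, 60.0, 90.0), (15.0, 30.0), 3.0, "vertebra_lumbar"),
        BoneElement("cylinder", (60.0, 60.0, 132.0), (15.0, 30.0), 3.0, "vertebra_thoracic"),
        BoneElement("cylinder", (60.0, 60.0, 200.0), (12.0, 60.0), 4.0, "long_bone"),
    ]
    params = dict(
        shape=(40, 40, 80),
        spacing=(3.0, 3.0, 3.0),
        elements=elements,
        red_fraction_per_tag={
            "vertebra_lumbar": 1.0,
            "vertebra_thoracic": 1.0,
            "long_bone": 0.2,
        },
        blur_fwhm_mm=4.0,
        seed=seed,
    )
    params.update(overrides)
    return PhantomSpec(**params)


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(small_phantom_spec(seed=11))


@pytest.fixture(scope="session")
def ref_phantom():
    """The canonical 96x96x220 @ 2 mm reference phantom."""
    return generate_phantom(reference_phantom_spec(seed=0))


@pytest.fixture(scope="session")
def ref_result(ref_phantom):
    """Full pipeline run on the reference phantom with default config."""
    config = PipelineConfig()
    training = sample_training_voxels(
        ref_phantom.ct,
        ref_phantom.truth_cortical,
        ref_phantom.truth_trabecular,
        n=config.training_size,
        seed=config.seed,
    )
    rois = {"vertebrae": ref_phantom.vertebral_roi, "skull": ref_phantom.skull_roi}
    return run_pipeline(ref_phantom.ct, ref_phantom.pet, training, rois, config=config)
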