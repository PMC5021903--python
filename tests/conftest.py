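import numpy as np
import pytest

from foveafinder.core import Appearance
from foveafinder.detect import PipelineConfig
from foveafinder.preprocess import (apply_mask, build_fovea_mask,
                                    correct_axial_motion, correct_tilt,
                                    denoise_speckle)
from foveafinder.synthetic import generate_phantom, make_spec


@pytest.fixture(scope="session")
def clean_phantoms():
    """One clean (noise-free, artefact-free) phantom per appearance class,
    with seed 0."""
    out = {}
    for app in Appearance:
        spec = make_spec(app, seed=0, noise_level="none")
        out[app] = generate_phantom(spec)
    return out


@pytest.fixture(scope="session")
def preprocessed(clean_phantoms):
    """Clean phantoms run through the preprocessing chain up to the masked
    foveal cylinder."""
    cfg = PipelineConfig()
    out = {}
    for app, (vol, truth) in clean_phantoms.items():
        corrected, _ = correct_axial_motion(vol)
        corrected, _ = correct_tilt(corrected)
        denoised = denoise_speckle(corrected)
        fmask = build_fovea_mask(vol.geometry)
        masked = apply_mask(denoised, fmask)
        out[app] = {"masked": masked, "mask": fmask, "truth": truth, "cfg": cfg}
    return out
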