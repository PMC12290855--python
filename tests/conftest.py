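import numpy as np
import pytest

from cordmap import synth
from cordmap.types import BoldImage


@pytest.fixture(scope="session")
def default_phantom():
    """One synthetic subject at the default study conditions."""
    config = synth.PhantomConfig(rng_seed=1)
    brain, cord, truth = synth.generate_phantom(config)
    return config, brain, cord, truth


@pytest.fixture(scope="session")
def denoised_phantom(default_phantom):
    """Default subject after confound regression (filtered + unfiltered)."""
    import warnings

    from cordmap import denoise, nuisance

    config, brain, cord, truth = default_phantom
    card, belt = truth.physio
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for organ, img in (("brain", brain), ("cord", cord)):
            design = nuisance.build_design(
                img, card, belt, truth.csf_masks[organ], truth.motion[organ]
            )
            out[organ] = {
                "filtered": denoise.denoise(img, design),
                "unfiltered": denoise.denoise(img, design, apply_bandpass=False),
                "design": design,
            }
    return config, truth, out


def make_bold(data, tr=1.55, organ="brain"):
    data = np.asarray(data, dtype=float)
    return BoldImage(data, tr, np.eye(4), organ)
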