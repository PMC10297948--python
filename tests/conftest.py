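"""Shared fixtures: one small synthetic slide reused across image tests."""

import numpy as np
import pytest

from foltme import slidesim, stains


@pytest.fixture(scope="session")
def slide_config():
    # 400 px at 1 um/px: ROI area = 2.56 HPF, cells ~3.5 um radius
    return slidesim.SlideConfig(roi_size=400, pixel_size_um=1.0,
                                target_if_fraction=0.5)


@pytest.fixture(scope="session")
def slide_truth(slide_config):
    return slidesim.generate_slide(slide_config, seed=3)


@pytest.fixture(scope="session")
def rendered_rounds(slide_truth):
    return {r: slidesim.render_round(slide_truth, r)
            for r in sorted({r for r, _ in slide_truth.panel.values()})}


@pytest.fixture(scope="session")
def unmixed_rounds(slide_truth, rendered_rounds):
    M = stains.StainMatrix.hax()
    out = {}
    for r, img in rendered_rounds.items():
        conc = stains.deconvolve(stains.rgb_to_od(img), M)
        out[r] = {"hematoxylin": conc.channel("hematoxylin"),
                  "chromogen": conc.channel("AEC")}
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
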