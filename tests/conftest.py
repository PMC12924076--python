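"""Shared fixtures: small synthetic recordings built at test time."""

import numpy as np
import pytest

import paratrack as pt


@pytest.fixture(scope="session")
def small_truth() -> pt.GroundTruth:
    """Five default swimmers for 10 minutes at 1 s steps."""
    return pt.simulate_swimmers(5, 600, pt.Chamber(), pt.SwimmerParams(), pt.LDSchedule(), seed=42)


@pytest.fixture(scope="session")
def small_frames(small_truth) -> pt.FrameSequence:
    return pt.render_frames(small_truth, pt.RenderParams())


def render_single_spot(cx: float, cy: float, amplitude: float = 120.0, sigma: float = 2.0,
                       shape: tuple[int, int] = (60, 80)) -> np.ndarray:
    """Analytic Gaussian spot image used as the localisation oracle."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amplitude * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma * sigma))


@pytest.fixture
def spot_image():
    return render_single_spot
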