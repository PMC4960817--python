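import numpy as np
import pytest

from gazeperim.geometry import build_default_device
from gazeperim.simulate import RenderConfig, render_frame
from gazeperim import frames as fr


@pytest.fixture(scope="session")
def default_arms():
    return build_default_device()


@pytest.fixture(scope="session")
def render_cfg():
    return RenderConfig(illumination_gradient=0.1, noise_sd=0.01)


@pytest.fixture(scope="session")
def fitted_chain(render_cfg):
    """Calibration model + gaze calibration fitted on rendered frames."""
    rng = np.random.default_rng(42)
    refs = [
        render_frame(g, render_cfg, rng=rng)
        for g in [(0, 0), (20, 0), (-20, 0), (0, 20), (0, -20)]
    ]
    model = fr.build_calibration_model(refs)
    cal0, _ = fr.calibrate_frame(refs[0], model)
    centre0, _ = fr.detect_eye(fr.median_filter(cal0))
    pairs = []
    for g in [
        (0, 0), (30, 0), (-30, 0), (0, 30), (0, -30),
        (20, 20), (-20, 20), (20, -20), (-20, -20),
    ]:
        f = render_frame(g, render_cfg, rng=rng)
        cal, _ = fr.calibrate_frame(f, model)
        (row, col), _ = fr.detect_eye(fr.median_filter(cal))
        pairs.append(((col - centre0[1], row - centre0[0]), g))
    gc = fr.fit_gaze_calibration(pairs)
    return model, gc, centre0
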