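import numpy as np
import pytest

from phantomqa.digital_phantom import build_default_phantom
from phantomqa.io_reporting import make_fixtures
from phantomqa.mr_simulator import SEQUENCE_PRESETS, render_slice

ROW_LAYOUT = ("oil", "cu1", "cu2", "cu3")
ROW_SPACING = 24.0


@pytest.fixture(scope="session")
def row_geometry():
    """Four-vial distortion row at 24 mm spacing, untilted."""
    return build_default_phantom(sample_layout=ROW_LAYOUT, spacing=ROW_SPACING)


@pytest.fixture(scope="session")
def t1w_render(row_geometry):
    """Noise-free T1w coronal render: (SliceImage, sidecar vials)."""
    return render_slice(row_geometry, SEQUENCE_PRESETS["t1w_coronal"])


@pytest.fixture(scope="session")
def t2w_render(row_geometry):
    return render_slice(row_geometry, SEQUENCE_PRESETS["t2w_coronal"])


@pytest.fixture(scope="session")
def fixture_set():
    return make_fixtures(seed=1)


def center_errors_px(vials, rois):
    """Match sidecar ground truth to ordered ROIs and return center errors."""
    gt = sorted(vials, key=lambda v: (v.center_px[1], v.center_px[0]))
    det = sorted(rois, key=lambda r: (r.center_xy[1], r.center_xy[0]))
    assert len(gt) == len(det)
    return [
        float(np.hypot(v.center_px[0] - r.center_xy[0], v.center_px[1] - r.center_xy[1]))
        for v, r in zip(gt, det)
    ]
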