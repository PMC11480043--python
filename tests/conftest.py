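import numpy as np
import pytest

from bodymetry import measure as me
from bodymetry import phantom as ph

ANGLES_30 = [float(a) for a in range(0, 181, 30)]


@pytest.fixture(scope="session")
def cylinder_spec():
    return ph.preset("cylinder")


@pytest.fixture(scope="session")
def hourglass_spec():
    return ph.preset("hourglass")


@pytest.fixture(scope="session")
def elliptic_spec():
    return ph.preset("elliptic")


@pytest.fixture(scope="session")
def cylinder_views(cylinder_spec):
    return {a: ph.render_view(cylinder_spec, a, 20.0) for a in ANGLES_30}


@pytest.fixture(scope="session")
def hourglass_views(hourglass_spec):
    return {a: ph.render_view(hourglass_spec, a, 20.0) for a in ANGLES_30}


@pytest.fixture(scope="session")
def hourglass_measured(hourglass_views, hourglass_spec):
    return me.measure_subject(hourglass_views, hourglass_spec.stature_cm)


@pytest.fixture()
def rectangle_mask():
    """10 wide x 20 tall foreground rectangle inside a 40x30 canvas."""
    mask = np.zeros((40, 30), dtype=bool)
    mask[5:25, 8:18] = True
    return mask


@pytest.fixture()
def disk_image():
    """White 201x201 image with a filled black disk of radius 50."""
    img = np.ones((201, 201))
    yy, xx = np.mgrid[:201, :201]
    img[(yy - 100) ** 2 + (xx - 100) ** 2 <= 50**2] = 0.0
    return img
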