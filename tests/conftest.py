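import logging

import numpy as np
import pytest

from lipidquant.chromophores import WavelengthGrid
from lipidquant.phantom import MultispectralStack, ROISet, generate_cohort

logging.getLogger("lipidquant").setLevel(logging.ERROR)

TWO_WL = WavelengthGrid(700, 710, 10)


def make_stack(pixels, grid=None, skin_row=0, **kw):
    """Toy stack around a raw pixel array (row, col, wavelength)."""
    pixels = np.asarray(pixels, dtype=float)
    if grid is None:
        grid = WavelengthGrid(700, 700 + 10 * (pixels.shape[2] - 1), 10)
    return MultispectralStack(
        pixels=pixels, grid=grid, pixel_pitch_cm=0.01, skin_row=skin_row, **kw
    )


def full_roiset(shape, skin_row=0):
    """ROISet whose BGR covers the whole image below the skin line."""
    bgr = np.zeros(shape, dtype=bool)
    bgr[skin_row:] = True
    return ROISet(masks={"BGR": bgr}, skin_row=skin_row)


@pytest.fixture(scope="session")
def human_cohort():
    """One reduced-size human phantom cohort (5 healthy + 5 steatosis)."""
    return generate_cohort("human", 5, base_seed=11, reduced=True)


@pytest.fixture(scope="session")
def mouse_cohort():
    return generate_cohort("mouse", 5, base_seed=11, reduced=True)
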