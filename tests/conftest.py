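import numpy as np
import pytest

from gliaquant.imaging import CalibratedStack, ChannelRole, RegionOfInterest


def rect_roi(ny: int, nx: int, name: str = "whole") -> RegionOfInterest:
    """Axis-aligned ROI covering the full (ny, nx) image."""
    return RegionOfInterest(
        [(0.0, 0.0), (0.0, nx - 1.0), (ny - 1.0, nx - 1.0), (ny - 1.0, 0.0)], name
    )


@pytest.fixture
def whole_roi_64():
    return rect_roi(64, 64)


def stack_from_2d(image: np.ndarray, role=ChannelRole.PLAQUE_6E10, px=1.0, nz=1) -> CalibratedStack:
    """Wrap a 2-D image as an nz-plane calibrated stack."""
    return CalibratedStack(np.repeat(np.asarray(image, float)[None], nz, axis=0), px, role)


@pytest.fixture
def damage_fixture():
    """64x64 single-plane scene: plaque disk r=5 at the center, a LAMP1
    annulus around it, a vertical microglia stripe, two-level intensities."""
    ny = nx = 64
    yy, xx = np.mgrid[0:ny, 0:nx]
    d2 = (yy - 32) ** 2 + (xx - 32) ** 2
    plaque = d2 <= 25
    lamp1 = (d2 > 36) & (d2 <= 144)
    microglia = (xx >= 40) & (xx <= 47)
    def img(mask, hi=200.0, lo=10.0):
        out = np.full((ny, nx), lo)
        out[mask] = hi
        return out
    return {
        "plaque": stack_from_2d(img(plaque)),
        "lamp1": stack_from_2d(img(lamp1), ChannelRole.LAMP1),
        "microglia": stack_from_2d(img(microglia), ChannelRole.MICROGLIA),
        "masks": {"plaque": plaque, "lamp1": lamp1, "microglia": microglia},
    }
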