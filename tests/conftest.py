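import numpy as np
import pytest

from hipwear.preprocess import EdgeMap


def make_ring_edge_map(
    shape=(128, 128), cx=64.0, cy=64.0, r=50.0, width=1.0, extra_rings=()
) -> EdgeMap:
    """Analytic EdgeMap of one or more ideal circular rims.

    combined/edges are 1 inside the ring band, grad_dir is radial (so
    gradient/normal alignment is perfect), grad_mag mirrors combined.
    """
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    combined = np.zeros((H, W))
    grad_dir = np.zeros((H, W))
    for ccx, ccy, cr in ((cx, cy, r), *extra_rings):
        dist = np.hypot(xx - ccx, yy - ccy)
        band = np.abs(dist - cr) <= width / 2.0 + 0.5
        combined[band] = 1.0
        grad_dir[band] = np.arctan2(yy - ccy, xx - ccx)[band]
    edges = combined > 0.5
    return EdgeMap(
        edges=edges,
        grad_mag=combined * 100.0,
        grad_dir=grad_dir,
        combined=combined,
    )


@pytest.fixture
def ring_edge_map():
    return make_ring_edge_map()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
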