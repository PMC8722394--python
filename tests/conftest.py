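import numpy as np
import pytest

from seamfish import SceneParams, simulate_embryo
from seamfish.pipeline import quantify_embryo


@pytest.fixture(scope="session")
def default_scene():
    """One rendered default embryo (noise on) with its ground truth."""
    params = SceneParams(seed=7)
    stack, rois, truth = simulate_embryo(params)
    return params, stack, rois, truth


@pytest.fixture(scope="session")
def quantified_scene(default_scene):
    """The default embryo pushed through the full quantification."""
    params, stack, rois, truth = default_scene
    table, counts, spots, cal, unassigned = quantify_embryo(
        stack, rois, interior_offset_px=params.membrane_band_px
    )
    return params, truth, table, counts, spots, cal, unassigned


@pytest.fixture(scope="session")
def noiseless_scene():
    """Small noise-free embryo for exact rendering checks."""
    params = SceneParams(
        seed=3, n_cells=2, n_spots_per_cell=6,
        poisson_noise=False, gaussian_noise_sd=0.0,
    )
    stack, rois, truth = simulate_embryo(params)
    return params, stack, rois, truth


def render_gaussians_2d(shape, spots, background=0.0):
    """Reference renderer for constructed detection inputs.

    ``spots`` is a list of ``(y, x, amplitude, sigma)``.
    """
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    img = np.full(shape, float(background))
    for y, x, amp, sigma in spots:
        img = img + amp * np.exp(
            -((yy - y) ** 2 + (xx - x) ** 2) / (2.0 * sigma**2)
        )
    return img
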