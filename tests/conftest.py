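import numpy as np
import pandas as pd
import pytest

import fieldlisa as fl


@pytest.fixture(scope="session")
def chain_weights():
    """Three collinear points 1 m apart with a 1 m distance band."""
    return fl.build_weights([(0.0, 0.0), (1.0, 0.0), (2.0, 0.0)], threshold=1.0)


@pytest.fixture(scope="session")
def chain_z():
    """Raw values [1, 1, 3], centered: Z = (-2/3, -2/3, 4/3), m = 8/9."""
    z = np.array([1.0, 1.0, 3.0])
    return z - z.mean()


@pytest.fixture(scope="session")
def small_field():
    """Noise-free miniature field: 6 germplasms x 2 reps, 5 plants/plot."""
    layout = fl.generate_layout(
        n_germplasms=6, n_reps=2, plants_per_plot=5, plant_spacing=0.25,
        plot_spacing=0.5, grid_cols=4, seed=3,
    )
    dtm = fl.generate_terrain(layout.extent, roughness_sd=0.0, cell_size=0.05, seed=3)
    means = fl.default_germplasm_means(list(layout.plots["germplasm"].unique()), seed=3)
    model = fl.GrowthModel(germplasm_means=means, env_effect=None, noise_sd=0.0)
    heights = fl.generate_true_heights(layout, dtm, model, seed=3)
    dsm = fl.render_dsm(layout, heights, dtm, render_noise_sd=0.0, seed=3)
    return layout, dtm, dsm, heights


def brute_force_global_moran(z, points, threshold, row_standardize=False):
    """Independent O(n^2) double-sum global Moran's I oracle."""
    z = np.asarray(z, dtype=float)
    z = z - z.mean()
    n = len(z)
    num = 0.0
    s0 = 0.0
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = np.hypot(*(np.asarray(points[i]) - np.asarray(points[j])))
            if d <= threshold:
                W[i, j] = 1.0
    if row_standardize:
        rs = W.sum(axis=1)
        W = np.divide(W, rs[:, None], out=np.zeros_like(W), where=rs[:, None] > 0)
    for i in range(n):
        for j in range(n):
            num += W[i, j] * z[i] * z[j]
    s0 = W.sum()
    return (n / s0) * num / (z @ z), s0
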