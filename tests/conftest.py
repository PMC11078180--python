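import numpy as np
import pytest

from mobflim import features as feat
from mobflim import synthetic as syn


@pytest.fixture(scope="session")
def registry():
    return feat.build_default_registry()


def make_scene(n_cells=1, alpha=0.5, tau=3.4, rate=25.0, radius=14.0,
               image_size=64, background_rate=0.2, noise=True, seed=0):
    """Small scene helper: cells on a grid with shared lifetime truth."""
    grid = int(np.ceil(np.sqrt(n_cells)))
    pitch = image_size / grid
    cells = [
        syn.CellSpec(center=(pitch * (0.5 + i // grid), pitch * (0.5 + i % grid)),
                     radius_px=radius, true_alpha_bound=alpha,
                     true_tau_bound=tau, nadph_rate=rate, fad_rate=rate / 2.0)
        for i in range(n_cells)
    ]
    return syn.SceneSpec(image_size=(image_size, image_size), cells=cells,
                         background_rate=background_rate, poisson_noise=noise,
                         seed=seed)


def one_factor_table(n=500, p=11, noise=0.3, seed=0, loadings=None):
    """x = w z + eps with a single dominant factor; returns (table, z, cols)."""
    import pandas as pd
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    w = loadings if loadings is not None else rng.uniform(0.5, 1.5, p)
    x = np.outer(z, w) + noise * rng.standard_normal((n, p))
    cols = [f"g{i:02d}" for i in range(p)]
    return pd.DataFrame(x, columns=cols), z, cols


@pytest.fixture(scope="session")
def noisefree_scene():
    """One disk-shaped cell, expected (float) histograms, no background."""
    spec = make_scene(background_rate=0.0, noise=False)
    return spec, syn.simulate_decay_image(spec)
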