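"""Image-to-features pipeline: the composition every stage agrees with.

``process_scene`` chains the per-image stages — phasor transform, 3x3
median filter, free/bound decomposition, segmentation, feature
extraction — exactly as the standalone CLI stages do, so end-to-end
results equal the composition of the parts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import features as feat
from . import phasor as ph
from . import segmentation as seg
from .io import PipelineConfig

__all__ = ["SceneResult", "process_scene", "bin_decay_2x2"]


@dataclass
class SceneResult:
    """Everything the per-image pipeline produces for one scene."""

    phasor: ph.PhasorMap
    lifetime: ph.LifetimeMap
    segmentation: seg.CellSegmentation
    features: pd.DataFrame
    nadph_intensity: np.ndarray
    fad_intensity: np.ndarray


def process_scene(nadph: ph.DecayImage, fad: ph.DecayImage,
                  config: PipelineConfig | None = None,
                  registry: feat.FeatureRegistry | None = None) -> SceneResult:
    """Run the full per-image chain on one NAD(P)H/FAD acquisition."""
    cfg = config or PipelineConfig()
    if nadph.shape != fad.shape:
        raise ValueError(f"channel shapes differ: {nadph.shape} vs {fad.shape}")

    pm = ph.phasor_transform(nadph, harmonic=cfg.harmonic)
    pm = ph.median_filter_phasor(pm, window=cfg.median_filter_window)
    lt = ph.resolve_bound_fraction(pm, tau_free=cfg.tau_free_ns)

    nad_int = nadph.intensity()
    fad_int = fad.intensity()
    cells = seg.segment_scene(nad_int, fad_int,
                              photon_threshold=cfg.photon_threshold,
                              min_size_px=cfg.min_cell_size_px,
                              max_size_px=cfg.max_cell_size_px,
                              erosion_iterations=cfg.erosion_iterations)

    alpha = np.where(lt.qc_flag == ph.QC_INVALID, np.nan, lt.alpha_bound)
    channels = {"nadph": nad_int.astype(float), "fad": fad_int.astype(float),
                "alpha_bound": alpha, "tau_bound": lt.tau_bound}
    table = feat.extract_feature_table(cells, channels, registry,
                                       pixel_size_um=cfg.pixel_size_um)
    return SceneResult(phasor=pm, lifetime=lt, segmentation=cells,
                       features=table, nadph_intensity=nad_int,
                       fad_intensity=fad_int)


def bin_decay_2x2(decay: ph.DecayImage) -> ph.DecayImage:
    """Sum photons over 2x2 pixel blocks (quadrupling photons/pixel).

    Odd trailing rows/columns are dropped.  Used for score-robustness
    checks against the native-resolution analysis.
    """
    c = decay.counts
    h, w = c.shape[1] // 2 * 2, c.shape[2] // 2 * 2
    c = c[:, :h, :w]
    binned = c.reshape(c.shape[0], h // 2, 2, w // 2, 2).sum(axis=(2, 4))
    return ph.DecayImage(binned, laser_period_ns=decay.laser_period_ns,
                         channel=decay.channel)
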