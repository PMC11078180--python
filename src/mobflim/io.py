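"""File formats: TIFF decay stacks and maps, CSV tables, JSON configs.

Decay histograms travel as multi-plane TIFFs (one plane per time bin)
with the laser period recorded in the image description; derived maps
(phasor coordinates, lifetimes, intensities) as float32 TIFFs.  Feature
tables are CSV with a sidecar JSON registry manifest so a table can be
validated against the feature definitions that produced it.  Vendor
microscope formats (.ptu, .lif, ...) are out of scope: convert to these
TIFF layouts first.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .phasor import DEFAULT_LASER_PERIOD_NS, TAU_FREE_NS, DecayImage

__all__ = [
    "PipelineConfig",
    "read_decay_tiff",
    "write_decay_tiff",
    "read_map_tiff",
    "write_map_tiff",
    "read_feature_csv",
    "write_feature_csv",
    "SchemaError",
]


class SchemaError(ValueError):
    """A file does not match its declared schema."""


def write_decay_tiff(path, decay: DecayImage) -> None:
    meta = {"laser_period_ns": decay.laser_period_ns,
            "channel": decay.channel,
            "axes_order": "time_bin,row,col"}
    tifffile.imwrite(path, np.asarray(decay.counts),
                     description=json.dumps(meta))


def read_decay_tiff(path) -> DecayImage:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description or "{}"
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    if data.ndim != 3:
        raise SchemaError(f"{path}: expected a 3-D stack (time, row, col), "
                          f"got shape {data.shape}")
    return DecayImage(data,
                      laser_period_ns=float(meta.get("laser_period_ns",
                                                     DEFAULT_LASER_PERIOD_NS)),
                      channel=str(meta.get("channel", "")))


def write_map_tiff(path, array: np.ndarray, name: str = "") -> None:
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32),
                     description=json.dumps({"name": name}))


def read_map_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def write_feature_csv(path, table: pd.DataFrame, registry=None) -> None:
    """Write a feature table; a registry adds a sidecar ``.manifest.json``."""
    path = Path(path)
    table.to_csv(path, index=False)
    if registry is not None:
        manifest_path = path.with_suffix(path.suffix + ".manifest.json")
        manifest_path.write_text(json.dumps(registry.manifest(), indent=1))


def read_feature_csv(path, registry=None) -> pd.DataFrame:
    """Read a feature table, validating its columns against the registry."""
    table = pd.read_csv(path)
    if registry is not None:
        missing = [f for f in registry.feature_ids if f not in table.columns]
        if missing:
            raise SchemaError(
                f"{path}: missing registry column(s): {missing[:5]}"
                + (" ..." if len(missing) > 5 else ""))
    return table


@dataclasses.dataclass
class PipelineConfig:
    """End-to-end pipeline parameters; defaults are the printed constants.

    A single ``seed`` is expanded per stage through ``numpy``'s
    SeedSequence so every stage is reproducible yet decorrelated.
    """

    laser_period_ns: float = DEFAULT_LASER_PERIOD_NS
    harmonic: int = 1
    tau_free_ns: float = TAU_FREE_NS
    median_filter_window: int = 3
    photon_threshold: float = 2.0
    pixel_size_um: float = 0.18
    min_cell_size_px: int = 200
    max_cell_size_px: int = 500_000
    erosion_iterations: int = 1
    f1_cut: float = 0.6
    ti_cut: float = 0.5
    node_fraction_cut: float = 0.5
    n_latent: int = 3
    dbscan_min_samples: int = 5
    seed: int = 0
    log_level: str = "INFO"

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed (< 2**31) derived from the config seed."""
        import zlib
        ss = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
        return int(ss.generate_state(1)[0] % (2**31))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))
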