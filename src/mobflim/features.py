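"""The metabolic-optical-biomarker (MOB) feature library.

Each segmented cell yields a fixed vector of features computed over four
channels — NAD(P)H intensity, bound fraction ``alpha_bound``, bound
lifetime ``tau_bound``, and the optical redox ratio (ORR, mitochondria
only) — in the mitochondrial and cytoplasmic/nuclear subregions, plus
whole-cell morphology.  Per (channel, region) the statistics fall into
three families:

* signal strength: average, median, 10th and 90th percentiles;
* statistical distribution: SD, variance, skewness, kurtosis, entropy,
  uniformity, interquartile range;
* spatial texture: gray-level co-occurrence (GLCM) and run-length (GLRLM)
  statistics on the region quantized to 16 gray levels.

Mito-vs-cyto contrast of every per-region statistic is summarized by the
compartmentalization index ``(m - c) / (m + c)``.

The registry is declarative: a table of feature definitions that the
extractor walks, so its composition is documented, versioned and
reconcilable rather than implied by code paths.  The default registry
enumerates 210 features.  Features that cannot be computed for a cell
(empty region, degenerate split, too few pixels) are NaN and listed in the
cell's flag set — never silently absent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats as sps
from skimage.measure import regionprops

from .phasor import compute_orr

__all__ = [
    "FeatureDef",
    "FeatureRegistry",
    "REGISTRY_VERSION",
    "build_default_registry",
    "region_statistics",
    "texture_features",
    "glcm_matrix",
    "glrlm_matrix",
    "morphology_features",
    "compartmentalization",
    "extract_cell_features",
    "extract_feature_table",
    "N_GRAY_LEVELS",
    "N_HIST_BINS",
]

REGISTRY_VERSION = "1.0"

#: Gray levels for texture quantization (min-max scaling per region).
N_GRAY_LEVELS = 16
#: Histogram bins for entropy/uniformity (min-max scaling per region).
N_HIST_BINS = 16
#: Minimum region size for higher moments and texture.
MIN_MOMENT_PIXELS = 3
MIN_TEXTURE_PIXELS = 9

CHANNELS = ("nadph", "alpha_bound", "tau_bound")
REGIONS = ("mito", "cyto")

STRENGTH_STATS = ("average", "median", "p10", "p90")
DISTRIBUTION_STATS = ("sd", "variance", "skewness", "kurtosis", "entropy",
                      "uniformity", "iqr")
TEXTURE_STATS = ("glcm_contrast", "glcm_difference_variance",
                 "glcm_difference_entropy", "glcm_inverse_difference_moment",
                 "glcm_energy", "glcm_correlation",
                 "glrlm_gray_level_variance", "glrlm_run_length_variance",
                 "glrlm_short_run_emphasis")
REGION_STATS = STRENGTH_STATS + DISTRIBUTION_STATS + TEXTURE_STATS

MORPHOLOGY_STATS = ("size", "major_axis_length", "minor_axis_length",
                    "circularity", "eccentricity", "solidity",
                    "mito_size", "mito_dispersity", "cyto_size")


@dataclass(frozen=True)
class FeatureDef:
    """One registry entry; ``feature_id`` is ``channel_region_statistic``."""

    feature_id: str
    channel: str     # nadph | alpha_bound | tau_bound | orr | morphology
    region: str      # mito | cyto | whole | compartmentalization
    statistic: str
    family: str      # strength | distribution | texture | morphology | comp | orr


class FeatureRegistry:
    """Ordered, unique collection of :class:`FeatureDef`."""

    def __init__(self, entries: list[FeatureDef],
                 version: str = REGISTRY_VERSION):
        ids = [e.feature_id for e in entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate feature ids in registry")
        self.entries = list(entries)
        self.version = version

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def feature_ids(self) -> list[str]:
        return [e.feature_id for e in self.entries]

    def manifest(self) -> dict:
        return {
            "version": self.version,
            "n_features": len(self),
            "n_gray_levels": N_GRAY_LEVELS,
            "n_hist_bins": N_HIST_BINS,
            "entries": [vars(e) for e in self.entries],
        }


def _stat_family(stat: str) -> str:
    if stat in STRENGTH_STATS:
        return "strength"
    if stat in DISTRIBUTION_STATS:
        return "distribution"
    return "texture"


def build_default_registry() -> FeatureRegistry:
    """The default MOB feature registry.

    3 lifetime/intensity channels x 2 regions x 20 statistics, ORR in the
    mitochondrial region (plus its baseline-corrected per-cell value),
    compartmentalization of every per-region statistic for the 3 channels,
    and 9 morphology features: 210 entries total.
    """
    entries: list[FeatureDef] = []
    for ch in CHANNELS:
        for rg in REGIONS:
            for st in REGION_STATS:
                entries.append(FeatureDef(f"{ch}_{rg}_{st}", ch, rg, st,
                                          _stat_family(st)))
    for st in REGION_STATS:
        entries.append(FeatureDef(f"orr_mito_{st}", "orr", "mito", st, "orr"))
    entries.append(FeatureDef("orr_corrected", "orr", "whole", "corrected",
                              "orr"))
    for ch in CHANNELS:
        for st in REGION_STATS:
            entries.append(FeatureDef(f"{ch}_comp_{st}", ch,
                                      "compartmentalization", st, "comp"))
    for st in MORPHOLOGY_STATS:
        entries.append(FeatureDef(f"morph_{st}", "morphology", "whole", st,
                                  "morphology"))
    return FeatureRegistry(entries)


# ---------------------------------------------------------------------------
# per-region statistics


def region_statistics(values: np.ndarray) -> dict[str, float]:
    """First-order statistics of the pixel values in one region.

    Percentiles use linear interpolation between closest ranks.  Entropy
    (bits) and uniformity are computed on a 16-bin min-max histogram; a
    constant region has entropy 0 and uniformity 1.  Higher moments
    (skewness, kurtosis — Fisher convention, i.e. normal -> 0) are NaN
    below 3 pixels.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    out = {k: np.nan for k in STRENGTH_STATS + DISTRIBUTION_STATS}
    if v.size == 0:
        return out
    out["average"] = float(np.mean(v))
    out["median"] = float(np.median(v))
    out["p10"] = float(np.percentile(v, 10))
    out["p90"] = float(np.percentile(v, 90))
    out["sd"] = float(np.std(v))
    out["variance"] = float(np.var(v))
    out["iqr"] = float(np.percentile(v, 75) - np.percentile(v, 25))
    if np.ptp(v) < 1e-12:
        hist = np.array([1.0])
    else:
        hist, _ = np.histogram(v, bins=N_HIST_BINS)
        hist = hist / hist.sum()
    nz = hist[hist > 0]
    out["entropy"] = float(-np.sum(nz * np.log2(nz)))
    out["uniformity"] = float(np.sum(hist**2))
    if v.size >= MIN_MOMENT_PIXELS and np.ptp(v) > 1e-12:
        out["skewness"] = float(sps.skew(v))
        out["kurtosis"] = float(sps.kurtosis(v))
    elif np.ptp(v) <= 1e-12 and v.size >= MIN_MOMENT_PIXELS:
        out["skewness"] = np.nan
        out["kurtosis"] = np.nan
    return out


# ---------------------------------------------------------------------------
# texture


def _quantize(image: np.ndarray, mask: np.ndarray,
              n_levels: int = N_GRAY_LEVELS) -> np.ndarray | None:
    """Min-max quantize masked values to integer levels 0..n_levels-1."""
    vals = image[mask]
    lo, hi = float(np.min(vals)), float(np.max(vals))
    if hi - lo < 1e-12:
        return None
    q = np.zeros(image.shape, dtype=np.int32)
    q[mask] = np.minimum(((image[mask] - lo) / (hi - lo) * n_levels).astype(int),
                         n_levels - 1)
    return q


_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))  # 4 directions at distance 1


def glcm_matrix(quantized: np.ndarray, mask: np.ndarray,
                n_levels: int = N_GRAY_LEVELS) -> np.ndarray:
    """Symmetrized, direction-aggregated gray-level co-occurrence matrix.

    Counts pairs at distance 1 along the 4 unique directions where both
    pixels lie in the region; normalized to sum to 1.
    """
    glcm = np.zeros((n_levels, n_levels))
    h, w = mask.shape
    for dy, dx in _OFFSETS:
        y0, y1 = max(0, -dy), min(h, h - dy)
        x0, x1 = max(0, -dx), min(w, w - dx)
        a_mask = mask[y0:y1, x0:x1]
        b_mask = mask[y0 + dy:y1 + dy, x0 + dx:x1 + dx]
        both = a_mask & b_mask
        a = quantized[y0:y1, x0:x1][both]
        b = quantized[y0 + dy:y1 + dy, x0 + dx:x1 + dx][both]
        np.add.at(glcm, (a, b), 1.0)
    glcm = glcm + glcm.T  # symmetrize
    total = glcm.sum()
    return glcm / total if total > 0 else glcm


def glrlm_matrix(quantized: np.ndarray, mask: np.ndarray,
                 n_levels: int = N_GRAY_LEVELS) -> np.ndarray:
    """Direction-aggregated gray-level run-length matrix.

    Runs of equal gray level within the region along the 4 directions;
    entry (i, j) counts runs of level i and length j+1.  A pixel outside
    the region terminates a run.
    """
    h, w = mask.shape
    max_run = max(h, w)
    glrlm = np.zeros((n_levels, max_run))

    def scan(line_levels, line_mask):
        run_level, run_len = None, 0
        for lev, ok in zip(line_levels, line_mask):
            if ok and lev == run_level:
                run_len += 1
            else:
                if run_len:
                    glrlm[run_level, run_len - 1] += 1
                run_level, run_len = (lev, 1) if ok else (None, 0)
        if run_len:
            glrlm[run_level, run_len - 1] += 1

    for row in range(h):
        scan(quantized[row], mask[row])
    for col in range(w):
        scan(quantized[:, col], mask[:, col])
    flipped_q, flipped_m = quantized[:, ::-1], mask[:, ::-1]
    for arr_q, arr_m in ((quantized, mask), (flipped_q, flipped_m)):
        for d in range(-h + 1, w):
            scan(np.diagonal(arr_q, d), np.diagonal(arr_m, d))
    return glrlm


def texture_features(image: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """GLCM and GLRLM texture statistics of one region.

    NaN for every statistic when the region is smaller than 9 pixels or
    quantizes to a single gray level.
    """
    out = {k: np.nan for k in TEXTURE_STATS}
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < MIN_TEXTURE_PIXELS:
        return out
    q = _quantize(np.asarray(image, dtype=float), mask)
    if q is None:
        return out

    p = glcm_matrix(q, mask)
    if p.sum() <= 0:
        return out
    i = np.arange(N_GRAY_LEVELS)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = np.abs(ii - jj)
    p_diff = np.array([p[diff == k].sum() for k in range(N_GRAY_LEVELS)])
    mu_diff = np.sum(np.arange(N_GRAY_LEVELS) * p_diff)
    out["glcm_contrast"] = float(np.sum(p * (ii - jj) ** 2))
    out["glcm_difference_variance"] = float(
        np.sum(p_diff * (np.arange(N_GRAY_LEVELS) - mu_diff) ** 2))
    nz = p_diff[p_diff > 0]
    out["glcm_difference_entropy"] = float(-np.sum(nz * np.log2(nz)))
    out["glcm_inverse_difference_moment"] = float(
        np.sum(p / (1.0 + (ii - jj) ** 2)))
    out["glcm_energy"] = float(np.sum(p**2))
    px = p.sum(axis=1)
    mu_x = np.sum(i * px)
    sd_x = np.sqrt(np.sum(px * (i - mu_x) ** 2))
    if sd_x > 1e-12:  # symmetric glcm: marginals coincide
        out["glcm_correlation"] = float(
            (np.sum(ii * jj * p) - mu_x**2) / sd_x**2)

    r = glrlm_matrix(q, mask)
    total = r.sum()
    if total > 0:
        p_level = r.sum(axis=1) / total
        p_len = r.sum(axis=0) / total
        levels = np.arange(N_GRAY_LEVELS)
        lengths = np.arange(1, r.shape[1] + 1)
        mu_l = np.sum(levels * p_level)
        mu_j = np.sum(lengths * p_len)
        out["glrlm_gray_level_variance"] = float(
            np.sum(p_level * (levels - mu_l) ** 2))
        out["glrlm_run_length_variance"] = float(
            np.sum(p_len * (lengths - mu_j) ** 2))
        out["glrlm_short_run_emphasis"] = float(
            np.sum(p_len / lengths**2))
    return out


# ---------------------------------------------------------------------------
# morphology and compartmentalization


def morphology_features(cell, pixel_size_um: float) -> dict[str, float]:
    """Whole-cell and subregion morphology.

    ``size`` is area in um^2; ``circularity = 4 pi A / P^2`` (clipped to 1;
    exactly 1 for an ideal disk); axis lengths come from the mask's second
    moments; ``mito_dispersity`` is the number of connected mitochondrial
    components per unit mitochondrial area (1/um^2) — a fragmentation
    measure that rises with many small puncta.
    """
    out = {k: np.nan for k in MORPHOLOGY_STATS}
    area_px = cell.pixel_count
    px_area = pixel_size_um**2
    out["size"] = area_px * px_area
    props = regionprops(cell.mask.astype(np.uint8))
    if props and area_px > 1:
        p = props[0]
        out["major_axis_length"] = p.axis_major_length * pixel_size_um
        out["minor_axis_length"] = p.axis_minor_length * pixel_size_um
        out["eccentricity"] = p.eccentricity
        out["solidity"] = p.solidity
        if p.perimeter > 0:
            out["circularity"] = min(4 * np.pi * p.area / p.perimeter**2, 1.0)
    if cell.split_ok:
        mito_px = int(cell.mito_mask.sum())
        out["mito_size"] = mito_px * px_area
        out["cyto_size"] = int(cell.cyto_mask.sum()) * px_area
        if mito_px > 0:
            _, n_comp = ndi.label(cell.mito_mask)
            out["mito_dispersity"] = n_comp / (mito_px * px_area)
    return out


def compartmentalization(feature_mito: float, feature_cyto: float,
                         atol: float = 1e-9) -> float:
    """Normalized mito-vs-cyto contrast: ``(m - c) / (m + c)``.

    Defined as 0 when both inputs are 0; NaN (undefined) when the inputs
    nearly cancel (opposite signs summing to ~0) or are not finite.
    """
    m, c = float(feature_mito), float(feature_cyto)
    if not (np.isfinite(m) and np.isfinite(c)):
        return np.nan
    if m == 0.0 and c == 0.0:
        return 0.0
    denom = m + c
    if abs(denom) <= atol * max(abs(m), abs(c)):
        return np.nan
    return (m - c) / denom


# ---------------------------------------------------------------------------
# per-cell extraction


def extract_cell_features(cell, channels: dict[str, np.ndarray],
                          registry: FeatureRegistry,
                          pixel_size_um: float = 0.18):
    """One feature row for one segmented cell.

    ``channels`` maps 'nadph', 'alpha_bound', 'tau_bound', 'fad' to
    full-image maps (NaNs in lifetime maps are ignored pixel-wise).  The
    per-pixel ORR channel is the raw FAD/NAD(P)H ratio, with statistics
    taken in the mitochondrial region only; the scalar ``orr_corrected``
    subtracts the cytoplasmic baseline ratio.  Returns ``(values, flags)``
    where ``flags`` lists the feature ids set to NaN and why computation
    was partial (e.g. a failed subregion split leaves morphology and
    whole-channel features intact but flags compartmental entries).
    """
    values: dict[str, float] = {}
    flags: set[str] = set()

    region_masks = {"mito": cell.mito_mask if cell.split_ok else None,
                    "cyto": cell.cyto_mask if cell.split_ok else None}

    nadph = channels.get("nadph")
    fad = channels.get("fad")
    orr_map = None
    if fad is not None and nadph is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            orr_map = np.where(nadph > 0, fad / np.maximum(nadph, 1e-30), np.nan)

    chan_maps = {"nadph": nadph, "alpha_bound": channels.get("alpha_bound"),
                 "tau_bound": channels.get("tau_bound"), "orr": orr_map}

    stats_cache: dict[tuple[str, str], dict[str, float]] = {}

    def region_stats(ch: str, rg: str) -> dict[str, float]:
        key = (ch, rg)
        if key not in stats_cache:
            img = chan_maps.get(ch)
            msk = region_masks.get(rg)
            if img is None or msk is None:
                stats_cache[key] = {k: np.nan for k in REGION_STATS}
            else:
                finite = msk & np.isfinite(img)
                s = region_statistics(img[finite])
                # texture on the region bounding box (scan cost scales with
                # the box, not the image)
                if finite.any():
                    rows = np.flatnonzero(finite.any(axis=1))
                    cols = np.flatnonzero(finite.any(axis=0))
                    box = (slice(rows[0], rows[-1] + 1),
                           slice(cols[0], cols[-1] + 1))
                    s.update(texture_features(np.nan_to_num(img[box]),
                                              finite[box]))
                else:
                    s.update({k: np.nan for k in TEXTURE_STATS})
                stats_cache[key] = s
        return stats_cache[key]

    morph = morphology_features(cell, pixel_size_um)

    for entry in registry:
        fid = entry.feature_id
        if entry.channel == "morphology":
            values[fid] = morph.get(entry.statistic, np.nan)
        elif entry.region == "compartmentalization":
            m = region_stats(entry.channel, "mito").get(entry.statistic, np.nan)
            c = region_stats(entry.channel, "cyto").get(entry.statistic, np.nan)
            values[fid] = compartmentalization(m, c) \
                if np.isfinite(m) and np.isfinite(c) else np.nan
        elif entry.statistic == "corrected":
            if fad is None or nadph is None or not cell.split_ok:
                values[fid] = np.nan
            else:
                orr, _ = compute_orr(fad, nadph, cell.mito_mask, cell.cyto_mask)
                values[fid] = orr
        else:
            values[fid] = region_stats(entry.channel, entry.region).get(
                entry.statistic, np.nan)
        if not np.isfinite(values[fid]):
            flags.add(fid)
    return values, flags


def extract_feature_table(segmentation, channels: dict[str, np.ndarray],
                          registry: FeatureRegistry | None = None,
                          pixel_size_um: float = 0.18) -> pd.DataFrame:
    """Feature table over all cells of one segmented scene.

    One row per cell; flagged (NaN) features are listed per row in the
    ``flagged_features`` column so missingness is explicit.
    """
    registry = registry or build_default_registry()
    rows = []
    for cell in segmentation.cells:
        vals, flags = extract_cell_features(cell, channels, registry,
                                            pixel_size_um)
        row = {"cell_id": cell.cell_id,
               "centroid_y": cell.centroid[0], "centroid_x": cell.centroid[1]}
        row.update(vals)
        row["flagged_features"] = ";".join(sorted(flags))
        rows.append(row)
    cols = (["cell_id", "centroid_y", "centroid_x"] + registry.feature_ids
            + ["flagged_features"])
    return pd.DataFrame(rows, columns=cols)
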