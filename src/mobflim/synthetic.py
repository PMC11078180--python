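"""Ground-truth-known synthetic FLIM data.

Three generators cover the three tiers of the pipeline:

* :func:`simulate_decay_image` — an image-level scene of disk-shaped cells
  with punctate mitochondrial subregions.  Each NAD(P)H pixel decays as a
  two-species mixture of free (``tau_free``) and enzyme-bound
  (``tau_bound``) coenzyme, sampled over one laser period with Poisson
  photon statistics at the low budgets (~20-30 photons/pixel) of live-cell
  autofluorescence imaging.  FAD contributes a mono-exponential decay whose
  intensity is elevated in mitochondria, which is what makes the
  Otsu-based mito/cyto split work downstream.
* :func:`simulate_population_features` — per-cell feature tables across
  differentiation stages with configurable monotone trends, for testing
  trend-based feature selection.
* :func:`simulate_division_dataset` — parent/daughter score tables with
  controlled score inheritance and a bimodal sibling score difference,
  emulating metabolically symmetric vs asymmetric stem-cell divisions.

The instrument response is ideal (delta); real phasor systems correct for
their response function internally, and the clean limit is what makes
closed-form oracles possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .phasor import DEFAULT_LASER_PERIOD_NS, TAU_FREE_NS, DecayImage

__all__ = [
    "CellSpec",
    "SceneSpec",
    "GroundTruth",
    "PopulationSpec",
    "DivisionSpec",
    "decay_histogram",
    "simulate_decay_image",
    "simulate_population_features",
    "simulate_division_dataset",
]


@dataclass
class CellSpec:
    """One synthetic cell: geometry, photon rates and true lifetimes."""

    center: tuple[float, float]            # (row, col) pixels
    radius_px: float
    true_alpha_bound: float                # bound NAD(P)H intensity fraction
    true_tau_bound: float                  # ns
    nadph_rate: float                      # mean photons/pixel
    fad_rate: float                        # mean photons/pixel (cytoplasm)
    mito_fraction: float = 0.25            # area fraction of mitochondria
    mito_contrast: float = 5.0             # FAD rate multiplier in mitochondria

    def validate(self, tau_free: float) -> None:
        if self.radius_px <= 0:
            raise ValueError("cell radius must be positive")
        if not 0.0 <= self.true_alpha_bound <= 1.0:
            raise ValueError("true_alpha_bound must be in [0, 1]")
        if self.true_tau_bound <= tau_free:
            raise ValueError("true_tau_bound must exceed tau_free")
        if self.nadph_rate < 0 or self.fad_rate < 0:
            raise ValueError("photon rates must be nonnegative")
        if not 0.0 < self.mito_fraction < 1.0:
            raise ValueError("mito_fraction must be in (0, 1)")
        if self.mito_contrast < 1.0:
            raise ValueError("mito_contrast must be >= 1")


@dataclass
class SceneSpec:
    """Full scene: image geometry, cells, background and acquisition."""

    image_size: tuple[int, int] = (128, 128)
    pixel_size_um: float = 0.18
    cells: list[CellSpec] = field(default_factory=list)
    background_rate: float = 0.2           # photons/pixel outside cells
    n_time_bins: int = 256
    laser_period_ns: float = DEFAULT_LASER_PERIOD_NS
    tau_free: float = TAU_FREE_NS
    tau_fad: float = 2.3                   # ns, mono-exponential FAD decay
    poisson_noise: bool = True             # False -> expected (noise-free) histograms
    seed: int = 0

    def validate(self) -> None:
        if self.background_rate < 0:
            raise ValueError("background_rate must be nonnegative")
        if self.n_time_bins < 2:
            raise ValueError("need at least 2 time bins")
        for c in self.cells:
            c.validate(self.tau_free)


@dataclass
class GroundTruth:
    """Per-pixel truth maps recorded alongside a simulated scene."""

    label_map: np.ndarray        # int, 0 = background, i = cell index + 1
    mito_mask: np.ndarray        # bool
    alpha_map: np.ndarray        # true alpha_bound (NaN outside cells)
    tau_map: np.ndarray          # true tau_bound (NaN outside cells)
    nadph_rate_map: np.ndarray
    fad_rate_map: np.ndarray


def decay_histogram(taus_ns, fractions, n_bins: int, period_ns: float) -> np.ndarray:
    """Expected per-bin probability of a periodic multi-exponential decay.

    Each species is an exponential restarted every laser period; the
    per-bin mass is the exact bin integral of the truncated, normalized
    exponential.  ``fractions`` are intensity fractions (they weight the
    normalized species histograms).
    """
    taus = np.atleast_1d(np.asarray(taus_ns, dtype=float))
    fracs = np.atleast_1d(np.asarray(fractions, dtype=float))
    if taus.shape != fracs.shape:
        raise ValueError("taus and fractions must align")
    if np.any(taus <= 0):
        raise ValueError("lifetimes must be positive")
    edges = np.linspace(0.0, period_ns, n_bins + 1)
    p = np.zeros(n_bins)
    total = fracs.sum()
    if total <= 0:
        raise ValueError("at least one positive fraction required")
    for tau, f in zip(taus, fracs):
        mass = np.exp(-edges[:-1] / tau) - np.exp(-edges[1:] / tau)
        p += (f / total) * mass / mass.sum()
    return p


def _disk_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _punctate_mito_mask(cell_mask: np.ndarray, fraction: float,
                        rng: np.random.Generator,
                        punctum_radius: float = 2.0) -> np.ndarray:
    """Random punctate disks inside the cell covering ~``fraction`` of it."""
    target = fraction * cell_mask.sum()
    mito = np.zeros_like(cell_mask)
    rows, cols = np.nonzero(cell_mask)
    if rows.size == 0:
        raise ValueError("zero-area cell")
    for _ in range(10_000):
        if mito.sum() >= target:
            break
        i = rng.integers(rows.size)
        puncta = _disk_mask(cell_mask.shape, (rows[i], cols[i]), punctum_radius)
        mito |= puncta & cell_mask
    return mito


def simulate_decay_image(spec: SceneSpec):
    """Simulate one scene; returns ``(nadph_decay, fad_decay, truth)``.

    NAD(P)H pixel decays are the free/bound two-exponential mixture with
    the cell's ``true_alpha_bound`` intensity fraction; background pixels
    are pure free NAD(P)H.  FAD is a mono-exponential whose rate is
    multiplied by ``mito_contrast`` in the mitochondrial puncta.  With
    ``poisson_noise=False`` the expected (float) histograms are returned,
    giving the exact noise-free limit used by closed-form oracles.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size

    label = np.zeros((h, w), dtype=np.int32)
    mito = np.zeros((h, w), dtype=bool)
    alpha = np.full((h, w), np.nan)
    tau = np.full((h, w), np.nan)
    nad_rate = np.full((h, w), float(spec.background_rate))
    fad_rate = np.full((h, w), float(spec.background_rate))

    for i, cell in enumerate(spec.cells):
        cmask = _disk_mask((h, w), cell.center, cell.radius_px)
        if not cmask.any():
            raise ValueError(f"cell {i} has zero area")
        label[cmask] = i + 1
        alpha[cmask] = cell.true_alpha_bound
        tau[cmask] = cell.true_tau_bound
        nad_rate[cmask] = cell.nadph_rate
        fad_rate[cmask] = cell.fad_rate
        cmito = _punctate_mito_mask(cmask, cell.mito_fraction, rng)
        mito |= cmito
        fad_rate[cmito] = cell.fad_rate * cell.mito_contrast

    n_bins, period = spec.n_time_bins, spec.laser_period_ns
    nad_expected = np.zeros((n_bins, h, w))
    bg_pdf = decay_histogram([spec.tau_free], [1.0], n_bins, period)
    bg = label == 0
    nad_expected[:, bg] = np.outer(bg_pdf, nad_rate[bg])
    for i, cell in enumerate(spec.cells):
        pdf = decay_histogram(
            [spec.tau_free, cell.true_tau_bound],
            [1.0 - cell.true_alpha_bound, cell.true_alpha_bound],
            n_bins, period)
        sel = label == i + 1
        nad_expected[:, sel] = np.outer(pdf, nad_rate[sel])

    fad_pdf = decay_histogram([spec.tau_fad], [1.0], n_bins, period)
    fad_expected = fad_pdf[:, None, None] * fad_rate[None, :, :]

    if spec.poisson_noise:
        nad_counts = rng.poisson(nad_expected).astype(np.uint16)
        fad_counts = rng.poisson(fad_expected).astype(np.uint16)
    else:
        nad_counts, fad_counts = nad_expected, fad_expected

    truth = GroundTruth(label_map=label, mito_mask=mito, alpha_map=alpha,
                        tau_map=tau, nadph_rate_map=nad_rate,
                        fad_rate_map=fad_rate)
    nadph = DecayImage(nad_counts, laser_period_ns=period, channel="NADPH")
    fad = DecayImage(fad_counts, laser_period_ns=period, channel="FAD")
    return nadph, fad, truth


@dataclass
class PopulationSpec:
    """Per-cell feature table across ordered differentiation stages.

    ``feature_means`` has shape ``(n_features, n_stages)``; features with
    ``monotone_mask`` True must have strictly ordered stage means (the
    intended "informative" features).  Cells are Gaussian around their
    stage mean with per-feature ``noise_sd``.
    """

    feature_means: np.ndarray
    monotone_mask: np.ndarray
    noise_sd: np.ndarray | float = 1.0
    cells_per_stage: int = 200
    seed: int = 0

    @property
    def n_features(self) -> int:
        return np.asarray(self.feature_means).shape[0]

    @property
    def n_stages(self) -> int:
        return np.asarray(self.feature_means).shape[1]

    def validate(self) -> None:
        means = np.asarray(self.feature_means, dtype=float)
        mono = np.asarray(self.monotone_mask, dtype=bool)
        if means.ndim != 2 or means.shape[1] < 2:
            raise ValueError("feature_means must be (n_features, n_stages>=2)")
        if mono.shape != (means.shape[0],):
            raise ValueError("monotone_mask must have one entry per feature")
        d = np.diff(means[mono], axis=1)
        if mono.any() and not np.all((d > 0).all(axis=1) | (d < 0).all(axis=1)):
            raise ValueError("monotone features must have strictly ordered stage means")


def simulate_population_features(spec: PopulationSpec) -> pd.DataFrame:
    """Sample the population table; columns f000.. plus ``stage``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    means = np.asarray(spec.feature_means, dtype=float)
    sds = np.broadcast_to(np.asarray(spec.noise_sd, dtype=float),
                          (spec.n_features,))
    rows = []
    for stage in range(spec.n_stages):
        x = means[:, stage] + sds * rng.standard_normal(
            (spec.cells_per_stage, spec.n_features))
        df = pd.DataFrame(x, columns=[f"f{i:03d}" for i in range(spec.n_features)])
        df.insert(0, "stage", stage)
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


@dataclass
class DivisionSpec:
    """Parent/daughter score tables with controlled inheritance.

    Parent scores are standard normal.  Each division draws a sibling
    score gap ``delta`` from the symmetric mode (mean ``delta_mean_sym``)
    with probability ``1 - asym_fraction``, else the asymmetric mode
    (mean ``delta_mean_asym``); both have sd ``delta_sd``, and deltas are
    taken as magnitudes.  Daughters sit at ``m +- delta/2`` around a pair
    midpoint built so that the parent-daughter Pearson correlation equals
    ``inheritance_r``: the midpoint's residual variance is reduced by the
    variance the signed half-gap adds (a variance budget; the half-gap is
    symmetric about zero, so it contributes ``E[delta^2]/4`` and
    ``inheritance_r**2 + E[delta^2]/4 <= 1`` is required).
    """

    n_pairs: int = 200
    inheritance_r: float = 0.8
    asym_fraction: float = 0.3
    delta_mean_sym: float = 0.3
    delta_mean_asym: float = 2.0
    delta_sd: float = 0.2
    site_pitch_um: float = 50.0     # micropattern grid spacing for positions
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.inheritance_r <= 1.0:
            raise ValueError("inheritance_r must be in [0, 1]")
        if not 0.0 <= self.asym_fraction <= 1.0:
            raise ValueError("asym_fraction must be in [0, 1]")
        if not self.delta_mean_asym > self.delta_mean_sym >= 0.0:
            raise ValueError("need delta_mean_asym > delta_mean_sym >= 0")
        if self.delta_sd < 0:
            raise ValueError("delta_sd must be nonnegative")
        if self.n_pairs < 1:
            raise ValueError("need at least one pair")

    def delta_second_moment(self) -> float:
        """E[delta^2] of the sibling gap under the two-mode mixture."""
        p = self.asym_fraction
        return ((1 - p) * (self.delta_mean_sym**2 + self.delta_sd**2)
                + p * (self.delta_mean_asym**2 + self.delta_sd**2))


def simulate_division_dataset(spec: DivisionSpec) -> pd.DataFrame:
    """One row per division: parent/daughter scores, truth label, position."""
    spec.validate()
    resid_var = 1.0 - spec.inheritance_r**2 - spec.delta_second_moment() / 4.0
    if resid_var < -1e-9:
        raise ValueError(
            "inheritance_r and delta spread are jointly infeasible: "
            "inheritance_r**2 + E[delta^2]/4 must be <= 1")
    resid_sd = np.sqrt(max(resid_var, 0.0))
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pairs
    parent = rng.standard_normal(n)
    asym = rng.random(n) < spec.asym_fraction
    delta_mean = np.where(asym, spec.delta_mean_asym, spec.delta_mean_sym)
    delta = np.abs(delta_mean + spec.delta_sd * rng.standard_normal(n))
    mid = spec.inheritance_r * parent + resid_sd * rng.standard_normal(n)
    side = rng.choice([-1.0, 1.0], size=n)

    grid = int(np.ceil(np.sqrt(n)))
    sites = np.arange(n)
    sx = (sites % grid) * spec.site_pitch_um
    sy = (sites // grid) * spec.site_pitch_um
    return pd.DataFrame({
        "pair_id": sites,
        "site_x_um": sx,
        "site_y_um": sy,
        "parent_score": parent,
        "daughter1_score": mid + side * delta / 2.0,
        "daughter2_score": mid - side * delta / 2.0,
        "true_pattern": np.where(asym, "M-asymmetric", "M-symmetric"),
    })
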