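"""Phasor-domain analysis of fluorescence-lifetime (FLIM) decay data.

The phasor transform maps a per-pixel fluorescence decay ``I(t)`` measured
over one laser period ``T`` to a point in the plane,

    g = sum_t I(t) cos(w t) / sum_t I(t),
    s = sum_t I(t) sin(w t) / sum_t I(t),        w = 2*pi*harmonic / T,

evaluated at time-bin centers.  Mono-exponential decays fall on the
"universal semicircle" ``(g - 1/2)^2 + s^2 = 1/4``; mixtures fall inside it
on the chord joining their pure components, with position proportional to
intensity fraction.  This fit-free representation is what makes lifetime
decomposition feasible at the low photon budgets (tens of photons per
pixel) typical of live-cell autofluorescence imaging.

NAD(P)H fluorescence is a two-species mixture of free coenzyme, whose
lifetime is fixed here at ``tau_free = 0.45 ns``, and enzyme-bound
coenzyme with variable lifetime ``tau_bound``.  :func:`resolve_bound_fraction`
reads the bound intensity fraction ``alpha_bound`` and ``tau_bound`` off
each pixel's phasor by the chord geometry: extend the line from the free
anchor through the pixel until it re-intersects the semicircle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TAU_FREE_NS",
    "DEFAULT_LASER_PERIOD_NS",
    "DecayImage",
    "PhasorMap",
    "LifetimeMap",
    "QC_OK",
    "QC_CLAMPED",
    "QC_INVALID",
    "omega_from_period",
    "monoexp_phasor",
    "mixture_phasor",
    "phasor_to_lifetime",
    "phasor_transform",
    "median_filter_phasor",
    "resolve_bound_fraction",
    "compute_orr",
]

#: Lifetime of free NAD(P)H in hematopoietic cells, fixed by calibration (ns).
TAU_FREE_NS = 0.45

#: One period of an 80 MHz pulsed laser (ns); the standard two-photon
#: Ti:Sapphire repetition rate.  All geometry is parameterized by omega, so
#: other repetition rates are supported by configuration.
DEFAULT_LASER_PERIOD_NS = 12.5

QC_OK = 0
QC_CLAMPED = 1
QC_INVALID = 2


@dataclass
class DecayImage:
    """Per-pixel photon decay histograms for one spectral channel.

    ``counts`` has shape ``(n_time_bins, H, W)``; plane ``k`` holds the
    photons detected in time bin ``k`` of the laser period.
    """

    counts: np.ndarray
    laser_period_ns: float = DEFAULT_LASER_PERIOD_NS
    channel: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be (n_time_bins, H, W)")
        if self.counts.shape[0] < 2:
            raise ValueError("need at least 2 time bins")
        if self.laser_period_ns <= 0:
            raise ValueError("laser period must be positive")

    @property
    def n_time_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[1:]

    def bin_centers(self) -> np.ndarray:
        dt = self.laser_period_ns / self.n_time_bins
        return (np.arange(self.n_time_bins) + 0.5) * dt

    def intensity(self) -> np.ndarray:
        """Total photons per pixel."""
        return self.counts.sum(axis=0)


@dataclass
class PhasorMap:
    """Per-pixel first-harmonic phasor coordinates.

    ``valid`` marks pixels with at least one photon; (g, s) is undefined
    (NaN) elsewhere.  ``omega`` is in rad/ns.
    """

    g: np.ndarray
    s: np.ndarray
    omega: float
    total_photons: np.ndarray
    harmonic: int = 1
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.isfinite(self.g) & np.isfinite(self.s)


@dataclass
class LifetimeMap:
    """Per-pixel free/bound NAD(P)H decomposition.

    ``qc_flag`` is 0 (ok), 1 (clamped to the physical chord) or 2
    (invalid: no photons or degenerate geometry).  ``tau_bound`` is NaN
    wherever it is undefined (invalid pixels, or alpha_bound == 0 where
    the bound species carries no intensity).
    """

    alpha_bound: np.ndarray
    tau_bound: np.ndarray
    tau_free: float
    qc_flag: np.ndarray

    def qc_fraction(self) -> dict[str, float]:
        n = self.qc_flag.size
        return {
            "ok": float(np.mean(self.qc_flag == QC_OK)),
            "clamped": float(np.mean(self.qc_flag == QC_CLAMPED)),
            "invalid": float(np.mean(self.qc_flag == QC_INVALID)),
        } if n else {"ok": 0.0, "clamped": 0.0, "invalid": 0.0}


def omega_from_period(laser_period_ns: float, harmonic: int = 1) -> float:
    """Angular modulation frequency (rad/ns) for a laser period in ns."""
    if laser_period_ns <= 0:
        raise ValueError("laser period must be positive")
    return 2.0 * np.pi * harmonic / laser_period_ns


def monoexp_phasor(tau_ns, omega: float):
    """Closed-form phasor of a mono-exponential decay.

    ``g = 1 / (1 + (w tau)^2)``, ``s = w tau g`` — the universal
    semicircle, approached exactly by a periodically excited decay.
    """
    wt = np.asarray(tau_ns, dtype=float) * omega
    g = 1.0 / (1.0 + wt**2)
    return g, wt * g


def mixture_phasor(fractions, taus_ns, omega: float):
    """Phasor of an intensity-weighted mixture of mono-exponentials.

    The transform is linear in intensity, so the mixture phasor is the
    convex combination of the pure-species phasors.
    """
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions < 0):
        raise ValueError("fractions must be nonnegative")
    total = fractions.sum()
    if total <= 0:
        raise ValueError("at least one positive fraction required")
    g, s = monoexp_phasor(np.asarray(taus_ns, dtype=float), omega)
    return float(np.dot(fractions, g) / total), float(np.dot(fractions, s) / total)


def phasor_to_lifetime(g, s, omega: float):
    """Invert semicircle phasor coordinates to a lifetime: tau = s / (w g)."""
    g = np.asarray(g, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.asarray(s, dtype=float) / (omega * g)


def phasor_transform(decay: DecayImage, harmonic: int = 1) -> PhasorMap:
    """First-harmonic phasor transform of a decay image.

    Uses bin-center timestamps; pixels with zero total photons are flagged
    invalid with NaN coordinates.
    """
    t = decay.bin_centers()
    omega = omega_from_period(decay.laser_period_ns, harmonic)
    counts = decay.counts.astype(float)
    total = counts.sum(axis=0)
    cos_w = np.cos(omega * t)
    sin_w = np.sin(omega * t)
    num_g = np.tensordot(cos_w, counts, axes=(0, 0))
    num_s = np.tensordot(sin_w, counts, axes=(0, 0))
    valid = total > 0
    if not valid.any():
        warnings.warn("all-zero decay image: every pixel flagged invalid",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(valid, num_g / total, np.nan)
        s = np.where(valid, num_s / total, np.nan)
    return PhasorMap(g=g, s=s, omega=omega, total_photons=total,
                     harmonic=harmonic, valid=valid)


def _masked_median_filter(values: np.ndarray, valid: np.ndarray,
                          window: int) -> np.ndarray:
    """Median over the window neighborhood, excluding invalid pixels.

    Borders use the reduced neighborhood that fits inside the image.
    Implemented by stacking shifted copies and taking a NaN-aware median,
    which is vectorized and fast for the 3x3 default.
    """
    h, w = values.shape
    r = window // 2
    padded = np.full((h + 2 * r, w + 2 * r), np.nan)
    padded[r:r + h, r:r + w] = np.where(valid, values, np.nan)
    stack = np.empty((window * window, h, w))
    k = 0
    for dy in range(window):
        for dx in range(window):
            stack[k] = padded[dy:dy + h, dx:dx + w]
            k += 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN neighborhoods
        out = np.nanmedian(stack, axis=0)
    # a valid pixel always has at least itself in the neighborhood
    return np.where(valid, out, np.nan)


def median_filter_phasor(p: PhasorMap, window: int = 3) -> PhasorMap:
    """Median-filter g and s independently to suppress shot noise.

    The default 3x3 window is the standard noise-reduction step applied to
    the coordinate matrices before lifetime decomposition.  Invalid pixels
    are excluded from every neighborhood and remain invalid.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window == 1:
        return PhasorMap(g=p.g.copy(), s=p.s.copy(), omega=p.omega,
                         total_photons=p.total_photons, harmonic=p.harmonic,
                         valid=p.valid.copy())
    g = _masked_median_filter(p.g, p.valid, window)
    s = _masked_median_filter(p.s, p.valid, window)
    return PhasorMap(g=g, s=s, omega=p.omega, total_photons=p.total_photons,
                     harmonic=p.harmonic, valid=p.valid.copy())


def resolve_bound_fraction(p: PhasorMap, tau_free: float = TAU_FREE_NS,
                           omega: float | None = None,
                           atol: float = 1e-12) -> LifetimeMap:
    """Decompose each phasor pixel into free/bound NAD(P)H components.

    The free-species anchor F is the semicircle point of ``tau_free``.  For
    a pixel P, the line through F and P is extended to its second
    intersection B with the semicircle; B is the pure bound species, so

        tau_bound  = s_B / (omega * g_B),
        alpha_bound = |P - F| / |B - F|.

    Pixels outside the physical chord (alpha outside [0, 1], or outside
    the semicircle — both routine under shot noise) are clamped and
    flagged rather than discarded, preserving per-cell statistics.
    Degenerate geometry (no second intersection with positive s) is
    flagged invalid.
    """
    if tau_free <= 0:
        raise ValueError("tau_free must be positive")
    omega = p.omega if omega is None else omega
    gf, sf = monoexp_phasor(tau_free, omega)

    g = np.asarray(p.g, dtype=float)
    s = np.asarray(p.s, dtype=float)
    alpha = np.zeros_like(g)
    tau = np.full_like(g, np.nan)
    qc = np.full(g.shape, QC_INVALID, dtype=np.int8)

    valid = p.valid & np.isfinite(g) & np.isfinite(s)
    dg = g - gf
    ds = s - sf
    d2 = dg**2 + ds**2

    # pixel coincides with the free anchor: pure free species
    at_anchor = valid & (d2 <= atol)
    alpha[at_anchor] = 0.0
    qc[at_anchor] = QC_OK

    work = valid & ~at_anchor
    # F lies on the circle centered c=(1/2, 0), radius 1/2; parametrize
    # X = F + t*(P-F).  t=0 is one root; the other is
    # t_B = -2 <F-c, P-F> / |P-F|^2.
    with np.errstate(divide="ignore", invalid="ignore"):
        t_b = -2.0 * ((gf - 0.5) * dg + sf * ds) / d2
    gb = gf + t_b * dg
    sb = sf + t_b * ds

    # B must lie forward of F with positive s to encode a real lifetime
    # longer than tau_free
    geom_ok = work & (t_b > atol) & (sb > atol)
    qc[work & ~geom_ok] = QC_INVALID

    with np.errstate(divide="ignore", invalid="ignore"):
        a_raw = np.where(geom_ok, 1.0 / t_b, 0.0)
        tau_b = sb / (omega * gb)

    inside = geom_ok & (a_raw <= 1.0 + atol)
    beyond = geom_ok & (a_raw > 1.0 + atol)  # pixel outside the semicircle
    alpha[inside] = np.clip(a_raw[inside], 0.0, 1.0)
    tau[geom_ok] = tau_b[geom_ok]
    qc[inside] = QC_OK
    alpha[beyond] = 1.0
    qc[beyond] = QC_CLAMPED

    # bound lifetime must exceed the free lifetime where we call it ok
    short = geom_ok & (tau_b <= tau_free)
    qc[short] = QC_INVALID
    tau[short] = np.nan

    return LifetimeMap(alpha_bound=alpha, tau_bound=tau, tau_free=tau_free,
                       qc_flag=qc)


def compute_orr(fad_intensity: np.ndarray, nadph_intensity: np.ndarray,
                mito_mask: np.ndarray, cyto_mask: np.ndarray):
    """Baseline-corrected optical redox ratio (ORR) for one cell.

    The observed FAD channel contains a constant spectral-bleed fraction of
    the NAD(P)H signal, so the observed ratio is the true ratio plus a
    constant.  Taking the FAD/NAD(P)H ratio over the mitochondrial region
    and subtracting the cytoplasmic/nuclear ratio cancels that constant:

        orr_corrected = (sum FAD / sum NADPH)_mito - (sum FAD / sum NADPH)_cyto

    Returns ``(orr_corrected, baseline)`` where ``baseline`` is the
    cytoplasmic ratio; both NaN when either region is empty or has zero
    NAD(P)H signal.
    """
    mito_mask = np.asarray(mito_mask, dtype=bool)
    cyto_mask = np.asarray(cyto_mask, dtype=bool)
    if np.any(mito_mask & cyto_mask):
        raise ValueError("mito and cyto masks must be disjoint")
    nad_m = float(np.sum(nadph_intensity[mito_mask])) if mito_mask.any() else 0.0
    nad_c = float(np.sum(nadph_intensity[cyto_mask])) if cyto_mask.any() else 0.0
    if nad_m <= 0 or nad_c <= 0:
        return float("nan"), float("nan")
    ratio_m = float(np.sum(fad_intensity[mito_mask])) / nad_m
    ratio_c = float(np.sum(fad_intensity[cyto_mask])) / nad_c
    return ratio_m - ratio_c, ratio_c
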