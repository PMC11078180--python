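"""Documented end-to-end benchmarks on ground-truth-known synthetic data.

Each function defines one fixed study condition — scene geometry, photon
budget, effect sizes, sample sizes — and recomputes a headline quantity
of the pipeline from scratch.  The conditions are part of the package
contract (the test suite asserts on them at fixed tolerances), so they
are deliberately centralized here rather than scattered through tests.

All randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import division as dv
from . import phasor as ph
from . import pipeline as pl
from . import scoring as sc
from . import selection as sel
from . import synthetic as syn
from .features import build_default_registry
from .io import PipelineConfig

__all__ = [
    "COUMARIN6_LIFETIME_NS",
    "coumarin_lifetime_recovery",
    "robust_scaling_anchors",
    "trending_index_examples",
    "lifetime_recovery",
    "selection_power",
    "latent_recovery",
    "division_recovery",
    "binning_robustness",
]

#: Reference lifetime of the Coumarin 6 calibration dye (ns).
COUMARIN6_LIFETIME_NS = 2.5


def coumarin_lifetime_recovery(n_bins: int = 1024,
                               laser_period_ns: float = 12.5) -> dict:
    """Simulate an ideal Coumarin 6 decay and invert its phasor.

    A noise-free mono-exponential at the 2.5 ns calibration lifetime is
    histogrammed over one laser period, phasor-transformed at the first
    harmonic, checked against the universal semicircle and inverted via
    ``tau = s / (omega g)``.
    """
    pdf = syn.decay_histogram([COUMARIN6_LIFETIME_NS], [1.0], n_bins,
                              laser_period_ns)
    decay = ph.DecayImage(pdf[:, None, None], laser_period_ns=laser_period_ns)
    pm = ph.phasor_transform(decay)
    g, s = float(pm.g[0, 0]), float(pm.s[0, 0])
    return {
        "g": g,
        "s": s,
        "semicircle_deviation": abs((g - 0.5) ** 2 + s**2 - 0.25),
        "tau_ns": float(ph.phasor_to_lifetime(g, s, pm.omega)),
    }


def robust_scaling_anchors() -> dict:
    """Fit the robust normalization on 0..10 and transform its anchors.

    Under linear-interpolation quartiles the training set has median 5
    and quartiles 2.5 / 7.5; the half-IQR convention maps them to
    0 / -1 / +1.
    """
    train = np.arange(11, dtype=float)
    scaler = sc.RobustScaler().fit(train)
    med, q1, q3 = (float(scaler.median_[0]), float(scaler.q1_[0]),
                   float(scaler.q3_[0]))
    t = scaler.transform(np.array([med, q1, q3]))
    return {"median_scaled": float(t[0]), "q1_scaled": float(t[1]),
            "q3_scaled": float(t[2])}


def trending_index_examples() -> dict:
    """TI of the reference stage-mean sequences over four stages."""
    return {
        "increasing": sel.trending_index([0.0, 1.0, 2.0, 3.0]),
        "decreasing": sel.trending_index([3.0, 2.0, 1.0, 0.0]),
        "fluctuating": sel.trending_index([0.0, 1.0, 0.0, 1.0]),
    }


def _recovery_scene(rate: float, noise: bool, background: float,
                    seed: int) -> syn.SceneSpec:
    cells = []
    for i in range(9):
        cells.append(syn.CellSpec(center=(32.0 + 64 * (i // 3),
                                          32.0 + 64 * (i % 3)),
                                  radius_px=14.0, true_alpha_bound=0.5,
                                  true_tau_bound=3.4, nadph_rate=rate,
                                  fad_rate=rate / 2.0))
    return syn.SceneSpec(image_size=(192, 192), cells=cells,
                         background_rate=background, poisson_noise=noise,
                         seed=seed)


def lifetime_recovery(seed: int = 0) -> dict:
    """End-to-end free/bound recovery, noise-free and at 25 photons/pixel.

    Noise-free (expected histograms, empty background so border
    neighborhoods stay clean): every per-cell mean must track truth to
    ~1e-3 relative error, limited only by time discretization.  At the
    live-cell photon budget of 25 photons/pixel the per-cell means are
    averaged over the scene's nine cells, which isolates the method's
    bias from single-cell Poisson sampling noise.
    """
    out = {}
    for label, spec in (("noisefree", _recovery_scene(25.0, False, 0.0, seed)),
                        ("photon25", _recovery_scene(25.0, True, 0.2, seed))):
        nadph, _, truth = syn.simulate_decay_image(spec)
        pm = ph.median_filter_phasor(ph.phasor_transform(nadph))
        lt = ph.resolve_bound_fraction(pm)
        a_err, t_err = [], []
        for i, cell in enumerate(spec.cells):
            m = truth.label_map == i + 1
            a_err.append(np.nanmean(lt.alpha_bound[m]) / cell.true_alpha_bound - 1)
            t_err.append(np.nanmean(lt.tau_bound[m]) / cell.true_tau_bound - 1)
        if label == "noisefree":
            out[label] = {"alpha_rel_err": float(np.max(np.abs(a_err))),
                          "tau_rel_err": float(np.max(np.abs(t_err)))}
        else:
            out[label] = {"alpha_rel_err": float(abs(np.mean(a_err))),
                          "tau_rel_err": float(abs(np.mean(t_err)))}
    return out


def _selection_population(seed: int) -> pd.DataFrame:
    """10 informative + 10 noise features, 4 stages, 200 cells/stage.

    Informative features step 1.5 noise-sd per stage (alternating
    direction), which puts the single-feature logistic F1 near 0.75 and
    |TI| at 1; noise features carry no signal at all.
    """
    stages = np.arange(4, dtype=float)
    means = np.zeros((20, 4))
    for i in range(10):
        means[i] = (1 if i % 2 == 0 else -1) * 1.5 * stages
    spec = syn.PopulationSpec(
        feature_means=means,
        monotone_mask=np.r_[np.ones(10, bool), np.zeros(10, bool)],
        noise_sd=1.0, cells_per_stage=200, seed=seed)
    return syn.simulate_population_features(spec)


def selection_power(seed: int = 0) -> dict:
    """Precision/recall of the joint F1+TI gate on the documented benchmark."""
    a = _selection_population(seed)
    b = _selection_population(seed + 1)
    feats = [f"f{i:03d}" for i in range(20)]
    res = sel.select_features(a, b, feats, seed=seed)
    selected = set(res.selected)
    truth = {f"f{i:03d}" for i in range(10)}
    tp = len(selected & truth)
    return {
        "precision": tp / len(selected) if selected else 1.0,
        "recall": tp / len(truth),
        "n_selected": len(selected),
    }


def latent_recovery(seed: int = 0, n: int = 500, p: int = 11) -> dict:
    """|corr(LV1, z)| for one-factor data x = w z + eps (11 features)."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    w = rng.uniform(0.5, 1.5, p)
    x = np.outer(z, w) + 0.3 * rng.standard_normal((n, p))
    cols = [f"g{i:02d}" for i in range(p)]
    table = pd.DataFrame(x, columns=cols)
    model = sc.fit_mob_model(table, cols, anchor_feature=cols[0], seed=seed)
    scores = sc.score_cells(model, table)
    return {"abs_corr": float(abs(np.corrcoef(scores, z)[0, 1]))}


def division_recovery(seed: int = 0) -> dict:
    """Mixture-threshold classification and inheritance on the benchmark.

    500 divisions, sibling-gap modes 0.3 / 2.0 (sd 0.2), 30% asymmetric,
    inheritance 0.8; reports classification accuracy vs truth, the
    estimated parent-daughter r and its Fisher 95% CI.
    """
    spec = syn.DivisionSpec(n_pairs=500, asym_fraction=0.3,
                            delta_mean_sym=0.3, delta_mean_asym=2.0,
                            delta_sd=0.2, inheritance_r=0.8, seed=seed)
    df = syn.simulate_division_dataset(spec)
    df["delta_mob"] = dv.delta_mob(df["daughter1_score"],
                                   df["daughter2_score"])
    fit = dv.fit_delta_mixture(df["delta_mob"], seed=seed)
    labeled = dv.classify_divisions(df, fit)
    acc = float((labeled["pattern"] == df["true_pattern"]).mean()) \
        if not fit.collapsed else 0.0
    corr = dv.inheritance_correlation(df)
    r = float(corr.loc["all", "r"])
    # siblings share a pair midpoint, so the 2N parent-daughter points are
    # clustered; the Fisher CI uses the effective sample size
    rho_sib = float(np.corrcoef(df["daughter1_score"],
                                df["daughter2_score"])[0, 1])
    n_pts = 2 * len(df) / (1.0 + max(rho_sib, 0.0))
    half = 1.96 / np.sqrt(n_pts - 3)
    ci = (float(np.tanh(np.arctanh(r) - half)),
          float(np.tanh(np.arctanh(r) + half)))
    return {"threshold": fit.threshold, "accuracy": acc, "r": r,
            "r_ci": ci, "true_r": spec.inheritance_r,
            "r_in_ci": bool(ci[0] <= spec.inheritance_r <= ci[1])}


BINNING_FEATURES = ["nadph_mito_average", "alpha_bound_mito_average",
                    "tau_bound_mito_average", "orr_corrected", "morph_size"]


def _binning_scene(seed: int, offset: int) -> syn.SceneSpec:
    rng = np.random.default_rng([seed, offset])
    cells = []
    for i in range(16):
        u = rng.random()  # latent "stemness" level per cell
        cells.append(syn.CellSpec(
            center=(40.0 + 80 * (i // 4), 40.0 + 80 * (i % 4)),
            radius_px=10.0 + 3.0 * u,
            true_alpha_bound=0.3 + 0.4 * u,
            true_tau_bound=2.6 + 1.2 * u,
            nadph_rate=20.0 + 10.0 * u,
            fad_rate=12.0))
    return syn.SceneSpec(image_size=(320, 320), cells=cells,
                         background_rate=0.2, seed=int(
                             np.random.SeedSequence([seed, offset])
                             .generate_state(1)[0] % (2**31)))


def binning_robustness(seed: int = 0) -> dict:
    """Correlation of MOB scores from native vs 2x2-binned images.

    Two 16-cell scenes at ~20-30 photons/pixel are processed natively
    and after 2x2 photon binning (which quadruples photons/pixel and
    halves resolution).  A latent model over five representative
    features is fitted on the native cells; binned cells are normalized
    against their own population (independent acquisitions are scaled
    independently) and scored with the same loadings.  Cells are matched
    across resolutions by centroid.
    """
    cfg_native = PipelineConfig()
    cfg_binned = dataclasses.replace(cfg_native, pixel_size_um=0.36,
                                     min_cell_size_px=50)
    registry = build_default_registry()

    native_rows, binned_rows = [], []
    for offset in (0, 1):
        spec = _binning_scene(seed, offset)
        nadph, fad, _ = syn.simulate_decay_image(spec)
        res_n = pl.process_scene(nadph, fad, cfg_native, registry)
        res_b = pl.process_scene(pl.bin_decay_2x2(nadph),
                                 pl.bin_decay_2x2(fad), cfg_binned, registry)
        # match cells across resolutions by centroid (binned coords x2)
        for _, row in res_n.features.iterrows():
            cy, cx = row["centroid_y"], row["centroid_x"]
            d = np.hypot(res_b.features["centroid_y"] * 2 - cy,
                         res_b.features["centroid_x"] * 2 - cx)
            if len(d) and d.min() < 10.0:
                native_rows.append(row)
                binned_rows.append(res_b.features.iloc[int(d.idxmin())])
    native = pd.DataFrame(native_rows).reset_index(drop=True)
    binned = pd.DataFrame(binned_rows).reset_index(drop=True)

    model = sc.fit_mob_model(native, BINNING_FEATURES,
                             anchor_feature="tau_bound_mito_average",
                             seed=seed)
    s_native = sc.score_cells(model, native)
    b_scaler = sc.RobustScaler().fit(binned[BINNING_FEATURES].to_numpy())
    model_b = dataclasses.replace(model, median=b_scaler.median_,
                                  q1=b_scaler.q1_, q3=b_scaler.q3_)
    s_binned = sc.score_cells(model_b, binned)
    ok = np.isfinite(s_native) & np.isfinite(s_binned)
    r = float(np.corrcoef(s_native[ok], s_binned[ok])[0, 1])
    return {"r": r, "n_cells": int(ok.sum())}
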