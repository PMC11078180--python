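"""The MOB score: a latent-variable summary of metabolic stemness.

Representative per-cell features are robust-scaled against a training
reference (stem cells, or all cells in paired-daughter studies) so that
the training median maps to 0 and the first/third quartiles map to -1/+1,
density-based outliers are removed, conditions are shuffled and trimmed
to equal n, and a 3-dimensional maximum-likelihood linear factor model is
fit by EM.  The first latent variable (LV1) is the MOB score; the Pearson correlation between
LV1 and each scaled feature is that feature's weight.  The sign of LV1 is
arbitrary in a factor model, so it is anchored to a named feature that is
known to be elevated in stem cells (mitochondrial tau_bound average by
default), making orientation reproducible on unlabeled data.

A two-component Gaussian mixture over scores yields a maximum-likelihood
threshold between stem-like and differentiated cells.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.decomposition import FactorAnalysis
from sklearn.mixture import GaussianMixture

__all__ = [
    "RobustScaler",
    "MOBModel",
    "remove_outliers",
    "trim_and_shuffle",
    "fit_mob_model",
    "score_cells",
    "stemness_threshold",
    "two_gaussian_threshold",
    "DEFAULT_ANCHOR_FEATURE",
]

#: Feature whose weight fixes the sign of the score: mitochondrial
#: tau_bound is higher in stem cells, so its weight must be positive.
DEFAULT_ANCHOR_FEATURE = "tau_bound_mito_average"


class RobustScaler:
    """Median/quartile normalization with the half-IQR convention.

    ``x -> (x - median) / ((q3 - q1) / 2)`` so the training median maps to
    0 and, by construction, the first and third quartiles map exactly to
    -1 and +1.  (The common full-IQR convention would map the quartiles to
    +-0.5 instead; it is available via ``half_iqr=False``.)  Quartiles use
    linear interpolation.  A feature with zero interquartile spread on the
    training set cannot be scaled and is rejected.
    """

    def __init__(self, half_iqr: bool = True):
        self.half_iqr = half_iqr
        self.median_: np.ndarray | None = None
        self.q1_: np.ndarray | None = None
        self.q3_: np.ndarray | None = None

    def fit(self, x) -> "RobustScaler":
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x.reshape(-1, 1)
        self.median_ = np.nanmedian(x, axis=0)
        self.q1_ = np.nanpercentile(x, 25, axis=0)
        self.q3_ = np.nanpercentile(x, 75, axis=0)
        if np.any(self.q3_ - self.q1_ <= 0):
            bad = np.nonzero(self.q3_ - self.q1_ <= 0)[0]
            raise ValueError(f"zero interquartile spread in column(s) {bad.tolist()}")
        return self

    def transform(self, x):
        if self.median_ is None:
            raise RuntimeError("scaler is not fitted")
        x = np.asarray(x, dtype=float)
        squeeze = x.ndim == 1
        if squeeze:
            x = x.reshape(-1, 1)
        scale = (self.q3_ - self.q1_) / 2.0 if self.half_iqr \
            else (self.q3_ - self.q1_)
        out = (x - self.median_) / scale
        return out.ravel() if squeeze else out

    def fit_transform(self, x):
        return self.fit(x).transform(x)


def remove_outliers(table: pd.DataFrame, feature_ids: list[str],
                    eps: float | None = None, min_samples: int = 5,
                    gap_factor: float = 3.0):
    """Drop density-based (DBSCAN) noise points from a feature table.

    Clustering runs on robustly standardized features (median/IQR, so the
    outliers themselves do not distort the scale).  When ``eps`` is not
    given it is chosen from the sorted k-distance curve
    (k = ``min_samples``): genuine outliers sit beyond a large gap in
    that curve, so eps is the midpoint of the largest gap when that gap
    exceeds ``gap_factor`` times the median k-distance, and just above
    the largest k-distance otherwise (meaning: no outlier regime, remove
    nothing).  Returns ``(filtered, outlier_index, eps_used)``; refuses
    to proceed if everything is labeled noise.
    """
    x = table[feature_ids].to_numpy(dtype=float)
    if x.shape[0] < min_samples:
        raise ValueError("fewer rows than min_samples")
    med = np.median(x, axis=0)
    iqr = np.percentile(x, 75, axis=0) - np.percentile(x, 25, axis=0)
    iqr[iqr == 0] = 1.0
    z = (x - med) / iqr
    if eps is None:
        from sklearn.neighbors import NearestNeighbors
        nn = NearestNeighbors(n_neighbors=min_samples).fit(z)
        kdist = np.sort(nn.kneighbors(z)[0][:, -1])
        gaps = np.diff(kdist)
        i = int(np.argmax(gaps)) if gaps.size else 0
        if gaps.size and gaps[i] > gap_factor * np.median(kdist):
            eps = float((kdist[i] + kdist[i + 1]) / 2)
        else:
            eps = float(kdist[-1] * 1.05) or 1.0
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(z)
    noise = labels == -1
    if noise.all():
        raise ValueError(
            f"all rows flagged as noise (eps={eps:.3g}); inspect features")
    return table.loc[~noise].copy(), table.index[noise], eps


def trim_and_shuffle(tables: dict[str, pd.DataFrame], seed: int = 0):
    """Shuffle each condition and trim all to the smallest n.

    Sampling is without replacement, so trimming never duplicates rows;
    equal n removes population-size bias from downstream comparisons.
    """
    if any(len(df) == 0 for df in tables.values()):
        empty = [k for k, df in tables.items() if len(df) == 0]
        raise ValueError(f"condition(s) with zero cells: {empty}")
    n = min(len(df) for df in tables.values())
    rng = np.random.default_rng(seed)
    out = {}
    for key in tables:
        idx = rng.permutation(len(tables[key]))[:n]
        out[key] = tables[key].iloc[idx].reset_index(drop=True)
    return out


@dataclass
class MOBModel:
    """Fitted normalization anchors plus latent loadings and weights."""

    feature_ids: list[str]
    median: np.ndarray
    q1: np.ndarray
    q3: np.ndarray
    loadings: np.ndarray          # (n_latent, n_features)
    mean: np.ndarray              # feature means of the scaled training set
    noise_variance: np.ndarray
    sign_orientation: int
    weights: np.ndarray           # corr(LV1, scaled feature)
    anchor_feature: str
    n_latent: int = 3
    half_iqr: bool = True
    registry_version: str = ""

    def scaler(self) -> RobustScaler:
        sc = RobustScaler(half_iqr=self.half_iqr)
        sc.median_, sc.q1_, sc.q3_ = (np.asarray(self.median),
                                      np.asarray(self.q1), np.asarray(self.q3))
        return sc

    def to_json(self) -> str:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in vars(self).items()}
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MOBModel":
        d = json.loads(text)
        for k in ("median", "q1", "q3", "loadings", "mean",
                  "noise_variance", "weights"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


def fit_mob_model(table: pd.DataFrame, feature_ids: list[str],
                  n_latent: int = 3,
                  anchor_feature: str = DEFAULT_ANCHOR_FEATURE,
                  training_reference: pd.DataFrame | None = None,
                  half_iqr: bool = True, seed: int = 0,
                  noise_variance_init: np.ndarray | None = None,
                  registry_version: str = "") -> MOBModel:
    """Fit scaling anchors and the maximum-likelihood latent factor model.

    ``training_reference`` supplies the normalization anchors (the stem
    population in differentiation studies); defaults to ``table`` itself
    (the all-cells convention of paired-daughter studies).  Requires at
    least 5 rows per feature.

    ``noise_variance_init`` defaults to the unit-variance EM start.  An
    all-zero start is accepted but not recommended: zero per-feature
    noise is an absorbing fixed point of the EM update, so the fit stalls
    in a degenerate solution where a couple of features dominate the
    latent posterior.
    """
    if anchor_feature not in feature_ids:
        raise ValueError(f"anchor feature {anchor_feature!r} not among features")
    x_raw = table[feature_ids].to_numpy(dtype=float)
    if not np.isfinite(x_raw).all():
        raise ValueError("fit requires finite feature values; filter flagged rows")
    if x_raw.shape[0] < 5 * len(feature_ids):
        raise ValueError("need at least 5 rows per feature to fit the model")
    ref = (training_reference if training_reference is not None
           else table)[feature_ids].to_numpy(dtype=float)
    scaler = RobustScaler(half_iqr=half_iqr).fit(ref)
    x = scaler.transform(x_raw)
    if np.linalg.matrix_rank(np.cov(x, rowvar=False)) < len(feature_ids):
        raise ValueError("singular feature covariance; drop collinear features")

    fa = FactorAnalysis(n_components=n_latent,
                        noise_variance_init=noise_variance_init,
                        random_state=seed)
    with warnings.catch_warnings():
        # log(0) from an explicit zero noise-variance start is benign
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        fa.fit(x)
    lv = fa.transform(x)[:, 0]
    if np.std(lv) == 0:
        raise ValueError("factor model did not converge to a nonzero LV1")
    weights = np.array([np.corrcoef(lv, x[:, j])[0, 1]
                        for j in range(x.shape[1])])
    a_idx = feature_ids.index(anchor_feature)
    orientation = 1 if weights[a_idx] >= 0 else -1
    weights = orientation * weights
    return MOBModel(feature_ids=list(feature_ids), median=scaler.median_,
                    q1=scaler.q1_, q3=scaler.q3_,
                    loadings=fa.components_, mean=fa.mean_,
                    noise_variance=fa.noise_variance_,
                    sign_orientation=orientation, weights=weights,
                    anchor_feature=anchor_feature, n_latent=n_latent,
                    half_iqr=half_iqr, registry_version=registry_version)


def _fa_scores(model: MOBModel, x_scaled: np.ndarray) -> np.ndarray:
    """LV scores via the Gaussian posterior mean of the fitted model."""
    w = model.loadings                     # (k, p)
    psi = np.maximum(model.noise_variance, 1e-12)
    wpsi = w / psi                         # (k, p)
    cov_z = np.linalg.inv(np.eye(w.shape[0]) + wpsi @ w.T)
    return (x_scaled - model.mean) @ wpsi.T @ cov_z


def score_cells(model: MOBModel, table: pd.DataFrame) -> pd.Series:
    """MOB score per cell: oriented LV1 of the scaled features.

    Rows with missing (NaN) features are not scored (NaN result) — the
    model is linear and deterministic, so missingness must be explicit.
    """
    x_raw = table[model.feature_ids].to_numpy(dtype=float)
    ok = np.isfinite(x_raw).all(axis=1)
    scores = np.full(x_raw.shape[0], np.nan)
    if ok.any():
        x = model.scaler().transform(x_raw[ok])
        scores[ok] = model.sign_orientation * _fa_scores(model, x)[:, 0]
    return pd.Series(scores, index=table.index, name="mob_score")


def two_gaussian_threshold(means, sds, weights, collapse_tol: float = 1e-3):
    """Decision boundary between two univariate Gaussian components.

    The score where the weighted component densities are equal, searched
    between the component means (equal-posterior point); reduces to the
    midpoint for equal weights and variances.  Returns None when the
    components have collapsed (means closer than ``collapse_tol``).
    """
    order = np.argsort(means)
    (m1, m2) = np.asarray(means, dtype=float)[order]
    (s1, s2) = np.asarray(sds, dtype=float)[order]
    (w1, w2) = np.asarray(weights, dtype=float)[order]
    if m2 - m1 < collapse_tol:
        return None
    # log w1 - (x-m1)^2/(2 s1^2) - log s1 = log w2 - (x-m2)^2/(2 s2^2) - log s2
    a = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    b = m1 / s1**2 - m2 / s2**2
    c = (m2**2 / (2 * s2**2) - m1**2 / (2 * s1**2)
         + np.log((w1 * s2) / (w2 * s1)))
    if abs(a) < 1e-12:
        if abs(b) < 1e-12:
            return None
        x = -c / b
        return float(x) if m1 <= x <= m2 else float((m1 + m2) / 2)
    roots = np.roots([a, b, c])
    roots = roots[np.isreal(roots)].real
    inside = roots[(roots >= m1) & (roots <= m2)]
    if inside.size == 0:
        return float((m1 + m2) / 2)
    return float(inside[0])


def mixture_has_dip(means, sds, weights, threshold) -> bool:
    """True when the two-component mixture density has a genuine antimode.

    A threshold is only meaningful between two actual peaks: the mixture
    density at the candidate threshold must fall below its value at both
    component means.  A two-component fit to unimodal data places its
    single mode between the fitted means, so this check fails there.
    """
    from scipy.stats import norm
    m = np.asarray(means, dtype=float)
    s = np.asarray(sds, dtype=float)
    w = np.asarray(weights, dtype=float)

    def pdf(x):
        return float(np.sum(w * norm.pdf(x, m, s)))

    return pdf(threshold) < (1.0 - 1e-9) * min(pdf(m[0]), pdf(m[1]))


def stemness_threshold(scores, seed: int = 0, collapse_tol: float = 1e-3):
    """Maximum-likelihood stem/differentiated score threshold.

    Fits a two-component Gaussian mixture by EM and returns the
    equal-posterior score between the component means, together with the
    fitted mixture parameters.  Returns ``(None, params)`` with a
    ``collapsed`` flag when the data are effectively unimodal.
    """
    x = np.asarray(scores, dtype=float).reshape(-1, 1)
    x = x[np.isfinite(x[:, 0])].reshape(-1, 1)
    if x.shape[0] < 4:
        raise ValueError("need at least 4 finite scores")
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=5).fit(x)
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    thr = two_gaussian_threshold(means, sds, weights, collapse_tol)
    if thr is not None and not mixture_has_dip(means, sds, weights, thr):
        thr = None
    params = {"means": np.sort(means).tolist(),
              "sds": sds[np.argsort(means)].tolist(),
              "weights": weights[np.argsort(means)].tolist(),
              "collapsed": thr is None}
    return thr, params
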