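"""Division-pattern analysis of paired daughter cells (PDCs).

Micropatterned single stem cells are imaged before division and their two
daughters after; the site position ties daughters back to their parent.
The absolute MOB-score gap between siblings (delta-MOB) is bimodal: a
low mode (metabolically symmetric divisions) and a high mode (asymmetric
divisions).  A two-component Gaussian mixture fit to the gaps yields the
threshold separating the patterns; parent-daughter score correlation
quantifies metabolic inheritance; post-division trajectories and
condition screens summarize how each pattern maintains or loses
stemness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.mixture import GaussianMixture

from .scoring import mixture_has_dip, two_gaussian_threshold

__all__ = [
    "MixtureFit",
    "pair_daughters",
    "delta_mob",
    "fit_delta_mixture",
    "classify_divisions",
    "inheritance_correlation",
    "score_dynamics",
    "condition_screen",
]


def delta_mob(d1, d2) -> np.ndarray:
    """Absolute sibling score difference; order-free by construction."""
    return np.abs(np.asarray(d1, dtype=float) - np.asarray(d2, dtype=float))


def pair_daughters(pre: pd.DataFrame, post: pd.DataFrame,
                   site_radius: float,
                   x_col: str = "x", y_col: str = "y",
                   score_col: str = "mob_score") -> pd.DataFrame:
    """Assign post-division cells to micropattern sites and form pairs.

    ``pre`` holds one parent per site (columns ``x, y, score``); each
    ``post`` cell is assigned to the nearest parent position within
    ``site_radius``.  Sites with exactly two post cells become division
    records; sites with one cell (no division) produce none, and sites
    with more than two (a second division) are flagged and excluded.

    Returns a DataFrame with columns ``pair_id, parent_score,
    daughter1_score, daughter2_score, delta_mob`` plus an ``excluded``
    frame attribute listing crowded sites.
    """
    sites = pre[[x_col, y_col]].to_numpy(dtype=float)
    post_xy = post[[x_col, y_col]].to_numpy(dtype=float)
    if sites.size == 0 or post_xy.size == 0:
        return pd.DataFrame(columns=["pair_id", "parent_score",
                                     "daughter1_score", "daughter2_score",
                                     "delta_mob"])
    d2 = ((post_xy[:, None, :] - sites[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)
    within = np.sqrt(d2[np.arange(len(post_xy)), nearest]) <= site_radius

    records, excluded = [], []
    for site_idx in range(len(sites)):
        members = np.nonzero((nearest == site_idx) & within)[0]
        if members.size == 2:
            s1, s2 = post.iloc[members][score_col].to_numpy(dtype=float)
            records.append({
                "pair_id": int(pre.index[site_idx]),
                "parent_score": float(pre.iloc[site_idx][score_col]),
                "daughter1_score": float(s1),
                "daughter2_score": float(s2),
                "delta_mob": abs(s1 - s2),
            })
        elif members.size > 2:
            excluded.append(int(pre.index[site_idx]))
    out = pd.DataFrame(records, columns=["pair_id", "parent_score",
                                         "daughter1_score", "daughter2_score",
                                         "delta_mob"])
    out.attrs["excluded_sites"] = excluded
    return out


@dataclass
class MixtureFit:
    """Two-component Gaussian mixture over delta-MOB with its threshold."""

    means: np.ndarray      # ascending
    sds: np.ndarray
    weights: np.ndarray
    threshold: float | None

    @property
    def collapsed(self) -> bool:
        return self.threshold is None


def fit_delta_mixture(deltas, seed: int = 0, min_n: int = 20,
                      collapse_tol: float = 1e-2) -> MixtureFit:
    """EM fit of the double Gaussian over sibling score gaps.

    Initialized at the 25th/75th percentiles of the gaps for a
    deterministic, seed-stable start.  The threshold is the
    equal-posterior density intersection between the two component means
    (the midpoint when weights and variances are equal).  Unimodal data
    yield no genuine antimode between the fitted means (or collapse the
    components outright); the fit is then flagged and no threshold is
    returned.
    """
    x = np.asarray(deltas, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} divisions to fit the mixture")
    init = np.percentile(x, [25, 75]).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, means_init=init,
                         random_state=seed).fit(x.reshape(-1, 1))
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel())[order]
    weights = gm.weights_.ravel()[order]
    thr = two_gaussian_threshold(means, sds, weights, collapse_tol)
    if thr is not None and not mixture_has_dip(means, sds, weights, thr):
        thr = None
    return MixtureFit(means=means, sds=sds, weights=weights, threshold=thr)


def classify_divisions(records: pd.DataFrame, fit: MixtureFit,
                       delta_col: str = "delta_mob") -> pd.DataFrame:
    """Label each division M-symmetric / M-asymmetric by the threshold.

    Requires an explicit fitted threshold; collapsed fits leave every
    pair unclassified (None) rather than silently reusing a stale cut.
    """
    out = records.copy()
    if fit.collapsed:
        out["pattern"] = None
        return out
    out["pattern"] = np.where(out[delta_col] > fit.threshold,
                              "M-asymmetric", "M-symmetric")
    return out


def inheritance_correlation(records: pd.DataFrame,
                            group_col: str | None = None) -> pd.DataFrame:
    """Parent-daughter Pearson r with a zero-slope p value, per group.

    Each daughter contributes one (parent, daughter) point.  Groups with
    fewer than 3 pairs, or with zero variance on either axis, yield NaN
    with an explanatory flag.
    """
    def one(df: pd.DataFrame) -> dict:
        p = df["parent_score"].to_numpy(dtype=float)
        parent = np.concatenate([p, p])
        daughter = np.concatenate([df["daughter1_score"].to_numpy(dtype=float),
                                   df["daughter2_score"].to_numpy(dtype=float)])
        if len(df) < 3:
            return {"r": np.nan, "p": np.nan, "n_pairs": len(df),
                    "flag": "too_few_pairs"}
        if np.std(parent) == 0 or np.std(daughter) == 0:
            return {"r": np.nan, "p": np.nan, "n_pairs": len(df),
                    "flag": "zero_variance"}
        r, p = sps.pearsonr(parent, daughter)
        return {"r": float(r), "p": float(p), "n_pairs": len(df), "flag": ""}

    if group_col is None:
        return pd.DataFrame([{"group": "all", **one(records)}]).set_index("group")
    rows = [{"group": g, **one(df)} for g, df in records.groupby(group_col)]
    return pd.DataFrame(rows).set_index("group")


def score_dynamics(long_records: pd.DataFrame, stem_threshold: float,
                   pattern_col: str = "pattern", time_col: str = "timepoint",
                   score_col: str = "daughter_score"):
    """Post-division score trajectories per division pattern.

    ``long_records`` is long-form: one row per daughter per timepoint.
    Returns ``(summary, tests)``: per (pattern, timepoint) mean/sd scores
    and the fraction of daughters above the stemness threshold, plus a
    Mann-Whitney rank test between the two patterns at each timepoint
    (NaN when either group is absent).  Records missing a follow-up
    timepoint are simply absent from that timepoint's rows and counted in
    the summary ``n``.
    """
    if long_records[time_col].nunique() < 1:
        raise ValueError("need at least one timepoint")
    grp = long_records.groupby([pattern_col, time_col])[score_col]
    summary = grp.agg(mean="mean", sd="std", n="count").reset_index()
    above = long_records.assign(
        _above=long_records[score_col] > stem_threshold)
    frac = above.groupby([pattern_col, time_col])["_above"].mean()
    summary["fraction_above_threshold"] = frac.to_numpy()

    tests = []
    patterns = sorted(long_records[pattern_col].dropna().unique())
    for t, df_t in long_records.groupby(time_col):
        row = {"timepoint": t, "p": np.nan}
        if len(patterns) == 2:
            a = df_t.loc[df_t[pattern_col] == patterns[0], score_col]
            b = df_t.loc[df_t[pattern_col] == patterns[1], score_col]
            if len(a) > 0 and len(b) > 0:
                row["p"] = float(sps.mannwhitneyu(a, b,
                                                  alternative="two-sided").pvalue)
        tests.append(row)
    return summary, pd.DataFrame(tests)


def condition_screen(records: pd.DataFrame, condition_col: str = "condition",
                     delta_col: str = "delta_mob",
                     pattern_col: str = "pattern", min_n: int = 3):
    """Per-condition division-pattern summaries with an omnibus test.

    For each treatment condition: the delta-MOB mean/sd, the asymmetric
    fraction, and per-pattern mean daughter scores.  Across conditions, a
    one-way ANOVA on delta-MOB (and on per-pattern daughter means where
    both patterns exist).  Conditions with fewer than ``min_n`` divisions
    are excluded with a warning entry in the output.
    """
    rows, groups, skipped = [], [], []
    for cond, df in records.groupby(condition_col):
        if len(df) < min_n:
            skipped.append(cond)
            continue
        daughters = np.concatenate([df["daughter1_score"], df["daughter2_score"]])
        row = {
            "condition": cond,
            "n_divisions": len(df),
            "delta_mean": float(df[delta_col].mean()),
            "delta_sd": float(df[delta_col].std()),
            "mean_daughter_score": float(np.mean(daughters)),
        }
        if pattern_col in df and df[pattern_col].notna().any():
            row["asymmetric_fraction"] = float(
                (df[pattern_col] == "M-asymmetric").mean())
            for pat, sub in df.groupby(pattern_col):
                d = np.concatenate([sub["daughter1_score"],
                                    sub["daughter2_score"]])
                row[f"mean_daughter_score_{pat}"] = float(np.mean(d))
        rows.append(row)
        groups.append(df[delta_col].to_numpy(dtype=float))
    summary = pd.DataFrame(rows)
    summary.attrs["excluded_conditions"] = skipped
    anova_p = np.nan
    if len(groups) >= 2:
        anova_p = float(sps.f_oneway(*groups).pvalue)
    return summary, anova_p
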