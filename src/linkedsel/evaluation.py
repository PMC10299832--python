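"""Evaluation surfaces for linked-selection maps.

Implements the standard diagnostics for a fitted diversity map:

* observed vs predicted diversity in (possibly overlapping) windows,
  mutation-rate corrected and normalised to the autosomal mean;
* variance explained (1 - SSE/SST) across spatial scales;
* diversity collated by genetic distance to the nearest feature
  (default 160 bins of 0.005 cM);
* calibration: observed diversity (rate- and pi0-normalised) across
  equal-count bins of predicted B, with the lowest bins optionally pooled
  and a presentation-only LOESS overlay on a finer binning;
* summaries of the B distribution (mean and per-decile reductions);
* accounting of fitted deleterious rates against the total mutation-rate
  bound per site.

Aggregation order follows the figure-caption convention: heterozygosity is
pooled within a bin/window first (sum h / sum C), then divided by the
bin's mean relative mutation rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import GeneticMap, PolymorphismTable, SubstitutionSet
from .likelihood import FitResult, PredictionTrack

__all__ = [
    "WindowSeries",
    "CollatedProfile",
    "CalibrationCurve",
    "windowed_diversity",
    "variance_explained",
    "collate_by_distance",
    "calibration_curve",
    "b_reduction_summary",
    "deleterious_rate_report",
]

TOTAL_RATE_RANGE = (1.29e-8, 1.51e-8)
"""Bounds on the total mutation rate per site per generation in humans
(point mutations, indels, mobile elements, structural events)."""


@dataclass
class WindowSeries:
    """Per-window observed and predicted diversity, both mutation-rate
    corrected and normalised so the autosome-wide mean is 1."""

    windows: pd.DataFrame  # chrom, start, end, obs, pred, n_sites
    window_bp: int
    overlap_bp: int
    n_dropped: int = 0


@dataclass
class CollatedProfile:
    """Diversity collated by genetic distance to the nearest feature."""

    bins: pd.DataFrame  # d_lo, d_hi, obs, pred, n_sites
    bin_cm: float
    n_beyond: int = 0


@dataclass
class CalibrationCurve:
    """Observed (normalised) diversity across equal-count predicted-B bins."""

    bins: pd.DataFrame          # b_pred, obs, n_sites, grouped flag
    pooled_lowest: dict | None  # pooled point for the lowest bins
    loess: pd.DataFrame | None  # fine-bin LOESS overlay (x, y)
    slope: float
    intercept: float
    r2: float


def _pooled_obs(h, C, m):
    """Aggregate-then-correct observed diversity of a site set."""
    return (h.sum() / C.sum()) / m.mean()


def windowed_diversity(
    data: PolymorphismTable,
    track: PredictionTrack,
    window_bp: int,
    overlap_bp: int = 0,
    min_sites: int = 1,
) -> WindowSeries:
    """Observed and predicted diversity in sliding windows.

    Windows start at 0 with stride ``window_bp - overlap_bp``.  Per window,
    obs = (sum h / sum C) / mean(m) and pred = mean(pi) / mean(m); both are
    then divided by their autosome-wide (all-site) counterparts, so a
    perfectly uniform genome gives 1 everywhere.  Windows with fewer than
    ``min_sites`` sites are dropped (counted in ``n_dropped``).
    """
    if window_bp <= 0:
        raise ValueError("window must be positive")
    if not 0 <= overlap_bp < window_bp:
        raise ValueError("require 0 <= overlap < window")
    stride = window_bp - overlap_bp
    h, C, m, pi = data.h, data.C, track.m, track.pi
    obs_norm = _pooled_obs(h, C, m)
    pred_norm = pi.mean() / m.mean()
    rows = []
    n_dropped = 0
    chroms = data.chrom
    pos0 = data.pos - 1  # 0-based coordinates
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        p = pos0[sel]
        extent = int(p.max()) + 1
        # full windows only: the last window starts at the largest multiple
        # of the stride with start + window <= chromosome extent
        for start in range(0, max(extent - window_bp, 0) + 1, stride):
            end = start + window_bp
            in_w = (p >= start) & (p < end)
            n = int(in_w.sum())
            if n < min_sites:
                n_dropped += 1
                continue
            obs = _pooled_obs(h[sel][in_w], C[sel][in_w], m[sel][in_w])
            pred = pi[sel][in_w].mean() / m[sel][in_w].mean()
            rows.append((chrom, start, end, obs / obs_norm, pred / pred_norm, n))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} windows with < {min_sites} sites")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "obs", "pred", "n_sites"])
    return WindowSeries(df, window_bp, overlap_bp, n_dropped)


def variance_explained(series_by_scale: dict) -> pd.DataFrame:
    """Per-scale R^2 of the model's own predictions.

    ``series_by_scale`` maps scale (bp) -> non-overlapping WindowSeries.
    Primary column ``r2`` is 1 - SSE/SST (no refit); ``pearson_r2`` is the
    squared correlation, reported alongside.
    """
    rows = []
    for scale, series in sorted(series_by_scale.items()):
        if series.overlap_bp != 0:
            raise ValueError("variance explained requires non-overlapping windows")
        df = series.windows
        if len(df) < 3:
            raise ValueError(f"need >= 3 windows at scale {scale}")
        obs = df["obs"].to_numpy()
        pred = df["pred"].to_numpy()
        sst = float(((obs - obs.mean()) ** 2).sum())
        sse = float(((obs - pred) ** 2).sum())
        r2 = 1.0 - sse / sst if sst > 0 else np.nan
        with np.errstate(invalid="ignore"):
            pr = float(np.corrcoef(obs, pred)[0, 1]) if pred.std() > 0 else 0.0
        rows.append((scale, r2, pr**2, len(df)))
    return pd.DataFrame(rows, columns=["scale_bp", "r2", "pearson_r2", "n_windows"])


def collate_by_distance(
    data: PolymorphismTable,
    track: PredictionTrack,
    features: SubstitutionSet,
    gmap: GeneticMap,
    feature_class: str | None = None,
    bin_cm: float = 0.005,
    n_bins: int = 160,
    clamp: bool = False,
) -> CollatedProfile:
    """Collated diversity around features (e.g. nonsynonymous substitutions).

    Each neutral site is assigned to bin floor(d / bin_cm) of its genetic
    distance d to the NEAREST feature; per bin, observed diversity is
    pooled then mutation-rate corrected, and both obs and pred are plotted
    relative to the autosomal mean.  Sites beyond the last bin are excluded
    (counted in ``n_beyond``).
    """
    if len(features.sites) == 0:
        raise ValueError("no features to collate around")
    labels = [feature_class] if feature_class else features.classes
    chroms = data.chrom
    d_near = np.full(len(data), np.inf)
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        fpos = np.concatenate([features.positions(chrom, lab) for lab in labels])
        if len(fpos) == 0:
            continue
        fcm = np.sort(np.asarray(gmap.interpolate(chrom, fpos, clamp=clamp)))
        scm = np.asarray(gmap.interpolate(chrom, data.pos[sel], clamp=clamp))
        idx = np.searchsorted(fcm, scm)
        left = np.abs(scm - fcm[np.maximum(idx - 1, 0)])
        right = np.abs(fcm[np.minimum(idx, len(fcm) - 1)] - scm)
        d_near[sel] = np.minimum(left, right)
    bin_idx = np.floor(d_near / bin_cm).astype(np.int64)
    in_range = bin_idx < n_bins
    n_beyond = int((~in_range).sum())
    if in_range.sum() == 0:
        raise ValueError("all neutral sites beyond the collation range")

    h, C, m, pi = data.h, data.C, track.m, track.pi
    obs_norm = _pooled_obs(h, C, m)
    pred_norm = pi.mean() / m.mean()
    rows = []
    for b in range(n_bins):
        sel = in_range & (bin_idx == b)
        n = int(sel.sum())
        if n == 0:
            rows.append((b * bin_cm, (b + 1) * bin_cm, np.nan, np.nan, 0))
            continue
        obs = _pooled_obs(h[sel], C[sel], m[sel])
        pred = pi[sel].mean() / m[sel].mean()
        rows.append((b * bin_cm, (b + 1) * bin_cm, obs / obs_norm, pred / pred_norm, n))
    df = pd.DataFrame(rows, columns=["d_lo", "d_hi", "obs", "pred", "n_sites"])
    return CollatedProfile(df, bin_cm, n_beyond)


def _equal_count_bins(order: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin ids (by sorted order) splitting ``len(order)`` sites into
    ``n_bins`` groups whose sizes differ by at most one."""
    n = len(order)
    ids = np.empty(n, dtype=np.int64)
    edges = (np.arange(n_bins + 1) * n) // n_bins
    for b in range(n_bins):
        ids[order[edges[b] : edges[b + 1]]] = b
    return ids


def calibration_curve(
    data: PolymorphismTable,
    track: PredictionTrack,
    pi0_hat: float,
    n_bins: int = 100,
    group_lowest: int = 5,
    loess_bins: int = 2000,
    loess_span: float = 0.1,
) -> CalibrationCurve:
    """Observed vs predicted-B calibration across equal-count B bins.

    x per bin is the mean predicted B; y is the bin's pooled observed
    diversity divided by its mean relative mutation rate and by
    ``pi0_hat`` (the fitted autosomal-average diversity without selection).
    The ``group_lowest`` lowest-B bins are additionally reported pooled
    into one point.  A LOESS fit (span ``loess_span``) over a
    ``loess_bins``-bin version of the scatter is attached for display; it
    feeds no statistic.
    """
    if pi0_hat <= 0:
        raise ValueError("pi0_hat must be positive")
    n = len(data)
    if n_bins > n:
        raise ValueError("more calibration bins than sites")
    h, C, m, B = data.h, data.C, track.m, track.B
    order = np.argsort(B, kind="stable")

    def binned(nb):
        ids = _equal_count_bins(order, nb)
        rows = []
        for b in range(nb):
            sel = ids == b
            x = B[sel].mean()
            y = (h[sel].sum() / C[sel].sum()) / m[sel].mean() / pi0_hat
            rows.append((x, y, int(sel.sum())))
        return pd.DataFrame(rows, columns=["b_pred", "obs", "n_sites"])

    df = binned(n_bins)
    df["grouped"] = np.arange(n_bins) < group_lowest
    pooled = None
    if group_lowest > 0:
        ids = _equal_count_bins(order, n_bins)
        sel = ids < group_lowest
        pooled = {
            "b_pred": float(B[sel].mean()),
            "obs": float((h[sel].sum() / C[sel].sum()) / m[sel].mean() / pi0_hat),
            "n_sites": int(sel.sum()),
        }
    loess_df = None
    if loess_bins and loess_bins <= n:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        fine = binned(loess_bins)
        sm = lowess(fine["obs"], fine["b_pred"], frac=loess_span, return_sorted=True)
        loess_df = pd.DataFrame(sm, columns=["x", "y"])
    x, y = df["b_pred"].to_numpy(), df["obs"].to_numpy()
    slope, intercept = np.polyfit(x, y, 1)
    r = np.corrcoef(x, y)[0, 1]
    return CalibrationCurve(df, pooled, loess_df, float(slope), float(intercept), float(r**2))


def b_reduction_summary(
    track: PredictionTrack, exclude_top_bins_pct: float = 2.0, n_bins: int = 100
) -> dict:
    """Mean and per-decile diversity reductions 1 - B.

    Sites in the top ``exclude_top_bins_pct`` percent of predicted-B
    percentile bins are excluded first (outlier guard); deciles are then
    taken over the remaining sites by predicted B (decile 1 = most
    affected, i.e. lowest B).
    """
    B = np.asarray(track.B, dtype=np.float64)
    order = np.argsort(B, kind="stable")
    ids = _equal_count_bins(order, n_bins)
    n_excl = int(round(n_bins * exclude_top_bins_pct / 100.0))
    keep = ids < (n_bins - n_excl)
    Bk = B[keep]
    order_k = np.argsort(Bk, kind="stable")
    dec = _equal_count_bins(order_k, 10)
    per_decile = [float(1.0 - Bk[dec == d].mean()) for d in range(10)]
    return {
        "mean_reduction": float(1.0 - Bk.mean()),
        "decile_reductions": per_decile,
        "most_affected_decile": per_decile[0],
        "least_affected_decile": per_decile[9],
        "n_sites": int(keep.sum()),
        "n_excluded": int((~keep).sum()),
    }


def deleterious_rate_report(
    fit_result: FitResult,
    class_site_counts: dict,
    total_rate_range: tuple = TOTAL_RATE_RANGE,
) -> dict:
    """Fitted deleterious rates vs the total mutation-rate bound.

    Per annotation class: the summed deleterious rate per selected site,
    its ratio to the lower/upper bounds on the total per-site mutation
    rate, and the class's share of total deleterious input (rate x number
    of selected sites).  Classes whose rate exceeds the upper bound are
    flagged; a healthy fit falls well below it.
    """
    theta = fit_result.theta_hat
    lo, hi = total_rate_range
    classes = {}
    inputs = {}
    for label in theta.U:
        if label not in class_site_counts:
            raise ValueError(f"missing site count for class {label!r}")
        u_del = theta.total_udel(label)
        inputs[label] = u_del * class_site_counts[label]
        classes[label] = {
            "u_del": u_del,
            "ratio_lower": u_del / hi,
            "ratio_upper": u_del / lo,
            "exceeds_bound": bool(u_del > hi),
            "n_sites": int(class_site_counts[label]),
        }
    total_input = sum(inputs.values())
    if total_input > 0:
        for label in classes:
            classes[label]["share_of_deleterious_input"] = inputs[label] / total_input
        flag = None
    else:
        flag = "no deleterious input"
        for label in classes:
            classes[label]["share_of_deleterious_input"] = np.nan
    return {
        "classes": classes,
        "total_rate_range": list(total_rate_range),
        "flag": flag,
    }
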