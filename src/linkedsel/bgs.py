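"""Background-selection (BGS) kernels and B-map composition.

The classical Hudson–Kaplan / Nordborg result gives, for a neutral site x
linked to a selected site i at recombination fraction r, a multiplicative
reduction of pairwise coalescence time

    B_i(x) = exp( -u_del * t / (t + r (1 - t))^2 ),

where t is the heterozygous selection coefficient of deleterious mutations
at i and u_del the deleterious mutation rate per site.  Effects multiply
across selected sites, so the log-reduction is additive:

    B(x) = exp( - sum_{a,g} U[a,g] * E[x,a,g] ),
    E[x,a,g] = sum_{i in class a} t_g / (t_g + r(x,i) (1 - t_g))^2 .

The unit-rate exponents E depend only on the site geometry and the
selection-coefficient grid, never on the free parameters U, so they are
precomputed once per genome and a candidate B map is a cheap linear
compose + exp.

Two evaluation paths are provided:

``exact``
    Sums over every selected site.  Cost is O(n_neutral * n_selected);
    used for toy problems, oracle tests and truth-bundle tripwires.

``tiered``
    Exact within ``near_cm`` of the focal site, then distance-binned on a
    fine (``w_fine``) and a coarse (``w_coarse``) cM histogram of selected
    sites, each bin contributing with its site count at its mean map
    position.  The three zones partition the selected sites exactly (zone
    boundaries are aligned to bin edges), so no site is dropped or double
    counted.  Agreement with the exact path is better than 0.1% on
    realistic geometries because the kernel is smooth at distances beyond
    ``near_cm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .genome_io import AnnotationSet, GeneticMap, cm_to_recfrac

__all__ = [
    "SelectionGrid",
    "BgsKernels",
    "TieredApprox",
    "bgs_site_term",
    "precompute_bgs",
    "compose_B",
    "bgs_exponents_brute",
]


@dataclass(frozen=True)
class SelectionGrid:
    """Log-spaced grid of heterozygous selection coefficients.

    The grid is the shared support of the deleterious DFE (weights U[a,g])
    and the beneficial DFE (weights alpha[c,g]); with one annotation class
    and the default 6 points, a BGS-only model has 7 free parameters
    (6 weights + Ne).
    """

    t_values: tuple

    def __post_init__(self) -> None:
        t = np.asarray(self.t_values, dtype=np.float64)
        if len(t) == 0 or np.any(t <= 0) or np.any(t > 1):
            raise ValueError("selection coefficients must satisfy 0 < t <= 1")
        if np.any(np.diff(t) <= 0):
            raise ValueError("selection grid must be strictly increasing")
        object.__setattr__(self, "t_values", tuple(float(x) for x in t))

    @classmethod
    def default(cls) -> "SelectionGrid":
        """10^-4.5 ... 10^-2, six log-spaced points."""
        return cls(tuple(10.0 ** np.arange(-4.5, -1.75, 0.5)))

    @property
    def size(self) -> int:
        return len(self.t_values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.t_values, dtype=np.float64)


@dataclass(frozen=True)
class TieredApprox:
    """Parameters of the tiered far-field aggregation (distances in cM)."""

    near_cm: float = 0.03     # exact summation within this half-width
    w_fine: float = 0.001     # fine histogram bin width
    mid_cm: float = 1.6       # fine bins out to here, coarse beyond
    w_coarse: float = 0.02    # coarse histogram bin width

    def __post_init__(self) -> None:
        if not (0 < self.w_fine <= self.near_cm <= self.mid_cm):
            raise ValueError("require 0 < w_fine <= near_cm <= mid_cm")
        ratio = self.w_coarse / self.w_fine
        if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
            raise ValueError("w_coarse must be an integer multiple of w_fine")


@dataclass
class BgsKernels:
    """Unit-rate BGS exponents E[x, a, g] (per unit deleterious rate).

    ``E`` has shape (n_sites, n_classes, n_grid); ``chrom``/``pos`` identify
    the neutral sites (1-based), ``classes`` the annotation class order.
    """

    E: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    classes: list
    grid: SelectionGrid
    d_max: float
    approx: TieredApprox | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.E.ndim != 3:
            raise ValueError("E must be (sites, classes, grid)")
        if np.any(self.E < 0) or not np.all(np.isfinite(self.E)):
            raise ValueError("exponents must be finite and non-negative")

    @property
    def n_sites(self) -> int:
        return self.E.shape[0]

    def class_index(self, label: str) -> int:
        return self.classes.index(label)


def bgs_site_term(t, r):
    """Per-selected-site exponent density t / (t + r(1-t))^2.

    Equals 1/t at r = 0 and decreases strictly in r.  ``t`` and ``r`` may be
    scalars or broadcastable arrays.
    """
    t = np.asarray(t, dtype=np.float64)
    r = np.asarray(r, dtype=np.float64)
    if np.any(t <= 0) or np.any(t > 1):
        raise ValueError("selection coefficient t must be in (0, 1]")
    if np.any(r < 0) or np.any(r > 0.5):
        raise ValueError("recombination fraction must be in [0, 0.5]")
    out = t / (t + r * (1.0 - t)) ** 2
    return out if out.shape else float(out)


# --- numba inner loops ------------------------------------------------------


@njit(cache=True, fastmath=True)
def _haldane(d_cm):
    return 0.5 * (1.0 - np.exp(-0.02 * d_cm))


@njit(cache=True, fastmath=True)
def _bgs_exact_nb(anchor_cm, sel_cm, t_vals, d_max):
    n = anchor_cm.shape[0]
    m = sel_cm.shape[0]
    G = t_vals.shape[0]
    E = np.zeros((n, G))
    for i in range(n):
        cx = anchor_cm[i]
        lo = np.searchsorted(sel_cm, cx - d_max)
        hi = np.searchsorted(sel_cm, cx + d_max, side="right")
        for j in range(lo, hi):
            d = abs(cx - sel_cm[j])
            r = _haldane(d)
            for g in range(G):
                t = t_vals[g]
                den = t + r * (1.0 - t)
                E[i, g] += t / (den * den)
    return E


@njit(cache=True, fastmath=True)
def _bgs_tiered_nb(
    anchor_cm,
    sel_cm,
    t_vals,
    d_max,
    w1,
    w2,
    n_near,          # exact half-width in fine bins
    n_mid,           # fine-zone half-width in coarse bins
    cnt1,
    mean1,
    cnt2,
    mean2,
):
    n = anchor_cm.shape[0]
    G = t_vals.shape[0]
    E = np.zeros((n, G))
    nb1 = cnt1.shape[0]
    nb2 = cnt2.shape[0]
    ratio = int(round(w2 / w1))
    for i in range(n):
        cx = anchor_cm[i]
        b1c = int(cx / w1)
        b2c = int(cx / w2)
        # exact zone: fine bins [b1c - n_near, b1c + n_near]
        e_lo_bin = b1c - n_near
        e_hi_bin = b1c + n_near
        e_lo = e_lo_bin * w1
        e_hi = (e_hi_bin + 1) * w1
        lo = np.searchsorted(sel_cm, e_lo)
        hi = np.searchsorted(sel_cm, e_hi)
        for j in range(lo, hi):
            d = abs(cx - sel_cm[j])
            if d > d_max:
                continue
            r = _haldane(d)
            for g in range(G):
                t = t_vals[g]
                den = t + r * (1.0 - t)
                E[i, g] += t / (den * den)
        # fine-bin zone: fine bins in [(b2c-n_mid)*ratio, (b2c+n_mid+1)*ratio)
        # excluding the exact zone
        m_lo_bin1 = (b2c - n_mid) * ratio
        m_hi_bin1 = (b2c + n_mid + 1) * ratio - 1
        lo1 = max(m_lo_bin1, 0)
        hi1 = min(m_hi_bin1, nb1 - 1)
        for b in range(lo1, hi1 + 1):
            if e_lo_bin <= b <= e_hi_bin:
                continue
            c = cnt1[b]
            if c == 0:
                continue
            d = abs(cx - mean1[b])
            if d > d_max:
                continue
            r = _haldane(d)
            for g in range(G):
                t = t_vals[g]
                den = t + r * (1.0 - t)
                E[i, g] += c * t / (den * den)
        # coarse zone: all coarse bins outside [b2c - n_mid, b2c + n_mid]
        for b in range(nb2):
            if b2c - n_mid <= b <= b2c + n_mid:
                continue
            c = cnt2[b]
            if c == 0:
                continue
            d = abs(cx - mean2[b])
            if d > d_max:
                continue
            r = _haldane(d)
            for g in range(G):
                t = t_vals[g]
                den = t + r * (1.0 - t)
                E[i, g] += c * t / (den * den)
    return E


def _histogram(sel_cm: np.ndarray, w: float):
    """Per-bin counts and mean cm on the absolute grid floor(cm / w)."""
    idx = np.floor(sel_cm / w).astype(np.int64)
    nb = int(idx.max()) + 1 if len(idx) else 1
    cnt = np.bincount(idx, minlength=nb).astype(np.float64)
    s = np.bincount(idx, weights=sel_cm, minlength=nb)
    mean = np.where(cnt > 0, s / np.maximum(cnt, 1), 0.0)
    return cnt, mean


# --- public API -------------------------------------------------------------


def _selected_cm(ann: AnnotationSet, gmap: GeneticMap, chrom: str, clamp: bool):
    pos = ann.site_positions(chrom)
    if len(pos) == 0:
        return np.empty(0)
    return np.sort(np.asarray(gmap.interpolate(chrom, pos, clamp=clamp), dtype=np.float64))


def precompute_bgs(
    neutral_chrom,
    neutral_pos,
    annotations: list,
    gmap: GeneticMap,
    grid: SelectionGrid,
    d_max: float = 100.0,
    approx: TieredApprox | None = None,
    clamp: bool = False,
) -> BgsKernels:
    """Precompute unit-rate BGS exponents at every neutral site.

    Parameters
    ----------
    neutral_chrom, neutral_pos
        Chromosome labels and 1-based positions of the neutral sites.
    annotations
        One :class:`AnnotationSet` per class of putatively selected regions.
    d_max
        Selected sites farther than this (cM) contribute nothing; their
        near-constant far-field effect is absorbed into the fitted Ne.
    approx
        ``None`` for the exact path; a :class:`TieredApprox` enables the
        tiered far-field aggregation.

    An annotation class with no selected sites yields an all-zero kernel
    (with a warning).
    """
    import warnings

    neutral_chrom = np.asarray(neutral_chrom)
    neutral_pos = np.asarray(neutral_pos, dtype=np.int64)
    t_vals = grid.as_array()
    n = len(neutral_pos)
    E = np.zeros((n, len(annotations), grid.size))
    for a, ann in enumerate(annotations):
        if ann.n_sites == 0:
            warnings.warn(f"annotation class {ann.class_label!r} is empty; zero kernel")
            continue
        for chrom in np.unique(neutral_chrom):
            mask = neutral_chrom == chrom
            anchors = np.asarray(
                gmap.interpolate(chrom, neutral_pos[mask], clamp=clamp), dtype=np.float64
            )
            sel = _selected_cm(ann, gmap, chrom, clamp)
            if len(sel) == 0:
                continue
            if approx is None:
                E[mask, a, :] = _bgs_exact_nb(anchors, sel, t_vals, float(d_max))
            else:
                cnt1, mean1 = _histogram(sel, approx.w_fine)
                cnt2, mean2 = _histogram(sel, approx.w_coarse)
                n_near = int(round(approx.near_cm / approx.w_fine))
                n_mid = int(round(approx.mid_cm / approx.w_coarse))
                E[mask, a, :] = _bgs_tiered_nb(
                    anchors,
                    sel,
                    t_vals,
                    float(d_max),
                    approx.w_fine,
                    approx.w_coarse,
                    n_near,
                    n_mid,
                    cnt1,
                    mean1,
                    cnt2,
                    mean2,
                )
    return BgsKernels(
        E=E,
        chrom=neutral_chrom,
        pos=neutral_pos,
        classes=[a.class_label for a in annotations],
        grid=grid,
        d_max=float(d_max),
        approx=approx,
    )


def compose_B(kernels: BgsKernels, U, e_cap: float | None = None) -> np.ndarray:
    """B(x) = exp(-sum_{a,g} U[a,g] E[x,a,g]), optionally capping the total
    exponent at ``e_cap`` (so B is floored at exp(-e_cap)).

    ``U`` is a mapping class label -> array of per-grid-point deleterious
    rates (mutations per site per generation), or a 2-D array aligned with
    ``kernels.classes``.
    """
    U_mat = _as_U_matrix(kernels, U)
    if np.any(U_mat < 0):
        raise ValueError("deleterious rates U must be non-negative")
    expo = np.einsum("xag,ag->x", kernels.E, U_mat)
    if e_cap is not None:
        expo = np.minimum(expo, e_cap)
    return np.exp(-expo)


def _as_U_matrix(kernels: BgsKernels, U) -> np.ndarray:
    if isinstance(U, dict):
        mat = np.zeros((len(kernels.classes), kernels.grid.size))
        for label, vals in U.items():
            mat[kernels.class_index(label), :] = np.asarray(vals, dtype=np.float64)
        return mat
    return np.asarray(U, dtype=np.float64).reshape(len(kernels.classes), kernels.grid.size)


def bgs_exponents_brute(
    neutral_cm, selected_cm, grid: SelectionGrid, d_max: float = 100.0
) -> np.ndarray:
    """Direct double loop over (neutral, selected) pairs (oracle path).

    Vectorised over selected sites per neutral site but mathematically the
    plain pair sum; used for truth-bundle tripwires.
    """
    neutral_cm = np.asarray(neutral_cm, dtype=np.float64)
    selected_cm = np.asarray(selected_cm, dtype=np.float64)
    t = grid.as_array()
    E = np.zeros((len(neutral_cm), grid.size))
    for i, cx in enumerate(neutral_cm):
        d = np.abs(selected_cm - cx)
        d = d[d <= d_max]
        r = cm_to_recfrac(d)
        E[i, :] = (t[None, :] / (t[None, :] + r[:, None] * (1.0 - t[None, :])) ** 2).sum(axis=0)
    return E
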