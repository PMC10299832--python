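"""Selective-sweep coalescence kernels and S-map composition.

Under the classical star-like approximation for a hard sweep with
heterozygous advantage s, a neutral lineage at recombination fraction r
from the swept site escapes the sweep with probability 1 - q where

    q(r, s) = exp(-r * tau(s)),      tau(s) = (2/s) * ln(4 Ne s),

tau being the sweep's fixation time.  A random pair of lineages is forced
to coalesce by the sweep with probability q^2 (both trapped in the
sweeping haplotype).

Summed over the substitutions of class c that occurred over a lineage span
of T generations, of which a fraction alpha[c,g] swept with coefficient
s_g, the sweep-induced pair coalescence rate at neutral site x is

    S(x) = sum_{c,g} (alpha[c,g] / T) * G[x,c,g],
    G[x,c,g] = sum_{j in c} q(r(x,j), s_g)^2 .

As with the BGS exponents, G never depends on the free parameters alpha,
so it is precomputed once (at a fixed reference Ne; tau depends on Ne only
logarithmically).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import GeneticMap, SubstitutionSet, cm_to_recfrac
from .bgs import SelectionGrid

__all__ = [
    "SweepKernels",
    "sweep_coal_prob",
    "sweep_duration",
    "precompute_sweeps",
    "compose_S",
]

DEFAULT_T_LINEAGE = 1e4
"""Default lineage span (generations) over which substitutions accrued,
per unit of synthetic divergence."""


@dataclass
class SweepKernels:
    """Summed pair-coalescence probabilities G[x, c, g] (unit beneficial
    fraction) and the lineage span converting counts to rates."""

    G: np.ndarray  # (n_sites, n_classes, n_grid)
    chrom: np.ndarray
    pos: np.ndarray
    classes: list
    grid: SelectionGrid
    ne_ref: float
    d_max: float
    t_lineage: float = DEFAULT_T_LINEAGE
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.G.ndim != 3:
            raise ValueError("G must be (sites, classes, grid)")
        if np.any(self.G < 0) or not np.all(np.isfinite(self.G)):
            raise ValueError("sweep kernels must be finite and non-negative")
        if self.t_lineage <= 0:
            raise ValueError("lineage span must be positive")

    @property
    def n_sites(self) -> int:
        return self.G.shape[0]

    def class_index(self, label: str) -> int:
        return self.classes.index(label)


def sweep_duration(s, ne) -> np.ndarray:
    """Sweep fixation time tau(s) = (2/s) ln(4 Ne s) (generations)."""
    s = np.asarray(s, dtype=np.float64)
    if np.any(s <= 0) or np.any(s > 1):
        raise ValueError("selection coefficient s must be in (0, 1]")
    if np.any(4.0 * ne * s <= 1.0):
        raise ValueError("sweep regime requires 4 Ne s > 1")
    out = (2.0 / s) * np.log(4.0 * ne * s)
    return out if out.shape else float(out)


def sweep_coal_prob(r, s, ne):
    """Pair coalescence probability q(r, s)^2 for a single sweep.

    ``r`` is the recombination fraction to the swept site, ``s`` the
    selection coefficient, ``ne`` the (reference) effective size.
    """
    r = np.asarray(r, dtype=np.float64)
    if np.any(r < 0) or np.any(r > 0.5):
        raise ValueError("recombination fraction must be in [0, 0.5]")
    tau = sweep_duration(s, ne)
    q = np.exp(-r * np.asarray(tau))
    out = q * q
    return out if out.shape else float(out)


def precompute_sweeps(
    neutral_chrom,
    neutral_pos,
    subs: SubstitutionSet,
    gmap: GeneticMap,
    grid: SelectionGrid,
    ne_ref: float,
    d_max: float = 100.0,
    t_lineage: float = DEFAULT_T_LINEAGE,
    clamp: bool = False,
    chunk: int = 2048,
) -> SweepKernels:
    """Sum q^2 over the substitutions of each class at each neutral site.

    Substitution counts are modest (point features), so this is a direct
    vectorised pair sum, blocked over neutral sites to bound memory.
    Classes with no substitutions yield a zero kernel with a warning.
    """
    import warnings

    neutral_chrom = np.asarray(neutral_chrom)
    neutral_pos = np.asarray(neutral_pos, dtype=np.int64)
    classes = subs.classes
    tau = np.array([sweep_duration(t, ne_ref) for t in grid.t_values])
    G = np.zeros((len(neutral_pos), len(classes), grid.size))
    for c, label in enumerate(classes):
        total = 0
        for chrom in np.unique(neutral_chrom):
            mask = neutral_chrom == chrom
            sub_pos = subs.positions(chrom, label)
            total += len(sub_pos)
            if len(sub_pos) == 0:
                continue
            anchors = np.asarray(
                gmap.interpolate(chrom, neutral_pos[mask], clamp=clamp), dtype=np.float64
            )
            sub_cm = np.sort(
                np.asarray(gmap.interpolate(chrom, sub_pos, clamp=clamp), dtype=np.float64)
            )
            out = np.zeros((mask.sum(), grid.size))
            for start in range(0, len(anchors), chunk):
                a = anchors[start : start + chunk]
                d = np.abs(a[:, None] - sub_cm[None, :])
                within = d <= d_max
                r = 0.5 * (-np.expm1(-0.02 * d))
                q2 = np.exp(-2.0 * r[:, :, None] * tau[None, None, :])
                q2 *= within[:, :, None]
                out[start : start + chunk] = q2.sum(axis=1)
            G[mask, c, :] = out
        if total == 0:
            warnings.warn(f"substitution class {label!r} is empty; zero kernel")
    return SweepKernels(
        G=G,
        chrom=neutral_chrom,
        pos=neutral_pos,
        classes=classes,
        grid=grid,
        ne_ref=float(ne_ref),
        d_max=float(d_max),
        t_lineage=float(t_lineage),
    )


def compose_S(kernels: SweepKernels, alpha, t_lineage: float | None = None) -> np.ndarray:
    """S(x) = sum_{c,g} (alpha[c,g] / T) G[x,c,g] (per-generation rate).

    ``alpha`` maps class label -> per-grid beneficial fractions (or a 2-D
    array aligned with ``kernels.classes``); each class's fractions must
    be non-negative and sum to at most 1.
    """
    T = kernels.t_lineage if t_lineage is None else float(t_lineage)
    mat = _as_alpha_matrix(kernels, alpha)
    if np.any(mat < 0):
        raise ValueError("beneficial fractions alpha must be non-negative")
    sums = mat.sum(axis=1)
    if np.any(sums > 1.0 + 1e-12):
        bad = kernels.classes[int(np.argmax(sums))]
        raise ValueError(f"per-class alpha sums must be <= 1 (class {bad!r})")
    return np.einsum("xcg,cg->x", kernels.G, mat) / T


def _as_alpha_matrix(kernels: SweepKernels, alpha) -> np.ndarray:
    if isinstance(alpha, dict):
        mat = np.zeros((len(kernels.classes), kernels.grid.size))
        for label, vals in alpha.items():
            mat[kernels.class_index(label), :] = np.asarray(vals, dtype=np.float64)
        return mat
    return np.asarray(alpha, dtype=np.float64).reshape(
        len(kernels.classes), kernels.grid.size
    )
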