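"""Composite-likelihood inference of linked-selection parameters.

The observable at neutral site x is the pair of counts (C, h): C = n(n-1)/2
pairs of sampled chromosomes and h = k(n-k) heterozygous pairs.  Treating
pairs within a site as exchangeable draws with mismatch probability

    pi(x) = 2 u(x) / ( 2 u(x) + 1/(2 Ne B(x)) + S(x) ),  u(x) = u0 * m(x),

and sites as independent, the composite log-likelihood of the parameters
theta = (Ne, U, alpha) is

    ll(theta) = sum_x  h ln pi(x) + (C - h) ln(1 - pi(x)).

Sites are not independent in real data (linkage), so this is a composite,
not a true, likelihood: it is maximised for point estimation and no
standard errors are derived from its curvature.

Free parameters are optimised in transformed coordinates (log Ne, box-
bounded U in units of 1e-8 per site per generation, box-bounded alpha)
with L-BFGS-B and an analytic gradient, from multiple seeded starts.
u0 (the total neutral mutation-rate scale) is a fixed input: only the
product Ne * u0 is identified where 4 Ne u << 1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .bgs import BgsKernels, compose_B
from .genome_io import PolymorphismTable
from .sweeps import SweepKernels, compose_S

__all__ = [
    "ThetaParams",
    "FitConfig",
    "FitResult",
    "PredictionTrack",
    "predict_pi",
    "composite_loglik",
    "loglik_and_grad",
    "fit",
    "crossfit",
    "predict_from_theta",
]

U_UNIT = 1e-8  # optimiser works in deleterious-rate units of 1e-8 /site/gen
PI_CLAMP = 1e-12


@dataclass
class ThetaParams:
    """All free parameters plus the fixed mutation-rate scale.

    ``U`` maps BGS annotation class -> per-grid-point deleterious rates
    (per site per generation); ``alpha`` maps substitution class ->
    per-grid-point beneficial fractions (each class summing to <= 1).
    """

    ne: float
    U: dict = field(default_factory=dict)
    alpha: dict = field(default_factory=dict)
    u0: float = 1.4e-8

    def __post_init__(self) -> None:
        if self.ne <= 0:
            raise ValueError("Ne must be positive")
        if self.u0 <= 0:
            raise ValueError("u0 must be positive")
        self.U = {k: np.asarray(v, dtype=np.float64) for k, v in self.U.items()}
        self.alpha = {k: np.asarray(v, dtype=np.float64) for k, v in self.alpha.items()}
        for k, v in self.U.items():
            if np.any(v < 0):
                raise ValueError(f"negative deleterious rate for class {k!r}")
        for k, v in self.alpha.items():
            if np.any(v < 0) or v.sum() > 1 + 1e-12:
                raise ValueError(f"invalid beneficial fractions for class {k!r}")

    def total_udel(self, class_label: str | None = None) -> float:
        """Summed deleterious rate per selected site (one class or all)."""
        if class_label is not None:
            return float(self.U[class_label].sum())
        return float(sum(v.sum() for v in self.U.values()))

    def to_dict(self) -> dict:
        return {
            "ne": self.ne,
            "u0": self.u0,
            "U": {k: list(map(float, v)) for k, v in self.U.items()},
            "alpha": {k: list(map(float, v)) for k, v in self.alpha.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThetaParams":
        return cls(ne=d["ne"], u0=d["u0"], U=d.get("U", {}), alpha=d.get("alpha", {}))


@dataclass
class PredictionTrack:
    """Per-neutral-site model surfaces: pi, B, S, pi0 and the mutation-rate
    covariate m."""

    chrom: np.ndarray
    pos: np.ndarray
    pi: np.ndarray
    B: np.ndarray
    S: np.ndarray
    pi0: np.ndarray
    m: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "pi": self.pi,
                "B": self.B,
                "S": self.S,
                "pi0": self.pi0,
                "m": self.m,
            }
        )


def predict_pi(theta: ThetaParams, B, S, m):
    """Expected heterozygosity pi(x) and its no-selection analogue pi0(x).

    pi0 uses B = 1 and S = 0 but keeps the site's mutation rate, so
    B(x) = pi/pi0 only in the low-mutation limit 4 Ne u << 1.
    """
    B = np.asarray(B, dtype=np.float64)
    S = np.asarray(S, dtype=np.float64)
    m = np.asarray(m, dtype=np.float64)
    if np.any(B <= 0) or np.any(B > 1):
        raise ValueError("B must be in (0, 1]")
    if np.any(S < 0):
        raise ValueError("S must be non-negative")
    if np.any(m <= 0):
        raise ValueError("relative mutation rates must be positive")
    a = 2.0 * theta.u0 * m
    drift = 1.0 / (2.0 * theta.ne)
    pi = a / (a + drift / B + S)
    pi0 = a / (a + drift)
    return pi, pi0


def _stack_columns(kernels_E: np.ndarray) -> np.ndarray:
    n, a, g = kernels_E.shape
    return kernels_E.reshape(n, a * g)


def loglik_and_grad(
    p: np.ndarray,
    E2: np.ndarray,
    G2: np.ndarray | None,
    t_lineage: float,
    a_x: np.ndarray,
    h: np.ndarray,
    C: np.ndarray,
    e_cap: float | None = None,
):
    """Composite log-likelihood and analytic gradient in packed coordinates.

    ``p`` = [log Ne, U/1e-8 (flattened), alpha (flattened)].
    """
    n_u = E2.shape[1]
    n_a = 0 if G2 is None else G2.shape[1]
    log_ne = p[0]
    u = p[1 : 1 + n_u] * U_UNIT
    expo = E2 @ u
    capped = None
    if e_cap is not None:
        capped = expo > e_cap
        expo = np.minimum(expo, e_cap)
    K = np.exp(np.minimum(expo - np.log(2.0) - log_ne, 700.0))
    if n_a:
        alpha = p[1 + n_u :]
        S = (G2 @ alpha) / t_lineage
    else:
        S = 0.0
    D = a_x + K + S
    pi = a_x / D
    clip_lo = pi < PI_CLAMP
    clip_hi = pi > 1.0 - PI_CLAMP
    pi = np.clip(pi, PI_CLAMP, 1.0 - PI_CLAMP)
    ll = float(np.sum(h * np.log(pi) + (C - h) * np.log1p(-pi)))

    # d ll / d D, zero where the clamp is active
    w = (h / pi - (C - h) / (1.0 - pi)) * (-a_x / (D * D))
    w[clip_lo | clip_hi] = 0.0
    grad = np.empty(1 + n_u + n_a)
    grad[0] = float(w @ (-K))  # d D / d log Ne = -K
    wK = w * K
    if capped is not None:
        wK = np.where(capped, 0.0, wK)
    grad[1 : 1 + n_u] = (wK @ E2) * U_UNIT
    if n_a:
        grad[1 + n_u :] = (w @ G2) / t_lineage
    return ll, grad


def composite_loglik(
    theta: ThetaParams,
    bgs_kernels: BgsKernels,
    data: PolymorphismTable,
    m: np.ndarray,
    sweep_kernels: SweepKernels | None = None,
    e_cap: float | None = None,
) -> float:
    """ll(theta) for a parameter object (deterministic; no optimisation)."""
    B = compose_B(bgs_kernels, theta.U, e_cap=e_cap)
    if sweep_kernels is not None and theta.alpha:
        S = compose_S(sweep_kernels, theta.alpha)
    else:
        S = np.zeros(bgs_kernels.n_sites)
    pi, _ = predict_pi(theta, B, S, m)
    pi = np.clip(pi, PI_CLAMP, 1.0 - PI_CLAMP)
    return float(np.sum(data.h * np.log(pi) + (data.C - data.h) * np.log1p(-pi)))


@dataclass
class FitConfig:
    """Optimiser settings for :func:`fit`.

    Bounds: Ne in ``ne_bounds``; each U grid weight in [0, ``u_max``];
    each alpha in [0, ``alpha_point_max``] with a smooth penalty keeping
    per-class sums below 1 (never active in practice).
    """

    u0: float = 1.4e-8
    e_cap: float | None = None
    n_starts: int = 10
    seed: int = 0
    ne_bounds: tuple = (1e2, 1e7)
    u_max: float = 4e-8
    alpha_point_max: float = 1.0
    maxiter: int = 500
    fit_sweeps: bool = True

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["ne_bounds"] = list(self.ne_bounds)
        return d


@dataclass
class FitResult:
    theta_hat: ThetaParams
    loglik: float
    n_sites: int
    n_pairs: float
    converged: bool
    starts: list
    config: FitConfig
    bgs_classes: list = field(default_factory=list)
    sweep_classes: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {
            "theta_hat": self.theta_hat.to_dict(),
            "loglik": self.loglik,
            "n_sites": self.n_sites,
            "n_pairs": self.n_pairs,
            "converged": self.converged,
            "starts": self.starts,
            "config": self.config.to_dict(),
            "bgs_classes": self.bgs_classes,
            "sweep_classes": self.sweep_classes,
        }
        s = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            d = json.load(fh)
        cfg = d["config"]
        cfg["ne_bounds"] = tuple(cfg["ne_bounds"])
        return cls(
            theta_hat=ThetaParams.from_dict(d["theta_hat"]),
            loglik=d["loglik"],
            n_sites=d["n_sites"],
            n_pairs=d["n_pairs"],
            converged=d["converged"],
            starts=d["starts"],
            config=FitConfig(**cfg),
            bgs_classes=d["bgs_classes"],
            sweep_classes=d["sweep_classes"],
        )


def _check_alignment(bgs_kernels: BgsKernels, data: PolymorphismTable):
    if bgs_kernels.n_sites != len(data) or np.any(bgs_kernels.pos != data.pos):
        raise ValueError("kernels and polymorphism data index different neutral sites")


def fit(
    bgs_kernels: BgsKernels,
    data: PolymorphismTable,
    m: np.ndarray,
    config: FitConfig | None = None,
    sweep_kernels: SweepKernels | None = None,
    site_mask: np.ndarray | None = None,
) -> FitResult:
    """Maximise the composite likelihood from multiple seeded starts.

    ``site_mask`` restricts the objective to a subset of sites (used by
    :func:`crossfit`); kernels and data must share the same site index.
    """
    config = config or FitConfig()
    _check_alignment(bgs_kernels, data)
    use_sweeps = sweep_kernels is not None and config.fit_sweeps
    if use_sweeps:
        _check_alignment_sweep(sweep_kernels, data)

    E2 = _stack_columns(bgs_kernels.E)
    G2 = _stack_columns(sweep_kernels.G) if use_sweeps else None
    h = data.h
    C = data.C
    m = np.asarray(m, dtype=np.float64)
    if site_mask is not None:
        site_mask = np.asarray(site_mask, dtype=bool)
        E2, h, C, m = E2[site_mask], h[site_mask], C[site_mask], m[site_mask]
        if G2 is not None:
            G2 = G2[site_mask]
    a_x = 2.0 * config.u0 * m
    n_u = E2.shape[1]
    n_a = 0 if G2 is None else G2.shape[1]
    t_lineage = sweep_kernels.t_lineage if use_sweeps else 1.0

    penalty_scale = 1e4 * (1.0 + float(C.sum()))

    def objective(p):
        ll, grad = loglik_and_grad(p, E2, G2, t_lineage, a_x, h, C, config.e_cap)
        f, g = -ll, -grad
        if n_a:
            # smooth penalty keeping per-class alpha sums <= 1
            alpha = p[1 + n_u :].reshape(len(sweep_kernels.classes), -1)
            excess = np.maximum(alpha.sum(axis=1) - 1.0, 0.0)
            f += penalty_scale * float((excess**2).sum())
            ga = (2.0 * penalty_scale * excess)[:, None] * np.ones_like(alpha)
            g[1 + n_u :] += ga.ravel()
        return f, g

    lo_ne, hi_ne = np.log(config.ne_bounds[0]), np.log(config.ne_bounds[1])
    bounds = (
        [(lo_ne, hi_ne)]
        + [(0.0, config.u_max / U_UNIT)] * n_u
        + [(0.0, config.alpha_point_max)] * n_a
    )

    # deterministic first start: Ne from the mean heterozygosity, tiny U
    pi_mean = float(h.sum() / C.sum())
    pi_mean = min(max(pi_mean, 1e-6), 0.5)
    ne0 = pi_mean / (4.0 * config.u0 * (1.0 - pi_mean))
    ne0 = float(np.clip(ne0, config.ne_bounds[0] * 1.01, config.ne_bounds[1] * 0.99))
    starts = [
        np.concatenate([[np.log(ne0)], np.full(n_u, 0.01), np.zeros(n_a)])
    ]
    rng = np.random.default_rng(config.seed)
    for _ in range(max(config.n_starts - 1, 0)):
        p0 = np.concatenate(
            [
                [rng.uniform(np.log(ne0 / 4.0), np.log(ne0 * 4.0))],
                rng.uniform(0.0, 0.5, size=n_u),
                rng.uniform(0.0, 0.1, size=n_a),
            ]
        )
        p0[0] = np.clip(p0[0], lo_ne, hi_ne)
        starts.append(p0)

    records, best, best_p = [], None, None
    for i, p0 in enumerate(starts):
        res = minimize(
            objective,
            p0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": config.maxiter, "ftol": 1e-12, "gtol": 1e-8},
        )
        records.append(
            {
                "start": i,
                "loglik": -float(res.fun),
                "n_iter": int(res.nit),
                "converged": bool(res.success),
            }
        )
        if best is None or -res.fun > best:
            best, best_p, best_success = -float(res.fun), res.x, bool(res.success)
    if best is None or not np.isfinite(best):
        raise RuntimeError(f"all optimiser starts failed: {records}")
    if not any(r["converged"] for r in records):
        warnings.warn("no optimiser start reported clean convergence")

    theta = _unpack(best_p, bgs_kernels, sweep_kernels if use_sweeps else None, config.u0)
    return FitResult(
        theta_hat=theta,
        loglik=best,
        n_sites=len(h),
        n_pairs=float(C.sum()),
        converged=best_success,
        starts=records,
        config=config,
        bgs_classes=list(bgs_kernels.classes),
        sweep_classes=list(sweep_kernels.classes) if use_sweeps else [],
    )


def _check_alignment_sweep(sweep_kernels: SweepKernels, data: PolymorphismTable):
    if sweep_kernels.n_sites != len(data) or np.any(sweep_kernels.pos != data.pos):
        raise ValueError("sweep kernels and data index different neutral sites")


def _unpack(p, bgs_kernels, sweep_kernels, u0) -> ThetaParams:
    g = bgs_kernels.grid.size
    n_u = len(bgs_kernels.classes) * g
    U = {
        label: p[1 + i * g : 1 + (i + 1) * g] * U_UNIT
        for i, label in enumerate(bgs_kernels.classes)
    }
    alpha = {}
    if sweep_kernels is not None:
        gs = sweep_kernels.grid.size
        for i, label in enumerate(sweep_kernels.classes):
            alpha[label] = p[1 + n_u + i * gs : 1 + n_u + (i + 1) * gs]
    return ThetaParams(ne=float(np.exp(p[0])), U=U, alpha=alpha, u0=u0)


def predict_from_theta(
    theta: ThetaParams,
    bgs_kernels: BgsKernels,
    m: np.ndarray,
    sweep_kernels: SweepKernels | None = None,
    e_cap: float | None = None,
) -> PredictionTrack:
    """Model surfaces (pi, B, S, pi0) at every kernel site for ``theta``."""
    B = compose_B(bgs_kernels, theta.U, e_cap=e_cap)
    if sweep_kernels is not None and theta.alpha:
        S = compose_S(sweep_kernels, theta.alpha)
    else:
        S = np.zeros(bgs_kernels.n_sites)
    pi, pi0 = predict_pi(theta, B, S, np.asarray(m, dtype=np.float64))
    return PredictionTrack(
        chrom=bgs_kernels.chrom,
        pos=bgs_kernels.pos,
        pi=pi,
        B=B,
        S=S,
        pi0=pi0,
        m=np.asarray(m, dtype=np.float64),
    )


def assign_windows(chrom, pos, window_bp: int) -> pd.DataFrame:
    """Contiguous non-overlapping window ids: a 1-based site at position p
    falls in window floor(p / window_bp) of its chromosome (so position
    2,000,000 with 2 Mb windows opens the second window)."""
    df = pd.DataFrame({"chrom": np.asarray(chrom), "pos": np.asarray(pos, dtype=np.int64)})
    df["window"] = df["pos"] // int(window_bp)
    return df


def crossfit(
    bgs_kernels: BgsKernels,
    data: PolymorphismTable,
    m: np.ndarray,
    config: FitConfig | None = None,
    sweep_kernels: SweepKernels | None = None,
    window_bp: int = 2_000_000,
    k_folds: int = 10,
):
    """Out-of-sample predictions by k-fold cross-fitting over contiguous
    windows.

    Windows of ``window_bp`` are assigned round-robin to ``k_folds`` folds;
    each fold's sites are predicted from a fit that excluded them.  The
    union of the fold predictions covers every neutral site exactly once.

    Returns ``(track, fold_of_site, fits)``.
    """
    config = config or FitConfig()
    _check_alignment(bgs_kernels, data)
    m = np.asarray(m, dtype=np.float64)
    wdf = assign_windows(data.chrom, data.pos, window_bp)
    windows = (
        wdf[["chrom", "window"]].drop_duplicates().sort_values(["chrom", "window"])
    ).reset_index(drop=True)
    n_windows = len(windows)
    if k_folds < 1:
        raise ValueError("k_folds must be >= 1")
    if k_folds == 1:
        warnings.warn("k_folds=1: in-sample fit applied everywhere (degenerate)")
    elif n_windows < k_folds:
        raise ValueError(f"only {n_windows} windows for {k_folds} folds")
    windows["fold"] = np.arange(n_windows) % k_folds
    key = pd.MultiIndex.from_frame(windows[["chrom", "window"]])
    fold_lookup = pd.Series(windows["fold"].to_numpy(), index=key)
    fold_of_site = fold_lookup.loc[
        pd.MultiIndex.from_frame(wdf[["chrom", "window"]])
    ].to_numpy()

    pi = np.empty(len(data))
    B = np.empty(len(data))
    S = np.empty(len(data))
    pi0 = np.empty(len(data))
    fits = []
    for fold in range(k_folds):
        test = fold_of_site == fold
        train = ~test if k_folds > 1 else np.ones(len(data), dtype=bool)
        fr = fit(
            bgs_kernels,
            data,
            m,
            config=config,
            sweep_kernels=sweep_kernels,
            site_mask=train,
        )
        fits.append(fr)
        tr = predict_from_theta(
            fr.theta_hat, bgs_kernels, m, sweep_kernels=sweep_kernels, e_cap=config.e_cap
        )
        sel = test if k_folds > 1 else np.ones(len(data), dtype=bool)
        pi[sel], B[sel], S[sel], pi0[sel] = tr.pi[sel], tr.B[sel], tr.S[sel], tr.pi0[sel]
    track = PredictionTrack(
        chrom=data.chrom, pos=data.pos, pi=pi, B=B, S=S, pi0=pi0, m=m
    )
    return track, fold_of_site, fits
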