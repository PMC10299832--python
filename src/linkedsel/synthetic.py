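"""Synthetic genomes with the statistical structure the inference assumes.

The generator emulates the inputs of the human analysis — recombination-
rate heterogeneity, ~6% of sites in constrained blocks split into exonic
and non-exonic classes, substitutions enriched in/near constrained
regions, relative mutation rates varying across blocks of consecutive
neutral sites, and pair-sampling noise at n = 216 sampled chromosomes —
without simulating selection dynamics themselves: data are drawn from the
model's own mean surface pi(x) plus sampling noise.  Parameter-recovery
tests on such data are therefore exact-model tests; they are optimistic
relative to real data, where linkage correlates sites and the mean
structure is misspecified.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bgs import (
    BgsKernels,
    SelectionGrid,
    TieredApprox,
    bgs_exponents_brute,
    compose_B,
    precompute_bgs,
)
from .genome_io import (
    AnnotationSet,
    GeneticMap,
    MutationRateBlocks,
    NeutralMask,
    PolymorphismTable,
    SubstitutionSet,
    write_bed,
    write_genetic_map,
    write_mutation_blocks,
    write_polymorphism,
    write_substitutions,
)
from .likelihood import ThetaParams, predict_pi
from .sweeps import SweepKernels, compose_S, precompute_sweeps

__all__ = [
    "SyntheticConfig",
    "SimulatedGenome",
    "TruthBundle",
    "default_config",
    "recovery_config",
    "simulate_genome",
    "simulate_polymorphism",
    "make_truth_bundle",
    "write_genome",
]


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic genome.

    Defaults emulate the human data set: 216 sampled chromosomes, 6% of
    sites constrained with a 0.17/0.83 exonic/non-exonic split, genetic-map
    rates lognormal around 1.2 cM/Mb in 500 kb segments, relative mutation
    rates per block of 6000 neutral sites with ~10% spread, and u0 =
    1.4e-8 with Ne = 2e4 giving human-like baseline diversity ~1.1e-3.
    """

    seed: int
    L: int = 50_000_000
    chrom: str = "chr1"
    n_chrom_samples: int = 216
    frac_selected: float = 0.06
    class_mix: dict = field(
        default_factory=lambda: {"conserved_exonic": 0.17, "conserved_nonexonic": 0.83}
    )
    # recombination map
    map_segment_bp: int = 500_000
    rate_mean_cm_mb: float = 1.2
    rate_sigma_log: float = 0.6
    # constrained-block geometry
    block_len_median_bp: float = 400.0
    block_len_sigma_log: float = 0.9
    block_gap_sigma_log: float = 1.2
    min_block_bp: int = 30
    neutral_buffer_bp: int = 100
    # neutral sites and mutation-rate blocks
    neutral_site_spacing: int = 1000
    block_size: int = 6000
    m_gamma_shape: float = 100.0
    # substitutions (features for the sweep model), per class per Mb
    substitution_density_mb: dict = field(
        default_factory=lambda: {"nonsynonymous": 12.0}
    )
    sub_frac_uniform: float = 0.3
    # truth parameters
    grid: SelectionGrid = field(default_factory=SelectionGrid.default)
    theta_true: ThetaParams | None = None
    ne_ref: float = 2e4
    t_lineage: float = 1e4
    introgression_outliers: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.L < 1_000_000:
            raise ValueError("genome length must be >= 1 Mb for meaningful tests")
        if not 0 <= self.frac_selected < 1:
            raise ValueError("frac_selected must be in [0, 1)")
        mix = sum(self.class_mix.values())
        if self.class_mix and abs(mix - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if self.frac_selected > 0.5:
            raise ValueError("frac_selected too high: too few neutral sites remain")
        if self.theta_true is None:
            self.theta_true = default_theta(
                list(self.class_mix), list(self.substitution_density_mb), self.grid
            )


def default_theta(
    bgs_classes: list, sub_classes: list, grid: SelectionGrid | None = None
) -> ThetaParams:
    """Plausible human-scale truth: total deleterious rate per selected site
    well below the total-rate bound, non-exonic mass biased to weak
    selection, exonic mass to strong; no sweeps (alpha = 0)."""
    grid = grid or SelectionGrid.default()
    g = grid.size

    def spread(weights, total):
        w = np.asarray(weights, dtype=np.float64)
        w = w / w.sum() * total
        if len(w) != g:
            raise ValueError("weight template does not match grid size")
        return w

    U = {}
    for label in bgs_classes:
        if "exonic" in label and "non" not in label:
            U[label] = spread([0.0, 0.0, 0.5, 1.0, 1.5, 1.0], 4e-9)
        else:
            U[label] = spread([3.0, 3.0, 2.0, 1.0, 0.8, 0.2], 1.0e-8)
    alpha = {label: np.zeros(g) for label in sub_classes}
    return ThetaParams(ne=2e4, U=U, alpha=alpha, u0=1.4e-8)


def default_config(seed: int, L: int = 50_000_000, **overrides) -> SyntheticConfig:
    """The two-class default genome (calibration/evaluation experiments)."""
    return SyntheticConfig(seed=seed, L=L, **overrides)


def recovery_config(
    seed: int,
    L: int = 50_000_000,
    alpha_strong: float = 0.0,
    **overrides,
) -> SyntheticConfig:
    """Single constrained class (7-parameter BGS fit: 6 weights + Ne) plus
    one substitution class.  ``alpha_strong`` is the true fraction of
    substitutions sweeping at s = 0.01 (the strongest default grid point)."""
    grid = SelectionGrid.default()
    U = {"conserved": np.array([3.0, 3.0, 2.0, 1.0, 0.8, 0.2]) / 10.0 * 1.0e-8}
    alpha_vec = np.zeros(grid.size)
    if alpha_strong:
        alpha_vec[-1] = alpha_strong
    theta = ThetaParams(ne=2e4, U=U, alpha={"nonsynonymous": alpha_vec}, u0=1.4e-8)
    return SyntheticConfig(
        seed=seed,
        L=L,
        class_mix={"conserved": 1.0},
        grid=grid,
        theta_true=theta,
        **overrides,
    )


@dataclass
class SimulatedGenome:
    """All generated inputs plus the neutral-site index used downstream."""

    config: SyntheticConfig
    gmap: GeneticMap
    annotations: list
    substitutions: SubstitutionSet
    mask: NeutralMask
    blocks: MutationRateBlocks
    neutral_chrom: np.ndarray
    neutral_pos: np.ndarray
    m: np.ndarray  # per-neutral-site relative mutation rate

    @property
    def n_neutral(self) -> int:
        return len(self.neutral_pos)


@dataclass
class TruthBundle:
    """Ground-truth per-site surfaces at theta_true, self-consistent with
    the package's own kernel code paths, plus a brute-force cross-check."""

    theta_true: ThetaParams
    B: np.ndarray
    S: np.ndarray
    pi: np.ndarray
    pi0: np.ndarray
    brute_check: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------


def _sim_map(cfg: SyntheticConfig, rng: np.random.Generator) -> GeneticMap:
    L, seg = cfg.L, cfg.map_segment_bp
    bounds = list(range(0, L, seg)) + [L]
    n_seg = len(bounds) - 1
    mu = np.log(cfg.rate_mean_cm_mb) - cfg.rate_sigma_log**2 / 2.0
    rates = np.exp(rng.normal(mu, cfg.rate_sigma_log, size=n_seg))
    pos = np.array([b + 1 for b in bounds[:-1]] + [L], dtype=np.int64)
    cm = np.zeros(n_seg + 1)
    for i in range(n_seg):
        cm[i + 1] = cm[i] + rates[i] * (pos[i + 1] - pos[i]) / 1e6
    rate_col = np.append(rates, rates[-1])
    return GeneticMap(
        pd.DataFrame({"chrom": cfg.chrom, "pos": pos, "rate": rate_col, "cm": cm})
    )


def _sim_blocks(cfg: SyntheticConfig, rng: np.random.Generator):
    """Constrained blocks: lognormal lengths, lognormal gaps (clustered
    spacing), covering ~frac_selected of the genome in expectation."""
    if cfg.frac_selected == 0 or not cfg.class_mix:
        return []
    mu_len = np.log(cfg.block_len_median_bp)
    mean_len = np.exp(mu_len + cfg.block_len_sigma_log**2 / 2.0)
    mean_gap = mean_len * (1.0 - cfg.frac_selected) / cfg.frac_selected
    mu_gap = np.log(mean_gap) - cfg.block_gap_sigma_log**2 / 2.0
    blocks = []
    cursor = 0
    while True:
        gap = int(np.exp(rng.normal(mu_gap, cfg.block_gap_sigma_log)))
        length = max(
            int(np.exp(rng.normal(mu_len, cfg.block_len_sigma_log))), cfg.min_block_bp
        )
        start = cursor + gap
        end = start + length
        if end >= cfg.L:
            break
        blocks.append((start, end))
        cursor = end
    return blocks


def _sim_substitutions(
    cfg: SyntheticConfig, blocks: list, rng: np.random.Generator
) -> SubstitutionSet:
    rows = []
    starts = np.array([b[0] for b in blocks], dtype=np.int64)
    lens = np.array([b[1] - b[0] for b in blocks], dtype=np.int64)
    wts = lens / lens.sum() if len(blocks) else None
    for label in sorted(cfg.substitution_density_mb):
        dens = cfg.substitution_density_mb[label]
        count = rng.poisson(dens * cfg.L / 1e6)
        n_unif = rng.binomial(count, cfg.sub_frac_uniform) if len(blocks) else count
        pos = list(rng.integers(1, cfg.L + 1, size=n_unif))
        n_in = count - n_unif
        if n_in and len(blocks):
            which = rng.choice(len(blocks), size=n_in, p=wts)
            offs = rng.random(n_in)
            pos += list((starts[which] + offs * lens[which]).astype(np.int64) + 1)
        for p in pos:
            rows.append((cfg.chrom, int(p), label))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "class_label"])
    df = df.drop_duplicates(subset=["chrom", "pos"])
    return SubstitutionSet(sites=df)


def simulate_genome(cfg: SyntheticConfig) -> SimulatedGenome:
    """Generate map, annotations, substitutions, neutral mask/sites and
    mutation-rate blocks.  Deterministic given ``cfg.seed``."""
    ss = np.random.SeedSequence(cfg.seed)
    r_map, r_blk, r_cls, r_sub, r_m = [np.random.default_rng(s) for s in ss.spawn(5)]

    gmap = _sim_map(cfg, r_map)
    raw_blocks = _sim_blocks(cfg, r_blk)

    # class assignment per block (expected site share = class_mix)
    labels = sorted(cfg.class_mix)
    probs = np.array([cfg.class_mix[l] for l in labels])
    annotations = []
    assign = (
        r_cls.choice(len(labels), size=len(raw_blocks), p=probs)
        if raw_blocks
        else np.empty(0, dtype=int)
    )
    for i, label in enumerate(labels):
        ivs = [b for b, a in zip(raw_blocks, assign) if a == i]
        df = pd.DataFrame(ivs, columns=["start", "end"], dtype=np.int64)
        df.insert(0, "chrom", cfg.chrom)
        annotations.append(AnnotationSet(class_label=label, intervals=df))

    subs = _sim_substitutions(cfg, raw_blocks, r_sub)

    # neutral mask: complement of buffered constrained blocks
    buffered = [
        (max(s - cfg.neutral_buffer_bp, 0), min(e + cfg.neutral_buffer_bp, cfg.L))
        for s, e in raw_blocks
    ]
    mask_ivs = []
    prev = 0
    for s, e in buffered:
        if s > prev:
            mask_ivs.append((prev, s))
        prev = max(prev, e)
    if prev < cfg.L:
        mask_ivs.append((prev, cfg.L))
    if not mask_ivs:
        raise ValueError("no neutral sites remain at this frac_selected")
    mask = NeutralMask(
        intervals=pd.DataFrame(
            [(cfg.chrom, s, e) for s, e in mask_ivs], columns=["chrom", "start", "end"]
        )
    )

    # neutral sites: fixed genome-wide grid restricted to the mask
    grid_pos = np.arange(1, cfg.L + 1, cfg.neutral_site_spacing, dtype=np.int64)
    keep = mask.contains(cfg.chrom, grid_pos)
    neutral_pos = grid_pos[keep]
    neutral_chrom = np.full(len(neutral_pos), cfg.chrom, dtype=object)

    # mutation-rate blocks over runs of block_size consecutive neutral sites
    n = len(neutral_pos)
    n_blocks = max(n // cfg.block_size, 1)
    edges = np.minimum(np.arange(n_blocks + 1) * cfg.block_size, n)
    edges[-1] = n
    m_raw = r_m.gamma(cfg.m_gamma_shape, 1.0 / cfg.m_gamma_shape, size=n_blocks)
    sizes = np.diff(edges)
    m_raw = m_raw / np.average(m_raw, weights=sizes)
    rows = []
    m_site = np.empty(n)
    for b in range(n_blocks):
        lo, hi = edges[b], edges[b + 1]
        start = int(neutral_pos[lo] - 1)
        end = int(neutral_pos[hi - 1])
        rows.append((cfg.chrom, start, end, m_raw[b]))
        m_site[lo:hi] = m_raw[b]
    blocks = MutationRateBlocks(
        blocks=pd.DataFrame(rows, columns=["chrom", "start", "end", "m"])
    )
    return SimulatedGenome(
        config=cfg,
        gmap=gmap,
        annotations=annotations,
        substitutions=subs,
        mask=mask,
        blocks=blocks,
        neutral_chrom=neutral_chrom,
        neutral_pos=neutral_pos,
        m=m_site,
    )


# ---------------------------------------------------------------------------
# truth bundle and polymorphism sampling
# ---------------------------------------------------------------------------


def make_truth_bundle(
    genome: SimulatedGenome,
    d_max: float = 100.0,
    approx: TieredApprox | str | None = "auto",
    n_check: int = 1000,
    return_kernels: bool = False,
):
    """True per-site B, S, pi, pi0 at theta_true via the production kernel
    code paths, cross-validated against a brute-force double loop on a
    subsample of neutral sites.

    With ``approx="auto"`` the tiered far-field aggregation is enabled when
    the exact pair sum would exceed ~2e8 pairs.  The brute-force tripwire
    tolerance is 1e-8 (relative, on B) for exact kernels and 2e-3 for
    tiered kernels; disagreement beyond it raises.
    """
    cfg = genome.config
    theta = cfg.theta_true
    n_sel = sum(a.n_sites for a in genome.annotations)
    if approx == "auto":
        approx = (
            TieredApprox() if genome.n_neutral * max(n_sel, 1) > 2e8 else None
        )
    bgs_k = precompute_bgs(
        genome.neutral_chrom,
        genome.neutral_pos,
        genome.annotations,
        genome.gmap,
        cfg.grid,
        d_max=d_max,
        approx=approx,
    )
    B = compose_B(bgs_k, theta.U)
    sweep_k = None
    S = np.zeros(genome.n_neutral)
    if theta.alpha and len(genome.substitutions.sites):
        sweep_k = precompute_sweeps(
            genome.neutral_chrom,
            genome.neutral_pos,
            genome.substitutions,
            genome.gmap,
            cfg.grid,
            ne_ref=cfg.ne_ref,
            d_max=d_max,
            t_lineage=cfg.t_lineage,
        )
        S = compose_S(sweep_k, theta.alpha)
    pi, pi0 = predict_pi(theta, B, S, genome.m)

    # brute-force tripwire on a deterministic subsample
    check = {}
    if n_check > 0 and n_sel > 0:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 178]))
        idx = np.sort(
            rng.choice(genome.n_neutral, size=min(n_check, genome.n_neutral), replace=False)
        )
        sub_cm = np.asarray(genome.gmap.interpolate(cfg.chrom, genome.neutral_pos[idx]))
        expo = np.zeros(len(idx))
        for a, ann in enumerate(genome.annotations):
            if ann.n_sites == 0:
                continue
            sel_cm = np.sort(
                np.asarray(genome.gmap.interpolate(cfg.chrom, ann.site_positions(cfg.chrom)))
            )
            if len(idx) * len(sel_cm) <= 2e7:
                E_bf = bgs_exponents_brute(sub_cm, sel_cm, cfg.grid, d_max=d_max)
            else:
                # direct pair sum, jit-compiled (independent of the tiered path)
                from .bgs import _bgs_exact_nb

                E_bf = _bgs_exact_nb(sub_cm, sel_cm, cfg.grid.as_array(), float(d_max))
            expo += E_bf @ theta.U[ann.class_label]
        B_bf = np.exp(-expo)
        rel = np.abs(B_bf - B[idx]) / B_bf
        tol = 1e-8 if approx is None else 2e-3
        check = {
            "n_check": int(len(idx)),
            "max_rel_err": float(rel.max()),
            "tolerance": tol,
            "approx": approx is not None,
        }
        if rel.max() > tol:
            raise RuntimeError(
                f"kernel tripwire: brute-force vs composed B disagree "
                f"(max rel err {rel.max():.3e} > {tol:g})"
            )

    bundle = TruthBundle(
        theta_true=theta, B=B, S=S, pi=pi, pi0=pi0, brute_check=check
    )
    if return_kernels:
        return bundle, bgs_k, sweep_k
    return bundle


def simulate_polymorphism(
    neutral_chrom,
    neutral_pos,
    pi: np.ndarray,
    n_chrom: int,
    seed: int,
    introgression_mask: np.ndarray | None = None,
) -> PolymorphismTable:
    """Draw per-site heterozygous pair counts h ~ Binomial(C, pi).

    Sites are independent given pi(x): the estimand of the inference is
    the mean surface, and independent pair-binomial noise is exactly the
    noise model the composite likelihood assumes.  The emitted table also
    carries a cosmetic allele count k (the admissible count closest to
    the drawn h); the exact h column is what the likelihood consumes, as
    rounding h onto the coarse k(n-k) grid would destroy the signal at
    human-scale diversity.
    """
    pi = np.asarray(pi, dtype=np.float64)
    if np.any(pi <= 0) or np.any(pi >= 1):
        raise ValueError("pi must be in (0, 1)")
    if introgression_mask is not None:
        pi = np.where(introgression_mask, pi * 1.2, pi)
    rng = np.random.default_rng(seed)
    n = int(n_chrom)
    C = n * (n - 1) // 2
    h = rng.binomial(C, pi)
    with np.errstate(invalid="ignore"):
        k = np.round(n * (1.0 - np.sqrt(np.maximum(0.0, 1.0 - 4.0 * h / n**2))) / 2.0)
    k = np.clip(k, 0, n // 2).astype(np.int64)
    df = pd.DataFrame(
        {
            "chrom": np.asarray(neutral_chrom),
            "pos": np.asarray(neutral_pos, dtype=np.int64),
            "n": n,
            "k": k,
            "h": h.astype(np.int64),
        }
    )
    return PolymorphismTable(sites=df)


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------


def _file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_genome(genome: SimulatedGenome, outdir, table: PolymorphismTable | None = None) -> dict:
    """Write every input file to ``outdir``; returns name -> checksum."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genetic_map(genome.gmap, outdir / "map.tsv")
    for ann in genome.annotations:
        write_bed(ann, outdir / f"annotations_{ann.class_label}.bed")
    write_substitutions(genome.substitutions, outdir / "substitutions.tsv")
    write_bed(genome.mask, outdir / "neutral_mask.bed")
    write_mutation_blocks(genome.blocks, outdir / "blocks.tsv")
    if table is not None:
        write_polymorphism(table, outdir / "poly.tsv")
    sums = {p.name: _file_checksum(p) for p in sorted(outdir.glob("*.tsv"))}
    sums.update({p.name: _file_checksum(p) for p in sorted(outdir.glob("*.bed"))})
    with open(outdir / "checksums.json", "w") as fh:
        json.dump(sums, fh, indent=2, sort_keys=True)
    return sums
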