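"""Genomic data model: readers, writers, genetic-map interpolation.

Conventions
-----------
* BED-style interval inputs (annotations, neutral mask, B-map tracks) are
  0-based half-open.
* Point positions (genetic map, substitutions, polymorphism sites) are
  1-based.
* All inputs are strandless; chromosome names are matched exactly.

File dialects (tab-separated, ``#`` comment lines allowed):

====================  =====================================================
genetic map           ``chrom  pos  rate_cM_Mb  cm``
polymorphism table    ``chrom  pos  n  k`` (optional 5th column ``h``)
mutation-rate blocks  ``chrom  block_start_pos  block_end_pos  m``
B-map track           ``chrom  start  end  value``
BED mask/annotation   ``chrom  start  end``
====================  =====================================================
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "AnnotationSet",
    "SubstitutionSet",
    "NeutralMask",
    "MutationRateBlocks",
    "PolymorphismTable",
    "BMapTrack",
    "read_genetic_map",
    "write_genetic_map",
    "read_bed",
    "write_bed",
    "read_substitutions",
    "write_substitutions",
    "read_mutation_blocks",
    "write_mutation_blocks",
    "read_polymorphism",
    "write_polymorphism",
    "read_bmap",
    "write_bmap",
    "interpolate_cm",
    "cm_to_recfrac",
]


class GenomeIOError(ValueError):
    """Raised when an input file violates its format or invariants."""


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------


@dataclass
class GeneticMap:
    """Piecewise-linear genetic map.

    ``table`` holds one row per map point with columns ``chrom`` (str),
    ``pos`` (bp, 1-based, strictly increasing within a chromosome),
    ``rate`` (local rate in cM/Mb, >= 0) and ``cm`` (cumulative map
    position in cM, non-decreasing).
    """

    table: pd.DataFrame
    _by_chrom: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        t = self.table
        if len(t) == 0:
            raise GenomeIOError("empty map")
        for chrom, sub in t.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy(dtype=np.float64)
            cm = sub["cm"].to_numpy(dtype=np.float64)
            rate = sub["rate"].to_numpy(dtype=np.float64)
            if len(pos) < 2:
                raise GenomeIOError(
                    f"map for {chrom} needs at least 2 points, got {len(pos)}"
                )
            if np.any(np.diff(pos) <= 0):
                i = int(np.argmax(np.diff(pos) <= 0)) + 1
                raise GenomeIOError(
                    f"non-monotone map: pos not strictly increasing for {chrom} "
                    f"at point {i}"
                )
            if np.any(np.diff(cm) < 0):
                i = int(np.argmax(np.diff(cm) < 0)) + 1
                raise GenomeIOError(
                    f"non-monotone map: cm decreasing for {chrom} at point {i}"
                )
            if np.any(rate < 0):
                raise GenomeIOError(f"negative recombination rate for {chrom}")
            self._by_chrom[chrom] = (pos, cm)

    @property
    def chroms(self) -> list:
        return list(self._by_chrom)

    def span(self, chrom: str) -> tuple:
        """(first, last) mapped physical position of ``chrom``."""
        pos, _ = self._lookup(chrom)
        return float(pos[0]), float(pos[-1])

    def _lookup(self, chrom: str):
        try:
            return self._by_chrom[chrom]
        except KeyError:
            raise GenomeIOError(f"unknown chromosome {chrom!r} in genetic map")

    def interpolate(self, chrom: str, pos, clamp: bool = False) -> np.ndarray:
        """Cumulative map position (cM) at physical position(s) ``pos``.

        Linear interpolation between flanking map points.  Positions outside
        the mapped range raise unless ``clamp`` is set, in which case they
        take the boundary cm value.
        """
        mp, mc = self._lookup(chrom)
        p = np.asarray(pos, dtype=np.float64)
        if not clamp and (np.any(p < mp[0]) or np.any(p > mp[-1])):
            raise GenomeIOError(
                f"position outside mapped range [{mp[0]:g}, {mp[-1]:g}] for "
                f"{chrom}; pass clamp=True to clamp to map ends"
            )
        out = np.interp(p, mp, mc)
        return out if out.shape else float(out)


def interpolate_cm(gmap: GeneticMap, chrom: str, pos, clamp: bool = False):
    """Functional alias for :meth:`GeneticMap.interpolate`."""
    return gmap.interpolate(chrom, pos, clamp=clamp)


def cm_to_recfrac(d):
    """Map distance (cM) -> recombination fraction via Haldane's function.

    r = (1 - exp(-2 d / 100)) / 2, so r ≈ d/100 for small d and r -> 0.5 as
    d -> infinity.
    """
    d = np.asarray(d, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("negative map distance")
    r = 0.5 * (-np.expm1(-0.02 * d))
    return r if r.shape else float(r)


def _read_table(path, columns, dtypes):
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=0,
            dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        raise GenomeIOError(f"empty file: {path}")
    if len(df.columns) < len(columns):
        raise GenomeIOError(
            f"{path}: expected columns {columns}, got {list(df.columns)}"
        )
    df = df.iloc[:, : len(columns) + (len(df.columns) - len(columns))]
    out = {}
    for i, (name, dt) in enumerate(zip(columns, dtypes)):
        col = df.iloc[:, i]
        if dt is str:
            out[name] = col.astype(str)
        else:
            try:
                out[name] = col.astype(dt)
            except (TypeError, ValueError) as exc:
                raise GenomeIOError(f"{path}: column {name!r} not parseable: {exc}")
    res = pd.DataFrame(out)
    res.attrs["extra_columns"] = list(df.columns[len(columns):])
    for extra in res.attrs["extra_columns"]:
        res[extra] = df[extra]
    return res


def read_genetic_map(path) -> GeneticMap:
    """Read a genetic-map TSV (``chrom pos rate_cM_Mb cm``)."""
    df = _read_table(path, ["chrom", "pos", "rate_cM_Mb", "cm"], [str, np.int64, float, float])
    if len(df) == 0:
        raise GenomeIOError("empty map")
    df = df.rename(columns={"rate_cM_Mb": "rate"})
    return GeneticMap(df[["chrom", "pos", "rate", "cm"]])


def write_genetic_map(gmap: GeneticMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\trate_cM_Mb\tcm\n")
        for row in gmap.table.itertuples(index=False):
            fh.write(f"{row.chrom}\t{int(row.pos)}\t{row.rate:.8g}\t{row.cm:.10g}\n")


# ---------------------------------------------------------------------------
# Interval sets (annotations, neutral mask)
# ---------------------------------------------------------------------------


def _validate_intervals(df: pd.DataFrame, what: str) -> pd.DataFrame:
    if np.any(df["start"] < 0):
        raise GenomeIOError(f"{what}: negative start coordinate")
    if np.any(df["end"] <= df["start"]):
        raise GenomeIOError(f"{what}: interval with end <= start")
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    for chrom, sub in df.groupby("chrom", sort=False):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        if np.any(s[1:] < e[:-1]):
            raise GenomeIOError(f"{what}: overlapping intervals on {chrom}")
    return df


@dataclass
class AnnotationSet:
    """Sorted non-overlapping 0-based half-open intervals of one annotation
    class (e.g. ``conserved_exonic``)."""

    class_label: str
    intervals: pd.DataFrame  # chrom, start, end

    def __post_init__(self) -> None:
        self.intervals = _validate_intervals(
            self.intervals[["chrom", "start", "end"]].copy(),
            f"annotation {self.class_label!r}",
        )

    @property
    def n_sites(self) -> int:
        return int((self.intervals["end"] - self.intervals["start"]).sum())

    def site_positions(self, chrom: str) -> np.ndarray:
        """All 1-based site positions covered on ``chrom``."""
        sub = self.intervals[self.intervals["chrom"] == chrom]
        if len(sub) == 0:
            return np.empty(0, dtype=np.int64)
        parts = [
            np.arange(s + 1, e + 1, dtype=np.int64)
            for s, e in zip(sub["start"], sub["end"])
        ]
        return np.concatenate(parts)


@dataclass
class NeutralMask:
    """Sorted non-overlapping 0-based half-open putatively neutral intervals."""

    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        self.intervals = _validate_intervals(
            self.intervals[["chrom", "start", "end"]].copy(), "neutral mask"
        )

    @property
    def n_sites(self) -> int:
        return int((self.intervals["end"] - self.intervals["start"]).sum())

    def contains(self, chrom, pos) -> np.ndarray:
        """Membership of 1-based positions in the mask (vectorised)."""
        sub = self.intervals[self.intervals["chrom"] == chrom]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        p0 = np.asarray(pos, dtype=np.int64) - 1
        idx = np.searchsorted(starts, p0, side="right") - 1
        ok = idx >= 0
        ok[ok] &= p0[ok] < ends[idx[ok]]
        return ok


def read_bed(path, class_label: str | None = None):
    """Read a 3-column BED. Returns :class:`AnnotationSet` when
    ``class_label`` is given, else :class:`NeutralMask`."""
    df = _read_table(path, ["chrom", "start", "end"], [str, np.int64, np.int64])
    if class_label is not None:
        return AnnotationSet(class_label=class_label, intervals=df)
    return NeutralMask(intervals=df)


def write_bed(obj, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\n")
        for row in obj.intervals.itertuples(index=False):
            fh.write(f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\n")


# ---------------------------------------------------------------------------
# Substitutions
# ---------------------------------------------------------------------------


@dataclass
class SubstitutionSet:
    """Point positions (1-based) of human-lineage substitutions, each with a
    class label (e.g. ``nonsynonymous``)."""

    sites: pd.DataFrame  # chrom, pos, class_label

    def __post_init__(self) -> None:
        df = self.sites[["chrom", "pos", "class_label"]].copy()
        if np.any(df["pos"] < 1):
            raise GenomeIOError("substitution with position < 1")
        self.sites = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
            drop=True
        )

    @property
    def classes(self) -> list:
        return sorted(self.sites["class_label"].unique())

    def positions(self, chrom: str, class_label: str) -> np.ndarray:
        sel = (self.sites["chrom"] == chrom) & (self.sites["class_label"] == class_label)
        return self.sites.loc[sel, "pos"].to_numpy(dtype=np.int64)


def read_substitutions(path) -> SubstitutionSet:
    df = _read_table(path, ["chrom", "pos", "class_label"], [str, np.int64, str])
    return SubstitutionSet(sites=df)


def write_substitutions(subs: SubstitutionSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tclass_label\n")
        for row in subs.sites.itertuples(index=False):
            fh.write(f"{row.chrom}\t{int(row.pos)}\t{row.class_label}\n")


# ---------------------------------------------------------------------------
# Mutation-rate blocks
# ---------------------------------------------------------------------------


@dataclass
class MutationRateBlocks:
    """Relative mutation rate m (genome mean 1) for blocks of consecutive
    neutral sites.

    Stored as bp intervals [start, end) per chromosome; each neutral site
    must fall in exactly one block.  The site-weighted mean of m over the
    neutral sites it is applied to must be 1 (checked in
    :meth:`rates_for_sites` to 1e-6 by default).
    """

    blocks: pd.DataFrame  # chrom, start, end, m

    def __post_init__(self) -> None:
        df = self.blocks[["chrom", "start", "end", "m"]].copy()
        if np.any(df["m"] <= 0):
            raise GenomeIOError("mutation-rate block with m <= 0")
        self.blocks = _validate_intervals(df, "mutation-rate blocks")

    def rates_for_sites(self, chrom, pos, check_mean: bool = False, tol: float = 1e-6):
        """m value per 1-based site position; every site must be covered."""
        out = np.empty(len(pos), dtype=np.float64)
        out.fill(np.nan)
        chrom = np.asarray(chrom)
        pos = np.asarray(pos, dtype=np.int64)
        for c in np.unique(chrom):
            sub = self.blocks[self.blocks["chrom"] == c]
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            mvals = sub["m"].to_numpy()
            mask = chrom == c
            p0 = pos[mask] - 1
            idx = np.searchsorted(starts, p0, side="right") - 1
            if np.any(idx < 0) or np.any(p0 >= ends[np.maximum(idx, 0)]):
                raise GenomeIOError(
                    f"neutral site on {c} not covered by any mutation-rate block"
                )
            vals = mvals[idx]
            out[mask] = vals
        if np.any(np.isnan(out)):
            raise GenomeIOError("neutral site chromosome absent from blocks")
        if check_mean and abs(out.mean() - 1.0) > tol:
            raise GenomeIOError(
                f"site-weighted mean relative mutation rate {out.mean():.8f} != 1"
            )
        return out


def read_mutation_blocks(path) -> MutationRateBlocks:
    df = _read_table(
        path,
        ["chrom", "block_start_pos", "block_end_pos", "m"],
        [str, np.int64, np.int64, float],
    )
    df = df.rename(columns={"block_start_pos": "start", "block_end_pos": "end"})
    return MutationRateBlocks(blocks=df)


def write_mutation_blocks(blocks: MutationRateBlocks, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tblock_start_pos\tblock_end_pos\tm\n")
        for row in blocks.blocks.itertuples(index=False):
            fh.write(f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{row.m:.10g}\n")


# ---------------------------------------------------------------------------
# Polymorphism table
# ---------------------------------------------------------------------------


@dataclass
class PolymorphismTable:
    """Per-neutral-site allele counts.

    Columns: ``chrom``, ``pos`` (1-based), ``n`` (sampled chromosomes),
    ``k`` (derived/minor allele count), ``h`` (heterozygous pair count,
    defaults to k(n-k)) and derived ``C`` = n(n-1)/2.  Monomorphic sites are
    retained with h = 0.
    """

    sites: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.sites.copy()
        if "h" not in df.columns:
            df["h"] = df["k"] * (df["n"] - df["k"])
        df["C"] = df["n"] * (df["n"] - 1) // 2
        if np.any(df["n"] < 2):
            raise GenomeIOError("polymorphism site with n < 2")
        if np.any((df["k"] < 0) | (df["k"] > df["n"])):
            raise GenomeIOError("allele count k outside [0, n]")
        if np.any((df["h"] < 0) | (df["h"] > df["C"])):
            raise GenomeIOError("heterozygous pair count h outside [0, C]")
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        dup = df.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise GenomeIOError("duplicate polymorphism site")
        self.sites = df[["chrom", "pos", "n", "k", "h", "C"]]

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def pos(self) -> np.ndarray:
        return self.sites["pos"].to_numpy(dtype=np.int64)

    @property
    def chrom(self) -> np.ndarray:
        return self.sites["chrom"].to_numpy()

    @property
    def h(self) -> np.ndarray:
        return self.sites["h"].to_numpy(dtype=np.float64)

    @property
    def C(self) -> np.ndarray:
        return self.sites["C"].to_numpy(dtype=np.float64)

    def subset(self, mask) -> "PolymorphismTable":
        return PolymorphismTable(self.sites[np.asarray(mask)].reset_index(drop=True))


def read_polymorphism(path) -> PolymorphismTable:
    df = _read_table(path, ["chrom", "pos", "n", "k"], [str, np.int64, np.int64, np.int64])
    if "h" in df.attrs.get("extra_columns", []):
        df["h"] = df["h"].astype(np.int64)
    return PolymorphismTable(sites=df)


def write_polymorphism(table: PolymorphismTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tn\tk\th\n")
        for row in table.sites.itertuples(index=False):
            fh.write(f"{row.chrom}\t{int(row.pos)}\t{int(row.n)}\t{int(row.k)}\t{int(row.h)}\n")


# ---------------------------------------------------------------------------
# B-map tracks
# ---------------------------------------------------------------------------


@dataclass
class BMapTrack:
    """Piecewise-constant track (B, S or pi) over neutral positions.

    Intervals are 0-based half-open with a float ``value`` column.  B tracks
    are dimensionless in [0, 1].
    """

    intervals: pd.DataFrame  # chrom, start, end, value
    kind: str = "B"

    def __post_init__(self) -> None:
        df = self.intervals[["chrom", "start", "end", "value"]].copy()
        df["value"] = df["value"].astype(np.float64)
        vals = df["value"].to_numpy()
        if self.kind == "B" and (np.any(vals < 0) or np.any(vals > 1)):
            raise GenomeIOError("B value outside [0, 1]")
        self.intervals = _validate_intervals(df, f"{self.kind} track")

    def value_at(self, chrom, pos) -> np.ndarray:
        """Track value at 1-based positions (NaN where uncovered)."""
        out = np.full(len(pos), np.nan)
        chrom = np.asarray(chrom)
        pos = np.asarray(pos, dtype=np.int64)
        for c in np.unique(chrom):
            sub = self.intervals[self.intervals["chrom"] == c]
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            vals = sub["value"].to_numpy()
            mask = chrom == c
            p0 = pos[mask] - 1
            idx = np.searchsorted(starts, p0, side="right") - 1
            ok = (idx >= 0) & (p0 < ends[np.maximum(idx, 0)])
            res = np.full(mask.sum(), np.nan)
            res[ok] = vals[idx[ok]]
            out[mask] = res
        return out


def write_bmap(track: BMapTrack, path, scale: int | None = 1000) -> None:
    """Write a track as BED-like TSV.

    With ``scale`` (default 1000), B values are written as the integer
    ``round(B * scale)`` (McVicker-style); with ``scale=None`` values are
    written as floats with 6 decimals.
    """
    vals = track.intervals["value"].to_numpy(dtype=np.float64)
    if track.kind == "B" and (np.any(vals < 0) or np.any(vals > 1)):
        raise GenomeIOError("B value outside [0, 1]")
    with open(path, "w") as fh:
        fh.write(f"#kind={track.kind} scale={scale if scale is not None else 'none'}\n")
        fh.write("chrom\tstart\tend\tvalue\n")
        for row in track.intervals.itertuples(index=False):
            if scale is not None:
                v = f"{int(round(row.value * scale))}"
            else:
                v = f"{row.value:.6f}"
            fh.write(f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{v}\n")


def read_bmap(path) -> BMapTrack:
    kind, scale = "B", 1000
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        fields = dict(
            kv.split("=", 1) for kv in first[1:].strip().split() if "=" in kv
        )
        kind = fields.get("kind", "B")
        s = fields.get("scale", "1000")
        scale = None if s == "none" else int(s)
    df = _read_table(path, ["chrom", "start", "end", "value"], [str, np.int64, np.int64, float])
    if scale is not None:
        df["value"] = df["value"] / scale
    return BMapTrack(intervals=df, kind=kind)
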