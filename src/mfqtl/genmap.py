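"""Genetic maps, the 1-cM interval grid, and Kosambi map-distance math.

A :class:`GeneticMap` holds ordered marker positions in centimorgans (and
optionally megabases) per chromosome.  The whole-genome scan operates on an
:class:`IntervalGrid` that tiles each chromosome into equal intervals
(1 cM by default, the last interval of a chromosome may be shorter).

All recombination-fraction <-> distance conversions use the Kosambi mapping
function, d = 0.25 * ln((1 + 2r) / (1 - 2r)) Morgans, whose inverse is
r = 0.5 * tanh(2d).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "kosambi_cM",
    "inverse_kosambi",
    "GeneticMap",
    "IntervalGrid",
    "RfEstimate",
    "estimate_rf_dh",
    "build_joint_map",
]

#: Largest map distance (cM) assigned to a single marker gap when the pooled
#: recombination fraction reaches or exceeds 0.5 (nominally infinite distance).
MAX_GAP_CM = 50.0


def kosambi_cM(r):
    """Map distance in cM for recombination fraction ``r`` (Kosambi).

    ``r`` may be a scalar or array in [0, 0.5); values >= 0.5 raise.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def inverse_kosambi(cm):
    """Recombination fraction for a map distance given in cM (inverse Kosambi)."""
    cm = np.asarray(cm, dtype=float)
    if np.any(cm < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * np.tanh(0.02 * cm)
    return float(r) if r.ndim == 0 else r


@dataclass
class GeneticMap:
    """Ordered marker map.

    ``table`` columns: ``marker``, ``chromosome``, ``cm`` and optionally
    ``mb``.  Markers must be unique and cM non-decreasing within each
    chromosome; chromosome order follows first appearance.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"marker", "chromosome", "cm"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"map table missing columns: {sorted(missing)}")
        dup = t["marker"][t["marker"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate marker ids: {list(dup[:5])}")
        for chrom, sub in t.groupby("chromosome", sort=False):
            cm = sub["cm"].to_numpy(float)
            if np.any(np.diff(cm) < 0):
                row = sub.index[np.argmax(np.diff(cm) < 0) + 1]
                raise ValueError(
                    f"cM positions decrease on chromosome {chrom} at row {row}"
                )
        self.table = t.reset_index(drop=True)

    @property
    def chromosomes(self) -> list:
        return list(pd.unique(self.table["chromosome"]))

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def chrom_length(self, chromosome) -> float:
        sub = self.table[self.table["chromosome"] == chromosome]
        if sub.empty:
            raise KeyError(f"unknown chromosome {chromosome!r}")
        return float(sub["cm"].max())

    @property
    def total_length(self) -> float:
        return float(sum(self.chrom_length(c) for c in self.chromosomes))

    def positions(self, chromosome) -> np.ndarray:
        return self.table.loc[
            self.table["chromosome"] == chromosome, "cm"
        ].to_numpy(float)


@dataclass
class IntervalGrid:
    """Tiling of every chromosome into equal-width intervals.

    Interval index ``l`` is genome-wide, concatenating chromosomes in the
    declared order.  Intervals are half-open ``[start, end)``; the last
    interval of a chromosome may be narrower than ``step``.
    """

    df: pd.DataFrame = field(repr=False)
    step: float = 1.0

    @classmethod
    def from_lengths(
        cls, lengths: Sequence[tuple], step: float = 1.0
    ) -> "IntervalGrid":
        """Build from ``[(chromosome, length_cM), ...]``."""
        if step <= 0:
            raise ValueError("interval step must be positive")
        rows = []
        for chrom, length in lengths:
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length")
            n = int(np.ceil(length / step - 1e-9))
            n = max(n, 1)
            for k in range(n):
                start = k * step
                end = min((k + 1) * step, length)
                rows.append((chrom, start, end, 0.5 * (start + end)))
        df = pd.DataFrame(rows, columns=["chromosome", "start_cm", "end_cm", "midpoint"])
        return cls(df=df, step=step)

    @classmethod
    def from_map(cls, gmap: GeneticMap, step: float = 1.0) -> "IntervalGrid":
        lengths = [(c, gmap.chrom_length(c)) for c in gmap.chromosomes]
        return cls.from_lengths(lengths, step=step)

    @property
    def m(self) -> int:
        return len(self.df)

    @property
    def chromosomes(self) -> list:
        return list(pd.unique(self.df["chromosome"]))

    def chrom_slice(self, chromosome) -> slice:
        idx = np.flatnonzero((self.df["chromosome"] == chromosome).to_numpy())
        if idx.size == 0:
            raise KeyError(f"unknown chromosome {chromosome!r}")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def chrom_of(self) -> np.ndarray:
        return self.df["chromosome"].to_numpy()

    def midpoints(self) -> np.ndarray:
        return self.df["midpoint"].to_numpy(float)

    def interval_of(self, chromosome, cm: float) -> int:
        """Genome-wide index of the interval containing position ``cm``."""
        sl = self.chrom_slice(chromosome)
        sub = self.df.iloc[sl]
        hit = (sub["start_cm"].to_numpy() <= cm) & (cm < sub["end_cm"].to_numpy())
        if not hit.any():
            if cm == float(sub["end_cm"].iloc[-1]):  # chromosome end
                return sl.stop - 1
            raise ValueError(f"position {cm} cM outside chromosome {chromosome!r}")
        return sl.start + int(np.argmax(hit))

    def adjacent_rf(self) -> np.ndarray:
        """Recombination fraction between consecutive interval midpoints.

        Entry ``l`` is the rf between intervals ``l-1`` and ``l``; the first
        interval of each chromosome gets NaN.
        """
        mid = self.midpoints()
        chrom = self.chrom_of()
        rf = np.full(self.m, np.nan)
        same = np.empty(self.m, dtype=bool)
        same[0] = False
        same[1:] = chrom[1:] == chrom[:-1]
        gaps = np.where(same, np.concatenate([[0.0], np.diff(mid)]), np.nan)
        rf[same] = inverse_kosambi(gaps[same])
        return rf


class RfEstimate(NamedTuple):
    rf: float
    n_pairs: int
    unlinked: bool


def estimate_rf_dh(col_a, col_b) -> RfEstimate:
    """Direct-count recombination fraction between two DH marker columns.

    Columns are coded +1/-1 with NaN for missing; the estimate is the share
    of jointly scored lines with opposite codes.  Estimates > 0.5 are
    returned but flagged ``unlinked``.
    """
    a = np.asarray(col_a, dtype=float)
    b = np.asarray(col_b, dtype=float)
    scored = ~np.isnan(a) & ~np.isnan(b)
    n = int(scored.sum())
    if n == 0:
        raise ValueError("no lines jointly scored at both markers")
    rec = int((a[scored] != b[scored]).sum())
    rf = rec / n
    return RfEstimate(rf=rf, n_pairs=n, unlinked=rf > 0.5)


def build_joint_map(genotypes, mb: pd.Series | None = None) -> GeneticMap:
    """Recompute a joint genetic map from physically ordered markers.

    ``genotypes`` is a :class:`mfqtl.simulate.MarkerGenotypes`; its map must
    carry ``mb`` positions (or ``mb`` is passed explicitly, indexed like the
    marker table) that define a total order per chromosome.  For each adjacent
    marker pair the recombination fraction is pooled over families by summing
    recombinant and scored counts across families where both markers are
    scored, then converted to cM with the Kosambi function and accumulated
    from 0 per chromosome.

    Markers scored in no family are dropped with a warning; a pooled rf
    >= 0.5 caps the gap at ``MAX_GAP_CM`` with a warning.
    """
    table = genotypes.gmap.table.copy()
    if mb is not None:
        table = table.assign(mb=np.asarray(mb, dtype=float))
    if "mb" not in table.columns:
        raise ValueError("joint map construction requires physical (mb) positions")

    codes = genotypes.codes  # lines x markers
    fam = np.asarray(genotypes.families)
    fam_labels = list(pd.unique(fam))

    keep = []
    for j in range(table.shape[0]):
        if np.any(~np.isnan(codes[:, j])):
            keep.append(j)
        else:
            warnings.warn(
                f"marker {table['marker'].iloc[j]!r} scored in no line; dropped"
            )
    rows = []
    for chrom in pd.unique(table["chromosome"]):
        idx = [j for j in keep if table["chromosome"].iloc[j] == chrom]
        idx = sorted(idx, key=lambda j: table["mb"].iloc[j])
        cm = 0.0
        for pos, j in enumerate(idx):
            if pos > 0:
                i_prev = idx[pos - 1]
                rec = 0
                tot = 0
                for f in fam_labels:
                    rowsel = fam == f
                    a = codes[rowsel, i_prev]
                    bb = codes[rowsel, j]
                    scored = ~np.isnan(a) & ~np.isnan(bb)
                    if scored.sum() == 0:
                        continue
                    rec += int((a[scored] != bb[scored]).sum())
                    tot += int(scored.sum())
                if tot == 0:
                    warnings.warn(
                        f"no family scores both {table['marker'].iloc[i_prev]!r} "
                        f"and {table['marker'].iloc[j]!r}; zero gap assumed"
                    )
                    gap = 0.0
                else:
                    r = rec / tot
                    if r >= 0.5:
                        warnings.warn(
                            f"pooled rf {r:.3f} >= 0.5 between adjacent markers "
                            f"on {chrom}; gap capped at {MAX_GAP_CM} cM"
                        )
                        gap = MAX_GAP_CM
                    else:
                        gap = kosambi_cM(r)
                cm += gap
            rows.append(
                (
                    table["marker"].iloc[j],
                    chrom,
                    cm,
                    float(table["mb"].iloc[j]),
                )
            )
    out = pd.DataFrame(rows, columns=["marker", "chromosome", "cm", "mb"])
    return GeneticMap(out)
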