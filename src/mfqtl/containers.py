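"""Shared in-memory containers for genotype and phenotype data.

Genotypes are coded by parental origin: +1 for the common-parent allele
(the shared paternal parent of all families), -1 for the alternative
(donor) allele, NaN for missing.  Doubled-haploid lines are fully
homozygous, so a single code per locus suffices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genmap import GeneticMap, IntervalGrid

__all__ = ["MarkerGenotypes", "IntervalGenotypes"]


@dataclass
class MarkerGenotypes:
    """Observed marker genotypes for a set of DH lines.

    ``codes`` is lines x markers (float, +1/-1/NaN), rows aligned with
    ``line_ids``/``families`` and columns with ``gmap.table`` rows.
    """

    gmap: GeneticMap
    codes: np.ndarray
    line_ids: list
    families: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        self.families = np.asarray(self.families)
        n, p = self.codes.shape
        if n != len(self.line_ids) or n != len(self.families):
            raise ValueError("codes rows must match line_ids/families")
        if p != self.gmap.n_markers:
            raise ValueError("codes columns must match the marker map")
        valid = np.isnan(self.codes) | (self.codes == 1) | (self.codes == -1)
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise ValueError(
                f"invalid genotype code {self.codes[i, j]!r} for line "
                f"{self.line_ids[i]!r}, marker {self.gmap.table['marker'].iloc[j]!r}"
            )

    @property
    def n_lines(self) -> int:
        return self.codes.shape[0]

    @property
    def family_labels(self) -> list:
        return list(pd.unique(self.families))

    def subset_lines(self, index) -> "MarkerGenotypes":
        index = np.asarray(index)
        return MarkerGenotypes(
            gmap=self.gmap,
            codes=self.codes[index],
            line_ids=[self.line_ids[i] for i in index],
            families=self.families[index],
        )


@dataclass
class IntervalGenotypes:
    """Per-interval genotype expectations on a shared grid.

    ``u`` holds the expected coded genotype in [-1, 1] per line x interval;
    ``hard`` the maximum-probability call in {-1, +1} (0 where a line has no
    marker information on the whole chromosome).
    """

    grid: IntervalGrid
    u: np.ndarray
    hard: np.ndarray
    line_ids: list
    families: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.hard = np.asarray(self.hard)
        self.families = np.asarray(self.families)
        if self.u.shape != self.hard.shape:
            raise ValueError("u and hard must have identical shapes")
        if self.u.shape[1] != self.grid.m:
            raise ValueError("interval count must match the grid")
        if np.any(np.abs(self.u) > 1 + 1e-9):
            raise ValueError("|u| must not exceed 1")

    @property
    def n_lines(self) -> int:
        return self.u.shape[0]

    @property
    def family_labels(self) -> list:
        return list(pd.unique(self.families))

    def subset_lines(self, index) -> "IntervalGenotypes":
        index = np.asarray(index)
        return IntervalGenotypes(
            grid=self.grid,
            u=self.u[index],
            hard=self.hard[index],
            line_ids=[self.line_ids[i] for i in index],
            families=self.families[index],
        )
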