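"""Interval-genotype imputation for DH lines.

Along a DH chromosome the coded genotype is a two-state Markov chain.  For a
locus (interval midpoint) between its nearest scored flanking markers L and R,
with recombination fractions r_L and r_R to the locus, the expected code

    u = (g_L * (1 - 2 r_L) + g_R * (1 - 2 r_R))
        / (1 + g_L * g_R * (1 - 2 r_L) * (1 - 2 r_R))

follows from conditioning the two-step chain on both flanks (no
interference, so r_LR = r_L + r_R - 2 r_L r_R).  Beyond the terminal scored
marker the locus is conditioned on that single marker: u = g * (1 - 2r).
A line with no scored marker on a chromosome gets u = 0 (no information)
there, with a warning.

The hard call is the maximum-probability genotype, sign(u); an exact tie
(discordant equidistant flanks) resolves to the left flank's allele.
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import IntervalGenotypes, MarkerGenotypes
from .genmap import IntervalGrid, inverse_kosambi

__all__ = ["impute_interval_genotypes", "expected_code"]


def expected_code(g_left, r_left, g_right, r_right):
    """Expected coded genotype given both flanking marker codes."""
    tl = np.asarray(g_left) * (1.0 - 2.0 * np.asarray(r_left))
    tr = np.asarray(g_right) * (1.0 - 2.0 * np.asarray(r_right))
    return (tl + tr) / (1.0 + tl * tr)


def impute_interval_genotypes(
    genotypes: MarkerGenotypes, grid: IntervalGrid
) -> IntervalGenotypes:
    """Expected and hard-called genotypes at every grid interval midpoint."""
    gmap = genotypes.gmap
    n = genotypes.n_lines
    m = grid.m
    u = np.zeros((n, m))
    hard = np.zeros((n, m), dtype=np.int8)
    warned = False

    for chrom in grid.chromosomes:
        sl = grid.chrom_slice(chrom)
        mids = grid.midpoints()[sl]
        marker_cols = np.flatnonzero(
            (gmap.table["chromosome"] == chrom).to_numpy()
        )
        marker_pos = gmap.table["cm"].to_numpy(float)[marker_cols]
        for i in range(n):
            codes = genotypes.codes[i, marker_cols]
            scored = ~np.isnan(codes)
            if not scored.any():
                if not warned:
                    warnings.warn(
                        "line(s) with no scored marker on a chromosome; "
                        "their intervals there are set to 0"
                    )
                    warned = True
                continue
            pos = marker_pos[scored]
            g = codes[scored]
            right = np.searchsorted(pos, mids)  # first scored marker >= midpoint
            left = right - 1
            uu = np.empty(len(mids))
            hh = np.empty(len(mids), dtype=np.int8)

            interior = (left >= 0) & (right < len(pos))
            if interior.any():
                gl = g[left[interior]]
                gr = g[right[interior]]
                rl = inverse_kosambi(mids[interior] - pos[left[interior]])
                rr = inverse_kosambi(pos[right[interior]] - mids[interior])
                uu[interior] = expected_code(gl, rl, gr, rr)
                sign = np.sign(uu[interior])
                hh[interior] = np.where(sign == 0, gl, sign).astype(np.int8)

            before = left < 0
            if before.any():
                r = inverse_kosambi(pos[0] - mids[before])
                uu[before] = g[0] * (1.0 - 2.0 * r)
                hh[before] = np.int8(g[0])

            after = right >= len(pos)
            if after.any():
                r = inverse_kosambi(mids[after] - pos[-1])
                uu[after] = g[-1] * (1.0 - 2.0 * r)
                hh[after] = np.int8(g[-1])

            u[i, sl] = uu
            hard[i, sl] = hh

    return IntervalGenotypes(
        grid=grid,
        u=u,
        hard=hard,
        line_ids=list(genotypes.line_ids),
        families=genotypes.families,
    )
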