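"""Ideotype design: QTL regions, pyramided genotypes, and their prediction.

A QTL region is a run of 1-cM intervals whose posterior QTL probability
exceeds a floor (0.01 by default), with isolated sub-floor intervals
absorbed when flanked on both sides by qualifying runs.  An ideotype fixes
the favorable allele in a chosen set of regions and leaves the rest of the
genome free; derivative genotypes are sampled from the no-interference
Markov chain along each chromosome, conditioned exactly on the fixed blocks
via backward-filtering/forward-sampling (a Markov bridge, never rejecting).
Fixed multi-interval regions are treated as single haplotype blocks with no
internal recombination.

Ideotype 1 fixes every region; ideotypes 2..n successively release the
regions of the secondary trait (flour redness a*, where lower is better) in
ascending order of their variance contribution, while primary-trait
(flour-yield) regions stay fixed throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import PosteriorField
from .genmap import IntervalGrid
from .predict import PredictionModel, predict

__all__ = [
    "QtlRegion",
    "IdeotypeSpec",
    "define_regions",
    "regions_from_table",
    "build_ideotypes",
    "generate_genotypes",
    "predict_ideotype_phenotypes",
]

#: trait -> +1 if larger values are favorable, -1 if smaller
DEFAULT_TRAIT_DIRECTIONS = {"FlYd": 1, "Fla": -1}


@dataclass
class QtlRegion:
    chromosome: str
    start_cm: float
    end_cm: float
    interval_indices: np.ndarray = field(repr=False)
    posterior_mass: float = 0.0
    traits: tuple = ()
    favorable: int = 0            # +1 common-parent allele, -1 donor
    contribution: float = 0.0
    name: str = ""
    start_mb: float | None = None
    end_mb: float | None = None


@dataclass
class IdeotypeSpec:
    """Fixed regions (region -> allele) of one ideotype; labels 1..n."""

    label: int
    fixed: list   # list of (QtlRegion, allele in {+1,-1})

    def __post_init__(self):
        spans = sorted(
            (r.chromosome, r.interval_indices[0], r.interval_indices[-1])
            for r, _ in self.fixed
        )
        for a, b in zip(spans, spans[1:]):
            if a[0] == b[0] and b[1] <= a[2]:
                raise ValueError("fixed regions overlap")


def define_regions(
    field_or_p, grid: IntervalGrid | None = None, p_min: float = 0.01,
    gap_max: int = 1,
) -> list[QtlRegion]:
    """Maximal runs of intervals with p > p_min, absorbing short sub-floor
    gaps (length <= gap_max) flanked on both sides by qualifying runs.

    Accepts a :class:`PosteriorField` or a raw probability array plus grid.
    """
    if isinstance(field_or_p, PosteriorField):
        p = field_or_p.p
        grid = field_or_p.grid
    else:
        p = np.asarray(field_or_p, dtype=float)
        if grid is None:
            raise ValueError("a grid is required with a raw probability array")
    regions: list[QtlRegion] = []
    for chrom in grid.chromosomes:
        sl = grid.chrom_slice(chrom)
        mask = p[sl] > p_min
        # absorb sub-floor runs of length <= gap_max flanked by above-floor runs
        absorbed = mask.copy()
        i = 0
        L = len(mask)
        while i < L:
            if not mask[i]:
                j = i
                while j < L and not mask[j]:
                    j += 1
                if i > 0 and j < L and (j - i) <= gap_max:
                    absorbed[i:j] = True
                i = j
            else:
                i += 1
        # extract maximal runs
        i = 0
        while i < L:
            if absorbed[i]:
                j = i
                while j < L and absorbed[j]:
                    j += 1
                idx = np.arange(sl.start + i, sl.start + j)
                sub = grid.df.iloc[idx]
                regions.append(
                    QtlRegion(
                        chromosome=str(chrom),
                        start_cm=float(sub["start_cm"].iloc[0]),
                        end_cm=float(sub["end_cm"].iloc[-1]),
                        interval_indices=idx,
                        posterior_mass=float(p[idx].sum()),
                    )
                )
                i = j
            else:
                i += 1
    return regions


def regions_from_table(
    region_table: pd.DataFrame,
    qtl_table: pd.DataFrame,
    grid: IntervalGrid,
    trait_directions: dict | None = None,
) -> list[QtlRegion]:
    """Build annotated regions from a region span table and a QTL report.

    ``region_table`` needs (chromosome, start_cm, end_cm, qtls) with QTL
    names ';'-separated; ``qtl_table`` maps ``qtl`` names to trait, effect
    (of the common-parent allele) and contribution.  The favorable allele
    follows the first trait (in ``trait_directions`` order) present in the
    region: common-parent allele when effect * direction > 0.
    """
    directions = trait_directions or DEFAULT_TRAIT_DIRECTIONS
    lookup = qtl_table.set_index("qtl")
    out = []
    for _, row in region_table.iterrows():
        names = [q.strip() for q in str(row["qtls"]).split(";")]
        traits = tuple(dict.fromkeys(lookup.loc[q, "trait"] for q in names))
        lead = next(t for t in directions if t in traits)
        lead_qtls = [q for q in names if lookup.loc[q, "trait"] == lead]
        eff = float(lookup.loc[lead_qtls[0], "effect"])
        favorable = 1 if eff * directions[lead] > 0 else -1
        # ordering weight: contribution of the region's secondary-trait QTLs
        contrib = float(
            sum(lookup.loc[q, "contribution"] for q in names)
        )
        lo = grid.interval_of(str(row["chromosome"]), float(row["start_cm"]))
        hi = grid.interval_of(
            str(row["chromosome"]),
            min(float(row["end_cm"]),
                float(grid.df.iloc[grid.chrom_slice(str(row["chromosome"])).stop - 1]["end_cm"]) - 1e-9),
        )
        out.append(
            QtlRegion(
                chromosome=str(row["chromosome"]),
                start_cm=float(row["start_cm"]),
                end_cm=float(row["end_cm"]),
                interval_indices=np.arange(lo, hi + 1),
                traits=traits,
                favorable=favorable,
                contribution=contrib,
                name=str(row.get("region", row.get("qtls"))),
                start_mb=float(row["start_mb"]) if "start_mb" in row else None,
                end_mb=float(row["end_mb"]) if "end_mb" in row else None,
            )
        )
    return out


def build_ideotypes(
    regions: list[QtlRegion],
    n_ideotypes: int = 10,
    primary_trait: str = "FlYd",
    release_trait: str = "Fla",
) -> list[IdeotypeSpec]:
    """Ideotype 1 fixes the favorable allele everywhere; ideotypes 2..n
    successively release the release-trait-only regions in ascending
    contribution order (ties broken by chromosome then position).  Regions
    containing a primary-trait QTL stay fixed in every ideotype.
    """
    releasable = [
        r for r in regions
        if release_trait in r.traits and primary_trait not in r.traits
    ]
    if n_ideotypes > 1 + len(releasable):
        raise ValueError(
            f"at most {1 + len(releasable)} ideotypes possible with "
            f"{len(releasable)} releasable region(s)"
        )
    order = sorted(releasable, key=lambda r: (r.contribution, r.chromosome, r.start_cm))
    specs = []
    for k in range(1, n_ideotypes + 1):
        released = {id(r) for r in order[: k - 1]}
        fixed = [(r, r.favorable) for r in regions if id(r) not in released]
        specs.append(IdeotypeSpec(label=k, fixed=fixed))
    return specs


def generate_genotypes(
    ideotype: IdeotypeSpec, grid: IntervalGrid, n: int, seed: int = 0
) -> np.ndarray:
    """Sample n whole-genome interval genotypes honoring the fixed blocks.

    Free stretches follow the DH Markov chain with transition probabilities
    from the grid's adjacent-interval recombination fractions; stretches
    between fixed blocks are sampled as exact Markov bridges, so fixed
    intervals match the ideotype with probability 1 and no sample is ever
    rejected.  Within a fixed region no internal recombination occurs.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    m = grid.m
    rf = grid.adjacent_rf()
    g = np.zeros((n, m), dtype=np.int8)

    blocks_by_chrom: dict = {}
    for region, allele in ideotype.fixed:
        idx = region.interval_indices
        blocks_by_chrom.setdefault(region.chromosome, []).append(
            (int(idx[0]), int(idx[-1]), int(allele))
        )

    for chrom in grid.chromosomes:
        sl = grid.chrom_slice(chrom)
        lo0, hi0 = sl.start, sl.stop
        theta = 1.0 - 2.0 * np.nan_to_num(rf[lo0:hi0], nan=0.0)  # theta[t]: step t-1 -> t
        blocks = sorted(blocks_by_chrom.get(str(chrom), []))
        for (a1, b1, _), (a2, b2, _) in zip(blocks, blocks[1:]):
            if a2 <= b1:
                raise ValueError("fixed regions overlap")

        if not blocks:
            v = rng.choice(np.array([-1, 1], dtype=np.int8), size=n)
            g[:, lo0] = v
            for t in range(lo0 + 1, hi0):
                stay = rng.random(n) < (1.0 + theta[t - lo0]) / 2.0
                v = np.where(stay, v, -v).astype(np.int8)
                g[:, t] = v
            continue

        for lo, hi, allele in blocks:
            g[:, lo: hi + 1] = allele

        # before the first block: backward chain from its left edge
        first_lo = blocks[0][0]
        v = np.full(n, blocks[0][2], dtype=np.int8)
        for t in range(first_lo - 1, lo0 - 1, -1):
            stay = rng.random(n) < (1.0 + theta[t + 1 - lo0]) / 2.0
            v = np.where(stay, v, -v).astype(np.int8)
            g[:, t] = v

        # between consecutive blocks: exact bridge
        for (_, e, ga), (s, _, gb) in zip(blocks, blocks[1:]):
            th = theta[e + 1 - lo0: s + 1 - lo0]  # steps e->e+1 ... s-1->s
            if s == e + 1:
                if ga != gb and th[-1] >= 1.0:
                    raise ValueError(
                        "adjacent fixed blocks with opposite alleles and no "
                        "recombination between them"
                    )
                continue
            if ga != gb and np.prod(th) >= 1.0:
                raise ValueError(
                    "fixed blocks with opposite alleles and zero recombination "
                    "between them are infeasible"
                )
            suffix = np.concatenate([np.cumprod(th[::-1])[::-1], [1.0]])
            v = np.full(n, ga, dtype=np.int8)
            for k, t in enumerate(range(e + 1, s)):
                p_plus = (1.0 + v * th[k]) / 2.0
                f_plus = (1.0 + gb * suffix[k + 1]) / 2.0
                f_minus = (1.0 - gb * suffix[k + 1]) / 2.0
                w_plus = p_plus * f_plus
                w_tot = w_plus + (1.0 - p_plus) * f_minus
                v = np.where(rng.random(n) < w_plus / w_tot, 1, -1).astype(np.int8)
                g[:, t] = v

        # after the last block: forward chain
        last_hi = blocks[-1][1]
        v = np.full(n, blocks[-1][2], dtype=np.int8)
        for t in range(last_hi + 1, hi0):
            stay = rng.random(n) < (1.0 + theta[t - lo0]) / 2.0
            v = np.where(stay, v, -v).astype(np.int8)
            g[:, t] = v

    for region, allele in ideotype.fixed:
        assert np.all(g[:, region.interval_indices] == allele)
    return g


def predict_ideotype_phenotypes(
    genotype_sets, models: dict, reference_label: str = "common_parent"
) -> pd.DataFrame:
    """Predict trait values for generated ideotype derivatives.

    ``genotype_sets`` maps ideotype label -> (n x m) genotype array;
    ``models`` maps trait -> :class:`PredictionModel` on the same grid.  The
    common parent (all +1 genome) is appended as a reference row set.
    Returns a long table (ideotype, genotype, trait, value).
    """
    ms = {model.m for model in models.values()}
    if len(ms) != 1:
        raise ValueError("all prediction models must share one grid")
    m = ms.pop()
    records = []
    for label, g in genotype_sets.items():
        g = np.asarray(g)
        if g.shape[1] != m:
            raise ValueError(f"ideotype {label!r}: genotype grid mismatch")
        for trait, model in models.items():
            vals = predict(model, g, use_family_intercept=False)
            records.extend(
                (label, i, trait, float(v)) for i, v in enumerate(vals)
            )
    ref = np.ones((1, m))
    for trait, model in models.items():
        v = predict(model, ref, use_family_intercept=False)[0]
        records.append((reference_label, 0, trait, float(v)))
    return pd.DataFrame(records, columns=["ideotype", "genotype", "trait", "value"])
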