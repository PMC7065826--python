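"""Synthetic multifamily doubled-haploid data generator.

Emulates the design of a multi-parent soft-wheat QTL study: several DH
families sharing one common (elite) parent, a few hundred markers over 21
chromosomes, biallelic QTLs that may segregate in only some families,
multi-environment phenotypes with cropping-season effects, Gaussian
residual noise, and missing observations.

Each DH line is one meiotic product of the F1, chromosome-doubled: the
genotype along a chromosome is a two-state Markov chain with transition
(recombination) probability given by the inverse Kosambi function of each
marker gap, with no crossover interference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import MarkerGenotypes
from .genmap import GeneticMap, inverse_kosambi

__all__ = [
    "QTLSpec",
    "SimulationConfig",
    "default_wheat_chromosomes",
    "simulate_map",
    "simulate_dh_genotypes",
    "simulate_phenotypes",
    "apply_missingness",
    "simulate_dataset",
]


def default_wheat_chromosomes() -> list[tuple[str, float]]:
    """21 hexaploid-wheat-like chromosomes with joint-map-scale cM lengths."""
    names = [f"{n}{g}" for g in "ABD" for n in range(1, 8)]
    lengths = [
        230, 200, 210, 235, 330, 130, 340,   # A genome
        200, 160, 210, 220, 225, 190, 280,   # B genome
        220, 230, 220, 255, 350, 185, 350,   # D genome
    ]
    return list(zip(names, [float(x) for x in lengths]))


@dataclass(frozen=True)
class QTLSpec:
    """A biallelic QTL: position, effect of the common-parent allele, and a
    per-family segregation flag (1 = the family's cross segregates there)."""

    chromosome: str
    position_cm: float
    effect: float
    segregating: tuple

    def __post_init__(self):
        if not np.isfinite(self.effect):
            raise ValueError("QTL effect must be finite")
        if not all(s in (0, 1) for s in self.segregating):
            raise ValueError("segregating flags must be 0/1")


def _default_qtls() -> list[QTLSpec]:
    # Eight QTLs across genomes, mixed segregation patterns; with the default
    # residual SD of 1.17 this architecture gives h2 ~ 0.6, in the range of
    # the milling/colour traits the generator emulates.
    return [
        QTLSpec("2B", 120.0, 0.80, (1, 1, 1)),
        QTLSpec("3B", 98.0, 0.70, (1, 1, 1)),
        QTLSpec("4D", 66.0, 0.60, (1, 1, 0)),
        QTLSpec("5A", 200.0, -0.50, (0, 1, 1)),
        QTLSpec("6B", 127.0, 0.45, (1, 1, 1)),
        QTLSpec("7A", 145.0, 0.40, (1, 1, 1)),
        QTLSpec("7B", 60.0, 0.35, (0, 1, 0)),
        QTLSpec("7D", 180.0, -0.30, (1, 0, 1)),
    ]


@dataclass
class SimulationConfig:
    """Study-shaped defaults: 3 families x 188 lines, 21 chromosomes,
    ~7 cM marker spacing, four cropping seasons, 5% missing genotypes."""

    n_families: int = 3
    lines_per_family: int = 188
    chromosomes: list = field(default_factory=default_wheat_chromosomes)
    marker_spacing_cm: float = 7.0
    qtls: list = field(default_factory=_default_qtls)
    env_effects: dict = field(
        default_factory=lambda: {"2011": 1.2, "2012": -0.8, "2013": 0.3, "2014": -0.7}
    )
    resid_sd: float = 1.17
    family_means: tuple = (65.0, 67.5, 66.5)
    missing_rate: float = 0.05
    seed: int = 0
    trait: str = "trait"

    def __post_init__(self):
        if self.n_families < 1 or self.lines_per_family < 1:
            raise ValueError("family count and size must be positive")
        if self.marker_spacing_cm <= 0:
            raise ValueError("marker spacing must be positive")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.resid_sd < 0:
            raise ValueError("residual SD must be non-negative")
        if len(self.family_means) < self.n_families:
            raise ValueError("need one family mean per family")
        chrom_names = {c for c, _ in self.chromosomes}
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        for q in self.qtls:
            if q.chromosome not in chrom_names:
                raise ValueError(f"QTL on undeclared chromosome {q.chromosome!r}")
            if len(q.segregating) != self.n_families:
                raise ValueError("QTL segregating flags must match n_families")

    @property
    def family_labels(self) -> list[str]:
        return [f"F{i + 1}" for i in range(self.n_families)]


def simulate_map(config: SimulationConfig) -> GeneticMap:
    """Regularly spaced markers per chromosome, with synthetic Mb positions
    monotone in cM (about 3.5 Mb per cM, wheat-like genome scale)."""
    rows = []
    for chrom, length in config.chromosomes:
        pos = np.arange(0.0, length + 1e-9, config.marker_spacing_cm)
        if pos[-1] < length - 1e-9:
            pos = np.append(pos, length)
        for k, cm in enumerate(pos):
            rows.append((f"{chrom}_m{k:03d}", chrom, float(cm), 3.5 * float(cm)))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chromosome", "cm", "mb"]))


def simulate_dh_genotypes(
    gmap: GeneticMap, n_lines: int, seed=None, rng=None
) -> MarkerGenotypes:
    """Draw complete DH genotypes: per chromosome, the first marker allele is
    Bernoulli(0.5) and each gap recombines independently with probability
    inverse-Kosambi(gap)."""
    if n_lines <= 0:
        raise ValueError("n_lines must be positive")
    if gmap.n_markers < 1:
        raise ValueError("map must contain at least one marker")
    rng = np.random.default_rng(seed) if rng is None else rng
    cols = []
    for chrom in gmap.chromosomes:
        pos = gmap.positions(chrom)
        g0 = rng.choice([-1.0, 1.0], size=n_lines)
        if len(pos) == 1:
            cols.append(g0[:, None])
            continue
        r = inverse_kosambi(np.diff(pos))
        flips = rng.random((n_lines, len(r))) < r
        signs = np.cumprod(1 - 2 * flips.astype(float), axis=1)
        cols.append(np.concatenate([g0[:, None], g0[:, None] * signs], axis=1))
    codes = np.concatenate(cols, axis=1)
    line_ids = [f"L{j:04d}" for j in range(n_lines)]
    fams = np.array(["F1"] * n_lines)
    return MarkerGenotypes(gmap=gmap, codes=codes, line_ids=line_ids, families=fams)


def apply_missingness(
    genotypes: MarkerGenotypes, rate: float, seed=None, rng=None
) -> MarkerGenotypes:
    """Mask genotype cells uniformly at random at the given rate."""
    if not (0 <= rate < 1):
        raise ValueError("missing rate must lie in [0, 1)")
    rng = np.random.default_rng(seed) if rng is None else rng
    codes = genotypes.codes.copy()
    codes[rng.random(codes.shape) < rate] = np.nan
    return replace(genotypes, codes=codes)


def _qtl_marker_index(gmap: GeneticMap, qtl: QTLSpec) -> int:
    sub = gmap.table[gmap.table["chromosome"] == qtl.chromosome]
    if sub.empty:
        raise ValueError(f"QTL chromosome {qtl.chromosome!r} absent from map")
    k = int(np.argmin(np.abs(sub["cm"].to_numpy(float) - qtl.position_cm)))
    return int(sub.index[k])


def genetic_values(genotypes: MarkerGenotypes, config: SimulationConfig) -> np.ndarray:
    """True genetic value per line: sum over QTLs of s_il * u_ijl * a_l, with
    each QTL resolved to its nearest marker."""
    fam_index = {f: i for i, f in enumerate(config.family_labels)}
    fidx = np.array([fam_index[f] for f in genotypes.families])
    gv = np.zeros(genotypes.n_lines)
    for q in config.qtls:
        j = _qtl_marker_index(genotypes.gmap, q)
        s = np.array(q.segregating, dtype=float)[fidx]
        gv += s * genotypes.codes[:, j] * q.effect
    return gv


def simulate_phenotypes(
    genotypes: MarkerGenotypes,
    config: SimulationConfig,
    environments=None,
    seed=None,
    rng=None,
) -> pd.DataFrame:
    """Per-plot phenotypes as a long table (line_id, family, environment,
    trait, value).

    Each plot value is mu_family + genetic value + environment effect +
    N(0, resid_sd^2); missing observations are injected at
    ``config.missing_rate``.  ``genotypes`` should be the complete (pre-
    missingness) matrix so genetic values reflect the truth.
    """
    if environments is None:
        environments = list(config.env_effects)
    unknown = [e for e in environments if e not in config.env_effects]
    if unknown:
        raise ValueError(f"unknown environment labels: {unknown}")
    if np.any(np.isnan(genotypes.codes)):
        raise ValueError("phenotype simulation needs complete genotypes")
    rng = np.random.default_rng(seed) if rng is None else rng
    fam_index = {f: i for i, f in enumerate(config.family_labels)}
    fidx = np.array([fam_index[f] for f in genotypes.families])
    gv = genetic_values(genotypes, config)
    mu = np.array(config.family_means[: config.n_families], dtype=float)[fidx]
    records = []
    for env in environments:
        noise = rng.normal(0.0, config.resid_sd, size=genotypes.n_lines)
        vals = mu + gv + config.env_effects[env] + noise
        miss = rng.random(genotypes.n_lines) < config.missing_rate
        vals = np.where(miss, np.nan, vals)
        for j, line in enumerate(genotypes.line_ids):
            records.append(
                (line, genotypes.families[j], env, config.trait, vals[j])
            )
    return pd.DataFrame(
        records, columns=["line_id", "family", "environment", "trait", "value"]
    )


def simulate_dataset(config: SimulationConfig, environments=None):
    """Full synthetic study: map, multifamily genotypes (with missingness),
    plot phenotypes, and the truth needed by recovery tests.

    Returns ``(observed_genotypes, phenotypes, truth)`` where ``truth`` is a
    dict with the complete genotypes, true genetic values and the map.
    """
    rng = np.random.default_rng(config.seed)
    gmap = simulate_map(config)
    mats = []
    ids: list[str] = []
    fams: list[str] = []
    for i, fam in enumerate(config.family_labels):
        g = simulate_dh_genotypes(gmap, config.lines_per_family, rng=rng)
        mats.append(g.codes)
        ids.extend(f"{fam}_{lid}" for lid in g.line_ids)
        fams.extend([fam] * config.lines_per_family)
    full = MarkerGenotypes(
        gmap=gmap,
        codes=np.concatenate(mats, axis=0),
        line_ids=ids,
        families=np.array(fams),
    )
    phenotypes = simulate_phenotypes(full, config, environments, rng=rng)
    observed = apply_missingness(full, config.missing_rate, rng=rng)
    truth = {
        "genotypes": full,
        "genetic_values": genetic_values(full, config),
        "map": gmap,
        "config": config,
    }
    return observed, phenotypes, truth
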