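"""Variable-dimension Bayesian QTL scan over the interval grid.

The model for the adjusted phenotype of line j in family i is

    y_ij = mu_i + sum_l s_il * u_ijl * a_l + e_ij,   e_ij ~ N(0, sigma_e^2)

with a variable number N of QTLs, each occupying one 1-cM interval of the
genome-wide grid; u_ijl in {-1, +1} is the line's coded genotype in the
QTL's interval, a_l the effect of the common-parent allele and s_il a
binary indicator of whether QTL l segregates in family i.

Posterior inference is by MCMC combining Gibbs updates (family means,
effects, segregation indicators, residual variance) with a reversible-jump
birth/death move over the number of QTLs and Metropolis position moves
(local and genome-wide) — in the style of variable-dimension multiple-QTL
samplers for inbred-line crosses.

Per-interval summaries: p_l is the share of retained samples in which a QTL
occupied interval l; the mean effect and per-family segregation frequencies
are averaged over those occupied samples.  The QTL intensity of a
chromosome is the sum of its p_l, i.e. the expected number of QTLs there;
significance thresholds come from within-family permutation of phenotypes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import IntervalGenotypes
from .genmap import IntervalGrid

__all__ = [
    "Priors",
    "ChainConfig",
    "PosteriorField",
    "QTLReport",
    "run_mcmc",
    "qtl_intensity",
    "threshold_from_maxima",
    "permutation_threshold",
    "PermutationResult",
    "call_qtls",
    "qtl_contribution",
]


@dataclass
class Priors:
    """Weakly informative defaults; all exposed in run configs.

    n_qtl_mean: Poisson mean of the prior on the number of QTLs, truncated
    at n_max.  effect_sd: prior SD of a QTL effect (None = phenotypic SD).
    seg_prior: prior probability that a QTL segregates in a family.  The
    residual variance gets the scale-free prior 1/sigma^2.
    """

    n_qtl_mean: float = 2.0
    n_max: int = 20
    effect_sd: float | None = None
    seg_prior: float = 0.5


@dataclass
class ChainConfig:
    iterations: int = 20000
    burn_in: int = 2000
    thin: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    def shortened(self, factor: float = 0.25) -> "ChainConfig":
        it = max(int(self.iterations * factor), 50)
        return ChainConfig(
            iterations=it,
            burn_in=min(self.burn_in, it // 4),
            thin=self.thin,
            seed=self.seed,
        )


@dataclass
class PosteriorField:
    """Per-interval posterior summaries of the scan."""

    grid: IntervalGrid
    p: np.ndarray                 # P(QTL in interval l)
    effect_mean: np.ndarray       # E[a_l | interval occupied]
    seg_freq: np.ndarray          # families x m, E[s_il | occupied]
    family_labels: list
    family_sizes: np.ndarray
    n_samples: int
    mean_n: float
    mu_mean: np.ndarray
    sigma2_mean: float
    var_y: float
    u_var: np.ndarray             # empirical Var(u_l) over lines

    def intensity(self, chromosome) -> float:
        return float(self.p[self.grid.chrom_slice(chromosome)].sum())

    def intensities(self) -> dict:
        return {c: self.intensity(c) for c in self.grid.chromosomes}


def qtl_intensity(field: PosteriorField, chromosome) -> float:
    """Sum of posterior QTL probabilities over a chromosome's intervals."""
    return field.intensity(chromosome)


def _align_phenotypes(adjusted, ivgen: IntervalGenotypes):
    """Return (y, ivgen) aligned; accepts an array or an adjusted table."""
    if isinstance(adjusted, pd.DataFrame):
        s = adjusted.set_index("line_id")["value"]
        have = [i for i, lid in enumerate(ivgen.line_ids) if lid in s.index]
        if len(have) < ivgen.n_lines:
            ivgen = ivgen.subset_lines(have)
        y = s.loc[ivgen.line_ids].to_numpy(float)
    else:
        y = np.asarray(adjusted, dtype=float)
        if len(y) != ivgen.n_lines:
            raise ValueError("phenotype length does not match genotype lines")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite phenotype value")
    return y, ivgen


def run_mcmc(
    adjusted,
    ivgen: IntervalGenotypes,
    priors: Priors | None = None,
    chain: ChainConfig | None = None,
    fix_s: bool = False,
    use_soft_u: bool = False,
) -> PosteriorField:
    """Fit the multifamily QTL model and return the posterior field.

    ``adjusted`` is an adjusted-phenotype table (line_id, family, value) or
    a plain array aligned with ``ivgen``.  ``fix_s`` pins every segregation
    indicator at 1 (standard Bayesian interval mapping for a single family).
    By default the sampler sees the maximum-probability hard genotype calls;
    ``use_soft_u`` switches to the expectations.
    """
    priors = priors or Priors()
    chain = chain or ChainConfig()
    y, ivgen = _align_phenotypes(adjusted, ivgen)

    fam_labels = ivgen.family_labels
    fam_to_idx = {f: i for i, f in enumerate(fam_labels)}
    fidx = np.array([fam_to_idx[f] for f in ivgen.families])
    F = len(fam_labels)
    fam_rows = [np.flatnonzero(fidx == i) for i in range(F)]

    U = (ivgen.u if use_soft_u else ivgen.hard).astype(float)
    m = ivgen.grid.m
    chrom_codes, _ = pd.factorize(ivgen.grid.chrom_of())
    n = len(y)
    var_y = float(np.var(y))
    sa = priors.effect_sd if priors.effect_sd is not None else math.sqrt(max(var_y, 1e-12))
    sa2 = sa * sa
    lam = priors.n_qtl_mean
    n_max = min(priors.n_max, m)
    pi_s = priors.seg_prior

    rng = np.random.default_rng(chain.seed)

    # state
    mu = np.array([y[rows].mean() for rows in fam_rows])
    sigma2 = max(var_y, 1e-12)
    qtl_iv: list[int] = []
    qtl_a: list[float] = []
    qtl_s: list[np.ndarray] = []
    occ = np.zeros(m, dtype=bool)
    r = y - mu[fidx]

    # accumulators
    occ_count = np.zeros(m)
    eff_sum = np.zeros(m)
    seg_sum = np.zeros((F, m))
    mu_sum = np.zeros(F)
    sig_sum = 0.0
    n_sum = 0.0
    kept = 0

    def x_col(iv, a, s):
        return s[fidx] * U[:, iv] * a

    def p_birth(N):
        if N == 0:
            return 1.0 if n_max > 0 else 0.0
        if N >= n_max:
            return 0.0
        return 0.5

    def p_death(N):
        if N == 0:
            return 0.0
        if N >= n_max:
            return 1.0
        return 0.5

    for it in range(chain.iterations):
        # --- family means (Gibbs, flat prior) ---
        for i in range(F):
            rows = fam_rows[i]
            resid_i = r[rows] + mu[i]
            post_var = sigma2 / len(rows)
            new_mu = rng.normal(resid_i.mean(), math.sqrt(post_var))
            r[rows] += mu[i] - new_mu
            mu[i] = new_mu

        # --- per-QTL updates ---
        for q in range(len(qtl_iv)):
            iv, a, s = qtl_iv[q], qtl_a[q], qtl_s[q]
            # effect (Gibbs)
            x = x_col(iv, 1.0, s)
            r_full = r + x * a
            xx = float(x @ x)
            prec = xx / sigma2 + 1.0 / sa2
            mean = (float(x @ r_full) / sigma2) / prec
            a_new = rng.normal(mean, math.sqrt(1.0 / prec))
            r = r_full - x * a_new
            qtl_a[q] = a = a_new

            # segregation indicators (Gibbs per family)
            if not fix_s:
                for i in range(F):
                    rows = fam_rows[i]
                    ui = U[rows, iv]
                    r0 = r[rows] + s[i] * ui * a  # residual with s_i = 0
                    d1 = r0 - ui * a
                    ll1 = -0.5 * float(d1 @ d1) / sigma2
                    ll0 = -0.5 * float(r0 @ r0) / sigma2
                    z = ll1 - ll0
                    p1 = pi_s / (pi_s + (1 - pi_s) * math.exp(min(-z, 700.0))) \
                        if z > -700 else 0.0
                    s_new = 1 if rng.random() < p1 else 0
                    if s_new != s[i]:
                        r[rows] = r0 - s_new * ui * a
                        s[i] = s_new

        # --- residual variance (Gibbs, prior 1/sigma^2) ---
        ssr = float(r @ r)
        sigma2 = max(ssr / rng.chisquare(n), 1e-12)

        # --- reversible-jump birth/death ---
        N = len(qtl_iv)
        if rng.random() < p_birth(N):
            iv_new = int(rng.integers(m))
            while occ[iv_new]:
                iv_new = int(rng.integers(m))
            a_new = rng.normal(0.0, sa)
            s_new = (
                np.ones(F, dtype=int)
                if fix_s
                else (rng.random(F) < pi_s).astype(int)
            )
            x = x_col(iv_new, a_new, s_new)
            dll = -0.5 * (-2.0 * float(x @ r) + float(x @ x)) / sigma2
            log_acc = dll + math.log(lam / (N + 1)) + math.log(
                p_death(N + 1) / p_birth(N)
            )
            if math.log(rng.random() + 1e-300) < log_acc:
                qtl_iv.append(iv_new)
                qtl_a.append(a_new)
                qtl_s.append(s_new)
                occ[iv_new] = True
                r = r - x
        elif N > 0:
            q = int(rng.integers(N))
            iv, a, s = qtl_iv[q], qtl_a[q], qtl_s[q]
            x = x_col(iv, a, s)
            r_new = r + x
            dll = -0.5 * (float(r_new @ r_new) - float(r @ r)) / sigma2
            log_acc = dll + math.log(N / lam) + math.log(
                p_birth(N - 1) / p_death(N)
            )
            if math.log(rng.random() + 1e-300) < log_acc:
                occ[iv] = False
                del qtl_iv[q], qtl_a[q], qtl_s[q]
                r = r_new

        # --- position moves (Metropolis, symmetric proposals) ---
        for q in range(len(qtl_iv)):
            iv, a, s = qtl_iv[q], qtl_a[q], qtl_s[q]
            if rng.random() < 0.5:  # local move within the chromosome
                delta = int(rng.choice([-2, -1, 1, 2]))
                iv_new = iv + delta
                if (
                    iv_new < 0
                    or iv_new >= m
                    or chrom_codes[iv_new] != chrom_codes[iv]
                    or occ[iv_new]
                ):
                    continue
            else:  # genome-wide move to a random interval
                iv_new = int(rng.integers(m))
                if iv_new == iv or occ[iv_new]:
                    continue
            x_old = x_col(iv, a, s)
            x_new = x_col(iv_new, a, s)
            r_prop = r + x_old - x_new
            dll = -0.5 * (float(r_prop @ r_prop) - float(r @ r)) / sigma2
            if math.log(rng.random() + 1e-300) < dll:
                occ[iv] = False
                occ[iv_new] = True
                qtl_iv[q] = iv_new
                r = r_prop

        # --- record ---
        if it >= chain.burn_in and (it - chain.burn_in) % chain.thin == 0:
            kept += 1
            n_sum += len(qtl_iv)
            mu_sum += mu
            sig_sum += sigma2
            for q in range(len(qtl_iv)):
                iv = qtl_iv[q]
                occ_count[iv] += 1
                eff_sum[iv] += qtl_a[q]
                seg_sum[:, iv] += qtl_s[q]

    with np.errstate(invalid="ignore", divide="ignore"):
        p = occ_count / kept
        eff = np.where(occ_count > 0, eff_sum / np.maximum(occ_count, 1), 0.0)
        seg = np.where(occ_count > 0, seg_sum / np.maximum(occ_count, 1), 0.0)

    return PosteriorField(
        grid=ivgen.grid,
        p=p,
        effect_mean=eff,
        seg_freq=seg,
        family_labels=fam_labels,
        family_sizes=np.array([len(rows) for rows in fam_rows]),
        n_samples=kept,
        mean_n=n_sum / kept,
        mu_mean=mu_sum / kept,
        sigma2_mean=sig_sum / kept,
        var_y=var_y,
        u_var=U.var(axis=0),
    )


def threshold_from_maxima(maxima, level: float = 0.05) -> float:
    """The ceil(level * n)-th highest recorded maximum (5th of 100 at 5%)."""
    maxima = np.sort(np.asarray(maxima, dtype=float))[::-1]
    k = int(math.ceil(level * len(maxima)))
    if k < 1:
        raise ValueError("level * n_perm must be at least 1")
    return float(maxima[k - 1])


@dataclass
class PermutationResult:
    threshold: float
    maxima: np.ndarray
    level: float
    shortened_chain: bool


def permutation_threshold(
    adjusted,
    ivgen: IntervalGenotypes,
    n_perm: int = 100,
    level: float = 0.05,
    priors: Priors | None = None,
    chain: ChainConfig | None = None,
    seed: int = 0,
    shorten: float | None = 0.25,
    fix_s: bool = False,
) -> PermutationResult:
    """Genome-wide QTL-intensity threshold by within-family permutation.

    Each permutation shuffles adjusted phenotypes across lines within each
    family (preserving family means under the no-QTL null), reruns the scan
    and records the maximum chromosome intensity; the threshold is the
    ceil(level*n_perm)-th highest maximum.  ``shorten`` runs permutation
    chains at a fraction of the configured length (flagged in the result);
    pass None for full-length chains.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be at least 20")
    if level * n_perm < 1:
        raise ValueError("level * n_perm must be at least 1")
    chain = chain or ChainConfig()
    y, ivgen = _align_phenotypes(adjusted, ivgen)
    fam = ivgen.families
    rng = np.random.default_rng(seed)
    perm_chain = chain if shorten is None else chain.shortened(shorten)
    maxima = np.empty(n_perm)
    for k in range(n_perm):
        yp = y.copy()
        for f in pd.unique(fam):
            rows = np.flatnonzero(fam == f)
            yp[rows] = yp[rng.permutation(rows)]
        cfg = ChainConfig(
            iterations=perm_chain.iterations,
            burn_in=perm_chain.burn_in,
            thin=perm_chain.thin,
            seed=int(rng.integers(2**31 - 1)),
        )
        fld = run_mcmc(yp, ivgen, priors=priors, chain=cfg, fix_s=fix_s)
        maxima[k] = max(fld.intensities().values())
    return PermutationResult(
        threshold=threshold_from_maxima(maxima, level),
        maxima=maxima,
        level=level,
        shortened_chain=shorten is not None,
    )


@dataclass
class QTLReport:
    """A called QTL: posterior-weighted position/effect over its region."""

    trait: str
    chromosome: str
    position_cm: float
    intensity: float
    contribution: float
    effect: float
    seg_prob: dict
    start_cm: float
    end_cm: float
    interval_indices: np.ndarray = field(repr=False, default=None)

    def as_dict(self) -> dict:
        d = {
            "trait": self.trait,
            "chromosome": self.chromosome,
            "position_cm": round(float(self.position_cm), 6),
            "intensity": round(float(self.intensity), 6),
            "contribution": round(float(self.contribution), 6),
            "effect": round(float(self.effect), 6),
            "start_cm": float(self.start_cm),
            "end_cm": float(self.end_cm),
        }
        for fam, v in self.seg_prob.items():
            d[f"seg_prob_{fam}"] = round(float(v), 6)
        return d


def qtl_contribution(field: PosteriorField, interval_indices) -> float:
    """Fraction of phenotypic variance attributed to a QTL region.

    Defined here as sum over the region of p_l * sbar_l * a_l^2 * Var(u_l)
    divided by the phenotypic variance, where sbar_l is the family-size-
    weighted mean segregation frequency.  (The reported 'contribution' of a
    QTL is this package's explicit definition of variance explained.)
    """
    if field.var_y <= 0:
        raise ValueError("zero phenotypic variance")
    idx = np.asarray(interval_indices)
    w = field.family_sizes / field.family_sizes.sum()
    sbar = (w[:, None] * field.seg_freq[:, idx]).sum(axis=0)
    num = float(
        np.sum(field.p[idx] * sbar * field.effect_mean[idx] ** 2 * field.u_var[idx])
    )
    return num / field.var_y


def _region_report(field: PosteriorField, idx: np.ndarray, trait: str,
                   chromosome) -> QTLReport:
    p = field.p[idx]
    total = float(p.sum())
    mids = field.grid.midpoints()[idx]
    w = p / total if total > 0 else np.full(len(idx), 1.0 / len(idx))
    pos = float(np.sum(w * mids))
    effect = float(np.sum(w * field.effect_mean[idx]))
    seg = {
        fam: float(np.sum(w * field.seg_freq[i, idx]))
        for i, fam in enumerate(field.family_labels)
    }
    sub = field.grid.df.iloc[idx]
    return QTLReport(
        trait=trait,
        chromosome=str(chromosome),
        position_cm=pos,
        intensity=total,
        contribution=qtl_contribution(field, idx),
        effect=effect,
        seg_prob=seg,
        start_cm=float(sub["start_cm"].iloc[0]),
        end_cm=float(sub["end_cm"].iloc[-1]),
        interval_indices=idx,
    )


def call_qtls(field: PosteriorField, threshold: float, trait: str = "trait"
              ) -> list[QTLReport]:
    """Declare QTLs per chromosome against an intensity threshold.

    A chromosome is significant when its intensity exceeds the threshold;
    above twice the threshold two QTLs are assumed, split at the interior
    interval with minimal p such that both sides' summed probabilities still
    exceed the threshold (single QTL with a warning if no such boundary
    exists).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    reports: list[QTLReport] = []
    for chrom in field.grid.chromosomes:
        sl = field.grid.chrom_slice(chrom)
        idx = np.arange(sl.start, sl.stop)
        p = field.p[idx]
        total = float(p.sum())
        if total <= threshold:
            continue
        if total > 2 * threshold and len(idx) >= 3:
            left = np.cumsum(p) - p       # sum strictly before each interval
            right = total - np.cumsum(p)  # sum strictly after each interval
            ok = (left > threshold) & (right > threshold)
            ok[0] = ok[-1] = False
            if ok.any():
                cand = np.flatnonzero(ok)
                b = cand[np.argmin(p[cand])]
                reports.append(_region_report(field, idx[:b], trait, chrom))
                reports.append(_region_report(field, idx[b + 1:], trait, chrom))
                continue
            warnings.warn(
                f"chromosome {chrom}: intensity {total:.3f} > 2x threshold but "
                "no valid split boundary; reporting a single QTL"
            )
        reports.append(_region_report(field, idx, trait, chrom))
    return reports
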