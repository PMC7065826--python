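"""Phenotype preparation: season adjustment, kinship, heritability,
trait correlations.

The QTL scan operates on one adjusted value per line and trait, obtained by
fitting an additive two-way least-squares model (line + environment, no
interaction) jointly over all lines, subtracting the sum-to-zero
environment (cropping-season) effects, and averaging the corrected plot
values per line.

Marker-based heritability uses the single-component mixed model
y = Xb + Zg + e with g ~ N(0, va*K) over a realized kinship K, solved by
REML via eigendecomposition, with a profile-likelihood 95% interval for
h2 = va / (va + ve).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats
from scipy.sparse.linalg import lsqr

from .containers import MarkerGenotypes

__all__ = [
    "adjust_for_environment",
    "realized_kinship",
    "HeritabilityEstimate",
    "marker_heritability",
    "CorrelationResult",
    "trait_correlations",
]


def adjust_for_environment(plots: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Season-corrected, replicate-averaged values, one row per line.

    ``plots`` is a long table (line_id, family, environment, trait, value).
    Environment effects are estimated jointly across all lines by least
    squares under a sum-to-zero constraint; lines without any finite
    observation are excluded with a warning.
    """
    df = plots[plots["trait"] == trait]
    if df.empty:
        raise ValueError(f"trait {trait!r} absent from the plot table")
    df = df[np.isfinite(df["value"].to_numpy(float))]
    if df.empty:
        raise ValueError(f"trait {trait!r} has no finite observations")
    dropped = set(plots.loc[plots["trait"] == trait, "line_id"]) - set(df["line_id"])
    if dropped:
        warnings.warn(f"{len(dropped)} line(s) with no observation excluded")

    lines = pd.unique(df["line_id"])
    envs = pd.unique(df["environment"])
    li = pd.Series(np.arange(len(lines)), index=lines)
    ei = pd.Series(np.arange(len(envs)), index=envs)
    n_obs = len(df)
    rows = np.arange(n_obs)
    line_idx = li[df["line_id"]].to_numpy()
    env_idx = ei[df["environment"]].to_numpy()
    y = df["value"].to_numpy(float)

    if len(envs) == 1:
        env_eff = np.zeros(1)
    else:
        # design: [line one-hot | env one-hot]; min-norm LS, then re-centre
        # the environment effects to sum to zero
        data = np.ones(2 * n_obs)
        ij_rows = np.concatenate([rows, rows])
        ij_cols = np.concatenate([line_idx, len(lines) + env_idx])
        A = sparse.csr_matrix(
            (data, (ij_rows, ij_cols)), shape=(n_obs, len(lines) + len(envs))
        )
        sol = lsqr(A, y, atol=1e-12, btol=1e-12, iter_lim=10000)[0]
        env_eff = sol[len(lines):]
        env_eff = env_eff - env_eff.mean()

    corrected = y - env_eff[env_idx]
    out = (
        df.assign(_corr=corrected)
        .groupby(["line_id", "family"], sort=False)["_corr"]
        .mean()
        .reset_index()
        .rename(columns={"_corr": "value"})
    )
    out.insert(2, "trait", trait)
    return out


def realized_kinship(genotypes: MarkerGenotypes) -> pd.DataFrame:
    """K = W W' / m over markers coded +/-1, missing mean-imputed per marker.

    All-missing markers are dropped with a warning.  Diagonal is ~1 for
    fully genotyped inbred lines.
    """
    if genotypes.n_lines < 2:
        raise ValueError("kinship needs at least two lines")
    W = genotypes.codes.copy()
    all_missing = np.isnan(W).all(axis=0)
    if all_missing.any():
        warnings.warn(f"{int(all_missing.sum())} all-missing marker(s) dropped")
        W = W[:, ~all_missing]
    if W.shape[1] == 0:
        raise ValueError("no scored markers")
    col_mean = np.nanmean(W, axis=0)
    nan_at = np.isnan(W)
    W[nan_at] = np.take(col_mean, np.nonzero(nan_at)[1])
    K = W @ W.T / W.shape[1]
    return pd.DataFrame(K, index=genotypes.line_ids, columns=genotypes.line_ids)


@dataclass
class HeritabilityEstimate:
    va: float
    ve: float
    h2: float
    conf_int: tuple

    def __post_init__(self):
        if self.va < 0 or self.ve < 0:
            raise ValueError("variance components must be non-negative")


def _reml_loglik(lam: float, d: np.ndarray, yt: np.ndarray, xt: np.ndarray):
    """Profile REML log-likelihood at variance ratio lam = va/ve.

    Works in the eigenbasis of H = Z K Z': V = lam*D + I is diagonal.
    Returns (loglik, sigma_e2_hat, beta_hat).
    """
    w = 1.0 / (lam * d + 1.0)
    xtwx = float(np.sum(xt * xt * w))
    beta = float(np.sum(xt * yt * w)) / xtwx
    r = yt - xt * beta
    rss = float(np.sum(r * r * w))
    nq = len(yt) - 1
    sigma_e2 = rss / nq
    ll = -0.5 * (
        nq * np.log(2 * np.pi * sigma_e2)
        + float(np.sum(np.log(lam * d + 1.0)))
        + np.log(xtwx)
        + nq
    )
    return ll, sigma_e2, beta


def marker_heritability(values: pd.DataFrame, kinship: pd.DataFrame,
                        psd_tol: float = 1e-6) -> HeritabilityEstimate:
    """REML heritability from per-line (optionally replicated) values.

    ``values`` needs columns ``line_id`` and ``value``; repeated rows per
    line act as replicates sharing the line's genetic effect.  ``kinship``
    must be positive semi-definite (within ``psd_tol`` of its largest
    eigenvalue) and indexed by line id.
    """
    df = values[np.isfinite(values["value"].to_numpy(float))]
    lines = [l for l in kinship.index if l in set(df["line_id"])]
    if len(lines) < 3:
        raise ValueError("heritability estimation needs at least 3 lines")
    df = df[df["line_id"].isin(lines)]
    K = kinship.loc[lines, lines].to_numpy(float)
    K = 0.5 * (K + K.T)
    eigvals = np.linalg.eigvalsh(K)
    if eigvals[0] < -psd_tol * max(1.0, eigvals[-1]):
        raise ValueError("kinship matrix is not positive semi-definite")

    li = pd.Series(np.arange(len(lines)), index=lines)
    idx = li[df["line_id"]].to_numpy()
    y = df["value"].to_numpy(float)
    n = len(y)
    # H = Z K Z' in one step; small studies only (n_obs a few thousand)
    H = K[np.ix_(idx, idx)]
    d, U = np.linalg.eigh(H)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def neg_ll(log_lam):
        return -_reml_loglik(np.exp(log_lam), d, yt, xt)[0]

    res = optimize.minimize_scalar(neg_ll, bounds=(-12.0, 12.0), method="bounded")
    lam = float(np.exp(res.x))
    ll_max, ve, _ = _reml_loglik(lam, d, yt, xt)
    va = lam * ve
    h2 = va / (va + ve)

    # profile-likelihood 95% interval on h2 (invert the LR statistic)
    crit = stats.chi2.ppf(0.95, df=1) / 2.0

    def deficit(h):
        h = min(max(h, 1e-12), 1 - 1e-12)
        ll = _reml_loglik(h / (1 - h), d, yt, xt)[0]
        return (ll_max - ll) - crit

    lo, hi = 0.0, 1.0
    if deficit(1e-12) > 0:
        lo = optimize.brentq(deficit, 1e-12, h2)
    if deficit(1 - 1e-12) > 0:
        hi = optimize.brentq(deficit, h2, 1 - 1e-12)
    return HeritabilityEstimate(va=va, ve=ve, h2=h2, conf_int=(float(lo), float(hi)))


@dataclass
class CorrelationResult:
    """Pairwise Pearson correlations with raw and Holm-adjusted p-values."""

    r: pd.DataFrame
    p: pd.DataFrame
    p_holm: pd.DataFrame
    n: pd.DataFrame

    def significant(self, alpha: float = 0.05, adjusted: bool = False) -> pd.DataFrame:
        p = self.p_holm if adjusted else self.p
        return p < alpha


def trait_correlations(adjusted: pd.DataFrame, traits=None, families="all") -> CorrelationResult:
    """Pearson correlations between traits on pairwise-complete lines.

    ``adjusted`` is long (line_id, family, trait, value).  ``families`` is
    ``"all"`` or a list restricting to those families.  Constant traits give
    NaN correlations with a warning.
    """
    df = adjusted
    if families != "all":
        df = df[df["family"].isin(families)]
    wide = df.pivot_table(index="line_id", columns="trait", values="value",
                          aggfunc="mean")
    if traits is None:
        traits = list(wide.columns)
    t = len(traits)
    r = np.full((t, t), np.nan)
    p = np.full((t, t), np.nan)
    n = np.zeros((t, t), dtype=int)
    for a in range(t):
        for b in range(a, t):
            xa = wide[traits[a]]
            xb = wide[traits[b]]
            ok = xa.notna() & xb.notna()
            n[a, b] = n[b, a] = int(ok.sum())
            if n[a, b] < 3:
                raise ValueError(
                    f"fewer than 3 complete pairs for {traits[a]!r}/{traits[b]!r}"
                )
            if a == b:
                r[a, a], p[a, a] = 1.0, 0.0
                continue
            x, yv = xa[ok].to_numpy(), xb[ok].to_numpy()
            if np.std(x) == 0 or np.std(yv) == 0:
                warnings.warn(
                    f"constant trait in pair {traits[a]!r}/{traits[b]!r}; r undefined"
                )
                continue
            rr, pp = stats.pearsonr(x, yv)
            r[a, b] = r[b, a] = rr
            p[a, b] = p[b, a] = pp

    iu = np.triu_indices(t, k=1)
    raw = p[iu]
    order = np.argsort(raw)
    adj = np.full_like(raw, np.nan)
    running = 0.0
    mtot = np.sum(~np.isnan(raw))
    rank = 0
    for k in order:
        if np.isnan(raw[k]):
            continue
        running = max(running, (mtot - rank) * raw[k])
        adj[k] = min(running, 1.0)
        rank += 1
    ph = np.full((t, t), np.nan)
    ph[iu] = adj
    ph.T[iu] = adj
    np.fill_diagonal(ph, 0.0)

    mk = lambda a: pd.DataFrame(a, index=traits, columns=traits)
    return CorrelationResult(r=mk(r), p=mk(p), p_holm=mk(ph), n=mk(n))
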