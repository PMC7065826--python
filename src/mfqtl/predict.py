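"""Posterior-weighted genomic prediction and cross-validation.

A trained scan yields, per 1-cM interval, the posterior probability p_l of
a QTL and its conditional mean effect a_l.  A new line with expected
interval genotypes u_l is predicted as

    y_hat = mu_hat + sum_l p_l * u_l * a_l

i.e. each interval contributes its posterior-mean allelic effect.  The
intercept is the line's family mean when the family is known (families from
the same crosses differ in mean), the grand mean otherwise.  Predictive
ability is assessed by k-fold cross-validation with the scan refit on every
training split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import ChainConfig, PosteriorField, Priors, run_mcmc
from .containers import IntervalGenotypes

__all__ = ["PredictionModel", "predict", "CVResult", "crossvalidate", "cv_partition"]


@dataclass
class PredictionModel:
    """Per-interval (p_l, a_l) weights plus intercepts from a trained scan."""

    m: int
    weights: np.ndarray           # p_l * a_l, length m
    mu_grand: float
    mu_by_family: dict

    @classmethod
    def from_field(cls, field: PosteriorField) -> "PredictionModel":
        mu_by_family = {
            fam: float(mu) for fam, mu in zip(field.family_labels, field.mu_mean)
        }
        w = field.family_sizes / field.family_sizes.sum()
        return cls(
            m=field.grid.m,
            weights=field.p * field.effect_mean,
            mu_grand=float(np.sum(w * field.mu_mean)),
            mu_by_family=mu_by_family,
        )


def predict(
    model: PredictionModel,
    genotypes,
    families=None,
    use_family_intercept: bool = True,
) -> np.ndarray:
    """Predicted trait values for lines on the model's interval grid.

    ``genotypes`` is an :class:`IntervalGenotypes` (its expected ``u`` is
    used) or a plain lines x m array of interval codes.
    """
    if isinstance(genotypes, IntervalGenotypes):
        u = genotypes.u
        if families is None:
            families = genotypes.families
    else:
        u = np.asarray(genotypes, dtype=float)
    if u.ndim == 1:
        u = u[None, :]
    if u.shape[1] != model.m:
        raise ValueError(
            f"genotypes have {u.shape[1]} intervals, model expects {model.m}"
        )
    if use_family_intercept and families is not None:
        mu = np.array(
            [model.mu_by_family.get(f, model.mu_grand) for f in families]
        )
    else:
        mu = model.mu_grand
    return mu + u @ model.weights


def cv_partition(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seed-reproducible near-equal partition of ``range(n)`` into k folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(order, k)]


@dataclass
class CVResult:
    fold_r: np.ndarray
    mean_r: float
    sd_r: float
    folds: list
    predictions: np.ndarray
    observed: np.ndarray

    def as_frame(self, trait: str = "trait") -> pd.DataFrame:
        cols = {f"cv{i + 1}": [r] for i, r in enumerate(self.fold_r)}
        cols["mean"] = [self.mean_r]
        cols["sd"] = [self.sd_r]
        return pd.DataFrame(cols, index=[trait])


def crossvalidate(
    adjusted,
    ivgen: IntervalGenotypes,
    k: int = 6,
    seed: int = 0,
    priors: Priors | None = None,
    chain: ChainConfig | None = None,
    fix_s: bool = False,
) -> CVResult:
    """k-fold cross-validated prediction accuracy.

    For each fold the Bayesian scan is refit on the remaining lines and the
    held-out lines are predicted from their expected interval genotypes;
    reported per fold is the Pearson correlation between predicted and
    adjusted observed values.
    """
    from .bayes import _align_phenotypes

    y, ivgen = _align_phenotypes(adjusted, ivgen)
    n = len(y)
    folds = cv_partition(n, k, seed)
    if min(len(f) for f in folds) < 3:
        raise ValueError("every fold needs at least 3 lines")
    chain = chain or ChainConfig()
    fold_r = np.empty(k)
    preds = np.empty(n)
    for i, fold in enumerate(folds):
        train = np.setdiff1d(np.arange(n), fold)
        cfg = ChainConfig(
            iterations=chain.iterations,
            burn_in=chain.burn_in,
            thin=chain.thin,
            seed=chain.seed + 1000 * (i + 1),
        )
        fld = run_mcmc(
            y[train], ivgen.subset_lines(train), priors=priors, chain=cfg,
            fix_s=fix_s,
        )
        model = PredictionModel.from_field(fld)
        yhat = predict(model, ivgen.subset_lines(fold))
        preds[fold] = yhat
        fold_r[i] = stats.pearsonr(yhat, y[fold])[0]
    return CVResult(
        fold_r=fold_r,
        mean_r=float(fold_r.mean()),
        sd_r=float(fold_r.std(ddof=1)),
        folds=folds,
        predictions=preds,
        observed=y,
    )
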