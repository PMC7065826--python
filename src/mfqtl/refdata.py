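"""Bundled reference QTL tables and report summaries.

The package ships the published flour-yield (FlYd) and flour-redness (Fla)
QTL tables from the three-family Kitahonami DH study it models — the
single-population and multifamily QTL lists and the 21 fixed-candidate
regions behind the ten ideotypes — as small TSVs.  They drive the examples,
the ideotype machinery, and the report-summary utilities below, which apply
equally to reports produced by this package's own scan.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_single_population_qtls",
    "load_multifamily_qtls",
    "load_ideotype_regions",
    "mean_intensity",
    "cumulative_contribution",
    "summarize_reports",
]


def _load(name: str) -> pd.DataFrame:
    with resources.files("mfqtl.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chromosome": str})


def load_single_population_qtls() -> pd.DataFrame:
    """Per-population FlYd/Fla QTL calls (trait, population, position,
    intensity, contribution, effect of the common-parent allele)."""
    return _load("single_population_qtls.tsv")


def load_multifamily_qtls() -> pd.DataFrame:
    """Joint three-family FlYd/Fla QTL calls with per-family segregation
    probabilities."""
    return _load("multifamily_qtls.tsv")


def load_ideotype_regions() -> pd.DataFrame:
    """The 21 fixed-candidate QTL regions (cM and Mb spans, member QTLs) and
    the published A/B/- fixing pattern of the ten ideotypes."""
    return _load("ideotype_regions.tsv")


def mean_intensity(reports: pd.DataFrame, trait=None, population=None) -> float:
    """Mean QTL intensity over report rows, optionally filtered."""
    df = _filter(reports, trait, population)
    if df.empty:
        raise ValueError("no report rows match the filter")
    return float(df["intensity"].mean())


def cumulative_contribution(reports: pd.DataFrame, trait=None, population=None) -> float:
    """Summed fraction of phenotypic variance over report rows."""
    df = _filter(reports, trait, population)
    if df.empty:
        raise ValueError("no report rows match the filter")
    return float(df["contribution"].sum())


def _filter(reports: pd.DataFrame, trait, population) -> pd.DataFrame:
    df = reports
    if trait is not None:
        df = df[df["trait"] == trait]
    if population is not None:
        df = df[df["population"] == population]
    return df


def summarize_reports(reports: pd.DataFrame) -> pd.DataFrame:
    """Per trait (and population when present): QTL count, mean intensity,
    cumulative contribution."""
    keys = ["trait"] + (["population"] if "population" in reports.columns else [])
    out = (
        reports.groupby(keys, sort=False)
        .agg(
            n_qtls=("intensity", "size"),
            mean_intensity=("intensity", "mean"),
            cumulative_contribution=("contribution", "sum"),
        )
        .reset_index()
    )
    return out
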