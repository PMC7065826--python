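"""Readers and writers for the package's tabular artifacts.

All artifacts are plain CSV/TSV with explicit headers.  Genotype tables use
the field's A/B coding for DH lines from a common paternal parent: ``B`` is
the common-parent allele (+1 internally), ``A`` the donor allele (-1), and
``NA`` missing.  Readers reject malformed cells with the offending
row/column rather than silently coercing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import MarkerGenotypes
from .genmap import GeneticMap

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_map",
    "write_map",
    "read_adjusted",
    "write_adjusted",
    "write_qtl_report",
    "read_qtl_report",
    "write_regions_bed",
    "write_posterior_field",
    "read_posterior_field",
]

_CODE_TO_NUM = {"B": 1.0, "A": -1.0, "NA": np.nan}
_NUM_TO_CODE = {1.0: "B", -1.0: "A"}


def write_genotypes(genotypes: MarkerGenotypes, path) -> None:
    """Markers as rows; line columns carry a second ``family`` header row."""
    gmap = genotypes.gmap.table
    has_mb = "mb" in gmap.columns
    meta_cols = ["marker", "chromosome", "cm"] + (["mb"] if has_mb else [])
    with open(path, "w") as fh:
        fh.write("# mfqtl genotype table; codes B=common-parent allele, "
                 "A=donor allele, NA=missing\n")
        fh.write(",".join(meta_cols + list(map(str, genotypes.line_ids))) + "\n")
        fams = ["family"] + [""] * (len(meta_cols) - 1) + [
            str(f) for f in genotypes.families
        ]
        fh.write(",".join(fams) + "\n")
        for j in range(gmap.shape[0]):
            meta = [str(gmap[c].iloc[j]) for c in meta_cols]
            cells = [
                "NA" if np.isnan(v) else _NUM_TO_CODE[v]
                for v in genotypes.codes[:, j]
            ]
            fh.write(",".join(meta + cells) + "\n")


def read_genotypes(path) -> MarkerGenotypes:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    header = lines[0].split(",")
    meta_cols = [c for c in header if c in ("marker", "chromosome", "cm", "mb")]
    n_meta = len(meta_cols)
    line_ids = header[n_meta:]
    fam_row = lines[1].split(",")
    if fam_row[0] != "family":
        raise ValueError("second header row must declare family membership")
    families = fam_row[n_meta:]
    if len(families) != len(line_ids):
        raise ValueError("family row length does not match line columns")
    meta_rows, codes = [], []
    for k, ln in enumerate(lines[2:], start=3):
        parts = ln.split(",")
        meta_rows.append(parts[:n_meta])
        row = []
        for col, cell in zip(line_ids, parts[n_meta:]):
            if cell not in _CODE_TO_NUM:
                raise ValueError(
                    f"unknown genotype code {cell!r} at file row {k}, line {col!r}"
                )
            row.append(_CODE_TO_NUM[cell])
        codes.append(row)
    gmap = pd.DataFrame(meta_rows, columns=meta_cols)
    gmap["cm"] = gmap["cm"].astype(float)
    if "mb" in gmap.columns:
        gmap["mb"] = gmap["mb"].astype(float)
    return MarkerGenotypes(
        gmap=GeneticMap(gmap),
        codes=np.array(codes, dtype=float).T,
        line_ids=line_ids,
        families=np.array(families),
    )


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"line_id": str, "family": str,
                                  "environment": str, "trait": str})
    required = {"line_id", "family", "environment", "trait", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    bad = df["value"].apply(lambda v: not (pd.isna(v) or np.isfinite(v)))
    if bad.any():
        raise ValueError(f"non-finite phenotype at rows {list(df.index[bad][:5])}")
    return df


def write_map(gmap: GeneticMap, path) -> None:
    gmap.table.to_csv(path, index=False)


def read_map(path) -> GeneticMap:
    return GeneticMap(pd.read_csv(path, dtype={"marker": str, "chromosome": str}))


def write_adjusted(adjusted: pd.DataFrame, path) -> None:
    adjusted.to_csv(path, index=False)


def read_adjusted(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"line_id": str, "family": str, "trait": str})
    required = {"line_id", "family", "trait", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"adjusted table missing columns: {sorted(missing)}")
    return df


def _reports_frame(reports) -> pd.DataFrame:
    if isinstance(reports, pd.DataFrame):
        return reports
    rows = [r.as_dict() if hasattr(r, "as_dict") else dict(r) for r in reports]
    if not rows:
        return pd.DataFrame(
            columns=["trait", "chromosome", "position_cm", "intensity",
                     "contribution", "effect"]
        )
    return pd.DataFrame(rows)


def write_qtl_report(reports, path) -> None:
    """TSV with one row per called QTL.

    Columns: trait, chromosome, position_cm, intensity, per-family
    ``seg_prob_<family>`` columns, contribution, effect, and the region span
    when present.  An empty report writes a header-only file.
    """
    df = _reports_frame(reports)
    front = [c for c in ("trait", "chromosome", "position_cm", "intensity")
             if c in df.columns]
    seg = sorted(c for c in df.columns if c.startswith("seg_prob_"))
    tail = [c for c in ("contribution", "effect", "start_cm", "end_cm",
                        "start_mb", "end_mb") if c in df.columns]
    other = [c for c in df.columns if c not in front + seg + tail]
    df[front + seg + tail + other].to_csv(path, sep="\t", index=False)


def read_qtl_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"trait": str, "chromosome": str})


def write_posterior_field(field, path) -> None:
    """Posterior field TSV: one row per interval, scan metadata in '#' lines."""
    import json

    meta = {
        "families": list(map(str, field.family_labels)),
        "family_sizes": [int(x) for x in field.family_sizes],
        "n_samples": int(field.n_samples),
        "mean_n": float(field.mean_n),
        "mu_mean": [float(x) for x in field.mu_mean],
        "sigma2_mean": float(field.sigma2_mean),
        "var_y": float(field.var_y),
    }
    df = field.grid.df.copy()
    df.insert(0, "interval", np.arange(field.grid.m))
    df["p"] = field.p
    df["effect_mean"] = field.effect_mean
    for i, fam in enumerate(field.family_labels):
        df[f"seg_freq_{fam}"] = field.seg_freq[i]
    df["u_var"] = field.u_var
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_posterior_field(path):
    import json

    from .bayes import PosteriorField
    from .genmap import IntervalGrid

    with open(path) as fh:
        meta = json.loads(fh.readline().lstrip("# "))
        df = pd.read_csv(fh, sep="\t", dtype={"chromosome": str})
    grid = IntervalGrid(
        df=df[["chromosome", "start_cm", "end_cm", "midpoint"]].copy()
    )
    fams = meta["families"]
    return PosteriorField(
        grid=grid,
        p=df["p"].to_numpy(float),
        effect_mean=df["effect_mean"].to_numpy(float),
        seg_freq=np.stack([df[f"seg_freq_{f}"].to_numpy(float) for f in fams]),
        family_labels=fams,
        family_sizes=np.array(meta["family_sizes"]),
        n_samples=meta["n_samples"],
        mean_n=meta["mean_n"],
        mu_mean=np.array(meta["mu_mean"]),
        sigma2_mean=meta["sigma2_mean"],
        var_y=meta["var_y"],
        u_var=df["u_var"].to_numpy(float),
    )


def write_regions_bed(regions, path) -> None:
    """0-based half-open BED on physical coordinates (Mb x 1e6, floored).

    Each region needs ``chromosome``, ``start_mb``, ``end_mb`` and a name
    (``name`` or ``trait``); a region without Mb coordinates is refused.
    """
    df = _reports_frame(regions)
    with open(path, "w") as fh:
        for k, row in df.iterrows():
            start = row.get("start_mb")
            end = row.get("end_mb")
            if start is None or end is None or pd.isna(start) or pd.isna(end):
                raise ValueError(
                    f"region at row {k} lacks Mb coordinates; BED export refused"
                )
            name = row.get("name") or row.get("trait") or f"region{k}"
            fh.write(
                f"{row['chromosome']}\t{int(np.floor(start * 1e6))}\t"
                f"{int(np.floor(end * 1e6))}\t{name}\n"
            )
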