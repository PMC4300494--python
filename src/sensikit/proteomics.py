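"""Differential analysis of triplex-ratio proteome and phosphoproteome tables.

Contrasts: ``1d_vs_ctrl`` (M/L), ``3d_vs_ctrl`` (H/L) by one-sample t-test of
replicate log2 ratios against 0, and ``3d_vs_1d`` by a two-sample t-test of
the H/L replicate group against the M/L group. Regulation calls require raw
p < 0.05 and |fold change| >= 1.5 (i.e. |mean log2 ratio| >= log2 1.5).

Phospho ratios are deliberately not normalized to protein-level changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrich import bh_adjust

CONTRASTS = ("1d_vs_ctrl", "3d_vs_ctrl", "3d_vs_1d")
_RATIO_PREFIX = {"1d_vs_ctrl": "ml", "3d_vs_ctrl": "hl", "3d_vs_1d": "hm"}


@dataclass
class RatioTableDialect:
    """Column conventions of an input ratio table.

    The native dialect stores log2 ratios in columns ``{ml,hl,hm}_log2_<r>``.
    A MaxQuant-proteinGroups-like layout can be described by setting
    ``linear=True`` and a column template such as
    ``"Ratio {channel} normalized {rep}"`` with channels M/L, H/L, H/M.
    """

    id_col: str = "protein_id"
    gene_col: str = "gene"
    linear: bool = False
    column_template: str = "{prefix}_log2_{rep}"
    channel_names: dict[str, str] = field(
        default_factory=lambda: {"ml": "ml", "hl": "hl", "hm": "hm"}
    )
    reverse_prefix: str = "REV__"
    contaminant_prefix: str = "CON__"

    def ratio_columns(self, prefix: str, n_replicates: int) -> list[str]:
        ch = self.channel_names[prefix]
        return [
            self.column_template.format(prefix=ch, channel=ch, rep=r)
            for r in range(1, n_replicates + 1)
        ]


MAXQUANT_LIKE = RatioTableDialect(
    id_col="Protein IDs",
    gene_col="Gene names",
    linear=True,
    column_template="Ratio {channel} normalized {rep}",
    channel_names={"ml": "M/L", "hl": "H/L", "hm": "H/M"},
)


class ProteinRatioTable:
    """Wide per-protein table of replicate log2 ratios for the three channels."""

    def __init__(self, df: pd.DataFrame, n_replicates: int = 3):
        if "protein_id" not in df.columns:
            raise ValueError("table must have a protein_id column")
        self.df = df.reset_index(drop=True)
        self.n_replicates = n_replicates

    def ratios(self, contrast: str) -> pd.DataFrame:
        """Replicate log2 ratios (proteins × replicates) for one contrast."""
        prefix = _RATIO_PREFIX[contrast]
        cols = [f"{prefix}_log2_{r}" for r in range(1, self.n_replicates + 1)]
        return self.df.set_index("protein_id")[cols]


def _infer_n_replicates(columns: Sequence[str], dialect: RatioTableDialect) -> int:
    n = 0
    while dialect.ratio_columns("ml", n + 1)[-1] in columns:
        n += 1
    if n == 0:
        raise ValueError(
            f"no ratio columns matching dialect template {dialect.column_template!r}"
        )
    return n


def load_ratio_table(
    path: str | Path, dialect: RatioTableDialect = RatioTableDialect()
) -> ProteinRatioTable:
    """Load a protein ratio TSV, dropping reverse/contaminant rows and
    converting linear ratios to log2 if the dialect stores linear values."""
    df = pd.read_csv(path, sep="\t")
    for col in (dialect.id_col,):
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r}")
    ids = df[dialect.id_col].astype(str)
    decoy = ids.str.startswith(dialect.reverse_prefix) | ids.str.startswith(
        dialect.contaminant_prefix
    )
    df = df.loc[~decoy].reset_index(drop=True)
    n_rep = _infer_n_replicates(df.columns, dialect)
    out = pd.DataFrame({"protein_id": df[dialect.id_col].astype(str)})
    out["gene"] = (
        df[dialect.gene_col].astype(str) if dialect.gene_col in df.columns else ""
    )
    for prefix in ("ml", "hl", "hm"):
        for r, col in enumerate(dialect.ratio_columns(prefix, n_rep), start=1):
            if col not in df.columns:
                raise ValueError(f"missing mandatory column {col!r}")
            vals = pd.to_numeric(df[col], errors="coerce")
            if dialect.linear:
                vals = np.log2(vals.where(vals > 0))
            out[f"{prefix}_log2_{r}"] = vals
    return ProteinRatioTable(out, n_replicates=n_rep)


def write_ratio_table(table: ProteinRatioTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------


def one_sample_test(values: Sequence[float], min_replicates: int = 3):
    """Two-sided one-sample t-test of log2 ratios against 0.

    Returns ``(n, mean, p, degenerate)`` or None when fewer than
    ``min_replicates`` finite values are present. Zero variance gives p = 1
    when the mean is 0 and p = 0 (degenerate flag) otherwise.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < min_replicates:
        return None
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        return (n, mean, 1.0 if mean == 0.0 else 0.0, True)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return (n, mean, min(p, 1.0), False)


def two_sample_test(
    x: Sequence[float],
    y: Sequence[float],
    min_replicates: int = 3,
    welch: bool = False,
):
    """Two-sided two-sample t-test (equal-variance default, Welch optional).

    Returns ``(n_x + n_y, mean difference, p, degenerate)`` or None when
    either group has fewer than ``min_replicates`` finite values.
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < min_replicates or b.size < min_replicates:
        return None
    diff = float(a.mean() - b.mean())
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        return (a.size + b.size, diff, 1.0 if diff == 0.0 else 0.0, True)
    if welch:
        se2 = va / a.size + vb / b.size
        dof = se2**2 / (
            (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
        )
    else:
        sp2 = ((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2)
        se2 = sp2 * (1.0 / a.size + 1.0 / b.size)
        dof = a.size + b.size - 2
    t = diff / math.sqrt(se2)
    p = 2.0 * float(stats.t.sf(abs(t), df=dof))
    return (a.size + b.size, diff, min(p, 1.0), False)


def differential_analysis(
    table: ProteinRatioTable,
    min_replicates: int = 3,
    welch: bool = False,
    id_col: str = "protein_id",
) -> pd.DataFrame:
    """One row per entity per contrast: n, mean log2 ratio, signed fold change,
    p-value and BH-adjusted p (adjusted within contrast).

    Signed fold change = sign(mean) * 2^|mean|, reported with magnitude >= 1.
    Entities with too few replicates in a contrast are excluded and tallied in
    the ``n_excluded`` attribute of the returned frame (``df.attrs``).
    """
    rows = []
    excluded = {c: 0 for c in CONTRASTS}
    ml = table.ratios("1d_vs_ctrl")
    hl = table.ratios("3d_vs_ctrl")
    for pid in table.df["protein_id"]:
        for contrast in ("1d_vs_ctrl", "3d_vs_ctrl"):
            res = one_sample_test(
                table.ratios(contrast).loc[pid], min_replicates=min_replicates
            )
            if res is None:
                excluded[contrast] += 1
                continue
            n, mean, p, degen = res
            rows.append(
                {
                    "protein_id": pid,
                    "contrast": contrast,
                    "n": n,
                    "mean_log2_ratio": mean,
                    "p_value": p,
                    "degenerate": degen,
                }
            )
        res = two_sample_test(
            hl.loc[pid], ml.loc[pid], min_replicates=min_replicates, welch=welch
        )
        if res is None:
            excluded["3d_vs_1d"] += 1
        else:
            n, mean, p, degen = res
            rows.append(
                {
                    "protein_id": pid,
                    "contrast": "3d_vs_1d",
                    "n": n,
                    "mean_log2_ratio": mean,
                    "p_value": p,
                    "degenerate": degen,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["protein_id", "contrast", "n", "mean_log2_ratio", "p_value", "degenerate"],
    )
    if len(out):
        out["fold_change"] = np.sign(out["mean_log2_ratio"]) * 2.0 ** np.abs(
            out["mean_log2_ratio"]
        )
        out["bh_adjusted_p"] = np.nan
        for contrast in CONTRASTS:
            m = out["contrast"] == contrast
            if m.any():
                out.loc[m, "bh_adjusted_p"] = bh_adjust(out.loc[m, "p_value"].to_numpy())
    out.attrs["n_excluded"] = excluded
    gene_of = dict(zip(table.df["protein_id"], table.df.get("gene", "")))
    if len(out):
        out.insert(1, "gene", out["protein_id"].map(gene_of))
    return out


@dataclass
class RegulationSummary:
    results: pd.DataFrame
    regulated: dict[str, set[str]]  # contrast → regulated protein ids
    union: set[str]


def apply_regulation_filters(
    results: pd.DataFrame, fc_min: float = 1.5, p_max: float = 0.05
) -> RegulationSummary:
    """Flag entities with p < ``p_max`` and |fold change| >= ``fc_min``.

    Equivalent log2 criterion: |mean log2 ratio| >= log2(fc_min), inclusive.
    Returns per-contrast regulated id sets, their unique union, and the
    results table augmented with ``significant`` and volcano columns.
    """
    out = results.copy()
    out["significant"] = (out["p_value"] < p_max) & (
        np.abs(out["mean_log2_ratio"]) >= math.log2(fc_min)
    )
    out["neg_log10_p"] = -np.log10(out["p_value"].clip(lower=1e-300))
    regulated = {
        c: set(out.loc[(out["contrast"] == c) & out["significant"], "protein_id"])
        for c in CONTRASTS
    }
    union = set().union(*regulated.values())
    return RegulationSummary(results=out, regulated=regulated, union=union)


def regulated_directions(summary: RegulationSummary) -> pd.DataFrame:
    """Per-gene regulation direction over the timepoint contrasts (for evidence
    integration): 'up' if any significant positive mean, 'down' if negative."""
    sig = summary.results[
        summary.results["significant"]
        & summary.results["contrast"].isin(["1d_vs_ctrl", "3d_vs_ctrl"])
    ]
    rows = []
    for gene, grp in sig.groupby("gene"):
        mean = grp["mean_log2_ratio"].mean()
        rows.append({"gene": gene, "direction": "up" if mean > 0 else "down"})
    return pd.DataFrame(rows, columns=["gene", "direction"])


# ---------------------------------------------------------------------------
# Phosphosites
# ---------------------------------------------------------------------------


def load_phosphosite_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "position", "residue", "localization_prob"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phosphosite table missing columns: {sorted(missing)}")
    bad = ~df["residue"].isin(["S", "T", "Y"])
    if bad.any():
        raise ValueError(f"invalid residues: {df.loc[bad, 'residue'].unique().tolist()}")
    return df


def filter_phosphosites(
    sites: pd.DataFrame, min_prob: float = 0.75
) -> tuple[pd.DataFrame, float]:
    """Keep sites with localization probability >= ``min_prob`` (inclusive);
    returns the filtered table and the retained fraction."""
    probs = sites["localization_prob"].to_numpy(dtype=float)
    if np.any((probs < 0) | (probs > 1) | ~np.isfinite(probs)):
        raise ValueError("localization probabilities must lie in [0, 1]")
    keep = probs >= min_prob
    retention = float(keep.mean()) if len(sites) else float("nan")
    return sites.loc[keep].reset_index(drop=True), retention


def phosphosite_ratio_table(sites: pd.DataFrame, n_replicates: int = 3) -> ProteinRatioTable:
    """View a (filtered) phosphosite table as a ratio table keyed by site id."""
    df = sites.copy()
    df["protein_id"] = (
        df["protein_id"].astype(str)
        + "_"
        + df["residue"].astype(str)
        + df["position"].astype(str)
    )
    df["gene"] = df.get("gene", df["protein_id"])
    return ProteinRatioTable(df, n_replicates=n_replicates)
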