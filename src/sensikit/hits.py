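"""Two-timepoint filter cascade, dual-screen intersection, gene-level hit
calling and evidence integration.

Selection rule per screen arm: a hairpin is kept iff its day-7 treated/DMSO
fold change is <= ``day7_fc_max`` (inclusive) AND its day-7 raw p-value is
< ``p_max`` AND its day-4 fold change is < ``day4_fc_max`` (strict; hairpins
enriched early are discarded as likely false positives). A gene is a hit iff
at least ``min_hairpins_per_gene`` of its hairpins were selected in BOTH arms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quant import HairpinLibrary


@dataclass
class FilterParams:
    day7_fc_max: float = 0.66
    p_max: float = 0.05
    day4_fc_max: float = 1.0
    min_hairpins_per_gene: int = 2
    allow_missing_day4: bool = False
    use_adjusted_p: bool = False

    def __post_init__(self):
        if not 0 < self.day7_fc_max < 1:
            raise ValueError("day7_fc_max must lie in (0, 1)")
        if not 0 < self.p_max < 1:
            raise ValueError("p_max must lie in (0, 1)")
        if self.min_hairpins_per_gene < 1:
            raise ValueError("min_hairpins_per_gene must be >= 1")


@dataclass
class HairpinHitSet:
    """Selected depleted hairpins for one screen arm."""

    screen: str
    table: pd.DataFrame  # columns: hairpin_id, fold_change, p_value, day4_fold_change

    @property
    def hairpin_ids(self) -> list[str]:
        return self.table["hairpin_id"].tolist()


def select_depleted_hairpins(
    day7: pd.DataFrame,
    day4: pd.DataFrame | None,
    params: FilterParams = FilterParams(),
    screen: str = "",
) -> HairpinHitSet:
    """Apply the three-clause filter to one arm's day-7 and day-4 test tables.

    ``day7``/``day4`` are differential tables with at least ``hairpin_id``,
    ``fold_change`` and (day 7) ``p_value`` columns. Hairpins absent from the
    day-4 table fail the day-4 clause unless ``params.allow_missing_day4``.
    """
    pcol = "bh_adjusted_p" if params.use_adjusted_p else "p_value"
    d7 = day7[["hairpin_id", "fold_change", pcol]].copy()
    d7.columns = ["hairpin_id", "fold_change", "p_value"]
    if day4 is not None:
        only7 = set(d7["hairpin_id"]) - set(day4["hairpin_id"])
        only4 = set(day4["hairpin_id"]) - set(d7["hairpin_id"])
        if only7 or only4:
            warnings.warn(
                f"day-7/day-4 hairpin universes differ "
                f"(day7-only: {sorted(only7)[:5]}…, day4-only: {sorted(only4)[:5]}…)",
                stacklevel=2,
            )
        d4 = day4[["hairpin_id", "fold_change"]].rename(
            columns={"fold_change": "day4_fold_change"}
        )
        d7 = d7.merge(d4, on="hairpin_id", how="left")
    else:
        d7["day4_fold_change"] = np.nan
    keep = (d7["fold_change"] <= params.day7_fc_max) & (d7["p_value"] < params.p_max)
    day4_ok = d7["day4_fold_change"] < params.day4_fc_max
    if params.allow_missing_day4:
        day4_ok |= d7["day4_fold_change"].isna()
    keep &= day4_ok
    out = (
        d7.loc[keep]
        .sort_values("hairpin_id", kind="stable")
        .reset_index(drop=True)
    )
    return HairpinHitSet(screen=screen, table=out)


def intersect_screens(hits_a: HairpinHitSet, hits_b: HairpinHitSet) -> list[str]:
    """Exact hairpin-id intersection of two arms, deterministically sorted."""
    shared = set(hits_a.hairpin_ids) & set(hits_b.hairpin_ids)
    return sorted(shared)


def call_gene_hits(
    hits_a: HairpinHitSet,
    hits_b: HairpinHitSet,
    lib: HairpinLibrary,
    params: FilterParams = FilterParams(),
) -> pd.DataFrame:
    """Genes with >= ``min_hairpins_per_gene`` selected hairpins in BOTH arms.

    Output columns: gene, hairpins/count per arm, evidence_score (2 — one per
    qualifying screen — before proteomic integration). Sorted by the smaller
    of the two counts (descending) then gene name.
    """
    gene_of = lib.gene_of
    for hs in (hits_a, hits_b):
        unknown = [h for h in hs.hairpin_ids if h not in gene_of]
        if unknown:
            raise ValueError(f"hairpins not in library: {unknown}")
    label_a = hs_label(hits_a, "a")
    label_b = hs_label(hits_b, "b")

    def by_gene(hs: HairpinHitSet) -> dict[str, list[str]]:
        d: dict[str, list[str]] = {}
        for h in hs.hairpin_ids:
            d.setdefault(gene_of[h], []).append(h)
        return d

    ga, gb = by_gene(hits_a), by_gene(hits_b)
    rows = []
    for gene in sorted(set(ga) & set(gb)):
        na, nb = len(ga[gene]), len(gb[gene])
        if na >= params.min_hairpins_per_gene and nb >= params.min_hairpins_per_gene:
            rows.append(
                {
                    "gene": gene,
                    f"hairpins_{label_a}": ",".join(sorted(ga[gene])),
                    f"n_{label_a}": na,
                    f"hairpins_{label_b}": ",".join(sorted(gb[gene])),
                    f"n_{label_b}": nb,
                    "evidence_score": 2,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene",
            f"hairpins_{label_a}",
            f"n_{label_a}",
            f"hairpins_{label_b}",
            f"n_{label_b}",
            "evidence_score",
        ],
    )
    if len(out):
        out["_min"] = out[[f"n_{label_a}", f"n_{label_b}"]].min(axis=1)
        out = (
            out.sort_values(["_min", "gene"], ascending=[False, True], kind="stable")
            .drop(columns="_min")
            .reset_index(drop=True)
        )
    return out


def hs_label(hs: HairpinHitSet, fallback: str) -> str:
    return hs.screen if hs.screen else fallback


def integrate_evidence(
    gene_hits: pd.DataFrame,
    regulated: pd.DataFrame,
    regulator_map: pd.DataFrame,
) -> pd.DataFrame:
    """Rank gene hits by combining screen and proteomic evidence.

    ``regulated`` lists significantly regulated proteins with columns
    ``gene`` and ``direction`` ("up"/"down"); ``regulator_map`` has columns
    ``regulator``, ``target`` and ``sign`` ("activates"/"inhibits"). Each map
    row adds +1 to its target's score when the regulator's measured direction
    is consistent with increased target activity or dependence: an inhibitor
    of the target down-regulated, or an activator up-regulated. Malformed map
    rows are skipped with a warning. Output is sorted by score then gene.
    """
    out = gene_hits.copy()
    direction = dict(zip(regulated["gene"].astype(str), regulated["direction"].astype(str)))
    bonus: dict[str, int] = {}
    support: dict[str, list[str]] = {}
    for i, row in regulator_map.iterrows():
        reg, target, sign = row.get("regulator"), row.get("target"), row.get("sign")
        if (
            not isinstance(reg, str)
            or not isinstance(target, str)
            or sign not in ("activates", "inhibits")
        ):
            warnings.warn(f"skipping malformed regulator-map row {i}: {row.to_dict()}")
            continue
        d = direction.get(reg)
        if d is None:
            continue
        if (sign == "inhibits" and d == "down") or (sign == "activates" and d == "up"):
            bonus[target] = bonus.get(target, 0) + 1
            support.setdefault(target, []).append(f"{reg} {d} ({sign})")
    out["evidence_score"] = out.apply(
        lambda r: r["evidence_score"] + bonus.get(r["gene"], 0), axis=1
    )
    out["proteomic_support"] = out["gene"].map(
        lambda g: "; ".join(support.get(g, []))
    )
    return (
        out.sort_values(["evidence_score", "gene"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
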