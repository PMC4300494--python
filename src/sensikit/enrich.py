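"""Hypergeometric over-representation analysis with Benjamini-Hochberg control.

Over-representation only (upper tail); the term map is taken as given — no
ontology parsing or DAG propagation.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    adj_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d array of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def read_term_map(path: str | Path, label_path: str | Path | None = None):
    """Two-column TSV (term_id, gene) → dict term → gene set, plus labels."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term_id", "gene"], dtype=str)
    terms = {t: set(g) for t, g in df.groupby("term_id")["gene"]}
    labels: dict[str, str] = {}
    if label_path is not None:
        ldf = pd.read_csv(
            label_path, sep="\t", header=None, names=["term_id", "label"], dtype=str
        )
        labels = dict(zip(ldf["term_id"], ldf["label"]))
    return terms, labels


def hypergeometric_enrichment(
    target: Iterable[str],
    background: Iterable[str],
    terms: Mapping[str, Iterable[str]],
    labels: Mapping[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of each term against the background.

    For each term: k = |target ∩ term|, K = |background ∩ term|, n = |target|,
    N = |background|, p = P(X >= k) for X ~ Hypergeom(N, K, n). BH adjustment
    runs across all tested terms; rows with adjusted p < ``alpha`` are flagged.
    Target members absent from every term still count in n and N.
    """
    target = set(target)
    background = set(background)
    if not target or not background:
        raise ValueError("target and background must be non-empty")
    stray = target - background
    if stray:
        raise ValueError(f"target genes absent from background: {sorted(stray)[:10]}")
    N, n = len(background), len(target)
    rows = []
    for term_id in sorted(terms):
        ann = set(terms[term_id]) & background
        K = len(ann)
        k = len(ann & target)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term_id,
                "label": (labels or {}).get(term_id, ""),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["bh_adjusted_p"] = bh_adjust(out["p_value"].to_numpy())
        out["significant"] = out["bh_adjusted_p"] < alpha
        out = out.sort_values(["p_value", "term_id"], kind="stable").reset_index(drop=True)
    return out
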