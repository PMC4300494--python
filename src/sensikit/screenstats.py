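"""Count normalization and the conditioned exact negative-binomial depletion test.

The estimators follow the classic count-based differential-analysis recipe:
median-of-ratios size factors, per-hairpin method-of-moments dispersions with a
parametric a0 + a1/mu mean trend, conservative sharing (max of raw and trend),
and a two-group exact test that conditions on the pooled count sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import nbinom, poisson

from .enrich import bh_adjust
from .quant import CountMatrix, HairpinLibrary, SampleSheet

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8
#: log-space slack when comparing outcome probabilities to the observed one
_PMF_TIE_TOL = 1e-7


# ---------------------------------------------------------------------------
# Size factors
# ---------------------------------------------------------------------------


def estimate_size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    s_j = median over hairpins i (restricted to hairpins with nonzero counts
    in every sample) of k_ij / (prod_v k_iv)^(1/m).
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples to estimate size factors")
    arr = counts.to_numpy(dtype=float)
    all_nonzero = (arr > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no hairpin has nonzero counts in all samples; "
            "size factors undefined (consider a pseudo-reference fallback)"
        )
    sub = arr[all_nonzero]
    log_geomean = np.log(sub).mean(axis=1, keepdims=True)
    sf = np.median(np.exp(np.log(sub) - log_geomean), axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    return counts / size_factors.reindex(counts.columns)


# ---------------------------------------------------------------------------
# Dispersion
# ---------------------------------------------------------------------------


@dataclass
class DispersionModel:
    """Raw per-hairpin dispersions, a fitted 1/mu trend, and the final values."""

    raw: pd.Series
    base_mean: pd.Series
    trend_coef: tuple[float, float]  # (a0, a1) in alpha(mu) = a0 + a1/mu
    fitted: pd.Series
    final: pd.Series
    sharing: str = "max"

    def alpha_of_mean(self, mu: float) -> float:
        a0, a1 = self.trend_coef
        return max(a0 + a1 / mu, DISPERSION_FLOOR) if mu > 0 else DISPERSION_FLOOR


def estimate_dispersions(
    counts: pd.DataFrame | CountMatrix,
    size_factors: pd.Series,
    groups: Sequence[Sequence[str]],
    sharing: str = "max",
) -> DispersionModel:
    """Method-of-moments NB dispersions pooled over replicate groups.

    Per hairpin: mu = mean normalized count over all group samples, var = the
    pooled within-group variance (ddof = n - n_groups); raw alpha =
    (var - mu) / mu^2 clamped at the floor. The trend alpha(mu) = a0 + a1/mu is
    least-squares fitted to the raw values; the final dispersion is
    max(raw, trend) (``sharing="max"``) or the trend alone (``"fit-only"``).
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    if sharing not in ("max", "fit-only"):
        raise ValueError("sharing must be 'max' or 'fit-only'")
    groups = [list(g) for g in groups]
    n_per_group = [len(g) for g in groups]
    if max(n_per_group) < 2:
        raise ValueError("dispersion estimation requires replicates in at least one group")
    all_samples = [s for g in groups for s in g]
    q = normalized_counts(counts[all_samples], size_factors)
    mu = q.mean(axis=1)
    ss = pd.Series(0.0, index=counts.index)
    df_resid = len(all_samples) - len(groups)
    for g in groups:
        sub = q[g]
        ss += ((sub.sub(sub.mean(axis=1), axis=0)) ** 2).sum(axis=1)
    var = ss / max(df_resid, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var - mu) / mu**2
    raw = raw.where(mu > 0, DISPERSION_FLOOR).clip(lower=DISPERSION_FLOOR)

    use = mu > 0
    x = np.column_stack([np.ones(use.sum()), 1.0 / mu[use].to_numpy()])
    coef, *_ = np.linalg.lstsq(x, raw[use].to_numpy(), rcond=None)
    a0, a1 = float(coef[0]), float(coef[1])
    with np.errstate(divide="ignore"):
        fitted = pd.Series(a0 + a1 / mu.to_numpy(), index=mu.index).clip(
            lower=DISPERSION_FLOOR
        )
    fitted = fitted.where(mu > 0, DISPERSION_FLOOR)
    final = np.maximum(raw, fitted) if sharing == "max" else fitted
    return DispersionModel(
        raw=raw, base_mean=mu, trend_coef=(a0, a1), fitted=fitted,
        final=pd.Series(final, index=mu.index), sharing=sharing,
    )


# ---------------------------------------------------------------------------
# Exact conditioned test
# ---------------------------------------------------------------------------


def _group_sum_logpmf(x: np.ndarray, mu: float, var: float) -> np.ndarray:
    """log pmf of a group count sum, NB parameterized by mean/variance
    (Poisson when var <= mu)."""
    if var > mu * (1.0 + 1e-12):
        r = mu * mu / (var - mu)
        return nbinom.logpmf(x, r, r / (r + mu))
    return poisson.logpmf(x, mu)


def nbinom_test(
    counts_a: Sequence[float],
    counts_b: Sequence[float],
    sf_a: Sequence[float],
    sf_b: Sequence[float],
    alpha: float,
) -> tuple[float, float]:
    """Two-sided exact NB test conditioned on the pooled count sum.

    Group sums K_A, K_B get NB models implied by the common per-unit mean
    q0 = (K_A + K_B)/(S_A + S_B) and dispersion ``alpha``; the p-value sums
    Pr(a, b) over all splits a + b = K_A + K_B no more probable than the
    observed one, normalized by the total over the condition.

    Returns ``(fold_change, p_value)`` with fold change = mean normalized B /
    mean normalized A (NaN if both groups are all-zero, then p = 1).
    """
    ka = np.asarray(counts_a, dtype=float)
    kb = np.asarray(counts_b, dtype=float)
    sa = np.asarray(sf_a, dtype=float)
    sb = np.asarray(sf_b, dtype=float)
    if not (np.isfinite(alpha) and alpha >= 0):
        raise ValueError("dispersion must be finite and non-negative")
    K_a, K_b = int(round(ka.sum())), int(round(kb.sum()))
    mean_a = float(np.mean(ka / sa))
    mean_b = float(np.mean(kb / sb))
    if K_a + K_b == 0:
        return (np.nan, 1.0)
    fc = np.inf if mean_a == 0 else mean_b / mean_a
    K = K_a + K_b
    S_a, S_b = sa.sum(), sb.sum()
    q0 = K / (S_a + S_b)
    mu_a = q0 * S_a
    mu_b = q0 * S_b
    var_a = mu_a + alpha * q0**2 * np.sum(sa**2)
    var_b = mu_b + alpha * q0**2 * np.sum(sb**2)
    a = np.arange(K + 1)
    logp = _group_sum_logpmf(a, mu_a, var_a) + _group_sum_logpmf(K - a, mu_b, var_b)
    log_total = logsumexp(logp)
    keep = logp <= logp[K_a] + _PMF_TIE_TOL
    p = float(np.exp(logsumexp(logp[keep]) - log_total))
    return (fc, min(p, 1.0))


# ---------------------------------------------------------------------------
# Contrasts and the per-screen differential table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison defined by sample-sheet metadata selectors."""

    name: str
    test: Mapping[str, object]  # e.g. {"condition": "treated", "treatment": "PLX", "day": 7}
    ref: Mapping[str, object]  # e.g. {"condition": "DMSO", "day": 7}


def treated_vs_dmso(arm: str, day: int) -> Contrast:
    return Contrast(
        name=f"{arm}_vs_DMSO_day{day}",
        test={"condition": "treated", "treatment": arm, "day": day},
        ref={"condition": "DMSO", "day": day},
    )


def dmso_vs_reference(day: int) -> Contrast:
    return Contrast(
        name=f"DMSO_day{day}_vs_reference",
        test={"condition": "DMSO", "day": day},
        ref={"condition": "reference"},
    )


def screen_differential(
    cm: CountMatrix,
    contrast: Contrast,
    library: HairpinLibrary | None = None,
    size_factors: pd.Series | None = None,
    sharing: str = "max",
) -> pd.DataFrame:
    """Per-hairpin depletion test for one contrast.

    Size factors default to median-of-ratios over the whole matrix; dispersions
    are estimated from the two contrast groups. Hairpins with zero counts in
    every contrast sample are dropped (and logged), fold change is
    test-group / reference-group normalized means, and BH-adjusted p-values are
    computed across the tested set. Rows are sorted by (p, hairpin_id).
    """
    test_ids = cm.samples.select(**contrast.test)
    ref_ids = cm.samples.select(**contrast.ref)
    if not test_ids or not ref_ids:
        raise ValueError(
            f"contrast {contrast.name!r}: empty group "
            f"(test n={len(test_ids)}, ref n={len(ref_ids)})"
        )
    if size_factors is None:
        size_factors = estimate_size_factors(cm)
    used = cm.counts[ref_ids + test_ids]
    nonzero = used.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info(
            "%s: dropping %d all-zero hairpins from testing", contrast.name, n_dropped
        )
    used = used.loc[nonzero]
    disp = estimate_dispersions(
        used, size_factors, groups=[ref_ids, test_ids], sharing=sharing
    )
    sf_ref = size_factors[ref_ids].to_numpy()
    sf_test = size_factors[test_ids].to_numpy()
    gene_of = library.gene_of if library is not None else {}
    rows = []
    for hid in used.index:
        k_ref = used.loc[hid, ref_ids].to_numpy()
        k_test = used.loc[hid, test_ids].to_numpy()
        fc, p = nbinom_test(k_ref, k_test, sf_ref, sf_test, float(disp.final[hid]))
        rows.append(
            {
                "hairpin_id": hid,
                "gene": gene_of.get(hid, ""),
                "contrast": contrast.name,
                "base_mean": disp.base_mean[hid],
                "mean_ref": np.mean(k_ref / sf_ref),
                "mean_test": np.mean(k_test / sf_test),
                "fold_change": fc,
                "dispersion": disp.final[hid],
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    out["bh_adjusted_p"] = bh_adjust(out["p_value"].to_numpy())
    out = out.sort_values(["p_value", "hairpin_id"], kind="stable").reset_index(drop=True)
    return out
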