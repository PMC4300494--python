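"""Viability normalization and four-parameter logistic (4PL) dose-response
fitting with analytic ICx solving.

ICx is defined on the normalized viability scale: ICx = the concentration at
which viability equals (100 - x)% — e.g. IC20 is the dose giving 80% residual
viability (20% inhibition), not 20% viability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares


class DegenerateFitError(RuntimeError):
    """Raised when the response is too flat for a meaningful 4PL fit."""


def normalize_viability(raw, neg_ctrl_mean: float, pos_ctrl_mean: float):
    """Map raw readings to percent viability: 100 * (raw - pos) / (neg - pos).

    The untreated (negative) control maps to 100%, the killing (positive)
    control to 0%. Values outside [0, 100] are allowed; values outside
    [-20, 120] are flagged. Returns ``(percent, flagged)`` arrays.
    """
    if neg_ctrl_mean == pos_ctrl_mean:
        raise ValueError("negative and positive control means must differ")
    raw = np.asarray(raw, dtype=float)
    pct = 100.0 * (raw - pos_ctrl_mean) / (neg_ctrl_mean - pos_ctrl_mean)
    flagged = (pct < -20.0) | (pct > 120.0)
    return pct, flagged


def four_pl(c, bottom: float, top: float, ic50: float, hill: float):
    """v(c) = bottom + (top - bottom) / (1 + (c/ic50)^hill); decreasing for
    hill > 0."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


@dataclass
class DoseResponseFit:
    bottom: float
    top: float
    ic50: float
    hill: float
    rss: float
    r_squared: float
    #: best-so-far RSS after each multi-start attempt (non-increasing)
    rss_path: list[float] = field(default_factory=list)

    def predict(self, c):
        return four_pl(c, self.bottom, self.top, self.ic50, self.hill)

    def icx(self, x: float) -> float:
        """Concentration giving (100 - x)% viability, from the fitted curve.

        Defined only when that viability lies strictly between the asymptotes.
        """
        target = 100.0 - x
        if not (self.bottom < target < self.top):
            raise ValueError(
                f"IC{x:g} undefined: {target}% viability outside the fitted "
                f"asymptotes ({self.bottom:.3g}, {self.top:.3g})"
            )
        ratio = (self.top - self.bottom) / (target - self.bottom) - 1.0
        return self.ic50 * ratio ** (1.0 / self.hill)


def fit_dose_response(
    concentrations,
    percents,
    min_r_squared: float = 0.2,
) -> DoseResponseFit:
    """Least-squares 4PL fit with a deterministic multi-start grid.

    Requires >= 5 distinct positive concentrations spanning >= 2 log units.
    Starts combine hill in {0.5, 1, 2} with ic50 at the 25/50/75% quantiles of
    the dose range; the best (lowest-RSS) solution wins. A flat response
    (variance explained < ``min_r_squared``) raises
    :class:`DegenerateFitError`.
    """
    conc = np.asarray(concentrations, dtype=float)
    pct = np.asarray(percents, dtype=float)
    ok = np.isfinite(conc) & np.isfinite(pct) & (conc > 0)
    conc, pct = conc[ok], pct[ok]
    distinct = np.unique(conc)
    if distinct.size < 5:
        raise ValueError("need at least 5 distinct positive concentrations")
    span = math.log10(distinct.max() / distinct.min())
    if span < 2.0:
        raise ValueError(f"concentrations span only {span:.2f} log units (< 2)")

    ss_tot = float(np.sum((pct - pct.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateFitError("constant response: nothing to fit")

    lo, hi = pct.min(), pct.max()
    log_c = np.log10(conc)

    def residuals(theta):
        bottom, span_, log_ic50, hill = theta
        return four_pl(conc, bottom, bottom + span_, 10.0**log_ic50, hill) - pct

    bounds = (
        [lo - 100.0, 0.0, log_c.min() - 3.0, 0.05],
        [hi + 100.0, 4 * max(hi - lo, 1.0) + 100.0, log_c.max() + 3.0, 20.0],
    )
    best = None
    rss_path: list[float] = []
    for hill0 in (0.5, 1.0, 2.0):
        for q in (25, 50, 75):
            theta0 = [lo, max(hi - lo, 1.0), np.percentile(log_c, q), hill0]
            theta0 = np.clip(theta0, bounds[0], bounds[1])
            sol = least_squares(residuals, theta0, bounds=bounds, method="trf")
            rss = float(2.0 * sol.cost)
            if best is None or rss < best[0]:
                best = (rss, sol.x)
            rss_path.append(best[0])
    rss, (bottom, span_, log_ic50, hill) = best
    r2 = 1.0 - rss / ss_tot
    if r2 < min_r_squared:
        raise DegenerateFitError(
            f"flat response: 4PL explains only {r2:.3f} of the variance"
        )
    return DoseResponseFit(
        bottom=float(bottom),
        top=float(bottom + span_),
        ic50=float(10.0**log_ic50),
        hill=float(hill),
        rss=rss,
        r_squared=float(r2),
        rss_path=rss_path,
    )
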