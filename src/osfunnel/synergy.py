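"""Median-effect (IC50) fitting, combination index, and Bliss scoring.

The median-effect equation fa/(1-fa) = (D/Dm)^m linearizes to
log(fa/(1-fa)) = m log D - m log Dm, so Dm (the IC50) and the
sigmoidicity m come from least squares on that line; only points with fa
strictly inside (0, 1) inform the fit.  The combination index at effect
level fa is CI = d1/Dx1(fa) + d2/Dx2(fa) with Dx(fa) = Dm (fa/(1-fa))^(1/m)
— CI < 1 synergy, 1 additivity, > 1 antagonism in the Loewe sense, scored
per observed dose pair (non-constant-ratio mode).  Bliss independence
scores efficacy: expected = A + B - A x B, delta = 100 x (observed -
expected) percentage points, classified as Antagonism (< -10), Additive
([-10, 10]), Synergistic ((10, 20]) or Markedly Synergistic (> 20) —
band edges closed on the additive/synergistic side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import DoseResponseMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MedianEffectFit",
    "fit_median_effect",
    "combination_index",
    "bliss_expected",
    "classify_delta",
    "bliss_matrix",
]


@dataclass(frozen=True)
class MedianEffectFit:
    """Median-effect line fit: Dm (IC50), sigmoidicity m, and the
    correlation r of the log-linearized fit."""

    dm: float
    m: float
    r: float
    n_points: int

    def __post_init__(self) -> None:
        if not (self.dm > 0 and self.m > 0):
            raise ValueError("median-effect fit requires Dm > 0 and m > 0")

    def fa(self, dose):
        """Fraction affected at a dose: fa = 1 / (1 + (Dm/D)^m)."""
        dose = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore"):
            out = 1.0 / (1.0 + (self.dm / dose) ** self.m)
        out = np.where(dose == 0, 0.0, out)
        return out if out.ndim else float(out)

    def dx(self, fa):
        """Dose producing effect level fa: Dx = Dm (fa/(1-fa))^(1/m)."""
        fa = np.asarray(fa, dtype=float)
        if ((fa <= 0) | (fa >= 1)).any():
            raise ValueError("effect level must lie strictly inside (0, 1)")
        out = self.dm * (fa / (1.0 - fa)) ** (1.0 / self.m)
        return out if out.ndim else float(out)


def fit_median_effect(doses, fraction_affected) -> MedianEffectFit:
    """Fit the median-effect line by least squares.

    Points with fa exactly 0 or 1 carry no information on the logit scale
    and are excluded (with a logged count); at least 2 usable points with
    positive dose are required.
    """
    doses = np.asarray(doses, dtype=float)
    fa = np.asarray(fraction_affected, dtype=float)
    if doses.shape != fa.shape:
        raise ValueError("doses and fraction_affected must align")
    usable = (doses > 0) & (fa > 0) & (fa < 1)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("fit_median_effect: excluded %d point(s) with fa in {0,1} or dose 0",
                    n_dropped)
    if usable.sum() < 2:
        raise ValueError("need at least 2 points with fa strictly inside (0, 1)")
    x = np.log(doses[usable])
    y = np.log(fa[usable] / (1.0 - fa[usable]))
    if np.ptp(x) == 0:
        raise ValueError("all usable points share one dose; slope undefined")
    m, intercept = np.polyfit(x, y, 1)
    if m <= 0:
        raise ValueError("fitted slope m is not positive; data are not dose-responsive")
    dm = float(np.exp(-intercept / m))
    r = 1.0 if np.ptp(y) == 0 else float(np.corrcoef(x, y)[0, 1])
    return MedianEffectFit(dm=dm, m=float(m), r=r, n_points=int(usable.sum()))


def combination_index(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    d1,
    d2,
    fa,
) -> np.ndarray:
    """Combination index per (dose pair, effect level) observation.

    ``d1``, ``d2`` and ``fa`` broadcast against each other; each entry is
    CI = d1/Dx_a(fa) + d2/Dx_b(fa).  With d2 = 0 this degenerates to
    d1/Dx_a; CI is linear in the dose pair at fixed fa.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    fa_arr = np.asarray(fa, dtype=float)
    if ((fa_arr <= 0) | (fa_arr >= 1)).any():
        raise ValueError("observed fa must lie strictly inside (0, 1)")
    ci = d1 / fit_a.dx(fa_arr) + d2 / fit_b.dx(fa_arr)
    return ci if ci.ndim else float(ci)


def ci_over_effect_grid(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    combo_fit: MedianEffectFit,
    ratio_a: float,
    fa_grid=None,
) -> pd.DataFrame:
    """CI across effect levels for a fixed-ratio combination.

    ``combo_fit`` is the median-effect fit of total combination dose
    against observed effect; ``ratio_a`` the fraction of total dose that is
    drug A.  Reported over fa = 0.20 ... 0.80 by default.
    """
    if fa_grid is None:
        fa_grid = np.round(np.arange(0.20, 0.801, 0.05), 2)
    fa_grid = np.asarray(fa_grid, dtype=float)
    total = combo_fit.dx(fa_grid)
    ci = combination_index(fit_a, fit_b, ratio_a * total, (1 - ratio_a) * total, fa_grid)
    return pd.DataFrame({"fa": fa_grid, "total_dose": total, "ci": ci})


def bliss_expected(a, b):
    """Bliss-independence expected effect of two independent agents."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if ((a < 0) | (a > 1) | (b < 0) | (b > 1)).any():
        raise ValueError("single-agent effects must lie in [0, 1]")
    out = a + b - a * b
    return out if out.ndim else float(out)


_BANDS = (
    (-np.inf, -10.0, "Antagonism"),
    (-10.0, 10.0, "Additive"),
    (10.0, 20.0, "Synergistic"),
    (20.0, np.inf, "Markedly Synergistic"),
)


def classify_delta(delta_pct) -> np.ndarray:
    """Classify observed-minus-expected deltas (percentage points).

    delta < -10 Antagonism; -10 <= delta <= 10 Additive; 10 < delta <= 20
    Synergistic; delta > 20 Markedly Synergistic.  The edges -10 and +10
    belong to Additive and +20 to Synergistic.
    """
    arr = np.asarray(delta_pct, dtype=float)
    out = np.empty(arr.shape, dtype=object)
    out[arr < -10.0] = "Antagonism"
    out[(arr >= -10.0) & (arr <= 10.0)] = "Additive"
    out[(arr > 10.0) & (arr <= 20.0)] = "Synergistic"
    out[arr > 20.0] = "Markedly Synergistic"
    if arr.ndim == 0:
        return out.item()
    return out


def bliss_matrix(matrix: DoseResponseMatrix) -> pd.DataFrame:
    """Score every combination cell of a checkerboard against Bliss.

    The matrix must carry single-agent margins (dose 0 rows/columns).
    Replicates are scored individually, then the per-cell delta is
    averaged with its SEM; the class comes from the mean delta.  Returns
    one row per interior cell: doses, single-agent effects, observed and
    expected means, delta_pct mean and SEM, and the class label.
    """
    if not matrix.has_margins:
        raise ValueError("dose matrix must encode single-agent margins (dose 0)")
    eff = matrix.effects  # (reps, na, nb)
    a_margin = eff[:, 1:, 0]  # per-replicate single-agent effects of A
    b_margin = eff[:, 0, 1:]
    combo = eff[:, 1:, 1:]
    expected = (
        a_margin[:, :, None] + b_margin[:, None, :] - a_margin[:, :, None] * b_margin[:, None, :]
    )
    delta = 100.0 * (combo - expected)
    mean_delta = delta.mean(axis=0)
    nrep = matrix.n_replicates
    sem = delta.std(axis=0, ddof=1) / np.sqrt(nrep) if nrep > 1 else np.zeros_like(mean_delta)

    rows = []
    for i, da in enumerate(matrix.doses_a[1:]):
        for j, db in enumerate(matrix.doses_b[1:]):
            rows.append(
                {
                    "dose_a": da,
                    "dose_b": db,
                    "effect_a": a_margin[:, i].mean(),
                    "effect_b": b_margin[:, j].mean(),
                    "observed": combo[:, i, j].mean(),
                    "expected": expected[:, i, j].mean(),
                    "delta_pct": mean_delta[i, j],
                    "delta_sem": sem[i, j],
                    "class": classify_delta(mean_delta[i, j]),
                }
            )
    return pd.DataFrame(rows)
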