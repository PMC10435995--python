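"""Dose-response pharmacology.

Asymmetric five-parameter logistic (5PL) viability fits with relative IC50,
rescue-shift (IC50 fold-change) computation, relative qPCR expression by
the 2^-dCt method, and Spearman rank correlation of expression versus drug
sensitivity.

The 5PL model on concentration x is

    y(x) = bottom + (top - bottom) / (1 + (x / c_mid)^hill)^asym

and the *relative* IC50 — the dose where the fitted curve crosses midway
between its own asymptotes — has the closed form

    ic50 = c_mid * (2^(1/asym) - 1)^(1/hill).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseFit",
    "five_pl",
    "fit_5pl",
    "rescue_shift",
    "RescueShift",
    "relative_expression",
    "sensitivity_correlation",
]


def five_pl(
    x: np.ndarray,
    bottom: float,
    top: float,
    hill: float,
    c_mid: float,
    asym: float,
) -> np.ndarray:
    """Evaluate the 5PL curve; x = 0 maps to the top asymptote (hill > 0)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(x > 0, x / c_mid, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio**hill) ** asym


def _relative_ic50(c_mid: float, hill: float, asym: float) -> float:
    return c_mid * (2.0 ** (1.0 / asym) - 1.0) ** (1.0 / hill)


@dataclass
class DoseResponseFit:
    """Fitted 5PL parameters and the derived relative IC50."""

    bottom: float
    top: float
    hill: float
    c_mid: float
    asym: float
    ic50_rel: float
    r2: float
    ok: bool = True
    message: str = ""
    cov: np.ndarray | None = field(default=None, repr=False)
    #: parameter order for ``cov``
    param_names: tuple[str, ...] = ("bottom", "top", "hill", "log10_c_mid", "asym")

    def predict(self, doses: np.ndarray) -> np.ndarray:
        return five_pl(doses, self.bottom, self.top, self.hill, self.c_mid, self.asym)


def fit_5pl(
    doses: np.ndarray,
    responses: np.ndarray,
    model: str = "5pl",
    zero_dose_decades: float = 2.0,
) -> DoseResponseFit:
    """Fit a 5PL (or 4PL) curve to a dose-response series.

    Fitting is on log10 dose; a zero-dose anchor is mapped to a floor
    ``zero_dose_decades`` below the lowest nonzero dose. ``model="4pl"``
    pins the asymmetry at 1. Multi-start initialisation over Hill slopes
    {0.5, 1, 2} and midpoints at dose quantiles. Non-convergence yields a
    flagged fit, never an exception; non-monotone mean responses trigger a
    warning only.
    """
    doses = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if doses.size != y.size:
        raise ValueError("doses and responses differ in length")
    if doses.size < 6:
        raise ValueError("need at least 6 dose points (including a low anchor)")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")
    if model not in ("5pl", "4pl"):
        raise ValueError("model must be '5pl' or '4pl'")

    pos = doses[doses > 0]
    if pos.size == 0:
        raise ValueError("all doses are zero")
    floor = pos.min() * 10.0 ** (-zero_dose_decades)
    t = np.log10(np.where(doses > 0, doses, floor))

    # monotonicity advisory on per-dose means
    means = pd.Series(y).groupby(pd.Series(doses)).mean()
    diffs = np.diff(means.to_numpy())
    if diffs.size and not (np.all(diffs <= 0) or np.all(diffs >= 0)):
        warnings.warn("per-dose mean responses are not monotone", stacklevel=2)

    def curve(theta: np.ndarray) -> np.ndarray:
        bottom, top, hill, log_c, asym = theta
        return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (t - log_c))) ** asym

    def resid(theta: np.ndarray) -> np.ndarray:
        return curve(theta) - y

    ymin, ymax = float(y.min()), float(y.max())
    span = max(ymax - ymin, 1e-12)
    lb = [ymin - span, ymin - span, 1e-3, np.log10(floor) - 2, 1e-3]
    ub = [ymax + span, ymax + span, 50.0, np.log10(doses.max()) + 2, 50.0]
    if model == "4pl":
        lb[4] = 1.0 - 1e-12
        ub[4] = 1.0 + 1e-12

    starts = []
    for h0 in (0.5, 1.0, 2.0):
        for q in (0.25, 0.5, 0.75):
            c0 = float(np.quantile(np.log10(pos), q))
            starts.append(np.array([ymin, ymax, h0, c0, 1.0]))

    best = None
    for theta0 in starts:
        theta0 = np.clip(theta0, lb, ub)
        try:
            sol = least_squares(resid, theta0, bounds=(lb, ub), method="trf")
        except Exception:  # pragma: no cover
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None or not np.all(np.isfinite(best.x)):
        return DoseResponseFit(*[np.nan] * 6, r2=np.nan, ok=False,
                               message="no start converged")

    bottom, top, hill, log_c, asym = best.x
    c_mid = float(10.0**log_c)
    ic50 = _relative_ic50(c_mid, hill, asym)
    rss = float(2.0 * best.cost)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan

    cov = None
    dof = max(y.size - (4 if model == "4pl" else 5), 1)
    try:
        cov = (rss / dof) * np.linalg.inv(best.jac.T @ best.jac)
    except np.linalg.LinAlgError:
        pass

    ok = True
    message = ""
    if top - bottom < 0.05 * span or not (floor / 10 <= ic50 <= doses.max() * 10):
        ok = False
        message = (
            "fitted transition is degenerate or the midpoint lies outside the "
            "dose range; IC50 is an extrapolation"
        )
    if top <= bottom:
        ok = False
        message = "fitted top asymptote does not exceed bottom"
    return DoseResponseFit(
        bottom=float(bottom), top=float(top), hill=float(hill), c_mid=c_mid,
        asym=float(asym), ic50_rel=float(ic50), r2=r2, ok=ok, message=message,
        cov=cov,
    )


@dataclass
class RescueShift:
    """Fold-change in IC50 between two fitted curves (rescued / unrescued)."""

    fold: float
    log10_fold_se: float | None
    ok: bool
    message: str = ""


def _log10_ic50_var(fit: DoseResponseFit) -> float | None:
    """Delta-method variance of log10(ic50) from the fit covariance."""
    if fit.cov is None:
        return None
    # ic50 = c_mid * (2^(1/asym)-1)^(1/hill); in log10:
    # log10 ic50 = log10_c_mid + log10(2^(1/asym)-1)/hill
    g = np.zeros(5)
    u = 2.0 ** (1.0 / fit.asym) - 1.0
    g[3] = 1.0  # d/d log10_c_mid
    g[2] = -math.log10(u) / fit.hill**2  # d/d hill
    # d/d asym of log10(u)/hill
    du_dasym = 2.0 ** (1.0 / fit.asym) * math.log(2.0) * (-1.0 / fit.asym**2)
    g[4] = du_dasym / (u * math.log(10.0) * fit.hill)
    return float(g @ fit.cov @ g)


def rescue_shift(
    fit_drug: DoseResponseFit, fit_drug_plus_rescue: DoseResponseFit
) -> RescueShift:
    """IC50 fold-change conferred by a rescue co-treatment.

    Returns ic50(rescued) / ic50(drug alone) with a delta-method standard
    error on the log10 fold where fit covariances are available. Flagged
    input fits propagate a flagged ratio.
    """
    if not (fit_drug.ok and fit_drug_plus_rescue.ok):
        bad = []
        if not fit_drug.ok:
            bad.append(f"drug fit: {fit_drug.message}")
        if not fit_drug_plus_rescue.ok:
            bad.append(f"rescued fit: {fit_drug_plus_rescue.message}")
        fold = fit_drug_plus_rescue.ic50_rel / fit_drug.ic50_rel
        return RescueShift(float(fold), None, ok=False, message="; ".join(bad))
    fold = fit_drug_plus_rescue.ic50_rel / fit_drug.ic50_rel
    va = _log10_ic50_var(fit_drug)
    vb = _log10_ic50_var(fit_drug_plus_rescue)
    se = math.sqrt(va + vb) if va is not None and vb is not None else None
    return RescueShift(float(fold), se, ok=True)


def relative_expression(table: pd.DataFrame) -> pd.DataFrame:
    """Relative qPCR expression by the 2^-dCt method.

    ``table`` needs columns ``sample``, ``gene``, ``ct`` and ``reference_ct``
    (the reference gene's Ct in the same sample); adds a
    ``relative_expression`` column equal to ``2^-(ct - reference_ct)``.
    """
    required = {"sample", "gene", "ct", "reference_ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"expression table is missing columns: {sorted(missing)}")
    if table["reference_ct"].isna().any():
        bad = table.loc[table["reference_ct"].isna(), "sample"].tolist()
        raise ValueError(f"missing reference Ct for samples: {bad}")
    if (table["ct"] <= 0).any() or (table["reference_ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    out = table.copy()
    out["relative_expression"] = 2.0 ** -(out["ct"] - out["reference_ct"])
    return out


def sensitivity_correlation(
    expression: np.ndarray, ic50: np.ndarray, exact_max_n: int = 9
) -> tuple[float, float]:
    """Spearman correlation between expression and drug sensitivity.

    rho is the Pearson correlation of mid-ranks (ties allowed). For
    n <= ``exact_max_n`` the p-value is the exact permutation tail
    probability of |rho|; otherwise the large-sample t approximation.
    """
    x = np.asarray(expression, dtype=float)
    y = np.asarray(ic50, dtype=float)
    if x.size != y.size:
        raise ValueError("paired vectors differ in length")
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 paired observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant input vector: Spearman rho is undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    if n <= exact_max_n:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            if abs(r) >= obs - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, float(p)
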