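"""Parametric fits to the zeta decline and diversity summaries.

The decline of zeta with order is fitted on the log scale by ordinary least
squares: an exponential form regresses log zeta on the order i, a power-law
form on log i, and the combined form on both,

    log zeta_i = a - b_exp * i - b_pl * log(i).

An exponential decline arises when every species has the same chance of
occurring in any site (stochastic assembly); a power-law decline arises when
occurrence chances are site- or species-specific (niche assembly).  Fitting
the two segments on either side of the retention-rate peak separates the
signal of rare species (low orders) from widespread species (high orders).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .community import CommunityMatrix
from .zeta import ZetaDecline

FORMS = ("exponential", "powerlaw", "combined")


@dataclass
class DeclineFit:
    """OLS fit of one parametric form over a segment of orders.

    Coefficients are reported as positive decline rates (the negated OLS
    slopes), with two-sided t-test p-values and the AIC of each candidate
    form evaluated on the same segment.
    """

    segment: tuple[int, int]            # inclusive order range
    form: str
    intercept: float
    exp_coeff: float | None             # b_exp, per unit order
    pl_coeff: float | None              # b_pl, per log order
    exp_p: float | None
    pl_p: float | None
    aic: dict[str, float]               # AIC per candidate form on this segment
    aicc: dict[str, float] = None       # small-sample corrected AIC
    chosen_form: str = ""               # AICc-minimal form

    def predict_log(self, orders: np.ndarray) -> np.ndarray:
        orders = np.asarray(orders, dtype=float)
        out = np.full(orders.shape, self.intercept)
        if self.exp_coeff is not None:
            out = out - self.exp_coeff * orders
        if self.pl_coeff is not None:
            out = out - self.pl_coeff * np.log(orders)
        return out


def _design(orders: np.ndarray, form: str) -> np.ndarray:
    cols = [np.ones_like(orders, dtype=float)]
    if form in ("exponential", "combined"):
        cols.append(orders.astype(float))
    if form in ("powerlaw", "combined"):
        cols.append(np.log(orders.astype(float)))
    return np.column_stack(cols)


def fit_decline(
    decline: ZetaDecline,
    segment: tuple[int, int] | None = None,
    form: str = "combined",
) -> DeclineFit:
    """Fit one decline form on log zeta over an inclusive order segment.

    All zeta values in the segment must be strictly positive; a zero or
    negative value raises with a hint to shorten the segment.  The AIC of all
    three candidate forms on the same data is attached for model comparison.
    """
    if form not in FORMS:
        raise ValueError(f"form must be one of {FORMS}")
    orders = np.asarray(decline.orders)
    zeta = np.asarray(decline.zeta, dtype=float)
    if segment is None:
        segment = (int(orders[0]), int(orders[-1]))
    lo, hi = segment
    mask = (orders >= lo) & (orders <= hi)
    o, z = orders[mask], zeta[mask]
    if (z <= 0).any():
        raise ValueError(
            f"zeta must be positive throughout segment {segment}; "
            "shorten the segment to exclude zero values"
        )
    n_coef = {"exponential": 2, "powerlaw": 2, "combined": 3}[form]
    if len(o) < n_coef + 1:
        raise ValueError(
            f"segment {segment} has {len(o)} points; need at least {n_coef + 1}"
        )
    y = np.log(z)
    aic = {}
    aicc = {}
    fits = {}
    n = len(o)
    for f in FORMS:
        p_coef = {"exponential": 2, "powerlaw": 2, "combined": 3}[f]
        if n < p_coef + 1:
            continue
        res = sm.OLS(y, _design(o, f)).fit()
        aic[f] = float(res.aic)
        # corrected criterion; k counts the residual variance as estimated
        k = p_coef + 1
        aicc[f] = (
            float(res.aic + 2.0 + 2.0 * k * (k + 1) / (n - k - 1))
            if n - k - 1 > 0
            else float("inf")
        )
        fits[f] = res
    res = fits[form]
    params, pvals = res.params, res.pvalues
    exp_coeff = pl_coeff = exp_p = pl_p = None
    k = 1
    if form in ("exponential", "combined"):
        exp_coeff, exp_p = float(-params[k]), float(pvals[k])
        k += 1
    if form in ("powerlaw", "combined"):
        pl_coeff, pl_p = float(-params[k]), float(pvals[k])
    finite_aicc = {f: v for f, v in aicc.items() if np.isfinite(v)}
    chosen = min(finite_aicc, key=finite_aicc.get) if finite_aicc else min(aic, key=aic.get)
    return DeclineFit(
        segment=(int(lo), int(hi)),
        form=form,
        intercept=float(params[0]),
        exp_coeff=exp_coeff,
        pl_coeff=pl_coeff,
        exp_p=exp_p,
        pl_p=pl_p,
        aic=aic,
        aicc=aicc,
        chosen_form=chosen,
    )


def coefficient_ci(decline: ZetaDecline, segment, form: str, level: float = 0.95):
    """Confidence intervals for the (negated) decline coefficients.

    Returns a dict mapping coefficient name to (low, high) on the positive
    decline-rate scale.
    """
    orders = np.asarray(decline.orders)
    zeta = np.asarray(decline.zeta, dtype=float)
    lo, hi = segment
    mask = (orders >= lo) & (orders <= hi)
    res = sm.OLS(np.log(zeta[mask]), _design(orders[mask], form)).fit()
    ci = res.conf_int(alpha=1 - level)
    out = {}
    k = 1
    if form in ("exponential", "combined"):
        out["exp_coeff"] = (float(-ci[k, 1]), float(-ci[k, 0]))
        k += 1
    if form in ("powerlaw", "combined"):
        out["pl_coeff"] = (float(-ci[k, 1]), float(-ci[k, 0]))
    return out


@dataclass
class Breakpoint:
    """Order separating rare (<= order) from widespread (> order) species."""

    order: int
    rule: str        # "retention-peak" or "no-peak-midpoint"
    no_peak: bool = False


def find_breakpoint(retention: np.ndarray, orders: np.ndarray | None = None) -> Breakpoint:
    """Locate the retention-rate peak separating rare from widespread species.

    The retention rate typically rises while rare species drop out of the
    shared set and falls once only widespread species remain; the peak order
    is the natural breakpoint.  Ties take the first (lowest-order) maximum.
    A monotone retention curve has no interior peak: the midpoint is returned
    with ``no_peak`` set.
    """
    retention = np.asarray(retention, dtype=float)
    if orders is None:
        orders = np.arange(2, 2 + len(retention))
    orders = np.asarray(orders)
    valid = ~np.isnan(retention)
    if valid.sum() < 4:
        raise ValueError("need retention values on at least 4 consecutive orders")
    r, o = retention[valid], orders[valid]
    diffs = np.diff(r)
    monotone = (diffs >= 0).all() or (diffs <= 0).all()
    if monotone:
        return Breakpoint(order=int(o[len(o) // 2]), rule="no-peak-midpoint", no_peak=True)
    return Breakpoint(order=int(o[int(np.argmax(r))]), rule="retention-peak")


def fit_piecewise(
    decline: ZetaDecline,
    retention: np.ndarray | None = None,
    form: str = "combined",
) -> tuple[DeclineFit, DeclineFit, Breakpoint]:
    """Combined-form fits on the rare (orders <= b) and widespread (> b) segments.

    ``b`` is the retention-rate breakpoint.  A segment too short to fit is
    widened by moving the breakpoint until both sides support the model.
    """
    if retention is None:
        retention = decline.retention_rate()
    orders = np.asarray(decline.orders)
    bp = find_breakpoint(retention, orders[1:])
    n_coef = {"exponential": 2, "powerlaw": 2, "combined": 3}[form]
    min_pts = n_coef + 1
    b = bp.order
    lo_n = int((orders <= b).sum())
    hi_n = int((orders > b).sum())
    moved = False
    while lo_n < min_pts and b < orders[-1]:
        b += 1
        moved = True
        lo_n, hi_n = int((orders <= b).sum()), int((orders > b).sum())
    while hi_n < min_pts and b > orders[0]:
        b -= 1
        moved = True
        lo_n, hi_n = int((orders <= b).sum()), int((orders > b).sum())
    if moved:
        import warnings

        warnings.warn(
            f"breakpoint moved from {bp.order} to {b} to give both segments "
            f"at least {min_pts} points",
            stacklevel=2,
        )
        bp = Breakpoint(order=b, rule=bp.rule + "+widened", no_peak=bp.no_peak)
    rare = fit_decline(decline, (int(orders[0]), b), form)
    widespread = fit_decline(decline, (b + 1, int(orders[-1])), form)
    return rare, widespread, bp


def beta_summary(
    cm: CommunityMatrix, n_star_formula=None
) -> dict[str, float]:
    """Gamma, mean alpha, Whittaker beta, and an N*-style beta index.

    Whittaker's multiplicative beta is gamma / mean alpha.  The N* index is
    exposed as a pluggable formula taking (gamma, mean_alpha, occupancy
    vector); when none is configured, Whittaker's value is reported under the
    distinct ``n_star`` key so downstream tables stay complete.
    """
    occ = cm.occupancy()
    gamma = int((occ >= 1).sum())
    if gamma == 0:
        raise ValueError("matrix has no occurrences; beta diversity undefined")
    mean_alpha = float(cm.richness().mean())
    whittaker = gamma / mean_alpha
    if n_star_formula is not None:
        n_star = float(n_star_formula(gamma, mean_alpha, occ))
    else:
        n_star = whittaker
    return {
        "gamma": float(gamma),
        "mean_alpha": mean_alpha,
        "whittaker_beta": whittaker,
        "n_star": n_star,
    }
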