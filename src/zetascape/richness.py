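"""Spatially corrected models of per-site species richness.

Richness counts are modelled by a Poisson log-link regression with a
3-knot natural cubic spline basis per covariate, after augmenting the
design with distance-based Moran eigenvectors (dbMEM) to absorb broad-scale
spatial autocorrelation.  With 3 knots the basis is low-dimensional, so the
regression is left unpenalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2

from .community import SiteTable


@dataclass
class SpatialEigenvectors:
    """dbMEM spatial eigenfunctions with positive eigenvalues.

    Columns of ``vectors`` are orthonormal and orthogonal to the constant
    vector (a consequence of double centring); eigenvalues are sorted
    decreasing, the leading ones describing the broadest spatial scales.
    """

    vectors: np.ndarray        # (n_sites, k)
    eigenvalues: np.ndarray    # (k,), all > 0
    truncation: float

    @property
    def k(self) -> int:
        return self.vectors.shape[1]


def dbmem(site_table: SiteTable, truncation: float | None = None) -> SpatialEigenvectors:
    """Distance-based Moran eigenvector maps from planar site coordinates.

    Pairwise Euclidean distances above the truncation threshold (default:
    the longest edge of the minimum spanning tree, which keeps the site graph
    connected) are replaced by 4x the threshold; the truncated distance
    matrix is double-centred (as in principal coordinates analysis) and
    eigendecomposed; eigenvectors with positive eigenvalues are returned.
    """
    coords = site_table.coords
    n = len(coords)
    if n < 3:
        raise ValueError("need at least 3 sites")
    D = squareform(pdist(coords))
    if not (D[np.triu_indices(n, 1)] > 0).any():
        raise ValueError("all sites coincide; no spatial structure")
    if truncation is None:
        mst = minimum_spanning_tree(D).toarray()
        truncation = float(mst[mst > 0].max())
    Dt = np.where(D <= truncation, D, 4.0 * truncation)
    np.fill_diagonal(Dt, 0.0)
    A = -0.5 * Dt**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    G = (G + G.T) / 2
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals).max(), 1.0) * 1e-10
    pos = vals > tol
    return SpatialEigenvectors(
        vectors=vecs[:, pos], eigenvalues=vals[pos], truncation=truncation
    )


def natural_spline_basis(x: np.ndarray, knots: np.ndarray | None = None) -> np.ndarray:
    """Natural cubic spline basis with 3 knots (min, median, max) -> 2 columns.

    The natural constraint (linearity beyond the boundary knots) reduces a
    3-knot cubic spline to a linear term plus one curvature term, matching a
    basis dimension of 3 once the model intercept is counted.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        knots = np.array([x.min(), np.median(x), x.max()])
    k1, k2, k3 = knots
    if not (k1 < k2 < k3):
        raise ValueError("spline knots must be strictly increasing")

    def d(xk, knot):
        return np.clip(xk - knot, 0, None) ** 3

    curv = (d(x, k1) - d(x, k3)) / (k3 - k1) - (d(x, k2) - d(x, k3)) / (k3 - k2)
    return np.column_stack([x, curv])


@dataclass
class RichnessFit:
    """Poisson log-link richness regression with spline + spatial terms."""

    deviance_explained: float
    pseudo_r2: float                       # squared corr(observed, fitted)
    coefficients: pd.Series
    covariate_pvalues: dict[str, float]    # likelihood-ratio test per covariate
    fitted: np.ndarray
    converged: bool
    aic: float
    model_columns: list[str] = field(default_factory=list)
    spline_knots: dict[str, np.ndarray] = field(default_factory=dict)

    def linearized_slope(self, covariate: str, x: np.ndarray) -> float:
        """OLS slope of the fitted linear predictor on a covariate: the
        log-scale effect size a linear model would report."""
        eta = np.log(self.fitted)
        A = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(A, eta, rcond=None)
        return float(coef[1])


def _build_design(
    site_table_df: pd.DataFrame,
    covariates: list[str],
    spatial: SpatialEigenvectors | None,
) -> tuple[np.ndarray, list[str], dict[str, list[int]], dict[str, np.ndarray]]:
    n = len(site_table_df)
    cols = [np.ones(n)]
    names = ["intercept"]
    groups: dict[str, list[int]] = {}
    knots: dict[str, np.ndarray] = {}
    for cov in covariates:
        x = site_table_df[cov].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"covariate {cov!r} is constant")
        kn = np.array([x.min(), np.median(x), x.max()])
        if not (kn[0] < kn[1] < kn[2]):
            kn[1] = (kn[0] + kn[2]) / 2
        B = natural_spline_basis(x, kn)
        start = len(names)
        for b in range(B.shape[1]):
            cols.append(B[:, b])
            names.append(f"{cov}_s{b + 1}")
        groups[cov] = list(range(start, start + B.shape[1]))
        knots[cov] = kn
    if spatial is not None and spatial.k > 0:
        for j in range(spatial.k):
            cols.append(spatial.vectors[:, j])
            names.append(f"MEM{j + 1}")
    return np.column_stack(cols), names, groups, knots


def _fit_poisson(X: np.ndarray, y: np.ndarray):
    model = sm.GLM(y, X, family=sm.families.Poisson())
    try:
        return model.fit()
    except (ValueError, np.linalg.LinAlgError):
        # IRLS can become infeasible on sparse counts with a rich design
        # (quasi-separation); retry with a gradient-based optimizer and let
        # the result's convergence flag report the outcome honestly.
        res = model.fit(method="lbfgs", maxiter=1000, disp=False)
        if not hasattr(res, "converged"):
            res.converged = bool(res.mle_retvals.get("converged", False))
        return res


def fit_richness(
    richness: np.ndarray,
    site_table: SiteTable,
    covariates: list[str],
    spatial: SpatialEigenvectors | None = None,
) -> RichnessFit:
    """Poisson log-link regression of per-site richness counts.

    Each covariate enters through a 3-knot natural cubic spline; spatial
    eigenvectors enter linearly.  Reports deviance explained
    (1 - residual/null deviance), pseudo-R^2 (squared Pearson correlation of
    observed and fitted counts), and a likelihood-ratio p-value per covariate
    from the fit without that covariate's columns.  Non-convergence is
    reported on the result, never silently replaced.
    """
    y = np.asarray(richness)
    if (y < 0).any() or not np.issubdtype(y.dtype, np.integer):
        y_int = np.asarray(richness, dtype=float)
        if (y_int < 0).any() or not np.allclose(y_int, np.round(y_int)):
            raise ValueError("richness must be non-negative integer counts")
        y = y_int.astype(int)
    X, names, groups, knots = _build_design(site_table.data, covariates, spatial)
    res = _fit_poisson(X, y)
    null = _fit_poisson(np.ones((len(y), 1)), y)
    dev_expl = float(1.0 - res.deviance / null.deviance) if null.deviance > 0 else 0.0
    fitted = np.asarray(res.fittedvalues)
    pseudo = (
        float(np.corrcoef(y, fitted)[0, 1] ** 2)
        if np.std(fitted) > 0 and np.std(y) > 0
        else 0.0
    )
    pvals: dict[str, float] = {}
    for cov, idx in groups.items():
        keep = [j for j in range(X.shape[1]) if j not in idx]
        reduced = _fit_poisson(X[:, keep], y)
        lr = 2.0 * (res.llf - reduced.llf)
        pvals[cov] = float(chi2.sf(max(lr, 0.0), df=len(idx)))
    return RichnessFit(
        deviance_explained=dev_expl,
        pseudo_r2=pseudo,
        coefficients=pd.Series(res.params, index=names),
        covariate_pvalues=pvals,
        fitted=fitted,
        converged=bool(res.converged),
        aic=float(res.aic),
        model_columns=names,
        spline_knots=knots,
    )


@dataclass
class RichnessRelationship:
    """Smooth Poisson regression of one category's richness on another's."""

    fit: RichnessFit
    grid: np.ndarray
    curve: np.ndarray          # fitted mean over the predictor grid
    hump: bool                 # interior maximum of the fitted curve


def richness_relationship(
    richness_a: np.ndarray, richness_b: np.ndarray, n_grid: int = 101
) -> RichnessRelationship:
    """Model richness_b as a smooth (3-knot spline, Poisson log-link)
    function of richness_a; flags a hump-shaped (interior-maximum) curve."""
    a = np.asarray(richness_a, dtype=float)
    b = np.asarray(richness_b)
    if len(a) != len(b):
        raise ValueError("richness vectors must be aligned")
    if np.ptp(a) == 0:
        raise ValueError("predictor richness is constant")
    table = SiteTable(
        pd.DataFrame(
            {"x": np.arange(len(a), dtype=float), "y": np.zeros(len(a)),
             "elevation": np.zeros(len(a)), "pred": a},
            index=[f"s{i}" for i in range(len(a))],
        )
    )
    fit = fit_richness(b, table, ["pred"], spatial=None)
    kn = fit.spline_knots["pred"]
    grid = np.linspace(a.min(), a.max(), n_grid)
    B = natural_spline_basis(grid, kn)
    beta = fit.coefficients
    eta = beta["intercept"] + B @ beta[[f"pred_s{j + 1}" for j in range(B.shape[1])]].to_numpy()
    curve = np.exp(eta)
    interior = int(np.argmax(curve))
    hump = 0 < interior < n_grid - 1 and curve[interior] > max(curve[0], curve[-1]) * (1 + 1e-9)
    return RichnessRelationship(fit=fit, grid=grid, curve=curve, hump=hump)
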