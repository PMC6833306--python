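"""Multi-Site Generalized Dissimilarity Modelling (MS-GDM).

Pairwise GDM regresses compositional dissimilarity between two sites on
monotone I-spline transforms of environmental distances.  The multi-site
extension used here replaces the pair with an order-*i* site combination:
the response is the normalized zeta (Sørensen or Simpson) of the
combination, and each predictor is the mean pairwise difference of a
covariate over the combination's sites, rescaled to [0, 1].

The monotone constraint is kept meaningful by fitting on the dissimilarity
orientation (1 - normalized zeta) with non-negative I-spline coefficients:
larger environmental differences can only predict larger compositional
differences.  A biotic variant adds the (dissimilarity-oriented) zeta of a
second species category on the identical combinations, asking how well one
category's turnover predicts another's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import lsq_linear
from scipy.spatial.distance import pdist, squareform

from .community import CommunityMatrix, SiteTable
from .zeta import CombinationRecord, records_for_combinations, sample_combinations


@dataclass
class ISplineBasis:
    """Integrated monotone spline basis on [0, 1].

    Each of the ``n_basis`` functions is non-decreasing, 0 at x = 0 and 1 at
    x = 1; any non-negative combination is therefore monotone non-decreasing.
    ``order`` is the order of the underlying M-splines (2 = piecewise-linear
    density, piecewise-quadratic I-spline); internal knots are equally spaced.
    """

    order: int = 2
    n_basis: int = 3

    def __post_init__(self) -> None:
        if self.n_basis < self.order:
            raise ValueError("n_basis must be >= order")
        m = self.n_basis - self.order  # number of interior knots
        interior = np.linspace(0, 1, m + 2)[1:-1]
        k = self.order  # B-spline degree used for the integrated representation
        self.knots = np.concatenate([np.zeros(k + 1), interior, np.ones(k + 1)])

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the basis at ``x`` in [0, 1] -> array (len(x), n_basis).

        Uses the identity I_j(x) = sum_{l >= j} B_l(x) over B-splines of
        degree ``order`` on the same interior knots.
        """
        x = np.asarray(x, dtype=float)
        if (x < 0).any() or (x > 1).any():
            raise ValueError("I-spline input must lie in [0, 1]; rescale first")
        B = BSpline.design_matrix(x, self.knots, self.order, extrapolate=False).toarray()
        # reverse cumulative sum, dropping the first B-spline (its I would be
        # the constant 1 on [0, 1])
        rev = np.cumsum(B[:, ::-1], axis=1)[:, ::-1]
        return rev[:, 1:]


def ispline_transform(x: np.ndarray, basis: ISplineBasis | None = None) -> np.ndarray:
    """I-spline design columns for one predictor (see :class:`ISplineBasis`)."""
    return (basis or ISplineBasis()).transform(x)


def _minmax(v: np.ndarray) -> np.ndarray | None:
    lo, hi = float(np.min(v)), float(np.max(v))
    if hi == lo:
        return None
    return (v - lo) / (hi - lo)


def _mean_pairwise(values: np.ndarray, combos: np.ndarray) -> np.ndarray:
    """Mean pairwise |difference| of per-site values over each combination."""
    sub = values[combos]                       # (n_records, order)
    order = sub.shape[1]
    if order == 1:
        return np.zeros(len(sub))
    diffs = np.abs(sub[:, :, None] - sub[:, None, :])
    iu = np.triu_indices(order, k=1)
    return diffs[:, iu[0], iu[1]].mean(axis=1)


def _mean_pairwise_distance(coords: np.ndarray, combos: np.ndarray) -> np.ndarray:
    d = squareform(pdist(coords))
    order = combos.shape[1]
    if order == 1:
        return np.zeros(len(combos))
    iu = np.triu_indices(order, k=1)
    return d[combos[:, iu[0]], combos[:, iu[1]]].mean(axis=1)


@dataclass
class MSGDMDesign:
    """Per-combination regression table: response and predictors in [0, 1]."""

    response: np.ndarray                 # normalized zeta (similarity scale)
    predictors: pd.DataFrame             # columns rescaled to [0, 1]
    order: int
    scheme: str
    dropped: list[str] = field(default_factory=list)


def build_design(
    cm: CommunityMatrix,
    site_table: SiteTable,
    order: int,
    records: list[CombinationRecord],
    covariates: list[str],
    biotic_cm: CommunityMatrix | None = None,
    scheme: str = "sorensen",
    biotic_name: str = "biotic",
    summary: str = "mean",
) -> MSGDMDesign:
    """Assemble the MS-GDM regression table from sampled combinations.

    Response: normalized zeta of the focal matrix per record.  Each covariate
    is summarized as the mean (or, with ``summary='max'``, the maximum)
    pairwise absolute difference over the record's sites and min-max rescaled
    across records; geographic distance likewise.  The optional biotic column
    is 1 - normalized zeta of ``biotic_cm`` on the identical site tuples
    (dissimilarity orientation), also rescaled.  Covariates constant across
    records cannot be rescaled and are dropped with a warning.
    """
    st = site_table.aligned_to(cm)
    combos = np.array([r.sites for r in records], dtype=int)
    if combos.shape[1] != order:
        raise ValueError("records do not all have the stated order")
    response = np.array([r.normalized(scheme) for r in records])

    cols: dict[str, np.ndarray] = {}
    dropped: list[str] = []

    def add(name: str, raw: np.ndarray) -> None:
        scaled = _minmax(raw)
        if scaled is None:
            dropped.append(name)
            warnings.warn(f"covariate {name!r} constant across records; dropped", stacklevel=3)
        else:
            cols[name] = scaled

    for cov in covariates:
        if cov not in st.data.columns:
            raise KeyError(f"covariate {cov!r} not in site table")
        v = st.data[cov].to_numpy(dtype=float)
        pair = _mean_pairwise(v, combos)
        if summary == "max":
            sub = v[combos]
            pair = (sub.max(axis=1) - sub.min(axis=1)) if order > 1 else np.zeros(len(combos))
        add(cov, pair)
    add("distance", _mean_pairwise_distance(st.coords, combos))

    if biotic_cm is not None:
        if biotic_cm.n_sites != cm.n_sites:
            raise ValueError("biotic matrix must share the focal site set")
        brecords = records_for_combinations(biotic_cm, combos)
        bvals = 1.0 - np.array([r.normalized(scheme) for r in brecords])
        add(biotic_name, bvals)

    return MSGDMDesign(
        response=response,
        predictors=pd.DataFrame(cols),
        order=order,
        scheme=scheme,
        dropped=dropped,
    )


@dataclass
class MSGDMFit:
    """Constrained I-spline regression of multi-site dissimilarity.

    ``coefficients`` maps predictor -> per-basis-function coefficients, all
    >= 0; the per-predictor ``importance`` is the maximum of its fitted
    spline, i.e. the coefficient sum (I-splines reach 1 at x = 1).
    ``variance_explained`` is the squared Pearson correlation of observed and
    predicted response.
    """

    order: int
    scheme: str
    intercept: float
    coefficients: dict[str, np.ndarray]
    importance: dict[str, float]
    variance_explained: float
    basis: ISplineBasis
    predictor_names: list[str]
    flagged: list[str] = field(default_factory=list)
    predicted: np.ndarray | None = None

    def predict_dissimilarity(self, predictors: pd.DataFrame) -> np.ndarray:
        out = np.full(len(predictors), self.intercept)
        for name in self.predictor_names:
            X = self.basis.transform(predictors[name].to_numpy(dtype=float))
            out = out + X @ self.coefficients[name]
        return out


def fit_msgdm(design: MSGDMDesign, basis: ISplineBasis | None = None) -> MSGDMFit:
    """Fit the MS-GDM by bounded least squares.

    The response is oriented as dissimilarity (1 - normalized zeta) and
    regressed on I-spline-transformed predictors with coefficients
    constrained non-negative (free intercept), so the fitted surface is
    monotone non-decreasing in every predictor.  Deterministic given the
    design.  A rank-deficient design does not abort the fit; predictors in
    exactly collinear blocks are flagged.
    """
    basis = basis or ISplineBasis()
    names = list(design.predictors.columns)
    p = basis.n_basis
    if len(design.response) < 10 * (1 + p * len(names)):
        warnings.warn(
            "fewer than 10 records per coefficient; fit may be unstable",
            stacklevel=2,
        )
    blocks = [np.ones((len(design.response), 1))]
    for name in names:
        blocks.append(basis.transform(design.predictors[name].to_numpy(dtype=float)))
    X = np.hstack(blocks)
    y = 1.0 - design.response

    flagged: list[str] = []
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # locate predictors participating in exact collinearity
        for i, name in enumerate(names):
            sub = np.delete(X, slice(1 + i * p, 1 + (i + 1) * p), axis=1)
            if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(X):
                flagged.append(name)

    lo = np.zeros(X.shape[1])
    lo[0] = -np.inf
    res = lsq_linear(X, y, bounds=(lo, np.full(X.shape[1], np.inf)))
    beta = res.x
    coefficients = {
        name: beta[1 + i * p : 1 + (i + 1) * p] for i, name in enumerate(names)
    }
    predicted_dis = X @ beta
    predicted = 1.0 - predicted_dis
    obs = design.response
    if np.std(obs) > 0 and np.std(predicted) > 0:
        r2 = float(np.corrcoef(obs, predicted)[0, 1] ** 2)
    else:
        r2 = 0.0
    return MSGDMFit(
        order=design.order,
        scheme=design.scheme,
        intercept=float(beta[0]),
        coefficients=coefficients,
        importance={n: float(c.sum()) for n, c in coefficients.items()},
        variance_explained=r2,
        basis=basis,
        predictor_names=names,
        flagged=flagged,
        predicted=predicted,
    )


def run_model_suite(
    cm: CommunityMatrix,
    site_table: SiteTable,
    focal_category: str,
    orders: list[int] | range,
    scheme: str = "sorensen",
    covariates: list[str] | None = None,
    n_samples: int = 1000,
    seed: int | np.random.Generator = 0,
    basis: ISplineBasis | None = None,
    models: tuple[str, ...] = ("abiotic", "biotic1", "biotic2"),
) -> dict[int, dict[str, MSGDMFit]]:
    """Abiotic and biotic MS-GDM fits per order for one focal category.

    * abiotic: environmental covariates + geographic distance;
    * biotic1: abiotic + non-endemic zeta on the same combinations (only
      defined for endemic focal categories);
    * biotic2: abiotic + the other endemic category's zeta.

    The identical combination samples are reused across models within an
    order so that variance-explained comparisons are paired.
    """
    if "biotic1" in models and focal_category == "NON_E":
        raise ValueError("biotic model I is undefined for a non-endemic focal category")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    focal = cm.subset_by_category(focal_category)
    non_e = cm.subset_by_category("NON_E")
    other_label = {"NE": "PE", "PE": "NE"}.get(focal_category)
    other = cm.subset_by_category(other_label) if other_label else None
    if covariates is None:
        covariates = [c for c in site_table.covariate_names()]

    out: dict[int, dict[str, MSGDMFit]] = {}
    for order in orders:
        combos = sample_combinations(cm.n_sites, int(order), n_samples, rng)
        records = records_for_combinations(focal, combos)
        fits: dict[str, MSGDMFit] = {}
        if "abiotic" in models:
            d = build_design(focal, site_table, int(order), records, covariates, scheme=scheme)
            fits["abiotic"] = fit_msgdm(d, basis)
        if "biotic1" in models:
            d = build_design(
                focal, site_table, int(order), records, covariates,
                biotic_cm=non_e, scheme=scheme, biotic_name="zeta_NON_E",
            )
            fits["biotic1"] = fit_msgdm(d, basis)
        if "biotic2" in models and other is not None and other.n_species > 0:
            d = build_design(
                focal, site_table, int(order), records, covariates,
                biotic_cm=other, scheme=scheme, biotic_name=f"zeta_{other_label}",
            )
            fits["biotic2"] = fit_msgdm(d, basis)
        out[int(order)] = fits
    return out
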