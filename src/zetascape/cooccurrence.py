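"""Species range statistics, permutational ANOVA, and co-occurrence metrics.

Species categories are compared on elevational statistics and geographic
range (occupied-site fraction) by a one-way permutational ANOVA with
pairwise permutation post-hoc tests.  Community structure is summarized by
the normalized checkerboard score (C-score, segregation) and the NODF
nestedness index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .community import CommunityMatrix, SiteTable


def range_stats(cm: CommunityMatrix, site_table: SiteTable) -> pd.DataFrame:
    """Per-species elevational and geographic range statistics.

    Columns: mean/min/max elevation of occupied sites (m), elevational range
    (max - min), and ``range_ratio`` = occupied sites / total sites.
    Zero-occupancy species get NaN elevational statistics and ratio 0.
    """
    st = site_table.aligned_to(cm)
    elev = st.elevation
    inc = cm.incidence.astype(bool)
    n_sites = cm.n_sites
    rows = []
    for j, sp in enumerate(cm.species):
        occ_sites = elev[inc[:, j]]
        if occ_sites.size == 0:
            rows.append((sp, np.nan, np.nan, np.nan, np.nan, 0.0))
        else:
            mn, mx = float(occ_sites.min()), float(occ_sites.max())
            rows.append((sp, float(occ_sites.mean()), mn, mx, mx - mn, occ_sites.size / n_sites))
    df = pd.DataFrame(
        rows,
        columns=["species", "mean_elevation", "min_elevation", "max_elevation",
                 "elevation_range", "range_ratio"],
    ).set_index("species")
    if cm.category:
        df["category"] = [cm.category[s] for s in cm.species]
    return df


def _f_statistic(values: np.ndarray, group_sizes: np.ndarray) -> float:
    """Classical one-way ANOVA F for values ordered by group blocks."""
    n = len(values)
    k = len(group_sizes)
    bounds = np.concatenate([[0], np.cumsum(group_sizes)])
    grand = values.mean()
    ssb = ssw = 0.0
    for g in range(k):
        block = values[bounds[g]:bounds[g + 1]]
        m = block.mean()
        ssb += len(block) * (m - grand) ** 2
        ssw += ((block - m) ** 2).sum()
    return (ssb / (k - 1)) / (ssw / (n - k))


@dataclass
class PermAnovaResult:
    """One-way permutational ANOVA with pairwise permutation post-hoc tests."""

    f_statistic: float
    p_value: float
    n_permutations: int
    groups: list[str]
    excluded: list[str] = field(default_factory=list)
    posthoc: pd.DataFrame | None = None   # pair, raw p, Holm-adjusted p


def _holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (monotone, capped at 1)."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj


def perm_anova(
    values: np.ndarray,
    groups: np.ndarray,
    n_perm: int = 4999,
    seed: int | np.random.Generator = 0,
    posthoc: bool = True,
) -> PermAnovaResult:
    """Permutational one-way ANOVA on a per-species statistic.

    The observed F is the classical one-way statistic; the p-value is the
    add-one permutation estimate (1 + #{F_perm >= F_obs}) / (1 + n_perm)
    under random relabelling.  Groups with fewer than 2 members are excluded
    with a warning.  Post-hoc: all pairwise permutation t-tests (difference
    of means statistic) with Holm step-down adjustment.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = ~np.isnan(values)
    values, groups = values[keep], groups[keep]
    labels, counts = np.unique(groups, return_counts=True)
    excluded = [str(l) for l, c in zip(labels, counts) if c < 2]
    if excluded:
        warnings.warn(f"groups excluded with < 2 members: {excluded}", stacklevel=2)
        m = ~np.isin(groups, excluded)
        values, groups = values[m], groups[m]
        labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups with >= 2 members")

    # order values by group blocks; permuting values is equivalent to
    # permuting labels
    order = np.argsort(groups, kind="stable")
    v = values[order]
    sizes = counts
    f_obs = _f_statistic(v, sizes)

    n = len(v)
    k = len(sizes)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    total_ss = ((v - v.mean()) ** 2).sum()
    perm = np.argsort(rng.random((n_perm, n)), axis=1)
    pv = v[perm]                                         # (n_perm, n)
    gsums = np.add.reduceat(pv, bounds[:-1], axis=1)     # (n_perm, k)
    ssb = (gsums ** 2 / sizes).sum(axis=1) - n * v.mean() ** 2
    ssw = total_ss - ssb
    f_perm = (ssb / (k - 1)) / (ssw / (n - k))
    p = (1 + int((f_perm >= f_obs).sum())) / (1 + n_perm)

    ph = None
    if posthoc and len(labels) >= 2:
        rows = []
        for a, b in combinations(range(k), 2):
            va = v[bounds[a]:bounds[a + 1]]
            vb = v[bounds[b]:bounds[b + 1]]
            obs = abs(va.mean() - vb.mean())
            pooled = np.concatenate([va, vb])
            na = len(va)
            pp = np.argsort(rng.random((n_perm, len(pooled))), axis=1)
            shuffled = pooled[pp]
            stat = np.abs(shuffled[:, :na].mean(axis=1) - shuffled[:, na:].mean(axis=1))
            praw = (1 + int((stat >= obs).sum())) / (1 + n_perm)
            rows.append((str(labels[a]), str(labels[b]), praw))
        ph = pd.DataFrame(rows, columns=["group_a", "group_b", "p_raw"])
        ph["p_adjusted"] = _holm(ph["p_raw"].to_numpy())

    return PermAnovaResult(
        f_statistic=float(f_obs),
        p_value=float(p),
        n_permutations=n_perm,
        groups=[str(l) for l in labels],
        excluded=excluded,
        posthoc=ph,
    )


def c_score(cm: CommunityMatrix) -> float:
    """Mean normalized checkerboard score over species pairs, in [0, 1].

    For species i, j with occupancies r_i, r_j and S shared sites the
    checkerboard unit is (r_i - S)(r_j - S) / (r_i r_j); 1 means perfect
    segregation, 0 identical distributions.  Zero-occupancy species are
    excluded from pairs.
    """
    inc = cm.incidence.astype(np.int64)
    occ = inc.sum(axis=0)
    keep = occ > 0
    inc = inc[:, keep]
    occ = occ[keep]
    s = inc.shape[1]
    if s < 2:
        raise ValueError("need at least 2 species with occurrences")
    shared = inc.T @ inc                       # (s, s) co-occurrence counts
    ri = occ[:, None]
    rj = occ[None, :]
    cu = (ri - shared) * (rj - shared) / (ri * rj)
    iu = np.triu_indices(s, k=1)
    return float(cu[iu].mean())


def _nodf_axis(mat: np.ndarray) -> tuple[float, int]:
    """Sum of paired-overlap percentages over row pairs with decreasing fill."""
    fills = mat.sum(axis=1)
    m = mat.shape[0]
    total = 0.0
    for i, j in combinations(range(m), 2):
        hi, lo = (i, j) if fills[i] > fills[j] else (j, i)
        if fills[hi] <= fills[lo]:          # equal fill -> no contribution
            continue
        if fills[lo] == 0:
            continue
        shared = int(np.logical_and(mat[hi], mat[lo]).sum())
        total += 100.0 * shared / fills[lo]
    return total, m * (m - 1) // 2


def nodf(cm: CommunityMatrix) -> float:
    """NODF nestedness (0-100): mean paired overlap over row and column pairs
    with strictly decreasing marginal totals."""
    mat = cm.incidence.astype(bool)
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("need at least 2 sites and 2 species")
    row_sum, row_pairs = _nodf_axis(mat)
    col_sum, col_pairs = _nodf_axis(mat.T)
    return (row_sum + col_sum) / (row_pairs + col_pairs)


def vif_screen(
    site_table: SiteTable | pd.DataFrame,
    covariates: list[str],
    threshold: float = 10.0,
) -> tuple[list[str], list[tuple[str, float]]]:
    """Iterative variance-inflation-factor screen.

    Repeatedly drops the covariate with the largest VIF = 1/(1 - R^2) of its
    regression on the remaining candidates until all VIFs are below
    ``threshold``.  Exactly collinear covariates have unbounded VIF and go
    first.  Returns (retained names in input order, drop log of
    (name, VIF-at-drop)).
    """
    df = site_table.data if isinstance(site_table, SiteTable) else site_table
    if len(covariates) < 2:
        raise ValueError("need at least 2 candidate covariates")
    if len(df) <= len(covariates):
        raise ValueError("need more sites than candidate covariates")
    X = df[covariates].to_numpy(dtype=float)
    active = list(range(len(covariates)))
    drop_log: list[tuple[str, float]] = []
    while len(active) >= 2:
        vifs = []
        for pos, j in enumerate(active):
            others = [c for c in active if c != j]
            A = np.column_stack([np.ones(len(X)), X[:, others]])
            y = X[:, j]
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            resid = y - A @ coef
            ss_tot = ((y - y.mean()) ** 2).sum()
            r2 = 1 - resid @ resid / ss_tot if ss_tot > 0 else 1.0
            vifs.append(np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2))
        worst = int(np.argmax(vifs))
        if vifs[worst] < threshold:
            break
        drop_log.append((covariates[active[worst]], float(vifs[worst])))
        active.pop(worst)
    retained = [covariates[j] for j in sorted(active)]
    return retained, drop_log
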