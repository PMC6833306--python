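"""Zeta diversity: the mean number of species shared by *i* sites.

Zeta of order 1 is mean site richness (mean alpha-diversity); order 2 is the
mean pairwise shared-species count; higher orders probe progressively more
widespread species.  Because a species shared by *i* sites is necessarily
shared by any *i* - 1 of them, zeta is non-increasing in the order, and the
shape of that decline (exponential vs power-law) is diagnostic of whether
occupancy is homogeneous (stochastic assembly) or species-specific
(niche assembly).

Exact values use the combinatorial identity

    zeta_i = sum_s C(occ_s, i) / C(N, i)

over species occupancies, which equals the mean over all C(N, i) site
combinations.  Monte Carlo sampling of combinations provides per-combination
records for dissimilarity modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .community import CommunityMatrix

SCHEMES = ("raw", "sorensen", "simpson")


def _log_comb(n: np.ndarray, k: int) -> np.ndarray:
    """log C(n, k) elementwise; -inf where n < k."""
    n = np.asarray(n, dtype=float)
    out = np.full(n.shape, -np.inf)
    ok = n >= k
    out[ok] = gammaln(n[ok] + 1) - gammaln(n[ok] - k + 1) - gammaln(k + 1)
    return out


def zeta_exact(cm: CommunityMatrix, order: int) -> float:
    """Exact zeta diversity of ``order`` i: mean shared species over all
    C(n_sites, i) site combinations, computed in O(n_species) from occupancies."""
    n = cm.n_sites
    if not 1 <= order <= n:
        raise ValueError(f"order must be in [1, {n}], got {order}")
    occ = cm.occupancy()
    log_num = _log_comb(occ, order)
    log_den = _log_comb(np.array([n]), order)[0]
    return float(np.exp(log_num - log_den).sum())


@dataclass
class CombinationRecord:
    """One sampled site combination: the unit of multi-site regression."""

    sites: tuple[int, ...]          # site indices, distinct
    shared: int                     # species present in every site of the tuple
    richness: tuple[int, ...]       # per-site richness of the tuple's sites

    def normalized(self, scheme: str) -> float:
        """Normalized zeta for this combination.

        ``sorensen`` divides the shared count by the mean richness of the
        combination's sites (richness-dependent turnover); ``simpson`` divides
        by the minimum richness ("true" turnover).  Combinations of all-empty
        sites are defined as 0.
        """
        if scheme == "raw":
            return float(self.shared)
        if scheme == "sorensen":
            denom = float(np.mean(self.richness))
        elif scheme == "simpson":
            denom = float(np.min(self.richness))
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        return self.shared / denom if denom > 0 else 0.0


def normalize_zeta(record: CombinationRecord, scheme: str) -> float:
    """Normalized zeta of a combination (Sørensen or Simpson rescaling to [0, 1])."""
    return record.normalized(scheme)


def sample_combinations(
    n_sites: int, order: int, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample ``n_samples`` combinations of ``order`` distinct sites, uniform
    over combinations, independent across samples.  Shape (n_samples, order)."""
    if order > n_sites:
        raise ValueError(f"order {order} exceeds number of sites {n_sites}")
    # argpartition of random keys = uniform subset without replacement
    keys = rng.random((n_samples, n_sites))
    idx = np.argpartition(keys, order - 1, axis=1)[:, :order]
    return np.sort(idx, axis=1)


def shared_counts(cm: CommunityMatrix, combos: np.ndarray) -> np.ndarray:
    """Number of species present in every site of each combination row."""
    sub = cm.incidence[combos]                # (n_samples, order, n_species)
    return sub.min(axis=1).sum(axis=1)


def records_for_combinations(cm: CommunityMatrix, combos: np.ndarray) -> list[CombinationRecord]:
    rich = cm.richness()
    shared = shared_counts(cm, combos)
    return [
        CombinationRecord(tuple(int(s) for s in row), int(sh), tuple(int(r) for r in rich[row]))
        for row, sh in zip(combos, shared)
    ]


def zeta_montecarlo(
    cm: CommunityMatrix,
    order: int,
    n_samples: int = 10_000,
    seed: int | np.random.Generator = 0,
    return_records: bool = True,
) -> tuple[float, float, list[CombinationRecord]]:
    """Monte Carlo zeta: mean shared-species count over sampled combinations.

    Returns ``(estimate, sd, records)`` where ``sd`` is the spread of shared
    counts across combinations and ``records`` can be reused to build a
    dissimilarity-model design (pass ``return_records=False`` to skip
    materializing them when only the estimate is needed).  Unbiased for
    :func:`zeta_exact`.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    combos = sample_combinations(cm.n_sites, order, n_samples, rng)
    shared = shared_counts(cm, combos).astype(float)
    est = float(shared.mean())
    sd = float(shared.std(ddof=1)) if n_samples > 1 else 0.0
    records = records_for_combinations(cm, combos) if return_records else []
    return est, sd, records


@dataclass
class ZetaDecline:
    """Zeta values across orders 1..max_order with normalization bookkeeping.

    ``zeta`` holds the per-order mean (raw shared counts for ``raw``; mean of
    per-combination normalized values otherwise); ``sd`` the spread across
    combinations (0 where exact raw values are computed).
    """

    orders: np.ndarray
    zeta: np.ndarray
    sd: np.ndarray
    mode: str = "exact"                     # "exact" or "montecarlo"
    normalization: str = "raw"
    records: dict[int, list[CombinationRecord]] = field(default_factory=dict)

    def retention_rate(self) -> np.ndarray:
        """Retention rate at each order i >= 2: the ratio zeta_i / zeta_{i-1}.

        This is the proportion of the species shared by i - 1 sites that are
        still shared when an i-th site is added, a value in [0, 1] indexed at
        the larger order.  Where the denominator is 0 the ratio is undefined
        and reported as NaN rather than raising.
        """
        z = np.asarray(self.zeta, dtype=float)
        out = np.full(len(z) - 1, np.nan)
        nz = z[:-1] > 0
        out[nz] = z[1:][nz] / z[:-1][nz]
        return out


def retention_rate(decline: ZetaDecline) -> np.ndarray:
    """Retention rates for orders ``decline.orders[1:]`` (see method docstring)."""
    return decline.retention_rate()


def zeta_decline(
    cm: CommunityMatrix,
    max_order: int | None = None,
    mode: str = "exact",
    n_samples: int = 10_000,
    seed: int | np.random.Generator = 0,
    normalization: str = "raw",
    keep_records: bool = False,
) -> ZetaDecline:
    """Compute the zeta decline over orders 1..max_order.

    ``mode='exact'`` uses the closed form (only for ``normalization='raw'``);
    normalized declines average per-combination normalized values over Monte
    Carlo samples, which is what a regression on combination records requires.
    Order 1 and full-order combinations are still sampled (they are degenerate
    but keep the record structure uniform).
    """
    if normalization not in SCHEMES:
        raise ValueError(f"normalization must be one of {SCHEMES}")
    n = cm.n_sites
    max_order = min(n, 50) if max_order is None else max_order
    if not 1 <= max_order <= n:
        raise ValueError(f"max_order must be in [1, {n}]")
    orders = np.arange(1, max_order + 1)

    if mode == "exact":
        if normalization != "raw":
            raise ValueError("exact mode supports raw normalization only; use montecarlo")
        zeta = np.array([zeta_exact(cm, int(i)) for i in orders])
        return ZetaDecline(orders, zeta, np.zeros_like(zeta), "exact", "raw")

    if mode != "montecarlo":
        raise ValueError(f"unknown mode {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rich = cm.richness()
    zeta = np.empty(len(orders))
    sd = np.empty(len(orders))
    records: dict[int, list[CombinationRecord]] = {}
    for k, i in enumerate(orders):
        combos = sample_combinations(cm.n_sites, int(i), n_samples, rng)
        shared = shared_counts(cm, combos).astype(float)
        if normalization == "raw":
            vals = shared
        else:
            combo_rich = rich[combos]
            denom = (
                combo_rich.mean(axis=1)
                if normalization == "sorensen"
                else combo_rich.min(axis=1)
            ).astype(float)
            vals = np.divide(shared, denom, out=np.zeros_like(shared), where=denom > 0)
        zeta[k] = vals.mean()
        sd[k] = vals.std(ddof=1) if len(vals) > 1 else 0.0
        if keep_records:
            records[int(i)] = records_for_combinations(cm, combos)
    return ZetaDecline(orders, zeta, sd, "montecarlo", normalization, records)
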