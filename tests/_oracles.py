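"""Independent brute-force reference implementations used only by tests.

These deliberately favour clarity over speed: explicit loops over site or
species combinations, no shared code with the package implementations.
"""

from itertools import combinations

import numpy as np


def zeta_enumeration(incidence: np.ndarray, order: int) -> float:
    """Mean shared-species count over every combination of ``order`` sites."""
    n_sites = incidence.shape[0]
    totals = []
    for combo in combinations(range(n_sites), order):
        shared = 0
        for j in range(incidence.shape[1]):
            if all(incidence[i, j] for i in combo):
                shared += 1
        totals.append(shared)
    return float(np.mean(totals))


def c_score_brute(incidence: np.ndarray) -> float:
    """Mean checkerboard unit over species pairs, plain double loop."""
    occ = incidence.sum(axis=0)
    cols = [j for j in range(incidence.shape[1]) if occ[j] > 0]
    units = []
    for a, b in combinations(cols, 2):
        shared = 0
        for i in range(incidence.shape[0]):
            if incidence[i, a] and incidence[i, b]:
                shared += 1
        ra, rb = occ[a], occ[b]
        units.append((ra - shared) * (rb - shared) / (ra * rb))
    return float(np.mean(units))


def nodf_brute(incidence: np.ndarray) -> float:
    """NODF by definition: paired overlap over row and column pairs with
    strictly decreasing marginal totals, averaged over all pairs."""

    def axis_terms(mat):
        fills = mat.sum(axis=1)
        terms = []
        for i, j in combinations(range(mat.shape[0]), 2):
            if fills[i] == fills[j]:
                terms.append(0.0)
                continue
            hi, lo = (i, j) if fills[i] > fills[j] else (j, i)
            if fills[lo] == 0:
                terms.append(0.0)
                continue
            overlap = sum(
                1 for k in range(mat.shape[1]) if mat[hi, k] and mat[lo, k]
            )
            terms.append(100.0 * overlap / fills[lo])
        return terms

    mat = incidence.astype(bool)
    terms = axis_terms(mat) + axis_terms(mat.T)
    return float(np.sum(terms) / len(terms))
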