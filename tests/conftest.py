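"""Shared fixtures: a hand-checkable toy community and its site table."""

import numpy as np
import pandas as pd
import pytest

from zetascape import CommunityMatrix, SiteTable


@pytest.fixture
def toy_matrix() -> CommunityMatrix:
    """3 sites x 3 species with occupancies (3, 2, 1).

    Hand-computed reference values:
      zeta_1 = 2, zeta_2 = 4/3, zeta_3 = 1;
      retention rates 2/3 (order 2) and 3/4 (order 3);
      pair (A, B): shared 2, Sorensen 0.8, Simpson 1.0;
      gamma = 3, mean alpha = 2, Whittaker beta = 1.5.
    """
    inc = np.array(
        [
            [1, 1, 1],  # site A: richness 3
            [1, 1, 0],  # site B: richness 2
            [1, 0, 0],  # site C: richness 1
        ]
    )
    return CommunityMatrix(
        sites=["A", "B", "C"],
        species=["sp1", "sp2", "sp3"],
        incidence=inc,
        category={"sp1": "NON_E", "sp2": "NE", "sp3": "PE"},
    )


@pytest.fixture
def toy_sites() -> SiteTable:
    return SiteTable(
        pd.DataFrame(
            {
                "x": [0.0, 10.0, 0.0],
                "y": [0.0, 0.0, 10.0],
                "elevation": [100.0, 300.0, 600.0],
                "rain": [400.0, 500.0, 800.0],
            },
            index=["A", "B", "C"],
        )
    )


def random_community(
    rng: np.random.Generator,
    n_sites: int,
    n_species: int,
    p_low: float = 0.2,
    p_high: float = 0.8,
) -> CommunityMatrix:
    """Random binary community with one uniform occurrence probability."""
    p = rng.uniform(p_low, p_high)
    inc = (rng.random((n_sites, n_species)) < p).astype(np.int8)
    return CommunityMatrix(
        sites=[f"s{i}" for i in range(n_sites)],
        species=[f"x{j}" for j in range(n_species)],
        incidence=inc,
    )
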