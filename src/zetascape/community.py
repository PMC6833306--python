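"""Data model and I/O for site-by-species incidence matrices and site attributes.

The package analyses binary incidence data (1 = species recorded in a site)
for an island flora partitioned into three distribution categories:
non-endemics (``NON_E``), single-island neo-endemics (``NE``) and single-island
palaeo-endemics (``PE``).  Every downstream statistic consumes the two
containers defined here.

File dialect: comma-delimited UTF-8; the incidence file has a leading site-id
column and one 0/1 column per species; the category file maps species id to
label; the site table has one row per site with planar coordinates in km.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Closed set of species-category labels.
CATEGORIES = ("NON_E", "NE", "PE")


class CommunityFormatError(ValueError):
    """Raised when an incidence or category file violates the expected format."""


class CommunityValidationError(ValueError):
    """Raised when parsed data violate a structural invariant."""


@dataclass
class CommunityMatrix:
    """Binary site x species incidence with a category label per species.

    Parameters
    ----------
    sites : list of str
        Ordered site identifiers (rows).
    species : list of str
        Ordered species identifiers (columns).
    incidence : ndarray of shape (n_sites, n_species)
        Binary presence records.
    category : dict
        Mapping species id -> label in :data:`CATEGORIES`.
    """

    sites: list[str]
    species: list[str]
    incidence: np.ndarray
    category: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence)
        if self.incidence.shape != (len(self.sites), len(self.species)):
            raise CommunityValidationError(
                f"incidence shape {self.incidence.shape} does not match "
                f"{len(self.sites)} sites x {len(self.species)} species"
            )
        if not np.isin(self.incidence, (0, 1)).all():
            raise CommunityFormatError("incidence entries must be 0 or 1")
        self.incidence = self.incidence.astype(np.int8)
        if len(set(self.sites)) != len(self.sites):
            raise CommunityValidationError("duplicate site identifiers")
        if len(set(self.species)) != len(self.species):
            raise CommunityValidationError("duplicate species identifiers")
        if self.category:
            missing = [s for s in self.species if s not in self.category]
            if missing:
                raise CommunityValidationError(
                    f"species missing a category: {missing}"
                )
            bad = {s: c for s, c in self.category.items() if c not in CATEGORIES}
            if bad:
                raise CommunityValidationError(
                    f"unknown category labels: {sorted(set(bad.values()))}"
                )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def occupancy(self) -> np.ndarray:
        """Per-species number of occupied sites, in species order."""
        return self.incidence.sum(axis=0).astype(int)

    def richness(self) -> np.ndarray:
        """Per-site species richness, in site order."""
        return self.incidence.sum(axis=1).astype(int)

    def zero_occupancy_species(self) -> list[str]:
        """Species recorded in no site (kept so gamma matches the checklist)."""
        occ = self.occupancy()
        return [sp for sp, o in zip(self.species, occ) if o == 0]

    def subset_by_category(self, label: str) -> "CommunityMatrix":
        """Restrict columns to species carrying ``label``; sites unchanged.

        Sites may become empty of species.  Raises ``ValueError`` for a label
        outside the closed category set.
        """
        if label not in CATEGORIES:
            raise ValueError(f"unknown category {label!r}; expected one of {CATEGORIES}")
        keep = [j for j, sp in enumerate(self.species) if self.category.get(sp) == label]
        species = [self.species[j] for j in keep]
        return CommunityMatrix(
            sites=list(self.sites),
            species=species,
            incidence=self.incidence[:, keep] if keep else np.zeros((self.n_sites, 0), dtype=np.int8),
            category={sp: label for sp in species},
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.incidence, index=self.sites, columns=self.species)


@dataclass
class SiteTable:
    """Per-site coordinates, elevation, and named numeric covariates.

    ``x``/``y`` are planar coordinates in km (projection is the caller's
    responsibility); ``elevation`` is in m; remaining columns of ``data`` are
    covariates (bioclimatic, human pressure, ...).
    """

    data: pd.DataFrame  # index = site ids; columns include x, y, elevation

    REQUIRED = ("x", "y", "elevation")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise CommunityValidationError(f"site table missing columns: {missing}")
        if self.data.index.has_duplicates:
            raise CommunityValidationError("duplicate site identifiers in site table")
        coords = list(zip(self.data["x"], self.data["y"]))
        if len(set(coords)) != len(coords):
            raise CommunityValidationError("coordinate pairs must be unique")
        numeric = self.data.select_dtypes(include=[np.number])
        if not np.isfinite(numeric.to_numpy(dtype=float)).all():
            raise CommunityValidationError("site covariates must be finite")

    @property
    def sites(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def coords(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(dtype=float)

    @property
    def elevation(self) -> np.ndarray:
        return self.data["elevation"].to_numpy(dtype=float)

    def covariate_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("x", "y")]

    def aligned_to(self, cm: CommunityMatrix) -> "SiteTable":
        """Reindex rows to the site order of ``cm`` (all sites must exist)."""
        missing = [s for s in cm.sites if s not in self.data.index]
        if missing:
            raise CommunityValidationError(f"sites absent from site table: {missing}")
        return SiteTable(self.data.loc[cm.sites])


def read_community(matrix_path, categories_path=None) -> CommunityMatrix:
    """Read an incidence CSV (site id column + 0/1 species columns).

    ``categories_path``, if given, is a two-column CSV mapping species to one
    of the labels in :data:`CATEGORIES`.  Row and column order are preserved
    from the files.  A non-binary cell raises :class:`CommunityFormatError`
    naming the offending (row, column); a species without a category raises
    :class:`CommunityValidationError` listing the species.
    """
    df = pd.read_csv(matrix_path, index_col=0)
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise CommunityFormatError(
            f"non-binary cell {values[i, j]!r} at site {df.index[i]!r}, "
            f"species {df.columns[j]!r}"
        )
    category: dict[str, str] = {}
    if categories_path is not None:
        cat = pd.read_csv(categories_path)
        if cat.shape[1] < 2:
            raise CommunityFormatError("category file needs species and label columns")
        category = dict(zip(cat.iloc[:, 0].astype(str), cat.iloc[:, 1].astype(str)))
    return CommunityMatrix(
        sites=[str(s) for s in df.index],
        species=[str(s) for s in df.columns],
        incidence=values,
        category={sp: category[sp] for sp in map(str, df.columns)} if category else {},
    )


def write_community(cm: CommunityMatrix, matrix_path, categories_path=None) -> None:
    """Write the incidence matrix (and optionally the category map) as CSV."""
    cm.to_frame().to_csv(matrix_path, index_label="site")
    if categories_path is not None and cm.category:
        pd.DataFrame(
            {"species": cm.species, "category": [cm.category[s] for s in cm.species]}
        ).to_csv(categories_path, index=False)


def read_site_table(path) -> SiteTable:
    """Read a per-site attribute CSV (site id column, then x, y, elevation, covariates)."""
    return SiteTable(pd.read_csv(path, index_col=0))


def write_site_table(table: SiteTable, path) -> None:
    table.data.to_csv(path, index_label="site")


def occupancy(cm: CommunityMatrix) -> np.ndarray:
    """Per-species site counts (column sums), order matching ``cm.species``."""
    return cm.occupancy()


def subset_by_category(cm: CommunityMatrix, label: str) -> CommunityMatrix:
    """Functional alias for :meth:`CommunityMatrix.subset_by_category`."""
    return cm.subset_by_category(label)
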