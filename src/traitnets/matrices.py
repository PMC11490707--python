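"""Community and trait matrices.

The pipeline starts from two tables: a site x species matrix of
abundances/biomass (or presence/absence) and a species x trait table of
categorical traits. Categorical traits are expanded one-hot into *trait
values* -- one binary column per (trait, level) pair -- and combined with
the community matrix into a site x trait-value matrix of community-weighted
means (CWM): the abundance-weighted proportion of each community carrying
each trait value. Where no site structure exists (fossil occurrence lists),
the species x trait-value matrix is used directly, with species as the
observation rows.

Trait-value columns are pandas MultiIndex ``(trait, level)`` pairs
throughout; flat identifiers use the ``trait:level`` convention on disk.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SiteSpeciesMatrix",
    "TraitTable",
    "TraitValueMatrix",
    "CWMMatrix",
    "expand_traits",
    "compute_cwm",
    "direct_trait_matrix",
    "read_site_species_csv",
    "read_trait_table_csv",
    "write_cwm_csv",
    "read_cwm_csv",
    "flat_ids",
]

SEP = ":"  # flat trait-value id separator: "trait:level"


def flat_ids(columns: pd.MultiIndex) -> list[str]:
    """Flatten (trait, level) column pairs to 'trait:level' strings."""
    return [f"{t}{SEP}{lv}" for t, lv in columns]


def _check_unique(values, what: str) -> None:
    dup = pd.Index(values)[pd.Index(values).duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate {what} identifier(s): {dup}")


@dataclass
class SiteSpeciesMatrix:
    """Site x species abundance/biomass or presence/absence matrix.

    Parameters
    ----------
    values : DataFrame
        Rows = sites, columns = species, cells nonnegative. In
        ``presence`` mode cells must be 0/1.
    mode : {'abundance', 'presence'}
    """

    values: pd.DataFrame
    mode: str = "abundance"

    def __post_init__(self) -> None:
        if self.mode not in ("abundance", "presence"):
            raise ValueError(f"mode must be 'abundance' or 'presence', got {self.mode!r}")
        _check_unique(self.values.index, "site")
        _check_unique(self.values.columns, "species")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("site x species matrix contains NaN or infinite values")
        if (arr < 0).any():
            bad = self.values.index[(arr < 0).any(axis=1)].tolist()
            raise ValueError(f"negative abundances at site(s): {bad}")
        if self.mode == "presence" and not np.isin(arr, (0.0, 1.0)).all():
            raise ValueError("presence mode requires all values in {0, 1}")
        empty = self.values.index[(arr.sum(axis=1) == 0)].tolist()
        if empty:
            raise ValueError(f"empty site row(s) (no species recorded): {empty}")

    @property
    def sites(self) -> list:
        return self.values.index.tolist()

    @property
    def species(self) -> list:
        return self.values.columns.tolist()


@dataclass
class TraitTable:
    """Species x trait table of categorical traits.

    One level per species per trait; missing entries (NaN) are allowed and
    flagged downstream. The first column of the CSV on disk is the species
    identifier.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.empty:
            raise ValueError("trait table is empty")
        _check_unique(self.values.index, "species")
        _check_unique(self.values.columns, "trait")

    @property
    def species(self) -> list:
        return self.values.index.tolist()

    @property
    def traits(self) -> list:
        return self.values.columns.tolist()


@dataclass
class TraitValueMatrix:
    """Species x binary trait-value matrix (one-hot expansion of traits).

    ``values`` has a (trait, level) MultiIndex on columns. For every
    species and every trait with non-missing data, exactly one of the
    trait's level columns is 1.
    """

    values: pd.DataFrame
    missing: dict = field(default_factory=dict)  # trait -> list of species with no data

    @property
    def species(self) -> list:
        return self.values.index.tolist()

    @property
    def trait_values(self) -> pd.MultiIndex:
        return self.values.columns

    @property
    def traits(self) -> list:
        return list(dict.fromkeys(self.values.columns.get_level_values(0)))


@dataclass
class CWMMatrix:
    """Observation x trait-value matrix of community-weighted means.

    Rows are sites (CWM mode) or species (direct / fossil mode); the
    ``observation_unit`` field records which. All values lie in [0, 1] and,
    for each fully observed trait, the trait's level columns sum to 1 per
    row.
    """

    values: pd.DataFrame
    observation_unit: str = "site"  # 'site' or 'species'

    @property
    def observations(self) -> list:
        return self.values.index.tolist()

    @property
    def trait_values(self) -> pd.MultiIndex:
        return self.values.columns


def expand_traits(table: TraitTable) -> TraitValueMatrix:
    """Expand categorical traits to a binary species x trait-value matrix.

    Each trait contributes one 0/1 column per observed level. A species
    missing data for a trait gets all-zero columns for that trait, and the
    (trait, species) pair is recorded in ``missing`` with a logged warning.
    Levels are ordered alphabetically within each trait for reproducible
    column order.
    """
    df = table.values
    blocks = []
    missing: dict[str, list] = {}
    for trait in df.columns:
        col = df[trait]
        levels = sorted(col.dropna().astype(str).unique())
        if not levels:
            raise ValueError(f"trait {trait!r} has no observed levels")
        if len(levels) == 1:
            warnings.warn(
                f"trait {trait!r} has a single level {levels[0]!r}; "
                "its column is constant and will not form network edges",
                stacklevel=2,
            )
        onehot = pd.DataFrame(
            {(trait, lv): (col.astype(str) == lv).astype(np.int8) for lv in levels},
            index=df.index,
        )
        na_species = df.index[col.isna()].tolist()
        if na_species:
            onehot.loc[na_species] = 0
            missing[trait] = na_species
            logger.warning(
                "trait %r missing for %d species (all-zero rows): %s",
                trait, len(na_species), na_species[:5],
            )
        blocks.append(onehot)
    values = pd.concat(blocks, axis=1)
    values.columns = pd.MultiIndex.from_tuples(values.columns, names=["trait", "level"])
    return TraitValueMatrix(values=values, missing=missing)


def compute_cwm(community: SiteSpeciesMatrix, tvm: TraitValueMatrix) -> CWMMatrix:
    """Community-weighted mean of each trait value at each site.

    CWM(site s, trait value t) = sum_i w_si x_it / sum_i w_si, with w the
    abundance (or 0/1 occupancy in presence mode, giving the proportion of
    present species that carry t). Species missing data for a trait are
    excluded from that trait's denominator only, so CWMs of fully observed
    traits are unaffected (per-trait denominators).
    """
    shared = [sp for sp in community.species if sp in set(tvm.species)]
    n_comm, n_tr = len(community.species), len(tvm.species)
    if not shared:
        raise ValueError("community matrix and trait table share no species")
    if len(shared) < n_comm:
        dropped = sorted(set(community.species) - set(shared))
        warnings.warn(
            f"{len(dropped)} species in the community matrix lack trait data "
            f"and are dropped: {dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            stacklevel=2,
        )
    if len(shared) < n_tr:
        logger.info("%d species in the trait table are absent from the community matrix",
                    n_tr - len(shared))

    W = community.values[shared].to_numpy(dtype=float)          # sites x shared species
    X = tvm.values.loc[shared].to_numpy(dtype=float)            # shared species x trait values
    num = W @ X                                                 # sites x trait values

    # per-trait denominators: total weight over species WITH data for that trait
    denom = np.empty_like(num)
    col_traits = tvm.values.columns.get_level_values(0)
    for trait in dict.fromkeys(col_traits):
        mask = np.ones(len(shared), dtype=bool)
        for j, sp in enumerate(shared):
            if sp in tvm.missing.get(trait, ()):
                mask[j] = False
        d = W[:, mask].sum(axis=1)
        denom[:, col_traits == trait] = d[:, None]

    if (denom == 0).any():
        bad = community.values.index[(denom == 0).any(axis=1)].tolist()
        raise ValueError(
            f"zero total weight for some trait at site(s) {bad}: every species "
            "present there lacks data for that trait"
        )
    cwm = pd.DataFrame(num / denom, index=community.values.index, columns=tvm.values.columns)
    return CWMMatrix(values=cwm, observation_unit="site")


def direct_trait_matrix(tvm: TraitValueMatrix) -> CWMMatrix:
    """Pass the species x trait-value matrix straight to correlation.

    Fossil mode: with no site/transect structure, species themselves are
    the observation rows and trait-value co-occurrence is measured across
    species. Values are identical to the input one-hot matrix.
    """
    if tvm.values.empty:
        raise ValueError("trait-value matrix is empty")
    if len(tvm.species) < 3:
        warnings.warn(
            f"only {len(tvm.species)} species: downstream correlation needs "
            "at least 3 observations",
            stacklevel=2,
        )
    return CWMMatrix(values=tvm.values.astype(float), observation_unit="species")


# ---------------------------------------------------------------- CSV I/O

def read_site_species_csv(path, mode: str = "abundance", delimiter: str = ",") -> SiteSpeciesMatrix:
    """Read a site x species CSV (first column = site id)."""
    df = pd.read_csv(path, index_col=0, sep=delimiter, encoding="utf-8")
    return SiteSpeciesMatrix(values=df, mode=mode)


def read_trait_table_csv(path, delimiter: str = ",") -> TraitTable:
    """Read a species x trait CSV (first column = species id)."""
    df = pd.read_csv(path, index_col=0, sep=delimiter, encoding="utf-8", dtype=str)
    return TraitTable(values=df)


def write_cwm_csv(cwm: CWMMatrix, path) -> None:
    """Write a CWM matrix with flat 'trait:level' column headers.

    A leading comment line declares the orientation (rows = observations).
    """
    out = cwm.values.copy()
    out.columns = flat_ids(cwm.values.columns)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# rows = observations ({cwm.observation_unit}s), "
                 "columns = trait values (trait:level)\n")
        out.to_csv(fh, index_label=cwm.observation_unit)


def read_cwm_csv(path) -> CWMMatrix:
    df = pd.read_csv(path, index_col=0, comment="#")
    unit = df.index.name if df.index.name in ("site", "species") else "site"
    cols = pd.MultiIndex.from_tuples(
        [tuple(c.split(SEP, 1)) for c in df.columns], names=["trait", "level"]
    )
    df.columns = cols
    return CWMMatrix(values=df, observation_unit=unit)
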