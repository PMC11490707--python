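"""Synthetic community and fossil data with planted trait structure.

The generator emulates the two data shapes the method is used on:

* *Modern surveys*: a site x species biomass matrix plus a categorical
  trait table (default shape: 183 species, five traits with 4/4/6/8/5
  levels, sites along an environmental gradient — the shape of a reef-fish
  biomass survey along a tropical-to-temperate coastline).
* *Fossil assemblages*: occurrence lists per time bin plus a trait table
  (default shape: 115 taxa, four traits expanding to 18 trait values),
  with a trait-targeted extinction filter between the bins.

Association between trait values is planted through latent *strategy
blocks* (think r-selected vs K-selected life histories): each species
belongs to a block, each block has a signature level per trait, and a
species picks its block's signature with probability ``rho_in`` (another
block's with ``rho_out``, otherwise uniformly). Site biomass follows a
log-normal scaled by a Gaussian site-block affinity along the gradient,
so sites at either end are dominated by one strategy and the signature
trait values co-vary across sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .matrices import SiteSpeciesMatrix, TraitTable, expand_traits

__all__ = [
    "SyntheticScenario",
    "FossilAssemblages",
    "generate_modern",
    "generate_two_regions",
    "generate_fossil",
    "write_community_csv",
    "write_trait_table_csv",
]

_MODERN_TRAITS = {
    "max_length": 4,
    "pelagic_larval_duration": 4,
    "trophic_level": 6,
    "water_column_position": 8,
    "reproductive_mode": 5,
}
_FOSSIL_TRAITS = {"motility": 4, "tiering": 5, "feeding": 5, "body_size": 4}


@dataclass
class SyntheticScenario:
    """Parameters of a planted-structure community scenario.

    ``rho_in`` is the probability that a species draws its own block's
    signature level for a trait; ``rho_out`` the probability of drawing a
    specific other block's signature (cross-strategy leakage). With
    ``rho_in == rho_out`` block membership is uninformative and the data
    carry no trait structure beyond chance.
    """

    n_species: int = 183
    n_sites: int = 40
    traits: dict = field(default_factory=lambda: dict(_MODERN_TRAITS))
    n_blocks: int = 2
    rho_in: float = 0.85
    rho_out: float = 0.0
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 0.8
    gradient_width: float = 0.4
    baseline_affinity: float = 0.05
    occupancy_min: float = 0.25

    def __post_init__(self) -> None:
        if self.n_species <= 0 or self.n_sites <= 0 or self.n_blocks <= 0:
            raise ValueError("n_species, n_sites and n_blocks must be positive")
        if not self.traits:
            raise ValueError("at least one trait is required")
        if any(k < 2 for k in self.traits.values()):
            raise ValueError("every trait needs at least 2 levels")
        if not (0.0 <= self.rho_out <= self.rho_in <= 1.0):
            raise ValueError("need 0 <= rho_out <= rho_in <= 1")
        if self.rho_in + (self.n_blocks - 1) * self.rho_out > 1.0 + 1e-12:
            raise ValueError("rho_in + (n_blocks-1)*rho_out must not exceed 1")
        if self.lognormal_sigma < 0 or self.gradient_width <= 0:
            raise ValueError("lognormal_sigma >= 0 and gradient_width > 0 required")

    @classmethod
    def fossil_default(cls, **overrides) -> "SyntheticScenario":
        """Scenario shaped like a fossil assemblage (115 taxa, 18 trait values)."""
        base = dict(n_species=115, n_sites=1, traits=dict(_FOSSIL_TRAITS))
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticScenario":
        with open(path, encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        from dataclasses import asdict
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _block_assignments(scenario: SyntheticScenario) -> np.ndarray:
    """Balanced block membership, species i -> block i mod K."""
    return np.arange(scenario.n_species) % scenario.n_blocks


def block_signature(scenario: SyntheticScenario, block: int) -> dict[str, str]:
    """The signature level of each trait for one strategy block."""
    return {
        trait: f"{trait}_v{block % n_levels}"
        for trait, n_levels in scenario.traits.items()
    }


def _draw_trait_table(scenario: SyntheticScenario, blocks: np.ndarray,
                      rng: np.random.Generator) -> TraitTable:
    species = [f"sp{i:04d}" for i in range(scenario.n_species)]
    K = scenario.n_blocks
    data = {}
    for trait, n_levels in scenario.traits.items():
        levels = [f"{trait}_v{j}" for j in range(n_levels)]
        sig = [b % n_levels for b in range(K)]
        # per-block level weights
        weights = np.full((K, n_levels), 0.0)
        leftover = 1.0 - scenario.rho_in - (K - 1) * scenario.rho_out
        weights += leftover / n_levels
        for b in range(K):
            for other in range(K):
                weights[b, sig[other]] += (
                    scenario.rho_in if other == b else scenario.rho_out
                )
        weights = np.clip(weights, 0.0, None)
        weights /= weights.sum(axis=1, keepdims=True)
        choice = np.array([
            rng.choice(n_levels, p=weights[blocks[i]])
            for i in range(scenario.n_species)
        ])
        data[trait] = [levels[c] for c in choice]
    return TraitTable(values=pd.DataFrame(data, index=species))


def generate_modern(scenario: SyntheticScenario, seed: int | None = None
                    ) -> tuple[SiteSpeciesMatrix, TraitTable]:
    """Biomass survey along an environmental gradient, plus a trait table.

    Sites sit at evenly spaced gradient positions in [0, 1]; blocks have
    evenly spaced gradient optima, and a species' expected biomass at a
    site is log-normal scaled by the Gaussian affinity between the site
    position and its block optimum. Occupancy (whether a species occurs
    at all) follows the same affinity, bounded below by
    ``occupancy_min``.
    """
    rng = np.random.default_rng(seed)
    blocks = _block_assignments(scenario)
    table = _draw_trait_table(scenario, blocks, rng)

    S, N, K = scenario.n_sites, scenario.n_species, scenario.n_blocks
    g = np.linspace(0.0, 1.0, S) if S > 1 else np.array([0.5])
    optima = np.linspace(0.0, 1.0, K) if K > 1 else np.array([0.5])
    affinity = scenario.baseline_affinity + np.exp(
        -((g[:, None] - optima[None, :]) ** 2) / (2 * scenario.gradient_width**2)
    )  # sites x blocks
    aff_norm = affinity / affinity.max()

    w = affinity[:, blocks]                      # sites x species
    p_occ = np.clip(aff_norm[:, blocks], scenario.occupancy_min, 1.0)
    biomass = (
        rng.lognormal(scenario.lognormal_mu, scenario.lognormal_sigma, size=(S, N))
        * w
        * (rng.random((S, N)) < p_occ)
    )
    # guarantee no empty site: put the single most-affine species back
    empty = biomass.sum(axis=1) == 0
    for s in np.flatnonzero(empty):
        j = int(np.argmax(w[s]))
        biomass[s, j] = rng.lognormal(scenario.lognormal_mu, scenario.lognormal_sigma) * w[s, j]

    sites = [f"site{s:03d}" for s in range(S)]
    community = SiteSpeciesMatrix(
        values=pd.DataFrame(biomass, index=sites, columns=table.species),
        mode="abundance",
    )
    return community, table


def generate_two_regions(scenario: SyntheticScenario, seed: int | None = None
                         ) -> tuple[dict[str, SiteSpeciesMatrix], TraitTable]:
    """Split the gradient into two regional site clusters.

    The lower half of the gradient becomes region 'tropical', the upper
    half 'temperate' (labels are conventional: the point is two site
    clusters dominated by different strategy blocks, the shape needed for
    a two-region bootstrap comparison).
    """
    community, table = generate_modern(scenario, seed=seed)
    half = scenario.n_sites // 2
    regions = {
        "tropical": SiteSpeciesMatrix(values=community.values.iloc[:half], mode=community.mode),
        "temperate": SiteSpeciesMatrix(values=community.values.iloc[half:], mode=community.mode),
    }
    return regions, table


@dataclass
class FossilAssemblages:
    """Pre- and post-extinction occurrence lists with their trait table."""

    pre_species: list
    post_species: list
    trait_table: TraitTable

    def table_for(self, bin_name: str) -> TraitTable:
        sp = {"pre": self.pre_species, "post": self.post_species}[bin_name]
        return TraitTable(values=self.trait_table.values.loc[sp])


def generate_fossil(
    scenario: SyntheticScenario,
    extinction: dict[str, float] | None = None,
    base_survival: float = 1.0,
    seed: int | None = None,
) -> FossilAssemblages:
    """Fossil occurrence lists across a trait-targeted extinction.

    ``extinction`` maps flat trait-value ids (``'trait:level'``) to
    survival probabilities in [0, 1]; a species' survival probability is
    ``base_survival`` times the product of the factors of the trait
    values it carries. Survival 0 for a trait value removes every carrier,
    driving that node out of the post network (the shape of losing an
    entire feeding mode in an extinction event). With all factors 1 the
    post assemblage equals the pre assemblage.
    """
    extinction = extinction or {}
    for key, s in extinction.items():
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"survival probability for {key!r} out of [0, 1]: {s}")
    if not 0.0 <= base_survival <= 1.0:
        raise ValueError(f"base_survival out of [0, 1]: {base_survival}")

    rng = np.random.default_rng(seed)
    blocks = _block_assignments(scenario)
    table = _draw_trait_table(scenario, blocks, rng)

    pre = list(table.species)
    surv = np.full(len(pre), base_survival)
    for i, sp in enumerate(pre):
        for trait in table.traits:
            level = table.values.loc[sp, trait]
            if pd.isna(level):
                continue
            surv[i] *= extinction.get(f"{trait}:{level}", 1.0)
    post = [sp for sp, s_i in zip(pre, surv)
            if (s_i >= 1.0) or (rng.random() < s_i)]
    return FossilAssemblages(pre_species=pre, post_species=post, trait_table=table)


# ---------------------------------------------------------------- writers

def write_community_csv(community: SiteSpeciesMatrix, path) -> None:
    community.values.to_csv(path, index_label="site")


def write_trait_table_csv(table: TraitTable, path) -> None:
    table.values.to_csv(path, index_label="species")
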