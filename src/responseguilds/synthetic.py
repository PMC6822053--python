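"""Synthetic guild-structured communities with known ground truth.

Every downstream stage (synchrony, guild allocation, phylogenetic and
function-score association tests) is testable against communities built
here, where the true guild structure, driver loadings and generating
tree are known.

The interannual-change model: each guild g has a latent yearly
environmental driver e_g(t) ~ N(0, 1) iid, and species i in guild g
changes by

    Delta_i,t = sqrt(rho) * e_g(t) + sqrt(1 - rho) * eps_i,t

so two species in the same guild have expected change-correlation rho
and species in different guilds 0.  In ``brownian_loadings`` mode each
species instead carries a unit-norm loading vector over the K = n_guilds
drivers, evolved by Brownian motion along a pure-birth tree; the
change-correlation of two species then equals the cosine similarity of
their loadings, which shrinks with patristic distance — heritable
response similarity.

Abundance integrates the changes through AR(1) density dependence with
strength phi: x_t = (1 - phi) * x_{t-1} + Delta_t, x_0 = 0.  phi = 0 is
a pure random walk (cumulative sum of changes); larger phi pulls the
log index back toward its long-run mean faster.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .data_io import AbundanceMatrix, TraitTable, TreeSet
from .dynamics import ChangeMatrix

__all__ = [
    "CommunityConfig",
    "GroundTruth",
    "SyntheticCommunity",
    "simulate_changes",
    "integrate_to_abundance",
    "apply_missingness",
    "simulate_true_tree",
    "simulate_trees",
    "simulate_traits",
    "simulate_community",
]


@dataclass(frozen=True)
class CommunityConfig:
    """Knobs of the synthetic community.

    Defaults emulate the UK butterfly study conditions: 54 species
    observed over 39 years (so 38 interannual changes), four response
    guilds of moderate within-guild synchrony, mild density dependence,
    a small fraction of missing species-year cells, and a set of 100
    candidate phylogenies perturbed around one generating tree.
    """

    n_species: int = 54
    n_years: int = 39
    n_guilds: int = 4
    within_guild_rho: float = 0.5
    density_dependence_phi: float = 0.3
    missing_fraction: float = 0.05
    heritability_mode: str = "guild_blocks"  # or "brownian_loadings"
    n_trees: int = 100
    tree_noise: float = 0.1
    seed: int = 0
    start_year: int = 1976
    scenario: str = "dispersed"  # or "clustered"
    families: tuple[str, ...] = ("Brassicaceae", "Caryophyllaceae")
    top_n: int = 18
    visit_prob: float = 0.16

    def __post_init__(self) -> None:
        if not 1 <= self.n_guilds <= self.n_species:
            raise ValueError("need n_species >= n_guilds >= 1")
        if self.n_years < 3:
            raise ValueError("need n_years >= 3")
        if not 0 <= self.within_guild_rho <= 1:
            raise ValueError("within_guild_rho must be in [0, 1]")
        if not 0 <= self.density_dependence_phi < 1:
            raise ValueError("density_dependence_phi must be in [0, 1)")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.heritability_mode not in ("guild_blocks", "brownian_loadings"):
            raise ValueError(f"unknown heritability_mode {self.heritability_mode!r}")
        if self.scenario not in ("dispersed", "clustered"):
            raise ValueError(f"unknown scenario {self.scenario!r}")


@dataclass
class GroundTruth:
    """What the generator knows: guilds, driver loadings, generating tree."""

    guild_of: pd.Series
    loadings: pd.DataFrame | None
    true_tree: dendropy.Tree | None


@dataclass
class SyntheticCommunity:
    """Bundle of all generated inputs plus their ground truth."""

    abundance: AbundanceMatrix
    traits: TraitTable
    trees: TreeSet
    truth: GroundTruth
    changes: ChangeMatrix
    config: CommunityConfig


def _species_names(n: int) -> list[str]:
    return [f"Simulatus sp{i:03d}" for i in range(1, n + 1)]


def _guild_assignment(n_species: int, n_guilds: int) -> np.ndarray:
    """Contiguous, near-equal guild blocks (guild labels 1..G)."""
    sizes = np.full(n_guilds, n_species // n_guilds)
    sizes[: n_species % n_guilds] += 1
    return np.repeat(np.arange(1, n_guilds + 1), sizes)


def simulate_true_tree(
    n_species: int, seed: int, names: list[str] | None = None
) -> dendropy.Tree:
    """Pure-birth (Yule) tree, unit birth rate, rescaled to height 1."""
    names = list(names or _species_names(n_species))
    rnd = _random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=rnd,
    )
    # names are shuffled onto leaves so that any externally imposed
    # structure over species (e.g. contiguous guild blocks) is
    # independent of the tree topology
    rnd.shuffle(names)
    # the process stops exactly at the n-th speciation, leaving the two
    # youngest tips at zero distance; run time forward by one more
    # exponential waiting period so all pairwise distances are positive
    extra = rnd.expovariate(n_species)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    for leaf, name in zip(tree.leaf_node_iter(), names):
        leaf.taxon.label = name
    height = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= height
    return tree


def _brownian_loadings(
    tree: dendropy.Tree, k: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Evolve a k-vector by Brownian motion along the tree; unit-normalize.

    Root state 0; each branch adds N(0, length * I).  Unit-norm rows make
    the change-correlation of two species exactly the cosine similarity
    of their loadings.
    """
    values: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = np.zeros(k)
        else:
            step = rng.normal(size=k) * np.sqrt(node.edge.length or 0.0)
            values[node] = values[node.parent_node] + step
    rows = {}
    for leaf in tree.leaf_node_iter():
        v = values[leaf]
        norm = np.linalg.norm(v)
        if norm == 0:  # pathological zero-length tree: fall back to random
            v = rng.normal(size=k)
            norm = np.linalg.norm(v)
        rows[leaf.taxon.label] = v / norm
    return pd.DataFrame.from_dict(rows, orient="index")


def simulate_changes(
    config: CommunityConfig,
) -> tuple[ChangeMatrix, GroundTruth]:
    """Draw the species x year interannual-change matrix and its truth.

    Produces ``n_years - 1`` change columns (labelled start_year+1 ...),
    so that integration yields ``n_years`` abundance values.
    """
    rng = np.random.default_rng(config.seed)
    n, t = config.n_species, config.n_years - 1
    names = _species_names(n)
    years = list(range(config.start_year + 1, config.start_year + 1 + t))
    guilds = _guild_assignment(n, config.n_guilds)
    drivers = rng.standard_normal((config.n_guilds, t))

    if config.heritability_mode == "guild_blocks":
        rho = config.within_guild_rho
        noise = rng.standard_normal((n, t))
        delta = np.sqrt(rho) * drivers[guilds - 1] + np.sqrt(1 - rho) * noise
        tree = simulate_true_tree(n, seed=config.seed + 1, names=names)
        loadings = None
    else:
        tree = simulate_true_tree(n, seed=config.seed + 1, names=names)
        loadings = _brownian_loadings(tree, config.n_guilds, rng)
        loadings = loadings.loc[names]
        delta = loadings.to_numpy() @ drivers
        guilds = loadings.to_numpy().argmax(axis=1) + 1

    changes = ChangeMatrix(pd.DataFrame(delta, index=names, columns=years))
    truth = GroundTruth(
        guild_of=pd.Series(guilds, index=names, name="guild"),
        loadings=loadings,
        true_tree=tree,
    )
    return changes, truth


def integrate_to_abundance(
    changes: ChangeMatrix,
    phi: float = 0.0,
    start_year: int | None = None,
) -> AbundanceMatrix:
    """AR(1) integration x_t = (1 - phi) * x_{t-1} + Delta_t with x_0 = 0.

    ``phi`` is the strength of density dependence: phi = 0 gives the
    plain cumulative sum of the changes (no regulation), larger phi
    erodes past abundance faster.  The output gains one leading year
    (the x_0 = 0 baseline).
    """
    if not 0 <= phi < 1:
        raise ValueError("phi must be in [0, 1)")
    delta = changes.data.to_numpy()
    n, t = delta.shape
    x = np.zeros((n, t + 1))
    for j in range(t):
        x[:, j + 1] = (1 - phi) * x[:, j] + delta[:, j]
    first = (start_year if start_year is not None else changes.change_years[0] - 1)
    years = list(range(first, first + t + 1))
    return AbundanceMatrix(pd.DataFrame(x, index=changes.species, columns=years))


def apply_missingness(
    abund: AbundanceMatrix, fraction: float, seed: int
) -> AbundanceMatrix:
    """Blank species-year cells completely at random.

    Each species' first two observations are protected so every series
    stays analyzable (>= 2 observations).
    """
    if fraction == 0:
        return abund
    rng = np.random.default_rng(seed)
    df = abund.data.copy()
    n, t = df.shape
    eligible = np.ones((n, t), dtype=bool)
    eligible[:, :2] = False
    idx = np.argwhere(eligible)
    k = int(round(fraction * n * t))
    k = min(k, len(idx))
    chosen = idx[rng.choice(len(idx), size=k, replace=False)]
    vals = df.to_numpy()
    vals[chosen[:, 0], chosen[:, 1]] = np.nan
    return AbundanceMatrix(pd.DataFrame(vals, index=df.index, columns=df.columns))


def simulate_trees(
    true_tree: dendropy.Tree,
    n_trees: int,
    tree_noise: float,
    seed: int,
) -> TreeSet:
    """A set of trees scattered around one generating tree.

    Each copy keeps the topology and multiplies every branch length by
    an independent lognormal factor with mean 1 (sigma = tree_noise), so
    the expected patristic matrix equals the generating tree's and the
    across-tree average converges to it.  tree_noise = 0 reproduces the
    generating tree exactly.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if tree_noise < 0:
        raise ValueError("tree_noise must be >= 0")
    rng = np.random.default_rng(seed)
    namespace = dendropy.TaxonNamespace()
    trees = dendropy.TreeList(taxon_namespace=namespace)
    newick = true_tree.as_string(schema="newick")
    for _ in range(n_trees):
        t = dendropy.Tree.get(
            data=newick, schema="newick", taxon_namespace=namespace
        )
        if tree_noise > 0:
            s = tree_noise
            for edge in t.preorder_edge_iter():
                if edge.length is not None:
                    factor = np.exp(rng.normal(-0.5 * s * s, s))
                    edge.length *= factor
        trees.append(t)
    return TreeSet(trees)


def simulate_traits(
    truth: GroundTruth,
    config: CommunityConfig,
    seed: int | None = None,
) -> TraitTable:
    """Trait table with ranges matching published UK butterfly inputs.

    O (occupied 10-km squares) and A (mean survey counts) are positive
    integers spanning several orders of magnitude; L (larval length, mm)
    and M (mobility) are lognormal; X visitation flags are Bernoulli per
    plant family; Y (public-survey counts) exists for exactly ``top_n``
    species.

    Scenario "clustered" concentrates the functionally dominant species
    (large O*A, the Y counts and the X flags) inside guild 1, creating a
    positive association between function distances and dynamics
    distances; "dispersed" spreads them at random across guilds, the
    null configuration.
    """
    rng = np.random.default_rng(config.seed + 1000 if seed is None else seed)
    species = list(truth.guild_of.index)
    n = len(species)
    guilds = truth.guild_of.to_numpy()

    if config.scenario == "clustered":
        elite_mask = guilds == 1
    else:
        k = max(int(round(n / max(config.n_guilds, 1))), 1)
        elite_mask = np.zeros(n, dtype=bool)
        elite_mask[rng.choice(n, size=k, replace=False)] = True
    n_elite = int(elite_mask.sum())

    # occupancy/abundance: lognormal with an elite boost of ~30x
    logO = rng.normal(4.5, 1.0, n) + np.where(elite_mask, 2.0, 0.0)
    logA = rng.normal(1.5, 1.0, n) + np.where(elite_mask, 1.5, 0.0)
    O = np.maximum(np.round(np.exp(logO)), 1)
    A = np.maximum(np.round(np.exp(logA)), 1)
    L = np.exp(rng.normal(3.0, 0.35, n))  # ~12-45 mm
    M = np.exp(rng.normal(1.0, 0.6, n))

    Y = np.full(n, np.nan)
    top_n = min(config.top_n, n)
    order = np.concatenate(
        [
            rng.permutation(np.flatnonzero(elite_mask)),
            rng.permutation(np.flatnonzero(~elite_mask)),
        ]
    )
    scored = order[:top_n]
    Y[scored] = np.exp(rng.normal(8.0, 1.0, top_n))

    visits = {}
    for fam in config.families:
        x = (rng.random(n) < config.visit_prob).astype(int)
        if config.scenario == "clustered":
            # concentrate visitation in the elite guild
            x = np.where(
                elite_mask, (rng.random(n) < 0.8).astype(int),
                (rng.random(n) < 0.05).astype(int),
            )
        if x.sum() == 0:  # guarantee the family has at least one visitor
            x[rng.integers(0, n)] = 1
        visits[fam] = x

    traits = pd.DataFrame(
        {"O": O, "A": A, "L": L, "M": M, "Y": Y}, index=species
    )
    # a few missing L and M cells, as in real trait compilations
    for col, frac in (("L", 0.1), ("M", 0.1)):
        k = int(round(frac * n))
        if k:
            miss = rng.choice(n, size=k, replace=False)
            traits.iloc[miss, traits.columns.get_loc(col)] = np.nan
    visits_df = pd.DataFrame(visits, index=species)
    del n_elite
    return TraitTable(traits=traits, visits=visits_df)


def simulate_community(config: CommunityConfig) -> SyntheticCommunity:
    """Generate the full input bundle: abundance CSV-ready matrix, trait
    table, tree set, plus ground truth."""
    ss = np.random.SeedSequence(config.seed)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    changes, truth = simulate_changes(config)
    abund = integrate_to_abundance(
        changes, phi=config.density_dependence_phi, start_year=config.start_year
    )
    abund = apply_missingness(abund, config.missing_fraction, seed=sub[0])
    trees = simulate_trees(
        truth.true_tree, config.n_trees, config.tree_noise, seed=sub[1]
    )
    traits = simulate_traits(truth, config, seed=sub[2])
    return SyntheticCommunity(
        abundance=abund,
        traits=traits,
        trees=trees,
        truth=truth,
        changes=changes,
        config=config,
    )
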