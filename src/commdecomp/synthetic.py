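"""Synthetic metacommunities with a known assembly mechanism.

Every downstream stage (distances, decomposition, spatial predictors,
variation partitioning) is exercised against data whose generating process
is known.  The generator emulates the structure of a mist-net bat survey
across a fragmented landscape: ~15 sites on a plane with a minimum spacing,
spatially autocorrelated environmental predictor columns (landscape
indices), a pure-birth ultrametric phylogeny for ~34 species, binary and
mensural traits with phylogenetic signal grouped into niche axes, and
Poisson count matrices whose structure is shaped by one of four mechanisms:

``filtering``
    species intensities peak where the site environment matches the species
    niche optimum, so species composition turns over along the gradient;
``dispersion_gradient``
    a core clade is abundant everywhere while peripheral-clade species
    scale with a site niche-availability score driven by the environment,
    so trait dispersion (not composition) tracks the gradient;
``spatial_only``
    intensities follow a smooth spatial trend unrelated to the measured
    environment;
``null``
    sites are exchangeable.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError, InputError
from .structure import AbundanceMatrix
from .traits import BINARY, MENSURAL, TraitTable, cophenetic

MECHANISMS = ("filtering", "dispersion_gradient", "spatial_only", "null")

#: landscape-index style names used when the config asks for 9 env columns
LANDSCAPE_NAMES = [
    "pct_forest", "pct_pasture", "mean_patch_size", "patch_density",
    "cover_diversity", "mean_proximity", "nearest_neighbor", "patch_shape",
    "edge_density",
]

#: niche-axis names for the default 7-axis trait design
AXIS_NAMES = [
    "diet", "foraging_location", "foraging_strategy", "roost_type",
    "body_size", "masticatory", "aerodynamic",
]


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic metacommunity scenario.

    Defaults mirror the study design the generator emulates: 15 sites with
    a minimum spacing of ~9% of the landscape extent, 34 species, 27
    attributes in 7 niche axes (4 binary axes, 3 mensural), 9 environmental
    columns, and a broad-scale environmental gradient (range half the
    landscape extent).
    """

    mechanism: str = "null"
    n_sites: int = 15
    n_species: int = 34
    n_axes: int = 7
    attrs_per_axis: list[int] = field(default_factory=lambda: [4, 4, 4, 5, 4, 3, 3])
    env_spatial_range: float = 0.5
    effect_size: float = 2.0
    noise_sd: float = 0.25
    seed: int = 0
    n_env: int = 9
    min_site_distance: float = 0.0875
    overdispersion: float | None = None  # gamma shape; None = pure Poisson
    n_binary_axes: int | None = None     # default: 4 of 7 axes scaled to n_axes

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ConfigurationError(
                f"unknown mechanism {self.mechanism!r}; options: {MECHANISMS}"
            )
        if self.n_sites < 4:
            raise ConfigurationError("n_sites must be at least 4")
        if self.n_species < 3:
            raise ConfigurationError("n_species must be at least 3")
        if len(self.attrs_per_axis) != self.n_axes:
            raise ConfigurationError("attrs_per_axis length must equal n_axes")
        if any(a < 1 for a in self.attrs_per_axis):
            raise ConfigurationError("attrs_per_axis entries must be >= 1")
        if self.effect_size < 0 or self.noise_sd < 0 or self.env_spatial_range < 0:
            raise ConfigurationError(
                "effect_size, noise_sd and env_spatial_range must be nonnegative"
            )
        if self.n_binary_axes is None:
            self.n_binary_axes = max(1, round(4 * self.n_axes / 7))
        if not (0 < self.n_binary_axes < self.n_axes) and self.n_axes > 1:
            self.n_binary_axes = min(max(self.n_binary_axes, 1), self.n_axes - 1)

    @property
    def n_attributes(self) -> int:
        return int(sum(self.attrs_per_axis))


@dataclass
class SyntheticTruth:
    """The generating quantities behind one abundance matrix."""

    mechanism: str
    gradient: pd.Series              # driving environmental gradient per site
    species_optima: pd.Series        # niche optimum per species
    site_niche_breadth: pd.Series | None = None  # availability score per site
    core_species: list[str] | None = None
    intensities: pd.DataFrame | None = None      # expected counts

    def to_json(self, path) -> None:
        out = {
            "mechanism": self.mechanism,
            "gradient": self.gradient.to_dict(),
            "species_optima": self.species_optima.to_dict(),
            "site_niche_breadth": (
                None if self.site_niche_breadth is None
                else self.site_niche_breadth.to_dict()
            ),
            "core_species": self.core_species,
        }
        with open(path, "w") as fh:
            json.dump(out, fh, indent=1)


@dataclass
class SpeciesPool:
    """Trait table plus phylogeny for the synthetic species."""

    traits: TraitTable
    newick: str
    optima: pd.Series          # heritable niche-optimum trait, sd 1
    core_species: list[str]    # trait-compact clade, abundant everywhere
    trait_axis: pd.Series | None = None  # leading functional axis scores


# ---------------------------------------------------------------------------
# Sites and environment
# ---------------------------------------------------------------------------

def _site_coordinates(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform points on the unit square with a minimum-spacing rejection."""
    pts: list[np.ndarray] = []
    min_d = config.min_site_distance
    attempts = 0
    while len(pts) < config.n_sites:
        cand = rng.uniform(0, 1, size=2)
        attempts += 1
        if attempts > 5000:  # relax spacing if the square fills up
            min_d *= 0.8
            attempts = 0
        if all(np.linalg.norm(cand - p) >= min_d for p in pts):
            pts.append(cand)
    return np.vstack(pts)


def generate_sites(config: ScenarioConfig) -> pd.DataFrame:
    """Site table: coordinates plus spatially autocorrelated env columns.

    Each environmental column is one draw from a Gaussian process with
    exponential covariance exp(-d / range) over the site coordinates, plus
    independent Gaussian noise of sd ``noise_sd``.  ``env_spatial_range=0``
    yields i.i.d. columns.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    xy = _site_coordinates(config, rng)
    n = config.n_sites
    if config.env_spatial_range > 0:
        d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
        cov = np.exp(-d / config.env_spatial_range) + 1e-9 * np.eye(n)
        L = np.linalg.cholesky(cov)
    else:
        L = np.eye(n)
    env = L @ rng.standard_normal((n, config.n_env))
    env = env + config.noise_sd * rng.standard_normal((n, config.n_env))
    names = (LANDSCAPE_NAMES if config.n_env == len(LANDSCAPE_NAMES)
             else [f"env_{k + 1}" for k in range(config.n_env)])
    sites = pd.DataFrame(env, columns=names,
                         index=[f"site{idx + 1:02d}" for idx in range(n)])
    sites.insert(0, "x", xy[:, 0])
    sites.insert(1, "y", xy[:, 1])
    sites.index.name = "site_id"
    return sites


# ---------------------------------------------------------------------------
# Species pool: tree and traits
# ---------------------------------------------------------------------------

def _pure_birth_tree(n_species: int, seed: int) -> tuple[str, dendropy.Tree]:
    from dendropy.simulate import treesim

    taxa = dendropy.TaxonNamespace([f"sp{i + 1:02d}" for i in range(n_species)])
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_species,
        taxon_namespace=taxa, rng=random.Random(seed),
    )
    # rescale to unit depth (tree is ultrametric: all tips contemporary)
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    return newick, tree


def _phylo_cov(newick: str, species: list[str]) -> np.ndarray:
    """Brownian covariance on a unit-depth ultrametric tree: V = 1 - D/2."""
    D = cophenetic(newick, species=species).values
    V = 1.0 - D / 2.0
    np.fill_diagonal(V, 1.0)
    return V + 1e-9 * np.eye(len(species))


def _clade_labels(tree: dendropy.Tree, cut_depth: float) -> dict[str, int]:
    """Group tips by their ancestor lineage at the given depth from the root."""
    labels: dict[str, int] = {}
    groups: dict[int, int] = {}
    for leaf in tree.leaf_node_iter():
        node = leaf
        while node.parent_node is not None:
            parent_depth = node.parent_node.distance_from_root()
            if parent_depth < cut_depth:
                break
            node = node.parent_node
        key = id(node)
        groups.setdefault(key, len(groups))
        labels[leaf.taxon.label] = groups[key]
    return labels


def generate_species_pool(config: ScenarioConfig) -> SpeciesPool:
    """Phylogeny plus trait table with phylogenetic signal.

    The tree is pure-birth, ultrametric, with unit depth.  Mensural
    attributes are lognormal transforms of Brownian-motion draws on the
    tree; binary attributes come from a threshold model on a Brownian
    liability (heritability 0.8).  The first body-size attribute is mass,
    the imputation predictor.  A heritable niche-optimum trait (not part of
    the observable table) and the core/peripheral clade split are carried
    along for the abundance generator.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    tree_seed = int(rng.integers(2**31))
    newick, tree = _pure_birth_tree(config.n_species, tree_seed)
    species = [f"sp{i + 1:02d}" for i in range(config.n_species)]
    V = _phylo_cov(newick, species)
    L = np.linalg.cholesky(V)
    n = config.n_species

    axis_names = (AXIS_NAMES if config.n_axes == len(AXIS_NAMES)
                  else [f"axis{k + 1}" for k in range(config.n_axes)])
    binary_axes = set(axis_names[: config.n_binary_axes])

    cols, axes, kinds = {}, {}, {}
    mass_attr = None
    for ax, n_attr in zip(axis_names, config.attrs_per_axis):
        for k in range(n_attr):
            bm = L @ rng.standard_normal(n)
            if ax in binary_axes:
                name = f"{ax}_{k + 1}"
                liab = np.sqrt(0.8) * bm + np.sqrt(0.2) * rng.standard_normal(n)
                thresh = rng.normal(0.0, 0.7)
                cols[name] = (liab > thresh).astype(float)
                kinds[name] = BINARY
            else:
                if (config.n_binary_axes < config.n_axes
                        and ax == axis_names[config.n_binary_axes] and k == 0):
                    name = "mass"
                    vals = np.exp(3.0 + 0.6 * bm)  # grams, ~20 g median
                    mass_attr = name
                else:
                    name = f"{ax}_{k + 1}"
                    vals = np.exp(1.0 + 0.5 * bm)
                cols[name] = vals
                kinds[name] = MENSURAL
            axes[name] = ax
    data = pd.DataFrame(cols, index=species)

    subfamily = pd.Series(_clade_labels(tree, 0.35), name="subfamily").reindex(species)
    genus = pd.Series(_clade_labels(tree, 0.7), name="genus").reindex(species)
    # monotypic genera leave masked categorical cells without a congener
    # donor; merge each with the genus of its nearest relative
    D = cophenetic(newick, species=species).to_frame()
    counts = genus.value_counts()
    for sp in genus.index[genus.map(counts) == 1]:
        others = [s for s in species if genus[s] != genus[sp]]
        genus[sp] = genus[min(others, key=lambda s: (D.loc[sp, s], s))]
    subfamily = "subfam" + subfamily.astype(str)
    genus = "genus" + genus.astype(str)

    traits = TraitTable(data=data, axis=pd.Series(axes), kind=pd.Series(kinds),
                        mass_attr=mass_attr, subfamily=subfamily, genus=genus)

    opt = L @ rng.standard_normal(n)
    opt = (opt - opt.mean()) / opt.std()
    optima = pd.Series(opt, index=species, name="niche_optimum")

    from .structure import species_scores
    from .traits import gower as _gower

    u = species_scores(_gower(traits)).scores
    core = _core_clade_split(tree, u)
    return SpeciesPool(traits=traits, newick=newick, optima=optima,
                       core_species=core, trait_axis=u)


def _core_clade_split(tree: dendropy.Tree, u: pd.Series) -> list[str]:
    """Split the pool into a trait-compact core and a peripheral remainder.

    Among mid-sized clades (1/3 to 2/3 of the species) the split chosen is
    the one whose two sides have the closest means on the leading functional
    axis, and the side with the smaller spread becomes the core.  The
    peripheral species then straddle the core in trait space, so their
    arrival widens the community spread without moving its weighted mean --
    the pure dispersion contrast (in real assemblages the ubiquitous core is
    a few related, functionally similar species, e.g. frugivores).
    """
    m = len(u)
    lo, hi = int(np.ceil(m / 3)), int(np.floor(2 * m / 3))
    candidates = []
    for node in tree.preorder_internal_node_iter():
        tips = sorted(leaf.taxon.label for leaf in node.leaf_iter())
        if lo <= len(tips) <= hi:
            candidates.append(tips)
    if not candidates:  # pathological topology: fall back to an axis split
        order = list(u.sort_values().index)
        candidates = [sorted(order[m // 4: m // 4 + m // 2])]
    best = min(candidates,
               key=lambda tips: abs(u[tips].mean() - u.drop(tips).mean()))
    other = sorted(set(u.index) - set(best))
    return best if u[best].var() <= u[other].var() else other


# ---------------------------------------------------------------------------
# Abundances
# ---------------------------------------------------------------------------

def generate_abundances(
    sites: pd.DataFrame,
    pool: SpeciesPool,
    config: ScenarioConfig,
) -> tuple[AbundanceMatrix, SyntheticTruth]:
    """Poisson counts around mechanism-determined intensities.

    The driving gradient is the first environmental column (standardised).
    Baseline log-abundances are Normal(log 5, 0.8), giving the right-skewed
    rank-abundance profile typical of mist-net samples.  All-zero site rows
    are redrawn.
    """
    if len(sites) != config.n_sites or len(pool.optima) != config.n_species:
        raise InputError("sites/pool dimensions do not match the config")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    species = list(pool.optima.index)
    n, m = config.n_sites, config.n_species

    env_cols = [c for c in sites.columns if c not in ("x", "y")]
    g = sites[env_cols[0]].to_numpy(dtype=float)
    g = (g - g.mean()) / g.std()
    opt = pool.optima.to_numpy(dtype=float)
    beta = rng.normal(np.log(5.0), 0.8, size=m)

    breadth = None
    if config.mechanism == "filtering":
        loglam = beta[None, :] - config.effect_size * (g[:, None] - opt[None, :]) ** 2 / 2.0
        lam = np.exp(loglam)
    elif config.mechanism == "dispersion_gradient":
        avail = expit(config.effect_size * g)
        is_core = np.array([s in pool.core_species for s in species])
        # the core is abundant everywhere (as the dominant frugivore genera
        # are in mist-net samples); peripheral species are sparser and track
        # the availability score, so the weighted mean stays put while the
        # weighted spread follows the gradient
        base = np.where(is_core, np.exp(rng.normal(np.log(8.0), 0.5, size=m)),
                        np.exp(rng.normal(np.log(4.0), 0.5, size=m)))
        lam = base[None, :] * np.where(is_core[None, :], 1.0, avail[:, None])
        breadth = pd.Series(avail, index=sites.index, name="niche_availability")
    elif config.mechanism == "spatial_only":
        # broad spatial trend of the site layout itself (leading eigenvector
        # of the centred connectivity matrix), independent of the env columns
        from .spatial import build_connectivity, mem_basis

        t = mem_basis(build_connectivity(sites)).predictor(0).to_numpy()
        t = (t - t.mean()) / t.std()
        lam = np.exp(beta[None, :] + config.effect_size * t[:, None] * opt[None, :] / 2.0)
    else:  # null
        lam = np.tile(np.exp(beta), (n, 1))

    if config.overdispersion is not None:
        k = float(config.overdispersion)
        lam = lam * rng.gamma(k, 1.0 / k, size=lam.shape)

    counts = rng.poisson(lam)
    for i in range(n):  # no empty communities: redraw offending rows
        tries = 0
        while counts[i].sum() == 0:
            counts[i] = rng.poisson(lam[i])
            tries += 1
            if tries > 100:
                counts[i, int(np.argmax(lam[i]))] = 1
    Y = AbundanceMatrix(
        counts=pd.DataFrame(counts, index=sites.index, columns=species),
        season=None,
    )
    truth = SyntheticTruth(
        mechanism=config.mechanism,
        gradient=pd.Series(g, index=sites.index, name="gradient"),
        species_optima=pool.optima,
        site_niche_breadth=breadth,
        core_species=pool.core_species,
        intensities=pd.DataFrame(lam, index=sites.index, columns=species),
    )
    return Y, truth


# ---------------------------------------------------------------------------
# Missingness injection
# ---------------------------------------------------------------------------

def inject_missing(traits: TraitTable, fraction: float, seed: int) -> TraitTable:
    """Mask exactly round(fraction * n_cells) trait cells uniformly at random.

    The mass attribute is never masked (it is the imputation predictor), a
    draw that would blank out every value of some attribute is an error, and
    masks are redrawn until every masked cell remains imputable (a congener
    with a known value for categorical cells, at least two same-subfamily
    species with known values for mensural cells) when taxonomy labels are
    present -- the missingness emulated here is the kind that was estimated
    or replaced, not irrecoverable gaps.
    """
    if not 0 <= fraction < 1:
        raise ConfigurationError("fraction must be in [0, 1)")
    n_cells = traits.data.size
    k = round(fraction * n_cells)
    if k == 0:
        return traits.copy()
    eligible = [
        (i, j) for j, attr in enumerate(traits.attributes)
        if attr != traits.mass_attr
        for i in range(len(traits.species))
    ]
    if k > len(eligible):
        raise ConfigurationError("fraction masks more cells than are eligible")
    rng = np.random.default_rng(seed)
    for _ in range(200):
        chosen = rng.choice(len(eligible), size=k, replace=False)
        cells = [eligible[idx] for idx in chosen]
        per_attr: dict[int, int] = {}
        for _, j in cells:
            per_attr[j] = per_attr.get(j, 0) + 1
        if any(cnt >= len(traits.species) for cnt in per_attr.values()):
            raise ConfigurationError(
                "fraction would mask every value of some attribute"
            )
        if _mask_imputable(traits, cells):
            out = traits.copy()
            for i, j in cells:
                out.data.iloc[i, j] = np.nan
            return out
    raise ConfigurationError(
        "could not draw an imputable mask; fraction too high for this taxonomy"
    )


def _mask_imputable(traits: TraitTable, cells: list[tuple[int, int]]) -> bool:
    masked = set(cells)
    species = traits.species
    for i, j in cells:
        sp, attr = species[i], traits.attributes[j]
        if traits.kind[attr] == BINARY and traits.genus is not None:
            donors = [
                s for s in traits.genus.index[traits.genus == traits.genus[sp]]
                if s != sp and (species.index(s), j) not in masked
                and not pd.isna(traits.data.loc[s, attr])
            ]
            if not donors:
                return False
        elif traits.kind[attr] == MENSURAL and traits.subfamily is not None:
            donors = [
                s for s in traits.subfamily.index[
                    traits.subfamily == traits.subfamily[sp]]
                if s != sp and (species.index(s), j) not in masked
                and not pd.isna(traits.data.loc[s, attr])
            ]
            if len(donors) < 2:
                return False
    return True


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------

@dataclass
class SimulationBundle:
    config: ScenarioConfig
    sites: pd.DataFrame
    pool: SpeciesPool
    abundance: AbundanceMatrix
    truth: SyntheticTruth


def simulate(config: ScenarioConfig) -> SimulationBundle:
    """Generate sites, species pool and abundances for one scenario."""
    sites = generate_sites(config)
    pool = generate_species_pool(config)
    Y, truth = generate_abundances(sites, pool, config)
    return SimulationBundle(config=config, sites=sites, pool=pool,
                            abundance=Y, truth=truth)


def write_bundle(bundle: SimulationBundle, outdir) -> None:
    """Write a simulated data set as the pipeline's input file formats."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.sites.to_csv(out / "sites.csv")
    bundle.abundance.to_csv(out / "abundance.csv")
    bundle.pool.traits.to_csv(out / "traits.csv")
    (out / "phylogeny.nwk").write_text(bundle.pool.newick + "\n")
    bundle.truth.to_json(out / "truth.json")
    with open(out / "scenario.json", "w") as fh:
        cfg = asdict(bundle.config)
        json.dump(cfg, fh, indent=1)
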