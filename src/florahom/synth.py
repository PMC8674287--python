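"""Synthetic world generator: regions, climates, phylogeny, native floras
with distance-decaying similarity, and climate/administration-driven
naturalizations, with the generating parameters recorded as ground truth.

Native floras are sampled from a thresholded Gaussian random field over
regions.  For each species a latent Gaussian vector Z over regions is drawn
with inter-region correlation chosen, via the bivariate-normal conditional
exceedance probability, so that the expected fraction of shared species
between two regions at great-circle distance d equals exp(-d ln2 / L), where
L is ``decay_scale_km``.  Because the Simpson similarity of two floras of
comparable richness is approximately their shared fraction, L is (by
construction) the halving distance of native similarity, which parameter-
recovery tests verify.  Species climatic niches are Gaussian in the two
latent climate gradients (thermal, moisture) and trim occupancy at the range
edge via a locally raised threshold.

Naturalizations follow the assumed invasion process: a species is introduced
into a non-native region from a donor region of its native range with
probability introduction_rate x exp(-climate_match_weight x climatic
distance to the donor) x admin_boost when the donor and recipient share an
administrative link (same country, or colonial/dependency tie).  The donor
is the nearest same-country native region when one exists, else the nearest
administratively linked one, else the nearest native region -- mirroring the
dominance of within-country and within-empire trade flows.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal, norm
from sklearn.cluster import KMeans

from .checklists import AdminLookup, PresenceData
from .exceptions import DomainError, EmptyInputError
from .geoclim import pairwise_geographic
from .phylo import as_newick, write_tree

logger = logging.getLogger(__name__)


@dataclass
class WorldParams:
    """Generating parameters; the defaults define the package's reference
    study conditions (a scaled-down analogue of a global multi-region
    checklist compilation)."""

    n_regions: int = 200
    n_countries: int = 20
    n_empires: int = 5
    n_species: int = 3000
    decay_scale_km: float = 1800.0  # halving scale of native similarity
    climate_match_weight: float = 1.0  # per latent-climate-distance unit
    admin_boost: float = 5.0  # multiplier for administratively linked pairs
    introduction_rate: float = 0.01  # baseline per species x region probability
    speciation_rate: float = 1.0  # Yule birth rate
    occupancy: float = 0.02  # marginal probability a species occupies a region
    niche_width: float = 2.0  # SD of the Gaussian niche in latent climate units
    island_fraction: float = 0.23
    exclave_fraction: float = 0.4  # regions governed by a spatially remote country
    max_abs_lat: float = 66.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_regions < 2 or self.n_countries < 2 or self.n_species < 2:
            raise DomainError("counts must be >= 2")
        if self.n_countries > self.n_regions:
            raise DomainError("more countries than regions")
        if self.n_empires < 1 or self.n_empires > self.n_countries:
            raise DomainError("n_empires must be in [1, n_countries]")
        if not 0 <= self.introduction_rate <= 1:
            raise DomainError("introduction_rate must be in [0, 1]")
        if self.decay_scale_km <= 0:
            raise DomainError("decay_scale_km must be positive (or inf)")
        if self.admin_boost < 1:
            raise DomainError("admin_boost must be >= 1")
        if self.climate_match_weight < 0:
            raise DomainError("climate_match_weight must be >= 0")
        if not 0 < self.occupancy < 0.5:
            raise DomainError("occupancy must be in (0, 0.5)")
        if self.niche_width <= 0:
            raise DomainError("niche_width must be positive")
        if not 0 <= self.exclave_fraction < 1:
            raise DomainError("exclave_fraction must be in [0, 1)")


@dataclass
class SyntheticWorld:
    regions: pd.DataFrame
    lookup: AdminLookup
    climate: pd.DataFrame
    latents: pd.DataFrame  # region_id, thermal, moisture (z-scaled)
    params: WorldParams

    @property
    def geo_distances(self) -> np.ndarray:
        return pairwise_geographic(
            self.regions["centroid_lon"].to_numpy(float),
            self.regions["centroid_lat"].to_numpy(float),
        )

    @property
    def latent_distances(self) -> np.ndarray:
        X = self.latents[["thermal", "moisture"]].to_numpy(float)
        diff = X[:, None, :] - X[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))


@dataclass
class SyntheticTruth:
    decay_scale_km: float
    climate_match_weight: float
    admin_boost: float
    core_region: dict[str, str] = field(default_factory=dict)
    introductions: list[tuple[str, str, str]] = field(default_factory=list)
    # (species, recipient region, donor region)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), stream)))


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


# ---------------------------------------------------------------------------
# world
# ---------------------------------------------------------------------------


def generate_world(params: WorldParams) -> SyntheticWorld:
    """Regions on the sphere, country/empire groupings and pseudo-bioclim.

    The 19 climate variables derive from two latent gradients: a thermal
    gradient (declining with absolute latitude) driving the temperature
    block, and an independent smooth moisture field driving the (skewed,
    positive) precipitation block, so the leading PCA axes separate
    temperature- and precipitation-related variation.
    """
    params.validate()
    rng = _rng(params.seed, 0)
    n = params.n_regions

    lon = rng.uniform(-180.0, 180.0, size=n)
    lat = np.degrees(
        np.arcsin(rng.uniform(np.sin(np.radians(-params.max_abs_lat)),
                              np.sin(np.radians(params.max_abs_lat)), size=n))
    )
    area = np.exp(rng.normal(np.log(15000.0), 1.5, size=n))
    is_island = rng.random(n) < params.island_fraction

    # spatially coherent countries
    xyz = np.column_stack(
        [
            np.cos(np.radians(lat)) * np.cos(np.radians(lon)),
            np.cos(np.radians(lat)) * np.sin(np.radians(lon)),
            np.sin(np.radians(lat)),
        ]
    )
    km = KMeans(
        n_clusters=params.n_countries,
        n_init=1,
        random_state=int(params.seed % (2**31 - 1)),
    ).fit(xyz)
    country_idx = np.asarray(km.labels_).copy()
    # exclaves: overseas territories and settled remote regions belong to a
    # spatially distant country, as in real administrative checklists
    exclave = rng.random(n) < params.exclave_fraction
    country_idx[exclave] = rng.integers(params.n_countries, size=int(exclave.sum()))
    width = len(str(params.n_countries))
    countries = [f"C{k + 1:0{width}d}" for k in range(params.n_countries)]
    country_codes = [countries[k] for k in country_idx]

    rwidth = len(str(n))
    region_ids = [f"R{i + 1:0{rwidth}d}" for i in range(n)]
    regions = pd.DataFrame(
        {
            "region_id": region_ids,
            "name": [f"Region {i + 1}" for i in range(n)],
            "country_code": country_codes,
            "centroid_lon": lon,
            "centroid_lat": lat,
            "area_km2": area,
            "is_island": is_island,
        }
    )

    # empires: random partition of countries; ties connect empire members
    order = rng.permutation(params.n_countries)
    empire_of = {countries[c]: int(k % params.n_empires) for k, c in enumerate(order)}
    ties = []
    for i, a in enumerate(countries):
        for b in countries[i + 1:]:
            if empire_of[a] == empire_of[b]:
                ties.append((a, b))
    colonial_df = pd.DataFrame(ties, columns=["country_a", "country_b"])
    n_dep = max(1, params.n_countries // 10)
    dep_rows = []
    tied = {frozenset(t) for t in ties}
    attempts = 0
    while len(dep_rows) < n_dep and attempts < 50 * n_dep:
        a, b = rng.choice(params.n_countries, size=2, replace=False)
        pair = frozenset((countries[a], countries[b]))
        if pair not in tied:
            tied.add(pair)
            dep_rows.append((countries[a], countries[b]))
        attempts += 1
    dependencies_df = pd.DataFrame(dep_rows, columns=["country_a", "country_b"])
    lookup = AdminLookup.from_tables(regions, colonial_df, dependencies_df)

    # latent climate gradients
    thermal = _standardize(1.0 - np.abs(lat) / 90.0 + 0.05 * rng.standard_normal(n))
    phi1, phi2 = rng.uniform(0, 2 * np.pi, size=2)
    lon_r, lat_r = np.radians(lon), np.radians(lat)
    moisture = _standardize(
        np.sin(2 * lon_r + phi1)
        + 0.6 * np.cos(3 * lat_r + phi2)
        + 0.15 * rng.standard_normal(n)
    )
    latents = pd.DataFrame(
        {"region_id": region_ids, "thermal": thermal, "moisture": moisture}
    )

    climate = {"region_id": region_ids}
    temp_block = [1, 2, 4, 5, 6, 7, 8, 9, 10, 11]
    precip_block = [12, 13, 14, 15, 16, 17, 18, 19]
    for b in temp_block:
        loading = -0.8 if b in (4, 7) else rng.uniform(0.7, 0.95)
        v = loading * thermal + 0.3 * rng.standard_normal(n)
        climate[f"bio{b}"] = 15.0 + 10.0 * v
    climate["bio3"] = 50.0 + 5.0 * (0.5 * thermal + 0.5 * rng.standard_normal(n))
    for b in precip_block:
        loading = rng.uniform(0.7, 0.95)
        v = loading * moisture + 0.3 * rng.standard_normal(n)
        climate[f"bio{b}"] = 10.0 * np.exp(1.0 + 0.8 * v)  # skewed, positive
    climate_df = pd.DataFrame(climate)[
        ["region_id"] + [f"bio{i}" for i in range(1, 20)]
    ]
    return SyntheticWorld(regions, lookup, climate_df, latents, params)


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------


def species_names(n_species: int) -> list[str]:
    return [f"sp{i + 1:05d}" for i in range(n_species)]


def generate_phylogeny(
    n_species: int, rate: float = 1.0, seed: int = 0
) -> dendropy.Tree:
    """Ultrametric pure-birth (Yule) tree with tips sp00001..spN."""
    if n_species < 2:
        raise DomainError("need at least 2 species")
    if rate <= 0:
        raise DomainError("birth rate must be positive")
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=rate,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=random.Random(int(seed)),
    )
    names = species_names(n_species)
    for leaf, name in zip(tree.leaf_node_iter(), names):
        leaf.taxon.label = name
    return tree


# ---------------------------------------------------------------------------
# native floras
# ---------------------------------------------------------------------------


def _conditional_exceedance_curve(tau: float, rho_grid: np.ndarray) -> np.ndarray:
    """P(Z2 > tau | Z1 > tau) for a standard bivariate normal, per rho."""
    p = norm.sf(tau)
    out = np.empty(rho_grid.size)
    for k, rho in enumerate(rho_grid):
        mvn = multivariate_normal(
            mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]], allow_singular=True
        )
        out[k] = float(mvn.cdf(np.array([-tau, -tau]))) / p
    return out


def _similarity_correlation(
    distances: np.ndarray, decay_scale_km: float, occupancy: float
) -> np.ndarray:
    """Latent-field correlation matrix delivering the target similarity decay."""
    n = distances.shape[0]
    if np.isinf(decay_scale_km):
        return np.eye(n)
    tau = norm.isf(occupancy)
    rho_grid = np.linspace(0.0, 0.9995, 60)
    cond = _conditional_exceedance_curve(tau, rho_grid)
    target = np.exp(-distances * np.log(2) / decay_scale_km)
    target = np.clip(target, cond[0], cond[-1])
    K = np.interp(target.ravel(), cond, rho_grid).reshape(n, n)
    np.fill_diagonal(K, 1.0)
    # nearest positive-semidefinite repair
    w, V = np.linalg.eigh(K)
    if w.min() < 1e-10:
        w = np.clip(w, 1e-10, None)
        K = (V * w) @ V.T
        d = np.sqrt(np.diag(K))
        K = K / np.outer(d, d)
    return K


def generate_native_floras(
    world: SyntheticWorld,
    params: WorldParams | None = None,
    max_retries: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the native presence matrix (regions x species).

    Returns the boolean matrix and the per-species core-region index (the
    region where the species' latent suitability peaks, used as its niche
    center and as the seed of its geographic range).
    """
    params = params or world.params
    params.validate()
    rng = _rng(params.seed, 2)
    n = params.n_regions
    D = world.geo_distances
    K = _similarity_correlation(D, params.decay_scale_km, params.occupancy)
    L = np.linalg.cholesky(K + 1e-9 * np.eye(n))
    tau = norm.isf(params.occupancy)

    # climatic niche: per-region-pair threshold adjustment
    LD2 = world.latent_distances**2
    q = np.exp(-LD2 / (2.0 * params.niche_width**2))
    tau_table = norm.isf(np.clip(params.occupancy * q, 1e-12, 0.5))

    for attempt in range(max_retries):
        Z = rng.standard_normal((params.n_species, n)) @ L.T
        cores = np.argmax(Z, axis=1)
        native = (Z > tau_table[cores, :]).T  # regions x species
        # a species is always native to its core region
        native[cores, np.arange(params.n_species)] = True
        if native.any(axis=1).all():
            return native, cores
        logger.warning(
            "attempt %d produced a region without natives; resampling", attempt + 1
        )
    raise EmptyInputError(
        "could not generate native floras with every region occupied; "
        "increase n_species or occupancy"
    )


# ---------------------------------------------------------------------------
# naturalizations
# ---------------------------------------------------------------------------


def generate_naturalizations(
    world: SyntheticWorld,
    native: np.ndarray,
    cores: np.ndarray,
    params: WorldParams | None = None,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Sample the naturalized presence matrix given native ranges.

    Each species can be introduced from its nearest native region (the
    donor) into any region where it is not native; climate matching and
    administrative links modulate the probability.  Native and naturalized
    matrices never overlap cellwise.
    """
    params = params or world.params
    params.validate()
    rng = _rng(params.seed, 3)
    n, n_species = native.shape
    D = world.geo_distances
    LD = world.latent_distances
    names = species_names(n_species)
    region_ids = list(world.regions["region_id"].astype(str))

    same_country, linked = _admin_pair_masks(world)

    truth = SyntheticTruth(
        decay_scale_km=params.decay_scale_km,
        climate_match_weight=params.climate_match_weight,
        admin_boost=params.admin_boost,
        core_region={names[s]: region_ids[cores[s]] for s in range(n_species)},
    )
    naturalized = np.zeros_like(native)
    if params.introduction_rate == 0:
        return naturalized, truth

    all_regions = np.arange(n)
    for s in range(n_species):
        native_idx = np.flatnonzero(native[:, s])
        if native_idx.size == 0:
            continue
        # donor preference mirrors trade flows: the nearest same-country
        # native region, else the nearest administratively linked one, else
        # simply the nearest native region
        Dsub = D[:, native_idx]
        Ssub = same_country[:, native_idx]
        Lsub = linked[:, native_idx]
        donors = native_idx[np.argmin(Dsub, axis=1)]
        has_linked = Lsub.any(axis=1)
        donors = np.where(
            has_linked,
            native_idx[np.argmin(np.where(Lsub, Dsub, np.inf), axis=1)],
            donors,
        )
        has_same = Ssub.any(axis=1)
        donors = np.where(
            has_same,
            native_idx[np.argmin(np.where(Ssub, Dsub, np.inf), axis=1)],
            donors,
        )
        p = params.introduction_rate * np.exp(
            -params.climate_match_weight * LD[all_regions, donors]
        )
        p = np.where(linked[all_regions, donors], p * params.admin_boost, p)
        p = np.clip(p, 0.0, 1.0)
        p[native_idx] = 0.0
        hits = np.flatnonzero(rng.random(n) < p)
        if hits.size:
            naturalized[hits, s] = True
            truth.introductions.extend(
                (names[s], region_ids[r], region_ids[donors[r]]) for r in hits
            )
    return naturalized, truth


def _admin_pair_masks(world: SyntheticWorld) -> tuple[np.ndarray, np.ndarray]:
    """Boolean region-pair masks: same country, and any administrative link
    (same country, colonial tie or dependency).  Diagonals are True."""
    codes = world.regions["country_code"].to_numpy(str)
    n = codes.size
    same = codes[:, None] == codes[None, :]
    linked = same.copy()
    pair_cache: dict[frozenset, bool] = {}
    for i in range(n):
        for j in range(i + 1, n):
            if not linked[i, j]:
                key = frozenset((codes[i], codes[j]))
                hit = pair_cache.get(key)
                if hit is None:
                    hit = world.lookup.linked_countries(codes[i], codes[j])
                    pair_cache[key] = hit
                linked[i, j] = linked[j, i] = hit
    return same, linked


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    world: SyntheticWorld
    tree: dendropy.Tree
    presence: PresenceData
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the file formats the checklist and climate readers consume."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "regions": outdir / "regions.csv",
            "checklists": outdir / "checklists.csv",
            "colonial_ties": outdir / "colonial_ties.csv",
            "dependencies": outdir / "dependencies.csv",
            "climate": outdir / "climate.csv",
            "tree": outdir / "tree.nwk",
        }
        self.world.regions.to_csv(paths["regions"], index=False)
        self.presence.write_csv(paths["checklists"])
        pd.DataFrame(
            sorted(tuple(sorted(p)) for p in self.world.lookup.colonial_ties),
            columns=["country_a", "country_b"],
        ).to_csv(paths["colonial_ties"], index=False)
        pd.DataFrame(
            sorted(tuple(sorted(p)) for p in self.world.lookup.dependencies),
            columns=["country_a", "country_b"],
        ).to_csv(paths["dependencies"], index=False)
        self.world.climate.to_csv(paths["climate"], index=False)
        write_tree(self.tree, paths["tree"])
        return paths


def generate_dataset(params: WorldParams, with_tree: bool = True) -> SyntheticDataset:
    """Generate a complete, internally consistent synthetic dataset."""
    params.validate()
    world = generate_world(params)
    native, cores = generate_native_floras(world, params)
    naturalized, truth = generate_naturalizations(world, native, cores, params)
    names = species_names(params.n_species)
    keep = (native | naturalized).any(axis=0)
    presence = PresenceData(
        regions=list(world.regions["region_id"].astype(str)),
        species=[s for s, k in zip(names, keep) if k],
        native=native[:, keep],
        naturalized=naturalized[:, keep],
    )
    tree = (
        generate_phylogeny(params.n_species, params.speciation_rate, seed=params.seed + 1)
        if with_tree
        else None
    )
    return SyntheticDataset(world=world, tree=tree, presence=presence, truth=truth)
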