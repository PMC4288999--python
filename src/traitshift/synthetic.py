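"""Synthetic landscapes, species, occurrences, traits and climate scenarios.

Everything downstream — distribution models, biomass weighting, trait
imputation, community-weighted means, regionalization — is exercised on
data generated here with the statistical structure the analysis assumes:

* environmental layers are spatially autocorrelated random fields
  (low-pass-filtered Gaussian white noise) plus categorical patch maps;
* each species has a unimodal (Gaussian) niche over the continuous layers
  and per-code multipliers on the categorical ones;
* field surveys record a species at a sampled site with probability
  increasing in its true abundance, with a 3-level abundance class
  (1 = single individuals, 2 = frequent, 3 = dominant) obtained by
  thresholding normalized true abundance;
* continuous traits evolve by Brownian motion on a phylogeny, with a
  missing-at-random gap mask; categorical traits follow the species' plant
  functional group deterministically;
* a climate scenario is an additive offset per climatic layer.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .abundance import AbundanceSurface
from .grids import CATEGORICAL, CONTINUOUS, EnvStack, ScenarioDelta
from .phylo import phylo_covariance
from .traits import CATEGORICAL_SCHEME, PFGS, WETLAND_TYPES, TraitMatrix

__all__ = [
    "SpeciesTruth",
    "OccurrenceSet",
    "generate_landscape",
    "generate_species",
    "true_abundance",
    "sample_occurrences",
    "generate_tree",
    "simulate_traits",
    "scenario_towards",
    "read_occurrences",
    "write_occurrences",
]

ABUNDANCE_CLASSES = (1, 2, 3)  # single, frequent, dominant


@dataclass
class SpeciesTruth:
    """Ground-truth niche and abundance parameters for one simulated species."""

    species: str
    optima: dict[str, float]
    breadths: dict[str, float]
    cat_multipliers: dict[str, dict[int, float]]
    max_abundance: float
    pfg: str
    wetland_types: tuple[str, ...]

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.breadths.values()):
            raise ValueError("niche breadths must be positive")
        if any(m < 0 for mult in self.cat_multipliers.values() for m in mult.values()):
            raise ValueError("categorical multipliers must be non-negative")
        if self.max_abundance < 0:
            raise ValueError("max abundance must be non-negative")


@dataclass
class OccurrenceSet:
    """Presence records: (species_id, row, col, abundance_class)."""

    records: pd.DataFrame
    shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        required = ["species_id", "row", "col", "abundance_class"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise ValueError(f"occurrence table missing columns {missing}")
        cls = self.records["abundance_class"]
        bad = ~cls.isin(ABUNDANCE_CLASSES)
        if bad.any():
            rows = self.records.index[bad].tolist()
            raise ValueError(f"abundance class outside {{1,2,3}} at rows {rows}")
        if self.shape is not None:
            nr, nc = self.shape
            oob = ((self.records["row"] < 0) | (self.records["row"] >= nr)
                   | (self.records["col"] < 0) | (self.records["col"] >= nc))
            if oob.any():
                raise ValueError(f"cell indices out of grid at rows "
                                 f"{self.records.index[oob].tolist()}")

    def __len__(self) -> int:
        return len(self.records)

    def species_ids(self) -> list[str]:
        return sorted(self.records["species_id"].unique())

    def for_species(self, species: str, abundance_class: int | None = None) -> pd.DataFrame:
        sel = self.records["species_id"] == species
        if abundance_class is not None:
            sel &= self.records["abundance_class"] == abundance_class
        return self.records[sel]


def write_occurrences(occ: OccurrenceSet, path: str) -> None:
    occ.records.to_csv(path, index=False)


def read_occurrences(path: str, shape: tuple[int, int] | None = None) -> OccurrenceSet:
    df = pd.read_csv(path)
    return OccurrenceSet(df, shape=shape)


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    return gaussian_filter(noise, sigma=sigma, mode="reflect")


def generate_landscape(nrows: int, ncols: int, n_continuous: int,
                       n_categorical: int, spatial_correlation_length: float = 5.0,
                       seed: int = 0, n_codes: int = 5,
                       nodata_fraction: float = 0.0,
                       standardize: bool = True,
                       cellsize: float = 500.0) -> EnvStack:
    """Simulate a stack of autocorrelated environmental layers.

    Continuous layers are Gaussian white noise low-pass filtered with a
    Gaussian kernel of width ``spatial_correlation_length`` (cells), then
    standardized to zero mean and unit variance over valid cells (set
    ``standardize=False`` to keep the raw filtered field, whose variance
    shrinks as the correlation length grows).  Categorical layers bin an
    independent smooth field into ``n_codes`` contiguous patch classes
    (codes 1..n_codes).  All continuous layers are flagged climatic.
    """
    if nrows < 2 or ncols < 2:
        raise ValueError("grid must be at least 2x2")
    if spatial_correlation_length <= 0:
        raise ValueError("spatial correlation length must be positive")
    if n_continuous < 0 or n_categorical < 0:
        raise ValueError("layer counts must be non-negative")
    if not 0 <= nodata_fraction < 1:
        raise ValueError("nodata_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    shape = (nrows, ncols)

    mask = np.ones(shape, dtype=bool)
    if nodata_fraction > 0:
        aux = _smooth_field(rng, shape, spatial_correlation_length)
        cut = np.quantile(aux, nodata_fraction)
        mask = aux >= cut

    layers: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}
    code_sets: dict[str, tuple[int, ...]] = {}
    for i in range(n_continuous):
        f = _smooth_field(rng, shape, spatial_correlation_length)
        if standardize:
            mu, sd = f[mask].mean(), f[mask].std()
            f = (f - mu) / sd if sd > 1e-12 else f - mu
        name = f"clim{i + 1}"
        layers[name] = f
        kinds[name] = CONTINUOUS
    for i in range(n_categorical):
        f = _smooth_field(rng, shape, spatial_correlation_length)
        edges = np.quantile(f[mask], np.linspace(0, 1, n_codes + 1)[1:-1])
        codes = np.digitize(f, edges) + 1  # 1..n_codes
        name = f"soil{i + 1}"
        layers[name] = codes
        kinds[name] = CATEGORICAL
        code_sets[name] = tuple(range(1, n_codes + 1))
    climatic = frozenset(n for n, k in kinds.items() if k == CONTINUOUS)
    return EnvStack(layers=layers, kinds=kinds, mask=mask, climatic=climatic,
                    cellsize=cellsize, code_sets=code_sets)


# ---------------------------------------------------------------------------
# Species and abundance
# ---------------------------------------------------------------------------

def generate_species(env: EnvStack, n_species: int,
                     pfg_scheme: tuple[str, ...] = PFGS,
                     seed: int = 0,
                     wetland_types: tuple[str, ...] = WETLAND_TYPES,
                     breadth_range: tuple[float, float] = (0.5, 1.5),
                     max_abundance_range: tuple[float, float] = (1.0, 10.0),
                     ) -> list[SpeciesTruth]:
    """Draw ground-truth species with Gaussian niches over the landscape.

    Niche optima are uniform within the observed range of each continuous
    layer; breadths are uniform multiples of the layer's standard deviation.
    The first ``len(pfg_scheme)`` species cycle through the PFG scheme so
    every group is represented whenever ``n_species >= len(pfg_scheme)``.
    """
    if n_species < 1:
        raise ValueError("need at least one species")
    if env.n_valid == 0:
        raise ValueError("environment has no valid cells")
    rng = np.random.default_rng(seed)
    cont = env.layer_names(CONTINUOUS)
    cat = env.layer_names(CATEGORICAL)
    ranges = {n: (env.layers[n][env.mask].min(), env.layers[n][env.mask].max())
              for n in cont}
    sds = {n: max(env.layers[n][env.mask].std(), 1e-6) for n in cont}
    out = []
    for i in range(n_species):
        pfg = pfg_scheme[i % len(pfg_scheme)] if i < len(pfg_scheme) \
            else pfg_scheme[rng.integers(len(pfg_scheme))]
        optima = {n: float(rng.uniform(*ranges[n])) for n in cont}
        breadths = {n: float(rng.uniform(*breadth_range) * sds[n]) for n in cont}
        mults = {n: {int(c): float(rng.uniform(0.25, 1.75))
                     for c in env.code_sets.get(n, ())} for n in cat}
        k = int(rng.integers(1, min(2, len(wetland_types)) + 1))
        wl = tuple(sorted(rng.choice(wetland_types, size=k, replace=False).tolist()))
        out.append(SpeciesTruth(
            species=f"sp{i + 1:03d}", optima=optima, breadths=breadths,
            cat_multipliers=mults,
            max_abundance=float(rng.uniform(*max_abundance_range)),
            pfg=pfg, wetland_types=wl))
    return out


def true_abundance(species: SpeciesTruth, env: EnvStack) -> AbundanceSurface:
    """Deterministic true abundance: Gaussian niche product times multipliers."""
    missing = [n for n in list(species.optima) + list(species.cat_multipliers)
               if n not in env.layers]
    if missing:
        raise KeyError(f"environment lacks layers {missing}")
    A = np.full(env.shape, float(species.max_abundance))
    for name, opt in species.optima.items():
        z = (env.layers[name] - opt) / species.breadths[name]
        A = A * np.exp(-0.5 * z * z)
    for name, mults in species.cat_multipliers.items():
        codes = env.layers[name]
        factor = np.ones(env.shape)
        for code, m in mults.items():
            factor[codes == code] = m
        A = A * factor
    A = np.where(env.mask, A, np.nan)
    return AbundanceSurface(species=species.species, values=A)


def sample_occurrences(truth: list[SpeciesTruth], env: EnvStack, n_sites: int,
                       class_thresholds: tuple[float, float] = (0.1, 0.5),
                       seed: int = 0,
                       detection: float | str = "proportional",
                       ) -> OccurrenceSet:
    """Survey ``n_sites`` cells and record detected species with a class.

    Sites are drawn without replacement from valid cells.  A species present
    at a site (normalized abundance a = A / max_abundance > 0) is recorded
    with probability a (``detection="proportional"``) or a fixed probability
    (``detection=<float>``); its class is 3 if a > t2, 2 if a > t1, else 1.
    """
    t1, t2 = class_thresholds
    if not t1 < t2:
        raise ValueError(f"class thresholds must satisfy t1 < t2, got {t1}, {t2}")
    valid = env.valid_indices()
    if n_sites > len(valid):
        raise ValueError(f"n_sites={n_sites} exceeds {len(valid)} valid cells")
    rng = np.random.default_rng(seed)
    sites = rng.choice(valid, size=n_sites, replace=False)
    rows_idx, cols_idx = np.unravel_index(sites, env.shape)
    records = []
    for sp in truth:
        A = true_abundance(sp, env).values
        a = A[rows_idx, cols_idx] / sp.max_abundance if sp.max_abundance > 0 \
            else np.zeros(n_sites)
        if detection == "proportional":
            p = a
        else:
            p = np.where(a > 0, float(detection), 0.0)
        hit = rng.random(n_sites) < p
        cls = np.where(a > t2, 3, np.where(a > t1, 2, 1))
        for r, c, k in zip(rows_idx[hit], cols_idx[hit], cls[hit]):
            records.append((sp.species, int(r), int(c), int(k)))
    df = pd.DataFrame(records, columns=["species_id", "row", "col", "abundance_class"])
    return OccurrenceSet(df, shape=env.shape)


# ---------------------------------------------------------------------------
# Phylogeny and traits
# ---------------------------------------------------------------------------

def generate_tree(species_ids: list[str], seed: int = 0,
                  min_branch: float = 0.01) -> dendropy.Tree:
    """Random birth-death phylogeny over the given species ids.

    Branch lengths are floored at ``min_branch`` so that no two tips are
    numerically indistinguishable (a pure-birth process can leave terminal
    branches arbitrarily close to zero, making the tip covariance matrix
    singular).
    """
    if len(species_ids) < 2:
        raise ValueError("need at least 2 species for a tree")
    from dendropy.simulate import treesim
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0,
        num_extant_tips=len(species_ids),
        rng=random.Random(seed))
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < min_branch:
            edge.length = min_branch
    for leaf, sid in zip(tree.leaf_node_iter(), species_ids):
        leaf.taxon.label = sid
    return tree


def simulate_traits(tree: dendropy.Tree, n_continuous_traits: int = 3,
                    sigma2: float = 1.0, root_state: float = 0.0,
                    missing_fraction: float = 0.1, seed: int = 0,
                    pfg: pd.Series | None = None,
                    trait_names: tuple[str, ...] | None = None,
                    lognormal: bool = False) -> TraitMatrix:
    """Simulate continuous traits by Brownian motion on the tree.

    Tip values are multivariate normal with mean ``root_state`` and
    covariance ``sigma2 * C`` (C = shared path lengths); with
    ``lognormal=True`` the BM runs on the log scale and values are
    exponentiated (size-like traits).  A fraction of entries per trait is
    masked missing uniformly at random (at least 2 observed tips are always
    kept).  If ``pfg`` is given, categorical traits are added per PFG from
    the declared scheme.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if not 0 <= missing_fraction < 1:
        raise ValueError("missing_fraction must be in [0, 1)")
    C, labels = phylo_covariance(tree)
    n = len(labels)
    if n < 2:
        raise ValueError("tree must have at least 2 tips")
    rng = np.random.default_rng(seed)
    # Cholesky with jitter: C can be singular for star-like trees with 0 depth
    jitter = 1e-12 * max(np.trace(C) / n, 1.0)
    L = np.linalg.cholesky(sigma2 * C + jitter * np.eye(n))
    if trait_names is None:
        base = ("SLA", "CH", "RD")
        trait_names = tuple(base[i] if i < 3 else f"trait{i + 1}"
                            for i in range(n_continuous_traits))
    data = {}
    for name in trait_names:
        x = root_state + L @ rng.standard_normal(n)
        data[name] = np.exp(x) if lognormal else x
    df = pd.DataFrame(data, index=pd.Index(labels, name="species_id"))
    n_missing = int(np.floor(missing_fraction * n))
    n_missing = min(n_missing, n - 2)  # keep >= 2 observed per trait
    for name in trait_names:
        if n_missing > 0:
            idx = rng.choice(n, size=n_missing, replace=False)
            df.iloc[idx, df.columns.get_loc(name)] = np.nan
    kinds = {name: "continuous" for name in trait_names}
    if pfg is not None:
        pfg = pfg.reindex(labels)
        for trait in ("leaf_persistence", "clonality", "mycorrhiza"):
            df[trait] = [CATEGORICAL_SCHEME.get(g, {}).get(trait, np.nan)
                         for g in pfg]
            kinds[trait] = "categorical"
    else:
        pfg = pd.Series(index=df.index, dtype=object)
    return TraitMatrix(df, kinds, pfg)


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

def scenario_towards(env: EnvStack, truths: list[SpeciesTruth],
                     strength: float = 1.0,
                     layers: list[str] | None = None) -> ScenarioDelta:
    """Build a scenario shifting each climatic layer toward given species' optima.

    The offset per layer is ``strength * (mean optimum - current mean)``;
    useful for constructing experiments where a chosen set of species is
    known to gain suitability.
    """
    if not truths:
        raise ValueError("need at least one species to aim at")
    names = layers if layers is not None else sorted(env.climatic)
    offsets = {}
    for name in names:
        cur = float(env.layers[name][env.mask].mean())
        target = float(np.mean([t.optima[name] for t in truths]))
        offsets[name] = strength * (target - cur)
    return ScenarioDelta(offsets=offsets)
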