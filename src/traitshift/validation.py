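"""Self-contained recovery experiments on synthetic ground truth.

Each function builds a synthetic dataset with a known answer, runs the
relevant part of the pipeline, and returns the measured quantity: niche
recovery of the maximum-entropy models, a constructed-sign end-to-end
experiment for community-weighted SLA change, K-means region recovery, and
Brownian-motion rate recovery.  They are deterministic given their seed and
small enough to run in seconds to minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import community as cw
from . import maxent
from .abundance import relative_biomass, weighted_abundance
from .grids import ScenarioDelta, apply_scenario
from .phylo import fit_bm, phylo_covariance
from .regions import kmeans, relabel_by_size
from .synthetic import (SpeciesTruth, generate_landscape,
                        generate_tree, sample_occurrences, true_abundance)

__all__ = [
    "gaussian_niche_instance",
    "implied_optimum",
    "niche_recovery",
    "sign_experiment",
    "region_recovery_experiment",
    "sigma2_recovery",
]


def gaussian_niche_instance(seed: int, *, n_presences: int = 200,
                            nrows: int = 40, ncols: int = 40):
    """One species with a 1-D Gaussian niche and suitability-biased presences.

    Returns ``(env, truth, presence_rows)`` where the rows index the feature
    matrix built from the single-layer stack.
    """
    env = generate_landscape(nrows, ncols, 1, 0, spatial_correlation_length=3,
                             seed=seed)
    rng = np.random.default_rng(seed + 10_000)
    layer = env.layers["clim1"]
    opt = float(rng.uniform(np.quantile(layer, 0.2), np.quantile(layer, 0.8)))
    breadth = float(rng.uniform(0.6, 1.2))
    truth = SpeciesTruth(species="sp", optima={"clim1": opt},
                         breadths={"clim1": breadth}, cat_multipliers={},
                         max_abundance=1.0, pfg="graminoid",
                         wetland_types=("fen",))
    A = true_abundance(truth, env).values
    cells = env.valid_indices()
    p = A.ravel()[cells]
    p = p / p.sum()
    rows = rng.choice(len(cells), size=n_presences, replace=True, p=p)
    return env, truth, rows


def implied_optimum(model: maxent.MaxentModel) -> tuple[float, float]:
    """Niche optimum implied by a linear+quadratic single-layer model.

    Undoes the per-feature standardization; returns ``(optimum, curvature)``
    on the layer's own scale, with NaN optimum if the response is not
    hump-shaped (non-negative curvature).
    """
    by_kind = {kind: i for i, (_, kind, _) in enumerate(model.defs)}
    lam1 = model.lambdas[by_kind["linear"]] / model.sds[by_kind["linear"]]
    lam2 = model.lambdas[by_kind["quadratic"]] / model.sds[by_kind["quadratic"]]
    if lam2 >= 0:
        return np.nan, float(lam2)
    return float(-lam1 / (2 * lam2)), float(lam2)


def niche_recovery(n_replicates: int = 100, n_presences: int = 200,
                   beta: float | None = None, seed: int = 0) -> float:
    """Fraction of replicates whose fitted niche recovers the simulated one.

    Success = negative quadratic weight AND implied optimum within half a
    breadth of the true optimum.  By default the L1 penalty follows the
    usual sample-size scaling ``beta = 1 / sqrt(n_presences)`` (heavier
    shrinkage at this sample size visibly biases the implied optimum).
    """
    if beta is None:
        beta = 1.0 / np.sqrt(n_presences)
    hits = 0
    for rep in range(n_replicates):
        env, truth, rows = gaussian_niche_instance(seed + rep,
                                                   n_presences=n_presences)
        fm = maxent.build_features(env)
        model = maxent.fit(fm, rows, beta=beta)
        opt, lam2 = implied_optimum(model)
        if lam2 < 0 and abs(opt - truth.optima["clim1"]) < 0.5 * truth.breadths["clim1"]:
            hits += 1
    return hits / n_replicates


@dataclass
class SignExperimentResult:
    fraction_positive: float
    n_cells: int
    n_species_fitted: int


def sign_experiment(nrows: int = 32, ncols: int = 32, n_species: int = 20,
                    shift: float = 0.75, seed: int = 0) -> SignExperimentResult:
    """Constructed-sign end-to-end run: high-SLA species gain suitability.

    SLA is tied affinely to each species' niche optimum on the single
    climatic layer, and the scenario shifts that layer upward.  Species
    optima are spaced evenly across the central (10th-90th percentile)
    realized range with one common niche breadth: the suitability ratio of
    any two species is then monotone in the layer value, so an upward shift
    favours the higher-optimum (higher-SLA) species in every cell and the
    sign of the community SLA change is known by construction.  (Unequal
    breadths let narrow low-optimum species transiently gain at
    trailing-edge cells, and optima in the rarely-realized tail of the
    layer produce unconstrained fits.)  All heights are equal so biomass
    weighting does not confound the sign.  Returns the fraction of valid
    cells with positive community-weighted SLA change.
    """
    env = generate_landscape(nrows, ncols, 1, 0, spatial_correlation_length=4,
                             seed=seed)
    layer = env.layers["clim1"][env.mask]
    optima = np.linspace(np.quantile(layer, 0.1), np.quantile(layer, 0.9),
                         n_species)
    truths = [SpeciesTruth(species=f"sp{i + 1:03d}",
                           optima={"clim1": float(o)},
                           breadths={"clim1": 1.0}, cat_multipliers={},
                           max_abundance=5.0, pfg="graminoid",
                           wetland_types=("fen",))
              for i, o in enumerate(optima)]
    occ = sample_occurrences(truths, env, n_sites=env.n_valid, seed=seed + 2)
    env_future = apply_scenario(env, ScenarioDelta({"clim1": shift}))
    result = maxent.fit_all(occ, env, scenario_env=env_future,
                            min_presences=5, scale="logistic", seed=seed + 3)
    fitted = sorted({sp for sp, _ in result.models})
    sla = {t.species: 20.0 + 3.0 * t.optima["clim1"] for t in truths}
    heights = {s: 1.0 for s in fitted}
    forms = {s: "non-tree" for s in fitted}
    shares = {}
    for scen in ("current", "scenario"):
        abund = {}
        for s in fitted:
            p1, p2, p3 = result.class_surfaces(s, scen)
            abund[s] = weighted_abundance(p1, p2, p3, species=s, scenario=scen)
        shares[scen], _ = relative_biomass(abund, heights, forms, pool=fitted)
    cur = cw.cwmt(shares["current"], sla, trait="SLA")
    fut = cw.cwmt(shares["scenario"], sla, trait="SLA", scenario="scenario")
    change = cw.delta(cur, fut).values
    ok = ~np.isnan(change)
    return SignExperimentResult(
        fraction_positive=float(np.mean(change[ok] > 0)),
        n_cells=int(ok.sum()), n_species_fitted=len(fitted))


def region_recovery_experiment(k: int = 4, cells_per_region: int = 60,
                               n_species: int = 6, separation: float = 5.0,
                               seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """K well-separated regional change patterns; returns (truth, recovered).

    Region centers are drawn ``separation`` standard deviations apart
    relative to the within-region scatter; recovery is best-of-10 K-means.
    """
    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((k, n_species)) * separation
    truth = np.repeat(np.arange(1, k + 1), cells_per_region)
    X = centers[truth - 1] + rng.normal(0.0, 1.0,
                                        size=(k * cells_per_region, n_species))
    part = relabel_by_size(kmeans(X, k=k, n_init=10, seed=seed + 1))
    return truth, part.labels


def sigma2_recovery(n_tips: int = 64, n_replicates: int = 500,
                    sigma2: float = 1.0, seed: int = 0) -> float:
    """Mean ML Brownian-motion rate estimate over simulated replicates."""
    tree = generate_tree([f"t{i}" for i in range(n_tips)], seed=seed)
    C, _ = phylo_covariance(tree)
    L = np.linalg.cholesky(sigma2 * C + 1e-12 * np.eye(n_tips))
    rng = np.random.default_rng(seed + 1)
    est = [fit_bm(L @ rng.standard_normal(n_tips), C).sigma2
           for _ in range(n_replicates)]
    return float(np.mean(est))
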