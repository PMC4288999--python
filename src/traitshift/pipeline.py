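"""End-to-end orchestration: simulate -> impute -> SDM -> biomass -> CWMT -> regions.

Each stage writes its outputs (plain-text rasters, CSV, YAML, JSON) under
the configured output directory and records them with checksums in a run
manifest; re-running with an identical config reproduces identical
checksums for every deterministic stage.  Any stage error aborts the run
with the failing stage named.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import abundance as ab
from . import grids, maxent, phylo, regions, synthetic
from . import community as cw
from .config import PipelineConfig
from .traits import CONTINUOUS_TRAITS, TraitMatrix, write_traits

__all__ = ["RunManifest", "run_all", "simulate_inputs"]

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config_digest: str
    stages: dict[str, dict[str, str]] = field(default_factory=dict)
    versions: dict[str, str] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def record(self, stage: str, *paths: str) -> None:
        entry = self.stages.setdefault(stage, {})
        for p in paths:
            with open(p, "rb") as fh:
                entry[os.path.basename(p)] = hashlib.sha256(fh.read()).hexdigest()

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _versions() -> dict[str, str]:
    import dendropy
    import scipy
    return {"traitshift": "0.1.0", "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "dendropy": dendropy.__version__}


@dataclass
class SimulatedInputs:
    env: grids.EnvStack
    env_future: grids.EnvStack
    truths: list[synthetic.SpeciesTruth]
    occurrences: synthetic.OccurrenceSet
    tree: object
    traits: TraitMatrix
    delta: grids.ScenarioDelta


def simulate_inputs(cfg: PipelineConfig) -> SimulatedInputs:
    """Generate every input the analysis needs, per the config's seeds."""
    env = synthetic.generate_landscape(
        cfg.nrows, cfg.ncols, cfg.n_continuous, cfg.n_categorical,
        spatial_correlation_length=cfg.correlation_length,
        seed=cfg.seeds["landscape"], n_codes=cfg.n_codes,
        nodata_fraction=cfg.nodata_fraction, cellsize=cfg.cellsize)
    truths = synthetic.generate_species(env, cfg.n_species,
                                        seed=cfg.seeds["species"])
    occ = synthetic.sample_occurrences(
        truths, env, n_sites=min(cfg.n_sites, env.n_valid),
        class_thresholds=cfg.class_thresholds,
        seed=cfg.seeds["occurrences"], detection=cfg.detection)
    tree = synthetic.generate_tree([t.species for t in truths],
                                   seed=cfg.seeds["tree"])
    pfg = pd.Series({t.species: t.pfg for t in truths})
    tm = synthetic.simulate_traits(
        tree, n_continuous_traits=cfg.n_continuous_traits,
        sigma2=cfg.trait_sigma2, root_state=cfg.trait_root_state,
        missing_fraction=cfg.missing_fraction, seed=cfg.seeds["traits"],
        pfg=pfg, lognormal=cfg.trait_lognormal)
    delta = grids.ScenarioDelta(offsets=dict(cfg.scenario))
    env_future = grids.apply_scenario(env, delta)
    return SimulatedInputs(env=env, env_future=env_future, truths=truths,
                           occurrences=occ, tree=tree, traits=tm, delta=delta)


def _write_surface(surface_values: np.ndarray, env: grids.EnvStack,
                   path: str) -> str:
    mask = ~np.isnan(surface_values)
    grids.write_grid(np.nan_to_num(surface_values, nan=0.0), path, mask=mask,
                     cellsize=env.cellsize, origin=env.origin)
    return path


def run_all(cfg: PipelineConfig) -> RunManifest:
    """Execute every stage, writing outputs and a checksum manifest."""
    out = cfg.out_dir
    os.makedirs(out, exist_ok=True)
    manifest = RunManifest(config_digest=cfg.digest(), versions=_versions(),
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    stage = "config"
    try:
        cfg_path = os.path.join(out, "config.yml")
        cfg.to_yaml(cfg_path)
        manifest.record(stage, cfg_path)

        stage = "simulate"
        sim = simulate_inputs(cfg)
        env, env_future = sim.env, sim.env_future
        man_cur = grids.write_stack(env, os.path.join(out, "env_current"))
        man_fut = grids.write_stack(env_future, os.path.join(out, "env_scenario"))
        occ_path = os.path.join(out, "occurrences.csv")
        synthetic.write_occurrences(sim.occurrences, occ_path)
        tree_path = os.path.join(out, "tree.nwk")
        sim.tree.write(path=tree_path, schema="newick",
                       suppress_rooting=True, unquoted_underscores=True)
        traits_path = os.path.join(out, "traits.csv")
        pfg_path = os.path.join(out, "pfg.csv")
        write_traits(sim.traits, traits_path, pfg_path)
        scen_path = os.path.join(out, "scenario.yml")
        grids.write_scenario(sim.delta, scen_path)
        truth_path = os.path.join(out, "species_truths.csv")
        pd.DataFrame([{"species_id": t.species, "pfg": t.pfg,
                       "max_abundance": t.max_abundance,
                       "wetland_types": ";".join(t.wetland_types)}
                      for t in sim.truths]).to_csv(truth_path, index=False)
        manifest.record(stage, man_cur, man_fut, occ_path, tree_path,
                        traits_path, pfg_path, scen_path, truth_path)

        stage = "impute"
        completed, report = phylo.impute(sim.traits, sim.tree,
                                         log_transform=cfg.log_transform)
        imp_path = os.path.join(out, "traits_imputed.csv")
        rep_path = os.path.join(out, "imputation_report.csv")
        write_traits(completed, imp_path)
        report.to_csv(rep_path, index=False)
        manifest.record(stage, imp_path, rep_path)

        stage = "fit-sdm"
        result = maxent.fit_all(sim.occurrences, env, scenario_env=env_future,
                                beta=cfg.beta, min_presences=cfg.min_presences,
                                scale=cfg.sdm_scale, seed=cfg.seeds["sdm"])
        if not result.models:
            raise RuntimeError("no species-class combination had enough records")
        model_dir = os.path.join(out, "models")
        os.makedirs(model_dir, exist_ok=True)
        surf_dir = os.path.join(out, "suitability")
        os.makedirs(surf_dir, exist_ok=True)
        paths = []
        for (sp, cls), model in result.models.items():
            p = os.path.join(model_dir, f"{sp}__c{cls}.json")
            with open(p, "w") as fh:
                fh.write(model.to_json())
            paths.append(p)
            for scen, surf in result.surfaces[(sp, cls)].items():
                sp_path = os.path.join(surf_dir, f"{sp}__c{cls}__{scen}.asc")
                paths.append(_write_surface(surf.values, env, sp_path))
        manifest.record(stage, *paths)

        stage = "abundance"
        weights = ab.ClassWeights(*cfg.weights)
        fitted_species = sorted({sp for sp, _ in result.models})
        abund: dict[str, dict[str, ab.AbundanceSurface]] = {}
        ab_dir = os.path.join(out, "abundance")
        os.makedirs(ab_dir, exist_ok=True)
        paths = []
        for sp in fitted_species:
            abund[sp] = {}
            for scen in ("current", "scenario"):
                p1, p2, p3 = result.class_surfaces(sp, scen)
                surf = ab.weighted_abundance(p1, p2, p3, weights,
                                             convention=cfg.convention,
                                             species=sp, scenario=scen)
                abund[sp][scen] = surf
                paths.append(_write_surface(
                    surf.values, env, os.path.join(ab_dir, f"{sp}__{scen}.asc")))
        manifest.record(stage, *paths)

        stage = "biomass"
        pfg = pd.Series({t.species: t.pfg for t in sim.truths})
        heights = completed.data["CH"].to_dict()
        forms = {s: ("tree" if pfg.get(s) == "tree" else "non-tree")
                 for s in fitted_species}
        vascular = [s for s in fitted_species if pfg.get(s) != "moss"
                    and s in heights and np.isfinite(heights[s])]
        if not vascular:
            raise RuntimeError("no vascular species with canopy height were fitted")
        shares = {}
        for scen in ("current", "scenario"):
            shares[scen], _ = ab.relative_biomass(
                {s: abund[s][scen] for s in vascular}, heights, forms,
                pool=vascular, mode=cfg.allometric_mode)
        sh_dir = os.path.join(out, "biomass_shares")
        os.makedirs(sh_dir, exist_ok=True)
        paths = []
        for scen in ("current", "scenario"):
            for s in vascular:
                paths.append(_write_surface(
                    shares[scen][s], env,
                    os.path.join(sh_dir, f"{s}__{scen}.asc")))
        manifest.record(stage, *paths)

        stage = "regions"
        change = regions.build_change_matrix(shares["current"],
                                             shares["scenario"], pool=vascular)
        k = min(cfg.k_regions, len(np.unique(change.X, axis=0)))
        part = regions.relabel_by_size(
            regions.kmeans(change, k=k, n_init=cfg.n_init,
                           seed=cfg.seeds["kmeans"]))
        labels = part.label_grid()
        reg_path = os.path.join(out, "regions.asc")
        grids.write_grid(labels.astype(float), reg_path, mask=labels > 0,
                         cellsize=env.cellsize, origin=env.origin, nodata=0.0)
        cent_path = os.path.join(out, "region_centroids.csv")
        pd.DataFrame(part.centroids, columns=change.species,
                     index=pd.Index(range(1, part.k + 1), name="region")
                     ).to_csv(cent_path)
        manifest.record(stage, reg_path, cent_path)

        stage = "cwmt"
        membership = {t.species: t.wetland_types for t in sim.truths}
        pools = cw.build_pools(pfg, membership)
        pools = {key: [s for s in pool if s in vascular]
                 for key, pool in pools.items()}
        pools = {key: pool for key, pool in pools.items() if len(pool) >= 2}
        cw_dir = os.path.join(out, "cwmt")
        os.makedirs(cw_dir, exist_ok=True)
        paths, summaries, contribs = [], [], []
        cont_traits = [t for t in CONTINUOUS_TRAITS
                       if t in completed.data.columns]
        cat_traits = completed.categorical_traits()
        for (wt, layer), pool in sorted(pools.items()):
            pool_shares = {scen: {s: shares[scen][s] for s in pool}
                           for scen in ("current", "scenario")}
            # Renormalise the global shares within the pool.
            for scen in pool_shares:
                tot = np.nansum([pool_shares[scen][s] for s in pool], axis=0)
                with np.errstate(invalid="ignore", divide="ignore"):
                    for s in pool:
                        pool_shares[scen][s] = np.where(
                            tot > 0, pool_shares[scen][s] / tot, np.nan)
            for trait in cont_traits:
                vals = completed.data[trait]
                cur = cw.cwmt(pool_shares["current"], vals, trait=trait,
                              layer=layer, wetland_type=wt, scenario="current")
                fut = cw.cwmt(pool_shares["scenario"], vals, trait=trait,
                              layer=layer, wetland_type=wt, scenario="scenario")
                ch = cw.delta(cur, fut)
                for surf, scen in ((cur, "current"), (fut, "scenario"),
                                   (ch, "delta")):
                    paths.append(_write_surface(
                        surf.values, env,
                        os.path.join(cw_dir, f"{wt}__{layer}__{trait}__{scen}.asc")))
                summ = cw.regional_summary(ch.values, labels,
                                           regions=list(range(1, part.k + 1)))
                summ.insert(0, "wetland_type", wt)
                summ.insert(1, "layer", layer)
                summ.insert(2, "trait", trait)
                summaries.append(summ)
                sc = cw.species_contribution(pool_shares["current"],
                                             pool_shares["scenario"], vals,
                                             pool=pool)
                contribs.append(pd.DataFrame({
                    "wetland_type": wt, "layer": layer, "trait": trait,
                    "species_id": sc.index, "score": sc.to_numpy()}))
            for trait in cat_traits:
                levels = completed.data[trait]
                try:
                    cur = cw.categorical_profile(pool_shares["current"], levels,
                                                 trait=trait, layer=layer,
                                                 wetland_type=wt)
                    fut = cw.categorical_profile(pool_shares["scenario"], levels,
                                                 trait=trait, layer=layer,
                                                 wetland_type=wt,
                                                 scenario="scenario",
                                                 levels=cur.levels)
                except ValueError:
                    continue  # every pooled species unknown for this trait
                ch = cw.delta(cur, fut)
                for lv in ch.levels:
                    paths.append(_write_surface(
                        ch.proportions[lv], env,
                        os.path.join(cw_dir,
                                     f"{wt}__{layer}__{trait}-{lv}__delta.asc")))
        summ_path = os.path.join(out, "regional_summaries.csv")
        summ_cols = ["wetland_type", "layer", "trait", "region", "mean", "sd",
                     "n_cells"]
        (pd.concat(summaries, ignore_index=True) if summaries
         else pd.DataFrame(columns=summ_cols)).to_csv(summ_path, index=False)
        contrib_path = os.path.join(out, "species_contributions.csv")
        contrib_cols = ["wetland_type", "layer", "trait", "species_id", "score"]
        (pd.concat(contribs, ignore_index=True) if contribs
         else pd.DataFrame(columns=contrib_cols)).to_csv(contrib_path, index=False)
        manifest.record(stage, *paths, summ_path, contrib_path)
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(os.path.join(out, "manifest.yml"))
    return manifest
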