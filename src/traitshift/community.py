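"""Community-weighted mean traits, categorical profiles and their change.

Under the mass-ratio hypothesis, ecosystem processes are driven by the
community-weighted mean trait (CWMT): the trait value averaged over the
species pool weighted by relative biomass share,

    CWMT(x) = sum_s share_s(x) * t_s.

CWMTs are computed separately per vegetation layer (field, shrub) within
each wetland type (bog, fen, riparian), per grid cell and scenario.
Categorical traits are summarised as per-cell biomass-proportion profiles
over the trait's levels.  Change surfaces (scenario minus current) are
averaged within regions of similar community change, and the contribution
of each species to the change is scored by the standardized mean squared
error incurred when that species is left out and the shares renormalised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CWMTSurface",
    "CategoricalProfile",
    "cwmt",
    "categorical_profile",
    "delta",
    "regional_summary",
    "species_contribution",
    "build_pools",
]

log = logging.getLogger(__name__)

_SHARE_TOL = 1e-6


@dataclass
class CWMTSurface:
    """Per-cell community-weighted mean of one continuous trait."""

    trait: str
    values: np.ndarray
    layer: str = ""
    wetland_type: str = ""
    scenario: str = "current"


@dataclass
class CategoricalProfile:
    """Per-cell biomass proportions over the levels of a categorical trait."""

    trait: str
    levels: tuple[str, ...]
    proportions: dict[str, np.ndarray]
    layer: str = ""
    wetland_type: str = ""
    scenario: str = "current"


def _check_shares(shares: dict[str, np.ndarray]) -> np.ndarray:
    """Validate that shares sum to ~1 cell-wise; returns the valid-cell mask."""
    if not shares:
        raise ValueError("empty species pool")
    total = None
    valid = None
    for arr in shares.values():
        arr = np.asarray(arr, dtype=float)
        v = ~np.isnan(arr)
        valid = v if valid is None else (valid & v)
        total = np.where(v, arr, 0.0) if total is None else total + np.where(v, arr, 0.0)
    if valid.any() and not np.allclose(total[valid], 1.0, atol=_SHARE_TOL):
        raise ValueError("relative biomass shares do not sum to 1 cell-wise")
    return valid


def cwmt(shares: dict[str, np.ndarray], trait_values: dict[str, float] | pd.Series,
         trait: str = "", layer: str = "", wetland_type: str = "",
         scenario: str = "current") -> CWMTSurface:
    """Biomass-share-weighted mean trait surface over a species pool."""
    valid = _check_shares(shares)
    missing = [s for s in shares
               if s not in trait_values or pd.isna(trait_values[s])]
    if missing:
        raise ValueError(f"species without a value for trait {trait!r}: {missing}")
    out = np.zeros(next(iter(shares.values())).shape)
    for s, arr in shares.items():
        out = out + np.where(valid, arr, 0.0) * float(trait_values[s])
    out = np.where(valid, out, np.nan)
    return CWMTSurface(trait=trait, values=out, layer=layer,
                       wetland_type=wetland_type, scenario=scenario)


def categorical_profile(shares: dict[str, np.ndarray],
                        levels_by_species: dict[str, str] | pd.Series,
                        trait: str = "", layer: str = "",
                        wetland_type: str = "", scenario: str = "current",
                        levels: tuple[str, ...] | None = None,
                        ) -> CategoricalProfile:
    """Per-level biomass proportions for one categorical trait.

    Species with an unknown level are excluded and the remaining shares
    renormalised (the excluded count is logged).  Cells where every pooled
    species is unknown (renormaliser zero) are masked.  Levels absent from
    the pool appear with proportion 0 when an explicit level set is given.
    """
    valid = _check_shares(shares)
    known = {s: lv for s, lv in
             ((s, levels_by_species.get(s) if hasattr(levels_by_species, "get")
               else levels_by_species[s]) for s in shares)
             if not pd.isna(lv)}
    n_unknown = len(shares) - len(known)
    if not known:
        raise ValueError(f"no pooled species has a known level for {trait!r}")
    if n_unknown:
        log.info("categorical profile %s: excluded %d species with unknown level",
                 trait, n_unknown)
    if levels is None:
        levels = tuple(sorted(set(known.values())))
    else:
        extra = set(known.values()) - set(levels)
        if extra:
            raise ValueError(f"species levels {sorted(extra)} outside declared set")
    shape = next(iter(shares.values())).shape
    denom = np.zeros(shape)
    for s in known:
        denom += np.where(valid, shares[s], 0.0)
    cell_valid = valid & (denom > 0)
    props = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for lv in levels:
            num = np.zeros(shape)
            for s, slv in known.items():
                if slv == lv:
                    num += np.where(valid, shares[s], 0.0)
            props[lv] = np.where(cell_valid, num / denom, np.nan)
    return CategoricalProfile(trait=trait, levels=levels, proportions=props,
                              layer=layer, wetland_type=wetland_type,
                              scenario=scenario)


def delta(current, future):
    """Change surface (future minus current) for CWMT or categorical profiles.

    Metadata (trait, layer, wetland type) and grids must match; categorical
    level deltas sum to 0 across levels on every valid cell by construction.
    """
    for attr in ("trait", "layer", "wetland_type"):
        if getattr(current, attr) != getattr(future, attr):
            raise ValueError(f"mismatched {attr}: "
                             f"{getattr(current, attr)!r} vs {getattr(future, attr)!r}")
    if isinstance(current, CWMTSurface) and isinstance(future, CWMTSurface):
        if current.values.shape != future.values.shape:
            raise ValueError("grid shape mismatch")
        return CWMTSurface(trait=current.trait,
                           values=future.values - current.values,
                           layer=current.layer, wetland_type=current.wetland_type,
                           scenario="delta")
    if isinstance(current, CategoricalProfile) and isinstance(future, CategoricalProfile):
        if current.levels != future.levels:
            raise ValueError(f"level sets differ: {current.levels} vs {future.levels}")
        props = {}
        for lv in current.levels:
            a, b = current.proportions[lv], future.proportions[lv]
            if a.shape != b.shape:
                raise ValueError("grid shape mismatch")
            props[lv] = b - a
        return CategoricalProfile(trait=current.trait, levels=current.levels,
                                  proportions=props, layer=current.layer,
                                  wetland_type=current.wetland_type,
                                  scenario="delta")
    raise TypeError("current and future must both be CWMTSurface or CategoricalProfile")


def regional_summary(values: np.ndarray, region_labels: np.ndarray,
                     regions: list[int] | None = None) -> pd.DataFrame:
    """Mean, sd (population) and cell count of a surface per region.

    Cells are weighted equally.  Regions with no unmasked cells are reported
    with n_cells = 0 and NaN statistics rather than propagating NaN into the
    other rows.
    """
    values = np.asarray(values, dtype=float)
    region_labels = np.asarray(region_labels)
    if values.shape != region_labels.shape:
        raise ValueError("surface and region grids differ in shape")
    ok = ~np.isnan(values) & (region_labels > 0)
    if regions is None:
        regions = sorted(int(r) for r in np.unique(region_labels[region_labels > 0]))
    rows = []
    for r in regions:
        sel = ok & (region_labels == r)
        n = int(sel.sum())
        if n == 0:
            rows.append({"region": r, "mean": np.nan, "sd": np.nan, "n_cells": 0})
        else:
            v = values[sel]
            rows.append({"region": r, "mean": float(v.mean()),
                         "sd": float(v.std()), "n_cells": n})
    return pd.DataFrame(rows)


def _delta_cwmt(shares_current: dict[str, np.ndarray],
                shares_future: dict[str, np.ndarray],
                trait_values, pool: list[str]) -> np.ndarray:
    cur = cwmt({s: shares_current[s] for s in pool}, trait_values).values
    fut = cwmt({s: shares_future[s] for s in pool}, trait_values).values
    return fut - cur


def species_contribution(shares_current: dict[str, np.ndarray],
                         shares_future: dict[str, np.ndarray],
                         trait_values: dict[str, float] | pd.Series,
                         pool: list[str] | None = None) -> pd.Series:
    """Leave-one-out contribution of each species to the CWMT change.

    For species s the pool is re-shared without s (each remaining share
    divided by 1 - share_s, cells where s held the whole community masked),
    the CWMT change recomputed, and the score is the mean squared deviation
    from the full-pool change standardized by the spatial variance of the
    full-pool change.  A species with zero share everywhere, or whose trait
    equals the CWMT everywhere, scores exactly 0.  Returned sorted
    descending.
    """
    if pool is None:
        pool = sorted(shares_current)
    if len(pool) < 2:
        raise ValueError("contribution needs a pool of at least 2 species")
    full = _delta_cwmt(shares_current, shares_future, trait_values, pool)
    valid_full = ~np.isnan(full)
    var_full = float(np.var(full[valid_full])) if valid_full.any() else 0.0
    scores = {}
    for s in pool:
        rest = [t for t in pool if t != s]
        reduced = []
        for shares in (shares_current, shares_future):
            denom = 1.0 - np.asarray(shares[s], dtype=float)
            with np.errstate(invalid="ignore", divide="ignore"):
                reduced.append({t: np.where(denom > 0, shares[t] / denom, np.nan)
                                for t in rest})
        cur = cwmt(reduced[0], trait_values).values
        fut = cwmt(reduced[1], trait_values).values
        diff = (fut - cur) - full
        ok = ~np.isnan(diff)
        if not ok.any():
            scores[s] = np.nan
            continue
        mse = float(np.mean(diff[ok] ** 2))
        if var_full > 0:
            scores[s] = mse / var_full
        else:
            scores[s] = 0.0 if mse == 0.0 else np.inf
    return pd.Series(scores, name="contribution").sort_values(ascending=False)


def build_pools(pfg: pd.Series, wetland_membership: dict[str, tuple[str, ...]],
                layer_pfgs: dict[str, tuple[str, ...]] | None = None,
                ) -> dict[tuple[str, str], list[str]]:
    """Species pools per (wetland type, vegetation layer).

    The field layer pools pteridophytes, graminoids and herbs; the shrub
    layer pools shrubs.  Mosses (no trait data) and trees (summarised per
    species) never enter a CWMT pool.  A species common to several wetland
    types appears in each of their pools.
    """
    if layer_pfgs is None:
        from .traits import LAYER_PFGS
        layer_pfgs = LAYER_PFGS
    pools: dict[tuple[str, str], list[str]] = {}
    for s, groups in wetland_membership.items():
        g = pfg.get(s)
        for layer, member_pfgs in layer_pfgs.items():
            if g in member_pfgs:
                for wt in groups:
                    pools.setdefault((wt, layer), []).append(s)
    return {k: sorted(v) for k, v in pools.items()}
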