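"""Presence-background maximum-entropy species distribution models.

A minimal Maxent-style estimator: the suitability distribution over
landscape cells is the Gibbs distribution q(x) proportional to
exp(lambda . f(x)) that maximises the L1-penalised log-likelihood of the
presence cells against a background sample,

    L(lambda) = mean_presences lambda.f  -  log sum_background exp(lambda.f)
                + log N_bg  -  beta * sum_j |lambda_j|.

Features are linear and quadratic terms of the continuous layers and one
indicator per categorical code, standardized on the background (hinge,
product and threshold features are deliberately omitted: linear+quadratic
captures unimodal niches).  The objective is concave; it is maximised
exactly by L-BFGS-B after splitting lambda into positive and negative parts,
which makes the penalty smooth.

Output scales: ``raw`` is q(x) normalised to sum to 1 over the background;
``logistic`` is the calibrated transform 1 - exp(-e^r * q(x) * N_bg) with
r the mean of lambda.f over the training presences.

One model is fitted per species per abundance class (single / frequent /
dominant) and projected onto the current and scenario environments.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .grids import CATEGORICAL, CONTINUOUS, EnvStack
from .synthetic import OccurrenceSet

__all__ = [
    "FeatureSpec",
    "FeatureMatrix",
    "MaxentModel",
    "SuitabilitySurface",
    "build_features",
    "fit",
    "project",
    "fit_all",
    "FitAllResult",
]

log = logging.getLogger(__name__)

BACKGROUND_LIMIT = 100_000
BACKGROUND_SAMPLE = 10_000


@dataclass(frozen=True)
class FeatureSpec:
    """Which features to build from which layers."""

    linear: tuple[str, ...]
    quadratic: tuple[str, ...]
    categorical: tuple[str, ...]

    @classmethod
    def default(cls, env: EnvStack) -> "FeatureSpec":
        cont = tuple(env.layer_names(CONTINUOUS))
        return cls(linear=cont, quadratic=cont,
                   categorical=tuple(env.layer_names(CATEGORICAL)))

    def validate(self, env: EnvStack) -> None:
        for name in set(self.linear) | set(self.quadratic) | set(self.categorical):
            if name not in env.layers:
                raise KeyError(f"feature spec references unknown layer {name!r}")
        if not (self.linear or self.quadratic or self.categorical):
            raise ValueError("feature spec declares no features")


def _raw_features(env: EnvStack, spec: FeatureSpec,
                  cells: np.ndarray) -> tuple[np.ndarray, list[tuple]]:
    """Unstandardized feature columns at the given flat cell indices."""
    rows, cols = np.unravel_index(cells, env.shape)
    columns, defs = [], []
    for name in spec.linear:
        columns.append(env.layers[name][rows, cols].astype(float))
        defs.append((name, "linear", None))
    for name in spec.quadratic:
        columns.append(env.layers[name][rows, cols].astype(float) ** 2)
        defs.append((name, "quadratic", None))
    for name in spec.categorical:
        codes = env.code_sets.get(name)
        if codes is None:
            codes = tuple(sorted(np.unique(env.layers[name][env.mask])))
        vals = env.layers[name][rows, cols]
        for code in codes:
            columns.append((vals == code).astype(float))
            defs.append((name, "indicator", int(code)))
    return np.column_stack(columns), defs


@dataclass
class FeatureMatrix:
    """Standardized design matrix over the valid cells of a stack."""

    X: np.ndarray                 # (n_valid_cells, n_features)
    defs: list[tuple]             # (layer, kind, code or None) per column
    means: np.ndarray
    sds: np.ndarray
    cells: np.ndarray             # flat cell index per row, ascending
    background_rows: np.ndarray   # row indices forming the background
    grid_shape: tuple[int, int]

    @property
    def names(self) -> list[str]:
        return [f"{layer}:{kind}" if code is None else f"{layer}:{kind}:{code}"
                for layer, kind, code in self.defs]

    def row_of_cell(self, flat_cells: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.cells, flat_cells)
        ok = (idx < len(self.cells)) & (self.cells[np.minimum(idx, len(self.cells) - 1)]
                                        == flat_cells)
        if not np.all(ok):
            raise KeyError("some cells are not valid cells of the stack")
        return idx


def build_features(env: EnvStack, spec: FeatureSpec | None = None,
                   seed: int = 0) -> FeatureMatrix:
    """Build the standardized feature matrix over the valid cells.

    The background is every valid cell when the grid has at most 1e5 of
    them, else a seeded uniform sample of 10 000.  Standardization constants
    (mean, sd) are computed on the background; zero-variance columns are
    dropped with a logged warning.
    """
    if env.n_valid == 0:
        raise ValueError("stack has no valid cells")
    for name in env.layers:
        if not env.mask.any():
            raise ValueError(f"layer {name!r} is entirely nodata")
    if spec is None:
        spec = FeatureSpec.default(env)
    spec.validate(env)
    cells = env.valid_indices()
    X, defs = _raw_features(env, spec, cells)
    if len(cells) <= BACKGROUND_LIMIT:
        background_rows = np.arange(len(cells))
    else:
        rng = np.random.default_rng(seed)
        background_rows = np.sort(rng.choice(len(cells), BACKGROUND_SAMPLE,
                                             replace=False))
    means = X[background_rows].mean(axis=0)
    sds = X[background_rows].std(axis=0)
    keep = sds > 0
    if not keep.all():
        dropped = [d for d, k in zip(defs, keep) if not k]
        log.warning("dropping %d zero-variance features: %s", len(dropped), dropped)
    if not keep.any():
        raise ValueError("all features have zero variance on the background")
    X = (X[:, keep] - means[keep]) / sds[keep]
    return FeatureMatrix(X=X, defs=[d for d, k in zip(defs, keep) if k],
                         means=means[keep], sds=sds[keep], cells=cells,
                         background_rows=background_rows, grid_shape=env.shape)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class MaxentModel:
    """A fitted penalised maximum-entropy model for one species x class."""

    lambdas: np.ndarray
    beta: float
    defs: list[tuple]
    means: np.ndarray
    sds: np.ndarray
    background_cells: np.ndarray
    grid_shape: tuple[int, int]
    r: float                      # entropy-calibration constant: mean lambda.f over presences
    n_presences: int
    converged: bool
    n_iter: int
    grad_norm: float
    objective: float
    species: str = ""
    abundance_class: int = 0

    def to_json(self) -> str:
        doc = {
            "species": self.species,
            "abundance_class": int(self.abundance_class),
            "beta": self.beta,
            "lambdas": self.lambdas.tolist(),
            "features": [list(d) for d in self.defs],
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "background_cells": self.background_cells.tolist(),
            "grid_shape": list(self.grid_shape),
            "r": self.r,
            "n_presences": int(self.n_presences),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "grad_norm": self.grad_norm,
            "objective": self.objective,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MaxentModel":
        doc = json.loads(text)
        return cls(
            lambdas=np.asarray(doc["lambdas"], dtype=float),
            beta=float(doc["beta"]),
            defs=[(f[0], f[1], None if f[2] is None else int(f[2]))
                  for f in doc["features"]],
            means=np.asarray(doc["means"], dtype=float),
            sds=np.asarray(doc["sds"], dtype=float),
            background_cells=np.asarray(doc["background_cells"], dtype=int),
            grid_shape=tuple(doc["grid_shape"]),
            r=float(doc["r"]),
            n_presences=int(doc["n_presences"]),
            converged=bool(doc["converged"]),
            n_iter=int(doc["n_iter"]),
            grad_norm=float(doc["grad_norm"]),
            objective=float(doc["objective"]),
            species=doc.get("species", ""),
            abundance_class=int(doc.get("abundance_class", 0)),
        )


def penalized_objective(lam: np.ndarray, F_pres: np.ndarray, F_bg: np.ndarray,
                        beta: float) -> float:
    """The concave objective L(lambda) (to be maximised)."""
    lam = np.asarray(lam, dtype=float)
    gain = F_pres @ lam
    return (float(np.mean(gain))
            - float(logsumexp(F_bg @ lam) - np.log(len(F_bg)))
            - beta * float(np.abs(lam).sum()))


def fit(features: FeatureMatrix, presence_rows: np.ndarray,
        beta: float = 0.1, tol: float = 1e-6, max_iter: int = 1000,
        species: str = "", abundance_class: int = 0) -> MaxentModel:
    """Maximise the L1-penalised presence-background log-likelihood.

    The non-smooth penalty is handled exactly by splitting lambda = u - v
    with u, v >= 0 and bounding both below by zero under L-BFGS-B.
    Non-convergence is flagged on the returned model, never silent.
    """
    presence_rows = np.asarray(presence_rows, dtype=int)
    if len(presence_rows) == 0:
        raise ValueError("no presence cells")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    F_pres = features.X[presence_rows]
    F_bg = features.X[features.background_rows]
    k = features.X.shape[1]
    s_p = F_pres.mean(axis=0)
    log_nbg = np.log(len(F_bg))

    def negobj(z: np.ndarray) -> tuple[float, np.ndarray]:
        u, v = z[:k], z[k:]
        lam = u - v
        eta = F_bg @ lam
        lz = logsumexp(eta)
        w = np.exp(eta - lz)
        eq = w @ F_bg
        val = -(s_p @ lam) + (lz - log_nbg) + beta * z.sum()
        g = eq - s_p
        return float(val), np.concatenate([g + beta, -g + beta])

    res = minimize(negobj, np.zeros(2 * k), jac=True, method="L-BFGS-B",
                   bounds=[(0.0, None)] * (2 * k),
                   options={"maxiter": max_iter, "ftol": 1e-14, "gtol": tol * 1e-2})
    lam = res.x[:k] - res.x[k:]
    # Subgradient optimality residual of the original objective.
    eta = F_bg @ lam
    w = np.exp(eta - logsumexp(eta))
    g = s_p - w @ F_bg
    resid = np.where(lam > 0, g - beta,
                     np.where(lam < 0, g + beta,
                              np.sign(g) * np.maximum(np.abs(g) - beta, 0.0)))
    grad_norm = float(np.max(np.abs(resid)))
    converged = grad_norm <= max(tol, 1e-5)
    if not converged:
        log.warning("maxent fit %s/class %d did not converge: |subgrad|=%.3g "
                    "after %d iterations", species, abundance_class, grad_norm,
                    res.nit)
    r = float(np.mean(F_pres @ lam))
    return MaxentModel(
        lambdas=lam, beta=beta, defs=list(features.defs),
        means=features.means.copy(), sds=features.sds.copy(),
        background_cells=features.cells[features.background_rows].copy(),
        grid_shape=features.grid_shape, r=r, n_presences=len(presence_rows),
        converged=converged, n_iter=int(res.nit), grad_norm=grad_norm,
        objective=penalized_objective(lam, F_pres, F_bg, beta),
        species=species, abundance_class=abundance_class)


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------

@dataclass
class SuitabilitySurface:
    """Per-cell suitability for one species x abundance class x scenario."""

    species: str
    abundance_class: int
    values: np.ndarray
    scale: str = "raw"
    scenario: str = "current"


def _model_features(model: MaxentModel, env: EnvStack,
                    cells: np.ndarray) -> np.ndarray:
    """Rebuild the model's feature columns on a (possibly shifted) stack."""
    rows, cols = np.unravel_index(cells, env.shape)
    columns = []
    for layer, kind, code in model.defs:
        if layer not in env.layers:
            raise KeyError(f"projection stack lacks layer {layer!r}")
        vals = env.layers[layer][rows, cols]
        if kind == "linear":
            columns.append(vals.astype(float))
        elif kind == "quadratic":
            columns.append(vals.astype(float) ** 2)
        elif kind == "indicator":
            columns.append((vals == code).astype(float))
        else:  # pragma: no cover - defs come from build_features
            raise ValueError(f"unknown feature kind {kind!r}")
    X = np.column_stack(columns)
    return (X - model.means) / model.sds


def project(model: MaxentModel, env: EnvStack, scale: str = "raw",
            scenario: str = "current") -> SuitabilitySurface:
    """Project a fitted model onto a stack.

    Standardization always uses the TRAINING constants.  ``raw`` output is
    the Gibbs distribution normalised over the model's background cells
    (sums to 1 there); ``logistic`` is
    ``1 - exp(-e^r * raw * N_bg)``, a monotone transform of raw lying in
    (0, 1).
    """
    if scale not in ("raw", "logistic"):
        raise ValueError(f"unknown output scale {scale!r}")
    if env.shape != model.grid_shape:
        raise ValueError(f"stack shape {env.shape} != model grid {model.grid_shape}")
    cells = env.valid_indices()
    X = _model_features(model, env, cells)
    eta = X @ model.lambdas
    # Normalise over the model's background cells within this stack.
    bg_pos = np.searchsorted(cells, model.background_cells)
    if np.any(cells[np.minimum(bg_pos, len(cells) - 1)] != model.background_cells):
        raise ValueError("model background cells are not valid in this stack")
    lz = logsumexp(eta[bg_pos])
    raw = np.exp(eta - lz)
    if scale == "raw":
        vals = raw
    else:
        n_bg = len(model.background_cells)
        # -expm1 keeps precision near 0; values saturate at 1.0 only by
        # floating underflow of exp(-x) for very large x.
        vals = -np.expm1(-np.exp(model.r) * raw * n_bg)
    grid = np.full(env.shape, np.nan)
    grid.ravel()[cells] = vals
    return SuitabilitySurface(species=model.species,
                              abundance_class=model.abundance_class,
                              values=grid, scale=scale, scenario=scenario)


# ---------------------------------------------------------------------------
# Batch fitting over species x abundance class
# ---------------------------------------------------------------------------

@dataclass
class FitAllResult:
    """Fitted models and projected surfaces per (species, class)."""

    models: dict[tuple[str, int], MaxentModel]
    surfaces: dict[tuple[str, int], dict[str, SuitabilitySurface]]
    skipped: list[tuple[str, int, int]] = field(default_factory=list)  # (sp, class, n_rec)

    def class_surfaces(self, species: str, scenario: str
                       ) -> tuple[np.ndarray | None, np.ndarray | None, np.ndarray | None]:
        """The three class surfaces (or None where absent) for one scenario."""
        out = []
        for cls in (1, 2, 3):
            surf = self.surfaces.get((species, cls), {}).get(scenario)
            out.append(None if surf is None else surf.values)
        return tuple(out)


def fit_all(occurrences: OccurrenceSet, env: EnvStack,
            scenario_env: EnvStack | None = None,
            spec: FeatureSpec | None = None, beta: float = 0.1,
            min_presences: int = 5, scale: str = "logistic",
            tol: float = 1e-6, max_iter: int = 1000,
            seed: int = 0) -> FitAllResult:
    """Fit one model per species per abundance class and project it.

    Classes with fewer than ``min_presences`` records yield no model and are
    recorded in ``skipped`` (downstream the class is treated as absent).
    Species with no fittable class at all are skipped with a warning.
    Deterministic given the seed (which only matters when the background is
    subsampled).
    """
    features = build_features(env, spec, seed=seed)
    scenarios = {"current": env}
    if scenario_env is not None:
        scenarios["scenario"] = scenario_env
    models: dict[tuple[str, int], MaxentModel] = {}
    surfaces: dict[tuple[str, int], dict[str, SuitabilitySurface]] = {}
    skipped: list[tuple[str, int, int]] = []
    for sp in occurrences.species_ids():
        fitted_any = False
        for cls in (1, 2, 3):
            recs = occurrences.for_species(sp, cls)
            if len(recs) < min_presences:
                skipped.append((sp, cls, len(recs)))
                continue
            flat = np.ravel_multi_index(
                (recs["row"].to_numpy(), recs["col"].to_numpy()), env.shape)
            on_valid = env.mask.ravel()[flat]
            if not on_valid.all():
                log.warning("%s class %d: dropping %d records on nodata cells",
                            sp, cls, int((~on_valid).sum()))
                flat = flat[on_valid]
            if len(flat) < min_presences:
                skipped.append((sp, cls, len(flat)))
                continue
            rows = features.row_of_cell(np.sort(flat))
            model = fit(features, rows, beta=beta, tol=tol, max_iter=max_iter,
                        species=sp, abundance_class=cls)
            models[(sp, cls)] = model
            surfaces[(sp, cls)] = {
                name: project(model, stack, scale=scale, scenario=name)
                for name, stack in scenarios.items()}
            fitted_any = True
        if not fitted_any:
            log.warning("species %s: no abundance class reached %d records; skipped",
                        sp, min_presences)
    log.info("fitted %d models, skipped %d species-class combinations",
             len(models), len(skipped))
    return FitAllResult(models=models, surfaces=surfaces, skipped=skipped)
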