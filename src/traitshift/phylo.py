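"""Phylogenetic gap-filling of continuous traits under Brownian motion.

A trait evolving by Brownian motion (BM) on a rooted tree makes the tip
values jointly Gaussian with covariance ``sigma^2 * C``, where ``C[i, j]``
is the shared root-to-MRCA path length of tips i and j.  The rate sigma^2
and root state mu have closed-form generalised-least-squares (ML) estimates,
and missing tips are filled with the conditional expectation of the
multivariate normal given the observed tips.  Size-like traits (SLA, CH, RD)
are log-transformed before fitting and back-transformed afterwards.

Traits are imputed independently of one another (univariate BM); categorical
traits are never imputed — unknown levels stay unknown and are excluded from
categorical biomass profiles downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .traits import TraitMatrix

__all__ = [
    "phylo_covariance",
    "fit_bm",
    "impute",
    "BMFit",
    "read_tree",
]

log = logging.getLogger(__name__)

_DEFAULT_LOG_TRAITS = ("SLA", "CH", "RD")


def read_tree(path: str) -> dendropy.Tree:
    """Read a rooted Newick tree, preserving underscores in tip labels."""
    tree = dendropy.Tree.get(path=path, schema="newick", preserve_underscores=True)
    return tree


def phylo_covariance(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Shared-path-length matrix of the tree's tips.

    Returns ``(C, labels)`` with ``C[i, j]`` the root-to-MRCA(i, j) distance
    and ``C[i, i]`` the root-to-tip distance.  C is symmetric positive
    semidefinite by construction.  Negative branch lengths are rejected.
    """
    tips: list[dendropy.Node] = []
    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        elen = node.edge.length
        if elen is None:
            elen = 0.0
        if elen < 0:
            raise ValueError(f"negative branch length {elen} on edge to {node}")
        parent = node.parent_node
        depth[id(node)] = (depth[id(parent)] if parent is not None else 0.0) + (
            elen if parent is not None else 0.0
        )
        if node.is_leaf():
            tips.append(node)
    labels = [t.taxon.label if t.taxon is not None else str(i)
              for i, t in enumerate(tips)]
    index = {id(t): i for i, t in enumerate(tips)}
    n = len(tips)
    C = np.zeros((n, n))
    for t in tips:
        C[index[id(t)], index[id(t)]] = depth[id(t)]
    # Postorder: tips below each child subtree; cross pairs share this node.
    below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = [index[id(node)]]
            continue
        groups = [below.pop(id(ch)) for ch in node.child_nodes()]
        d = depth[id(node)]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        C[a, b] = C[b, a] = d
        below[id(node)] = [i for g in groups for i in g]
    return C, labels


@dataclass(frozen=True)
class BMFit:
    """Maximum-likelihood Brownian-motion fit for one trait."""

    mu: float
    sigma2: float
    log_likelihood: float
    n_observed: int


def _chol(C: np.ndarray):
    """Cholesky factor with a tiny jitter fallback for near-singular C."""
    try:
        return cho_factor(C, lower=True)
    except np.linalg.LinAlgError:
        eps = 1e-10 * np.trace(C) / len(C)
        return cho_factor(C + eps * np.eye(len(C)), lower=True)


def fit_bm(x: np.ndarray, C: np.ndarray) -> BMFit:
    """Closed-form GLS estimate of (mu, sigma^2) for one trait.

    mu_hat = (1' C^-1 x) / (1' C^-1 1);
    sigma2_hat = (x - mu_hat)' C^-1 (x - mu_hat) / n  (ML, not REML).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("Brownian-motion fit needs at least 2 observed tips")
    if C.shape != (n, n):
        raise ValueError(f"covariance shape {C.shape} does not match {n} tips")
    cf = _chol(C)
    ones = np.ones(n)
    Cinv_x = cho_solve(cf, x)
    Cinv_1 = cho_solve(cf, ones)
    mu = float(ones @ Cinv_x / (ones @ Cinv_1))
    resid = x - mu
    sigma2 = float(resid @ cho_solve(cf, resid) / n)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    if sigma2 > 0:
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    else:
        ll = np.inf  # degenerate: all residuals zero
    return BMFit(mu=mu, sigma2=sigma2, log_likelihood=ll, n_observed=n)


def impute(tm: TraitMatrix, tree: dendropy.Tree,
           log_transform: tuple[str, ...] = _DEFAULT_LOG_TRAITS,
           ) -> tuple[TraitMatrix, pd.DataFrame]:
    """Fill continuous-trait gaps by BM conditioning on the phylogeny.

    For each continuous trait: fit (mu, sigma2) on the observed tips, then
    set the missing tips to ``E[x_m | x_o] = mu + S_mo S_oo^-1 (x_o - mu)``
    with ``S = sigma2 * C``, reporting the conditional SD of each filled
    value.  Observed entries are returned bit-exact.  Traits named in
    ``log_transform`` (and strictly positive where observed) are fitted on
    the log scale and back-transformed.

    Returns the completed :class:`TraitMatrix` and a report frame with
    columns (species_id, trait, value, conditional_sd).
    """
    C_full, labels = phylo_covariance(tree)
    pos = {lab: i for i, lab in enumerate(labels)}
    missing_tips = [s for s in tm.species if s not in pos]
    if missing_tips:
        raise ValueError(f"species absent from the tree: {missing_tips}")

    out = tm.copy()
    rows = []
    for trait in tm.continuous_traits():
        col = tm.data[trait]
        observed = col.notna()
        n_obs = int(observed.sum())
        if n_obs == 0:
            raise ValueError(f"trait {trait!r} has no observed values")
        if n_obs < 2:
            raise ValueError(f"trait {trait!r} has fewer than 2 observed values")
        if not observed.all():
            obs_sp = col.index[observed]
            mis_sp = col.index[~observed]
            x = col[observed].to_numpy(dtype=float)
            use_log = trait in log_transform and np.all(x > 0)
            if use_log:
                x = np.log(x)
            io = [pos[s] for s in obs_sp]
            im = [pos[s] for s in mis_sp]
            Coo = C_full[np.ix_(io, io)]
            Cmo = C_full[np.ix_(im, io)]
            Cmm = C_full[np.ix_(im, im)]
            fit = fit_bm(x, Coo)
            if fit.sigma2 > 0:
                cf = _chol(Coo)
                w = cho_solve(cf, x - fit.mu)
                cond_mean = fit.mu + Cmo @ w
                cond_var = fit.sigma2 * (
                    np.diag(Cmm) - np.einsum("ij,ji->i", Cmo, cho_solve(cf, Cmo.T))
                )
                cond_var = np.maximum(cond_var, 0.0)
            else:
                cond_mean = np.full(len(im), fit.mu)
                cond_var = np.zeros(len(im))
            values = np.exp(cond_mean) if use_log else cond_mean
            sds = np.sqrt(cond_var)
            for sp, v, sd in zip(mis_sp, values, sds):
                out.data.loc[sp, trait] = v
                rows.append({"species_id": sp, "trait": trait,
                             "value": float(v), "conditional_sd": float(sd)})
    n_cat_unknown = int(out.data[out.categorical_traits()].isna().sum().sum()) \
        if out.categorical_traits() else 0
    if n_cat_unknown:
        log.info("categorical traits left unimputed: %d unknown entries", n_cat_unknown)
    report = pd.DataFrame(rows, columns=["species_id", "trait", "value", "conditional_sd"])
    return out, report
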