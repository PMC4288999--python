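"""Relative abundance from abundance-class suitabilities, and allometric biomass.

The three abundance classes (single individuals, frequent, dominant) are
modeled separately; their per-cell occurrence probabilities are combined by
a weighted average (weights 0.01, 0.1, 1) into a relative-abundance
estimate.  Canopy height H (m) is converted to maximum potential biomass
density B_max (kg dry weight per m^2) through allometric scaling between
height, individual mass and maximum density:

    B_max = 1.769e5 * (H / b) ** (-0.757 / a)

with a = 0.264, b = 2.58 for non-trees and a = 0.345, b = 3.71 for trees.
As printed, the exponent is negative, so B_max decreases with height; an
alternative "derived" mode uses exponent (1 - 0.757) / a, the product of
the two cited scaling laws (B = M * N), and is provided for sensitivity
analysis.  Relative biomass shares are A_s * B_max(H_s) normalised over the
species pool per cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClassWeights",
    "AllometricParams",
    "AbundanceSurface",
    "ALLOMETRY",
    "weighted_abundance",
    "b_max",
    "relative_biomass",
]


@dataclass(frozen=True)
class ClassWeights:
    """Weights for the single / frequent / dominant abundance classes."""

    single: float = 0.01
    frequent: float = 0.1
    dominant: float = 1.0

    def __post_init__(self) -> None:
        if not (self.single > 0 and self.frequent > 0 and self.dominant > 0):
            raise ValueError("class weights must all be positive")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.single, self.frequent, self.dominant)


@dataclass(frozen=True)
class AllometricParams:
    """Constants of the height-to-biomass power law for one growth form."""

    a: float  # height ~ mass^a
    b: float  # reference height (m)
    c: float = 1.769e5  # prefactor, kg DW m^-2
    d: float = -0.757  # maximum density ~ mass^d

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ValueError("allometric constants a, b, c must be positive")


ALLOMETRY = {
    "non-tree": AllometricParams(a=0.264, b=2.58),
    "tree": AllometricParams(a=0.345, b=3.71),
}


@dataclass
class AbundanceSurface:
    """Per-cell relative abundance estimate for one species and scenario."""

    species: str
    values: np.ndarray
    scenario: str = "current"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        valid = ~np.isnan(v)
        if np.any(v[valid] < 0):
            raise ValueError("relative abundance must be non-negative")
        self.values = v


def weighted_abundance(p1, p2, p3, weights: ClassWeights = ClassWeights(),
                       convention: str = "normalized",
                       species: str = "", scenario: str = "current",
                       ) -> AbundanceSurface:
    """Combine per-class occurrence probabilities into relative abundance.

    ``p1``/``p2``/``p3`` are the single/frequent/dominant class surfaces
    (arrays in [0, 1], NaN-masked) or None for a class with no fitted model.
    Under the ``"normalized"`` convention the weighted sum is divided by the
    sum of the weights of the classes actually present; under ``"sum"`` it
    is not divided.  At least one class must be present.
    """
    if convention not in ("normalized", "sum"):
        raise ValueError(f"unknown convention {convention!r}")
    surfaces = [p1, p2, p3]
    if all(p is None for p in surfaces):
        raise ValueError("all three abundance classes are absent")
    w = weights.as_tuple()
    num = None
    wsum = 0.0
    for pi, wi in zip(surfaces, w):
        if pi is None:
            continue
        pi = np.asarray(pi, dtype=float)
        valid = ~np.isnan(pi)
        if np.any((pi[valid] < 0) | (pi[valid] > 1)):
            raise ValueError("class probabilities must lie in [0, 1]")
        num = wi * pi if num is None else num + wi * pi
        wsum += wi
    values = num / wsum if convention == "normalized" else num
    return AbundanceSurface(species=species, values=values, scenario=scenario)


def b_max(H, form: str = "non-tree", mode: str = "printed") -> float | np.ndarray:
    """Maximum potential biomass density (kg DW m^-2) from canopy height (m).

    ``mode="printed"`` evaluates c * (H/b) ** (d/a) (the default);
    ``mode="derived"`` uses exponent (1 + d)/a, corresponding to biomass
    density as the product of individual mass and maximum density.
    """
    if form not in ALLOMETRY:
        raise ValueError(f"unknown growth form {form!r}; expected {sorted(ALLOMETRY)}")
    params = ALLOMETRY[form]
    H_arr = np.asarray(H, dtype=float)
    if np.any(H_arr <= 0):
        raise ValueError("canopy height must be positive")
    if mode == "printed":
        expo = params.d / params.a
    elif mode == "derived":
        expo = (1.0 + params.d) / params.a
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = params.c * (H_arr / params.b) ** expo
    return float(out) if np.isscalar(H) or out.ndim == 0 else out


def relative_biomass(abundances: dict[str, AbundanceSurface],
                     heights: dict[str, float],
                     forms: dict[str, str],
                     pool: list[str] | None = None,
                     mode: str = "printed",
                     ) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-cell relative biomass shares over a species pool.

    share_s(x) = A_s(x) B_max(H_s) / sum_{s' in pool} A_{s'}(x) B_max(H_{s'})

    Cells where the denominator is zero (or any input is NaN) are masked.
    Returns ``(shares, valid)`` where ``shares[s]`` is a grid of shares with
    NaN on masked cells and ``valid`` is the boolean cell mask.  Shares sum
    to 1 on every valid cell.
    """
    if pool is None:
        pool = list(abundances)
    if not pool:
        raise ValueError("empty species pool")
    missing = [s for s in pool if s not in abundances]
    if missing:
        raise KeyError(f"species without abundance surfaces: {missing}")
    no_height = [s for s in pool if s not in heights]
    if no_height:
        raise KeyError(f"species without canopy height: {no_height}")

    weighted = {}
    denom = None
    valid = None
    # accumulate in sorted order so shares are bit-identical for any pool order
    for s in sorted(pool):
        arr = np.asarray(abundances[s].values, dtype=float)
        ws = arr * b_max(heights[s], forms.get(s, "non-tree"), mode=mode)
        weighted[s] = ws
        denom = ws.copy() if denom is None else denom + ws
        v = ~np.isnan(arr)
        valid = v if valid is None else (valid & v)
    valid = valid & (np.nan_to_num(denom, nan=0.0) > 0)
    shares = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for s in pool:
            sh = np.where(valid, weighted[s] / denom, np.nan)
            shares[s] = sh
    return shares, valid
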