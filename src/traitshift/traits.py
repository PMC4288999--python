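"""Species-by-trait tables with plant functional group assignments.

Continuous traits (specific leaf area SLA, canopy height CH, root depth RD)
are stored as floats with NaN marking a gap; categorical traits (leaf
persistence, clonality, mycorrhiza, and the hydrophyte traits) as strings
with NaN for unknown.  Each species carries a plant functional group (PFG)
which decides its vegetation layer: pteridophytes, graminoids and herbs form
the field layer, shrubs the shrub layer; mosses have no trait data and trees
are summarised separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import pandas as pd

__all__ = [
    "TraitMatrix",
    "PFGS",
    "WETLAND_TYPES",
    "LAYER_PFGS",
    "CATEGORICAL_SCHEME",
    "CONTINUOUS_TRAITS",
    "read_traits",
    "write_traits",
]

PFGS = ("moss", "pteridophyte", "graminoid", "herbaceous", "shrub", "tree")
WETLAND_TYPES = ("bog", "fen", "riparian")

# Vegetation layers used for community-weighted means.  Mosses are excluded
# (no trait data); trees are treated per species, not as a community mean.
LAYER_PFGS = {
    "field": ("pteridophyte", "graminoid", "herbaceous"),
    "shrub": ("shrub",),
}

CONTINUOUS_TRAITS = ("SLA", "CH", "RD")

# Deterministic categorical-trait assignment per PFG.  Fixed so that
# categorical biomass profiles have a known ground truth in simulations.
CATEGORICAL_SCHEME: dict[str, dict[str, str]] = {
    "moss": {"leaf_persistence": "evergreen", "clonality": "nonclonal",
             "mycorrhiza": "nonmycorrhizal"},
    "pteridophyte": {"leaf_persistence": "summergreen", "clonality": "rhizomatous",
                     "mycorrhiza": "facultative"},
    "graminoid": {"leaf_persistence": "summergreen", "clonality": "tussock",
                  "mycorrhiza": "facultative"},
    "herbaceous": {"leaf_persistence": "summergreen", "clonality": "nonclonal",
                   "mycorrhiza": "facultative"},
    "shrub": {"leaf_persistence": "evergreen", "clonality": "nonclonal",
              "mycorrhiza": "obligatory"},
    "tree": {"leaf_persistence": "summergreen", "clonality": "nonclonal",
             "mycorrhiza": "obligatory"},
}


@dataclass
class TraitMatrix:
    """Species x traits table plus PFG assignment.

    ``data`` is indexed by species id; ``kinds`` maps each trait column to
    ``"continuous"`` or ``"categorical"``; ``pfg`` maps species id to PFG.
    """

    data: pd.DataFrame
    kinds: dict[str, str]
    pfg: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate species ids: {dups}")
        unknown = [c for c in self.data.columns if c not in self.kinds]
        if unknown:
            raise ValueError(f"traits without a declared kind: {unknown}")
        for col, kind in self.kinds.items():
            if kind not in ("continuous", "categorical"):
                raise ValueError(f"trait {col!r} has unknown kind {kind!r}")
            if kind == "continuous" and col in self.data:
                self.data[col] = pd.to_numeric(self.data[col])

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def mask(self) -> pd.DataFrame:
        """True where a value is missing."""
        return self.data.isna()

    def continuous_traits(self) -> list[str]:
        return [c for c in self.data.columns if self.kinds[c] == "continuous"]

    def categorical_traits(self) -> list[str]:
        return [c for c in self.data.columns if self.kinds[c] == "categorical"]

    def copy(self) -> "TraitMatrix":
        return TraitMatrix(self.data.copy(), dict(self.kinds), self.pfg.copy())


def write_traits(tm: TraitMatrix, path: str, pfg_path: str | None = None) -> None:
    """Write the trait table as CSV (empty cell = missing); PFGs separately."""
    tm.data.to_csv(path, index_label="species_id")
    if pfg_path is not None:
        tm.pfg.rename("pfg").to_csv(pfg_path, index_label="species_id")


def read_traits(path: str, kinds: dict[str, str] | None = None,
                pfg_path: str | None = None) -> TraitMatrix:
    """Read a trait CSV; columns not named in ``kinds`` are sniffed by dtype."""
    df = pd.read_csv(path, index_col="species_id")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate species ids")
    kinds = dict(kinds or {})
    for col in df.columns:
        if col not in kinds:
            numeric = pd.to_numeric(df[col], errors="coerce")
            observed = df[col].notna()
            kinds[col] = "continuous" if numeric[observed].notna().all() else "categorical"
            if kinds[col] == "continuous":
                df[col] = numeric
    pfg = pd.Series(dtype=object)
    if pfg_path is not None:
        pfg = pd.read_csv(pfg_path, index_col="species_id")["pfg"]
    return TraitMatrix(df, kinds, pfg)
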