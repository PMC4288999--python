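"""Gridded environmental layers and plain-text raster I/O.

The covariate space for the distribution models is a stack of named raster
layers on a common grid: continuous layers (climate, terrain, pH) and
categorical layers (soil class, bedrock class) sharing one nodata mask.

Grid convention (used everywhere in the package): row-major, 0-based cell
indices, origin at the upper-left corner, half-open cell extents.  Rasters
are exchanged as ESRI ASCII grids (one file per layer) plus a YAML manifest
recording each layer's name, kind, units and whether it is climatic.
"""

from __future__ import annotations


import os
import re
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "EnvStack",
    "ScenarioDelta",
    "apply_scenario",
    "read_grid",
    "write_grid",
    "read_stack",
    "write_stack",
    "read_scenario",
    "write_scenario",
]

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass
class EnvStack:
    """A stack of co-registered raster layers.

    Parameters
    ----------
    layers
        Mapping layer name -> 2-D array (nrows, ncols).  Continuous layers
        are float; categorical layers hold integer codes.
    kinds
        Mapping layer name -> ``"continuous"`` or ``"categorical"``.
    mask
        Boolean array, True where the cell is valid (not nodata).
    climatic
        Names of the continuous layers a climate scenario may shift.
    cellsize
        Cell edge length in metres.
    origin
        (x0, y0) of the lower-left corner, metres.
    code_sets
        For each categorical layer, the declared set of valid codes.
    """

    layers: dict[str, np.ndarray]
    kinds: dict[str, str]
    mask: np.ndarray
    climatic: frozenset[str] = frozenset()
    cellsize: float = 500.0
    origin: tuple[float, float] = (0.0, 0.0)
    code_sets: dict[str, tuple[int, ...]] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.layers:
            raise ValueError("EnvStack needs at least one layer")
        shape = self.mask.shape
        for name, arr in self.layers.items():
            arr = np.asarray(arr)
            if arr.shape != shape:
                raise ValueError(
                    f"layer {name!r} has shape {arr.shape}, mask has {shape}"
                )
            kind = self.kinds.get(name)
            if kind not in (CONTINUOUS, CATEGORICAL):
                raise ValueError(f"layer {name!r} has unknown kind {kind!r}")
            if kind == CONTINUOUS:
                arr = arr.astype(float)
                if not np.all(np.isfinite(arr[self.mask])):
                    raise ValueError(f"continuous layer {name!r} has non-finite valid cells")
            else:
                arr = np.asarray(np.round(arr), dtype=int)
                codes = self.code_sets.get(name)
                if codes is not None and not np.isin(arr[self.mask], codes).all():
                    raise ValueError(f"categorical layer {name!r} has codes outside its code set")
            self.layers[name] = arr
        self.climatic = frozenset(self.climatic)
        bad = [n for n in self.climatic if self.kinds.get(n) != CONTINUOUS]
        if bad:
            raise ValueError(f"climatic flag on non-continuous layers: {bad}")

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def nrows(self) -> int:
        return self.mask.shape[0]

    @property
    def ncols(self) -> int:
        return self.mask.shape[1]

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def layer_names(self, kind: str | None = None) -> list[str]:
        if kind is None:
            return list(self.layers)
        return [n for n, k in self.kinds.items() if k == kind]

    def valid_indices(self) -> np.ndarray:
        """Flat (row-major) indices of valid cells, ascending."""
        return np.flatnonzero(self.mask.ravel())

    def copy(self) -> "EnvStack":
        return EnvStack(
            layers={n: a.copy() for n, a in self.layers.items()},
            kinds=dict(self.kinds),
            mask=self.mask.copy(),
            climatic=self.climatic,
            cellsize=self.cellsize,
            origin=self.origin,
            code_sets=dict(self.code_sets),
            units=dict(self.units),
        )


@dataclass(frozen=True)
class ScenarioDelta:
    """Additive per-layer offsets describing a climate scenario.

    Only continuous layers flagged climatic may appear; unlisted layers are
    left untouched.  Offsets are in the layer's own units (e.g. +2.85 for a
    temperature layer in degrees C).
    """

    offsets: dict[str, float]

    def __post_init__(self) -> None:
        for name, off in self.offsets.items():
            if not np.isfinite(off):
                raise ValueError(f"offset for layer {name!r} is not finite")


def apply_scenario(env: EnvStack, delta: ScenarioDelta) -> EnvStack:
    """Return a new stack with the scenario offsets added.

    Named layers must exist, be continuous and be flagged climatic; every
    other layer and the mask are carried over bit-identically.
    """
    for name in delta.offsets:
        if name not in env.layers:
            raise KeyError(f"scenario names unknown layer {name!r}")
        if env.kinds[name] != CONTINUOUS:
            raise ValueError(f"scenario targets categorical layer {name!r}")
        if name not in env.climatic:
            raise ValueError(f"layer {name!r} is not flagged climatic")
    out = env.copy()
    for name, off in delta.offsets.items():
        out.layers[name] = out.layers[name] + float(off)
    return out


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def write_grid(values: np.ndarray, path: str, *, mask: np.ndarray | None = None,
               cellsize: float = 500.0, origin: tuple[float, float] = (0.0, 0.0),
               nodata: float = -9999.0, fmt: str = "%.10g") -> None:
    """Write one layer as an ESRI ASCII grid (6-line header + rows)."""
    values = np.asarray(values, dtype=float)
    out = values.copy()
    if mask is not None:
        out[~np.asarray(mask, dtype=bool)] = nodata
    nrows, ncols = out.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {origin[0]:.10g}\n")
        fh.write(f"yllcorner {origin[1]:.10g}\n")
        fh.write(f"cellsize {cellsize:.10g}\n")
        fh.write(f"NODATA_value {nodata:.10g}\n")
        for row in out:
            fh.write(" ".join(fmt % v for v in row) + "\n")


def read_grid(path: str) -> tuple[np.ndarray, np.ndarray, float, tuple[float, float]]:
    """Read an ESRI ASCII grid.

    Returns ``(values, mask, cellsize, origin)`` where nodata cells hold NaN
    and ``mask`` is True on valid cells.  Malformed headers raise with the
    offending line number.
    """
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    nodata = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            key = parts[0].lower()
            if key in _HEADER_KEYS or key == "nodata_value":
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: malformed header line {line!r}")
                try:
                    val = float(parts[1])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad header value {parts[1]!r}") from exc
                if key == "nodata_value":
                    nodata = val
                else:
                    header[key] = val
            else:
                try:
                    rows.append([float(v) for v in parts])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad data value") from exc
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise ValueError(f"{path}: header missing {missing}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    values = np.array(rows, dtype=float)
    if values.shape != (nrows, ncols):
        raise ValueError(
            f"{path}: data shape {values.shape} != header ({nrows}, {ncols})"
        )
    if nodata is None:
        nodata = -9999.0
    mask = values != nodata
    values = np.where(mask, values, np.nan)
    return values, mask, header["cellsize"], (header["xllcorner"], header["yllcorner"])


# ---------------------------------------------------------------------------
# Stack manifest (YAML) + per-layer grids
# ---------------------------------------------------------------------------

def _slug(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]+", "_", name)


def write_stack(env: EnvStack, directory: str, manifest: str = "stack.yml") -> str:
    """Write each layer as ``<name>.asc`` plus a YAML manifest; returns manifest path."""
    os.makedirs(directory, exist_ok=True)
    entries = []
    for name in env.layers:
        fname = _slug(name) + ".asc"
        write_grid(env.layers[name].astype(float), os.path.join(directory, fname),
                   mask=env.mask, cellsize=env.cellsize, origin=env.origin)
        entries.append({
            "name": name,
            "file": fname,
            "kind": env.kinds[name],
            "units": env.units.get(name, ""),
            "climatic": name in env.climatic,
            "codes": list(map(int, env.code_sets[name])) if name in env.code_sets else None,
        })
    path = os.path.join(directory, manifest)
    with open(path, "w") as fh:
        yaml.safe_dump({"cellsize": env.cellsize,
                        "origin": list(env.origin),
                        "layers": entries}, fh, sort_keys=False)
    return path


def read_stack(manifest_path: str) -> EnvStack:
    """Read a stack manifest and its layer grids back into an :class:`EnvStack`."""
    with open(manifest_path) as fh:
        doc = yaml.safe_load(fh)
    directory = os.path.dirname(manifest_path)
    layers, kinds, climatic, code_sets, units = {}, {}, set(), {}, {}
    mask = None
    cellsize = float(doc.get("cellsize", 500.0))
    origin = tuple(doc.get("origin", (0.0, 0.0)))
    for entry in doc["layers"]:
        name = entry["name"]
        values, m, cellsize, origin = read_grid(os.path.join(directory, entry["file"]))
        mask = m if mask is None else (mask & m)
        kinds[name] = entry["kind"]
        if entry.get("climatic"):
            climatic.add(name)
        if entry.get("codes"):
            code_sets[name] = tuple(entry["codes"])
        if entry.get("units"):
            units[name] = entry["units"]
        layers[name] = values
    for name, kind in kinds.items():
        arr = layers[name]
        arr = np.where(mask, arr, 0.0)
        layers[name] = arr.astype(int) if kind == CATEGORICAL else arr
    return EnvStack(layers=layers, kinds=kinds, mask=mask, climatic=frozenset(climatic),
                    cellsize=cellsize, origin=(float(origin[0]), float(origin[1])),
                    code_sets=code_sets, units=units)


def write_scenario(delta: ScenarioDelta, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: float(v) for k, v in delta.offsets.items()}, fh)


def read_scenario(path: str) -> ScenarioDelta:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return ScenarioDelta(offsets={str(k): float(v) for k, v in doc.items()})
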