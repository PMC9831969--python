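"""Discrete state space and habitat/distance covariates.

The spatial capture-recapture model integrates latent activity centers over a
coarse pixel grid (the *state space*).  This module builds that grid from the
trap array, summarises a fine categorical land-cover raster onto it by
majority vote, assigns each trap a land-cover class from a circular buffer,
and computes nearest-distance covariates to landscape features (water,
artificial surfaces, agricultural fields).

All coordinates are planar metric (meters, projected); no geodesy is applied
— study extents here are a few kilometers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "HABITAT_CODES",
    "PIXEL_TIE_PRIORITY",
    "TRAP_TIE_PRIORITY",
    "TRAP_HABITAT_CLASSES",
    "FineRaster",
    "StateSpace",
    "TrapArray",
    "FeatureSet",
    "read_ascii_grid",
    "write_ascii_grid",
    "build_state_space",
    "aggregate_majority",
    "assign_trap_habitat",
    "distance_to_feature",
]

#: Integer class codes for the categorical land-cover raster.
HABITAT_CODES = {
    "agricultural": 1,
    "coniferous": 2,
    "mixed": 3,
    "transitional": 4,
    "deciduous": 5,
    "artificial": 6,
    "water": 7,
}
CODE_TO_HABITAT = {v: k for k, v in HABITAT_CODES.items()}

#: Tie priority for pixel-level majority aggregation (first wins).
PIXEL_TIE_PRIORITY = ("agricultural", "mixed", "coniferous", "transitional")
#: Classes a trap may take, also its tie priority (first wins).
TRAP_TIE_PRIORITY = ("mixed", "coniferous", "transitional")
TRAP_HABITAT_CLASSES = frozenset(TRAP_TIE_PRIORITY)


@dataclass
class FineRaster:
    """Fine-resolution categorical land-cover raster (ESRI ASCII layout).

    ``values`` is a (nrows, ncols) integer array in raster order: row 0 is the
    *northernmost* row.  ``xll``/``yll`` give the lower-left corner of the
    grid, ``cellsize`` the square cell edge in meters (default 20 m, the
    resolution of the Corine Land Cover product this emulates).
    """

    xll: float
    yll: float
    cellsize: float
    values: np.ndarray
    nodata: int = -9999

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")
        valid = set(CODE_TO_HABITAT) | {self.nodata}
        present = set(np.unique(self.values).tolist())
        unknown = present - valid
        if unknown:
            raise ValueError(f"unknown class codes in raster: {sorted(unknown)}")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates of every cell, matching ``values`` shape."""
        x = self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize
        # row 0 is the top row
        y = self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize
        return np.meshgrid(x, y)

    def class_points(self, habitat: str) -> np.ndarray:
        """(n, 2) center coordinates of all cells of one habitat class."""
        xx, yy = self.cell_centers()
        mask = self.values == HABITAT_CODES[habitat]
        return np.column_stack([xx[mask], yy[mask]])


@dataclass
class StateSpace:
    """Pixel grid over which activity centers are marginalised.

    ``x``/``y`` are pixel centers (m); ``resolution`` the pixel edge (m).
    ``habitat`` holds one class name per pixel; distance covariates are in
    meters.  Pixel area is carried in km² so that densities back-transform
    directly to individuals/km².
    """

    x: np.ndarray
    y: np.ndarray
    resolution: float
    habitat: np.ndarray | None = None
    dist_artificial: np.ndarray | None = None
    dist_water: np.ndarray | None = None
    extent: tuple[float, float, float, float] | None = None  # xmin,xmax,ymin,ymax

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("pixel centers must be matching 1-D arrays")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def n_pixels(self) -> int:
        return self.x.size

    @property
    def pixel_area_km2(self) -> float:
        return (self.resolution / 1000.0) ** 2

    @property
    def total_area_km2(self) -> float:
        return self.n_pixels * self.pixel_area_km2

    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"x": self.x, "y": self.y})
        if self.habitat is not None:
            df["habitat"] = self.habitat
        if self.dist_artificial is not None:
            df["dist_artificial"] = self.dist_artificial
        if self.dist_water is not None:
            df["dist_water"] = self.dist_water
        return df


@dataclass
class TrapArray:
    """Sampling-plot ("trap") locations with trap-level covariates."""

    ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    habitat: np.ndarray | None = None
    dist_agricultural: np.ndarray | None = None
    dist_artificial: np.ndarray | None = None
    dist_water: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(set(self.ids.tolist())) != self.ids.size:
            raise ValueError("trap ids must be unique")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("trap coordinates must be finite")
        if self.habitat is not None:
            bad = set(np.asarray(self.habitat).tolist()) - TRAP_HABITAT_CLASSES
            if bad:
                raise ValueError(f"trap habitat must be one of {sorted(TRAP_HABITAT_CLASSES)}, got {bad}")

    @property
    def n_traps(self) -> int:
        return self.ids.size

    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.ids, "x": self.x, "y": self.y})
        for name in ("habitat", "dist_agricultural", "dist_artificial", "dist_water"):
            val = getattr(self, name)
            if val is not None:
                df[name] = val
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrapArray":
        kw = {}
        for name in ("habitat", "dist_agricultural", "dist_artificial", "dist_water"):
            if name in df.columns:
                kw[name] = df[name].to_numpy()
        return cls(df["id"].to_numpy(), df["x"].to_numpy(), df["y"].to_numpy(), **kw)


@dataclass
class FeatureSet:
    """Named point sets (m) standing for water bodies, artificial surfaces and
    agricultural fields.  Features are pre-densified points (e.g. rasterised
    cell centers); segment geometry is never interpolated, so distances are
    exact point-to-point minima."""

    points: dict[str, np.ndarray] = field(default_factory=dict)

    def add(self, name: str, pts: np.ndarray) -> None:
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        self.points[name] = pts

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def __contains__(self, name: str) -> bool:
        return name in self.points


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

def read_ascii_grid(path_or_buf) -> FineRaster:
    """Read an ESRI ASCII grid (.asc) into a :class:`FineRaster`."""
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf) as fh:
            text = fh.read()
    lines = text.strip().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid header missing {key}")
    values = np.loadtxt(io.StringIO("\n".join(lines[i:])), dtype=int, ndmin=2)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid data shape does not match header")
    return FineRaster(
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        values=values,
        nodata=int(header.get("nodata_value", -9999)),
    )


def write_ascii_grid(raster: FineRaster, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.xll:g}\n")
        fh.write(f"yllcorner {raster.yll:g}\n")
        fh.write(f"cellsize {raster.cellsize:g}\n")
        fh.write(f"NODATA_value {raster.nodata}\n")
        np.savetxt(fh, raster.values, fmt="%d")


# ---------------------------------------------------------------------------
# Operations

def build_state_space(traps: TrapArray, buffer_m: float = 1000.0,
                      resolution_m: float = 120.0) -> StateSpace:
    """Tile the buffered minimum-area axis-aligned trap rectangle with pixels.

    Pixel centers start at ``rectangle minimum + resolution/2`` and step by
    the resolution along each axis; an edge pixel is kept whenever its center
    lies inside the buffered rectangle.  Total area is therefore exactly
    ``n_pixels * (resolution/1000)**2`` km².
    """
    if traps.n_traps == 0:
        raise ValueError("cannot build a state space from an empty trap array")
    if buffer_m <= 0 or resolution_m <= 0:
        raise ValueError("buffer and resolution must be positive")
    xmin, xmax = traps.x.min() - buffer_m, traps.x.max() + buffer_m
    ymin, ymax = traps.y.min() - buffer_m, traps.y.max() + buffer_m
    # 1e-9 m guard keeps centers that sit on the boundary up to float error
    xs = np.arange(xmin + resolution_m / 2, xmax + 1e-9, resolution_m)
    ys = np.arange(ymin + resolution_m / 2, ymax + 1e-9, resolution_m)
    xx, yy = np.meshgrid(xs, ys)
    return StateSpace(
        x=xx.ravel(), y=yy.ravel(), resolution=resolution_m,
        extent=(xmin, xmax, ymin, ymax),
    )


def _majority(classes: np.ndarray, priority: tuple[str, ...]) -> str | None:
    """Modal class among ``classes`` (names), ties broken by ``priority``;
    classes not in ``priority`` are not eligible."""
    eligible = [c for c in classes if c in priority]
    if not eligible:
        return None
    counts = {c: 0 for c in priority}
    for c in eligible:
        counts[c] += 1
    best = max(counts.values())
    for c in priority:  # priority order decides ties
        if counts[c] == best:
            return c
    return None  # pragma: no cover


def aggregate_majority(fine: FineRaster, space: StateSpace) -> np.ndarray:
    """Per-pixel modal habitat class from the fine raster.

    A fine cell contributes to the coarse pixel whose square footprint
    contains the cell's center.  Artificial (and water/deciduous/nodata)
    cells are excluded from candidacy; ties resolve by
    :data:`PIXEL_TIE_PRIORITY`.  A pixel covered by no fine cell is an error.
    """
    half = space.resolution / 2
    xx, yy = fine.cell_centers()
    cx, cy = xx.ravel(), yy.ravel()
    codes = fine.values.ravel()
    names = np.array([CODE_TO_HABITAT.get(c, "nodata") for c in codes])
    out = np.empty(space.n_pixels, dtype=object)
    for i, (px, py) in enumerate(zip(space.x, space.y)):
        inside = (np.abs(cx - px) <= half) & (np.abs(cy - py) <= half)
        if not inside.any():
            raise ValueError(f"state-space pixel {i} at ({px:g},{py:g}) has no covering fine cells")
        cls = _majority(names[inside], PIXEL_TIE_PRIORITY)
        if cls is None:
            # all covering cells are ineligible (water/artificial/...); fall
            # back to the dominant eligible class of the whole raster is not
            # defensible — treat as most-frequent ineligible-excluded error
            raise ValueError(f"pixel {i} has no eligible habitat cells")
        out[i] = cls
    return out


def assign_trap_habitat(trap_xy: tuple[float, float], fine: FineRaster,
                        buffer_m: float = 30.0) -> str:
    """Modal land-cover class within ``buffer_m`` of the trap center,
    restricted to {coniferous, mixed, transitional}; ties resolve by
    :data:`TRAP_TIE_PRIORITY`."""
    if buffer_m <= 0:
        raise ValueError("buffer must be positive")
    xx, yy = fine.cell_centers()
    d2 = (xx.ravel() - trap_xy[0]) ** 2 + (yy.ravel() - trap_xy[1]) ** 2
    inside = d2 <= buffer_m ** 2
    if not inside.any():
        raise ValueError("no fine cells within trap buffer")
    names = np.array([CODE_TO_HABITAT.get(c, "nodata") for c in fine.values.ravel()])
    cls = _majority(names[inside], TRAP_TIE_PRIORITY)
    if cls is None:
        raise ValueError("no eligible (forest-class) cells within trap buffer")
    return cls


def distance_to_feature(points: np.ndarray, feature: np.ndarray) -> np.ndarray:
    """Minimum Euclidean distance (m) from each query point to the feature
    point set."""
    feature = np.asarray(feature, dtype=float).reshape(-1, 2)
    if feature.size == 0:
        raise ValueError("feature point set is empty")
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    dist, _ = cKDTree(feature).query(points)
    return np.asarray(dist, dtype=float)
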