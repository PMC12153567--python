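"""Micro-area partitioning of a square walled arena.

The arena is divided into four micro-areas from the cumulated movement
positions of a whole observation:

* **food-provision** — the fixed central food circle; pure geometry,
  independent of the data, and always assigned first.
* **center-diffusion** — the footprint of the 2-D density (DBSCAN) cluster
  of cumulated positions that contains the arena centre, minus food cells.
* **edge** — grid cells in a band along the walls whose positions, collapsed
  onto a single unrolled-perimeter coordinate, form 1-D density clusters.
* **intermediate** — everything else.

Areas are measured as occupied-grid-cell counts times the cell area, so the
four areas always close to the arena area to within one cell of rounding.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

FOOD = "food-provision"
CENTER = "center-diffusion"
INTERMEDIATE = "intermediate"
EDGE = "edge"
AREA_LABELS = (FOOD, CENTER, INTERMEDIATE, EDGE)


@dataclass(frozen=True)
class ArenaSpec:
    """Geometry and clustering parameters of the observation arena.

    ``side`` is the inner wall length in mm; the food circle sits at
    ``food_center`` with diameter ``food_diameter``.  ``grid_cell`` sets the
    occupancy-grid resolution used to turn point clusters into regions, and
    ``perimeter_band`` is the wall-distance within which a position counts
    as "at the wall".  ``dbscan_eps`` doubles as the unit social distance.
    """

    side: float = 140.0
    food_center: tuple[float, float] | None = None
    food_diameter: float = 10.0
    grid_cell: float = 1.0
    perimeter_band: float = 5.0
    dbscan_eps: float = 4.0
    dbscan_min_pts: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.food_diameter < self.side:
            raise ValueError("food_diameter must lie in (0, side)")
        n = self.side / self.grid_cell
        if abs(n - round(n)) > 1e-9:
            raise ValueError("grid_cell must divide side")

    @property
    def center(self) -> tuple[float, float]:
        return self.food_center or (self.side / 2, self.side / 2)

    @property
    def n_cells(self) -> int:
        return int(round(self.side / self.grid_cell))

    @property
    def food_area_exact(self) -> float:
        """Area of the food circle, mm² (the grid-free limit)."""
        return np.pi * (self.food_diameter / 2) ** 2


@dataclass
class MicroAreaMap:
    """Labelled occupancy-grid partition of the arena.

    ``labels`` is an (n, n) array of indices into :data:`AREA_LABELS`,
    indexed ``[ix, iy]`` with cell (0, 0) at the origin corner.
    """

    spec: ArenaSpec
    labels: np.ndarray

    @property
    def areas(self) -> dict[str, float]:
        cell_area = self.spec.grid_cell**2
        return {
            lab: float(np.count_nonzero(self.labels == i) * cell_area)
            for i, lab in enumerate(AREA_LABELS)
        }

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        if not (0 <= x <= self.spec.side and 0 <= y <= self.spec.side):
            raise ValueError(f"position ({x}, {y}) outside arena")
        n = self.spec.n_cells
        ix = min(int(x / self.spec.grid_cell), n - 1)
        iy = min(int(y / self.spec.grid_cell), n - 1)
        return ix, iy

    def to_frame(self) -> pd.DataFrame:
        ix, iy = np.meshgrid(
            np.arange(self.spec.n_cells), np.arange(self.spec.n_cells), indexing="ij"
        )
        return pd.DataFrame(
            {
                "cell_x": ix.ravel(),
                "cell_y": iy.ravel(),
                "label": [AREA_LABELS[i] for i in self.labels.ravel()],
            }
        )

    def save(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(d / "micro_areas.csv", index=False)
        (d / "areas.json").write_text(json.dumps(self.areas, indent=2))

    @classmethod
    def load(cls, directory, spec: ArenaSpec) -> "MicroAreaMap":
        from pathlib import Path

        df = pd.read_csv(Path(directory) / "micro_areas.csv")
        n = spec.n_cells
        labels = np.zeros((n, n), dtype=np.int8)
        idx = {lab: i for i, lab in enumerate(AREA_LABELS)}
        labels[df.cell_x.to_numpy(), df.cell_y.to_numpy()] = [
            idx[v] for v in df.label
        ]
        return cls(spec, labels)


def _cell_centers(spec: ArenaSpec) -> tuple[np.ndarray, np.ndarray]:
    c = (np.arange(spec.n_cells) + 0.5) * spec.grid_cell
    return np.meshgrid(c, c, indexing="ij")


def perimeter_coordinate(position, spec: ArenaSpec) -> float | None:
    """Arclength of the wall projection of ``position``, or None off-band.

    Positions farther than ``perimeter_band`` from every wall return None.
    The arclength runs from the origin corner up the left wall, along the
    top, down the right wall and back along the bottom, covering
    ``[0, 4·side)``.
    """
    x, y = position
    s = spec.side
    d = {"left": x, "top": s - y, "right": s - x, "bottom": y}
    wall = min(d, key=d.get)
    if d[wall] > spec.perimeter_band:
        return None
    if wall == "left":
        return float(y)
    if wall == "top":
        return float(s + x)
    if wall == "right":
        return float(2 * s + (s - y))
    return float(3 * s + (s - x))


def _perimeter_coords(points: np.ndarray, spec: ArenaSpec) -> np.ndarray:
    """Vectorised wall-collapse; NaN for points outside the band."""
    x, y = points[:, 0], points[:, 1]
    s = spec.side
    dists = np.stack([x, s - y, s - x, y], axis=1)  # left, top, right, bottom
    wall = np.argmin(dists, axis=1)
    wall_d = dists[np.arange(len(x)), wall]
    arclen = np.choose(wall, [y, s + x, 2 * s + (s - y), 3 * s + (s - x)])
    return np.where(wall_d <= spec.perimeter_band, arclen, np.nan)


def partition_micro_areas(
    positions: np.ndarray,
    spec: ArenaSpec | None = None,
    stride: int = 1,
) -> MicroAreaMap:
    """Partition the arena into the four micro-areas from cumulated positions.

    Parameters
    ----------
    positions
        (N, 2) array of cumulated movement positions, mm.  Identity-free:
        all individuals and all times pooled.
    spec
        Arena geometry and DBSCAN parameters.
    stride
        Subsampling stride applied to ``positions`` before clustering, to
        bound memory on day-long inputs.  The occupancy-grid construction
        keeps the partition stable under moderate strides.
    """
    spec = spec or ArenaSpec()
    pts = np.asarray(positions, dtype=float)[::max(1, int(stride))]
    if len(pts) < spec.dbscan_min_pts:
        raise ValueError(
            f"need at least dbscan_min_pts={spec.dbscan_min_pts} positions"
        )
    n = spec.n_cells
    labels = np.full((n, n), AREA_LABELS.index(INTERMEDIATE), dtype=np.int8)

    # 1. food circle first; its cells are excluded from every other label.
    cx, cy = _cell_centers(spec)
    fx, fy = spec.center
    food_mask = (cx - fx) ** 2 + (cy - fy) ** 2 <= (spec.food_diameter / 2) ** 2

    # 2. centre-diffusion: 2-D DBSCAN cluster whose footprint holds the centre.
    # Day-long recordings pile tens of thousands of points into a few cells,
    # which explodes raw DBSCAN neighbourhood lists; clustering the occupied
    # grid cells with occupancy weights is equivalent at grid resolution and
    # bounds memory by the cell count.
    cell_pts, cell_w = _occupied_cells(pts, spec)
    db = DBSCAN(eps=spec.dbscan_eps, min_samples=spec.dbscan_min_pts).fit(
        cell_pts, sample_weight=cell_w
    )
    center_mask = np.zeros((n, n), dtype=bool)
    center_cell = (
        min(int(fx / spec.grid_cell), n - 1),
        min(int(fy / spec.grid_cell), n - 1),
    )
    chosen = None
    for k in set(db.labels_) - {-1}:
        mask = _occupancy(cell_pts[db.labels_ == k], spec)
        if mask[center_cell]:
            chosen = k
            center_mask = mask
            break
    if chosen is None:
        warnings.warn(
            "no position cluster contains the arena centre; "
            "centre-diffusion left empty"
        )

    # 3. edge: wall-band cells backed by a 1-D cluster of collapsed positions.
    edge_mask = np.zeros((n, n), dtype=bool)
    arclens = _perimeter_coords(pts, spec)
    band_coords = arclens[~np.isnan(arclens)]
    if len(band_coords) >= spec.dbscan_min_pts:
        bins = np.round(band_coords / spec.grid_cell).astype(int)
        uniq, counts = np.unique(bins, return_counts=True)
        coords_1d = (uniq * spec.grid_cell).reshape(-1, 1)
        db1 = DBSCAN(eps=spec.dbscan_eps, min_samples=spec.dbscan_min_pts).fit(
            coords_1d, sample_weight=counts.astype(float)
        )
        clustered = np.sort(coords_1d[db1.labels_ != -1, 0])
        if len(clustered):
            wall_d = np.minimum.reduce(
                [cx, cy, spec.side - cx, spec.side - cy]
            )
            in_band = wall_d <= spec.perimeter_band
            cell_arc = _perimeter_coords(
                np.stack([cx[in_band], cy[in_band]], axis=1), spec
            )
            j = np.searchsorted(clustered, cell_arc)
            j_lo = np.clip(j - 1, 0, len(clustered) - 1)
            j_hi = np.clip(j, 0, len(clustered) - 1)
            near = np.minimum(
                np.abs(clustered[j_lo] - cell_arc), np.abs(clustered[j_hi] - cell_arc)
            )
            hit = np.zeros_like(in_band)
            hit[in_band] = near <= spec.dbscan_eps
            edge_mask = hit

    labels[edge_mask] = AREA_LABELS.index(EDGE)
    labels[center_mask & ~edge_mask] = AREA_LABELS.index(CENTER)
    labels[food_mask] = AREA_LABELS.index(FOOD)
    return MicroAreaMap(spec, labels)


def _occupied_cells(points: np.ndarray, spec: ArenaSpec) -> tuple[np.ndarray, np.ndarray]:
    """Unique occupied grid-cell centres and their occupancy counts."""
    n = spec.n_cells
    ix = np.clip((points[:, 0] / spec.grid_cell).astype(int), 0, n - 1)
    iy = np.clip((points[:, 1] / spec.grid_cell).astype(int), 0, n - 1)
    flat = ix * n + iy
    uniq, counts = np.unique(flat, return_counts=True)
    centers = np.column_stack(
        [(uniq // n + 0.5) * spec.grid_cell, (uniq % n + 0.5) * spec.grid_cell]
    )
    return centers, counts.astype(float)


def _occupancy(points: np.ndarray, spec: ArenaSpec) -> np.ndarray:
    """Boolean occupancy grid of a point set."""
    n = spec.n_cells
    ix = np.clip((points[:, 0] / spec.grid_cell).astype(int), 0, n - 1)
    iy = np.clip((points[:, 1] / spec.grid_cell).astype(int), 0, n - 1)
    mask = np.zeros((n, n), dtype=bool)
    mask[ix, iy] = True
    return mask


def assign_area(area_map: MicroAreaMap, position) -> str:
    """Micro-area label of the grid cell containing ``position``."""
    ix, iy = area_map.cell_of(*position)
    return AREA_LABELS[area_map.labels[ix, iy]]


def assign_areas(area_map: MicroAreaMap, table: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`assign_area` over a trajectory table (adds ``area``)."""
    spec = area_map.spec
    n = spec.n_cells
    x = table["x"].to_numpy(dtype=float)
    y = table["y"].to_numpy(dtype=float)
    if (x < 0).any() or (x > spec.side).any() or (y < 0).any() or (y > spec.side).any():
        raise ValueError("positions outside arena")
    ix = np.clip((x / spec.grid_cell).astype(int), 0, n - 1)
    iy = np.clip((y / spec.grid_cell).astype(int), 0, n - 1)
    out = table.copy()
    out["area"] = pd.Categorical(
        [AREA_LABELS[i] for i in area_map.labels[ix, iy]], categories=list(AREA_LABELS)
    )
    return out
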