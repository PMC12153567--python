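"""Dispersion indices of cumulated movement positions in time windows.

Group dispersion is measured identity-free: all individuals' positions in a
fixed time window are pooled into one point set and summarised by

* **cluster count** — number of DBSCAN density clusters (noise excluded),
  representing local groups formed by local enhancement;
* **I-index** — nearest-neighbour aggregation statistic
  ``I = (N+1)·Σ r_i⁴ / (4·(Σ r_i²)²)`` where r_i is the distance from point
  i to its nearest other point;
* **mean crowding (MC)** — ``c = m + v/m`` over lattice-cell occupancy
  counts (m mean, v population variance), a local crowdedness measure;
* **SSI** (social space index) — count of nearest-neighbour distances in
  ``[0, l)`` minus the count in ``[l, 2l)``; at or below 0 suggests no
  social attraction at range l.

Windows are non-overlapping, aligned to phase starts, and swept over window
lengths and spatial scales; window values are averaged per
(trial, area, phase, setting).
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from .arena import AREA_LABELS, ArenaSpec, MicroAreaMap
from .trackio import PhaseSchedule

#: Default window lengths, s.
WINDOWS = (10, 20, 30, 40, 50, 60)
#: Default DBSCAN / SSI unit distances, mm (just under the closest observed
#: inter-fly distance).
EPS_VALUES = (4.0, 8.0)
#: Default MC lattice cell lengths, mm: the arena side divided by
#: 4, 6, 14, 28 and 42, i.e. cells of 1225, 544, 100, 25 and 11.1 mm².
def mc_cell_lengths(side: float = 140.0) -> tuple[float, ...]:
    return tuple(side / k for k in (4, 6, 14, 28, 42))


def nearest_neighbor_distances(points: np.ndarray) -> np.ndarray:
    """Distance from each point to its nearest *other* point."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return d[:, 1]


def cluster_count(points: np.ndarray, eps: float = 4.0, min_pts: int = 5) -> int:
    """Number of DBSCAN clusters at radius ``eps`` and density ``min_pts``.

    Noise points belong to no cluster; an empty or all-noise set counts 0.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return 0
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit(pts).labels_
    return int(len(set(labels) - {-1}))


def i_index(points: np.ndarray) -> float:
    """Nearest-neighbour aggregation index (N+1)Σr⁴ / 4(Σr²)².

    Scale-invariant; 0.375 for every 2-point set and (N+1)/(4N) whenever
    all nearest-neighbour distances are equal.  NaN when all points
    coincide (0/0).
    """
    r = nearest_neighbor_distances(points)
    denom = 4.0 * (r**2).sum() ** 2
    if denom == 0.0:
        return float("nan")
    return float((len(r) + 1) * (r**4).sum() / denom)


def mean_crowding(
    points: np.ndarray,
    cell_length: float,
    region_cells: np.ndarray | None = None,
    side: float = 140.0,
    origin: tuple[float, float] = (0.0, 0.0),
    variance: str = "population",
) -> float:
    """Lattice mean crowding ``c = m + v/m`` over occupancy counts.

    The region is tiled by square cells of ``cell_length`` mm.  By default
    every cell of the ``side``×``side`` lattice enters the count vector;
    ``region_cells`` (boolean (k, k) mask) restricts the lattice to a
    micro-area's cells.  ``variance`` selects the population (divide by the
    cell count; default — m and v describe the realised lattice) or sample
    estimator.  NaN when the region holds no points (m = 0).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    k = int(np.ceil(side / cell_length - 1e-9))
    ix = np.clip(((pts[:, 0] - origin[0]) / cell_length).astype(int), 0, k - 1)
    iy = np.clip(((pts[:, 1] - origin[1]) / cell_length).astype(int), 0, k - 1)
    counts = np.zeros((k, k), dtype=float)
    np.add.at(counts, (ix, iy), 1.0)
    vec = counts[region_cells] if region_cells is not None else counts.ravel()
    if vec.size == 0:
        return float("nan")
    m = float(vec.mean())
    if m == 0.0:
        return float("nan")
    v = float(vec.var(ddof=0 if variance == "population" else 1))
    return m + v / m


def ssi(points: np.ndarray, l: float = 4.0) -> int:
    """First-bin minus second-bin nearest-neighbour frequency.

    Bins are half-open: ``[0, l)`` and ``[l, 2l)``.  Raw counts, not
    percentages, so micro-areas of different occupancy stay comparable on
    an absolute footing.
    """
    r = nearest_neighbor_distances(points)
    return int(np.count_nonzero(r < l) - np.count_nonzero((r >= l) & (r < 2 * l)))


def window_positions(
    table: pd.DataFrame,
    window: int,
    schedule: PhaseSchedule | None = None,
    area: str | None = None,
) -> Iterator[tuple[str, int, pd.DataFrame]]:
    """Yield (phase, window start, window rows) for consecutive windows.

    Windows are non-overlapping, of length ``window`` seconds, aligned to
    each phase start; all individuals' rows in the window are pooled,
    optionally restricted to one micro-area.  The yielded frame keeps
    ``ind`` and ``t`` so per-second social distances remain computable;
    ``frame[["x", "y"]].to_numpy()`` gives the identity-free cumulated
    positions.
    """
    if not (isinstance(window, (int, np.integer)) and window > 0):
        raise ValueError("window must be a positive integer")
    schedule = schedule or PhaseSchedule()
    df = table
    if area is not None:
        df = df[df["area"] == area]
    t = df["t"].to_numpy(dtype=float)
    t_min, t_max = table["t"].min(), table["t"].max()
    for phase, (p0, p1) in schedule.phases.items():
        if p1 <= t_min or p0 > t_max:
            continue
        for w0 in range(p0, min(p1, int(t_max) + 1), window):
            sel = (t >= w0) & (t < w0 + window)
            yield phase, w0, df.loc[sel]


def social_distances(window_frame: pd.DataFrame) -> np.ndarray:
    """Per-second nearest-neighbour distances *between individuals*.

    For every second of the window holding at least two individuals, each
    individual contributes its distance to the nearest other individual at
    that same second; all seconds are pooled.  Unlike distances on the
    cumulated position cloud, these are never contaminated by an
    individual's own 1-s trail.
    """
    out: list[np.ndarray] = []
    for _, snap in window_frame.groupby("t", sort=False):
        if snap["ind"].nunique() < 2:
            continue
        pts = snap.drop_duplicates("ind")[["x", "y"]].to_numpy(dtype=float)
        out.append(nearest_neighbor_distances(pts))
    if not out:
        return np.empty(0)
    return np.concatenate(out)


def ssi_social(window_frame: pd.DataFrame, l: float = 4.0) -> int:
    """Windowed SSI on per-second inter-individual distances.

    First-bin minus second-bin count over all (individual, second) pairs of
    the window; positive when individuals sit within the social distance of
    a conspecific more often than just beyond it.
    """
    r = social_distances(window_frame)
    if r.size == 0:
        raise ValueError("need at least 2 individuals in the window")
    return int(np.count_nonzero(r < l) - np.count_nonzero((r >= l) & (r < 2 * l)))


def _area_region_cells(area_map: MicroAreaMap, area: str, cell_length: float) -> np.ndarray:
    """MC-lattice mask of cells whose centre lies in ``area``."""
    spec = area_map.spec
    k = int(np.ceil(spec.side / cell_length - 1e-9))
    c = (np.arange(k) + 0.5) * cell_length
    cx, cy = np.meshgrid(c, c, indexing="ij")
    cx = np.minimum(cx, spec.side - 1e-9)
    cy = np.minimum(cy, spec.side - 1e-9)
    n = spec.n_cells
    ix = np.clip((cx / spec.grid_cell).astype(int), 0, n - 1)
    iy = np.clip((cy / spec.grid_cell).astype(int), 0, n - 1)
    return np.asarray(
        area_map.labels[ix, iy] == AREA_LABELS.index(area), dtype=bool
    )


def sweep_dispersion(
    table: pd.DataFrame,
    area_map: MicroAreaMap | None = None,
    windows: Iterable[int] = WINDOWS,
    eps_values: Iterable[float] = EPS_VALUES,
    cell_lengths: Iterable[float] | None = None,
    schedule: PhaseSchedule | None = None,
    min_pts: int = 5,
    per_area: bool = True,
) -> pd.DataFrame:
    """Sweep all dispersion parameters over windows, unit distances and scales.

    Returns tidy rows (trial, strain, area, phase, window, eps, cell_length,
    parameter, value): every parameter is computed per window and averaged
    over the windows of each (trial, area, phase, setting).  ``area`` is
    ``"total"`` for the unrestricted arena; with ``per_area`` and an
    ``area``-labelled table, each micro-area is additionally measured on its
    own positions (and, for MC, its own lattice cells).
    """
    schedule = schedule or PhaseSchedule()
    side = area_map.spec.side if area_map is not None else 140.0
    if cell_lengths is None:
        cell_lengths = mc_cell_lengths(side)
    windows = list(windows)
    eps_values = list(eps_values)
    cell_lengths = list(cell_lengths)

    area_scopes: list[str | None] = [None]
    if per_area and "area" in table.columns:
        area_scopes += [a for a in AREA_LABELS if (table["area"] == a).any()]
    region_masks = {}
    if area_map is not None:
        for a in area_scopes:
            if a is not None:
                region_masks[a] = {
                    cl: _area_region_cells(area_map, a, cl) for cl in cell_lengths
                }

    records: list[dict] = []
    for (trial, strain), sub in table.groupby(["trial", "strain"], sort=False, observed=True):
        for scope in area_scopes:
            scope_name = scope or "total"
            for w in windows:
                acc: dict[tuple, list[float]] = {}
                for phase, _, frame in window_positions(sub, w, schedule, scope):
                    pts = frame[["x", "y"]].to_numpy(dtype=float)
                    if len(pts) >= 2:
                        social = social_distances(frame)
                        for eps in eps_values:
                            acc.setdefault((phase, "cluster_count", eps, np.nan), []).append(
                                cluster_count(pts, eps, min_pts)
                            )
                            if social.size:
                                acc.setdefault((phase, "ssi", eps, np.nan), []).append(
                                    int(
                                        np.count_nonzero(social < eps)
                                        - np.count_nonzero(
                                            (social >= eps) & (social < 2 * eps)
                                        )
                                    )
                                )
                        acc.setdefault((phase, "i_index", np.nan, np.nan), []).append(
                            i_index(pts)
                        )
                    if len(pts) >= 1:
                        for cl in cell_lengths:
                            mask = region_masks.get(scope, {}).get(cl) if scope else None
                            acc.setdefault((phase, "mean_crowding", np.nan, cl), []).append(
                                mean_crowding(pts, cl, region_cells=mask, side=side)
                            )
                for (phase, param, eps, cl), vals in acc.items():
                    vals = [v for v in vals if np.isfinite(v)]
                    if not vals:
                        continue
                    records.append(
                        {
                            "trial": trial,
                            "strain": strain,
                            "area": scope_name,
                            "phase": phase,
                            "window": w,
                            "eps": eps,
                            "cell_length": cl,
                            "parameter": param,
                            "value": float(np.mean(vals)),
                        }
                    )
    return pd.DataFrame.from_records(records)
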