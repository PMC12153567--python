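"""Synthetic multi-fly trajectories and analytic point patterns.

The group simulator is a two-state (move/pause) correlated random walk for
each of 10 individuals in a 140 mm square walled arena, sampled at 1 Hz
over 24 h — the design of the observations the analysis pipeline expects.
Moving individuals draw right-skewed (lognormal) step lengths scaled by a
diel phase multiplier, persist in heading, are biased toward the central
food circle and toward their nearest neighbour within a contact range, and
tend to follow the wall inside an edge band.  None of this is a
biomechanical fly model; it reproduces the *statistical* structure the
downstream parameters measure — right-skewed speeds mostly below
0.2 mm/s, diel speed modulation, central and wall occupancy, and local
aggregation at nearest-neighbour ranges of a few millimetres.

Point patterns (:func:`sample_point_pattern`) provide analytically
transparent inputs for the dispersion indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trackio import PhaseSchedule

#: Hard cap on per-second displacement, mm — keeps lognormal tails physical.
STEP_CAP = 20.0

#: Diel speed multipliers: activity peaks in the photo→scoto transition and
#: stays elevated through the scotoperiod.
DEFAULT_PHASE_SCALE = {
    "PI": 1.0,
    "PII": 1.0,
    "PIII": 1.2,
    "P-S": 2.0,
    "SI": 1.5,
    "SII": 1.4,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the group-trajectory simulator.

    Defaults encode the study design: 10 males, 24 h at 1 Hz, a 140 mm
    arena with a 10 mm food circle at its centre, a 14 h photoperiod.
    """

    n_individuals: int = 10
    duration: int = 86_400  # s; scale down for quick runs
    dt: int = 1  # s
    t_offset: int = 0  # s from lights-on; lets a short run sit in any phase
    arena_side: float = 140.0
    food_center: tuple[float, float] | None = None
    food_diameter: float = 10.0
    phase_speed_scale: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_SCALE)
    )
    pause_entry_prob: float = 0.05  # per-second move → pause
    pause_exit_prob: float = 0.25  # per-second pause → move
    base_step: float = 0.1  # mm; median move-state step before phase scaling
    step_sigma: float = 1.5  # lognormal shape: most steps < 0.2 mm yet a
    # few-percent tail beyond 1 mm/s, as arena speed histograms show
    heading_persistence: float = 0.7  # 0 = fresh heading each step
    food_attraction: float = 0.3
    food_range: float = 40.0  # mm; food bias acts only within this radius
    neighbor_attraction: float = 0.5
    neighbor_range: float = 10.0  # mm
    edge_band: float = 5.0  # mm
    wall_follow_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pause_entry_prob", "pause_exit_prob", "wall_follow_prob",
                     "heading_persistence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be at least 1")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.duration % self.dt:
            raise ValueError("duration must be divisible by dt")
        if min(self.food_attraction, self.neighbor_attraction) < 0:
            raise ValueError("attraction weights must be non-negative")

    @property
    def center(self) -> tuple[float, float]:
        return self.food_center or (self.arena_side / 2, self.arena_side / 2)


def _phase_scale_per_second(
    config: SimulationConfig, schedule: PhaseSchedule
) -> np.ndarray:
    labels = schedule.labels
    starts = np.array([schedule.phases[p][0] for p in labels])
    order = np.argsort(starts)
    scale_by_label = np.array(
        [config.phase_speed_scale.get(labels[i], 1.0) for i in order]
    )
    t = (config.t_offset + np.arange(config.duration)) % 86_400
    bins = np.searchsorted(starts[order], t, side="right") - 1
    return scale_by_label[bins]


def simulate_group(
    config: SimulationConfig,
    trial: str = "t1",
    strain: str = "synthetic",
    schedule: PhaseSchedule | None = None,
) -> pd.DataFrame:
    """Simulate one trial; returns rows (trial, strain, ind, t, x, y).

    One row per (individual, integer second), positions in mm inside the
    arena, byte-identical across runs for a fixed ``config.seed``.  Each
    individual owns a random stream spawned deterministically from the root
    seed, so adding individuals does not perturb existing tracks.
    """
    schedule = schedule or PhaseSchedule()
    n, T = config.n_individuals, config.duration // config.dt
    side = config.arena_side
    fx, fy = config.center
    streams = np.random.SeedSequence(config.seed).spawn(n)

    # pre-drawn per-individual randomness (fixed draw order per stream)
    init = np.empty((n, 3))
    pause_u = np.empty((n, T))
    step_len = np.empty((n, T))
    turn = np.empty((n, T))
    wall_u = np.empty((n, T))
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        init[i] = [rng.uniform(0, side), rng.uniform(0, side), rng.uniform(-np.pi, np.pi)]
        pause_u[i] = rng.random(T)
        step_len[i] = rng.lognormal(mean=np.log(config.base_step),
                                    sigma=config.step_sigma, size=T)
        turn[i] = rng.normal(0.0, (1.0 - config.heading_persistence) * np.pi, size=T)
        wall_u[i] = rng.random(T)

    phase_scale = _phase_scale_per_second(config, schedule)
    x = init[:, 0].copy()
    y = init[:, 1].copy()
    heading = init[:, 2].copy()
    paused = np.zeros(n, dtype=bool)

    xs = np.empty((T, n))
    ys = np.empty((T, n))
    xs[0], ys[0] = x, y

    for t in range(1, T):
        # state transition decided before the step
        entering = ~paused & (pause_u[:, t] < config.pause_entry_prob)
        leaving = paused & (pause_u[:, t] < config.pause_exit_prob)
        paused = (paused | entering) & ~leaving
        moving = ~paused

        if moving.any():
            heading[moving] = heading[moving] + turn[moving, t]
            ux = np.cos(heading)
            uy = np.sin(heading)
            vx = ux.copy()
            vy = uy.copy()
            if config.food_attraction > 0:
                dxf, dyf = fx - x, fy - y
                norm = np.hypot(dxf, dyf)
                ok = (norm > 1e-9) & (norm <= config.food_range)
                vx[ok] += config.food_attraction * dxf[ok] / norm[ok]
                vy[ok] += config.food_attraction * dyf[ok] / norm[ok]
            if config.neighbor_attraction > 0 and n > 1:
                dx = x[:, None] - x[None, :]
                dy = y[:, None] - y[None, :]
                dist = np.hypot(dx, dy)
                np.fill_diagonal(dist, np.inf)
                nb = np.argmin(dist, axis=1)
                nbd = dist[np.arange(n), nb]
                ok = nbd <= config.neighbor_range
                if ok.any():
                    vx[ok] += config.neighbor_attraction * (x[nb[ok]] - x[ok]) / nbd[ok]
                    vy[ok] += config.neighbor_attraction * (y[nb[ok]] - y[ok]) / nbd[ok]
            heading[moving] = np.arctan2(vy[moving], vx[moving])

            # wall-following: project heading onto the tangent of the
            # nearest wall while in the edge band
            wall_d = np.minimum.reduce([x, y, side - x, side - y])
            follow = moving & (wall_d <= config.edge_band) & (
                wall_u[:, t] < config.wall_follow_prob
            )
            if follow.any():
                dists = np.stack([x, side - y, side - x, y], axis=1)
                wall = np.argmin(dists, axis=1)
                vertical = (wall == 0) | (wall == 2)  # left/right wall: tangent ±y
                tangent = np.where(vertical, np.pi / 2, 0.0)
                h = heading[follow]
                tg = tangent[follow]
                flip = np.cos(h - tg) < 0
                heading[follow] = np.where(flip, tg + np.pi, tg)

            length = np.minimum(
                step_len[:, t] * phase_scale[t] * config.dt, STEP_CAP * config.dt
            )
            nx = x + np.where(moving, length * np.cos(heading), 0.0)
            ny = y + np.where(moving, length * np.sin(heading), 0.0)
            # reflect at the walls
            nx = np.where(nx < 0, -nx, nx)
            nx = np.where(nx > side, 2 * side - nx, nx)
            ny = np.where(ny < 0, -ny, ny)
            ny = np.where(ny > side, 2 * side - ny, ny)
            nx = np.clip(nx, 0.0, side)
            ny = np.clip(ny, 0.0, side)
            # realized heading (reflections included) feeds the next step
            heading[moving] = np.arctan2(ny - y, nx - x)[moving]
            x, y = nx, ny
        xs[t], ys[t] = x, y

    t_index = config.t_offset + np.arange(T) * config.dt
    frames = []
    for i in range(n):
        frames.append(
            pd.DataFrame(
                {
                    "trial": trial,
                    "strain": strain,
                    "ind": f"{trial}-i{i}",
                    "t": t_index,
                    "x": xs[:, i],
                    "y": ys[:, i],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_trials(
    config: SimulationConfig,
    n_trials: int = 8,
    strain: str = "synthetic",
    trial_prefix: str = "t",
) -> pd.DataFrame:
    """Simulate a strain's worth of replicate trials with derived seeds."""
    parts = []
    for j in range(n_trials):
        cfg = replace(config, seed=(config.seed * 1_000_003 + j) % (2**31 - 1))
        parts.append(simulate_group(cfg, trial=f"{trial_prefix}{j + 1}", strain=strain))
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# analytic point patterns


@dataclass(frozen=True)
class PatternSpec:
    """Recipe for an analytically transparent point set."""

    kind: str  # uniform | single_cluster | k_clusters | clustered_plus_outlier | grid
    n_points: int = 50
    region: tuple[float, float, float, float] = (0.0, 0.0, 140.0, 140.0)
    cluster_sd: float = 1.0
    k: int = 3
    centers: tuple[tuple[float, float], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be at least 1")
        x0, y0, x1, y1 = self.region
        if x1 <= x0 or y1 <= y0:
            raise ValueError("degenerate region")
        if self.kind in ("single_cluster", "k_clusters", "clustered_plus_outlier"):
            if self.cluster_sd <= 0:
                raise ValueError("cluster_sd must be positive")


def _blob(rng, center, sd, n, region):
    x0, y0, x1, y1 = region
    pts = rng.normal(loc=center, scale=sd, size=(n, 2))
    pts[:, 0] = np.clip(pts[:, 0], x0, x1)
    pts[:, 1] = np.clip(pts[:, 1], y0, y1)
    return pts


def sample_point_pattern(spec: PatternSpec) -> np.ndarray:
    """Sample an (n_points, 2) array according to the pattern recipe.

    ``grid`` is deterministic: a near-square regular lattice of cell
    centres.  ``k_clusters`` places k Gaussian blobs at the given centres,
    or at a jittered regular layout guaranteeing separation.
    """
    rng = np.random.default_rng(spec.seed)
    x0, y0, x1, y1 = spec.region
    w, h = x1 - x0, y1 - y0
    n = spec.n_points

    if spec.kind == "uniform":
        return np.column_stack(
            [rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)]
        )
    if spec.kind == "grid":
        k = int(np.ceil(np.sqrt(n)))
        cx = x0 + (np.arange(k) + 0.5) * w / k
        cy = y0 + (np.arange(k) + 0.5) * h / k
        gx, gy = np.meshgrid(cx, cy, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])[:n]
    if spec.kind == "single_cluster":
        center = ((x0 + x1) / 2, (y0 + y1) / 2)
        return _blob(rng, center, spec.cluster_sd, n, spec.region)
    if spec.kind == "k_clusters":
        if spec.centers is not None:
            centers = np.asarray(spec.centers, dtype=float)
        else:
            g = int(np.ceil(np.sqrt(spec.k)))
            cx = x0 + (np.arange(g) + 0.5) * w / g
            cy = y0 + (np.arange(g) + 0.5) * h / g
            gx, gy = np.meshgrid(cx, cy, indexing="ij")
            centers = np.column_stack([gx.ravel(), gy.ravel()])[: spec.k]
        sizes = np.full(spec.k, n // spec.k)
        sizes[: n % spec.k] += 1
        return np.vstack(
            [_blob(rng, c, spec.cluster_sd, s, spec.region)
             for c, s in zip(centers, sizes)]
        )
    if spec.kind == "clustered_plus_outlier":
        center = (x0 + w / 4, y0 + h / 4)
        pts = _blob(rng, center, spec.cluster_sd, n - 1, spec.region)
        return np.vstack([pts, [(x1 - 1e-6, y1 - 1e-6)]])
    raise ValueError(f"unknown pattern kind: {spec.kind!r}")


# ---------------------------------------------------------------------------
# deterministic unit-test fixture


def make_reference_fixture() -> pd.DataFrame:
    """Tiny hand-constructed trajectory table with known parameter values.

    Two individuals, 60 s each, trial ``ref``:

    * ``A`` moves at exactly 1 mm/s throughout — 50 steps east then, after
      a single 90° turn, 9 steps north; mean speed 1.0 mm/s, no pause.
    * ``B`` moves at 0.5 mm/s west for 30 s, holds position for 10
      consecutive seconds (one pause bout of 10 s), then moves north at
      0.5 mm/s.
    """
    t = np.arange(60)

    ax = np.where(t <= 50, 10.0 + t, 60.0)
    ay = np.where(t <= 50, 10.0, 10.0 + (t - 50))

    bx = np.where(t <= 30, 100.0 - 0.5 * t, 85.0)
    by = np.where(t <= 40, 100.0, 100.0 + 0.5 * (t - 40))

    rows = []
    for ind, x, y in (("A", ax, ay), ("B", bx, by)):
        rows.append(
            pd.DataFrame(
                {"trial": "ref", "strain": "fixture", "ind": ind,
                 "t": t, "x": x, "y": y}
            )
        )
    return pd.concat(rows, ignore_index=True)
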