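"""Instantaneous movement parameters of 1-Hz tracks.

All parameters are defined on per-second displacement units of a single
individual and then aggregated — per individual first, then unweighted over
individuals — to one value per (trial, micro-area, light phase):

* **speed** — mean displacement per second over all units, pauses included.
* **locomotory rate** — mean speed over moving units only (displacement at
  or above the pause threshold).
* **DCR** (direction change rate) — absolute heading change per second in
  [0, 180]°; undefined while either flanking displacement is sub-threshold.
* **sinuosity** — path length over net start-to-end displacement of a
  segment; 1 for a straight path, larger the more tortuous.
* **stop number / stop time** — count and total duration of maximal runs of
  sub-threshold units (pause bouts).
* **duration rate** — percentage of unit-seconds a group spends in a
  micro-area during a phase.

A 1-s unit is attributed to the micro-area of its starting position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arena import AREA_LABELS, MicroAreaMap, assign_areas
from .trackio import PhaseSchedule, assign_phases

#: Default pause threshold, mm per 1-s unit.  Tracked centroids jitter, so
#: "no movement" is operationalised as sub-threshold displacement; the bulk
#: of observed per-second speeds sits well below 0.2 mm/s, motivating 0.25.
PAUSE_THRESHOLD = 0.25

PARAMETERS = (
    "speed",
    "locomotory_rate",
    "dcr",
    "sinuosity",
    "stop_number",
    "stop_time",
    "duration_rate",
)


@dataclass(frozen=True)
class KinematicsThresholds:
    pause_threshold: float = PAUSE_THRESHOLD  # mm per unit
    min_net: float = 0.1  # mm; sinuosity undefined below this net displacement
    min_bout_samples: int = 3  # sinuosity needs at least this many positions


def step_displacements(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Euclidean displacement of each 1-s unit (length n-1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    return np.hypot(np.diff(x), np.diff(y))


def mean_speed(displacements: np.ndarray, dt: float = 1.0) -> float:
    """Mean displacement rate over all units, pauses included, mm/s."""
    d = np.asarray(displacements, dtype=float)
    if d.size == 0:
        raise ValueError("empty displacement series")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return float(d.mean() / dt)


def locomotory_rate(
    displacements: np.ndarray, pause_threshold: float = PAUSE_THRESHOLD, dt: float = 1.0
) -> float:
    """Mean speed over moving units only; NaN when no unit moves."""
    d = np.asarray(displacements, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    moving = d[d >= pause_threshold]
    if moving.size == 0:
        return float("nan")
    return float(moving.mean() / dt)


def direction_change_rate(
    x: np.ndarray,
    y: np.ndarray,
    pause_threshold: float = PAUSE_THRESHOLD,
) -> np.ndarray:
    """Absolute heading change per unit, degrees in [0, 180].

    Heading is undefined over sub-threshold displacements; interior units
    flanked by any such displacement yield NaN rather than zero, so rest
    does not deflate the rate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    dx, dy = np.diff(x), np.diff(y)
    disp = np.hypot(dx, dy)
    heading = np.arctan2(dy, dx)
    turn = np.abs(np.angle(np.exp(1j * np.diff(heading))))
    dcr = np.degrees(turn)
    defined = (disp[:-1] >= pause_threshold) & (disp[1:] >= pause_threshold)
    return np.where(defined, dcr, np.nan)


def sinuosity(
    x: np.ndarray, y: np.ndarray, min_net: float = 0.1
) -> float:
    """Path length over net displacement for one segment; NaN if the net
    start-to-end displacement is below ``min_net`` mm (closed loops)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 positions")
    path = float(np.hypot(np.diff(x), np.diff(y)).sum())
    net = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
    if net < min_net:
        return float("nan")
    return path / net


def detect_pauses(
    displacements: np.ndarray, pause_threshold: float = PAUSE_THRESHOLD, dt: float = 1.0
) -> list[tuple[int, int]]:
    """Maximal runs of sub-threshold units as ``(start_index, length)`` bouts."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    paused = np.asarray(displacements, dtype=float) < pause_threshold
    bouts: list[tuple[int, int]] = []
    start = None
    for i, p in enumerate(paused):
        if p and start is None:
            start = i
        elif not p and start is not None:
            bouts.append((start, i - start))
            start = None
    if start is not None:
        bouts.append((start, len(paused) - start))
    return bouts


def stop_stats(
    displacements: np.ndarray, pause_threshold: float = PAUSE_THRESHOLD, dt: float = 1.0
) -> tuple[int, float]:
    """(stop number, stop time in seconds) from the pause bouts."""
    bouts = detect_pauses(displacements, pause_threshold, dt)
    return len(bouts), float(sum(n for _, n in bouts) * dt)


def duration_rate(labeled: pd.DataFrame) -> pd.DataFrame:
    """Percentage of unit-seconds per (trial, area, phase).

    For each phase the four micro-area percentages sum to 100.  Input rows
    must carry ``area`` and ``phase`` labels.
    """
    counts = (
        labeled.groupby(["trial", "phase", "area"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    totals = counts.groupby(["trial", "phase"], observed=True)["n"].transform("sum")
    if (totals == 0).any():
        raise ValueError("phase with zero rows")
    counts["duration_rate"] = 100.0 * counts["n"] / totals
    return counts.drop(columns="n")


def _label_steps(grp: pd.DataFrame) -> pd.DataFrame:
    """Per-unit frame for one individual: displacement + start-position labels."""
    x = grp["x"].to_numpy(dtype=float)
    y = grp["y"].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "disp": np.hypot(np.diff(x), np.diff(y)),
            "area": grp["area"].to_numpy()[:-1],
            "phase": grp["phase"].to_numpy()[:-1],
        }
    )


def summarize_kinematics(
    table: pd.DataFrame,
    area_map: MicroAreaMap,
    schedule: PhaseSchedule | None = None,
    thresholds: KinematicsThresholds | None = None,
) -> pd.DataFrame:
    """All movement parameters per (trial, strain, area, phase), tidy.

    The table must be 1 Hz; area and phase labels are attached if absent.
    Each individual contributes one value per parameter and cell; the trial
    value is the unweighted mean over its individuals.  Sinuosity is
    computed per continuous residence bout of one individual within one
    area and phase (bouts shorter than ``min_bout_samples`` skipped) and
    averaged over bouts.  Stop number and stop time are totals per cell.
    """
    th = thresholds or KinematicsThresholds()
    if "area" not in table.columns:
        table = assign_areas(area_map, table)
    if "phase" not in table.columns:
        table = assign_phases(table, schedule)

    rows: list[dict] = []
    for (trial, strain, ind), grp in table.groupby(
        ["trial", "strain", "ind"], sort=False, observed=True
    ):
        grp = grp.sort_values("t", kind="mergesort")
        if len(grp) < 2:
            continue
        steps = _label_steps(grp)
        x = grp["x"].to_numpy(dtype=float)
        y = grp["y"].to_numpy(dtype=float)
        dcr_series = (
            direction_change_rate(x, y, th.pause_threshold) if len(grp) >= 3 else None
        )

        # contiguous residence bouts of constant (area, phase)
        lab = steps["area"].astype(str) + "\x00" + steps["phase"].astype(str)
        bout_id = (lab != lab.shift()).cumsum()

        for (area, phase), cell in steps.groupby(["area", "phase"], observed=True):
            idx = cell.index.to_numpy()
            disp = cell["disp"].to_numpy()
            n_stop, t_stop = stop_stats(disp, th.pause_threshold)
            # DCR units sit between steps i and i+1; attribute to step i's cell
            if dcr_series is not None:
                dcr_vals = dcr_series[idx[idx < len(dcr_series)]]
                dcr_vals = dcr_vals[~np.isnan(dcr_vals)]
            else:
                dcr_vals = np.array([])
            sins = []
            for _, bout in cell.groupby(bout_id.loc[idx]):
                bidx = bout.index.to_numpy()
                # positions spanning the bout's steps: start of first .. end of last
                pos = np.arange(bidx[0], bidx[-1] + 2)
                if len(pos) >= th.min_bout_samples:
                    s = sinuosity(x[pos], y[pos], th.min_net)
                    if np.isfinite(s):
                        sins.append(s)
            rows.append(
                {
                    "trial": trial,
                    "strain": strain,
                    "ind": ind,
                    "area": area,
                    "phase": phase,
                    "speed": mean_speed(disp),
                    "locomotory_rate": locomotory_rate(disp, th.pause_threshold),
                    "dcr": float(np.mean(dcr_vals)) if dcr_vals.size else np.nan,
                    "sinuosity": float(np.mean(sins)) if sins else np.nan,
                    "stop_number": float(n_stop),
                    "stop_time": t_stop,
                    "n_units": len(disp),
                }
            )
    per_ind = pd.DataFrame(rows)
    if per_ind.empty:
        raise ValueError("no individual produced at least two samples")

    agg = {p: "mean" for p in ("speed", "locomotory_rate", "dcr", "sinuosity")}
    agg.update({"stop_number": "sum", "stop_time": "sum", "n_units": "sum"})
    summary = (
        per_ind.groupby(["trial", "strain", "area", "phase"], observed=True)
        .agg(agg)
        .reset_index()
    )

    dur = duration_rate(table)
    summary = summary.merge(dur, on=["trial", "area", "phase"], how="left")
    return summary


def to_tidy(summary: pd.DataFrame) -> pd.DataFrame:
    """Wide per-cell summary → tidy (trial, strain, area, phase, parameter, value)."""
    value_cols = [c for c in PARAMETERS if c in summary.columns]
    return summary.melt(
        id_vars=["trial", "strain", "area", "phase"],
        value_vars=value_cols,
        var_name="parameter",
        value_name="value",
    )
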