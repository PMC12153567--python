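"""Reading, validating, resampling and phase-annotating trajectory tables.

A trajectory table is a tidy :class:`pandas.DataFrame` with columns
``trial, strain, ind, t, x, y`` — one row per (individual, time sample),
coordinates in millimetres, time in seconds.  After resampling, ``t`` is an
integer second and consecutive samples of one individual differ by exactly
one second.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("trial", "strain", "ind", "t", "x", "y")

#: Seconds per hour, used for phase arithmetic.
HOUR = 3600


@dataclass(frozen=True)
class PhaseSchedule:
    """Six contiguous 4-h diel phases covering a 24-h light:dark cycle.

    The default schedule places three phases in the photoperiod (PI, PII,
    PIII), one transitional phase straddling lights-off (P-S), and two in the
    scotoperiod (SI, SII).  With a 14 h photoperiod and 10 h scotoperiod,
    lights-off at t = 14 h falls inside P-S = [12 h, 16 h).

    Intervals are half-open ``[start, end)`` in seconds from lights-on.
    """

    photoperiod_s: int = 14 * HOUR
    scotoperiod_s: int = 10 * HOUR
    phases: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "PI": (0, 4 * HOUR),
            "PII": (4 * HOUR, 8 * HOUR),
            "PIII": (8 * HOUR, 12 * HOUR),
            "P-S": (12 * HOUR, 16 * HOUR),
            "SI": (16 * HOUR, 20 * HOUR),
            "SII": (20 * HOUR, 24 * HOUR),
        }
    )

    def __post_init__(self) -> None:
        if self.photoperiod_s + self.scotoperiod_s != 24 * HOUR:
            raise ValueError("photoperiod + scotoperiod must equal 24 h")
        edges = sorted(self.phases.values())
        if edges[0][0] != 0 or edges[-1][1] != 24 * HOUR:
            raise ValueError("phases must cover [0, 24 h)")
        for (_, e0), (s1, _) in zip(edges, edges[1:]):
            if e0 != s1:
                raise ValueError("phases must be contiguous")

    @property
    def labels(self) -> list[str]:
        return list(self.phases)

    def phase_of(self, t: float) -> str:
        """Label of the phase whose half-open interval contains ``t``."""
        if t < 0 or t >= 24 * HOUR:
            raise ValueError(f"t={t} outside [0, 86400)")
        for label, (s, e) in self.phases.items():
            if s <= t < e:
                return label
        raise AssertionError("unreachable: phases cover [0, 24 h)")


class TrajectoryValidationError(ValueError):
    """Raised when a trajectory file violates the table contract."""


def validate_trajectories(df: pd.DataFrame, arena_side: float) -> pd.DataFrame:
    """Check column presence, coordinate bounds and key uniqueness.

    Returns the table sorted by (trial, ind, t).  Rows with coordinates
    outside ``[0, arena_side]`` and duplicated (trial, ind, t) keys raise
    :class:`TrajectoryValidationError` naming the offending rows.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryValidationError(f"missing columns: {missing}")
    for c in ("t", "x", "y"):
        if not np.issubdtype(df[c].dtype, np.number):
            raise TrajectoryValidationError(f"non-numeric column: {c!r}")
    bad = df[(df.x < 0) | (df.x > arena_side) | (df.y < 0) | (df.y > arena_side)]
    if len(bad):
        raise TrajectoryValidationError(
            f"{len(bad)} rows outside the {arena_side} mm arena; "
            f"first offending row index {bad.index[0]}: "
            f"(x={bad.x.iloc[0]}, y={bad.y.iloc[0]})"
        )
    dup = df.duplicated(subset=["trial", "ind", "t"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["trial", "ind", "t"]].drop_duplicates().head(5)
        raise TrajectoryValidationError(
            f"duplicate (trial, ind, t) keys: {keys.to_dict('records')}"
        )
    return df.sort_values(["trial", "ind", "t"], kind="mergesort").reset_index(drop=True)


def read_trajectories(path, arena_side: float = 140.0) -> pd.DataFrame:
    """Read a trajectory CSV (header trial,strain,ind,t,x,y) and validate it."""
    df = pd.read_csv(path)
    return validate_trajectories(df, arena_side)


def write_trajectories(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=list(REQUIRED_COLUMNS))


def resample_to_unit(
    raw: pd.DataFrame, max_gap: float = 5.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Downsample an arbitrary-rate stream to 1 Hz by nearest-frame selection.

    For each individual and each integer second spanned by its samples, the
    frame whose timestamp is nearest to that second is selected; ties break
    toward the earlier frame.  No interpolation is performed, so no motion is
    manufactured between frames.

    Returns ``(table, gap_report)`` where ``gap_report`` lists target seconds
    whose nearest frame is farther than ``max_gap`` seconds (those seconds
    are dropped from the output).
    """
    if raw.empty:
        raise ValueError("empty input")
    out_rows: list[pd.DataFrame] = []
    gaps: list[dict] = []
    for (trial, ind), grp in raw.groupby(["trial", "ind"], sort=False):
        grp = grp.sort_values("t", kind="mergesort")
        ts = grp["t"].to_numpy(dtype=float)
        seconds = np.arange(np.ceil(ts.min()), np.floor(ts.max()) + 1, dtype=float)
        if len(seconds) == 0:
            continue
        # nearest frame per target second, earlier frame on ties
        idx = np.searchsorted(ts, seconds)
        idx_lo = np.clip(idx - 1, 0, len(ts) - 1)
        idx_hi = np.clip(idx, 0, len(ts) - 1)
        d_lo = np.abs(ts[idx_lo] - seconds)
        d_hi = np.abs(ts[idx_hi] - seconds)
        take = np.where(d_lo <= d_hi, idx_lo, idx_hi)
        dist = np.minimum(d_lo, d_hi)
        ok = dist <= max_gap
        for sec, d in zip(seconds[~ok], dist[~ok]):
            gaps.append({"trial": trial, "ind": ind, "t": int(sec), "nearest_frame_s": d})
        sel = grp.iloc[take[ok]].copy()
        sel["t"] = seconds[ok].astype(int)
        out_rows.append(sel)
    table = pd.concat(out_rows, ignore_index=True)
    table = table.sort_values(["trial", "ind", "t"], kind="mergesort").reset_index(drop=True)
    return table, pd.DataFrame(gaps, columns=["trial", "ind", "t", "nearest_frame_s"])


def assign_phases(table: pd.DataFrame, schedule: PhaseSchedule | None = None) -> pd.DataFrame:
    """Attach a ``phase`` column labelling each row by its diel phase."""
    schedule = schedule or PhaseSchedule()
    t = table["t"].to_numpy(dtype=float)
    if (t < 0).any() or (t >= 24 * HOUR).any():
        raise ValueError("t outside [0, 86400); phase undefined")
    labels = schedule.labels
    starts = np.array([schedule.phases[p][0] for p in labels], dtype=float)
    order = np.argsort(starts)
    sorted_starts = starts[order]
    sorted_labels = [labels[i] for i in order]
    bins = np.searchsorted(sorted_starts, t, side="right") - 1
    out = table.copy()
    out["phase"] = pd.Categorical(
        [sorted_labels[i] for i in bins], categories=sorted_labels
    )
    return out


def fill_gaps(table: pd.DataFrame, max_gap: int = 5) -> pd.DataFrame:
    """Forward-fill missing integer seconds up to ``max_gap`` per individual.

    Gaps longer than ``max_gap`` are left open (the track splits into bouts);
    a warning reports how many seconds stayed missing.
    """
    out: list[pd.DataFrame] = []
    n_open = 0
    for (trial, ind), grp in table.groupby(["trial", "ind"], sort=False):
        grp = grp.sort_values("t", kind="mergesort")
        t = grp["t"].to_numpy(dtype=int)
        full = np.arange(t[0], t[-1] + 1)
        g = grp.set_index("t").reindex(full)
        observed = g["x"].notna().to_numpy()
        # fill a gap only when its whole length is at most max_gap; longer
        # gaps stay open and split the track into bouts
        fill_ok = observed.copy()
        i = 0
        while i < len(full):
            if not observed[i]:
                j = i
                while j < len(full) and not observed[j]:
                    j += 1
                if j - i <= max_gap:
                    fill_ok[i:j] = True
                i = j
            else:
                i += 1
        n_open += int((~fill_ok).sum())
        g = g.ffill()
        g = g[fill_ok]
        g["trial"], g["ind"] = trial, ind
        out.append(g.reset_index(names="t"))
    if n_open:
        warnings.warn(f"{n_open} seconds in gaps longer than {max_gap} s left unfilled")
    res = pd.concat(out, ignore_index=True)
    return res[list(REQUIRED_COLUMNS)].sort_values(
        ["trial", "ind", "t"], kind="mergesort"
    ).reset_index(drop=True)
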