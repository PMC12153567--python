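"""Summary surfaces: behaviour profiles, normalized panels, CV tables and
averaged log-probability grids.

The heatmap grids visualise *relative differentiation* of parameters across
cells — averaged common-log p-values of the two paired tests — and are
explicitly not significance maps.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .arena import AREA_LABELS


def behavior_profile(summary: pd.DataFrame) -> pd.DataFrame:
    """One row per (strain, phase): arena-wide mean speed + duration rates.

    ``summary`` is the wide kinematics table (one row per trial, area,
    phase).  Speed is averaged over trials and areas weighted by occupancy
    (unit counts); duration rates are averaged over trials per area and sum
    to 100 within each row.
    """
    needed = {"strain", "phase", "area", "speed", "duration_rate", "n_units"}
    missing = needed - set(summary.columns)
    if missing:
        raise ValueError(f"summary lacks columns: {sorted(missing)}")
    rows = []
    for (strain, phase), g in summary.groupby(["strain", "phase"], observed=True):
        if g["area"].nunique() == 0:
            raise ValueError(f"no areas for phase {phase}")
        w = g["n_units"].to_numpy(dtype=float)
        speed = float(np.average(g["speed"].to_numpy(), weights=w))
        row = {"strain": strain, "phase": phase, "speed": speed}
        per_trial = g.pivot_table(
            index="trial", columns="area", values="duration_rate",
            fill_value=0.0, observed=False,
        )
        for a in AREA_LABELS:
            row[f"duration_{a}"] = float(per_trial[a].mean()) if a in per_trial else 0.0
        rows.append(row)
    out = pd.DataFrame(rows)
    return out


def normalize_minmax(series) -> np.ndarray:
    """Min–max rescale to [0, 1]; constant input maps to 0.5 with a warning.

    Display-only: raw values are what enters the statistics.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        warnings.warn("constant series; min–max normalization undefined, using 0.5")
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def probability_heatmap(
    p_wilcoxon: np.ndarray, p_permutation: np.ndarray
) -> np.ndarray:
    """Cellwise mean of log10 p across the two paired tests.

    Inputs are equal-shaped grids of p-values in (0, 1]; zeros are clamped
    to the smallest positive float with a warning.  Output is ≤ 0
    everywhere and monotone in each input.
    """
    pw = np.asarray(p_wilcoxon, dtype=float)
    pp = np.asarray(p_permutation, dtype=float)
    if pw.shape != pp.shape:
        raise ValueError("p grids must have equal shape")
    tiny = np.finfo(float).tiny
    if (pw <= 0).any() or (pp <= 0).any():
        warnings.warn("p = 0 encountered; clamping to the smallest positive float")
        pw = np.maximum(pw, tiny)
        pp = np.maximum(pp, tiny)
    return (np.log10(pw) + np.log10(pp)) / 2.0


def heatmap_grids(results: pd.DataFrame) -> dict[tuple[str, str, str], pd.DataFrame]:
    """Averaged log10-p grids per (strain, parameter, factor) from a tidy
    result table produced by :func:`flygroup.stats.run_comparisons`."""
    grids: dict[tuple[str, str, str], pd.DataFrame] = {}
    pair = results[results["test"].isin(["wilcoxon", "permutation"])]
    for (strain, parameter, factor), g in pair.groupby(
        ["strain", "parameter", "factor"], observed=True
    ):
        pw = g[g.test == "wilcoxon"].pivot_table(
            index="held", columns=["cell_a", "cell_b"], values="p", observed=True
        )
        pp = g[g.test == "permutation"].pivot_table(
            index="held", columns=["cell_a", "cell_b"], values="p", observed=True
        )
        pp = pp.reindex(index=pw.index, columns=pw.columns)
        grid = pd.DataFrame(
            probability_heatmap(pw.to_numpy(), pp.to_numpy()),
            index=pw.index, columns=pw.columns,
        )
        grids[(strain, parameter, factor)] = grid
    return grids


def render_heatmap(grid: pd.DataFrame, path, title: str = "") -> None:
    """Optional PNG rendering of one log10-p grid (relative differences,
    not statistical significance)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + 0.6 * grid.shape[1], 1 + 0.5 * grid.shape[0]))
    im = ax.imshow(grid.to_numpy(), cmap="viridis_r", aspect="auto")
    ax.set_xticks(range(grid.shape[1]))
    ax.set_xticklabels(["–".join(map(str, c)) for c in grid.columns], rotation=90)
    ax.set_yticks(range(grid.shape[0]))
    ax.set_yticklabels(grid.index)
    fig.colorbar(im, ax=ax, label="mean log10 p (relative difference, not significance)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
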