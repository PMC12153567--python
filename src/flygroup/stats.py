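"""Paired nonparametric differentiation of per-trial behavioural parameters.

Each trial contributes one representative value per (area, phase,
parameter): per-trial means are treated as approximately Gaussian by the
central limit theorem, but comparisons rely on exact distribution-free
paired tests because the underlying per-second data are strongly
right-skewed.

The scheme: a Friedman test first screens each released factor (micro-areas
within a phase, or phases within an area — the two factors are coupled in
the raw design and are analysed separately); where it runs, every treatment
pair is compared with BOTH the exact Wilcoxon signed-rank test (ranks) and
the exact paired sign-flip permutation test (means), at an alpha divided by
the number of pairs (0.05/6 = 0.0083 for four areas, 0.05/15 = 0.00333 for
six phases).  Strain contrasts are paired by trial index and flagged at
0.05 and at a 0.10 trend level.

Exactness: at the study size of n = 8 trials both paired tests enumerate
all 2^8 sign assignments, so the p-values are combinatorial constants, not
approximations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Full enumeration bounds; beyond them the Wilcoxon test falls back to the
#: normal approximation and the permutation test to seeded Monte-Carlo.
WILCOXON_EXACT_MAX_N = 12
PERMUTATION_EXACT_MAX_N = 16


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p: float
    n: int
    adjusted_alpha: float = 0.05
    extra: dict | None = None

    @property
    def significant(self) -> bool:
        return self.p < self.adjusted_alpha


# ---------------------------------------------------------------------------
# representatives


def trial_representatives(values: np.ndarray) -> tuple[float, float, float]:
    """(mean, sample SD, CV) of per-trial values; CV is NaN at mean 0."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 trials")
    m = float(v.mean())
    sd = float(v.std(ddof=1))
    cv = sd / m if m != 0 else float("nan")
    return m, sd, cv


def summarize_representatives(
    tidy: pd.DataFrame, by=("strain", "area", "phase", "parameter")
) -> pd.DataFrame:
    """Mean, SD and CV over trials for every cell of a tidy value table."""
    def _agg(g: pd.Series) -> pd.Series:
        m, sd, cv = trial_representatives(g.to_numpy())
        return pd.Series({"mean": m, "sd": sd, "cv": cv, "n_trials": g.size})

    return (
        tidy.groupby(list(by), observed=True)["value"].apply(_agg).unstack().reset_index()
    )


# ---------------------------------------------------------------------------
# Friedman


def friedman_test(matrix: np.ndarray) -> TestResult:
    """Friedman rank test over a blocks × treatments matrix.

    Values are ranked within each block (average ranks on ties); the
    tie-corrected chi-square statistic is referred to the chi-square
    distribution with k−1 degrees of freedom.  A matrix whose every block
    is fully tied carries no ordering information and returns statistic 0,
    p = 1.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 blocks and 2 treatments")
    n, k = m.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, m)
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * (rank_sums**2).sum() - 3.0 * n * (k + 1)
    # tie correction: 1 - sum(t^3 - t) / (n (k^3 - k))
    tie_term = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float((counts**3 - counts).sum())
    correction = 1.0 - tie_term / (n * (k**3 - k))
    if correction <= 0:
        return TestResult("friedman", 0.0, 1.0, n)
    chi2 /= correction
    p = float(sps.chi2.sf(chi2, df=k - 1))
    return TestResult("friedman", float(chi2), p, n)


# ---------------------------------------------------------------------------
# exact paired tests


def _signed_ranks(differences: np.ndarray) -> np.ndarray:
    """Average ranks of |d| after dropping zero differences."""
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size < 2:
        raise ValueError("need at least 2 non-zero differences")
    return d, sps.rankdata(np.abs(d))


def wilcoxon_signed_rank(differences: np.ndarray) -> TestResult:
    """Exact two-sided Wilcoxon signed-rank test on paired differences.

    Conventions: zero differences dropped, average ranks on tied absolute
    values, statistic W = min(positive-rank sum, negative-rank sum).  For
    n ≤ 12 the two-sided p is the exact share of the 2^n equally likely
    sign assignments whose min-rank-sum is at most the observed W (the
    sign-flip distribution is symmetric, so this equals twice the one-tail
    mass, capped at 1).  Larger n uses the tie-corrected normal
    approximation.
    """
    d, ranks = _signed_ranks(differences)
    n = d.size
    w_pos = float(ranks[d > 0].sum())
    total = float(ranks.sum())
    w = min(w_pos, total - w_pos)
    if n <= WILCOXON_EXACT_MAX_N:
        sums = np.zeros(1)
        for r in ranks:  # convolution over sign choices
            sums = np.concatenate([sums, sums + r])
        mins = np.minimum(sums, total - sums)
        p = float(np.count_nonzero(mins <= w + 1e-9) / len(sums))
    else:
        mu = total / 2.0
        # variance of the rank sum under sign flips: sum(r^2)/4
        sigma = np.sqrt((ranks**2).sum() / 4.0)
        z = (w - mu) / sigma
        p = float(min(1.0, 2.0 * sps.norm.cdf(z)))
    return TestResult("wilcoxon", w, p, n)


def paired_permutation(
    differences: np.ndarray, seed: int | None = None, n_resamples: int = 20000
) -> TestResult:
    """Exact two-sided paired sign-flip permutation test on the mean.

    The statistic is the observed mean difference Δμ; the p-value is the
    share of sign assignments s ∈ {−1, +1}^n with |mean(s·d)| ≥ |Δμ|,
    including the observed assignment (so p > 0 and the test is valid).
    Full 2^n enumeration for n ≤ 16; seeded Monte-Carlo beyond.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 paired differences")
    n = d.size
    observed = float(d.mean())
    if np.all(d == 0):
        return TestResult("permutation", 0.0, 1.0, n)
    tol = 1e-12 * max(1.0, np.abs(d).max())
    if n <= PERMUTATION_EXACT_MAX_N:
        sums = np.zeros(1)
        for x in d:
            sums = np.concatenate([sums - x, sums + x])
        means = sums / n
        p = float(np.count_nonzero(np.abs(means) >= abs(observed) - tol) / len(means))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_resamples, n))
        means = (signs * d).mean(axis=1)
        hits = np.count_nonzero(np.abs(means) >= abs(observed) - tol)
        p = float((hits + 1) / (n_resamples + 1))
    return TestResult("permutation", observed, p, n)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


def rm_anova_two_way(data: np.ndarray) -> dict[str, TestResult]:
    """Two-way fully within-subject ANOVA on a (subjects, A, B) array.

    Every subject (trial) is measured in every A×B cell.  Each effect is
    tested against its own subject-interaction error term: MS_A over
    MS_{A×S}, MS_B over MS_{B×S}, and MS_{A×B} over MS_{A×B×S}.  The
    between-subjects effect is reported for completeness.  Requires a
    complete balanced design (no NaNs).
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 3:
        raise ValueError("data must be (subjects, A, B)")
    if np.isnan(y).any():
        raise ValueError("unbalanced design: missing cells")
    s, a, b = y.shape
    if min(s, a, b) < 2:
        raise ValueError("need at least 2 levels on every axis")
    gm = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_s = a * b * ((m_s - gm) ** 2).sum()
    ss_a = s * b * ((m_a - gm) ** 2).sum()
    ss_b = s * a * ((m_b - gm) ** 2).sum()
    ss_as = b * ((m_sa - m_s[:, None] - m_a[None, :] + gm) ** 2).sum()
    ss_bs = a * ((m_sb - m_s[:, None] - m_b[None, :] + gm) ** 2).sum()
    ss_ab = s * ((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2).sum()
    ss_tot = ((y - gm) ** 2).sum()
    ss_abs = ss_tot - ss_s - ss_a - ss_b - ss_as - ss_bs - ss_ab

    def _f(ss_eff, df_eff, ss_err, df_err, name):
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        if ms_err == 0:
            f = np.inf if ms_eff > 0 else 0.0
            p = 0.0 if ms_eff > 0 else 1.0
        else:
            f = ms_eff / ms_err
            p = float(sps.f.sf(f, df_eff, df_err))
        return TestResult(
            name, float(f), p, s,
            extra={"df": (df_eff, df_err), "ss": float(ss_eff), "ss_error": float(ss_err)},
        )

    return {
        "A": _f(ss_a, a - 1, ss_as, (a - 1) * (s - 1), "rm_anova:A"),
        "B": _f(ss_b, b - 1, ss_bs, (b - 1) * (s - 1), "rm_anova:B"),
        "A×B": _f(ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (s - 1), "rm_anova:A×B"),
        "subjects": TestResult(
            "rm_anova:subjects", float(ss_s / (s - 1)), float("nan"), s,
            extra={"ss": float(ss_s), "df": (s - 1,)},
        ),
    }


# ---------------------------------------------------------------------------
# multiplicity


def count_pairs(k_treatments: int) -> int:
    """Number of unordered treatment pairs, k(k−1)/2."""
    if k_treatments < 2:
        raise ValueError("need at least 2 treatments")
    return k_treatments * (k_treatments - 1) // 2


def adjust_alpha(alpha: float, n_tests: int) -> float:
    """Bonferroni-divided alpha for a family of paired tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# the full comparison plan


def _pivot(tidy: pd.DataFrame, factor: str) -> pd.DataFrame:
    """trials × factor-levels value matrix, restricted to the levels every
    trial observed (paired tests need complete blocks)."""
    wide = tidy.pivot_table(
        index="trial", columns=factor, values="value", observed=True
    )
    return wide.dropna(axis=1, how="any")

def run_comparisons(
    tidy: pd.DataFrame,
    family_alpha: float = 0.05,
    trend_alpha: float = 0.10,
    permutation_seed: int | None = None,
) -> pd.DataFrame:
    """Run the full differentiation scheme on a tidy value table.

    ``tidy`` holds columns (trial, strain, area, phase, parameter, value)
    with one row per trial and cell.  For each strain and parameter the
    coupled area×phase dependence is released twice: comparing micro-areas
    within each phase (alpha/6) and phases within each area (alpha/15).  A
    Friedman screen runs first per released factor; pairwise Wilcoxon and
    permutation tests follow.  Strain pairs are compared per (area, phase)
    at ``family_alpha`` with ``trend_alpha`` marking near-significance.

    Returns a tidy result table (strain, parameter, factor, held, cell_a,
    cell_b, test, statistic, p, adjusted_alpha, significant, trend).
    """
    records: list[dict] = []

    def _emit(strain, parameter, factor, held, a_lab, b_lab, res: TestResult, alpha):
        records.append(
            {
                "strain": strain,
                "parameter": parameter,
                "factor": factor,
                "held": held,
                "cell_a": a_lab,
                "cell_b": b_lab,
                "test": res.test,
                "statistic": res.statistic,
                "p": res.p,
                "n": res.n,
                "adjusted_alpha": alpha,
                "significant": res.p < alpha,
                "trend": alpha <= res.p < trend_alpha if alpha == family_alpha else False,
            }
        )

    for (strain, parameter), sub in tidy.groupby(["strain", "parameter"], observed=True):
        for factor, held_factor in (("area", "phase"), ("phase", "area")):
            for held, cell in sub.groupby(held_factor, observed=True):
                wide = _pivot(cell, factor)
                levels = list(wide.columns)
                if len(levels) < 2 or len(wide) < 2:
                    continue
                alpha = adjust_alpha(family_alpha, count_pairs(len(levels)))
                fr = friedman_test(wide.to_numpy())
                _emit(strain, parameter, factor, held, None, None, fr, family_alpha)
                for la, lb in combinations(levels, 2):
                    d = (wide[la] - wide[lb]).to_numpy()
                    if np.all(d == 0):
                        continue
                    if np.count_nonzero(d) >= 2:  # Wilcoxon drops zeros
                        _emit(strain, parameter, factor, held, la, lb,
                              wilcoxon_signed_rank(d), alpha)
                    _emit(strain, parameter, factor, held, la, lb,
                          paired_permutation(d, seed=permutation_seed), alpha)

    strains = sorted(tidy["strain"].unique())
    for sa, sb in combinations(strains, 2):
        for (parameter, area, phase), cell in tidy.groupby(
            ["parameter", "area", "phase"], observed=True
        ):
            wa = cell[cell.strain == sa].set_index("trial")["value"]
            wb = cell[cell.strain == sb].set_index("trial")["value"]
            # strain trials are independent replicates paired by trial order
            na, nb = wa.sort_index().to_numpy(), wb.sort_index().to_numpy()
            k = min(len(na), len(nb))
            if k < 2:
                continue
            d = na[:k] - nb[:k]
            if np.all(d == 0):
                continue
            if np.count_nonzero(d) >= 2:
                _emit(f"{sa} vs {sb}", parameter, "strain", f"{area}|{phase}",
                      sa, sb, wilcoxon_signed_rank(d), family_alpha)
            _emit(f"{sa} vs {sb}", parameter, "strain", f"{area}|{phase}",
                  sa, sb, paired_permutation(d, seed=permutation_seed), family_alpha)
    return pd.DataFrame.from_records(records)
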