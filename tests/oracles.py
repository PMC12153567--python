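"""Independent brute-force oracles used by the test suite.

Everything here is written directly from first principles (plain loops,
explicit enumeration) and deliberately shares no code with the package.
"""

from __future__ import annotations

import itertools
import math


# -- kinematics -------------------------------------------------------------


def displacements(xs, ys):
    return [
        math.sqrt((xs[i + 1] - xs[i]) ** 2 + (ys[i + 1] - ys[i]) ** 2)
        for i in range(len(xs) - 1)
    ]


def mean_speed(disps, dt=1.0):
    return sum(disps) / len(disps) / dt


def locomotory_rate(disps, threshold, dt=1.0):
    moving = [d for d in disps if d >= threshold]
    if not moving:
        return None
    return sum(moving) / len(moving) / dt


def dcr_series(xs, ys, threshold):
    """Absolute heading change per interior unit, degrees; None if undefined."""
    out = []
    for i in range(len(xs) - 2):
        d1x, d1y = xs[i + 1] - xs[i], ys[i + 1] - ys[i]
        d2x, d2y = xs[i + 2] - xs[i + 1], ys[i + 2] - ys[i + 1]
        if math.hypot(d1x, d1y) < threshold or math.hypot(d2x, d2y) < threshold:
            out.append(None)
            continue
        a1 = math.atan2(d1y, d1x)
        a2 = math.atan2(d2y, d2x)
        diff = abs(a2 - a1) % (2 * math.pi)
        if diff > math.pi:
            diff = 2 * math.pi - diff
        out.append(math.degrees(diff))
    return out


def sinuosity(xs, ys, min_net):
    path = sum(displacements(xs, ys))
    net = math.hypot(xs[-1] - xs[0], ys[-1] - ys[0])
    if net < min_net:
        return None
    return path / net


def pause_bouts(disps, threshold):
    bouts = []
    i = 0
    while i < len(disps):
        if disps[i] < threshold:
            j = i
            while j < len(disps) and disps[j] < threshold:
                j += 1
            bouts.append((i, j - i))
            i = j
        else:
            i += 1
    return bouts


# -- DBSCAN -----------------------------------------------------------------


def dbscan_cluster_count(points, eps, min_pts):
    """Textbook reachability DBSCAN; counts clusters, noise in none.

    A point is core if at least ``min_pts`` points (itself included) lie
    within ``eps``; clusters grow by BFS over core neighbourhoods.
    """
    n = len(points)
    neigh = []
    for i in range(n):
        ni = [
            j
            for j in range(n)
            if math.dist(points[i], points[j]) <= eps
        ]
        neigh.append(ni)
    core = [len(neigh[i]) >= min_pts for i in range(n)]
    label = [None] * n
    k = 0
    for i in range(n):
        if label[i] is not None or not core[i]:
            continue
        k += 1
        queue = [i]
        label[i] = k
        while queue:
            q = queue.pop()
            if not core[q]:
                continue
            for j in neigh[q]:
                if label[j] is None:
                    label[j] = k
                    queue.append(j)
    return k


# -- exact paired tests -----------------------------------------------------


def wilcoxon_min_rank_sum_p(differences):
    """Exact two-sided p by sign-pattern enumeration on the rank scale."""
    d = [v for v in differences if v != 0]
    n = len(d)
    ranks = _average_ranks([abs(v) for v in d])
    total = sum(ranks)
    w_pos = sum(r for r, v in zip(ranks, d) if v > 0)
    w_obs = min(w_pos, total - w_pos)
    hits = 0
    for signs in itertools.product((0, 1), repeat=n):
        s = sum(r for r, b in zip(ranks, signs) if b)
        if min(s, total - s) <= w_obs + 1e-9:
            hits += 1
    return w_obs, hits / 2**n


def _average_ranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def permutation_mean_p(differences):
    """Exact two-sided sign-flip p on the mean difference."""
    n = len(differences)
    obs = abs(sum(differences) / n)
    hits = 0
    for signs in itertools.product((-1, 1), repeat=n):
        m = abs(sum(s * v for s, v in zip(signs, differences)) / n)
        if m >= obs - 1e-12:
            hits += 1
    return hits / 2**n


# -- two-way within-subject ANOVA ------------------------------------------


def rm_anova_f(values):
    """F statistics for (subjects, A, B) data by explicit SS loops."""
    s = len(values)
    a = len(values[0])
    b = len(values[0][0])
    gm = sum(values[i][j][k] for i in range(s) for j in range(a) for k in range(b)) / (s * a * b)

    def m_s(i):
        return sum(values[i][j][k] for j in range(a) for k in range(b)) / (a * b)

    def m_a(j):
        return sum(values[i][j][k] for i in range(s) for k in range(b)) / (s * b)

    def m_b(k):
        return sum(values[i][j][k] for i in range(s) for j in range(a)) / (s * a)

    def m_sa(i, j):
        return sum(values[i][j][k] for k in range(b)) / b

    def m_sb(i, k):
        return sum(values[i][j][k] for j in range(a)) / a

    def m_ab(j, k):
        return sum(values[i][j][k] for i in range(s)) / s

    ss_a = s * b * sum((m_a(j) - gm) ** 2 for j in range(a))
    ss_b = s * a * sum((m_b(k) - gm) ** 2 for k in range(b))
    ss_as = b * sum(
        (m_sa(i, j) - m_s(i) - m_a(j) + gm) ** 2 for i in range(s) for j in range(a)
    )
    ss_bs = a * sum(
        (m_sb(i, k) - m_s(i) - m_b(k) + gm) ** 2 for i in range(s) for k in range(b)
    )
    ss_ab = s * sum(
        (m_ab(j, k) - m_a(j) - m_b(k) + gm) ** 2 for j in range(a) for k in range(b)
    )
    ss_abs = sum(
        (
            values[i][j][k]
            - m_sa(i, j)
            - m_sb(i, k)
            - m_ab(j, k)
            + m_s(i)
            + m_a(j)
            + m_b(k)
            - gm
        )
        ** 2
        for i in range(s)
        for j in range(a)
        for k in range(b)
    )
    f_a = (ss_a / (a - 1)) / (ss_as / ((a - 1) * (s - 1)))
    f_b = (ss_b / (b - 1)) / (ss_bs / ((b - 1) * (s - 1)))
    f_ab = (ss_ab / ((a - 1) * (b - 1))) / (ss_abs / ((a - 1) * (b - 1) * (s - 1)))
    return f_a, f_b, f_ab
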