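"""Independent brute-force oracles for the texture matrices, their features,
and the BH-FDR procedure.

Everything here is written as plain Python loops straight from the
definitions, sharing no code with the package implementation, so agreement
is meaningful evidence of correctness.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

DIRS_13 = [(dx, dy, dz)
           for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
           if (dx, dy, dz) > (0, 0, 0)]
NEIGHBORS_26 = [(dx, dy, dz)
                for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
                if (dx, dy, dz) != (0, 0, 0)]


def _inside(grid, v):
    return all(0 <= v[i] < grid.shape[i] for i in range(3)) and grid[v] > 0


def bf_glcm(grid, ng, directions=DIRS_13):
    """Exhaustive ordered-pair enumeration; symmetric accumulation."""
    mat = np.zeros((ng, ng))
    for d in directions:
        for v in product(*[range(n) for n in grid.shape]):
            if grid[v] == 0:
                continue
            w = tuple(v[i] + d[i] for i in range(3))
            if _inside(grid, w):
                mat[grid[v] - 1, grid[w] - 1] += 1
                mat[grid[w] - 1, grid[v] - 1] += 1
    return mat


def bf_glcm_features(mat):
    total = mat.sum()
    f = {k: 0.0 for k in ["energy", "contrast", "entropy", "homogeneity",
                          "correlation", "sum_average", "variance",
                          "dissimilarity", "autocorrelation"]}
    if total == 0:
        f["energy"] = 1.0
        return f
    ng = mat.shape[0]
    p = mat / total
    pi = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * pi[i] for i in range(ng))
    var = sum((i + 1 - mu) ** 2 * pi[i] for i in range(ng))
    sd = math.sqrt(var)
    for i in range(ng):
        for j in range(ng):
            pij = p[i, j]
            f["energy"] += pij ** 2
            f["contrast"] += (i - j) ** 2 * pij
            if pij > 0:
                f["entropy"] -= pij * math.log2(pij)
            f["homogeneity"] += pij / (1 + abs(i - j))
            if sd > 0:
                f["correlation"] += (i + 1 - mu) * (j + 1 - mu) * pij / var
            f["sum_average"] += (i + j + 2) * pij / 2
            f["dissimilarity"] += abs(i - j) * pij
            f["autocorrelation"] += (i + 1) * (j + 1) * pij
    f["variance"] = var
    return f


def bf_runs(grid, directions=DIRS_13):
    """Enumerate maximal constant-level runs; returns list of (level, length)."""
    runs = []
    for d in directions:
        for v in product(*[range(n) for n in grid.shape]):
            if grid[v] == 0:
                continue
            prev = tuple(v[i] - d[i] for i in range(3))
            if _inside(grid, prev) and grid[prev] == grid[v]:
                continue  # not a run start
            length = 1
            w = tuple(v[i] + d[i] for i in range(3))
            while _inside(grid, w) and grid[w] == grid[v]:
                length += 1
                w = tuple(w[i] + d[i] for i in range(3))
            runs.append((int(grid[v]), length))
    return runs


def bf_glrlm(grid, ng, directions=DIRS_13):
    runs = bf_runs(grid, directions)
    rmax = max((l for _, l in runs), default=1)
    mat = np.zeros((ng, rmax))
    for g, l in runs:
        mat[g - 1, l - 1] += 1
    return mat


def bf_zones(grid):
    """26-connected equal-level zones by flood fill; list of (level, size)."""
    seen = np.zeros(grid.shape, dtype=bool)
    zones = []
    for v in product(*[range(n) for n in grid.shape]):
        if grid[v] == 0 or seen[v]:
            continue
        stack, size, level = [v], 0, grid[v]
        seen[v] = True
        while stack:
            u = stack.pop()
            size += 1
            for d in NEIGHBORS_26:
                w = tuple(u[i] + d[i] for i in range(3))
                if (all(0 <= w[i] < grid.shape[i] for i in range(3))
                        and not seen[w] and grid[w] == level):
                    seen[w] = True
                    stack.append(w)
        zones.append((int(level), size))
    return zones


def bf_glszm(grid, ng):
    zones = bf_zones(grid)
    zmax = max((s for _, s in zones), default=1)
    mat = np.zeros((ng, zmax))
    for g, s in zones:
        mat[g - 1, s - 1] += 1
    return mat


def bf_rlm_features(mat, n_incidences):
    """Shared run-length/size-zone feature definitions, looped explicitly."""
    nr = mat.sum()
    names = ["sre", "lre", "gln", "rln", "rp", "lgre", "hgre", "srlge",
             "srhge", "lrlge", "lrhge", "glv", "rlv"]
    f = {k: 0.0 for k in names}
    if nr == 0:
        return f
    ng, rmax = mat.shape
    for i in range(ng):
        for j in range(rmax):
            c = mat[i, j]
            gi, rj = i + 1, j + 1
            f["sre"] += c / rj ** 2
            f["lre"] += c * rj ** 2
            f["lgre"] += c / gi ** 2
            f["hgre"] += c * gi ** 2
            f["srlge"] += c / (gi ** 2 * rj ** 2)
            f["srhge"] += c * gi ** 2 / rj ** 2
            f["lrlge"] += c * rj ** 2 / gi ** 2
            f["lrhge"] += c * gi ** 2 * rj ** 2
    for k in ["sre", "lre", "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge"]:
        f[k] /= nr
    f["gln"] = sum(mat[i, :].sum() ** 2 for i in range(ng)) / nr
    f["rln"] = sum(mat[:, j].sum() ** 2 for j in range(rmax)) / nr
    f["rp"] = nr / n_incidences
    mu_i = sum((i + 1) * mat[i, j] for i in range(ng) for j in range(rmax)) / nr
    mu_j = sum((j + 1) * mat[i, j] for i in range(ng) for j in range(rmax)) / nr
    f["glv"] = sum((i + 1 - mu_i) ** 2 * mat[i, j]
                   for i in range(ng) for j in range(rmax)) / nr
    f["rlv"] = sum((j + 1 - mu_j) ** 2 * mat[i, j]
                   for i in range(ng) for j in range(rmax)) / nr
    return f


def bf_ngtdm(grid, ng):
    """Per-level (n_i, s_i) by explicit neighbor averaging."""
    n = np.zeros(ng)
    s = np.zeros(ng)
    for v in product(*[range(m) for m in grid.shape]):
        if grid[v] == 0:
            continue
        nb = [grid[tuple(v[i] + d[i] for i in range(3))]
              for d in NEIGHBORS_26
              if _inside(grid, tuple(v[i] + d[i] for i in range(3)))]
        if not nb:
            continue
        i = grid[v] - 1
        n[i] += 1
        s[i] += abs(grid[v] - sum(nb) / len(nb))
    return n, s


def bf_ngtdm_features(n, s, eps=1e-6):
    N = n.sum()
    f = {k: 0.0 for k in ["coarseness", "busyness", "contrast", "complexity",
                          "strength"]}
    if N == 0:
        f["coarseness"] = 1.0 / eps
        return f
    ng = len(n)
    p = n / N
    act = [i for i in range(ng) if p[i] > 0]
    f["coarseness"] = 1.0 / (sum(p[i] * s[i] for i in act) + eps)
    if len(act) > 1:
        tot = 0.0
        for i in act:
            for j in act:
                tot += p[i] * p[j] * (i - j) ** 2
        f["contrast"] = tot / (len(act) * (len(act) - 1)) * s.sum() / N
        denom = sum(abs((i + 1) * p[i] - (j + 1) * p[j])
                    for i in act for j in act)
        if denom > 0:
            f["busyness"] = sum(p[i] * s[i] for i in act) / denom
        f["complexity"] = sum(
            abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
            for i in act for j in act) / N
        f["strength"] = sum((p[i] + p[j]) * (i - j) ** 2
                            for i in act for j in act) / (s.sum() + eps)
    return f


def bf_histogram_features(levels):
    x = [float(v) for v in levels]
    n = len(x)
    mu = sum(x) / n
    var = sum((v - mu) ** 2 for v in x) / n
    if var == 0:
        return {"variance": 0.0, "skewness": 0.0, "kurtosis": 0.0}
    skew = sum((v - mu) ** 3 for v in x) / n / var ** 1.5
    kurt = sum((v - mu) ** 4 for v in x) / n / var ** 2
    return {"variance": var, "skewness": skew, "kurtosis": kurt}


def bf_bh_cutoff(pvals, q):
    """O(m^2) Benjamini-Hochberg straight from the definition."""
    ps = sorted(pvals)
    m = len(ps)
    best = None
    for k in range(1, m + 1):
        if ps[k - 1] <= k * q / m:
            best = ps[k - 1]
    return best
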