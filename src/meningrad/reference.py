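"""Naive reference implementations used to cross-validate the fast paths.

Everything here is written as direct enumeration — voxel-pair loops, run
walks, flood fills, hypergeometric sums — with no shared code with the
production implementations in :mod:`meningrad.features` and
:mod:`meningrad.stats`.  They are exponential-to-quadratic and meant for
tiny inputs only.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

from .features import DIRECTIONS_3D

# ---------------------------------------------------------------------------
# Texture-matrix oracles (triple-loop enumeration on level grids;
# level 0 = background)


def _inside(shape, p) -> bool:
    return all(0 <= pi < si for pi, si in zip(p, shape))


def glcm_oracle(levels: np.ndarray, ng: int) -> dict[str, float]:
    """CP / DE / IDN by exhaustive voxel-pair enumeration, 13 directions."""
    shape = levels.shape
    cp_l, de_l, idn_l = [], [], []
    for d in DIRECTIONS_3D:
        counts = np.zeros((ng, ng))
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    a = levels[x, y, z]
                    q = (x + d[0], y + d[1], z + d[2])
                    if a == 0 or not _inside(shape, q):
                        continue
                    b = levels[q]
                    if b == 0:
                        continue
                    counts[a - 1, b - 1] += 1
                    counts[b - 1, a - 1] += 1  # symmetrize
        tot = counts.sum()
        if tot == 0:
            continue
        p = counts / tot
        mux = sum((i + 1) * p[i, :].sum() for i in range(ng))
        muy = sum((j + 1) * p[:, j].sum() for j in range(ng))
        cp = sum(
            ((i + 1) + (j + 1) - mux - muy) ** 4 * p[i, j]
            for i in range(ng)
            for j in range(ng)
        )
        de = 0.0
        for k in range(ng):
            pk = sum(p[i, j] for i in range(ng) for j in range(ng) if abs(i - j) == k)
            if pk > 0:
                de -= pk * math.log2(pk)
        idn = sum(
            p[i, j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
        )
        cp_l.append(cp)
        de_l.append(de)
        idn_l.append(idn)
    return {
        "Cluster Prominence": float(np.mean(cp_l)),
        "Difference Entropy": float(np.mean(de_l)),
        "Inv. Diff. Normalized": float(np.mean(idn_l)),
    }


def glrlm_oracle(levels: np.ndarray, ng: int) -> dict[str, float]:
    """RLN / SRLGLE by walking every maximal run in each direction."""
    shape = levels.shape
    rln_l, srl_l = [], []
    for d in DIRECTIONS_3D:
        runs: list[tuple[int, int]] = []  # (level, length)
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    lv = levels[x, y, z]
                    if lv == 0:
                        continue
                    prev = (x - d[0], y - d[1], z - d[2])
                    if _inside(shape, prev) and levels[prev] == lv:
                        continue  # not a run start
                    length = 1
                    nxt = (x + d[0], y + d[1], z + d[2])
                    while _inside(shape, nxt) and levels[nxt] == lv:
                        length += 1
                        nxt = (nxt[0] + d[0], nxt[1] + d[1], nxt[2] + d[2])
                    runs.append((int(lv), length))
        if not runs:
            continue
        nr = len(runs)
        max_j = max(length for _, length in runs)
        col = [0] * (max_j + 1)
        srl = 0.0
        for lv, length in runs:
            col[length] += 1
            srl += 1.0 / (lv * lv * length * length)
        rln_l.append(sum(c * c for c in col) / nr)
        srl_l.append(srl / nr)
    return {
        "Run Length Non-uniformity": float(np.mean(rln_l)),
        "Short Run Low Gray Level Emp.": float(np.mean(srl_l)),
    }


def glszm_oracle(levels: np.ndarray, ng: int) -> dict[str, float]:
    """HILAE / LILAE / LISAE by 26-connectivity BFS flood fill."""
    shape = levels.shape
    visited = np.zeros(shape, dtype=bool)
    neigh = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    zones: list[tuple[int, int]] = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if levels[x, y, z] == 0 or visited[x, y, z]:
                    continue
                lv = levels[x, y, z]
                size = 0
                q = deque([(x, y, z)])
                visited[x, y, z] = True
                while q:
                    cx, cy, cz = q.popleft()
                    size += 1
                    for dx, dy, dz in neigh:
                        p = (cx + dx, cy + dy, cz + dz)
                        if _inside(shape, p) and not visited[p] and levels[p] == lv:
                            visited[p] = True
                            q.append(p)
                zones.append((int(lv), size))
    nz = len(zones)
    hil = sum(i * i * j * j for i, j in zones) / nz
    lil = sum(j * j / (i * i) for i, j in zones) / nz
    lis = sum(1.0 / (i * i * j * j) for i, j in zones) / nz
    return {
        "High Intensity Large Area Emp.": float(hil),
        "Low Intensity Large Area Emp.": float(lil),
        "Low Intensity Small Area Emp.": float(lis),
    }


# ---------------------------------------------------------------------------
# Statistical oracles


def auc_pair_oracle(scores, labels) -> float:
    """AUC by explicit enumeration of all (positive, negative) pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def bh_oracle(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up by direct definition."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adj[i] = min(running_min, 1.0)
    return adj


def _nc_hypergeom_weights(table) -> tuple[np.ndarray, np.ndarray, int]:
    """Support and central weights of X = table[0,0] given fixed margins."""
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    r1, r2, c1 = a + b, c + d, a + c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    xs = np.arange(lo, hi + 1)
    w = np.array([math.comb(r1, x) * math.comb(r2, c1 - x) for x in xs], dtype=float)
    return xs, w, a


def fisher_p_oracle(table) -> float:
    """Two-sided Fisher p: sum of hypergeometric probabilities <= observed."""
    xs, w, a = _nc_hypergeom_weights(table)
    probs = w / w.sum()
    p_obs = probs[xs == a][0]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def _cond_mean(xs, w, log_psi) -> float:
    lw = np.log(w) + xs * log_psi
    lw -= lw.max()
    ew = np.exp(lw)
    return float((xs * ew).sum() / ew.sum())


def cmle_or_oracle(table) -> float:
    """Conditional-MLE odds ratio by bisection on the noncentral
    hypergeometric conditional mean."""
    xs, w, a = _nc_hypergeom_weights(table)
    if a == xs[-1]:
        return float("inf") if a > xs[0] else float("nan")
    if a == xs[0]:
        return 0.0 if a < xs[-1] else float("nan")
    lo, hi = -50.0, 50.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _cond_mean(xs, w, mid) < a:
            lo = mid
        else:
            hi = mid
    return float(math.exp(0.5 * (lo + hi)))


def exact_tail_prob(table, psi: float, upper: bool) -> float:
    """P(X >= a) (upper) or P(X <= a) under the noncentral hypergeometric
    distribution with odds ratio psi; used to verify CI inversion."""
    xs, w, a = _nc_hypergeom_weights(table)
    if psi <= 0 or not np.isfinite(psi):
        raise ValueError("psi must be positive and finite")
    lw = np.log(w) + xs * math.log(psi)
    lw -= lw.max()
    probs = np.exp(lw)
    probs /= probs.sum()
    return float(probs[xs >= a].sum() if upper else probs[xs <= a].sum())
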