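"""Independent brute-force oracles used only by the test suite.

Each function recomputes a quantity by exhaustive enumeration or naive
geometry, deliberately sharing no code with the implementation under
test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def hull_area_bruteforce(points: np.ndarray) -> float:
    """Convex-hull area by testing every point pair as a candidate edge (O(n^3)).

    A directed pair (i, j) is a hull edge iff every other point lies
    left of (or on) the line i->j; the hull polygon is then the set of
    edge endpoints ordered by angle about their centroid, and the area
    follows from the shoelace formula.
    """
    pts = np.unique(np.asarray(points, dtype=float).reshape(-1, 2), axis=0)
    n = pts.shape[0]
    if n < 3:
        return 0.0
    # cross[i, j, k] = (p_j - p_i) x (p_k - p_i); pair (i, j) is a hull edge
    # iff every k lies left of (or on) the directed line i -> j
    rel = pts[None, :, :] - pts[:, None, :]              # rel[i, j] = p_j - p_i
    cross = (rel[:, :, None, 0] * rel[:, None, :, 1]
             - rel[:, :, None, 1] * rel[:, None, :, 0])
    ok = np.all(cross >= -1e-12, axis=2)
    np.fill_diagonal(ok, False)
    ii, jj = np.nonzero(ok)
    on_hull = set(ii) | set(jj)
    if len(on_hull) < 3:
        return 0.0
    hull = pts[sorted(on_hull)]
    c = hull.mean(axis=0)
    ang = np.arctan2(hull[:, 1] - c[1], hull[:, 0] - c[0])
    hull = hull[np.argsort(ang)]
    x, y = hull[:, 0], hull[:, 1]
    area = abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0
    return float(area)


def wilcoxon_exact_p(diffs: np.ndarray) -> float:
    """Two-sided signed-rank p by enumerating all 2^n sign assignments.

    Assumes no zero differences and no tied absolute values.
    """
    d = np.asarray(diffs, dtype=float)
    assert np.all(d != 0)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = ranks[d > 0].sum()
    n = d.size
    total = w_max = ranks.sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        # two-sided: as or more extreme in either tail
        if min(w, w_max - w) <= min(w_obs, w_max - w_obs):
            count += 1
    return count / 2**n


def mannwhitney_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney p by enumerating all C(n_a+n_b, n_a) splits.

    Assumes no ties across the pooled sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    assert np.unique(pooled).size == pooled.size
    n_a, n = a.size, pooled.size
    ranks = np.argsort(np.argsort(pooled)) + 1
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    u_max = n_a * (n - n_a)
    count = total = 0
    for combo in itertools.combinations(range(n), n_a):
        u = ranks[list(combo)].sum() - n_a * (n_a + 1) / 2
        if min(u, u_max - u) <= min(u_obs, u_max - u_obs):
            count += 1
        total += 1
    return count / total


def spearman_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided permutation p for Spearman's rho (no ties, n small)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ra = np.argsort(np.argsort(a)).astype(float)
    rb = np.argsort(np.argsort(b)).astype(float)

    def rho(x, y):
        return np.corrcoef(x, y)[0, 1]

    obs = abs(rho(ra, rb))
    count = total = 0
    for perm in itertools.permutations(rb):
        if abs(rho(ra, np.array(perm))) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def icc_consistency_from_variances(x: np.ndarray) -> float:
    """ICC(3,1) via the mixed-model variance-ratio route (independent path).

    Centres each column (occasion fixed effect), then forms the subject
    and residual variance components from the centred data.
    """
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    xc = x - x.mean(axis=0, keepdims=True)
    subj = xc.mean(axis=1)
    ss_subj = k * np.sum((subj - subj.mean()) ** 2)
    ss_res = np.sum((xc - subj[:, None]) ** 2)
    ms_subj = ss_subj / (n - 1)
    ms_res = ss_res / ((n - 1) * (k - 1))
    var_subj = (ms_subj - ms_res) / k
    return var_subj / (var_subj + ms_res)
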