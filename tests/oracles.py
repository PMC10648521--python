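"""Independent brute-force oracles used by the test suite.

These deliberately avoid the vectorized code paths of the package: the
region-growing oracle is a sweep-synchronous set/loop implementation, the
regression oracle solves the normal equations with an explicit matrix
solve, and the t-test oracle is the textbook pooled formula evaluated with
mpmath-free scipy distribution calls.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats


def grow_region_bruteforce(g, interior, seed_fraction, floor_fraction, alpha,
                           convergence_tol=1e-4, max_iterations=50):
    """Sweep-synchronous adaptive region growing over python sets.

    Accepts 26-connected neighbours with glandular fraction >=
    max(floor, alpha*(1 - D)) where D is the running mean fraction of the
    grown region; mirrors the published growing rule voxel for voxel.
    """
    inside = {tuple(p) for p in np.argwhere(interior)}
    region = {p for p in inside if g[p] >= seed_fraction}
    if not region:
        return region, []
    density = sum(float(g[p]) for p in region) / len(region)
    trace = [density]
    for _ in range(max_iterations):
        threshold = max(floor_fraction, alpha * (1.0 - density))
        frontier = set()
        for p in region:
            for dz, dr, dc in itertools.product((-1, 0, 1), repeat=3):
                if dz == dr == dc == 0:
                    continue
                q = (p[0] + dz, p[1] + dr, p[2] + dc)
                if q in inside and q not in region and g[q] >= threshold:
                    frontier.add(q)
        grew = bool(frontier)
        region |= frontier
        new_density = sum(float(g[p]) for p in region) / len(region)
        converged = abs(new_density - density) < convergence_tol
        density = new_density
        trace.append(density)
        if not grew and converged:
            break
    return region, trace


def wls_normal_equations(x, y, w=None):
    """(a, b) for y = a*x + b by an explicit weighted normal-equations solve."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.ones_like(x) if w is None else np.asarray(w, float)
    X = np.column_stack([x, np.ones_like(x)])
    A = X.T @ (w[:, None] * X)
    rhs = X.T @ (w * y)
    return np.linalg.solve(A, rhs)


def pooled_t_oracle(a, b):
    """Textbook pooled two-sample t and two-sided p."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = a.size, b.size
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
    return float(t), float(p)
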