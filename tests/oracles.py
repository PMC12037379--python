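"""Independent brute-force oracles used to validate the implementation.

Each function here deliberately re-derives a quantity by the most direct
method available (flood fill, exhaustive enumeration, closed forms) and
shares no code with the package paths it checks.
"""

from __future__ import annotations

import itertools
from collections import deque
from math import comb

import numpy as np

_OFFSETS = {
    6: [
        (dx, dy, dz)
        for dx, dy, dz in itertools.product((-1, 0, 1), repeat=3)
        if abs(dx) + abs(dy) + abs(dz) == 1
    ],
    18: [
        (dx, dy, dz)
        for dx, dy, dz in itertools.product((-1, 0, 1), repeat=3)
        if 1 <= abs(dx) + abs(dy) + abs(dz) <= 2
    ],
    26: [
        (dx, dy, dz)
        for dx, dy, dz in itertools.product((-1, 0, 1), repeat=3)
        if (dx, dy, dz) != (0, 0, 0)
    ],
}


def flood_fill_components(binary: np.ndarray, connectivity: int) -> list[frozenset]:
    """Connected components of a 3-D boolean grid by breadth-first search."""
    offsets = _OFFSETS[connectivity]
    shape = binary.shape
    seen = np.zeros(shape, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(binary)):
        if seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            x, y, z = queue.popleft()
            comp.add((x, y, z))
            for dx, dy, dz in offsets:
                nx, ny, nz = x + dx, y + dy, z + dz
                if (
                    0 <= nx < shape[0]
                    and 0 <= ny < shape[1]
                    and 0 <= nz < shape[2]
                    and binary[nx, ny, nz]
                    and not seen[nx, ny, nz]
                ):
                    seen[nx, ny, nz] = True
                    queue.append((nx, ny, nz))
        comps.append(frozenset(comp))
    return comps


def mann_whitney_u_pairwise(a: np.ndarray, b: np.ndarray) -> float:
    """U of sample *a* counted pair by pair (ties count one half)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def mann_whitney_exact_p(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating group assignments."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n1, n = len(a), len(a) + len(b)
    mu = len(a) * len(b) / 2.0
    u_obs = mann_whitney_u_pairwise(np.array(a), np.array(b))
    dev = abs(u_obs - mu)
    hits = 0
    for pick in itertools.combinations(range(n), n1):
        ga = [pooled[i] for i in pick]
        gb = [pooled[i] for i in range(n) if i not in set(pick)]
        u = mann_whitney_u_pairwise(np.array(ga), np.array(gb))
        if abs(u - mu) >= dev - 1e-9:
            hits += 1
    return u_obs, hits / comb(n, n1)


def fisher_two_sided_p(table) -> float:
    """Two-sided Fisher exact p from the hypergeometric pmf, directly."""
    (a, b), (c, d) = np.asarray(table, dtype=int)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(x: int) -> float:
        if x < max(0, c1 - r2) or x > min(r1, c1):
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = pmf(a)
    return sum(pmf(x) for x in range(0, min(r1, c1) + 1) if pmf(x) <= p_obs * (1 + 1e-9))


def spearman_exact_p(x, y) -> float:
    """Exact two-sided permutation p for Spearman rho (small n)."""
    from scipy.stats import rankdata

    rx = rankdata(x)
    ry = rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    hits = total = 0
    for perm in itertools.permutations(ry):
        r = np.corrcoef(rx, np.asarray(perm))[0, 1]
        if abs(r) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def histogram_entropy(values: np.ndarray, edges: np.ndarray) -> float:
    """Plug-in entropy (nats) of a sample under the given binning."""
    counts, _ = np.histogram(values, bins=edges)
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())
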