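"""Independent brute-force oracles, deliberately naive.

These share no code with the package: region statistics by explicit BFS
flood fill over neighbour offsets, moments by explicit Python sums over the
pixel multiset.
"""

from __future__ import annotations

import math

NEIGHBORS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
NEIGHBORS_4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]


def flood_fill_components(frame, value, neighbors):
    """List of components (sets of (r, c)) of cells equal to ``value``."""
    m, n = len(frame), len(frame[0])
    seen = set()
    comps = []
    for r0 in range(m):
        for c0 in range(n):
            if frame[r0][c0] != value or (r0, c0) in seen:
                continue
            comp, stack = set(), [(r0, c0)]
            seen.add((r0, c0))
            while stack:
                r, c = stack.pop()
                comp.add((r, c))
                for dr, dc in neighbors:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < m and 0 <= cc < n and frame[rr][cc] == value \
                            and (rr, cc) not in seen:
                        seen.add((rr, cc))
                        stack.append((rr, cc))
            comps.append(comp)
    return comps


def brute_region_stats(frame):
    """(connected, max_island, second_island, max_void, n_islands, n_voids)
    with areas as FOV fractions; islands 8-connected, voids 4-connected;
    percolation = one white component touching left+right or top+bottom."""
    m, n = len(frame), len(frame[0])
    area = m * n
    islands = flood_fill_components(frame, 1, NEIGHBORS_8)
    voids = flood_fill_components(frame, 0, NEIGHBORS_4)
    sizes = sorted((len(c) for c in islands), reverse=True)
    max_island = sizes[0] / area if sizes else 0.0
    second = sizes[1] / area if len(sizes) > 1 else 0.0
    max_void = max((len(c) for c in voids), default=0) / area
    connected = 0
    for comp in islands:
        cols = {c for _, c in comp}
        rows = {r for r, _ in comp}
        if (0 in cols and n - 1 in cols) or (0 in rows and m - 1 in rows):
            connected = 1
            break
    return connected, max_island, second, max_void, len(islands), len(voids)


def brute_moments(pixels):
    """(mean, median, sigma, mu4, K, S1) by explicit sums over the multiset."""
    xs = sorted(float(x) for x in pixels)
    n = len(xs)
    mean = sum(xs) / n
    mid = n // 2
    median = xs[mid] if n % 2 else 0.5 * (xs[mid - 1] + xs[mid])
    var = sum((x - mean) ** 2 for x in xs) / n
    mu4 = sum((x - mean) ** 4 for x in xs) / n
    sigma = math.sqrt(var)
    K = mu4 / var ** 2 - 3.0 if var > 0 else 0.0
    S1 = (mean - median) / sigma if sigma > 0 else 0.0
    return mean, median, sigma, mu4, K, S1
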