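"""Independent brute-force oracles shared by the test modules."""

import math

import numpy as np

SQRT2 = math.sqrt(2.0)


def bellman_ford_oracle(resistance, pixel_size, origin):
    """All-pixels least cost by exhaustive edge relaxation.

    Deliberately independent of the package's Dijkstra implementation:
    plain repeated relaxation over the 8-neighbour edge list until no
    distance improves.
    """
    r = np.asarray(resistance, dtype=float)
    nrows, ncols = r.shape
    dist = np.full((nrows, ncols), np.inf)
    dist[origin] = 0.0
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    changed = True
    while changed:
        changed = False
        for i in range(nrows):
            for j in range(ncols):
                if not np.isfinite(dist[i, j]):
                    continue
                for di, dj in offsets:
                    ni, nj = i + di, j + dj
                    if not (0 <= ni < nrows and 0 <= nj < ncols):
                        continue
                    step = pixel_size * (SQRT2 if di and dj else 1.0)
                    cand = dist[i, j] + step * (r[i, j] + r[ni, nj]) / 2.0
                    if cand < dist[ni, nj] - 1e-12:
                        dist[ni, nj] = cand
                        changed = True
    return dist
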