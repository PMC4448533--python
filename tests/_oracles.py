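"""Independent brute-force oracles used only by the test suite.

Deliberately naive implementations (queue-based flood fill, exhaustive
threshold sweep) kept free of the library code paths they verify.
"""

from collections import deque

import numpy as np


def _flood(mask_bool, start, visited, neighbors):
    q = deque([start])
    visited.add(start)
    comp = {start}
    h = len(mask_bool)
    w = len(mask_bool[0])
    while q:
        r, c = q.popleft()
        for dr, dc in neighbors:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and (rr, cc) not in visited \
                    and mask_bool[rr][cc]:
                visited.add((rr, cc))
                comp.add((rr, cc))
                q.append((rr, cc))
    return comp


_N8 = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
_N4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]


def betti_oracle(mask) -> tuple[int, int]:
    """(b0, b1) by explicit flood fill: 8-connected foreground components,
    4-connected complement components that never touch the border."""
    arr = np.asarray(mask, dtype=bool)
    h, w = arr.shape
    fg = arr.tolist()
    bg = (~arr).tolist()

    visited: set = set()
    b0 = 0
    for r in range(h):
        for c in range(w):
            if fg[r][c] and (r, c) not in visited:
                _flood(fg, (r, c), visited, _N8)
                b0 += 1

    visited = set()
    b1 = 0
    for r in range(h):
        for c in range(w):
            if bg[r][c] and (r, c) not in visited:
                comp = _flood(bg, (r, c), visited, _N4)
                touches = any(rr in (0, h - 1) or cc in (0, w - 1)
                              for rr, cc in comp)
                if not touches:
                    b1 += 1
    return b0, b1


def euler_oracle(mask) -> int:
    """V - E + F by explicit enumeration of shared cubical cells."""
    arr = np.asarray(mask, dtype=bool)
    verts, h_edges, v_edges = set(), set(), set()
    faces = 0
    for r, c in zip(*np.nonzero(arr)):
        r, c = int(r), int(c)
        faces += 1
        for dv in ((0, 0), (0, 1), (1, 0), (1, 1)):
            verts.add((r + dv[0], c + dv[1]))
        h_edges.add((r, c))
        h_edges.add((r + 1, c))
        v_edges.add((r, c))
        v_edges.add((r, c + 1))
    return len(verts) - (len(h_edges) + len(v_edges)) + faces


def otsu_sweep(values) -> list[int]:
    """All integer thresholds maximizing between-class variance of an
    integer sample in [0, 255]; classes are (<= t) vs (> t)."""
    vals = np.asarray(values, dtype=np.int64)
    best, arg = -1.0, []
    n = vals.size
    for t in range(256):
        lo = vals[vals <= t]
        hi = vals[vals > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0 = lo.size / n
        w1 = hi.size / n
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best + 1e-12:
            best, arg = var, [t]
        elif abs(var - best) <= 1e-12:
            arg.append(t)
    return arg
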