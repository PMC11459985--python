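"""Independent exhaustive-enumeration oracles for the texture matrices.

Deliberately naive (voxel loops, BFS flood fill) and kept free of any
code shared with the implementation under test.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def _in_bounds(pos, shape) -> bool:
    return all(0 <= p < s for p, s in zip(pos, shape))


def glcm_oracle(levels: np.ndarray, ng: int, distance: int,
                directions) -> np.ndarray:
    """Count co-occurring level pairs, both orderings, per direction."""
    counts = np.zeros((ng, ng))
    shape = levels.shape
    for d in directions:
        off = tuple(distance * c for c in d)
        for v in np.ndindex(shape):
            a = levels[v]
            if a == 0:
                continue
            u = tuple(p + o for p, o in zip(v, off))
            if not _in_bounds(u, shape):
                continue
            b = levels[u]
            if b == 0:
                continue
            counts[a - 1, b - 1] += 1
            counts[b - 1, a - 1] += 1
    return counts


def glrlm_oracle(levels: np.ndarray, ng: int, directions) -> np.ndarray:
    """Enumerate maximal same-level runs by walking each direction."""
    shape = levels.shape
    runs: list[tuple[int, int]] = []
    for d in directions:
        for v in np.ndindex(shape):
            g = levels[v]
            if g == 0:
                continue
            prev = tuple(p - c for p, c in zip(v, d))
            if _in_bounds(prev, shape) and levels[prev] == g:
                continue  # not a run start
            length = 1
            cur = v
            while True:
                nxt = tuple(p + c for p, c in zip(cur, d))
                if not _in_bounds(nxt, shape) or levels[nxt] != g:
                    break
                length += 1
                cur = nxt
            runs.append((g, length))
    lmax = max(l for _, l in runs)
    counts = np.zeros((ng, lmax))
    for g, l in runs:
        counts[g - 1, l - 1] += 1
    return counts


def _zones_oracle(levels: np.ndarray):
    """26-connected same-level components via BFS flood fill."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    offsets = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
               for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
    zones = []
    for start in np.ndindex(shape):
        g = levels[start]
        if g == 0 or seen[start]:
            continue
        queue = deque([start])
        seen[start] = True
        members = []
        while queue:
            v = queue.popleft()
            members.append(v)
            for off in offsets:
                u = tuple(p + o for p, o in zip(v, off))
                if _in_bounds(u, shape) and not seen[u] and levels[u] == g:
                    seen[u] = True
                    queue.append(u)
        zones.append((int(g), members))
    return zones


def glszm_oracle(levels: np.ndarray, ng: int) -> np.ndarray:
    zones = _zones_oracle(levels)
    smax = max(len(m) for _, m in zones)
    counts = np.zeros((ng, smax))
    for g, members in zones:
        counts[g - 1, len(members) - 1] += 1
    return counts


def border_distance_oracle(levels: np.ndarray) -> np.ndarray:
    """City-block distance to the nearest outside-ROI voxel.

    The region outside the array boundary counts as outside the ROI, so
    the candidate set is every zero voxel plus every beyond-edge plane.
    """
    shape = levels.shape
    outside = [v for v in np.ndindex(shape) if levels[v] == 0]
    dist = np.zeros(shape, dtype=int)
    for v in np.ndindex(shape):
        if levels[v] == 0:
            continue
        edge = min(min(p + 1, s - p) for p, s in zip(v, shape))
        best = edge
        for u in outside:
            d = sum(abs(a - b) for a, b in zip(v, u))
            best = min(best, d)
        dist[v] = best
    return dist


def gldzm_oracle(levels: np.ndarray, ng: int) -> np.ndarray:
    zones = _zones_oracle(levels)
    dist = border_distance_oracle(levels)
    zone_dists = [(g, min(dist[v] for v in members)) for g, members in zones]
    dmax = max(d for _, d in zone_dists)
    counts = np.zeros((ng, dmax))
    for g, d in zone_dists:
        counts[g - 1, d - 1] += 1
    return counts


def ngtdm_oracle(levels: np.ndarray, ng: int):
    """Per-level occurrence counts and summed neighbourhood differences."""
    shape = levels.shape
    offsets = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
               for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
    n_g = np.zeros(ng)
    s_g = np.zeros(ng)
    total = 0
    for v in np.ndindex(shape):
        g = levels[v]
        if g == 0:
            continue
        nb = [levels[u] for u in
              (tuple(p + o for p, o in zip(v, off)) for off in offsets)
              if _in_bounds(u, shape) and levels[u] != 0]
        if not nb:
            continue
        n_g[g - 1] += 1
        s_g[g - 1] += abs(g - sum(nb) / len(nb))
        total += 1
    return n_g, s_g, total


def random_levels(rng: np.random.Generator, shape=(4, 4, 4),
                  ng: int = 4) -> np.ndarray:
    """Random sentinel-0 level grid with a non-trivial mask (>= 2 voxels)."""
    while True:
        levels = rng.integers(1, ng + 1, size=shape).astype(np.int32)
        mask = rng.random(shape) < rng.uniform(0.3, 0.9)
        levels[~mask] = 0
        if (levels > 0).sum() >= 2:
            return levels
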