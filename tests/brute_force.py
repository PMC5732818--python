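"""Independent brute-force oracles for the gray-level matrix builders.

Everything here is written by direct enumeration — nested Python loops over
voxels, runs followed one step at a time, flood-fill for zones — so the
vectorized builders in the package can be checked against first-principles
counts.  Nothing in this module shares code with the implementation.
"""

from __future__ import annotations

import itertools

import numpy as np


def glcm_counts(levels, mask, n_levels, offsets, distance=1):
    """Symmetric co-occurrence counts by enumerating every voxel/offset pair."""
    levels = np.asarray(levels)
    mask = np.asarray(mask).astype(bool)
    counts = np.zeros((n_levels, n_levels), dtype=int)
    for pos in itertools.product(*[range(n) for n in levels.shape]):
        if not mask[pos]:
            continue
        for off in offsets:
            nb = tuple(p + d * distance for p, d in zip(pos, off))
            if all(0 <= c < n for c, n in zip(nb, levels.shape)) and mask[nb]:
                i, j = levels[pos], levels[nb]
                counts[i, j] += 1
                counts[j, i] += 1
    return counts


def glrlm_counts(levels, mask, n_levels, offset):
    """Run-length counts by walking each maximal run one voxel at a time."""
    levels = np.asarray(levels)
    mask = np.asarray(mask).astype(bool)
    runs = []
    for pos in itertools.product(*[range(n) for n in levels.shape]):
        if not mask[pos]:
            continue
        prev = tuple(p - d for p, d in zip(pos, offset))
        in_prev = all(0 <= c < n for c, n in zip(prev, levels.shape))
        if in_prev and mask[prev] and levels[prev] == levels[pos]:
            continue  # not a run start
        length = 1
        cur = pos
        while True:
            nxt = tuple(p + d for p, d in zip(cur, offset))
            if not all(0 <= c < n for c, n in zip(nxt, levels.shape)):
                break
            if not mask[nxt] or levels[nxt] != levels[pos]:
                break
            length += 1
            cur = nxt
        runs.append((int(levels[pos]), length))
    max_len = max((l for _, l in runs), default=1)
    counts = np.zeros((n_levels, max_len), dtype=int)
    for lvl, length in runs:
        counts[lvl, length - 1] += 1
    return counts


def glszm_counts(levels, mask, n_levels):
    """Size-zone counts via explicit flood fill with full connectivity."""
    levels = np.asarray(levels)
    mask = np.asarray(mask).astype(bool)
    seen = np.zeros(levels.shape, dtype=bool)
    neighbors = [d for d in itertools.product((-1, 0, 1), repeat=levels.ndim)
                 if any(d)]
    zones = []
    for pos in itertools.product(*[range(n) for n in levels.shape]):
        if not mask[pos] or seen[pos]:
            continue
        lvl = levels[pos]
        stack = [pos]
        seen[pos] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for d in neighbors:
                nb = tuple(c + dd for c, dd in zip(cur, d))
                if not all(0 <= c < n for c, n in zip(nb, levels.shape)):
                    continue
                if mask[nb] and not seen[nb] and levels[nb] == lvl:
                    seen[nb] = True
                    stack.append(nb)
        zones.append((int(lvl), size))
    max_size = max((s for _, s in zones), default=1)
    counts = np.zeros((n_levels, max_size), dtype=int)
    for lvl, s in zones:
        counts[lvl, s - 1] += 1
    return counts


def ngtdm_sums(levels, mask, n_levels):
    """Per-level counts and gray-tone difference sums by direct neighborhood
    averaging at every voxel."""
    levels = np.asarray(levels)
    mask = np.asarray(mask).astype(bool)
    neighbors = [d for d in itertools.product((-1, 0, 1), repeat=levels.ndim)
                 if any(d)]
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for pos in itertools.product(*[range(n) for n in levels.shape]):
        if not mask[pos]:
            continue
        vals = []
        for d in neighbors:
            nb = tuple(c + dd for c, dd in zip(pos, d))
            if all(0 <= c < n for c, n in zip(nb, levels.shape)) and mask[nb]:
                vals.append(levels[nb])
        if not vals:
            continue
        lvl = int(levels[pos])
        n_i[lvl] += 1
        s_i[lvl] += abs(lvl - sum(vals) / len(vals))
    return n_i, s_i


def glgcm_counts(levels, mask, n_levels, n_grad_bins=16):
    """GLGCM joint counts via explicit 3x3 Sobel stencils on interior pixels."""
    levels = np.asarray(levels)
    mask = np.asarray(mask).astype(bool)
    kx = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=float)
    # matches scipy.ndimage.sobel(axis=0) sign convention up to magnitude use
    grads = {}
    for x in range(levels.shape[0]):
        for y in range(levels.shape[1]):
            if not mask[x, y]:
                continue
            interior = True
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    nx, ny = x + dx, y + dy
                    if not (0 <= nx < levels.shape[0]
                            and 0 <= ny < levels.shape[1]) or not mask[nx, ny]:
                        interior = False
            if not interior:
                continue
            gx = gy = 0.0
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    gx += kx[dx + 1, dy + 1] * levels[x + dx, y + dy]
                    gy += kx[dy + 1, dx + 1] * levels[x + dx, y + dy]
            grads[(x, y)] = np.hypot(gx, gy)
    counts = np.zeros((n_levels, n_grad_bins), dtype=int)
    if not grads:
        return counts
    gvals = np.array(list(grads.values()))
    lo, hi = gvals.min(), gvals.max()
    for (x, y), g in grads.items():
        if hi == lo:
            b = 0
        else:
            b = min(int(n_grad_bins * (g - lo) / (hi - lo)), n_grad_bins - 1)
        counts[levels[x, y], b] += 1
    return counts
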