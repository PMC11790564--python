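"""Independent brute-force oracles the tests compare the package against.

Deliberately naive: all-pairs physical distances and recursive flood fill,
O(N*M) and O(N) respectively, usable only on tiny grids — which is the
point: they share no code path with the scipy-based implementation.
"""

from __future__ import annotations

import numpy as np


def brute_force_distance(mask: np.ndarray, voxel_size_mm) -> np.ndarray:
    """Per-voxel min physical distance to any mask-voxel centre, all pairs."""
    mask = np.asarray(mask, dtype=bool)
    vs = np.asarray(voxel_size_mm, dtype=float)
    src = np.argwhere(mask) * vs
    out = np.empty(mask.shape, dtype=float)
    for idx in np.ndindex(mask.shape):
        p = np.asarray(idx) * vs
        out[idx] = np.sqrt(((src - p) ** 2).sum(axis=1)).min()
    return out


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[set]:
    """Connected components by explicit stack-based flood fill."""
    mask = np.asarray(mask, dtype=bool)
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros(mask.shape, dtype=bool)
    components = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp = set()
        stack = [start]
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.add(v)
            for off in offsets:
                w = tuple(a + b for a, b in zip(v, off))
                if all(0 <= c < s for c, s in zip(w, mask.shape)) and mask[w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        components.append(comp)
    return components
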