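"""Independent brute-force oracles shared across test modules."""

import numpy as np


def bh_brute_force(p, alpha):
    """Step-up FDR from the definition: largest k with p_(k) <= k/m * alpha."""
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k / m * alpha:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def flood_fill_oracle(vol, connectivity):
    """BFS connected components over an explicit neighbor stencil."""
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
    seen = set()
    comps = []
    active = {tuple(c) for c in np.argwhere(vol)}
    for start in sorted(active):
        if start in seen:
            continue
        queue, comp = [start], set()
        seen.add(start)
        while queue:
            cur = queue.pop()
            comp.add(cur)
            for off in offsets:
                nb = (cur[0] + off[0], cur[1] + off[1], cur[2] + off[2])
                if nb in active and nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        comps.append(frozenset(comp))
    return set(comps)


def clusters_as_sets(clusters, shape):
    return {
        frozenset(map(tuple, np.array(np.unravel_index(c.voxels, shape)).T))
        for c in clusters
    }
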