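"""Independent brute-force oracles used to cross-check the library.

Everything here is deliberately naive pure Python over nested loops and
sets — no scipy, no vectorization — so agreement with the library is a real
two-route check rather than the same code called twice.
"""

from __future__ import annotations

import math
from itertools import product


def voxel_set(mask) -> set[tuple[int, int, int]]:
    sx, sy, sz = mask.shape
    return {
        (i, j, k)
        for i in range(sx)
        for j in range(sy)
        for k in range(sz)
        if mask[i, j, k]
    }


def brute_dice(a, b) -> float:
    sa, sb = voxel_set(a), voxel_set(b)
    if not sa and not sb:
        return 1.0
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def brute_recall(pred, truth) -> float:
    sp, st = voxel_set(pred), voxel_set(truth)
    return len(sp & st) / len(st)


def brute_dice_global(cases) -> float:
    inter = denom = 0
    for p, t in cases:
        sp, st = voxel_set(p), voxel_set(t)
        inter += len(sp & st)
        denom += len(sp) + len(st)
    return 1.0 if denom == 0 else 2.0 * inter / denom


def _neighbors6(v):
    i, j, k = v
    yield i + 1, j, k
    yield i - 1, j, k
    yield i, j + 1, k
    yield i, j - 1, k
    yield i, j, k + 1
    yield i, j, k - 1


def brute_surface(mask) -> set[tuple[int, int, int]]:
    """Foreground voxels with at least one 6-neighbor outside the mask
    (array borders count as outside)."""
    fg = voxel_set(mask)
    shape = mask.shape
    surf = set()
    for v in fg:
        for n in _neighbors6(v):
            inside = all(0 <= n[d] < shape[d] for d in range(3))
            if not inside or n not in fg:
                surf.add(v)
                break
    return surf


def brute_hausdorff(a, b, spacing=(1.0, 1.0, 1.0)) -> float:
    """All-pairs symmetric Hausdorff over surface voxels, physical units."""
    pa = [tuple(c * s for c, s in zip(v, spacing)) for v in brute_surface(a)]
    pb = [tuple(c * s for c, s in zip(v, spacing)) for v in brute_surface(b)]

    def directed(src, dst):
        worst = 0.0
        for p in src:
            best = min(math.dist(p, q) for q in dst)
            worst = max(worst, best)
        return worst

    return max(directed(pa, pb), directed(pb, pa))


def flood_fill_components(mask, connectivity: int = 26) -> list[set]:
    """Connected components by iterative flood fill."""
    if connectivity == 26:
        offsets = [o for o in product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
    elif connectivity == 6:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        raise ValueError(connectivity)
    remaining = voxel_set(mask)
    comps = []
    while remaining:
        seed = next(iter(remaining))
        comp = {seed}
        frontier = [seed]
        remaining.discard(seed)
        while frontier:
            i, j, k = frontier.pop()
            for di, dj, dk in offsets:
                n = (i + di, j + dj, k + dk)
                if n in remaining:
                    remaining.discard(n)
                    comp.add(n)
                    frontier.append(n)
        comps.append(comp)
    return comps


def brute_largest_component(mask, connectivity: int = 26) -> set:
    comps = flood_fill_components(mask, connectivity)
    return max(comps, key=len) if comps else set()


def brute_lesion_recall(pred, truth, threshold: float = 0.5):
    """Fraction of truth lesions whose best-IoU predicted component >= threshold."""
    truth_comps = flood_fill_components(truth, 26)
    if not truth_comps:
        return None
    pred_comps = flood_fill_components(pred, 26)
    detected = 0
    for lesion in truth_comps:
        best = 0.0
        for comp in pred_comps:
            inter = len(lesion & comp)
            if inter == 0:
                continue
            best = max(best, inter / len(lesion | comp))
        if best >= threshold:
            detected += 1
    return detected / len(truth_comps)
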