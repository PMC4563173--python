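"""Independent brute-force oracles used only by the tests."""

from collections import deque
from itertools import product

import numpy as np


def neighbor_offsets(connectivity: int):
    """Offsets of the 6/18/26 neighbourhoods, by count of nonzero axes."""
    max_nonzero = {6: 1, 18: 2, 26: 3}[connectivity]
    return [
        off
        for off in product((-1, 0, 1), repeat=3)
        if off != (0, 0, 0) and sum(o != 0 for o in off) <= max_nonzero
    ]


def flood_fill_components(mask: np.ndarray, connectivity: int):
    """Label connected components by breadth-first flood fill.

    Returns (labels array, list of component sizes); labels start at 1.
    Deliberately naive — the oracle for the fast labeling path.
    """
    mask = np.asarray(mask, dtype=bool)
    offsets = neighbor_offsets(connectivity)
    labels = np.zeros(mask.shape, dtype=np.int32)
    sizes = []
    shape = mask.shape
    foreground = list(zip(*np.nonzero(mask)))
    for start in foreground:
        if labels[start]:
            continue
        label = len(sizes) + 1
        labels[start] = label
        queue = deque([start])
        size = 0
        while queue:
            vox = queue.popleft()
            size += 1
            for off in offsets:
                nb = (vox[0] + off[0], vox[1] + off[1], vox[2] + off[2])
                if all(0 <= nb[a] < shape[a] for a in range(3)):
                    if mask[nb] and not labels[nb]:
                        labels[nb] = label
                        queue.append(nb)
        sizes.append(size)
    return labels, sizes


def flood_fill_filter(mask: np.ndarray, min_size: int, connectivity: int) -> np.ndarray:
    """Brute-force islanding: keep components of at least ``min_size`` voxels."""
    labels, sizes = flood_fill_components(mask, connectivity)
    keep = np.zeros(len(sizes) + 1, dtype=bool)
    for i, size in enumerate(sizes, start=1):
        keep[i] = size >= min_size
    return keep[labels]
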