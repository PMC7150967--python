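"""Independent brute-force oracles used to cross-check the pipeline.

Deliberately implemented with plain-Python breadth-first flood fill (no
scipy/skimage labeling) so they share no code path with the package.
"""

from collections import deque

import numpy as np

_NBRS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def flood_fill_vacuoles(
    cyto: np.ndarray,
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    threshold: float = 19_000.0,
    min_area: int = 4,
) -> list[int]:
    """Areas (px) of sub-threshold 8-connected components inside one cell.

    Candidate pixels are strictly below ``threshold``, inside ``cell_mask``
    and outside ``nucleus_mask``.  Components smaller than ``min_area`` or
    with any pixel 8-adjacent to a non-cell pixel are discarded, mirroring
    the measurement contract.
    """
    h, w = cyto.shape
    cand = (np.asarray(cyto, float) < threshold) & cell_mask & ~nucleus_mask
    seen = np.zeros_like(cand, bool)
    areas = []
    for sy in range(h):
        for sx in range(w):
            if not cand[sy, sx] or seen[sy, sx]:
                continue
            comp = []
            touches = False
            queue = deque([(sy, sx)])
            seen[sy, sx] = True
            while queue:
                y, x = queue.popleft()
                comp.append((y, x))
                for dy, dx in _NBRS8:
                    ny, nx = y + dy, x + dx
                    if not (0 <= ny < h and 0 <= nx < w):
                        touches = True  # frame edge counts as outside the cell
                        continue
                    if not cell_mask[ny, nx]:
                        touches = True
                    if cand[ny, nx] and not seen[ny, nx]:
                        seen[ny, nx] = True
                        queue.append((ny, nx))
            if len(comp) >= min_area and not touches:
                areas.append(len(comp))
    return sorted(areas)
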