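"""Independent brute-force oracle for superlevel-set merge-tree pairs.

Thresholds at every distinct positive value in descending order, flood-fills
connected components with scipy.ndimage.label (26-connectivity), and reads
off for every strict local maximum:

* elder death d  — the largest threshold at which the maximum's component
  contains a maximum with a larger value,
* childhood death d' — the largest threshold at which its component
  contains any other maximum.

Deaths that never occur take the terminal value.  This is deliberately
O(#values * volume) and shares no code with the union-find sweep it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_STRUCT = np.ones((3, 3, 3), dtype=bool)


def brute_local_maxima(arr: np.ndarray) -> list[tuple[tuple[int, int, int], float]]:
    """Strict 26-neighborhood maxima by exhaustive per-voxel check."""
    out = []
    s0, s1, s2 = arr.shape
    for i in range(s0):
        for j in range(s1):
            for k in range(s2):
                v = arr[i, j, k]
                if v <= 0:
                    continue
                is_max = True
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        for dk in (-1, 0, 1):
                            if (di, dj, dk) == (0, 0, 0):
                                continue
                            ni, nj, nk = i + di, j + dj, k + dk
                            if 0 <= ni < s0 and 0 <= nj < s1 and 0 <= nk < s2:
                                if arr[ni, nj, nk] >= v:
                                    is_max = False
                if is_max:
                    out.append(((i, j, k), float(v)))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def brute_force_pairs(
    arr: np.ndarray, terminal: float = 0.0
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """((b, d) elder pairs, (b, d') childhood pairs), one per maximum, rank order."""
    arr = np.asarray(arr, dtype=float)
    maxima = brute_local_maxima(arr)
    values = sorted({float(v) for v in arr[arr > 0]}, reverse=True)
    m = len(maxima)
    elder = [None] * m
    childhood = [None] * m
    max_value = {vox: val for vox, val in maxima}

    for t in values:
        lab, _ = ndimage.label(arr >= t, structure=_STRUCT)
        # which maxima live in each component at this threshold
        comp_members: dict[int, list[int]] = {}
        for idx, (vox, val) in enumerate(maxima):
            if val >= t:
                comp_members.setdefault(int(lab[vox]), []).append(idx)
        for members in comp_members.values():
            if len(members) < 2:
                continue
            best = min(members)  # maxima are rank-ordered: smaller index = larger value
            for idx in members:
                if childhood[idx] is None:
                    childhood[idx] = t
                if idx != best and elder[idx] is None:
                    elder[idx] = t

    pairs_elder = []
    pairs_child = []
    for idx, (_, val) in enumerate(maxima):
        d = elder[idx] if elder[idx] is not None else terminal
        dp = childhood[idx] if childhood[idx] is not None else terminal
        pairs_elder.append((val, d))
        pairs_child.append((val, dp))
    return pairs_elder, pairs_child
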