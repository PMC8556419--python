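"""Half-open interval arithmetic on sorted numpy arrays.

All coordinates are 0-based, half-open ``[start, end)``.  Functions accept
``(starts, ends)`` pairs of equal-length integer arrays and assume nothing
about overlap or order unless stated.
"""

from __future__ import annotations

import numpy as np

Arr = np.ndarray


def as_intervals(pairs) -> tuple[Arr, Arr]:
    """Coerce an iterable of (start, end) pairs to two int64 arrays."""
    if len(pairs) == 0:
        z = np.empty(0, dtype=np.int64)
        return z, z.copy()
    a = np.asarray(pairs, dtype=np.int64)
    return np.ascontiguousarray(a[:, 0]), np.ascontiguousarray(a[:, 1])


def merge(starts: Arr, ends: Arr) -> tuple[Arr, Arr]:
    """Union of intervals: sorted, non-overlapping, non-adjacent-merged."""
    if len(starts) == 0:
        return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)
    order = np.argsort(starts, kind="stable")
    s = np.asarray(starts)[order]
    e = np.asarray(ends)[order]
    out_s = [int(s[0])]
    out_e = [int(e[0])]
    for i in range(1, len(s)):
        if s[i] <= out_e[-1]:
            out_e[-1] = max(out_e[-1], int(e[i]))
        else:
            out_s.append(int(s[i]))
            out_e.append(int(e[i]))
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def total_length(starts: Arr, ends: Arr) -> int:
    s, e = merge(starts, ends)
    return int(np.sum(e - s))


def intersect(a_starts: Arr, a_ends: Arr, b_starts: Arr, b_ends: Arr) -> tuple[Arr, Arr]:
    """Intersection of two interval sets (each merged internally first)."""
    a_s, a_e = merge(a_starts, a_ends)
    b_s, b_e = merge(b_starts, b_ends)
    out_s, out_e = [], []
    i = j = 0
    while i < len(a_s) and j < len(b_s):
        lo = max(a_s[i], b_s[j])
        hi = min(a_e[i], b_e[j])
        if lo < hi:
            out_s.append(int(lo))
            out_e.append(int(hi))
        if a_e[i] < b_e[j]:
            i += 1
        else:
            j += 1
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def intersect_length(a_starts: Arr, a_ends: Arr, b_starts: Arr, b_ends: Arr) -> int:
    s, e = intersect(a_starts, a_ends, b_starts, b_ends)
    return int(np.sum(e - s))


def subtract(a_starts: Arr, a_ends: Arr, b_starts: Arr, b_ends: Arr) -> tuple[Arr, Arr]:
    """A minus B, both merged internally."""
    a_s, a_e = merge(a_starts, a_ends)
    b_s, b_e = merge(b_starts, b_ends)
    out_s, out_e = [], []
    j = 0
    for s, e in zip(a_s, a_e):
        cur = s
        while j < len(b_s) and b_e[j] <= cur:
            j += 1
        k = j
        while k < len(b_s) and b_s[k] < e:
            if b_s[k] > cur:
                out_s.append(int(cur))
                out_e.append(int(b_s[k]))
            cur = max(cur, b_e[k])
            k += 1
        if cur < e:
            out_s.append(int(cur))
            out_e.append(int(e))
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def n_sites_in(positions: Arr, starts: Arr, ends: Arr) -> int:
    """Count of positions falling inside any interval (intervals merged first)."""
    s, e = merge(starts, ends)
    if len(s) == 0 or len(positions) == 0:
        return 0
    lo = np.searchsorted(positions, s, side="left")
    hi = np.searchsorted(positions, e, side="left")
    return int(np.sum(hi - lo))


def mask_sites_in(positions: Arr, starts: Arr, ends: Arr) -> Arr:
    """Boolean mask over positions: inside any interval."""
    s, e = merge(starts, ends)
    mask = np.zeros(len(positions), dtype=bool)
    if len(s) == 0:
        return mask
    idx = np.searchsorted(s, positions, side="right") - 1
    valid = idx >= 0
    mask[valid] = positions[valid] < e[idx[valid]]
    return mask
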