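"""Half-open genomic interval arithmetic on numpy arrays.

All coordinates are 0-based half-open (BED convention).  Intervals are
represented as (n, 2) integer arrays or parallel start/end arrays; most
callers keep one array per chromosome.
"""

from __future__ import annotations

import numpy as np


def as_interval_array(intervals) -> np.ndarray:
    """Coerce a sequence of (start, end) pairs to an (n, 2) int64 array."""
    arr = np.asarray(list(intervals), dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected (start, end) pairs")
    return arr


def merge(intervals, book_ended: bool = True) -> np.ndarray:
    """Union of intervals; adjacent (book-ended) intervals merge by default."""
    arr = as_interval_array(intervals)
    if len(arr) == 0:
        return arr
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = []
    cur_s, cur_e = arr[0]
    for s, e in arr[1:]:
        joined = (s <= cur_e) if book_ended else (s < cur_e)
        if joined:
            cur_e = max(cur_e, e)
        else:
            out.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    out.append((cur_s, cur_e))
    return np.asarray(out, dtype=np.int64)


def total_length(intervals) -> int:
    arr = as_interval_array(intervals)
    if len(arr) == 0:
        return 0
    return int((arr[:, 1] - arr[:, 0]).sum())


def intersect(a, b) -> np.ndarray:
    """Intersection of two interval sets (each need not be disjoint)."""
    a = merge(a)
    b = merge(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return as_interval_array(out)


def subtract(a, b) -> np.ndarray:
    """Parts of ``a`` not covered by ``b`` (both merged first)."""
    a = merge(a)
    b = merge(b)
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < e:
            if b[k, 0] > cur:
                out.append((cur, b[k, 0]))
            cur = max(cur, b[k, 1])
            k += 1
        if cur < e:
            out.append((cur, e))
    return as_interval_array(out)


def intersect_length(a, b) -> int:
    return total_length(intersect(a, b))
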