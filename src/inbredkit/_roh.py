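"""Linear-time scan for maximal homozygous windows (numba kernel).

Genotype codes per SNP: 0 = homozygous, 1 = heterozygous, 2 = missing.
A window is admissible when its heterozygote count, missing count and every
internal adjacent-marker gap are within bounds; the kernel emits exactly the
admissible windows that cannot be extended on either side, then filters them
by the minimum SNP count and minimum physical span.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def scan_matrix(codes, pos, max_het, max_miss, max_gap, min_snp, min_len, out):
    """Scan every row of a (samples x SNP) code matrix on one chromosome.

    ``out`` is an (capacity, 5) int64 buffer receiving rows of
    (sample_index, start_index, end_index, n_het, n_miss); returns the number
    of segments, or -1 if the buffer overflowed.
    """
    cap = out.shape[0]
    total = 0
    row = np.empty((codes.shape[1] + 1, 4), dtype=np.int64)
    for i in range(codes.shape[0]):
        k = scan_row(codes[i], pos, max_het, max_miss, max_gap,
                     min_snp, min_len, row)
        if total + k > cap:
            return -1
        for s in range(k):
            out[total, 0] = i
            out[total, 1] = row[s, 0]
            out[total, 2] = row[s, 1]
            out[total, 3] = row[s, 2]
            out[total, 4] = row[s, 3]
            total += 1
    return total


@njit(cache=True)
def scan_row(codes, pos, max_het, max_miss, max_gap, min_snp, min_len, out):
    """Scan one sample on one chromosome; returns the number of segments.

    ``out`` is an (n+1, 4) int64 buffer receiving rows of
    (start_index, end_index, n_het, n_miss).
    """
    n = codes.shape[0]
    n_out = 0
    left = 0
    het = 0
    miss = 0
    for r in range(n):
        if r > 0 and pos[r] - pos[r - 1] > max_gap:
            # hard break: no admissible window crosses this gap
            if r - 1 >= left:
                ln = r - left
                if ln >= min_snp and pos[r - 1] - pos[left] >= min_len:
                    out[n_out, 0] = left
                    out[n_out, 1] = r - 1
                    out[n_out, 2] = het
                    out[n_out, 3] = miss
                    n_out += 1
            left = r
            het = 0
            miss = 0
        c = codes[r]
        if c == 1:
            het += 1
        elif c == 2:
            miss += 1
        if het > max_het or miss > max_miss:
            # [left, r-1] is maximal: cannot take r, and left was advanced
            # minimally, so extending leftwards is also inadmissible
            eh = het
            em = miss
            if c == 1:
                eh -= 1
            elif c == 2:
                em -= 1
            if r - 1 >= left:
                ln = r - left
                if ln >= min_snp and pos[r - 1] - pos[left] >= min_len:
                    out[n_out, 0] = left
                    out[n_out, 1] = r - 1
                    out[n_out, 2] = eh
                    out[n_out, 3] = em
                    n_out += 1
            while het > max_het or miss > max_miss:
                cl = codes[left]
                if cl == 1:
                    het -= 1
                elif cl == 2:
                    miss -= 1
                left += 1
    if n - 1 >= left:
        ln = n - left
        if ln >= min_snp and pos[n - 1] - pos[left] >= min_len:
            out[n_out, 0] = left
            out[n_out, 1] = n - 1
            out[n_out, 2] = het
            out[n_out, 3] = miss
            n_out += 1
    return n_out
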