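"""Independent reference implementations used only by the tests.

These deliberately use different algorithms from the package: the tabular
relationship matrix and Wright's path counting for pedigree inbreeding,
exhaustive window enumeration for ROH, and full multinomial enumeration for
the exact HWE test.
"""

from __future__ import annotations

from math import comb
from typing import Optional

import numpy as np

from inbredkit.pedigree import Pedigree


def tabular_f(ped: Pedigree) -> dict[str, float]:
    """F from the diagonal of the additive relationship matrix (tabular method)."""
    ids = list(ped.ids)
    pos = {iid: k for k, iid in enumerate(ids)}
    # order by generation so parents are processed first
    depth: dict[str, int] = {}
    for iid in ids:
        stack = [iid]
        while stack:
            node = stack[-1]
            pars = [p for p in ped.parents(node) if p is not None and p in ped]
            missing = [p for p in pars if p not in depth]
            if missing:
                stack.extend(missing)
            else:
                depth[node] = 1 + max((depth[p] for p in pars), default=-1)
                stack.pop()
    order = sorted(ids, key=lambda i: (depth[i], pos[i]))
    k_of = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for i, iid in enumerate(order):
        s, d = ped.parents(iid)
        si = k_of[s] if s is not None and s in k_of else None
        di = k_of[d] if d is not None and d in k_of else None
        for j in range(i):
            a = 0.0
            if si is not None:
                a += 0.5 * A[si, j]
            if di is not None:
                a += 0.5 * A[di, j]
            A[i, j] = A[j, i] = a
        A[i, i] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None
                         else 0.0)
    return {iid: float(A[k_of[iid], k_of[iid]] - 1.0) for iid in order}


def wright_path_f(ped: Pedigree, focal: str) -> float:
    """Wright's path-counting inbreeding coefficient for one individual.

    Sums (1/2)^(n_s + n_d + 1) (1 + F_A) over all common ancestors A of the
    focal's parents and all pairs of ancestor paths that share only A.
    """
    memo: dict[str, float] = {}

    def paths_to_ancestors(start: str) -> list[list[str]]:
        """All simple paths start -> ancestor (inclusive of both ends)."""
        out = [[start]]
        frontier = [[start]]
        while frontier:
            nxt = []
            for path in frontier:
                for par in ped.parents(path[-1]):
                    if par is not None and par in ped:
                        new = path + [par]
                        out.append(new)
                        nxt.append(new)
            frontier = nxt
        return out

    def f_of(iid: str) -> float:
        if iid in memo:
            return memo[iid]
        s, d = ped.parents(iid)
        if s is None or d is None or s not in ped or d not in ped:
            memo[iid] = 0.0
            return 0.0
        total = 0.0
        for ps in paths_to_ancestors(s):
            for pd_ in paths_to_ancestors(d):
                if ps[-1] != pd_[-1]:
                    continue
                # paths may share only the common ancestor itself
                if set(ps[:-1]) & set(pd_[:-1]):
                    continue
                anc = ps[-1]
                total += 0.5 ** (len(ps) + len(pd_) - 1) * (1.0 + f_of(anc))
        memo[iid] = total
        return total

    return f_of(focal)


def roh_maximal_windows(codes: np.ndarray, pos: np.ndarray, max_het: int,
                        max_miss: int, max_gap: int, min_snp: int,
                        min_len: int) -> set[tuple[int, int]]:
    """Exhaustive enumeration of maximal admissible windows on one chromosome.

    ``codes``: 0 hom, 1 het, 2 missing.  A window [i, j] is admissible when
    its het and missing counts and all internal adjacent gaps are within
    bounds; maximality is containment-maximality among admissible windows.
    The returned set keeps maximal windows meeting the min SNP count and
    minimum span, as (start_index, end_index) pairs.
    """
    n = len(codes)
    het = np.concatenate([[0], np.cumsum(codes == 1)])
    mis = np.concatenate([[0], np.cumsum(codes == 2)])
    gaps = np.diff(pos)

    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    # gap admissibility: all internal gaps of [i, j] within bound
    big = np.concatenate([gaps > max_gap, [True]])
    # reach[i] = largest j such that no gap inside [i, j] exceeds the bound
    reach = np.empty(n, dtype=np.int64)
    r = n - 1
    for i in range(n - 1, -1, -1):
        if big[i]:
            r = i
        reach[i] = r

    valid = ((ii <= jj)
             & (het[jj + 1] - het[ii] <= max_het)
             & (mis[jj + 1] - mis[ii] <= max_miss)
             & (jj <= reach[ii]))

    left_ext = np.zeros_like(valid)
    left_ext[1:, :] = valid[:-1, :]     # [i-1, j] admissible
    right_ext = np.zeros_like(valid)
    right_ext[:, :-1] = valid[:, 1:]    # [i, j+1] admissible
    maximal = valid & ~left_ext & ~right_ext

    keep = ((jj - ii + 1 >= min_snp)
            & (pos[jj] - pos[ii] >= min_len))
    out = {(int(i), int(j)) for i, j in zip(*np.nonzero(maximal & keep))}
    return out


def hwe_enum_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE p-value by full enumeration with exact integer arithmetic."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab

    def weight(h: int) -> int:
        aa = (na - h) // 2
        bb = (nb - h) // 2
        # multinomial coefficient x 2^h
        num = comb(n, aa) * comb(n - aa, h) * 2 ** h
        return num

    hs = [h for h in range(min(na, nb) + 1)
          if (na - h) % 2 == 0 and h % 2 == (na % 2)]
    weights = {h: weight(h) for h in hs}
    total = sum(weights.values())
    obs = weights[n_ab]
    return sum(w for w in weights.values() if w <= obs) / total
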