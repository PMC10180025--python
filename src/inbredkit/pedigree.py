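"""Pedigree inbreeding (Wright's F via Meuwissen–Luo) and pedigree completeness.

The pedigree is a directed acyclic parent map in birth (topological) order.
Missing ancestors contribute zero relationship: founders and individuals with
an unknown parent have F = 0.
"""

from __future__ import annotations

import heapq
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (e.g. cycles)."""


class Pedigree:
    """Parent map with birth ordering.

    Records are ``(id, sire, dam)`` with ``None`` for an unknown parent.
    Construction preserves the given order, which is expected to be
    topological (parents before offspring); use :func:`validate_pedigree`
    to check.
    """

    def __init__(self, records: Iterable[tuple[str, Optional[str], Optional[str]]]):
        self.ids: list[str] = []
        self.sire: dict[str, Optional[str]] = {}
        self.dam: dict[str, Optional[str]] = {}
        for rec in records:
            iid, sire, dam = rec
            if iid in self.sire:
                raise PedigreeError(f"duplicate individual id {iid!r}")
            self.ids.append(iid)
            self.sire[iid] = sire if sire not in (None, "0", "") else None
            self.dam[iid] = dam if dam not in (None, "0", "") else None

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, iid: str) -> bool:
        return iid in self.sire

    def parents(self, iid: str) -> tuple[Optional[str], Optional[str]]:
        return self.sire[iid], self.dam[iid]

    def is_founder(self, iid: str) -> bool:
        return self.sire[iid] is None and self.dam[iid] is None

    def records(self) -> list[tuple[str, Optional[str], Optional[str]]]:
        return [(i, self.sire[i], self.dam[i]) for i in self.ids]

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Pedigree":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("0")
        cols = list(df.columns[:3])
        return cls((r[cols[0]], r[cols[1]], r[cols[2]]) for _, r in df.iterrows())

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tsire\tdam\n")
            for iid in self.ids:
                s = self.sire[iid] or "0"
                d = self.dam[iid] or "0"
                fh.write(f"{iid}\t{s}\t{d}\n")


@dataclass
class PedigreeReport:
    """Structural validation findings."""
    cycles: list[str] = field(default_factory=list)          # one member per cycle
    self_parents: list[str] = field(default_factory=list)
    order_violations: list[str] = field(default_factory=list)  # child before parent
    unknown_parents: list[str] = field(default_factory=list)   # parent id never defined

    @property
    def ok(self) -> bool:
        return not (self.cycles or self.self_parents or self.order_violations)


def validate_pedigree(ped: Pedigree) -> PedigreeReport:
    """Report cycles, self-parenting and birth-order violations."""
    report = PedigreeReport()
    index = {iid: k for k, iid in enumerate(ped.ids)}
    for iid in ped.ids:
        for par in ped.parents(iid):
            if par is None:
                continue
            if par == iid:
                report.self_parents.append(iid)
            elif par not in index:
                report.unknown_parents.append(par)
            elif index[par] > index[iid]:
                report.order_violations.append(iid)

    # iterative DFS over parent links for cycle detection
    WHITE, GREY, BLACK = 0, 1, 2
    color = {iid: WHITE for iid in ped.ids}
    for start in ped.ids:
        if color[start] != WHITE:
            continue
        stack: list[tuple[str, int]] = [(start, 0)]
        while stack:
            node, pi = stack[-1]
            if pi == 0:
                color[node] = GREY
            pars = [p for p in ped.parents(node) if p is not None and p in color]
            if pi < len(pars):
                stack[-1] = (node, pi + 1)
                nxt = pars[pi]
                if color[nxt] == GREY:
                    report.cycles.append(nxt)
                elif color[nxt] == WHITE:
                    stack.append((nxt, 0))
            else:
                color[node] = BLACK
                stack.pop()
    return report


def _topological_order(ped: Pedigree) -> list[str]:
    """Order with parents before offspring; raises on cycles."""
    report = validate_pedigree(ped)
    if report.cycles:
        raise PedigreeError(f"pedigree cycle involving {report.cycles[0]!r}")
    if report.self_parents:
        raise PedigreeError(f"{report.self_parents[0]!r} is its own ancestor")
    depth: dict[str, int] = {}

    def gen(iid: str) -> int:
        stack = [iid]
        while stack:
            node = stack[-1]
            if node in depth:
                stack.pop()
                continue
            pars = [p for p in ped.parents(node) if p is not None and p in ped]
            missing = [p for p in pars if p not in depth]
            if missing:
                stack.extend(missing)
            else:
                depth[node] = 1 + max((depth[p] for p in pars), default=-1)
                stack.pop()
        return depth[iid]

    for iid in ped.ids:
        gen(iid)
    # stable by generation, then original order
    pos = {iid: k for k, iid in enumerate(ped.ids)}
    return sorted(ped.ids, key=lambda i: (depth[i], pos[i]))


def _generation_depth(ped: Pedigree, order: list[str]) -> dict[str, int]:
    depth: dict[str, int] = {}
    for iid in order:
        pars = [p for p in ped.parents(iid) if p is not None and p in ped]
        depth[iid] = 1 + max((depth[p] for p in pars), default=-1)
    return depth


def _meuwissen_luo(ped: Pedigree, order: list[str]) -> dict[str, float]:
    """Exact F for every individual by the Meuwissen & Luo ancestor trace."""
    pos = {iid: k for k, iid in enumerate(order)}
    sire_i = np.full(len(order), -1, dtype=np.int64)
    dam_i = np.full(len(order), -1, dtype=np.int64)
    for k, iid in enumerate(order):
        s, d = ped.parents(iid)
        sire_i[k] = pos[s] if s is not None and s in pos else -1
        dam_i[k] = pos[d] if d is not None and d in pos else -1

    F = np.zeros(len(order))
    D = np.zeros(len(order))  # within-family segregation variance

    def _D(k: int) -> float:
        s, d = sire_i[k], dam_i[k]
        if s >= 0 and d >= 0:
            return 0.5 - 0.25 * (F[s] + F[d])
        if s >= 0:
            return 0.75 - 0.25 * F[s]
        if d >= 0:
            return 0.75 - 0.25 * F[d]
        return 1.0

    for k in range(len(order)):
        D[k] = _D(k)
        s, d = sire_i[k], dam_i[k]
        if s < 0 or d < 0:
            F[k] = 0.0
            continue
        # trace a_kk = sum over ancestors j of L_j^2 D_j, with L combined
        # across paths before squaring; process youngest ancestors first
        L: dict[int, float] = {k: 1.0}
        heap = [-k]
        a_kk = 0.0
        while heap:
            j = -heapq.heappop(heap)
            Lj = L.pop(j)
            a_kk += Lj * Lj * D[j]
            for par in (sire_i[j], dam_i[j]):
                if par < 0:
                    continue
                if par in L:
                    L[par] += 0.5 * Lj
                else:
                    L[par] = 0.5 * Lj
                    heapq.heappush(heap, -par)
        F[k] = a_kk - 1.0
    return {iid: float(F[pos[iid]]) for iid in order}


def _truncated_ancestors(ped: Pedigree, focal: str, max_depth: int) -> dict[str, int]:
    """Ancestors of ``focal`` at minimum path depth <= max_depth (focal depth 0)."""
    best: dict[str, int] = {focal: 0}
    frontier = [focal]
    d = 0
    while frontier and d < max_depth:
        d += 1
        nxt = []
        for iid in frontier:
            for par in ped.parents(iid):
                if par is None or par not in ped:
                    continue
                if par not in best or best[par] > d:
                    best[par] = d
                    nxt.append(par)
        frontier = nxt
    return best


def compute_f_ped(ped: Pedigree, max_depth: Optional[int] = 10) -> dict[str, float]:
    """Wright's inbreeding coefficient for every individual.

    ``max_depth`` truncates each individual's pedigree at that many ancestral
    generations; ancestors beyond the horizon are treated as unknown (and thus
    unrelated, non-inbred founders).  ``max_depth=None`` disables truncation.
    Implemented with the Meuwissen–Luo linear-memory ancestor trace.
    """
    order = _topological_order(ped)
    if max_depth is not None and max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if max_depth is None:
        return _meuwissen_luo(ped, order)
    depth = _generation_depth(ped, order)
    if max(depth.values(), default=0) <= max_depth:
        # truncation cannot bind: every ancestor path is within the horizon
        return _meuwissen_luo(ped, order)

    # per-focal exact computation on the truncated subpedigree
    pos = {iid: k for k, iid in enumerate(order)}
    out: dict[str, float] = {}
    for focal in order:
        anc = _truncated_ancestors(ped, focal, max_depth)
        sub_order = sorted(anc, key=lambda i: pos[i])
        sub_records = []
        for iid in sub_order:
            s, d = ped.parents(iid)
            # a link survives only if the parent is inside the horizon
            s = s if (s in anc and anc[s] <= max_depth) else None
            d = d if (d in anc and anc[d] <= max_depth) else None
            sub_records.append((iid, s, d))
        sub = Pedigree(sub_records)
        out[focal] = _meuwissen_luo(sub, sub_order)[focal]
    return out


def pedigree_completeness(ped: Pedigree, d: int = 10
                          ) -> tuple[dict[str, float], float]:
    """MacCluer-style pedigree completeness index per individual, plus the mean.

    For each parental line, ``C_line = (1/d) * sum_{i=1..d} k_i / 2**i`` where
    ``k_i`` counts known ancestor slots in generation ``i`` of that line
    (generation 1 is the parent itself, so ``k_i <= 2**(i-1)``).  The index
    combines the two lines as ``4*C_sire*C_dam / (C_sire + C_dam)``, which is
    1 when both lines are fully known to depth ``d`` and 0 when either line is
    entirely unknown.
    """
    if d < 1:
        raise ValueError("d must be >= 1")

    def line(root: Optional[str]) -> float:
        if root is None or root not in ped:
            return 0.0
        total = 0.0
        level: Counter[str] = Counter({root: 1})
        for i in range(1, d + 1):
            total += sum(level.values()) / 2 ** i
            nxt: Counter[str] = Counter()
            for iid, mult in level.items():
                for par in ped.parents(iid):
                    if par is not None and par in ped:
                        nxt[par] += mult
            level = nxt
            if not level:
                break
        return total / d

    out: dict[str, float] = {}
    for iid in ped.ids:
        cs = line(ped.sire[iid])
        cd = line(ped.dam[iid])
        if cs == 0.0 or cd == 0.0:
            out[iid] = 0.0
        else:
            out[iid] = 4.0 * cs * cd / (cs + cd)
    mean = float(np.mean(list(out.values()))) if out else float("nan")
    return out, mean
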