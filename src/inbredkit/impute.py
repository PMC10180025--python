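"""Seeded family-then-frequency genotype imputation.

A deliberately simple imputation channel for concordance studies: it fills
missing dosages from parental genotypes where Mendelian transmission pins
them down, falls back to the most probable genotype given whatever parental
information exists plus the population allele frequency, and otherwise
samples from Hardy–Weinberg proportions with a seeded generator.  It does no
phasing and uses no haplotype reference — its only promise is a reproducible
fill whose error rate grows as the genotyped fraction shrinks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import AlleleFrequencies
from .io import MISSING, GenotypeDataset, MarkerMap
from .pedigree import Pedigree


@dataclass(frozen=True)
class ImputationConfig:
    """Imputation settings; the seed is required for reproducibility."""

    seed: int
    mode: str = "family_then_frequency"

    def __post_init__(self) -> None:
        if self.mode != "family_then_frequency":
            raise ValueError(f"unknown imputation mode {self.mode!r}")


def impute(masked: GenotypeDataset, full_map: MarkerMap, ped: Pedigree,
           ref_freqs: AlleleFrequencies, cfg: ImputationConfig) -> GenotypeDataset:
    """Fill every missing dosage; genotyped entries pass through unchanged.

    Fill order per missing cell:

    1. Mendelian-certain: both parental transmissions are determined
       (homozygous parents, or certain-heterozygous combinations).
    2. At least one parental genotype available: the most probable genotype
       given parental transmission probabilities and the population
       frequency, ties broken toward the lower dosage.
    3. No parental information: a draw from Hardy–Weinberg proportions at
       ``ref_freqs`` using the seeded generator.

    Samples absent from the pedigree fall through to rule 3.  The masked map
    must be a subset of ``full_map`` (same ids); output is on ``full_map``
    with zero missing entries.
    """
    full_ids = {s: j for j, s in enumerate(full_map.snp_id)}
    cols = []
    for s in masked.map.snp_id:
        if s not in full_ids:
            raise ValueError(f"masked map SNP {s!r} not present in the full map")
        cols.append(full_ids[s])
    cols = np.asarray(cols, dtype=np.int64)
    if len(ref_freqs.p) != len(full_map):
        raise ValueError("reference frequencies are not aligned to the full map")

    n, m = masked.n_samples, len(full_map)
    dosage = np.full((n, m), MISSING, dtype=np.int8)
    dosage[:, cols] = masked.dosage

    p = np.where(np.isfinite(ref_freqs.p), ref_freqs.p, 0.5)

    # parental row indices (-1 = parent not genotyped / unknown)
    row = {s: i for i, s in enumerate(masked.samples)}
    par1 = np.full(n, -1, dtype=np.int64)
    par2 = np.full(n, -1, dtype=np.int64)
    for i, s in enumerate(masked.samples):
        if s in ped:
            sire, dam = ped.parents(s)
            if sire is not None and sire in row:
                par1[i] = row[sire]
            if dam is not None and dam in row:
                par2[i] = row[dam]

    def transmission(par_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """P(transmit counted allele) per cell, and whether it came from a genotype."""
        has = par_idx >= 0
        g = np.where(has[:, None], dosage[np.maximum(par_idx, 0)], MISSING)
        informed = g != MISSING
        prob = np.where(informed, g * np.float32(0.5), p32[None, :])
        return prob.astype(np.float32, copy=False), informed

    p32 = p.astype(np.float32)
    prob1, inf1 = transmission(par1)
    prob2, inf2 = transmission(par2)

    p0 = (1.0 - prob1) * (1.0 - prob2)
    p2 = prob1 * prob2
    p1 = 1.0 - p0 - p2
    # argmax over (p0, p1, p2) with ties broken toward the lower dosage
    best = (p1 > p0).astype(np.int8)
    np.putmask(best, (p2 > p1) & (p2 > p0), 2)
    informed = inf1 | inf2

    to_fill = dosage == MISSING
    rule12 = to_fill & informed
    dosage[rule12] = best[rule12]

    rule3 = to_fill & ~informed
    if rule3.any():
        rng = np.random.default_rng(cfg.seed)
        cell_p = np.broadcast_to(p[None, :], (n, m))[rule3]
        dosage[rule3] = rng.binomial(2, cell_p).astype(np.int8)

    return GenotypeDataset(list(masked.samples), full_map, dosage)
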