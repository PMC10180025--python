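"""Gene-drop simulation with tracked founder alleles.

Generates a discrete-generation pedigree with few sires (driving inbreeding,
as in dairy AI breeding), drops founder alleles down it with Haldane
recombination (Poisson crossovers, no interference), and records the founder
origin of every chromosome segment so each individual's TRUE autozygosity —
the genome fraction where the two haplotypes descend from the same founder
allele — is known exactly.  Panels mirroring commercial chips are uniform
random SNP subsets at specified overlap fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import GenotypeDataset, MarkerMap, PanelDefinition
from .pedigree import Pedigree

#: Overlap fractions of the six commercial panels with the imputation set.
DEFAULT_PANEL_FRACTIONS = (0.9462, 0.9128, 0.1642, 0.1997, 0.3237, 0.4763)
DEFAULT_PANEL_NAMES = ("BovineHD", "GP-HD150K", "GGP3", "GGP4",
                       "GeneSeekMD", "LabogenaMD")

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Desk-scale population settings.

    Defaults: 200 founders plus 6 generations of 200 offspring each
    (1,400 animals), 5 sires per generation, 5 chromosomes of 100 Mbp with
    2,000 SNP each, founder allele frequencies uniform on [0.05, 0.95] and a
    1 cM/Mb physical-to-genetic map.
    """

    n_founders: int = 200
    n_generations: int = 6
    sires_per_generation: int = 5
    n_offspring_per_generation: Optional[int] = None  # default: n_founders
    n_chromosomes: int = 5
    chromosome_length_bp: int = 100_000_000
    snps_per_chromosome: int = 2000
    founder_maf_range: tuple[float, float] = (0.05, 0.95)
    cM_per_Mb: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_founders, self.n_generations, self.sires_per_generation,
               self.n_chromosomes, self.chromosome_length_bp) < 1:
            raise ValueError("all counts must be positive")
        if self.snps_per_chromosome < 2:
            raise ValueError("need at least 2 SNP per chromosome")
        lo, hi = self.founder_maf_range
        if not (0 < lo <= hi < 1):
            raise ValueError("founder_maf_range must satisfy 0 < lo <= hi < 1")
        if self.cM_per_Mb < 0:
            raise ValueError("cM_per_Mb must be non-negative")

    @property
    def offspring_per_generation(self) -> int:
        return self.n_offspring_per_generation or self.n_founders


class FounderOriginTracks:
    """Per-haplotype founder-origin segments for every simulated individual.

    ``tracks[sample][chrom_index]`` is a pair of segment lists, one per
    haplotype; each segment is ``(start_bp, end_bp, founder_allele_id)`` and
    the segments tile ``[0, chromosome_length_bp)`` exactly.  Founder
    haplotypes carry the 2 x n_founders distinct ids.
    """

    def __init__(self, chromosome_length_bp: int, n_chromosomes: int):
        self.chromosome_length_bp = chromosome_length_bp
        self.n_chromosomes = n_chromosomes
        self.tracks: dict[str, list[tuple[list, list]]] = {}

    def samples(self) -> list[str]:
        return list(self.tracks)

    def autozygous_length(self, sample: str) -> int:
        """Total bp where the two haplotypes carry the same founder allele id."""
        total = 0
        for track0, track1 in self.tracks[sample]:
            i = j = 0
            while i < len(track0) and j < len(track1):
                s0, e0, o0 = track0[i]
                s1, e1, o1 = track1[j]
                lo, hi = max(s0, s1), min(e0, e1)
                if hi > lo and o0 == o1:
                    total += hi - lo
                if e0 <= e1:
                    i += 1
                else:
                    j += 1
        return total

    def true_autozygosity(self, sample: str) -> float:
        return self.autozygous_length(sample) / (
            self.chromosome_length_bp * self.n_chromosomes)


def true_autozygosity(tracks: FounderOriginTracks) -> pd.Series:
    """Genome fraction identical by descent, per sample, in [0, 1]."""
    return pd.Series({s: tracks.true_autozygosity(s) for s in tracks.samples()},
                     name="true_autozygosity")


def simulate_pedigree(cfg: SimulationConfig) -> Pedigree:
    """Discrete-generation pedigree with a small sire pool.

    Founders are half male, half female (by index parity).  Each offspring
    draws its sire uniformly from ``sires_per_generation`` males of the
    previous generation and its dam uniformly from the previous generation's
    females.  Ids encode the generation (``G0_000`` ...), so birth order is
    topological by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5ED1]))
    records: list[tuple[str, Optional[str], Optional[str]]] = []
    males = [f"G0_{i:04d}" for i in range(0, cfg.n_founders, 2)]
    females = [f"G0_{i:04d}" for i in range(1, cfg.n_founders, 2)]
    for i in range(cfg.n_founders):
        records.append((f"G0_{i:04d}", None, None))
    if not males or not females:
        raise ValueError("need founders of both sexes")

    for g in range(1, cfg.n_generations + 1):
        k = min(cfg.sires_per_generation, len(males))
        sires = rng.choice(males, size=k, replace=False)
        n_off = cfg.offspring_per_generation
        sire_pick = rng.integers(0, len(sires), size=n_off)
        dam_pick = rng.integers(0, len(females), size=n_off)
        new_males, new_females = [], []
        for i in range(n_off):
            iid = f"G{g}_{i:04d}"
            records.append((iid, str(sires[sire_pick[i]]), females[dam_pick[i]]))
            (new_males if i % 2 == 0 else new_females).append(iid)
        males, females = new_males, new_females
    return Pedigree(records)


def _make_map(cfg: SimulationConfig, rng: np.random.Generator) -> MarkerMap:
    snp_id, chrom, pos, aa, ab = [], [], [], [], []
    for c in range(1, cfg.n_chromosomes + 1):
        want = cfg.snps_per_chromosome
        uniq = np.empty(0, dtype=np.int64)
        while len(uniq) < want:  # rejection-sample distinct positions
            draw = rng.integers(1, cfg.chromosome_length_bp, size=2 * want)
            uniq = np.unique(np.concatenate([uniq, draw]))
        positions = np.sort(rng.choice(uniq, size=want, replace=False))
        base_pairs = rng.integers(0, 4, size=(cfg.snps_per_chromosome, 2))
        # resample identical pairs deterministically: shift the second base
        same = base_pairs[:, 0] == base_pairs[:, 1]
        base_pairs[same, 1] = (base_pairs[same, 0] + 1) % 4
        letters = _BASES[base_pairs]
        letters.sort(axis=1)  # counted allele = lexicographically smaller
        for j in range(cfg.snps_per_chromosome):
            snp_id.append(f"c{c}_s{j:05d}")
        chrom.extend([c] * cfg.snps_per_chromosome)
        pos.extend(positions.tolist())
        aa.extend(letters[:, 0].tolist())
        ab.extend(letters[:, 1].tolist())
    return MarkerMap(np.array(snp_id, dtype=object), np.array(chrom),
                     np.array(pos), np.array(aa, dtype=object),
                     np.array(ab, dtype=object))


def _recombine(rng: np.random.Generator, length_bp: int, morgans: float,
               hap_pair: np.ndarray, track_pair: tuple[list, list],
               snp_pos: np.ndarray) -> tuple[np.ndarray, list]:
    """One meiosis: crossovers ~ Poisson(morgans), uniform positions."""
    k = rng.poisson(morgans) if morgans > 0 else 0
    cross = np.sort(rng.integers(1, length_bp, size=k)) if k else \
        np.empty(0, dtype=np.int64)
    start = int(rng.integers(0, 2))
    # allele mosaic at SNP positions
    phase = (np.searchsorted(cross, snp_pos, side="right") + start) % 2
    gamete = np.where(phase == 0, hap_pair[0], hap_pair[1])
    # splice the origin tracks at the same crossovers
    bounds = [0, *cross.tolist(), length_bp]
    track: list = []
    for seg_i in range(len(bounds) - 1):
        lo, hi = bounds[seg_i], bounds[seg_i + 1]
        if hi <= lo:
            continue
        src = track_pair[(seg_i + start) % 2]
        for s, e, o in src:
            s2, e2 = max(s, lo), min(e, hi)
            if e2 > s2:
                if track and track[-1][2] == o and track[-1][1] == s2:
                    track[-1] = (track[-1][0], e2, o)
                else:
                    track.append((s2, e2, o))
    return gamete, track


def gene_drop(ped: Pedigree, cfg: SimulationConfig
              ) -> tuple[GenotypeDataset, FounderOriginTracks]:
    """Drop founder alleles down the pedigree with Haldane recombination.

    Founder haplotypes are drawn SNP-wise at frequencies from
    ``founder_maf_range``; each transmission recombines the parent's two
    haplotypes with a Poisson crossover count (chromosome length in Morgans)
    and uniform crossover positions.  Returns the dosage dataset (all
    individuals, no missing calls) and the founder-origin tracks.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xD20]))
    mp = _make_map(cfg, rng)
    m_per_chrom = cfg.snps_per_chromosome
    L = cfg.chromosome_length_bp
    morgans = (L / 1e6) * cfg.cM_per_Mb / 100.0
    p = rng.uniform(*cfg.founder_maf_range, size=len(mp))

    chrom_cols = [np.flatnonzero(mp.chromosome == c)
                  for c in range(1, cfg.n_chromosomes + 1)]
    chrom_pos = [mp.position_bp[cols] for cols in chrom_cols]

    haps: dict[str, list[np.ndarray]] = {}   # sample -> per-chrom (2, m) uint8
    tracks = FounderOriginTracks(L, cfg.n_chromosomes)
    founder_no = 0
    for iid in ped.ids:
        sire, dam = ped.parents(iid)
        if sire is None or dam is None:
            ids = (2 * founder_no, 2 * founder_no + 1)
            founder_no += 1
            per_chrom, per_track = [], []
            for cols in chrom_cols:
                hap = (rng.random((2, len(cols))) < p[cols]).astype(np.uint8)
                per_chrom.append(hap)
                per_track.append(([(0, L, ids[0])], [(0, L, ids[1])]))
            haps[iid] = per_chrom
            tracks.tracks[iid] = per_track
        else:
            per_chrom, per_track = [], []
            for ci in range(cfg.n_chromosomes):
                gam_s, trk_s = _recombine(rng, L, morgans, haps[sire][ci],
                                          tracks.tracks[sire][ci], chrom_pos[ci])
                gam_d, trk_d = _recombine(rng, L, morgans, haps[dam][ci],
                                          tracks.tracks[dam][ci], chrom_pos[ci])
                per_chrom.append(np.stack([gam_s, gam_d]))
                per_track.append((trk_s, trk_d))
            haps[iid] = per_chrom
            tracks.tracks[iid] = per_track

    dosage = np.empty((len(ped.ids), len(mp)), dtype=np.int8)
    for i, iid in enumerate(ped.ids):
        for ci, cols in enumerate(chrom_cols):
            dosage[i, cols] = haps[iid][ci].sum(axis=0)
    return GenotypeDataset(list(ped.ids), mp, dosage), tracks


def define_panels(mp: MarkerMap,
                  overlap_fractions: Sequence[float] = DEFAULT_PANEL_FRACTIONS,
                  seed: int = 0,
                  names: Optional[Sequence[str]] = None) -> list[PanelDefinition]:
    """Uniform random SNP panels at given overlap fractions with the map.

    Each panel is a random subset of ``round(f * |map|)`` SNP; defaults
    mirror the documented overlaps of six commercial bovine chips with an
    84k imputation set.
    """
    if names is None:
        names = (DEFAULT_PANEL_NAMES
                 if tuple(overlap_fractions) == DEFAULT_PANEL_FRACTIONS
                 else [f"panel_{f:.4f}" for f in overlap_fractions])
    if len(names) != len(overlap_fractions):
        raise ValueError("names and overlap_fractions differ in length")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xAE1]))
    panels = []
    for name, f in zip(names, overlap_fractions):
        if not (0 < f <= 1):
            raise ValueError(f"overlap fraction {f} outside (0, 1]")
        size = int(round(f * len(mp)))
        chosen = rng.choice(mp.snp_id, size=max(size, 1), replace=False)
        panels.append(PanelDefinition(name, frozenset(chosen.tolist())))
    return panels
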