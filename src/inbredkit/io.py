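"""Genotype I/O in PLINK text format, SNP panels, and marker-spacing summaries.

Genotypes are held as an individuals x SNP dosage matrix counting copies of
``allele_a`` (the lexicographically smaller observed allele), with ``-1``
marking a missing call.  Coordinates are 1-based inclusive base pairs, as in
the PLINK MAP convention, and chromosomes are restricted to the bovine
autosome set (1..29).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Dosage code for a missing genotype call.
MISSING: int = -1

#: Valid autosome numbers (cattle karyotype: 29 autosomes).
AUTOSOMES = frozenset(range(1, 30))


class PlinkParseError(ValueError):
    """Raised when a PED/MAP file cannot be parsed."""


@dataclass(frozen=True)
class MarkerMap:
    """Physical map of biallelic autosomal SNP.

    Parameters
    ----------
    snp_id
        Unique marker identifiers.
    chromosome
        Autosome number (1..29) per marker.
    position_bp
        1-based physical position in base pairs.
    allele_a, allele_b
        Single-character allele codes; ``allele_a`` is the counted allele.
    """

    snp_id: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    allele_a: np.ndarray
    allele_b: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "snp_id", np.asarray(self.snp_id, dtype=object))
        object.__setattr__(self, "chromosome", np.asarray(self.chromosome, dtype=np.int64))
        object.__setattr__(self, "position_bp", np.asarray(self.position_bp, dtype=np.int64))
        object.__setattr__(self, "allele_a", np.asarray(self.allele_a, dtype=object))
        object.__setattr__(self, "allele_b", np.asarray(self.allele_b, dtype=object))
        n = len(self.snp_id)
        for name in ("chromosome", "position_bp", "allele_a", "allele_b"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"MarkerMap field {name!r} has length "
                                 f"{len(getattr(self, name))}, expected {n}")
        if len(set(self.snp_id)) != n:
            raise ValueError("MarkerMap snp_ids are not unique")
        bad = set(np.unique(self.chromosome)) - AUTOSOMES
        if bad:
            raise ValueError(f"chromosome(s) {sorted(bad)} outside the autosome set 1..29")
        if np.any(self.position_bp < 0):
            raise ValueError("negative position_bp")

    def __len__(self) -> int:
        return len(self.snp_id)

    @property
    def is_sorted(self) -> bool:
        """True if markers are grouped by chromosome with strictly increasing positions."""
        chrom, pos = self.chromosome, self.position_bp
        if len(chrom) < 2:
            return True
        # chromosomes must appear in non-decreasing blocks
        if np.any(np.diff(chrom) < 0):
            return False
        same = np.diff(chrom) == 0
        return bool(np.all(np.diff(pos)[same] > 0))

    def subset(self, indices: Sequence[int]) -> "MarkerMap":
        idx = np.asarray(indices, dtype=np.int64)
        return MarkerMap(self.snp_id[idx], self.chromosome[idx],
                         self.position_bp[idx], self.allele_a[idx], self.allele_b[idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": self.snp_id, "chromosome": self.chromosome,
            "position_bp": self.position_bp,
            "allele_a": self.allele_a, "allele_b": self.allele_b,
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MarkerMap":
        return cls(df["snp_id"].to_numpy(), df["chromosome"].to_numpy(),
                   df["position_bp"].to_numpy(), df["allele_a"].to_numpy(),
                   df["allele_b"].to_numpy())


@dataclass
class GenotypeDataset:
    """Dosage-coded genotype matrix with its marker map and sample ids."""

    samples: list[str]
    map: MarkerMap
    dosage: np.ndarray  # int8, shape (n_samples, n_snp), codes {0,1,2,MISSING}

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.map)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.map)} SNP")
        codes = np.unique(self.dosage)
        bad = set(codes.tolist()) - {MISSING, 0, 1, 2}
        if bad:
            raise ValueError(f"illegal dosage codes {sorted(bad)}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids are not unique")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snp(self) -> int:
        return len(self.map)

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(list(self.samples), self.map, self.dosage.copy())


@dataclass(frozen=True)
class PanelDefinition:
    """A named SNP subset, modelling one genotyping chip's content.

    ``snp_ids`` need not all exist in a given map; intersections are taken
    explicitly where needed.
    """

    name: str
    snp_ids: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "snp_ids", frozenset(self.snp_ids))
        if not self.snp_ids:
            raise ValueError(f"panel {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.snp_ids)


# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------

def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypeDataset:
    """Read a PLINK text PED/MAP pair into a :class:`GenotypeDataset`.

    The counted allele (``allele_a``) at each SNP is the lexicographically
    smaller of the observed alleles; an allele pair containing ``0`` is read
    as a missing call.  More than two distinct alleles at a SNP is an error.
    """
    map_df = pd.read_csv(map_path, sep=r"\s+", header=None,
                         names=["chromosome", "snp_id", "cm", "position_bp"],
                         dtype={"snp_id": str})
    n_snp = len(map_df)

    samples: list[str] = []
    pairs: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != 6 + 2 * n_snp:
                raise PlinkParseError(
                    f"{ped_path}: line {lineno} has {len(tokens)} fields, "
                    f"expected {6 + 2 * n_snp}")
            samples.append(tokens[1])
            pairs.append(np.array(tokens[6:], dtype=object).reshape(n_snp, 2))

    n = len(samples)
    dosage = np.full((n, n_snp), MISSING, dtype=np.int8)
    allele_a = np.empty(n_snp, dtype=object)
    allele_b = np.empty(n_snp, dtype=object)
    alleles = np.stack(pairs, axis=0) if n else np.empty((0, n_snp, 2), dtype=object)

    for j in range(n_snp):
        col = alleles[:, j, :]
        observed = sorted(set(col.ravel()) - {"0"})
        if len(observed) > 2:
            raise PlinkParseError(
                f"{ped_path}: SNP {map_df['snp_id'].iloc[j]!r} has more than "
                f"two alleles: {observed}")
        if not observed:
            allele_a[j] = "0"
            allele_b[j] = "0"
            continue
        a = observed[0]
        b = observed[1] if len(observed) == 2 else observed[0]
        allele_a[j], allele_b[j] = a, b
        missing = (col[:, 0] == "0") | (col[:, 1] == "0")
        dos = (col[:, 0] == a).astype(np.int8) + (col[:, 1] == a).astype(np.int8)
        dos[missing] = MISSING
        dosage[:, j] = dos

    mmap = MarkerMap(map_df["snp_id"].to_numpy(), map_df["chromosome"].to_numpy(),
                     map_df["position_bp"].to_numpy(), allele_a, allele_b)
    return GenotypeDataset(samples, mmap, dosage)


def write_plink_text(ds: GenotypeDataset, ped_path: str | Path,
                     map_path: str | Path) -> None:
    """Write a dataset as a PLINK text PED/MAP pair (missing written as ``0 0``)."""
    mp = ds.map
    with open(map_path, "w") as fh:
        for j in range(len(mp)):
            fh.write(f"{mp.chromosome[j]}\t{mp.snp_id[j]}\t0\t{mp.position_bp[j]}\n")

    # genotype strings per SNP, indexed by dosage code (row 3 = MISSING via -1)
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(ds.samples):
            fields = [sample, sample, "0", "0", "0", "-9"]
            row = ds.dosage[i]
            for j in range(len(mp)):
                a, b = mp.allele_a[j], mp.allele_b[j]
                d = row[j]
                if d == 2:
                    fields.append(f"{a} {a}")
                elif d == 1:
                    fields.append(f"{a} {b}")
                elif d == 0:
                    fields.append(f"{b} {b}")
                else:
                    fields.append("0 0")
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Panels
# ---------------------------------------------------------------------------

def read_panel(path: str | Path, name: str | None = None) -> PanelDefinition:
    """Read a panel definition from a one-snp_id-per-line text file."""
    ids = [ln.strip() for ln in open(path) if ln.strip()]
    return PanelDefinition(name or Path(path).stem, frozenset(ids))


def write_panel(panel: PanelDefinition, path: str | Path) -> None:
    with open(path, "w") as fh:
        for snp in sorted(panel.snp_ids):
            fh.write(snp + "\n")


def subset_to_panel(ds: GenotypeDataset, panel: PanelDefinition) -> GenotypeDataset:
    """Restrict a dataset to the SNP it shares with a panel, keeping map order."""
    keep = [j for j, s in enumerate(ds.map.snp_id) if s in panel.snp_ids]
    if not keep:
        raise ValueError(f"panel {panel.name!r} shares no SNP with the dataset map")
    idx = np.asarray(keep, dtype=np.int64)
    return GenotypeDataset(list(ds.samples), ds.map.subset(idx), ds.dosage[:, idx])


def panel_overlap_percentage(panel: PanelDefinition, imputation_map: MarkerMap) -> float:
    """Percentage of the imputation SNP set covered by a panel, to 2 decimals.

    Defined as 100 x |panel ∩ imputation ids| / |imputation ids| — the share
    of the fixed imputation set that a chip genotypes directly, the key driver
    of imputation-induced bias in downstream inbreeding estimates.
    """
    if len(imputation_map) == 0:
        raise ValueError("imputation map is empty")
    inter = panel.snp_ids.intersection(imputation_map.snp_id.tolist())
    return round(100.0 * len(inter) / len(imputation_map), 2)


# ---------------------------------------------------------------------------
# Marker spacing
# ---------------------------------------------------------------------------

def marker_spacing_summary(mp: MarkerMap, pooled: bool = True
                           ) -> tuple[pd.DataFrame, float]:
    """Per-chromosome SNP counts and mean adjacent-marker distances.

    Returns ``(table, genome_wide_mean_bp)``.  The genome-wide mean pools all
    adjacent pairs across chromosomes by default (``pooled=True``); with
    ``pooled=False`` it averages the per-chromosome means instead.
    Chromosomes with fewer than two SNP get an undefined (NaN) spacing.
    """
    if not mp.is_sorted:
        raise ValueError("marker map must be sorted by chromosome and position")
    rows = []
    all_diffs: list[np.ndarray] = []
    for chrom in np.unique(mp.chromosome):
        pos = mp.position_bp[mp.chromosome == chrom]
        if len(pos) >= 2:
            diffs = np.diff(pos)
            all_diffs.append(diffs)
            mean = float(np.mean(diffs))
        else:
            mean = float("nan")
        rows.append({"chromosome": int(chrom), "n_snp": int(len(pos)),
                     "mean_spacing_bp": mean})
    table = pd.DataFrame(rows)
    if all_diffs:
        if pooled:
            genome_mean = float(np.mean(np.concatenate(all_diffs)))
        else:
            genome_mean = float(np.nanmean(table["mean_spacing_bp"].to_numpy()))
    else:
        genome_mean = float("nan")
    return table, genome_mean
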