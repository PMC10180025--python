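from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from inbredkit import GenotypeDataset, MarkerMap, Pedigree

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


def make_map(n_snp: int = 5, chromosome: int = 1, spacing: int = 100_000,
             start: int = 1) -> MarkerMap:
    """Evenly spaced one-chromosome toy map with A/C alleles."""
    return MarkerMap(
        snp_id=np.array([f"snp{j}" for j in range(n_snp)], dtype=object),
        chromosome=np.full(n_snp, chromosome),
        position_bp=start + spacing * np.arange(n_snp),
        allele_a=np.array(["A"] * n_snp, dtype=object),
        allele_b=np.array(["C"] * n_snp, dtype=object),
    )


def make_dataset(dosage, chromosome: int = 1, spacing: int = 100_000,
                 positions=None) -> GenotypeDataset:
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    mp = make_map(m, chromosome, spacing)
    if positions is not None:
        mp = MarkerMap(mp.snp_id, mp.chromosome, np.asarray(positions),
                       mp.allele_a, mp.allele_b)
    return GenotypeDataset([f"ind{i}" for i in range(n)], mp, dosage)


def random_pedigree(rng: np.random.Generator, n: int,
                    founder_fraction: float = 0.3) -> Pedigree:
    """Random valid pedigree: each non-founder picks two earlier parents."""
    records = []
    n_founders = max(2, int(founder_fraction * n))
    for i in range(n):
        if i < n_founders:
            records.append((f"a{i}", None, None))
        else:
            # parents drawn among earlier individuals; occasionally unknown
            s = f"a{rng.integers(0, i)}" if rng.random() > 0.1 else None
            d = f"a{rng.integers(0, i)}" if rng.random() > 0.1 else None
            if s is not None and s == d:
                d = None
            records.append((f"a{i}", s, d))
    return Pedigree(records)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_dataset() -> GenotypeDataset:
    """4 samples x 5 SNP with one missing call and one monomorphic SNP."""
    dosage = np.array([
        [2, 1, 0, 2, 2],
        [1, 1, 1, 2, 0],
        [0, 0, 2, 2, 1],
        [2, -1, 1, 2, 1],
    ], dtype=np.int8)
    return make_dataset(dosage)
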