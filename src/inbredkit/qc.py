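"""Post-imputation SNP quality control.

Five per-SNP filters, all with strict inequalities: call rate, parent-offspring
Mendelian mismatch rate, minor allele frequency, minimum genotype-class
frequency, and an exact two-sided Hardy–Weinberg test.  Each rule is evaluated
on the input dataset independently (order-free filtering).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import MISSING, GenotypeDataset
from .pedigree import Pedigree


@dataclass(frozen=True)
class QcThresholds:
    """Per-SNP filter thresholds.

    Defaults follow routine dairy-cattle practice: call rate >= 95%,
    parent-offspring mismatch <= 1%, MAF >= 2%, each genotype class >= 0.1%,
    and HWE exact p >= 0.005.  All comparisons are strict, so a SNP sitting
    exactly on a threshold is retained.
    """

    min_call_rate: float = 0.95
    max_mendel_rate: float = 0.01
    min_maf: float = 0.02
    min_genotype_freq: float = 0.001
    hwe_alpha: float = 0.005

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "max_mendel_rate", "min_maf",
                     "min_genotype_freq", "hwe_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name}={v} must lie in (0, 1)")


def snp_call_rate(ds: GenotypeDataset) -> np.ndarray:
    """Fraction of non-missing calls per SNP."""
    return np.mean(ds.dosage != MISSING, axis=0)


def _parent_offspring_pairs(ds: GenotypeDataset, ped: Pedigree
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Row-index arrays (parents, offspring) for genotyped pairs."""
    row = {s: i for i, s in enumerate(ds.samples)}
    par_idx, off_idx = [], []
    for iid in ds.samples:
        if iid not in ped:
            continue
        for par in ped.parents(iid):
            if par is not None and par in row:
                par_idx.append(row[par])
                off_idx.append(row[iid])
    return np.asarray(par_idx, dtype=np.int64), np.asarray(off_idx, dtype=np.int64)


def mendelian_error_rate(ds: GenotypeDataset, ped: Pedigree) -> np.ndarray:
    """Per-SNP rate of impossible parent-offspring transmissions.

    An error is a pair of opposing homozygotes (parent dosage 0 with offspring
    dosage 2, or vice versa); pairs with a missing genotype are excluded.
    SNP with zero informative pairs get NaN (they pass the filter downstream).
    """
    par_idx, off_idx = _parent_offspring_pairs(ds, ped)
    if len(par_idx) == 0:
        raise ValueError("no genotyped parent-offspring pair in the dataset")
    dp = ds.dosage[par_idx]
    do = ds.dosage[off_idx]
    informative = (dp != MISSING) & (do != MISSING)
    errors = ((dp == 0) & (do == 2)) | ((dp == 2) & (do == 0))
    n_inf = informative.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(n_inf > 0, errors.sum(axis=0) / np.maximum(n_inf, 1),
                        np.nan)
    rate[n_inf == 0] = np.nan
    return rate


def hwe_exact_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy–Weinberg test p-value.

    With allele counts fixed, sums the probabilities of every heterozygote
    count no more probable than the observed one (the exact conditional test
    of Haldane/Wigginton).  Monomorphic samples return 1.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("negative genotype count")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("all genotype counts are zero")
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab
    rare = min(na, nb)
    if rare == 0:
        return 1.0

    # log P(het = h | allele counts), vectorized over all feasible h
    hs = np.arange(rare % 2, rare + 1, 2)
    aa = (na - hs) // 2
    bb = (nb - hs) // 2
    logs = (hs * log(2.0) - gammaln(aa + 1) - gammaln(hs + 1) - gammaln(bb + 1))
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = probs[int(np.searchsorted(hs, n_ab))]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def hwe_chisq_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """One-degree chi-square Hardy–Weinberg test (large-sample alternative
    to :func:`hwe_exact_pvalue`)."""
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p = (2 * n_aa + n_ab) / (2 * n)
    exp = np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)]) * n
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    nz = exp > 0
    stat = float(((obs[nz] - exp[nz]) ** 2 / exp[nz]).sum())
    from scipy.stats import chi2
    return float(chi2.sf(stat, df=1))


def _genotype_counts(ds: GenotypeDataset) -> np.ndarray:
    """(3, n_snp) counts of dosage 0/1/2 per SNP."""
    d = ds.dosage
    return np.stack([(d == 0).sum(axis=0), (d == 1).sum(axis=0),
                     (d == 2).sum(axis=0)])


def apply_snp_qc(ds: GenotypeDataset, ped: Optional[Pedigree],
                 t: QcThresholds = QcThresholds(),
                 hwe_method: str = "exact",
                 genotype_freq_over: str = "called"
                 ) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Filter SNP by the five QC rules; returns the kept dataset and a report.

    The report lists, per SNP, every computed metric and the comma-joined
    names of the rules it failed (empty for retained SNP).  A pedigree of
    ``None`` or one yielding no genotyped parent-offspring pair skips the
    Mendel rule.  ``hwe_method`` selects the exact or chi-square HWE test;
    ``genotype_freq_over`` sets the denominator of the genotype-class rule
    to called genotypes (default) or all samples.
    """
    if hwe_method not in ("exact", "chisq"):
        raise ValueError("hwe_method must be 'exact' or 'chisq'")
    if genotype_freq_over not in ("called", "all"):
        raise ValueError("genotype_freq_over must be 'called' or 'all'")
    counts = _genotype_counts(ds)
    n_called = counts.sum(axis=0)
    call_rate = snp_call_rate(ds)

    geno_denom = (np.maximum(n_called, 1) if genotype_freq_over == "called"
                  else max(ds.n_samples, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * counts[2] + counts[1]) / (2 * np.maximum(n_called, 1))
        maf = np.minimum(p, 1 - p)
        geno_freq = counts / geno_denom
    maf[n_called == 0] = np.nan
    min_geno = geno_freq.min(axis=0)
    min_geno[n_called == 0] = np.nan

    try:
        mendel = (mendelian_error_rate(ds, ped) if ped is not None
                  else np.full(ds.n_snp, np.nan))
    except ValueError:
        mendel = np.full(ds.n_snp, np.nan)

    hwe_test = hwe_exact_pvalue if hwe_method == "exact" else hwe_chisq_pvalue
    hwe_p = np.full(ds.n_snp, np.nan)
    for j in range(ds.n_snp):
        if n_called[j] > 0:
            hwe_p[j] = hwe_test(int(counts[0, j]), int(counts[1, j]),
                                int(counts[2, j]))

    # strict inequalities; NaN comparisons are False, so unevaluable rules pass
    with np.errstate(invalid="ignore"):
        fails = {
            "call_rate": call_rate < t.min_call_rate,
            "mendel": mendel > t.max_mendel_rate,
            "maf": maf < t.min_maf,
            "geno_freq": min_geno < t.min_genotype_freq,
            "hwe": hwe_p < t.hwe_alpha,
        }
    failed_any = np.zeros(ds.n_snp, dtype=bool)
    for mask in fails.values():
        failed_any |= mask

    failed_rules = [",".join(name for name, mask in fails.items() if mask[j])
                    for j in range(ds.n_snp)]
    report = pd.DataFrame({
        "snp_id": ds.map.snp_id, "call_rate": call_rate, "mendel_rate": mendel,
        "maf": maf, "min_geno_freq": min_geno, "hwe_p": hwe_p,
        "failed_rules": failed_rules, "removed": failed_any,
    })

    keep = np.flatnonzero(~failed_any)
    if len(keep) == 0:
        raise ValueError("QC removed every SNP")
    filtered = GenotypeDataset(list(ds.samples), ds.map.subset(keep),
                               ds.dosage[:, keep])
    return filtered, report
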