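"""Genomic inbreeding estimators.

Seven per-individual coefficients from a dosage matrix X (copies of the
counted allele) with per-SNP frequencies p (counted) and q = 1 - p:

* ``F`` — excess homozygosity, (O - E)/(N - E), the Li & Horvitz method-of-
  moments estimator (PLINK ``--het``), with the small-sample correction
  n/(n-1) applied to the expected heterozygosity.
* ``F_hat1`` — (1/n) Σ (X - 2p)^2 / 2pq - 1 (variance of standardized dosage).
* ``F_hat2`` — 1 - (1/n) Σ X(2 - X) / 2pq (per-SNP excess homozygosity,
  a sum of ratios where ``F`` is a ratio of sums).
* ``F_hat3`` — (1/n) Σ [X^2 - (1 + 2p)X + 2p^2] / 2pq (correlation between
  uniting gametes).
* ``F_grm`` — diagonal of the VanRaden method-1 genomic relationship matrix
  minus 1, with observed frequencies: diag(ZZ')/2Σpq - 1, Z = X - 2p.
* ``F_grm2`` — a simplified VanRaden method-3 estimator: the diagonal of XX'
  regressed on pedigree inbreeding to obtain an intercept and slope, then
  rescaled.
* ``F_roh`` — fraction of the SNP-covered genome lying in runs of
  homozygosity found by the consecutive-runs method.

Monomorphic SNP and per-sample missing calls are excluded from all
2pq-denominated sums (with n adjusted per sample); only ``F_roh`` has a
guaranteed [0, 1] range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._kernels import dosage_weighted_sums
from ._roh import scan_matrix
from .io import MISSING, GenotypeDataset, MarkerMap

ESTIMATOR_COLUMNS = ["F", "F_hat1", "F_hat2", "F_hat3", "F_grm", "F_grm2", "F_roh"]


@dataclass(frozen=True)
class AlleleFrequencies:
    """Per-SNP frequency of the counted allele, NaN where all calls are missing."""

    p: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "p", np.asarray(self.p, dtype=np.float64))
        with np.errstate(invalid="ignore"):
            if np.any((self.p < 0) | (self.p > 1)):
                raise ValueError("allele frequencies outside [0, 1]")

    @property
    def q(self) -> np.ndarray:
        return 1.0 - self.p


def allele_frequencies(ds: GenotypeDataset) -> AlleleFrequencies:
    """Observed counted-allele frequencies from the non-missing dosages."""
    called = ds.dosage != MISSING
    n_called = called.sum(axis=0)
    totals = np.where(called, ds.dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = totals / (2.0 * n_called)
    p = np.where(n_called > 0, p, np.nan)
    return AlleleFrequencies(p)


def _polymorphic(freqs: AlleleFrequencies) -> np.ndarray:
    return np.isfinite(freqs.p) & (freqs.p > 0) & (freqs.p < 1)


def _per_code_terms(*rows) -> np.ndarray:
    """Stack per-SNP term vectors into the (3, k, m) layout of the kernel.

    Each argument is a (t0, t1, t2) triple of per-SNP vectors giving the term
    value at dosage 0, 1 and 2.
    """
    return np.ascontiguousarray(
        np.stack([np.stack([r[c] for r in rows]) for c in range(3)]))


def excess_homozygosity_F(ds: GenotypeDataset, freqs: AlleleFrequencies,
                          small_sample_correction: bool = True) -> pd.Series:
    """Method-of-moments excess homozygosity, F = (O - E)/(N - E) per sample.

    O is the observed homozygous count over the sample's non-missing
    polymorphic SNP, N that SNP count, and E the expected homozygous count
    Σ (1 - 2pq * n/(n-1)) with n the per-SNP called-sample count (the
    correction is dropped when ``small_sample_correction=False``).
    Degenerate samples with N = E are returned as NaN.
    """
    poly = _polymorphic(freqs).astype(np.float64)
    p, q = freqs.p, freqs.q
    n_called = (ds.dosage != MISSING).sum(axis=0).astype(np.float64)
    corr = np.ones_like(n_called)
    if small_sample_correction:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(n_called > 1, n_called / (n_called - 1.0), 1.0)
    e_snp = 1.0 - 2.0 * p * q * corr  # expected P(homozygous) per SNP
    e_snp = np.where(np.isfinite(e_snp), e_snp, 0.0) * poly

    zero = np.zeros_like(poly)
    terms = _per_code_terms((poly, poly, poly),      # N: usable SNP count
                            (poly, zero, poly),      # O: homozygous among them
                            (e_snp, e_snp, e_snp))   # E: expected homozygous
    sums = dosage_weighted_sums(ds.dosage, terms)
    N, O, E = sums[:, 0], sums[:, 1], sums[:, 2]
    denom = N - E
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(np.abs(denom) > 1e-12, (O - E) / denom, np.nan)
    return pd.Series(f, index=ds.samples, name="F")


def fhat_estimators(ds: GenotypeDataset, freqs: AlleleFrequencies) -> pd.DataFrame:
    """The three GCTA/PLINK ``--ibc`` estimators F_hat1, F_hat2, F_hat3.

    Sums run over each sample's non-missing SNP with 0 < p < 1, with n
    adjusted per sample; samples with no usable SNP are NaN.
    """
    poly = _polymorphic(freqs).astype(np.float64)
    p = np.where(np.isfinite(freqs.p), freqs.p, 0.5)
    two_pq = 2.0 * p * (1.0 - p)
    inv = np.where(two_pq > 0, 1.0 / np.where(two_pq > 0, two_pq, 1.0), 0.0) * poly
    zero = np.zeros_like(p)
    # per-SNP term values at dosage 0 / 1 / 2
    terms = _per_code_terms(
        (poly, poly, poly),
        (4 * p ** 2 * inv, (1 - 2 * p) ** 2 * inv, (2 - 2 * p) ** 2 * inv),
        (zero, inv, zero),
        (2 * p ** 2 * inv, (2 * p ** 2 - 2 * p) * inv,
         (2 * p ** 2 - 4 * p + 2) * inv))
    sums = dosage_weighted_sums(ds.dosage, terms)
    n, s1, s2, s3 = sums[:, 0], sums[:, 1], sums[:, 2], sums[:, 3]
    with np.errstate(invalid="ignore", divide="ignore"):
        fhat1 = s1 / n - 1.0
        fhat2 = 1.0 - s2 / n
        fhat3 = s3 / n
    for arr in (fhat1, fhat2, fhat3):
        arr[n == 0] = np.nan
    return pd.DataFrame({"F_hat1": fhat1, "F_hat2": fhat2, "F_hat3": fhat3},
                        index=ds.samples)


def grm_inbreeding(ds: GenotypeDataset, freqs: AlleleFrequencies) -> pd.Series:
    """VanRaden method-1 GRM diagonal minus 1 (observed allele frequencies).

    Z centers each dosage column by twice the counted-allele frequency;
    missing dosages contribute 0 to Z, and the denominator 2 Σ p(1-p) runs
    over the full SNP set (monomorphic SNP contribute zero to both).
    """
    p = np.where(np.isfinite(freqs.p), freqs.p, 0.0)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all SNP monomorphic: GRM denominator is zero")
    terms = _per_code_terms(((2 * p) ** 2, (1 - 2 * p) ** 2, (2 - 2 * p) ** 2))
    diag = dosage_weighted_sums(ds.dosage, terms)[:, 0]
    return pd.Series(diag / denom - 1.0, index=ds.samples, name="F_grm")


def grm2_inbreeding(ds: GenotypeDataset, f_ped: Mapping[str, float],
                    offset: str = "one") -> pd.Series:
    """Pedigree-calibrated GRM-diagonal estimator (simplified VanRaden method 3).

    The diagonal d_i = Σ X_im^2 (over non-missing SNP) is regressed on the
    pedigree inbreeding coefficients; F_grm2_i = (d_i - intercept)/slope - c,
    with c = 1 (``offset="one"``, the default, which yields coefficients on
    the usual inbreeding scale around F_ped - 1) or c = intercept
    (``offset="intercept"``).  The two readings differ by an additive
    constant, so all downstream correlations are unaffected.
    """
    if offset not in ("intercept", "one"):
        raise ValueError("offset must be 'intercept' or 'one'")
    fp = np.array([f_ped[s] for s in ds.samples], dtype=np.float64)
    if len(np.unique(fp)) < 2:
        raise ValueError("need >= 2 distinct F_ped values to fit the regression")
    d = ((ds.dosage == 1).sum(axis=1) + 4.0 * (ds.dosage == 2).sum(axis=1)
         ).astype(np.float64)
    slope, intercept = np.polyfit(fp, d, 1)
    if abs(slope) < 1e-12:
        raise ValueError("degenerate regression: zero slope of diag(XX') on F_ped")
    c = intercept if offset == "intercept" else 1.0
    return pd.Series((d - intercept) / slope - c, index=ds.samples, name="F_grm2")


# ---------------------------------------------------------------------------
# Runs of homozygosity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RohParameters:
    """Consecutive-runs detection parameters.

    ``min_length_bp`` and ``min_snp`` define what counts as a run; up to
    ``max_het_in_run`` heterozygous and ``max_miss_in_run`` missing calls are
    tolerated inside a run (absorbing genotyping error), and a physical gap
    above ``max_gap_bp`` between adjacent SNP breaks any run.
    """

    min_length_bp: int = 1_000_000
    min_snp: int = 15
    max_het_in_run: int = 1
    max_miss_in_run: int = 1
    max_gap_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if min(self.min_length_bp, self.min_snp) < 1 or \
                min(self.max_het_in_run, self.max_miss_in_run) < 0 or \
                self.max_gap_bp < 1:
            raise ValueError("invalid ROH parameters")


@dataclass(frozen=True)
class RohSegment:
    """One run of homozygosity in one individual."""

    sample: str
    chromosome: int
    start_bp: int
    end_bp: int
    n_snp: int
    n_het: int = 0
    n_miss: int = 0

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp


def detect_roh(ds: GenotypeDataset, params: RohParameters = RohParameters()
               ) -> list[RohSegment]:
    """Consecutive-runs ROH detection.

    Emits, per sample and chromosome, every maximal window of consecutive SNP
    whose heterozygote count, missing count and internal gaps stay within the
    parameters, then keeps windows meeting the minimum SNP count and span
    (span = last SNP position - first SNP position).  Overlapping maximal
    windows can occur when an allowed heterozygote splits a long run.
    """
    if not ds.map.is_sorted:
        raise ValueError("marker map must be sorted by chromosome and position")
    segments: list[RohSegment] = []
    codes_all = np.where(ds.dosage == MISSING, 2,
                         np.where(ds.dosage == 1, 1, 0)).astype(np.int8)
    for chrom in np.unique(ds.map.chromosome):
        cols = np.flatnonzero(ds.map.chromosome == chrom)
        pos = np.ascontiguousarray(ds.map.position_bp[cols])
        codes = np.ascontiguousarray(codes_all[:, cols])
        cap = 64 * ds.n_samples
        while True:
            buf = np.empty((cap, 5), dtype=np.int64)
            k = scan_matrix(codes, pos, params.max_het_in_run,
                            params.max_miss_in_run, params.max_gap_bp,
                            params.min_snp, params.min_length_bp, buf)
            if k >= 0:
                break
            cap *= 4
        for i, a, b, nh, nm in buf[:k]:
            segments.append(RohSegment(
                sample=ds.samples[i], chromosome=int(chrom),
                start_bp=int(pos[a]), end_bp=int(pos[b]),
                n_snp=int(b - a + 1), n_het=int(nh), n_miss=int(nm)))
    return segments


def roh_to_dataframe(segments: Iterable[RohSegment]) -> pd.DataFrame:
    """BED-like table of ROH segments."""
    return pd.DataFrame(
        [(s.sample, s.chromosome, s.start_bp, s.end_bp, s.n_snp, s.n_het, s.n_miss)
         for s in segments],
        columns=["sample", "chromosome", "start_bp", "end_bp", "n_snp",
                 "n_het", "n_miss"])


def _union_length(intervals: list[tuple[int, int]]) -> int:
    intervals.sort()
    total = 0
    cur_s, cur_e = None, None
    for s, e in intervals:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def froh(segments: Iterable[RohSegment], mp: MarkerMap,
         samples: Iterable[str]) -> pd.Series:
    """Genomic inbreeding from ROH: covered genome fraction per sample.

    The numerator is the per-sample union of segment spans (overlapping
    maximal windows are not double-counted) and the denominator is the
    SNP-covered genome length, Σ over chromosomes of (last - first SNP
    position), which keeps F_roh in [0, 1] by construction.
    """
    L = 0
    for chrom in np.unique(mp.chromosome):
        pos = mp.position_bp[mp.chromosome == chrom]
        L += int(pos.max() - pos.min())
    if L == 0:
        raise ValueError("SNP-covered genome length is zero")

    per: dict[str, dict[int, list[tuple[int, int]]]] = {}
    for seg in segments:
        per.setdefault(seg.sample, {}).setdefault(seg.chromosome, []).append(
            (seg.start_bp, seg.end_bp))
    out = {}
    for sample in samples:
        tot = sum(_union_length(iv) for iv in per.get(sample, {}).values())
        out[sample] = tot / L
    return pd.Series(out, name="F_roh")


def all_estimators(ds: GenotypeDataset, f_ped: Mapping[str, float],
                   roh_params: RohParameters = RohParameters(),
                   grm2_offset: str = "one") -> pd.DataFrame:
    """All seven genomic coefficients from one shared frequency estimate.

    Returns a sample-indexed table with columns
    F, F_hat1, F_hat2, F_hat3, F_grm, F_grm2, F_roh.
    """
    freqs = allele_frequencies(ds)
    table = pd.DataFrame(index=pd.Index(ds.samples, name="sample"))
    table["F"] = excess_homozygosity_F(ds, freqs)
    table = table.join(fhat_estimators(ds, freqs))
    table["F_grm"] = grm_inbreeding(ds, freqs)
    table["F_grm2"] = grm2_inbreeding(ds, f_ped, offset=grm2_offset)
    segments = detect_roh(ds, roh_params)
    table["F_roh"] = froh(segments, ds.map, ds.samples)
    return table[ESTIMATOR_COLUMNS]
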