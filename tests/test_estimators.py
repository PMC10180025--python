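import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import inbredkit as ik
from inbredkit.estimators import (AlleleFrequencies, RohParameters,
                                  excess_homozygosity_F, fhat_estimators,
                                  grm2_inbreeding, grm_inbreeding)

from conftest import make_dataset
from oracles import roh_maximal_windows


def half_freqs(m):
    return AlleleFrequencies(np.full(m, 0.5))


class TestAlleleFrequencies:
    def test_simple_cases(self):
        ds = make_dataset([[0], [1], [2]])
        assert ik.allele_frequencies(ds).p[0] == pytest.approx(0.5)
        ds = make_dataset([[2], [2]])
        assert ik.allele_frequencies(ds).p[0] == 1.0

    def test_matches_counting_oracle(self, rng):
        dosage = rng.integers(-1, 3, size=(25, 15)).astype(np.int8)
        got = ik.allele_frequencies(make_dataset(dosage)).p
        for j in range(15):
            col = dosage[:, j][dosage[:, j] != -1]
            if len(col) == 0:
                assert np.isnan(got[j])
            else:
                assert got[j] == pytest.approx(col.sum() / (2 * len(col)))


class TestExcessHomozygosityF:
    def test_fully_homozygous_sample_is_one(self):
        dosage = np.array([[2, 0, 2, 0], [1, 1, 0, 2], [0, 1, 1, 1]], dtype=np.int8)
        ds = make_dataset(dosage)
        f = excess_homozygosity_F(ds, ik.allele_frequencies(ds))
        assert f.iloc[0] == pytest.approx(1.0)

    def test_half_heterozygous_at_half_frequency_near_zero(self):
        # with p = 0.5 everywhere and the correction disabled, E = N/2
        dosage = np.tile([1, 1, 0, 2], 10).reshape(1, -1).astype(np.int8)
        ds = make_dataset(dosage)
        f = excess_homozygosity_F(ds, half_freqs(40),
                                  small_sample_correction=False)
        assert f.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_scalar_loop_oracle(self, rng):
        dosage = rng.integers(-1, 3, size=(4, 30)).astype(np.int8)
        ds = make_dataset(dosage)
        freqs = ik.allele_frequencies(ds)
        got = excess_homozygosity_F(ds, freqs)
        n_called = (dosage != -1).sum(axis=0)
        for i in range(4):
            O = E = N = 0.0
            for j in range(30):
                pj = freqs.p[j]
                if dosage[i, j] == -1 or not (0 < pj < 1):
                    continue
                N += 1
                O += dosage[i, j] != 1
                c = n_called[j] / (n_called[j] - 1)
                E += 1 - 2 * pj * (1 - pj) * c
            assert got.iloc[i] == pytest.approx((O - E) / (N - E), abs=1e-10)


class TestFhat:
    def test_fully_heterozygous_gives_minus_one(self):
        ds = make_dataset(np.ones((1, 20), dtype=np.int8))
        fh = fhat_estimators(ds, half_freqs(20))
        assert np.allclose(fh.iloc[0], [-1, -1, -1])

    def test_fully_homozygous_counted_allele_gives_one(self):
        ds = make_dataset(np.full((1, 20), 2, dtype=np.int8))
        fh = fhat_estimators(ds, half_freqs(20))
        assert np.allclose(fh.iloc[0], [1, 1, 1])

    @given(st.lists(st.sampled_from([0, 1, 2]), min_size=5, max_size=60))
    def test_identity_at_half_frequency(self, genotypes):
        """At p = 0.5 everywhere the three F_hat estimators coincide for any
        genotype vector (X(2-X) = 1 - (X-1)^2)."""
        ds = make_dataset(np.array([genotypes], dtype=np.int8))
        fh = fhat_estimators(ds, half_freqs(len(genotypes)))
        assert fh.iloc[0, 0] == pytest.approx(fh.iloc[0, 1], abs=1e-10)
        assert fh.iloc[0, 1] == pytest.approx(fh.iloc[0, 2], abs=1e-10)


class TestGrm:
    def test_forced_values_at_half_frequency(self):
        ds = make_dataset(np.vstack([np.ones(10), np.full(10, 2)]).astype(np.int8))
        f = grm_inbreeding(ds, half_freqs(10))
        assert f.iloc[0] == pytest.approx(-1.0)
        assert f.iloc[1] == pytest.approx(1.0)

    def test_matches_dense_matrix_oracle(self, rng):
        dosage = rng.integers(-1, 3, size=(6, 25)).astype(np.int8)
        ds = make_dataset(dosage)
        freqs = ik.allele_frequencies(ds)
        got = grm_inbreeding(ds, freqs)
        p = np.where(np.isfinite(freqs.p), freqs.p, 0.0)
        Z = np.where(dosage != -1, dosage - 2 * p, 0.0)
        grm = Z @ Z.T / (2 * np.sum(p * (1 - p)))
        np.testing.assert_allclose(got.to_numpy(), np.diag(grm) - 1, atol=1e-12)

    def test_monomorphic_only_errors(self):
        ds = make_dataset(np.full((3, 4), 2, dtype=np.int8))
        with pytest.raises(ValueError):
            grm_inbreeding(ds, ik.allele_frequencies(ds))


class TestGrm2:
    def affine_toy(self):
        """diag(XX') is an exact affine function of F_ped by construction."""
        # d_i = (# hets) + 4 (# hom-a): rows built to give d = 10, 20, 30, 40
        dosage = np.array([
            [1] * 10 + [0] * 30,
            [1] * 20 + [0] * 20,
            [1] * 30 + [0] * 10,
            [1] * 40,
        ], dtype=np.int8)
        ds = make_dataset(dosage)
        f_ped = {f"ind{i}": 0.05 * i for i in range(4)}  # d = 10 + 200 * F_ped
        return ds, f_ped

    def test_ols_recovers_constructed_line(self):
        ds, f_ped = self.affine_toy()
        got = grm2_inbreeding(ds, f_ped, offset="one")
        expected = (np.array([10, 20, 30, 40]) - 10.0) / 200.0 - 1.0
        np.testing.assert_allclose(got.to_numpy(), expected, atol=1e-10)

    def test_correlation_with_fped_is_one_under_either_offset(self):
        ds, f_ped = self.affine_toy()
        fp = np.array([f_ped[s] for s in ds.samples])
        for offset in ("one", "intercept"):
            got = grm2_inbreeding(ds, f_ped, offset=offset).to_numpy()
            assert np.corrcoef(got, fp)[0, 1] == pytest.approx(1.0)

    def test_offset_switch_is_additive_constant(self):
        ds, f_ped = self.affine_toy()
        a = grm2_inbreeding(ds, f_ped, offset="one").to_numpy()
        b = grm2_inbreeding(ds, f_ped, offset="intercept").to_numpy()
        np.testing.assert_allclose(np.diff(a - b), 0, atol=1e-12)

    def test_constant_fped_errors(self):
        ds, _ = self.affine_toy()
        with pytest.raises(ValueError):
            grm2_inbreeding(ds, {s: 0.1 for s in ds.samples})


class TestDetectRoh:
    def test_long_homozygous_run_detected(self):
        # 20 homozygous SNP spanning ~2 Mbp
        ds = make_dataset(np.full((1, 20), 2, dtype=np.int8), spacing=100_000)
        segs = ik.detect_roh(ds, RohParameters())
        assert len(segs) == 1
        assert segs[0].n_snp == 20
        assert segs[0].span_bp == 19 * 100_000

    def test_short_span_rejected(self):
        # 20 homozygous SNP spanning ~0.5 Mbp fails the length threshold
        ds = make_dataset(np.full((1, 20), 0, dtype=np.int8), spacing=25_000)
        assert ik.detect_roh(ds, RohParameters()) == []

    def test_unsorted_map_errors(self):
        ds = make_dataset(np.full((1, 5), 2, dtype=np.int8),
                          positions=np.array([5, 4, 3, 2, 1]))
        with pytest.raises(ValueError):
            ik.detect_roh(ds)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_window_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 200))
        codes = rng.choice([0, 1, 2], size=n, p=[0.8, 0.15, 0.05])
        pos = np.sort(rng.choice(np.arange(1, 4_000_000, dtype=np.int64),
                                 size=n, replace=False))
        params = RohParameters(
            min_length_bp=int(rng.integers(1, 1_500_000)),
            min_snp=int(rng.integers(1, 25)),
            max_het_in_run=int(rng.integers(0, 4)),
            max_miss_in_run=int(rng.integers(0, 4)),
            max_gap_bp=int(rng.integers(50_000, 2_000_000)))
        dosage = np.where(codes == 2, -1, np.where(codes == 1, 1, 0)).astype(np.int8)
        ds = make_dataset(dosage.reshape(1, -1), positions=pos)
        got = {(int(np.flatnonzero(pos == s.start_bp)[0]),
                int(np.flatnonzero(pos == s.end_bp)[0]))
               for s in ik.detect_roh(ds, params)}
        expected = roh_maximal_windows(
            codes, pos, params.max_het_in_run, params.max_miss_in_run,
            params.max_gap_bp, params.min_snp, params.min_length_bp)
        assert got == expected


class TestFroh:
    def make_segments(self, spans, L=10_000_000):
        mp = make_dataset(np.zeros((1, 2), dtype=np.int8),
                          positions=np.array([0, L])).map
        segs = [ik.RohSegment("ind0", 1, s, e, n_snp=15) for s, e in spans]
        return segs, mp

    def test_no_segments_gives_zero(self):
        segs, mp = self.make_segments([])
        assert ik.froh(segs, mp, ["ind0"])["ind0"] == 0.0

    def test_full_coverage_gives_one(self):
        segs, mp = self.make_segments([(0, 10_000_000)])
        assert ik.froh(segs, mp, ["ind0"])["ind0"] == 1.0

    def test_two_segments_sum(self):
        segs, mp = self.make_segments([(0, 1_000_000), (4_000_000, 7_000_000)])
        assert ik.froh(segs, mp, ["ind0"])["ind0"] == pytest.approx(0.4)

    def test_overlapping_segments_not_double_counted(self):
        segs, mp = self.make_segments([(0, 2_000_000), (1_000_000, 3_000_000)])
        assert ik.froh(segs, mp, ["ind0"])["ind0"] == pytest.approx(0.3)


class TestInvariantsAndComposition:
    def build(self, rng, n=12, m=80):
        dosage = rng.choice([0, 1, 2], size=(n, m), p=[0.3, 0.4, 0.3]).astype(np.int8)
        ds = make_dataset(dosage, spacing=50_000)
        f_ped = {s: float(f) for s, f in zip(ds.samples, rng.random(n) * 0.3)}
        return ds, f_ped

    def test_composition_matches_individual_operations(self, rng):
        ds, f_ped = self.build(rng)
        params = RohParameters(min_length_bp=100_000, min_snp=3)
        table = ik.all_estimators(ds, f_ped, params)
        freqs = ik.allele_frequencies(ds)
        pd.testing.assert_series_equal(
            table["F"], excess_homozygosity_F(ds, freqs), check_names=False)
        pd.testing.assert_series_equal(
            table["F_grm"], grm_inbreeding(ds, freqs), check_names=False)
        segs = ik.detect_roh(ds, params)
        pd.testing.assert_series_equal(
            table["F_roh"], ik.froh(segs, ds.map, ds.samples), check_names=False)
        assert len(table) == ds.n_samples
        assert list(table.columns) == ["F", "F_hat1", "F_hat2", "F_hat3",
                                       "F_grm", "F_grm2", "F_roh"]

    def test_froh_bounded_and_others_not_forced_positive(self, rng):
        ds, f_ped = self.build(rng, n=20, m=120)
        table = ik.all_estimators(ds, f_ped,
                                  RohParameters(min_length_bp=100_000, min_snp=3))
        assert ((table["F_roh"] >= 0) & (table["F_roh"] <= 1)).all()

    def test_allele_relabel_invariance(self, rng):
        """Swapping which allele is counted (X -> 2 - X) leaves F, F_hat*,
        F_grm and F_roh unchanged."""
        ds, f_ped = self.build(rng)
        flipped = ik.GenotypeDataset(
            list(ds.samples), ds.map,
            np.where(ds.dosage == -1, -1, 2 - ds.dosage).astype(np.int8))
        params = RohParameters(min_length_bp=100_000, min_snp=3)
        a = ik.all_estimators(ds, f_ped, params)
        b = ik.all_estimators(flipped, f_ped, params)
        for col in ["F", "F_hat1", "F_hat2", "F_hat3", "F_grm", "F_roh"]:
            np.testing.assert_allclose(a[col], b[col], atol=1e-10,
                                       err_msg=col)
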