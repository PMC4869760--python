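"""Marker QC, MVN-EM imputation, and genomic relationship."""

import numpy as np
import pytest

from cyclegs.markers import (
    KinshipMatrix,
    MarkerMatrix,
    compute_kinship,
    filter_markers,
    impute_missing,
)


def _mm(codes, line_prefix="L", marker_prefix="M"):
    codes = np.asarray(codes, dtype=float)
    return MarkerMatrix(
        [f"{line_prefix}{i}" for i in range(codes.shape[0])],
        [f"{marker_prefix}{j}" for j in range(codes.shape[1])],
        codes,
    )


class TestFilterMarkers:
    def test_brute_force_on_hand_set_fixture(self):
        """Surviving markers equal an explicit evaluation of the three rules."""
        rng = np.random.default_rng(42)
        codes = rng.choice([-1.0, 0.0, 1.0], size=(10, 6), p=[0.45, 0.1, 0.45])
        codes[:, 1] = 1.0  # monomorphic
        codes[0:2, 2] = np.nan  # 20% missing -> fails call rate & missing
        codes[0, 3] = np.nan  # 10% missing -> call rate 0.9 passes, missing ok
        codes[:, 4] = [-1, -1, -1, -1, -1, -1, -1, -1, -1, 1]  # MAF 0.10
        codes[:, 5] = [-1] * 9 + [0]  # MAF 0.05 fails strict < comparison? no: 0.05 >= 0.05 passes
        m = _mm(codes)

        # independent brute-force evaluation of the rules
        expected_keep = []
        for j in range(6):
            col = codes[:, j]
            obs = col[~np.isnan(col)]
            call_rate = obs.size / col.size
            p = (obs.mean() + 1) / 2
            maf = min(p, 1 - p)
            miss = 1 - call_rate
            expected_keep.append(call_rate >= 0.9 and maf >= 0.05 and miss <= 0.10)

        filtered, report = filter_markers(m)
        kept = set(filtered.marker_ids)
        assert kept == {f"M{j}" for j in range(6) if expected_keep[j]}
        assert report.n_kept == sum(expected_keep)
        assert report.n_low_maf >= 1  # the monomorphic marker

    def test_monomorphic_removed_and_good_marker_kept(self):
        codes = np.array([[1.0, 1.0], [1.0, -1.0], [1.0, -1.0], [1.0, 1.0]])
        filtered, _ = filter_markers(_mm(codes))
        assert list(filtered.marker_ids) == ["M1"]

    def test_all_removed_raises(self):
        codes = np.ones((5, 3))
        with pytest.raises(ValueError, match="empty marker set"):
            filter_markers(_mm(codes))

    @pytest.mark.parametrize("kw", [{"min_maf": 0.0}, {"min_call_rate": 1.5}, {"max_missing": 1.0}])
    def test_threshold_range_validated(self, kw):
        with pytest.raises(ValueError):
            filter_markers(_mm(np.ones((3, 2))), **kw)


class TestImputeMissing:
    def test_complete_matrix_returned_unchanged(self):
        codes = np.array([[1.0, -1.0], [-1.0, 1.0], [1.0, 1.0]])
        out = impute_missing(_mm(codes))
        np.testing.assert_array_equal(out.codes, codes)

    def test_duplicated_line_recovers_missing_entry(self):
        """Lines with identical observed profiles pin the imputed value."""
        rng = np.random.default_rng(3)
        base = rng.choice([-1.0, 1.0], size=(8, 30))
        codes = np.vstack([base, base[0], base[0]])  # L8, L9 duplicate L0
        codes[9, 5] = np.nan
        out = impute_missing(_mm(codes))
        assert abs(out.codes[9, 5] - base[0, 5]) < 0.1
        # observed entries untouched
        mask = np.isnan(codes)
        np.testing.assert_array_equal(out.codes[~mask], codes[~mask])

    def test_beats_column_mean_imputation(self):
        """MSE strictly below the column-mean oracle on the same mask."""
        rng = np.random.default_rng(11)
        n, m = 40, 120
        # correlated lines: founder mixture structure
        founders = rng.choice([-1.0, 1.0], size=(6, m))
        mix = rng.integers(0, 6, size=n)
        truth = founders[mix].copy()
        flip = rng.random((n, m)) < 0.08
        truth[flip] *= -1
        mask = rng.random((n, m)) < 0.05
        obs = truth.copy()
        obs[mask] = np.nan
        out = impute_missing(_mm(obs))
        col_mean = np.nanmean(obs, axis=0)
        mse_em = np.mean((out.codes[mask] - truth[mask]) ** 2)
        mse_cm = np.mean((np.broadcast_to(col_mean, (n, m))[mask] - truth[mask]) ** 2)
        assert mse_em < mse_cm

    def test_requires_two_calls_per_marker(self):
        codes = np.array([[1.0, np.nan], [np.nan, np.nan], [-1.0, 1.0]])
        with pytest.raises(ValueError, match="non-missing"):
            impute_missing(_mm(codes))


class TestKinship:
    def test_identical_homozygous_lines(self):
        codes = np.array([[1.0, -1.0, 1.0, -1.0], [1.0, -1.0, 1.0, -1.0], [-1.0, 1.0, -1.0, 1.0]])
        K = compute_kinship(_mm(codes))
        np.testing.assert_allclose(K.K[0], K.K[1])
        assert K.K[0, 1] == pytest.approx(K.K[0, 0])

    def test_hand_computed_three_by_four_fixture(self):
        """K matches the centered cross-product formula computed longhand."""
        codes = np.array(
            [
                [1.0, -1.0, 1.0, 1.0],
                [-1.0, 1.0, 1.0, -1.0],
                [1.0, 1.0, -1.0, -1.0],
            ]
        )
        # longhand: per-column allele frequency, centering, normalisation
        expected = np.zeros((3, 3))
        p = np.array([(codes[:, j].mean() + 1) / 2 for j in range(4)])
        denom = 2 * sum(pk * (1 - pk) for pk in p)
        W = np.array([[codes[i, j] - codes[:, j].mean() for j in range(4)] for i in range(3)])
        for i in range(3):
            for j in range(3):
                expected[i, j] = sum(W[i, k] * W[j, k] for k in range(4)) / denom
        K = compute_kinship(_mm(codes))
        np.testing.assert_allclose(K.K, expected, atol=1e-12)

    def test_row_sums_zero(self, small_pop):
        filtered, _ = filter_markers(small_pop.genotypes)
        K = compute_kinship(impute_missing(filtered))
        assert np.abs(K.K.sum(axis=1)).max() < 1e-8

    def test_monomorphic_marker_rejected(self):
        codes = np.array([[1.0, 1.0], [-1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="QC"):
            compute_kinship(_mm(codes))

    def test_missing_entries_rejected(self):
        codes = np.array([[1.0, np.nan], [-1.0, 1.0], [1.0, -1.0]])
        with pytest.raises(ValueError, match="impute"):
            compute_kinship(_mm(codes))

    def test_permutation_invariance(self, rng):
        codes = rng.choice([-1.0, 1.0], size=(12, 40))
        m = _mm(codes)
        K = compute_kinship(m)
        # marker order must not matter at all
        perm_m = rng.permutation(40)
        K_marker = compute_kinship(MarkerMatrix(m.line_ids, m.marker_ids[perm_m], codes[:, perm_m]))
        np.testing.assert_allclose(K.K, K_marker.K, atol=1e-12)
        # line permutation permutes rows/columns identically
        perm_l = rng.permutation(12)
        K_line = compute_kinship(MarkerMatrix(m.line_ids[perm_l], m.marker_ids, codes[perm_l]))
        np.testing.assert_allclose(K_line.K, K.K[np.ix_(perm_l, perm_l)], atol=1e-12)

    def test_inbred_mean_diagonal_near_two(self, small_pop):
        """For near-fully-inbred lines mean G_ii is near 1 + f with f ~ 1."""
        filtered, _ = filter_markers(small_pop.genotypes)
        K = compute_kinship(impute_missing(filtered))
        assert 1.5 < float(K.diagonal.mean()) < 2.5


class TestPipelineAndIO:
    def test_filter_impute_kinship_idempotent_on_clean_data(self, rng):
        codes = rng.choice([-1.0, 1.0], size=(15, 50), p=[0.5, 0.5])
        m = _mm(codes)
        f1, _ = filter_markers(m)
        i1 = impute_missing(f1)
        f2, _ = filter_markers(i1)
        i2 = impute_missing(f2)
        np.testing.assert_array_equal(i1.codes, i2.codes)
        np.testing.assert_allclose(compute_kinship(i1).K, compute_kinship(i2).K)

    def test_tsv_roundtrip(self, tmp_path):
        codes = np.array([[1.0, np.nan], [-1.0, 0.0]])
        m = _mm(codes)
        path = tmp_path / "geno.tsv"
        m.to_tsv(path)
        back = MarkerMatrix.from_tsv(path)
        assert list(back.line_ids) == list(m.line_ids)
        np.testing.assert_array_equal(np.isnan(back.codes), np.isnan(codes))
        np.testing.assert_allclose(back.codes[~np.isnan(codes)], codes[~np.isnan(codes)])

    def test_kinship_csv_roundtrip(self, tmp_path):
        codes = np.array([[1.0, -1.0, 1.0], [-1.0, 1.0, 1.0], [1.0, 1.0, -1.0]])
        K = compute_kinship(_mm(codes))
        path = tmp_path / "K.csv"
        K.to_csv(path)
        back = KinshipMatrix.from_csv(path)
        np.testing.assert_allclose(back.K, K.K, atol=1e-12)

    def test_duplicate_line_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicated"):
            MarkerMatrix(["A", "A"], ["M0"], np.array([[1.0], [0.0]]))

    def test_vcf_reader_maps_gt_and_skips_multiallelic(self, tmp_path):
        pytest.importorskip("cyvcf2")
        vcf = tmp_path / "toy.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
            "1\t100\tm1\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\tm2\tG\tC\t.\tPASS\t.\tGT\t./.\t0/0\t1/1\n"
            "1\t300\tm3\tG\tC,A\t.\tPASS\t.\tGT\t0/0\t0/2\t1/1\n"
        )
        with pytest.warns(UserWarning, match="multiallelic"):
            mm = MarkerMatrix.from_vcf(vcf)
        assert list(mm.marker_ids) == ["m1", "m2"]
        np.testing.assert_array_equal(mm.codes[:, 0], [-1.0, 0.0, 1.0])
        assert np.isnan(mm.codes[0, 1]) and mm.codes[1, 1] == -1.0 and mm.codes[2, 1] == 1.0
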