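"""Normalization, filtering, outlier replicates and imputation."""

import numpy as np
import pandas as pd
import pytest

from evflux import (AbundanceMatrix, MinimumImputer,
                    detect_outlier_replicates, filter_proteotypic,
                    impute_min_random, log2_normalize)


def _matrix(values, conditions=("CTR", "CTR", "T1", "T1"), peptides=None,
            scale="raw"):
    values = np.asarray(values, dtype=float)
    samples = [f"{c}_{i}" for i, c in enumerate(conditions)]
    ids = [f"P{i}" for i in range(values.shape[0])]
    return AbundanceMatrix(
        intensities=pd.DataFrame(values, index=ids, columns=samples),
        peptide_counts=pd.Series(peptides if peptides is not None
                                 else [2] * values.shape[0], index=ids),
        design=pd.Series(list(conditions), index=samples),
        control="CTR", scale=scale)


class TestLog2Normalize:
    def test_power_of_two(self):
        m = log2_normalize(_matrix([[1024.0, 2.0, 4.0, 8.0]]))
        assert m.intensities.iloc[0, 0] == 10.0
        assert m.scale == "log2"

    def test_missing_stays_missing(self):
        m = log2_normalize(_matrix([[8.0, np.nan, 4.0, 2.0]]))
        assert np.isnan(m.intensities.iloc[0, 1])
        assert m.n_missing() == 1

    def test_random_matrix_elementwise_oracle(self, rng):
        vals = rng.uniform(1.0, 1e6, (20, 4))
        m = log2_normalize(_matrix(vals))
        np.testing.assert_allclose(m.intensities.to_numpy(),
                                   np.log2(vals), rtol=1e-14)

    def test_double_normalization_rejected(self):
        m = log2_normalize(_matrix([[8.0, 4.0, 2.0, 1.0]]))
        with pytest.raises(ValueError):
            log2_normalize(m)

    def test_nonpositive_raw_intensity_rejected(self):
        with pytest.raises(ValueError):
            _matrix([[0.0, 1.0, 1.0, 1.0]])


class TestFilterProteotypic:
    def test_threshold_of_two(self):
        m = _matrix(np.ones((3, 4)), peptides=[1, 2, 3])
        out = filter_proteotypic(m, min_peptides=2)
        assert list(out.intensities.index) == ["P1", "P2"]

    def test_min_one_is_identity(self):
        m = _matrix(np.ones((3, 4)), peptides=[1, 2, 3])
        out = filter_proteotypic(m, min_peptides=1)
        assert out.intensities.equals(m.intensities)

    def test_matches_brute_force_filter(self, rng):
        counts = rng.integers(1, 8, size=50)
        m = _matrix(np.ones((50, 4)), peptides=counts)
        out = filter_proteotypic(m, min_peptides=3)
        expected = [f"P{i}" for i in range(50) if counts[i] >= 3]
        assert list(out.intensities.index) == expected

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            filter_proteotypic(_matrix(np.ones((2, 4))), min_peptides=0)


class TestOutlierReplicates:
    def test_identical_replicates_unflagged(self, rng):
        base = rng.uniform(10, 20, 30)
        vals = np.column_stack([base] * 3 + [base] * 3)
        m = _matrix(vals, conditions=("CTR",) * 3 + ("T1",) * 3, scale="log2")
        assert not detect_outlier_replicates(m).any()

    def test_permuted_replicate_flagged(self, rng):
        base = rng.normal(20, 3, 200)
        good1 = base + rng.normal(0, 0.05, 200)
        good2 = base + rng.normal(0, 0.05, 200)
        permuted = rng.permutation(base)
        ctrl = rng.normal(20, 3, (200, 2))
        vals = np.column_stack([ctrl, good1, good2, permuted])
        m = _matrix(vals, conditions=("CTR", "CTR", "T1", "T1", "T1"),
                    scale="log2")
        flags = detect_outlier_replicates(m, min_correlation=0.8)
        assert flags.tolist() == [False, False, False, False, True]
        # oracle: the permuted column's median correlation, recomputed
        cols = m.intensities
        r1 = np.corrcoef(permuted, good1)[0, 1]
        r2 = np.corrcoef(permuted, good2)[0, 1]
        assert np.median([r1, r2]) < 0.8
        assert np.corrcoef(good1, good2)[0, 1] > 0.8
        assert cols.shape == (200, 5)

    def test_lower_bound_never_flags(self, rng):
        vals = rng.normal(20, 3, (50, 4))
        m = _matrix(vals, scale="log2")
        assert not detect_outlier_replicates(m, min_correlation=-1.0).any()

    def test_hard_floor_keeps_best_two(self, rng):
        # three mutually uncorrelated CTR replicates: at most one may go
        vals = rng.normal(20, 3, (100, 5))
        m = _matrix(vals, conditions=("CTR",) * 3 + ("T1",) * 2, scale="log2")
        flags = detect_outlier_replicates(m, min_correlation=0.99)
        kept = (~flags[m.samples_for("CTR")]).sum()
        assert kept >= 2

    def test_single_replicate_condition_rejected(self):
        m = _matrix(np.ones((5, 3)), conditions=("CTR", "CTR", "T1"),
                    scale="log2")
        with pytest.raises(ValueError):
            detect_outlier_replicates(m)


class TestImputation:
    def test_no_missing_is_identity(self, rng):
        vals = rng.normal(20, 2, (10, 4))
        m = _matrix(vals, scale="log2")
        out = impute_min_random(m, seed=1)
        assert out.intensities.equals(m.intensities)

    def test_zero_sd_fills_exact_minimum(self):
        vals = np.array([[10.0, 12.0, np.nan, 14.0]])
        m = _matrix(vals, scale="log2")
        out = impute_min_random(m, sd=0.0, seed=1)
        assert out.intensities.iloc[0, 2] == 10.0

    def test_imputed_mean_anchored_at_minimum(self, rng):
        vals = rng.normal(20, 2, (500, 4))
        vals[rng.uniform(size=vals.shape) < 0.5] = np.nan
        vals[0, 0] = 10.0  # global minimum
        m = _matrix(np.where(np.isnan(vals), np.nan, np.clip(vals, 10, None)),
                    scale="log2")
        n_missing = m.n_missing()
        assert n_missing >= 900
        out = impute_min_random(m, sd=0.3, seed=5)
        imputed = out.intensities.to_numpy()[np.isnan(m.intensities.to_numpy())]
        # Monte-Carlo check: se = 0.3 / sqrt(n) ~ 0.0095 at n = 1000
        assert imputed.mean() == pytest.approx(10.0, abs=0.03)

    def test_present_values_untouched_and_seeded(self, rng):
        vals = rng.normal(20, 2, (50, 4))
        vals[rng.uniform(size=vals.shape) < 0.2] = np.nan
        vals[0, 0] = 5.0
        m = _matrix(vals, scale="log2")
        a = impute_min_random(m, seed=7)
        b = impute_min_random(m, seed=7)
        assert a.intensities.equals(b.intensities)
        present = ~np.isnan(vals)
        np.testing.assert_array_equal(a.intensities.to_numpy()[present],
                                      vals[present])

    def test_entirely_missing_rejected(self):
        with pytest.raises(ValueError):
            MinimumImputer().fit(np.full((3, 3), np.nan))

    def test_requires_log2_scale(self):
        with pytest.raises(ValueError):
            impute_min_random(_matrix([[1.0, 2.0, 3.0, 4.0]]), seed=0)


def test_tsv_round_trip(tmp_path, rng):
    vals = rng.uniform(1, 1e6, (8, 4))
    m = _matrix(vals, peptides=[1, 2, 3, 4, 5, 6, 7, 8])
    m.to_tsv(tmp_path / "m.tsv", tmp_path / "d.csv")
    back = AbundanceMatrix.from_tsv(tmp_path / "m.tsv", tmp_path / "d.csv")
    np.testing.assert_allclose(back.intensities.to_numpy(), vals, rtol=1e-12)
    assert back.peptide_counts.tolist() == m.peptide_counts.tolist()
    assert back.design.equals(m.design)
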