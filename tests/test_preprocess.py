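import numpy as np
import pytest

from proteosig.io_core import QuantMatrix
from proteosig.preprocess import (
    combat_correct,
    detect_outlier_samples,
    filter_quantifiable,
    impute_missing,
    log2_transform,
    run_preprocess,
    zscore,
)


def make_quant(values, peptides=None, mask=None, batch=None):
    values = np.asarray(values, float)
    p, n = values.shape
    if mask is None:
        mask = np.isnan(values)
    return QuantMatrix(
        protein_ids=[f"P{i}" for i in range(p)],
        sample_ids=[f"s{j}" for j in range(n)],
        values=values,
        missing_mask=mask,
        unique_peptides=np.array(peptides if peptides is not None else [2] * p),
        batch=batch,
    )


class TestFilterQuantifiable:
    def test_boundary_inclusive(self):
        # detected in 3 of 4 (exactly 0.75), 2 peptides -> kept
        m = make_quant([[1, 2, 3, np.nan]], peptides=[2])
        assert filter_quantifiable(m).n_proteins == 1

    def test_single_peptide_dropped_even_if_complete(self):
        m = make_quant([[1, 2, 3, 4]], peptides=[1])
        with pytest.warns(UserWarning):
            assert filter_quantifiable(m).n_proteins == 0

    def test_low_detection_dropped(self):
        m = make_quant([[1, np.nan, np.nan, 4]], peptides=[5])
        with pytest.warns(UserWarning):
            assert filter_quantifiable(m).n_proteins == 0

    def test_monotone_in_detect_frac(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 10, (50, 8))
        vals[rng.random((50, 8)) < 0.3] = np.nan
        m = make_quant(vals, peptides=rng.integers(1, 6, 50))
        kept = [
            filter_quantifiable(m, min_detect_frac=f).n_proteins
            for f in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert kept == sorted(kept, reverse=True)

    def test_empty_result_warns_not_raises(self):
        m = make_quant([[1, 2]], peptides=[1])
        with pytest.warns(UserWarning):
            out = filter_quantifiable(m)
        assert out.n_proteins == 0


class TestOutlierRule:
    def test_hand_arithmetic_case(self):
        counts = [1000] * 23 + [400]
        ids = [f"s{i}" for i in range(24)]
        assert detect_outlier_samples(counts, ids) == ["s23"]

    def test_all_equal_none_excluded(self):
        assert detect_outlier_samples([500] * 10) == []

    def test_small_n_insensitivity(self):
        # threshold is -94: even a zero count survives
        assert detect_outlier_samples([1000, 1000, 1000, 1000, 0]) == []

    def test_needs_three_samples(self):
        with pytest.raises(ValueError):
            detect_outlier_samples([1, 2])


class TestLog2:
    def test_values(self):
        m = make_quant([[8.0, 1.0]])
        out = log2_transform(m)
        assert out.values[0, 0] == 3.0 and out.values[0, 1] == 0.0

    def test_mask_untouched(self):
        m = make_quant([[8.0, np.nan]])
        out = log2_transform(m)
        assert out.missing_mask[0, 1]

    def test_nonpositive_unmasked_errors(self):
        m = make_quant([[0.0, 2.0]], mask=np.zeros((1, 2), bool))
        with pytest.raises(ValueError):
            log2_transform(m)


class TestImpute:
    def test_identity_without_missing(self):
        m = make_quant([[1.0, 2.0, 3.0]])
        out, n = impute_missing(m, rng=np.random.default_rng(0))
        assert n == 0
        np.testing.assert_array_equal(out.values, m.values)

    def test_draw_moments_match_stated_normal(self):
        """Observed mean 20, SD 2 -> imputed ~ N(16.4, 0.6^2)."""
        rng = np.random.default_rng(42)
        n_draws = 10_000
        vals = np.full((1, n_draws + 3), np.nan)
        vals[0, :3] = [18.0, 20.0, 22.0]  # mean 20, sd 2
        m = make_quant(vals)
        out, n = impute_missing(m, width=0.3, downshift=1.8, rng=rng)
        draws = out.values[0, 3:]
        assert n == n_draws
        assert abs(draws.mean() - 16.4) < 0.02
        assert abs(draws.std(ddof=1) - 0.6) < 0.02

    def test_only_masked_entries_change(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(10, 20, (20, 10))
        vals[rng.random((20, 10)) < 0.2] = np.nan
        m = make_quant(vals)
        out, _ = impute_missing(m, rng=np.random.default_rng(2))
        obs = ~m.missing_mask
        np.testing.assert_array_equal(out.values[obs], m.values[obs])
        assert not out.missing_mask.any()
        assert np.isfinite(out.values).all()

    def test_reproducible_under_seed(self):
        vals = [[1.0, 2.0, np.nan], [4.0, np.nan, 6.0]]
        a, _ = impute_missing(make_quant(vals), rng=np.random.default_rng(7))
        b, _ = impute_missing(make_quant(vals), rng=np.random.default_rng(7))
        np.testing.assert_array_equal(a.values, b.values)

    def test_sparse_protein_falls_back_to_column_moments(self, caplog):
        vals = np.array(
            [
                [np.nan, np.nan, 5.0],
                [10.0, 20.0, 30.0],
                [12.0, 22.0, 32.0],
                [14.0, 24.0, 34.0],
            ]
        )
        m = make_quant(vals)
        with caplog.at_level("INFO", logger="proteosig.preprocess"):
            out, _ = impute_missing(m, rng=np.random.default_rng(3))
        assert np.isfinite(out.values).all()
        assert "sample-wise" in caplog.text


class TestZscore:
    def test_simple_row(self):
        m = make_quant([[1.0, 2.0, 3.0]])
        np.testing.assert_allclose(zscore(m).values[0], [-1, 0, 1])

    def test_row_means_zero(self):
        rng = np.random.default_rng(5)
        m = make_quant(rng.uniform(0, 9, (30, 12)))
        out = zscore(m)
        np.testing.assert_allclose(out.values.mean(axis=1), 0, atol=1e-12)

    def test_constant_row_errors_with_name(self):
        m = make_quant([[2.0, 2.0, 2.0]])
        with pytest.raises(ValueError, match="P0"):
            zscore(m)


class TestCombat:
    def test_single_batch_identity(self):
        rng = np.random.default_rng(6)
        m = make_quant(rng.standard_normal((10, 8)),
                       batch=np.array(["A"] * 8, dtype=object))
        out = combat_correct(m)
        np.testing.assert_array_equal(out.values, m.values)

    def test_two_batch_shift_removed(self):
        rng = np.random.default_rng(7)
        vals = rng.standard_normal((60, 1000))
        vals[:, 500:] += 1.0
        batch = np.array(["A"] * 500 + ["B"] * 500, dtype=object)
        m = make_quant(vals, batch=batch)
        out = combat_correct(m)
        diff = out.values[:, :500].mean(axis=1) - out.values[:, 500:].mean(axis=1)
        # residual per-protein shrinkage noise stays far below the 1.0 shift
        assert np.abs(diff).max() < 0.2
        # the systematic batch effect is gone
        assert abs(diff.mean()) < 0.02

    def test_matches_frozen_reference_adjustment(self):
        """Pinned against the R sva reference implementation (tolerance 1e-5)."""
        from tests.data_combat_reference import BATCH, INPUT, EXPECTED
        from proteosig.preprocess import _combat_adjust

        adjusted = _combat_adjust(np.array(INPUT), np.array(BATCH))
        np.testing.assert_allclose(adjusted, np.array(EXPECTED), atol=1e-5)

    def test_grand_mean_approximately_preserved(self):
        rng = np.random.default_rng(8)
        vals = rng.standard_normal((40, 400))
        vals[:, 200:] += 0.8
        m = make_quant(vals, batch=np.array(["A"] * 200 + ["B"] * 200, dtype=object))
        out = combat_correct(m)
        np.testing.assert_allclose(
            out.values.mean(axis=1), m.values.mean(axis=1), atol=0.05
        )

    def test_incomplete_matrix_rejected(self):
        m = make_quant([[1.0, np.nan, 3.0, 4.0]],
                       batch=np.array(["A", "A", "B", "B"], dtype=object))
        with pytest.raises(ValueError, match="complete"):
            combat_correct(m)

    def test_tiny_batch_rejected(self):
        m = make_quant([[1.0, 2.0, 3.0]],
                       batch=np.array(["A", "A", "B"], dtype=object))
        with pytest.raises(ValueError, match="< 2"):
            combat_correct(m)


class TestRunPreprocess:
    def test_full_chain_dimensions_and_report(self):
        from proteosig.synthetic_data import SimSpec, simulate_cohort

        qm, _, _ = simulate_cohort(
            SimSpec(n_samples=40, n_proteins=80, n_batches=2, batch_shift=0.5,
                    seed=30)
        )
        processed, report = run_preprocess(qm, rng=np.random.default_rng(30))
        assert processed.n_proteins == report.n_proteins_out
        assert processed.n_samples == report.n_samples_out
        assert not processed.missing_mask.any()
        stage_names = [s["stage"] for s in report.stages]
        assert stage_names == [
            "input", "detect_outlier_samples", "filter_quantifiable",
            "log2_transform", "impute_missing", "zscore", "combat_correct",
        ]
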