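import numpy as np
import pytest

from proteosig.io_core import ClinicalTable, QuantMatrix
from proteosig.signature import (
    CorrelationGroups,
    assign_risk,
    correlation_groups,
    default_fit_and_split,
    fit_supervised_pc,
    loocv_risk,
    permutation_pvalue,
    sample_reduced_profiles,
)
from proteosig.survstats import compare_groups, logrank_test


def make_processed(values, prefix="P"):
    values = np.asarray(values, float)
    p, n = values.shape
    return QuantMatrix(
        protein_ids=[f"{prefix}{i}" for i in range(p)],
        sample_ids=[f"s{j}" for j in range(n)],
        values=values,
        missing_mask=np.zeros((p, n), bool),
        unique_peptides=np.full(p, 2),
    )


def make_clin(n, time, event):
    return ClinicalTable(
        sample_ids=[f"s{j}" for j in range(n)],
        time=np.asarray(time, float),
        event=np.asarray(event, int),
    )


class TestCorrelationGroups:
    def test_proportional_rows_grouped(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        m = make_processed(np.vstack([x, 2 * x, rng.standard_normal(50)]))
        groups = correlation_groups(m, m.protein_ids)
        assert sorted(map(sorted, groups.groups)) == [["P0", "P1"], ["P2"]]

    def test_independent_proteins_are_singletons(self):
        rng = np.random.default_rng(1)
        m = make_processed(rng.standard_normal((3, 500)))
        groups = correlation_groups(m, m.protein_ids)
        assert groups.n_groups == 3

    def test_transitive_chain_closes(self):
        """r(1,2)=0.6, r(2,3)=0.6, r(1,3)=0.1 -> one component of 3."""
        cov = np.array([[1.0, 0.6, 0.1], [0.6, 1.0, 0.6], [0.1, 0.6, 1.0]])
        rng = np.random.default_rng(2)
        vals = rng.multivariate_normal(np.zeros(3), cov, size=4000).T
        m = make_processed(vals)
        r = np.corrcoef(vals)
        assert r[0, 1] > 0.5 and r[1, 2] > 0.5 and r[0, 2] < 0.5
        groups = correlation_groups(m, m.protein_ids)
        assert groups.n_groups == 1

    def test_partition_covers_input(self, planted_cohort):
        processed, _, _ = planted_cohort
        ids = processed.protein_ids[:40]
        groups = correlation_groups(processed, ids)
        flat = sorted(p for g in groups.groups for p in g)
        assert flat == sorted(ids)

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError):
            CorrelationGroups(groups=[["A", "B"], ["B"]])


class TestSampleReducedProfiles:
    def singletons(self, k):
        return CorrelationGroups(groups=[[f"G{i}"] for i in range(k)])

    def test_forced_unique_profile(self):
        groups = self.singletons(3)
        profiles = sample_reduced_profiles(
            groups, size_range=(3, 3), per_group=(1, 1), n_profiles=1,
            rng=np.random.default_rng(0),
        )
        assert profiles == [["G0", "G1", "G2"]]

    def test_sizes_within_range_and_distinct(self):
        groups = CorrelationGroups(
            groups=[[f"A{i}" for i in range(5)], [f"B{i}" for i in range(6)],
                    [f"C{i}" for i in range(7)], ["D0", "D1"]]
        )
        profiles = sample_reduced_profiles(
            groups, n_profiles=12, rng=np.random.default_rng(3)
        )
        assert len(profiles) == 12
        assert len({frozenset(p) for p in profiles}) == 12
        assert all(3 <= len(p) <= 7 for p in profiles)

    def test_per_group_constraint(self):
        groups = CorrelationGroups(
            groups=[[f"A{i}" for i in range(9)], [f"B{i}" for i in range(9)]]
        )
        for prof in sample_reduced_profiles(
            groups, size_range=(3, 4), n_profiles=8, rng=np.random.default_rng(4)
        ):
            a = sum(1 for p in prof if p.startswith("A"))
            b = sum(1 for p in prof if p.startswith("B"))
            assert a <= 2 and b <= 2

    def test_seed_reproducibility(self):
        groups = self.singletons(8)
        a = sample_reduced_profiles(groups, rng=np.random.default_rng(7))
        b = sample_reduced_profiles(groups, rng=np.random.default_rng(7))
        assert a == b

    def test_infeasible_size_range(self):
        groups = self.singletons(2)
        with pytest.raises(ValueError, match="infeasible"):
            sample_reduced_profiles(
                groups, size_range=(5, 7), rng=np.random.default_rng(0)
            )

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 correlation groups"):
            sample_reduced_profiles(
                self.singletons(1), rng=np.random.default_rng(0)
            )


class TestFitSupervisedPc:
    def test_two_perfectly_correlated_proteins(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(20)
        m = make_processed(np.vstack([x, 3 * x + 1]))
        clin = make_clin(20, rng.exponential(1, 20) + 0.01,
                         (rng.random(20) < 0.8).astype(int))
        model = fit_supervised_pc(m, ["P0", "P1"], clin, 0.5)
        np.testing.assert_allclose(np.abs(model.loading), [2**-0.5, 2**-0.5],
                                   atol=1e-10)
        ra = assign_risk(model, m)
        z = (x - x.mean()) / x.std(ddof=1)
        np.testing.assert_allclose(np.abs(ra.score), np.sqrt(2) * np.abs(z),
                                   atol=1e-8)

    def test_fifty_fifty_split_on_distinct_scores(self):
        rng = np.random.default_rng(6)
        m = make_processed(rng.standard_normal((4, 10)))
        clin = make_clin(10, rng.exponential(1, 10) + 0.01,
                         (rng.random(10) < 0.8).astype(int))
        model = fit_supervised_pc(m, m.protein_ids, clin, 0.5)
        ra = assign_risk(model, m)
        assert ra.high.sum() == 5

    def test_orientation_higher_score_higher_hazard(self, planted_cohort):
        processed, clin, truth = planted_cohort
        model = fit_supervised_pc(processed, truth.planted_proteins, clin, 0.5)
        assert model.cox_beta_on_score >= 0
        ra = assign_risk(model, processed)
        cmp_res = compare_groups(ra.high, clin.align_to(processed.sample_ids).time,
                                 clin.align_to(processed.sample_ids).event)
        assert cmp_res.hr > 1

    def test_degenerate_submatrix_errors(self):
        m = make_processed(np.zeros((2, 5)) + np.arange(5))
        clin = make_clin(5, [1, 2, 3, 4, 5], [1, 1, 1, 0, 0])
        m.values[1] = m.values[0]  # rank 1 but nonzero: works
        m2 = make_processed(np.ones((2, 5)))
        with pytest.raises(ValueError):
            fit_supervised_pc(m2, m2.protein_ids, clin, 0.5)

    def test_serialization_round_trip(self, tmp_path, planted_cohort):
        processed, clin, truth = planted_cohort
        model = fit_supervised_pc(processed, truth.planted_proteins, clin, 0.7)
        path = tmp_path / "model.json"
        model.to_json(path)
        from proteosig.signature import SignatureModel

        back = SignatureModel.from_json(path)
        ra1 = assign_risk(model, processed)
        ra2 = assign_risk(back, processed)
        np.testing.assert_array_equal(ra1.score, ra2.score)
        np.testing.assert_array_equal(ra1.high, ra2.high)


class TestAssignRisk:
    def test_training_split_reproduced(self, planted_cohort):
        processed, clin, truth = planted_cohort
        model = fit_supervised_pc(processed, truth.planted_proteins, clin, 0.5)
        ra = assign_risk(model, processed)
        k = int(np.ceil(0.5 * processed.n_samples))
        assert (~ra.high).sum() == k

    def test_boundary_score_is_low_risk(self):
        rng = np.random.default_rng(8)
        m = make_processed(rng.standard_normal((3, 9)))
        clin = make_clin(9, rng.exponential(1, 9) + 0.01,
                         (rng.random(9) < 0.9).astype(int))
        model = fit_supervised_pc(m, m.protein_ids, clin, 0.5)
        ra = assign_risk(model, m)
        at_cut = np.isclose(ra.score, model.cutoff_value)
        assert at_cut.any()
        assert not ra.high[at_cut].any()

    def test_missing_protein_listed(self, planted_cohort):
        processed, clin, truth = planted_cohort
        model = fit_supervised_pc(processed, truth.planted_proteins, clin, 0.5)
        sub = processed.subset_proteins(np.arange(20, 40))
        with pytest.raises(KeyError):
            assign_risk(model, sub)

    def test_frozen_standardization_hand_check(self):
        """Shifting every sample's profile by +c moves all scores by
        c * sum(loading/sd): verified against hand arithmetic."""
        rng = np.random.default_rng(9)
        m = make_processed(rng.standard_normal((2, 12)))
        clin = make_clin(12, rng.exponential(1, 12) + 0.01,
                         (rng.random(12) < 0.8).astype(int))
        model = fit_supervised_pc(m, m.protein_ids, clin, 0.5)
        shifted = m.copy()
        shifted.values = shifted.values + 0.5
        ra0 = assign_risk(model, m)
        ra1 = assign_risk(model, shifted)
        expected_shift = 0.5 * float(np.sum(model.loading / model.train_sds))
        np.testing.assert_allclose(ra1.score - ra0.score, expected_shift,
                                   atol=1e-10)


class TestLoocv:
    def test_deterministic_and_finite_on_small_cohort(self):
        rng = np.random.default_rng(10)
        m = make_processed(rng.standard_normal((5, 12)))
        clin = make_clin(12, rng.exponential(1, 12) + 0.01,
                         np.ones(12, int))
        ra1 = loocv_risk(m, clin, 0.5, alpha=1.0)
        ra2 = loocv_risk(m, clin, 0.5, alpha=1.0)
        assert np.isfinite(ra1.score).all()
        np.testing.assert_array_equal(ra1.score, ra2.score)
        np.testing.assert_array_equal(ra1.high, ra2.high)

    def test_zero_event_fold_flagged_nan(self):
        rng = np.random.default_rng(11)
        m = make_processed(rng.standard_normal((5, 10)))
        event = np.zeros(10, int)
        event[0] = 1  # the only event: its fold has zero training events
        clin = make_clin(10, rng.exponential(1, 10) + 0.01, event)
        ra = loocv_risk(m, clin, 0.5, alpha=1.0)
        assert np.isnan(ra.score[0])
        assert np.isfinite(np.delete(ra.score, 0)).all()

    def test_planted_cohort_held_out_hr_above_one(self, planted_cohort):
        processed, clin, _ = planted_cohort
        ra = loocv_risk(processed, clin, 0.5)
        clin_a = clin.align_to(processed.sample_ids)
        cmp_res = compare_groups(ra.high, clin_a.time, clin_a.event)
        assert cmp_res.hr > 1

    def test_minimum_samples(self):
        m = make_processed(np.random.default_rng(0).standard_normal((3, 2)))
        clin = make_clin(2, [1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="3 samples"):
            loocv_risk(m, clin)


class TestPermutationPvalue:
    def fixed_split(self, high):
        def _fit(m, clin):
            return high
        return _fit

    def test_add_one_rule_lower_bound(self, null_cohort):
        """Observed larger than every permuted statistic -> p = 1/(B+1)."""
        processed, clin, _ = null_cohort
        n = processed.n_samples
        high = np.zeros(n, bool)
        high[: n // 2] = True
        p = permutation_pvalue(
            np.inf if False else 1e9, processed, self.fixed_split(high), clin,
            n_permutations=50, rng=np.random.default_rng(1),
        )
        assert p == pytest.approx(1 / 51)

    def test_single_permutation_exceeding(self, null_cohort):
        processed, clin, _ = null_cohort
        n = processed.n_samples
        high = np.zeros(n, bool)
        high[: n // 2] = True
        p = permutation_pvalue(
            0.0, processed, self.fixed_split(high), clin,
            n_permutations=1, rng=np.random.default_rng(2),
        )
        assert p == 1.0

    def test_planted_signal_significant(self, planted_cohort):
        processed, clin, _ = planted_cohort
        closure = default_fit_and_split(0.01, 0.5)
        clin_a = clin.align_to(processed.sample_ids)
        high = closure(processed, clin_a)
        chi2, _ = logrank_test(
            clin_a.time[~high], clin_a.event[~high],
            clin_a.time[high], clin_a.event[high],
        )
        p = permutation_pvalue(
            chi2, processed, closure, clin_a, n_permutations=99,
            rng=np.random.default_rng(3),
        )
        assert p <= 0.05
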