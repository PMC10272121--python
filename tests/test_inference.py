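"""Permutation tests, BH-FDR, bootstrap CI, outlier rule, cascade logic."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_feature_table
from dynconn.inference import (CohortFeatures, bh_fdr, bootstrap_ci,
                               flag_outliers, permutation_pvalue, run_cascade)

import pandas as pd


class TestPermutation:
    def test_perfect_prediction_attains_minimum_p(self, rng):
        y = rng.permutation(np.arange(20.0))
        res = permutation_pvalue(y, y, 10000, rng)
        assert res.p_value == pytest.approx(1.0 / 10001)

    def test_matches_exhaustive_enumeration_at_n5(self, rng):
        y_true = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        y_pred = np.array([0.9, 2.5, 2.2, 4.0, 4.8])
        r_obs = np.corrcoef(y_true, y_pred)[0, 1]
        null = [np.corrcoef(np.array(p), y_pred)[0, 1]
                for p in itertools.permutations(y_true)]
        exact = sum(r >= r_obs for r in null) / len(null)
        res = permutation_pvalue(y_true, y_pred, 10000, rng)
        assert abs(res.p_value - exact) <= 0.02

    def test_p_bounded_away_from_zero(self, rng):
        y = rng.standard_normal(15)
        res = permutation_pvalue(y, rng.standard_normal(15), 200, rng,
                                 store_null=True)
        assert 1.0 / 201 <= res.p_value <= 1.0
        assert res.null_distribution.shape == (200,)

    def test_too_few_permutations_rejected(self, rng):
        y = rng.standard_normal(10)
        with pytest.raises(ValueError):
            permutation_pvalue(y, y, 50, rng)


class TestBhFdr:
    def brute_force(self, p, q):
        """Step-up rule applied literally (test oracle)."""
        p = np.asarray(p)
        m = len(p)
        order = np.argsort(p)
        k_max = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= k * q / m:
                k_max = k
        passed = np.zeros(m, bool)
        if k_max:
            passed[order[:k_max]] = True
        return passed

    def test_hand_worked_example(self):
        flags, thr = bh_fdr([0.001, 0.2, 0.9], q=0.05)
        assert list(flags) == [True, False, False]
        assert thr == pytest.approx(0.001)

    def test_all_ones_pass_nothing(self):
        flags, thr = bh_fdr(np.ones(6))
        assert not flags.any()
        assert np.isnan(thr)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            p = rng.uniform(1e-6, 1.0, 60)
            flags, _ = bh_fdr(p, q=0.05)
            np.testing.assert_array_equal(flags, self.brute_force(p, 0.05))

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(20):
            p = rng.uniform(1e-6, 1.0, 40)
            flags, _ = bh_fdr(p, q=0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            np.testing.assert_array_equal(flags, ref)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=30),
           st.integers(0, 29))
    def test_monotone_in_individual_pvalues(self, pvals, idx):
        p = np.asarray(pvals)
        idx = idx % p.size
        flags_before, _ = bh_fdr(p)
        p2 = p.copy()
        p2[idx] = p2[idx] / 2.0
        flags_after, _ = bh_fdr(p2)
        # lowering one p never turns a passing test into a failing one
        assert not np.any(flags_before & ~flags_after)

    def test_empty_and_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([])
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])


class TestBootstrap:
    def test_identical_vectors_collapse_to_one(self, rng):
        y = rng.standard_normal(25)
        lo, hi = bootstrap_ci(y, y, n_boot=500, rng=rng)
        assert lo == pytest.approx(1.0, abs=1e-12)
        assert hi == pytest.approx(1.0, abs=1e-12)

    def test_interval_contains_point_estimate(self, rng):
        for _ in range(5):
            y = rng.standard_normal(30)
            x = 0.5 * y + rng.standard_normal(30)
            lo, hi = bootstrap_ci(y, x, n_boot=2000, rng=rng)
            assert lo <= np.corrcoef(y, x)[0, 1] <= hi

    def test_small_sample_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_ci(np.arange(5.0), np.arange(5.0))


class TestOutliers:
    def test_single_extreme_point_flagged(self):
        v = np.array([0.0] * 20 + [100.0])
        mask = flag_outliers(v)
        assert mask.sum() == 1 and mask[-1]

    @pytest.mark.parametrize("v", [(1.0, 2.0, 3.0), (5.0, 5.0, 5.0)])
    def test_unremarkable_vectors_flag_nothing(self, v):
        assert not flag_outliers(np.array(v)).any()

    def test_single_pass_not_iterative(self):
        # after removing the big outlier, 10 would look extreme; a single
        # pass must not flag it
        v = np.array([0.0] * 30 + [10.0, 1000.0])
        mask = flag_outliers(v)
        assert mask.sum() == 1 and mask[-1]


class TestCascade:
    def family(self, rng, n_seeds, n_sub, p=5, signal_seed=None):
        feats, out = {}, {}
        u = rng.standard_normal(n_sub)
        for s in range(n_seeds):
            sid = f"seed_{s + 1}"
            X = rng.random((n_sub, p))
            if sid == signal_seed:
                X[:, 0] += 2.0 * (u - u.min())
                X[:, 1] += 2.0 * (u - u.min())
            feats[sid] = make_feature_table(X, seed_id=sid)
        out["trait"] = 10 + 2 * u + 0.3 * rng.standard_normal(n_sub)
        out["nuisance_1"] = rng.standard_normal(n_sub)
        out["nuisance_2"] = rng.standard_normal(n_sub)
        return CohortFeatures(features=feats, outcomes=pd.DataFrame(out))

    def test_full_family_enumeration(self, rng):
        # 20 seeds x 3 outcomes -> 60 stage-1 models
        train = self.family(rng, 20, 15)
        val = self.family(rng, 20, 15)
        test = self.family(rng, 20, 15)
        report = run_cascade(train, val, test,
                            [f"seed_{s + 1}" for s in range(20)],
                            ["trait", "nuisance_1", "nuisance_2"],
                            n_permutations=200, n_boot=200, rng=rng)
        assert len(report.stage1) == 60
        # nestedness holds by construction (validated in CascadeReport)
        assert set(map(tuple, report.stage2[["seed", "outcome"]].to_numpy())) \
            <= set(map(tuple,
                       report.stage1.loc[report.stage1["fdr_pass"],
                                         ["seed", "outcome"]].to_numpy()))

    def test_signal_seed_survives_and_lazy_cohorts_untouched_when_dead(self, rng):
        train = self.family(rng, 2, 40, signal_seed="seed_1")
        val = self.family(rng, 2, 40, signal_seed="seed_1")
        test = self.family(rng, 2, 40, signal_seed="seed_1")
        report = run_cascade(train, val, test, ["seed_1", "seed_2"],
                            ["trait"], n_permutations=500, n_boot=500, rng=rng)
        assert ("seed_1", "trait") in set(
            map(tuple, report.stage3[["seed", "outcome"]].to_numpy()))

        # all-null family: later cohorts must never be materialized
        calls = []
        null_train = self.family(rng, 2, 40)

        def never():
            calls.append(1)
            raise AssertionError("lazy cohort should not be built")

        report = run_cascade(null_train, never, never, ["seed_1", "seed_2"],
                            ["nuisance_1"], n_permutations=500, rng=rng)
        if not report.stage1["fdr_pass"].any():
            assert not calls
            assert len(report.stage3) == 0


def test_cascade_and_lesion_reports_serialize_to_json(tmp_path, rng):
    import json
    from conftest import make_feature_table, make_model
    from dynconn.lesion import virtual_lesion
    from dynconn.model import pattern_expression

    model = make_model([1.0, -0.5, 0.3])
    X = rng.random((25, 3))
    y = pattern_expression(model, make_feature_table(X)) \
        + 0.2 * rng.standard_normal(25)
    rep = virtual_lesion(model, [(make_feature_table(X), y)])
    path = tmp_path / "lesion.json"
    rep.to_json(path)
    payload = json.loads(path.read_text())
    assert set(payload["delta_corr"]["cohort_1"]) == set(rep.feature_ids)
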