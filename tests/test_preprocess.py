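"""Filters, compositional transforms and visit selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import resilmet as rm
from resilmet.preprocess import (blank_filter, dead_volume_filter, nzv_filter,
                                 pseudocount_log, rclr, residualize_covariate,
                                 select_external_visit, select_visit_min_age_sd,
                                 sparsity_filter, spls_branch, lmm_branch)


class TestFilters:
    def test_dead_volume(self, toy_table):
        out = dead_volume_filter(toy_table, rt_min=0.7)
        assert list(out.feature_ids) == ["FB", "FC"]
        assert list(dead_volume_filter(toy_table, rt_min=0.0).feature_ids) == \
            list(toy_table.feature_ids)

    def test_dead_volume_removes_exactly_planted(self, small_cohort):
        _, table, _, _, truth = small_cohort
        out = dead_volume_filter(table, 0.7)
        removed = set(table.feature_ids) - set(out.feature_ids)
        assert removed == set(truth.early_rt_feature_ids)

    def test_blank_filter_thresholds(self, toy_metadata):
        features = pd.DataFrame({"mz": [200.0, 300.0], "rt": [2.0, 2.0]},
                                index=pd.Index(["kept", "dropped"],
                                               name="feature_id"))
        areas = pd.DataFrame([[600.0, 600, 600, 600, 100.0],
                              [400.0, 400, 400, 400, 100.0]],
                             index=features.index,
                             columns=toy_metadata["sample_id"])
        t = rm.FeatureTable(features, areas)
        out = blank_filter(t, toy_metadata, factor=5)
        assert list(out.feature_ids) == ["kept"]

    def test_blank_filter_requires_blanks(self, toy_table, toy_metadata):
        meta = toy_metadata.assign(is_blank=False, participant_id="P9",
                                   visit=range(5))
        with pytest.raises(ValueError, match="blank"):
            blank_filter(toy_table, meta)

    def test_blank_filter_separates_planted_labels(self, small_cohort):
        _, table, meta, _, truth = small_cohort
        out = blank_filter(table, meta, factor=5)
        survivors = set(out.feature_ids)
        assert not (set(truth.contaminant_feature_ids) & survivors)
        planted = set(truth.resilience_feature_ids) | set(truth.age_feature_ids)
        assert planted <= survivors

    def test_sparsity_filter_matches_recount_oracle(self, small_cohort):
        _, table, meta, *_ = small_cohort
        out = sparsity_filter(table, 0.4, metadata=meta)
        nb = meta.loc[~meta["is_blank"], "sample_id"]
        oracle = ((table.areas[nb] > 0).mean(axis=1) >= 0.4).sum()
        assert len(out.feature_ids) == oracle

    def test_sparsity_threshold_one_keeps_only_zero_free(self, small_cohort):
        _, table, meta, *_ = small_cohort
        out = sparsity_filter(table, 1.0, metadata=meta)
        nb = meta.loc[~meta["is_blank"], "sample_id"]
        assert (out.areas[nb].to_numpy() > 0).all()


class TestTransforms:
    def test_pseudocount_log_hand_example(self):
        features = pd.DataFrame({"mz": [200.0], "rt": [2.0]},
                                index=pd.Index(["F1"], name="feature_id"))
        t = rm.FeatureTable(features, pd.DataFrame(
            [[0.0, 4.0, 8.0]], index=features.index, columns=["a", "b", "c"]))
        out = pseudocount_log(t)
        np.testing.assert_allclose(out.loc["F1"],
                                   [np.log(2), np.log(4), np.log(8)])

    def test_pseudocount_log_zero_free_is_plain_log(self, toy_table):
        t = toy_table.subset_features(["FB"])
        out = pseudocount_log(t)
        np.testing.assert_allclose(out.to_numpy(),
                                   np.log(t.areas.to_numpy()))

    def test_pseudocount_preserves_monotonicity(self, small_cohort):
        _, table, meta, *_ = small_cohort
        t = sparsity_filter(table, 0.3, metadata=meta)
        out = pseudocount_log(t)
        a = t.areas.to_numpy()
        x = out.to_numpy()
        for i in range(a.shape[0]):
            order = np.argsort(a[i], kind="stable")
            assert (np.diff(x[i][order]) >= -1e-12).all()

    def test_rclr_hand_examples(self):
        features = pd.DataFrame({"mz": [200.0, 300.0, 400.0],
                                 "rt": [2.0, 2.0, 2.0]},
                                index=pd.Index(list("abc"), name="feature_id"))
        areas = pd.DataFrame([[10.0, np.e], [10.0, np.e ** 3], [10.0, 0.0]],
                             index=features.index, columns=["s1", "s2"])
        out = rclr(rm.FeatureTable(features, areas))
        np.testing.assert_allclose(out["s1"], [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(out["s2"].iloc[:2], [-1, 1], atol=1e-12)
        assert np.isnan(out["s2"].iloc[2])

    def test_rclr_sample_means_zero(self, small_cohort):
        _, table, meta, *_ = small_cohort
        nb = meta.loc[~meta["is_blank"], "sample_id"]
        out = rclr(table.subset_samples(list(nb)))
        means = np.nanmean(out.to_numpy(), axis=0)
        assert np.abs(means).max() < 1e-10

    def test_rclr_rejects_sample_with_one_observation(self):
        features = pd.DataFrame({"mz": [200.0, 300.0], "rt": [2.0, 2.0]},
                                index=pd.Index(["a", "b"], name="feature_id"))
        areas = pd.DataFrame([[10.0], [0.0]], index=features.index,
                             columns=["s1"])
        with pytest.raises(ValueError, match="s1"):
            rclr(rm.FeatureTable(features, areas))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 10.0))
    def test_rclr_scale_invariance_per_sample(self, scale, small_cohort):
        # multiplying one sample's areas by a constant leaves RCLR unchanged
        _, table, meta, *_ = small_cohort
        nb = list(meta.loc[~meta["is_blank"], "sample_id"])[:10]
        t = table.subset_samples(nb)
        a = rclr(t)
        areas2 = t.areas.copy()
        areas2[nb[0]] = areas2[nb[0]] * scale
        b = rclr(rm.FeatureTable(t.features, areas2))
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-9,
                                   equal_nan=True)

    def test_residualize_matches_ols_oracle(self):
        ages = np.array([60.0, 65, 70, 75, 80])
        rng = np.random.default_rng(0)
        y = 0.1 * ages + rng.normal(size=5)
        data = pd.DataFrame([y], index=["F1"], columns=[f"s{i}" for i in range(5)])
        meta = pd.DataFrame({"sample_id": data.columns, "age": ages})
        out = residualize_covariate(data, meta)
        X = np.column_stack([np.ones(5), ages])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(out.loc["F1"], y - X @ beta, atol=1e-10)
        # perfectly linear feature → all residuals ~ 0
        lin = pd.DataFrame([2.0 * ages + 1], index=["L"], columns=data.columns)
        np.testing.assert_allclose(residualize_covariate(lin, meta).loc["L"],
                                   0.0, atol=1e-10)

    def test_residualize_constant_covariate_warns_identity(self):
        data = pd.DataFrame([[1.0, 2, 3]], index=["F1"],
                            columns=["s1", "s2", "s3"])
        meta = pd.DataFrame({"sample_id": data.columns, "age": [70.0, 70, 70]})
        with pytest.warns(UserWarning, match="constant"):
            out = residualize_covariate(data, meta)
        pd.testing.assert_frame_equal(out, data)

    def test_nzv_filter(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(
            {"s%d" % i: v for i, v in enumerate(
                np.column_stack([np.full(3, 1.0),
                                 rng.normal(size=3),
                                 [1.0, 1.0, 2.0]]).T)},
        )
        data = pd.DataFrame(
            [np.full(20, 1.0), rng.normal(size=20),
             np.r_[np.full(19, 5.0), 6.0]],
            index=["constant", "spread", "dominated"],
            columns=[f"s{i}" for i in range(20)])
        out = nzv_filter(data, dominance=0.9)
        assert list(out.index) == ["spread"]
        # survivor set equals direct recomputation
        var_ok = data.var(axis=1) >= 1e-8
        dom = data.apply(lambda r: r.value_counts().max() / len(r) <= 0.9, axis=1)
        assert set(out.index) == set(data.index[var_ok & dom])


class TestVisitSelection:
    def _meta(self, ages_by_pid):
        rows = []
        for p, ages in ages_by_pid.items():
            for j, a in enumerate(ages):
                rows.append({"sample_id": f"{p}v{j}", "participant_id": p,
                             "visit": j + 1, "age": a, "is_blank": False})
        return pd.DataFrame(rows)

    def test_identical_grids_hit_uniform_optimum(self):
        meta = self._meta({f"P{i}": [70.0, 74.0, 78.0] for i in range(5)})
        sel, sd = select_visit_min_age_sd(meta)
        assert sd == pytest.approx(0.0, abs=1e-12)
        assert len(set(sel.values())) == 1

    def test_matches_exhaustive_on_random_small_cohorts(self):
        rng = np.random.default_rng(42)
        for _ in range(12):
            ages = {f"P{i}": sorted(rng.uniform(62, 85, 3)) for i in range(6)}
            meta = self._meta(ages)
            _, sd = select_visit_min_age_sd(meta)
            best = min(
                np.std([ages[f"P{i}"][c[i]] for i in range(6)])
                for c in itertools.product(range(3), repeat=6))
            assert sd == pytest.approx(best, abs=1e-9)

    def test_never_worse_than_uniform_choice(self):
        rng = np.random.default_rng(7)
        ages = {f"P{i}": sorted(rng.uniform(60, 85, 3)) for i in range(40)}
        meta = self._meta(ages)
        _, sd = select_visit_min_age_sd(meta)
        for j in range(3):
            uniform = np.std([ages[p][j] for p in ages])
            assert sd <= uniform + 1e-12

    def test_external_visit_closest_in_age_tie_earlier(self):
        meta = self._meta({"P1": [70.0, 74.0, 78.0]})
        ext = select_external_visit(meta, {"P1": 2})
        assert ext["P1"] == 1  # equidistant 70 vs 78 → earlier visit
        ext = select_external_visit(meta, {"P1": 3})
        assert ext["P1"] == 2

    def test_external_disjoint_from_selected(self, small_cohort):
        _, _, meta, _, _ = small_cohort
        sel, _ = select_visit_min_age_sd(meta)
        ext = select_external_visit(meta, sel)
        assert set(ext) == set(sel)
        assert all(ext[p] != sel[p] for p in ext)

    def test_single_visit_participant_dropped_with_warning(self):
        meta = self._meta({"P1": [70.0, 74.0], "P2": [71.0]})
        with pytest.warns(UserWarning, match="single-visit"):
            ext = select_external_visit(meta, {"P1": 1, "P2": 1})
        assert "P2" not in ext


class TestBranches:
    def test_spls_branch_counts_nonincreasing(self, small_cohort):
        _, table, meta, _, truth = small_cohort
        meta = meta.copy()
        meta["resilience"] = meta["participant_id"].map(
            pd.Series({p: v for p, v in truth.true_random_slopes.items()}))
        x, meta_sel, report = spls_branch(table, meta)
        counts = [s["n_in"] for s in report.steps] + [report.steps[-1]["n_out"]]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert x.shape[1] == len(meta_sel)
        # one selected sample per participant
        assert meta_sel["participant_id"].is_unique

    def test_lmm_branch_output_is_log_scale(self, small_cohort):
        _, table, meta, *_ = small_cohort
        x, meta_nb, report = lmm_branch(table, meta)
        assert x.shape[1] == (~meta["is_blank"]).sum()
        assert np.isfinite(x.to_numpy()).all()
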