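"""Hurdle model, age mixed models, BH-FDR, fold changes, chain classes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

import resilmet as rm
from resilmet.stats import (ChainClass, bh_adjust, chain_class,
                            direction_summary, fold_change, hurdle, lmm_age,
                            split_resilience_groups)


class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_itself(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            m = int(rng.integers(1, 200))
            p = rng.random(m)
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)

    def test_uniform_null_calibration(self):
        rng = np.random.default_rng(1)
        fracs = [np.mean(bh_adjust(rng.random(1000)) < 0.05) for _ in range(20)]
        assert np.mean(fracs) <= 0.05 + 0.02

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])


def _toy_hurdle_table(areas, samples):
    features = pd.DataFrame({"mz": [300.0], "rt": [2.0]},
                            index=pd.Index(["F1"], name="feature_id"))
    return rm.FeatureTable(features, pd.DataFrame(
        [areas], index=features.index, columns=samples))


class TestHurdle:
    def test_step1_sign_matches_grid_search_oracle(self):
        # presence (1,1,1,0,0,0) against resilience (3,2,1,-1,-2,-3):
        # compare the IRLS coefficient against a brute-force ML grid search
        samples = [f"s{i}" for i in range(6)]
        areas = [10.0, 12.0, 9.0, 0.0, 0.0, 0.0]
        r = pd.Series([3.0, 2.0, 1.0, -1.0, -2.0, -3.0], index=samples)
        table = _toy_hurdle_table(areas, samples)
        df = hurdle(table, r, min_group=3)
        row = df.loc["F1"]
        # this pattern is perfectly separated: flagged inestimable, sign +
        assert not row["step1_estimable"]
        assert row["n_present"] == 3 and row["n_absent"] == 3

        # a non-separated pattern: oracle by grid search over (b0, b1)
        pres = np.array([1, 1, 0, 1, 0, 0], dtype=float)
        table2 = _toy_hurdle_table([10.0, 12.0, 0.0, 9.0, 0.0, 0.0], samples)
        df2 = hurdle(rm.FeatureTable(table2.features,
                                     table2.areas), r, min_group=3)
        coef = df2.loc["F1", "step1_coef"]
        x = r.to_numpy()
        grid = np.linspace(-5, 5, 801)
        best, best_ll = None, -np.inf
        for b0 in grid:
            eta = b0 + np.outer(grid, x)
            ll = (pres * eta - np.log1p(np.exp(eta))).sum(axis=1)
            j = int(np.argmax(ll))
            if ll[j] > best_ll:
                best_ll, best = ll[j], grid[j]
        assert coef == pytest.approx(best, abs=0.02)
        assert coef > 0

    def test_always_present_feature_skips_step1_fits_step2(self):
        rng = np.random.default_rng(2)
        samples = [f"s{i}" for i in range(40)]
        areas = np.exp(rng.normal(10, 1, 40))
        r = pd.Series(rng.normal(size=40), index=samples)
        df = hurdle(_toy_hurdle_table(areas, samples), r)
        row = df.loc["F1"]
        assert not row["step1_estimable"]
        assert row["step2_estimable"]
        assert row["n_absent"] == 0

    def test_planted_negative_feature_detected(self):
        # power simulation at the generator's stated example conditions
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = rm.GeneratorConfig(n_participants=237, n_visits=1,
                                     n_features=60, n_resilience_features=10,
                                     n_age_features=0,
                                     effect_size_resilience=0.5, seed=seed)
            records, truth = rm.generate_cohort(cfg)
            table, meta = rm.generate_feature_table(cfg, truth, records)
            nb = meta[~meta["is_blank"]]
            t = table.subset_samples(list(nb["sample_id"]))
            res = pd.Series(truth.true_random_slopes)
            res.index = ["S_" + p + "_V1" for p in res.index]
            df = hurdle(t, res)
            neg = [f for f, s in truth.resilience_feature_signs.items()
                   if s == -1]
            sub = df.loc[neg]
            sub = sub[sub["step2_estimable"]]
            ok = (sub["step2_coef"] < 0) & (sub["q2"] < 0.05)
            hits += ok.mean() >= 0.5
        assert hits >= 0.9 * n_seeds

    def test_constant_resilience_rejected(self):
        samples = ["s1", "s2", "s3", "s4"]
        r = pd.Series([1.0, 1.0, 1.0, 1.0], index=samples)
        with pytest.raises(ValueError, match="constant"):
            hurdle(_toy_hurdle_table([1, 2, 3, 4.0], samples), r)

    def test_presence_decomposition(self, small_cohort):
        _, table, meta, _, truth = small_cohort
        nb = meta[~meta["is_blank"]]
        sel = nb[nb["visit"] == 1]
        t = table.subset_samples(list(sel["sample_id"]))
        res = pd.Series(truth.true_random_slopes)
        res.index = ["S_" + p + "_V1" for p in res.index]
        df = hurdle(t, res)
        assert ((df["n_present"] + df["n_absent"]) == len(sel)).all()


class TestLmmAge:
    def test_zero_noise_zero_slope_not_selected(self):
        # feature constant in age with tiny noise → p ~ 1
        rng = np.random.default_rng(3)
        n_p, n_v = 30, 3
        samples, ages, pids = [], [], []
        for i in range(n_p):
            for j in range(n_v):
                samples.append(f"P{i}_v{j}")
                ages.append(65.0 + 2 * i % 10 + 7.5 * j)
                pids.append(f"P{i}")
        meta = pd.DataFrame({"sample_id": samples, "participant_id": pids,
                             "age": ages, "is_blank": False})
        data = pd.DataFrame(
            [10.0 + 1e-8 * rng.normal(size=len(samples)),
             0.05 * np.array(ages) + 0.3 * rng.normal(size=len(samples))],
            index=["flat", "aging"], columns=samples)
        df, summary = lmm_age(data, meta)
        assert df.loc["flat", "p_fixed"] > 0.5
        assert df.loc["aging", "q_fixed"] < 0.05
        assert summary["n_features"] == 2

    def test_no_heterogeneity_features_flagged_singular(self):
        # strong common age slope, no per-person slope spread → singular fits
        cfg = rm.GeneratorConfig(n_participants=40, n_features=30,
                                 n_age_features=10, n_resilience_features=0,
                                 effect_size_age=0.08, detection_limit=0.0,
                                 n_contaminants=0, seed=4)
        records, truth = rm.generate_cohort(cfg)
        table, meta = rm.generate_feature_table(cfg, truth, records)
        from resilmet.preprocess import lmm_branch
        x, _, _ = lmm_branch(table, meta, min_presence=0.3)
        df, summary = lmm_age(x, meta, selection_rule="require_singular")
        planted = [f for f in truth.age_feature_ids if f in df.index]
        sub = df.loc[planted]
        assert (sub["q_fixed"] < 0.05).mean() >= 0.8
        assert sub["singular_fit"].mean() >= 0.7
        assert summary["n_significant_singular"] >= summary["n_selected"]

    def test_null_features_bh_controlled(self):
        cfg = rm.GeneratorConfig(n_participants=50, n_features=60,
                                 n_age_features=0, n_resilience_features=0,
                                 detection_limit=0.0, n_contaminants=0, seed=5)
        records, truth = rm.generate_cohort(cfg)
        table, meta = rm.generate_feature_table(cfg, truth, records)
        from resilmet.preprocess import lmm_branch
        x, _, _ = lmm_branch(table, meta, min_presence=0.3)
        df, summary = lmm_age(x, meta)
        assert (df["q_fixed"] < 0.05).mean() <= 0.08

    def test_reduces_to_ols_without_grouping_structure(self):
        # one visit per participant → no random effects identifiable; the
        # precondition (≥2 visits somewhere) is enforced
        meta = pd.DataFrame({"sample_id": ["a", "b"], "participant_id":
                             ["P1", "P2"], "age": [70.0, 75.0],
                             "is_blank": False})
        data = pd.DataFrame([[1.0, 2.0]], index=["F1"], columns=["a", "b"])
        with pytest.raises(ValueError, match="visits"):
            lmm_age(data, meta)


class TestGroupsAndFoldChange:
    def test_median_split_hand_example(self):
        r = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        g = split_resilience_groups(r)
        assert set(r.index[g == "low"]) == {"a", "b"}
        assert set(r.index[g == "high"]) == {"c", "d"}

    def test_all_equal_scores_everything_low(self):
        r = pd.Series([1.0] * 6, index=[f"s{i}" for i in range(6)])
        g = split_resilience_groups(r)
        assert (g == "low").all()

    def test_group_sizes_balanced_at_scale(self):
        rng = np.random.default_rng(6)
        r = pd.Series(rng.normal(size=237),
                      index=[f"s{i}" for i in range(237)])
        g = split_resilience_groups(r)
        assert abs((g == "low").sum() - (g == "high").sum()) <= 1

    def test_fold_change_identical_groups(self):
        samples = [f"s{i}" for i in range(20)]
        rng = np.random.default_rng(7)
        vals = np.exp(rng.normal(10, 1, 10))
        areas = np.r_[vals, vals]
        g = pd.Series(["low"] * 10 + ["high"] * 10, index=samples)
        df = fold_change(_toy_hurdle_table(areas, samples), g)
        assert df.loc["F1", "log2_fc"] == pytest.approx(0.0, abs=1e-12)
        assert df.loc["F1", "p"] > 0.9

    def test_fold_change_exact_doubling(self):
        samples = [f"s{i}" for i in range(8)]
        areas = [100.0] * 4 + [200.0] * 4
        g = pd.Series(["low"] * 4 + ["high"] * 4, index=samples)
        df = fold_change(_toy_hurdle_table(areas, samples), g)
        assert df.loc["F1", "log2_fc"] == pytest.approx(1.0)

    def test_absent_in_one_group_flagged(self):
        samples = [f"s{i}" for i in range(8)]
        areas = [0.0] * 4 + [200.0, 210.0, 190.0, 205.0]
        g = pd.Series(["low"] * 4 + ["high"] * 4, index=samples)
        df = fold_change(_toy_hurdle_table(areas, samples), g)
        assert np.isinf(df.loc["F1", "log2_fc"])
        assert not df.loc["F1", "tested"]

    def test_planted_negative_features_lower_in_high_group(self):
        cfg = rm.GeneratorConfig(n_participants=150, n_visits=1, n_features=60,
                                 n_resilience_features=16, n_age_features=0,
                                 seed=8)
        records, truth = rm.generate_cohort(cfg)
        table, meta = rm.generate_feature_table(cfg, truth, records)
        nb = meta[~meta["is_blank"]]
        t = table.subset_samples(list(nb["sample_id"]))
        res = pd.Series(truth.true_random_slopes)
        res.index = ["S_" + p + "_V1" for p in res.index]
        g = split_resilience_groups(res)
        df = fold_change(t, g)
        neg = [f for f, s in truth.resilience_feature_signs.items() if s == -1]
        fcs = df.loc[neg, "log2_fc"]
        fcs = fcs[np.isfinite(fcs)]
        assert (fcs < 0).mean() > 0.5


class TestChainClass:
    @pytest.mark.parametrize("text, carbons, unsat, cls", [
        ("C12:1 carnitine", 12, 1, "medium"),
        ("C2:0", 2, 0, "short"),
        ("C5 acylcarnitine", 5, 0, "short"),
        ("C6:0", 6, 0, "medium"),
        ("C13:2-OH", 13, 2, "long"),
        ("C21:0", 21, 0, "long"),
        ("C22:0", 22, 0, "very_long"),
        ("sphingosine phosphate", None, None, "unknown"),
        ("", None, None, "unknown"),
    ])
    def test_boundaries(self, text, carbons, unsat, cls):
        got = chain_class(text)
        assert got == ChainClass(carbons, unsat, cls)

    def test_direction_summary(self):
        w = pd.Series([-1.0, -2.0, 3.0, -0.5, 0.2],
                      index=list("abcde"))
        labels = pd.Series(["medium"] * 3 + ["short"] * 2, index=list("abcde"))
        out = direction_summary(w, labels)
        assert out["medium"] == pytest.approx(2 / 3)
        assert out["short"] == pytest.approx(0.5)

    def test_direction_summary_recovers_planted_fraction(self):
        rng = np.random.default_rng(9)
        n = 200
        signs = rng.random(n) < 0.8
        w = pd.Series(np.where(signs, -1.0, 1.0) * rng.uniform(0.1, 1, n),
                      index=[f"F{i}" for i in range(n)])
        labels = pd.Series("carnitine", index=w.index)
        assert direction_summary(w, labels)["carnitine"] == \
            pytest.approx(0.8, abs=0.1)

    def test_empty_overlap_rejected(self):
        with pytest.raises(ValueError):
            direction_summary(pd.Series([1.0], index=["a"]),
                              pd.Series(["x"], index=["b"]))
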