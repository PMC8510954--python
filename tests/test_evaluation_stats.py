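import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hgpradiomics.evaluation_stats import (
    ExperimentDesign,
    augment_multiobserver,
    bonferroni,
    chi_square_2xk,
    compute_metrics,
    corrected_resampled_ci,
    make_splits,
    mann_whitney,
    roc_band,
    single_observer_design,
)


def _metadata(n_patients=76, balance=0.49, lesions=1, seed=0):
    rng = np.random.default_rng(seed)
    n_pos = int(round(balance * n_patients))
    rows = []
    for i in range(n_patients):
        label = "dHGP" if i < n_pos else "rHGP"
        for j in range(lesions):
            rows.append(
                {"patient_id": f"P{i:03d}", "lesion_id": f"P{i:03d}_L{j}", "label": label}
            )
    return pd.DataFrame(rows)


class TestMakeSplits:
    def test_sizes_80_20(self):
        meta = _metadata(76)
        plan = make_splits(meta, n_iterations=10, seed=0)
        for train, test in plan.iterations:
            assert len(train) + len(test) == 76
            assert abs(len(train) - round(0.8 * 76)) <= 1

    def test_patient_disjoint(self):
        plan = make_splits(_metadata(40), n_iterations=25, seed=1)
        for train, test in plan.iterations:
            assert set(train) & set(test) == set()

    def test_stratified_within_one_patient(self):
        meta = _metadata(76, balance=46 / 93)
        global_ratio = (meta.drop_duplicates("patient_id")["label"] == "dHGP").mean()
        plan = make_splits(meta, n_iterations=20, seed=2)
        labels = meta.drop_duplicates("patient_id").set_index("patient_id")["label"]
        for _, test in plan.iterations:
            n_pos = int((labels.loc[test] == "dHGP").sum())
            expected = global_ratio * len(test)
            assert abs(n_pos - expected) <= 1.0

    def test_deterministic(self):
        meta = _metadata(30)
        a = make_splits(meta, n_iterations=5, seed=3)
        b = make_splits(meta, n_iterations=5, seed=3)
        assert a.iterations == b.iterations

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            make_splits(_metadata(10), train_frac=1.0)


class TestAugmentMultiobserver:
    def _rows(self, n_lesions=10):
        rows = []
        for i in range(n_lesions):
            for obs in ("STUD2", "PhD", "RAD", "CNN"):
                rows.append(
                    {
                        "patient_id": f"P{i}",
                        "lesion_id": f"L{i}",
                        "observer": obs,
                        "label": "dHGP",
                        "f1": float(i),
                    }
                )
        return pd.DataFrame(rows)

    def test_threefold(self):
        out = augment_multiobserver(self._rows(10))
        assert len(out) == 30

    def test_observer_panel_exact(self):
        out = augment_multiobserver(self._rows(5))
        assert set(out["observer"]) == {"STUD2", "PhD", "RAD"}
        assert (out.groupby("lesion_id")["observer"].nunique() == 3).all()

    def test_single_observer_identity(self):
        rows = self._rows(4)
        only = rows[rows["observer"] == "CNN"]
        out = augment_multiobserver(only, observers=("CNN",))
        pd.testing.assert_frame_equal(out.reset_index(drop=True), only.reset_index(drop=True))

    def test_missing_observer_raises(self):
        rows = self._rows(4)
        rows = rows.drop(rows[(rows.lesion_id == "L0") & (rows.observer == "PhD")].index)
        with pytest.raises(ValueError):
            augment_multiobserver(rows)


def brute_force_auc(scores, y_bin):
    """Concordant-pair oracle (ties count half)."""
    pos = [s for s, t in zip(scores, y_bin) if t == 1]
    neg = [s for s, t in zip(scores, y_bin) if t == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestComputeMetrics:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array(["dHGP", "dHGP", "rHGP", "rHGP"])
        m = compute_metrics(scores, labels)
        assert m["auc"] == 1.0 and m["accuracy"] == 1.0
        assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(4000)
        labels = np.where(rng.random(4000) < 0.5, "dHGP", "rHGP")
        assert compute_metrics(scores, labels)["auc"] == pytest.approx(0.5, abs=0.03)

    def test_auc_matches_pair_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            scores = rng.integers(0, 5, size=10) / 4.0  # force some ties
            y = rng.integers(0, 2, size=10)
            if len(np.unique(y)) < 2:
                continue
            m = compute_metrics(scores, y)
            assert m["auc"] == pytest.approx(brute_force_auc(scores, y), abs=1e-10)

    def test_degenerate_labels_nan_auc(self):
        m = compute_metrics(np.array([0.2, 0.8]), np.array(["dHGP", "dHGP"]))
        assert np.isnan(m["auc"])
        assert m["sensitivity"] == 0.5


class TestCorrectedResampledCI:
    def test_matches_independent_formula(self):
        rng = np.random.default_rng(2)
        vals = rng.random(100)
        n_train, n_test = 61.0, 15.0
        mean, lo, hi = corrected_resampled_ci(vals, n_train, n_test)
        k = len(vals)
        s = float(np.std(vals, ddof=1))
        t = sps.t.ppf(0.975, k - 1)
        half = t * s * np.sqrt(1 / k + n_test / n_train)
        assert mean == pytest.approx(float(np.mean(vals)), abs=1e-12)
        assert hi - mean == pytest.approx(half, abs=1e-12)
        assert mean - lo == pytest.approx(half, abs=1e-12)

    def test_half_width_ratio_sqrt26(self):
        # k=100, n_test/n_train=0.25: corrected/naive = sqrt(26) ~ 5.0990
        rng = np.random.default_rng(3)
        vals = rng.random(100)
        mean, lo, hi = corrected_resampled_ci(vals, n_train=80, n_test=20)
        k = 100
        naive_half = sps.t.ppf(0.975, k - 1) * np.std(vals, ddof=1) / np.sqrt(k)
        assert (hi - mean) / naive_half == pytest.approx(np.sqrt(26.0), abs=1e-9)

    def test_equal_values_zero_width(self):
        mean, lo, hi = corrected_resampled_ci([0.7] * 10, 80, 20)
        assert mean == lo == hi == 0.7

    def test_corrected_wider_than_naive(self):
        rng = np.random.default_rng(4)
        vals = rng.random(30)
        mean, lo, hi = corrected_resampled_ci(vals, 80, 20)
        naive_half = sps.t.ppf(0.975, 29) * np.std(vals, ddof=1) / np.sqrt(30)
        assert (hi - mean) > naive_half

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            corrected_resampled_ci([0.5], 80, 20)


class TestRocBand:
    def _curves(self, n=20, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        curves = []
        for _ in range(n):
            fpr = np.linspace(0, 1, 25)
            tpr = np.clip(np.sqrt(fpr) + jitter * rng.normal(size=25), 0, 1)
            tpr = np.maximum.accumulate(tpr)
            curves.append((fpr, tpr))
        return curves

    def test_identical_curves_zero_width(self):
        band = roc_band(self._curves(jitter=0.0))
        assert band["half_width"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_band_contains_level_fraction(self):
        curves = self._curves(n=40, jitter=0.05, seed=5)
        band = roc_band(curves, level=0.95)
        grid = band["fpr"].to_numpy()
        inside = 0
        for fpr, tpr in curves:
            interp = np.interp(grid, fpr, tpr)
            lo = band["tpr_mean"].to_numpy() - band["half_width"].iloc[0]
            hi = band["tpr_mean"].to_numpy() + band["half_width"].iloc[0]
            if ((interp >= lo - 1e-12) & (interp <= hi + 1e-12)).all():
                inside += 1
        assert inside >= 0.95 * len(curves)

    def test_monotone_mean_from_monotone_inputs(self):
        band = roc_band(self._curves(n=15, jitter=0.03, seed=6))
        assert (np.diff(band["tpr_mean"].to_numpy()) >= -1e-12).all()


class TestUnivariateStats:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([[24, 13], [20, 19]], 0.23),  # sex by class
            ([[18, 19], [17, 22]], 0.66),  # nodal status
            ([[17, 20], [20, 19]], 0.64),  # disease-free interval
            ([[25, 12], [29, 10]], 0.51),  # number of lesions
            ([[30, 6], [30, 8]], 0.63),  # largest-lesion size
        ],
    )
    def test_chi_square_reference_tables(self, counts, expected):
        _, p = chi_square_2xk(np.array(counts).T)
        assert round(p, 2) == expected

    def test_chi_square_identical_distributions(self):
        stat, p = chi_square_2xk([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_mann_whitney_identical_groups(self):
        x = np.arange(200.0)
        _, p = mann_whitney(x, x)
        assert p > 0.9

    def test_mann_whitney_exact_enumeration_3v3(self):
        a, b = [1.0, 4.0, 6.0], [2.0, 3.0, 5.0]
        _, p = mann_whitney(a, b)
        # enumerate all 20 assignments of 6 values into two groups of 3
        values = sorted(a + b)
        u_obs = sum(1 for x in a for y in b if x > y)
        us = []
        for combo in itertools.combinations(range(6), 3):
            ga = [values[i] for i in combo]
            gb = [values[i] for i in range(6) if i not in combo]
            us.append(sum(1 for x in ga for y in gb if x > y))
        u_max = max(u_obs, 9 - u_obs)
        p_exact = sum(1 for u in us if max(u, 9 - u) >= u_max) / len(us)
        assert p == pytest.approx(p_exact, abs=1e-12)

    def test_mann_whitney_shift_detected(self):
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(20):
            a = rng.normal(0, 1, 200)
            b = rng.normal(1, 1, 200)
            _, p = mann_whitney(a, b)
            rejections += p < 0.001
        assert rejections == 20

    def test_bonferroni(self):
        np.testing.assert_allclose(bonferroni([0.001], m=564), [0.564])
        np.testing.assert_allclose(bonferroni([0.01], m=564), [1.0])
        np.testing.assert_allclose(bonferroni([0.03, 0.2], m=1), [0.03, 0.2])


class TestExperimentDesign:
    def test_multi_defaults(self):
        d = ExperimentDesign(name="multi")
        assert d.train_observers == ("STUD2", "PhD", "RAD")
        assert d.test_observer == "CNN"

    def test_single_requires_same_observer(self):
        d = single_observer_design("RAD")
        assert d.train_observers == ("RAD",) and d.test_observer == "RAD"
        with pytest.raises(ValueError):
            ExperimentDesign(
                name="bad", mode="single", train_observers=("RAD",), test_observer="CNN"
            )

    def test_invalid_options_rejected(self):
        with pytest.raises(ValueError):
            ExperimentDesign(name="x", roi_kind="blob")
        with pytest.raises(ValueError):
            ExperimentDesign(name="x", robustness_option="icc>0.5")


def _fake_feature_table(n_patients=20, n_feats=10, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        label = "dHGP" if i % 2 == 0 else "rHGP"
        for obs in ("STUD2", "PhD", "RAD", "CNN"):
            rows.append(
                {
                    "patient_id": f"P{i:02d}",
                    "lesion_id": f"P{i:02d}_L0",
                    "observer": obs,
                    "roi_kind": "lesion",
                    "label": label,
                    "manufacturer": "S" if i % 3 else "T",
                    "slice_thickness": 3.0,
                    **{f"feat{k}": rng.normal() for k in range(n_feats)},
                }
            )
    return pd.DataFrame(rows)


class TestRunExperiment:
    def test_leakage_sentinel(self):
        """Corrupting one test row must not change other rows' predictions."""
        import warnings

        from hgpradiomics.evaluation_stats import SearchSettings, run_experiment

        warnings.filterwarnings("ignore", category=UserWarning)
        table = _fake_feature_table()
        plan = make_splits(table, n_iterations=2, seed=4)
        settings = SearchSettings(n_candidates=6, ensemble_k=2)
        res1 = run_experiment(table, ExperimentDesign(name="multi"), plan, settings, seed=1)

        _, test_pids = plan.iterations[0]
        victim = f"{test_pids[0]}_L0"
        corrupted = table.copy()
        sel = (corrupted["lesion_id"] == victim) & (corrupted["observer"] == "CNN")
        feat_cols = [c for c in table.columns if c.startswith("feat")]
        corrupted.loc[sel, feat_cols] = 1e6
        res2 = run_experiment(corrupted, ExperimentDesign(name="multi"), plan, settings, seed=1)

        p1 = res1.predictions[0].set_index("lesion_id")["proba"].drop(victim)
        p2 = res2.predictions[0].set_index("lesion_id")["proba"].drop(victim)
        pd.testing.assert_series_equal(p1, p2)

    def test_summary_structure(self):
        import warnings

        from hgpradiomics.evaluation_stats import SearchSettings, run_experiment

        warnings.filterwarnings("ignore", category=UserWarning)
        table = _fake_feature_table()
        plan = make_splits(table, n_iterations=2, seed=0)
        res = run_experiment(
            table, single_observer_design("CNN"), plan,
            SearchSettings(n_candidates=5, ensemble_k=1), seed=0,
        )
        assert list(res.summary["metric"]) == ["auc", "accuracy", "sensitivity", "specificity"]
        assert (res.summary["ci_lo"] <= res.summary["mean"]).all()
        assert (res.summary["mean"] <= res.summary["ci_hi"]).all()
        assert len(res.per_iteration) == 2


class TestUnivariateTables:
    def test_clinical_table_tests_and_pvalues(self):
        from hgpradiomics.evaluation_stats import univariate_clinical_table

        rng = np.random.default_rng(0)
        n = 60
        meta = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "label": ["dHGP"] * 30 + ["rHGP"] * 30,
                "clinical_age": rng.normal(68, 9, n),
                "clinical_sex": rng.choice(["M", "F"], n),
            }
        )
        table = univariate_clinical_table(meta)
        assert set(table["covariate"]) == {"clinical_age", "clinical_sex"}
        tests = table.set_index("covariate")["test"]
        assert tests["clinical_age"] == "mann-whitney"
        assert tests["clinical_sex"] == "chi-square"
        assert ((table["p_value"] >= 0) & (table["p_value"] <= 1)).all()

    def test_feature_stats_bonferroni_and_signal(self):
        from hgpradiomics.evaluation_stats import univariate_feature_stats

        table = _fake_feature_table(n_patients=40, n_feats=5, seed=3)
        # inject a strong class difference into feat0 for the CNN rows
        cnn = table["observer"] == "CNN"
        table.loc[cnn & (table["label"] == "dHGP"), "feat0"] += 10.0
        stats = univariate_feature_stats(table)
        assert len(stats) == 5
        by_feat = stats.set_index("feature")
        assert by_feat.loc["feat0", "p_adjusted"] < 0.01
        assert (stats["p_adjusted"] >= stats["p_value"] - 1e-15).all()
        assert (stats["p_adjusted"] <= 1.0).all()
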