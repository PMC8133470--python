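"""Classification protocol: splits, ensembles, regimes, controls."""

import numpy as np
import pandas as pd
import pytest

from gazexpert.features import FEATURE_NAMES
from gazexpert.modeling import (
    feature_importance,
    most_frequent_features,
    participant_wise_split,
    relabel_control,
    run_experiment,
    sample_wise_split,
    significance_screen,
    train_ensemble,
)


def toy_matrix(n_participants=10, trials=6, shift_features=("pursuit_dispersion_px_avg",),
               shift=3.0, seed=0, labels=("expert", "intermediate", "novice")):
    """Synthetic feature table: Gaussian noise plus class shifts on chosen columns."""
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for ci, lab in enumerate(labels):
        for _ in range(n_participants):
            pid += 1
            for t in range(trials):
                feats = dict(zip(FEATURE_NAMES, rng.normal(size=46)))
                for f in shift_features:
                    feats[f] += ci * shift
                rows.append({"participant_id": f"P{pid:02d}", "class_label": lab,
                             "trial_id": f"P{pid:02d}_T{t}", **feats})
    return pd.DataFrame(rows)


class TestSplits:
    def test_participant_counts_and_idle(self):
        m = toy_matrix()
        counts = {"expert": 12, "intermediate": 10, "novice": 13}
        rows = []
        pid = 0
        rng = np.random.default_rng(0)
        for lab, c in counts.items():
            for _ in range(c):
                pid += 1
                rows.append({"participant_id": f"P{pid}", "class_label": lab,
                             "trial_id": f"P{pid}_T0",
                             **dict(zip(FEATURE_NAMES, np.zeros(46)))})
        m = pd.DataFrame(rows)
        plan = participant_wise_split(m, 8, 2, rng)
        assert all(len(v) == 8 for v in plan.train.values())
        assert all(len(v) == 2 for v in plan.eval_.values())
        used = set(plan.train_ids) | set(plan.eval_ids)
        idle = set(m["participant_id"]) - used
        idle_by_class = {
            lab: len({p for p in idle if m.loc[m.participant_id == p, "class_label"].iloc[0] == lab})
            for lab in counts
        }
        assert idle_by_class == {"expert": 2, "intermediate": 0, "novice": 3}

    def test_no_overlap_ever(self):
        m = toy_matrix()
        for seed in range(20):
            plan = participant_wise_split(m, 7, 2, np.random.default_rng(seed))
            assert not set(plan.train_ids) & set(plan.eval_ids)

    def test_deterministic_given_seed(self):
        m = toy_matrix()
        p1 = participant_wise_split(m, 7, 2, np.random.default_rng(5))
        p2 = participant_wise_split(m, 7, 2, np.random.default_rng(5))
        assert p1.train == p2.train and p1.eval_ == p2.eval_

    def test_insufficient_participants_rejected(self):
        m = toy_matrix(n_participants=4)
        with pytest.raises(ValueError):
            participant_wise_split(m, 8, 2, np.random.default_rng(0))

    def test_sample_wise_masks_partition_rows(self):
        m = toy_matrix()
        tr, ev = sample_wise_split(m, 8, 2, np.random.default_rng(0))
        assert tr.sum() + ev.sum() == len(m)
        assert not np.any(tr & ev)


class TestEnsemble:
    def test_separable_two_feature_toy_perfect(self):
        rng = np.random.default_rng(1)
        centers = {"expert": (0, 0), "intermediate": (8, 0), "novice": (0, 8)}
        rows = []
        for lab, (cx, cy) in centers.items():
            for p in range(9):
                for t in range(6):
                    rows.append({"participant_id": f"{lab[:3]}{p}", "class_label": lab,
                                 "f1": cx + rng.normal(), "f2": cy + rng.normal()})
        m = pd.DataFrame(rows)
        plan = participant_wise_split(m, 7, 2, np.random.default_rng(1))
        train = m[m.participant_id.isin(plan.train_ids)]
        ev = m[m.participant_id.isin(plan.eval_ids)]
        model = train_ensemble(train[["f1", "f2"]], train["class_label"].to_numpy(),
                               k=10, seed=0)
        assert (model.predict(ev[["f1", "f2"]]) == ev["class_label"]).mean() == 1.0

    def test_k1_reduces_to_single_fit(self):
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        m = toy_matrix(shift=2.0)
        X = m[FEATURE_NAMES]
        y = m["class_label"].to_numpy()
        model = train_ensemble(X, y, k=1, seed=0)
        direct = Pipeline([("s", StandardScaler()),
                           ("m", SVC(kernel="linear", C=1.0))]).fit(X.to_numpy(), y)
        assert np.array_equal(model.predict(X), direct.predict(X.to_numpy()))

    def test_single_class_rejected(self):
        m = toy_matrix(labels=("expert",))
        with pytest.raises(ValueError):
            train_ensemble(m[FEATURE_NAMES], m["class_label"].to_numpy(), k=5)

    def test_every_fold_keeps_all_classes(self):
        m = toy_matrix(n_participants=4, trials=3)
        model = train_ensemble(m[FEATURE_NAMES], m["class_label"].to_numpy(), k=50)
        assert model.k <= 12  # clamped to the smallest class count
        for sub in model.models:
            assert len(sub.named_steps["svc"].classes_) == 3


class TestImportance:
    def test_informative_feature_ranked_first(self):
        m = toy_matrix(shift=5.0, shift_features=("saccade_duration_ms_std",))
        model = train_ensemble(m[FEATURE_NAMES], m["class_label"].to_numpy(), k=5)
        ranking = feature_importance(model)
        assert ranking[0][0] == "saccade_duration_ms_std"

    def test_ranking_is_complete_permutation(self):
        m = toy_matrix(shift=0.0)
        model = train_ensemble(m[FEATURE_NAMES], m["class_label"].to_numpy(), k=5)
        names = [n for n, _ in feature_importance(model)]
        assert sorted(names) == sorted(FEATURE_NAMES)

    def test_duplicated_columns_tie_break_by_name(self):
        m = toy_matrix(shift=4.0, shift_features=("fixation_duration_ms_avg",))
        m["fixation_duration_ms_max"] = m["fixation_duration_ms_avg"]
        model = train_ensemble(m[FEATURE_NAMES], m["class_label"].to_numpy(), k=5)
        ranking = feature_importance(model)
        dup = [n for n, _ in ranking if n.startswith("fixation_duration_ms_")][:2]
        assert dup == sorted(dup)


class TestSignificanceScreen:
    def test_null_keeps_roughly_alpha_fraction(self):
        rng = np.random.default_rng(0)
        n = 300
        extra = [f"noise_{i}" for i in range(400)]
        df = pd.DataFrame(rng.normal(size=(2 * n, 400)), columns=extra)
        df["class_label"] = ["a"] * n + ["b"] * n
        kept, table = significance_screen(df, alpha=0.011, features=extra)
        frac = len(kept) / len(extra)
        assert frac < 0.04  # type-I calibration: ~alpha, generously bounded
        assert (table["p_value"] >= 0).all() and (table["p_value"] <= 1).all()

    def test_shifted_feature_kept(self):
        rng = np.random.default_rng(1)
        n = 200
        df = pd.DataFrame({
            "shifted": np.concatenate([rng.normal(0, 1, n), rng.normal(3, 1, n)]),
            "flat": rng.normal(size=2 * n),
            "class_label": ["a"] * n + ["b"] * n,
        })
        kept, _ = significance_screen(df, alpha=0.011, features=["shifted", "flat"])
        assert "shifted" in kept

    def test_weak_difference_not_kept(self):
        # overlapping samples with p on the 0.2 scale stay out at alpha=0.011
        rng = np.random.default_rng(2)
        a = rng.normal(0.0, 1.0, 40)
        b = rng.normal(0.3, 1.0, 40)
        from scipy.stats import mannwhitneyu

        p = mannwhitneyu(a, b, alternative="two-sided").pvalue
        assert p > 0.011
        df = pd.DataFrame({"weak": np.concatenate([a, b]),
                           "class_label": ["a"] * 40 + ["b"] * 40})
        kept, _ = significance_screen(df, alpha=0.011, features=["weak"])
        assert kept == []

    def test_constant_feature_gets_p_one(self):
        df = pd.DataFrame({"const": np.ones(40),
                           "class_label": ["a"] * 20 + ["b"] * 20})
        kept, table = significance_screen(df, features=["const"])
        assert table.loc[0, "p_value"] == 1.0 and kept == []


class TestRunExperiment:
    def test_deterministic_given_master_seed(self):
        m = toy_matrix(shift=2.0)
        r1 = run_experiment(m, "ALL", n_runs=2, seed=3, k=5, n_train=7, n_eval=2)
        r2 = run_experiment(m, "ALL", n_runs=2, seed=3, k=5, n_train=7, n_eval=2)
        assert [r.accuracy for r in r1] == [r.accuracy for r in r2]
        assert [r.seed for r in r1] == [r.seed for r in r2]

    def test_sf_regime_restricts_features(self):
        m = toy_matrix(shift=5.0, shift_features=("pursuit_dispersion_px_avg",
                                                  "pursuit_dispersion_px_max"))
        res = run_experiment(m, "SF", n_runs=1, seed=0, k=5, n_train=7, n_eval=2)
        assert set(res[0].selected_features) < set(FEATURE_NAMES)
        assert "pursuit_dispersion_px_avg" in res[0].selected_features

    def test_mff_requires_subset(self):
        m = toy_matrix()
        with pytest.raises(ValueError):
            run_experiment(m, "MFF", n_runs=1, seed=0, k=5)

    def test_mff_uses_given_subset(self):
        m = toy_matrix(shift=4.0)
        subset = ["pursuit_dispersion_px_avg", "fixation_duration_ms_avg"]
        res = run_experiment(m, "MFF", n_runs=1, seed=0, k=5, n_train=7, n_eval=2,
                             feature_subset=subset)
        assert list(res[0].selected_features) == subset


class TestMostFrequentFeatures:
    def test_single_run_returns_its_top_m(self):
        m = toy_matrix(shift=4.0)
        res = run_experiment(m, "ALL", n_runs=1, seed=0, k=5, n_train=7, n_eval=2)
        assert most_frequent_features(res, top_m=7) == list(res[0].importance[:7])

    def test_dominant_separation_dominates_selection(self):
        m = toy_matrix(shift=6.0, shift_features=("pursuit_dispersion_px_avg",
                                                  "pursuit_dispersion_px_min",
                                                  "pursuit_dispersion_px_max"))
        res = run_experiment(m, "ALL", n_runs=5, seed=1, k=5, n_train=7, n_eval=2)
        mff = most_frequent_features(res, top_m=3)
        assert set(mff) == {"pursuit_dispersion_px_avg", "pursuit_dispersion_px_min",
                            "pursuit_dispersion_px_max"}


class TestRelabelControl:
    def test_deterministic_single_iteration(self):
        m = toy_matrix(labels=("expert",), n_participants=12)
        a1 = relabel_control(m, n_iter=1, seed=4)
        a2 = relabel_control(m, n_iter=1, seed=4)
        assert np.array_equal(a1, a2)

    def test_too_few_experts_rejected(self):
        m = toy_matrix(labels=("expert",), n_participants=1)
        with pytest.raises(ValueError):
            relabel_control(m, n_iter=1, seed=0)
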