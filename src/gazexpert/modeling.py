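"""Expertise classification protocol: participant-wise resampled SVM ensembles.

A single evaluation run draws a participant-wise split (all trials of a
participant land on exactly one side — gaze is idiosyncratic, so sample-wise
splitting lets a classifier identify *people* rather than expertise), trains
a k-fold ensemble of linear maximum-margin classifiers on the training side,
and scores the held-out participants' trials.  The experiment repeats this
over many runs with fresh random splits; three feature regimes are
supported: ALL (every feature), SF (features passing a rank-sum significance
screen), and MFF (the features most frequently ranked important across
runs).  A sample-wise splitter is included solely to demonstrate the
identity-leakage inflation that participant-wise assignment prevents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kruskal, mannwhitneyu
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .evaluation import confusion_and_metrics
from .features import FEATURE_NAMES

REGIMES = ("ALL", "SF", "MFF")
DEFAULT_ALPHA = 0.011
DEFAULT_TOP_M = 7


@dataclass
class SplitPlan:
    """Participant assignment for one run; train and eval never overlap."""

    run_index: int
    train: dict
    eval_: dict
    seed: int

    @property
    def train_ids(self):
        return sorted(pid for ids in self.train.values() for pid in ids)

    @property
    def eval_ids(self):
        return sorted(pid for ids in self.eval_.values() for pid in ids)


@dataclass
class EnsembleModel:
    models: list
    classes_: np.ndarray
    feature_names: list
    k: int
    combine: str = "score"
    fold_accuracies: list = field(default_factory=list)

    def _matrix(self, X):
        if isinstance(X, pd.DataFrame):
            return X[self.feature_names].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def decision_scores(self, X) -> np.ndarray:
        """Averaged per-class scores across the k fold models."""
        Xm = self._matrix(X)
        total = np.zeros((Xm.shape[0], len(self.classes_)))
        for m in self.models:
            d = m.decision_function(Xm)
            if d.ndim == 1:  # binary: score is w.r.t. classes_[1]
                d = np.column_stack([-d, d])
            total += d
        return total / len(self.models)

    def predict(self, X) -> np.ndarray:
        if self.combine == "vote":
            Xm = self._matrix(X)
            votes = np.stack([m.predict(Xm) for m in self.models])
            out = []
            for col in votes.T:
                vals, counts = np.unique(col, return_counts=True)
                out.append(vals[np.argmax(counts)])
            return np.asarray(out)
        return self.classes_[np.argmax(self.decision_scores(X), axis=1)]


@dataclass
class RunResult:
    run_index: int
    regime: str
    labels: tuple
    confusion: np.ndarray
    accuracy: float
    miss_rates: dict
    recalls: dict
    importance: tuple          # full feature ranking, most important first
    selected_features: tuple
    n_eval: int
    seed: int


def participant_wise_split(matrix: pd.DataFrame, n_train: int = 8, n_eval: int = 2,
                           rng: np.random.Generator | None = None,
                           run_index: int = 0) -> SplitPlan:
    """Randomly assign whole participants to train/eval, per class.

    Every trial of a participant lands on exactly one side; participants
    beyond ``n_train + n_eval`` per class sit the run out.
    """
    rng = rng or np.random.default_rng()
    train, eval_ = {}, {}
    for label, group in matrix.groupby("class_label"):
        pids = sorted(group["participant_id"].unique())
        need = n_train + n_eval
        if len(pids) < need:
            raise ValueError(
                f"class {label!r} has {len(pids)} participants, needs {need}"
            )
        picked = rng.choice(pids, size=need, replace=False)
        train[label] = sorted(picked[:n_train])
        eval_[label] = sorted(picked[n_train:])
    plan = SplitPlan(run_index, train, eval_, seed=0)
    assert not set(plan.train_ids) & set(plan.eval_ids)
    return plan


def sample_wise_split(matrix: pd.DataFrame, n_train: int = 8, n_eval: int = 2,
                      rng: np.random.Generator | None = None):
    """Random *row* assignment ignoring participants (leakage demonstration).

    Returns boolean masks (train, eval) with per-class training fractions
    matching the participant-wise protocol.
    """
    rng = rng or np.random.default_rng()
    frac = n_train / (n_train + n_eval)
    train_mask = np.zeros(len(matrix), dtype=bool)
    for _, group in matrix.groupby("class_label"):
        idx = group.index.to_numpy()
        take = rng.permutation(idx)[: int(round(frac * idx.size))]
        train_mask[matrix.index.get_indexer(take)] = True
    return train_mask, ~train_mask


def train_ensemble(X, y, k: int = 50, C: float = 1.0, seed: int = 0,
                   combine: str = "score", kernel: str = "linear") -> EnsembleModel:
    """k-fold ensemble of standardized linear SVMs.

    Model i trains on the out-of-fold data of fold i and records its in-fold
    accuracy; standardization statistics come from each model's own training
    rows only.  ``k`` is clamped so stratification keeps every class in every
    fold; ``k = 1`` reduces to a single direct fit.
    """
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"f{i}" for i in range(np.asarray(X).shape[1])
    ]
    Xm = X[feature_names].to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain at least two classes")
    if Xm.shape[0] < 2:
        raise ValueError(f"need at least 2 rows, got {Xm.shape[0]}")

    def _svm(rs):
        return Pipeline([
            ("scale", StandardScaler()),
            ("svc", SVC(kernel=kernel, C=C, decision_function_shape="ovr",
                        random_state=rs)),
        ])

    min_count = int(np.bincount(pd.factorize(y)[0]).min())
    k_eff = max(1, min(k, min_count))
    if k_eff == 1:
        model = _svm(seed).fit(Xm, y)
        return EnsembleModel([model], classes, feature_names, 1, combine,
                             [float(model.score(Xm, y))])
    folds = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    models, accs = [], []
    for i, (out_of_fold, in_fold) in enumerate(folds.split(Xm, y)):
        m = _svm(seed + i).fit(Xm[out_of_fold], y[out_of_fold])
        accs.append(float(m.score(Xm[in_fold], y[in_fold])))
        models.append(m)
    return EnsembleModel(models, classes, feature_names, k_eff, combine, accs)


def feature_importance(model: EnsembleModel, X=None, y=None):
    """Features ranked by mean |weight| across fold models (linear kernel).

    Ties break by canonical name order.  For non-linear kernels a permutation
    fallback is used and requires scoring data.
    """
    svc0 = model.models[0].named_steps["svc"]
    if svc0.kernel == "linear":
        weights = np.mean(
            [np.abs(m.named_steps["svc"].coef_).mean(axis=0) for m in model.models],
            axis=0,
        )
    else:
        if X is None or y is None:
            raise ValueError("permutation importance needs X and y for non-linear kernels")
        Xm = model._matrix(X)
        y = np.asarray(y)
        rng = np.random.default_rng(0)
        base = float((model.predict(Xm) == y).mean())
        weights = np.empty(Xm.shape[1])
        for j in range(Xm.shape[1]):
            Xp = Xm.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            weights[j] = base - float((model.predict(Xp) == y).mean())
    order = sorted(
        range(len(model.feature_names)),
        key=lambda j: (-weights[j], model.feature_names[j]),
    )
    return [(model.feature_names[j], float(weights[j])) for j in order]


def evaluate_leave_out(model: EnsembleModel, eval_rows: pd.DataFrame,
                       labels=None, run_index: int = 0, regime: str = "ALL",
                       seed: int = 0) -> RunResult:
    """Score held-out rows the model has never seen; fill confusion metrics."""
    if len(eval_rows) == 0:
        raise ValueError("evaluation set is empty")
    labels = list(labels) if labels is not None else sorted(eval_rows["class_label"].unique())
    y_true = eval_rows["class_label"].to_numpy()
    y_pred = model.predict(eval_rows)
    cm, acc, miss, rec = confusion_and_metrics(y_true, y_pred, labels)
    ranking = tuple(name for name, _ in feature_importance(model))
    return RunResult(
        run_index=run_index, regime=regime, labels=tuple(labels), confusion=cm,
        accuracy=acc, miss_rates=miss, recalls=rec, importance=ranking,
        selected_features=tuple(model.feature_names), n_eval=len(eval_rows),
        seed=seed,
    )


def significance_screen(matrix: pd.DataFrame, alpha: float = DEFAULT_ALPHA,
                        method: str = "pairwise_min", features=None):
    """Features whose class differences pass a rank-sum screen at ``alpha``.

    Per feature, two-sided Mann-Whitney-U tests run between every class pair
    and the feature's p-value is the minimum over pairs (``method="kruskal"``
    swaps in the omnibus Kruskal-Wallis test).  Constant features get p = 1.
    Returns ``(kept_names, p_table)``.
    """
    features = list(features) if features is not None else FEATURE_NAMES
    groups = {lab: g for lab, g in matrix.groupby("class_label")}
    labels = sorted(groups)
    if len(labels) < 2:
        raise ValueError("need at least two classes to screen features")
    rows = []
    for feat in features:
        samples = [groups[lab][feat].dropna().to_numpy() for lab in labels]
        pooled = np.concatenate(samples)
        if np.all(pooled == pooled[0]):
            p = 1.0
        elif method == "kruskal":
            p = float(kruskal(*samples).pvalue)
        else:
            p = min(
                float(mannwhitneyu(samples[i], samples[j],
                                   alternative="two-sided").pvalue)
                for i in range(len(samples))
                for j in range(i + 1, len(samples))
            )
        rows.append((feat, p, p < alpha))
    table = pd.DataFrame(rows, columns=["feature", "p_value", "kept"])
    kept = table.loc[table["kept"], "feature"].tolist()
    return kept, table


def most_frequent_features(results, top_m: int = DEFAULT_TOP_M):
    """The ``top_m`` features appearing most often in per-run top-m rankings.

    Ties break by total rank score (lower is more important), then by name.
    """
    counts: dict = {}
    rank_sum: dict = {}
    for res in results:
        for rank, name in enumerate(res.importance[:top_m]):
            counts[name] = counts.get(name, 0) + 1
            rank_sum[name] = rank_sum.get(name, 0) + rank
    ordered = sorted(counts, key=lambda n: (-counts[n], rank_sum[n], n))
    return ordered[:top_m]


def run_experiment(matrix: pd.DataFrame, regime: str = "ALL", n_runs: int = 1000,
                   seed: int = 0, k: int = 50, n_train: int = 8, n_eval: int = 2,
                   C: float = 1.0, feature_subset=None, alpha: float = DEFAULT_ALPHA,
                   assignment: str = "participant"):
    """Resampled evaluation: fresh split, ensemble and leave-out score per run.

    Per-run seeds derive deterministically from the master seed.  ``regime``
    picks the feature set: ``ALL`` uses every feature, ``SF`` re-screens
    significant features on each run's training side, ``MFF`` requires an
    explicit ``feature_subset`` (see :func:`most_frequent_features`).
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}")
    if regime == "MFF" and not feature_subset:
        raise ValueError("MFF regime requires a feature_subset")
    labels = sorted(matrix["class_label"].unique())
    children = np.random.SeedSequence(seed).spawn(n_runs)
    results = []
    for run_idx, child in enumerate(children):
        rng = np.random.default_rng(child)
        run_seed = int(rng.integers(0, 2**31 - 1))
        if assignment == "participant":
            plan = participant_wise_split(matrix, n_train, n_eval, rng, run_idx)
            train_rows = matrix[matrix["participant_id"].isin(plan.train_ids)]
            eval_rows = matrix[matrix["participant_id"].isin(plan.eval_ids)]
            assert not set(train_rows["participant_id"]) & set(eval_rows["participant_id"])
        elif assignment == "sample":
            tr_mask, ev_mask = sample_wise_split(matrix, n_train, n_eval, rng)
            train_rows, eval_rows = matrix[tr_mask], matrix[ev_mask]
        else:
            raise ValueError(f"unknown assignment {assignment!r}")
        if regime == "ALL":
            feats = list(FEATURE_NAMES)
        elif regime == "SF":
            feats, _ = significance_screen(train_rows, alpha)
            feats = feats or list(FEATURE_NAMES)
        else:
            feats = list(feature_subset)
        model = train_ensemble(train_rows[feats], train_rows["class_label"].to_numpy(),
                               k=k, C=C, seed=run_seed)
        results.append(
            evaluate_leave_out(model, eval_rows, labels, run_idx, regime, run_seed)
        )
    return results


def select_most_frequent(matrix: pd.DataFrame, n_runs: int = 100, seed: int = 0,
                         k: int = 50, top_m: int = DEFAULT_TOP_M, **kwargs):
    """Pilot ALL-regime runs followed by most-frequent-feature selection."""
    pilot = run_experiment(matrix, "ALL", n_runs=n_runs, seed=seed, k=k, **kwargs)
    return most_frequent_features(pilot, top_m), pilot


def relabel_control(matrix: pd.DataFrame, n_iter: int = 100, seed: int = 0,
                    relabel_participants=None, k: int = 10, n_train: int = 4,
                    n_eval: int = 2, expert_label: str = "expert",
                    relabel_to: str = "intermediate") -> np.ndarray:
    """Half-relabel control: can a model tell experts from 'experts'?

    Each iteration relabels half of the expert participants (a fixed set if
    ``relabel_participants`` is given, otherwise a fresh random half) as
    intermediates, then runs one participant-wise binary classification.
    Chance-level accuracies mean expert gaze is homogeneous — within-class
    variation is smaller than between-class differences.
    """
    experts = matrix[matrix["class_label"] == expert_label].copy()
    pids = sorted(experts["participant_id"].unique())
    if len(pids) < 2:
        raise ValueError("relabel control needs at least two expert participants")
    children = np.random.SeedSequence(seed).spawn(n_iter)
    accuracies = np.empty(n_iter)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        half = (
            list(relabel_participants)
            if relabel_participants is not None
            else list(rng.choice(pids, size=len(pids) // 2, replace=False))
        )
        relabeled = experts.copy()
        relabeled.loc[relabeled["participant_id"].isin(half), "class_label"] = relabel_to
        plan = participant_wise_split(relabeled, n_train, n_eval, rng, i)
        train_rows = relabeled[relabeled["participant_id"].isin(plan.train_ids)]
        eval_rows = relabeled[relabeled["participant_id"].isin(plan.eval_ids)]
        model = train_ensemble(train_rows[FEATURE_NAMES],
                               train_rows["class_label"].to_numpy(),
                               k=k, seed=int(rng.integers(0, 2**31 - 1)))
        accuracies[i] = float((model.predict(eval_rows) == eval_rows["class_label"]).mean())
    return accuracies
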