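"""SVM-RFE feature ranking and incremental-construction SVM evaluation.

Ranking (SVM-RFE)
-----------------
The dataset is split into 10 random folds; each leave-one-fold-out subset
(9 folds, 90% of the rows) trains one recursive-feature-elimination run
with a linear SVM (regularization parameter C fixed at 1): at every step
the feature with the smallest squared weight is eliminated and receives the
worst remaining rank, so the last survivor holds rank 1.  With 10 repeats
of the 10-fold split there are 100 constructions; a feature's final score
is the mean (and sd) of its 100 ranks.

Incremental construction (SVM-IC)
---------------------------------
Features are added one at a time from best to worst mean rank.  For each
top-k set a linear SVM (C = 1) is evaluated by stratified 10-fold
cross-validation; test-fold decision values are pooled over the folds into
one rank-aggregated ROC per k.  Each model is compared against chance (a
seeded Bernoulli(1/2) guesser on the same test rows via McNemar, an exact
binomial test of accuracy vs 0.5, and DeLong AUC vs 0.5) and against the
previous (k-1)-feature model (McNemar on paired correctness, DeLong on
paired scores).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_X_y

from .stats import PairedOutcomes, delong_test, delong_vs_chance, mcnemar_test

__all__ = ["SVMRFERanker", "ICCurve", "ICStep", "rfe_rank", "ic_evaluate"]


def _svm(C: float) -> SVC:
    return SVC(kernel="linear", C=C)


def _rfe_ranking(X: np.ndarray, y: np.ndarray, C: float) -> np.ndarray:
    """One RFE run: rank per feature (1 = last survivor, K = first out)."""
    n_features = X.shape[1]
    surviving = list(range(n_features))
    ranks = np.empty(n_features, dtype=int)
    while len(surviving) > 1:
        clf = _svm(C).fit(X[:, surviving], y)
        w2 = np.ravel(clf.coef_) ** 2
        drop = int(np.argmin(w2))  # ties: lowest index, deterministic
        ranks[surviving[drop]] = len(surviving)
        surviving.pop(drop)
    ranks[surviving[0]] = 1
    return ranks


class SVMRFERanker(BaseEstimator):
    """Linear-SVM recursive-feature-elimination ranking over repeated folds.

    Parameters
    ----------
    C : float
        SVM regularization parameter (fixed to 1 in the reference
        protocol).
    n_folds, n_repeats : int
        Fold count of the random split and number of repeats;
        n_folds * n_repeats model constructions in total.
    random_state : int or None
        Seed; results are deterministic given the seed.

    Attributes
    ----------
    ranks_ : (n_constructions, n_features) int array
        Rank of every feature in every construction (each row is a
        permutation of 1..K).
    mean_rank_, std_rank_ : (n_features,) arrays
    ranking_order_ : (n_features,) int array
        Feature indices sorted best (lowest mean rank) to worst; ties
        broken by feature index.
    """

    def __init__(
        self,
        C: float = 1.0,
        n_folds: int = 10,
        n_repeats: int = 10,
        random_state: int | None = None,
    ):
        self.C = C
        self.n_folds = n_folds
        self.n_repeats = n_repeats
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if len(np.unique(y)) < 2:
            raise ValueError("ranking requires two classes")
        rng = np.random.default_rng(self.random_state)
        all_ranks = []
        for _ in range(self.n_repeats):
            kf = KFold(
                n_splits=self.n_folds,
                shuffle=True,
                random_state=int(rng.integers(2**31 - 1)),
            )
            for train_idx, _test_idx in kf.split(X):
                all_ranks.append(_rfe_ranking(X[train_idx], y[train_idx], self.C))
        self.ranks_ = np.asarray(all_ranks)
        self.mean_rank_ = self.ranks_.mean(axis=0)
        self.std_rank_ = self.ranks_.std(axis=0)
        self.ranking_order_ = np.lexsort(
            (np.arange(X.shape[1]), self.mean_rank_)
        )
        self.n_features_in_ = X.shape[1]
        return self

    def summary(self, feature_names: list[str] | None = None) -> pd.DataFrame:
        names = (
            list(feature_names)
            if feature_names is not None
            else [f"f{i}" for i in range(self.n_features_in_)]
        )
        df = pd.DataFrame(
            {
                "feature": names,
                "mean_rank": self.mean_rank_,
                "std_rank": self.std_rank_,
            }
        ).sort_values("mean_rank", kind="stable")
        return df.reset_index(drop=True)


def rfe_rank(
    table: pd.DataFrame,
    feature_names: list[str],
    C: float = 1.0,
    n_folds: int = 10,
    n_repeats: int = 10,
    seed: int | None = None,
) -> SVMRFERanker:
    """Rank the feature columns of a FeatureTable; thin estimator wrapper."""
    ranker = SVMRFERanker(
        C=C, n_folds=n_folds, n_repeats=n_repeats, random_state=seed
    )
    return ranker.fit(table[feature_names].to_numpy(), table["label"].to_numpy())


@dataclass
class ICStep:
    """Cross-validated results of the top-k-feature SVM."""

    k: int
    features: list[int]
    fold_accuracies: np.ndarray
    scores: np.ndarray  # pooled test decision values, original row order
    correct: np.ndarray  # pooled test correctness
    accuracy: float  # pooled over all test predictions
    accuracy_fold_mean: float
    auroc: float
    p_mcnemar_chance: float
    p_binomial_chance: float
    p_delong_chance: float
    p_mcnemar_prev: float | None = None
    p_delong_prev: float | None = None


@dataclass
class ICCurve:
    steps: list[ICStep] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "k": s.k,
                    "accuracy": s.accuracy,
                    "accuracy_fold_mean": s.accuracy_fold_mean,
                    "auroc": s.auroc,
                    "p_mcnemar_chance": s.p_mcnemar_chance,
                    "p_binomial_chance": s.p_binomial_chance,
                    "p_delong_chance": s.p_delong_chance,
                    "p_mcnemar_prev": s.p_mcnemar_prev,
                    "p_delong_prev": s.p_delong_prev,
                }
                for s in self.steps
            ]
        )


def ic_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    ranking_order: np.ndarray,
    n_folds: int = 10,
    C: float = 1.0,
    seed: int | None = None,
    max_k: int | None = None,
) -> ICCurve:
    """Incremental-construction evaluation over nested top-k feature sets.

    One stratified fold partition is drawn and reused for every k, so the
    pooled decision scores of successive models are paired sample-by-sample
    for the DeLong and McNemar comparisons.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    ranking_order = np.asarray(ranking_order)
    if len(ranking_order) != X.shape[1]:
        raise ValueError("ranking must cover all feature columns")
    max_k = max_k or X.shape[1]
    if max_k > X.shape[1]:
        raise ValueError("k exceeds the number of feature columns")

    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(
        n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
    )
    folds = list(skf.split(X, y))
    chance_guess = rng.integers(0, 2, size=len(y))  # Bernoulli(1/2) comparator
    chance_correct = chance_guess == y

    curve = ICCurve()
    prev: ICStep | None = None
    for k in range(1, max_k + 1):
        cols = ranking_order[:k]
        scores = np.empty(len(y))
        pred = np.empty(len(y), dtype=int)
        fold_acc = []
        for train_idx, test_idx in folds:
            clf = _svm(C).fit(X[np.ix_(train_idx, cols)], y[train_idx])
            s = clf.decision_function(X[np.ix_(test_idx, cols)])
            p = (s > 0).astype(int)
            if clf.classes_[1] != 1:  # decision sign follows class order
                s, p = -s, 1 - p
            scores[test_idx] = s
            pred[test_idx] = p
            fold_acc.append(float(np.mean(p == y[test_idx])))
        correct = pred == y
        accuracy = float(correct.mean())
        auc, _, p_dl_chance = delong_vs_chance(scores, y)
        _, p_mc_chance = mcnemar_test(
            PairedOutcomes(correct, chance_correct), mode="exact"
        )
        p_binom = float(sps.binomtest(int(correct.sum()), len(y), 0.5).pvalue)

        step = ICStep(
            k=k,
            features=list(map(int, cols)),
            fold_accuracies=np.asarray(fold_acc),
            scores=scores,
            correct=correct,
            accuracy=accuracy,
            accuracy_fold_mean=float(np.mean(fold_acc)),
            auroc=auc,
            p_mcnemar_chance=p_mc_chance,
            p_binomial_chance=p_binom,
            p_delong_chance=p_dl_chance,
        )
        if prev is not None:
            _, step.p_mcnemar_prev = mcnemar_test(
                PairedOutcomes(step.correct, prev.correct), mode="exact"
            )
            _, _, _, step.p_delong_prev = delong_test(step.scores, prev.scores, y)
        curve.steps.append(step)
        prev = step
    return curve
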