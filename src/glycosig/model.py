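"""Signature-restricted immunotherapy response modelling.

A merged, batch-adjusted expression matrix restricted to signature genes
is split 80/20 (stratified by response, round-half-up), several
classifiers are tuned by stratified 5-fold cross-validation repeated 10
times, and the model with the best validation-set AUC is selected; its
predicted risk groups (NR = high risk) are then compared by Cox
proportional-hazards regression and Kaplan–Meier curves.

Two classifiers are implemented here rather than taken from scikit-learn:

* :class:`KernelNaiveBayes` — naive Bayes with per-class, per-feature
  Gaussian kernel densities (Silverman bandwidth x ``adjust``) when
  ``usekernel`` is on, Gaussian densities otherwise, and Laplace
  smoothing ``fL`` on the class priors;
* :class:`CorrelationCentroid` — a parameter-free nearest-centroid rule
  using Pearson correlation to the class centroids.

The remaining algorithms (kNN, random forest, SVM, AdaBoost trees,
boosted logistic regression as gradient boosting with log loss) are
scikit-learn estimators behind the same interface.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .io import ClinicalRecord, ExpressionMatrix, clinical_frame

__all__ = [
    "SplitPlan",
    "ClassifierConfig",
    "RocResult",
    "SurvivalComparison",
    "KernelNaiveBayes",
    "CorrelationCentroid",
    "make_split",
    "train_select",
    "predict_response",
    "roc_auc",
    "survival_compare",
    "DEFAULT_ALGORITHMS",
]

POSITIVE = "NR"  # the modelled (high-risk) class


# ---------------------------------------------------------------------------
# Split


@dataclass
class SplitPlan:
    train_ids: list[str]
    validation_ids: list[str]
    test_ids: list[str]
    train_frac: float
    seed: int


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def make_split(
    clinical: list[ClinicalRecord] | pd.DataFrame,
    train_frac: float = 0.8,
    seed: int = 0,
    test_cohorts: list[str] | None = None,
) -> SplitPlan:
    """Stratified train/validation split with designated held-out cohorts.

    Samples from ``test_cohorts`` go untouched into the test set; the
    rest are split by response so that the train set has
    round-half-up(train_frac * n) samples, allocated per response class
    by largest remainder.
    """
    df = clinical if isinstance(clinical, pd.DataFrame) else clinical_frame(clinical)
    if (df["response"] == "NA").any():
        raise ValueError("response labels required for every sample in the split")
    test_cohorts = set(test_cohorts or [])
    test_ids = df.loc[df["cohort"].isin(test_cohorts), "sample_id"].tolist()
    pool = df.loc[~df["cohort"].isin(test_cohorts)]
    n = len(pool)
    n_train = _round_half_up(train_frac * n)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    classes = sorted(pool["response"].unique())
    exact = {c: train_frac * (pool["response"] == c).sum() for c in classes}
    alloc = {c: _round_half_up(exact[c]) for c in classes}
    # largest-remainder fixup so per-class allocations sum to n_train
    while sum(alloc.values()) != n_train:
        drift = sum(alloc.values()) - n_train
        frac_part = {c: exact[c] - math.floor(exact[c]) for c in classes}
        order = sorted(classes, key=lambda c: frac_part[c], reverse=drift < 0)
        c = order[0]
        alloc[c] += 1 if drift < 0 else -1
    train_ids: list[str] = []
    val_ids: list[str] = []
    for c in classes:
        ids = pool.loc[pool["response"] == c, "sample_id"].tolist()
        perm = rng.permutation(len(ids))
        k = alloc[c]
        train_ids += [ids[i] for i in perm[:k]]
        val_ids += [ids[i] for i in perm[k:]]
    train_resp = df.loc[train_ids, "response"]
    for c in classes:
        if (train_resp == c).sum() == 0:
            raise ValueError(f"response class {c!r} absent from the training split")
    return SplitPlan(
        train_ids=sorted(train_ids),
        validation_ids=sorted(val_ids),
        test_ids=sorted(test_ids),
        train_frac=train_frac,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Classifiers


class KernelNaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes with per-feature Gaussian or kernel class densities.

    ``usekernel=True`` estimates each class-conditional feature density
    with a Gaussian kernel density estimate using Silverman's
    rule-of-thumb bandwidth multiplied by ``adjust``; ``usekernel=False``
    uses a Gaussian with the class's feature mean and sd. ``fL`` adds
    Laplace smoothing to the class priors: (n_c + fL) / (n + fL * K).
    """

    def __init__(self, usekernel: bool = True, adjust: float = 1.0, fL: float = 0.0):
        self.usekernel = usekernel
        self.adjust = adjust
        self.fL = fL

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        n, self.n_features_in_ = X.shape
        k = len(self.classes_)
        self.log_prior_ = np.log(
            np.array([(np.sum(y == c) + self.fL) for c in self.classes_])
            / (n + self.fL * k)
        )
        self.class_data_ = []
        self.class_stats_ = []
        for c in self.classes_:
            Xc = X[y == c]
            sd = Xc.std(axis=0, ddof=1) if len(Xc) > 1 else np.ones(X.shape[1])
            sd = np.maximum(sd, 1e-9)
            self.class_data_.append(Xc)
            if self.usekernel:
                # Silverman rule of thumb per feature, scaled by adjust
                bw = 0.9 * sd * len(Xc) ** (-0.2) * self.adjust
                self.class_stats_.append(np.maximum(bw, 1e-9))
            else:
                self.class_stats_.append((Xc.mean(axis=0), sd))
        return self

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, dtype=float)
        jll = np.empty((X.shape[0], len(self.classes_)))
        for ci in range(len(self.classes_)):
            if self.usekernel:
                Xc = self.class_data_[ci]
                bw = self.class_stats_[ci]
                # log mean_j N(x | x_j, bw) per feature, summed over features
                ll = np.zeros(X.shape[0])
                for f in range(X.shape[1]):
                    z = (X[:, [f]] - Xc[None, :, f].reshape(1, -1)) / bw[f]
                    logk = -0.5 * z * z - math.log(bw[f] * math.sqrt(2 * math.pi))
                    ll += logsumexp(logk, axis=1) - math.log(Xc.shape[0])
            else:
                mu, sd = self.class_stats_[ci]
                z = (X - mu) / sd
                ll = (-0.5 * z * z - np.log(sd * math.sqrt(2 * math.pi))).sum(axis=1)
            jll[:, ci] = ll + self.log_prior_[ci]
        return jll

    def predict_proba(self, X):
        jll = self._joint_log_likelihood(X)
        jll -= jll.max(axis=1, keepdims=True)
        p = np.exp(jll)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class CorrelationCentroid(BaseEstimator, ClassifierMixin):
    """Parameter-free nearest-centroid classifier with Pearson distance.

    Each class is summarized by its feature centroid; a sample's score
    for a class increases with its Pearson correlation to that centroid.
    predict_proba maps the correlation difference to [0, 1] linearly —
    monotone in the decision value, which is all ROC analysis needs.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("CorrelationCentroid is a two-class rule")
        self.centroids_ = np.vstack([X[y == c].mean(axis=0) for c in self.classes_])
        self.n_features_in_ = X.shape[1]
        return self

    @staticmethod
    def _corr(X, c):
        Xd = X - X.mean(axis=1, keepdims=True)
        cd = c - c.mean()
        denom = np.sqrt((Xd * Xd).sum(axis=1) * float(cd @ cd))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, Xd @ cd / denom, 0.0)
        return r

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        r0 = self._corr(X, self.centroids_[0])
        r1 = self._corr(X, self.centroids_[1])
        p1 = np.clip(0.5 * (1.0 + (r1 - r0) / 2.0), 0.0, 1.0)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]


class SigmoidSVC(BaseEstimator, ClassifierMixin):
    """RBF SVM scored through a logistic map of its decision function.

    The sigmoid is monotone in the margin, so ranking metrics (AUC) are
    those of the raw SVM, and the 0.5 score threshold coincides with the
    SVM decision boundary.
    """

    def __init__(self, C: float = 1.0, gamma: str | float = "scale"):
        self.C = C
        self.gamma = gamma

    def fit(self, X, y):
        self.svc_ = SVC(kernel="rbf", C=self.C, gamma=self.gamma)
        self.svc_.fit(X, y)
        self.classes_ = self.svc_.classes_
        self.n_features_in_ = self.svc_.n_features_in_
        return self

    def predict_proba(self, X):
        d = self.svc_.decision_function(X)  # positive toward classes_[1]
        p1 = 1.0 / (1.0 + np.exp(-d))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return self.svc_.predict(X)


@dataclass
class ClassifierConfig:
    algorithm: str  # nb, knn, rf, svm, logitboost, adaboost, cancerclass
    hyperparameters: dict = field(default_factory=dict)
    cv_folds: int = 5
    cv_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.cv_repeats < 1:
            raise ValueError("cv_repeats must be >= 1")


DEFAULT_ALGORITHMS = ("nb", "knn", "rf", "svm", "logitboost", "adaboost", "cancerclass")

_GRIDS: dict[str, list[dict]] = {
    "nb": [{"usekernel": True, "adjust": 1.0, "fL": 0.0}],
    "knn": [{"n_neighbors": k} for k in (5, 9, 15)],
    "rf": [{"n_estimators": 200, "min_samples_leaf": l} for l in (1, 5)],
    "svm": [{"C": c} for c in (0.1, 1.0, 10.0)],
    "logitboost": [{"n_estimators": n, "max_depth": 1} for n in (50, 100)],
    "adaboost": [{"n_estimators": n} for n in (50, 100)],
    "cancerclass": [{}],
}


def _build(algorithm: str, params: dict, seed: int):
    if algorithm == "nb":
        return KernelNaiveBayes(**params)
    if algorithm == "knn":
        return KNeighborsClassifier(**params)
    if algorithm == "rf":
        return RandomForestClassifier(random_state=seed, **params)
    if algorithm == "svm":
        return SigmoidSVC(**params)
    if algorithm == "logitboost":
        return GradientBoostingClassifier(random_state=seed, **params)
    if algorithm == "adaboost":
        return AdaBoostClassifier(random_state=seed, **params)
    if algorithm == "cancerclass":
        return CorrelationCentroid(**params)
    raise ValueError(f"unknown algorithm {algorithm!r}")


@dataclass
class FittedModel:
    algorithm: str
    hyperparameters: dict
    features: list[str]
    feature_means: np.ndarray  # training means, used to impute missing genes
    estimator: object
    cv_auc: float | None
    validation_auc: float | None


def _nr_proba(est, X, classes=None) -> np.ndarray:
    proba = est.predict_proba(X)
    classes = np.asarray(est.classes_)
    return proba[:, list(classes).index(POSITIVE)]


def _cv_auc(est, X, y, folds: int, repeats: int, seed: int) -> float:
    """Mean AUC over repeated stratified k-fold CV with derived seeds."""
    ss = np.random.SeedSequence(seed)
    aucs = []
    for child in ss.spawn(repeats):
        rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        for tr, te in skf.split(X, y):
            e = clone(est)
            e.fit(X[tr], y[tr])
            aucs.append(roc_auc(_nr_proba(e, X[te]), y[te]).auc)
    return float(np.mean(aucs))


def _expression_features(
    expr: ExpressionMatrix, features: list[str], sample_ids: list[str]
) -> np.ndarray:
    sub = expr.subset_obs(sample_ids)
    return sub.values[sub.gene_index(features)].T  # samples x features


def train_select(
    expr: ExpressionMatrix,
    clinical: list[ClinicalRecord] | pd.DataFrame,
    split: SplitPlan,
    signature_genes: list[str],
    algorithms: tuple[str, ...] = DEFAULT_ALGORITHMS,
    cv_folds: int = 5,
    cv_repeats: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, FittedModel]:
    """Tune each algorithm by repeated stratified CV on the training set,
    refit on the full training set, and select by validation-set AUC.

    The parameter-free correlation-centroid rule skips CV and is trained
    on the whole training set directly. Returns (per-model stats, best
    fitted model).
    """
    df = clinical if isinstance(clinical, pd.DataFrame) else clinical_frame(clinical)
    features = [g.upper() for g in signature_genes if g.upper() in set(expr.gene_ids)]
    if len(features) < 2:
        raise ValueError("fewer than 2 signature genes present in the matrix")
    X_tr = _expression_features(expr, features, split.train_ids)
    y_tr = df.loc[split.train_ids, "response"].to_numpy()
    if len(set(y_tr)) < 2:
        raise ValueError("training set has fewer than 2 response classes")
    X_va = _expression_features(expr, features, split.validation_ids)
    y_va = df.loc[split.validation_ids, "response"].to_numpy()

    rows = []
    fitted: dict[str, FittedModel] = {}
    for alg in algorithms:
        best_params, best_cv = None, -np.inf
        if alg == "cancerclass" or len(_GRIDS[alg]) == 1:
            best_params = _GRIDS[alg][0]
            best_cv = (
                np.nan
                if alg == "cancerclass"
                else _cv_auc(
                    _build(alg, best_params, seed), X_tr, y_tr, cv_folds, cv_repeats, seed
                )
            )
        else:
            for params in _GRIDS[alg]:
                cv = _cv_auc(
                    _build(alg, params, seed), X_tr, y_tr, cv_folds, cv_repeats, seed
                )
                if cv > best_cv:
                    best_cv, best_params = cv, params
        est = _build(alg, best_params, seed)
        est.fit(X_tr, y_tr)
        val_auc = roc_auc(_nr_proba(est, X_va), y_va).auc
        fitted[alg] = FittedModel(
            algorithm=alg,
            hyperparameters=dict(best_params),
            features=features,
            feature_means=X_tr.mean(axis=0),
            estimator=est,
            cv_auc=None if np.isnan(best_cv) else float(best_cv),
            validation_auc=float(val_auc),
        )
        rows.append((alg, str(best_params), fitted[alg].cv_auc, val_auc))
    stats_df = pd.DataFrame(
        rows, columns=["algorithm", "hyperparameters", "cv_auc", "validation_auc"]
    ).sort_values("validation_auc", ascending=False, ignore_index=True)
    best = fitted[stats_df.loc[0, "algorithm"]]
    return stats_df, best


def predict_response(model: FittedModel, expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-sample probability of non-response and hard label.

    Model features missing from the matrix are imputed with the training
    means (with a warning); score >= 0.5 labels a sample NR.
    """
    present = [f for f in model.features if f in set(expr.gene_ids)]
    if not present:
        raise ValueError("expression matrix shares no genes with the model features")
    n = len(expr.obs_ids)
    X = np.tile(model.feature_means, (n, 1))
    have = [i for i, f in enumerate(model.features) if f in set(present)]
    X[:, have] = expr.values[expr.gene_index([model.features[i] for i in have])].T
    missing = len(model.features) - len(have)
    if missing:
        warnings.warn(
            f"{missing} model features absent; imputed with training means",
            stacklevel=2,
        )
    score = _nr_proba(model.estimator, X)
    return pd.DataFrame(
        {
            "sample_id": expr.obs_ids,
            "score": score,
            "label": np.where(score >= 0.5, "NR", "R"),
        }
    ).set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


def roc_auc(scores: np.ndarray, labels: np.ndarray, positive: str = POSITIVE) -> RocResult:
    """Tie-corrected Mann–Whitney AUC with a DeLong 95% CI.

    AUC = (concordant pairs + half ties) / (n_pos * n_neg), where
    positive-class samples are expected to score higher.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present for ROC analysis")
    # placements via midranks (DeLong's fast formulation)
    all_scores = np.concatenate([pos, neg])
    mid_all = stats.rankdata(all_scores)
    mid_pos = stats.rankdata(pos)
    mid_neg = stats.rankdata(neg)
    m, n = pos.size, neg.size
    v10 = (mid_all[:m] - mid_pos) / n  # per-positive placement
    v01 = 1.0 - (mid_all[m:] - mid_neg) / m  # per-negative placement
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = math.sqrt(s10 / m + s01 / n)
    z = stats.norm.ppf(0.975)
    return RocResult(
        auc=auc,
        ci_low=max(0.0, auc - z * se),
        ci_high=min(1.0, auc + z * se),
        n_pos=m,
        n_neg=n,
    )


# ---------------------------------------------------------------------------
# Survival


@dataclass
class SurvivalComparison:
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    median_os: dict[str, float]
    n: dict[str, int]
    km_curves: dict[str, pd.DataFrame]


def survival_compare(
    clinical: list[ClinicalRecord] | pd.DataFrame,
    predicted_labels: pd.Series | pd.DataFrame,
) -> SurvivalComparison:
    """Cox PH (predicted NR vs R; Efron ties) and Kaplan–Meier medians.

    ``predicted_labels`` maps sample_id -> "R"/"NR" (a Series, or the
    DataFrame from :func:`predict_response`). Samples without survival
    data are dropped. A group without events yields a warning; the HR is
    still reported.
    """
    df = clinical if isinstance(clinical, pd.DataFrame) else clinical_frame(clinical)
    if isinstance(predicted_labels, pd.DataFrame):
        predicted_labels = predicted_labels["label"]
    lab = predicted_labels.reindex(df.index)
    keep = df["os_months"].notna() & df["event"].notna() & lab.notna()
    sub = df.loc[keep]
    lab = lab.loc[keep]
    for g in ("R", "NR"):
        if (lab == g).sum() < 2:
            raise ValueError(f"fewer than 2 samples with survival data in group {g}")
        if sub.loc[(lab == g).to_numpy(), "event"].sum() == 0:
            warnings.warn(f"group {g} has no events; HR is unstable", stacklevel=2)
    fit_df = pd.DataFrame(
        {
            "os_months": sub["os_months"].astype(float),
            "event": sub["event"].astype(int),
            "nr": (lab == "NR").astype(int).to_numpy(),
        }
    )
    cph = CoxPHFitter()
    cph.fit(fit_df, duration_col="os_months", event_col="event")
    hr = float(np.exp(cph.params_["nr"]))
    ci = cph.confidence_intervals_.loc["nr"]
    medians: dict[str, float] = {}
    ns: dict[str, int] = {}
    curves: dict[str, pd.DataFrame] = {}
    for g in ("R", "NR"):
        mask = (lab == g).to_numpy()
        km = KaplanMeierFitter()
        km.fit(fit_df.loc[mask, "os_months"], fit_df.loc[mask, "event"], label=g)
        medians[g] = float(km.median_survival_time_)
        ns[g] = int(mask.sum())
        curves[g] = km.survival_function_.reset_index().rename(
            columns={"timeline": "time", g: "survival"}
        )
    return SurvivalComparison(
        hr=hr,
        ci_low=float(np.exp(ci.iloc[0])),
        ci_high=float(np.exp(ci.iloc[1])),
        p_value=float(cph.summary.loc["nr", "p"]),
        median_os=medians,
        n=ns,
        km_curves=curves,
    )
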