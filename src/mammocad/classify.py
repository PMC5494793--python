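"""Classifier contracts, cascade orchestration, voting and cross-validation.

Eight classifier kinds are supported.  Fisher's linear discriminant analysis
(FLDA) is implemented here: the projection maximises the Fisher criterion
J(w) = (w' S_B w) / (w' S_W w) and a test vector is assigned to the class
whose projected mean is nearest in Euclidean distance.  The remaining kinds
(LDC, linear SVM, logistic linear classifier, decision tree, random forest,
Gaussian naive Bayes, kNN) are standard algorithms backed by scikit-learn.

Three cascade schemes are orchestrated over stratified k-fold CV (default
k = 11, stratified by the 12-way tissue x health class):

* one-stage  — direct 3-class health classification;
* two-stage  — 4-class tissue classification, then a per-tissue 3-class
  health classifier;
* three-stage — tissue, then per-tissue normal-vs-abnormal, then
  benign-vs-malignant for abnormal-routed samples.

Downstream models are trained on truth-grouped training samples but applied
along *predicted* routes; a routed branch with no trained model falls back
to the global one-stage model of that fold.  The final output is always a
health-status label per sample, so every scheme is scored on the same 3-class
confusion matrix.  For multi-stage schemes the predictions of the top three
classifiers (ranked by overall CV accuracy) are combined by majority voting
with ties broken by the top-ranked voter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .evaluate import ConfusionMatrix, accumulate
from .io_dataset import HEALTH_LABELS, TISSUE_LABELS, FeatureTable, ValidationError

CLASSIFIER_KINDS = (
    "flda", "ldc", "svm_linear", "llc", "decision_tree",
    "random_forest", "naive_bayes", "knn",
)
SCHEMES = ("one_stage", "two_stage", "three_stage")


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to build, plus the hyperparameters that matter.

    ``knn_k`` defaults to 5; it must be positive and not a multiple of the
    class count of the task it is applied to (checked at fit time would be
    overkill — checked against the 3-class health task here).
    """

    kind: str
    knn_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValidationError(
                f"unknown classifier kind {self.kind!r}; allowed: {CLASSIFIER_KINDS}"
            )
        if self.kind == "knn":
            if self.knn_k <= 0:
                raise ValidationError("knn k must be positive")
            if self.knn_k % len(HEALTH_LABELS) == 0:
                raise ValidationError(
                    "knn k must not be a multiple of the class count"
                )


class FLDA:
    """Fisher's linear discriminant with nearest-projected-mean decision.

    S_W is the pooled within-class scatter, S_B the between-class scatter;
    the projection directions are the leading generalised eigenvectors of
    (S_B, S_W).  Features are standardised internally before the scatter
    matrices are formed — the decision rule is affine invariant in exact
    arithmetic, so this only conditions the eigenproblem, which matters when
    feature magnitudes span many orders (raw energies vs descriptor bins).
    S_W additionally carries a small ridge against exact singularity.
    """

    def __init__(self, reg: float = 1e-6):
        self.reg = reg
        self.classes_: np.ndarray | None = None
        self.W: np.ndarray | None = None  # (d, n_components)
        self.projected_means_: np.ndarray | None = None
        self._shift: np.ndarray | None = None
        self._scale: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: Sequence) -> "FLDA":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self._shift = X.mean(axis=0)
        sd = X.std(axis=0)
        self._scale = np.where(sd > 0, sd, 1.0)
        X = (X - self._shift) / self._scale
        classes = np.unique(y)
        if classes.size < 2:
            raise ValidationError("FLDA requires at least 2 classes")
        d = X.shape[1]
        overall = X.mean(axis=0)
        Sw = np.zeros((d, d))
        Sb = np.zeros((d, d))
        means = []
        for c in classes:
            Xc = X[y == c]
            mc = Xc.mean(axis=0)
            means.append(mc)
            dc = Xc - mc
            Sw += dc.T @ dc
            db = (mc - overall)[:, None]
            Sb += Xc.shape[0] * (db @ db.T)
        # ridge keeps the generalized eigenproblem well posed
        scale = np.trace(Sw) / d
        Sw_reg = Sw + self.reg * (scale if scale > 0 else 1.0) * np.eye(d)
        from scipy.linalg import eigh

        evals, evecs = eigh(Sb, Sw_reg)
        n_comp = classes.size - 1
        order = np.argsort(evals)[::-1][:n_comp]
        self.W = evecs[:, order]
        self.classes_ = classes
        self.projected_means_ = np.vstack(means) @ self.W
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.W is None:
            raise ValidationError("FLDA model is not fitted")
        Xs = (np.asarray(X, dtype=np.float64) - self._shift) / self._scale
        Z = Xs @ self.W
        d2 = ((Z[:, None, :] - self.projected_means_[None, :, :]) ** 2).sum(axis=2)
        return self.classes_[np.argmin(d2, axis=1)]


class _ConstantModel:
    """Predicts a single class; used when a training group is one-class."""

    def __init__(self, label):
        self.label = label

    def fit(self, X, y):  # noqa: D102 - trivially no-op
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.label, dtype=object)


def make_classifier(spec: ClassifierSpec):
    """Instantiate a model with ``fit(X, y)`` / ``predict(X)``."""
    kind = spec.kind
    if kind == "flda":
        return FLDA()
    if kind == "ldc":
        return LinearDiscriminantAnalysis()
    if kind == "svm_linear":
        return SVC(kernel="linear", random_state=spec.seed)
    if kind == "llc":
        return LogisticRegression(max_iter=2000)
    if kind == "decision_tree":
        return DecisionTreeClassifier(random_state=spec.seed)
    if kind == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=spec.seed)
    if kind == "naive_bayes":
        return GaussianNB()
    if kind == "knn":
        return KNeighborsClassifier(n_neighbors=spec.knn_k)
    raise ValidationError(f"unknown classifier kind {kind!r}")


@dataclass
class CVPlan:
    """Stratified fold assignment: ``assignment[i]`` is record i's fold."""

    n_folds: int
    assignment: np.ndarray
    seed: int

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.flatnonzero(self.assignment == fold)
        train = np.flatnonzero(self.assignment != fold)
        return train, test


def make_cv_plan(strata: Sequence[str], k: int = 11, seed: int = 0) -> CVPlan:
    """Stratified k-fold plan over the given per-record class labels.

    Every class must have at least ``k`` members; per-class fold sizes then
    differ by at most one.  Deterministic given the seed.
    """
    strata = np.asarray(list(strata))
    labels, counts = np.unique(strata, return_counts=True)
    for lab, cnt in zip(labels, counts):
        if cnt < k:
            raise ValidationError(
                f"class {lab!r} has only {cnt} members; needs >= {k} for "
                f"{k}-fold stratified CV"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(strata.size, dtype=np.int64)
    for fold, (_, test) in enumerate(skf.split(np.zeros((strata.size, 1)), strata)):
        assignment[test] = fold
    return CVPlan(n_folds=k, assignment=assignment, seed=seed)


@dataclass(frozen=True)
class StagePlan:
    """Declarative description of a classification cascade."""

    scheme: str

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValidationError(f"scheme must be one of {SCHEMES}")

    @property
    def stages(self) -> tuple[str, ...]:
        return {
            "one_stage": ("health(3)",),
            "two_stage": ("tissue(4)", "per-tissue health(3)"),
            "three_stage": (
                "tissue(4)",
                "per-tissue normal-vs-abnormal(2)",
                "per-tissue benign-vs-malignant(2)",
            ),
        }[self.scheme]


def majority_vote(preds: Sequence[Sequence], ranking: Sequence[int]) -> list:
    """Per-sample majority label from three voters, ties to the best voter.

    ``ranking`` lists voter indices best-first; a label with >= 2 votes wins,
    and a three-way disagreement resolves to the top-ranked voter's label.
    """
    if len(preds) != 3:
        raise ValidationError("majority_vote expects exactly three voters")
    n = len(preds[0])
    if any(len(p) != n for p in preds):
        raise ValidationError("voter prediction sequences must share length")
    if sorted(ranking) != [0, 1, 2]:
        raise ValidationError("ranking must be a permutation of voter indices")
    out = []
    for i in range(n):
        votes = [preds[v][i] for v in range(3)]
        winner = None
        for lab in votes:
            if votes.count(lab) >= 2:
                winner = lab
                break
        out.append(winner if winner is not None else preds[ranking[0]][i])
    return out


def _fit_branch(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray):
    """Fit a branch model; one-class groups get a constant predictor,
    empty groups return None (caller falls back to the one-stage model)."""
    if y.size == 0:
        return None
    classes = np.unique(y)
    if classes.size == 1:
        return _ConstantModel(classes[0])
    return make_classifier(spec).fit(X, y)


@dataclass
class SchemeResult:
    """Per-classifier CV outputs for one cascade scheme."""

    scheme: str
    predictions: dict[str, list]          # kind -> health label per record
    confusions: dict[str, ConfusionMatrix]
    accuracies: dict[str, float]          # kind -> overall CV health accuracy
    fallback_events: int = 0
    top3: tuple[str, ...] | None = None
    combined_predictions: list | None = None
    combined_confusion: ConfusionMatrix | None = None
    combined_accuracy: float | None = None


def run_scheme(table: FeatureTable, plan: StagePlan, cv: CVPlan,
               specs: Sequence[ClassifierSpec],
               vote_top3: bool | None = None) -> SchemeResult:
    """Run one cascade scheme for every classifier spec under the CV plan.

    For each fold, all stage models are fitted on the training split only
    (stage-2/3 branch models on the *true* tissue / abnormality groups of
    the training samples); test samples are routed by *predicted* upstream
    labels and always receive a final health label.  Confusion matrices are
    accumulated over folds.  ``vote_top3`` defaults to True for the two- and
    three-stage schemes (requires >= 3 specs).
    """
    X = table.features
    tissue = np.asarray(table.tissue, dtype=object)
    health = np.asarray(table.health, dtype=object)
    n = X.shape[0]
    if cv.assignment.size != n:
        raise ValidationError("CV plan does not cover the feature table")
    if vote_top3 is None:
        vote_top3 = plan.scheme in ("two_stage", "three_stage") and len(specs) >= 3

    preds: dict[str, np.ndarray] = {
        s.kind: np.empty(n, dtype=object) for s in specs
    }
    fallbacks = 0

    for fold in range(cv.n_folds):
        tr, te = cv.fold_indices(fold)
        Xtr, Xte = X[tr], X[te]
        ttr, htr = tissue[tr], health[tr]
        for spec in specs:
            # global one-stage health model: the scheme itself for
            # one_stage, the empty-branch fallback otherwise
            global_model = make_classifier(spec).fit(Xtr, htr)
            if plan.scheme == "one_stage":
                preds[spec.kind][te] = global_model.predict(Xte)
                continue

            tissue_model = make_classifier(spec).fit(Xtr, ttr)
            pred_tissue = tissue_model.predict(Xte)

            if plan.scheme == "two_stage":
                branch = {
                    t: _fit_branch(spec, Xtr[ttr == t], htr[ttr == t])
                    for t in TISSUE_LABELS
                }
                out = np.empty(te.size, dtype=object)
                for t in TISSUE_LABELS:
                    sel = pred_tissue == t
                    if not np.any(sel):
                        continue
                    model = branch[t]
                    if model is None:
                        fallbacks += int(sel.sum())
                        model = global_model
                    out[sel] = model.predict(Xte[sel])
                preds[spec.kind][te] = out
                continue

            # three_stage
            abn_tr = np.where(htr == "normal", "normal", "abnormal")
            screen = {
                t: _fit_branch(spec, Xtr[ttr == t], abn_tr[ttr == t])
                for t in TISSUE_LABELS
            }
            abn_mask = htr != "normal"
            diag = {
                t: _fit_branch(
                    spec,
                    Xtr[(ttr == t) & abn_mask],
                    htr[(ttr == t) & abn_mask],
                )
                for t in TISSUE_LABELS
            }
            out = np.empty(te.size, dtype=object)
            for t in TISSUE_LABELS:
                sel = np.flatnonzero(pred_tissue == t)
                if sel.size == 0:
                    continue
                if screen[t] is None:
                    fallbacks += sel.size
                    out[sel] = global_model.predict(Xte[sel])
                    continue
                status = screen[t].predict(Xte[sel])
                normal_sel = sel[status == "normal"]
                out[normal_sel] = "normal"
                abn_sel = sel[status == "abnormal"]
                if abn_sel.size:
                    if diag[t] is None:
                        fallbacks += abn_sel.size
                        out[abn_sel] = global_model.predict(Xte[abn_sel])
                    else:
                        out[abn_sel] = diag[t].predict(Xte[abn_sel])
            preds[spec.kind][te] = out

    confusions = {
        k: accumulate(p, health, HEALTH_LABELS) for k, p in preds.items()
    }
    accuracies = {k: cm.accuracy for k, cm in confusions.items()}
    result = SchemeResult(
        scheme=plan.scheme,
        predictions={k: list(p) for k, p in preds.items()},
        confusions=confusions,
        accuracies=accuracies,
        fallback_events=fallbacks,
    )
    if vote_top3:
        if len(specs) < 3:
            raise ValidationError("top-3 voting requires at least 3 classifiers")
        kinds = [s.kind for s in specs]
        ranked = sorted(kinds, key=lambda k: -accuracies[k])
        top3 = tuple(ranked[:3])
        voter_preds = [preds[k] for k in top3]
        combined = majority_vote(voter_preds, ranking=[0, 1, 2])
        cm = accumulate(combined, health, HEALTH_LABELS)
        result.top3 = top3
        result.combined_predictions = combined
        result.combined_confusion = cm
        result.combined_accuracy = cm.accuracy
    return result
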