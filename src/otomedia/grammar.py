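"""Three-stage hierarchical rule classifier ("grammar") over the vocabulary.

The tree mimics the diagnostic order of expert otoscopists, deciding one
category per stage:

* Stage 1 (AOM): a high bulging, light or concavity value with no visible
  malleus marks an AOM candidate; within candidates a high amber level is
  the partial-bulging escape that diverts to OME.
* Stage 2 (NOE): among non-AOM images, high translucency — or uniformly low
  values of every OME cue (amber, bubbles, variance) — gives NOE.
* Stage 3 (OME): everything remaining.

Decision thresholds are learned by minimising misclassification on a
held-out validation split (grid over empirical deciles, refined once),
sequentially in tree order; :func:`nested_cv` wraps this in stratified
k-fold cross-validation with the inner learning/validation split nested in
each training fold.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split
from sklearn.utils.validation import check_is_fitted

from .core import AOM, CLASS_LABELS, FEATURE_NAMES, NOE, OME, FeatureVector

__all__ = [
    "GrammarThresholds",
    "GrammarClassifier",
    "CvReport",
    "classify",
    "classify_with_trace",
    "learn_thresholds",
    "nested_cv",
]

#: tree-order learning sequence (malleus is binary and needs no threshold)
_LEARN_ORDER = ("bulging", "light", "concavity", "amber",
                "translucency", "bubbles", "variance")


@dataclass
class GrammarThresholds:
    """Per-feature decision thresholds of the rule tree (feature scales)."""

    bulging: float
    light: float
    concavity: float
    translucency: float
    amber: float
    bubbles: float
    variance: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GrammarThresholds":
        return cls(**json.loads(Path(path).read_text()))

    def replace(self, **kw) -> "GrammarThresholds":
        return dataclasses.replace(self, **kw)


def _as_feature_dict(fv) -> dict:
    if isinstance(fv, FeatureVector):
        return fv.as_dict()
    arr = np.asarray(fv, dtype=float)
    return dict(zip(FEATURE_NAMES, arr))


def classify_with_trace(
    fv, thresholds: GrammarThresholds, malleus_veto: bool = True
) -> tuple[str, list[str]]:
    """Classify one feature vector, returning the label and the fired rules.

    Accepts a :class:`FeatureVector` or an 8-array in canonical feature
    order.  Raises ``ValueError`` naming the feature on NaN input.  Total and
    single-valued: exactly one of AOM/OME/NOE is returned.
    """
    f = _as_feature_dict(fv)
    for name, v in f.items():
        if not np.isfinite(v):
            raise ValueError(f"feature '{name}' is not finite: {v}")
    t = thresholds
    trace: list[str] = []

    aom_cue = (
        f["bulging"] > t.bulging
        or f["light"] > t.light
        or f["concavity"] > t.concavity
    )
    candidate = aom_cue and (not malleus_veto or f["malleus"] == 0)
    if candidate:
        trace.append("stage1:aom-candidate")
        if f["amber"] > t.amber:
            trace.append("stage1:amber-escape->OME")
            return OME, trace
        trace.append("stage1:->AOM")
        return AOM, trace
    if aom_cue:
        trace.append("stage1:malleus-veto")

    if f["translucency"] > t.translucency:
        trace.append("stage2:translucent->NOE")
        return NOE, trace
    if (
        f["amber"] <= t.amber
        and f["bubbles"] <= t.bubbles
        and f["variance"] <= t.variance
    ):
        trace.append("stage2:all-ome-cues-low->NOE")
        return NOE, trace

    trace.append("stage3:->OME")
    return OME, trace


def classify(fv, thresholds: GrammarThresholds, malleus_veto: bool = True) -> str:
    """Label one feature vector with the three-stage rule tree."""
    return classify_with_trace(fv, thresholds, malleus_veto)[0]


# ---------------------------------------------------------------------------
# threshold learning

def _predict_matrix(X: np.ndarray, thr: GrammarThresholds, malleus_veto: bool) -> np.ndarray:
    return np.array([classify(row, thr, malleus_veto) for row in X])


def _misclassification(X, y, thr, malleus_veto) -> float:
    return float(np.mean(_predict_matrix(X, thr, malleus_veto) != y))


def learn_thresholds(
    X: np.ndarray,
    y: np.ndarray,
    val_fraction: float = 0.3,
    sweeps: int = 2,
    n_refine: int = 11,
    malleus_veto: bool = True,
    seed: int = 0,
) -> tuple[GrammarThresholds, float]:
    """Learn the seven thresholds on a stratified learning/validation split.

    Each threshold is tuned in tree order (bulging, light, concavity, amber,
    then translucency, bubbles, variance), greedily: candidate values are the
    empirical deciles of the feature on the learning split, refined once with
    a uniform grid between the deciles flanking the best cell; the candidate
    minimising validation misclassification wins.  Ties are resolved to the
    median element of the minimising plateau — the margin-preserving choice:
    a threshold hugging the edge of the plateau sits at the boundary of a
    class's observed support and misfires on fresh draws.  Thresholds not
    yet tuned sit at their learning-split medians.  The sequence is swept
    ``sweeps`` times so late thresholds can inform early ones.
    Deterministic for a fixed seed.

    Returns (thresholds, validation misclassification rate).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"X must be (n, {len(FEATURE_NAMES)})")
    X_learn, X_val, y_learn, y_val = train_test_split(
        X, y, test_size=val_fraction, stratify=y, random_state=seed
    )
    missing = set(CLASS_LABELS) - set(y_learn)
    if missing:
        raise ValueError(
            f"classes {sorted(missing)} absent from the learning split; "
            "re-stratify or supply more data"
        )

    col = {name: i for i, name in enumerate(FEATURE_NAMES)}
    thr = GrammarThresholds(
        **{
            name: float(np.median(X_learn[:, col[name]]))
            for name in _LEARN_ORDER
        }
    )

    def _evaluate(name: str, candidates: np.ndarray) -> np.ndarray:
        return np.array([
            _misclassification(
                X_val, y_val, thr.replace(**{name: float(c)}), malleus_veto
            )
            for c in candidates
        ])

    def _plateau_median(candidates: np.ndarray, errs: np.ndarray) -> tuple[float, float]:
        best = errs.min()
        winners = candidates[errs == best]
        return float(winners[len(winners) // 2]), float(best)

    err = _misclassification(X_val, y_val, thr, malleus_veto)
    for _ in range(sweeps):
        for name in _LEARN_ORDER:
            feat = X_learn[:, col[name]]
            deciles = np.unique(np.quantile(feat, np.arange(0.1, 0.95, 0.1)))
            dec_errs = _evaluate(name, deciles)
            anchor, _ = _plateau_median(deciles, dec_errs)
            # refine once between the deciles flanking the best cell
            i = int(np.searchsorted(deciles, anchor))
            lo = deciles[max(i - 1, 0)]
            hi = deciles[min(i + 1, len(deciles) - 1)]
            refined = np.linspace(lo, hi, n_refine)
            pool = np.unique(np.concatenate([deciles, refined]))
            v0, e0 = _plateau_median(pool, _evaluate(name, pool))
            if e0 <= err:
                thr = thr.replace(**{name: v0})
                err = e0
    return thr, err


@dataclass
class CvReport:
    """Aggregated nested cross-validation result."""

    fold_thresholds: list[GrammarThresholds]
    fold_validation_error: list[float]
    confusion: np.ndarray  # (3, 3), rows true, cols predicted, CLASS_LABELS order
    labels: tuple = CLASS_LABELS

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())


class GrammarClassifier(ClassifierMixin, BaseEstimator):
    """sklearn-style wrapper: ``fit`` learns the rule-tree thresholds on an
    internal stratified learning/validation split, ``predict`` applies the
    three-stage grammar.

    Parameters
    ----------
    val_fraction : float
        Fraction of the fitting data held out as the validation split.
    sweeps, n_refine : int
        Sweeps over the tree-order threshold sequence and refinement grid
        size (see :func:`learn_thresholds`).
    malleus_veto : bool
        Whether a visible malleus vetoes the Stage-1 AOM candidacy.
    random_state : int or None
        Seeds the learning/validation split; None means 0 (the classifier
        is deterministic by default).

    Attributes
    ----------
    thresholds_ : GrammarThresholds
    validation_error_ : float
    classes_ : ndarray of the three diagnostic labels
    """

    def __init__(self, val_fraction=0.3, sweeps=2, n_refine=11,
                 malleus_veto=True, random_state=None):
        self.val_fraction = val_fraction
        self.sweeps = sweeps
        self.n_refine = n_refine
        self.malleus_veto = malleus_veto
        self.random_state = random_state

    def fit(self, X, y):
        X = self._as_matrix(X)
        y = np.asarray(y)
        seed = 0 if self.random_state is None else int(self.random_state)
        self.thresholds_, self.validation_error_ = learn_thresholds(
            X, y,
            val_fraction=self.val_fraction,
            sweeps=self.sweeps,
            n_refine=self.n_refine,
            malleus_veto=self.malleus_veto,
            seed=seed,
        )
        self.classes_ = np.array(sorted(set(y)))
        return self

    def predict(self, X):
        check_is_fitted(self, "thresholds_")
        X = self._as_matrix(X)
        return _predict_matrix(X, self.thresholds_, self.malleus_veto)

    @staticmethod
    def _as_matrix(X) -> np.ndarray:
        if len(X) and isinstance(X[0], FeatureVector):
            return np.vstack([fv.as_array() for fv in X])
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
            raise ValueError(f"X must be (n, {len(FEATURE_NAMES)})")
        return X


def nested_cv(
    X,
    y,
    k_folds: int = 5,
    seed: int = 0,
    **classifier_params,
) -> CvReport:
    """Stratified k-fold nested cross-validation of the grammar.

    Outer folds test thresholds learned on their training folds (each with
    its own nested learning/validation split); the confusion matrix is
    aggregated over outer test folds.  When ``k_folds`` exceeds the smallest
    class count (e.g. leave-one-out), plain k-fold splitting is used instead
    of stratification, with a warning.
    """
    X = GrammarClassifier._as_matrix(X)
    y = np.asarray(y)
    if len(X) < k_folds:
        raise ValueError("need at least k_folds samples")
    _, counts = np.unique(y, return_counts=True)
    if k_folds <= counts.min():
        splitter = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        splits = splitter.split(X, y)
    else:
        warnings.warn(
            f"k_folds={k_folds} exceeds the smallest class count "
            f"({counts.min()}); falling back to unstratified folds",
            RuntimeWarning,
            stacklevel=2,
        )
        splitter = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
        splits = splitter.split(X)

    lab_index = {lab: i for i, lab in enumerate(CLASS_LABELS)}
    confusion = np.zeros((3, 3), dtype=int)
    fold_thresholds, fold_errors = [], []
    for fold, (train_idx, test_idx) in enumerate(splits):
        clf = GrammarClassifier(random_state=seed + fold, **classifier_params)
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[test_idx])
        for t, p in zip(y[test_idx], pred):
            confusion[lab_index[t], lab_index[p]] += 1
        fold_thresholds.append(clf.thresholds_)
        fold_errors.append(clf.validation_error_)
    return CvReport(
        fold_thresholds=fold_thresholds,
        fold_validation_error=fold_errors,
        confusion=confusion,
    )
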