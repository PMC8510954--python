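"""Random search over preprocessing+classifier workflows, ranked and ensembled.

A *workflow* is one sampled combination of feature scaling, feature
selection, class-imbalance handling, and one of eight classifiers with
hyperparameters drawn from declared priors. Candidates are scored by
internal patient-grouped random-split validation on the training rows
only; the top-k are refitted on the full training rows and averaged into
a probability ensemble.

Preprocessing is implemented directly on numpy arrays (median
imputation, scaling, zero-variance filtering, univariate top-k) rather
than through estimator pipelines: the univariate F-ranking is invariant
to per-feature affine scaling, so it is computed once per internal split
and shared across all candidates, which keeps searches with thousands of
candidates tractable on one CPU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

CLASSIFIERS = ("lr", "svm", "rf", "gnb", "lda", "qda", "adaboost", "gboost")
SCALERS = ("standard", "robust", "minmax", "none")
SELECTORS = ("none", "kbest")
IMBALANCE = ("none", "class_weight", "oversample")


@dataclass(frozen=True)
class WorkflowConfig:
    """One candidate preprocessing+classifier pipeline."""

    scaler: str
    selector: str
    k_best: int
    imbalance: str
    classifier: str
    params: dict
    draw_index: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.scaler not in SCALERS:
            raise ValueError(f"unknown scaler {self.scaler!r}")
        if self.selector not in SELECTORS:
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.imbalance not in IMBALANCE:
            raise ValueError(f"unknown imbalance handling {self.imbalance!r}")
        if self.selector == "kbest" and self.k_best < 1:
            raise ValueError("k_best must be >= 1")


#: classifiers that always get univariate top-k selection: tree ensembles
#: for tractability at 564 features, discriminant analysis because the
#: class covariance estimates need fewer features than samples
_FORCE_KBEST = ("rf", "adaboost", "gboost", "qda")


def sample_workflow(rng: np.random.Generator, draw_index: int = 0) -> WorkflowConfig:
    """Draw one workflow from the declared priors (reproducible under seed)."""
    classifier = str(rng.choice(CLASSIFIERS))
    params: dict = {}
    if classifier == "lr":
        params["C"] = float(10 ** rng.uniform(-3, 3))
    elif classifier == "svm":
        params["kernel"] = str(rng.choice(["rbf", "linear"]))
        params["C"] = float(10 ** rng.uniform(-2, 2))
        params["gamma"] = float(10 ** rng.uniform(-4, 0))
    elif classifier == "rf":
        params["n_estimators"] = int(rng.integers(10, 31))
        params["max_depth"] = int(rng.integers(3, 11))
    elif classifier == "qda":
        params["reg_param"] = float(rng.uniform(0.0, 1.0))
    elif classifier == "adaboost":
        params["n_estimators"] = int(rng.integers(10, 31))
        params["learning_rate"] = float(10 ** rng.uniform(-1, 0))
    elif classifier == "gboost":
        params["n_estimators"] = int(rng.integers(10, 31))
        params["max_depth"] = int(rng.integers(2, 5))
        params["learning_rate"] = float(10 ** rng.uniform(-1.3, -0.5))

    if classifier in _FORCE_KBEST:
        selector = "kbest"
    else:
        selector = str(rng.choice(SELECTORS, p=[0.25, 0.75]))
    k_hi = 31 if classifier == "qda" else 65
    cfg = WorkflowConfig(
        scaler=str(rng.choice(SCALERS)),
        selector=selector,
        k_best=int(rng.integers(5, k_hi)),
        imbalance=str(rng.choice(IMBALANCE)),
        classifier=classifier,
        params=params,
        draw_index=draw_index,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    cfg.validate()
    return cfg


def _make_estimator(cfg: WorkflowConfig, class_weight):
    p = cfg.params
    if cfg.classifier == "lr":
        return LogisticRegression(C=p["C"], max_iter=500, class_weight=class_weight)
    if cfg.classifier == "svm":
        return SVC(
            kernel=p["kernel"], C=p["C"], gamma=p["gamma"], class_weight=class_weight,
            # libsvm can spin nearly forever on badly scaled candidates
            max_iter=20_000,
        )
    if cfg.classifier == "rf":
        return RandomForestClassifier(
            n_estimators=p["n_estimators"],
            max_depth=p["max_depth"],
            class_weight=class_weight,
            random_state=cfg.seed,
        )
    if cfg.classifier == "gnb":
        return GaussianNB()
    if cfg.classifier == "lda":
        # lsqr + shrinkage stays well-posed when features outnumber samples
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    if cfg.classifier == "qda":
        return QuadraticDiscriminantAnalysis(reg_param=p["reg_param"])
    if cfg.classifier == "adaboost":
        return AdaBoostClassifier(
            n_estimators=p["n_estimators"],
            learning_rate=p["learning_rate"],
            random_state=cfg.seed,
        )
    if cfg.classifier == "gboost":
        return GradientBoostingClassifier(
            n_estimators=p["n_estimators"],
            max_depth=p["max_depth"],
            learning_rate=p["learning_rate"],
            subsample=0.8,
            max_features="sqrt",
            random_state=cfg.seed,
        )
    raise ValueError(cfg.classifier)


def _proba(estimator, x: np.ndarray) -> np.ndarray:
    """Positive-class probability; decision margins squashed for SVMs."""
    if hasattr(estimator, "predict_proba"):
        return estimator.predict_proba(x)[:, 1]
    margin = estimator.decision_function(x)
    return 1.0 / (1.0 + np.exp(-margin))


# ---------------------------------------------------------------------------
# fitted workflow

@dataclass
class FittedWorkflow:
    """A workflow with its learned preprocessing state and estimator."""

    config: WorkflowConfig
    medians: np.ndarray
    shift: np.ndarray
    scale: np.ndarray
    keep_idx: np.ndarray
    estimator: object

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        x = np.where(np.isfinite(x), x, self.medians[None, :])
        x = (x - self.shift[None, :]) / self.scale[None, :]
        return x[:, self.keep_idx]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _proba(self.estimator, self.transform(x))


def _fit_scaling(cfg: WorkflowConfig, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if cfg.scaler == "standard":
        shift, scale = x.mean(axis=0), x.std(axis=0)
    elif cfg.scaler == "robust":
        q1, med, q3 = np.percentile(x, [25, 50, 75], axis=0)
        shift, scale = med, q3 - q1
    elif cfg.scaler == "minmax":
        shift, scale = x.min(axis=0), np.ptp(x, axis=0)
    else:
        shift = np.zeros(x.shape[1])
        scale = np.ones(x.shape[1])
    return shift, np.where(scale <= 0, 1.0, scale)


def _oversample(
    x: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    idx = []
    for c, n in zip(classes, counts):
        members = np.flatnonzero(y == c)
        idx.append(members)
        if n < target:
            idx.append(rng.choice(members, size=target - n, replace=True))
    idx = np.concatenate(idx)
    return x[idx], y[idx]


def fit_workflow(
    cfg: WorkflowConfig,
    x: np.ndarray,
    y: np.ndarray,
    f_order: np.ndarray | None = None,
) -> FittedWorkflow:
    """Fit preprocessing and classifier on (x, y) only.

    ``f_order`` optionally supplies a precomputed univariate ranking
    (descending F-score) for the k-best selector.
    """
    cfg.validate()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    medians = np.nanmedian(np.where(np.isfinite(x), x, np.nan), axis=0)
    medians = np.where(np.isfinite(medians), medians, 0.0)
    x = np.where(np.isfinite(x), x, medians[None, :])

    shift, scale = _fit_scaling(cfg, x)
    xs = (x - shift[None, :]) / scale[None, :]

    nonconstant = xs.std(axis=0) > 0
    if cfg.selector == "kbest":
        if f_order is None:
            with np.errstate(divide="ignore", invalid="ignore"):
                f, _ = f_classif(xs, y)
            f = np.where(np.isfinite(f), f, -np.inf)
            f_order = np.argsort(-f)
        ranked = [i for i in f_order if nonconstant[i]]
        keep_idx = np.array(sorted(ranked[: cfg.k_best]), dtype=int)
    else:
        keep_idx = np.flatnonzero(nonconstant)
    if keep_idx.size == 0:
        keep_idx = np.arange(xs.shape[1])

    xk = xs[:, keep_idx]
    rng = np.random.default_rng(cfg.seed)
    class_weight = None
    if cfg.imbalance == "class_weight" and cfg.classifier in ("lr", "svm", "rf"):
        class_weight = "balanced"
    elif cfg.imbalance == "oversample" or (
        cfg.imbalance == "class_weight" and class_weight is None
    ):
        xk, y = _oversample(xk, y, rng)

    estimator = _make_estimator(cfg, class_weight)
    estimator.fit(xk, y)
    return FittedWorkflow(
        config=cfg, medians=medians, shift=shift, scale=scale,
        keep_idx=keep_idx, estimator=estimator,
    )


# ---------------------------------------------------------------------------
# internal validation

def make_internal_splits(
    patient_ids: Sequence[str],
    y: np.ndarray,
    n_splits: int = 5,
    val_frac: float = 0.15,
    rng: np.random.Generator | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Patient-grouped, class-stratified random train/validation splits.

    Stratification operates on patient-level labels; every validation
    set contains at least one patient of each class.
    """
    rng = rng or np.random.default_rng()
    patient_ids = np.asarray(patient_ids)
    y = np.asarray(y)
    patient_label = {}
    for pid, lab in zip(patient_ids, y):
        patient_label.setdefault(pid, lab)
    by_class: dict = {}
    for pid, lab in patient_label.items():
        by_class.setdefault(lab, []).append(pid)
    if len(by_class) < 2:
        raise ValueError("need patients from both classes")
    for lab, pids in by_class.items():
        if len(pids) < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 patients")
    splits = []
    for _ in range(n_splits):
        val_patients = set()
        for pids in by_class.values():
            pids = sorted(pids)
            n_val = max(1, int(round(val_frac * len(pids))))
            val_patients.update(rng.choice(pids, size=n_val, replace=False).tolist())
        val_mask = np.isin(patient_ids, sorted(val_patients))
        splits.append((np.flatnonzero(~val_mask), np.flatnonzero(val_mask)))
    return splits


class _SplitCache:
    """Per-internal-split state shared by every candidate workflow."""

    def __init__(self, x, y, splits):
        x = np.asarray(x, dtype=float)
        self.entries = []
        for tr, va in splits:
            xtr = x[tr]
            medians = np.nanmedian(np.where(np.isfinite(xtr), xtr, np.nan), axis=0)
            medians = np.where(np.isfinite(medians), medians, 0.0)
            xtr = np.where(np.isfinite(xtr), xtr, medians[None, :])
            xva = np.where(np.isfinite(x[va]), x[va], medians[None, :])
            # F-ranking is invariant to per-feature affine scaling, so it can
            # be computed once here and reused by every candidate
            with np.errstate(divide="ignore", invalid="ignore"):
                f, _ = f_classif(xtr, y[tr])
            f = np.where(np.isfinite(f), f, -np.inf)
            self.entries.append((xtr, y[tr], xva, y[va], np.argsort(-f)))


def _binarize(y: np.ndarray, positive: str) -> np.ndarray:
    """Map labels to {0, 1} with the positive class as 1."""
    y = np.asarray(y)
    if y.dtype.kind in "USO":
        return (y == positive).astype(int)
    return y.astype(int)


def _score(metric: str, y_true, proba, positive) -> float:
    y_bin = _binarize(y_true, positive)
    if metric == "auc":
        if len(np.unique(y_bin)) < 2:
            return np.nan
        return float(roc_auc_score(y_bin, proba))
    if metric == "f1_weighted":
        return float(f1_score(y_bin, (proba >= 0.5).astype(int), average="weighted"))
    raise ValueError(f"unknown metric {metric!r}")


def evaluate_workflow(
    cfg: WorkflowConfig,
    x: np.ndarray,
    y: np.ndarray,
    patient_ids: Sequence[str] | None = None,
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
    metric: str = "f1_weighted",
    positive: str = "dHGP",
    rng: np.random.Generator | None = None,
    _cache: _SplitCache | None = None,
) -> float:
    """Mean validation score of one workflow over the internal splits."""
    y = _binarize(np.asarray(y), positive)
    if splits is None:
        if patient_ids is None:
            raise ValueError("need patient_ids or explicit splits")
        splits = make_internal_splits(patient_ids, y, rng=rng or np.random.default_rng(cfg.seed))
    cache = _cache or _SplitCache(x, y, splits)
    scores = []
    for xtr, ytr, xva, yva, f_order in cache.entries:
        if len(np.unique(yva)) < 2 or len(np.unique(ytr)) < 2:
            raise ValueError("degenerate internal split: a class is absent")
        fitted = fit_workflow(cfg, xtr, ytr, f_order=f_order)
        scores.append(_score(metric, yva, fitted.predict_proba(xva), positive))
    return float(np.nanmean(scores))


# ---------------------------------------------------------------------------
# search + ensemble

@dataclass
class EnsembleModel:
    """Top-k workflows refitted on the full training rows."""

    members: list[FittedWorkflow]
    scores: list[float]
    configs: list[WorkflowConfig] = field(default_factory=list)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        probs = np.stack([m.predict_proba(x) for m in self.members])
        return probs.mean(axis=0)

    def predict(self, x: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(x) >= threshold).astype(int)


def search_and_ensemble(
    x: np.ndarray,
    y: np.ndarray,
    patient_ids: Sequence[str],
    n_candidates: int = 1000,
    k: int = 10,
    metric: str = "f1_weighted",
    positive: str = "dHGP",
    seed: int | np.random.Generator = 0,
    n_internal_splits: int = 5,
    val_frac: float = 0.15,
) -> EnsembleModel:
    """Random search; rank by internal validation; ensemble the top k.

    Ties in validation score are broken by draw index (earlier draw
    wins). The returned members are refitted on all training rows.
    """
    if n_candidates < k:
        raise ValueError("n_candidates must be >= ensemble size k")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = _binarize(np.asarray(y), positive)
    splits = make_internal_splits(patient_ids, y, n_splits=n_internal_splits,
                                  val_frac=val_frac, rng=rng)
    cache = _SplitCache(x, y, splits)

    scored: list[tuple[float, int, WorkflowConfig]] = []
    n_failed = 0
    for i in range(n_candidates):
        cfg = sample_workflow(rng, draw_index=i)
        try:
            s = evaluate_workflow(cfg, x, y, splits=splits, metric=metric,
                                  positive=positive, _cache=cache)
        except Exception as exc:  # noqa: BLE001 - a candidate may legitimately fail
            logger.debug("candidate %d failed: %s", i, exc)
            n_failed += 1
            continue
        scored.append((s, i, cfg))
    if not scored:
        raise RuntimeError(f"all {n_candidates} candidate workflows failed")
    if n_failed:
        logger.info("%d/%d candidate workflows failed and were skipped", n_failed, n_candidates)

    scored.sort(key=lambda t: (-t[0], t[1]))
    top = scored[:k]
    members = [fit_workflow(cfg, x, y) for _, _, cfg in top]
    return EnsembleModel(
        members=members,
        scores=[s for s, _, _ in top],
        configs=[cfg for _, _, cfg in top],
    )
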