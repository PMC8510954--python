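"""Repeated random-split evaluation with corrected-resampled-t intervals.

Implements the outer evaluation harness: patient-grouped stratified
80/20 split plans, the multi-observer training augmentation, test
metrics (AUC / accuracy / sensitivity / specificity with dHGP as the
positive class), Nadeau–Bengio corrected confidence intervals, ROC
fixed-width bands, and the univariate statistics used for the cohort
characteristics table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve

from hgpradiomics import robustness
from hgpradiomics.feature_bank import extract_all
from hgpradiomics.model_search import EnsembleModel, search_and_ensemble
from hgpradiomics.roi_masks import derive_nlp, make_ring
from hgpradiomics.synthetic_cohort import (
    CNN_OBSERVER,
    TRAIN_OBSERVERS,
    SyntheticCohort,
)

logger = logging.getLogger(__name__)

POSITIVE_CLASS = "dHGP"
ROI_KINDS = ("lesion", "nlp", "nlp_plus_lesion", "ring")
META_COLUMNS = (
    "patient_id", "lesion_id", "observer", "roi_kind", "label",
    "manufacturer", "slice_thickness",
)


# ---------------------------------------------------------------------------
# split plan

@dataclass
class SplitPlan:
    """Patient-grouped, class-stratified outer train/test partitions."""

    iterations: list[tuple[list[str], list[str]]]  # (train pids, test pids)
    train_frac: float
    seed: int

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)


def make_splits(
    metadata: pd.DataFrame,
    n_iterations: int = 100,
    train_frac: float = 0.8,
    seed: int = 0,
) -> SplitPlan:
    """Build the outer split plan from a lesion metadata table.

    Stratifies at the patient level using each patient's class label;
    within each class, ``round(train_frac * n_class)`` patients go to
    training. Lesions always follow their patient.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    patient_label = (
        metadata.drop_duplicates("patient_id").set_index("patient_id")["label"]
    )
    by_class: dict[str, list[str]] = {}
    for pid, lab in patient_label.items():
        by_class.setdefault(str(lab), []).append(str(pid))
    for lab, pids in by_class.items():
        if len(pids) < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 patients")
    rng = np.random.default_rng(seed)
    iterations = []
    for _ in range(n_iterations):
        train: list[str] = []
        test: list[str] = []
        for pids in by_class.values():
            pids = sorted(pids)
            n_train = int(round(train_frac * len(pids)))
            n_train = min(max(n_train, 1), len(pids) - 1)
            perm = rng.permutation(pids)
            train.extend(perm[:n_train].tolist())
            test.extend(perm[n_train:].tolist())
        iterations.append((sorted(train), sorted(test)))
    return SplitPlan(iterations=iterations, train_frac=train_frac, seed=seed)


def augment_multiobserver(
    train_rows: pd.DataFrame, observers: Sequence[str] = TRAIN_OBSERVERS
) -> pd.DataFrame:
    """Keep one row per (lesion, observer) for the training observer panel.

    Applied to a long-format feature table restricted to training
    patients: each training lesion then appears ``len(observers)`` times
    (once per observer's segmentation). Test rows are never augmented.
    """
    out = train_rows[train_rows["observer"].isin(list(observers))].copy()
    counts = out.groupby("lesion_id")["observer"].nunique()
    if not (counts == len(observers)).all():
        missing = counts[counts != len(observers)].index.tolist()
        raise ValueError(f"lesions missing observer rows: {missing}")
    return out


# ---------------------------------------------------------------------------
# metrics

def compute_metrics(
    scores: np.ndarray,
    labels: Sequence[str],
    positive: str = POSITIVE_CLASS,
    threshold: float = 0.5,
) -> dict[str, float]:
    """AUC (rank statistic) and threshold metrics; sensitivity on dHGP.

    AUC is NaN for a single-class label vector (degenerate iteration).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    y_bin = (y == positive).astype(int) if y.dtype.kind in "USO" else y.astype(int)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y_bin == 1)).sum())
    tn = int(((pred == 0) & (y_bin == 0)).sum())
    fp = int(((pred == 1) & (y_bin == 0)).sum())
    fn = int(((pred == 0) & (y_bin == 1)).sum())
    auc = (
        float(roc_auc_score(y_bin, scores)) if len(np.unique(y_bin)) == 2 else float("nan")
    )
    return {
        "auc": auc,
        "accuracy": (tp + tn) / len(y_bin),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }


def corrected_resampled_ci(
    values: Sequence[float],
    n_train: float,
    n_test: float,
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Nadeau–Bengio corrected-resampled-t confidence interval.

    ``mean ± t_{(1+level)/2, k-1} * s * sqrt(1/k + n_test/n_train)``
    with ``k`` iterations and ``s`` the sample standard deviation of the
    per-iteration values. NaN iterations are excluded (and must leave at
    least two values).
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    k = len(vals)
    if k < 2:
        raise ValueError("need at least 2 finite per-iteration values")
    if n_train <= 0 or n_test < 0:
        raise ValueError("invalid train/test sizes")
    mean = float(vals.mean())
    s = float(vals.std(ddof=1))
    t_crit = float(sps.t.ppf(0.5 * (1.0 + level), df=k - 1))
    half = t_crit * s * np.sqrt(1.0 / k + n_test / n_train)
    return mean, mean - half, mean + half


def roc_band(
    roc_curves: list[tuple[np.ndarray, np.ndarray]],
    level: float = 0.95,
    grid_size: int = 101,
) -> pd.DataFrame:
    """Vertically averaged ROC with a fixed-width confidence band.

    Each input curve is ``(fpr, tpr)``. Curves are interpolated onto a
    common FPR grid and averaged; the band half-width is the smallest
    ``w`` such that at least ``level`` of the curves lie within
    ``mean ± w`` everywhere (computed as the ``level`` quantile of the
    per-curve sup-deviation from the mean). TPR bounds are clipped to
    [0, 1].
    """
    if not roc_curves:
        raise ValueError("no ROC curves supplied")
    grid = np.linspace(0.0, 1.0, grid_size)
    interp = np.stack([np.interp(grid, fpr, tpr) for fpr, tpr in roc_curves])
    mean = interp.mean(axis=0)
    sup_dev = np.abs(interp - mean[None, :]).max(axis=1)
    w = float(np.quantile(sup_dev, level, method="higher"))
    return pd.DataFrame(
        {
            "fpr": grid,
            "tpr_mean": mean,
            "tpr_lo": np.clip(mean - w, 0.0, 1.0),
            "tpr_hi": np.clip(mean + w, 0.0, 1.0),
            "half_width": w,
        }
    )


# ---------------------------------------------------------------------------
# univariate statistics

def chi_square_2xk(counts: np.ndarray | list) -> tuple[float, float]:
    """Pearson chi-square without continuity correction; (statistic, p)."""
    table = np.asarray(counts, dtype=float)
    if table.min() < 0:
        raise ValueError("negative counts")
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def mann_whitney(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U rank-sum test; (U, p).

    Uses the exact null distribution for small samples without ties.
    """
    res = sps.mannwhitneyu(values_a, values_b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Multiply by the number of tests, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = len(p) if m is None else m
    return np.minimum(p * m, 1.0)


def univariate_clinical_table(
    patient_meta: pd.DataFrame, label_col: str = "label"
) -> pd.DataFrame:
    """Per-covariate class comparison mirroring a cohort-characteristics table.

    Continuous covariates get a two-sided Mann–Whitney U test, categorical
    ones a Pearson chi-square without continuity correction. Expects one
    row per patient with ``clinical_*`` columns.
    """
    rows = []
    pos = patient_meta[patient_meta[label_col] == POSITIVE_CLASS]
    neg = patient_meta[patient_meta[label_col] != POSITIVE_CLASS]
    for col in [c for c in patient_meta.columns if c.startswith("clinical_")]:
        if pd.api.types.is_numeric_dtype(patient_meta[col]):
            _, p = mann_whitney(pos[col].dropna(), neg[col].dropna())
            test = "mann-whitney"
        else:
            counts = pd.crosstab(patient_meta[col], patient_meta[label_col])
            if min(counts.shape) < 2:  # a level or class absent: no test
                p = 1.0
            else:
                _, p = chi_square_2xk(counts.to_numpy())
            test = "chi-square"
        rows.append({"covariate": col, "test": test, "p_value": p})
    return pd.DataFrame(rows)


def univariate_feature_stats(
    feature_table: pd.DataFrame,
    observer: str = CNN_OBSERVER,
    m: int | None = None,
) -> pd.DataFrame:
    """Per-feature Mann–Whitney p-values with Bonferroni adjustment.

    Uses the rows of the stated observer (the one whose segmentations
    feed the test sets), one row per lesion.
    """
    rows = feature_table[feature_table["observer"] == observer]
    feat_cols = _feature_columns(rows)
    pos = rows[rows["label"] == POSITIVE_CLASS]
    neg = rows[rows["label"] != POSITIVE_CLASS]
    p_values = []
    for col in feat_cols:
        a, b = pos[col].to_numpy(), neg[col].to_numpy()
        if np.ptp(np.concatenate([a, b])) == 0:
            p_values.append(1.0)
        else:
            p_values.append(mann_whitney(a, b)[1])
    return pd.DataFrame(
        {
            "feature": feat_cols,
            "p_value": p_values,
            "p_adjusted": bonferroni(p_values, m=m),
        }
    )


# ---------------------------------------------------------------------------
# feature-table construction

def extract_feature_table(
    cohort: SyntheticCohort,
    roi_kind: str = "lesion",
    observers: Sequence[str] | None = None,
    ring_width: int = 2,
) -> pd.DataFrame:
    """Long-format feature table: one row per (lesion, observer, roi_kind).

    For ``nlp`` the liver-minus-lesions region is derived per observer
    from that observer's lesion masks; ``ring`` straddles the observer's
    lesion boundary.
    """
    if roi_kind not in ROI_KINDS:
        raise ValueError(f"unknown roi_kind {roi_kind!r}")
    if observers is None:
        observers = list(TRAIN_OBSERVERS) + [CNN_OBSERVER]
    rows = []
    for patient in cohort.patients:
        spacing = cohort.config.spacing
        obs_lesion_masks: dict[str, list[np.ndarray]] = {
            obs: [les.observer_masks[obs] for les in patient.lesions] for obs in observers
        }
        for lesion in patient.lesions:
            for obs in observers:
                mask = lesion.observer_masks[obs]
                if roi_kind == "lesion":
                    roi = mask
                elif roi_kind == "ring":
                    roi = make_ring(mask, ring_width)
                else:
                    nlp = derive_nlp(patient.liver_mask, obs_lesion_masks[obs])
                    roi = nlp if roi_kind == "nlp" else np.logical_or(nlp, mask)
                vec = extract_all(patient.volume, roi, spacing)
                rows.append(
                    {
                        "patient_id": patient.patient_id,
                        "lesion_id": lesion.lesion_id,
                        "observer": obs,
                        "roi_kind": roi_kind,
                        "label": lesion.label,
                        "manufacturer": patient.acquisition.manufacturer,
                        "slice_thickness": patient.acquisition.slice_thickness,
                        **vec.to_dict(),
                    }
                )
    return pd.DataFrame(rows)


def clinical_feature_table(cohort: SyntheticCohort) -> pd.DataFrame:
    """One-hot encoded clinical covariates, one row per lesion."""
    meta = cohort.metadata()
    clin_cols = [c for c in meta.columns if c.startswith("clinical_")]
    clin = pd.get_dummies(meta[clin_cols], dtype=float)
    out = pd.concat(
        [meta[["patient_id", "lesion_id", "label", "manufacturer", "slice_thickness"]], clin],
        axis=1,
    )
    return out


# ---------------------------------------------------------------------------
# experiment designs

@dataclass
class ExperimentDesign:
    """One model variant: observer setup, ROI, feature source, robustness."""

    name: str
    mode: str = "multi"  # "single" or "multi"
    train_observers: tuple[str, ...] = TRAIN_OBSERVERS
    test_observer: str = CNN_OBSERVER
    roi_kind: str = "lesion"
    feature_source: str = "imaging"  # imaging | clinical | imaging+clinical
    robustness_option: str = "none"  # none | icc>0.75 | icc>0.90 | combat-manufacturer | combat-protocol

    def __post_init__(self) -> None:
        if self.mode not in ("single", "multi"):
            raise ValueError("mode must be 'single' or 'multi'")
        if self.mode == "single":
            if len(self.train_observers) != 1 or self.train_observers[0] != self.test_observer:
                raise ValueError("single-observer design trains and tests on one observer")
        if self.roi_kind not in ROI_KINDS:
            raise ValueError(f"unknown roi_kind {self.roi_kind!r}")
        if self.feature_source not in ("imaging", "clinical", "imaging+clinical"):
            raise ValueError(f"unknown feature source {self.feature_source!r}")
        valid = ("none", "icc>0.75", "icc>0.90", "combat-manufacturer", "combat-protocol")
        if self.robustness_option not in valid:
            raise ValueError(f"unknown robustness option {self.robustness_option!r}")


def single_observer_design(observer: str, **kw) -> ExperimentDesign:
    return ExperimentDesign(
        name=f"single-{observer}", mode="single",
        train_observers=(observer,), test_observer=observer, **kw,
    )


@dataclass
class SearchSettings:
    n_candidates: int = 1000
    ensemble_k: int = 10
    metric: str = "f1_weighted"


@dataclass
class ExperimentResult:
    design: ExperimentDesign
    per_iteration: pd.DataFrame  # columns auc/accuracy/sensitivity/specificity
    summary: pd.DataFrame  # metric, mean, ci_lo, ci_hi
    roc_curves: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    #: per-iteration test predictions: (patient_id, lesion_id, observer, label, proba)
    predictions: list[pd.DataFrame] = field(default_factory=list)
    n_degenerate: int = 0

    def roc_band(self, level: float = 0.95) -> pd.DataFrame:
        return roc_band(self.roc_curves, level=level)


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def _apply_robustness(
    design: ExperimentDesign,
    train: pd.DataFrame,
    test: pd.DataFrame,
    icc_source: pd.DataFrame | None,
    feat_cols: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Fit the robustness transform on training rows only."""
    option = design.robustness_option
    if option == "none":
        return train, test, feat_cols
    if option.startswith("icc>"):
        threshold = float(option.split(">")[1])
        if icc_source is None:
            raise ValueError("ICC filtering needs multi-observer rows for training lesions")
        records = robustness.icc_table(
            icc_source, feature_names=feat_cols
        )
        selected = robustness.select_reliable(records, threshold)
        if not selected:
            logger.warning("no feature passed ICC > %.2f; keeping all", threshold)
            selected = feat_cols
        return train, test, selected
    mode = "manufacturer" if option == "combat-manufacturer" else "protocol"
    assignment = robustness.define_batches(train, mode=mode)
    params = robustness.combat_fit(train[feat_cols], assignment)
    train = train.copy()
    train[feat_cols] = robustness.combat_apply(train[feat_cols], params, assignment)
    test_assignment = _assign_test_batches(test, assignment)
    test = test.copy()
    test[feat_cols] = robustness.combat_apply(test[feat_cols], params, test_assignment)
    return train, test, feat_cols


def _assign_test_batches(
    test: pd.DataFrame, fitted: robustness.BatchAssignment
) -> robustness.BatchAssignment:
    """Batch ids for test rows using the train-fitted mode and median."""
    if fitted.mode == "manufacturer":
        batches = test["manufacturer"].astype(str)
    else:
        half = np.where(
            test["slice_thickness"] > fitted.thickness_median, "thick", "thin"
        )
        batches = test["manufacturer"].astype(str) + "/" + half
    batches = pd.Series(batches, index=test.index)
    known = set(fitted.batches.unique()) - fitted.excluded
    excluded = set(batches.unique()) - known
    return robustness.BatchAssignment(
        batches=batches, mode=fitted.mode, excluded=excluded,
        thickness_median=fitted.thickness_median,
    )


def run_experiment(
    feature_table: pd.DataFrame,
    design: ExperimentDesign,
    splits: SplitPlan,
    search: SearchSettings | None = None,
    seed: int = 0,
    clinical_table: pd.DataFrame | None = None,
) -> ExperimentResult:
    """Evaluate one design over the outer split plan.

    ``feature_table`` is the long-format imaging feature table for the
    design's ROI kind (all needed observers present). All learned state
    (scaling, selection, ICC filtering, ComBat, the workflow search) is
    fitted inside each outer training set.
    """
    search = search or SearchSettings()
    rng = np.random.default_rng(seed)

    table = feature_table
    if design.feature_source in ("clinical", "imaging+clinical"):
        if clinical_table is None:
            raise ValueError("design needs a clinical table")
        clin_cols = [
            c for c in clinical_table.columns
            if c not in ("patient_id", "lesion_id", "label", "manufacturer", "slice_thickness")
        ]
        if design.feature_source == "clinical":
            table = feature_table[list(META_COLUMNS)].merge(
                clinical_table[["lesion_id", *clin_cols]], on="lesion_id", how="left"
            )
        else:
            table = feature_table.merge(
                clinical_table[["lesion_id", *clin_cols]], on="lesion_id", how="left"
            )
    feat_cols = _feature_columns(table)

    records = []
    curves: list[tuple[np.ndarray, np.ndarray]] = []
    predictions: list[pd.DataFrame] = []
    n_degenerate = 0
    for train_pids, test_pids in splits.iterations:
        train_all = table[table["patient_id"].isin(train_pids)]
        test_all = table[table["patient_id"].isin(test_pids)]
        if design.mode == "multi":
            train = augment_multiobserver(train_all, design.train_observers)
        else:
            train = train_all[train_all["observer"] == design.train_observers[0]]
        test = test_all[test_all["observer"] == design.test_observer]

        icc_source = None
        if design.robustness_option.startswith("icc>"):
            icc_source = train_all[train_all["observer"].isin(TRAIN_OBSERVERS)][
                ["lesion_id", "observer", *feat_cols]
            ]
        train, test, cols = _apply_robustness(design, train, test, icc_source, feat_cols)

        model: EnsembleModel = search_and_ensemble(
            train[cols].to_numpy(dtype=float),
            train["label"].to_numpy(),
            train["patient_id"].to_numpy(),
            n_candidates=search.n_candidates,
            k=search.ensemble_k,
            metric=search.metric,
            positive=POSITIVE_CLASS,
            seed=np.random.default_rng(rng.integers(0, 2**63)),
        )
        proba = model.predict_proba(test[cols].to_numpy(dtype=float))
        labels = test["label"].to_numpy()
        pred = test[["patient_id", "lesion_id", "observer", "label"]].copy()
        pred["proba"] = proba
        predictions.append(pred.reset_index(drop=True))
        metrics = compute_metrics(proba, labels)
        metrics["n_train"] = len(train)
        metrics["n_test"] = len(test)
        metrics["n_train_patients"] = len(train_pids)
        metrics["n_test_patients"] = len(test_pids)
        records.append(metrics)
        y_bin = (labels == POSITIVE_CLASS).astype(int)
        if len(np.unique(y_bin)) == 2:
            fpr, tpr, _ = roc_curve(y_bin, proba)
            curves.append((fpr, tpr))
        else:
            n_degenerate += 1
            logger.warning("degenerate iteration (single-class test set); AUC skipped")

    per_iter = pd.DataFrame(records)
    n_train_p = float(per_iter["n_train_patients"].mean())
    n_test_p = float(per_iter["n_test_patients"].mean())
    rows = []
    for metric in ("auc", "accuracy", "sensitivity", "specificity"):
        try:
            mean, lo, hi = corrected_resampled_ci(per_iter[metric], n_train_p, n_test_p)
        except ValueError:  # fewer than 2 finite iterations: no interval
            mean = float(np.nanmean(per_iter[metric]))
            lo = hi = float("nan")
        rows.append({"metric": metric, "mean": mean, "ci_lo": lo, "ci_hi": hi})
    return ExperimentResult(
        design=design,
        per_iteration=per_iter,
        summary=pd.DataFrame(rows),
        roc_curves=curves,
        predictions=predictions,
        n_degenerate=n_degenerate,
    )
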