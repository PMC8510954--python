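"""Feature reliability across observers (ICC) and batch harmonization (ComBat).

The ICC is the two-way random-effects, absolute-agreement, single-rater
form (the form presumed by the 0.75/0.90 reliability thresholds).
ComBat is the standard location/scale empirical-Bayes harmonization with
parametric priors and no moderation covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GOOD_ICC = 0.75
EXCELLENT_ICC = 0.90


# ---------------------------------------------------------------------------
# ICC

def icc(feature_matrix: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Parameters
    ----------
    feature_matrix
        ``(n_subjects, n_raters)`` array of one feature's values, no
        missing cells.

    Notes
    -----
    Computed from the mean squares of the subject x rater ANOVA
    decomposition::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    A matrix with zero total variance is defined to have ICC 1
    (perfect agreement on a constant).
    """
    x = np.asarray(feature_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if not np.isfinite(x).all():
        raise ValueError("missing or non-finite cells")
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        return 1.0
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()  # subjects (rows)
    ssc = n * ((col_means - grand) ** 2).sum()  # raters (columns)
    sse = ((x - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return 1.0
    return float((msr - mse) / denom)


@dataclass(frozen=True)
class ICCRecord:
    feature: str
    icc: float

    @property
    def reliability(self) -> str:
        if self.icc > EXCELLENT_ICC:
            return "excellent"
        if self.icc > GOOD_ICC:
            return "good"
        return "below-good"


def icc_table(
    features: pd.DataFrame,
    lesion_col: str = "lesion_id",
    observer_col: str = "observer",
    feature_names: list[str] | None = None,
) -> list[ICCRecord]:
    """Per-feature ICC over a long-format (lesion, observer) feature table.

    Only lesions with a value from every observer contribute.
    """
    if feature_names is None:
        meta = {lesion_col, observer_col}
        feature_names = [c for c in features.columns if c not in meta]
    records = []
    for name in feature_names:
        wide = features.pivot_table(
            index=lesion_col, columns=observer_col, values=name
        ).dropna(axis=0)
        records.append(ICCRecord(feature=name, icc=icc(wide.to_numpy())))
    return records


def select_reliable(records: list[ICCRecord], threshold: float) -> list[str]:
    """Features with ICC strictly above the threshold, in input order."""
    return [r.feature for r in records if r.icc > threshold]


# ---------------------------------------------------------------------------
# batch definition

@dataclass
class BatchAssignment:
    """Sample -> batch id map with singleton batches excluded."""

    batches: pd.Series  # index = sample index, values = batch label
    mode: str
    excluded: set[str] = field(default_factory=set)
    thickness_median: float | None = None

    def included_index(self) -> pd.Index:
        return self.batches.index[~self.batches.isin(self.excluded)]


def define_batches(metadata: pd.DataFrame, mode: str = "manufacturer") -> BatchAssignment:
    """Assign batches by manufacturer or manufacturer x slice-thickness half.

    ``mode='manufacturer'`` uses the scanner manufacturer alone;
    ``mode='protocol'`` combines it with slice thickness dichotomized at
    the cohort median. Batches with fewer than 2 members are excluded
    (passed through harmonization unchanged).
    """
    if mode == "manufacturer":
        batches = metadata["manufacturer"].astype(str)
        median = None
    elif mode == "protocol":
        median = float(metadata["slice_thickness"].median())
        half = np.where(metadata["slice_thickness"] > median, "thick", "thin")
        batches = metadata["manufacturer"].astype(str) + "/" + half
        batches = pd.Series(batches, index=metadata.index)
    else:
        raise ValueError(f"unknown batch mode {mode!r}")
    counts = batches.value_counts()
    excluded = set(counts.index[counts < 2])
    if excluded:
        logger.info("excluding singleton batches from harmonization: %s", sorted(excluded))
    return BatchAssignment(
        batches=pd.Series(batches, index=metadata.index),
        mode=mode,
        excluded=excluded,
        thickness_median=median,
    )


# ---------------------------------------------------------------------------
# ComBat

@dataclass
class ComBatParams:
    """Fitted harmonization parameters (location gamma*, scale delta*)."""

    feature_names: list[str]
    grand_mean: np.ndarray  # (features,)
    pooled_var: np.ndarray  # (features,)
    gamma_star: dict[str, np.ndarray]  # batch -> (features,)
    delta_star: dict[str, np.ndarray]  # batch -> (features,)
    mode: str
    constant_features: np.ndarray  # boolean (features,); passed through


def _aprior(delta_hat: np.ndarray) -> tuple[float, float]:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    if s2 <= 0:
        return 2.0, m
    return (2 * s2 + m**2) / s2, (m * s2 + m**3) / s2


def combat_fit(
    features: pd.DataFrame,
    assignment: BatchAssignment,
    eb: bool = True,
    eb_iterations: int = 50,
) -> ComBatParams:
    """Fit location/scale harmonization parameters.

    No covariate / moderation term is used. With ``eb=True`` (default)
    the per-batch location/scale estimates are shrunk via parametric
    empirical-Bayes priors (normal / inverse-gamma across features);
    ``eb=False`` uses the raw per-batch estimates, which equalizes batch
    means and variances exactly. Features with zero pooled variance are
    flagged constant and passed through by :func:`combat_apply`.
    """
    idx = assignment.included_index()
    idx = idx.intersection(features.index)
    x = features.loc[idx].to_numpy(dtype=float)
    batches = assignment.batches.loc[idx]
    labels = sorted(batches.unique())
    if any((batches == b).sum() < 2 for b in labels):
        raise ValueError("every included batch needs >= 2 samples")

    n, p = x.shape
    grand = x.mean(axis=0)
    pooled_var = x.var(axis=0, ddof=0)
    constant = pooled_var <= 1e-12
    if constant.any():
        logger.info("%d constant features passed through ComBat", int(constant.sum()))
    sd = np.sqrt(np.where(constant, 1.0, pooled_var))
    z = (x - grand) / sd

    gamma_star: dict[str, np.ndarray] = {}
    delta_star: dict[str, np.ndarray] = {}
    for b in labels:
        zb = z[(batches == b).to_numpy()]
        nb = zb.shape[0]
        gamma_hat = zb.mean(axis=0)
        # population variance so that a single whole-dataset batch is the
        # exact identity (z is standardized with ddof=0)
        delta_hat = zb.var(axis=0, ddof=0)
        delta_hat = np.where(delta_hat <= 1e-12, 1e-12, delta_hat)

        # parametric EB priors: gamma ~ N(g_bar, t2), delta ~ InvGamma(a, b)
        g_bar = gamma_hat.mean()
        t2 = gamma_hat.var(ddof=1)
        a_prior, b_prior = _aprior(delta_hat)

        g_star = gamma_hat.copy()
        d_star = delta_hat.copy()
        if eb and t2 > 0:
            for _ in range(eb_iterations):
                g_new = (t2 * nb * gamma_hat + d_star * g_bar) / (t2 * nb + d_star)
                ssq = ((zb - g_new[None, :]) ** 2).sum(axis=0)
                d_new = (b_prior + 0.5 * ssq) / (nb / 2.0 + a_prior - 1.0)
                if np.allclose(g_new, g_star, atol=1e-10) and np.allclose(
                    d_new, d_star, atol=1e-10
                ):
                    g_star, d_star = g_new, d_new
                    break
                g_star, d_star = g_new, d_new
        gamma_star[b] = g_star
        delta_star[b] = np.maximum(d_star, 1e-12)

    return ComBatParams(
        feature_names=list(features.columns),
        grand_mean=grand,
        pooled_var=np.where(constant, 1.0, pooled_var),
        gamma_star=gamma_star,
        delta_star=delta_star,
        mode=assignment.mode,
        constant_features=constant,
    )


def combat_apply(
    features: pd.DataFrame,
    params: ComBatParams,
    assignment: BatchAssignment,
) -> pd.DataFrame:
    """Remove the fitted batch location/scale effects.

    Samples in excluded batches, or in batches unseen at fit time, are
    passed through unchanged; so are constant features. Row order and
    feature count are preserved.
    """
    if list(features.columns) != params.feature_names:
        raise ValueError("feature columns differ from the fitted parameters")
    out = features.copy()
    sd = np.sqrt(params.pooled_var)
    for b, gamma in params.gamma_star.items():
        rows = features.index[
            (assignment.batches.reindex(features.index) == b).fillna(False)
        ]
        if len(rows) == 0:
            continue
        z = (features.loc[rows].to_numpy(dtype=float) - params.grand_mean) / sd
        z = (z - gamma) / np.sqrt(params.delta_star[b])
        adjusted = z * sd + params.grand_mean
        adjusted[:, params.constant_features] = features.loc[
            rows, features.columns[params.constant_features]
        ].to_numpy(dtype=float)
        out.loc[rows] = adjusted
    return out
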