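"""Scalar statistics shared by the intensity and filter-response features."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

_ENTROPY_BINS = 16


def shannon_entropy(values: np.ndarray, bins: int = _ENTROPY_BINS) -> float:
    """Histogram entropy (nats) over the value range; 0 for constant input."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return 0.0
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return 0.0
    counts, _ = np.histogram(values, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / values.size
    return float(-(p * np.log(p)).sum())


def _moment_stats(values: np.ndarray) -> tuple[float, float]:
    # skew/kurtosis of a constant sample are undefined; pin them to 0
    if values.size < 2 or np.ptp(values) == 0:
        return 0.0, 0.0
    return float(sps.skew(values)), float(sps.kurtosis(values))


def response_stats(values: np.ndarray) -> dict[str, float]:
    """The 9 statistics computed over every masked filter response."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        return {k: 0.0 for k in (
            "mean", "std", "min", "max", "median",
            "skewness", "kurtosis", "energy", "entropy",
        )}
    skew, kurt = _moment_stats(values)
    return {
        "mean": float(values.mean()),
        "std": float(values.std(ddof=0)),
        "min": float(values.min()),
        "max": float(values.max()),
        "median": float(np.median(values)),
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float(np.mean(values**2)),
        "entropy": shannon_entropy(values),
    }


def histogram_stats(values: np.ndarray) -> dict[str, float]:
    """The 13 first-order intensity statistics."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty ROI")
    p10, p90 = np.percentile(values, [10, 90])
    q1, q3 = np.percentile(values, [25, 75])
    skew, kurt = _moment_stats(values)
    return {
        "mean": float(values.mean()),
        "std": float(values.std(ddof=0)),
        "min": float(values.min()),
        "max": float(values.max()),
        "median": float(np.median(values)),
        "range": float(np.ptp(values)),
        "iqr": float(q3 - q1),
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float(np.mean(values**2)),
        "entropy": shannon_entropy(values),
        "p10": float(p10),
        "p90": float(p90),
    }


def aggregate_slices(per_slice: list[dict[str, float]], stats: tuple[str, ...]) -> dict[str, float]:
    """Mean and population-sd of each statistic across axial slices."""
    out: dict[str, float] = {}
    for stat in stats:
        vals = np.array([d[stat] for d in per_slice], dtype=float)
        if vals.size == 0:
            out[f"{stat}_mean"], out[f"{stat}_sd"] = 0.0, 0.0
        else:
            out[f"{stat}_mean"] = float(vals.mean())
            out[f"{stat}_sd"] = float(vals.std(ddof=0))
    return out
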