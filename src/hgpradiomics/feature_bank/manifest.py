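"""The feature manifest: the fixed, ordered list of the 564 feature names.

The manifest is the single source of truth for feature naming and order;
a copy is packaged as ``data/manifest.json`` and the two are verified
against each other in the test suite. Changing the manifest is a
breaking change for any stored feature table.

Layout (names follow ``family_parameters_statistic`` convention):

================  =====  =========================================================
family            count  parameterization
================  =====  =========================================================
hist                 13  first-order intensity statistics of the ROI
shape                23  8 per-slice 2D descriptors x {mean, sd} + 7 3D descriptors
texture_glcm         96  d in {1,3}, angle in {0,45,90,135} deg, 6 matrix statistics
                         x {mean, sd} over slices (16 gray levels)
texture_gabor       216  freq in {0.05, 0.2, 0.5} cyc/px, 4 angles, 9 response
                         statistics x {mean, sd}
texture_log          54  sigma in {1, 5, 10} px, 9 statistics x {mean, sd}
texture_vessel       54  region in {full, edge, inner}, 9 statistics x {mean, sd}
texture_phase        54  map in {monogenic phase, phase congruency, phase
                         symmetry}, 9 statistics x {mean, sd}
texture_lbp          54  (r, n) in {(1,8), (2,12), (3,16)}, 9 statistics x {mean, sd}
================  =====  =========================================================
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

N_FEATURES = 564

GLCM_DISTANCES = (1, 3)
GLCM_ANGLES_DEG = (0, 45, 90, 135)
GLCM_LEVELS = 16
GLCM_PROPS = ("contrast", "dissimilarity", "homogeneity", "ASM", "energy", "correlation")

GABOR_FREQS = (0.05, 0.2, 0.5)
GABOR_ANGLES_DEG = (0, 45, 90, 135)

LOG_SIGMAS = (1, 5, 10)

VESSEL_REGIONS = ("full", "edge", "inner")

PHASE_MAPS = ("monogenic_phase", "phase_congruency", "phase_symmetry")

LBP_PARAMS = ((1, 8), (2, 12), (3, 16))

#: statistics computed over the masked response of every filter map
RESPONSE_STATS = (
    "mean", "std", "min", "max", "median",
    "skewness", "kurtosis", "energy", "entropy",
)

#: first-order intensity statistics (3D, over all ROI voxels)
HIST_STATS = (
    "mean", "std", "min", "max", "median", "range", "iqr",
    "skewness", "kurtosis", "energy", "entropy", "p10", "p90",
)

#: per-slice 2D shape descriptors, aggregated with {mean, sd}
SHAPE_2D = (
    "area", "perimeter", "circularity", "eccentricity",
    "solidity", "extent", "major_axis", "minor_axis",
)

#: global 3D shape descriptors
SHAPE_3D = (
    "volume_vox", "volume_mm3", "n_slices", "surface_area_mm2",
    "compactness", "elongation", "flatness",
)

SLICE_AGGS = ("mean", "sd")


def _fmt(x: float) -> str:
    return f"{x:g}".replace(".", "p")


def build_manifest() -> list[dict[str, str]]:
    """Construct the ordered manifest as ``[{"name": ..., "family": ...}]``."""
    entries: list[dict[str, str]] = []

    def add(family: str, name: str) -> None:
        entries.append({"name": name, "family": family})

    for stat in HIST_STATS:
        add("hist", f"hist_{stat}")

    for prop in SHAPE_2D:
        for agg in SLICE_AGGS:
            add("shape", f"shape_2d_{prop}_{agg}")
    for prop in SHAPE_3D:
        add("shape", f"shape_3d_{prop}")

    for d in GLCM_DISTANCES:
        for a in GLCM_ANGLES_DEG:
            for prop in GLCM_PROPS:
                for agg in SLICE_AGGS:
                    add("texture_glcm", f"texture_glcm_d{d}_a{a}_{prop}_{agg}")

    for f in GABOR_FREQS:
        for a in GABOR_ANGLES_DEG:
            for stat in RESPONSE_STATS:
                for agg in SLICE_AGGS:
                    add("texture_gabor", f"texture_gabor_f{_fmt(f)}_a{a}_{stat}_{agg}")

    for s in LOG_SIGMAS:
        for stat in RESPONSE_STATS:
            for agg in SLICE_AGGS:
                add("texture_log", f"texture_log_s{s}_{stat}_{agg}")

    for region in VESSEL_REGIONS:
        for stat in RESPONSE_STATS:
            for agg in SLICE_AGGS:
                add("texture_vessel", f"texture_vessel_{region}_{stat}_{agg}")

    for pmap in PHASE_MAPS:
        for stat in RESPONSE_STATS:
            for agg in SLICE_AGGS:
                add("texture_phase", f"texture_phase_{pmap}_{stat}_{agg}")

    for r, n in LBP_PARAMS:
        for stat in RESPONSE_STATS:
            for agg in SLICE_AGGS:
                add("texture_lbp", f"texture_lbp_r{r}n{n}_{stat}_{agg}")

    assert len(entries) == N_FEATURES, len(entries)
    names = [e["name"] for e in entries]
    assert len(set(names)) == N_FEATURES, "duplicate feature names"
    return entries


@lru_cache(maxsize=1)
def feature_names() -> tuple[str, ...]:
    """The 564 feature names in manifest order."""
    return tuple(e["name"] for e in build_manifest())


@lru_cache(maxsize=1)
def feature_families() -> dict[str, str]:
    return {e["name"]: e["family"] for e in build_manifest()}


def load_packaged_manifest() -> list[dict[str, str]]:
    """Read the manifest JSON shipped inside the package."""
    ref = resources.files("hgpradiomics") / "data" / "manifest.json"
    return json.loads(ref.read_text())
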