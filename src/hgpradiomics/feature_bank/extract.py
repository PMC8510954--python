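"""Per-family feature extractors and the 564-feature ``extract_all``.

Conventions
-----------
* Volumes and masks are numpy arrays in ``(z, y, x)`` order; ``spacing``
  is millimetres per axis in the same order.
* Texture families are computed in 2D per axial slice intersecting the
  mask and aggregated with {mean, sd} across slices (segmentations are
  drawn slice-wise in the transverse plane, and slice spacing is usually
  far coarser than in-plane spacing, so 3D texture kernels would mix
  incommensurate scales).
* Filters are applied to a bounding-box crop of the volume (with an
  in-plane context margin) and statistics are taken over masked pixels
  only, which makes every feature invariant to whole-voxel translation
  of (volume, mask) together.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage import measure
from skimage.feature import graycomatrix, local_binary_pattern
from skimage.filters import frangi, gabor_kernel

from hgpradiomics.feature_bank import _stats, manifest
from hgpradiomics.feature_bank.filters import monogenic_maps
from hgpradiomics.roi_masks import STRUCT_6, EmptyMaskError

logger = logging.getLogger(__name__)

_INPLANE_MARGIN = 16


# ---------------------------------------------------------------------------
# helpers

def _check_inputs(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask) > 0
    if volume.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    if volume.ndim != 3:
        raise ValueError("expected 3D volume")
    if not mask.any():
        raise EmptyMaskError("cannot extract features from an empty mask")
    return mask


def _crop(volume: np.ndarray, mask: np.ndarray, margin: int = _INPLANE_MARGIN):
    """Crop to the mask bounding box with in-plane context margin."""
    zs, ys, xs = np.nonzero(mask)
    z0, z1 = zs.min(), zs.max() + 1
    y0 = max(0, ys.min() - margin)
    y1 = min(mask.shape[1], ys.max() + 1 + margin)
    x0 = max(0, xs.min() - margin)
    x1 = min(mask.shape[2], xs.max() + 1 + margin)
    sl = (slice(z0, z1), slice(y0, y1), slice(x0, x1))
    return volume[sl], mask[sl]


def _mask_slices(mask: np.ndarray):
    return [z for z in range(mask.shape[0]) if mask[z].any()]


def quantize(roi_intensities: np.ndarray, n_levels: int) -> np.ndarray:
    """Equal-width binning of ``[min, max]`` into integer levels ``0..n-1``.

    A constant input maps entirely to level 0.
    """
    if n_levels < 2:
        raise ValueError("need at least 2 gray levels")
    values = np.asarray(roi_intensities, dtype=float)
    if values.size == 0:
        raise ValueError("empty ROI")
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return np.zeros(values.shape, dtype=np.int64)
    levels = np.floor((values - lo) / (hi - lo) * n_levels).astype(np.int64)
    return np.clip(levels, 0, n_levels - 1)


# ---------------------------------------------------------------------------
# GLCM

def glcm_matrix(
    quantized: np.ndarray,
    mask2d: np.ndarray,
    distance: int,
    angle_deg: int,
    levels: int = manifest.GLCM_LEVELS,
) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix restricted to the mask.

    Pixels outside the mask are assigned a sentinel level and the
    corresponding row/column is dropped before normalization, so only
    pairs with both ends inside the mask contribute. Returns the
    ``levels x levels`` matrix (all zeros if no valid pair exists).
    """
    img = np.where(mask2d, quantized, levels).astype(np.uint8)
    p = graycomatrix(
        img,
        distances=[distance],
        angles=[math.radians(angle_deg)],
        levels=levels + 1,
        symmetric=True,
        normed=False,
    )[:levels, :levels, 0, 0].astype(float)
    total = p.sum()
    if total == 0:
        return p
    return p / total


def glcm_statistics(p: np.ndarray) -> dict[str, float]:
    """The 6 scalar co-occurrence statistics of one normalized matrix."""
    if p.sum() == 0:
        return {k: 0.0 for k in manifest.GLCM_PROPS}
    levels = p.shape[0]
    i, j = np.mgrid[0:levels, 0:levels]
    diff = i - j
    asm = float((p**2).sum())
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    var_i = float(((i - mu_i) ** 2 * p).sum())
    var_j = float(((j - mu_j) ** 2 * p).sum())
    if var_i > 0 and var_j > 0:
        corr = float((((i - mu_i) * (j - mu_j) * p).sum()) / math.sqrt(var_i * var_j))
    else:
        corr = 1.0  # degenerate single-level matrix: perfect agreement
    return {
        "contrast": float((p * diff**2).sum()),
        "dissimilarity": float((p * np.abs(diff)).sum()),
        "homogeneity": float((p / (1.0 + diff**2)).sum()),
        "ASM": asm,
        "energy": math.sqrt(asm),
        "correlation": corr,
    }


def glcm_features(
    volume: np.ndarray,
    mask: np.ndarray,
    distances: tuple[int, ...] = manifest.GLCM_DISTANCES,
    angles_deg: tuple[int, ...] = manifest.GLCM_ANGLES_DEG,
    levels: int = manifest.GLCM_LEVELS,
) -> dict[str, float]:
    mask = _check_inputs(volume, mask)
    vol, msk = _crop(np.asarray(volume, dtype=float), mask, margin=0)
    quantized = np.zeros(vol.shape, dtype=np.int64)
    quantized[msk] = quantize(vol[msk], levels)
    out: dict[str, float] = {}
    for d in distances:
        for a in angles_deg:
            per_slice = []
            for z in _mask_slices(msk):
                p = glcm_matrix(quantized[z], msk[z], d, a, levels)
                if p.sum() == 0:
                    # mask thinner than the offset in this slice: skip it;
                    # if no slice has a valid pair the aggregate zero-fills
                    logger.debug("GLCM d=%d a=%d: slice %d has no pairs, skipped", d, a, z)
                    continue
                per_slice.append(glcm_statistics(p))
            agg = _stats.aggregate_slices(per_slice, manifest.GLCM_PROPS)
            for prop in manifest.GLCM_PROPS:
                out[f"texture_glcm_d{d}_a{a}_{prop}_mean"] = agg[f"{prop}_mean"]
                out[f"texture_glcm_d{d}_a{a}_{prop}_sd"] = agg[f"{prop}_sd"]
    return out


# ---------------------------------------------------------------------------
# filter-bank families

def _filter_family(
    volume: np.ndarray,
    mask: np.ndarray,
    slice_maps,
    variants: list[str],
) -> dict[str, float]:
    """Aggregate the 9 response statistics for a family of filter maps.

    ``slice_maps(image2d) -> {variant: response2d}`` is called per axial
    slice; statistics are taken over masked pixels and aggregated.
    """
    mask = _check_inputs(volume, mask)
    vol, msk = _crop(np.asarray(volume, dtype=float), mask)
    per_variant: dict[str, list[dict[str, float]]] = {v: [] for v in variants}
    for z in _mask_slices(msk):
        responses = slice_maps(vol[z])
        for v in variants:
            per_variant[v].append(_stats.response_stats(responses[v][msk[z]]))
    out: dict[str, float] = {}
    for v in variants:
        agg = _stats.aggregate_slices(per_variant[v], manifest.RESPONSE_STATS)
        for stat in manifest.RESPONSE_STATS:
            out[f"{v}_{stat}_mean"] = agg[f"{stat}_mean"]
            out[f"{v}_{stat}_sd"] = agg[f"{stat}_sd"]
    return out


def gabor_features(
    volume: np.ndarray,
    mask: np.ndarray,
    freqs: tuple[float, ...] = manifest.GABOR_FREQS,
    angles_deg: tuple[int, ...] = manifest.GABOR_ANGLES_DEG,
) -> dict[str, float]:
    kernels = {
        (f, a): gabor_kernel(frequency=f, theta=math.radians(a))
        for f in freqs
        for a in angles_deg
    }
    variants = [
        f"texture_gabor_f{manifest._fmt(f)}_a{a}" for f in freqs for a in angles_deg
    ]

    def slice_maps(image2d: np.ndarray) -> dict[str, np.ndarray]:
        centered = image2d - image2d.mean()  # zero DC: flat field -> zero response
        out = {}
        for (f, a), kern in kernels.items():
            resp = fftconvolve(centered, kern, mode="same")
            out[f"texture_gabor_f{manifest._fmt(f)}_a{a}"] = np.abs(resp)
        return out

    return _filter_family(volume, mask, slice_maps, variants)


def log_features(
    volume: np.ndarray,
    mask: np.ndarray,
    sigmas: tuple[int, ...] = manifest.LOG_SIGMAS,
) -> dict[str, float]:
    variants = [f"texture_log_s{s}" for s in sigmas]

    def slice_maps(image2d: np.ndarray) -> dict[str, np.ndarray]:
        centered = image2d - image2d.mean()  # flat field -> exactly zero response
        return {
            f"texture_log_s{s}": ndimage.gaussian_laplace(centered, sigma=s)
            for s in sigmas
        }

    return _filter_family(volume, mask, slice_maps, variants)


def lbp_features(
    volume: np.ndarray,
    mask: np.ndarray,
    params: tuple[tuple[int, int], ...] = manifest.LBP_PARAMS,
) -> dict[str, float]:
    variants = [f"texture_lbp_r{r}n{n}" for r, n in params]

    def slice_maps(image2d: np.ndarray) -> dict[str, np.ndarray]:
        with warnings.catch_warnings():
            # float input is intentional: sign-based codes stay exactly
            # invariant under constant intensity offsets
            warnings.simplefilter("ignore", UserWarning)
            return {
                f"texture_lbp_r{r}n{n}": local_binary_pattern(image2d, P=n, R=r, method="default")
                for r, n in params
            }

    return _filter_family(volume, mask, slice_maps, variants)


def local_phase_features(volume: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    variants = [f"texture_phase_{m}" for m in manifest.PHASE_MAPS]

    def slice_maps(image2d: np.ndarray) -> dict[str, np.ndarray]:
        maps = monogenic_maps(image2d)
        return {f"texture_phase_{m}": maps[m] for m in manifest.PHASE_MAPS}

    return _filter_family(volume, mask, slice_maps, variants)


def vessel_features(
    volume: np.ndarray,
    mask: np.ndarray,
    erosion_width: int = 1,
) -> dict[str, float]:
    """Tubular-structure (vesselness) response statistics per sub-region.

    ``edge``/``inner`` partition the mask by a fixed-width 3D erosion;
    an empty inner region zero-fills its statistics.
    """
    mask = _check_inputs(volume, mask)
    vol, msk = _crop(np.asarray(volume, dtype=float), mask)
    inner = ndimage.binary_erosion(msk, STRUCT_6, iterations=erosion_width)
    edge = np.logical_and(msk, np.logical_not(inner))
    regions = {"full": msk, "edge": edge, "inner": inner}

    per_region: dict[str, list[dict[str, float]]] = {r: [] for r in regions}
    for z in _mask_slices(msk):
        with np.errstate(invalid="ignore", divide="ignore"):
            vmap = frangi(vol[z], sigmas=(1.0, 2.0, 3.0), black_ridges=False)
        vmap = np.nan_to_num(vmap)
        for rname, rmask in regions.items():
            if rmask[z].any():
                per_region[rname].append(_stats.response_stats(vmap[rmask[z]]))
    out: dict[str, float] = {}
    for rname in manifest.VESSEL_REGIONS:
        agg = _stats.aggregate_slices(per_region[rname], manifest.RESPONSE_STATS)
        for stat in manifest.RESPONSE_STATS:
            out[f"texture_vessel_{rname}_{stat}_mean"] = agg[f"{stat}_mean"]
            out[f"texture_vessel_{rname}_{stat}_sd"] = agg[f"{stat}_sd"]
    return out


# ---------------------------------------------------------------------------
# first-order intensity + shape

def _surface_area_mm2(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Exposed-face (voxelized) surface area in mm^2."""
    area = 0.0
    face = (spacing[1] * spacing[2], spacing[0] * spacing[2], spacing[0] * spacing[1])
    for axis in range(3):
        m = np.moveaxis(mask, axis, 0)
        exposed = int(np.sum(m[:-1] != m[1:])) + int(m[0].sum()) + int(m[-1].sum())
        area += exposed * face[axis]
    return float(area)


def _largest_region(mask2d: np.ndarray):
    labels = measure.label(mask2d)
    regions = measure.regionprops(labels)
    return max(regions, key=lambda r: r.area)


def histogram_shape_features(
    volume: np.ndarray,
    mask: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> dict[str, float]:
    mask = _check_inputs(volume, mask)
    volume = np.asarray(volume, dtype=float)
    out: dict[str, float] = {}

    for stat, val in _stats.histogram_stats(volume[mask]).items():
        out[f"hist_{stat}"] = val

    per_slice: list[dict[str, float]] = []
    for z in _mask_slices(mask):
        region = _largest_region(mask[z])
        perim = float(region.perimeter)
        circ = 4.0 * math.pi * region.area / perim**2 if perim > 0 else 0.0
        per_slice.append(
            {
                "area": float(region.area),
                "perimeter": perim,
                "circularity": circ,
                "eccentricity": float(region.eccentricity),
                "solidity": float(region.solidity),
                "extent": float(region.extent),
                "major_axis": float(region.axis_major_length),
                "minor_axis": float(region.axis_minor_length),
            }
        )
    agg = _stats.aggregate_slices(per_slice, manifest.SHAPE_2D)
    for prop in manifest.SHAPE_2D:
        out[f"shape_2d_{prop}_mean"] = agg[f"{prop}_mean"]
        out[f"shape_2d_{prop}_sd"] = agg[f"{prop}_sd"]

    n_vox = int(mask.sum())
    voxel_volume = float(np.prod(spacing))
    volume_mm3 = n_vox * voxel_volume
    surface = _surface_area_mm2(mask, spacing)
    compactness = (36.0 * math.pi * volume_mm3**2) ** (1.0 / 3.0) / surface
    coords = np.argwhere(mask) * np.asarray(spacing)
    if len(coords) > 1:
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(coords.T)))[::-1]
        eigvals = np.clip(eigvals, 0.0, None)
        elongation = math.sqrt(eigvals[1] / eigvals[0]) if eigvals[0] > 0 else 1.0
        flatness = math.sqrt(eigvals[2] / eigvals[0]) if eigvals[0] > 0 else 1.0
    else:
        elongation = flatness = 1.0
    out.update(
        {
            "shape_3d_volume_vox": float(n_vox),
            "shape_3d_volume_mm3": volume_mm3,
            "shape_3d_n_slices": float(len(per_slice)),
            "shape_3d_surface_area_mm2": surface,
            "shape_3d_compactness": compactness,
            "shape_3d_elongation": elongation,
            "shape_3d_flatness": flatness,
        }
    )
    return out


# ---------------------------------------------------------------------------
# full extraction

def extract_all(
    volume: np.ndarray,
    mask: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> pd.Series:
    """Extract the full 564-feature vector for one ROI, in manifest order."""
    _check_inputs(volume, mask)
    values: dict[str, float] = {}
    values.update(histogram_shape_features(volume, mask, spacing))
    values.update(glcm_features(volume, mask))
    values.update(gabor_features(volume, mask))
    values.update(log_features(volume, mask))
    values.update(vessel_features(volume, mask))
    values.update(local_phase_features(volume, mask))
    values.update(lbp_features(volume, mask))

    names = manifest.feature_names()
    missing = set(names) - set(values)
    if missing:
        raise RuntimeError(f"extractor returned no value for: {sorted(missing)[:5]}...")
    vec = pd.Series([values[n] for n in names], index=list(names), dtype=float)
    bad = ~np.isfinite(vec.to_numpy())
    if bad.any():
        logger.warning("non-finite features zero-filled: %s", list(vec.index[bad]))
        vec[bad] = 0.0
    return vec
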