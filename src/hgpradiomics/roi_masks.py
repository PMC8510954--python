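"""Binary-mask algebra: Dice agreement and derivation of the four ROI kinds.

All masks are boolean 3D numpy arrays aligned to a common voxel grid.
Morphology uses a 6-connected (face-adjacency) structuring element.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

#: 6-connected structuring element used for all ring/NLP morphology.
STRUCT_6 = ndimage.generate_binary_structure(3, 1)


class EmptyMaskError(ValueError):
    """Raised when an operation receives or produces an empty mask."""


def _as_bool(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype != bool:
        mask = mask > 0
    return mask


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient ``2|a∩b| / (|a|+|b|)``.

    Two empty masks have DSC 1.0 (agreement on absence).

    Raises
    ------
    ValueError
        If the masks are not on the same grid.
    """
    a = _as_bool(a)
    b = _as_bool(b)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    size = int(a.sum()) + int(b.sum())
    if size == 0:
        return 1.0
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / size


def pairwise_dice_table(
    masks_by_lesion: Mapping[str, Mapping[str, np.ndarray]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean and standard deviation of pairwise DSC per observer pair.

    Parameters
    ----------
    masks_by_lesion
        ``{lesion_id: {observer: mask}}``. Observers may be missing for
        individual lesions; a pair is averaged over the lesions it shares.

    Returns
    -------
    (mean, sd)
        Two square data frames indexed by observer. The diagonal of the
        mean table is 1 (sd 0). Pairs sharing no lesion are NaN.
    """
    observers = sorted({o for m in masks_by_lesion.values() for o in m})
    if len(observers) < 2:
        raise ValueError("need at least two observers")
    mean = pd.DataFrame(np.nan, index=observers, columns=observers)
    sd = pd.DataFrame(np.nan, index=observers, columns=observers)
    for o in observers:
        mean.loc[o, o] = 1.0
        sd.loc[o, o] = 0.0
    for o1, o2 in combinations(observers, 2):
        vals = [
            dice(m[o1], m[o2])
            for m in masks_by_lesion.values()
            if o1 in m and o2 in m
        ]
        if not vals:
            logger.warning("observers %s/%s share no lesions", o1, o2)
            continue
        mean.loc[o1, o2] = mean.loc[o2, o1] = float(np.mean(vals))
        sd.loc[o1, o2] = sd.loc[o2, o1] = float(np.std(vals, ddof=0))
    return mean, sd


def make_ring(lesion: np.ndarray, width_voxels: int = 2) -> np.ndarray:
    """Morphological shell straddling the lesion boundary.

    ``dilation(lesion, w) \\ erosion(lesion, w)`` with a 6-connected
    element. If the erosion removes the lesion entirely the degenerate
    rule ``dilation \\ lesion`` is used and logged.
    """
    if width_voxels < 1:
        raise ValueError("ring width must be >= 1 voxel")
    lesion = _as_bool(lesion)
    if not lesion.any():
        raise EmptyMaskError("cannot ring an empty lesion mask")
    dil = ndimage.binary_dilation(lesion, STRUCT_6, iterations=width_voxels)
    ero = ndimage.binary_erosion(lesion, STRUCT_6, iterations=width_voxels)
    if not ero.any():
        logger.info("lesion vanished under erosion; using dilation \\ lesion")
        return np.logical_and(dil, np.logical_not(lesion))
    return np.logical_and(dil, np.logical_not(ero))


def derive_nlp(
    liver_mask: np.ndarray, lesion_masks: Sequence[np.ndarray]
) -> np.ndarray:
    """Normal-parenchyma ROI: liver minus the union of all lesion masks."""
    liver = _as_bool(liver_mask)
    if not liver.any():
        raise EmptyMaskError("liver mask is empty")
    out = liver.copy()
    for m in lesion_masks:
        out &= np.logical_not(_as_bool(m))
    if not out.any():
        raise EmptyMaskError("lesions cover the entire liver mask")
    return out


@dataclass(frozen=True)
class RoiSet:
    """The four ROI masks derived for one lesion.

    Invariants: ``nlp_plus_lesion == nlp | lesion``, ``lesion & nlp`` is
    empty, and ``ring`` lies within ``dilation(lesion) \\ erosion(lesion)``.
    """

    lesion: np.ndarray
    nlp: np.ndarray
    nlp_plus_lesion: np.ndarray
    ring: np.ndarray

    def validate(self) -> None:
        if np.logical_and(self.lesion, self.nlp).any():
            raise ValueError("lesion and NLP overlap")
        if not np.array_equal(
            self.nlp_plus_lesion, np.logical_or(self.nlp, self.lesion)
        ):
            raise ValueError("nlp_plus_lesion is not union(nlp, lesion)")


def derive_roi_set(
    liver_mask: np.ndarray,
    lesion_mask: np.ndarray,
    all_lesion_masks: Sequence[np.ndarray] | None = None,
    ring_width: int = 2,
) -> RoiSet:
    """Build the full :class:`RoiSet` for one lesion."""
    lesion = _as_bool(lesion_mask)
    lesions = list(all_lesion_masks) if all_lesion_masks is not None else [lesion]
    nlp = derive_nlp(liver_mask, lesions)
    return RoiSet(
        lesion=lesion,
        nlp=nlp,
        nlp_plus_lesion=np.logical_or(nlp, lesion),
        ring=make_ring(lesion, ring_width),
    )
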