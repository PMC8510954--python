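"""Synthetic cohort generator: the testable stand-in for the patient CTs.

Generates per-patient 3D volumes (smooth parenchyma-like background plus
ellipsoidal lesions), a reference mask per lesion, perturbed masks for a
panel of observers with calibrated Dice agreement, scanner batch effects
on voxel intensities, and a lesion/patient metadata table.

The two lesion classes differ only through a parameterized texture
signal (a bright boundary rim plus fine-grained interior texture for the
positive class versus coarse-grained texture for the negative class),
scaled by ``texture_effect``; at ``texture_effect=0`` the classes are
statistically identical, which is the null configuration used for
calibration tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from hgpradiomics.roi_masks import dice

HUMAN_OBSERVERS = ("STUD1", "STUD2", "PhD", "RAD")
CNN_OBSERVER = "CNN"
TRAIN_OBSERVERS = ("STUD2", "PhD", "RAD")  # multi-observer training panel

#: default per-observer Dice targets versus the reference mask, calibrated
#: so that the simulated panel reproduces intra-observer pairwise DSC near
#: 0.80 (STUD1 vs STUD2) and a mean inter-observer pairwise DSC near 0.69.
DEFAULT_DSC_TARGETS: dict[str, float] = {
    "STUD1": 0.88,
    "STUD2": 0.88,
    "PhD": 0.79,
    "RAD": 0.76,
    "CNN": 0.84,
}

#: additive HU shift and multiplicative scale per manufacturer
DEFAULT_BATCH_EFFECTS: dict[str, tuple[float, float]] = {
    "Siemens": (0.0, 1.00),
    "Philips": (12.0, 1.06),
    "Toshiba": (-12.0, 0.94),
    "GE": (20.0, 1.10),
}

#: sampling weights mirroring the 43/16/16/1 manufacturer split
DEFAULT_MANUFACTURER_WEIGHTS: dict[str, float] = {
    "Siemens": 43.0,
    "Philips": 16.0,
    "Toshiba": 16.0,
    "GE": 1.0,
}


class PerturbationInfeasibleError(ValueError):
    """Raised when a Dice target cannot be met for a (tiny) mask."""


@dataclass(frozen=True)
class AcquisitionMeta:
    manufacturer: str
    slice_thickness: float
    pixel_spacing: float
    tube_current: float
    peak_kilovoltage: float

    def __post_init__(self) -> None:
        for name in ("slice_thickness", "pixel_spacing", "tube_current", "peak_kilovoltage"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort (defaults mirror the study cohort)."""

    n_patients: int = 76
    #: probability of 1, 2, 3, ... lesions for a patient
    lesions_per_patient: tuple[float, ...] = (0.76, 0.20, 0.04)
    class_balance: float = 46.0 / 93.0
    texture_effect: float = 1.0
    batch_effects: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BATCH_EFFECTS)
    )
    manufacturer_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MANUFACTURER_WEIGHTS)
    )
    observer_dsc_targets: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DSC_TARGETS)
    )
    cnn_miss_rate: float = 8.0 / 93.0
    clinical_effect: float = 0.0
    shape: tuple[int, int, int] = (24, 64, 64)  # (z, y, x)
    spacing: tuple[float, float, float] = (2.0, 0.8, 0.8)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        for frac in (self.class_balance, self.cnn_miss_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(self.lesions_per_patient) - 1.0) > 1e-9:
            raise ValueError("lesions_per_patient must sum to 1")
        if min(self.shape) < 16 or self.shape[1] < 32 or self.shape[2] < 32:
            raise ValueError(f"grid {self.shape} too small to host lesions")
        for obs, t in self.observer_dsc_targets.items():
            if not 0.0 < t <= 1.0:
                raise ValueError(f"DSC target for {obs} outside (0, 1]")


@dataclass
class SyntheticLesion:
    patient_id: str
    lesion_id: str
    label: str  # "dHGP" or "rHGP"
    reference_mask: np.ndarray
    observer_masks: dict[str, np.ndarray]
    cnn_missed: bool = False


@dataclass
class SyntheticPatient:
    patient_id: str
    volume: np.ndarray
    liver_mask: np.ndarray
    acquisition: AcquisitionMeta
    clinical: dict[str, float | str]
    lesions: list[SyntheticLesion]


@dataclass
class SyntheticCohort:
    config: CohortConfig
    patients: list[SyntheticPatient]

    def iter_lesions(self) -> Iterator[tuple[SyntheticPatient, SyntheticLesion]]:
        for p in self.patients:
            for lesion in p.lesions:
                yield p, lesion

    @property
    def n_lesions(self) -> int:
        return sum(len(p.lesions) for p in self.patients)

    def metadata(self) -> pd.DataFrame:
        """Lesion-level metadata table (one row per lesion)."""
        rows = []
        for p, lesion in self.iter_lesions():
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "lesion_id": lesion.lesion_id,
                    "label": lesion.label,
                    "manufacturer": p.acquisition.manufacturer,
                    "slice_thickness": p.acquisition.slice_thickness,
                    "pixel_spacing": p.acquisition.pixel_spacing,
                    "cnn_missed": lesion.cnn_missed,
                    **{f"clinical_{k}": v for k, v in p.clinical.items()},
                }
            )
        return pd.DataFrame(rows)

    def to_directory(self, path: str | Path) -> None:
        """Write volumes/masks as NIfTI and the metadata table as CSV."""
        import nibabel as nib

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        affine = np.diag([*self.config.spacing[::-1], 1.0])

        def save(arr: np.ndarray, name: str) -> None:
            img = nib.Nifti1Image(
                np.asarray(arr, dtype=np.float32).transpose(2, 1, 0), affine
            )
            nib.save(img, path / name)

        for p in self.patients:
            save(p.volume, f"{p.patient_id}_volume.nii.gz")
            save(p.liver_mask, f"{p.patient_id}_liver.nii.gz")
            for lesion in p.lesions:
                save(lesion.reference_mask, f"{lesion.lesion_id}_ref.nii.gz")
                for obs, m in lesion.observer_masks.items():
                    save(m, f"{lesion.lesion_id}_{obs}.nii.gz")
        self.metadata().to_csv(path / "metadata.csv", index=False)


# ---------------------------------------------------------------------------
# mask perturbation

def _signed_distance(mask: np.ndarray) -> np.ndarray:
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return inside - outside


def boundary_perturbation(
    sdf: np.ndarray, noise: np.ndarray, magnitude: float, bias: float = 0.0
) -> np.ndarray:
    """Threshold a jittered signed-distance function.

    ``magnitude`` scales a smooth noise field added to the SDF; ``bias``
    > 0 shrinks the mask (conservative outline). Exposed separately so
    the monotone magnitude→DSC relationship is directly testable.
    """
    return (sdf + magnitude * noise - bias) > 0


def perturb_mask(
    mask: np.ndarray,
    target_dsc: float,
    seed: int | np.random.Generator,
    bias: float = 0.0,
    tol: float = 0.02,
) -> np.ndarray:
    """Random boundary perturbation solved to a Dice target by bisection.

    Raises :class:`PerturbationInfeasibleError` when the target cannot be
    approached within ``±0.05`` (typically masks below ~30 voxels).
    """
    if not 0.0 < target_dsc <= 1.0:
        raise ValueError("target_dsc must lie in (0, 1]")
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("cannot perturb an empty mask")
    if target_dsc == 1.0 and bias == 0.0:
        return mask.copy()

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sdf = _signed_distance(mask)
    noise = ndimage.gaussian_filter(rng.standard_normal(mask.shape), sigma=1.5)
    noise /= max(noise.std(), 1e-12)

    def dsc_at(a: float) -> float:
        return dice(mask, boundary_perturbation(sdf, noise, a, bias))

    lo, hi = 0.0, 1.0
    while dsc_at(hi) > target_dsc and hi < 64.0:
        lo, hi = hi, hi * 2.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if dsc_at(mid) > target_dsc:
            lo = mid
        else:
            hi = mid
    best = min((lo, hi, 0.5 * (lo + hi)), key=lambda a: abs(dsc_at(a) - target_dsc))
    out = boundary_perturbation(sdf, noise, best, bias)
    if abs(dice(mask, out) - target_dsc) > 0.05 or not out.any():
        raise PerturbationInfeasibleError(
            f"cannot reach DSC {target_dsc:.2f} for a {int(mask.sum())}-voxel mask"
        )
    return out


def simulate_cnn_observer(
    cohort: SyntheticCohort,
    miss_rate: float | None = None,
    fallback_observer: str = "RAD",
    seed: int | None = None,
) -> SyntheticCohort:
    """Attach the automated observer's masks to every lesion (in place).

    A fraction ``miss_rate`` of lesions is flagged missed and receives
    the fallback observer's mask verbatim; all other lesions receive a
    conservatively biased (slightly eroded) boundary perturbation.
    """
    if miss_rate is None:
        miss_rate = cohort.config.cnn_miss_rate
    if not 0.0 <= miss_rate <= 1.0:
        raise ValueError("miss_rate must lie in [0, 1]")
    rng = np.random.default_rng(
        cohort.config.seed + 104729 if seed is None else seed
    )
    lesions = [lesion for _, lesion in cohort.iter_lesions()]
    for lesion in lesions:
        if fallback_observer not in lesion.observer_masks:
            raise ValueError(f"lesion {lesion.lesion_id} lacks fallback {fallback_observer}")
    n_missed = int(round(miss_rate * len(lesions)))
    missed_idx = set(rng.choice(len(lesions), size=n_missed, replace=False).tolist())
    target = cohort.config.observer_dsc_targets.get(CNN_OBSERVER, 0.84)
    for i, lesion in enumerate(lesions):
        if i in missed_idx:
            lesion.observer_masks[CNN_OBSERVER] = lesion.observer_masks[fallback_observer]
            lesion.cnn_missed = True
        else:
            lesion.observer_masks[CNN_OBSERVER] = perturb_mask(
                lesion.reference_mask, target, rng, bias=0.3
            )
            lesion.cnn_missed = False
    return cohort


# ---------------------------------------------------------------------------
# volume synthesis

def _ellipsoid(shape: tuple[int, int, int], center: np.ndarray, radii: np.ndarray) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((zz - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((xx - center[2]) / radii[2]) ** 2
    ) <= 1.0


def _smooth_field(rng: np.random.Generator, shape, sigma, sd: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    f *= sd / max(f.std(), 1e-12)
    return f


def _class_texture(
    rng: np.random.Generator,
    lesion_mask: np.ndarray,
    label: str,
    effect: float,
) -> np.ndarray:
    """Additive texture signal inside the lesion, scaled by ``effect``."""
    shape = lesion_mask.shape
    if effect == 0.0:
        return np.zeros(shape)
    if label == "dHGP":
        # fibrous-rim analogue: bright shell at the boundary + fine texture
        depth = ndimage.distance_transform_edt(lesion_mask)
        rim = np.exp(-0.5 * (depth - 1.0) ** 2) * lesion_mask
        fine = _smooth_field(rng, shape, sigma=0.7, sd=8.0)
        signal = 12.0 * rim + fine * lesion_mask
    else:
        # replacement analogue: coarse, blob-like interior texture
        coarse = _smooth_field(rng, shape, sigma=2.2, sd=8.0)
        signal = coarse * lesion_mask
    return effect * signal


def _sample_acquisition(rng: np.random.Generator, config: CohortConfig) -> AcquisitionMeta:
    manus = list(config.manufacturer_weights)
    w = np.array([config.manufacturer_weights[m] for m in manus], dtype=float)
    manufacturer = str(rng.choice(manus, p=w / w.sum()))
    return AcquisitionMeta(
        manufacturer=manufacturer,
        slice_thickness=float(rng.choice([2.5, 3.0, 4.0, 5.0])),
        pixel_spacing=float(np.round(rng.normal(0.74, 0.05), 3)),
        tube_current=float(int(np.clip(rng.normal(240, 60), 80, 500))),
        peak_kilovoltage=120.0,
    )


def _sample_clinical(
    rng: np.random.Generator, label: str, effect: float
) -> dict[str, float | str]:
    # independent of the class label by default (effect shifts age only)
    shift = effect * (5.0 if label == "dHGP" else -5.0)
    return {
        "age": float(np.round(np.clip(rng.normal(68, 9) + shift, 30, 95), 1)),
        "sex": str(rng.choice(["M", "F"], p=[0.58, 0.42])),
        "nodal_status": str(rng.choice(["N0", "N+"], p=[0.46, 0.54])),
        "dfi_over_12m": str(rng.choice(["no", "yes"])),
        "cea": float(np.round(np.clip(rng.lognormal(2.0, 1.0), 0.5, 400.0), 1)),
    }


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort (deterministic under the seed)."""
    config.validate()
    root = np.random.default_rng(config.seed)
    nz, ny, nx = config.shape

    n_pos = int(round(config.class_balance * config.n_patients))
    labels = ["dHGP"] * n_pos + ["rHGP"] * (config.n_patients - n_pos)
    root.shuffle(labels)

    patients: list[SyntheticPatient] = []
    for idx in range(config.n_patients):
        rng = np.random.default_rng(root.integers(0, 2**63))
        pid = f"P{idx:03d}"
        label = labels[idx]
        acquisition = _sample_acquisition(rng, config)

        volume = 100.0 + _smooth_field(rng, config.shape, sigma=(1.5, 6.0, 6.0), sd=10.0)
        liver_center = np.array([nz / 2, ny / 2, nx / 2])
        liver_radii = np.array([nz * 0.42, ny * 0.40, nx * 0.40])
        liver = _ellipsoid(config.shape, liver_center, liver_radii)

        n_lesions = int(
            rng.choice(np.arange(1, len(config.lesions_per_patient) + 1),
                       p=np.asarray(config.lesions_per_patient)))
        lesions: list[SyntheticLesion] = []
        occupied = np.zeros(config.shape, dtype=bool)
        for j in range(n_lesions):
            for _attempt in range(60):
                radii = np.array([
                    rng.uniform(2.5, 4.0),
                    rng.uniform(5.0, 9.0),
                    rng.uniform(5.0, 9.0),
                ])
                center = liver_center + (rng.uniform(-0.45, 0.45, size=3) * liver_radii)
                ref = _ellipsoid(config.shape, center, radii) & liver
                if ref.sum() >= 150 and not (ref & occupied).any():
                    break
            else:  # pragma: no cover - extremely unlikely at default sizes
                continue
            occupied |= ndimage.binary_dilation(ref, iterations=2)
            volume[ref] = 70.0 + volume[ref] - 100.0  # hypodense core
            volume += _class_texture(rng, ref, label, config.texture_effect)

            observer_masks = {
                obs: perturb_mask(ref, config.observer_dsc_targets[obs], rng)
                for obs in HUMAN_OBSERVERS
            }
            lesions.append(
                SyntheticLesion(
                    patient_id=pid,
                    lesion_id=f"{pid}_L{j}",
                    label=label,
                    reference_mask=ref,
                    observer_masks=observer_masks,
                )
            )

        shift, scale = config.batch_effects.get(acquisition.manufacturer, (0.0, 1.0))
        volume = volume * scale + shift

        patients.append(
            SyntheticPatient(
                patient_id=pid,
                volume=volume,
                liver_mask=liver,
                acquisition=acquisition,
                clinical=_sample_clinical(rng, label, config.clinical_effect),
                lesions=lesions,
            )
        )

    cohort = SyntheticCohort(config=config, patients=patients)
    simulate_cnn_observer(cohort)
    return cohort
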