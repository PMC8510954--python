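"""2D monogenic-signal local-phase maps (phase, congruency, symmetry).

The monogenic signal extends the analytic signal to 2D via the Riesz
transform. Band-pass selection uses log-Gabor radial filters (which have
zero DC response, so constant images map to identically zero phase
energy). Phase congruency and phase symmetry follow the usual
"vector sum over scales / scalar sum of amplitudes" construction, which
makes both measures invariant to positive rescaling of the image.
"""

from __future__ import annotations

import numpy as np

DEFAULT_WAVELENGTHS = (4.0, 8.0, 16.0)
_SIGMA_ON_F = 0.55


def _log_gabor(radius: np.ndarray, wavelength: float) -> np.ndarray:
    f0 = 1.0 / wavelength
    with np.errstate(divide="ignore"):
        lg = np.exp(-(np.log(radius / f0) ** 2) / (2 * np.log(_SIGMA_ON_F) ** 2))
    lg[radius == 0] = 0.0  # kill DC
    return lg


def monogenic_maps(
    image: np.ndarray, wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS
) -> dict[str, np.ndarray]:
    """Return the three local-phase maps for a 2D image.

    Returns a dict with keys ``monogenic_phase`` (radians, mid scale),
    ``phase_congruency`` (in [0, 1]) and ``phase_symmetry`` (in [-1, 1]).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    rows, cols = image.shape
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    radius = np.hypot(fy, fx)
    radius_safe = np.where(radius == 0, 1.0, radius)
    # Riesz transfer functions
    h1 = -1j * fx / radius_safe
    h2 = -1j * fy / radius_safe

    spectrum = np.fft.fft2(image)

    sum_even = np.zeros_like(image)
    sum_odd1 = np.zeros_like(image)
    sum_odd2 = np.zeros_like(image)
    sum_amp = np.zeros_like(image)
    sum_abs_even = np.zeros_like(image)
    sum_abs_odd = np.zeros_like(image)
    mid_phase = np.zeros_like(image)

    mid = len(wavelengths) // 2
    for i, wl in enumerate(wavelengths):
        lg = _log_gabor(radius, wl)
        banded = spectrum * lg
        even = np.real(np.fft.ifft2(banded))
        odd1 = np.real(np.fft.ifft2(banded * h1))
        odd2 = np.real(np.fft.ifft2(banded * h2))
        odd = np.hypot(odd1, odd2)
        amp = np.hypot(even, odd)
        sum_even += even
        sum_odd1 += odd1
        sum_odd2 += odd2
        sum_amp += amp
        sum_abs_even += np.abs(even)
        sum_abs_odd += odd
        if i == mid:
            mid_phase = np.arctan2(odd, even)

    # relative epsilon keeps the maps invariant to positive intensity scaling
    eps = 1e-12 + 1e-4 * float(sum_amp.mean())
    congruency = np.sqrt(sum_even**2 + sum_odd1**2 + sum_odd2**2) / (sum_amp + eps)
    symmetry = (sum_abs_even - sum_abs_odd) / (sum_amp + eps)
    return {
        "monogenic_phase": mid_phase,
        "phase_congruency": congruency,
        "phase_symmetry": symmetry,
    }
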