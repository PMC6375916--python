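"""Synthetic spin-lock phantoms and contrast-enhanced image pairs.

The phantom is deliberately simple — circular lesions and vessels on a
uniform parenchymal background — because its purpose is to exercise the
relaxometry and ROI machinery against a known ground truth, not to look
like a liver.  Parenchyma pixels decay mono-exponentially with the
spin-lock time; vessel pixels carry a flat bright signal so that failing
to exclude them measurably biases a T1rho estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .relaxometry import SpinLockSeries

DEFAULT_SPIN_LOCK_TIMES = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0)
#: 30 cm field of view over a 128x128 matrix.
DEFAULT_PIXEL_SPACING_MM = 300.0 / 128


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and signal model of a 2D spin-lock phantom.

    Lesions are ``(row, col, radius_px, t1rho_ms)`` circles painted over the
    background relaxation time; vessels are ``(row, col, radius_px)`` circles
    flagged as non-parenchyma and rendered with a flat bright signal.
    """

    grid_shape: tuple[int, int] = (128, 128)
    background_t1rho: float = 47.56  # ms, noncirrhotic parenchyma scale
    lesions: tuple[tuple[float, float, float, float], ...] = ()
    vessels: tuple[tuple[float, float, float], ...] = ()
    s0_value: float = 1000.0
    vessel_signal: float = 2500.0
    noise_sigma: float = 0.0
    noise_model: str = "gaussian"  # or "rician"
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 2 or any(n < 1 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be 2D positive, got {self.grid_shape}")
        if self.background_t1rho <= 0:
            raise ValueError("background_t1rho must be > 0")
        if self.s0_value <= 0:
            raise ValueError("s0_value must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        for r, c, rad, t1 in self.lesions:
            if t1 <= 0:
                raise ValueError(f"lesion t1rho must be > 0, got {t1}")
            self._check_circle(r, c, rad, "lesion")
        for r, c, rad in self.vessels:
            self._check_circle(r, c, rad, "vessel")

    def _check_circle(self, row: float, col: float, radius: float, what: str) -> None:
        if radius < 1:
            raise ValueError(f"{what} radius must be >= 1 px, got {radius}")
        nr, nc = self.grid_shape
        if not (radius <= row <= nr - 1 - radius and radius <= col <= nc - 1 - radius):
            raise ValueError(f"{what} at ({row}, {col}) r={radius} exceeds grid bounds")

    def t1rho_truth(self) -> np.ndarray:
        """Ground-truth T1rho map in ms (vessel pixels keep the background value)."""
        t1 = np.full(self.grid_shape, self.background_t1rho, dtype=float)
        for r, c, rad, val in self.lesions:
            t1[_disk(self.grid_shape, (r, c), rad)] = val
        return t1

    def vessel_mask(self) -> np.ndarray:
        mask = np.zeros(self.grid_shape, dtype=bool)
        for r, c, rad in self.vessels:
            mask |= _disk(self.grid_shape, (r, c), rad)
        return mask


@dataclass(frozen=True)
class DecayPhantom:
    """A simulated spin-lock series together with its ground truth."""

    series: SpinLockSeries
    t1rho_truth: np.ndarray
    vessel_mask: np.ndarray = field(repr=False)


def _disk(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _add_noise(clean: np.ndarray, sigma: float, model: str, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return clean.copy()
    if model == "gaussian":
        return clean + rng.normal(0.0, sigma, clean.shape)
    # Rician: magnitude of a complex signal with iid Gaussian channel noise.
    re = clean + rng.normal(0.0, sigma, clean.shape)
    im = rng.normal(0.0, sigma, clean.shape)
    return np.hypot(re, im)


def simulate_decay_series(
    spec: PhantomSpec,
    spin_lock_times: "list[float] | tuple[float, ...]" = DEFAULT_SPIN_LOCK_TIMES,
    slice_id: str = "cranial",
    rng: np.random.Generator | None = None,
) -> DecayPhantom:
    """Simulate one T1rho-weighted image per spin-lock time.

    Parenchyma pixels follow ``S = S0 * exp(-T_SL / T1rho(pixel))``; vessel
    pixels hold a flat bright value independent of T_SL.  Noise is added per
    ``spec.noise_model``.  Returns the series plus the ground-truth T1rho map
    and vessel mask.
    """
    tsl = np.asarray(spin_lock_times, dtype=float)
    if tsl.size == 0:
        raise ValueError("spin_lock_times must be non-empty")
    if np.any(tsl < 0):
        raise ValueError("spin_lock_times must be non-negative")
    if np.any(np.diff(tsl) <= 0):
        raise ValueError("spin_lock_times must be strictly increasing (no duplicates)")
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    t1 = spec.t1rho_truth()
    vessels = spec.vessel_mask()
    images = np.empty((tsl.size, *spec.grid_shape), dtype=float)
    for i, t in enumerate(tsl):
        clean = spec.s0_value * np.exp(-t / t1)
        clean[vessels] = spec.vessel_signal
        images[i] = _add_noise(clean, spec.noise_sigma, spec.noise_model, rng)

    series = SpinLockSeries(
        images=images,
        spin_lock_times=tsl,
        slice_id=slice_id,
        pixel_spacing_mm=spec.pixel_spacing_mm,
    )
    return DecayPhantom(series=series, t1rho_truth=t1, vessel_mask=vessels)


def simulate_contrast_pair(
    spec: PhantomSpec,
    true_re_map: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate an unenhanced / 20-min hepatobiliary-phase image pair.

    The noiseless pre-contrast image is flat at ``spec.s0_value`` (vessels at
    ``spec.vessel_signal``); the post-contrast image is ``pre * (1 + RE)``
    pixel-wise, so an ROI-level relative-enhancement measurement on the
    noiseless pair recovers the signal-weighted mean of ``true_re_map``.
    """
    true_re_map = np.asarray(true_re_map, dtype=float)
    if true_re_map.shape != tuple(spec.grid_shape):
        raise ValueError(
            f"re map shape {true_re_map.shape} does not match grid {spec.grid_shape}"
        )
    if np.any(true_re_map <= -1):
        raise ValueError("true RE must be > -1 everywhere")
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    pre_clean = np.full(spec.grid_shape, spec.s0_value, dtype=float)
    pre_clean[spec.vessel_mask()] = spec.vessel_signal
    post_clean = pre_clean * (1.0 + true_re_map)
    pre = _add_noise(pre_clean, spec.noise_sigma, spec.noise_model, rng)
    post = _add_noise(post_clean, spec.noise_sigma, spec.noise_model, rng)
    return pre, post
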