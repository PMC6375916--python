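"""Per-pixel T1rho mapping from multi-spin-lock image series.

The signal during a spin-lock pulse of duration ``T_SL`` decays
mono-exponentially, ``S(T_SL) = S0 * exp(-T_SL / T1rho)``.  Dividing by the
signal at the shortest spin-lock time and taking logs gives the linear
model fitted here by ordinary least squares:

    ln(S(T_SL) / S0) = -T_SL / T1rho + C

so the relaxation time is minus the reciprocal slope.  The fit is done in
the log domain, unweighted, exactly as quantitative-MRI vendor tooling
does it; a nonlinear signal-domain fit exists in the test suite as an
independent oracle only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

#: The protocol requires at least this many usable (positive-signal) samples
#: per pixel for a fit.
MIN_SAMPLES = 5


@dataclass(frozen=True)
class SpinLockSeries:
    """A stack of co-registered 2D images, one per spin-lock time.

    Parameters
    ----------
    images : ndarray, shape (n_tsl, nrow, ncol)
        Signal intensities in arbitrary units.
    spin_lock_times : ndarray, shape (n_tsl,)
        Spin-lock durations in ms, strictly increasing, >= 0.
    slice_id : str
        Free-form slice label (e.g. ``"cranial"`` / ``"caudal"``).
    pixel_spacing_mm : float or None
        In-plane pixel spacing, used to convert physical ROI sizes.
    """

    images: np.ndarray = field(repr=False)
    spin_lock_times: np.ndarray
    slice_id: str = ""
    pixel_spacing_mm: float | None = None

    def __post_init__(self) -> None:
        images = np.asarray(self.images, dtype=float)
        tsl = np.asarray(self.spin_lock_times, dtype=float)
        object.__setattr__(self, "images", images)
        object.__setattr__(self, "spin_lock_times", tsl)
        if images.ndim != 3:
            raise ValueError(f"images must be (n_tsl, nrow, ncol), got shape {images.shape}")
        if tsl.ndim != 1 or tsl.size != images.shape[0]:
            raise ValueError(
                f"{tsl.size} spin-lock times for {images.shape[0]} images"
            )
        if np.any(tsl < 0):
            raise ValueError("spin-lock times must be >= 0")
        if np.any(np.diff(tsl) <= 0):
            raise ValueError("spin-lock times must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1:]

    def subset(self, use_tsl: Sequence[float]) -> "SpinLockSeries":
        """Restrict the series to a subset of its spin-lock times."""
        wanted = np.asarray(use_tsl, dtype=float)
        idx = []
        for t in wanted:
            hit = np.flatnonzero(np.isclose(self.spin_lock_times, t))
            if hit.size == 0:
                raise ValueError(f"T_SL={t} ms not present in series")
            idx.append(hit[0])
        idx = np.sort(np.asarray(idx))
        return SpinLockSeries(
            images=self.images[idx],
            spin_lock_times=self.spin_lock_times[idx],
            slice_id=self.slice_id,
            pixel_spacing_mm=self.pixel_spacing_mm,
        )


class PixelFit(NamedTuple):
    t1rho: float
    intercept_c: float
    r2: float
    valid: bool


@dataclass(frozen=True)
class T1RhoMapResults:
    """Per-pixel T1rho estimates with fit diagnostics.

    ``t1rho`` is NaN wherever ``valid_mask`` is False (non-positive slope,
    fewer than the minimum usable samples, or outside the fit mask).
    ``s0`` is the fitted back-extrapolated signal at T_SL = 0,
    ``normalising_signal * exp(C)``.
    """

    t1rho: np.ndarray = field(repr=False)
    s0: np.ndarray = field(repr=False)
    intercept_c: np.ndarray = field(repr=False)
    valid_mask: np.ndarray = field(repr=False)
    fit_r2: np.ndarray = field(repr=False)
    n_samples: np.ndarray = field(repr=False)
    slice_id: str = ""
    pixel_spacing_mm: float | None = None

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def fraction_invalid(self) -> float:
        return 1.0 - self.n_valid / self.valid_mask.size

    def summary_dict(self) -> dict:
        valid = self.t1rho[self.valid_mask]
        return {
            "slice_id": self.slice_id,
            "n_pixels": int(self.valid_mask.size),
            "n_valid": self.n_valid,
            "percent_invalid": round(100.0 * self.fraction_invalid, 2),
            "t1rho_mean_ms": float(valid.mean()) if valid.size else None,
            "t1rho_sd_ms": float(valid.std(ddof=1)) if valid.size > 1 else None,
            "median_r2": float(np.median(self.fit_r2[self.valid_mask])) if valid.size else None,
        }

    def summary(self) -> str:
        d = self.summary_dict()
        lines = ["T1rho map fit summary", "=" * 21]
        for k, v in d.items():
            lines.append(f"{k:>16}: {v}")
        return "\n".join(lines)


class T1RhoModel:
    """Log-linear mono-exponential decay model for a spin-lock series.

    Parameters
    ----------
    series : SpinLockSeries
    mask : ndarray of bool, optional
        Pixels to fit; everything outside is marked invalid.  An empty mask
        is accepted with a warning.
    use_tsl : sequence of float, optional
        Fit only these spin-lock times (the acquisition protocol allows any
        subset of at least :data:`MIN_SAMPLES` of the acquired times).  The
        normalising signal S0 is taken at the smallest *used* time, so when
        T_SL = 0 is excluded the true S0 is absorbed into the intercept.
    min_samples : int
        Minimum usable (positive-signal) samples per pixel.
    """

    def __init__(
        self,
        series: SpinLockSeries,
        mask: np.ndarray | None = None,
        use_tsl: Sequence[float] | None = None,
        min_samples: int = MIN_SAMPLES,
    ) -> None:
        if use_tsl is not None:
            series = series.subset(use_tsl)
        self.series = series
        self.min_samples = int(min_samples)
        if mask is None:
            mask = np.ones(series.shape, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != series.shape:
            raise ValueError(f"mask shape {mask.shape} != image shape {series.shape}")
        if not mask.any():
            warnings.warn("empty fit mask: no pixels will be fitted", stacklevel=2)
        self.mask = mask

    def fit(self) -> T1RhoMapResults:
        S = self.series.images
        tsl = self.series.spin_lock_times
        s_norm = S[0]  # signal at the smallest used T_SL
        usable = (S > 0) & (s_norm > 0)[None]

        with np.errstate(divide="ignore", invalid="ignore"):
            y = np.where(usable, np.log(np.where(S > 0, S, 1.0) / np.where(s_norm > 0, s_norm, 1.0)[None]), 0.0)
        w = usable.astype(float)
        x = tsl[:, None, None]

        n = w.sum(axis=0)
        sx = (w * x).sum(axis=0)
        sy = (w * y).sum(axis=0)
        sxx = (w * x * x).sum(axis=0)
        sxy = (w * x * y).sum(axis=0)
        syy = (w * y * y).sum(axis=0)

        with np.errstate(divide="ignore", invalid="ignore"):
            sxx_c = sxx - sx * sx / n
            sxy_c = sxy - sx * sy / n
            syy_c = syy - sy * sy / n
            slope = sxy_c / sxx_c
            intercept = (sy - slope * sx) / n
            ss_res = syy_c - slope * sxy_c
            r2 = 1.0 - ss_res / syy_c

        fittable = (n >= self.min_samples) & (sxx_c > 0) & self.mask
        valid = fittable & (slope < 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t1rho = np.where(valid, -1.0 / slope, np.nan)
        intercept_c = np.where(fittable, intercept, np.nan)
        # clip fp fuzz: residual variance cannot exceed total variance
        r2 = np.clip(np.where(fittable & (syy_c > 0), r2, np.nan), 0.0, 1.0)
        s0 = np.where(fittable, s_norm * np.exp(np.where(fittable, intercept, 0.0)), np.nan)

        return T1RhoMapResults(
            t1rho=t1rho,
            s0=s0,
            intercept_c=intercept_c,
            valid_mask=valid,
            fit_r2=r2,
            n_samples=n.astype(int),
            slice_id=self.series.slice_id,
            pixel_spacing_mm=self.series.pixel_spacing_mm,
        )


def fit_pixel(
    signals: Sequence[float],
    spin_lock_times: Sequence[float],
    min_samples: int = MIN_SAMPLES,
) -> PixelFit:
    """Fit a single pixel's decay curve; see :class:`T1RhoModel`.

    Never raises for degenerate signals — a pixel with no decay or too few
    positive samples simply comes back with ``valid=False``.
    """
    signals = np.asarray(signals, dtype=float)
    tsl = np.asarray(spin_lock_times, dtype=float)
    if signals.shape != tsl.shape:
        raise ValueError(f"{signals.size} signals for {tsl.size} spin-lock times")
    series = SpinLockSeries(images=signals.reshape(-1, 1, 1), spin_lock_times=tsl)
    res = T1RhoModel(series, min_samples=min_samples).fit()
    return PixelFit(
        t1rho=float(res.t1rho[0, 0]),
        intercept_c=float(res.intercept_c[0, 0]),
        r2=float(res.fit_r2[0, 0]),
        valid=bool(res.valid_mask[0, 0]),
    )


def fit_map(
    series: SpinLockSeries,
    mask: np.ndarray | None = None,
    use_tsl: Sequence[float] | None = None,
    min_samples: int = MIN_SAMPLES,
) -> T1RhoMapResults:
    """Functional wrapper around ``T1RhoModel(series, mask, ...).fit()``."""
    return T1RhoModel(series, mask=mask, use_tsl=use_tsl, min_samples=min_samples).fit()
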