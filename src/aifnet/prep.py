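"""Curve preprocessing: arrival detection, cropping, fixed-length
representation, saturated-max normalization, and blood-pool ROI extraction.

The network consumes pairs of saturated / unsaturated AIF curves cropped to
begin four beats before contrast arrival, cropped or padded to exactly 64
samples, and normalized by the maximum of the saturated curve (the same
scale for both, so the pair stays quantitatively comparable and can be
unnormalized after prediction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_model import SignalCurve

__all__ = [
    "AIFPair",
    "ArrivalNotFoundError",
    "detect_arrival",
    "crop_pre_contrast",
    "fix_length",
    "normalize_pair",
    "unnormalize",
    "extract_aif_roi",
    "INPUT_LENGTH",
    "N_PRE_CONTRAST",
]

INPUT_LENGTH = 64
N_PRE_CONTRAST = 4


class ArrivalNotFoundError(ValueError):
    """Raised when no contrast-arrival frame can be located in a curve."""


@dataclass
class AIFPair:
    """A normalized saturated/unsaturated AIF pair, the network's training unit.

    ``scale`` is the pre-normalization maximum of the saturated curve; the
    unsaturated curve shares it, so its normalized values may exceed 1.
    """

    sat: np.ndarray
    unsat: np.ndarray
    scale: float
    dt: float
    arrival_index: int = 0

    def __post_init__(self):
        self.sat = np.asarray(self.sat, dtype=float)
        self.unsat = np.asarray(self.unsat, dtype=float)
        if self.sat.shape != (INPUT_LENGTH,) or self.unsat.shape != (INPUT_LENGTH,):
            raise ValueError(f"pair curves must have length {INPUT_LENGTH}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def detect_arrival(curve: SignalCurve, n_base: int = 4, k_sigma: float = 5.0) -> int:
    """First frame where the signal exceeds baseline mean + k_sigma*SD.

    Falls back to a 5%-of-range threshold when the baseline is noise-free
    (SD = 0).  Raises :class:`ArrivalNotFoundError` if no frame qualifies.
    """
    if n_base < 2:
        raise ValueError("n_base must be >= 2")
    v = curve.values
    if len(v) <= n_base:
        raise ValueError("curve must be longer than the baseline window")
    base = v[:n_base]
    sd = float(np.std(base))
    if sd > 0:
        thresh = float(np.mean(base)) + k_sigma * sd
    else:
        rng = float(v.max() - v.min())
        if rng == 0:
            raise ArrivalNotFoundError("flat curve: no contrast arrival")
        thresh = float(np.mean(base)) + 0.05 * rng
    above = np.nonzero(v > thresh)[0]
    if above.size == 0:
        raise ArrivalNotFoundError("no frame exceeds the arrival threshold")
    return int(above[0])


def crop_pre_contrast(curve: SignalCurve, arrival_index: int, n_pre: int = N_PRE_CONTRAST) -> SignalCurve:
    """Crop so the curve starts ``n_pre`` beats before contrast arrival.

    The time axis is re-zeroed at the new first sample.
    """
    if arrival_index < 0:
        raise ValueError("arrival_index must be >= 0")
    start = max(0, arrival_index - n_pre)
    times = curve.times[start:] - curve.times[start]
    values = curve.values[start:]
    baseline_n = min(curve.baseline_n, max(1, len(values) - 1))
    return SignalCurve(times=times, values=values, ts=curve.ts, baseline_n=baseline_n)


def fix_length(values: np.ndarray, n: int = INPUT_LENGTH) -> np.ndarray:
    """Crop or pad a 1D array to exactly ``n`` samples.

    Longer inputs lose their tail (the recirculation phase carries no
    first-pass information); shorter inputs are padded by repeating the
    final value, avoiding a step edge.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot fix length of an empty curve")
    if values.size >= n:
        return values[:n].copy()
    return np.concatenate([values, np.full(n - values.size, values[-1])])


def normalize_pair(
    sat: np.ndarray,
    unsat: np.ndarray,
    dt: float,
    arrival_index: int = 0,
) -> AIFPair:
    """Divide both curves by the maximum of the saturated curve."""
    sat = fix_length(sat)
    unsat = fix_length(unsat)
    scale = float(sat.max())
    if scale <= 0:
        raise ValueError("saturated curve maximum must be positive")
    return AIFPair(sat=sat / scale, unsat=unsat / scale, scale=scale, dt=dt, arrival_index=arrival_index)


def unnormalize(pair: AIFPair) -> tuple[np.ndarray, np.ndarray]:
    """Restore both curves to signal units (exact inverse of normalize_pair)."""
    return pair.sat * pair.scale, pair.unsat * pair.scale


def pair_from_curves(sat: SignalCurve, unsat: SignalCurve, n_base: int = 4, k_sigma: float = 5.0) -> AIFPair:
    """Full preprocessing of one acquisition pair.

    Arrival is detected on the saturated (standard-acquisition) curve and
    the same crop is applied to both curves, so they stay beat-aligned.
    """
    arrival = detect_arrival(sat, n_base=n_base, k_sigma=k_sigma)
    sat_c = crop_pre_contrast(sat, arrival)
    unsat_c = crop_pre_contrast(unsat, arrival)
    return normalize_pair(sat_c.values, unsat_c.values, dt=sat.dt, arrival_index=arrival)


def extract_aif_roi(pixel_curves: np.ndarray, blood_mask: np.ndarray, times=None, ts: float = 0.100) -> SignalCurve:
    """Average the brightest blood-pool pixel curves into one AIF.

    ``pixel_curves`` is (n_pixels, n_frames); ``blood_mask`` a boolean
    selector of blood-pool pixels.  Pixels are ranked by their peak
    intensity; the curves of pixels whose peak strictly exceeds the 75th
    percentile (linear-interpolation convention) of peaks within the mask
    are averaged.
    """
    pixel_curves = np.asarray(pixel_curves, dtype=float)
    blood_mask = np.asarray(blood_mask, dtype=bool)
    if pixel_curves.ndim != 2:
        raise ValueError("pixel_curves must be (n_pixels, n_frames)")
    if blood_mask.shape[0] != pixel_curves.shape[0]:
        raise ValueError("mask length must match pixel count")
    selected = pixel_curves[blood_mask]
    if selected.shape[0] == 0:
        raise ValueError("empty blood-pool mask")
    if selected.shape[0] < 4:
        raise ValueError("mask must select at least 4 pixels")
    peaks = selected.max(axis=1)
    q75 = np.percentile(peaks, 75)
    bright = peaks > q75
    if not bright.any():  # all peaks identical
        bright = np.ones_like(bright)
    mean_curve = selected[bright].mean(axis=0)
    if times is None:
        times = np.arange(pixel_curves.shape[1], dtype=float)
    return SignalCurve(times=np.asarray(times, dtype=float), values=mean_curve, ts=ts)
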