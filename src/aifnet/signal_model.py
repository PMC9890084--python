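"""Saturation-recovery MR signal physics and concentration conversion.

First-pass perfusion imaging uses a saturation-recovery (SR) spoiled
gradient-echo readout: after a saturation pulse, longitudinal magnetization
regrows for a saturation time ``TS`` before the readout, so the signal is

    S(t) = gain * (1 - exp(-TS * R1(t))),     R1(t) = 1/T1_0 + r1 * C(t)

where ``C(t)`` is the gadolinium concentration (mM) and ``r1`` the contrast
agent relaxivity (L mmol^-1 s^-1).  At the standard saturation time
(100 ms) the signal is strongly compressed ("saturated") at peak arterial
concentrations; at the short reference time (23.5 ms) the response is much
closer to linear.  This nonlinearity is the phenomenon the saturation
network learns to undo.

Concentration is recovered from measured signal with the relative signal
enhancement conversion used in clinical quantification,

    C(t) = 1/(r1 * T1b) * (S(t) - S(0)) / S_LV(0)

with ``S(0)`` the pre-contrast baseline of the curve itself and
``S_LV(0)`` the baseline of the left-ventricular blood-pool curve.  The
conversion is exactly linear in S(t); it is accurate only to the extent the
SR response is linear, which is why short-TS (or network-corrected) AIFs
yield less biased concentrations.

The ideal-saturation model here deliberately omits the readout train and
T2* decay: it reproduces the concentration-to-signal nonlinearity that
matters for AIF correction without a Bloch simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AcquisitionParams",
    "SignalCurve",
    "ConcentrationCurve",
    "t1_post_contrast",
    "sr_signal",
    "concentration_from_signal",
]

# Pre-contrast blood T1 (s) by field strength
_T1_BLOOD = {3.0: 1.736, 1.5: 1.435}
# Nominal pre-contrast myocardial T1 (s), simulator only
_T1_MYO = {3.0: 1.2, 1.5: 1.0}


@dataclass(frozen=True)
class AcquisitionParams:
    """Pulse-sequence parameters of the dual-sequence perfusion acquisition.

    ``ts_standard`` is the saturation time of the standard high-resolution
    imaging (100 ms); ``ts_aif`` the short saturation time of the
    low-resolution AIF reference slice (23.5 ms).
    """

    field_strength: float = 3.0
    ts_standard: float = 0.100
    ts_aif: float = 0.0235
    tr: float = 0.0022
    te: float = 0.0010
    flip_angle: float = 15.0
    t1_blood: float | None = None
    t1_myo: float | None = None
    r1: float = 4.5

    def __post_init__(self):
        if self.field_strength not in _T1_BLOOD:
            raise ValueError(f"field_strength must be 1.5 or 3.0, got {self.field_strength}")
        if self.t1_blood is None:
            object.__setattr__(self, "t1_blood", _T1_BLOOD[self.field_strength])
        if self.t1_myo is None:
            object.__setattr__(self, "t1_myo", _T1_MYO[self.field_strength])
        if not 0 < self.ts_aif < self.ts_standard:
            raise ValueError("require 0 < ts_aif < ts_standard")
        if self.t1_blood <= 0 or self.t1_myo <= 0:
            raise ValueError("T1 values must be positive")
        if self.r1 <= 0:
            raise ValueError("r1 must be positive")

    def to_dict(self) -> dict:
        return {
            "field_strength": self.field_strength,
            "ts_standard": self.ts_standard,
            "ts_aif": self.ts_aif,
            "tr": self.tr,
            "te": self.te,
            "flip_angle": self.flip_angle,
            "t1_blood": self.t1_blood,
            "t1_myo": self.t1_myo,
            "r1": self.r1,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionParams":
        return cls(**d)


def _validate_curve(times, values):
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.ndim != 1 or values.ndim != 1:
        raise ValueError("times and values must be 1D")
    if times.shape != values.shape:
        raise ValueError("times and values must have the same length")
    if times.size >= 2 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    return times, values


@dataclass
class SignalCurve:
    """Sampled MR signal intensity vs time for one ROI or pixel.

    ``ts`` records the saturation time the curve was acquired with;
    ``baseline_n`` the number of pre-contrast frames used for S(0).
    """

    times: np.ndarray
    values: np.ndarray
    ts: float
    baseline_n: int = 4

    def __post_init__(self):
        self.times, self.values = _validate_curve(self.times, self.values)
        if self.ts <= 0:
            raise ValueError("ts must be positive")
        if not 1 <= self.baseline_n < len(self.values):
            raise ValueError("baseline_n must be in [1, len(curve))")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def baseline(self) -> float:
        """S(0): mean of the first ``baseline_n`` pre-contrast frames."""
        return float(np.mean(self.values[: self.baseline_n]))

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times)))


@dataclass
class ConcentrationCurve:
    """Gadolinium concentration vs time (mM)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times, self.values = _validate_curve(self.times, self.values)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times)))


def t1_post_contrast(c, t1_0: float, r1: float = 4.5):
    """Post-contrast T1 under the fast-exchange relaxation model.

    1/T1 = 1/T1_0 + r1*C.  Accepts scalar or array concentration (mM).
    """
    c = np.asarray(c, dtype=float)
    if t1_0 <= 0:
        raise ValueError("t1_0 must be positive")
    if r1 <= 0:
        raise ValueError("r1 must be positive")
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    out = 1.0 / (1.0 / t1_0 + r1 * c)
    return float(out) if out.ndim == 0 else out


def sr_signal(
    conc: ConcentrationCurve,
    t1_0: float,
    ts: float,
    gain: float = 1.0,
    r1: float = 4.5,
) -> SignalCurve:
    """Forward saturation-recovery signal for a concentration curve.

    S(t) = gain*(1 - exp(-ts*R1(t))), R1(t) = 1/t1_0 + r1*C(t).  The map
    C -> S is increasing and concave: equal concentration increments yield
    progressively smaller signal increments, i.e. saturation.
    """
    if ts <= 0:
        raise ValueError("ts must be positive")
    if gain <= 0:
        raise ValueError("gain must be positive")
    r1_rate = 1.0 / t1_0 + r1 * np.maximum(conc.values, 0.0)
    values = gain * (1.0 - np.exp(-ts * r1_rate))
    return SignalCurve(times=conc.times.copy(), values=values, ts=ts)


def concentration_from_signal(
    sig: SignalCurve,
    s_lv0: float | None = None,
    t1_blood: float = 1.736,
    r1: float = 4.5,
) -> ConcentrationCurve:
    """Relative-enhancement conversion of signal to concentration.

    C(t) = (1/(r1*T1b)) * (S(t) - S(0)) / S_LV(0), with S(0) the mean of
    the curve's first ``baseline_n`` frames.  ``s_lv0`` is the blood-pool
    baseline; for an AIF curve it defaults to the curve's own baseline.
    Negative values (noise below baseline) are retained to keep the map
    exactly affine in S.
    """
    s0 = sig.baseline
    if s_lv0 is None:
        s_lv0 = s0
    if s_lv0 <= 0:
        raise ValueError("blood-pool baseline s_lv0 must be positive")
    values = (sig.values - s0) / (r1 * t1_blood * s_lv0)
    return ConcentrationCurve(times=sig.times.copy(), values=values)
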