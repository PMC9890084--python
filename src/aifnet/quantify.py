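"""Myocardial blood flow estimation by Fermi-constrained deconvolution.

The tissue concentration curve is modelled as the convolution of the
arterial input with a Fermi-shaped impulse response,

    C_t(t) = (MBF/60) * (C_a(. - delay) * R_F)(t),
    R_F(u) = 1 / (1 + exp(k * (u - tau0)))

whose amplitude parameter is the myocardial blood flow in mL/min/g
(reported directly as the fitted amplitude, with R_F(0) ~ 1).

Deconvolution at one sample per heartbeat is ill-posed: under measurement
noise the amplitude trades off against the impulse-response shape and the
arterial delay, so an unconstrained fit carries large MBF variance.  The
fit is therefore bounded nonlinear least squares with weak Gaussian priors
on the nuisance shape parameters (tau0 ~ N(3.5, 0.87) s, k ~ N(1.0, 0.29)
1/s, delay ~ N(1.0, 0.58) s — moment-matched to the physiological ranges;
MBF itself carries no prior so the estimand is not shrunk), with the data
residual whitened by a robust noise estimate taken from the curve's
successive differences.  As the noise level goes to zero the data term
dominates and recovery of noiseless curves is exact to fit tolerance.  A
small multi-start fallback handles convergence failures.  Diagnostic
classification uses the stress-MBF cut-off of 1.35 mL/min/g: a segment is
abnormal iff its MBF is strictly below the threshold, and a coronary
territory is abnormal iff the mean of its two lowest segment MBFs is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .signal_model import ConcentrationCurve
from .synthetic import tissue_forward

__all__ = [
    "FermiFitResult",
    "SegmentResult",
    "VesselResult",
    "AHA_TERRITORIES",
    "MBF_THRESHOLD",
    "fermi_deconvolve",
    "quantify_pixelwise",
    "classify_segment",
    "classify_vessel",
]

MBF_THRESHOLD = 1.35  # mL/min/g, stress-MBF diagnostic cut-off

# Standard 16-segment AHA model to coronary-territory assignment
AHA_TERRITORIES = {
    "LAD": (1, 2, 7, 8, 13, 14),
    "RCA": (3, 4, 9, 10, 15),
    "LCX": (5, 6, 11, 12, 16),
}

_BOUNDS_LO = np.array([0.0, 0.0, 0.01, 0.0])  # mbf, tau0, k, delay
_BOUNDS_HI = np.array([10.0, 30.0, 5.0, 3.0])
_X0 = np.array([1.5, 3.0, 0.5, 0.5])
# alternative starts used only if the first fit fails to converge
_MULTISTART = [
    np.array([0.5, 5.0, 1.0, 0.5]),
    np.array([3.0, 2.0, 0.2, 1.0]),
    np.array([1.0, 10.0, 2.0, 0.0]),
]
# weak physiological priors on the nuisance parameters: (mean, SD)
_PRIOR_TAU0 = (3.5, 0.866)  # s
_PRIOR_K = (1.0, 0.289)  # 1/s
_PRIOR_DELAY = (1.0, 0.577)  # s


def _robust_noise_sd(y: np.ndarray) -> float:
    """Noise SD from the median absolute successive difference (smooth-signal
    contributions are suppressed by the median)."""
    d = np.diff(y)
    return float(np.median(np.abs(d - np.median(d))) / 0.6745 / np.sqrt(2.0))


@dataclass(frozen=True)
class FermiFitResult:
    mbf: float
    tau0: float
    k: float
    delay: float
    rss: float
    converged: bool


@dataclass(frozen=True)
class SegmentResult:
    aha_id: int
    mbf: float
    abnormal: bool


@dataclass(frozen=True)
class VesselResult:
    territory: str
    mbf_two_lowest_mean: float
    abnormal: bool


def fermi_deconvolve(
    aif: ConcentrationCurve,
    tissue: ConcentrationCurve,
    regularized: bool = True,
) -> FermiFitResult:
    """Fit the Fermi convolution model to one tissue curve.

    Both curves must share the same uniform time grid with at least 16
    samples.  Negative concentration samples (noise below baseline) are
    clipped to zero before fitting.  ``regularized=False`` disables the
    physiological shape priors and runs a plain bounded least-squares fit.
    """
    if len(aif) != len(tissue) or not np.allclose(aif.times, tissue.times):
        raise ValueError("AIF and tissue curves must share one time grid")
    if len(aif) < 16:
        raise ValueError("need at least 16 samples for deconvolution")
    times = aif.times
    a = np.maximum(aif.values, 0.0)
    y = np.maximum(tissue.values, 0.0)

    if not np.any(y > 0):
        return FermiFitResult(mbf=0.0, tau0=_X0[1], k=_X0[2], delay=_X0[3], rss=0.0, converged=True)

    sd = max(_robust_noise_sd(y), 1e-12)

    def residual(x):
        data = tissue_forward(a, times, *x) - y
        if not regularized:
            return data
        pen = np.array(
            [
                (x[1] - _PRIOR_TAU0[0]) / _PRIOR_TAU0[1],
                (x[2] - _PRIOR_K[0]) / _PRIOR_K[1],
                (x[3] - _PRIOR_DELAY[0]) / _PRIOR_DELAY[1],
            ]
        )
        return np.concatenate([data / sd, pen])

    def run(x0):
        return least_squares(residual, x0, bounds=(_BOUNDS_LO, _BOUNDS_HI), method="trf")

    res = run(_X0)
    if not res.success:
        for x0 in _MULTISTART:
            alt = run(x0)
            if alt.success and (not res.success or alt.cost < res.cost):
                res = alt
            if res.success:
                break
    mbf, tau0, k, delay = (float(v) for v in res.x)
    data_res = tissue_forward(a, times, mbf, tau0, k, delay) - y
    return FermiFitResult(
        mbf=mbf,
        tau0=tau0,
        k=k,
        delay=delay,
        rss=float(np.sum(data_res**2)),
        converged=bool(res.success),
    )


def quantify_pixelwise(aif: ConcentrationCurve, tissue_matrix: np.ndarray, times=None) -> list[FermiFitResult]:
    """Independent Fermi fit per pixel curve ((n_pixels, n_frames) matrix)."""
    tissue_matrix = np.asarray(tissue_matrix, dtype=float)
    if tissue_matrix.ndim != 2:
        raise ValueError("tissue_matrix must be (n_pixels, n_frames)")
    grid = aif.times if times is None else np.asarray(times, dtype=float)
    return [
        fermi_deconvolve(aif, ConcentrationCurve(times=grid, values=row))
        for row in tissue_matrix
    ]


def classify_segment(mbf: float, threshold: float = MBF_THRESHOLD) -> bool:
    """Abnormal iff MBF is strictly lower than the threshold."""
    if mbf < 0:
        raise ValueError("mbf must be >= 0")
    return bool(mbf < threshold)


def classify_vessel(
    segment_results: list[SegmentResult],
    territory_map: dict | None = None,
    threshold: float = MBF_THRESHOLD,
) -> list[VesselResult]:
    """Per-territory diagnosis from the mean of the two lowest segment MBFs.

    Ties at the minimum are resolved by taking the two smallest values in
    sorted order (the tied pair itself when exactly two segments tie).
    """
    territory_map = territory_map or AHA_TERRITORIES
    by_id = {r.aha_id: r for r in segment_results}
    out = []
    for territory, ids in territory_map.items():
        missing = [i for i in ids if i not in by_id]
        if missing:
            raise ValueError(f"missing AHA segments {missing} for territory {territory}")
        mbfs = np.sort([by_id[i].mbf for i in ids])
        two_lowest = float(np.mean(mbfs[:2]))
        out.append(
            VesselResult(
                territory=territory,
                mbf_two_lowest_mean=two_lowest,
                abnormal=classify_segment(two_lowest, threshold),
            )
        )
    return out
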