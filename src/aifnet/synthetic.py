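"""Synthetic dual-sequence perfusion cohort generator.

Each simulated patient consists of a ground-truth arterial concentration
curve (gamma-variate bolus with a recirculation tail), 16 AHA-segment
tissue curves generated by convolving that AIF with a Fermi impulse
response of known myocardial blood flow (MBF), and the two saturation-
recovery acquisitions of a dual-sequence protocol: the standard imaging at
TS = 100 ms (strongly saturated) and the low-resolution AIF reference at
TS = 23.5 ms.  Both derive from the identical true AIF, so the saturated /
unsaturated pairing the network trains on is exact by construction.

Sampling is one frame per heartbeat at a constant per-subject heart rate;
additive Gaussian signal noise models measurement noise.  Default
parameter ranges put the reference curves in the bolus-shape regime of
clinical stress perfusion (time-to-peak ~6.6 s and FWHM ~5.3 s from the
cropped-curve origin, normalized peak values ~1.5) with peak arterial
concentrations of 2-3.5 mM and both normal and ischaemic segment flows, so
the 1.35 mL/min/g diagnostic threshold separates two genuinely present
classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .signal_model import (
    AcquisitionParams,
    ConcentrationCurve,
    SignalCurve,
    sr_signal,
)

__all__ = [
    "GammaVariateParams",
    "FermiKinetics",
    "SyntheticSubject",
    "CohortConfig",
    "gen_aif_concentration",
    "gen_tissue_curve",
    "fermi_residue",
    "tissue_forward",
    "simulate_subject",
    "gen_cohort",
    "write_cohort",
    "read_cohort",
]

N_SEGMENTS = 16


@dataclass(frozen=True)
class GammaVariateParams:
    """Shape of the first-pass bolus: C(t) = peak*((t-t0)/(a*b))^a * exp(a-(t-t0)/b).

    The mode (time-to-peak) is t0 + a*b and the peak value is ``peak``
    exactly.  ``recirc_frac``/``recirc_delay`` add a delayed copy of the
    first pass smoothed by an exponential tail, emulating recirculation.
    """

    t0: float
    alpha: float
    beta: float
    peak: float
    recirc_frac: float = 0.0
    recirc_delay: float = 12.0
    recirc_tau: float = 8.0

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0 or self.peak <= 0:
            raise ValueError("alpha, beta, peak must be positive")
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0")
        if not 0 <= self.recirc_frac < 1:
            raise ValueError("recirc_frac must be in [0, 1)")


@dataclass(frozen=True)
class FermiKinetics:
    """Fermi impulse-response parameters for one myocardial segment.

    R_F(u) = 1/(1 + exp(k*(u - tau0))); MBF (mL/min/g) is the amplitude of
    the tissue impulse response, entering the convolution as mbf/60 with
    time in seconds (unit tissue density).
    """

    mbf: float
    tau0: float = 4.0
    k: float = 0.8
    delay: float = 0.5

    def __post_init__(self):
        if self.mbf < 0:
            raise ValueError("mbf must be >= 0")
        if self.tau0 < 0 or self.delay < 0:
            raise ValueError("tau0 and delay must be >= 0")
        if self.k <= 0:
            raise ValueError("k must be positive")


@dataclass
class SyntheticSubject:
    subject_id: str
    heart_rate: float
    acq: AcquisitionParams
    aif_true: ConcentrationCurve
    segment_kinetics: list  # 16 FermiKinetics, AHA order
    tissue_true: list  # 16 ConcentrationCurve
    sat_aif: SignalCurve
    ref_aif: SignalCurve
    tissue_signal: list  # 16 SignalCurve
    noise_sd: float
    seed: int

    def __post_init__(self):
        if len(self.segment_kinetics) != N_SEGMENTS:
            raise ValueError(f"expected {N_SEGMENTS} segments")


@dataclass(frozen=True)
class CohortConfig:
    """Parameter distributions and split fractions for a simulated cohort."""

    n_subjects: int = 50
    seed: int = 0
    fractions: tuple = (0.8, 0.1, 0.1)  # train / val / test
    heart_rate_range: tuple = (60.0, 120.0)
    n_frames_range: tuple = (60, 80)
    arrival_range: tuple = (8.0, 12.0)  # bolus arrival time, s
    alpha_range: tuple = (2.2, 3.2)
    beta_range: tuple = (1.1, 1.6)
    peak_range: tuple = (2.0, 3.5)  # mM
    recirc_frac_range: tuple = (0.10, 0.25)
    recirc_delay_range: tuple = (10.0, 15.0)
    mbf_normal_range: tuple = (1.5, 4.5)  # mL/min/g
    mbf_abnormal_range: tuple = (0.4, 1.3)
    p_abnormal: float = 0.3
    tau0_range: tuple = (2.0, 5.0)
    k_range: tuple = (0.5, 1.5)
    delay_range: tuple = (0.0, 2.0)
    noise_frac: float = 0.01  # SD as a fraction of baseline blood signal
    gain: float = 100.0
    field_strength: float = 3.0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if len(self.fractions) != 3 or any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be 3 non-negative numbers")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def gen_aif_concentration(p: GammaVariateParams, times: np.ndarray) -> ConcentrationCurve:
    """Gamma-variate arterial concentration, optionally with recirculation."""
    times = np.asarray(times, dtype=float)
    first = _gamma_variate(times, p)
    values = first
    if p.recirc_frac > 0:
        dt = float(np.median(np.diff(times)))
        shifted = _gamma_variate(times - p.recirc_delay, p)
        # unit-area discrete exponential smoothing kernel
        ku = np.arange(0, 5 * p.recirc_tau, dt)
        kern = np.exp(-ku / p.recirc_tau)
        kern /= kern.sum()
        tail = np.convolve(shifted, kern)[: len(times)]
        values = first + p.recirc_frac * tail
    return ConcentrationCurve(times=times.copy(), values=values)


def _gamma_variate(times: np.ndarray, p: GammaVariateParams) -> np.ndarray:
    u = times - p.t0
    out = np.zeros_like(u, dtype=float)
    pos = u > 0
    x = u[pos] / (p.alpha * p.beta)
    out[pos] = p.peak * np.power(x, p.alpha) * np.exp(p.alpha - u[pos] / p.beta)
    return out


def fermi_residue(u: np.ndarray, tau0: float, k: float) -> np.ndarray:
    """Fermi-shaped tissue impulse response, amplitude ~1 at u=0."""
    return 1.0 / (1.0 + np.exp(k * (np.asarray(u, dtype=float) - tau0)))


def tissue_forward(
    aif_values: np.ndarray,
    times: np.ndarray,
    mbf: float,
    tau0: float,
    k: float,
    delay: float,
) -> np.ndarray:
    """Discrete tissue forward model C_t = (mbf/60) * (C_a(.-delay) * R_F).

    The convolution is evaluated by trapezoid quadrature on an internally
    refined grid (8x linear upsampling of the AIF) so that one-sample-per-
    heartbeat acquisition grids do not introduce visible quadrature error
    at the sharp bolus upslope; the result is subsampled back onto the
    acquisition grid.  The arterial delay is applied by linear
    interpolation, so it is not restricted to whole frames.  The same
    operator is used for generation and for deconvolution fitting.
    """
    times = np.asarray(times, dtype=float)
    dt = np.diff(times)
    if dt.size == 0:
        return np.zeros(1)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("tissue forward model requires a uniform time grid (resample first)")
    dt = float(dt[0])
    refine = 8
    n = len(times)
    nf = (n - 1) * refine + 1
    dtf = dt / refine
    tf = times[0] + np.arange(nf) * dtf
    a = np.interp(tf - delay, times, aif_values, left=0.0)
    r = fermi_residue(tf - times[0], tau0, k)
    y = np.convolve(a, r)[:nf] * dtf
    # trapezoid end-point correction of the quadrature
    y -= 0.5 * dtf * (a[0] * r + a * r[0])
    y = np.maximum(y, 0.0)
    return (mbf / 60.0) * y[::refine]


def gen_tissue_curve(aif: ConcentrationCurve, kin: FermiKinetics) -> ConcentrationCurve:
    values = tissue_forward(aif.values, aif.times, kin.mbf, kin.tau0, kin.k, kin.delay)
    return ConcentrationCurve(times=aif.times.copy(), values=values)


def _uniform(rng, lo_hi):
    return float(rng.uniform(*lo_hi))


def simulate_subject(cfg: CohortConfig, seed: int, subject_id: str = "s0000") -> SyntheticSubject:
    """Draw one simulated patient; fully reproducible for a fixed seed."""
    rng = np.random.default_rng(seed)
    acq = AcquisitionParams(field_strength=cfg.field_strength)

    heart_rate = _uniform(rng, cfg.heart_rate_range)
    dt = 60.0 / heart_rate
    n_frames = int(rng.integers(cfg.n_frames_range[0], cfg.n_frames_range[1] + 1))
    times = np.arange(n_frames) * dt

    gv = GammaVariateParams(
        t0=_uniform(rng, cfg.arrival_range),
        alpha=_uniform(rng, cfg.alpha_range),
        beta=_uniform(rng, cfg.beta_range),
        peak=_uniform(rng, cfg.peak_range),
        recirc_frac=_uniform(rng, cfg.recirc_frac_range),
        recirc_delay=_uniform(rng, cfg.recirc_delay_range),
    )
    aif_true = gen_aif_concentration(gv, times)

    kinetics, tissue_true = [], []
    for _ in range(N_SEGMENTS):
        abnormal = rng.random() < cfg.p_abnormal
        mbf = _uniform(rng, cfg.mbf_abnormal_range if abnormal else cfg.mbf_normal_range)
        kin = FermiKinetics(
            mbf=mbf,
            tau0=_uniform(rng, cfg.tau0_range),
            k=_uniform(rng, cfg.k_range),
            delay=_uniform(rng, cfg.delay_range),
        )
        kinetics.append(kin)
        tissue_true.append(gen_tissue_curve(aif_true, kin))

    # Reference (short-TS) gain scaled so pre-contrast blood baselines match
    # the standard sequence, putting both acquisitions on one intensity scale.
    g_sat = cfg.gain
    b_std = 1.0 - np.exp(-acq.ts_standard / acq.t1_blood)
    b_ref = 1.0 - np.exp(-acq.ts_aif / acq.t1_blood)
    g_ref = g_sat * b_std / b_ref

    noise_sd = cfg.noise_frac * g_sat * b_std

    def noisy(curve: SignalCurve) -> SignalCurve:
        v = curve.values + rng.normal(0.0, noise_sd, size=len(curve))
        return SignalCurve(times=curve.times, values=np.maximum(v, 0.0), ts=curve.ts)

    sat_aif = noisy(sr_signal(aif_true, acq.t1_blood, acq.ts_standard, gain=g_sat, r1=acq.r1))
    ref_aif = noisy(sr_signal(aif_true, acq.t1_blood, acq.ts_aif, gain=g_ref, r1=acq.r1))
    tissue_signal = [
        noisy(sr_signal(ct, acq.t1_myo, acq.ts_standard, gain=g_sat, r1=acq.r1))
        for ct in tissue_true
    ]

    return SyntheticSubject(
        subject_id=subject_id,
        heart_rate=heart_rate,
        acq=acq,
        aif_true=aif_true,
        segment_kinetics=kinetics,
        tissue_true=tissue_true,
        sat_aif=sat_aif,
        ref_aif=ref_aif,
        tissue_signal=tissue_signal,
        noise_sd=noise_sd,
        seed=seed,
    )


def _split_counts(n: int, fractions) -> tuple[int, int, int]:
    counts = [int(np.floor(n * f)) for f in fractions]
    counts[0] += n - sum(counts)
    return tuple(counts)


def gen_cohort(cfg: CohortConfig) -> dict:
    """Generate a seeded cohort split into train/val/test subject lists."""
    n_train, n_val, n_test = _split_counts(cfg.n_subjects, cfg.fractions)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_subjects) % (2**31)
    subjects = [
        simulate_subject(cfg, seed=int(seeds[i]), subject_id=f"s{i:04d}")
        for i in range(cfg.n_subjects)
    ]
    return {
        "train": subjects[:n_train],
        "val": subjects[n_train : n_train + n_val],
        "test": subjects[n_train + n_val :],
    }


def write_cohort(out_dir: str | Path, cohort: dict, cfg: CohortConfig) -> None:
    """Write a cohort as per-subject CSV curve files plus a JSON manifest."""
    from .io import write_concentration_curve, write_signal_curve

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": {k: list(v) if isinstance(v, tuple) else v for k, v in vars(cfg).items()}, "splits": {}}
    for split, subjects in cohort.items():
        manifest["splits"][split] = []
        for s in subjects:
            sdir = out_dir / s.subject_id
            sdir.mkdir(exist_ok=True)
            write_signal_curve(sdir / "sat_aif.csv", s.sat_aif, s.acq)
            write_signal_curve(sdir / "ref_aif.csv", s.ref_aif, s.acq)
            write_concentration_curve(sdir / "aif_true.csv", s.aif_true)
            for i, (ts_sig, ts_true) in enumerate(zip(s.tissue_signal, s.tissue_true), start=1):
                write_signal_curve(sdir / f"tissue_{i:02d}.csv", ts_sig, s.acq)
                write_concentration_curve(sdir / f"tissue_true_{i:02d}.csv", ts_true)
            manifest["splits"][split].append(
                {
                    "id": s.subject_id,
                    "seed": s.seed,
                    "heart_rate": s.heart_rate,
                    "noise_sd": s.noise_sd,
                    "mbf_true": [k.mbf for k in s.segment_kinetics],
                }
            )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def read_cohort(out_dir: str | Path) -> dict:
    """Reload the curves of a written cohort (ground-truth kinetics come
    from the manifest's MBF table; full kinetic parameters are not stored)."""
    from .io import read_concentration_curve, read_signal_curve

    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    cohort = {}
    for split, entries in manifest["splits"].items():
        subjects = []
        for e in entries:
            sdir = out_dir / e["id"]
            sat, acq = read_signal_curve(sdir / "sat_aif.csv")
            ref, _ = read_signal_curve(sdir / "ref_aif.csv")
            aif_true = read_concentration_curve(sdir / "aif_true.csv")
            tissue_signal, tissue_true = [], []
            for i in range(1, N_SEGMENTS + 1):
                tissue_signal.append(read_signal_curve(sdir / f"tissue_{i:02d}.csv")[0])
                tissue_true.append(read_concentration_curve(sdir / f"tissue_true_{i:02d}.csv"))
            kinetics = [FermiKinetics(mbf=m) for m in e["mbf_true"]]
            subjects.append(
                SyntheticSubject(
                    subject_id=e["id"],
                    heart_rate=e["heart_rate"],
                    acq=acq,
                    aif_true=aif_true,
                    segment_kinetics=kinetics,
                    tissue_true=tissue_true,
                    sat_aif=sat,
                    ref_aif=ref,
                    tissue_signal=tissue_signal,
                    noise_sd=e["noise_sd"],
                    seed=e["seed"],
                )
            )
        cohort[split] = subjects
    return cohort
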