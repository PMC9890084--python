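"""Synthetic cohort generator: bolus shapes, tissue kinetics, acquisitions."""

import numpy as np
import pytest

from aifnet.signal_model import ConcentrationCurve, concentration_from_signal
from aifnet.synthetic import (
    CohortConfig,
    FermiKinetics,
    GammaVariateParams,
    gen_aif_concentration,
    gen_cohort,
    gen_tissue_curve,
    fermi_residue,
    read_cohort,
    simulate_subject,
    write_cohort,
)

GV = GammaVariateParams(t0=3.0, alpha=2.5, beta=1.2, peak=5.0)


class TestGammaVariate:
    def test_peak_location_and_value(self):
        times = np.arange(0, 40, 0.01)
        aif = gen_aif_concentration(GV, times)
        assert times[np.argmax(aif.values)] == pytest.approx(3.0 + 2.5 * 1.2, abs=0.02)
        assert aif.values.max() == pytest.approx(5.0, rel=1e-6)

    def test_zero_before_arrival(self):
        times = np.arange(0, 40, 0.5)
        aif = gen_aif_concentration(GV, times)
        assert np.all(aif.values[times <= 3.0] == 0)

    def test_fwhm_matches_dense_grid_oracle(self):
        # independent oracle: half-maximum crossings on a 1 ms grid
        t = np.arange(0, 40, 0.001)
        v = gen_aif_concentration(GV, t).values
        half = v.max() / 2
        above = np.nonzero(v >= half)[0]
        fwhm_oracle = t[above[-1]] - t[above[0]]
        # gaussian approximation of the gamma-variate width is close
        assert fwhm_oracle == pytest.approx(2.355 * 1.2 * np.sqrt(2.5), rel=0.1)
        # coarse-grid curve has the same width up to one sample
        tc = np.arange(0, 40, 0.5)
        vc = gen_aif_concentration(GV, tc).values
        above_c = np.nonzero(vc >= vc.max() / 2)[0]
        width_c = tc[above_c[-1]] - tc[above_c[0]]
        assert abs(width_c - fwhm_oracle) <= 1.0

    def test_recirculation_adds_delayed_tail(self):
        times = np.arange(0, 60, 0.5)
        p = GammaVariateParams(t0=3.0, alpha=2.5, beta=1.2, peak=5.0, recirc_frac=0.2, recirc_delay=12.0)
        plain = gen_aif_concentration(GV, times).values
        with_rc = gen_aif_concentration(p, times).values
        assert np.allclose(with_rc[times < 15.0], plain[times < 15.0])
        assert np.all(with_rc[times > 25.0] >= plain[times > 25.0])


class TestTissueForward:
    def test_zero_flow_gives_zero_tissue(self):
        times = np.arange(0, 40.0)
        aif = gen_aif_concentration(GV, times)
        ct = gen_tissue_curve(aif, FermiKinetics(mbf=0.0))
        assert np.allclose(ct.values, 0.0)

    def test_linear_in_mbf(self):
        times = np.arange(0, 40.0)
        aif = gen_aif_concentration(GV, times)
        c1 = gen_tissue_curve(aif, FermiKinetics(mbf=1.0, tau0=4, k=0.3, delay=0.5))
        c2 = gen_tissue_curve(aif, FermiKinetics(mbf=2.0, tau0=4, k=0.3, delay=0.5))
        assert np.allclose(c2.values, 2 * c1.values, rtol=1e-12)

    def test_matches_fine_grid_quadrature_oracle(self):
        # heart rate 60: dt = 1 s; oracle integrates on a 10x finer grid
        kin = FermiKinetics(mbf=2.0, tau0=4.0, k=0.3, delay=0.5)
        t = np.arange(0, 48.0, 1.0)
        coarse = gen_tissue_curve(gen_aif_concentration(GV, t), kin).values

        tf = np.arange(0, 48.0, 0.1)
        af = gen_aif_concentration(GV, tf).values
        a_shift = np.interp(tf - kin.delay, tf, af, left=0.0)
        r = fermi_residue(tf, kin.tau0, kin.k)
        fine = np.array(
            [np.trapezoid(a_shift[: i + 1] * r[: i + 1][::-1], dx=0.1) for i in range(len(tf))]
        ) * (kin.mbf / 60.0)
        oracle = fine[::10]
        # error relative to each sample where the curve is established, and
        # relative to curve scale at the bolus foot
        mask = oracle > 0.2 * oracle.max()
        rel = np.abs(coarse[mask] - oracle[mask]) / oracle[mask]
        assert rel.max() < 0.01
        # at the bolus foot the operator only sees sampled AIF values, so
        # the residual is limited by linear interpolation between beats
        assert np.abs(coarse - oracle).max() < 0.02 * oracle.max()

    def test_nonuniform_grid_rejected(self):
        times = np.array([0.0, 1.0, 2.0, 4.0])
        aif = ConcentrationCurve(times, np.ones(4))
        with pytest.raises(ValueError, match="uniform"):
            gen_tissue_curve(aif, FermiKinetics(mbf=1.0))

    def test_tissue_peak_below_arterial_peak(self):
        times = np.arange(0, 48.0)
        aif = gen_aif_concentration(GV, times)
        ct = gen_tissue_curve(aif, FermiKinetics(mbf=4.0, tau0=4, k=0.8, delay=0.5))
        assert ct.values.max() < aif.values.max()


class TestSimulateSubject:
    def test_same_seed_reproduces_subject(self):
        cfg = CohortConfig()
        a = simulate_subject(cfg, seed=42)
        b = simulate_subject(cfg, seed=42)
        assert np.array_equal(a.sat_aif.values, b.sat_aif.values)
        assert np.array_equal(a.ref_aif.values, b.ref_aif.values)
        assert [k.mbf for k in a.segment_kinetics] == [k.mbf for k in b.segment_kinetics]

    def test_converted_peak_ordering(self):
        s = simulate_subject(CohortConfig(), seed=3)
        peak_sat = concentration_from_signal(s.sat_aif).values.max()
        peak_ref = concentration_from_signal(s.ref_aif).values.max()
        assert peak_sat < peak_ref

    def test_shared_time_grid_and_segment_count(self):
        s = simulate_subject(CohortConfig(), seed=4)
        dt = 60.0 / s.heart_rate
        assert np.allclose(np.diff(s.aif_true.times), dt)
        assert len(s.tissue_true) == 16 == len(s.tissue_signal)
        for ct in s.tissue_true:
            assert len(ct) == len(s.aif_true)

    def test_noise_is_zero_mean(self):
        # average the added noise over many subjects sharing parameters
        cfg = CohortConfig(noise_frac=0.02)
        resid = []
        for seed in range(30):
            s = simulate_subject(cfg, seed=1000 + seed)
            from aifnet.signal_model import sr_signal

            clean = sr_signal(
                s.aif_true, s.acq.t1_blood, s.acq.ts_standard, gain=cfg.gain, r1=s.acq.r1
            )
            resid.extend(s.sat_aif.values - clean.values)
        resid = np.asarray(resid)
        se = resid.std() / np.sqrt(len(resid))
        assert abs(resid.mean()) < 3 * se + 1e-9


class TestCohort:
    def test_split_sizes_and_disjoint_ids(self):
        cfg = CohortConfig(n_subjects=10, seed=1, fractions=(0.8, 0.1, 0.1))
        cohort = gen_cohort(cfg)
        assert [len(cohort[k]) for k in ("train", "val", "test")] == [8, 1, 1]
        ids = [s.subject_id for split in cohort.values() for s in split]
        assert len(set(ids)) == 10

    def test_different_seeds_differ(self):
        a = gen_cohort(CohortConfig(n_subjects=3, seed=1))["train"][0]
        b = gen_cohort(CohortConfig(n_subjects=3, seed=2))["train"][0]
        assert not np.array_equal(a.sat_aif.values, b.sat_aif.values)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=5, fractions=(0.5, 0.2, 0.2))

    def test_write_read_round_trip(self, tmp_path):
        cfg = CohortConfig(n_subjects=3, seed=5, fractions=(1 / 3, 1 / 3, 1 / 3))
        cohort = gen_cohort(cfg)
        write_cohort(tmp_path / "cohort", cohort, cfg)
        back = read_cohort(tmp_path / "cohort")
        for split in ("train", "val", "test"):
            for orig, rb in zip(cohort[split], back[split]):
                assert rb.subject_id == orig.subject_id
                np.testing.assert_allclose(rb.sat_aif.values, orig.sat_aif.values, rtol=1e-7)
                np.testing.assert_allclose(
                    [k.mbf for k in rb.segment_kinetics],
                    [k.mbf for k in orig.segment_kinetics],
                    rtol=1e-7,
                )
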