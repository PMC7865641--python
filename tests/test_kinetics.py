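"""Binding-curve extraction, specificity calls and Langmuir fitting."""

import numpy as np
import pytest

from irisqc import kinetics, synthgen
from irisqc.kinetics import (
    BindingCurve,
    InjectionSchedule,
    NoBindingSignalError,
    langmuir_trajectory,
)


def single_injection_schedule(c=50e-9, assoc=1200.0, wash=600.0, baseline=60.0):
    return InjectionSchedule.sequential(
        ["T"], concentration_m=c, association_s=assoc, wash_s=wash, baseline_s=baseline
    )


class TestLangmuirModel:
    def test_association_plateau_closed_form(self):
        # t -> inf plateau is Gamma_max * C / (C + K_d)
        k_on, k_off, gmax, c = 1e5, 1e-4, 2.0, 50e-9
        sched = InjectionSchedule.sequential(
            ["T"], concentration_m=c, association_s=2e5, wash_s=100.0, baseline_s=0.0
        )
        g = langmuir_trajectory(np.array([1.9e5]), sched, k_on, k_off, gmax, analyte="T")
        k_d = k_off / k_on
        assert g[0] == pytest.approx(gmax * c / (c + k_d), rel=1e-6)

    def test_zero_off_rate_keeps_wash_flat_at_gamma_max_limit(self):
        sched = single_injection_schedule(assoc=5e4)
        t = np.array([sched.phases[1].end_s, sched.end_s])
        g = langmuir_trajectory(t, sched, 1e5, 0.0, 2.0, analyte="T")
        assert g[1] == pytest.approx(g[0])  # no dissociation
        assert g[0] == pytest.approx(2.0, rel=1e-3)  # K_d -> 0: plateau = Gamma_max

    def test_gamma_max_scales_linearly(self):
        sched = single_injection_schedule()
        t = np.linspace(0, sched.end_s, 50)
        g1 = langmuir_trajectory(t, sched, 1e5, 1e-4, 1.0, analyte="T")
        g2 = langmuir_trajectory(t, sched, 1e5, 1e-4, 2.0, analyte="T")
        assert np.allclose(g2, 2 * g1)


class TestCurveExtraction:
    def test_drift_cancels_without_binding(self):
        # 2% linear illumination drift, zero on-rate: the spot-minus-background
        # differential stays flat at zero within noise
        sc = synthgen.scenario_specificity(seed=4, drift_amplitude=0.02)
        for p in sc.kinetics:
            sc.kinetics[p] = synthgen.KineticsParams(k_on=0.0, k_off=0.0)
        ts = synthgen.generate_timeseries(sc)
        curves = synthgen.binding_curves_from_timeseries(ts)
        # also run the identical scenario without drift: the curves must agree
        # point by point far below the per-point conversion noise, i.e. the
        # drift contributes nothing to the differential
        sc0 = synthgen.scenario_specificity(seed=4, drift_amplitude=0.0)
        for p in sc0.kinetics:
            sc0.kinetics[p] = synthgen.KineticsParams(k_on=0.0, k_off=0.0)
        ts0 = synthgen.generate_timeseries(sc0)
        curves0 = synthgen.binding_curves_from_timeseries(ts0)
        for p, c in curves.items():
            # flat at zero within the baseline-referencing noise floor
            assert abs(float(np.median(c.mass_mean))) < 0.15
            # and identical to the drift-free run: the drift fully cancels
            assert np.max(np.abs(c.mass_mean - curves0[p].mass_mean)) < 0.02

    def test_early_time_slope_matches_closed_form(self):
        # k_on C t << 1: dGamma/dt ~ Gamma_max k_on C
        sc = synthgen.scenario_specificity(seed=8, noise_sigma=0.0)
        sc.kinetics = {p: synthgen.KineticsParams(k_on=2e3, k_off=0.0, gamma_max=2.0)
                       for p in sc.kinetics}
        ts = synthgen.generate_timeseries(sc, dt_s=5.0)
        curves = synthgen.binding_curves_from_timeseries(ts)
        probe = "NRAS-WT"  # first injection
        inj = [p for p in ts.schedule.injections if p.analyte == probe][0]
        c = curves[probe]
        sel = (c.times_s >= inj.start_s) & (c.times_s <= inj.start_s + 200.0)
        slope = np.polyfit(c.times_s[sel], c.mass_mean[sel], 1)[0]
        want = 2.0 * 2e3 * 50e-9
        assert slope == pytest.approx(want, rel=0.05)

    def test_replicate_averaging_matches_single_spot(self):
        sc = synthgen.scenario_specificity(seed=9)
        ts = synthgen.generate_timeseries(sc)
        curves = synthgen.binding_curves_from_timeseries(ts)
        c = curves["KRAS-WT"]
        assert c.n_replicates == 2
        # replicate scatter should be on the noise scale, far below the signal
        assert np.median(c.mass_sd) < 0.2
        assert np.max(c.mass_mean) > 1.5

    def test_averaging_commutes_with_conversion_in_linear_range(self, water_config):
        # averaging intensities then converting vs converting then averaging
        # agree within the linearization tolerance for small mass changes
        from irisqc import optics

        op = optics.ThicknessFit(110.0, 1.0, 0.0, np.ones(4))
        i_ref = optics.reflectance(water_config, 452.0, 110.0, 1.0)
        deltas = np.array([0.4, 0.8, 1.3, 1.9])  # nm, all < 2 nm
        i_t = np.array([
            optics.reflectance(water_config, 452.0, 110.0, 1.0 + d) for d in deltas
        ])
        per_spot = np.array([
            optics.single_wavelength_delta_mass(i, i_ref, op, water_config, 452.0)
            for i in i_t
        ])
        pooled = optics.single_wavelength_delta_mass(
            float(np.mean(i_t)), i_ref, op, water_config, 452.0
        )
        assert pooled == pytest.approx(float(np.mean(per_spot)), rel=0.01)

    def test_stack_extraction_matches_traces(self, water_config):
        # the image-stack path and the trace path agree on the same scenario
        from irisqc import optics

        sc = synthgen.scenario_specificity(seed=6)
        sc.schedule = InjectionSchedule.sequential(
            synthgen.SPECIFICITY_PROBES[:1], association_s=600.0, wash_s=300.0
        )
        ts = synthgen.generate_timeseries(sc, dt_s=60.0, mode="frames")
        lut = optics.build_lut(ts.optics)
        curves = kinetics.extract_binding_curves(
            ts.stack, ts.prescan_images, lut, ts.optics, ts.schedule
        )
        ref = synthgen.binding_curves_from_timeseries(ts, lut)
        probe = synthgen.SPECIFICITY_PROBES[0]
        a, b = curves[probe], ref[probe]
        # the two paths carry independent noise realizations (~0.1 ng/mm^2
        # per point each); they must agree to that level, not exactly
        diff = np.abs(a.mass_mean - b.mass_mean)
        assert float(np.median(diff)) < 0.15
        assert float(diff.max()) < 0.6
        assert a.mass_mean[-1] == pytest.approx(b.mass_mean[-1], abs=0.4)

    def test_single_frame_stack_rejected(self, water_config):
        from irisqc import optics
        from irisqc.chip_io import ChipImageSet

        sc = synthgen.scenario_specificity(seed=6)
        ts = synthgen.generate_timeseries(sc, dt_s=200.0, mode="frames")
        one = ChipImageSet(
            images=ts.stack.images[:1], labels=ts.stack.labels[:1],
            layout=ts.stack.layout, kind="time", wavelength_nm=452.0,
        )
        lut = optics.build_lut(ts.optics)
        with pytest.raises(ValueError, match="at least 2 frames"):
            kinetics.extract_binding_curves(one, ts.prescan_images, lut, ts.optics)


class TestSpecificity:
    @pytest.fixture(scope="class")
    def cognate_run(self):
        sc = synthgen.scenario_specificity(seed=1)
        ts = synthgen.generate_timeseries(sc)
        curves = synthgen.binding_curves_from_timeseries(ts)
        return ts, curves

    def test_diagonal_only(self, cognate_run):
        ts, curves = cognate_run
        m = kinetics.specificity_matrix(curves, ts.schedule)
        for p in curves:
            assert m.calls.loc[p, p]
        off = [
            (p, a) for p in m.calls.index for a in m.calls.columns
            if p != a and m.calls.loc[p, a]
        ]
        assert off == []

    def test_matrix_shape_one_column_per_injection(self, cognate_run):
        ts, curves = cognate_run
        m = kinetics.specificity_matrix(curves, ts.schedule)
        assert list(m.net.columns) == [p.label for p in ts.schedule.injections]
        assert sorted(m.net.index) == sorted(curves)

    def test_all_wash_schedule_gives_empty_matrix(self, cognate_run):
        ts, curves = cognate_run
        washes = InjectionSchedule([kinetics.Phase("wash", "", 0.0, 0.0, ts.schedule.end_s)])
        m = kinetics.specificity_matrix(curves, washes)
        assert m.net.shape[1] == 0

    def test_planted_cross_reactivity_called(self):
        # 50% cross-binding of the first-injected analyte on a probe whose own
        # cognate comes later (so its surface is still free)
        sc = synthgen.scenario_specificity(
            seed=3, cross_reactivity={("KRAS-G13D", "NRAS-WT"): 0.5}
        )
        ts = synthgen.generate_timeseries(sc)
        curves = synthgen.binding_curves_from_timeseries(ts)
        m = kinetics.specificity_matrix(curves, ts.schedule)
        assert bool(m.calls.loc["KRAS-G13D", "NRAS-WT"])

    def test_calls_invariant_to_common_drift(self, cognate_run):
        ts, curves = cognate_run
        base = kinetics.specificity_matrix(curves, ts.schedule).calls
        shifted = {
            p: BindingCurve(
                p, c.times_s, c.mass_mean + 0.002 * c.times_s / ts.schedule.end_s,
                c.mass_sd, c.n_replicates, c.schedule,
            )
            for p, c in curves.items()
        }
        drifted = kinetics.specificity_matrix(shifted, ts.schedule).calls
        assert base.equals(drifted)

    def test_short_injection_shrinks_window_with_warning(self, cognate_run):
        ts, curves = cognate_run
        sched = InjectionSchedule([
            kinetics.Phase("baseline", "", 0.0, 0.0, 120.0),
            kinetics.Phase("quick", "NRAS-WT", 50e-9, 120.0, 20.0),
            kinetics.Phase("wash", "", 0.0, 140.0, ts.schedule.end_s - 140.0),
        ])
        with pytest.warns(UserWarning, match="shorter than the averaging window"):
            kinetics.specificity_matrix(curves, sched)


class TestLangmuirFit:
    def test_noise_free_recovery_within_one_percent(self):
        # the documented experiment timing: 20 min association at 50 nM,
        # 10 min wash
        sched = single_injection_schedule()
        t = np.arange(0.0, sched.end_s + 1, 2.0)
        g = langmuir_trajectory(t, sched, 1e5, 1e-4, 2.0, analyte="T")
        curve = BindingCurve("T", t, g, np.zeros_like(t), 1, sched)
        fit = kinetics.fit_langmuir(curve, sched, analyte="T")
        assert fit.k_on == pytest.approx(1e5, rel=0.01)
        assert fit.k_off == pytest.approx(1e-4, rel=0.01)
        assert fit.gamma_max == pytest.approx(2.0, rel=0.01)
        assert fit.k_d == pytest.approx(fit.k_off / fit.k_on)

    def test_zero_off_rate_reported_as_upper_bound(self):
        sched = single_injection_schedule()
        t = np.arange(0.0, sched.end_s + 1, 2.0)
        g = langmuir_trajectory(t, sched, 1e5, 0.0, 2.0, analyte="T")
        curve = BindingCurve("T", t, g, np.zeros_like(t), 1, sched)
        fit = kinetics.fit_langmuir(curve, sched, analyte="T")
        assert fit.k_off_is_upper_bound
        assert fit.k_off <= 0.02 / 600.0 * 1.001

    def test_flat_curve_raises_no_binding_signal(self):
        sched = single_injection_schedule()
        t = np.arange(0.0, sched.end_s + 1, 10.0)
        curve = BindingCurve("T", t, np.zeros_like(t), np.zeros_like(t), 1, sched)
        with pytest.raises(NoBindingSignalError):
            kinetics.fit_langmuir(curve, sched, analyte="T")

    def test_parameter_recovery_at_snr_20(self):
        # additive noise at Gamma_max/20; median relative errors stay inside 10%
        sched = single_injection_schedule()
        t = np.arange(0.0, sched.end_s + 1, 2.0)
        clean = langmuir_trajectory(t, sched, 1e5, 1e-4, 2.0, analyte="T")
        errs_on, errs_off = [], []
        for seed in range(25):
            rng = np.random.default_rng(seed)
            y = clean + 0.1 * rng.standard_normal(len(t))
            curve = BindingCurve("T", t, y, np.zeros_like(t), 1, sched)
            fit = kinetics.fit_langmuir(curve, sched, analyte="T")
            errs_on.append(abs(fit.k_on - 1e5) / 1e5)
            errs_off.append(abs(fit.k_off - 1e-4) / 1e-4)
        assert np.median(errs_on) <= 0.10
        assert np.median(errs_off) <= 0.10
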