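"""Synthetic cohort generator: determinism, calibration, bias structure."""

import numpy as np
import pytest

import cowflow as cf
from cowflow.synthetic_data import (
    FLOW_TABLE,
    _COW_TEMPLATE,
    _canonical_shape,
    _recording_for_flow,
)
from cowflow.waveforms import ensemble_average, poiseuille_flow, total_cbf


class TestSynthNetwork:
    def test_zero_jitter_is_template(self):
        net = cf.synth_network(seed=0, jitter_cv=0.0)
        diam = {s.id: s.diameter_mm for s in net.segments}
        for sid, _, _, _, d, _ in _COW_TEMPLATE:
            assert diam[sid] == d

    def test_deterministic_per_seed(self):
        a = cf.synth_network(seed=11, jitter_cv=0.05)
        b = cf.synth_network(seed=11, jitter_cv=0.05)
        c = cf.synth_network(seed=12, jitter_cv=0.05)
        da = [s.diameter_mm for s in a.segments]
        assert da == [s.diameter_mm for s in b.segments]
        assert da != [s.diameter_mm for s in c.segments]

    def test_jitter_cv_calibrated(self):
        d = np.array(
            [cf.synth_network(seed=k, jitter_cv=0.05).segments[0].diameter_mm for k in range(1000)]
        )
        cv = d.std() / d.mean()
        assert cv == pytest.approx(0.05, abs=0.01)

    def test_every_region_has_an_outlet(self):
        net = cf.synth_network(seed=0)
        covered = set(net.outlets.values())
        assert covered == set(cf.REGIONS)
        assert set(net.inlets.values()) == set(cf.ARTERIES)


class TestCanonicalShape:
    def test_mean_one_and_pulsatility(self):
        shape = _canonical_shape(96, 4, 1.2)
        assert shape.mean() == pytest.approx(1.0, rel=1e-12)
        assert np.ptp(shape) / shape.mean() == pytest.approx(1.2, rel=1e-6)
        assert shape.min() > 0

    def test_peak_near_quarter_phase(self):
        shape = _canonical_shape(200, 4, 1.2)
        assert abs(np.argmax(shape) / 200 - 0.25) < 0.05


class TestSynthInletRecording:
    def test_zero_noise_identical_cycles(self):
        cfg = cf.CohortConfig(cycle_noise_cv=0.0)
        rec = cf.synth_inlet_recording("LICA", "rest", cfg, seed=5)
        assert len(rec.cycles) == 3
        for cyc in rec.cycles[1:]:
            assert np.array_equal(cyc.values, rec.cycles[0].values)
            assert cyc.period == rec.cycles[0].period

    def test_processed_flow_recovers_draw(self):
        """Ensemble averaging + Poiseuille conversion recovers the drawn
        time-averaged flow (the generator's defining contract)."""
        cfg = cf.CohortConfig(cycle_noise_cv=0.0)
        rng = np.random.default_rng(0)
        rec = _recording_for_flow("RICA", 250.0, 0.9, cfg, rng)
        ens = ensemble_average(rec.cycles, n_points=96)
        q = poiseuille_flow(ens, rec.diameter_mm)
        assert cf.time_average(q) == pytest.approx(250.0, rel=0.005)

    def test_resting_tcbf_calibration(self):
        """Mean tCBF of a large synthetic resting cohort sits within two
        standard errors of the calibration target 618.1 mL/min."""
        cfg = cf.CohortConfig(cycle_noise_cv=0.0)
        root = np.random.SeedSequence(2024)
        tcbfs = []
        for ss in root.spawn(500):
            sub = ss.spawn(4)
            flows = []
            for artery, s in zip(cf.ARTERIES, sub):
                rec = cf.synth_inlet_recording(artery, "rest", cfg, seed=s)
                ens = ensemble_average(rec.cycles, n_points=64)
                flows.append(poiseuille_flow(ens, rec.diameter_mm))
            tcbfs.append(total_cbf(flows))
        tcbfs = np.asarray(tcbfs)
        se = tcbfs.std(ddof=1) / np.sqrt(len(tcbfs))
        assert abs(tcbfs.mean() - 618.1) < 2 * se + 1e-9

    def test_hypercapnia_raises_every_artery(self):
        root = np.random.SeedSequence(77)
        cfg = cf.CohortConfig()
        for artery in cf.ARTERIES:
            draws = {"rest": [], "hypercapnia": []}
            for cond in draws:
                for ss in root.spawn(120):
                    rec = cf.synth_inlet_recording(artery, cond, cfg, seed=ss)
                    ens = ensemble_average(rec.cycles, n_points=64)
                    draws[cond].append(cf.time_average(poiseuille_flow(ens, rec.diameter_mm)))
            assert np.mean(draws["hypercapnia"]) > np.mean(draws["rest"])
            # and the configured targets themselves are ordered that way
            assert FLOW_TABLE["hypercapnia"][artery][0] > FLOW_TABLE["rest"][artery][0]


class TestSynthTcdEnvelope:
    def envelope(self):
        phi = np.arange(96) / 96
        return cf.SampledWaveform(40 + 30 * np.sin(np.pi * phi) ** 2, 0.9, "cm/s")

    def test_unit_bias_zero_noise_identity(self):
        env = self.envelope()
        out = cf.synth_tcd_envelope(env, cf.BiasFactors(1.0, 1.0, 1.0), noise_cv=0.0, seed=0)
        assert np.allclose(out.values, env.values, rtol=1e-14)

    def test_uniform_bias_scales_all_metrics(self):
        env = self.envelope()
        out = cf.synth_tcd_envelope(env, cf.BiasFactors(1.6, 1.6, 1.6), noise_cv=0.0, seed=0)
        m_in, m_out = cf.extract_metrics(env), cf.extract_metrics(out)
        for name in cf.METRIC_NAMES:
            assert m_out.as_dict()[name] == pytest.approx(1.6 * m_in.as_dict()[name], rel=1e-12)

    def test_diastolic_bias_gradient(self):
        env = self.envelope()
        out = cf.synth_tcd_envelope(env, cf.BiasFactors(1.5, 1.7, 1.9), noise_cv=0.0, seed=0)
        m_in, m_out = cf.extract_metrics(env), cf.extract_metrics(out)
        ratio_sys = m_out.systolic / m_in.systolic
        ratio_ed = m_out.end_diastolic / m_in.end_diastolic
        assert ratio_sys == pytest.approx(1.5, rel=1e-12)
        assert ratio_ed > ratio_sys


class TestSynthCohort:
    def test_bit_identical_under_master_seed(self):
        a = cf.synth_cohort(cf.CohortConfig(n_participants=3, master_seed=9))
        b = cf.synth_cohort(cf.CohortConfig(n_participants=3, master_seed=9))
        for pa, pb in zip(a, b):
            assert pa.bias == pb.bias
            for cond in cf.CONDITIONS:
                assert np.array_equal(
                    pa.tcd_envelopes[cond].values, pb.tcd_envelopes[cond].values
                )
                assert pa.sim_results[cond].tcbf_ml_min == pb.sim_results[cond].tcbf_ml_min

    def test_participant_substreams_independent(self):
        small = cf.synth_cohort(cf.CohortConfig(n_participants=3, master_seed=9))
        larger = cf.synth_cohort(cf.CohortConfig(n_participants=5, master_seed=9))
        for pa, pb in zip(small, larger[:3]):
            assert pa.bias == pb.bias
            assert np.array_equal(
                pa.tcd_envelopes["rest"].values, pb.tcd_envelopes["rest"].values
            )

    def test_cohort_passes_upstream_invariants(self, small_cohort):
        for p in small_cohort:
            for cond in cf.CONDITIONS:
                for artery in cf.ARTERIES:
                    rec = p.recordings[cond][artery]
                    assert rec.diameter_mm > 0
                    assert all(np.all(c.values >= 0) for c in rec.cycles)
                sol = p.sim_results[cond].solution
                assert np.all(np.isfinite(sol.v_max_cm_s))

    def test_constant_bias_zero_noise_relative_change_identity(self):
        """With a within-participant constant (uniform) bias and no noise,
        TCD and CFD relative changes coincide exactly — the generator
        reproduces absolute disagreement with relative agreement."""
        cfg = cf.CohortConfig(
            n_participants=3,
            master_seed=21,
            noise_cv=0.0,
            bias_means=cf.BiasFactors(1.6, 1.6, 1.6),
            bias_sd=0.0,
        )
        cohort = cf.synth_cohort(cfg)
        records = cf.cohort_study_records(cohort)
        for pid, conds in records.items():
            for stim in ("hypercapnia", "exercise"):
                d_tcd = cf.relative_change(conds["rest"].tcd, conds[stim].tcd)
                d_cfd = cf.relative_change(conds["rest"].cfd, conds[stim].cfd)
                for name in cf.METRIC_NAMES:
                    assert d_tcd.as_dict()[name] == pytest.approx(
                        d_cfd.as_dict()[name], rel=1e-9, abs=1e-9
                    )

    def test_study_runs_end_to_end(self, small_cohort):
        tables = cf.run_study(cf.cohort_study_records(small_cohort))
        # TCD systematically above CFD in absolute metrics
        assert (tables.bland_altman_abs["bias"] > 0).all()
        assert len(tables.distributions) == 3 * 3 * 2
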