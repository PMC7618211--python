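"""Cell model, diffusive stimulus, APD measurement, lookup table, drug block."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiotwin.cells import (
    CellModelParams,
    DrugSpec,
    IdiffParams,
    WAVEFORM_SAMPLES,
    apd90,
    apply_drug,
    build_lookup,
    calibrate_hill,
    dofetilide_spec,
    hill_block,
    idiff,
    pace_to_steady_state,
    repace_table_with_params,
)
from cardiotwin.errors import (
    CoverageError,
    InvalidArgumentError,
    NotAnActionPotentialError,
    TruncatedTraceError,
)

FITTED = IdiffParams()  # the fitted diffusive-current constants


class TestIdiff:
    def test_closed_form_at_first_peak(self):
        # at t = mu1 the first Gaussian contributes exactly A1
        expected = 25.83 - 27.42 * np.exp(-1.0 / (2 * 0.4432**2))
        assert idiff(13.9, FITTED) == pytest.approx(expected, rel=1e-12)

    def test_decays_to_zero_far_from_the_bumps(self):
        assert abs(idiff(-1e3, FITTED)) < 1e-12
        assert abs(idiff(1e3, FITTED)) < 1e-12

    def test_identical_gaussians_cancel(self):
        p = IdiffParams(A1=5, A2=5, mu1=10, mu2=10, sigma1=0.5, sigma2=0.5)
        t = np.linspace(0, 30, 301)
        assert np.allclose(idiff(t, p), 0.0)

    def test_rejects_nonpositive_width(self):
        with pytest.raises(InvalidArgumentError):
            IdiffParams(sigma1=0.0)


class TestPacing:
    def test_zero_amplitude_stimulus_leaves_cell_at_rest(self, cell_params):
        quiet = IdiffParams(A1=0.0, A2=0.0)
        trace, _ = pace_to_steady_state(cell_params, quiet, n_beats=2)
        assert trace.max() - trace[0] < 2.0

    def test_apd_reaches_steady_state_after_100_beats(self, cell_params):
        t99, _ = pace_to_steady_state(cell_params, n_beats=99)
        t100, _ = pace_to_steady_state(cell_params, n_beats=100)
        assert abs(apd90(t100) - apd90(t99)) < 1.0

    def test_high_gks_shortens_apd_relative_to_low_gks(self, cell_params):
        hi, _ = pace_to_steady_state(replace(cell_params, gKs_scale=50.0), n_beats=20)
        lo, _ = pace_to_steady_state(replace(cell_params, gKs_scale=1 / 50), n_beats=20)
        assert apd90(hi) < apd90(lo)

    def test_diffusive_stimulus_triggers_an_upstroke(self, cell_params):
        trace, _ = pace_to_steady_state(cell_params, n_beats=3)
        assert trace.max() > 0.0  # overshoot above 0 mV

    def test_requires_at_least_one_beat(self, cell_params):
        with pytest.raises(InvalidArgumentError):
            pace_to_steady_state(cell_params, n_beats=0)


class TestApd90:
    def test_square_pulse(self):
        w = np.zeros(400)
        w[1:200] = 40.0
        assert apd90(w) == pytest.approx(200.0, abs=1.0)

    def test_triangular_ap_has_analytic_crossing(self):
        # peak 40 mV at t=1, linear return to -85 mV at t=301: 90% level is
        # crossed exactly at t = 271
        t = np.arange(0, 400)
        w = np.full(400, -85.0)
        w[1:302] = 40.0 - (t[1:302] - 1) * (125.0 / 300.0)
        assert apd90(w) == pytest.approx(271.0, abs=0.5)

    def test_flat_trace_is_not_an_ap(self):
        with pytest.raises(NotAnActionPotentialError):
            apd90(np.full(300, -85.0))

    def test_unrepolarised_trace_is_truncated(self):
        w = np.full(300, -85.0)
        w[10:] = 30.0
        with pytest.raises(TruncatedTraceError):
            apd90(w)


class TestLookupTable:
    def test_waveforms_store_601_samples(self, small_table):
        assert small_table.waveforms.shape == (small_table.apd_values.size, 601)
        assert WAVEFORM_SAMPLES == 601

    def test_every_key_matches_its_waveform_apd(self, small_table):
        for i, key in enumerate(small_table.apd_values):
            assert apd90(small_table.waveforms[i]) == pytest.approx(key, abs=1.0)

    def test_gks_strictly_decreasing_with_apd(self, small_table):
        assert np.all(np.diff(small_table.gks) < 0)

    def test_apd_to_gks_map_is_one_to_one(self, small_table):
        assert np.unique(small_table.gks).size == small_table.gks.size

    def test_unachievable_bounds_raise_coverage_error(self, cell_params):
        with pytest.raises(CoverageError) as exc:
            build_lookup(
                cell_params, apd_bounds=(500.0, 600.0), n_beats=5, n_initial=8,
                max_refine=0,
            )
        assert exc.value.achievable[1] < 500.0

    def test_roundtrip_through_hdf5(self, small_table, tmp_path):
        p = tmp_path / "table.h5"
        small_table.save(p)
        back = type(small_table).load(p)
        assert np.array_equal(back.apd_values, small_table.apd_values)
        assert np.allclose(back.waveforms, small_table.waveforms)
        assert back.u_rest == pytest.approx(small_table.u_rest)

    def test_modified_baseline_widens_achievable_apd_range(self, cell_params):
        def apd_span(modified):
            p = CellModelParams(modified_baseline=modified)
            apds = []
            for g in (1 / 50, 50.0):
                tr, _ = pace_to_steady_state(replace(p, gKs_scale=g), n_beats=15)
                apds.append(apd90(tr))
            return max(apds) - min(apds)

        assert apd_span(True) / apd_span(False) > 1.0

    def test_repacing_with_ikr_block_prolongs_stored_waveforms(self, small_table):
        blocked = apply_drug(CellModelParams(), dofetilide_spec(), 3.0)
        dosed = repace_table_with_params(small_table, blocked, n_beats=12)
        mid = small_table.apd_values.size // 2
        assert apd90(dosed.waveforms[mid]) > apd90(small_table.waveforms[mid])


class TestHillBlock:
    def test_zero_dose_means_no_block(self):
        assert hill_block(0.0, DrugSpec(ic50=2.0, hill=1.3)) == 1.0

    @given(h=st.floats(0.2, 5.0), ic50=st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_half_block_at_ic50_for_any_hill_coefficient(self, h, ic50):
        assert hill_block(ic50, DrugSpec(ic50=ic50, hill=h)) == pytest.approx(0.5)

    def test_calibration_to_two_anchor_pairs_is_exact(self):
        ic50, h = calibrate_hill([(0.5, 0.40), (1.0, 0.50)])
        spec = DrugSpec(ic50=ic50, hill=h)
        assert 1 - hill_block(0.5, spec) == pytest.approx(0.40, abs=1e-12)
        assert 1 - hill_block(1.0, spec) == pytest.approx(0.50, abs=1e-12)

    @given(st.floats(0.1, 50.0), st.floats(0.1, 50.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_block_is_monotone_in_dose(self, d1, d2):
        spec = dofetilide_spec()
        lo, hi = sorted([d1, d2])
        assert hill_block(hi, spec) <= hill_block(lo, spec)


class TestApplyDrug:
    def test_zero_dose_leaves_params_unchanged(self):
        p = CellModelParams()
        assert apply_drug(p, dofetilide_spec(), 0.0) == p

    def test_successive_doses_compose_multiplicatively(self):
        p = CellModelParams()
        spec = dofetilide_spec()
        once = apply_drug(apply_drug(p, spec, 1.0), spec, 2.0)
        expected = p.gKr_scale * hill_block(1.0, spec) * hill_block(2.0, spec)
        assert once.gKr_scale == pytest.approx(expected)

    def test_dose_ramp_strictly_decreases_gkr(self):
        p = CellModelParams()
        spec = dofetilide_spec()
        scales = [apply_drug(p, spec, d).gKr_scale for d in (0.5, 1, 2, 3, 4, 5, 6)]
        assert np.all(np.diff(scales) < 0)

    def test_unknown_target_is_rejected(self):
        with pytest.raises(InvalidArgumentError):
            apply_drug(CellModelParams(), DrugSpec(target="INa"), 1.0)
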