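"""Pseudo-ECG forward model, normalisation, biomarkers and the discrepancy."""

import numpy as np
import pytest

from cardiotwin.ecg import (
    DiscrepancyConfig,
    ECGRecording,
    discrepancy,
    electrode_weights,
    extract_biomarkers,
    normalise_r_progression,
    pseudo_ecg,
    qtc_fridericia,
)
from cardiotwin.errors import (
    DegenerateSignalError,
    InvalidArgumentError,
    SingularKernelError,
)
from cardiotwin.geometry import ElectrodeSet, generate_slab, place_electrodes
from cardiotwin.re_model import VmSolution


def _recording(data, rr=1.0):
    return ECGRecording(np.asarray(data, dtype=float), rate=1000.0, rr=rr)


class TestPseudoEcg:
    def test_uniform_potential_produces_zero_leads(self, small_slab, slab_electrodes):
        vm = VmSolution(np.full((small_slab.n_nodes, 51), -20.0), duration=50.0)
        ecg = pseudo_ecg(vm, small_slab, slab_electrodes)
        assert np.allclose(ecg.data, 0.0, atol=1e-12)

    def test_mirror_symmetric_electrodes_see_a_planar_wave_identically(self):
        mesh = generate_slab(8, 5, 3, 1.0)
        centre_y = mesh.nodes[:, 1].mean()
        e1 = np.array([20.0, centre_y + 7.0, 1.0])
        e2 = np.array([20.0, centre_y - 7.0, 1.0])
        es = ElectrodeSet({"A": e1, "B": e2, **{
            k: v for k, v in place_electrodes(mesh, 4.0).positions.items()
        }})
        # planar wave: potential depends on x only
        t = np.arange(0, 40.0)
        u = np.empty((mesh.n_nodes, t.size))
        for i, x in enumerate(mesh.nodes[:, 0]):
            u[i] = -85.0 + 105.0 / (1 + np.exp(-(t - 5 - x / 0.5)))
        w = electrode_weights(mesh, es)
        phi_a = w["A"] @ u
        phi_b = w["B"] @ u
        assert np.allclose(phi_a, phi_b, atol=1e-9 * np.abs(phi_a).max())

    def test_matches_brute_force_dipole_sum_on_a_small_slab(self, rng):
        mesh = generate_slab(6, 6, 4, 1.0)  # 125 hexahedra
        es = place_electrodes(mesh, 3.0)
        u = rng.uniform(-90, 40, size=(mesh.n_nodes, 3))
        vm = VmSolution(u, duration=2.0)
        ecg = pseudo_ecg(vm, mesh, es)
        # naive double loop over elements and frames
        el = mesh.elements
        x = mesh.nodes
        name = "V3"
        pos = es.positions[name]
        phi = np.zeros(3)
        for elem in el:
            pts = x[elem]
            cent = pts.mean(axis=0)
            h = pts.max(axis=0) - pts.min(axis=0)
            vol = np.prod(h)
            r = pos - cent
            ginv = r / np.linalg.norm(r) ** 3
            for frame in range(3):
                vals = u[elem, frame]
                grad = np.array([
                    (vals[[1, 2, 5, 6]].mean() - vals[[0, 3, 4, 7]].mean()) / h[0],
                    (vals[[2, 3, 6, 7]].mean() - vals[[0, 1, 4, 5]].mean()) / h[1],
                    (vals[[4, 5, 6, 7]].mean() - vals[[0, 1, 2, 3]].mean()) / h[2],
                ])
                phi[frame] += -vol * grad @ ginv
        w = electrode_weights(mesh, es)
        assert np.allclose(w[name] @ u, phi, rtol=1e-10, atol=1e-12)

    def test_scaling_the_potential_scales_the_ecg_linearly(
        self, small_slab, slab_electrodes, rng
    ):
        u = rng.uniform(-90, 40, size=(small_slab.n_nodes, 4))
        e1 = pseudo_ecg(VmSolution(u, duration=3.0), small_slab, slab_electrodes)
        e3 = pseudo_ecg(VmSolution(3 * u, duration=3.0), small_slab, slab_electrodes)
        assert np.allclose(e3.data, 3 * e1.data, rtol=1e-12)

    def test_electrode_inside_the_mesh_is_rejected(self, small_slab):
        es = ElectrodeSet({"bad": small_slab.nodes.mean(axis=0), **{
            k: v for k, v in place_electrodes(small_slab, 3.0).positions.items()
        }})
        with pytest.raises(SingularKernelError):
            electrode_weights(small_slab, es)


class TestNormalisation:
    def test_identity_when_reference_equals_signal(self, rng):
        data = rng.normal(size=(8, 200))
        ecg = _recording(data)
        out = normalise_r_progression(ecg, _recording(data.copy()))
        assert np.allclose(out.data, data)

    def test_recovers_reference_amplitude_from_scaled_signal(self, rng):
        data = rng.normal(size=(8, 200))
        ref = _recording(data)
        out = normalise_r_progression(_recording(3 * data), ref)
        assert np.abs(out.data[:, :121]).max() == pytest.approx(
            np.abs(data[:, :121]).max()
        )

    def test_single_factor_preserves_inter_lead_ratios(self, rng):
        data = rng.normal(size=(8, 200))
        sim = _recording(2.7 * data)
        out = normalise_r_progression(sim, _recording(data))
        ratio = out.data / sim.data
        assert np.allclose(ratio, ratio.flat[0], rtol=1e-12)

    def test_flat_simulation_is_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            normalise_r_progression(
                _recording(np.zeros((8, 200))), _recording(np.ones((8, 200)))
            )


class TestQtcFridericia:
    @pytest.mark.parametrize(
        "qt,rr,expected", [(400, 1.0, 400.0), (400, 0.512, 500.0), (400, 8.0, 200.0)]
    )
    def test_cube_root_correction(self, qt, rr, expected):
        assert qtc_fridericia(qt, rr) == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive_rr(self):
        with pytest.raises(InvalidArgumentError):
            qtc_fridericia(400, 0.0)


def _gaussian_t_wave_recording(c=300.0, s=20.0, amp=0.4, n=500):
    t = np.arange(n, dtype=float)
    qrs = 1.0 * np.exp(-((t - 30) ** 2) / (2 * 4.0**2))
    tw = amp * np.exp(-((t - c) ** 2) / (2 * s**2))
    lead = qrs + tw
    return _recording(np.tile(lead, (8, 1)))


class TestBiomarkers:
    def test_gaussian_t_wave_tangent_end_is_analytic(self):
        # max downslope of a Gaussian at c + s; tangent hits zero at c + 2s
        ecg = _gaussian_t_wave_recording(c=300.0, s=20.0)
        bm = extract_biomarkers(ecg)
        assert bm.qt == pytest.approx(340.0, abs=2.0)
        assert bm.tpe == pytest.approx(40.0, abs=2.0)

    def test_inverting_the_trace_flips_polarity_only(self):
        ecg = _gaussian_t_wave_recording()
        flipped = _recording(-ecg.data)
        a = extract_biomarkers(ecg)
        b = extract_biomarkers(flipped)
        assert np.all(a.t_polarity == 1.0) and np.all(b.t_polarity == -1.0)
        assert b.qt == pytest.approx(a.qt, abs=1e-9)
        assert b.tpe == pytest.approx(a.tpe, abs=1e-9)
        assert b.t_amplitude == pytest.approx(a.t_amplitude, abs=1e-12)

    def test_tpeak_dispersion_between_v3_and_v5(self):
        base = _gaussian_t_wave_recording().data
        data = base.copy()
        t = np.arange(base.shape[1], dtype=float)
        data[4] = np.exp(-((t - 30) ** 2) / 32.0) + 0.4 * np.exp(-((t - 300) ** 2) / 800.0)
        data[6] = np.exp(-((t - 30) ** 2) / 32.0) + 0.4 * np.exp(-((t - 310) ** 2) / 800.0)
        bm = extract_biomarkers(_recording(data))
        assert bm.tpeak_dispersion_v3_v5 == pytest.approx(10.0, abs=1.0)

    def test_flat_post_qrs_signal_has_no_t_wave(self):
        t = np.arange(500, dtype=float)
        lead = np.exp(-((t - 30) ** 2) / 32.0)
        with pytest.raises(DegenerateSignalError):
            extract_biomarkers(_recording(np.tile(lead, (8, 1))))


class TestDiscrepancy:
    def test_perfect_match_scores_zero(self, rng):
        data = rng.normal(size=(8, 300))
        ecg = _recording(data)
        assert discrepancy(ecg, _recording(data.copy())) == pytest.approx(0.0)

    def test_sign_flipped_signal_evaluates_by_hand(self, rng):
        data = rng.normal(size=(8, 300))
        data /= np.abs(data).max()
        target = _recording(data)
        sim = _recording(-data)
        cfg = DiscrepancyConfig(w_p=100.0, w_r=2.0)
        rmse = np.sqrt(np.mean((2 * data) ** 2, axis=1))
        expected = np.mean(100.0 * (1 - (-1.0)) ** 2 + 2.0 * rmse / np.abs(data).max())
        assert discrepancy(sim, target, cfg) == pytest.approx(expected, rel=1e-9)

    def test_pcc_term_is_linear_in_its_weight(self, rng):
        a = rng.normal(size=(8, 300))
        b = rng.normal(size=(8, 300))
        sim, target = _recording(a), _recording(b)
        e1 = discrepancy(sim, target, DiscrepancyConfig(w_p=100, w_r=2))
        e2 = discrepancy(sim, target, DiscrepancyConfig(w_p=200, w_r=2))
        e_p = discrepancy(sim, target, DiscrepancyConfig(w_p=100, w_r=0))
        assert e2 - e1 == pytest.approx(e_p, rel=1e-9)

    def test_invariant_under_joint_lead_permutation(self, rng):
        a = rng.normal(size=(8, 300))
        b = rng.normal(size=(8, 300))
        perm = rng.permutation(8)
        e1 = discrepancy(_recording(a), _recording(b))
        e2 = discrepancy(_recording(a[perm]), _recording(b[perm]))
        assert e2 == pytest.approx(e1, rel=1e-12)

    def test_nonnegative_and_zero_only_at_exact_match(self, rng):
        a = rng.normal(size=(8, 100))
        b = a.copy()
        b[0, 0] += 0.5
        assert discrepancy(_recording(b), _recording(a)) > 0

    def test_zero_variance_lead_warns_and_scores_pcc_zero(self, rng):
        a = rng.normal(size=(8, 100))
        sim = a.copy()
        sim[2] = 0.0
        with pytest.warns(UserWarning, match="zero-variance"):
            e = discrepancy(_recording(sim), _recording(a))
        assert np.isfinite(e)
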