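"""APD field, reaction-solution assembly and the pseudo-diffusion smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiotwin.eikonal import ActivationMap, ConductionSpeeds, RootNodes, solve_activation
from cardiotwin.geometry import generate_slab
from cardiotwin.re_model import (
    APDFieldParams,
    SmoothingConfig,
    adjacency_weights,
    apd_field,
    assemble_vm,
    run_pseudo_diffusion_re,
    smooth,
    smoothing_matrix,
)


class TestApdField:
    def test_pure_ab_gradient_is_an_affine_map(self, small_slab):
        p = APDFieldParams(g_ab=1.0, apd_min=200, apd_max=300)
        apd = apd_field(small_slab, p)
        assert apd[np.isclose(small_slab.ab, 0.0)].min() == 200
        assert apd[np.isclose(small_slab.ab, 1.0)].max() == 300
        mid = np.isclose(small_slab.ab, 0.5, atol=0.11)
        assert np.all(np.abs(apd[mid] - 250) <= 15)

    def test_subject2_best_match_field_orientation(self, biventricle):
        p = APDFieldParams(g_ab=1.0, g_pa=-1.0, apd_min=216, apd_max=294)
        apd = apd_field(biventricle, p)
        assert apd.min() == 216 and apd.max() == 294
        basal = apd[biventricle.ab > 0.8].mean()
        apical = apd[biventricle.ab < 0.2].mean()
        posterior = apd[biventricle.pa < 0.2].mean()
        anterior = apd[biventricle.pa > 0.8].mean()
        assert basal > apical and posterior > anterior

    def test_negating_all_weights_complements_the_field(self, biventricle):
        p = APDFieldParams(g_ab=0.6, g_tm=-0.3, g_pa=0.2, g_tv=0.1,
                           apd_min=200, apd_max=300)
        q = APDFieldParams(g_ab=-0.6, g_tm=0.3, g_pa=-0.2, g_tv=-0.1,
                           apd_min=200, apd_max=300)
        a, b = apd_field(biventricle, p), apd_field(biventricle, q)
        assert np.all(np.abs((a + b) - (200 + 300)) <= 1)  # integer rounding

    def test_degenerate_field_warns_and_uses_mid_range(self, small_slab):
        p = APDFieldParams(apd_min=200, apd_max=300)
        with pytest.warns(UserWarning, match="degenerate"):
            apd = apd_field(small_slab, p)
        assert np.all(apd == 250)


class TestAssembleVm:
    def test_nodes_rest_before_activation(self, small_slab, small_table):
        act = solve_activation(small_slab, ConductionSpeeds(), RootNodes([0], [0.0]))
        apd = np.full(small_slab.n_nodes, 230)
        vm = assemble_vm(small_slab, act, apd, small_table, 400.0)
        late = np.argmax(act.times)
        assert vm.data[late, 0] == pytest.approx(small_table.u_rest)

    def test_integer_shift_reproduces_table_samples(self, small_slab, small_table):
        act = ActivationMap(np.full(small_slab.n_nodes, 10.0))
        apd = np.full(small_slab.n_nodes, 230)
        vm = assemble_vm(small_slab, act, apd, small_table, 400.0)
        wf = small_table.lookup(230)[1]
        for k in (0, 5, 50, 200):
            assert vm.data[3, 10 + k] == pytest.approx(wf[k], abs=1e-9)

    def test_fractional_shifts_are_time_shifted_copies(self, small_slab, small_table):
        apd = np.full(small_slab.n_nodes, 240)
        t_a = np.zeros(small_slab.n_nodes)
        t_a[1] = 7.0
        vm = assemble_vm(small_slab, ActivationMap(t_a), apd, small_table, 400.0)
        # node 1 is node 0 delayed by exactly 7 samples
        assert np.allclose(vm.data[1, 7:350], vm.data[0, 0:343], atol=1e-9)

    def test_apd_outside_table_range_raises_key_error(self, small_slab, small_table):
        act = ActivationMap(np.zeros(small_slab.n_nodes))
        apd = np.full(small_slab.n_nodes, 230)
        apd[3] = 500
        with pytest.raises(KeyError, match="500"):
            assemble_vm(small_slab, act, apd, small_table, 900.0)


class TestAdjacencyWeights:
    def test_fibre_aligned_unit_edge_has_unit_weight(self):
        mesh = generate_slab(3, 2, 2, 1.0, 0.0)
        sp = ConductionSpeeds(Vf=65, Vs=48, Vn=48)
        k_m = adjacency_weights(mesh, sp)
        e = mesh.edges
        p = mesh.edge_vectors
        along_f = (np.abs(p[:, 0]) > 0.99) & (np.isclose(np.linalg.norm(p, axis=1), 1.0))
        assert np.allclose(k_m[along_f], 1.0, atol=1e-9)

    def test_normal_aligned_edge_weight_is_speed_ratio(self):
        mesh = generate_slab(2, 2, 3, 1.0, 0.0)
        sp = ConductionSpeeds(Vf=65, Vs=48, Vn=48)
        k_m = adjacency_weights(mesh, sp)
        p = mesh.edge_vectors
        along_n = (np.abs(p[:, 2]) > 0.99) & (np.isclose(np.linalg.norm(p, axis=1), 1.0))
        assert np.allclose(k_m[along_n], 48.0 / 65.0, atol=1e-9)

    @pytest.mark.parametrize("fixture", ["slab", "biventricle"])
    def test_weight_bounds_hold_on_every_edge(self, fixture, biventricle):
        mesh = generate_slab(5, 4, 3, 0.8, 35.0) if fixture == "slab" else biventricle
        sp = ConductionSpeeds(Vf=65, Vs=48, Vn=40)
        k_m = adjacency_weights(mesh, sp)
        lengths = mesh.edge_lengths
        lo = (40.0 / 65.0) / lengths
        hi = 1.0 / lengths
        assert np.all(k_m >= lo - 1e-9)
        assert np.all(k_m <= hi + 1e-9)


class TestSmoothing:
    def test_constant_field_is_a_fixed_point(self, small_slab):
        S = smoothing_matrix(small_slab, ConductionSpeeds(), 10.0)
        u = np.full(small_slab.n_nodes, -55.5)
        assert np.allclose(smooth(u, S), u, atol=1e-12)

    def test_single_neighbour_hand_computation(self):
        # Eq-by-hand: two nodes, k_m = k_i = 1 -> S(u)_0 = (u_1 + u_0) / 2
        mesh = generate_slab(2, 2, 2, 1.0)
        sp = ConductionSpeeds(Vf=50, Vs=50, Vn=50, Vd=50, Ve=50)
        k_m = adjacency_weights(mesh, sp)
        e = mesh.edges
        # node 0's neighbours within the single hex: weights 1/|p|
        u = np.zeros(mesh.n_nodes)
        u[1] = 1.0
        S = smoothing_matrix(mesh, sp, 10.0)
        ks = {tuple(sorted(pair)): k for pair, k in zip(e.tolist(), k_m)}
        num = sum(ks[tuple(sorted((0, m)))] * u[m] for m in range(1, 8)) + 10.0 * u[0]
        den = sum(ks[tuple(sorted((0, m)))] for m in range(1, 8)) + 10.0
        assert (S @ u)[0] == pytest.approx(num / den, rel=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_smoothing_is_a_convex_combination(self, seed):
        mesh = generate_slab(4, 3, 3, 1.0, 10.0)
        S = smoothing_matrix(mesh, ConductionSpeeds(), 10.0)
        u = np.random.default_rng(seed).uniform(-90, 40, mesh.n_nodes)
        su = smooth(u, S)
        assert su.min() >= u.min() - 1e-9
        assert su.max() <= u.max() + 1e-9


class TestRunPseudoDiffusionRe:
    @pytest.fixture()
    def setup(self, small_slab, small_table):
        sp = ConductionSpeeds()
        act = solve_activation(small_slab, sp, RootNodes([0], [0.0]))
        params = APDFieldParams(g_tm=1.0, apd_min=205, apd_max=255)
        return small_slab, act, params, small_table, sp

    def test_disabled_window_reproduces_the_reaction_solution(self, setup):
        mesh, act, params, table, sp = setup
        cfg = SmoothingConfig(window=None)
        vm = run_pseudo_diffusion_re(mesh, act, params, table, sp, cfg, 400.0)
        ref = assemble_vm(mesh, act, apd_field(mesh, params), table, 400.0)
        assert np.array_equal(vm.data, ref.data)

    def test_huge_self_weight_approaches_no_smoothing(self, setup):
        mesh, act, params, table, sp = setup
        vm_ref = run_pseudo_diffusion_re(
            mesh, act, params, table, sp, SmoothingConfig(window=None), 400.0
        )
        vm = run_pseudo_diffusion_re(
            mesh, act, params, table, sp, SmoothingConfig(k_i=1e6), 400.0
        )
        assert np.max(np.abs(vm.data - vm_ref.data)) < 0.1

    def test_smoothing_shrinks_repolarisation_jumps_across_an_apd_step(
        self, small_table
    ):
        from dataclasses import replace

        base = generate_slab(9, 4, 4, 1.0)
        # binary transmural coordinate turns the linear field into a hard step
        mesh = replace(base, tm=(base.nodes[:, 2] > 1.5).astype(float), _edges=None)
        sp = ConductionSpeeds()
        act = ActivationMap(np.zeros(mesh.n_nodes))
        params = APDFieldParams(g_tm=1.0, apd_min=205, apd_max=255)
        rough = run_pseudo_diffusion_re(
            mesh, act, params, small_table, sp, SmoothingConfig(window=None), 400.0
        )
        smoothed = run_pseudo_diffusion_re(
            mesh, act, params, small_table, sp, SmoothingConfig(), 400.0
        )
        e = mesh.edges

        def max_jump(vm):
            rt = vm.repolarisation_times()
            return np.abs(rt[e[:, 0]] - rt[e[:, 1]]).max()

        assert max_jump(smoothed) < max_jump(rough)

    def test_smoothing_effect_shrinks_as_repolarisation_becomes_uniform(
        self, small_slab, small_table, slab_electrodes
    ):
        """With uniform APD the T wave stems from activation staggering alone;
        compressing the activation map towards simultaneity must shrink the
        smoothing-induced T-wave change towards zero."""
        from cardiotwin.ecg import pseudo_ecg

        sp = ConductionSpeeds()
        act_full = solve_activation(small_slab, sp, RootNodes([0], [0.0]))
        deltas = []
        with pytest.warns(UserWarning, match="degenerate"):
            params = APDFieldParams(apd_min=205, apd_max=255)
            for scale in (1.0, 0.05):
                act = ActivationMap(act_full.times * scale)
                vm_s = run_pseudo_diffusion_re(
                    small_slab, act, params, small_table, sp,
                    SmoothingConfig(), 400.0,
                )
                vm_r = run_pseudo_diffusion_re(
                    small_slab, act, params, small_table, sp,
                    SmoothingConfig(window=None), 400.0,
                )
                ecg_s = pseudo_ecg(vm_s, small_slab, slab_electrodes)
                ecg_r = pseudo_ecg(vm_r, small_slab, slab_electrodes)
                t_window = ecg_r.times > 100
                deltas.append(
                    np.abs(ecg_s.data[:, t_window] - ecg_r.data[:, t_window]).max()
                )
        assert deltas[1] < 0.1 * deltas[0]
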