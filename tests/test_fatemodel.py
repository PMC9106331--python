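"""Fate-network model: signal fields, fixed points, determinism,
boundedness, hysteresis, phase diagram, and the condition panel."""

import numpy as np
import pytest

from pgcolony.fatemodel import (
    FATES,
    Condition,
    ConditionError,
    FateField,
    ModelParams,
    SignalParams,
    condition_panel,
    dominant_ring_order,
    edge_band_summary,
    phase_diagram,
    signal_input,
    simulate_fates,
)


class TestSignalInput:
    sp = SignalParams()

    def test_nodal_ko_without_activin_has_no_nodal(self):
        cond = Condition("KO", endogenous_nodal=False)
        _, N = signal_input(cond, self.sp)
        d = np.linspace(0, 350, 50)
        for t in (0.0, 12.0, 30.0, 42.0):
            assert np.all(N(d, t) == 0.0)

    def test_receptor_inhibitions_zero_the_fields(self):
        d = np.linspace(0, 350, 50)
        cond = Condition("TGFBRi@0", inhibitions=(("Nodal/Activin", 0.0),))
        _, N = signal_input(cond, self.sp)
        for t in (0.0, 20.0, 40.0):
            assert np.all(N(d, t) == 0.0)
        cond = Condition("BMPRi@24", inhibitions=(("BMP", 24.0),))
        B, _ = signal_input(cond, self.sp)
        assert np.all(B(d, 23.9) > 0)
        assert np.all(B(d, 24.0) == 0.0)

    def test_wavefront_position(self):
        # at time t the endogenous front sits v*(t - t0) from the edge:
        # N is high behind it and low well beyond it
        cond = Condition("WT")
        _, N = signal_input(cond, self.sp)
        t = self.sp.t0 + 10.0
        front = self.sp.v * 10.0
        d = np.array([front - 30.0, front, front + 30.0])
        vals = N(d, t)
        assert vals[0] > 0.85 * self.sp.N_amp
        assert vals[1] == pytest.approx(0.5 * self.sp.N_amp, rel=0.05)
        assert vals[2] < 0.15 * self.sp.N_amp

    def test_bmp_uniform_then_gradient(self):
        cond = Condition("WT")
        B, _ = signal_input(cond, self.sp)
        d = np.array([0.0, 100.0, 300.0])
        early = B(d, 0.5 * self.sp.bmp_uniform_duration)
        assert np.ptp(early) == 0.0
        late = B(d, self.sp.bmp_uniform_duration + 1.0)
        assert late[0] > late[1] > late[2]
        assert late[1] == pytest.approx(late[0] * np.exp(-100.0 / self.sp.lambda_B))

    def test_activin_schedule_windows(self):
        cond = Condition(
            "pulse", endogenous_nodal=False, activin_schedule=((10.0, 20.0, 100.0),)
        )
        _, N = signal_input(cond, self.sp)
        d = np.array([0.0])
        assert N(d, 9.9)[0] == 0.0
        assert N(d, 15.0)[0] > 0.0
        assert N(d, 20.0)[0] == 0.0

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ConditionError):
            Condition("bad", activin_schedule=((30.0, 20.0, 10.0),)).validate(self.sp)
        with pytest.raises(ConditionError):
            Condition("bad", inhibitions=(("WNT", 0.0),)).validate(self.sp)

    def test_dose_maps_saturate(self):
        sp = self.sp
        assert sp.bmp_amplitude(0.0) == 0.0
        assert sp.bmp_amplitude(1e6) == pytest.approx(sp.bmp_amp_max, rel=1e-3)
        assert sp.activin_amplitude(30.0) < sp.activin_amplitude(100.0)


class TestSimulateFates:
    def test_no_input_keeps_pluripotency(self):
        cond = Condition("null", bmp_dose=0.0, endogenous_nodal=False, radius=100.0)
        field = simulate_fates(cond)
        assert np.allclose(field.final[0], 1.0, atol=1e-6)
        assert np.allclose(field.final[1:], 0.0, atol=1e-6)

    def test_levels_bounded_everywhere(self):
        panel = condition_panel()
        for name in ("WT", "Activin100_0-42", "BMPRi@24", "WT_r50"):
            field = simulate_fates(panel[name])
            assert field.levels.min() >= 0.0
            assert field.levels.max() <= 1.0

    def test_bit_identical_reruns(self):
        cond = Condition("WT", radius=200.0)
        f1 = simulate_fates(cond)
        f2 = simulate_fates(cond)
        assert np.array_equal(f1.levels, f2.levels)

    def test_edge_anchored_grid_includes_edge_and_center(self):
        field = simulate_fates(Condition("WT", radius=101.0), dr=2.0)
        assert field.r_grid.max() == pytest.approx(101.0)
        assert field.r_grid.min() <= 2.0

    def test_am_commitment_is_hysteretic(self):
        # a cell driven into the amnion basin by early high BMP stays
        # committed after BMP drops below the induction threshold
        mp = ModelParams()

        def uniform_cell(b_levels, hours, state=None):
            from pgcolony.fatemodel import _integrate

            if state is None:
                state = np.zeros((5, 1))
                state[0] = 1.0
            for b, h in zip(b_levels, hours):
                drive = lambda t, b=b: (np.array([b]), np.array([0.0]))
                state, _ = _integrate(state, drive, mp, 0.0, h, 0.05)
            return state

        committed = uniform_cell([1.5, 0.45], [24.0, 24.0])
        naive = uniform_cell([0.45], [48.0])
        assert committed[1, 0] > 0.6
        assert naive[1, 0] < 0.3

    def test_dominant_label_ties_go_to_plu(self):
        field = FateField(
            Condition("x"),
            np.array([0.0, 1.0]),
            np.array([0.0]),
            np.array([[[0.5, 0.2]], [[0.5, 0.6]], [[0.1, 0.0]], [[0.0, 0.0]]]),
            radius=1.0,
        )
        dom = field.dominant()
        assert dom[0] == "Plu"  # tie with Am resolved to Plu
        assert dom[1] == "Am"


class TestEdgeBand:
    def test_uniform_field_band_mean(self):
        field = FateField(
            Condition("u", radius=100.0),
            np.linspace(0, 100, 51),
            np.array([0.0]),
            np.full((4, 1, 51), 0.25),
            radius=100.0,
        )
        band = edge_band_summary(field, 30.0)
        assert all(v == pytest.approx(0.25) for v in band.values())

    def test_full_radius_band_equals_colony_mean(self):
        rng = np.random.default_rng(0)
        r = np.linspace(0, 100, 51)
        levels = rng.random((4, 1, 51))
        field = FateField(Condition("u", radius=100.0), r, np.array([0.0]), levels, 100.0)
        band = edge_band_summary(field, 100.0)
        w = np.maximum(r, 1e-9)
        expect = (levels[2, 0] * w).sum() / w.sum()
        assert band["PGC"] == pytest.approx(expect)

    def test_invalid_band_width_rejected(self):
        field = FateField(
            Condition("u", radius=100.0),
            np.linspace(0, 100, 11),
            np.array([0.0]),
            np.zeros((4, 1, 11)),
            100.0,
        )
        with pytest.raises(ValueError):
            edge_band_summary(field, 0.0)
        with pytest.raises(ValueError):
            edge_band_summary(field, 500.0)


@pytest.fixture(scope="module")
def labels():
    B = np.array([0.0, 0.5, 1.0, 2.0])
    N = np.array([0.0, 0.5, 1.0, 2.0])
    return phase_diagram(B, N, t_max=300.0), B, N


class TestPhaseDiagram:

    def test_origin_is_pluripotent(self, labels):
        lab, _, _ = labels
        assert lab[0, 0] == "Plu"

    def test_axes_are_amnion_and_ps(self, labels):
        lab, _, _ = labels
        assert lab[-1, 0] == "Am"   # high BMP, no Nodal
        assert lab[0, -1] == "PS"   # no BMP, sustained high Nodal

    def test_pgc_occupies_intermediate_levels(self, labels):
        lab, _, _ = labels
        interior = lab[1:-1, 1:-1]
        assert (interior == "PGC").any()


class TestConditionPanel:
    def test_panel_contents(self):
        panel = condition_panel()
        assert len(panel) >= 10
        grid = [c for c in panel.values() if c.name.startswith("grid_")]
        assert len(grid) == 25
        assert "WT_r50" in panel  # 100 um diameter colony
        radii = {c.radius for c in panel.values() if c.name.startswith("WT_r")}
        assert radii == {50.0, 75.0, 100.0, 150.0, 350.0}

    def test_nodal_ko_conditions_disable_endogenous_nodal(self):
        panel = condition_panel()
        assert not panel["NodalKO"].endogenous_nodal
        assert not panel["grid_B50_A10"].endogenous_nodal


class TestRingOrderHelper:
    def test_collapses_runs_from_edge_inward(self):
        r = np.arange(0.0, 101.0, 2.0)
        levels = np.zeros((4, 1, len(r)))
        # edge (high r): Am; middle: PGC; center: Plu
        levels[1, 0, r > 70] = 0.9
        levels[2, 0, (r > 40) & (r <= 70)] = 0.9
        levels[0, 0] = 0.3
        field = FateField(Condition("x", radius=100.0), r, np.array([0.0]), levels, 100.0)
        assert dominant_ring_order(field) == ["Am", "PGC", "Plu"]
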