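import numpy as np
import pytest

import dblsim as ds
from dblsim.cell import (
    CellConfig,
    Compartment,
    NumericalDivergenceError,
    balance_leak,
    ca_reversal,
    init_state,
)
from dblsim.mechanism import ShiftState


def passive_cell(g_leak=5e-5):
    """Leak-only cell with identical compartments (no active channels)."""
    comps = tuple(Compartment(n, area=2e-5, g_leak=g_leak)
                  for n in ("soma", "prox", "dist"))
    return CellConfig(compartments=comps, axial_uS=(0.05, 0.05), channels=())


class TestCaReversal:
    def test_equal_concentrations(self):
        assert ca_reversal(2.0, 2.0) == 0.0

    def test_tenfold_ratio_closed_form(self):
        # (RT/2F) ln 10 at 308.15 K
        assert ca_reversal(0.2, 2.0) == pytest.approx(30.57, abs=0.02)

    def test_ratio_invariance(self):
        assert ca_reversal(1e-4, 2.0) == pytest.approx(ca_reversal(2e-4, 4.0))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ca_reversal(0.0, 2.0)


class TestRestingState:
    def test_rest_is_a_fixed_point(self, cell):
        """With balanced leak and an equilibrated Ca pool, 100 ms of free
        evolution moves the somatic potential by < 1e-6 mV."""
        res = ds.run(cell, t_total=100.0)
        assert np.abs(res.v - cell.v_rest).max() < 1e-6

    def test_net_current_at_rest_vanishes(self, cell):
        """After 500 ms of relaxation the membrane sits where it started, i.e.
        total membrane current density is < 1e-4 mA/cm^2 everywhere."""
        res = ds.run(cell, t_total=500.0)
        # dv/dt ~ I/C: bound the current via the residual drift rate
        drift = np.abs(np.diff(res.v[-400:, :], axis=0)).max() / 0.025  # mV/ms
        i_density = drift * 1.0 * 1e-3  # cm = 1 uF/cm^2 -> mA/cm^2
        assert i_density < 1e-4

    def test_conventional_cell_also_at_rest(self, conv_cell):
        res = ds.run(conv_cell, t_total=100.0)
        assert np.abs(res.v - conv_cell.v_rest).max() < 1e-6


class TestPassiveResponses:
    def test_rc_step_response_matches_closed_form(self):
        """Uniform current step into a leak-only cell follows
        v(t) = v_rest + IR(1 - exp(-t/RC)) to < 0.5%."""
        cfg = passive_cell()
        area = 2e-5
        g = 5e-5 * area * 1e6            # uS per compartment
        c = 1.0 * area * 1e3             # nF per compartment
        tau = c / g                       # ms
        i_per_comp = 0.01                 # nA, same everywhere -> uniform response
        res = ds.run(cfg, t_total=100.0,
                     inj={"soma": i_per_comp, "prox": i_per_comp, "dist": i_per_comp},
                     t_on=0.0, t_off=100.0)
        expect = -70.0 + (i_per_comp / g) * (1.0 - np.exp(-res.t / tau))
        err = np.abs(res.v[:, 0] - expect)[1:] / (i_per_comp / g)
        assert err.max() < 0.005

    def test_halving_dt_changes_subthreshold_trajectory_marginally(self, cell):
        """Self-convergence: a subthreshold 500-ms trajectory changes by
        < 0.1 mV RMS when dt is halved."""
        kw = dict(t_total=500.0, inj={"soma": 0.05}, t_on=50.0, t_off=450.0)
        r1 = ds.run(cell, dt=0.025, **kw)
        r2 = ds.run(cell, dt=0.0125, **kw)
        v2 = r2.v[::2, 0]
        rms = np.sqrt(np.mean((r1.v[:, 0] - v2) ** 2))
        assert rms < 0.1


class TestRunContracts:
    def test_same_inputs_bit_identical(self, cell):
        kw = dict(t_total=300.0, inj={"soma": 0.3}, t_on=50.0, t_off=250.0,
                  mechanism=ds.CELL_203030003_R)
        r1 = ds.run(cell, **kw)
        r2 = ds.run(cell, **kw)
        assert np.array_equal(r1.v, r2.v)
        assert np.array_equal(r1.shifts["ema"], r2.shifts["ema"])

    def test_mechanism_off_equals_all_B_zero(self, cell):
        """Setting every Hill amplitude B to 0 reproduces the plain
        fixed-parameter trajectory bit for bit."""
        kw = dict(t_total=400.0, inj={"soma": 0.3}, t_on=50.0, t_off=350.0)
        r_off = ds.run(cell, mechanism=None, **kw)
        r_b0 = ds.run(cell, mechanism=ds.CELL_203030003_R.switched_off(), **kw)
        assert np.array_equal(r_off.v, r_b0.v)
        assert np.all(r_b0.shifts["dE_K"] == 0.0)
        assert np.all(r_b0.shifts["sh_Na"] == 0.0)

    def test_divergence_is_reported_with_time(self):
        cfg = passive_cell(g_leak=1e-6)
        with pytest.raises(NumericalDivergenceError) as exc:
            ds.run(cfg, t_total=2000.0, inj={"soma": 10.0}, t_on=0.0, t_off=2000.0)
        assert exc.value.t_ms > 0

    def test_bad_dt_rejected(self, cell):
        with pytest.raises(ValueError):
            ds.run(cell, t_total=10.0, dt=0.5)

    def test_shift_course_is_returned(self, cell):
        res = ds.run(cell, t_total=200.0, inj={"soma": 0.3}, t_on=20.0, t_off=180.0,
                     mechanism=ds.CELL_203030003_R)
        assert res.shifts["ema"].max() > 10.0
        assert res.shifts["dE_K"].max() > 10.0
        assert res.shifts["dE_Na"].min() < -2.0


class TestStep:
    def test_resting_state_is_unmoved(self, cell):
        s0 = init_state(cell)
        s1 = ds.step(s0, cell, dt=0.025, shift=ShiftState())
        assert np.abs(s1.v - s0.v).max() < 1e-9

    def test_reversal_offsets_are_honored(self, cell):
        """A large K+ reversal offset makes the step depolarizing at rest."""
        s0 = init_state(cell)
        s1 = ds.step(s0, cell, dt=0.1, shift=ShiftState(dE_K=60.0))
        assert s1.v[0] > s0.v[0]


class TestConfigValidation:
    def test_rest_range_enforced(self):
        with pytest.raises(ValueError):
            CellConfig(
                compartments=tuple(Compartment(n, area=1e-5) for n in ("a", "b", "c")),
                axial_uS=(0.05, 0.05), channels=(), v_rest=-40.0)

    def test_unknown_density_rejected(self):
        with pytest.raises(ValueError, match="unknown channel"):
            CellConfig(
                compartments=tuple(Compartment(n, area=1e-5) for n in ("a", "b", "c")),
                axial_uS=(0.05, 0.05), channels=(), densities={"Na": (1, 1, 1)})

    def test_balance_leak_sets_equilibrium(self):
        cfg = ds.default_cell(balanced=False)
        balanced = balance_leak(cfg)
        res = ds.run(balanced, t_total=50.0)
        assert np.abs(res.v - cfg.v_rest).max() < 1e-6
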