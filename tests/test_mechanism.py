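import numpy as np
import pytest
from hypothesis import given, strategies as st

import dblsim as ds
from dblsim.mechanism import (
    CELL_170518_4E,
    CELL_203030003_R,
    DBLParams,
    EMAConfig,
    EMAState,
    IonShiftParams,
    compute_shifts,
    ema_alpha,
    ema_update,
    fvrun,
    shift_report,
)


def ema_bruteforce(xs, F=2.0, t_step=1000):
    """Independent oracle: expand the recursion into an explicit weighted sum.

    Sample x[n-i] (0-based from the end) carries weight
    a_{n-i} * prod_{j>n-i} (1 - a_j) with a_k = F/(min(k, t_step)+1), which for
    n > t_step reduces to the geometric weights a(1-a)^i of a fixed-window EMA.
    """
    n = len(xs)
    alphas = [F / (min(k, t_step) + 1.0) for k in range(1, n + 1)]
    total = 0.0
    for i, x in enumerate(xs):  # i = 0 .. n-1, sample k = i+1
        w = alphas[i]
        for j in range(i + 1, n):
            w *= 1.0 - alphas[j]
        total += w * x
    return total


class TestEMA:
    cfg = EMAConfig(t_step=50, v_rest=-70.0)

    def _run(self, vs):
        s = EMAState()
        for v in vs:
            s = ema_update(s, v, self.cfg)
        return s

    def test_first_sample_at_rest_gives_zero(self):
        s = ema_update(EMAState(), -70.0, self.cfg)
        assert s.ema == 0.0 and s.cnt == 1

    def test_first_sample_equals_depolarization(self):
        s = ema_update(EMAState(), -60.0, self.cfg)
        assert s.ema == pytest.approx(10.0)

    def test_constant_input_converges_to_it(self):
        s = self._run([-45.0] * 2000)
        assert s.ema == pytest.approx(25.0, rel=1e-6)

    def test_counter_caps_at_window_length(self):
        s = self._run([-60.0] * 200)
        assert s.cnt == self.cfg.t_step

    def test_recursion_matches_bruteforce_expansion(self):
        """Recursive EMA equals the explicit weighted sum over the whole input
        history, including the growing-window phase, to < 1e-10."""
        rng = np.random.default_rng(7)
        xs = rng.uniform(0.0, 60.0, 180)
        s = self._run(-70.0 + xs)
        assert s.ema == pytest.approx(ema_bruteforce(xs, t_step=self.cfg.t_step), abs=1e-10)

    def test_steady_state_weights_are_geometric(self):
        """For n > t_step the weight of the sample i steps back is a(1-a)^i."""
        t_step = 20
        a = ema_alpha(t_step)  # F/(t_step+1)
        n = 400
        for i in (0, 1, 5, 19):
            xs = np.zeros(n)
            xs[n - 1 - i] = 1.0
            got = ema_bruteforce(xs, t_step=t_step)
            assert got == pytest.approx(a * (1 - a) ** i, rel=1e-12)

    def test_clamped_at_zero_for_hyperpolarization(self):
        s = self._run([-90.0] * 100)
        assert s.ema == 0.0

    def test_effective_window_rescales_with_dt(self):
        cfg = EMAConfig(t_step=1000, reference_dt=0.025)
        assert cfg.effective_t_step(0.025) == 1000
        assert cfg.effective_t_step(0.0125) == 2000
        assert cfg.effective_t_step(0.1) == 250


class TestHillDriver:
    na1 = CELL_203030003_R.Na  # B=2.60, C=60
    k1 = CELL_203030003_R.K    # B=2.11, C=48

    def test_zero_at_zero(self):
        assert fvrun(0.0, self.na1) == 0.0

    def test_half_saturation_at_C(self):
        assert fvrun(60.0, self.na1) == pytest.approx(78.0)

    def test_hand_arithmetic_point(self):
        # 2.11 * 48 * 48 / 96
        assert fvrun(48.0, self.k1) == pytest.approx(50.64)

    def test_asymptote_is_BC(self):
        assert fvrun(1e12, self.na1) == pytest.approx(156.0, rel=1e-6)

    @given(e1=st.floats(0, 500), e2=st.floats(0, 500))
    def test_monotone_and_bounded(self, e1, e2):
        lo, hi = sorted([e1, e2])
        p = self.na1
        assert fvrun(lo, p) <= fvrun(hi, p) <= p.B * p.C

    @given(e=st.floats(0, 400))
    def test_concavity(self, e):
        p = self.k1
        mid = fvrun(e / 2 + 25.0, p)
        assert mid >= 0.5 * (fvrun(e, p) + fvrun(50.0, p)) - 1e-9

    def test_negative_ema_rejected(self):
        with pytest.raises(ValueError):
            fvrun(-1.0, self.na1)


class TestComputeShifts:
    def test_zero_ema_gives_zero_shifts(self):
        s = compute_shifts(0.0, CELL_203030003_R)
        assert s == ds.ShiftState()

    def test_all_B_zero_gives_zero_shifts_for_any_ema(self):
        off = CELL_203030003_R.switched_off()
        assert off.disabled
        for ema in (0.0, 10.0, 300.0):
            assert compute_shifts(ema, off) == ds.ShiftState()

    def test_hand_computed_K_reversal_shift(self):
        # 1.06 * (2.11*48*45/93)
        s = compute_shifts(45.0, CELL_203030003_R)
        assert s.dE_K == pytest.approx(1.06 * 2.11 * 48 * 45 / 93, rel=1e-12)
        assert s.dE_K == pytest.approx(51.95, abs=0.05)

    def test_sign_convention_reduces_gradient_magnitudes(self):
        s = compute_shifts(40.0, CELL_203030003_R)
        assert s.dE_Na < 0 and s.dE_K > 0
        assert s.sh_Na > 0 and s.sh_K > 0 and s.sh_Ca > 0

    def test_literal_sign_variant_lowers_EK(self):
        import dataclasses
        lit = dataclasses.replace(CELL_203030003_R, literal_eq1_signs=True)
        assert compute_shifts(40.0, lit).dE_K < 0

    @given(ema=st.floats(0, 1000))
    def test_kinetic_shifts_bounded_by_saturation(self, ema):
        for p in (CELL_203030003_R, CELL_170518_4E):
            s = compute_shifts(ema, p)
            assert s.sh_Na <= p.Na.alpha_sh * p.Na.B * p.Na.C + 1e-9
            assert s.sh_K <= p.K.alpha_sh * p.K.B * p.K.C + 1e-9
            assert s.sh_Ca <= p.Ca.alpha_sh * p.Ca.B * p.Ca.C + 1e-9


def test_table1_parameter_sets():
    """The two built-in fitted sets carry the published coefficients."""
    c1, c2 = CELL_203030003_R, CELL_170518_4E
    assert (c1.Na.alpha_E, c1.Na.alpha_sh, c1.Na.B, c1.Na.C) == (0.25, 0.13, 2.60, 60.0)
    assert (c1.K.alpha_E, c1.K.alpha_sh, c1.K.B, c1.K.C) == (1.06, 0.15, 2.11, 48.0)
    assert (c1.Ca.alpha_sh, c1.Ca.B, c1.Ca.C) == (0.15, 2.0, 50.0)
    assert (c2.Na.alpha_E, c2.Na.alpha_sh, c2.Na.B, c2.Na.C) == (0.30, 0.17, 2.50, 68.0)
    assert (c2.K.alpha_E, c2.K.alpha_sh, c2.K.B, c2.K.C) == (1.12, 0.12, 2.13, 68.0)
    assert (c2.Ca.alpha_sh, c2.Ca.B, c2.Ca.C) == (0.10, 2.0, 70.0)


def test_shift_report_zero_when_mechanism_off(sweep_fixed):
    rep = shift_report(sweep_fixed)
    cols = [c for c in rep.columns if c != "amplitude_nA"]
    assert (rep[cols].to_numpy() == 0).all()


def test_shift_report_magnitudes_monotone_with_current(sweep_cell1):
    rep = shift_report(sweep_cell1)
    for col in ("max_dE_K", "max_sh_Na", "max_sh_K"):
        vals = rep[col].to_numpy()
        assert np.all(np.diff(vals) >= -0.5), col  # jitter between firing limit cycles

    # predicted Na+ reversal shifts stay within the 20 mV scale of the fits
    assert np.abs(rep["max_dE_Na"]).max() <= 20.0


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        IonShiftParams(alpha_sh=0.1, B=-1.0, C=50.0)
    with pytest.raises(ValueError):
        IonShiftParams(alpha_sh=0.1, B=1.0, C=0.0)
    with pytest.raises(ValueError):
        EMAConfig(F=0.0)
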