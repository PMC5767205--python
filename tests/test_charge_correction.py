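"""Finite-size correction terms: hand-arithmetic oracles and physics rules."""

import math

import numpy as np
import pytest

from fepnet.charge_correction import (
    CorrectionInput,
    apply_correction,
    dsc_term,
    emp_term,
    evaluate_terms,
    net_usv_term,
    rip_term,
    solvation_radius,
    transformation_correction,
)
from fepnet.units import COULOMB_CONSTANT


def make_input(env="complex", **kw):
    base = dict(
        environment=env,
        I_P=-800.0 if env == "complex" else 0.0,
        I_L=120.0,
        I_L_hom=60.0,
        Q_P=-10.0 if env == "complex" else 0.0,
        Q_L=-1.0,
        L=7.9,
        N_s=14000,
    )
    base.update(kw)
    return CorrectionInput(**base)


class TestTerms:
    def test_net_usv_hand_arithmetic(self):
        # 2.837 * (138.935458/2) * ((QP+QL)^2 - QP^2) / (eps_s L)
        # = 2.837 * 69.468 * 21 / (97 * 7.9) = +5.401 kJ/mol
        inp = make_input()
        expected = 2.837 * (COULOMB_CONSTANT / 2) * 21.0 / (97.0 * 7.9)
        value = net_usv_term(inp)
        assert value == pytest.approx(expected, rel=1e-12)
        assert value == pytest.approx(5.401, abs=5e-4)

    def test_dsc_hand_arithmetic(self):
        # -gamma_s QL Ns/(6 eps0 L^3) with 1/eps0 = 4 pi * 138.935458
        inp = make_input()
        expected = 0.00764 * 14000 * 4 * math.pi * COULOMB_CONSTANT / (6 * 7.9**3)
        value = dsc_term(inp)
        assert value == pytest.approx(expected, rel=1e-12)
        assert value == pytest.approx(63.13, abs=5e-3)

    def test_rip_free_environment_hand_arithmetic(self):
        inp = make_input("free", I_L=100.0, L=3.9, N_s=1800)
        assert rip_term(inp) == pytest.approx(100.0 * (-1.0) / 3.9**3, rel=1e-12)
        assert rip_term(inp) == pytest.approx(-1.686, abs=5e-4)

    def test_rip_zero_for_zero_rips(self):
        assert rip_term(make_input(I_P=0.0, I_L=0.0)) == 0.0

    def test_all_terms_vanish_for_neutral_ligand(self):
        terms = evaluate_terms(make_input(), q_l=0.0)
        assert terms.total == 0.0
        assert (terms.g_net_usv, terms.g_rip, terms.g_emp, terms.g_dsc) == (0, 0, 0, 0)

    def test_solvation_radius_algebraic_inversion(self):
        inp = make_input()
        denom = (COULOMB_CONSTANT / 2) * (4 * math.pi / 3) * (1 - 1 / 97.0) * 1.0
        inp = make_input(I_L=denom * 0.25, I_L_hom=0.0)
        assert solvation_radius(inp) == pytest.approx(0.5, rel=1e-12)

    def test_inconsistent_rip_pair_rejected(self):
        with pytest.raises(ValueError, match="inconsistent RIP"):
            solvation_radius(make_input(I_L=0.0, I_L_hom=50.0))

    def test_emp_zero_cases(self):
        inp = make_input()
        assert emp_term(inp, 0.0) == 0.0
        assert evaluate_terms(inp, q_l=0.0).g_emp == 0.0

    def test_dsc_zero_without_solvent(self):
        assert dsc_term(make_input(N_s=0)) == 0.0


class TestScalingLaws:
    @pytest.mark.parametrize(
        "term, power",
        [
            (net_usv_term, 1),
            (rip_term, 3),
            (dsc_term, 3),
            (lambda i: emp_term(i, 0.8), 6),
        ],
    )
    def test_box_length_power_laws(self, term, power):
        ls = np.array([4.0, 5.5, 7.9, 11.0, 16.0])
        vals = np.array([term(make_input(L=l)) for l in ls])
        # value * L^power must be constant across the grid
        scaled = vals * ls**power
        assert np.allclose(scaled, scaled[0], rtol=1e-12)

    def test_doubling_l_halves_net_usv(self):
        a = net_usv_term(make_input(L=7.9))
        b = net_usv_term(make_input(L=15.8))
        assert b == pytest.approx(a / 2, rel=1e-12)


class TestTransformationCorrection:
    def _snapshots(self, env, n=8, jitter=0.0):
        rng = np.random.default_rng(1)
        return [
            make_input(
                env,
                snapshot_id=s,
                I_L=120.0 + jitter * rng.standard_normal(),
                I_L_hom=60.0,
            )
            for s in range(n)
        ]

    def test_neutral_to_neutral_is_exactly_zero(self):
        value, sem = transformation_correction(
            self._snapshots("complex"), self._snapshots("free"), 0.0, 0.0
        )
        assert (value, sem) == (0.0, 0.0)

    def test_antisymmetry_under_end_state_swap(self):
        cpx = self._snapshots("complex", jitter=5.0)
        free = self._snapshots("free", jitter=5.0)
        v_fwd, s_fwd = transformation_correction(cpx, free, -1.0, 0.0)
        v_bwd, s_bwd = transformation_correction(cpx, free, 0.0, -1.0)
        assert v_bwd == pytest.approx(-v_fwd, rel=1e-12)
        assert s_bwd == pytest.approx(s_fwd, rel=1e-12)

    def test_sem_over_snapshots_combines_environments(self):
        cpx = self._snapshots("complex", jitter=20.0)
        free = self._snapshots("free", jitter=20.0)
        value, sem = transformation_correction(cpx, free, -1.0, 0.0)
        assert sem > 0.0
        # zero jitter removes all snapshot variance
        _, sem0 = transformation_correction(
            self._snapshots("complex"), self._snapshots("free"), -1.0, 0.0
        )
        assert sem0 == 0.0

    def test_mismatched_snapshot_counts_warn(self):
        with pytest.warns(UserWarning, match="mismatch"):
            transformation_correction(
                self._snapshots("complex", n=8), self._snapshots("free", n=4), -1.0, 0.0
            )


class TestTable2Plumbing:
    def test_corrected_equals_raw_plus_correction(self, table2):
        # the published corrected value for 101->91: raw -4.5 + cc 8.4 = 3.9
        row = table2[(table2["from"] == "101") & (table2["to"] == "91")].iloc[0]
        corr, se = apply_correction(
            row["ddg_raw"], row["se_raw"], row["ddg_cc"], row["se_cc"]
        )
        assert corr == pytest.approx(row["ddg_corr"], abs=1e-12)
        assert se == pytest.approx(np.hypot(0.6, 0.3), rel=1e-12)

    def test_sign_rule_and_magnitude_window(self, table2):
        # positive correction when the starting ligand is charged (-1),
        # negative when the final ligand is charged; magnitudes 6.8-8.4
        charged_start = {("101", "91"), ("10", "73")}
        charged_end = {("38", "10"), ("41", "12"), ("M1", "84")}
        cc = table2[table2["charge_change"] == 1]
        for _, row in cc.iterrows():
            edge = (row["from"], row["to"])
            assert 6.8 <= abs(row["ddg_cc"]) <= 8.4
            if edge in charged_start:
                assert row["ddg_cc"] > 0
            else:
                assert edge in charged_end
                assert row["ddg_cc"] < 0
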