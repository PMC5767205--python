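"""Finite-size corrections for charge-changing alchemical transformations.

Ligand transformations that change the net charge under periodic boundary
conditions with Ewald summation carry box-size-dependent artifacts.  This
module evaluates the five semi-analytic correction terms of the Rocklin
scheme — periodicity-induced net-charge interaction plus undersolvation
(NET+USV, evaluated as one expression), residual-integrated-potential
effects (RIP), the empirical cavity term calibrated on the Born case (EMP)
and the discrete-solvent term (DSC) — and combines them over simulation
snapshots into a corrected relative binding free energy.

Unit system: kJ/mol, nm, elementary charges; the only electrostatic
constant is 1/(4*pi*eps0) = 138.935458 kJ mol^-1 nm e^-2.  All terms vanish
identically for a neutral ligand.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .units import COULOMB_CONSTANT, TIP3P_EPSILON, TIP3P_GAMMA, XI_LS

__all__ = [
    "CorrectionInput",
    "CorrectionTerms",
    "net_usv_term",
    "rip_term",
    "solvation_radius",
    "emp_term",
    "dsc_term",
    "evaluate_terms",
    "transformation_correction",
    "apply_correction",
]

#: 1/(8*pi*eps0) in kJ mol^-1 nm e^-2
_HALF_COULOMB = COULOMB_CONSTANT / 2.0


@dataclass(frozen=True)
class CorrectionInput:
    """Per-snapshot electrostatic inputs for one environment.

    RIPs (``I_P``, ``I_L``, ``I_L_hom``) are in kJ mol^-1 nm^3 e^-1, charges
    in e, the cubic box edge ``L`` in nm.  ``environment`` is ``"complex"``
    (protein + ligand) or ``"free"`` (solvated ligand; then I_P = Q_P = 0).
    ``eps_s`` is the bulk solvent dielectric and ``gamma_s`` the
    quadrupole-moment trace of the solvent model (e nm^2); the defaults are
    the TIP3P values.
    """

    environment: str
    I_P: float = 0.0
    I_L: float = 0.0
    I_L_hom: float = 0.0
    Q_P: float = 0.0
    Q_L: float = 0.0
    L: float = 7.9
    N_s: int = 14000
    eps_s: float = TIP3P_EPSILON
    gamma_s: float = TIP3P_GAMMA
    snapshot_id: int = 0

    def __post_init__(self) -> None:
        if self.environment not in ("complex", "free"):
            raise ValueError(f"unknown environment {self.environment!r}")
        if self.L <= 0:
            raise ValueError("box edge L must be positive")
        if self.N_s < 0:
            raise ValueError("solvent count N_s must be >= 0")
        if self.eps_s <= 1:
            raise ValueError("solvent dielectric eps_s must exceed 1")
        if self.environment == "free" and (self.I_P != 0.0 or self.Q_P != 0.0):
            raise ValueError("free environment requires I_P = 0 and Q_P = 0")


@dataclass(frozen=True)
class CorrectionTerms:
    """The evaluated correction terms (kJ/mol) for one snapshot/charge."""

    g_net_usv: float
    g_rip: float
    g_emp: float
    g_dsc: float
    r_l: float  # nm; 0 when unused (neutral ligand)

    @property
    def total(self) -> float:
        return self.g_net_usv + self.g_rip + self.g_emp + self.g_dsc


def net_usv_term(inp: CorrectionInput) -> float:
    """Periodicity-induced net-charge interaction + undersolvation (kJ/mol).

    -xi_LS/(8 pi eps0) * ((Q_P + Q_L)^2 - Q_P^2) / (eps_s * L)
    """
    dq2 = (inp.Q_P + inp.Q_L) ** 2 - inp.Q_P**2
    return -XI_LS * _HALF_COULOMB * dq2 / (inp.eps_s * inp.L)


def rip_term(inp: CorrectionInput) -> float:
    """Residual-integrated-potential correction (kJ/mol).

    ((I_P + I_L)(Q_P + Q_L) - I_P Q_P) / L^3
    """
    return ((inp.I_P + inp.I_L) * (inp.Q_P + inp.Q_L) - inp.I_P * inp.Q_P) / inp.L**3


def solvation_radius(inp: CorrectionInput) -> float:
    """Effective solvation radius R_L (nm) from the heterogeneous/homogeneous
    RIP pair:

    R_L = sqrt[ (I_L - I_L_hom) /
                ( 1/(8 pi eps0) * (4 pi/3) * (1 - 1/eps_s) * |Q_L| ) ]
    """
    if inp.Q_L == 0:
        raise ValueError("solvation radius undefined for a neutral ligand")
    denom = _HALF_COULOMB * (4.0 * math.pi / 3.0) * (1.0 - 1.0 / inp.eps_s) * abs(inp.Q_L)
    radicand = (inp.I_L - inp.I_L_hom) / denom
    if radicand < 0:
        raise ValueError(
            "inconsistent RIP pair: I_L - I_L_hom and the Born denominator "
            f"have opposite signs (radicand {radicand:.4g})"
        )
    return math.sqrt(radicand)


def emp_term(inp: CorrectionInput, r_l: float) -> float:
    """Empirical Born-cavity term (kJ/mol).

    -1/(8 pi eps0) * (16 pi^2/45) * (1 - 1/eps_s)
        * ((Q_P + Q_L)^2 - Q_P^2) * R_L^5 / L^6
    """
    if r_l < 0:
        raise ValueError("solvation radius must be >= 0")
    dq2 = (inp.Q_P + inp.Q_L) ** 2 - inp.Q_P**2
    return (
        -_HALF_COULOMB
        * (16.0 * math.pi**2 / 45.0)
        * (1.0 - 1.0 / inp.eps_s)
        * dq2
        * r_l**5
        / inp.L**6
    )


def dsc_term(inp: CorrectionInput) -> float:
    """Discrete-solvent correction (kJ/mol).

    -gamma_s * Q_L * N_s / (6 eps0 L^3), with eps0 expressed through the
    Coulomb constant: 1/eps0 = 4 pi * 138.935458 kJ mol^-1 nm e^-2.
    """
    inv_eps0 = 4.0 * math.pi * COULOMB_CONSTANT
    return -inp.gamma_s * inp.Q_L * inp.N_s * inv_eps0 / (6.0 * inp.L**3)


def evaluate_terms(inp: CorrectionInput, q_l: float | None = None) -> CorrectionTerms:
    """All terms for one snapshot, optionally at an end-state ligand charge.

    ``q_l`` overrides the input's ligand charge (the two alchemical end
    states share the snapshot geometry and RIPs but differ in Q_L).  For a
    neutral end state every term is zero and R_L is not evaluated.
    """
    if q_l is not None:
        inp = replace(inp, Q_L=q_l)
    if inp.Q_L == 0:
        return CorrectionTerms(0.0, 0.0, 0.0, 0.0, 0.0)
    r_l = solvation_radius(inp)
    return CorrectionTerms(
        g_net_usv=net_usv_term(inp),
        g_rip=rip_term(inp),
        g_emp=emp_term(inp, r_l),
        g_dsc=dsc_term(inp),
        r_l=r_l,
    )


def _environment_series(inputs, q_start: float, q_end: float) -> np.ndarray:
    ordered = sorted(inputs, key=lambda i: i.snapshot_id)
    return np.array(
        [evaluate_terms(i, q_end).total - evaluate_terms(i, q_start).total for i in ordered]
    )


def transformation_correction(
    complex_inputs,
    free_inputs,
    q_l_start: float,
    q_l_end: float,
) -> tuple[float, float]:
    """Charge correction ddG_CC (kJ/mol) for one transformation.

    Per snapshot and environment the five terms are evaluated at both
    end-state ligand charges; the correction is

        ddG_CC = [G(complex, Q_L^1) - G(complex, Q_L^0)]
               - [G(free,    Q_L^1) - G(free,    Q_L^0)]

    averaged over snapshots.  The uncertainty is the standard error of the
    mean per environment (n-1 denominator), combined in quadrature.
    Returns ``(value, sem)``.
    """
    cpx = [i for i in complex_inputs if i.environment == "complex"]
    free = [i for i in free_inputs if i.environment == "free"]
    if not cpx or not free:
        raise ValueError("need at least one snapshot per environment")
    if len(cpx) != len(free):
        warnings.warn(
            f"snapshot count mismatch (complex {len(cpx)}, free {len(free)}); "
            "environments are averaged independently",
            stacklevel=2,
        )
    d_cpx = _environment_series(cpx, q_l_start, q_l_end)
    d_free = _environment_series(free, q_l_start, q_l_end)
    value = float(d_cpx.mean() - d_free.mean())
    sem2 = 0.0
    for series in (d_cpx, d_free):
        if series.size > 1:
            sem2 += series.var(ddof=1) / series.size
    return value, float(np.sqrt(sem2))


def apply_correction(
    ddg_raw: float, se_raw: float, ddg_cc: float, se_cc: float
) -> tuple[float, float]:
    """Corrected binding free energy: raw + correction, SEs in quadrature."""
    return ddg_raw + ddg_cc, float(np.hypot(se_raw, se_cc))
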