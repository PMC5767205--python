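"""Convergence and phase-space overlap diagnostics for a lambda interval.

Seven measures are computed per adjacent pair of lambda states from the
forward and backward reduced-energy differences:

* Omega — Bhattacharyya coefficient of the forward and (negated) backward
  energy distributions on a shared histogram;
* K_AB — Wu-Kofke-style overlap integral of the two energy distributions,
  here the harmonic-mean form K_AB = sum 2 p q/(p + q) (Wu & Kofke,
  J. Chem. Phys. 123, 054103/084109, 2005);
* Pi_f, Pi_b — Wu-Kofke bias metrics, implemented as
  Pi = sqrt(2 ln N) - sqrt(2 s) with s the Kullback-Leibler divergence of
  the sampled distribution from its partner (sampling is deemed adequate
  when ln N exceeds the relative entropy, i.e. Pi > 0; the common
  rule-of-thumb threshold is 0.5);
* w_max — weight of the largest term in the forward exponential average;
* the forward/backward exponential-average gap |dF_fwd - dF_bwd|;
* the MBAR-BAR gap (supplied by the caller);
* sigma_f, sigma_b — standard deviations of the two energy distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .estimators import exp_estimate

__all__ = [
    "OverlapReport",
    "overlap_measures",
    "flag_poor_overlap",
    "max_exp_weight",
    "DEFAULT_THRESHOLDS",
]


def max_exp_weight(delta_u) -> float:
    """Weight of the largest term in the exponential average (>= 1 sample)."""
    du = np.asarray(delta_u, dtype=float)
    if du.size == 0:
        raise ValueError("delta_u must be non-empty")
    log_w = -du - logsumexp(-du)
    return float(np.exp(log_w.max()))


@dataclass(frozen=True)
class OverlapReport:
    omega: float
    k_ab: float
    pi_f: float
    pi_b: float
    w_max: float
    dg_ea_gap: float
    dg_bar_gap: float
    sigma_f: float
    sigma_b: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.omega <= 1.0 + 1e-12):
            raise ValueError("omega must lie in [0, 1]")
        if not (0.0 <= self.k_ab <= 1.0 + 1e-12):
            raise ValueError("k_ab must lie in [0, 1]")
        if not (0.0 < self.w_max <= 1.0 + 1e-12):
            raise ValueError("w_max must lie in (0, 1]")


def _shared_histograms(a: np.ndarray, b: np.ndarray, bins: int):
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:  # degenerate: all samples identical
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, bins + 1)
    p, _ = np.histogram(a, bins=edges)
    q, _ = np.histogram(b, bins=edges)
    return p / p.sum(), q / q.sum()


def overlap_measures(
    delta_u_fwd,
    delta_u_bwd,
    mbar_minus_bar: float = 0.0,
    bins: int = 50,
) -> OverlapReport:
    """Compute the overlap diagnostics for one lambda interval.

    ``delta_u_fwd`` are u_j - u_i samples drawn in state i; ``delta_u_bwd``
    are u_i - u_j samples drawn in state j (they are negated internally so
    both histograms live on the same energy axis).  ``mbar_minus_bar`` is
    the externally computed MBAR-BAR discrepancy for the interval, in
    reduced units.
    """
    du_f = np.asarray(delta_u_fwd, dtype=float)
    du_b = np.asarray(delta_u_bwd, dtype=float)
    if du_f.size == 0 or du_b.size == 0:
        raise ValueError("both energy-difference sequences must be non-empty")
    if du_f.size < 2 or du_b.size < 2:
        raise ValueError("need >= 2 samples per direction for distribution measures")

    b_on_f_axis = -du_b  # backward samples mapped to the forward energy axis
    p, q = _shared_histograms(du_f, b_on_f_axis, bins)

    omega = float(np.sum(np.sqrt(p * q)))
    with np.errstate(divide="ignore", invalid="ignore"):
        k_ab = float(np.nansum(np.where(p + q > 0, 2.0 * p * q / (p + q), 0.0)))

    # KL divergences with Laplace pseudo-counts (bins with zero partner
    # probability would otherwise make s infinite)
    def kl(pp, qq, n_q):
        qq = (qq * n_q + 1.0) / (n_q + bins)
        m = pp > 0
        return float(np.sum(pp[m] * np.log(pp[m] / qq[m])))

    s_f = kl(p, q, du_b.size)
    s_b = kl(q, p, du_f.size)
    pi_f = float(np.sqrt(2.0 * np.log(du_f.size)) - np.sqrt(2.0 * s_f))
    pi_b = float(np.sqrt(2.0 * np.log(du_b.size)) - np.sqrt(2.0 * s_b))

    w_max = max_exp_weight(du_f)

    f_fwd = exp_estimate(du_f, "forward").value
    f_bwd = exp_estimate(du_b, "backward").value

    return OverlapReport(
        omega=min(omega, 1.0),
        k_ab=min(k_ab, 1.0),
        pi_f=pi_f,
        pi_b=pi_b,
        w_max=min(w_max, 1.0),
        dg_ea_gap=abs(f_fwd - f_bwd),
        dg_bar_gap=abs(float(mbar_minus_bar)),
        sigma_f=float(du_f.std(ddof=1)),
        sigma_b=float(du_b.std(ddof=1)),
    )


#: reduced-unit warning thresholds; config-exposed, chosen so converged
#: Gaussian fixtures pass and disjoint fixtures fail
DEFAULT_THRESHOLDS = {
    "omega_min": 0.7,
    "k_ab_min": 0.7,
    "pi_min": 0.5,
    "w_max_max": 0.5,
    "dg_ea_gap_max": 1.0,
    "dg_bar_gap_max": 0.5,
}


def flag_poor_overlap(report: OverlapReport, thresholds: dict | None = None) -> list[str]:
    """Deterministic warning list for an interval's overlap report."""
    t = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        t.update(thresholds)
    warnings = []
    if report.omega < t["omega_min"]:
        warnings.append(
            f"energy-distribution overlap is poor (omega = {report.omega:.3f} "
            f"< {t['omega_min']})"
        )
    if report.k_ab < t["k_ab_min"]:
        warnings.append(
            f"distribution overlap K_AB = {report.k_ab:.3f} < {t['k_ab_min']}"
        )
    if min(report.pi_f, report.pi_b) < t["pi_min"]:
        warnings.append(
            f"bias metric Pi = {min(report.pi_f, report.pi_b):.3f} < {t['pi_min']}"
        )
    if report.w_max > t["w_max_max"]:
        warnings.append(
            "exponential average dominated by one sample "
            f"(w_max = {report.w_max:.3f} > {t['w_max_max']})"
        )
    if report.dg_ea_gap > t["dg_ea_gap_max"]:
        warnings.append(
            f"forward/backward exponential averages differ by "
            f"{report.dg_ea_gap:.3f} kT > {t['dg_ea_gap_max']}"
        )
    if report.dg_bar_gap > t["dg_bar_gap_max"]:
        warnings.append(
            f"MBAR and BAR estimates differ by {report.dg_bar_gap:.3f} kT "
            f"> {t['dg_bar_gap_max']}"
        )
    return warnings
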