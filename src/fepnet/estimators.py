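"""Free-energy estimators for staged alchemical transformations.

Implements one-sided exponential averaging (EXP), the Bennett acceptance
ratio (BAR) and its multistate generalisation (MBAR), together with
autocorrelation-based decorrelation of the sampled energies, bootstrap
standard errors, and the thermodynamic-cycle combination of bound and free
legs into a relative binding free energy.

All estimators consume *reduced* potentials u = U/(k_B T); conversion to
kJ/mol happens only at the API boundary (see :func:`combine_legs` and
:mod:`fepnet.io`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

from .io import ReducedPotentialSet

__all__ = [
    "FreeEnergyEstimate",
    "MBARResult",
    "statistical_inefficiency",
    "subsample_indices",
    "decorrelate",
    "exp_estimate",
    "bar_estimate",
    "mbar_estimate",
    "combine_legs",
]


@dataclass(frozen=True)
class FreeEnergyEstimate:
    """A free-energy difference with its standard error.

    ``units`` is either ``"reduced"`` (dimensionless, k_B T) or ``"kJ/mol"``.
    ``leg`` tags the provenance: the protein-bound leg, the solvated-ligand
    leg, or their combination into a binding free energy.
    """

    value: float
    se: float
    method: str  # EXP_fwd | EXP_bwd | BAR | MBAR
    leg: str = "unknown"  # bound | free | combined | unknown
    units: str = "reduced"

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("free-energy estimate is not finite")
        if self.se < 0 or not np.isfinite(self.se):
            raise ValueError("standard error must be finite and >= 0")

    def to_kj_per_mol(self, temperature: float) -> "FreeEnergyEstimate":
        from .units import kt_kj_per_mol

        if self.units == "kJ/mol":
            return self
        kt = kt_kj_per_mol(temperature)
        return replace(self, value=self.value * kt, se=self.se * kt, units="kJ/mol")


@dataclass
class MBARResult:
    """Per-state reduced free energies relative to state 0 plus covariance."""

    f: np.ndarray  # (K,), f[0] == 0
    covariance: np.ndarray  # (K, K) asymptotic covariance of f
    bootstrap_se: np.ndarray | None = None  # (K,), optional
    n_iterations: int = 0

    def se(self, prefer_bootstrap: bool = True) -> np.ndarray:
        if prefer_bootstrap and self.bootstrap_se is not None:
            return self.bootstrap_se
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    def delta_f(self, i: int = 0, j: int = -1) -> FreeEnergyEstimate:
        j = j % len(self.f)
        var = (
            self.covariance[i, i]
            + self.covariance[j, j]
            - 2.0 * self.covariance[i, j]
        )
        if self.bootstrap_se is not None:
            # bootstrap covariance of the difference is not tracked per pair;
            # fall back to the quadrature bound
            se = float(np.hypot(self.bootstrap_se[i], self.bootstrap_se[j]))
        else:
            se = float(np.sqrt(max(var, 0.0)))
        return FreeEnergyEstimate(
            value=float(self.f[j] - self.f[i]), se=se, method="MBAR"
        )


# ---------------------------------------------------------------------------
# decorrelation
# ---------------------------------------------------------------------------

def statistical_inefficiency(series) -> float:
    """Statistical inefficiency g >= 1 of a scalar time series.

    g = 1 + 2 * sum_t C(t), where C(t) is the normalised autocorrelation
    function; the sum runs over positive lags and is truncated at the first
    non-positive C(t).  A constant (zero-variance) series returns g = 1 by
    convention.  The subsampling stride is ceil(g).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 samples, got {n}")
    if np.ptp(x) == 0.0:  # constant series: zero-variance convention
        return 1.0
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var <= 0 or not np.isfinite(var):
        return 1.0
    g = 1.0
    for t in range(1, n - 1):
        c = np.dot(x[:-t], x[t:]) / ((n - t) * var)
        if c <= 0.0:
            break
        g += 2.0 * c
    return max(g, 1.0)


def subsample_indices(series) -> np.ndarray:
    """Indices of approximately independent samples (stride ceil(g))."""
    g = statistical_inefficiency(series)
    stride = int(np.ceil(g))
    return np.arange(0, len(np.asarray(series)), stride)


def decorrelate(data: ReducedPotentialSet) -> ReducedPotentialSet:
    """Subsample a ReducedPotentialSet state by state.

    The decorrelation observable is the reduced-energy difference to the
    adjacent state (the last state uses its left neighbour), evaluated on the
    samples from each sampling state; the stride is ceil(g) for that state.
    """
    keep: list[np.ndarray] = []
    for k in range(data.n_states):
        rows = np.flatnonzero(data.sampled_state == k)
        adjacent = k + 1 if k + 1 < data.n_states else k - 1
        obs = data.u[rows, adjacent] - data.u[rows, k]
        if rows.size < 4:
            keep.append(rows)
            continue
        keep.append(rows[subsample_indices(obs)])
    rows = np.concatenate(keep)
    rows.sort()
    return ReducedPotentialSet(
        u=data.u[rows],
        sampled_state=data.sampled_state[rows],
        temperature=data.temperature,
        label=data.label,
    )


# ---------------------------------------------------------------------------
# EXP
# ---------------------------------------------------------------------------

def exp_estimate(delta_u, direction: str = "forward", leg: str = "unknown") -> FreeEnergyEstimate:
    """One-sided exponential-averaging estimate of Delta F (reduced units).

    ``forward``: delta_u = u_target - u_sampling measured in the sampling
    (initial) state; Delta F = -ln< exp(-delta_u) >.
    ``backward``: delta_u = u_initial - u_target measured in the target
    (final) state; the sign convention is flipped so that both directions
    estimate the same forward Delta F.
    """
    du = np.asarray(delta_u, dtype=float)
    if du.ndim != 1 or du.size == 0:
        raise ValueError("delta_u must be a non-empty 1-D sequence")
    if direction not in ("forward", "backward"):
        raise ValueError(f"unknown direction {direction!r}")
    n = du.size
    # max-shift for numerical stability: -ln mean e^{-du}
    log_mean = logsumexp(-du) - np.log(n)
    value = -log_mean
    # delta-method SE of -ln mean(w), w = e^{-du}, computed with the shift
    w = np.exp(-du - (-du).max())  # e^{-du - max(-du)} in (0, 1]
    mw = w.mean()
    se = float(np.sqrt(w.var(ddof=1) / n) / mw) if n > 1 else 0.0
    if direction == "backward":
        value = -value
    return FreeEnergyEstimate(float(value), se, method=f"EXP_{direction[0]}wd", leg=leg)


# ---------------------------------------------------------------------------
# BAR
# ---------------------------------------------------------------------------

def bar_estimate(
    delta_u_fwd,
    delta_u_bwd,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    leg: str = "unknown",
) -> FreeEnergyEstimate:
    """Bennett acceptance-ratio estimate of Delta F (reduced units).

    Solves the self-consistent Bennett equation

        sum_f 1/(1 + (n_f/n_b) e^{du_f - DF}) =
        sum_b 1/(1 + (n_b/n_f) e^{du_b + DF})

    by bracketed root finding between the two one-sided EXP estimates
    (bracket widened by +/-50 k_B T).  The standard error is the asymptotic
    MBAR covariance of the equivalent two-state problem.
    """
    du_f = np.asarray(delta_u_fwd, dtype=float)
    du_b = np.asarray(delta_u_bwd, dtype=float)
    if du_f.size == 0 or du_b.size == 0:
        raise ValueError("both work distributions must be non-empty")
    m = np.log(du_f.size / du_b.size)

    def imbalance(df: float) -> float:
        # logistic form of the Bennett equation, monotone increasing in df
        lhs = expit(df - du_f - m).sum()
        rhs = expit(m - df - du_b).sum()
        return lhs - rhs

    f_fwd = exp_estimate(du_f, "forward").value
    f_bwd = exp_estimate(du_b, "backward").value
    lo = min(f_fwd, f_bwd) - 50.0
    hi = max(f_fwd, f_bwd) + 50.0
    flo, fhi = imbalance(lo), imbalance(hi)
    for _ in range(60):  # widen if the EXP bracket fails (extreme inputs)
        if flo * fhi <= 0:
            break
        lo, hi = lo - 100.0, hi + 100.0
        flo, fhi = imbalance(lo), imbalance(hi)
    else:
        raise RuntimeError(
            f"BAR bracketing failed: imbalance({lo})={flo}, imbalance({hi})={fhi}"
        )
    if flo == 0.0:
        value = lo
    elif fhi == 0.0:
        value = hi
    else:
        value = brentq(imbalance, lo, hi, xtol=tol, maxiter=max_iter)
    se = _bar_asymptotic_se(du_f, du_b, value)
    return FreeEnergyEstimate(float(value), se, method="BAR", leg=leg)


def _bar_asymptotic_se(du_f: np.ndarray, du_b: np.ndarray, df: float) -> float:
    """Asymptotic variance of the BAR estimate (Bennett 1976 form)."""
    n_f, n_b = du_f.size, du_b.size
    m = np.log(n_f / n_b)
    # Fermi weights of all samples evaluated at the solution
    wf = expit(-(du_f - df + m))
    wb = expit(-(du_b + df - m))
    s = np.concatenate([wf * (1 - wf), wb * (1 - wb)]).sum()
    if s <= 0:
        return 0.0
    var = 1.0 / s - (n_f + n_b) / (n_f * n_b)
    return float(np.sqrt(max(var, 0.0)))


# ---------------------------------------------------------------------------
# MBAR
# ---------------------------------------------------------------------------

def _mbar_objective_parts(f: np.ndarray, u: np.ndarray, n_k: np.ndarray):
    """log denominators and sample weights for the MBAR equations.

    u has shape (N, K); returns (log_denom (N,), W (N, K)) with
    W[n, i] = exp(f_i - u[n, i]) / sum_k N_k exp(f_k - u[n, k]).
    """
    log_nk = np.log(n_k)
    log_denom = logsumexp(f + log_nk - u, axis=1)
    w = np.exp(f - u - log_denom[:, None])
    return log_denom, w


def _mbar_self_consistent(f, u, n_k):
    log_denom, _ = _mbar_objective_parts(f, u, n_k)
    f_new = -logsumexp(-(u.T) - log_denom, axis=1)
    return f_new - f_new[0]


def _mbar_hessian(w: np.ndarray, n_k: np.ndarray) -> np.ndarray:
    """Hessian of the MBAR convex objective at weights W (free f, all K)."""
    nw = w * n_k  # (N, K), rows sum to 1
    h = -(nw.T @ nw)
    h[np.diag_indices_from(h)] += nw.sum(axis=0)
    return h


def _mbar_covariance(w: np.ndarray, n_k: np.ndarray) -> np.ndarray:
    """Asymptotic covariance of the reduced free energies (f_0 pinned).

    Uses the sandwich estimator Theta = W^T (I - W N W^T)^+ W evaluated
    through the thin SVD of W (Shirts & Chodera 2008, appendix D), which
    avoids forming any N x N matrix.  Returned as the covariance of
    (f_i - f_0), i.e. row/column 0 are zero.
    """
    u_mat, s, vt = np.linalg.svd(w, full_matrices=False)
    del u_mat
    k = len(n_k)
    sv = s[:, None] * vt  # S V^T, (K, K)
    inner = np.eye(k) - sv @ (n_k[:, None] * sv.T)
    theta = sv.T @ np.linalg.pinv(inner, hermitian=True) @ sv
    cov = (
        theta
        - theta[:, [0]]
        - theta[[0], :]
        + theta[0, 0]
    )
    return cov


def mbar_estimate(
    data: ReducedPotentialSet,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    n_self_consistent: int = 50,
    bootstrap: int | None = None,
    seed: int | None = None,
) -> MBARResult:
    """Multistate Bennett acceptance ratio free energies for all states.

    Solves the MBAR self-consistent equations

        f_i = -ln sum_n exp(-u_i(x_n)) / sum_k N_k exp(f_k - u_k(x_n))

    with f_0 pinned to 0, by damped self-consistent iteration followed by
    Newton polish on the convex MBAR objective; convergence is declared when
    max |delta f| < tol.  The asymptotic covariance is the standard MBAR
    sandwich estimator (see :func:`_mbar_covariance`); if ``bootstrap`` is
    given, bootstrap standard errors over whole decorrelated samples
    (resampled within each sampling state) are attached as well.
    """
    data.validate()
    u = np.asarray(data.u, dtype=float)
    states = np.asarray(data.sampled_state)
    k_states = data.n_states
    n_k = np.bincount(states, minlength=k_states).astype(float)
    if np.any(n_k == 0):
        raise ValueError("every state must contribute at least one sample")

    f = np.zeros(k_states)
    converged = False
    iterations = 0
    for it in range(max_iter):
        iterations = it + 1
        if it < n_self_consistent:
            f_new = _mbar_self_consistent(f, u, n_k)
            # damping keeps early iterations stable for poor overlap
            f_new = 0.5 * (f + f_new) if it < 5 else f_new
        else:
            _, w = _mbar_objective_parts(f, u, n_k)
            grad = n_k * (w.sum(axis=0) - 1.0)
            h = _mbar_hessian(w, n_k)
            try:
                step = np.linalg.solve(h[1:, 1:], grad[1:])
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(h[1:, 1:], grad[1:], rcond=None)[0]
            f_new = f.copy()
            f_new[1:] -= step
            f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            converged = True
            break
    if not converged:
        _, w = _mbar_objective_parts(f, u, n_k)
        grad = n_k * (w.sum(axis=0) - 1.0)
        raise RuntimeError(
            "MBAR did not converge in "
            f"{max_iter} iterations; max gradient residual {np.max(np.abs(grad)):.3e}"
        )

    _, w = _mbar_objective_parts(f, u, n_k)
    cov = _mbar_covariance(w, n_k)

    boot_se = None
    if bootstrap:
        rng = np.random.default_rng(seed)
        rows_by_state = [np.flatnonzero(states == k) for k in range(k_states)]
        fs = np.empty((bootstrap, k_states))
        for b in range(bootstrap):
            rows = np.concatenate(
                [rng.choice(r, size=r.size, replace=True) for r in rows_by_state]
            )
            fb = f.copy()
            ub = u[rows]
            for it in range(max_iter):
                f_new = _mbar_self_consistent(fb, ub, n_k)
                delta = np.max(np.abs(f_new - fb))
                fb = f_new
                if delta < max(tol, 1e-8):
                    break
            fs[b] = fb
        boot_se = fs.std(axis=0, ddof=1)

    return MBARResult(f=f, covariance=cov, bootstrap_se=boot_se, n_iterations=iterations)


# ---------------------------------------------------------------------------
# leg combination (thermodynamic cycle)
# ---------------------------------------------------------------------------

def _as_list(x) -> list[FreeEnergyEstimate]:
    if isinstance(x, FreeEnergyEstimate):
        return [x]
    return list(x)


def combine_legs(bound, free) -> FreeEnergyEstimate:
    """Relative binding free energy from the bound and free legs.

    ddG_bind = ddG_bound - ddG_free, where each leg may be a single estimate
    or a list of per-interval estimates that are summed first.  The total
    variance is the sum of the individual variances.  Both legs must carry
    the same units.
    """
    bound, free = _as_list(bound), _as_list(free)
    if not bound or not free:
        raise ValueError("both legs must contain at least one estimate")
    units = {e.units for e in bound} | {e.units for e in free}
    if len(units) != 1:
        raise ValueError(f"unit mismatch between legs: {sorted(units)}")
    value = sum(e.value for e in bound) - sum(e.value for e in free)
    var = sum(e.se**2 for e in bound) + sum(e.se**2 for e in free)
    return FreeEnergyEstimate(
        value=float(value),
        se=float(np.sqrt(var)),
        method=bound[0].method,
        leg="combined",
        units=units.pop(),
    )
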