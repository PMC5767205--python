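"""Benchmark statistics against experiment, with resampled uncertainties.

Quality measures for calculated vs experimental relative binding free
energies: mean absolute deviation (MAD), the direction-agnostic squared
correlation R^2 (each transformation enters in both directions, which
equals the uncentered r^2 of the originals), Kendall's tau restricted to
the explicitly computed transformations (tau_r, tau-b tie correction), its
95%-significance-filtered variant (tau_r,95) and Spearman's rho.

Uncertainties of all measures come from a Gaussian parametric resampling
procedure: each calculated value is redrawn from N(calc, se_calc) and each
experimental value from N(exp, se_exp) (default se_exp = 2.4 kJ/mol), the
measure is recomputed, and the standard deviation over repetitions is
reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_EXPERIMENTAL_SE",
    "QualityReport",
    "pairs_from_network_table",
    "mad",
    "r_squared_bidirectional",
    "kendall_tau_r",
    "spearman_rho",
    "resample_uncertainty",
    "quality_report",
]

#: assumed experimental uncertainty for relative affinities, kJ/mol (1.7*sqrt(2))
DEFAULT_EXPERIMENTAL_SE = 2.4

PAIR_COLUMNS = ["calc", "se_calc", "exp", "se_exp", "label"]


def pairs_from_network_table(
    table: pd.DataFrame,
    values: str = "corrected",
    subset: str | int = "all",
    exclude_charge_changes: bool = False,
    se_exp: float = DEFAULT_EXPERIMENTAL_SE,
) -> pd.DataFrame:
    """Benchmark pairs (calc vs exp) from a network table.

    ``values`` selects the calculated column (``corrected`` or ``raw``);
    ``subset`` is ``"all"`` or a perturbation-set id.  Rows without an
    experimental value are dropped; rows flagged as charge-changing can be
    excluded for sensitivity analyses.
    """
    if values not in ("corrected", "raw"):
        raise ValueError("values must be 'corrected' or 'raw'")
    df = table.copy()
    if subset != "all":
        df = df[df["set"] == int(subset)]
    if exclude_charge_changes and "charge_change" in df.columns:
        df = df[df["charge_change"] == 0]
    df = df[df["ddg_exp"].notna()]
    col, se_col = ("ddg_corr", "se_corr") if values == "corrected" else ("ddg_raw", "se_raw")
    out = pd.DataFrame(
        {
            "calc": df[col].astype(float).to_numpy(),
            "se_calc": df[se_col].astype(float).to_numpy(),
            "exp": df["ddg_exp"].astype(float).to_numpy(),
            "se_exp": se_exp,
            "label": (df["from"] + "->" + df["to"]).to_numpy(),
        }
    )
    return out


def _check_pairs(pairs: pd.DataFrame, minimum: int = 1) -> pd.DataFrame:
    if len(pairs) < minimum:
        raise ValueError(f"need at least {minimum} benchmark pairs, got {len(pairs)}")
    return pairs


def mad(pairs: pd.DataFrame) -> float:
    """Mean absolute deviation of calc from exp (kJ/mol)."""
    p = _check_pairs(pairs, 1)
    return float(np.abs(p["calc"] - p["exp"]).mean())


def r_squared_bidirectional(pairs: pd.DataFrame) -> float:
    """Direction-agnostic R^2.

    Every pair is included as (calc, exp) and (-calc, -exp); the squared
    Pearson correlation of the doubled set equals the uncentered
    (sum cx)^2 / (sum c^2 sum x^2) of the originals, which is what is
    computed here (both forms are cross-checked in the test suite).
    """
    p = _check_pairs(pairs, 2)
    c = p["calc"].to_numpy()
    e = p["exp"].to_numpy()
    denom = float(np.sum(c * c) * np.sum(e * e))
    if denom == 0.0:
        raise ValueError("all-zero calculated or experimental values")
    return float(np.sum(c * e) ** 2 / denom)


def kendall_tau_r(
    pairs: pd.DataFrame, significant_only: bool = False, z: float = 1.96
) -> tuple[float, int]:
    """Kendall tau-b over the studied transformations.

    With ``significant_only`` the comparison keeps only pairs whose
    calculated *and* experimental values differ from zero at the level
    implied by ``z`` (|value| > z * se).  Returns ``(tau, n_pairs)``; tau is
    NaN when fewer than two pairs survive the filter.
    """
    p = _check_pairs(pairs, 2)
    if significant_only:
        keep = (np.abs(p["calc"]) > z * p["se_calc"]) & (
            np.abs(p["exp"]) > z * p["se_exp"]
        )
        p = p[keep]
    if len(p) < 2:
        return float("nan"), len(p)
    tau = stats.kendalltau(p["calc"], p["exp"]).statistic
    return float(tau), len(p)


def spearman_rho(pairs: pd.DataFrame) -> float:
    """Spearman rank correlation (average ranks on ties)."""
    p = _check_pairs(pairs, 2)
    return float(stats.spearmanr(p["calc"], p["exp"]).statistic)


def resample_uncertainty(
    pairs: pd.DataFrame,
    metric,
    n_rep: int = 1000,
    seed: int | None = None,
) -> float:
    """Standard deviation of ``metric`` under Gaussian resampling.

    ``metric`` is any callable mapping a pairs DataFrame to a float (e.g.
    :func:`mad`); per repetition every calc is redrawn from N(calc, se_calc)
    and every exp from N(exp, se_exp).
    """
    if n_rep < 2:
        raise ValueError("need at least 2 repetitions")
    p = _check_pairs(pairs, 1)
    rng = np.random.default_rng(seed)
    calc = p["calc"].to_numpy()
    se_calc = p["se_calc"].to_numpy()
    exp = p["exp"].to_numpy()
    se_exp = np.broadcast_to(np.asarray(p["se_exp"], dtype=float), calc.shape)
    values = np.empty(n_rep)
    work = p.copy()
    for i in range(n_rep):
        work = work.assign(
            calc=rng.normal(calc, se_calc), exp=rng.normal(exp, se_exp)
        )
        values[i] = metric(work)
    return float(np.std(values, ddof=1))


@dataclass(frozen=True)
class QualityReport:
    mad: float
    mad_sd: float
    r2: float
    r2_sd: float
    tau_r: float
    tau_r_sd: float
    tau_r95: float
    tau_r95_sd: float
    rho: float
    rho_sd: float
    n_pairs: int
    n_pairs_95: int


def quality_report(
    pairs: pd.DataFrame, n_rep: int = 1000, seed: int | None = None
) -> QualityReport:
    """All quality measures with resampled uncertainties in one pass."""
    tau, n = kendall_tau_r(pairs)
    tau95, n95 = kendall_tau_r(pairs, significant_only=True)
    seeds = np.random.SeedSequence(seed).generate_state(4)
    return QualityReport(
        mad=mad(pairs),
        mad_sd=resample_uncertainty(pairs, mad, n_rep, int(seeds[0])),
        r2=r_squared_bidirectional(pairs),
        r2_sd=resample_uncertainty(pairs, r_squared_bidirectional, n_rep, int(seeds[1])),
        tau_r=tau,
        tau_r_sd=resample_uncertainty(
            pairs, lambda p: kendall_tau_r(p)[0], n_rep, int(seeds[2])
        ),
        tau_r95=tau95,
        tau_r95_sd=resample_uncertainty(
            pairs,
            lambda p: _nan_to_zero(kendall_tau_r(p, significant_only=True)[0]),
            n_rep,
            int(seeds[3]),
        ),
        rho=spearman_rho(pairs),
        rho_sd=resample_uncertainty(pairs, spearman_rho, n_rep, int(seeds[3])),
        n_pairs=n,
        n_pairs_95=n95,
    )


def _nan_to_zero(x: float) -> float:
    return 0.0 if np.isnan(x) else x
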