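"""File formats and packaged reference tables.

Three text formats are supported:

* the ``u_kn`` CSV dialect for per-lambda reduced-potential samples
  (header ``sampled_state,sample_index,u_0,...,u_{K-1}``; energies in
  kJ/mol, converted to reduced units on load);
* the network CSV dialect for perturbation-edge tables
  (header ``from,to,set,ddg_raw,se_raw,ddg_cc,se_cc,ddg_corr,se_corr,ddg_exp``,
  all energies kJ/mol, missing experimental values as empty fields);
* INI-like blocks of finite-size-correction inputs, one block per snapshot
  per environment (``[snapshot.<n>.<env>]``).

The benchmark tables of the source study (docking scores, perturbation
network with experimental affinities, thermodynamic cycles) ship as packaged
CSV fixtures and are exposed through :func:`load_fixture`.
"""

from __future__ import annotations

import configparser
import io as _io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .units import DEFAULT_TEMPERATURE, kt_kj_per_mol

__all__ = [
    "ParseError",
    "ReducedPotentialSet",
    "read_energy_samples",
    "write_energy_samples",
    "read_network_table",
    "write_network_table",
    "read_correction_inputs",
    "write_correction_inputs",
    "load_fixture",
    "fixture_cycles",
]

NETWORK_COLUMNS = [
    "from", "to", "set", "ddg_raw", "se_raw",
    "ddg_cc", "se_cc", "ddg_corr", "se_corr", "ddg_exp",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


@dataclass
class ReducedPotentialSet:
    """Reduced potentials u_k(x_n) of N samples evaluated in all K states.

    ``u`` has shape (N, K); ``sampled_state`` gives, per sample, the index of
    the lambda state it was drawn from.  Energies are dimensionless
    (divided by k_B*T at ``temperature``).
    """

    u: np.ndarray
    sampled_state: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE
    label: str = ""

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.sampled_state = np.asarray(self.sampled_state, dtype=int)
        self.validate()

    @property
    def n_states(self) -> int:
        return self.u.shape[1]

    @property
    def n_samples(self) -> int:
        return self.u.shape[0]

    def counts(self) -> np.ndarray:
        return np.bincount(self.sampled_state, minlength=self.n_states)

    def validate(self) -> None:
        if self.u.ndim != 2 or self.u.shape[1] < 2:
            raise ValueError("u must be (n_samples, K) with K >= 2")
        if self.sampled_state.shape != (self.u.shape[0],):
            raise ValueError("sampled_state must have one entry per sample")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("all reduced potentials must be finite")
        if self.sampled_state.min(initial=0) < 0 or (
            self.u.shape[0] and self.sampled_state.max() >= self.n_states
        ):
            raise ValueError("sampled_state indices out of range")
        if np.any(self.counts() == 0):
            missing = np.flatnonzero(self.counts() == 0).tolist()
            raise ValueError(f"states without samples: {missing}")

    def delta_u(self, i: int, j: int, sampled_in: int | None = None) -> np.ndarray:
        """u_j - u_i over the samples drawn from ``sampled_in`` (default i)."""
        k = i if sampled_in is None else sampled_in
        rows = self.sampled_state == k
        return self.u[rows, j] - self.u[rows, i]


def read_energy_samples(
    path, temperature: float = DEFAULT_TEMPERATURE, label: str = ""
) -> ReducedPotentialSet:
    """Read a u_kn CSV file (energies kJ/mol) into reduced units."""
    path = Path(path)
    kt = kt_kj_per_mol(temperature)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split(",")
        if len(cols) < 4 or cols[0] != "sampled_state" or cols[1] != "sample_index":
            raise ParseError(
                f"{path}:1: malformed header; expected "
                "'sampled_state,sample_index,u_0,...' got {header!r}"
            )
        expected = [f"u_{k}" for k in range(len(cols) - 2)]
        if cols[2:] != expected:
            raise ParseError(f"{path}:1: energy columns must be {expected}")
        n_states = len(expected)
        states, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != n_states + 2:
                raise ParseError(f"{path}:{lineno}: expected {n_states + 2} fields")
            try:
                state = int(parts[0])
                energies = [float(p) for p in parts[2:]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            if not 0 <= state < n_states:
                raise ParseError(
                    f"{path}:{lineno}: sampled_state {state} out of range [0, {n_states})"
                )
            states.append(state)
            rows.append(energies)
    if not rows:
        raise ParseError(f"{path}: no samples")
    u = np.asarray(rows, dtype=float) / kt
    return ReducedPotentialSet(
        u=u, sampled_state=np.asarray(states), temperature=temperature,
        label=label or path.stem,
    )


def write_energy_samples(data: ReducedPotentialSet, path) -> None:
    """Write a ReducedPotentialSet as a u_kn CSV (energies kJ/mol).

    Values are written with 17 significant digits so that a read round-trips
    bit-identically.
    """
    path = Path(path)
    kt = kt_kj_per_mol(data.temperature)
    header = "sampled_state,sample_index," + ",".join(
        f"u_{k}" for k in range(data.n_states)
    )
    with path.open("w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        for i, (state, row) in enumerate(zip(data.sampled_state, data.u)):
            cells = ",".join(repr(float(v * kt)) for v in row)
            fh.write(f"{state},{i},{cells}\n")


# ---------------------------------------------------------------------------
# network tables
# ---------------------------------------------------------------------------

def _validate_network_table(df: pd.DataFrame, origin: str) -> pd.DataFrame:
    missing = [c for c in NETWORK_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{origin}: missing columns {missing}")
    df = df.copy()
    df["from"] = df["from"].astype(str)
    df["to"] = df["to"].astype(str)
    if (df["from"].str.len() == 0).any() or (df["to"].str.len() == 0).any():
        raise ParseError(f"{origin}: empty ligand name")
    for col in ("se_raw", "se_cc", "se_corr"):
        if (df[col].dropna() < 0).any():
            raise ParseError(f"{origin}: negative standard error in {col}")
    # where no correction applies, corrected must equal raw
    no_cc = df["ddg_cc"].isna()
    if not np.allclose(df.loc[no_cc, "ddg_corr"], df.loc[no_cc, "ddg_raw"]):
        raise ParseError(f"{origin}: ddg_corr != ddg_raw on rows without ddg_cc")
    return df


def read_network_table(path) -> pd.DataFrame:
    """Read a perturbation-edge CSV into a validated DataFrame."""
    df = pd.read_csv(path, dtype={"from": str, "to": str})
    return _validate_network_table(df, str(path))


def write_network_table(df: pd.DataFrame, path) -> None:
    df = df.copy()
    float_cols = [c for c in df.columns if df[c].dtype.kind == "f"]
    df.to_csv(path, index=False, float_format="%.17g")
    del float_cols


# ---------------------------------------------------------------------------
# correction inputs (INI-like blocks)
# ---------------------------------------------------------------------------

_CORRECTION_KEYS = ("I_P", "I_L", "I_L_hom", "Q_P", "Q_L", "L", "N_s")


def read_correction_inputs(path):
    """Read finite-size-correction input blocks.

    Returns a list of :class:`fepnet.charge_correction.CorrectionInput`, one
    per ``[snapshot.<n>.<env>]`` block with ``env`` in {complex, free}.  Free
    blocks must have I_P = Q_P = 0 (no protein in the solvated-ligand leg).
    """
    from .charge_correction import CorrectionInput

    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise ParseError(f"{path}: cannot read correction input file")
    inputs = []
    for section in parser.sections():
        parts = section.split(".")
        if len(parts) != 3 or parts[0] != "snapshot":
            raise ParseError(f"{path}: bad section name [{section}]")
        try:
            snapshot_id = int(parts[1])
        except ValueError:
            raise ParseError(f"{path}: non-integer snapshot id in [{section}]") from None
        environment = parts[2]
        if environment not in ("complex", "free"):
            raise ParseError(
                f"{path}: environment must be 'complex' or 'free' in [{section}]"
            )
        block = parser[section]
        for key in _CORRECTION_KEYS:
            if key not in block:
                raise ParseError(f"{path}: [{section}] missing key {key}")
        kwargs = dict(
            environment=environment,
            snapshot_id=snapshot_id,
            I_P=block.getfloat("I_P"),
            I_L=block.getfloat("I_L"),
            I_L_hom=block.getfloat("I_L_hom"),
            Q_P=block.getfloat("Q_P"),
            Q_L=block.getfloat("Q_L"),
            L=block.getfloat("L"),
            N_s=block.getint("N_s"),
        )
        if "eps_s" in block:
            kwargs["eps_s"] = block.getfloat("eps_s")
        if "gamma_s" in block:
            kwargs["gamma_s"] = block.getfloat("gamma_s")
        try:
            inputs.append(CorrectionInput(**kwargs))
        except ValueError as exc:
            raise ParseError(f"{path}: [{section}]: {exc}") from None
    return inputs


def write_correction_inputs(inputs, path) -> None:
    lines = []
    for inp in inputs:
        lines.append(f"[snapshot.{inp.snapshot_id}.{inp.environment}]")
        for key in ("I_P", "I_L", "I_L_hom", "Q_P", "Q_L", "L"):
            lines.append(f"{key} = {getattr(inp, key)!r}")
        lines.append(f"N_s = {inp.N_s}")
        lines.append(f"eps_s = {inp.eps_s!r}")
        lines.append(f"gamma_s = {inp.gamma_s!r}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def _fixture_text(name: str) -> str:
    return (resources.files("fepnet.data") / f"{name}.csv").read_text(encoding="utf-8")


def load_fixture(name: str):
    """Load one of the packaged benchmark tables.

    ``"table1"``: docking-score table (DataFrame indexed by ligand id, five
    method columns plus the published consensus columns).
    ``"table2"``: perturbation-network table (network CSV dialect plus a
    ``charge_change`` flag).
    ``"table3"``: thermodynamic cycles with published hysteresis values
    (DataFrame with ``cycle`` tuples, ``hysteresis`` and ``se``).
    """
    if name == "table1":
        df = pd.read_csv(_io.StringIO(_fixture_text("table1")), index_col="ligand")
        return df
    if name == "table2":
        df = pd.read_csv(
            _io.StringIO(_fixture_text("table2")), dtype={"from": str, "to": str}
        )
        return _validate_network_table(df, "table2 fixture")
    if name == "table3":
        df = pd.read_csv(_io.StringIO(_fixture_text("table3")))
        df["cycle"] = df["cycle"].map(lambda s: tuple(s.split("-")))
        return df
    raise KeyError(f"unknown fixture {name!r}; expected table1|table2|table3")


def fixture_cycles() -> list[tuple[str, ...]]:
    """The studied thermodynamic cycles as ligand sequences."""
    return list(load_fixture("table3")["cycle"])
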