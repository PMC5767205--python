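"""Perturbation networks: cycle-closure hysteresis and absolute affinities.

A perturbation network is an undirected graph of ligands whose edges carry
directed relative binding free energies (kJ/mol) with standard errors, in up
to three flavours: ``raw`` (uncorrected), ``corrected`` (after finite-size
charge correction) and ``experimental``.  Traversing an edge against its
stored direction negates the value and preserves the standard error.

The cycle-closure hysteresis — the signed sum of edge values around a closed
loop — vanishes for exact free energies; its magnitude estimates the
sampling error of the calculations.  Relative values are converted to
absolute affinities by anchoring one reference ligand and summing edges
along minimum-edge-count paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CycleResult",
    "PerturbationNetwork",
    "cycle_hysteresis",
    "enumerate_cycles",
    "to_absolute",
]

KINDS = ("raw", "corrected", "experimental")


def _ligand_key(name: str):
    """Natural sort key: numeric ids first, then alphanumeric names."""
    return (0, int(name), "") if name.isdigit() else (1, 0, name)


@dataclass(frozen=True)
class CycleResult:
    cycle: tuple[str, ...]
    hysteresis: float  # kJ/mol
    se: float  # kJ/mol, quadrature over edges


class PerturbationNetwork:
    """Ligand graph with directed edge free energies.

    Edges are stored once with their direction; lookups in either direction
    are handled by :meth:`edge_value`.  Self-edges are rejected.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()

    # -- construction -------------------------------------------------------

    def add_edge(
        self, a: str, b: str, ddg: float, se: float, kind: str = "corrected"
    ) -> None:
        a, b = str(a), str(b)
        if a == b:
            raise ValueError(f"self-edge {a}->{b} not allowed")
        if kind not in KINDS:
            raise ValueError(f"unknown edge kind {kind!r}")
        if se < 0:
            raise ValueError("standard error must be >= 0")
        data = self.graph.get_edge_data(a, b)
        if data is None:
            self.graph.add_edge(a, b, direction=(a, b), values={})
            data = self.graph.get_edge_data(a, b)
        sign = 1.0 if data["direction"] == (a, b) else -1.0
        data["values"][kind] = (sign * float(ddg), float(se))

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "PerturbationNetwork":
        """Build a network from a network-CSV DataFrame (all kinds at once)."""
        net = cls()
        for _, row in table.iterrows():
            a, b = str(row["from"]), str(row["to"])
            net.add_edge(a, b, row["ddg_raw"], row["se_raw"], kind="raw")
            net.add_edge(a, b, row["ddg_corr"], row["se_corr"], kind="corrected")
            if "ddg_exp" in row and pd.notna(row["ddg_exp"]):
                net.add_edge(a, b, row["ddg_exp"], 0.0, kind="experimental")
        return net

    # -- queries -------------------------------------------------------------

    @property
    def ligands(self) -> list[str]:
        return sorted(self.graph.nodes, key=_ligand_key)

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(str(a), str(b))

    def edge_value(self, a: str, b: str, kind: str = "corrected") -> tuple[float, float]:
        """(ddG, se) for traversing a -> b; reversed traversal negates ddG."""
        a, b = str(a), str(b)
        data = self.graph.get_edge_data(a, b)
        if data is None or kind not in data["values"]:
            raise KeyError(f"no {kind} edge between {a} and {b}")
        ddg, se = data["values"][kind]
        sign = 1.0 if data["direction"] == (a, b) else -1.0
        return sign * ddg, se


def cycle_hysteresis(
    net: PerturbationNetwork, cycle, kind: str = "corrected"
) -> CycleResult:
    """Signed sum of edge values around a closed ligand sequence.

    The cycle must start and end at the same ligand and every consecutive
    pair must be a network edge (in either direction); the uncertainty is
    the quadrature sum of the edge standard errors.
    """
    cycle = tuple(str(c) for c in cycle)
    # 2-cycles (A-B-A, the same edge twice) are legal and close exactly
    if len(cycle) < 3 or cycle[0] != cycle[-1]:
        raise ValueError("cycle must close on its first ligand and have >= 2 edges")
    total, var = 0.0, 0.0
    for a, b in zip(cycle[:-1], cycle[1:]):
        try:
            ddg, se = net.edge_value(a, b, kind)
        except KeyError:
            raise KeyError(f"cycle step {a}->{b}: no such edge") from None
        total += ddg
        var += se**2
    return CycleResult(cycle=cycle, hysteresis=total, se=float(np.sqrt(var)))


def _canonical(cycle: tuple[str, ...]) -> tuple[str, ...]:
    """Rotate to the smallest ligand and pick the lexicographically smaller
    direction; the closing ligand is appended."""
    nodes = list(cycle)
    keys = [_ligand_key(n) for n in nodes]
    start = keys.index(min(keys))
    fwd = nodes[start:] + nodes[:start]
    bwd = [fwd[0]] + list(reversed(fwd[1:]))
    best = min(fwd, bwd, key=lambda seq: [_ligand_key(n) for n in seq])
    return tuple(best) + (best[0],)


def enumerate_cycles(net: PerturbationNetwork, max_len: int) -> list[tuple[str, ...]]:
    """All simple cycles with at most ``max_len`` edges, canonicalized.

    Cycles are rotated to start at their smallest ligand id, oriented in the
    lexicographically smaller direction, deduplicated, and returned sorted.
    """
    if max_len < 3:
        raise ValueError("max_len must be >= 3")
    seen = {_canonical(tuple(c)) for c in nx.simple_cycles(net.graph, length_bound=max_len)
            if len(c) >= 3}
    return sorted(seen, key=lambda seq: (len(seq), [_ligand_key(n) for n in seq]))


def to_absolute(
    net: PerturbationNetwork,
    reference: str,
    ref_value: float = 0.0,
    kind: str = "corrected",
) -> dict[str, tuple[float, float]]:
    """Absolute affinities by path summation from a reference ligand.

    Every reachable ligand gets ``ref_value`` plus the signed edge sum along
    the minimum-edge-count path from the reference (ties broken by the
    lexicographically smallest ligand sequence); the uncertainty grows by
    quadrature with path length.  Disconnected ligands are omitted from the
    result rather than raising.
    """
    reference = str(reference)
    if reference not in net.graph:
        raise KeyError(f"reference ligand {reference!r} not in network")
    out: dict[str, tuple[float, float]] = {reference: (float(ref_value), 0.0)}
    for target in net.graph.nodes:
        if target == reference:
            continue
        try:
            paths = nx.all_shortest_paths(net.graph, reference, target)
            path = min(paths, key=lambda p: [_ligand_key(n) for n in p])
        except nx.NetworkXNoPath:
            continue
        value, var = float(ref_value), 0.0
        for a, b in zip(path[:-1], path[1:]):
            ddg, se = net.edge_value(a, b, kind)
            value += ddg
            var += se**2
        out[target] = (value, float(np.sqrt(var)))
    return out
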