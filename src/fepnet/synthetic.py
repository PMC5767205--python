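"""Synthetic inputs with analytically known free energies.

Three generators cover the toolkit's test surface without any simulation
data: Crooks-consistent Gaussian work distributions (exact Delta F by the
fluctuation relation), harmonic-oscillator state chains with exact
independent sampling (Delta f = 1/2 ln(k_j/k_i) analytically), and noisy
perturbation networks over known node values (every cycle hysteresis is a
known Gaussian sum).

All generators are pure functions of their parameters and seed; random
streams are split per state/edge with ``numpy.random.SeedSequence`` spawn
keys, so enlarging a system does not perturb the streams of existing
states.
"""

from __future__ import annotations

import numpy as np

from .io import ReducedPotentialSet
from .network import PerturbationNetwork
from .units import DEFAULT_TEMPERATURE

__all__ = ["gen_gaussian_work", "gen_harmonic_chain", "gen_noisy_network"]


def gen_gaussian_work(
    delta_f: float, sigma: float, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Forward/backward reduced-energy differences satisfying the Crooks
    fluctuation relation.

    forward ~ N(delta_f + sigma^2/2, sigma^2) sampled in the initial state,
    backward ~ N(-delta_f + sigma^2/2, sigma^2) sampled in the final state;
    both one-sided and bidirectional estimators converge to ``delta_f``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    ss = np.random.SeedSequence(seed)
    rng_f, rng_b = (np.random.default_rng(s) for s in ss.spawn(2))
    fwd = rng_f.normal(delta_f + sigma**2 / 2.0, sigma, size=n)
    bwd = rng_b.normal(-delta_f + sigma**2 / 2.0, sigma, size=n)
    return fwd, bwd


def gen_harmonic_chain(
    spring_constants,
    n_per_state: int,
    seed: int,
    temperature: float = DEFAULT_TEMPERATURE,
) -> tuple[ReducedPotentialSet, np.ndarray]:
    """Exact samples from a chain of 1-D harmonic states u_i(x) = k_i x^2/2.

    Each state i is sampled independently from its Boltzmann distribution
    N(0, 1/k_i); the reduced-potential matrix evaluates every sample in all
    states.  Returns ``(data, f_true)`` with the analytic reduced free
    energies f_i = 1/2 ln(k_i/k_0).
    """
    k = np.asarray(spring_constants, dtype=float)
    if np.any(k <= 0):
        raise ValueError("spring constants must be positive")
    if k.size < 2:
        raise ValueError("need at least two states")
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(k.size)]
    xs = np.concatenate(
        [rng.normal(0.0, 1.0 / np.sqrt(ki), size=n_per_state) for rng, ki in zip(rngs, k)]
    )
    states = np.repeat(np.arange(k.size), n_per_state)
    u = 0.5 * k[None, :] * xs[:, None] ** 2
    f_true = 0.5 * np.log(k / k[0])
    data = ReducedPotentialSet(
        u=u, sampled_state=states, temperature=temperature, label="harmonic_chain"
    )
    return data, f_true


def gen_noisy_network(
    true_values: dict[str, float],
    edges,
    sigma: float,
    seed: int,
) -> PerturbationNetwork:
    """Perturbation network with i.i.d. Gaussian edge noise.

    Edge a->b carries ddG = value(b) - value(a) + N(0, sigma^2) and
    se = sigma.  With sigma = 0 every cycle hysteresis is exactly zero and
    path summation recovers ``true_values`` exactly.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    edges = list(edges)
    ss = np.random.SeedSequence(seed)
    net = PerturbationNetwork()
    for spawned, (a, b) in zip(ss.spawn(len(edges)), edges):
        a, b = str(a), str(b)
        if a not in true_values or b not in true_values:
            raise ValueError(f"edge {a}->{b} references an unknown ligand")
        rng = np.random.default_rng(spawned)
        noise = rng.normal(0.0, sigma) if sigma > 0 else 0.0
        ddg = true_values[b] - true_values[a] + noise
        net.add_edge(a, b, ddg, sigma, kind="corrected")
    return net
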