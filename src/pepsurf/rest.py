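"""Replica exchange with solute tempering (REST): ladders, energy scaling,
Metropolis exchange, and a toy demonstration.

In REST only the solute-involving interactions are tempered: replica i runs
at the common bath temperature T0 but on the scaled potential

    E_i = beta_i * Epp + sqrt(beta_i) * Eps + Ess,

with beta_i = T0 / T_i, where Epp, Eps, Ess are the protein-protein,
protein-solvent, and solvent-solvent interaction energies and T_i the
effective temperature of the replica.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

KB_KCAL = 0.0019872041  # kcal / (mol K)


@dataclass(frozen=True)
class EnergyDecomposition:
    """Protein-protein / protein-solvent / solvent-solvent energies
    (kcal/mol)."""

    epp: float
    eps: float
    ess: float


@dataclass
class ReplicaLadder:
    """Geometric effective-temperature ladder with scaling factors
    beta_i = T0 / T_i (beta_0 = 1, strictly decreasing)."""

    t0: float
    temperatures: np.ndarray

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.temperatures[0] != self.t0:
            raise ValueError("ladder must start at T0")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must increase strictly")

    @property
    def betas(self) -> np.ndarray:
        return self.t0 / self.temperatures

    @property
    def n_replicas(self) -> int:
        return len(self.temperatures)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replica": np.arange(self.n_replicas),
                "temperature_K": self.temperatures,
                "beta": self.betas,
            }
        )


def build_ladder(t0: float, tmax: float, n_replicas: int) -> ReplicaLadder:
    """Geometric ladder T_i = T0 * (Tmax/T0)^(i/(n-1)); endpoints exact."""
    if not (tmax > t0 > 0):
        raise ValueError("require Tmax > T0 > 0")
    if n_replicas < 2:
        raise ValueError("need at least 2 replicas")
    i = np.arange(n_replicas)
    temps = t0 * (tmax / t0) ** (i / (n_replicas - 1))
    temps[0], temps[-1] = t0, tmax
    return ReplicaLadder(t0=t0, temperatures=temps)


def scale_energy(decomp: EnergyDecomposition, beta: float) -> float:
    """Scaled replica potential beta*Epp + sqrt(beta)*Eps + Ess."""
    if not 0.0 < beta <= 1.0:
        raise ValueError("beta must be in (0, 1]")
    return beta * decomp.epp + np.sqrt(beta) * decomp.eps + decomp.ess


def exchange_probability(
    decomp_i: EnergyDecomposition,
    decomp_j: EnergyDecomposition,
    beta_i: float,
    beta_j: float,
    t0: float = 300.0,
) -> float:
    """Metropolis acceptance for swapping configurations between replicas.

    Delta = [E_i(x_j) + E_j(x_i)] - [E_i(x_i) + E_j(x_j)], evaluated with
    the scaled potentials at the common bath temperature T0.
    """
    delta = (
        scale_energy(decomp_j, beta_i)
        + scale_energy(decomp_i, beta_j)
        - scale_energy(decomp_i, beta_i)
        - scale_energy(decomp_j, beta_j)
    )
    return float(min(1.0, np.exp(-delta / (KB_KCAL * t0))))


@dataclass(frozen=True)
class DoubleWellLandscape:
    """1D toy system: a double-well 'protein' coordinate x coupled to a
    harmonic 'solvent' coordinate y.

    Epp(x) = barrier * ((x/x0)^2 - 1)^2   (minima at +-x0, barrier at 0)
    Eps(x, y) = k_couple/2 * (x - y)^2
    Ess(y) = k_solvent/2 * y^2

    The double well is symmetric, so the Boltzmann weight of each well is
    exactly 1/2 at any temperature.
    """

    barrier: float = 5.0  # kcal/mol
    x0: float = 1.0
    k_couple: float = 2.0  # kcal/mol/A^2
    k_solvent: float = 2.0

    def epp(self, x):
        return self.barrier * ((x / self.x0) ** 2 - 1.0) ** 2

    def eps(self, x, y):
        return 0.5 * self.k_couple * (x - y) ** 2

    def ess(self, y):
        return 0.5 * self.k_solvent * y**2

    def scaled(self, x, y, beta):
        return beta * self.epp(x) + np.sqrt(beta) * self.eps(x, y) + self.ess(y)


@dataclass
class ToyRestResult:
    """Outcome of a toy REST run.

    ``x`` has shape (n_steps, n_replicas): the protein coordinate occupying
    each ladder slot over time (slot 0 is the physical beta = 1 replica).
    ``walker`` tracks which walker occupies each slot at recorded steps.
    """

    x: np.ndarray
    walker: np.ndarray
    attempts: np.ndarray
    accepts: np.ndarray
    ladder: ReplicaLadder
    seed: int
    params: dict = field(default_factory=dict)

    def acceptance_table(self) -> pd.DataFrame:
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(self.attempts > 0, self.accepts / self.attempts, np.nan)
        return pd.DataFrame(
            {
                "pair": [f"{i}-{i + 1}" for i in range(len(self.attempts))],
                "attempts": self.attempts,
                "accepts": self.accepts,
                "rate": rate,
            }
        )


def count_well_transitions(x: np.ndarray, threshold: float = 0.5) -> int:
    """Well-to-well transitions of a 1D series, with hysteresis at
    +-threshold to ignore barrier-top jitter."""
    x = np.asarray(x, dtype=float)
    inside = x[np.abs(x) >= threshold]
    if len(inside) == 0:
        return 0
    signs = np.sign(inside)
    return int(np.sum(signs[1:] != signs[:-1]))


def toy_rest_run(
    ladder: ReplicaLadder,
    landscape: DoubleWellLandscape | None = None,
    n_steps: int = 30000,
    exchange_every: int | None = 100,
    step_size: float = 0.35,
    seed: int = 0,
) -> ToyRestResult:
    """Metropolis REST dynamics of the double-well toy system.

    Every replica evolves (x, y) by Gaussian-proposal Metropolis moves on
    its scaled potential at the common bath temperature T0; configuration
    swaps between neighbouring ladder slots are attempted every
    ``exchange_every`` steps (alternating pair parity).  Pass
    ``exchange_every=None`` to disable exchanges.
    """
    if landscape is None:
        landscape = DoubleWellLandscape()
    rng = np.random.default_rng(seed)
    betas = ladder.betas
    R = ladder.n_replicas
    kt = KB_KCAL * ladder.t0
    x = rng.choice([-1.0, 1.0], size=R) * landscape.x0
    y = x.copy()
    walker = np.arange(R)
    xs = np.empty((n_steps, R))
    walkers = np.empty((n_steps, R), dtype=int)
    n_pairs = max(R - 1, 0)
    attempts = np.zeros(n_pairs, dtype=int)
    accepts = np.zeros(n_pairs, dtype=int)
    energy = landscape.scaled(x, y, betas)
    for t in range(n_steps):
        for coord in (0, 1):
            if coord == 0:
                prop_x = x + rng.normal(0.0, step_size, R)
                prop_y = y
            else:
                prop_x = x
                prop_y = y + rng.normal(0.0, step_size, R)
            e_new = landscape.scaled(prop_x, prop_y, betas)
            accept = rng.random(R) < np.exp(np.minimum(0.0, -(e_new - energy) / kt))
            x = np.where(accept, prop_x, x)
            y = np.where(accept, prop_y, y)
            energy = np.where(accept, e_new, energy)
        if exchange_every and (t + 1) % exchange_every == 0 and R > 1:
            parity = ((t + 1) // exchange_every) % 2
            for i in range(parity, R - 1, 2):
                j = i + 1
                delta = (
                    landscape.scaled(x[j], y[j], betas[i])
                    + landscape.scaled(x[i], y[i], betas[j])
                    - landscape.scaled(x[i], y[i], betas[i])
                    - landscape.scaled(x[j], y[j], betas[j])
                )
                attempts[i] += 1
                if rng.random() < np.exp(min(0.0, -delta / kt)):
                    accepts[i] += 1
                    x[i], x[j] = x[j], x[i]
                    y[i], y[j] = y[j], y[i]
                    walker[i], walker[j] = walker[j], walker[i]
                    energy[i] = landscape.scaled(x[i], y[i], betas[i])
                    energy[j] = landscape.scaled(x[j], y[j], betas[j])
        xs[t] = x
        walkers[t] = walker
    return ToyRestResult(
        x=xs,
        walker=walkers,
        attempts=attempts,
        accepts=accepts,
        ladder=ladder,
        seed=seed,
        params=dict(
            n_steps=n_steps, exchange_every=exchange_every, step_size=step_size,
            barrier=landscape.barrier,
        ),
    )
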