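"""Single-cell stochastic kinetics of the toxin-antitoxin network.

The intracellular network has three species — free toxin T, free antitoxin
A, and the inert bound complex TA — with toxin and antitoxin synthesis,
reversible binding, and growth-mediated dilution of every species at the
cell's current growth rate.  Growth feeds back on the network through

    g(T, t) = lambda_max * exp(-alpha * T / Omega)

where ``Omega`` is the (dimensionless) cell volume and ``alpha`` sets how
toxic free toxin is: ``alpha = 0`` decouples growth from the network, and
large free-toxin concentrations drive ``g`` toward zero (growth arrest).

Counts are advanced by an exact stochastic simulation within each report
step of length ``dt``, holding ``g`` fixed over the step; the volume then
grows exponentially at the recomputed rate.  Two model variants are
supported: ``unstable_antitoxin`` adds first-order antitoxin degradation,
and ``telegraph`` makes both genes burst via ON/OFF promoter switching with
the mean synthesis rates preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _kernels

__all__ = [
    "LAMBDA_DEFAULT",
    "RateParameters",
    "GrowthLaw",
    "CellState",
    "growth_rate",
    "propensities",
    "step_cell",
    "seed_stochastic",
    "REACTION_LABELS",
]

#: Maximal growth rate (1/min) for a 30-minute doubling time.
LAMBDA_DEFAULT = math.log(2.0) / 30.0

REACTION_LABELS = (
    "toxin_synthesis",
    "antitoxin_synthesis",
    "binding",
    "unbinding",
    "dilution_T",
    "dilution_A",
    "dilution_TA",
    "antitoxin_degradation",
)


@dataclass
class RateParameters:
    """Kinetic constants of the toxin-antitoxin network.

    Defaults are the base-model constants: antitoxin production fixed at
    4.2 /min so that scanning ``k_t`` scans the toxin:antitoxin production
    ratio, binding and unbinding both 0.1, and no antitoxin degradation.
    """

    k_t: float = 0.0   # toxin production, molecules/min
    k_a: float = 4.2   # antitoxin production, molecules/min
    k_b: float = 0.1   # binding, 1/min per molecule pair
    k_u: float = 0.1   # unbinding, 1/min
    d_a: float = 0.0   # antitoxin degradation, 1/min (unstable-antitoxin variant)
    k_on: float = 0.1  # promoter OFF->ON, 1/min (telegraph variant)
    k_off: float = 0.1  # promoter ON->OFF, 1/min (telegraph variant)

    def __post_init__(self) -> None:
        for name in ("k_t", "k_a", "k_b", "k_u", "d_a", "k_on", "k_off"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate parameter {name} must be >= 0")

    @property
    def p_on(self) -> float:
        """Stationary ON probability of a telegraph promoter."""
        return self.k_on / (self.k_on + self.k_off)


@dataclass
class GrowthLaw:
    """Map from free-toxin concentration to cellular growth rate."""

    lambda_max: float = LAMBDA_DEFAULT  # 1/min
    alpha: float = 0.1  # toxicity, volume/molecule

    def __post_init__(self) -> None:
        if self.lambda_max <= 0:
            raise ValueError("lambda_max must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


@dataclass
class CellState:
    """Instantaneous state of one cell agent.

    Volume is dimensionless with newborn volume 1; between divisions
    ``1 <= volume / birth_volume < 2``.
    """

    T: int = 0
    A: int = 0
    TA: int = 0
    volume: float = 1.0
    birth_volume: float = 1.0
    birth_time: float = 0.0
    growth_rate: float = LAMBDA_DEFAULT
    toxin_gene_on: int = 1
    antitoxin_gene_on: int = 1

    @property
    def toxin_concentration(self) -> float:
        """Free toxin per unit volume."""
        return self.T / self.volume


def growth_rate(T: float, omega: float, law: GrowthLaw) -> float:
    """Growth rate ``lambda_max * exp(-alpha * T / omega)`` (1/min)."""
    if T < 0:
        raise ValueError("toxin count must be >= 0")
    if omega <= 0:
        raise ValueError("volume must be > 0")
    return law.lambda_max * math.exp(-law.alpha * T / omega)


def propensities(state: CellState, rates: RateParameters) -> np.ndarray:
    """Per-reaction propensity vector for the base reaction scheme.

    Order matches :data:`REACTION_LABELS`.  Dilution uses the cell's
    current growth rate; bimolecular binding uses raw molecule numbers
    (no volume scaling).
    """
    g = state.growth_rate
    return np.array([
        rates.k_t,
        rates.k_a,
        rates.k_b * state.T * state.A,
        rates.k_u * state.TA,
        g * state.T,
        g * state.A,
        g * state.TA,
        rates.d_a * state.A,
    ])


def seed_stochastic(seed: int) -> None:
    """Seed the compiled kernels' global RNG stream (call once per replicate)."""
    _kernels.seed_kernel(seed)


def step_cell(state: CellState, dt: float, rates: RateParameters,
              law: GrowthLaw, variant: str = "base") -> CellState:
    """Advance one cell by a single report step of ``dt`` minutes.

    Molecule counts evolve by exact SSA over ``[t, t+dt]`` with the growth
    rate frozen at its start-of-step value; the growth rate is then
    recomputed from the new toxin count and the pre-step volume, and the
    volume grows by ``exp(g*dt)`` at the new rate.

    Draws randomness from the kernels' global stream; seed with
    :func:`seed_stochastic` for reproducibility.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if variant == "telegraph":
        kt_on = rates.k_t / rates.p_on
        ka_on = rates.k_a / rates.p_on
        T, A, TA, st, sa = _kernels.ssa_telegraph(
            state.T, state.A, state.TA,
            state.toxin_gene_on, state.antitoxin_gene_on,
            state.growth_rate, dt, kt_on, ka_on,
            rates.k_b, rates.k_u, rates.d_a, rates.k_on, rates.k_off)
    elif variant in ("base", "unstable_antitoxin"):
        T, A, TA = _kernels.ssa_base(
            state.T, state.A, state.TA, state.growth_rate, dt,
            rates.k_t, rates.k_a, rates.k_b, rates.k_u, rates.d_a)
        st, sa = state.toxin_gene_on, state.antitoxin_gene_on
    else:
        raise ValueError(f"unknown variant {variant!r}")
    g = growth_rate(T, state.volume, law)
    return replace(state, T=int(T), A=int(A), TA=int(TA),
                   volume=state.volume * math.exp(g * dt), growth_rate=g,
                   toxin_gene_on=int(st), antitoxin_gene_on=int(sa))
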