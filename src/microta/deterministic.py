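"""Deterministic companion models of threshold growth arrest.

Two minimal models that illustrate the growth-feedback mechanism without
the full agent-based machinery:

* A Hill-form toxin ODE with growth-mediated dilution,

      dT/dt = k_t - [gamma * theta / (theta + T)] * T,

  whose per-capita dilution rate ``gamma*theta/(theta+T)`` falls as toxin
  accumulates.  It has the closed-form steady state
  ``T_hat = k_t*theta / (gamma*theta - k_t)`` when ``k_t < gamma*theta``;
  otherwise production always outpaces dilution, toxin diverges, and the
  cell is driven into growth arrest.

* A generation-based binomial-inheritance model: each generation every cell
  gains a fixed number of molecules and, if still below the arrest
  threshold, divides with its content split Binomial(n, 1/2) between the two
  daughters.  Without a threshold the population regresses to the fixed
  point of m -> (m + production)/2; with a threshold the distribution skews
  as high-count cells stop dividing but keep accumulating.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DeterministicTAParams",
    "BinomialInheritanceConfig",
    "hill_steady_state",
    "hill_growth_rate",
    "hill_rhs",
    "simulate_binomial_inheritance",
]


@dataclass
class DeterministicTAParams:
    k_t: float  # toxin production, molecules/min
    gamma: float  # maximum growth rate, 1/min
    theta: float  # toxicity scale, molecules

    def __post_init__(self) -> None:
        if self.k_t < 0 or self.gamma < 0:
            raise ValueError("k_t and gamma must be >= 0")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")


def hill_growth_rate(T: float, params: DeterministicTAParams) -> float:
    """Per-capita dilution/growth rate ``gamma*theta/(theta+T)``.

    Equals ``gamma`` at T=0 and decreases monotonically toward 0 as toxin
    accumulates (half-saturation at ``T = theta``).
    """
    if T < 0:
        raise ValueError("toxin level must be >= 0")
    return params.gamma * params.theta / (params.theta + T)


def hill_rhs(T: float, params: DeterministicTAParams) -> float:
    """Right-hand side of the toxin ODE, ``k_t - hill_growth_rate(T)*T``."""
    return params.k_t - hill_growth_rate(T, params) * T


def hill_steady_state(params: DeterministicTAParams) -> Optional[float]:
    """Closed-form steady-state toxin level, or ``None`` if none exists.

    A steady state ``T_hat = k_t*theta / (gamma*theta - k_t)`` exists only
    when ``k_t < gamma*theta``; at or above that boundary toxin grows
    without bound and the cell enters growth arrest.
    """
    if params.k_t >= params.gamma * params.theta:
        return None  # growth-arrest regime
    if params.k_t == 0:
        return 0.0
    return params.k_t * params.theta / (params.gamma * params.theta - params.k_t)


@dataclass
class BinomialInheritanceConfig:
    generations: int = 12
    production_per_generation: int = 10
    arrest_threshold: float = 20  # math.inf disables arrest
    initial_counts: Sequence[int] = (0, 10, 20, 30)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.production_per_generation < 0:
            raise ValueError("production_per_generation must be >= 0")
        if any(c < 0 for c in self.initial_counts):
            raise ValueError("initial counts must be >= 0")


def simulate_binomial_inheritance(config: BinomialInheritanceConfig,
                                  rng: Optional[np.random.Generator] = None,
                                  ) -> pd.DataFrame:
    """Run the generation-based inheritance model, one run per initial count.

    Each generation, every cell first gains ``production_per_generation``
    molecules; any cell at or above ``arrest_threshold`` is (permanently)
    arrested and no longer divides, while the rest divide with contents
    partitioned Binomial(n, 1/2).  Molecules are conserved exactly at every
    division.

    Returns a tidy frame with columns ``initial``, ``generation`` (0 = the
    initial state), ``cell``, ``count`` and ``arrested``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    frames = [
        _run_one(config, int(initial), rng).assign(initial=int(initial))
        for initial in config.initial_counts
    ]
    out = pd.concat(frames, ignore_index=True)
    return out[["initial", "generation", "cell", "count", "arrested"]]


def _run_one(config: BinomialInheritanceConfig, initial: int,
             rng: np.random.Generator) -> pd.DataFrame:
    counts = np.array([initial], dtype=np.int64)
    arrested = counts >= config.arrest_threshold
    rows = [(0, i, int(c), bool(a)) for i, (c, a) in enumerate(zip(counts, arrested))]
    for gen in range(1, config.generations + 1):
        counts = counts + config.production_per_generation
        arrested = arrested | (counts >= config.arrest_threshold)
        next_counts: list[int] = []
        next_arrested: list[bool] = []
        for c, a in zip(counts, arrested):
            if a:
                next_counts.append(int(c))
                next_arrested.append(True)
            else:
                left = int(rng.binomial(int(c), 0.5))
                next_counts.extend([left, int(c) - left])
                next_arrested.extend([False, False])
        counts = np.array(next_counts, dtype=np.int64)
        arrested = np.array(next_arrested, dtype=bool)
        rows.extend((gen, i, int(c), bool(a))
                    for i, (c, a) in enumerate(zip(counts, arrested)))
    return pd.DataFrame(rows, columns=["generation", "cell", "count", "arrested"])
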