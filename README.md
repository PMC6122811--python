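# microta

Agent-based simulation of bacterial microcolonies carrying a stochastic
toxin–antitoxin (TA) growth-control module, with the lineage-space
analytics needed to study how genealogy structures phenotype — persister
formation, bet hedging, and growth-arrest clustering — plus a
growth-trajectory fitting pipeline for single-cell microscopy-style length
time series.

## Who this is for

Researchers in microbial systems biology who want a small, fully
reproducible sandbox for threshold-based growth regulation: how binomial
partitioning of a toxin at cell division, coupled to growth-rate feedback,
produces lineage-correlated growth arrest, and how to quantify that
correlation with information-theoretic statistics on the lineage tree.

## The model

Each cell agent carries free toxin T, free antitoxin A, and the inert
complex TA, evolving by exact stochastic simulation of

```
∅ →(k_t) T        ∅ →(k_a) A        T + A ⇌(k_b, k_u) TA
T, A, TA →(g) ∅                      (growth-mediated dilution)
```

with k_a = 4.2 /min, k_b = k_u = 0.1, and k_t the control parameter. The
cell's growth rate follows the toxin concentration instantaneously:

```
g(T, t) = λ · exp(−α · T / Ω),      λ = ln 2 / 30 /min,  α ∈ {0, 0.1, 0.3}
```

where Ω is the cell volume (newborn = 1). Volume grows as dΩ/dt = gΩ; at
Ω = 2× birth volume the cell divides and every molecular species is
partitioned Binomial(n, ½) between the daughters. Colonies start from a
single toxin-free founder with excess antitoxin, grow unstressed for 100
minutes, then face a constant toxin production rate until t = 250 min.
Free toxin above the stoichiometric threshold collapses g — an absorbing
growth-arrested state — and because molecule counts are heritable, arrest
clusters in the lineage.

Two companion deterministic models are included: a Hill-form toxin ODE with
closed-form steady state T̂ = k_t·θ/(γθ − k_t) (no steady state — growth
arrest — when k_t ≥ γθ), and a generation-based binomial-inheritance model
showing regression to the mean without an arrest threshold and skewed
distributions with one.

Analytics: pairwise lineage distance (time since the most recent common
ancestor), plug-in mutual information between phenotype differences and
lineage distance (one random pair per independent simulation, 100
bootstrap resamples), fine/binary population entropy, replicate-averaged
autocorrelation of growing-cell counts with zero-crossing counting,
arrested-cluster extraction in depth-first leaf order with exponential
size-distribution fits, and one-tailed Mann–Whitney U comparisons
(enumeration-exact for small samples, ties included).

## Worked example

```python
import numpy as np
import microta as m
from microta import analytics as an

cfg = m.SimulationConfig(seed=7, rates=m.RateParameters(k_t=5.0))
tree = m.simulate_lineage(cfg)
extant = tree.extant_nodes()
g = np.array([n.growth_rate for n in extant])
print(len(extant))                                        # 23
print(round(np.mean(g <= cfg.arrest_cutoff), 3))          # 0.739
print(sorted(an.arrested_clusters(tree, cfg.arrest_cutoff)))
#   [1, 2, 3, 3, 3, 5]
print(round(an.entropy(g, mode="binary",
                       threshold=cfg.arrest_cutoff), 3))  # 0.828
```

At k_t = 5 /min the colony (8 cells at toxin onset) freezes near 23 cells
by 250 min; ~74% of cells are growth-arrested, and the arrested cells form
contiguous lineage clusters (sizes 1–5) rather than scattering — the
binary growth/arrest entropy of 0.83 bits is close to its 1-bit maximum,
the bet-hedging signature. The same colony at k_t = 0 reaches 256 cells
with no arrest.

From the shell:

```
microta deterministic steady-state --k-t 1.15    # T_hat = 100 molecules
microta simulate --seed 7 --out-dir run/         # lineage CSV + Newick
microta scan --k-min 0 --k-max 8 --k-step 1 --seed 1
microta analyze clusters run/lineage.csv
```

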