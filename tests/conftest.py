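"""Shared fixtures: hand-built toy trees and session-scoped ensembles.

The k_t scan and the large pair-sampling ensembles are expensive, so they
are computed once per session and shared by the analysis tests.
"""

import numpy as np
import pytest

import microta as m
from microta.population import LineageNode, LineageTree

SCAN_GRID = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
SCAN_REPLICATES = 20
MI_GRID = [0.0, 3.0, 3.5, 4.0, 4.5, 8.0]
MI_REPLICATES = 100


def make_node(nid, parent, birth, end=None, divided=False, children=(),
              g=m.LAMBDA_DEFAULT, T=0, A=0, TA=0, vol=1.0, birth_step=0):
    return LineageNode(id=nid, parent=parent, birth_time=birth,
                       birth_volume=vol / 2 if parent >= 0 else 1.0,
                       birth_step=birth_step, end_time=end, divided=divided,
                       children=list(children), T=T, A=A, TA=TA, volume=vol,
                       growth_rate=g)


def four_leaf_tree():
    """Root divides at t=100 -> (1, 2); 1 divides at 120, 2 at 180; 250 end.

    Leaves in depth-first order: 3, 4, 5, 6.
    """
    lam = m.LAMBDA_DEFAULT
    nodes = [
        make_node(0, -1, 0.0, end=100.0, divided=True, children=(1, 2)),
        make_node(1, 0, 100.0, end=120.0, divided=True, children=(3, 4)),
        make_node(2, 0, 100.0, end=180.0, divided=True, children=(5, 6)),
        make_node(3, 1, 120.0, end=250.0, g=lam),
        make_node(4, 1, 120.0, end=250.0, g=lam / 2),
        make_node(5, 2, 180.0, end=250.0, g=0.0),
        make_node(6, 2, 180.0, end=250.0, g=lam),
    ]
    return LineageTree(nodes, dt=0.5, t_end=250.0, t_onset=100.0,
                       record="summary")


def six_leaf_arrest_tree():
    """Six extant cells whose depth-first arrest pattern is 1,1,0,0,1,0."""
    lam = m.LAMBDA_DEFAULT
    arr = 0.0  # growth rate below any positive cutoff
    pattern = [arr, arr, lam, lam, arr, lam]
    nodes = [
        make_node(0, -1, 0.0, end=30.0, divided=True, children=(1, 2)),
        make_node(1, 0, 30.0, end=60.0, divided=True, children=(3, 4)),
        make_node(2, 0, 30.0, end=60.0, divided=True, children=(5, 6)),
        make_node(3, 1, 60.0, end=90.0, divided=True, children=(7, 8)),
        make_node(4, 1, 60.0, end=250.0, g=pattern[2]),
        make_node(5, 2, 60.0, end=90.0, divided=True, children=(9, 10)),
        make_node(6, 2, 60.0, end=250.0, g=pattern[5]),
        make_node(7, 3, 90.0, end=250.0, g=pattern[0]),
        make_node(8, 3, 90.0, end=250.0, g=pattern[1]),
        make_node(9, 5, 90.0, end=250.0, g=pattern[3]),
        make_node(10, 5, 90.0, end=250.0, g=pattern[4]),
    ]
    return LineageTree(nodes, dt=0.5, t_end=250.0, t_onset=100.0,
                       record="summary")


@pytest.fixture(scope="session")
def scan_result():
    """Integer-grid k_t scan, 20 replicates each, with trees retained."""
    cfg = m.SimulationConfig(seed=1202, n_replicates=SCAN_REPLICATES,
                             record="growth")
    df, ensembles = m.scan_toxin_production(SCAN_GRID, cfg, keep_trees=True)
    return df, ensembles, cfg


@pytest.fixture(scope="session")
def mi_ensembles():
    """100-replicate ensembles at selected k_t for pair-sampling analyses."""
    out = {}
    for j, k in enumerate(MI_GRID):
        cfg = m.SimulationConfig(seed=7305 + 13 * j, n_replicates=MI_REPLICATES,
                                 rates=m.RateParameters(k_t=k),
                                 record="summary")
        out[k] = m.run_ensemble(cfg)
    return out


@pytest.fixture(scope="session")
def mi_ensembles_alpha0():
    """Ensembles with growth feedback abolished (alpha = 0)."""
    out = {}
    for j, k in enumerate([0.0, 4.0, 8.0]):
        cfg = m.SimulationConfig(seed=5401 + 17 * j, n_replicates=MI_REPLICATES,
                                 rates=m.RateParameters(k_t=k),
                                 law=m.GrowthLaw(alpha=0.0),
                                 record="summary")
        out[k] = m.run_ensemble(cfg)
    return out
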