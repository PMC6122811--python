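"""Microcolony engine: grow a lineage tree from a single founder.

All extant cells are advanced synchronously on a fixed report grid of step
``dt``.  Within a step each cell's molecule counts evolve by exact SSA with
its growth rate frozen; the rate is then recomputed and the volume grown
exponentially.  A cell divides at the first report time its volume has
doubled relative to birth, partitioning every molecular species
Binomial(n, 1/2) between two daughters (conservation is exact).  The toxin
production rate (and, in the unstable-antitoxin variant, antitoxin
degradation) switches on at ``t_onset`` so the colony first establishes an
antitoxin excess.

Reproducibility: replicate ``i`` of a run with global seed ``s`` uses RNG
streams that are a pure function of ``(s, i)`` — one numpy stream for
divisions and daughter ordering, one compiled-kernel stream for the SSA —
so identical configurations reproduce trees bit-identically regardless of
which replicates are run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _kernels
from .kinetics import (CellState, GrowthLaw, RateParameters, growth_rate,
                       LAMBDA_DEFAULT)

__all__ = [
    "ARREST_CUTOFF_PER_HOUR",
    "arrest_cutoff_per_min",
    "SimulationConfig",
    "LineageNode",
    "LineageTree",
    "PopulationCapError",
    "divide",
    "simulate_lineage",
    "run_ensemble",
    "scan_toxin_production",
    "growing_cell_count_series",
]

#: Growth-rate cutoff below which a cell counts as growth-arrested (1/h).
ARREST_CUTOFF_PER_HOUR = 0.01

VARIANTS = ("base", "unstable_antitoxin", "telegraph")
RECORD_MODES = ("summary", "growth", "full")


def arrest_cutoff_per_min(cutoff_per_hour: float = ARREST_CUTOFF_PER_HOUR) -> float:
    """Convert the arrest cutoff from 1/h (as conventionally quoted) to 1/min."""
    return cutoff_per_hour / 60.0


class PopulationCapError(RuntimeError):
    """Raised when a lineage exceeds the configured hard population cap."""


@dataclass
class SimulationConfig:
    """Full parameterization of a microcolony simulation.

    ``initial_antitoxin`` defaults to the pre-onset stationary mean
    ``round(k_a / lambda_max)`` so the founder starts with the antitoxin
    excess of a long-growing unstressed cell.
    """

    rates: RateParameters = field(default_factory=RateParameters)
    law: GrowthLaw = field(default_factory=GrowthLaw)
    dt: float = 0.5            # report step, min
    t_onset: float = 100.0     # toxin production switch-on, min
    t_end: float = 250.0       # end of simulation, min
    n_replicates: int = 1
    seed: int = 0
    variant: str = "base"
    initial_antitoxin: Optional[int] = None
    population_cap: int = 5000
    record: str = "growth"     # summary | growth | full
    arrest_cutoff_per_hour: float = ARREST_CUTOFF_PER_HOUR

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not self.t_onset < self.t_end:
            raise ValueError("t_onset must be < t_end")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.record not in RECORD_MODES:
            raise ValueError(f"record must be one of {RECORD_MODES}")
        if self.population_cap < 1:
            raise ValueError("population_cap must be >= 1")
        if self.initial_antitoxin is None:
            self.initial_antitoxin = int(round(self.rates.k_a /
                                               self.law.lambda_max))
        if self.initial_antitoxin < 0:
            raise ValueError("initial_antitoxin must be >= 0")

    @property
    def arrest_cutoff(self) -> float:
        """Arrest cutoff in 1/min."""
        return arrest_cutoff_per_min(self.arrest_cutoff_per_hour)


@dataclass
class LineageNode:
    """One cell of a recorded lineage tree."""

    id: int
    parent: int                 # -1 for the founder
    birth_time: float
    birth_volume: float
    birth_step: int
    birth_T: int = 0            # counts inherited at birth; the two
    birth_A: int = 0            # daughters' birth counts sum exactly to
    birth_TA: int = 0           # the parent's final counts
    end_time: Optional[float] = None
    divided: bool = False
    children: List[int] = field(default_factory=list)
    # final state (at division or at t_end)
    T: int = 0
    A: int = 0
    TA: int = 0
    volume: float = 1.0
    growth_rate: float = LAMBDA_DEFAULT
    # optional per-report-step histories, aligned to steps
    # birth_step+1 .. end_step (the steps during which the cell was advanced)
    g_history: Optional[List[float]] = None
    state_history: Optional[List[Tuple[int, int, int, float]]] = None

    @property
    def toxin_concentration(self) -> float:
        return self.T / self.volume


class LineageTree:
    """Time-stamped binary genealogy of a simulated microcolony."""

    def __init__(self, nodes: List[LineageNode], dt: float, t_end: float,
                 t_onset: float, record: str = "growth"):
        self.nodes = nodes
        self.dt = dt
        self.t_end = t_end
        self.t_onset = t_onset
        self.record = record

    # -- structure ---------------------------------------------------------

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))

    @property
    def root(self) -> LineageNode:
        return self.nodes[0]

    def extant_nodes(self) -> List[LineageNode]:
        """Cells alive at ``t_end`` (the colony's final population)."""
        return [n for n in self.nodes if not n.divided]

    def leaves_in_order(self) -> List[LineageNode]:
        """Extant cells in depth-first order (the lineage-neighbor order)."""
        out: List[LineageNode] = []
        stack = [0]
        while stack:
            node = self.nodes[stack.pop()]
            if node.divided:
                stack.extend(reversed(node.children))
            else:
                out.append(node)
        return out

    def population_at(self, t: float) -> int:
        """Number of cells present at time ``t`` (daughters count from their
        birth instant, the parent up to it)."""
        eps = 1e-9
        return sum(1 for n in self.nodes
                   if n.birth_time <= t + eps
                   and (not n.divided or n.end_time > t + eps))

    def lineage_distance(self, i: int, j: int,
                         at_time: Optional[float] = None) -> float:
        """Time since the most recent common ancestor of cells ``i``, ``j``.

        Both cells must coexist at ``at_time`` (default ``t_end``).  The
        distance is ``at_time`` minus the division time of the MRCA; it is
        symmetric and zero only for a cell paired with itself.
        """
        if at_time is None:
            at_time = self.t_end
        if i == j:
            return 0.0
        for c in (i, j):
            if not 0 <= c < len(self.nodes):
                raise KeyError(f"cell {c} not in tree")
            n = self.nodes[c]
            end = n.end_time if n.divided else self.t_end
            if not (n.birth_time <= at_time + 1e-9 <= end + 2e-9):
                raise ValueError(f"cell {c} not extant at t={at_time}")
        path_i = [i]
        while self.nodes[path_i[-1]].parent >= 0:
            path_i.append(self.nodes[path_i[-1]].parent)
        pos = {node: k for k, node in enumerate(path_i)}
        node = j
        while node not in pos:
            node = self.nodes[node].parent
        mrca = self.nodes[node]
        if not mrca.divided:  # can only happen for i == j, guarded above
            raise ValueError("cells do not have a divided common ancestor")
        return at_time - mrca.end_time

    # -- per-time series ---------------------------------------------------

    def growth_rate_matrix(self) -> Tuple[np.ndarray, np.ndarray]:
        """(times, counts-compatible growth-rate table) helper.

        Returns the report-time grid (steps 1..n_steps) and a list, per
        step, of the growth rates of the cells advanced during that step.
        Requires ``record`` mode ``growth`` or ``full``.
        """
        if self.record == "summary":
            raise ValueError("growth histories were not recorded")
        n_steps = self.n_steps
        per_step: List[List[float]] = [[] for _ in range(n_steps)]
        for node in self.nodes:
            hist = node.g_history or []
            for k, g in enumerate(hist):
                per_step[node.birth_step + k].append(g)
        times = (np.arange(1, n_steps + 1)) * self.dt
        return times, per_step

    def growing_cell_count_series(self, cutoff: Optional[float] = None
                                  ) -> Tuple[np.ndarray, np.ndarray]:
        """Number of growing cells (g > cutoff, 1/min) at each report time."""
        if cutoff is None:
            cutoff = arrest_cutoff_per_min()
        if cutoff < 0:
            raise ValueError("cutoff must be >= 0")
        times, per_step = self.growth_rate_matrix()
        counts = np.array([sum(1 for g in step if g > cutoff)
                           for step in per_step])
        return times, counts

    # -- export ------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format record: one row per cell per report time.

        With ``record='full'`` the rows carry counts and volume; with
        ``record='growth'`` only the growth rate; the final row of every
        cell always carries its final state.
        """
        rows = []
        for n in self.nodes:
            end = n.end_time if n.end_time is not None else self.t_end
            if self.record == "full" and n.state_history:
                for k, (T, A, TA, vol) in enumerate(n.state_history):
                    t = (n.birth_step + k + 1) * self.dt
                    rows.append((n.id, n.parent, t, T, A, TA, vol,
                                 n.g_history[k]))
            elif self.record == "growth" and n.g_history:
                for k, g in enumerate(n.g_history):
                    t = (n.birth_step + k + 1) * self.dt
                    rows.append((n.id, n.parent, t, np.nan, np.nan, np.nan,
                                 np.nan, g))
            rows.append((n.id, n.parent, end, n.T, n.A, n.TA, n.volume,
                         n.growth_rate))
        df = pd.DataFrame(rows, columns=["cell_id", "parent_id", "time", "T",
                                         "A", "TA", "volume", "growth_rate"])
        return df.drop_duplicates(subset=["cell_id", "time"], keep="last")

    def summary_frame(self) -> pd.DataFrame:
        """One row per cell: identity, times, and final state."""
        rows = [(n.id, n.parent, n.birth_time,
                 n.end_time if n.end_time is not None else self.t_end,
                 n.divided, n.T, n.A, n.TA, n.volume, n.growth_rate)
                for n in self.nodes]
        return pd.DataFrame(rows, columns=[
            "cell_id", "parent_id", "birth_time", "end_time", "divided",
            "T", "A", "TA", "volume", "growth_rate"])

    def to_newick(self, arrest_cutoff: Optional[float] = None) -> str:
        """Newick string with branch lengths = cell lifetimes (minutes).

        Each node carries annotations: final growth rate ``g``, final free
        toxin concentration ``toxin_conc``, and an ``arrested`` flag.
        """
        import dendropy

        if arrest_cutoff is None:
            arrest_cutoff = arrest_cutoff_per_min()
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)

        def annotate(dnode, n: LineageNode):
            dnode.annotations.add_new("g", f"{n.growth_rate:.6g}")
            dnode.annotations.add_new("toxin_conc",
                                      f"{n.toxin_concentration:.6g}")
            dnode.annotations.add_new(
                "arrested", int(n.growth_rate <= arrest_cutoff))

        dmap = {}
        for n in self.nodes:  # parents precede children by construction
            if n.parent < 0:
                dnode = tree.seed_node
            else:
                dnode = dmap[n.parent].new_child()
            end = n.end_time if n.end_time is not None else self.t_end
            dnode.edge.length = end - n.birth_time
            if not n.divided:
                dnode.taxon = taxa.new_taxon(label=f"c{n.id}")
            annotate(dnode, n)
            dmap[n.id] = dnode
        return tree.as_string(schema="newick", suppress_annotations=False,
                              suppress_rooting=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, dt: Optional[float] = None,
                   t_onset: float = 100.0) -> "LineageTree":
        """Rebuild a tree from the long-format frame written by
        :meth:`to_frame` (children keep their recorded order)."""
        if dt is None:
            times = np.sort(df["time"].unique())
            dt = float(np.min(np.diff(times))) if len(times) > 1 else 0.5
        t_end = float(df["time"].max())
        nodes: List[LineageNode] = []
        for cell_id, grp in df.groupby("cell_id", sort=True):
            grp = grp.sort_values("time")
            first, last = grp.iloc[0], grp.iloc[-1]
            birth_time = float(first["time"]) - dt
            node = LineageNode(
                id=int(cell_id), parent=int(first["parent_id"]),
                birth_time=birth_time if int(first["parent_id"]) >= 0 else 0.0,
                birth_volume=np.nan,
                birth_step=int(round(birth_time / dt)) if int(first["parent_id"]) >= 0 else 0,
                end_time=float(last["time"]),
                T=int(last["T"]) if pd.notna(last["T"]) else 0,
                A=int(last["A"]) if pd.notna(last["A"]) else 0,
                TA=int(last["TA"]) if pd.notna(last["TA"]) else 0,
                volume=float(last["volume"]) if pd.notna(last["volume"]) else np.nan,
                growth_rate=float(last["growth_rate"]),
                g_history=list(grp["growth_rate"].astype(float)),
            )
            nodes.append(node)
        nodes.sort(key=lambda n: n.id)
        by_id = {n.id: n for n in nodes}
        order = {n.id: k for k, n in enumerate(nodes)}
        for n in nodes:
            if n.parent >= 0:
                by_id[n.parent].children.append(n.id)
                by_id[n.parent].divided = True
        for n in nodes:  # preserve recorded child order (already by id asc;
            n.children.sort(key=lambda c: order[c])  # ids encode order)
        for n in nodes:
            if n.divided and n.end_time is None:
                n.end_time = max(by_id[c].birth_time for c in n.children)
        return cls(nodes, dt=dt, t_end=t_end, t_onset=t_onset,
                   record="growth")


def divide(parent: CellState, rng: np.random.Generator, law: GrowthLaw,
           time: Optional[float] = None) -> Tuple[CellState, CellState]:
    """Split a doubled cell into two daughters by binomial partitioning.

    Every species count ``n`` is distributed Binomial(n, 1/2) to the first
    daughter with the remainder to the second, so conservation is exact.
    Each daughter takes half the parent volume and has its growth rate
    recomputed from its own toxin count.  Promoter states are inherited.
    """
    if parent.volume < 2.0 * parent.birth_volume - 1e-9:
        raise ValueError("cell has not doubled its birth volume yet")
    if time is None:
        time = parent.birth_time
    half = parent.volume / 2.0
    t1 = int(rng.binomial(parent.T, 0.5))
    a1 = int(rng.binomial(parent.A, 0.5))
    ta1 = int(rng.binomial(parent.TA, 0.5))

    def mk(T, A, TA):
        return CellState(T=T, A=A, TA=TA, volume=half, birth_volume=half,
                         birth_time=time, growth_rate=growth_rate(T, half, law),
                         toxin_gene_on=parent.toxin_gene_on,
                         antitoxin_gene_on=parent.antitoxin_gene_on)

    return (mk(t1, a1, ta1),
            mk(parent.T - t1, parent.A - a1, parent.TA - ta1))


def _replicate_streams(seed: int, replicate: int
                       ) -> Tuple[np.random.Generator, int]:
    """Independent (numpy, kernel) streams as a pure function of (seed, i)."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(replicate,))
    py_child, kernel_child = ss.spawn(2)
    kernel_seed = int(kernel_child.generate_state(1, np.uint32)[0] % (2**31))
    return np.random.default_rng(py_child), kernel_seed


def simulate_lineage(config: SimulationConfig, replicate: int = 0
                     ) -> LineageTree:
    """Grow one microcolony from a single founder and record its genealogy.

    The founder starts with no toxin, ``initial_antitoxin`` free antitoxin
    molecules, and unit volume.  Toxin production (and antitoxin
    degradation, if any) is zero before ``t_onset``.
    """
    rng, kernel_seed = _replicate_streams(config.seed, replicate)
    _kernels.seed_kernel(kernel_seed)

    rates, law = config.rates, config.law
    dt = config.dt
    n_steps = int(round(config.t_end / dt))
    telegraph = config.variant == "telegraph"
    record = config.record

    p_on = rates.p_on if telegraph else 1.0
    founder_st = int(rng.random() < p_on) if telegraph else 1
    founder_sa = int(rng.random() < p_on) if telegraph else 1

    founder = LineageNode(id=0, parent=-1, birth_time=0.0, birth_volume=1.0,
                          birth_step=0, birth_A=config.initial_antitoxin,
                          A=config.initial_antitoxin,
                          growth_rate=law.lambda_max)
    if record != "summary":
        founder.g_history = []
        if record == "full":
            founder.state_history = []
    nodes = [founder]

    # dynamic state arrays for live cells, aligned with live_ids
    live_ids = [0]
    T = np.array([0], dtype=np.int64)
    A = np.array([config.initial_antitoxin], dtype=np.int64)
    TA = np.array([0], dtype=np.int64)
    st = np.array([founder_st], dtype=np.int64)
    sa = np.array([founder_sa], dtype=np.int64)
    g = np.array([law.lambda_max], dtype=np.float64)
    vol = np.array([1.0], dtype=np.float64)
    birth_vol = np.array([1.0], dtype=np.float64)

    for step in range(1, n_steps + 1):
        t_start = (step - 1) * dt
        stressed = t_start >= config.t_onset - 1e-9
        kt_eff = rates.k_t if stressed else 0.0
        da_eff = rates.d_a if stressed else 0.0
        kt_on = kt_eff / p_on
        ka_on = rates.k_a / p_on
        n_live = len(live_ids)
        _kernels.advance_cells(T, A, TA, st, sa, g, vol, n_live, dt,
                               kt_eff, rates.k_a, rates.k_b, rates.k_u,
                               da_eff, law.lambda_max, law.alpha,
                               telegraph, kt_on, ka_on,
                               rates.k_on, rates.k_off)
        if record != "summary":
            for i in range(n_live):
                node = nodes[live_ids[i]]
                node.g_history.append(float(g[i]))
                if record == "full":
                    node.state_history.append(
                        (int(T[i]), int(A[i]), int(TA[i]), float(vol[i])))

        div_mask = vol[:n_live] >= 2.0 * birth_vol[:n_live]
        if div_mask.any():
            t_now = step * dt
            keep = dict(ids=[], T=[], A=[], TA=[], st=[], sa=[], g=[],
                        vol=[], bvol=[])
            for i in range(n_live):
                node = nodes[live_ids[i]]
                if not div_mask[i]:
                    keep["ids"].append(live_ids[i])
                    for key, arr in (("T", T), ("A", A), ("TA", TA),
                                     ("st", st), ("sa", sa), ("g", g),
                                     ("vol", vol), ("bvol", birth_vol)):
                        keep[key].append(arr[i])
                    continue
                parent_state = CellState(
                    T=int(T[i]), A=int(A[i]), TA=int(TA[i]),
                    volume=float(vol[i]), birth_volume=float(birth_vol[i]),
                    birth_time=node.birth_time, growth_rate=float(g[i]),
                    toxin_gene_on=int(st[i]), antitoxin_gene_on=int(sa[i]))
                d1, d2 = divide(parent_state, rng, law, time=t_now)
                if rng.random() < 0.5:  # randomize recorded daughter order
                    d1, d2 = d2, d1
                node.end_time = t_now
                node.divided = True
                node.T, node.A, node.TA = parent_state.T, parent_state.A, parent_state.TA
                node.volume = parent_state.volume
                node.growth_rate = parent_state.growth_rate
                for d in (d1, d2):
                    child = LineageNode(
                        id=len(nodes), parent=node.id, birth_time=t_now,
                        birth_volume=d.birth_volume, birth_step=step,
                        birth_T=d.T, birth_A=d.A, birth_TA=d.TA,
                        T=d.T, A=d.A, TA=d.TA, volume=d.volume,
                        growth_rate=d.growth_rate)
                    if record != "summary":
                        child.g_history = []
                        if record == "full":
                            child.state_history = []
                    node.children.append(child.id)
                    nodes.append(child)
                    keep["ids"].append(child.id)
                    keep["T"].append(d.T)
                    keep["A"].append(d.A)
                    keep["TA"].append(d.TA)
                    keep["st"].append(d.toxin_gene_on)
                    keep["sa"].append(d.antitoxin_gene_on)
                    keep["g"].append(d.growth_rate)
                    keep["vol"].append(d.volume)
                    keep["bvol"].append(d.birth_volume)
            live_ids = keep["ids"]
            T = np.array(keep["T"], dtype=np.int64)
            A = np.array(keep["A"], dtype=np.int64)
            TA = np.array(keep["TA"], dtype=np.int64)
            st = np.array(keep["st"], dtype=np.int64)
            sa = np.array(keep["sa"], dtype=np.int64)
            g = np.array(keep["g"], dtype=np.float64)
            vol = np.array(keep["vol"], dtype=np.float64)
            birth_vol = np.array(keep["bvol"], dtype=np.float64)
            if len(live_ids) > config.population_cap:
                raise PopulationCapError(
                    f"population {len(live_ids)} exceeds the hard cap "
                    f"{config.population_cap} at t={t_now:.1f} min; raise "
                    f"population_cap or shorten t_end")

    for i, cid in enumerate(live_ids):  # finalize survivors
        node = nodes[cid]
        node.end_time = config.t_end
        node.T, node.A, node.TA = int(T[i]), int(A[i]), int(TA[i])
        node.volume = float(vol[i])
        node.growth_rate = float(g[i])

    return LineageTree(nodes, dt=dt, t_end=config.t_end,
                       t_onset=config.t_onset, record=record)


def run_ensemble(config: SimulationConfig) -> List[LineageTree]:
    """Run ``config.n_replicates`` independent lineages (replicate ``i``'s
    randomness is a pure function of ``(config.seed, i)``)."""
    return [simulate_lineage(config, replicate=i)
            for i in range(config.n_replicates)]


def _condition_seed(seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(index, 0xC0FFEE))
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def scan_toxin_production(k_grid: Sequence[float], config: SimulationConfig,
                          n_replicates: Optional[int] = None,
                          keep_trees: bool = False):
    """Scan the toxin production rate over ``k_grid``.

    For each ``k_t`` runs an independent replicate ensemble and summarizes
    the extant population at ``t_end``: mean and SD (across replicates) of
    the population-mean growth rate and free-toxin concentration, the
    arrested cell fraction, and population sizes at onset and at the end.

    Returns the summary :class:`pandas.DataFrame`; with ``keep_trees=True``
    also returns the per-``k_t`` tree ensembles (memory permitting).
    """
    from dataclasses import replace as _dc_replace

    if len(k_grid) == 0:
        raise ValueError("k_grid must be non-empty")
    if n_replicates is None:
        n_replicates = config.n_replicates
    cutoff = config.arrest_cutoff
    rows = []
    ensembles = {}
    for j, k_t in enumerate(k_grid):
        cond = _dc_replace(
            config, rates=_dc_replace(config.rates, k_t=float(k_t)),
            n_replicates=n_replicates,
            seed=_condition_seed(config.seed, j))
        trees = run_ensemble(cond)
        mean_g, mean_c, arrested, pop_end, pop_onset = [], [], [], [], []
        for tree in trees:
            extant = tree.extant_nodes()
            gs = np.array([n.growth_rate for n in extant])
            cs = np.array([n.toxin_concentration for n in extant])
            mean_g.append(gs.mean())
            mean_c.append(cs.mean())
            arrested.append(np.mean(gs <= cutoff))
            pop_end.append(len(extant))
            pop_onset.append(tree.population_at(config.t_onset))
        rows.append((float(k_t), np.mean(mean_g), np.std(mean_g),
                     np.mean(mean_c), np.std(mean_c), np.mean(arrested),
                     np.mean(pop_end), np.mean(pop_onset)))
        if keep_trees:
            ensembles[float(k_t)] = trees
    df = pd.DataFrame(rows, columns=[
        "k_t", "mean_growth_rate", "sd_growth_rate", "mean_toxin_conc",
        "sd_toxin_conc", "arrested_fraction", "mean_population_end",
        "mean_population_onset"])
    return (df, ensembles) if keep_trees else df


def growing_cell_count_series(tree: LineageTree,
                              cutoff: Optional[float] = None
                              ) -> Tuple[np.ndarray, np.ndarray]:
    """Module-level alias for :meth:`LineageTree.growing_cell_count_series`."""
    return tree.growing_cell_count_series(cutoff)
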