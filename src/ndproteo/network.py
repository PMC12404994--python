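"""Signed Boolean regulatory-network construction, dynamics, reconstruction
and in-silico perturbation.

A disease network starts from a confidence-filtered protein-protein
interaction (PPI) graph over FDR-significant proteins, each carrying a
Booleanized expression state (1 = increased in disease, 0 = decreased).
STRING-style PPIs are undirected and unsigned; the reconstruction step
searches, with a genetic algorithm, for an orientation/sign assignment (or
removal) of every edge such that the observed state vector is a fixed point
of the Boolean dynamics, preferring parsimonious networks that still explain
as many nodes as possible. Upstream regulators are then ranked by the number
of downstream states that flip when the regulator's own state is inverted
and held (the perturbation score).

Boolean update rule (inhibitor-dominant, the default): a node with at least
one parent becomes 1 iff some activating parent is 1 and no inhibiting
parent is 1; a node without parents holds its state. A majority rule
(sum of signed parent states) is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx

from .containers import PipelineError, SpecificationError, rng_for

ACTIVATE = 1
INHIBIT = -1

# chromosome gene values for one undirected edge (a, b)
GENE_ABSENT = 0
GENE_AB_ACT = 1
GENE_AB_INH = 2
GENE_BA_ACT = 3
GENE_BA_INH = 4


@dataclass
class SignedBooleanNetwork:
    """Directed signed graph plus observed binary node states."""

    graph: nx.DiGraph
    states: dict
    clamped: set = field(default_factory=set)

    def __post_init__(self) -> None:
        for u, v in self.graph.edges():
            if u == v:
                raise SpecificationError(f"self-loop at node {u!r}")
            if self.graph.edges[u, v].get("sign") not in (ACTIVATE, INHIBIT):
                raise SpecificationError(f"edge ({u}, {v}) lacks a sign")
        for node in self.graph.nodes():
            if self.states.get(node) not in (0, 1):
                raise SpecificationError(f"node {node!r} lacks a binary state")

    @property
    def nodes(self):
        return list(self.graph.nodes())

    def to_sif_frame(self) -> pd.DataFrame:
        rows = [(u, "activates" if d["sign"] == ACTIVATE else "inhibits", v)
                for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["source", "interaction", "target"])


@dataclass
class SimulationResult:
    final_states: dict
    n_steps: int
    reached_cycle: bool
    cycle_length: int = 0


def _step(graph: nx.DiGraph, states: dict, clamped: dict,
          rule: str) -> dict:
    nxt = {}
    for v in graph.nodes():
        if v in clamped:
            nxt[v] = clamped[v]
            continue
        parents = list(graph.predecessors(v))
        if not parents:
            nxt[v] = states[v]
            continue
        if rule == "inhibitor_dominant":
            act = any(states[p] == 1 and graph.edges[p, v]["sign"] == ACTIVATE
                      for p in parents)
            inh = any(states[p] == 1 and graph.edges[p, v]["sign"] == INHIBIT
                      for p in parents)
            nxt[v] = 1 if (act and not inh) else 0
        elif rule == "majority":
            total = sum(graph.edges[p, v]["sign"] * states[p] for p in parents)
            nxt[v] = 1 if total > 0 else (0 if total < 0 else states[v])
        else:
            raise SpecificationError(f"unknown update rule {rule!r}")
    return nxt


def simulate_dynamics(network: SignedBooleanNetwork, initial_states: dict,
                      clamped_nodes: dict | None = None,
                      rule: str = "inhibitor_dominant",
                      max_steps: int | None = None) -> SimulationResult:
    """Run synchronous Boolean updates to a fixed point or a cycle.

    ``clamped_nodes`` maps node -> value held fixed for the whole run. On a
    cycle, each node's reported final state is its majority value over the
    cycle, ties resolved to the node's initial (t=0) state.
    """
    graph = network.graph
    clamped = dict(clamped_nodes or {})
    states = {v: int(initial_states[v]) for v in graph.nodes()}
    for v, val in clamped.items():
        states[v] = int(val)
    init = dict(states)
    if max_steps is None:
        max_steps = 2 ** min(len(states), 20) + len(states) + 4

    seen: dict[tuple, int] = {}
    trajectory = []
    key_order = list(graph.nodes())

    def key(s):
        return tuple(s[v] for v in key_order)

    for step in range(max_steps + 1):
        k = key(states)
        if k in seen:
            start = seen[k]
            cycle = trajectory[start:]
            if len(cycle) == 1:  # fixed point
                return SimulationResult(dict(states), step, False, 0)
            final = {}
            half = len(cycle) / 2.0
            for idx, v in enumerate(key_order):
                ones = sum(s[idx] for s in cycle)
                if ones > half:
                    final[v] = 1
                elif ones < half:
                    final[v] = 0
                else:
                    final[v] = init[v]
            return SimulationResult(final, step, True, len(cycle))
        seen[k] = len(trajectory)
        trajectory.append(k)
        states = _step(graph, states, clamped, rule)
    raise PipelineError("simulation exceeded max_steps")  # pragma: no cover


# ---------------------------------------------------------------------------
# graph construction from association results + STRING-style interactions
# ---------------------------------------------------------------------------

def collapse_aptamers(assoc_tables: dict, annotation: pd.DataFrame):
    """Pick one representative aptamer per protein: the aptamer with the
    lowest FDR q across all supplied disease tables (ties by aptamer id)."""
    ann = annotation.set_index("aptamer_id")["protein"]
    qmin = None
    for tab in assoc_tables.values():
        q = tab.set_index("aptamer")["q"]
        qmin = q if qmin is None else np.minimum(qmin, q.reindex(qmin.index))
    qmin = qmin.dropna()
    frame = pd.DataFrame({"q": qmin})
    frame["protein"] = ann.reindex(frame.index)
    frame = frame.dropna(subset=["protein"]).sort_index().sort_values(
        "q", kind="stable")
    reps = frame.groupby("protein", sort=True).head(1)
    return {p: a for a, p in reps["protein"].items()}


def build_graph(interactions: pd.DataFrame, assoc_tables: dict,
                annotation: pd.DataFrame, q_threshold: float = 0.05,
                min_score: float = 0.7):
    """Confidence-filtered PPI graph over significant proteins with
    Booleanized node states.

    A protein enters the graph when its representative aptamer is
    FDR-significant in every supplied association table; its state is the
    sign of the effect in the table where that aptamer is most significant.
    Edges below ``min_score`` are dropped (boundary inclusive), then
    singleton nodes and isolated pairs are removed.

    Returns ``(graph, info)`` where ``graph`` is an undirected
    ``networkx.Graph`` with a ``state`` attribute per node.
    """
    reps = collapse_aptamers(assoc_tables, annotation)
    states = {}
    excluded_zero_beta = []
    for protein, aptamer in reps.items():
        sig = True
        best_q, best_beta = np.inf, np.nan
        for tab in assoc_tables.values():
            row = tab.loc[tab["aptamer"] == aptamer]
            if row.empty or not (row["q"].iloc[0] < q_threshold):
                sig = False
                break
            if row["q"].iloc[0] < best_q:
                best_q = row["q"].iloc[0]
                best_beta = row["beta"].iloc[0]
        if not sig:
            continue
        if best_beta == 0:
            excluded_zero_beta.append(protein)
            continue
        states[protein] = 1 if best_beta > 0 else 0

    g = nx.Graph()
    g.add_nodes_from(states)
    scores = interactions["combined_score"].astype(float)
    if scores.max() > 1.0:
        scores = scores / 1000.0
    for (a, b), s in zip(
            interactions[["protein1", "protein2"]].itertuples(index=False),
            scores):
        if s >= min_score and a in states and b in states and a != b:
            g.add_edge(a, b, combined_score=float(s))

    # drop disconnected proteins and isolated pairs
    for comp in list(nx.connected_components(g)):
        if len(comp) <= 2:
            g.remove_nodes_from(comp)
    nx.set_node_attributes(g, {v: states[v] for v in g.nodes()}, "state")
    info = {
        "excluded_zero_beta": excluded_zero_beta,
        "n_significant_proteins": len(states),
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
    }
    return g, info


# ---------------------------------------------------------------------------
# GA reconstruction
# ---------------------------------------------------------------------------

@dataclass
class GAParams:
    population: int = 100
    generations: int = 300
    mutation_rate: float = 0.02
    crossover_rate: float = 0.7
    parsimony_weight: float = 0.05   # cost per retained edge
    explain_weight: float = 0.25     # reward per node with >= 1 parent
    elitism: int = 2
    tournament: int = 3
    restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise SpecificationError("population must be >= 2")
        for name in ("mutation_rate", "crossover_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecificationError(f"{name} must be in [0, 1]")
        if self.parsimony_weight < 0:
            raise SpecificationError("parsimony_weight must be >= 0")


class _FitnessEvaluator:
    """Vectorized fitness for chromosome populations.

    fitness = (#nodes whose observed state is a fixed point of the update
    rule given their parents' observed states) + explain_weight * (#nodes
    with at least one parent) - parsimony_weight * (#retained edges).
    """

    def __init__(self, graph: nx.Graph, states: dict, params: GAParams):
        self.nodes = sorted(graph.nodes())
        self.node_idx = {v: i for i, v in enumerate(self.nodes)}
        self.edges = sorted(tuple(sorted(e)) for e in graph.edges())
        self.state_vec = np.array([states[v] for v in self.nodes], dtype=bool)
        self.params = params
        n_e = len(self.edges)
        # per edge, per gene value: does it make b (resp. a) a child, and
        # does it supply an active activating/inhibiting input?
        self.par_a = np.zeros((n_e, 5), dtype=bool)
        self.par_b = np.zeros((n_e, 5), dtype=bool)
        self.act_a = np.zeros((n_e, 5), dtype=bool)
        self.act_b = np.zeros((n_e, 5), dtype=bool)
        self.inh_a = np.zeros((n_e, 5), dtype=bool)
        self.inh_b = np.zeros((n_e, 5), dtype=bool)
        self.ai = np.zeros(n_e, dtype=int)
        self.bi = np.zeros(n_e, dtype=int)
        for e, (a, b) in enumerate(self.edges):
            sa = bool(states[a])
            sb = bool(states[b])
            self.ai[e], self.bi[e] = self.node_idx[a], self.node_idx[b]
            self.par_b[e, [GENE_AB_ACT, GENE_AB_INH]] = True
            self.par_a[e, [GENE_BA_ACT, GENE_BA_INH]] = True
            self.act_b[e, GENE_AB_ACT] = sa
            self.inh_b[e, GENE_AB_INH] = sa
            self.act_a[e, GENE_BA_ACT] = sb
            self.inh_a[e, GENE_BA_INH] = sb

    def fitness(self, pop: np.ndarray):
        """Fitness and consistency fraction for a (P, n_edges) population."""
        pop = np.atleast_2d(pop)
        n_pop = pop.shape[0]
        n_nodes = len(self.nodes)
        par = np.zeros((n_pop, n_nodes), dtype=bool)
        act = np.zeros((n_pop, n_nodes), dtype=bool)
        inh = np.zeros((n_pop, n_nodes), dtype=bool)
        for e in range(len(self.edges)):
            g = pop[:, e]
            a, b = self.ai[e], self.bi[e]
            par[:, a] |= self.par_a[e, g]
            par[:, b] |= self.par_b[e, g]
            act[:, a] |= self.act_a[e, g]
            act[:, b] |= self.act_b[e, g]
            inh[:, a] |= self.inh_a[e, g]
            inh[:, b] |= self.inh_b[e, g]
        nxt = np.where(par, act & ~inh, self.state_vec[None, :])
        consistent = (nxt == self.state_vec[None, :]).sum(axis=1)
        n_edges_used = (pop != GENE_ABSENT).sum(axis=1)
        fit = (consistent
               + self.params.explain_weight * par.sum(axis=1)
               - self.params.parsimony_weight * n_edges_used)
        return fit, consistent / max(n_nodes, 1)

    def decode(self, chrom: np.ndarray, states: dict) -> SignedBooleanNetwork:
        dg = nx.DiGraph()
        dg.add_nodes_from(self.nodes)
        for e, gene in enumerate(chrom):
            a, b = self.edges[e]
            if gene == GENE_AB_ACT:
                dg.add_edge(a, b, sign=ACTIVATE)
            elif gene == GENE_AB_INH:
                dg.add_edge(a, b, sign=INHIBIT)
            elif gene == GENE_BA_ACT:
                dg.add_edge(b, a, sign=ACTIVATE)
            elif gene == GENE_BA_INH:
                dg.add_edge(b, a, sign=INHIBIT)
        return SignedBooleanNetwork(dg, dict(states))


def enumerate_optimum(graph: nx.Graph, states: dict, params: GAParams,
                      batch: int = 65536):
    """Exhaustive search over all 5^|E| chromosomes (small graphs only)."""
    ev = _FitnessEvaluator(graph, states, params)
    n_e = len(ev.edges)
    if n_e > 10:
        raise SpecificationError("exhaustive search limited to <= 10 edges")
    total = 5 ** n_e
    best_fit, best_chrom = -np.inf, None
    powers = 5 ** np.arange(n_e)
    for start in range(0, total, batch):
        idx = np.arange(start, min(start + batch, total))
        pop = (idx[:, None] // powers[None, :]) % 5
        fit, _ = ev.fitness(pop)
        k = int(np.argmax(fit))
        if fit[k] > best_fit:
            best_fit = float(fit[k])
            best_chrom = pop[k].copy()
    return best_fit, best_chrom


def reconstruct_boolean(graph: nx.Graph, states: dict,
                        params: GAParams | None = None):
    """Genetic-algorithm search for a signed orientation of the PPI skeleton
    under which the observed states are self-consistent.

    Returns ``(network, consistency, details)`` with ``consistency`` the
    fraction of nodes whose observed state matches its Boolean update given
    the observed parent states.
    """
    params = params or GAParams()
    if graph.number_of_nodes() == 0:
        raise PipelineError("cannot reconstruct an empty graph")
    ev = _FitnessEvaluator(graph, states, params)
    n_e = len(ev.edges)
    if n_e == 0:
        net = ev.decode(np.zeros(0, dtype=int), states)
        return net, 1.0, {"fitness": float(len(ev.nodes)), "restarts": []}

    best = None
    restart_fits = []
    for r in range(max(params.restarts, 1)):
        rng = rng_for(params.seed, f"ga-restart-{r}")
        pop = rng.integers(0, 5, size=(params.population, n_e))
        pop[0] = GENE_ABSENT  # seed the always-consistent empty network
        fit, cons = ev.fitness(pop)
        for _ in range(params.generations):
            order = np.argsort(fit)[::-1]
            elite = pop[order[:params.elitism]]
            # tournament selection
            cand = rng.integers(0, params.population,
                                size=(2 * params.population, params.tournament))
            winners = cand[np.arange(cand.shape[0]),
                           np.argmax(fit[cand], axis=1)]
            parents = pop[winners].reshape(2, params.population, n_e)
            # uniform crossover
            cross = rng.random(params.population) < params.crossover_rate
            mask = rng.random((params.population, n_e)) < 0.5
            children = np.where(mask, parents[0], parents[1])
            children[~cross] = parents[0][~cross]
            # per-gene mutation
            mut = rng.random((params.population, n_e)) < params.mutation_rate
            children[mut] = rng.integers(0, 5, size=int(mut.sum()))
            children[:params.elitism] = elite
            pop = children
            fit, cons = ev.fitness(pop)
        k = int(np.argmax(fit))
        restart_fits.append(float(fit[k]))
        if best is None or fit[k] > best[0]:
            best = (float(fit[k]), float(cons[k]), pop[k].copy())

    net = ev.decode(best[2], states)
    details = {"fitness": best[0], "restarts": restart_fits,
               "plateau": len(set(np.round(restart_fits, 9))) == 1}
    return net, best[1], details


# ---------------------------------------------------------------------------
# perturbation ranking
# ---------------------------------------------------------------------------

def rank_perturbagens(network: SignedBooleanNetwork,
                      rule: str = "inhibitor_dominant") -> pd.DataFrame:
    """Rank every node by how many downstream states flip when the node is
    clamped to the opposite of its observed state.

    Score = number of nodes (other than the perturbagen) reachable from it
    whose steady state differs from the observed state. Ties are broken by
    out-degree, then node id.
    """
    g = network.graph
    observed = network.states
    # when the observed states are a fixed point, nothing outside the
    # perturbagen's reachable set can move — checked as a sanity invariant
    baseline = simulate_dynamics(network, dict(observed), rule=rule)
    at_fixed_point = (not baseline.reached_cycle
                      and baseline.final_states == observed)
    rows = []
    for v in g.nodes():
        reachable = nx.descendants(g, v)
        res = simulate_dynamics(network, dict(observed),
                                clamped_nodes={v: 1 - observed[v]}, rule=rule)
        flipped = [u for u in reachable
                   if u != v and res.final_states[u] != observed[u]]
        stray = {u for u in g.nodes()
                 if u != v and u not in reachable
                 and res.final_states[u] != observed[u]}
        if at_fixed_point and stray:
            raise PipelineError(f"flips outside reachable set of {v}: {stray}")
        rows.append({"node": v, "score": len(flipped),
                     "out_degree": g.out_degree(v),
                     "flipped": sorted(flipped)})
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(["score", "out_degree", "node"],
                              ascending=[False, False, True],
                              kind="stable").reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame
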