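"""Exhaustive synchronous attractor analysis in simplified mode.

With all delays zero the model is a plain synchronous Boolean network: the
global state is one bit per gene and the successor function applies every
rule to the current protein snapshot at once.  Because the successor is a
function, the state graph is a functional graph: every trajectory ends on a
unique cycle (an attractor — a point attractor if the cycle has period 1),
and the basins of all attractors partition the full state space of ``2^n``
states.  Attractors are found by the exhaustive method: every initial
condition's trajectory is followed to its cycle.

States are encoded as integers with the gene roster defining bit order
(gene 0 of the roster = least significant bit).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .grn import ConfigError, RuleSet

#: refuse to materialise state graphs above this roster size
DEFAULT_GENE_CAP = 20


@dataclass(frozen=True)
class GlobalState:
    """A full Boolean assignment over a roster, encodable as an integer."""

    genes: tuple[str, ...]
    code: int

    def __post_init__(self):
        if not 0 <= self.code < (1 << len(self.genes)):
            raise ConfigError(f"state code {self.code} out of range for {len(self.genes)} genes")

    @classmethod
    def from_set(cls, genes: Sequence[str], on: Sequence[str]) -> "GlobalState":
        on = set(on)
        unknown = on - set(genes)
        if unknown:
            raise ConfigError(f"unknown genes in state: {sorted(unknown)}")
        code = sum(1 << i for i, g in enumerate(genes) if g in on)
        return cls(tuple(genes), code)

    def as_set(self) -> frozenset[str]:
        return frozenset(g for i, g in enumerate(self.genes) if (self.code >> i) & 1)


@dataclass
class StateGraph:
    """The functional graph of the synchronous successor over all 2^n states."""

    genes: tuple[str, ...]
    successors: np.ndarray  # successors[s] = successor code of state s

    @property
    def n_states(self) -> int:
        return len(self.successors)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_edges_from((int(s), int(t)) for s, t in enumerate(self.successors))
        return g

    def to_edge_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"state": np.arange(self.n_states), "successor": self.successors}
        )


@dataclass(frozen=True)
class Attractor:
    """A cycle of distinct global states; ``basin_size`` counts every state
    whose trajectory reaches the cycle (``None`` if basins were not computed)."""

    genes: tuple[str, ...]
    cycle: tuple[int, ...]
    basin_size: int | None = None

    @property
    def period(self) -> int:
        return len(self.cycle)

    def states_as_sets(self) -> list[frozenset[str]]:
        return [GlobalState(self.genes, c).as_set() for c in self.cycle]

    def canonical(self) -> "Attractor":
        """Rotate so the smallest encoded state comes first."""
        i = self.cycle.index(min(self.cycle))
        return Attractor(self.genes, self.cycle[i:] + self.cycle[:i], self.basin_size)


def classify_attractor(attractor: Attractor) -> str:
    """'point' for period 1, otherwise 'cycle'."""
    return "point" if attractor.period == 1 else "cycle"


def _require_simplified(ruleset: RuleSet):
    if not ruleset.is_simplified:
        raise ConfigError(
            "attractor analysis requires simplified mode (all delays 0); "
            "use RuleSet.with_delays('simplified')"
        )


def successor_state(
    ruleset: RuleSet, state: GlobalState, timer_values: Mapping[str, bool] | None = None
) -> GlobalState:
    """Synchronous successor of one global state (simplified mode)."""
    _require_simplified(ruleset)
    genes = ruleset.gene_names
    if state.genes != genes:
        raise ConfigError("state roster does not match the rule set")
    tv = dict(timer_values or {})
    on = state.as_set()

    def protein(g: str) -> bool:
        if g not in genes:
            raise ConfigError(f"protein({g}) not in roster")
        return g in on

    def inputs(x: str) -> bool:
        try:
            return bool(tv[x])
        except KeyError:
            raise ConfigError(f"input({x}) not supplied")

    code = 0
    for i, g in enumerate(genes):
        if ruleset.rules[g].expression.evaluate(protein, inputs):
            code |= 1 << i
    return GlobalState(genes, code)


def _successor_table(
    ruleset: RuleSet, timer_values: Mapping[str, bool] | None, cap: int
) -> np.ndarray:
    """Vectorised successor codes for all 2^n states."""
    _require_simplified(ruleset)
    genes = ruleset.gene_names
    n = len(genes)
    if n > cap:
        raise ConfigError(
            f"{n} genes exceeds the {cap}-gene cap for exhaustive analysis; "
            "use trajectory_to_attractor for single initial conditions"
        )
    tv = dict(timer_values or {})
    states = np.arange(1 << n, dtype=np.int64)
    bits = {g: ((states >> i) & 1).astype(bool) for i, g in enumerate(genes)}

    def protein(g: str):
        try:
            return bits[g]
        except KeyError:
            raise ConfigError(f"protein({g}) not in roster")

    def inputs(x: str):
        try:
            return np.broadcast_to(bool(tv[x]), states.shape)
        except KeyError:
            raise ConfigError(f"input({x}) not supplied")

    succ = np.zeros(len(states), dtype=np.int64)
    for i, g in enumerate(genes):
        val = ruleset.rules[g].expression.evaluate(protein, inputs)
        val = np.broadcast_to(val, states.shape)
        succ |= val.astype(np.int64) << i
    return succ


def build_state_graph(
    ruleset: RuleSet,
    timer_values: Mapping[str, bool] | None = None,
    cap: int = DEFAULT_GENE_CAP,
) -> StateGraph:
    """The full functional graph over all 2^n global states."""
    return StateGraph(ruleset.gene_names, _successor_table(ruleset, timer_values, cap))


def find_attractors_exhaustive(
    ruleset: RuleSet,
    timer_values: Mapping[str, bool] | None = None,
    cap: int = DEFAULT_GENE_CAP,
) -> list[Attractor]:
    """All attractors with exact basin sizes, smallest-state-first ordering.

    Follows the trajectory from every initial condition (the exhaustive
    method), memoising the attractor each visited state drains to.
    """
    succ = _successor_table(ruleset, timer_values, cap)
    n_states = len(succ)
    # attractor id per state; -1 unknown
    owner = np.full(n_states, -1, dtype=np.int64)
    cycles: list[tuple[int, ...]] = []
    for start in range(n_states):
        if owner[start] != -1:
            continue
        path = []
        pos_in_path: dict[int, int] = {}
        s = start
        while owner[s] == -1 and s not in pos_in_path:
            pos_in_path[s] = len(path)
            path.append(s)
            s = int(succ[s])
        if owner[s] != -1:
            aid = int(owner[s])
        else:
            entry = pos_in_path[s]
            cycle = tuple(path[entry:])
            aid = len(cycles)
            cycles.append(cycle)
        for v in path:
            owner[v] = aid
    basins = np.bincount(owner, minlength=len(cycles))
    attractors = [
        Attractor(ruleset.gene_names, cyc, int(basins[aid])).canonical()
        for aid, cyc in enumerate(cycles)
    ]
    attractors.sort(key=lambda a: a.cycle[0])
    return attractors


def trajectory_to_attractor(
    ruleset: RuleSet,
    initial: GlobalState,
    timer_values: Mapping[str, bool] | None = None,
) -> tuple[list[GlobalState], Attractor]:
    """Transient prefix and the attractor reached from one initial state.

    The transient is the maximal prefix before the first state that repeats;
    the returned attractor has no basin size (compute it with
    :func:`find_attractors_exhaustive` if needed).
    """
    genes = ruleset.gene_names
    seen: dict[int, int] = {}
    order: list[int] = []
    s = initial
    while s.code not in seen:
        seen[s.code] = len(order)
        order.append(s.code)
        s = successor_state(ruleset, s, timer_values)
    entry = seen[s.code]
    transient = [GlobalState(genes, c) for c in order[:entry]]
    attractor = Attractor(genes, tuple(order[entry:])).canonical()
    return transient, attractor
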