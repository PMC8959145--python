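"""Boolean cellular-row simulator with RNA/protein delay semantics.

The embryo is idealised as a one-dimensional row of autonomous cells.  Each
cell carries, per gene, a Boolean RNA state and a Boolean protein state with
age counters; regulatory rules read *protein* states (transcription-factor
logic) plus extrinsic timer inputs, and every gene in every cell is updated
synchronously from the time-``t`` snapshot.

Delay semantics
---------------
Let ``rule(t)`` be a gene's regulatory rule evaluated on the time-``t``
protein/timer snapshot, and let ``s(t+1)`` be the number of steps since the
rule last held (0 if it held at ``t``).  Then

* ``RNA(t+1)`` is on iff ``s(t+1) <= rna_decay_delay`` — transcription turns
  on immediately when the rule holds, and the transcript persists
  ``rna_decay_delay`` extra steps after the rule last held;
* protein is on once RNA has been continuously on for at least
  ``synthesis_delay`` prior steps, and it persists ``protein_decay_delay``
  steps after RNA switches off (a fresh RNA pulse must again accumulate
  ``synthesis_delay`` steps before protein reappears).

With all three delays zero the protein trajectory collapses onto the RNA
trajectory and the model reduces to a plain synchronous Boolean network on
the rule values ("simplified mode", used for attractor analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .logic import Formula, FormulaError, parse_formula


class ConfigError(ValueError):
    """Raised when a rule set, tissue or schedule is inconsistent."""


# ---------------------------------------------------------------------------
# rule-set types


@dataclass(frozen=True)
class GeneSpec:
    """A gene's identity and its three delay parameters (in time-steps)."""

    name: str
    synthesis_delay: int = 0
    rna_decay_delay: int = 0
    protein_decay_delay: int = 0

    def __post_init__(self):
        for attr in ("synthesis_delay", "rna_decay_delay", "protein_decay_delay"):
            v = getattr(self, attr)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigError(f"gene {self.name}: {attr} must be a non-negative integer, got {v!r}")


@dataclass(frozen=True)
class RegulatoryRule:
    target: str
    expression: Formula

    @classmethod
    def parse(cls, target: str, text: str) -> "RegulatoryRule":
        return cls(target, parse_formula(text))


#: named delay presets: (synthesis, rna_decay, protein_decay)
DELAY_PRESETS: dict[str, tuple[int, int, int]] = {
    # multi-step expression consistent with an 8-phase, 40-step oscillation
    # of the pair-rule ring (5 steps per phase)
    "framework": (2, 3, 3),
    # transcription-translation gap ignored: plain synchronous network
    "simplified": (0, 0, 0),
}


@dataclass(frozen=True)
class RuleSet:
    """A gene roster, the timer inputs it reads, and one rule per gene."""

    genes: tuple[GeneSpec, ...]
    inputs: tuple[str, ...]
    rules: Mapping[str, RegulatoryRule]

    def __post_init__(self):
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate gene names in roster: {names}")
        if len(set(self.inputs)) != len(self.inputs):
            raise ConfigError(f"duplicate inputs: {self.inputs}")
        if set(self.rules) != set(names):
            missing = set(names) - set(self.rules)
            orphan = set(self.rules) - set(names)
            raise ConfigError(f"rules must cover the roster exactly; missing={sorted(missing)}, orphan={sorted(orphan)}")
        for rule in self.rules.values():
            for kind, ref in rule.expression.literals():
                if kind == "protein" and ref not in names:
                    raise ConfigError(f"rule for {rule.target}: protein({ref}) references an undeclared gene")
                if kind == "input" and ref not in self.inputs:
                    raise ConfigError(f"rule for {rule.target}: input({ref}) references an undeclared input")

    @property
    def gene_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.genes)

    @property
    def is_simplified(self) -> bool:
        return all(
            g.synthesis_delay == 0 and g.rna_decay_delay == 0 and g.protein_decay_delay == 0
            for g in self.genes
        )

    def spec(self, gene: str) -> GeneSpec:
        for g in self.genes:
            if g.name == gene:
                return g
        raise KeyError(gene)

    def with_delays(self, preset: str | tuple[int, int, int]) -> "RuleSet":
        """Return a copy with every gene's delays replaced by a preset."""
        sy, rd, pd = DELAY_PRESETS[preset] if isinstance(preset, str) else preset
        genes = tuple(
            replace(g, synthesis_delay=sy, rna_decay_delay=rd, protein_decay_delay=pd)
            for g in self.genes
        )
        return RuleSet(genes, self.inputs, self.rules)


def make_ruleset(
    rules: Mapping[str, str],
    inputs: Sequence[str] = (),
    delays: str | tuple[int, int, int] = "simplified",
    per_gene_delays: Mapping[str, tuple[int, int, int]] | None = None,
) -> RuleSet:
    """Convenience constructor from ``{gene: rule string}``."""
    sy, rd, pd = DELAY_PRESETS[delays] if isinstance(delays, str) else delays
    genes = []
    for name in rules:
        gsy, grd, gpd = (per_gene_delays or {}).get(name, (sy, rd, pd))
        genes.append(GeneSpec(name, gsy, grd, gpd))
    parsed = {name: RegulatoryRule.parse(name, text) for name, text in rules.items()}
    return RuleSet(tuple(genes), tuple(inputs), parsed)


# ---------------------------------------------------------------------------
# per-gene / per-cell state


@dataclass(frozen=True)
class GeneState:
    """Boolean RNA/protein state of one gene in one cell, with age counters.

    ``rna_age`` / ``protein_age`` count how many *additional* steps the
    current Boolean value has been held (0 right after a flip);
    ``steps_since_rule_true`` is 0 whenever the rule held on the step that
    produced this state.  Counters saturate one step beyond the largest
    behavioural threshold, so long-held states are literal fixed points.
    """

    rna_on: bool = False
    protein_on: bool = False
    rna_age: int = 0
    protein_age: int = 0
    steps_since_rule_true: int = 0

    def __post_init__(self):
        if min(self.rna_age, self.protein_age, self.steps_since_rule_true) < 0:
            raise ConfigError("age counters must be non-negative")

    @classmethod
    def off(cls, spec: GeneSpec) -> "GeneState":
        """A long-silent gene: all decay windows expired."""
        sat = _age_cap(spec)
        return cls(
            rna_on=False,
            protein_on=False,
            rna_age=sat,
            protein_age=sat,
            steps_since_rule_true=spec.rna_decay_delay + 1,
        )

    @classmethod
    def on_mature(cls, spec: GeneSpec) -> "GeneState":
        """A gene with established expression: RNA and protein both on."""
        sat = _age_cap(spec)
        return cls(
            rna_on=True,
            protein_on=True,
            rna_age=sat,
            protein_age=sat,
            steps_since_rule_true=0,
        )


def _age_cap(spec: GeneSpec) -> int:
    return max(spec.synthesis_delay, spec.protein_decay_delay) + 1


@dataclass(frozen=True)
class CellState:
    index: int
    states: Mapping[str, GeneState]


@dataclass(frozen=True)
class TissueState:
    cells: tuple[CellState, ...]
    time: int = 0

    def __post_init__(self):
        for pos, cell in enumerate(self.cells):
            if cell.index != pos:
                raise ConfigError(f"cell indices must be 0..N-1 in order; cell at {pos} has index {cell.index}")
        rosters = {frozenset(c.states) for c in self.cells}
        if len(rosters) > 1:
            raise ConfigError("all cells must share the same gene roster")


def make_tissue(
    ruleset: RuleSet, n_cells: int, on_genes: Iterable[Iterable[str]] | None = None
) -> TissueState:
    """Build a time-0 tissue; ``on_genes[c]`` lists genes mature-ON in cell c."""
    on_genes = list(on_genes) if on_genes is not None else [()] * n_cells
    if len(on_genes) != n_cells:
        raise ConfigError(f"on_genes has {len(on_genes)} entries for {n_cells} cells")
    cells = []
    for c in range(n_cells):
        on = set(on_genes[c])
        unknown = on - set(ruleset.gene_names)
        if unknown:
            raise ConfigError(f"cell {c}: unknown genes {sorted(unknown)}")
        states = {
            g.name: (GeneState.on_mature(g) if g.name in on else GeneState.off(g))
            for g in ruleset.genes
        }
        cells.append(CellState(c, states))
    return TissueState(tuple(cells), time=0)


# ---------------------------------------------------------------------------
# update semantics


def evaluate_rule(rule: RegulatoryRule, cell: CellState, timer_values: Mapping[str, bool]) -> bool:
    """Evaluate a rule on a cell's protein snapshot; pure."""

    def protein(gene: str) -> bool:
        try:
            return cell.states[gene].protein_on
        except KeyError:
            raise ConfigError(f"rule for {rule.target}: protein({gene}) not resolvable in cell {cell.index}")

    def inputs(name: str) -> bool:
        try:
            return bool(timer_values[name])
        except KeyError:
            raise ConfigError(f"rule for {rule.target}: input({name}) not supplied")

    return bool(rule.expression.evaluate(protein, inputs))


def update_gene_state(state: GeneState, rule_value: bool, spec: GeneSpec) -> GeneState:
    """One synchronous step of the delay semantics for a single gene."""
    sat = _age_cap(spec)
    s_next = 0 if rule_value else min(state.steps_since_rule_true + 1, spec.rna_decay_delay + 1)
    rna_next = s_next <= spec.rna_decay_delay

    if rna_next == state.rna_on:
        rna_age_next = min(state.rna_age + 1, sat)
    else:
        rna_age_next = 0

    if rna_next:
        # rna_age counts steps held beyond the first ON step
        protein_next = rna_age_next >= spec.synthesis_delay
    else:
        protein_next = state.protein_on and rna_age_next < spec.protein_decay_delay

    protein_age_next = min(state.protein_age + 1, sat) if protein_next == state.protein_on else 0
    return GeneState(
        rna_on=rna_next,
        protein_on=protein_next,
        rna_age=rna_age_next,
        protein_age=protein_age_next,
        steps_since_rule_true=s_next,
    )


def step_tissue(tissue: TissueState, ruleset: RuleSet, schedule=None) -> TissueState:
    """Synchronous update of every gene in every cell from the time-t snapshot.

    ``schedule`` may be a :class:`~boolseg.timers.TimerSchedule`, a plain
    ``{input: bool}`` mapping (frozen timer values), or ``None`` when the
    rule set reads no inputs.
    """
    roster = set(ruleset.gene_names)
    new_cells = []
    for cell in tissue.cells:
        if set(cell.states) != roster:
            raise ConfigError(f"cell {cell.index} roster does not match the rule set")
        timer_values = _timer_values(schedule, ruleset.inputs, cell.index, tissue.time)
        new_states = {}
        for g in ruleset.genes:
            rv = evaluate_rule(ruleset.rules[g.name], cell, timer_values)
            new_states[g.name] = update_gene_state(cell.states[g.name], rv, g)
        new_cells.append(CellState(cell.index, new_states))
    return TissueState(tuple(new_cells), time=tissue.time + 1)


def _timer_values(schedule, inputs: Sequence[str], cell: int, time: int) -> dict[str, bool]:
    if schedule is None:
        return {}
    if isinstance(schedule, Mapping):
        return {k: bool(v) for k, v in schedule.items()}
    return {name: schedule.state_at(name, cell, time) for name in inputs}


# ---------------------------------------------------------------------------
# simulation result


@dataclass
class SimulationResult:
    """Space-time Boolean record of a run: arrays indexed [time, cell, gene]."""

    rna: np.ndarray
    protein: np.ndarray
    gene_order: tuple[str, ...]
    n_cells: int = field(init=False)
    n_steps: int = field(init=False)

    def __post_init__(self):
        if self.rna.shape != self.protein.shape:
            raise ConfigError("rna and protein arrays must have identical shape")
        self.n_cells = self.rna.shape[1]
        self.n_steps = self.rna.shape[0] - 1

    def layer(self, name: str) -> np.ndarray:
        if name not in ("rna", "protein"):
            raise ValueError(f"layer must be 'rna' or 'protein', got {name!r}")
        return self.rna if name == "rna" else self.protein


def simulate(ruleset: RuleSet, initial: TissueState, schedule=None, n_steps: int = 0) -> SimulationResult:
    """Run ``n_steps`` synchronous steps and record every state, t=0 included."""
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    order = ruleset.gene_names
    n_cells = len(initial.cells)
    rna = np.zeros((n_steps + 1, n_cells, len(order)), dtype=bool)
    protein = np.zeros_like(rna)
    tissue = initial
    for t in range(n_steps + 1):
        for c, cell in enumerate(tissue.cells):
            for gi, g in enumerate(order):
                rna[t, c, gi] = cell.states[g].rna_on
                protein[t, c, gi] = cell.states[g].protein_on
        if t < n_steps:
            tissue = step_tissue(tissue, ruleset, schedule)
    return SimulationResult(rna=rna, protein=protein, gene_order=order)


def expressed_set(result: SimulationResult, time: int, cell: int, layer: str = "rna") -> frozenset[str]:
    """The set of genes ON in the chosen layer at (time, cell)."""
    arr = result.layer(layer)
    if not (0 <= time < arr.shape[0]) or not (0 <= cell < arr.shape[1]):
        raise IndexError(f"(time={time}, cell={cell}) out of range for shape {arr.shape[:2]}")
    row = arr[time, cell]
    return frozenset(g for g, on in zip(result.gene_order, row) if on)
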