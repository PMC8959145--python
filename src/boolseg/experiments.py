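"""Drivers for the in-silico experiments.

* timer-regime runs: broad-stripe prepattern + simultaneous vs progressive
  cad/opa dynamics, summarised by the spatial repeat period of the final
  pattern and per-cell maturation times;
* late-network cell fates: per-cell attractors of the opa-frozen late
  network from scenario fixtures (C1..C8);
* the prepattern-dependency check: does patterning survive when part of the
  initial stripe pattern is withheld?
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .attractors import Attractor, GlobalState, classify_attractor, trajectory_to_attractor
from .grn import ConfigError, RuleSet, SimulationResult, TissueState, expressed_set, simulate
from .timers import TimerSchedule

#: sentinel returned when no spatial period divides the trimmed core
NO_PERIOD = None


# ---------------------------------------------------------------------------
# pattern measurement


def measure_repeat_period(
    result: SimulationResult,
    time: int = -1,
    layer: str = "rna",
    margin: int = 8,
) -> int | None:
    """Smallest p >= 1 such that every core cell's expressed-set equals that
    of the cell p positions away; uniform patterns give 1, aperiodic cores
    give the ``NO_PERIOD`` sentinel.

    Candidate periods run to half the trimmed core so that every accepted
    period is confirmed over at least one full repeat."""
    arr = result.layer(layer)
    if time < 0:
        time = arr.shape[0] + time
    n_cells = arr.shape[1]
    core = arr[time, margin : n_cells - margin]
    if len(core) < 2:
        raise ConfigError(f"margin {margin} leaves fewer than 2 cells of a {n_cells}-cell row")
    for p in range(1, len(core) // 2 + 1):
        if (core[:-p] == core[p:]).all():
            return p
    return NO_PERIOD


def maturation_profile(result: SimulationResult, layer: str = "both") -> np.ndarray:
    """Per cell, the first step from which its expression state never changes
    again (cells still changing at the end of the run get the last step).

    ``layer`` may be 'rna', 'protein' or 'both' (default: a cell counts as
    mature only once RNA and protein have both settled)."""
    if layer == "both":
        arr = np.concatenate([result.rna, result.protein], axis=2)
    else:
        arr = result.layer(layer)
    n_t, n_cells, _ = arr.shape
    changed = (arr[1:] != arr[:-1]).any(axis=2)  # [t, cell]: change at step t+1
    mat = np.zeros(n_cells, dtype=int)
    for c in range(n_cells):
        nz = np.nonzero(changed[:, c])[0]
        mat[c] = (nz[-1] + 1) if len(nz) else 0
    return mat


def final_stripe_widths(result: SimulationResult, layer: str = "rna") -> dict[str, list[int]]:
    """Lengths of the maximal ON-runs of each gene in the final pattern."""
    arr = result.layer(layer)[-1]
    widths: dict[str, list[int]] = {}
    for gi, g in enumerate(result.gene_order):
        col = arr[:, gi]
        runs, n = [], 0
        for v in col:
            if v:
                n += 1
            elif n:
                runs.append(n)
                n = 0
        if n:
            runs.append(n)
        widths[g] = runs
    return widths


@dataclass
class PatternSummary:
    """Summary statistics of a space-time run."""

    repeat_period: int | None
    maturation_time: np.ndarray
    stripe_widths: dict[str, list[int]]
    margin: int

    @property
    def maturation_monotone(self) -> bool:
        core = self.maturation_time[self.margin : len(self.maturation_time) - self.margin]
        return bool((np.diff(core) >= 0).all()) if len(core) > 1 else True

    @property
    def maturation_uniform(self) -> bool:
        core = self.maturation_time[self.margin : len(self.maturation_time) - self.margin]
        return bool((core == core[0]).all()) if len(core) else True


def run_timer_experiment(
    ruleset: RuleSet,
    initial: TissueState,
    schedule: TimerSchedule,
    n_steps: int,
    margin: int = 8,
) -> tuple[SimulationResult, PatternSummary]:
    """Full space-time run plus pattern summary."""
    n_cells = len(initial.cells)
    if n_cells == 0:
        empty = simulate(ruleset, initial, schedule, 0)
        return empty, PatternSummary(NO_PERIOD, np.zeros(0, dtype=int), {}, margin)
    if schedule.n_cells != n_cells:
        raise ConfigError(
            f"schedule covers {schedule.n_cells} cells but the row has {n_cells}"
        )
    result = simulate(ruleset, initial, schedule, n_steps)
    summary = PatternSummary(
        repeat_period=measure_repeat_period(result, margin=margin),
        maturation_time=maturation_profile(result),
        stripe_widths=final_stripe_widths(result),
        margin=margin,
    )
    return result, summary


# ---------------------------------------------------------------------------
# late-network cell fates


@dataclass
class CellFate:
    cell: str
    initial: frozenset[str]
    transient_steps: int
    attractor: Attractor

    @property
    def kind(self) -> str:
        return classify_attractor(self.attractor)

    def gene_fate(self, gene: str) -> str:
        """'on' | 'off' | 'cycling' in the attractor."""
        states = self.attractor.states_as_sets()
        on = sum(gene in s for s in states)
        if on == len(states):
            return "on"
        if on == 0:
            return "off"
        return "cycling"


@dataclass
class CellFateTable:
    scenario: str
    fates: dict[str, CellFate]

    def genes(self) -> tuple[str, ...]:
        first = next(iter(self.fates.values()))
        return first.attractor.genes

    def to_frame(self):
        import pandas as pd

        rows = []
        for cid, fate in self.fates.items():
            for g in fate.attractor.genes:
                rows.append(
                    {
                        "cell": cid,
                        "gene": g,
                        "final_state": fate.gene_fate(g),
                        "attractor_period": fate.attractor.period,
                    }
                )
        return pd.DataFrame(rows)


def run_late_network_cells(
    ruleset: RuleSet,
    fixture: Mapping[str, Sequence[str]],
    timer_values: Mapping[str, bool] | None = None,
    scenario: str = "",
) -> CellFateTable:
    """Per-cell attractors of the late network from fixture initial states.

    Cells are autonomous: each is followed independently to its attractor.
    ``timer_values`` defaults to the late regime (opa frozen ON).
    """
    tv = dict(timer_values) if timer_values is not None else {"opa": True}
    genes = ruleset.gene_names
    fates = {}
    for cid, on in fixture.items():
        unknown = set(on) - set(genes)
        if unknown:
            raise ConfigError(f"{cid}: fixture genes {sorted(unknown)} not in roster")
        init = GlobalState.from_set(genes, tuple(on))
        transient, attractor = trajectory_to_attractor(ruleset, init, tv)
        fates[cid] = CellFate(cid, frozenset(on), len(transient), attractor)
    return CellFateTable(scenario, fates)


def compare_cell_fates(
    a: CellFateTable,
    b: CellFateTable,
    ignore: Sequence[tuple[str, str]] = (),
) -> list[tuple[str, str, str, str]]:
    """Per-(cell, gene) fate disagreements not in the ignore set.

    Returns tuples (cell, gene, fate_in_a, fate_in_b); an empty list means
    the tables agree modulo the ignored pairs.
    """
    if set(a.fates) != set(b.fates):
        raise ConfigError(f"cell ids differ: {sorted(a.fates)} vs {sorted(b.fates)}")
    ignored = set(ignore)
    diffs = []
    for cid in a.fates:
        genes = set(a.fates[cid].attractor.genes) | set(b.fates[cid].attractor.genes)
        for g in sorted(genes):
            if (cid, g) in ignored:
                continue
            fa = a.fates[cid].gene_fate(g) if g in a.fates[cid].attractor.genes else "absent"
            fb = b.fates[cid].gene_fate(g) if g in b.fates[cid].attractor.genes else "absent"
            if fa != fb:
                diffs.append((cid, g, fa, fb))
    return diffs


def fate_table_from_final_sets(
    scenario: str, genes: Sequence[str], final: Mapping[str, frozenset[str]]
) -> CellFateTable:
    """Build a point-attractor fate table from plain final expressed-sets
    (useful for comparing against pinned reference outputs)."""
    fates = {}
    for cid, on in final.items():
        att = Attractor(tuple(genes), (GlobalState.from_set(tuple(genes), tuple(on)).code,))
        fates[cid] = CellFate(cid, frozenset(on), 0, att)
    return CellFateTable(scenario, fates)


# ---------------------------------------------------------------------------
# prepattern dependency


@dataclass
class PrepatternReport:
    full_final: list[frozenset[str]]
    partial_final: list[frozenset[str]]
    full_matches: bool
    partial_matches: bool
    margin: int


def run_prepattern_dependency(
    ruleset: RuleSet,
    full_initial: TissueState,
    partial_initial: TissueState,
    schedule: TimerSchedule,
    n_steps: int,
    margin: int = 8,
) -> PrepatternReport:
    """Does the network still pattern when initial stripes are withheld?

    "Normal patterning" means the margin-trimmed final expressed-set pattern
    equals that of the full-prepattern run; the full run therefore always
    passes and the partial run is the test.
    """
    res_full = simulate(ruleset, full_initial, schedule, n_steps)
    res_part = simulate(ruleset, partial_initial, schedule, n_steps)
    n_cells = res_full.rna.shape[1]

    def final_sets(res) -> list[frozenset[str]]:
        return [
            expressed_set(res, res.rna.shape[0] - 1, c, "rna")
            for c in range(margin, n_cells - margin)
        ]

    full_final = final_sets(res_full)
    partial_final = final_sets(res_part)
    return PrepatternReport(
        full_final=full_final,
        partial_final=partial_final,
        full_matches=True,
        partial_matches=partial_final == full_final,
        margin=margin,
    )
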