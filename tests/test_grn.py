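"""Cellular-row simulator: delay semantics, synchrony, cell autonomy."""

import itertools

import numpy as np
import pytest

from boolseg import (
    ConfigError,
    GeneSpec,
    GeneState,
    RuleSet,
    evaluate_rule,
    expressed_set,
    make_ruleset,
    make_tissue,
    simulate,
    step_tissue,
    update_gene_state,
)
from boolseg.grn import RegulatoryRule
from boolseg.synth import random_ruleset


# ---------------------------------------------------------------------------
# rule evaluation


def test_evaluate_rule_reads_protein_snapshot():
    rs = make_ruleset({"prd": "protein(prd)", "eve": "TRUE"})
    tissue = make_tissue(rs, 1, [("eve",)])
    cell = tissue.cells[0]
    assert evaluate_rule(rs.rules["prd"], cell, {}) is False
    assert evaluate_rule(rs.rules["eve"], cell, {}) is True


def test_evaluate_rule_unresolvable_literal_names_it():
    rule = RegulatoryRule.parse("a", "protein(ghost)")
    rs = make_ruleset({"a": "TRUE"})
    cell = make_tissue(rs, 1).cells[0]
    with pytest.raises(ConfigError, match="ghost"):
        evaluate_rule(rule, cell, {})


def test_ruleset_validation():
    with pytest.raises(ConfigError, match="undeclared gene"):
        make_ruleset({"a": "protein(b)"})
    with pytest.raises(ConfigError, match="undeclared input"):
        make_ruleset({"a": "input(cad)"})
    with pytest.raises(ConfigError, match="duplicate gene"):
        RuleSet(
            (GeneSpec("a"), GeneSpec("a")),
            (),
            {"a": RegulatoryRule.parse("a", "TRUE")},
        )


# ---------------------------------------------------------------------------
# single-gene delay semantics


def test_all_off_state_is_absorbing():
    spec = GeneSpec("g", 2, 3, 3)
    state = GeneState.off(spec)
    assert update_gene_state(state, False, spec) == state


def test_hand_stepped_delay_table_111():
    """Delays (1,1,1), rule true at t=0,1,2: RNA on from step 1, protein from 2."""
    spec = GeneSpec("g", 1, 1, 1)
    s = GeneState.off(spec)
    seen = []
    for t in range(3):
        s = update_gene_state(s, True, spec)
        seen.append((s.rna_on, s.protein_on))
    assert seen == [(True, False), (True, True), (True, True)]
    # rule now permanently false: RNA survives 1 extra step, protein 1 more
    s = update_gene_state(s, False, spec)
    assert (s.rna_on, s.protein_on) == (True, True)
    s = update_gene_state(s, False, spec)
    assert (s.rna_on, s.protein_on) == (False, True)
    s = update_gene_state(s, False, spec)
    assert (s.rna_on, s.protein_on) == (False, False)


def test_zero_delays_collapse_protein_onto_rule_value():
    spec = GeneSpec("g", 0, 0, 0)
    s = GeneState.off(spec)
    for rule_value in [True, True, False, True, False, False]:
        s = update_gene_state(s, rule_value, spec)
        assert s.rna_on == s.protein_on == rule_value


def test_monotone_decay_once_rule_permanently_false():
    """Expression dies within rna_decay + protein_decay + 1 steps, never returns."""
    for sy, rd, pd in itertools.product(range(3), repeat=3):
        spec = GeneSpec("g", sy, rd, pd)
        s = GeneState.on_mature(spec)
        alive_limit = rd + pd + 1
        history = []
        for _ in range(alive_limit + 4):
            s = update_gene_state(s, False, spec)
            history.append(s.rna_on or s.protein_on)
        assert not any(history[alive_limit:]), (sy, rd, pd, history)
        # once off, stays off
        first_off = history.index(False)
        assert not any(history[first_off:])


# ---------------------------------------------------------------------------
# tissue stepping


def _naive_step(tissue, ruleset, timer_values):
    """Oracle: double-buffered, cell-by-cell, gene-by-gene recomputation."""
    from boolseg.grn import CellState, TissueState

    new_cells = []
    for cell in tissue.cells:
        states = {}
        for g in ruleset.genes:
            rv = evaluate_rule(ruleset.rules[g.name], cell, timer_values)
            states[g.name] = update_gene_state(cell.states[g.name], rv, g)
        new_cells.append(CellState(cell.index, states))
    return TissueState(tuple(new_cells), tissue.time + 1)


def test_step_tissue_equals_naive_double_buffered_oracle():
    rs = random_ruleset(4, 0.5, seed=7, delays=(1, 2, 1))
    tissue = make_tissue(rs, 5, [("g0",), ("g1", "g2"), (), ("g3",), ("g0", "g3")])
    for _ in range(12):
        expected = _naive_step(tissue, rs, {})
        tissue = step_tissue(tissue, rs)
        assert tissue == expected


def test_identical_cells_stay_identical():
    rs = random_ruleset(3, 0.6, seed=3, delays="framework")
    tissue = make_tissue(rs, 2, [("g0",), ("g0",)])
    for _ in range(20):
        tissue = step_tissue(tissue, rs)
        assert tissue.cells[0].states == tissue.cells[1].states


def test_cell_autonomy_deleting_a_cell_changes_nothing_else():
    from boolseg.grn import CellState, TissueState

    rs = random_ruleset(3, 0.5, seed=11, delays="framework")
    on = [("g0",), ("g1",), ("g2",), ("g0", "g2")]
    full = make_tissue(rs, 4, on)
    reduced = make_tissue(rs, 3, [on[0], on[1], on[3]])  # cell 2 deleted
    for _ in range(15):
        full = step_tissue(full, rs)
        reduced = step_tissue(reduced, rs)
    assert full.cells[0].states == reduced.cells[0].states
    assert full.cells[1].states == reduced.cells[1].states
    assert full.cells[3].states == reduced.cells[2].states


def test_roster_mismatch_is_config_error():
    rs_a = make_ruleset({"a": "TRUE"})
    rs_b = make_ruleset({"b": "TRUE"})
    tissue = make_tissue(rs_a, 1)
    with pytest.raises(ConfigError, match="roster"):
        step_tissue(tissue, rs_b)


# ---------------------------------------------------------------------------
# simulate / expressed_set


def test_simulate_zero_steps_records_only_initial():
    rs = make_ruleset({"a": "TRUE"})
    res = simulate(rs, make_tissue(rs, 2, [("a",), ()]), None, 0)
    assert res.rna.shape == (1, 2, 1)
    assert res.rna[0, 0, 0] and not res.rna[0, 1, 0]


def test_all_false_rules_kill_expression_immediately_in_simplified_mode():
    rs = make_ruleset({"a": "FALSE", "b": "FALSE"})
    res = simulate(rs, make_tissue(rs, 3, [("a", "b")] * 3), None, 4)
    assert res.rna[0].all()
    assert not res.rna[1:].any() and not res.protein[1:].any()


def test_simulation_is_deterministic_and_bit_identical():
    rs = random_ruleset(4, 0.4, seed=5, delays="framework")
    init = make_tissue(rs, 3, [("g0",), ("g1",), ("g2", "g3")])
    a = simulate(rs, init, None, 30)
    b = simulate(rs, init, None, 30)
    assert (a.rna == b.rna).all() and (a.protein == b.protein).all()


def test_expressed_set_agrees_with_array_lookup():
    rs = random_ruleset(3, 0.5, seed=9)
    res = simulate(rs, make_tissue(rs, 2, [("g0",), ("g1",)]), None, 6)
    for t in range(7):
        for c in range(2):
            direct = {g for gi, g in enumerate(res.gene_order) if res.rna[t, c, gi]}
            assert expressed_set(res, t, c) == direct
    with pytest.raises(IndexError):
        expressed_set(res, 99, 0)


def test_simplified_mode_equals_plain_synchronous_boolean_network():
    """With all delays 0 the RNA trajectory is the plain synchronous update
    of the rule values — exhaustively over 2-gene and 3-gene repression
    rule sets and all initial states, plus sampled 4-gene rule sets."""

    def plain_synchronous(ruleset, on0, n_steps):
        state = set(on0)
        out = [frozenset(state)]
        for _ in range(n_steps):
            nxt = set()
            for g in ruleset.gene_names:
                expr = ruleset.rules[g].expression
                if expr.evaluate(lambda p: p in state, lambda x: False):
                    nxt.add(g)
            state = nxt
            out.append(frozenset(state))
        return out

    cases = []
    for bits in range(1 << 2):  # all 2-gene repression topologies
        cases.append((2, bits))
    for bits in range(1 << 6):  # all 3-gene repression topologies
        cases.append((3, bits))
    rng = np.random.default_rng(0)
    cases += [(4, int(b)) for b in rng.integers(0, 1 << 12, size=40)]

    from boolseg.screen import TopologyMatrix, topology_to_ruleset

    for k, bits in cases:
        topo = TopologyMatrix.from_bits(tuple(f"g{i}" for i in range(k)), bits)
        rs = topology_to_ruleset(topo, delays="simplified")
        for mask in range(1 << k):
            on0 = [g for i, g in enumerate(rs.gene_names) if (mask >> i) & 1]
            res = simulate(rs, make_tissue(rs, 1, [on0]), None, 6)
            got = [expressed_set(res, t, 0) for t in range(7)]
            assert got == plain_synchronous(rs, on0, 6), (k, bits, mask)
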