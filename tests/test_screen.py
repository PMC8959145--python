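"""Topology enumeration, phase matching, and screen oracle equivalence."""

import itertools

import pytest

from boolseg import (
    ConfigError,
    PhaseSequence,
    ScreenConfig,
    TopologyMatrix,
    count_full_cycles,
    enumerate_topologies,
    matches_target_sequence,
    run_phase_trajectory,
    topology_to_ruleset,
)
from boolseg.screen import (
    CORE_GENES,
    FOUR_GENE_SOLUTION,
    PAIR_RULE_TARGET,
    _screen_vectorised,
    is_core_equivalent,
    ruleset_to_topology,
    screen_topologies,
)


# ---------------------------------------------------------------------------
# enumeration and the topology<->ruleset mapping


@pytest.mark.parametrize("k,expected", [(2, 4), (3, 64), (4, 4096)])
def test_enumeration_is_exhaustive_and_duplicate_free(k, expected):
    seen = {t.bits for t in enumerate_topologies(k)}
    assert len(seen) == expected
    assert seen == set(range(expected))


def test_empty_matrix_gives_all_true_rules():
    topo = TopologyMatrix.from_edges(("a", "b"), [])
    rs = topology_to_ruleset(topo)
    assert {str(rs.rules[g].expression) for g in rs.gene_names} == {"TRUE"}


def test_single_edge_becomes_single_repression():
    topo = TopologyMatrix.from_edges(("runt", "eve"), [("runt", "eve")])
    rs = topology_to_ruleset(topo)
    assert str(rs.rules["eve"].expression) == "NOT protein(runt)"
    assert str(rs.rules["runt"].expression) == "TRUE"


def test_topology_ruleset_round_trip_is_exact():
    for bits in [0, 1, 37, 4095]:
        topo = TopologyMatrix.from_bits(CORE_GENES, bits)
        assert ruleset_to_topology(topology_to_ruleset(topo)).matrix == topo.matrix


def test_self_repression_rejected():
    with pytest.raises(ConfigError, match="self"):
        TopologyMatrix.from_edges(("a", "b"), [("a", "a")])


# ---------------------------------------------------------------------------
# phase-sequence matching


H, E, R, O = ({"hairy"}, {"eve"}, {"runt"}, {"odd"})
HE = {"hairy", "eve"}
ER = {"eve", "runt"}
RO = {"runt", "odd"}
OH = {"odd", "hairy"}
PRINTED = [H, HE, E, ER, R, RO, O, OH, H]


def fs(seq):
    return [frozenset(s) for s in seq]


def test_printed_nine_entry_sequence_matches():
    assert matches_target_sequence(fs(PRINTED), PAIR_RULE_TARGET)


def test_sequence_skipping_overlap_phases_fails():
    assert not matches_target_sequence(fs([H, E, R, O, H]), PAIR_RULE_TARGET)


def test_foreign_phase_fails():
    bad = fs([H, HE, E, {"hairy", "runt"}, R])
    assert not matches_target_sequence(bad, PAIR_RULE_TARGET)


def test_stalled_trajectory_never_completing_the_cycle_fails():
    assert not matches_target_sequence(fs([H]), PAIR_RULE_TARGET)
    assert not matches_target_sequence(fs([H, HE, E]), PAIR_RULE_TARGET)


def test_partial_final_cycle_allowed():
    one_and_a_half = PRINTED + [HE, E, ER, R]
    assert matches_target_sequence(fs(one_and_a_half), PAIR_RULE_TARGET)


def test_count_full_cycles():
    assert count_full_cycles(fs(PRINTED), PAIR_RULE_TARGET) == 1.0
    one_and_a_half = PRINTED + [HE, E, ER, R]
    assert count_full_cycles(fs(one_and_a_half), PAIR_RULE_TARGET) == 1.5
    with pytest.raises(ValueError):
        count_full_cycles(fs([H, E]), PAIR_RULE_TARGET)


def test_phase_sequence_validation():
    with pytest.raises(ConfigError):
        PhaseSequence((frozenset({"a"}), frozenset({"a"})))
    with pytest.raises(ConfigError):
        PhaseSequence((frozenset(),))


# ---------------------------------------------------------------------------
# trajectories


def test_edgeless_topology_trajectory_collapses_to_two_entries():
    topo = TopologyMatrix.from_edges(CORE_GENES, [])
    config = ScreenConfig(n_steps=10)
    traj = run_phase_trajectory(topo, config)
    assert traj == [frozenset({"hairy"}), frozenset(CORE_GENES)]


def test_projection_removes_auxiliary_gene_everywhere():
    genes = CORE_GENES + ("X",)
    topo = TopologyMatrix.from_edges(genes, [("X", "eve")])
    config = ScreenConfig(
        n_steps=20,
        initial_phase=frozenset({"hairy", "X"}),
        auxiliary_genes=frozenset({"X"}),
    )
    traj = run_phase_trajectory(topo, config)
    assert all("X" not in phase for phase in traj)


def test_unique_solution_traverses_the_printed_sequence():
    """Regression: the pinned four-gene matrix reproduces the printed cycle."""
    traj = run_phase_trajectory(FOUR_GENE_SOLUTION, ScreenConfig())
    assert matches_target_sequence(traj, PAIR_RULE_TARGET)
    assert traj[:9] == fs(PRINTED)


# ---------------------------------------------------------------------------
# naive set-algebra oracle for small screens


def naive_delayed_trajectory(topo, init_on, n_steps, sy, rd, pd):
    """Independent reimplementation of the delay semantics with dicts/sets."""
    genes = topo.genes
    reps = {g: set(topo.repressors_of(g)) for g in genes}
    rna = {g: g in init_on for g in genes}
    prot = dict(rna)
    since_true = {g: (0 if rna[g] else rd + 1) for g in genes}
    on_run = {g: (sy + 1 if rna[g] else 0) for g in genes}
    off_run = {g: (0 if rna[g] else pd + 1) for g in genes}
    out = [frozenset(g for g in genes if rna[g])]
    for _ in range(n_steps):
        rule = {g: not any(prot[r] for r in reps[g]) for g in genes}
        for g in genes:
            since_true[g] = 0 if rule[g] else min(since_true[g] + 1, rd + 1)
        new_rna = {g: since_true[g] <= rd for g in genes}
        for g in genes:
            if new_rna[g]:
                on_run[g] = (on_run[g] if rna[g] else 0) + 1
                off_run[g] = 0
            else:
                off_run[g] = (off_run[g] if not rna[g] else 0) + 1
                on_run[g] = 0
        new_prot = {
            g: (new_rna[g] and on_run[g] >= sy + 1)
            or (not new_rna[g] and prot[g] and off_run[g] <= pd)
            for g in genes
        }
        rna, prot = new_rna, new_prot
        out.append(frozenset(g for g in genes if rna[g]))
    return out


def naive_matches(trajectory, cycle):
    collapsed = [trajectory[0]]
    for s in trajectory[1:]:
        if s != collapsed[-1]:
            collapsed.append(s)
    if collapsed[0] != cycle[0]:
        return False
    pos, adv = 0, 0
    for phase in collapsed[1:]:
        if phase == cycle[(pos + 1) % len(cycle)]:
            pos = (pos + 1) % len(cycle)
            adv += 1
        elif phase != cycle[pos]:
            return False
    return adv >= len(cycle)


@pytest.mark.parametrize(
    "genes,cycle",
    [
        (("a", "b"), [{"a"}, {"a", "b"}, {"b"}]),
        (("a", "b", "c"), [{"a"}, {"a", "b"}, {"b"}, {"b", "c"}, {"c"}, {"c", "a"}]),
        (("a", "b", "c"), [{"a"}, {"b"}, {"c"}]),
    ],
)
def test_vectorised_screen_equals_naive_set_algebra(genes, cycle):
    cyc = [frozenset(s) for s in cycle]
    config = ScreenConfig(
        n_steps=40,
        initial_phase=cyc[0],
        target=PhaseSequence(tuple(cyc)),
        delay_preset="framework",
    )
    result = screen_topologies(genes, config)
    got = {t.bits for t in result.passing}
    sy, rd, pd = (2, 3, 3)
    expected = set()
    for bits in range(1 << (len(genes) * (len(genes) - 1))):
        topo = TopologyMatrix.from_bits(genes, bits)
        traj = naive_delayed_trajectory(topo, set(cyc[0]), 40, sy, rd, pd)
        if naive_matches(traj, cyc):
            expected.add(bits)
    assert got == expected


def test_scalar_and_vectorised_paths_agree_on_every_three_gene_topology():
    genes = ("a", "b", "c")
    cyc = [frozenset(s) for s in [{"a"}, {"a", "b"}, {"b"}, {"b", "c"}, {"c"}, {"c", "a"}]]
    config = ScreenConfig(n_steps=30, initial_phase=cyc[0], target=PhaseSequence(tuple(cyc)))
    bits_passing, _ = _screen_vectorised(genes, config)
    vec = set(int(b) for b in bits_passing)
    scal = set()
    for topo in enumerate_topologies(3, genes):
        traj = run_phase_trajectory(topo, config)
        if matches_target_sequence(traj, config.target):
            scal.add(topo.bits)
    assert vec == scal


def test_screen_determinism_and_relabelling_closure():
    genes = ("a", "b", "c")
    cyc = [frozenset(s) for s in [{"a"}, {"a", "b"}, {"b"}, {"b", "c"}, {"c"}, {"c", "a"}]]
    config = ScreenConfig(n_steps=30, initial_phase=cyc[0], target=PhaseSequence(tuple(cyc)))
    r1 = screen_topologies(genes, config)
    r2 = screen_topologies(genes, config)
    assert [t.bits for t in r1.passing] == [t.bits for t in r2.passing]
    # relabel a<->b everywhere: count must be preserved
    swap = {"a": "b", "b": "a", "c": "c"}
    cyc2 = [frozenset(swap[g] for g in s) for s in cyc]
    config2 = ScreenConfig(
        n_steps=30, initial_phase=cyc2[0], target=PhaseSequence(tuple(cyc2))
    )
    r3 = screen_topologies(genes, config2)
    assert r3.n_passing == r1.n_passing


# ---------------------------------------------------------------------------
# the five-gene filter


def test_core_equivalence_filter_modes():
    genes = CORE_GENES + ("X",)
    base = TopologyMatrix.from_edges(genes, FOUR_GENE_SOLUTION.edges())
    assert is_core_equivalent(base, mode="inert")
    assert is_core_equivalent(base, mode="core")
    with_x_in = TopologyMatrix.from_edges(
        genes, FOUR_GENE_SOLUTION.edges() + [("hairy", "X")]
    )
    assert is_core_equivalent(with_x_in, mode="inert")  # X still silent
    with_x_out = TopologyMatrix.from_edges(
        genes, FOUR_GENE_SOLUTION.edges() + [("X", "eve")]
    )
    assert not is_core_equivalent(with_x_out, mode="inert")
    assert is_core_equivalent(with_x_out, mode="core")
    different_core = TopologyMatrix.from_edges(genes, [("eve", "hairy")])
    assert not is_core_equivalent(different_core, mode="inert")
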