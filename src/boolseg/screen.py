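"""Exhaustive screening of repression-only network topologies.

The early pair-rule network is modelled as a square repression matrix over a
small gene roster (entry ``[i][j]`` means gene *i*'s protein represses gene
*j*'s transcription; no self-edges) with constitutive activation: a gene is
transcribed whenever none of its repressors' proteins are present.  Every
zero-diagonal Boolean matrix is enumerated and a single autonomous cell is
simulated from a chosen initial phase; a topology passes if the cell's
collapsed RNA expression trajectory traverses the observed eight-phase
pair-rule cycle

    hairy → hairy/eve → eve → eve/runt → runt → runt/odd → odd → odd/hairy →

in order, completing the cycle at least once, with no foreign or
out-of-order phases.

Two equivalent execution paths exist: a scalar path through the full
:mod:`boolseg.grn` simulator (used for single trajectories and as the
reference semantics) and a bit-packed vectorised engine that advances the
whole enumeration in parallel (used for the 4096-matrix four-gene and
1,048,576-matrix five-gene screens).  Their agreement is part of the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .grn import (
    DELAY_PRESETS,
    ConfigError,
    RuleSet,
    make_ruleset,
    make_tissue,
    simulate,
)

#: the observed pair-rule phase sequence (first phase repeated at the end)
PAIR_RULE_SEQUENCE: tuple[frozenset[str], ...] = tuple(
    frozenset(p)
    for p in (
        {"hairy"},
        {"hairy", "eve"},
        {"eve"},
        {"eve", "runt"},
        {"runt"},
        {"runt", "odd"},
        {"odd"},
        {"odd", "hairy"},
        {"hairy"},
    )
)

CORE_GENES = ("hairy", "eve", "runt", "odd")


@dataclass(frozen=True)
class TopologyMatrix:
    """A repression adjacency matrix: ``matrix[i][j]`` ⇔ gene i represses gene j."""

    genes: tuple[str, ...]
    matrix: tuple[tuple[bool, ...], ...]

    def __post_init__(self):
        k = len(self.genes)
        if len(self.matrix) != k or any(len(row) != k for row in self.matrix):
            raise ConfigError("matrix dimension must equal roster size")
        if any(self.matrix[i][i] for i in range(k)):
            raise ConfigError("self-repression is outside the enumerated space")

    @classmethod
    def from_edges(cls, genes: Sequence[str], edges: Sequence[tuple[str, str]]) -> "TopologyMatrix":
        idx = {g: i for i, g in enumerate(genes)}
        m = [[False] * len(genes) for _ in genes]
        for a, b in edges:
            m[idx[a]][idx[b]] = True
        return cls(tuple(genes), tuple(tuple(row) for row in m))

    @classmethod
    def from_bits(cls, genes: Sequence[str], bits: int) -> "TopologyMatrix":
        """Decode the enumeration index: off-diagonal cells in row-major order,
        bit ``b`` set ⇔ the b-th off-diagonal cell carries a repression."""
        k = len(genes)
        m = [[False] * k for _ in range(k)]
        for b, (i, j) in enumerate(_offdiag(k)):
            m[i][j] = bool((bits >> b) & 1)
        return cls(tuple(genes), tuple(tuple(row) for row in m))

    @property
    def bits(self) -> int:
        out = 0
        for b, (i, j) in enumerate(_offdiag(len(self.genes))):
            if self.matrix[i][j]:
                out |= 1 << b
        return out

    def edges(self) -> list[tuple[str, str]]:
        return [
            (self.genes[i], self.genes[j])
            for i in range(len(self.genes))
            for j in range(len(self.genes))
            if self.matrix[i][j]
        ]

    def repressors_of(self, gene: str) -> list[str]:
        j = self.genes.index(gene)
        return [self.genes[i] for i in range(len(self.genes)) if self.matrix[i][j]]

    def core(self, genes: Sequence[str]) -> "TopologyMatrix":
        """The submatrix over ``genes`` (in that order)."""
        idx = [self.genes.index(g) for g in genes]
        sub = tuple(tuple(self.matrix[i][j] for j in idx) for i in idx)
        return TopologyMatrix(tuple(genes), sub)


#: the unique four-gene topology passing the screen: each gene is repressed
#: by its two successors in the hairy→eve→runt→odd cycle (regression fixture,
#: recomputed by the screen itself in the tests)
FOUR_GENE_SOLUTION = TopologyMatrix.from_edges(
    CORE_GENES,
    [
        ("eve", "hairy"), ("runt", "hairy"),
        ("runt", "eve"), ("odd", "eve"),
        ("odd", "runt"), ("hairy", "runt"),
        ("hairy", "odd"), ("eve", "odd"),
    ],
)


def _offdiag(k: int) -> Iterator[tuple[int, int]]:
    return ((i, j) for i in range(k) for j in range(k) if i != j)


def enumerate_topologies(n_genes: int, genes: Sequence[str] | None = None) -> Iterator[TopologyMatrix]:
    """Yield every zero-diagonal Boolean matrix once, in bit-string order."""
    if n_genes < 2:
        raise ConfigError("n_genes must be >= 2")
    roster = tuple(genes) if genes is not None else tuple(f"g{i}" for i in range(n_genes))
    for bits in range(1 << (n_genes * (n_genes - 1))):
        yield TopologyMatrix.from_bits(roster, bits)


def topology_to_ruleset(
    topology: TopologyMatrix, delays: str | tuple[int, int, int] = "framework"
) -> RuleSet:
    """Constitutive activation + repression-dominant logic, one rule per gene."""
    rules = {}
    for g in topology.genes:
        reps = topology.repressors_of(g)
        rules[g] = " AND ".join(f"NOT protein({r})" for r in reps) if reps else "TRUE"
    return make_ruleset(rules, inputs=(), delays=delays)


def ruleset_to_topology(ruleset: RuleSet) -> TopologyMatrix:
    """Inverse of :func:`topology_to_ruleset` (round-trip exact)."""
    from .logic import And, Const, Not, ProteinLit

    edges = []
    for g in ruleset.gene_names:
        expr = ruleset.rules[g].expression
        stack = [expr]
        while stack:
            node = stack.pop()
            if isinstance(node, And):
                stack += [node.left, node.right]
            elif isinstance(node, Not) and isinstance(node.operand, ProteinLit):
                edges.append((node.operand.gene, g))
            elif isinstance(node, Const) and node.value:
                pass
            else:
                raise ConfigError(f"rule for {g} is not in repression-only form")
    return TopologyMatrix.from_edges(ruleset.gene_names, edges)


# ---------------------------------------------------------------------------
# phase sequences and matching


@dataclass(frozen=True)
class PhaseSequence:
    """An ordered cycle of co-expressed gene sets; the final entry may repeat
    the first to close the cycle explicitly."""

    phases: tuple[frozenset[str], ...]

    def __post_init__(self):
        if not self.phases or any(not p for p in self.phases):
            raise ConfigError("phases must be non-empty gene sets")
        for a, b in zip(self.phases, self.phases[1:]):
            if a == b:
                raise ConfigError("consecutive phases must differ")

    @property
    def cycle(self) -> tuple[frozenset[str], ...]:
        """Distinct phases of one traversal (closing repeat dropped)."""
        if len(self.phases) > 1 and self.phases[0] == self.phases[-1]:
            return self.phases[:-1]
        return self.phases


PAIR_RULE_TARGET = PhaseSequence(PAIR_RULE_SEQUENCE)


def _collapse(seq: Sequence[frozenset[str]]) -> list[frozenset[str]]:
    out: list[frozenset[str]] = []
    for s in seq:
        if not out or out[-1] != s:
            out.append(s)
    return out


def _walk_cycle(trajectory: Sequence[frozenset[str]], target: PhaseSequence) -> int | None:
    """Advances made along the target cycle, or None if the walk breaks."""
    cycle = target.cycle
    collapsed = _collapse(trajectory)
    if not collapsed or collapsed[0] != cycle[0]:
        return None
    pos, advances = 0, 0
    for phase in collapsed[1:]:
        if phase == cycle[(pos + 1) % len(cycle)]:
            pos = (pos + 1) % len(cycle)
            advances += 1
        elif phase != cycle[pos]:
            return None
    return advances


def matches_target_sequence(trajectory: Sequence[frozenset[str]], target: PhaseSequence) -> bool:
    """True iff the collapsed trajectory follows the target cycle from its
    first phase, with no foreign or out-of-order phases, completing at least
    one full traversal (a partial extra cycle at the end is fine)."""
    adv = _walk_cycle(trajectory, target)
    return adv is not None and adv >= len(target.cycle)


def count_full_cycles(trajectory: Sequence[frozenset[str]], target: PhaseSequence) -> float:
    """Complete traversals of the target cycle plus the completed fraction of
    the final partial traversal."""
    adv = _walk_cycle(trajectory, target)
    if adv is None:
        raise ValueError("trajectory does not follow the target cycle")
    return adv / len(target.cycle)


# ---------------------------------------------------------------------------
# screen configuration and drivers


@dataclass(frozen=True)
class ScreenConfig:
    """Parameters of a phase-sequence screen."""

    n_steps: int = 100
    initial_phase: frozenset[str] = frozenset({"hairy"})
    target: PhaseSequence = PAIR_RULE_TARGET
    delay_preset: str = "framework"
    auxiliary_genes: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.n_steps < 1:
            raise ConfigError("n_steps must be >= 1")
        if not self.initial_phase:
            raise ConfigError("initial_phase must be non-empty")


@dataclass
class ScreenResult:
    passing: list[TopologyMatrix]
    n_enumerated: int
    config: ScreenConfig
    genes: tuple[str, ...] = ()

    @property
    def n_passing(self) -> int:
        return len(self.passing)


def run_phase_trajectory(
    topology: TopologyMatrix, config: ScreenConfig
) -> list[frozenset[str]]:
    """Collapsed RNA expressed-set trajectory of one autonomous cell, with
    auxiliary genes projected out before collapsing.  Scalar reference path."""
    ruleset = topology_to_ruleset(topology, delays=config.delay_preset)
    tissue = make_tissue(ruleset, 1, [set(config.initial_phase) & set(topology.genes)])
    result = simulate(ruleset, tissue, None, config.n_steps)
    aux = config.auxiliary_genes
    raw = []
    for t in range(config.n_steps + 1):
        on = frozenset(
            g for gi, g in enumerate(topology.genes) if result.rna[t, 0, gi] and g not in aux
        )
        raw.append(on)
    return _collapse(raw)


def _screen_vectorised(
    genes: Sequence[str], config: ScreenConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Advance every zero-diagonal matrix over ``genes`` in parallel.

    Returns (passing_bits, advances) where passing_bits are the enumeration
    indices whose trajectory matches the target, in ascending order.
    """
    k = len(genes)
    sy, rd, pd = DELAY_PRESETS[config.delay_preset]
    n_off = k * (k - 1)
    m_total = 1 << n_off
    cells = list(_offdiag(k))
    mids = np.arange(m_total, dtype=np.uint32)
    colmask = np.zeros((m_total, k), dtype=np.uint32)
    for b, (i, j) in enumerate(cells):
        colmask[:, j] |= (((mids >> np.uint32(b)) & 1) << np.uint32(i)).astype(np.uint32)

    aux = config.auxiliary_genes
    core_mask = np.uint32(sum(1 << gi for gi, g in enumerate(genes) if g not in aux))
    bitvals = (1 << np.arange(k, dtype=np.uint32)).astype(np.uint32)
    cycle = config.target.cycle
    name_to_bit = {g: 1 << gi for gi, g in enumerate(genes)}
    cyc_int = np.array(
        [sum(name_to_bit[g] for g in phase) for phase in cycle], dtype=np.uint32
    )

    cap_s, cap_on, cap_off = rd + 1, sy + 1, pd + 1
    init = np.array([g in config.initial_phase for g in genes], dtype=bool)

    s = np.where(init, 0, cap_s).astype(np.uint8)[None, :].repeat(m_total, 0)
    rna = init[None, :].repeat(m_total, 0)
    prot = rna.copy()
    on_run = np.where(init, cap_on, 0).astype(np.uint8)[None, :].repeat(m_total, 0)
    off_run = np.where(init, 0, cap_off).astype(np.uint8)[None, :].repeat(m_total, 0)

    phase0 = (rna.astype(np.uint32) * bitvals).sum(1).astype(np.uint32) & core_mask
    alive = phase0 == cyc_int[0]
    idx = np.nonzero(alive)[0].astype(np.int64)
    s, rna, prot, on_run, off_run, cm = (
        a[idx] for a in (s, rna, prot, on_run, off_run, colmask)
    )
    pos = np.zeros(len(idx), dtype=np.uint8)
    adv = np.zeros(len(idx), dtype=np.uint16)
    L = len(cycle)

    for _ in range(config.n_steps):
        packed = (prot.astype(np.uint32) * bitvals).sum(1).astype(np.uint32)
        rule = (packed[:, None] & cm) == 0
        s = np.where(rule, 0, np.minimum(s + 1, cap_s)).astype(np.uint8)
        rna_new = s <= rd
        on_run = np.where(
            rna_new, np.minimum(np.where(rna, on_run, 0) + 1, cap_on), 0
        ).astype(np.uint8)
        off_run = np.where(
            ~rna_new, np.minimum(np.where(~rna, off_run, 0) + 1, cap_off), 0
        ).astype(np.uint8)
        prot = (rna_new & (on_run >= cap_on)) | (~rna_new & prot & (off_run <= pd))
        rna = rna_new
        phase = (rna.astype(np.uint32) * bitvals).sum(1).astype(np.uint32) & core_mask
        stay = phase == cyc_int[pos]
        step = phase == cyc_int[(pos + 1) % L]
        ok = stay | step
        pos = np.where(step, (pos + 1) % L, pos).astype(np.uint8)
        adv = adv + step.astype(np.uint16)
        if not ok.all():
            keep = np.nonzero(ok)[0]
            idx = idx[keep]
            s, rna, prot, on_run, off_run, cm, pos, adv = (
                a[keep] for a in (s, rna, prot, on_run, off_run, cm, pos, adv)
            )
    full = adv >= L
    return idx[full], adv[full]


def screen_topologies(
    genes: Sequence[str], config: ScreenConfig | None = None
) -> ScreenResult:
    """Screen every zero-diagonal repression matrix over ``genes``."""
    config = config or ScreenConfig()
    bits, _ = _screen_vectorised(genes, config)
    passing = [TopologyMatrix.from_bits(tuple(genes), int(b)) for b in bits]
    return ScreenResult(passing, 1 << (len(genes) * (len(genes) - 1)), config, tuple(genes))


def screen_four_gene(config: ScreenConfig | None = None) -> ScreenResult:
    """The 4096-matrix screen over {hairy, eve, runt, odd}."""
    return screen_topologies(CORE_GENES, config or ScreenConfig())


def is_core_equivalent(
    topology: TopologyMatrix,
    reference: TopologyMatrix = FOUR_GENE_SOLUTION,
    aux_gene: str = "X",
    mode: str = "inert",
) -> bool:
    """Is a five-gene topology "identical to the four-gene network"?

    ``mode='inert'`` (default): the core submatrix equals the reference AND
    the auxiliary gene has no outgoing repressions onto core genes (it cannot
    influence the core dynamics).  ``mode='core'``: the core submatrix equals
    the reference, regardless of the auxiliary gene's edges.
    """
    core_genes = [g for g in topology.genes if g != aux_gene]
    if topology.core(core_genes).matrix != reference.matrix:
        return False
    if mode == "core":
        return True
    if mode == "inert":
        xi = topology.genes.index(aux_gene)
        return not any(
            topology.matrix[xi][j] for j, g in enumerate(topology.genes) if g != aux_gene
        )
    raise ConfigError(f"unknown filter mode {mode!r}")


def screen_five_gene(
    config: ScreenConfig | None = None, filter_mode: str = "inert"
) -> ScreenResult:
    """The 2^20-matrix screen over {hairy, eve, runt, odd, X}.

    Gene X starts co-expressed with hairy and is projected out of every
    expressed-set before phase matching; topologies identical to the
    four-gene solution (see :func:`is_core_equivalent`) are then removed.
    """
    genes = CORE_GENES + ("X",)
    if config is None:
        config = ScreenConfig(
            initial_phase=frozenset({"hairy", "X"}), auxiliary_genes=frozenset({"X"})
        )
    raw = screen_topologies(genes, config)
    passing = [
        t for t in raw.passing if not is_core_equivalent(t, mode=filter_mode)
    ]
    return ScreenResult(passing, raw.n_enumerated, config, tuple(genes))


def interaction_frequencies(result: ScreenResult) -> np.ndarray:
    """Entry [i][j] = number of passing topologies with repression i→j."""
    k = len(result.genes) if result.genes else (
        len(result.passing[0].genes) if result.passing else 0
    )
    out = np.zeros((k, k), dtype=int)
    for t in result.passing:
        out += np.array(t.matrix, dtype=int)
    return out
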