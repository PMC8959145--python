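"""Generators for every input the pipeline needs: stripe prepatterns,
per-cell state fixtures, and random repression-only rule sets.

The default *Nasonia*-like prepattern places the four primary pair-rule
genes in six-cell-wide stripes around a sixteen-cell repeat on a 64-cell
row, phased in the observed order hairy → eve → runt → odd (adjacent genes
overlap by two cells, reproducing the eight-phase expression sequence along
the axis).  A *Drosophila*-like preset uses four-cell stripes on an
eight-cell repeat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grn import ConfigError, RuleSet, TissueState, make_tissue
from .attractors import GlobalState


@dataclass(frozen=True)
class StripeSpec:
    """Spatially periodic stripe prepattern parameters (units: cells)."""

    n_cells: int = 64
    stripe_width: int = 6
    repeat_length: int = 16
    phase_offsets: Mapping[str, int] = field(
        default_factory=lambda: {"hairy": 0, "eve": 4, "runt": 8, "odd": 12}
    )

    def __post_init__(self):
        if not 1 <= self.stripe_width <= self.repeat_length:
            raise ConfigError(
                f"stripe_width must be in 1..repeat_length, got {self.stripe_width}/{self.repeat_length}"
            )
        if self.n_cells < 0:
            raise ConfigError("n_cells must be >= 0")
        for g, off in self.phase_offsets.items():
            if not 0 <= off < self.repeat_length:
                raise ConfigError(f"offset for {g} must be in [0, repeat_length), got {off}")


#: Drosophila-like narrow stripes: four-cell stripes, eight-cell repeat
DROSOPHILA_STRIPES = StripeSpec(
    n_cells=64,
    stripe_width=4,
    repeat_length=8,
    phase_offsets={"hairy": 0, "eve": 2, "runt": 4, "odd": 6},
)


def stripe_mask(spec: StripeSpec, gene: str) -> np.ndarray:
    """Boolean ON-mask along the row for one gene of the prepattern."""
    off = spec.phase_offsets[gene]
    pos = (np.arange(spec.n_cells) - off) % spec.repeat_length
    return pos < spec.stripe_width


def make_broad_stripe_pattern(spec: StripeSpec, ruleset: RuleSet) -> TissueState:
    """Time-0 tissue with mature expression exactly in the specified stripes.

    Genes carrying stripes must belong to the rule set's roster; roster genes
    without an offset start fully off.  Initial expression is mature (RNA and
    protein both on): the prepattern represents established stripes, and an
    oscillator gated on protein repression needs standing protein to start
    from its observed phase.
    """
    unknown = set(spec.phase_offsets) - set(ruleset.gene_names)
    if unknown:
        raise ConfigError(f"stripe genes not in roster: {sorted(unknown)}")
    masks = {g: stripe_mask(spec, g) for g in spec.phase_offsets}
    on_genes = [
        [g for g, m in masks.items() if m[c]] for c in range(spec.n_cells)
    ]
    return make_tissue(ruleset, spec.n_cells, on_genes)


# ---------------------------------------------------------------------------
# per-cell state fixtures


def make_cell_fixture(
    scenario: str,
    assignments: Mapping[str, Sequence[str]],
    genes: Sequence[str],
    path=None,
) -> pd.DataFrame:
    """Per-cell Boolean states in the documented TSV format (cell, gene, on).

    ``assignments`` maps cell ids (``C1``..``Cn``) to the genes ON in that
    cell; every (cell, gene) pair of the roster appears in the output.
    """
    for cid in assignments:
        if not (cid.startswith("C") and cid[1:].isdigit()):
            raise ConfigError(f"cell id {cid!r} must look like C1, C2, ...")
        unknown = set(assignments[cid]) - set(genes)
        if unknown:
            raise ConfigError(f"{scenario}/{cid}: unknown genes {sorted(unknown)}")
    rows = [
        {"cell": cid, "gene": g, "on": int(g in set(on))}
        for cid, on in assignments.items()
        for g in genes
    ]
    df = pd.DataFrame(rows, columns=["cell", "gene", "on"])
    df.attrs["scenario"] = scenario
    if path is not None:
        df.to_csv(Path(path), sep="\t", index=False)
    return df


def read_cell_fixture(path) -> dict[str, list[str]]:
    """Inverse of :func:`make_cell_fixture`: ``{cell id: genes ON}``."""
    df = pd.read_csv(Path(path), sep="\t")
    out: dict[str, list[str]] = {}
    for cid, sub in df.groupby("cell", sort=False):
        out[str(cid)] = [str(g) for g, on in zip(sub["gene"], sub["on"]) if on]
    return out


def fixture_to_states(
    assignments: Mapping[str, Sequence[str]], genes: Sequence[str]
) -> dict[str, GlobalState]:
    return {
        cid: GlobalState.from_set(tuple(genes), tuple(on))
        for cid, on in assignments.items()
    }


# ---------------------------------------------------------------------------
# random rule sets


def random_topology_matrix(
    n_genes: int, edge_probability: float, seed: int, genes: Sequence[str] | None = None
):
    from .screen import TopologyMatrix

    if not 0 <= edge_probability <= 1:
        raise ConfigError("edge_probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    roster = tuple(genes) if genes is not None else tuple(f"g{i}" for i in range(n_genes))
    m = rng.random((n_genes, n_genes)) < edge_probability
    np.fill_diagonal(m, False)
    return TopologyMatrix(roster, tuple(tuple(bool(v) for v in row) for row in m))


def random_ruleset(
    n_genes: int,
    edge_probability: float = 0.5,
    seed: int = 0,
    delays: str | tuple[int, int, int] = "simplified",
    genes: Sequence[str] | None = None,
) -> RuleSet:
    """Repression-only rule set with i.i.d. edges; same seed → same rule set."""
    from .screen import topology_to_ruleset

    topo = random_topology_matrix(n_genes, edge_probability, seed, genes)
    return topology_to_ruleset(topo, delays=delays)
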