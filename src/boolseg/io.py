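"""Configuration files, result tables, kymographs and run manifests.

Rule sets, timer schedules and stripe specs share one structured-text
dialect (YAML with a strict schema: unknown keys are errors, so typos in
gene names fail loudly).  A rule-set file looks like::

    genes: [hairy, eve, runt, odd]
    inputs: [cad, opa]
    delays:
      preset: framework          # or synthesis/rna_decay/protein_decay keys
      hairy: {synthesis: 2, rna_decay: 3, protein_decay: 3}   # per-gene
    rules:
      hairy: "NOT protein(eve) AND NOT protein(runt)"
      ...

Simulation results are exchanged as long-format TSV with columns
``time, cell, gene, rna, protein`` (lossless round trip).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .grn import (
    DELAY_PRESETS,
    ConfigError,
    GeneSpec,
    RegulatoryRule,
    RuleSet,
    SimulationResult,
)
from . import timers


def _check_keys(mapping: Mapping, allowed: set[str], where: str):
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)} (allowed: {sorted(allowed)})")


def _parse_delay_entry(entry, where: str) -> tuple[int, int, int]:
    if isinstance(entry, str):
        if entry not in DELAY_PRESETS:
            raise ConfigError(f"{where}: unknown delay preset {entry!r}")
        return DELAY_PRESETS[entry]
    if not isinstance(entry, Mapping):
        raise ConfigError(f"{where}: delay entry must be a preset name or a mapping")
    _check_keys(entry, {"synthesis", "rna_decay", "protein_decay"}, where)
    return (
        int(entry.get("synthesis", 0)),
        int(entry.get("rna_decay", 0)),
        int(entry.get("protein_decay", 0)),
    )


def ruleset_from_dict(doc: Mapping, where: str = "ruleset") -> RuleSet:
    if not isinstance(doc, Mapping):
        raise ConfigError(f"{where}: document must be a mapping")
    _check_keys(doc, {"genes", "inputs", "delays", "rules"}, where)
    genes = doc.get("genes")
    rules = doc.get("rules")
    if not genes or not isinstance(genes, list):
        raise ConfigError(f"{where}: 'genes' must be a non-empty list")
    if not isinstance(rules, Mapping):
        raise ConfigError(f"{where}: 'rules' must map each gene to a rule string")
    inputs = tuple(doc.get("inputs") or ())

    delays_doc = doc.get("delays") or {}
    if isinstance(delays_doc, str):
        default = _parse_delay_entry(delays_doc, f"{where}.delays")
        per_gene = {}
    else:
        if not isinstance(delays_doc, Mapping):
            raise ConfigError(f"{where}: 'delays' must be a mapping or preset name")
        _check_keys(delays_doc, {"preset", *genes}, f"{where}.delays")
        default = _parse_delay_entry(
            delays_doc.get("preset", "simplified"), f"{where}.delays.preset"
        )
        per_gene = {
            g: _parse_delay_entry(delays_doc[g], f"{where}.delays.{g}")
            for g in genes
            if g in delays_doc
        }

    specs = []
    for g in genes:
        sy, rd, pd_ = per_gene.get(g, default)
        specs.append(GeneSpec(g, sy, rd, pd_))
    parsed = {}
    for g, text in rules.items():
        if not isinstance(text, str):
            raise ConfigError(f"{where}.rules.{g}: rule must be a string")
        parsed[g] = RegulatoryRule.parse(g, text)
    return RuleSet(tuple(specs), inputs, parsed)


def ruleset_to_dict(ruleset: RuleSet) -> dict:
    delays: dict = {}
    for g in ruleset.genes:
        delays[g.name] = {
            "synthesis": g.synthesis_delay,
            "rna_decay": g.rna_decay_delay,
            "protein_decay": g.protein_decay_delay,
        }
    return {
        "genes": list(ruleset.gene_names),
        "inputs": list(ruleset.inputs),
        "delays": delays,
        "rules": {g: str(ruleset.rules[g].expression) for g in ruleset.gene_names},
    }


def load_ruleset_config(path) -> RuleSet:
    """Load and validate a rule-set file; errors name the offending entry."""
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"{path}: {e}") from e
    return ruleset_from_dict(doc, where=str(path))


def save_ruleset_config(ruleset: RuleSet, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(ruleset_to_dict(ruleset), sort_keys=False))
    return path


# ---------------------------------------------------------------------------
# schedule configs

_SCHEDULE_KEYS = {
    "simultaneous": {"n_cells", "cad_off_time", "opa_on_time"},
    "progressive": {"n_cells", "cad_off_start", "opa_on_start", "steps_per_cell", "block"},
    "posterior_sequential": {"n_cells", "wavefront_speed", "stage_length"},
}


def schedule_from_dict(doc: Mapping, where: str = "schedule") -> timers.TimerSchedule:
    if not isinstance(doc, Mapping) or "regime" not in doc:
        raise ConfigError(f"{where}: schedule config must declare a 'regime'")
    regime = doc["regime"]
    if regime not in _SCHEDULE_KEYS:
        raise ConfigError(f"{where}: unknown regime {regime!r}")
    params = {k: v for k, v in doc.items() if k != "regime"}
    _check_keys(params, _SCHEDULE_KEYS[regime], f"{where}({regime})")
    maker = {
        "simultaneous": timers.make_simultaneous_schedule,
        "progressive": timers.make_progressive_schedule,
        "posterior_sequential": timers.make_posterior_sequential_schedule,
    }[regime]
    return maker(**params)


def load_schedule_config(path) -> timers.TimerSchedule:
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    return schedule_from_dict(doc, where=str(path))


# ---------------------------------------------------------------------------
# result tables


def result_to_frame(result: SimulationResult) -> pd.DataFrame:
    t, c, g = result.rna.shape
    times, cells, genes = np.meshgrid(
        np.arange(t), np.arange(c), np.arange(g), indexing="ij"
    )
    return pd.DataFrame(
        {
            "time": times.ravel(),
            "cell": cells.ravel(),
            "gene": np.array(result.gene_order)[genes.ravel()],
            "rna": result.rna.ravel().astype(int),
            "protein": result.protein.ravel().astype(int),
        }
    )


def save_result_table(result: SimulationResult, path) -> Path:
    """Long-format TSV (time, cell, gene, rna, protein)."""
    path = Path(path)
    result_to_frame(result).to_csv(path, sep="\t", index=False)
    return path


def load_result_table(path) -> SimulationResult:
    df = pd.read_csv(Path(path), sep="\t")
    gene_order = tuple(pd.unique(df["gene"]))
    n_t = df["time"].max() + 1 if len(df) else 0
    n_c = df["cell"].max() + 1 if len(df) else 0
    rna = np.zeros((n_t, n_c, len(gene_order)), dtype=bool)
    protein = np.zeros_like(rna)
    gidx = {g: i for i, g in enumerate(gene_order)}
    gi = df["gene"].map(gidx).to_numpy()
    rna[df["time"], df["cell"], gi] = df["rna"].astype(bool)
    protein[df["time"], df["cell"], gi] = df["protein"].astype(bool)
    return SimulationResult(rna=rna, protein=protein, gene_order=gene_order)


# ---------------------------------------------------------------------------
# kymographs


def render_kymograph(
    result: SimulationResult,
    genes=None,
    path=None,
    layer: str = "rna",
    cmap_colors=None,
    dpi: int = 100,
):
    """Space (x, anterior left) × time (y, downwards) raster, one colour per gene.

    Cells expressing several of the selected genes blend additively.
    Returns the matplotlib figure; writes ``path`` if given (PNG/SVG by
    suffix, deterministic for fixed inputs).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    genes = list(genes) if genes is not None else list(result.gene_order)
    if not genes:
        raise ValueError("gene selection must be non-empty")
    unknown = set(genes) - set(result.gene_order)
    if unknown:
        raise ValueError(f"unknown genes {sorted(unknown)}")
    arr = result.layer(layer)
    palette = cmap_colors or [
        (0.85, 0.10, 0.10),
        (0.10, 0.55, 0.10),
        (0.15, 0.25, 0.80),
        (0.85, 0.65, 0.10),
        (0.55, 0.10, 0.65),
        (0.10, 0.65, 0.65),
        (0.40, 0.40, 0.40),
        (0.80, 0.40, 0.10),
    ]
    t, c, _ = arr.shape
    img = np.ones((t, c, 3))
    for n, g in enumerate(genes):
        gi = result.gene_order.index(g)
        colour = np.array(palette[n % len(palette)])
        mask = arr[:, :, gi]
        img[mask] = img[mask] * colour  # multiplicative blend, stain-like
    fig, ax = plt.subplots(figsize=(max(3, c / 12), max(2, t / 30)), dpi=dpi)
    ax.imshow(img, aspect="auto", interpolation="nearest", origin="upper")
    ax.set_xlabel("cell (anterior → posterior)")
    ax.set_ylabel("time step")
    handles = [
        plt.Line2D([], [], marker="s", linestyle="", color=palette[n % len(palette)], label=g)
        for n, g in enumerate(genes)
    ]
    ax.legend(handles=handles, loc="upper right", fontsize="small")
    fig.tight_layout()
    if path is not None:
        fig.savefig(Path(path), metadata=_stable_metadata(Path(path).suffix))
        plt.close(fig)
    return fig


def _stable_metadata(suffix: str) -> dict:
    if suffix == ".png":
        return {"Software": "boolseg"}
    if suffix == ".svg":
        return {"Date": None}
    return {}


# ---------------------------------------------------------------------------
# manifests


@dataclasses.dataclass
class RunManifest:
    """Everything needed to regenerate a pipeline output."""

    command: str
    config_paths: list[str]
    seed: int | None
    delay_preset: str | None
    output_paths: list[str]
    started: str = dataclasses.field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )
    package_version: str = ""

    def __post_init__(self):
        if not self.package_version:
            from . import __version__

            self.package_version = __version__

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path
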