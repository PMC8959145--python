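"""Space-time schedules for the timer genes (cad, D, opa).

Timer genes are extrinsic to the pair-rule network: their expression is
imposed on the row as deterministic ON/OFF fronts rather than computed by
regulatory rules.  Three regimes are provided:

* **simultaneous** — cad switches off (and opa on) at the same step in every
  cell: the whole row leaves the early regime at once, as in *Drosophila*;
* **progressive** — the cad-off / opa-on fronts sweep anterior-to-posterior
  at a fixed rate, so anterior cells hand over to the late network first, as
  in *Nasonia*;
* **posterior-sequential** — a wavefront moving posteriorly exposes each
  cell to the temporal sequence cad → D → opa, the spatial arrangement seen
  in posteriorly elongating (sequentially segmenting) insects.

All switch times are half-open: a front at step ``t`` means the new value
holds from ``t`` onwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .grn import ConfigError

#: sentinel switch time for "never"
NEVER = math.inf


@dataclass(frozen=True)
class TimerFront:
    """A single ON- or OFF-switch front for one timer input.

    ``time_at_cell[c]`` is the step at which the switch occurs in cell ``c``
    (``NEVER`` if it does not).  Progressive fronts are non-decreasing in the
    cell index (anterior cells switch first).
    """

    input: str
    kind: str  # 'switch_on' | 'switch_off'
    time_at_cell: tuple[float, ...]

    def __post_init__(self):
        if self.kind not in ("switch_on", "switch_off"):
            raise ConfigError(f"front kind must be switch_on/switch_off, got {self.kind!r}")


@dataclass(frozen=True)
class TimerSchedule:
    """Baseline values plus at most one on-front and one off-front per input."""

    n_cells: int
    baseline: Mapping[str, bool]
    fronts: tuple[TimerFront, ...] = ()

    def __post_init__(self):
        seen: set[tuple[str, str]] = set()
        for f in self.fronts:
            if f.input not in self.baseline:
                raise ConfigError(f"front for undeclared input {f.input!r}")
            if len(f.time_at_cell) != self.n_cells:
                raise ConfigError(
                    f"front for {f.input}: {len(f.time_at_cell)} times for {self.n_cells} cells"
                )
            key = (f.input, f.kind)
            if key in seen:
                raise ConfigError(f"duplicate {f.kind} front for input {f.input}")
            seen.add(key)

    @property
    def inputs(self) -> tuple[str, ...]:
        return tuple(self.baseline)

    def state_at(self, input: str, cell: int, time: int) -> bool:
        """Boolean value of a timer input at (cell, time); total and pure."""
        if input not in self.baseline:
            raise ConfigError(f"undeclared timer input {input!r}")
        if not 0 <= cell < self.n_cells:
            raise IndexError(f"cell {cell} out of range 0..{self.n_cells - 1}")
        # most recent front at or before `time` wins; ties: switch applies at its step
        value = bool(self.baseline[input])
        best_t = -math.inf
        for f in self.fronts:
            if f.input != input:
                continue
            t = f.time_at_cell[cell]
            if t <= time and t >= best_t:
                best_t = t
                value = f.kind == "switch_on"
        return value

    def to_frame(self, n_steps: int):
        """Long-format DataFrame (input, cell, time, value) for inspection."""
        import pandas as pd

        rows = [
            (name, c, t, self.state_at(name, c, t))
            for name in self.baseline
            for c in range(self.n_cells)
            for t in range(n_steps + 1)
        ]
        return pd.DataFrame(rows, columns=["input", "cell", "time", "value"])


# ---------------------------------------------------------------------------
# regime constructors

#: default per-cell gap between cad switching off and opa switching on; must
#: not exceed the rna_decay_delay of the gated genes or expression decays
#: during the handover and the late network finds nothing to latch
DEFAULT_HANDOVER_GAP = 2


def _front_times(n_cells: int, start: float, steps_per_cell: float, block: int) -> tuple[float, ...]:
    """Linear anterior-to-posterior front; ``block`` cells advance together."""
    if block < 1:
        raise ConfigError("block must be >= 1")
    return tuple(start + math.floor(steps_per_cell * block * (c // block)) for c in range(n_cells))


def make_simultaneous_schedule(
    n_cells: int, cad_off_time: float, opa_on_time: float | None = None
) -> TimerSchedule:
    """cad off and opa on at the same step in every cell (Drosophila-like)."""
    if n_cells < 1:
        raise ConfigError("n_cells must be >= 1")
    if opa_on_time is None:
        opa_on_time = cad_off_time + DEFAULT_HANDOVER_GAP
    if opa_on_time < cad_off_time:
        raise ConfigError("opa must not switch on before cad retracts")
    return TimerSchedule(
        n_cells=n_cells,
        baseline={"cad": True, "D": True, "opa": False},
        fronts=(
            TimerFront("cad", "switch_off", (cad_off_time,) * n_cells),
            TimerFront("D", "switch_off", (cad_off_time,) * n_cells),
            TimerFront("opa", "switch_on", (opa_on_time,) * n_cells),
        ),
    )


def make_progressive_schedule(
    n_cells: int,
    cad_off_start: float,
    opa_on_start: float | None = None,
    steps_per_cell: float = 0.0,
    block: int = 1,
) -> TimerSchedule:
    """cad retracts and opa expands anterior-to-posterior (Nasonia-like).

    Switch times grow linearly with the cell index at ``steps_per_cell``;
    with ``block > 1`` the front advances in blocks of that many cells
    (fractional rates then still yield integer switch times).  Rate 0
    reproduces :func:`make_simultaneous_schedule` exactly.
    """
    if n_cells < 1:
        raise ConfigError("n_cells must be >= 1")
    if steps_per_cell < 0:
        raise ConfigError("steps_per_cell must be >= 0")
    if opa_on_start is None:
        opa_on_start = cad_off_start + DEFAULT_HANDOVER_GAP
    if opa_on_start < cad_off_start:
        raise ConfigError("opa must not switch on before cad retracts in the same cell")
    cad_times = _front_times(n_cells, cad_off_start, steps_per_cell, block)
    opa_times = _front_times(n_cells, opa_on_start, steps_per_cell, block)
    return TimerSchedule(
        n_cells=n_cells,
        baseline={"cad": True, "D": True, "opa": False},
        fronts=(
            TimerFront("cad", "switch_off", cad_times),
            TimerFront("D", "switch_off", cad_times),
            TimerFront("opa", "switch_on", opa_times),
        ),
    )


def make_posterior_sequential_schedule(
    n_cells: int, wavefront_speed: float = 1.0, stage_length: float | None = None
) -> TimerSchedule:
    """A posterior segment-addition-zone regime.

    Each cell experiences the temporal sequence cad → D → opa as the
    maturation wavefront passes; at any fixed time the ON-domains along the
    row are ordered (posterior to anterior) cad, then D, then opa.
    ``wavefront_speed`` is in steps per cell; ``stage_length`` is the dwell
    time of each timer stage per cell (default: one wavefront step).
    """
    if n_cells < 1:
        raise ConfigError("n_cells must be >= 1")
    if wavefront_speed < 0:
        raise ConfigError("wavefront_speed must be >= 0")
    stage = stage_length if stage_length is not None else max(wavefront_speed, 1.0)
    arrival = tuple(math.floor(wavefront_speed * c) for c in range(n_cells))
    cad_off = tuple(a + stage for a in arrival)
    d_on = cad_off
    d_off = tuple(a + 2 * stage for a in arrival)
    opa_on = d_off
    return TimerSchedule(
        n_cells=n_cells,
        baseline={"cad": True, "D": False, "opa": False},
        fronts=(
            TimerFront("cad", "switch_off", cad_off),
            TimerFront("D", "switch_on", d_on),
            TimerFront("D", "switch_off", d_off),
            TimerFront("opa", "switch_on", opa_on),
        ),
    )


def timer_state_at(schedule: TimerSchedule, input: str, cell: int, time: int) -> bool:
    """Functional alias for :meth:`TimerSchedule.state_at`."""
    return schedule.state_at(input, cell, time)
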