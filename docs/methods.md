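# Methods

## Model

The embryo is idealised as a one-dimensional row of cells on the
anterior-posterior axis (cell 0 anterior-most).  Cells are autonomous —
there is no cell-cell signalling, division or growth — so a row simulation
is exactly N independent single-cell simulations sharing a clock, and
deleting a cell never changes any other cell's trajectory.  Time is
discrete; all updates are synchronous from the time-*t* snapshot, so the
order in which genes or cells are evaluated can never matter.

Each gene in each cell carries a Boolean RNA state and a Boolean protein
state plus three age counters.  Regulatory rules are Boolean formulas over
`protein(g)` literals (transcription-factor logic reads protein, not RNA)
and `input(x)` literals for the extrinsic timer genes; `AND`/`OR`/`NOT`,
parentheses and `TRUE`/`FALSE` are the only connectives.

### Delay semantics

Let `rule(t)` be the rule value on the time-*t* snapshot and `s` the number
of steps since the rule last held.  Per gene, with delay parameters
`synthesis_delay`, `rna_decay_delay`, `protein_decay_delay` (time-steps,
all ≥ 0):

* `RNA(t+1)` is on iff `s ≤ rna_decay_delay`: transcription follows the
  rule immediately and the transcript outlives the rule by
  `rna_decay_delay` steps;
* protein switches on once RNA has been continuously on for
  `synthesis_delay` prior steps, and persists `protein_decay_delay` steps
  after RNA switches off; a fresh RNA pulse must accumulate the synthesis
  delay again.

Counters saturate one step beyond the largest behavioural threshold, so a
long-silent or long-expressed gene is a literal fixed point of the state
dataclass.  With all delays 0 ("simplified" preset) protein equals RNA
equals the previous rule value and the model reduces to a plain synchronous
Boolean network — verified in the tests against an independent synchronous
updater over every 2- and 3-gene repression rule set and all of their
initial states.

### Delay presets and calibration

Two presets are shipped.  `simplified` (0,0,0) is used for all attractor
analysis, avoiding arbitrary age assignments when initialising from
expression snapshots.  `framework` (synthesis 2, RNA decay 3, protein decay
3) is used for row simulations and the topology screens.  The framework
values are a calibration, not measurements: they are chosen so that the
screened four-gene ring oscillates with an eight-phase period of exactly 40
steps (five steps per phase), i.e. 2.5 full oscillations in a 100-step run.
The screen's *qualitative* outcome is insensitive to this choice — the
four-gene screen returns the same unique topology for every delay
combination in 0..4³ — but the oscillation count obviously scales with the
phase duration.

### Initial conditions

Stripe prepatterns and screen initial phases set genes to *mature*
expression (RNA and protein on, ages saturated).  A prepattern is an
established expression domain; in a repression-only network a gene with RNA
but no protein represses nothing, so an immature initialisation would let
every gene switch on one step later and erase the supplied phasing.

## Timer schedules

`cad`, `D` and `opa` are inputs, not modelled genes: deterministic
space-time Boolean profiles with at most one on- and one off-switch per
cell (no flicker), half-open in time.  Three regimes:

* **simultaneous** — `cad` off (with `D`) and `opa` on at the same step in
  every cell;
* **progressive** — the same two fronts sweep anterior→posterior at
  `steps_per_cell`, optionally advancing in blocks of cells;
* **posterior-sequential** — a wavefront exposes each cell to the temporal
  sequence `cad` → `D` → `opa`, so at any instant the spatial order along
  the row is (posterior→anterior) `cad`, `D`, `opa`.

The default gap between `cad`-off and `opa`-on in a cell is 2 steps.  The
gap must not exceed the gated genes' RNA decay delay: during the handover
neither regime's rule term holds, and a longer gap lets RNA (then protein)
decay before the late regime can latch, erasing the pattern.

The shipped *progressive* reference schedule advances one 16-cell repeat
per 40-step oscillation (2.5 steps/cell) in two-cell blocks, matching the
two-cell phase granularity of the prepattern.  Block-wise advance keeps
per-cell maturation times exactly non-decreasing; a strictly per-cell
linear front gives the same final 8-cell repeat but with ±2-step local
jitter in maturation times.

## The topology screens

Enumeration space: all zero-diagonal Boolean repression matrices — 2^12 =
4096 over {hairy, eve, runt, odd}, 2^20 = 1,048,576 with the fifth free
gene X.  Matrices map to rule sets by constitutive activation with
repression dominance: a gene's rule is the conjunction of `NOT protein(r)`
over its repressors (`TRUE` if none).  Self-repression is excluded from the
space; activating edges are out of scope.

A single autonomous cell is simulated 100 steps from initial phase
{hairy} (plus X for the five-gene screen, X mature like hairy).  The RNA
expressed-set trajectory — auxiliary genes projected out first — is
collapsed over consecutive duplicates and matched against the eight-phase
cycle.  Matching is strict: the collapsed trajectory must begin at the
cycle's first phase and follow it in order with no foreign or out-of-order
phases, and must complete **at least one full traversal** (a trailing
partial cycle is fine).  The traversal requirement is essential: without
it, every topology that freezes at {hairy} forever — hundreds of thousands
of them — would match vacuously.

The screen runs in a bit-packed vectorised engine (one numpy row per
topology, cycle matching as a per-topology automaton, failed topologies
compacted away each step); the whole 2^20 five-gene screen takes seconds.
The engine's semantics are pinned to the scalar simulator by tests: the
passing sets agree with per-topology scalar simulation on every 3-gene
topology and with an independent set-algebra reimplementation on 2- and
3-gene rosters.

The four-gene screen returns exactly one passing topology, the
double-repression ring in which each gene is repressed by its two
successors in the hairy→eve→runt→odd cycle; it is pinned in
`boolseg.screen.FOUR_GENE_SOLUTION` as a regression fixture and recomputed
by the tests.

The five-gene screen then removes topologies "identical to the four-gene
network".  The default reading (`filter_mode="inert"`): the 4×4 core equals
the unique solution *and* X has no outgoing repressions onto core genes
(with no outgoing edges X cannot influence the core, so such networks are
the four-gene network with a passenger).  The stricter alternative
(`filter_mode="core"`) removes every network whose core equals the solution
regardless of X's edges.  Under the shipped defaults the screen finds 101
passing topologies, 85 after the inert filter and 29 after the core filter.
In the filtered sets no single repression edge occurs in every network.

## Attractor analysis

In simplified mode the successor function is evaluated vectorially over all
2^n states (roster order = bit order, gene 0 least significant); the
functional graph is traversed from every initial condition with
memoisation, yielding every attractor with its exact basin size.  Basins
partition the state space (asserted in tests), attractor cycles are rotated
so the smallest encoded state leads, and attractors are sorted by that
state for reproducible output.  A 20-gene cap guards against accidentally
materialising huge graphs; single trajectories (`trajectory_to_attractor`)
have no cap.  Equivalence with a naive per-state trajectory-following
oracle is tested on 100 seeded random rule sets of 2–5 genes.

## Reference rule sets

The **early** rule set is the screened four-gene ring, gated by the timers:
each gene's rule is `(cad AND NOT opa AND <ring repression>) OR (opa AND
protein(self))`.  While `cad` is on the ring oscillates; when `opa` arrives
each gene latches its own protein state, freezing the cell's current phase
— a minimal stand-in for late-network stabilisation that preserves exactly
the quantity the timer experiments measure (the spatial repeat of the
frozen pattern).

The **late** rule set (simplified mode, `opa` frozen on) is assembled from
the regulatory constraints the expression data support: slp/odd mutual
repression; prd autoactivation only (so prd can never arise in a cell that
lacks it — a structural property asserted over all 256 states); eve
maintained but never initiated (no secondary eve stripes); slp repressing
odd and ftz; en arising where eve or ftz persist, wg where slp persists,
mutually exclusive.  Its synchronous attractors are the segment-polarity
vocabulary — point attractors {eve,en}, {ftz,en}, {odd}, {slp,runt,wg}
(±prd) — plus a two-cycle in which slp and odd, co-expressed with neither
dominant, blink in antiphase.  That cycle is reached exactly by cells whose
initial state co-expresses slp and odd, which is how the stage-iv C4 cell
acquires a cycling fate in this model; the underlying cause here is the
slp/odd co-expression being inconsistent with their mutual repression, a
mechanism the model makes explicit.

The C1–C8 fixtures are synthetic transcriptions of a two-parasegment
expression map in three scenarios (*Drosophila*-like; *Nasonia* stage iii
with no prd and slp co-expressed with odd; *Nasonia* stage iv partially
resolved), pinned in `boolseg.reference.FIXTURES` together with the
resulting *Drosophila* reference fates.  The fixture format (TSV of cell,
gene, on) is the normative part; the values are modelling choices.  slp is
omitted from C1 because no rule sustains it there — it would decay on the
first step regardless.

Both rule sets live in editable YAML config files (`boolseg/data/`), so an
alternative transcription of the regulatory logic can be dropped in with no
code changes.

## Synthetic data

The stripe generator emulates the blastoderm pair-rule prepattern: the
four primary genes in six-cell stripes phased hairy→eve→runt→odd around a
16-cell repeat on a 64-cell row (adjacent genes overlapping by two cells,
which reproduces the eight observed co-expression phases along the axis); a
*Drosophila*-like preset uses four-cell stripes on an eight-cell repeat.
What it does **not** emulate: graded (non-Boolean) expression, nuclear
density changes, stripe-to-stripe irregularity, terminal regions, and the
anterior stripe-shifting dynamics of real embryos.  Passing tests therefore
show internal consistency of the model under idealised inputs, not
agreement with imaging data.  Random repression-only rule sets
(seed-deterministic, i.i.d. edges) exist solely to drive the oracle
property suites.

## Numerical and design choices

* Coordinates: cell 0 anterior; time from 0; all intervals half-open.
* Spatial repeat measurement trims a margin (default 8 cells) from both
  row ends and accepts the smallest period p confirmed over the whole
  trimmed core, with candidates capped at half the core so every accepted
  period is seen at least twice; aperiodic cores return a sentinel, not an
  exception.  A 64-cell row with margin 8 is the smallest default that
  holds two full 16-cell repeats inside the margins.
* Maturation time is the first step from which a cell's RNA *and* protein
  never change again; RNA alone settles 2–3 steps before the protein layer
  and shows phase-dependent ±1-step jitter.
* Phase sets are read from the RNA layer (expression data describe RNA).
* Topologies are enumerated in lexicographic bit-string order
  (off-diagonal cells row-major); screens are deterministic and
  order-stable.
* There is no randomness anywhere in the pipeline proper; seeds only drive
  the synthetic rule-set generator used by the property tests.

## Known limitations

* The delay update table is a documented minimal model of "expression with
  age"; other delay conventions would shift phase durations and could
  reshuffle the margins of the screen's passing sets (the four-gene
  screen's uniqueness is robust across all delay presets tested, but the
  five-gene passing count is not expected to be portable across update
  conventions).
* The opa-latch early rule set freezes the early phase rather than
  resolving it through a full late network; it reproduces repeat-period
  and maturation-order observables only.
* The late network is a constraint-based reconstruction, not a transcribed
  reference network; fate tables are pinned against this package's own
  rule set.
* No asynchronous or stochastic updating, no activating-edge screens, no
  cell-cell signalling, and no model of the opa-only middle-embryo stripe
  (stripe 6), which follows a different timer sequence in the embryo.
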