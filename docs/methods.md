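# Methods

This note documents the data model, the analyses, the synthetic-data
generator and the numerical/design choices behind `homecage`, at the level
of detail a user needs to interpret results or extend the package.

## Data model and conventions

A recording session is a stream of immutable records: `Visit` (one corner
entry of one mouse, with its ordered `Nosepoke`s), `EnvironmentalConditions`,
`LogEntry` and `HardwareEvent` side channels, plus the `Animal`/`Group`
roster.  Immutability (frozen dataclasses) makes records safely shareable
across analyses; all derived quantities are pure functions of them.

**Time.**  Every timestamp is timezone-aware; naive datetimes are rejected
at construction.  Comparisons and differences are taken on the absolute
(UTC) axis, so records and phases defined in different zones compose
correctly.  The archive dialect stores milliseconds; the writer rejects
sub-millisecond timestamps rather than silently truncating, keeping
`write ∘ read` and `read ∘ write` exact inverses.  All intervals
(phases, query windows, visits, failure periods) are half-open
`[start, end)`, which makes consecutive windows partition time without
double counting.

**Side numbering.**  Sides are integers 1–8 over the whole cage; sides
`2k-1`/`2k` are the left/right doors of corner `k`, and `Nosepoke.Door`
derives `"left"`/`"right"` from the parity.  The controller hardware this
emulates does not publish its integer coding; this package's convention is
self-consistent across generator, archive dialect and metrics, which is
what the analyses require.

**Condition flags.**  `CornerCondition`/`SideCondition` take values
`{-1, 0, +1}`: positive means the visited corner / poked side was the one
marked correct (rewarded, accessible) for that mouse in the experiment
design, zero means no contingency was in force (free adaptation).  All
metrics test positivity only, so a two-level design loses nothing.

**No implicit filtering.**  The loader materializes every parsable row —
including mutually inconsistent ones (a nosepoke outside its visit, a side
from another corner).  Loaded counts always equal table line counts.
Cleaning is a *reporting* concern: `check_integrity` lists structural
problems (containment violations, side/corner mismatches, overlapping
visits in one corner, visits outside the session interval, more than 16
distinct mice in a cage) and `flag_affected` marks visits that overlap
hardware-failure windows.  Nothing is ever dropped or repaired.

## Failure detection

The cage controller reports RFID detection failures and lickometer
failures in its log (in this dialect: category/type `Error`/`Presence`
scoped to a corner, and `Warning`/`Lickometer` scoped to a side).  The log
entry marks an instant, but the data around it is suspect for longer, so
each entry is expanded to a symmetric window of ±`pad` seconds (default
one hour — wide enough to cover the uncertainty about when the hardware
actually degraded and recovered, narrow enough not to swallow a 12-h
phase; configurable per call and via `--pad`).  Overlapping or adjacent
windows at the same location coalesce.  A visit is affected by a presence
window when it overlaps it in the same cage and corner; by a lickometer
window when any of its nosepokes to the affected side overlaps it.
Detectors are registered by `(category, type, scope)` descriptor, so new
failure classes can be added without modifying the package.

## Analyses

- `first_nosepoke_side_counts`: visits with no nosepoke are skipped; the
  first nosepoke is the one with minimal `Start` (ties keep archive
  order — equivalent to taking the first element of the stored,
  start-ordered tuple).
- `discrimination_performance`: denominator = visits with
  `CornerCondition > 0` and ≥ 1 nosepoke; numerator = those whose first
  nosepoke has `SideCondition > 0`.
- `corner_preference_performance`: numerator = visits with
  `CornerCondition > 0`; denominator = all visits.
- Empty denominators yield *undefined* (`None`/`NaN`), never 0: a zero
  would drag cohort means down for mice that happened not to visit during
  a phase.  Cohort summaries (column means, SEM) skip undefined cells.
- `performance_matrix` slices visits per mouse × phase by visit **start**
  (a visit belongs to the phase it began in); overlap-based selection is
  available via `get_visits(..., select="overlap")` but is not the
  default, because a visit spanning a phase boundary is almost always
  dominated by its onset context.
- `intervisit_intervals` pools all mice per (cage, corner) — it measures
  corner traffic and vacancy, the quantity relevant for social dynamics —
  and by default measures **end-to-start** gaps (how long the corner stood
  empty).  Start-to-start spacing is available via `gap="start_to_start"`;
  per-mouse gaps are obtained by pre-filtering with `get_visits`.
  Negative gaps (overlap anomalies in the source data) are reported, not
  dropped.
- `log_histogram` uses bin edges `lo · 10^(k / bins_per_decade)` with
  half-open bins (last bin truncated at `hi`).  Non-positive inputs cannot
  be placed on a log axis and are counted in a separate anomaly bucket;
  positive inputs outside `[lo, hi)` are counted as out-of-range.

## Session merging

Record sequences are concatenated and stably re-sorted by their time
field, so equal timestamps keep (source order, row order) — merging is
deterministic and conserves every per-kind count (no deduplication;
duplicate detection is a validation concern).  Animals unify across
sessions: one transponder tag must always belong to one animal name, and
one name accumulates the union of its tags (re-tagging between sessions).
An `unknown` sex is treated as compatible with a known one and resolves to
it; female-vs-male is a merge conflict.  This keeps real-world rosters
(where sex is sometimes unrecorded in one session) mergeable without
weakening true conflicts.

## Synthetic experiments

The generator emulates the corner-learning protocols these cages are used
for, with enough statistical structure to exercise every code path:

- **Protocol.**  Default: 12 mice, one cage, six 12-h dark phases — two
  nosepoke-adaptation phases with uniform corner choice
  (`p_corner = 0.25`) followed by four place-preference phases with
  `p_corner = 0.55, 0.65, 0.75, 0.80` (and `p_side` ramping identically).
  Rewarded corners are assigned round-robin so mice spread over corners as
  evenly as possible; rewarded sides alternate left/right.  Condition
  flags are written from the assignment (the rewarded side is marked
  correct in every marked phase, so discrimination can be read out before
  the discrimination phase proper, as in real designs).
- **Visit process.**  Per mouse and phase, onsets are a homogeneous
  Poisson process at `visit_rate` (default 10/3 per hour ≈ 40 visits per
  12-h phase — a realistic activity level for a dark phase).  Durations
  are log-normal with median 10 s (σ = 0.8 log-units); only positivity and
  ordering matter to the analyses, so the exact family is a free choice.
  Nosepoke counts per visit are Poisson (mean 2), lick counts Poisson per
  poke (mean 6 on the rewarded side, one third of that elsewhere).
- **Corner exclusivity.**  One mouse per corner at a time is a physical
  property of the hardware, so colliding visits are shifted to start 1 ms
  after the earlier visit ends (nosepokes shift with their visit).  If any
  shift would exceed one hour the configuration is rejected as infeasible
  rather than silently distorted.  At the default rates shifts are rare
  and tiny, so the Poisson character is preserved to well within the
  binomial/Poisson tolerances the tests use.
- **Failures.**  Injected presence/lickometer failures are written into
  the log exactly as the controller would report them, and the ground
  truth records each failure's padded window and the exact set of visits
  overlapping it (computed by direct quadratic scan), giving the test
  suite an independent oracle for the detection pipeline.
- **Determinism.**  All randomness flows from one `numpy` generator seeded
  by the config; identical configs produce byte-identical archives (ZIP
  member metadata is fixed).

What the generator does **not** model: circadian modulation within phases,
social following/imitation dynamics, within-phase learning drift (choice
probabilities are per-phase step functions), and the manufacturer's
proprietary archive layout (this package defines its own documented
dialect; a real-format adapter is out of scope).  Passing tests therefore
demonstrate correctness of the *analysis machinery* under the stated
statistical assumptions, not fidelity to any particular real cohort.

## Timeline handling

Timelines are INI-style files mapping phase names to wall-clock boundaries
plus an IANA zone (see FORMAT.md).  Daylight-saving edge cases follow
common library behavior: ambiguous wall times resolve to the earlier
occurrence, nonexistent ones shift forward past the gap; both warn.  Phase
names are case-sensitive and may overlap in time (a phase and its dark
half).  Lookup failures list the available names.

## Problem sizes in the test suite

The bundled tests run on generated cohorts chosen to make the statistical
checks sharp but quick: the round-trip identity uses 100 small randomized
sessions; parameter recovery uses 40 replicates of the default 12-mouse,
6-phase protocol (~480 visits per phase column), asserting column means
within 3 binomial standard errors and monotonicity of the recovered
learning curve in ≥ 95 % of replicates; the chance-level check uses a
non-learning cohort with ≥ 10,000 visits, where the Monte-Carlo error of
the cohort mean is ≈ 0.4 percentage points, comfortably inside the ±1
point acceptance band.  The whole suite completes in well under a minute.

## Known limitations

- The integer side coding and log category/type strings of the real
  controller are undocumented in public sources; this package's choices
  are internally consistent but an adapter would be needed for
  vendor-produced archives.
- Clock drift between cages is not modeled or corrected.
- Interval membership for visits is start-based by default (see above);
  analyses that need strict overlap semantics must opt in.
- The plotting helpers are conveniences; their appearance is untested.
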