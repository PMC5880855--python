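# File dialects

This document specifies, bit-exactly, every file format the `homecage`
package reads or writes.

## Session archive (`MCD-1`)

A recording session is a ZIP archive containing exactly these members, each
a tab-delimited UTF-8 text table whose first line is the column header:

| member | columns |
|---|---|
| `Session.txt` | key/value lines (see below) |
| `Animals.txt` | `Name`, `Sex`, `Tag` |
| `Groups.txt` | `Name`, `Animals` |
| `Visits.txt` | `VisitID`, `Animal`, `Cage`, `Corner`, `Start`, `End`, `CornerCondition` |
| `Nosepokes.txt` | `VisitID`, `Side`, `Start`, `End`, `SideCondition`, `LickNumber`, `LickDuration` |
| `Environment.txt` | `DateTime`, `Cage`, `Illumination`, `Temperature` |
| `Log.txt` | `DateTime`, `Category`, `Type`, `Cage`, `Corner`, `Side`, `Notes` |
| `HardwareEvents.txt` | `DateTime`, `Cage`, `Corner`, `Side`, `Type`, `State` |

General rules:

- Fields never contain tabs, carriage returns or newlines; rows end with
  `\n`; the final row is newline-terminated.
- Timestamps are `YYYY-MM-DD HH:MM:SS.mmm ±HHMM` — millisecond resolution
  with a mandatory UTC offset.  Naive timestamps are a format error.
- Optional integer columns (`Cage`/`Corner`/`Side` in `Log.txt`, `Side` in
  `HardwareEvents.txt`) encode absence as the empty string.
- `Sex` is one of `female`, `male`, `unknown`.  `Tag` is one or more RFID
  transponder codes joined by `;` (sorted when written).
- `Groups.txt` `Animals` is a `;`-joined list of animal names, each of which
  must appear in `Animals.txt`.
- `VisitID` is unique within one archive; `Nosepokes.txt` uses it as a
  foreign key.  A `VisitID` without a matching visit row is an integrity
  error.  Uniqueness across archives is *not* assumed.
- `Side` is 1–8 over the whole cage: sides `2k-1` (odd, left door) and `2k`
  (even, right door) belong to corner `k`.
- `CornerCondition` / `SideCondition` are `-1`, `0` or `+1`; positive means
  the corner/side was marked correct (rewarded) for that mouse, zero means
  no contingency was in force.
- `Session.txt` holds `key<TAB>value` lines with mandatory keys `Version`
  (must be `MCD-1`), `Label`, `Start`, `End` (the recorded session
  interval, half-open).

Canonical writing order (what `write_archive` produces): visits sorted by
`Start` (stable) and numbered 1..n in that order; nosepokes grouped by
visit in visit order, each visit's pokes sorted by `Start`; all other
tables time-sorted.  ZIP member metadata is fixed, so identical sessions
produce byte-identical archives.

The loader applies **no implicit filtering**: every parsable row becomes a
record, even when rows are mutually inconsistent; inconsistencies are
surfaced by `homecage.validation`, never silently repaired or dropped.

## Timeline file

INI dialect, UTF-8, full-line `#` comments.  One section per phase; the
section name is the (case-sensitive) phase name and may contain spaces:

```ini
[DEFAULT]
tzinfo = Etc/GMT-2          # optional, inherited by sections lacking one

[PP dark]
start = 2012-08-01 13:00    # local wall clock, YYYY-MM-DD HH:MM[:SS]
end = 2012-08-02 01:00
tzinfo = Etc/GMT-2          # IANA zone name
```

`start`/`end` are wall-clock times in the named zone; phases are half-open
`[start, end)` on the absolute (UTC) axis.  At daylight-saving
transitions, an ambiguous wall time resolves to its earlier occurrence and
a nonexistent one is shifted forward past the gap (both with a warning).
Phases may overlap; names must be unique.

## Generator config (YAML)

A mapping mirroring `homecage.synth.ExperimentConfig`; all keys optional.
Example:

```yaml
n_mice: 12
n_cages: 1
start: "2012-08-01 12:00"
tzinfo: Etc/GMT-2
visit_rate: 3.3333          # visits / mouse / hour
phases:
  - {name: NPA 1 dark, duration_hours: 12.0, p_corner: 0.25, p_side: 0.5}
  - {name: Place Pref 1 dark, duration_hours: 12.0, p_corner: 0.55, p_side: 0.55}
failures:
  - {kind: presence, cage: 1, corner: 3, at_hours: 18.0}
seed: 0
```

## CLI outputs

- `validate`: TSV with columns `kind`, `cage`, `corner`, `side`, `start`,
  `end`, `n_affected_visits`, `detail`; ISO-8601 timestamps with offset.
- `summary`: TSV `mouse`, `phase`, `n_visits`, `n_nosepokes`, `n_licks`.
- `performance`: CSV `group`, `mouse`, `phase`, `performance`, `n`.
- `intervals`: CSV `cage`, `corner`, `kind`, `bin_start_s`, `bin_end_s`,
  `count` (`kind` is `bin` or `nonpositive` for anomaly counts).

All outputs are deterministic functions of the input files and flags.
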