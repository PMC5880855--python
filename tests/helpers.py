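"""Brute-force oracles used by the tests.

Everything in this module recomputes quantities directly from the raw
archive member tables (plain text parsing, quadratic algorithms), entirely
independently of the package's record model and analysis code.
"""

from __future__ import annotations

import zipfile
from datetime import datetime


def read_table(archive_path, member):
    """Member table as a list of dict rows (header-keyed, all strings)."""
    with zipfile.ZipFile(archive_path) as archive:
        text = archive.read(member).decode("utf-8")
    lines = [line for line in text.split("\n") if line != ""]
    header = lines[0].split("\t")
    return [dict(zip(header, line.split("\t"))) for line in lines[1:]]


def count_data_lines(archive_path, member):
    with zipfile.ZipFile(archive_path) as archive:
        text = archive.read(member).decode("utf-8")
    return sum(1 for line in text.split("\n") if line != "") - 1


def parse_time(text):
    return datetime.strptime(text, "%Y-%m-%d %H:%M:%S.%f %z")


def rewrite_member(src, dst, member, edit):
    """Copy an archive, passing one member's text through ``edit``."""
    with zipfile.ZipFile(src) as archive:
        members = {name: archive.read(name).decode("utf-8")
                   for name in archive.namelist()}
    members[member] = edit(members[member])
    with zipfile.ZipFile(dst, "w") as archive:
        for name, text in members.items():
            archive.writestr(name, text)


def drop_member(src, dst, member):
    with zipfile.ZipFile(src) as archive:
        members = {name: archive.read(name).decode("utf-8")
                   for name in archive.namelist() if name != member}
    with zipfile.ZipFile(dst, "w") as archive:
        for name, text in members.items():
            archive.writestr(name, text)


# --------------------------------------------------------------------------
# metric oracles (raw-table recomputation)


def _first_pokes(archive_path):
    """VisitID -> row of the earliest nosepoke (ties: first table row)."""
    first = {}
    for row in read_table(archive_path, "Nosepokes.txt"):
        vid = row["VisitID"]
        when = parse_time(row["Start"])
        if vid not in first or when < first[vid][0]:
            first[vid] = (when, row)
    return {vid: row for vid, (_, row) in first.items()}


def brute_first_poke_side_counts(archive_path, mouse=None):
    first = _first_pokes(archive_path)
    counts = {"left": 0, "right": 0}
    for row in read_table(archive_path, "Visits.txt"):
        if mouse is not None and row["Animal"] != mouse:
            continue
        poke = first.get(row["VisitID"])
        if poke is None:
            continue
        side = int(poke["Side"])
        counts["left" if side % 2 == 1 else "right"] += 1
    return counts


def brute_discrimination(archive_path, mouse=None):
    first = _first_pokes(archive_path)
    hits = total = 0
    for row in read_table(archive_path, "Visits.txt"):
        if mouse is not None and row["Animal"] != mouse:
            continue
        if int(row["CornerCondition"]) <= 0:
            continue
        poke = first.get(row["VisitID"])
        if poke is None:
            continue
        total += 1
        if int(poke["SideCondition"]) > 0:
            hits += 1
    return hits / total if total else None


def brute_intervisit(archive_path, gap="end_to_start"):
    """(cage, corner) -> gap list in seconds, recomputed quadratically."""
    rows = read_table(archive_path, "Visits.txt")
    parsed = [
        (
            (int(r["Cage"]), int(r["Corner"])),
            parse_time(r["Start"]),
            parse_time(r["End"]),
        )
        for r in rows
    ]
    result = {}
    for key in {p[0] for p in parsed}:
        located = sorted(
            [(s, e) for k, s, e in parsed if k == key], key=lambda p: p[0]
        )
        gaps = []
        for (s1, e1), (s2, _) in zip(located, located[1:]):
            anchor = e1 if gap == "end_to_start" else s1
            gaps.append((s2 - anchor).total_seconds())
        result[key] = gaps
    return result


def brute_interval_union(intervals):
    """Union of closed-open intervals by exhaustive pairwise merging."""
    remaining = list(intervals)
    merged = []
    while remaining:
        start, end = remaining.pop()
        changed = True
        while changed:
            changed = False
            for other in list(remaining):
                if other[0] <= end and start <= other[1]:
                    start = min(start, other[0])
                    end = max(end, other[1])
                    remaining.remove(other)
                    changed = True
        merged.append((start, end))
    return sorted(merged)
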