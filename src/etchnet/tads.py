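"""9aaTAD transactivation-domain motif scanning.

Nine-amino-acid transactivation domains (9aaTADs) are short degenerate
motifs that mediate interaction with KIX-domain coactivators (EP300,
CREBBP, MED15). Each 9-residue window of a protein is scored against a
pattern of per-position residue classes, optionally with flanking
constraints; ``percent_match`` is the percentage of satisfied
constraints, and windows at or above a cutoff are reported.

Two stringencies ship as an editable plain-text configuration
(``data/tad_patterns.cfg``): a moderately stringent pattern and a looser
one whose position classes are supersets of the moderate classes. The
shipped classes are reconstructed from the published prediction tool's
rules; the pattern set is data, not code.

Scanning is deterministic, reports all (possibly overlapping) windows,
and never scans the reverse sequence. ``X`` residues never satisfy a
constraint.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

WINDOW = 9
VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class TADPattern:
    """Per-position residue-class constraints over a 9-residue window."""

    name: str
    stringency: str  # "moderate" | "low"
    positions: tuple[frozenset, ...]
    flank_before_disallowed: frozenset = frozenset()
    flank_after_disallowed: frozenset = frozenset()

    def __post_init__(self) -> None:
        if len(self.positions) != WINDOW:
            raise ValueError("a 9aaTAD pattern needs exactly 9 positions")
        if any(not p for p in self.positions):
            raise ValueError("every position's allowed set must be non-empty")

    @property
    def n_constraints(self) -> int:
        return (WINDOW
                + bool(self.flank_before_disallowed)
                + bool(self.flank_after_disallowed))

    def consensus(self) -> str:
        """One canonical residue per position (alphabetically first)."""
        return "".join(sorted(p)[0] for p in self.positions)


def load_patterns(path=None) -> list[TADPattern]:
    """Load patterns from a plain key-value config (shipped by default)."""
    parser = configparser.ConfigParser()
    if path is None:
        text = (resources.files("etchnet") / "data" / "tad_patterns.cfg"
                ).read_text()
        parser.read_string(text)
    else:
        with open(path) as fh:
            parser.read_file(fh)
    patterns = []
    for section in parser.sections():
        positions = tuple(
            frozenset(parser[section][f"pos{i}"].strip().upper())
            for i in range(1, WINDOW + 1))
        before = frozenset(parser[section].get(
            "flank_before_disallowed", "").strip().upper())
        after = frozenset(parser[section].get(
            "flank_after_disallowed", "").strip().upper())
        patterns.append(TADPattern(
            name=section, stringency=section, positions=positions,
            flank_before_disallowed=before, flank_after_disallowed=after))
    return patterns


def _score_window(sequence: str, start: int, pattern: TADPattern) -> float:
    """Percent of satisfied constraints for the window at 0-based start."""
    satisfied = 0
    for i, allowed in enumerate(pattern.positions):
        residue = sequence[start + i]
        if residue != "X" and residue in allowed:
            satisfied += 1
    total = WINDOW
    if pattern.flank_before_disallowed:
        total += 1
        if start == 0 or sequence[start - 1] not in \
                pattern.flank_before_disallowed:
            satisfied += 1
    if pattern.flank_after_disallowed:
        total += 1
        end = start + WINDOW
        if end >= len(sequence) or sequence[end] not in \
                pattern.flank_after_disallowed:
            satisfied += 1
    return 100.0 * satisfied / total


def scan_9aaTAD(sequence: str, patterns: Sequence[TADPattern] | None = None,
                min_percent: float = 100.0,
                seq_id: str = "seq") -> pd.DataFrame:
    """Scan every 9-residue window against every pattern.

    Returns a table (seq_id, position, window, stringency, percent_match)
    with 1-based inclusive start positions, sorted by position then
    stringency; windows below ``min_percent`` are dropped. Sequences
    shorter than 9 residues yield an empty result.
    """
    if patterns is None:
        patterns = load_patterns()
    sequence = sequence.upper()
    bad = set(sequence) - VALID_AA - {"X"}
    if bad:
        raise ValueError(f"invalid residues in sequence: {sorted(bad)}")
    rows = []
    for start in range(len(sequence) - WINDOW + 1):
        for pattern in patterns:
            pct = _score_window(sequence, start, pattern)
            if pct >= min_percent:
                rows.append((seq_id, start + 1,
                             sequence[start:start + WINDOW],
                             pattern.stringency, round(pct, 4)))
    return pd.DataFrame(rows, columns=["seq_id", "position", "window",
                                       "stringency", "percent_match"])


def scan_records(records, patterns: Sequence[TADPattern] | None = None,
                 min_percent: float = 100.0) -> pd.DataFrame:
    """Scan an iterable of Bio.SeqRecord objects."""
    if patterns is None:
        patterns = load_patterns()
    frames = [scan_9aaTAD(str(rec.seq), patterns, min_percent, rec.id)
              for rec in records]
    if not frames:
        return pd.DataFrame(columns=["seq_id", "position", "window",
                                     "stringency", "percent_match"])
    return pd.concat(frames, ignore_index=True)


STRINGENCY_ORDER = {"moderate": 0, "low": 1}


def report_tads(matches: pd.DataFrame,
                protein_ids: Iterable[str]) -> pd.DataFrame:
    """One summary row per protein: best stringency, best percent, positions.

    The best match is the highest percent_match; among equal percents the
    more stringent pattern wins. Proteins without matches are reported
    with stringency "none".
    """
    rows = []
    for protein in sorted(set(protein_ids)):
        sub = matches[matches["seq_id"] == protein]
        if sub.empty:
            rows.append((protein, "none", 0.0, ""))
            continue
        best_pct = sub["percent_match"].max()
        best = sub[sub["percent_match"] == best_pct].copy()
        best["order"] = best["stringency"].map(STRINGENCY_ORDER)
        stringency = best.sort_values("order").iloc[0]["stringency"]
        positions = sorted(best[best["stringency"] == stringency]
                           ["position"].unique())
        rows.append((protein, stringency, float(best_pct),
                     ",".join(map(str, positions))))
    return pd.DataFrame(rows, columns=["protein", "best_stringency",
                                       "best_percent", "positions"])
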