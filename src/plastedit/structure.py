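"""Protein secondary structure (Chou–Fasman) and transmembrane topology
(hydropathy windows) before and after RNA editing.

The Chou–Fasman implementation follows the classic nucleation/extension
formulation: helix nuclei are 6-residue windows with ≥4 helix formers,
sheet nuclei 5-residue windows with ≥3 sheet formers, both extended while
the adjacent 4-residue window keeps an average propensity above 1.00
(tables are on a ×100 scale); turns use the four-position bend-frequency
product with threshold 7.5×10⁻⁵.  Transmembrane segments are called with a
Kyte–Doolittle sliding window (default 19 residues, mean hydropathy > 1.6)
— a deliberately simple, deterministic stand-in for HMM topology tools, so
before/after comparisons stay self-contained.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

HELIX, SHEET, TURN, COIL = "H", "E", "T", "C"

KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

TURN_PRODUCT_THRESHOLD = 7.5e-5


class StructureError(Exception):
    pass


def load_propensity_table() -> dict[str, dict[str, float]]:
    """The packaged Chou–Fasman propensity/bend-frequency table."""
    table = {}
    ref = resources.files("plastedit.data") / "chou_fasman.tsv"
    with ref.open() as fh:
        for row in csv.DictReader(
                (l for l in fh if not l.startswith("#")), delimiter="\t"):
            table[row["residue"]] = {k: float(v) for k, v in row.items()
                                     if k != "residue"}
    if len(table) != 20:
        raise StructureError("propensity table must have 20 residues")
    return table


_TABLE = None


def _arrays(protein: str):
    global _TABLE
    _TABLE = _TABLE or load_propensity_table()
    bad = set(protein) - set(_TABLE)
    if bad:
        raise StructureError(f"non-standard residues {sorted(bad)}")
    get = lambda key: np.array([_TABLE[r][key] for r in protein])
    return get("p_helix"), get("p_sheet"), get("p_turn"), (
        np.array([_TABLE[r]["f0"] for r in protein]),
        np.array([_TABLE[r]["f1"] for r in protein]),
        np.array([_TABLE[r]["f2"] for r in protein]),
        np.array([_TABLE[r]["f3"] for r in protein]),
    )


def _nucleate_and_extend(p: np.ndarray, window: int, min_formers: int) -> set[int]:
    """Residue indices covered by nucleated-and-extended regions."""
    n = len(p)
    covered: set[int] = set()
    formers = p > 100.0
    for i in range(n - window + 1):
        if formers[i:i + window].sum() >= min_formers:
            covered.update(range(i, i + window))
    if not covered:
        return covered
    # extension: grow each maximal covered run while the 4-residue window
    # just beyond the boundary keeps average propensity > 1.00
    runs = _runs(sorted(covered))
    grown: set[int] = set()
    for start, end in runs:
        while start > 0 and np.mean(p[max(0, start - 1):start + 3]) > 100.0:
            start -= 1
        while end < n - 1 and np.mean(p[max(0, end - 2):end + 2]) > 100.0:
            end += 1
        grown.update(range(start, end + 1))
    return grown


def _runs(indices: list[int]) -> list[tuple[int, int]]:
    runs = []
    for idx in indices:
        if runs and idx == runs[-1][1] + 1:
            runs[-1][1] = idx
        else:
            runs.append([idx, idx])
    return [tuple(r) for r in runs]


def chou_fasman(protein: str) -> str:
    """Per-residue secondary-structure states over {H, E, T, C}.

    Helix/sheet overlaps are resolved by the higher average propensity over
    the contested run (helix wins exact ties); turn assignments take
    precedence where the turn condition — bend product above threshold,
    mean turn propensity above 1.00 and above both helix and sheet means —
    holds.  Pure function: identical input gives identical output.
    """
    protein = protein.upper()
    if not protein:
        return ""
    pa, pb, pt, (f0, f1, f2, f3) = _arrays(protein)
    n = len(protein)
    helix = _nucleate_and_extend(pa, 6, 4)
    sheet = _nucleate_and_extend(pb, 5, 3)
    states = [COIL] * n
    for i in sorted(helix - sheet):
        states[i] = HELIX
    for i in sorted(sheet - helix):
        states[i] = SHEET
    for start, end in _runs(sorted(helix & sheet)):
        seg = slice(start, end + 1)
        winner = HELIX if pa[seg].mean() >= pb[seg].mean() else SHEET
        for i in range(start, end + 1):
            states[i] = winner
    for i in range(n - 3):
        product = f0[i] * f1[i + 1] * f2[i + 2] * f3[i + 3]
        window = slice(i, i + 4)
        if (product > TURN_PRODUCT_THRESHOLD
                and pt[window].mean() > 100.0
                and pt[window].mean() > pa[window].mean()
                and pt[window].mean() > pb[window].mean()):
            for j in range(i, i + 4):
                states[j] = TURN
    return "".join(states)


# ---------------------------------------------------------------------------
# transmembrane segments


def transmembrane_segments(protein: str, window: int = 19,
                           threshold: float = 1.6) -> list[tuple[int, int]]:
    """Candidate transmembrane segments as 1-based closed residue intervals.

    A residue belongs to a segment iff some length-``window`` window
    containing it has mean Kyte–Doolittle hydropathy above ``threshold``;
    overlapping windows merge.  Proteins shorter than the window yield an
    empty list with a warning.
    """
    protein = protein.upper()
    if window % 2 == 0:
        raise StructureError("window must be odd")
    n = len(protein)
    if n < window:
        warnings.warn(f"protein length {n} < window {window}; no call")
        return []
    bad = set(protein) - set(KYTE_DOOLITTLE)
    if bad:
        raise StructureError(f"non-standard residues {sorted(bad)}")
    kd = np.array([KYTE_DOOLITTLE[r] for r in protein])
    means = np.convolve(kd, np.ones(window) / window, mode="valid")
    hot = means > threshold  # window starting at index k covers k..k+window-1
    marked = np.zeros(n, dtype=bool)
    for k in np.nonzero(hot)[0]:
        marked[k:k + window] = True
    return [(int(s) + 1, int(e) + 1)
            for s, e in _runs([int(i) for i in np.nonzero(marked)[0]])]


# ---------------------------------------------------------------------------
# before/after comparison


@dataclass(frozen=True)
class SegmentDiff:
    kind: str  # unchanged | expanded | contracted | shifted | new | lost
    before: tuple[int, int] | None
    after: tuple[int, int] | None
    direction: str | None = None  # N or C, for expanded/contracted/shifted


@dataclass
class TopologyReport:
    segments_before: list[tuple[int, int]]
    segments_after: list[tuple[int, int]]
    diffs: list[SegmentDiff] = field(default_factory=list)
    changed_windows: list[tuple[int, int]] = field(default_factory=list)

    @property
    def changed(self) -> bool:
        return bool(self.changed_windows
                    or [d for d in self.diffs if d.kind != "unchanged"])


def _classify_pair(a: tuple[int, int], b: tuple[int, int]) -> SegmentDiff:
    if a == b:
        return SegmentDiff("unchanged", a, b)
    if b[0] <= a[0] and b[1] >= a[1]:
        direction = "C" if b[1] > a[1] and b[0] == a[0] else (
            "N" if b[0] < a[0] and b[1] == a[1] else "both")
        return SegmentDiff("expanded", a, b, direction)
    if a[0] <= b[0] and a[1] >= b[1]:
        direction = "C" if a[1] > b[1] and a[0] == b[0] else (
            "N" if a[0] < b[0] and a[1] == b[1] else "both")
        return SegmentDiff("contracted", a, b, direction)
    return SegmentDiff("shifted", a, b, "C" if b[0] > a[0] else "N")


def diff_segments(before: list[tuple[int, int]],
                  after: list[tuple[int, int]]) -> list[SegmentDiff]:
    """Classify interval changes between two sorted segment lists.

    Overlapping pairs classify by interval algebra (identical, expanded,
    contracted, shifted); disjoint segments pair with their mutual nearest
    counterpart as shifted when closer than the longer segment's length;
    leftovers are new/lost.
    """
    before, after = sorted(before), sorted(after)
    unmatched_b, unmatched_a = list(before), list(after)
    diffs = []
    for a in before:
        overlapping = [b for b in unmatched_a if b[0] <= a[1] and b[1] >= a[0]]
        if overlapping:
            b = max(overlapping,
                    key=lambda iv: min(iv[1], a[1]) - max(iv[0], a[0]))
            diffs.append(_classify_pair(a, b))
            unmatched_b.remove(a)
            unmatched_a.remove(b)
    # disjoint-but-nearest pairing → shifted
    for a in list(unmatched_b):
        if not unmatched_a:
            break
        mid = lambda iv: (iv[0] + iv[1]) / 2
        b = min(unmatched_a, key=lambda iv: abs(mid(iv) - mid(a)))
        max_len = max(a[1] - a[0] + 1, b[1] - b[0] + 1)
        if abs(mid(b) - mid(a)) <= max_len:
            diffs.append(SegmentDiff("shifted", a, b,
                                     "C" if mid(b) > mid(a) else "N"))
            unmatched_b.remove(a)
            unmatched_a.remove(b)
    diffs.extend(SegmentDiff("lost", a, None) for a in unmatched_b)
    diffs.extend(SegmentDiff("new", None, b) for b in unmatched_a)
    diffs.sort(key=lambda d: (d.before or d.after)[0])
    return diffs


def structure_diff(before, after) -> TopologyReport:
    """Compare structures before and after editing.

    Accepts either two per-residue state strings (equal length required) or
    two transmembrane segment lists.  State strings yield changed-window
    runs plus per-state (H/E) segment diffs; interval lists yield the
    classified topology diff.
    """
    if isinstance(before, str) != isinstance(after, str):
        raise StructureError("before/after must be the same kind")
    if isinstance(before, str):
        if len(before) != len(after):
            raise StructureError("state strings differ in length")
        changed = _runs([i for i, (x, y) in enumerate(zip(before, after))
                         if x != y])
        diffs = []
        for state in (HELIX, SHEET, TURN):
            segs_b = _state_segments(before, state)
            segs_a = _state_segments(after, state)
            diffs.extend(diff_segments(segs_b, segs_a))
        return TopologyReport(
            _state_segments(before, HELIX) + _state_segments(before, SHEET),
            _state_segments(after, HELIX) + _state_segments(after, SHEET),
            [d for d in diffs if d.kind != "unchanged"],
            [(s + 1, e + 1) for s, e in changed])
    return TopologyReport(sorted(before), sorted(after),
                          diff_segments(before, after))


def _state_segments(states: str, state: str) -> list[tuple[int, int]]:
    return [(s + 1, e + 1) for s, e in
            _runs([i for i, ch in enumerate(states) if ch == state])]
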