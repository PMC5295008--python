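"""Cross-species editing-site conservation: status matrices, per-site
conservation classes, and Venn-style set comparison.

Status alphabet (glyphs follow the field's tabular convention):

* ``+``   complete editing observed
* ``+a``  partial editing observed
* ``-``   no editing, C encoded in genomic DNA
* ``(-)`` no editing, T already encoded in genomic DNA (re-mutation)
* blank   unknown / no information
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import pandas as pd

EDITED = "+"
PARTIAL = "+a"
UNEDITED_C = "-"
GENOMIC_T = "(-)"
UNKNOWN = ""

STATUSES = (EDITED, PARTIAL, UNEDITED_C, GENOMIC_T, UNKNOWN)


class ComparativeError(Exception):
    pass


def classify_status(genomic_base: str, edited_observed: bool,
                    efficiency: float | None = None) -> str:
    """Status of one species at one ortholog site.

    ``genomic_base`` is the base on the coding strand at the site; an
    encoded T needs no editing ("(-)"); an encoded C is "+" at 100%
    efficiency, "+a" below, "-" when unedited, blank when unobserved.
    """
    if genomic_base not in ("C", "T"):
        raise ComparativeError(
            f"genomic base at an editing column must be C or T, got "
            f"{genomic_base!r}")
    if genomic_base == "T":
        return GENOMIC_T
    if not edited_observed:
        return UNKNOWN if efficiency is None else UNEDITED_C
    if efficiency is None or efficiency >= 100:
        return EDITED
    return PARTIAL


@dataclass
class SpeciesSiteMatrix:
    """Ortholog site × species status matrix.

    ``data`` holds status glyphs, indexed by (gene, site ordinal) with one
    column per species; ``meta`` carries per-row annotation (amino-acid
    position with optional alias, edited codon, conversion).
    """

    data: pd.DataFrame
    meta: pd.DataFrame | None = None

    def __post_init__(self):
        bad = set(self.data.to_numpy().ravel()) - set(STATUSES)
        if bad:
            raise ComparativeError(f"unknown status glyphs {sorted(bad)}")
        if self.data.index.duplicated().any():
            raise ComparativeError("duplicate site keys")

    @classmethod
    def from_rows(cls, row_keys, species, cells, meta=None) -> "SpeciesSiteMatrix":
        idx = pd.MultiIndex.from_tuples(row_keys, names=["gene", "site"])
        data = pd.DataFrame(cells, index=idx, columns=list(species))
        mdf = pd.DataFrame(meta, index=idx) if meta else None
        return cls(data, mdf)

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        if self.meta is not None:
            out = pd.concat([self.meta, out], axis=1)
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, n_meta: int = 0) -> "SpeciesSiteMatrix":
        df = pd.read_csv(path, sep="\t", index_col=[0, 1], keep_default_na=False)
        meta = df.iloc[:, :n_meta] if n_meta else None
        return cls(df.iloc[:, n_meta:], meta)


def classify_row(statuses: list[str], mode: str = "ignore_unknown") -> dict:
    """Conservation class of one matrix row.

    conserved-edited: every known status shows editing; lineage-specific:
    editing in a proper, nonempty subset of known columns; re-mutated flag:
    any species carries T in genomic DNA.  In strict mode a row containing
    unknown cells is classified indeterminate.
    """
    known = [s for s in statuses if s != UNKNOWN]
    if len(known) < 2:
        raise ComparativeError("need ≥ 2 known statuses to classify a row")
    has_unknown = len(known) < len(statuses)
    re_mutated = GENOMIC_T in known
    edited = [s for s in known if s in (EDITED, PARTIAL)]
    if mode == "strict" and has_unknown:
        cls = "indeterminate"
    elif len(edited) == len(known):
        cls = "conserved-edited"
    elif edited:
        cls = "lineage-specific"
    elif re_mutated:
        cls = "re-mutated"
    else:
        cls = "mixed"
    return {"class": cls, "re_mutated": re_mutated,
            "n_known": len(known), "has_unknown": has_unknown}


def conservation_summary(matrix: SpeciesSiteMatrix) -> pd.DataFrame:
    """Per-row conservation classes under both blank-cell conventions.

    Rows with every cell unknown are excluded.  Returns a frame with the
    ignore-unknown class, the strict class, and the re-mutation flag.
    """
    records = {}
    for key, row in matrix.data.iterrows():
        statuses = list(row)
        if all(s == UNKNOWN for s in statuses):
            continue  # excluded with warning at the reporting layer
        loose = classify_row(statuses, "ignore_unknown")
        strict = classify_row(statuses, "strict")
        records[key] = {
            "class": loose["class"], "class_strict": strict["class"],
            "re_mutated": loose["re_mutated"], "n_known": loose["n_known"],
        }
    df = pd.DataFrame.from_dict(records, orient="index")
    df.index = pd.MultiIndex.from_tuples(df.index, names=["gene", "site"])
    return df


def conservation_counts(matrix: SpeciesSiteMatrix) -> dict:
    """Class counts with and without unknown-containing rows."""
    summary = conservation_summary(matrix)
    return {
        "ignore_unknown": summary["class"].value_counts().to_dict(),
        "strict": summary["class_strict"].value_counts().to_dict(),
        "conserved_edited_ignore_unknown":
            int((summary["class"] == "conserved-edited").sum()),
        "conserved_edited_strict":
            int((summary["class_strict"] == "conserved-edited").sum()),
    }


def venn(sets: dict[str, set]) -> dict[frozenset, int]:
    """Exclusive region cardinalities for up to four named sets.

    Keys are frozensets of the names whose sets contain the region's
    elements (and no others); the empty region is omitted.  Region counts
    sum to the size of the union.
    """
    names = list(sets)
    if not 1 <= len(names) <= 4:
        raise ComparativeError("venn supports 1–4 sets")
    regions: dict[frozenset, int] = {}
    for membership in product([False, True], repeat=len(names)):
        if not any(membership):
            continue
        inside = [n for n, m in zip(names, membership) if m]
        outside = [n for n, m in zip(names, membership) if not m]
        region = set.intersection(*(set(sets[n]) for n in inside))
        for n in outside:
            region -= set(sets[n])
        regions[frozenset(inside)] = len(region)
    return regions


def compare_site_sets(sets: dict[str, set]) -> dict:
    """Shared core, per-species unique sites, and pairwise intersections."""
    names = list(sets)
    shared = set.intersection(*(set(s) for s in sets.values()))
    unique = {n: set(sets[n]) - set.union(*(set(sets[m]) for m in names if m != n))
              for n in names} if len(names) > 1 else {names[0]: set(sets[names[0]])}
    pairwise = {frozenset((a, b)): len(set(sets[a]) & set(sets[b]))
                for i, a in enumerate(names) for b in names[i + 1:]}
    missing = {n: set.union(*(set(s) for s in sets.values())) - set(sets[n])
               for n in names}
    return {"shared": shared, "unique": unique, "pairwise": pairwise,
            "absent": missing}
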