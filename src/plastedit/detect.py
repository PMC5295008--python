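"""C-to-U editing-site calling from per-position base-count tables.

A site is a genomic position whose transcript-strand reference base is C and
whose reads show the edited base (T on the coding strand): genomic C→T for
sense transcripts, genomic G→A read as C→T for antisense transcripts.
Editing efficiency is edited reads over total mapped reads; a candidate is
kept when at least one sample passes both the efficiency and the
read-support filter (defaults: ≥5% and more than five edited reads).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .plastome import ANTISENSE, SENSE, Plastome, SiteAddress, locate

COLUMNS = ["pos", "ref", "A", "C", "G", "T", "depth"]


class DetectError(Exception):
    pass


class ConsistencyError(DetectError):
    pass


def efficiency(edited_reads: int, total_reads: int) -> float:
    """Editing efficiency in percent: 100 × edited / total mapped reads.

    Stored unrounded; reports round to the nearest integer percent.
    """
    if total_reads <= 0:
        raise DetectError("efficiency undefined for total_reads = 0")
    if not 0 <= edited_reads <= total_reads:
        raise DetectError("edited_reads must lie in [0, total_reads]")
    return 100.0 * edited_reads / total_reads


def round_percent(eff: float) -> int:
    """Half-up rounding to integer percent, as printed in site reports
    (32.5 prints as 33)."""
    return int(math.floor(eff + 0.5))


@dataclass
class CountTable:
    """Per-position base counts for one sample, on the published strand."""

    sample_id: str
    data: pd.DataFrame  # columns: pos, ref, A, C, G, T, depth

    def __post_init__(self):
        missing = set(COLUMNS) - set(self.data.columns)
        if missing:
            raise DetectError(f"{self.sample_id}: missing columns {sorted(missing)}")
        counts = self.data[["A", "C", "G", "T"]]
        if (counts.to_numpy() < 0).any():
            raise DetectError(f"{self.sample_id}: negative base count")
        if (counts.sum(axis=1) > self.data["depth"]).any():
            raise DetectError(f"{self.sample_id}: base counts exceed depth")

    @classmethod
    def from_tsv(cls, path: str | Path, sample_id: str | None = None) -> "CountTable":
        df = pd.read_csv(path, sep="\t")
        if sample_id is None:
            sample_id = df["sample"].iloc[0] if "sample" in df else Path(path).stem
        return cls(sample_id, df[COLUMNS].copy())

    def to_tsv(self, path: str | Path) -> None:
        out = self.data[COLUMNS].copy()
        out["sample"] = self.sample_id
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_sam(cls, path: str | Path, plastome: Plastome,
                 sample_id: str | None = None, min_base_quality: int = 0,
                 ) -> "CountTable":
        """Pile up a SAM/BAM alignment into a count table.

        No mapping- or base-quality filtering is applied beyond
        ``min_base_quality`` (default 0), mirroring a plain pileup.
        """
        import numpy as np
        import pysam

        index = {"A": 0, "C": 1, "G": 2, "T": 3}
        counts = np.zeros((plastome.length, 4), dtype=np.int64)
        with pysam.AlignmentFile(str(path)) as af:
            for read in af:
                if read.is_unmapped:
                    continue
                seq = read.query_sequence
                quals = read.query_qualities
                for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                    if quals is not None and quals[qpos] < min_base_quality:
                        continue
                    b = index.get(seq[qpos])
                    if b is not None:
                        counts[rpos, b] += 1
        df = pd.DataFrame({
            "pos": range(1, plastome.length + 1),
            "ref": list(plastome.sequence),
            "A": counts[:, 0], "C": counts[:, 1],
            "G": counts[:, 2], "T": counts[:, 3],
        })
        df["depth"] = df[["A", "C", "G", "T"]].sum(axis=1)
        return cls(sample_id or Path(path).stem, df)


@dataclass(frozen=True)
class SampleCall:
    edited: int
    total: int

    @property
    def efficiency(self) -> float:
        return efficiency(self.edited, self.total)

    @property
    def complete(self) -> bool:
        return self.edited == self.total

    @property
    def status(self) -> str:
        return "complete" if self.complete else "partial"


@dataclass
class EditingSite:
    """A called C-to-U site with per-sample efficiencies.

    ``samples`` holds only samples passing both filters (others render
    blank); ``counts`` keeps the raw (edited, total) pairs for every sample
    with coverage, for downstream calibration work.
    """

    genome_pos: int
    strand: str
    address: SiteAddress | None
    samples: dict[str, SampleCall] = field(default_factory=dict)
    counts: dict[str, SampleCall] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return self.address.label if self.address else str(self.genome_pos)

    def status(self, sample: str) -> str:
        """complete / partial for passing samples, absent otherwise."""
        call = self.samples.get(sample)
        return call.status if call else "absent"


def _passes(edited: int, total: int, min_efficiency: float,
            min_edited_reads: int, support_mode: str) -> bool:
    if total == 0:
        return False
    support = edited if support_mode == "edited" else total
    return (efficiency(edited, total) >= min_efficiency
            and support >= min_edited_reads)


def call_sites(plastome: Plastome, tables: list[CountTable],
               min_efficiency: float = 5.0, min_edited_reads: int = 6,
               support_mode: str = "edited", locate_sites: bool = True,
               ) -> list[EditingSite]:
    """Call C-to-U candidate sites across samples.

    Both strands are evaluated at every position: genomic C rows are sense
    candidates (edited base count = T), genomic G rows are antisense
    candidates (edited base count = A).  A (position, strand) pair becomes a
    site when at least one sample passes both thresholds; output is sorted
    sense section first, then by genome position, as in per-strand report
    tables.
    """
    if min_efficiency < 0 or min_edited_reads < 0:
        raise DetectError("thresholds must be ≥ 0")
    if support_mode not in ("edited", "total"):
        raise DetectError(f"unknown support_mode {support_mode!r}")
    sites: dict[tuple[str, int], EditingSite] = {}
    for table in tables:
        df = table.data
        if (df["pos"].lt(1) | df["pos"].gt(plastome.length)).any():
            raise ConsistencyError(
                f"{table.sample_id}: positions outside the plastome")
        if plastome.sequence is not None:
            ref = df["pos"].map(lambda p: plastome.sequence[p - 1])
            if not (ref == df["ref"]).all():
                bad = df.loc[ref != df["ref"], "pos"].iloc[0]
                raise ConsistencyError(
                    f"{table.sample_id}: ref base disagrees with plastome at "
                    f"position {bad}")
        for strand, ref_base, edited_col in ((SENSE, "C", "T"), (ANTISENSE, "G", "A")):
            cand = df[df["ref"] == ref_base]
            edited = cand[edited_col].to_numpy()
            total = cand["depth"].to_numpy()
            covered = total > 0
            eff = pd.Series(0.0, index=cand.index)
            eff[covered] = 100.0 * edited[covered] / total[covered]
            support = edited if support_mode == "edited" else total
            ok = covered & (eff.to_numpy() >= min_efficiency) & (support >= min_edited_reads)
            for idx, passes in zip(cand.index, ok):
                pos = int(cand.at[idx, "pos"])
                e, t = int(cand.at[idx, edited_col]), int(cand.at[idx, "depth"])
                if not passes and (strand, pos) not in sites:
                    continue
                site = sites.get((strand, pos))
                if site is None:
                    site = EditingSite(pos, strand, None)
                    sites[(strand, pos)] = site
                if t > 0:
                    site.counts[table.sample_id] = SampleCall(e, t)
                if passes:
                    site.samples[table.sample_id] = SampleCall(e, t)
    # second pass: drop candidates created only to hold raw counts
    called = [s for s in sites.values() if s.samples]
    # back-fill raw counts for all samples at called positions
    for site in called:
        col = "T" if site.strand == SENSE else "A"
        for table in tables:
            if site.samples.get(table.sample_id) or site.counts.get(table.sample_id):
                continue
            row = table.data[table.data["pos"] == site.genome_pos]
            if len(row) and int(row["depth"].iloc[0]) > 0:
                site.counts[table.sample_id] = SampleCall(
                    int(row[col].iloc[0]), int(row["depth"].iloc[0]))
        if locate_sites:
            site.address = locate(plastome, site.genome_pos, site.strand)
    called.sort(key=lambda s: (s.strand != SENSE, s.genome_pos))
    return called


def tissue_specificity(sites: list[EditingSite],
                       sample_groups: dict[str, list[str]],
                       ) -> dict[tuple[str, int], dict]:
    """Per-site tissue profile from passing samples.

    A site is tissue-specific when every passing sample belongs to one
    tissue; the profile lists all tissues with at least one passing sample.
    """
    if not sample_groups:
        raise DetectError("empty sample group map")
    owner: dict[str, str] = {}
    for tissue, samples in sample_groups.items():
        for s in samples:
            if s in owner:
                raise DetectError(f"sample {s} assigned to two tissues")
            owner[s] = tissue
    profiles = {}
    for site in sites:
        tissues = sorted({owner[s] for s in site.samples if s in owner})
        if len(tissues) < len({owner.get(s) for s in site.samples}):
            raise DetectError("passing sample missing from the group map")
        profiles[(site.strand, site.genome_pos)] = {
            "tissues": tissues,
            "specific": len(tissues) == 1,
        }
    return profiles


def sites_to_tsv(sites: list[EditingSite], samples: list[str],
                 path: str | Path, annotations: dict | None = None) -> None:
    """Write a per-strand site report: one efficiency column per sample.

    Complete editing renders "+", failing samples render blank; other
    efficiencies round to the nearest integer percent.
    """
    rows = []
    for s in sites:
        ann = (annotations or {}).get((s.strand, s.genome_pos), {})
        row = {
            "genome_pos": s.genome_pos,
            "strand": s.strand,
            "gene_position": s.label,
            "codon": ann.get("codon_conversion", ""),
            "amino_acid": ann.get("aa_conversion", ""),
        }
        for sample in samples:
            call = s.samples.get(sample)
            if call is None:
                row[sample] = ""
            elif call.complete:
                row[sample] = "+"
            else:
                row[sample] = str(round_percent(call.efficiency))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
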