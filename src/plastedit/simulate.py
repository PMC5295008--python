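"""Synthetic plastomes, planted C-to-U editing events, and error-bearing
count tables / reads, with a ground-truth ledger.

The generator states a small but structurally complete world: a multi-gene
plastome with sense and antisense genes, one intron-containing gene and
intergenic spacers; planted editing sites with per-tissue true
efficiencies; per-sample read depth with a uniform substitution-error
process (rate ε, ε/3 to each alternative base, independent per read-base,
applied after editing).  Edited read counts at a planted site are
Binomial(depth, efficiency/100) draws.  Defaults mirror the study design:
8 tissues with 1–5 replicates (24 samples), depth 100, 1% error.

Everything is deterministic under a seed, and the ledger suffices to
recompute every expected detection outcome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .detect import COLUMNS, CountTable
from .plastome import ANTISENSE, SENSE, GeneModel, Plastome, revcomp

import pandas as pd

# replicate layout of the study's 24 RNA-seq samples
STUDY_TISSUES = {"Leaf": 5, "Pistil": 1, "Root": 4, "Seed": 3,
                 "Sheath": 4, "Spike": 3, "Stamen": 1, "Stem": 3}

_GENE_NAMES = ["psbA", "rps16", "ndhB", "atpA", "rpoB", "petB", "ndhA",
               "rps4", "ycf3", "rpl20", "ndhF", "rpoA", "rps8", "matK",
               "ndhD", "atpB"]

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"


class SimulateError(Exception):
    pass


@dataclass(frozen=True)
class PlannedSite:
    genome_pos: int
    strand: str  # transcript strand carrying the C
    efficiencies: dict  # tissue -> true efficiency in [0, 100]

    @property
    def edited_base(self) -> str:
        """Published-strand base that edited reads carry."""
        return "T" if self.strand == SENSE else "A"

    @property
    def genomic_base(self) -> str:
        return "C" if self.strand == SENSE else "G"


@dataclass
class EditingPlan:
    sites: list[PlannedSite]
    seed: int | None = None

    def validate(self, plastome: Plastome) -> None:
        for s in self.sites:
            if not 1 <= s.genome_pos <= plastome.length:
                raise SimulateError(f"planted position {s.genome_pos} out of range")
            if plastome.sequence[s.genome_pos - 1] != s.genomic_base:
                raise SimulateError(
                    f"position {s.genome_pos} ({s.strand}) is not a genomic C "
                    f"on the edited strand")
            for eff in s.efficiencies.values():
                if not 0 <= eff <= 100:
                    raise SimulateError("efficiency must lie in [0, 100]")


@dataclass
class GroundTruthLedger:
    """Everything needed to recompute expected detection outcomes."""

    params: dict
    sites: list[dict] = field(default_factory=list)
    # each: {genome_pos, strand, true_efficiencies, draws: {sample: edited}}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"params": self.params, "sites": self.sites}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthLedger":
        raw = json.loads(Path(path).read_text())
        return cls(raw["params"], raw["sites"])

    def expected_site_keys(self, min_true_efficiency: float = 0.0) -> set:
        return {(s["strand"], s["genome_pos"]) for s in self.sites
                if max(s["true_efficiencies"].values()) >= min_true_efficiency}


# ---------------------------------------------------------------------------
# plastome generation


def _random_cds(rng, n_codons: int) -> str:
    codons = ["".join(c) for c in __import__("itertools").product(_BASES, repeat=3)]
    sense_codons = [c for c in codons if c not in _STOPS]
    body = rng.choice(sense_codons, size=n_codons - 2)
    return "ATG" + "".join(body) + _STOPS[rng.integers(len(_STOPS))]


def make_plastome(n_genes: int = 5, gene_lengths=300, strands=None,
                  intron_spec: tuple[int, int] | None = (1, 120),
                  intergenic_lengths=150, seed: int = 0,
                  plastome_id: str = "synthetic-plastome",
                  outdir: str | Path | None = None) -> Plastome:
    """Generate a toy plastome (deterministic under ``seed``).

    ``intron_spec`` is (gene index, intron length) for the one optional
    intron-containing gene; ``strands`` defaults to a sense/antisense mix.
    When ``outdir`` is given, FASTA, GFF3 and GenBank renditions are
    written (byte-identical for identical inputs).
    """
    if n_genes < 1:
        raise SimulateError("need at least one gene")
    lengths = ([gene_lengths] * n_genes if isinstance(gene_lengths, int)
               else list(gene_lengths))
    if len(lengths) != n_genes or any(l % 3 or l < 9 for l in lengths):
        raise SimulateError("gene lengths must be ≥9 and divisible by 3")
    if strands is None:
        strands = [ANTISENSE if i % 3 == 2 else SENSE for i in range(n_genes)]
    if len(strands) != n_genes:
        raise SimulateError("strands must match n_genes")
    spacers = ([intergenic_lengths] * (n_genes + 1)
               if isinstance(intergenic_lengths, int) else list(intergenic_lengths))
    if len(spacers) != n_genes + 1:
        raise SimulateError("need n_genes + 1 intergenic lengths")
    if intron_spec is not None and not 0 <= intron_spec[0] < n_genes:
        raise SimulateError("intron gene index out of range")

    rng = np.random.default_rng(seed)
    parts: list[str] = []
    genes: list[GeneModel] = []
    cursor = 0

    def spacer(length):
        nonlocal cursor
        parts.append("".join(rng.choice(list(_BASES), size=length)))
        cursor += length

    spacer(spacers[0])
    for i in range(n_genes):
        name = _GENE_NAMES[i % len(_GENE_NAMES)] + ("" if i < len(_GENE_NAMES)
                                                    else f"_{i}")
        cds = _random_cds(rng, lengths[i] // 3)
        block = cds if strands[i] == SENSE else revcomp(cds)
        start = cursor + 1
        if intron_spec is not None and i == intron_spec[0]:
            ilen = intron_spec[1]
            split = len(block) // 2
            intron = "".join(rng.choice(list(_BASES), size=ilen))
            parts.append(block[:split] + intron + block[split:])
            exons = ((start, start + split - 1),
                     (start + split + ilen, start + len(block) + ilen - 1))
            cursor += len(block) + ilen
        else:
            parts.append(block)
            exons = ((start, start + len(block) - 1),)
            cursor += len(block)
        genes.append(GeneModel(name, strands[i], exons, "CDS"))
        spacer(spacers[i + 1])

    plastome = Plastome(plastome_id, "".join(parts), cursor, genes)
    if outdir is not None:
        write_plastome(plastome, outdir)
    return plastome


def write_plastome(plastome: Plastome, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA, GFF3 and GenBank renditions of a plastome."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / f"{plastome.id}.{ext}"
             for k, ext in (("fasta", "fasta"), ("gff3", "gff3"), ("genbank", "gb"))}

    with open(paths["fasta"], "w") as fh:
        fh.write(f">{plastome.id}\n")
        for i in range(0, plastome.length, 70):
            fh.write(plastome.sequence[i:i + 70] + "\n")

    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {plastome.id} 1 {plastome.length}\n")
        for g in plastome.genes:
            sym = "+" if g.strand == SENSE else "-"
            fh.write(f"{plastome.id}\tplastedit\tgene\t{g.start}\t{g.end}\t."
                     f"\t{sym}\t.\tID=gene-{g.uid};gene={g.name}\n")
            for j, (s, e) in enumerate(g.exons):
                phase = "0" if g.type == "CDS" else "."
                fh.write(f"{plastome.id}\tplastedit\t{g.type}\t{s}\t{e}\t."
                         f"\t{sym}\t{phase}\tID=cds-{g.uid};Parent=gene-{g.uid};"
                         f"gene={g.name}\n")

    record = SeqRecord(Seq(plastome.sequence), id=plastome.id,
                       description="synthetic plastome")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["date"] = "01-JAN-2000"  # fixed for determinism
    for g in plastome.genes:
        strand = 1 if g.strand == SENSE else -1
        locs = [SimpleLocation(s - 1, e, strand) for s, e in g.exons]
        if strand == -1:
            locs = list(reversed(locs))
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        record.features.append(
            SeqFeature(loc, type=g.type, qualifiers={"gene": [g.name]}))
    SeqIO.write(record, str(paths["genbank"]), "genbank")
    return paths


# ---------------------------------------------------------------------------
# plans


def make_plan(plastome: Plastome, n_sites: int, tissues=None,
              efficiency=80.0, seed: int = 0,
              features: tuple[str, ...] = ("CDS",)) -> EditingPlan:
    """Plant ``n_sites`` editing sites at genomic Cs on transcript strands.

    ``efficiency`` is a constant percent, a (low, high) range to draw from
    uniformly per site, or a mapping tissue → percent.  CDS sites are
    planted on the gene's coding strand; intergenic/intron sites on the
    strand where the genomic base is C.
    """
    from .plastome import locate

    tissues = list(tissues or STUDY_TISSUES)
    rng = np.random.default_rng(seed)
    candidates = []
    for pos in range(1, plastome.length + 1):
        for strand, base in ((SENSE, "C"), (ANTISENSE, "G")):
            if plastome.sequence[pos - 1] != base:
                continue
            addr = locate(plastome, pos, strand)
            if addr.feature in features:
                # keep start codons intact: skip the first codon of a CDS
                if addr.feature == "CDS" and addr.gene_pos <= 3:
                    continue
                candidates.append((pos, strand))
    if len(candidates) < n_sites:
        raise SimulateError(f"only {len(candidates)} candidate Cs available")
    chosen = rng.choice(len(candidates), size=n_sites, replace=False)
    sites = []
    for idx in sorted(chosen):
        pos, strand = candidates[idx]
        if isinstance(efficiency, dict):
            eff = dict(efficiency)
        elif isinstance(efficiency, (tuple, list)):
            value = float(rng.uniform(*efficiency))
            eff = {t: value for t in tissues}
        else:
            eff = {t: float(efficiency) for t in tissues}
        sites.append(PlannedSite(pos, strand, eff))
    plan = EditingPlan(sites, seed)
    plan.validate(plastome)
    return plan


# ---------------------------------------------------------------------------
# count simulation


def _samples(replicates: dict[str, int]) -> list[tuple[str, str]]:
    return [(tissue, f"{tissue}-{i}") for tissue, n in replicates.items()
            for i in range(1, n + 1)]


_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def _draw_edits(plan: EditingPlan, samples, depth: int, rng) -> dict:
    """Binomial edited-read draws, consumed sample-major then plan-order —
    the shared randomness between the count and read simulators."""
    draws = {}
    for tissue, sample in samples:
        for site in plan.sites:
            eff = site.efficiencies.get(tissue, 0.0)
            draws[(sample, site.genome_pos, site.strand)] = int(
                rng.binomial(depth, eff / 100.0))
    return draws


def simulate_counts(plastome: Plastome, plan: EditingPlan, depth: int = 100,
                    error_rate: float = 0.01, replicates=None, seed: int = 0,
                    ) -> tuple[list[CountTable], GroundTruthLedger]:
    """Per-sample base-count tables with planted edits and uniform errors."""
    if depth <= 0:
        raise SimulateError("depth must be positive")
    if not 0 <= error_rate < 1:
        raise SimulateError("error_rate must lie in [0, 1)")
    plan.validate(plastome)
    replicates = dict(replicates or STUDY_TISSUES)
    samples = _samples(replicates)
    ss = np.random.SeedSequence(seed)
    child_edit, child_err = ss.spawn(2)
    draws = _draw_edits(plan, samples, depth, np.random.default_rng(child_edit))
    rng_err = np.random.default_rng(child_err)

    n = plastome.length
    ref_idx = np.array([_BASE_INDEX[b] for b in plastome.sequence])
    tables = []
    ledger = GroundTruthLedger(params={
        "depth": depth, "error_rate": error_rate, "seed": seed,
        "replicates": replicates, "plastome": plastome.id,
        "plan_seed": plan.seed,
    })
    site_records = {
        (s.genome_pos, s.strand): {
            "genome_pos": s.genome_pos, "strand": s.strand,
            "true_efficiencies": dict(s.efficiencies), "draws": {}}
        for s in plan.sites}
    for tissue, sample in samples:
        true = np.zeros((n, 4), dtype=np.int64)
        true[np.arange(n), ref_idx] = depth
        for site in plan.sites:
            k = draws[(sample, site.genome_pos, site.strand)]
            i = site.genome_pos - 1
            true[i, _BASE_INDEX[site.genomic_base]] -= k
            true[i, _BASE_INDEX[site.edited_base]] += k
            site_records[(site.genome_pos, site.strand)]["draws"][sample] = k
        if error_rate > 0:
            observed = np.zeros_like(true)
            for src in range(4):
                pvals = np.full(4, error_rate / 3.0)
                pvals[src] = 1.0 - error_rate
                observed += rng_err.multinomial(true[:, src], pvals)
        else:
            observed = true
        df = pd.DataFrame({
            "pos": np.arange(1, n + 1), "ref": list(plastome.sequence),
            "A": observed[:, 0], "C": observed[:, 1],
            "G": observed[:, 2], "T": observed[:, 3],
        })
        df["depth"] = depth
        tables.append(CountTable(sample, df[COLUMNS]))
    ledger.sites = list(site_records.values())
    return tables, ledger


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(plastome: Plastome, plan: EditingPlan, depth: int = 100,
                   read_length: int = 100, error_rate: float = 0.0,
                   replicates=None, seed: int = 0,
                   outdir: str | Path | None = None, max_bases: int = 5e7,
                   ) -> tuple[dict[str, Path], GroundTruthLedger]:
    """SAM alignments consistent with :func:`simulate_counts`.

    Reads tile the genome in ``depth`` offset layers so every position has
    exactly ``depth``-fold coverage; at each planted site exactly the
    ledger's binomial draw of covering reads carries the edited base, so at
    error 0 the SAM-derived count table equals the direct one for the same
    seed.  Orientation flags alternate; all records are mapped with full
    CIGARs.
    """
    import pysam

    if read_length > plastome.length:
        raise SimulateError("read length exceeds the plastome")
    plan.validate(plastome)
    replicates = dict(replicates or STUDY_TISSUES)
    samples = _samples(replicates)
    if depth * plastome.length * len(samples) > max_bases:
        raise SimulateError("depth × length × samples exceeds max_bases cap")
    ss = np.random.SeedSequence(seed)
    child_edit, child_err = ss.spawn(2)
    draws = _draw_edits(plan, samples, depth, np.random.default_rng(child_edit))
    rng_err = np.random.default_rng(child_err)

    outdir = Path(outdir) if outdir else Path(".")
    outdir.mkdir(parents=True, exist_ok=True)
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": plastome.id, "LN": plastome.length}]}
    ledger = GroundTruthLedger(params={
        "depth": depth, "error_rate": error_rate, "seed": seed,
        "read_length": read_length, "replicates": replicates,
        "plastome": plastome.id, "plan_seed": plan.seed,
    })
    site_records = {
        (s.genome_pos, s.strand): {
            "genome_pos": s.genome_pos, "strand": s.strand,
            "true_efficiencies": dict(s.efficiencies), "draws": {}}
        for s in plan.sites}

    n = plastome.length
    reads: list[tuple[int, int, int]] = []  # (layer, start, end) 1-based closed
    for layer in range(depth):
        offset = (layer * read_length) // depth
        if offset > 0:
            reads.append((layer, 1, offset))
        start = offset + 1
        while start <= n:
            reads.append((layer, start, min(start + read_length - 1, n)))
            start += read_length

    paths = {}
    for tissue, sample in samples:
        path = outdir / f"{sample}.sam"
        paths[sample] = path
        edited_layers = {}
        for site in plan.sites:
            k = draws[(sample, site.genome_pos, site.strand)]
            edited_layers[(site.genome_pos, site.strand)] = set(range(k))
            site_records[(site.genome_pos, site.strand)]["draws"][sample] = k
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for ridx, (layer, start, end) in enumerate(reads):
                seq = list(plastome.sequence[start - 1:end])
                for site in plan.sites:
                    if start <= site.genome_pos <= end and \
                            layer in edited_layers[(site.genome_pos, site.strand)]:
                        seq[site.genome_pos - start] = site.edited_base
                if error_rate > 0:
                    mask = rng_err.random(len(seq)) < error_rate
                    for i in np.nonzero(mask)[0]:
                        alts = [b for b in _BASES if b != seq[i]]
                        seq[i] = alts[rng_err.integers(3)]
                a = pysam.AlignedSegment()
                a.query_name = f"{sample}.L{layer}.{start}"
                a.query_sequence = "".join(seq)
                a.flag = 16 if ridx % 2 else 0
                a.reference_id = 0
                a.reference_start = start - 1
                a.mapping_quality = 60
                a.cigarstring = f"{end - start + 1}M"
                a.query_qualities = pysam.qualitystring_to_array(
                    "I" * (end - start + 1))
                out.write(a)
    ledger.sites = list(site_records.values())
    return paths, ledger
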