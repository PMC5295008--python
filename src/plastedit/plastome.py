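"""Plastome sequence + gene models, and strand-aware coordinate transforms.

The plastome is held as the published (GenBank) strand; genes on the
antisense strand are transcribed right-to-left and all "gene position"
arithmetic counts along the coding strand from the first base of the start
codon.  Coordinates are 1-based closed intervals throughout, matching the
conventions of plastid annotation records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

SENSE = "sense"
ANTISENSE = "antisense"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement on the A/C/G/T/N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class PlastomeError(Exception):
    """Base error for plastome parsing and coordinate problems."""


class ParseError(PlastomeError):
    pass


class LookupError_(PlastomeError):
    pass


class BoundsError(PlastomeError):
    pass


@dataclass(frozen=True)
class GeneModel:
    """A gene on the plastome.

    exons are 1-based closed genomic intervals in *genome order*; for
    antisense genes the coding order is the reverse.  ``warnings`` carries
    soft validation findings (e.g. CDS length not divisible by 3).
    """

    name: str
    strand: str  # SENSE or ANTISENSE, relative to the published sequence
    exons: tuple[tuple[int, int], ...]
    type: str = "CDS"  # CDS | tRNA | rRNA | other
    warnings: tuple[str, ...] = ()

    def __post_init__(self):
        if self.strand not in (SENSE, ANTISENSE):
            raise ValueError(f"bad strand {self.strand!r}")
        prev_end = 0
        for s, e in self.exons:
            if s > e or s <= prev_end:
                raise ValueError(f"{self.name}: exons must be ordered, non-overlapping")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def is_cds(self) -> bool:
        return self.type == "CDS"

    @property
    def uid(self) -> str:
        """Unique id; inverted-repeat paralogs share a name but not a start."""
        return f"{self.name}@{self.start}"


@dataclass
class Plastome:
    """Plastome sequence plus gene models.

    ``sequence`` may be None for annotation-only workflows (coordinate
    transforms and :func:`locate` still work; CDS extraction does not).
    """

    id: str
    sequence: str | None
    length: int
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self):
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.length:
                raise ValueError("sequence length disagrees with declared length")
        if self.length <= 0:
            raise ValueError("empty plastome")
        for g in self.genes:
            if g.start < 1 or g.end > self.length:
                raise ValueError(f"{g.name}: coordinates outside [1, {self.length}]")
        seen = set()
        for g in self.genes:
            if g.uid in seen:
                raise ValueError(f"duplicate gene {g.uid}")
            seen.add(g.uid)
        self.genes.sort(key=lambda g: (g.start, g.name))

    def base(self, genome_pos: int, strand: str = SENSE) -> str:
        """Base at a 1-based position, on the requested strand."""
        if self.sequence is None:
            raise PlastomeError("plastome has no sequence")
        if not 1 <= genome_pos <= self.length:
            raise BoundsError(f"position {genome_pos} outside [1, {self.length}]")
        b = self.sequence[genome_pos - 1]
        return b if strand == SENSE else b.translate(_COMPLEMENT)

    def genes_named(self, name: str) -> list[GeneModel]:
        return [g for g in self.genes if g.name == name]

    def gene(self, name: str) -> GeneModel:
        hits = self.genes_named(name)
        if not hits:
            raise LookupError_(f"unknown gene {name!r}")
        return hits[0]

    def cds_genes(self) -> list[GeneModel]:
        return [g for g in self.genes if g.is_cds]


@dataclass(frozen=True)
class SiteAddress:
    """Address of a genomic site on a transcript strand.

    feature is one of ``CDS`` (with gene and 1-based gene_pos counted along
    the coding strand from the start codon), ``intron`` (gene only) or
    ``intergenic`` (left/right flanking genes in genome order).
    """

    genome_pos: int
    strand: str
    feature: str
    gene: str | None = None
    gene_pos: int | None = None
    gene_uid: str | None = None
    left: str | None = None
    right: str | None = None

    @property
    def codon_index(self) -> int | None:
        if self.feature != "CDS":
            return None
        return math.ceil(self.gene_pos / 3)

    @property
    def codon_pos(self) -> int | None:
        if self.feature != "CDS":
            return None
        return (self.gene_pos - 1) % 3 + 1

    @property
    def label(self) -> str:
        if self.feature == "CDS":
            return f"{self.gene}-{self.gene_pos}"
        if self.feature == "intron":
            return f"{self.gene}-intron"
        return f"{self.left or ''}~{self.right or ''}"


# ---------------------------------------------------------------------------
# loading


def _genemodel_from_feature(feat, kind: str) -> GeneModel | None:
    quals = feat.qualifiers
    name = (quals.get("gene") or quals.get("locus_tag") or [None])[0]
    if name is None:
        return None
    parts = sorted(
        ((int(p.start) + 1, int(p.end)) for p in feat.location.parts),
        key=lambda iv: iv[0],
    )
    strand = SENSE if feat.location.strand != -1 else ANTISENSE
    warnings = []
    model = GeneModel(name=name, strand=strand, exons=tuple(parts), type=kind)
    if kind == "CDS" and model.spliced_length % 3 != 0:
        warnings.append(f"CDS length {model.spliced_length} not divisible by 3")
        model = GeneModel(name, strand, tuple(parts), kind, tuple(warnings))
    return model


def load_plastome(path: str | Path, fasta: str | Path | None = None) -> Plastome:
    """Load a plastome from a GenBank flat file, or a GFF3 + FASTA pair.

    GenBank is canonical; GFF3 with its companion FASTA yields identical
    semantics.  All CDS features become gene models; tRNA/rRNA features are
    kept for intergenic flank naming.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        if fasta is None:
            raise ParseError("GFF3 input needs a companion FASTA")
        return _load_gff3(path, Path(fasta))
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ParseError(f"{path}: not a readable GenBank record ({exc})") from exc
    genes: list[GeneModel] = []
    seen = set()
    for feat in record.features:
        if feat.type not in ("CDS", "tRNA", "rRNA"):
            continue
        model = _genemodel_from_feature(feat, feat.type)
        if model is None or model.uid in seen:
            continue
        seen.add(model.uid)
        genes.append(model)
    if not any(g.is_cds for g in genes):
        raise ParseError(f"{path}: no CDS feature found")
    plastome = Plastome(record.id or path.stem, str(record.seq), len(record.seq), genes)
    _validate_cds(plastome)
    return plastome


def _load_gff3(path_gff: Path, path_fasta: Path) -> Plastome:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path_gff), ":memory:", merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"{path_gff}: not readable GFF3 ({exc})") from exc
    record = SeqIO.read(str(path_fasta), "fasta")
    genes: list[GeneModel] = []
    seen = set()
    for kind in ("CDS", "tRNA", "rRNA"):
        by_gene: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for feat in db.features_of_type(kind):
            name = (feat.attributes.get("gene")
                    or feat.attributes.get("Name")
                    or feat.attributes.get("ID") or [None])[0]
            if name is None:
                raise ParseError(f"{path_gff}: {kind} feature without gene/Name/ID")
            strand = ANTISENSE if feat.strand == "-" else SENSE
            # CDS parts of one gene share a name; collect into exons
            key = (name.split(".")[0] if kind == "CDS" else name, strand)
            by_gene.setdefault(key, []).append((feat.start, feat.end))
        for (name, strand), ivals in by_gene.items():
            ivals.sort()
            # split discontiguous paralog copies: group runs of intervals that
            # are separated by another gene's span is out of scope; IR copies
            # must use distinct IDs in GFF3 input (e.g. ndhB.1 / ndhB.2)
            model = GeneModel(name, strand, tuple(ivals), kind)
            if kind == "CDS" and model.spliced_length % 3:
                model = GeneModel(name, strand, tuple(ivals), kind,
                                  (f"CDS length {model.spliced_length} not divisible by 3",))
            if model.uid not in seen:
                seen.add(model.uid)
                genes.append(model)
    if not any(g.is_cds for g in genes):
        raise ParseError(f"{path_gff}: no CDS feature found")
    plastome = Plastome(record.id, str(record.seq), len(record.seq), genes)
    _validate_cds(plastome)
    return plastome


def _validate_cds(plastome: Plastome) -> None:
    """Attach soft warnings: internal stop codons in spliced CDS translations."""
    if plastome.sequence is None:
        return
    for i, g in enumerate(plastome.genes):
        if not g.is_cds or g.spliced_length % 3:
            continue
        prot = str(Seq(extract_cds(plastome, g)).translate())
        if "*" in prot[:-1]:
            plastome.genes[i] = GeneModel(
                g.name, g.strand, g.exons, g.type,
                g.warnings + ("internal stop codon in translation",),
            )


# ---------------------------------------------------------------------------
# coordinate transforms


def extract_cds(plastome: Plastome, gene: str | GeneModel) -> str:
    """Spliced CDS on the coding strand (reverse complement for antisense)."""
    if isinstance(gene, str):
        model = plastome.gene(gene)
        if not model.is_cds:
            raise LookupError_(f"{gene} is not a CDS gene")
    else:
        model = gene
    if plastome.sequence is None:
        raise PlastomeError("plastome has no sequence")
    spliced = "".join(plastome.sequence[s - 1:e] for s, e in model.exons)
    return revcomp(spliced) if model.strand == ANTISENSE else spliced


def cds_to_genome(gene: GeneModel, gene_pos: int) -> int:
    """Map a 1-based coding-strand position to the published-strand position."""
    if not 1 <= gene_pos <= gene.spliced_length:
        raise BoundsError(f"{gene.name}: gene_pos {gene_pos} outside CDS")
    exons = gene.exons if gene.strand == SENSE else tuple(reversed(gene.exons))
    remaining = gene_pos
    for s, e in exons:
        width = e - s + 1
        if remaining <= width:
            return s + remaining - 1 if gene.strand == SENSE else e - remaining + 1
        remaining -= width
    raise AssertionError("unreachable")


def genome_to_cds(gene: GeneModel, genome_pos: int) -> int:
    """Inverse of :func:`cds_to_genome`; genome_pos must fall in an exon."""
    offset = 0
    exons = gene.exons if gene.strand == SENSE else tuple(reversed(gene.exons))
    for s, e in exons:
        if s <= genome_pos <= e:
            within = genome_pos - s if gene.strand == SENSE else e - genome_pos
            return offset + within + 1
        offset += e - s + 1
    raise BoundsError(f"{gene.name}: position {genome_pos} not exonic")


def locate(plastome: Plastome, genome_pos: int, strand: str = SENSE) -> SiteAddress:
    """Classify a genomic position on a transcript strand.

    CDS when the position is exonic in a gene whose coding strand matches
    ``strand``; intron when inside such a gene but between its exons;
    otherwise intergenic with flanking genes named in genome order.
    """
    if not 1 <= genome_pos <= plastome.length:
        raise BoundsError(f"position {genome_pos} outside [1, {plastome.length}]")
    for g in plastome.genes:
        if g.strand != strand or not g.is_cds:
            continue
        if not g.start <= genome_pos <= g.end:
            continue
        try:
            gp = genome_to_cds(g, genome_pos)
        except BoundsError:
            return SiteAddress(genome_pos, strand, "intron", gene=g.name, gene_uid=g.uid)
        return SiteAddress(genome_pos, strand, "CDS", gene=g.name, gene_pos=gp,
                           gene_uid=g.uid)
    left = right = None
    for g in plastome.genes:  # genome order by start
        if g.end < genome_pos and (left is None or g.end > left.end):
            left = g
        elif g.start > genome_pos and right is None:
            right = g
    return SiteAddress(genome_pos, strand, "intergenic",
                       left=left.name if left else None,
                       right=right.name if right else None)


# ---------------------------------------------------------------------------
# gene-model TSV dump (annotation-only interchange)


def write_gene_table(plastome: Plastome, path: str | Path) -> None:
    """Dump gene models as TSV: name, strand, type, exon intervals."""
    with open(path, "w") as fh:
        fh.write(f"#plastome\t{plastome.id}\t{plastome.length}\n")
        fh.write("gene\tstrand\ttype\texons\n")
        for g in plastome.genes:
            ivals = ",".join(f"{s}-{e}" for s, e in g.exons)
            fh.write(f"{g.name}\t{g.strand}\t{g.type}\t{ivals}\n")


def load_gene_table(path: str | Path, sequence: str | None = None) -> Plastome:
    """Rebuild an (optionally sequence-less) Plastome from a gene-model TSV."""
    genes = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "#plastome":
            raise ParseError(f"{path}: missing #plastome header line")
        pid, length = header[1], int(header[2])
        fh.readline()  # column header
        for line in fh:
            name, strand, kind, ivals = line.rstrip("\n").split("\t")
            exons = tuple(
                tuple(int(x) for x in iv.split("-")) for iv in ivals.split(",")
            )
            genes.append(GeneModel(name, strand, exons, kind))
    return Plastome(pid, sequence, length, genes)
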