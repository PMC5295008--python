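"""Annotation of C-to-U editing sites: codon context, amino-acid
consequence, hydrophobicity transition, and flanking-nucleotide context.

Codon conversions are written in the field's compact notation: the codon in
lowercase with the edited base capitalized, before and after (e.g.
``tCa>tTa`` for a serine→leucine edit at codon position 2).  Context
triples are read on the coding strand for CDS sites and on the edited
strand for intron/intergenic sites.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from importlib import resources

from Bio.Seq import Seq

from .detect import EditingSite
from .plastome import ANTISENSE, SENSE, Plastome, SiteAddress, extract_cds, revcomp

HYDROPHILIC = "hydrophilic"
HYDROPHOBIC = "hydrophobic"
PHILIC_TO_PHOBIC = "philic->phobic"
PHOBIC_TO_PHILIC = "phobic->philic"


class AnnotateError(Exception):
    pass


class ConsistencyError(AnnotateError):
    pass


def load_hydrophobicity_table() -> dict[str, str]:
    """The packaged 20-residue binary hydrophobicity table."""
    table = {}
    ref = resources.files("plastedit.data") / "hydrophobicity.tsv"
    with ref.open() as fh:
        for row in csv.DictReader(
                (l for l in fh if not l.startswith("#")), delimiter="\t"):
            table[row["residue"]] = row["class"]
    if len(table) != 20:
        raise AnnotateError("hydrophobicity table must have 20 residues")
    return table


_HYDRO = None


def hydro_transition(aa_conversion: str, table: dict[str, str] | None = None) -> str:
    """Classify an amino-acid conversion ("S>L") by hydrophobicity exchange.

    Returns philic->phobic, phobic->philic, none (no exchange, including
    identity), or n/a for stop-involving conversions.
    """
    global _HYDRO
    if table is None:
        table = _HYDRO = _HYDRO or load_hydrophobicity_table()
    before, _, after = aa_conversion.partition(">")
    if "Stop" in (before, after) or "*" in (before, after):
        return "n/a"
    try:
        cls_b, cls_a = table[before], table[after]
    except KeyError as exc:
        raise AnnotateError(f"unknown residue in {aa_conversion!r}") from exc
    if cls_b == cls_a:
        return "none"
    return PHILIC_TO_PHOBIC if cls_b == HYDROPHILIC else PHOBIC_TO_PHILIC


def _aa(codon: str) -> str:
    aa = str(Seq(codon).translate())
    return "Stop" if aa == "*" else aa


def _conversion_strings(codon: str, codon_pos: int) -> tuple[str, str, str]:
    """(codon_conversion, aa_conversion, consequence) for a C→T edit."""
    i = codon_pos - 1
    if codon[i] != "C":
        raise ConsistencyError(f"codon {codon} has no C at position {codon_pos}")
    edited = codon[:i] + "T" + codon[i + 1:]
    fmt = lambda c: c[:i].lower() + c[i] + c[i + 1:].lower()
    aa_from, aa_to = _aa(codon), _aa(edited)
    if aa_to == "Stop":
        consequence = "stop-gain"
    elif aa_from == aa_to:
        consequence = "silent"
    else:
        consequence = "nonsynonymous"
    return f"{fmt(codon)}>{fmt(edited)}", f"{aa_from}>{aa_to}", consequence


def complete_conversion(before: str) -> str:
    """Expand a before-codon in compact notation ("tCa") to the full
    conversion string ("tCa>tTa")."""
    uppers = [i for i, ch in enumerate(before) if ch.isupper()]
    if len(uppers) != 1 or before[uppers[0]] != "C":
        raise AnnotateError(f"bad edited codon {before!r}")
    conv, _, _ = _conversion_strings(before.upper(), uppers[0] + 1)
    return conv


@dataclass(frozen=True)
class SiteAnnotation:
    """Annotation of one editing site.

    ``context`` is the (pos−1, C, pos+1) trinucleotide as a 3-char string
    with the edited C in the middle (None when no sequence is available);
    ``hydro_class`` applies to amino-acid-changing CDS sites only.
    """

    gene: str | None
    gene_pos: int | None
    label: str
    codon_index: int | None = None
    codon_pos: int | None = None
    codon_conversion: str | None = None
    aa_conversion: str | None = None
    consequence: str = "n/a"  # nonsynonymous | silent | stop-gain | n/a
    hydro_class: str = "n/a"
    context: str | None = None
    address: SiteAddress | None = None

    @property
    def site_key(self) -> tuple:
        """Deduplication key: within-gene position for CDS sites, so
        inverted-repeat copies tally once; label+genome position otherwise."""
        if self.gene is not None and self.gene_pos is not None:
            return (self.gene, self.gene_pos)
        return (self.label, self.address.genome_pos if self.address else None)

    @classmethod
    def from_codon_conversion(cls, gene: str, gene_pos: int,
                              codon_conversion: str,
                              context: str | None = None) -> "SiteAnnotation":
        """Build an annotation from the compact codon-conversion notation,
        recomputing the amino-acid consequence from the codon itself."""
        before = codon_conversion.split(">")[0]
        uppers = [i for i, ch in enumerate(before) if ch.isupper()]
        if len(uppers) != 1 or before[uppers[0]] != "C":
            raise AnnotateError(f"bad codon conversion {codon_conversion!r}")
        codon_pos = uppers[0] + 1
        conv, aa_conv, consequence = _conversion_strings(before.upper(), codon_pos)
        if conv != codon_conversion:
            raise ConsistencyError(
                f"{codon_conversion!r} is not a C→T edit at position {codon_pos}")
        hydro = (hydro_transition(aa_conv) if consequence == "nonsynonymous"
                 else "n/a")
        return cls(gene=gene, gene_pos=gene_pos, label=f"{gene}-{gene_pos}",
                   codon_index=(gene_pos - 1) // 3 + 1, codon_pos=codon_pos,
                   codon_conversion=conv, aa_conversion=aa_conv,
                   consequence=consequence, hydro_class=hydro, context=context)


def annotate_site(plastome: Plastome, site: EditingSite | SiteAddress,
                  ) -> SiteAnnotation:
    """Annotate a called site (or bare address) against the plastome."""
    addr = site if isinstance(site, SiteAddress) else site.address
    if addr is None:
        raise AnnotateError("site has no resolved address")
    if addr.feature != "CDS":
        return SiteAnnotation(gene=addr.gene, gene_pos=None, label=addr.label,
                              context=_genomic_context(plastome, addr),
                              address=addr)
    gene = plastome.gene(addr.gene) if addr.gene_uid is None else next(
        g for g in plastome.genes if g.uid == addr.gene_uid)
    cds = extract_cds(plastome, gene)
    ci, cp = addr.codon_index, addr.codon_pos
    codon = cds[3 * (ci - 1):3 * ci]
    if codon[cp - 1] != "C":
        raise ConsistencyError(
            f"{addr.label}: plastome codon {codon} has no C at position {cp}")
    conv, aa_conv, consequence = _conversion_strings(codon, cp)
    hydro = hydro_transition(aa_conv) if consequence == "nonsynonymous" else "n/a"
    context = _cds_context(plastome, gene, cds, addr.gene_pos)
    return SiteAnnotation(gene=addr.gene, gene_pos=addr.gene_pos,
                          label=addr.label, codon_index=ci, codon_pos=cp,
                          codon_conversion=conv, aa_conversion=aa_conv,
                          consequence=consequence, hydro_class=hydro,
                          context=context, address=addr)


def _cds_context(plastome, gene, cds: str, gene_pos: int) -> str | None:
    """Coding-strand trinucleotide around the edited C, crossing codon
    boundaries; falls back to the genomic neighbour at CDS ends."""
    i = gene_pos - 1
    up = cds[i - 1] if i >= 1 else _neighbour(plastome, gene, gene_pos, -1)
    down = cds[i + 1] if i + 1 < len(cds) else _neighbour(plastome, gene, gene_pos, +1)
    if up is None or down is None:
        return None
    return f"{up.lower()}C{down.lower()}"


def _neighbour(plastome, gene, gene_pos: int, step: int) -> str | None:
    from .plastome import cds_to_genome

    if plastome.sequence is None:
        return None
    gpos = cds_to_genome(gene, gene_pos)
    genomic_step = step if gene.strand == SENSE else -step
    npos = gpos + genomic_step
    if not 1 <= npos <= plastome.length:
        npos = (npos - 1) % plastome.length + 1  # circular plastome
    return plastome.base(npos, gene.strand)


def _genomic_context(plastome, addr: SiteAddress) -> str | None:
    if plastome.sequence is None:
        return None
    p = addr.genome_pos
    lo = (p - 2 - 1) % plastome.length + 1
    hi = (p + 1 - 1) % plastome.length + 1
    triple = (plastome.sequence[lo - 1] + plastome.sequence[p - 1]
              + plastome.sequence[hi - 1])
    if addr.strand == ANTISENSE:
        triple = revcomp(triple)
    if triple[1] != "C":
        raise ConsistencyError(
            f"position {p} ({addr.strand}) is not a genomic C")
    return triple[0].lower() + "C" + triple[2].lower()


# ---------------------------------------------------------------------------
# summaries


def dedup_by_site(annotations: list[SiteAnnotation]) -> list[SiteAnnotation]:
    """Drop duplicate annotations sharing a site key (inverted-repeat
    copies, prediction/detection overlap); first occurrence wins."""
    seen, out = set(), []
    for ann in annotations:
        if ann.site_key in seen:
            continue
        seen.add(ann.site_key)
        out.append(ann)
    return out


def codon_position_distribution(annotations: list[SiteAnnotation]) -> Counter:
    """Counts of edited codon positions (1–3) over CDS annotations."""
    return Counter(a.codon_pos for a in annotations if a.codon_pos is not None)


def context_summary(annotations: list[SiteAnnotation]) -> dict:
    """Trinucleotide-context frequencies over sites that carry a context.

    Reports the tCa fraction, the tCn-or-nCa fraction, and the 5′-pyrimidine
    fraction with its T/C split, as counts and percentages of the full list.
    """
    contexts = [a.context if isinstance(a, SiteAnnotation) else a
                for a in annotations]
    contexts = [c for c in contexts if c]
    if not contexts:
        raise AnnotateError("no contexts to summarise")
    for c in contexts:
        if len(c) != 3 or c[1] != "C":
            raise AnnotateError(f"malformed context {c!r}")
    n = len(contexts)
    tca = sum(1 for c in contexts if c == "tCa")
    tcn_nca = sum(1 for c in contexts if c[0] == "t" or c[2] == "a")
    five_t = sum(1 for c in contexts if c[0] == "t")
    five_c = sum(1 for c in contexts if c[0] == "c")
    pct = lambda x: 100.0 * x / n
    return {
        "n": n,
        "tCa": {"count": tca, "pct": pct(tca)},
        "tCn_or_nCa": {"count": tcn_nca, "pct": pct(tcn_nca)},
        "five_prime_pyrimidine": {
            "count": five_t + five_c, "pct": pct(five_t + five_c),
            "T": {"count": five_t, "pct": pct(five_t)},
            "C": {"count": five_c, "pct": pct(five_c)},
        },
        "pairs": Counter((c[0], c[2]) for c in contexts),
    }


def exchange_tally(annotations: list[SiteAnnotation]) -> dict:
    """Tally amino-acid conversions over deduplicated CDS annotations.

    Silent and stop-gain sites are tallied separately; hydrophobicity
    fractions are computed over the amino-acid-changing set only.
    """
    cds = [a for a in annotations if a.aa_conversion is not None]
    if len({a.site_key for a in cds}) != len(cds):
        raise AnnotateError("annotations must be deduplicated by site")
    changing = [a for a in cds if a.consequence == "nonsynonymous"]
    silent = [a for a in cds if a.consequence == "silent"]
    stop = [a for a in cds if a.consequence == "stop-gain"]
    conversions = Counter(a.aa_conversion for a in changing)
    hydro = Counter(a.hydro_class for a in changing)
    n = len(changing)
    return {
        "total_cds_sites": len(cds),
        "changing": n,
        "silent": len(silent),
        "stop_gain": len(stop),
        "conversions": conversions,
        "silent_conversions": Counter(a.aa_conversion for a in silent),
        "stop_conversions": Counter(a.aa_conversion for a in stop),
        "hydro_counts": hydro,
        "hydro_pct": {k: 100.0 * v / n for k, v in hydro.items()} if n else {},
    }
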