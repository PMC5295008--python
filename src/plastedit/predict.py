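"""Prediction of restorative C-to-U editing sites from homolog conservation.

Plant-organelle editing predictors exploit the fact that most editing
events restore the amino acid conserved among homologs.  For every genomic
C at codon positions 1 and 2 of a CDS, the C is substituted to T in silico;
if the resulting amino acid is supported by at least a cutoff fraction
(default 0.8) of the aligned homologs — and better supported than the
genomic amino acid — the site is predicted as edited.  Silent changes are
never predicted.

This is a self-contained reimplementation of the method class; it scores
user-supplied homolog alignments and does not bundle a homolog database.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from Bio import AlignIO
from Bio.Seq import Seq

GAP = "-"


class PredictError(Exception):
    pass


class ConsistencyError(PredictError):
    pass


@dataclass
class HomologAlignment:
    """Aligned homolog proteins for one gene; one row is the query species."""

    gene: str
    rows: list[tuple[str, str]]  # (species, aligned residues with '-')
    target_row: int = 0

    def __post_init__(self):
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) != 1:
            raise PredictError(f"{self.gene}: rows differ in aligned length")
        if not 0 <= self.target_row < len(self.rows):
            raise PredictError(f"{self.gene}: bad target row")

    @classmethod
    def from_fasta(cls, path: str | Path, gene: str | None = None,
                   target: str | int = 0) -> "HomologAlignment":
        aln = AlignIO.read(str(path), "fasta")
        rows = [(rec.id, str(rec.seq).upper()) for rec in aln]
        if isinstance(target, str):
            ids = [r[0] for r in rows]
            if target not in ids:
                raise PredictError(f"target {target!r} not in alignment")
            target = ids.index(target)
        return cls(gene or Path(path).stem, rows, target)

    @property
    def target_seq(self) -> str:
        return self.rows[self.target_row][1]

    def column_of_residue(self, residue_index: int) -> int:
        """Alignment column (0-based) of the target's residue_index-th
        (0-based, gaps excluded) residue."""
        seen = -1
        for col, ch in enumerate(self.target_seq):
            if ch != GAP:
                seen += 1
                if seen == residue_index:
                    return col
        raise ConsistencyError(
            f"{self.gene}: residue index {residue_index} beyond target")


@dataclass(frozen=True)
class PredictionScore:
    gene: str
    gene_pos: int  # CDS nucleotide position of the edited C (1-based)
    aa_pos: int
    codon_conversion: str
    aa_conversion: str
    support_edited: float
    support_original: float
    n_informative: int
    predicted: bool


def predict_sites(cds: str, alignment: HomologAlignment, cutoff: float = 0.8,
                  positions: tuple[int, ...] = (1, 2),
                  min_informative: int = 3) -> list[PredictionScore]:
    """Score every candidate C in a CDS against the homolog alignment.

    Returns one record per tested (nonsynonymous) C→T substitution, sorted
    by CDS position, with ``predicted`` set where support for the edited
    residue reaches the cutoff and exceeds support for the genomic residue.
    Ties are conservatively not predicted.  Homologs gapped at a column are
    excluded from its denominator; columns with fewer than
    ``min_informative`` informative homologs are skipped with a warning.
    """
    from .annotate import _conversion_strings

    if not 0 < cutoff <= 1:
        raise PredictError("cutoff must lie in (0, 1]")
    cds = cds.upper()
    if len(cds) % 3:
        raise ConsistencyError("CDS length not divisible by 3")
    protein = str(Seq(cds).translate()).rstrip("*")
    target_ungapped = alignment.target_seq.replace(GAP, "").rstrip("*")
    if protein != target_ungapped:
        raise ConsistencyError(
            f"{alignment.gene}: CDS translation disagrees with the "
            f"alignment's target row")
    scores = []
    for aa_index in range(len(protein)):
        codon = cds[3 * aa_index:3 * aa_index + 3]
        for p in positions:
            if codon[p - 1] != "C":
                continue
            conv, aa_conv, consequence = _conversion_strings(codon, p)
            if consequence == "silent":
                continue
            aa_orig, aa_edit = aa_conv.split(">")
            if aa_edit == "Stop":
                aa_edit = "*"
            col = alignment.column_of_residue(aa_index)
            homologs = [seq[col] for i, (_, seq) in enumerate(alignment.rows)
                        if i != alignment.target_row and seq[col] != GAP]
            if len(homologs) < min_informative:
                warnings.warn(
                    f"{alignment.gene} aa {aa_index + 1}: only "
                    f"{len(homologs)} informative homologs; skipped")
                continue
            support_e = sum(1 for h in homologs if h == aa_edit) / len(homologs)
            support_o = sum(1 for h in homologs if h == aa_orig) / len(homologs)
            predicted = (support_e >= cutoff and support_e > support_o
                         and aa_edit != "*")
            scores.append(PredictionScore(
                gene=alignment.gene, gene_pos=3 * aa_index + p,
                aa_pos=aa_index + 1, codon_conversion=conv,
                aa_conversion=aa_conv, support_edited=support_e,
                support_original=support_o, n_informative=len(homologs),
                predicted=predicted))
    scores.sort(key=lambda s: s.gene_pos)
    return scores


def predicted_only(scores: list[PredictionScore]) -> list[PredictionScore]:
    return [s for s in scores if s.predicted]


def compare_species_predictions(per_species: dict[str, list]) -> dict:
    """Shared and species-specific predicted sites across species.

    Input lists may contain PredictionScore records or raw
    (gene, amino-acid position) keys; duplicates within one species are an
    input error.  Returns shared/unique/pairwise/absent set algebra plus the
    full Venn region counts (for up to four species).
    """
    from .comparative import compare_site_sets, venn

    keyed: dict[str, set] = {}
    for species, entries in per_species.items():
        keys = [(e.gene, e.aa_pos) if isinstance(e, PredictionScore) else tuple(e)
                for e in entries]
        if len(set(keys)) != len(keys):
            raise PredictError(f"{species}: duplicate site keys")
        keyed[species] = set(keys)
    result = compare_site_sets(keyed)
    if len(keyed) <= 4:
        result["venn"] = venn(keyed)
    return result
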