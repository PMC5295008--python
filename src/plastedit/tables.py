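"""Loaders for the packaged *Aegilops tauschii* (AL8/78) study tables.

Three TSVs ship with the package, transcribed from the published editing
study of the KJ614412.1 plastome:

* ``predicted_sites.tsv`` — 34 conservation-predicted C-to-U sites in 15
  protein-coding genes (gene, CDS nucleotide position, codon conversion).
* ``rnaseq_sites.tsv`` — 60 sites detected from RNA-seq read mapping across
  24 samples (8 tissues), with per-sample editing efficiencies in percent;
  "+" marks complete (100%) editing, blank marks a sample that failed the
  detection filters.
* ``poaceae_sites.tsv`` — a 31-row editing-site status matrix across six
  Poaceae species using the +, +a, −, (−) status glyphs.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources

from .annotate import SiteAnnotation, complete_conversion
from .comparative import SpeciesSiteMatrix

TISSUES = ("Leaf", "Pistil", "Root", "Seed", "Sheath", "Spike", "Stamen", "Stem")


def _open(name: str):
    return (resources.files("plastedit.data") / "ae_tauschii" / name).open()


def load_predicted_sites() -> list[SiteAnnotation]:
    """The 34 conservation-predicted sites, re-annotated from their codon
    conversion strings (consequence and hydrophobicity are recomputed, not
    copied)."""
    out = []
    with _open("predicted_sites.tsv") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            ann = SiteAnnotation.from_codon_conversion(
                row["gene"], int(row["nt_pos"]), row["codon_conversion"])
            assert ann.aa_conversion == row["aa_conversion"], row
            out.append(ann)
    return out


@dataclass(frozen=True)
class DetectedSite:
    """One row of the RNA-seq detection table."""

    genome_pos: int
    strand: str  # sense | antisense
    label: str
    feature: str  # CDS | intron | intergenic
    gene: str | None
    gene_pos: int | None
    codon: str | None  # compact before-codon, e.g. "tCa"
    aa_conversion: str | None
    predicted: bool  # agrees with the conservation prediction
    efficiencies: dict[str, float]  # passing samples only, percent

    @property
    def site_key(self) -> tuple:
        if self.gene is not None and self.gene_pos is not None:
            return (self.gene, self.gene_pos)
        return (self.label, self.genome_pos)

    def annotation(self) -> SiteAnnotation | None:
        """Codon-level annotation for CDS rows (None otherwise)."""
        if self.feature != "CDS" or not self.codon:
            return None
        return SiteAnnotation.from_codon_conversion(
            self.gene, self.gene_pos, complete_conversion(self.codon))


def load_rnaseq_sites() -> tuple[list[DetectedSite], list[str]]:
    """The 60 RNA-seq-detected sites and the ordered 24-sample list."""
    sites = []
    with _open("rnaseq_sites.tsv") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        samples = reader.fieldnames[6:]
        for row in reader:
            label = row["gene_label"]
            if "~" in label:
                feature, gene, gene_pos = "intergenic", None, None
            elif label.endswith("-intron"):
                feature, gene, gene_pos = "intron", label[:-len("-intron")], None
            else:
                m = re.match(r"(.+)-(\d+)$", label)
                feature, gene, gene_pos = "CDS", m.group(1), int(m.group(2))
            eff = {}
            for s in samples:
                cell = row[s]
                if cell == "+":
                    eff[s] = 100.0
                elif cell:
                    eff[s] = float(cell)
            sites.append(DetectedSite(
                genome_pos=int(row["genome_pos"]), strand=row["strand"],
                label=label, feature=feature, gene=gene, gene_pos=gene_pos,
                codon=row["codon"] or None,
                aa_conversion=row["aa_conversion"] or None,
                predicted="a" in row["flags"].split(","),
                efficiencies=eff))
    return sites, samples


def load_poaceae_matrix() -> SpeciesSiteMatrix:
    """The six-species editing-site status matrix."""
    rows, meta, cells = [], [], []
    with _open("poaceae_sites.tsv") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        species = reader.fieldnames[6:]
        for row in reader:
            rows.append((row["gene"], int(row["site"])))
            meta.append({
                "aa_pos": int(row["aa_pos"]),
                "aa_pos_alias": int(row["aa_pos_alias"]) if row["aa_pos_alias"] else None,
                "edited_codon": row["edited_codon"],
                "aa_conversion": row["aa_conversion"],
            })
            cells.append([row[sp] for sp in species])
    return SpeciesSiteMatrix.from_rows(rows, species, cells, meta)


def union_coding_annotations() -> list[SiteAnnotation]:
    """Deduplicated union of predicted and RNA-seq-detected CDS sites,
    keyed by (gene, within-gene position) so inverted-repeat copies count
    once — the basis of the exchange and hydrophobicity tallies."""
    anns = {a.site_key: a for a in load_predicted_sites()}
    detected, _ = load_rnaseq_sites()
    for site in detected:
        ann = site.annotation()
        if ann is not None and ann.site_key not in anns:
            anns[ann.site_key] = ann
    return list(anns.values())
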