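# Methods

This note records the models, conventions and numerical choices behind
`plastedit`, and what its synthetic tests do and do not establish.

## Coordinates and strand conventions

The plastome is stored on the published (GenBank) strand with 1-based
closed intervals. A gene's "gene position" counts along its coding strand
from the first base of the start codon, so for antisense genes it runs
right-to-left across the published sequence; reports keep both the genome
position (published strand) and the gene-coordinate label. For a CDS
position *g*, `codon_index = ceil(g/3)` and `codon_pos = ((g−1) mod 3)+1`.
Inverted-repeat gene copies are distinct records keyed by (name, genome
start); deduplication happens only in tallies, by (gene, within-gene
position), so a two-copy gene contributes one event to exchange statistics
but two rows to per-position reports.

`locate()` classifies a (position, transcript strand) pair as CDS when it
falls in an exon of a gene whose coding strand matches, as intron when
inside such a gene between its exons, and as intergenic otherwise, naming
the flanking genes in genome order (`geneA~geneB`, `~geneB` when no left
flank exists). A position inside a gene on the *opposite* strand is
intergenic for the queried strand; the flanks are the nearest genes wholly
before and after the position.

## Detection

Editing efficiency is `100 · edited_reads / total_mapped_reads`, stored as
an exact ratio and rounded half-up to integer percent only in reports
(so 32.5% prints as 33). A (position, strand) pair is a candidate iff the
transcript-strand base is C; the edited count is the T count on that strand
(genomic C→T for sense, genomic G→A for antisense transcripts). A site is
kept when **any** sample reaches both `efficiency ≥ 5%` and
`edited_reads ≥ 6` ("more than five individual read supports" read
literally as ≥ 6 edited reads, applied per sample; a flag switches the
support filter to total reads). Samples failing the filters render blank,
not zero — raw counts are retained separately for calibration work.
Both strand orientations are evaluated everywhere, so one genomic position
can yield two sites. No base- or mapping-quality filtering is applied
beyond an optional minimum base quality (default 0) in the SAM adapter.
Complete editing means efficiency exactly 100% in that sample.

## Annotation

Codon conversions use compact notation: lowercase codon with the edited
base capitalised, before and after (`tCa>tTa`). Consequence is silent when
the amino acid is unchanged, stop-gain when the edited codon is TAA/TAG/TGA,
nonsynonymous otherwise. Sequence context is the (−1, C, +1) triple read on
the coding strand for CDS sites (crossing codon boundaries; falling back to
the genomic neighbour, circularly, at CDS ends) and on the edited strand
for intron/intergenic sites.

The 20-residue binary hydrophobicity table is pinned by the eight observed
plastid conversion types (S→L, S→F, T→M, T→I, H→Y hydrophilic→hydrophobic;
P→S the reverse; P→L and L→F no exchange); the residues those conversions
do not constrain follow the common binary assignment (A, V, C, G, W
hydrophobic; charged and amide residues hydrophilic). Hydrophobicity
fractions are computed over the amino-acid-changing set only — silent and
stop-gain sites have their own tallies.

## Conservation-based prediction

For each genomic C at codon positions 1–2 (position 3 is skipped by
default: a C→T there is always silent for the codons involved; a flag
enables it), the C is substituted to T in silico and the edited amino acid
is scored against the homolog alignment column of that residue:
`support_edited` and `support_original` are the fractions of non-gap,
non-target homologs carrying each residue. A site is predicted when
`support_edited ≥ cutoff` (default 0.8), `support_edited >
support_original` (ties conservatively rejected), and the change is
nonsynonymous. Columns with fewer than 3 informative homologs are skipped
with a warning. The homolog set is user-supplied: published predictor
servers keep internal databases, so exact reproduction of their site lists
is not promised — the method class, not a bit-exact oracle, is what is
implemented.

## Secondary structure and topology

The Chou–Fasman caller uses the classic propensity and bend-frequency
tables (shipped as a versioned TSV fixture, ×100 scale). Helix nuclei are
6-residue windows with ≥ 4 residues of Pα > 1.00, sheet nuclei 5-residue
windows with ≥ 3 of Pβ > 1.00; both extend outward while the tetrapeptide
window spanning the boundary averages > 1.00. Turns are called at *i* when
`f(i)·f(i+1)·f(i+2)·f(i+3) > 7.5×10⁻⁵`, mean Pt over the tetrapeptide
exceeds 1.00, and exceeds both the helix and sheet means there. Helix/sheet
overlaps go to the higher regional average (helix wins exact ties); the
turn condition, which already requires turn dominance, takes precedence.

Locality caveat: a single substitution directly affects only windows within
±5 residues, but the extension rule can cascade a change through a
contiguous above-threshold region, so no fixed radius bounds the effect in
principle (a distance-21 case arises in seeded random peptides). The tested
invariant is the provable one: changes beyond 19 residues must be connected
to the edit through an unbroken non-coil run.

Transmembrane segments use a Kyte–Doolittle sliding window (default 19
residues, mean hydropathy > 1.6; a residue is in a segment iff some window
containing it passes, overlapping windows merging). This deliberately
replaces HMM topology predictors, which cannot be reimplemented from their
outputs: segment *boundaries* are therefore not comparable to HMM tools,
but before/after comparisons — expansion, contraction, shift, gain, loss of
segments — are well-defined and deterministic. The diff classifies
overlapping interval pairs by containment, pairs disjoint leftovers with
their mutual nearest counterpart as "shifted" when their midpoints are
closer than the longer segment's length, and labels the rest new/lost.

## Cross-species comparison

Status glyphs: `+` complete editing, `+a` partial, `−` unedited with C in
DNA, `(−)` T already in DNA (re-mutation), blank unknown. Because published
matrices contain many blanks and the blank convention is never stated,
conservation classes are reported under **both** conventions:
ignore-unknown (blanks dropped from the row) and strict (any blank makes
the row indeterminate); neither is asserted as "the" published count. A row
is conserved-edited when every known status shows editing, lineage-specific
when editing covers a proper nonempty subset, and carries a re-mutation
flag whenever any species shows `(−)`. Venn regions are exact exclusive
intersections for up to four sets.

## Synthetic data: the stated world

The generator emulates the study design: a multi-gene plastome
(default 5 × 300 bp genes, a sense/antisense mix, one intron-containing
gene, 150 bp spacers; valid start/stop codons and no internal stops by
construction), 8 tissues with 1–5 replicates (24 samples) as the default
sample layout, depth 100, substitution error 1%. Editing is applied at the
transcript level before error: the edited-read count at a planted site is
Binomial(depth, efficiency/100), then every read base substitutes with
probability ε, uniformly ε/3 to each alternative base — no indels, no
quality modelling, no coverage heterogeneity, no splice-aware reads (intron
positions are simulated pre-splicing). The read simulator tiles the genome
in `depth` offset layers so coverage is exact and, at ε = 0, the SAM-derived
count table equals the direct one under the same seed; the ledger records
every draw, so expected detection outcomes are recomputable.

A green synthetic test therefore establishes correctness of the statistics
and plumbing under binomial sampling with uniform errors — not robustness
to alignment artefacts, strand bias, PCR duplicates or coverage dips, which
real RNA-seq exhibits and this world deliberately omits.

Recovery and calibration are binomial claims: at depth 100 the ≥ 6-read
filter passes with probability `1 − F(5; 100, p)`, which is below 1 near
p = 10%, so "every planted site recovered" and "every estimate inside the
99% interval" hold in expectation; tests assert the 3σ envelopes of those
expectations rather than certainties.

## Known limitations

* The headline site counts of any particular study require its actual
  RNA-seq runs; the packaged tables make the *published* statistics
  reproducible, not the read-level analysis.
* Predictor output depends entirely on the homolog set supplied.
* U-to-C editing, editing that creates or destroys start codons, and
  statistical tests against genomic-DNA control libraries are out of scope.
* Two printed rows of the shipped detection table (psbB-414, ndhD-1398)
  carry codon `atC` with conversion "L>L"; ATC encodes isoleucine, so the
  package recomputes I>I — silent either way.
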