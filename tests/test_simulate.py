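"""Synthetic plastomes, planted edits, counts/reads and the ledger."""

from pathlib import Path

import numpy as np
import pytest
from Bio.Seq import Seq

from plastedit.detect import CountTable, call_sites, tissue_specificity
from plastedit.plastome import ANTISENSE, SENSE, extract_cds
from plastedit.simulate import (EditingPlan, PlannedSite, SimulateError,
                                make_plan, make_plastome, simulate_counts,
                                simulate_reads, write_plastome)


class TestMakePlastome:
    def test_generated_cds_translate_cleanly(self):
        """Every generated CDS starts with ATG, ends with a stop, and has
        no internal stop in any gene (brute-force re-translation)."""
        p = make_plastome(n_genes=6, seed=2)
        for gene in p.cds_genes():
            cds = extract_cds(p, gene)
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG")
            prot = str(Seq(cds).translate())
            assert prot.endswith("*") and "*" not in prot[:-1]
            assert gene.warnings == ()

    def test_deterministic_files(self, tmp_path):
        a = write_plastome(make_plastome(seed=9), tmp_path / "a")
        b = write_plastome(make_plastome(seed=9), tmp_path / "b")
        for key in a:
            assert Path(a[key]).read_bytes() == Path(b[key]).read_bytes()

    def test_strand_mix_and_intron(self):
        p = make_plastome(n_genes=5, seed=1)
        strands = {g.strand for g in p.genes}
        assert strands == {SENSE, ANTISENSE}
        assert sum(len(g.exons) == 2 for g in p.genes) == 1

    @pytest.mark.parametrize("kwargs", [
        {"n_genes": 0},
        {"gene_lengths": 100},            # not divisible by 3
        {"gene_lengths": [300, 300]},     # wrong count for 5 genes
        {"intron_spec": (99, 50)},
    ])
    def test_bad_configuration(self, kwargs):
        with pytest.raises(SimulateError):
            make_plastome(**kwargs)


class TestSimulateCounts:
    def test_no_editing_no_error_is_clean(self, sim_plastome):
        plan = EditingPlan([])
        tables, _ = simulate_counts(sim_plastome, plan, depth=50,
                                    error_rate=0.0, replicates={"Leaf": 1},
                                    seed=0)
        df = tables[0].data
        for base in "ACGT":
            rows = df[df["ref"] == base]
            assert (rows[base] == 50).all()

    def test_deterministic_under_seed(self, sim_plastome):
        plan = make_plan(sim_plastome, 5, ["Leaf"], efficiency=60.0, seed=1)
        t1, l1 = simulate_counts(sim_plastome, plan, replicates={"Leaf": 2}, seed=4)
        t2, l2 = simulate_counts(sim_plastome, plan, replicates={"Leaf": 2}, seed=4)
        for a, b in zip(t1, t2):
            assert a.data.equals(b.data)
        assert l1.sites == l2.sites

    def test_ledger_draw_matches_counts(self, sim_counts, sim_plastome):
        """At error 0 the edited-base count at each planted site equals the
        ledger's recorded binomial draw, and efficiency() recovers it."""
        from plastedit.detect import efficiency

        plan, tables, ledger = sim_counts
        by_sample = {t.sample_id: t.data for t in tables}
        for rec in ledger.sites:
            col = "T" if rec["strand"] == SENSE else "A"
            for sample, k in rec["draws"].items():
                row = by_sample[sample][
                    by_sample[sample]["pos"] == rec["genome_pos"]]
                assert int(row[col].iloc[0]) == k
                assert efficiency(k, 100) == 100.0 * k / 100

    def test_planting_requires_genomic_c(self, sim_plastome):
        pos = sim_plastome.sequence.index("A") + 1
        plan = EditingPlan([PlannedSite(pos, SENSE, {"Leaf": 50.0})])
        with pytest.raises(SimulateError):
            simulate_counts(sim_plastome, plan, replicates={"Leaf": 1}, seed=0)

    def test_tissue_specific_pattern_recovered(self, sim_plastome):
        """Sites planted leaf-only are profiled as leaf-specific."""
        plan = make_plan(sim_plastome, 4,
                         efficiency={"Leaf": 80.0, "Seed": 0.0}, seed=3)
        tables, ledger = simulate_counts(
            sim_plastome, plan, depth=100, error_rate=0.0,
            replicates={"Leaf": 2, "Seed": 2}, seed=6)
        sites = call_sites(sim_plastome, tables)
        groups = {"Leaf": ["Leaf-1", "Leaf-2"], "Seed": ["Seed-1", "Seed-2"]}
        profiles = tissue_specificity(sites, groups)
        assert len(sites) == 4
        for profile in profiles.values():
            assert profile == {"tissues": ["Leaf"], "specific": True}


class TestSimulateReads:
    def test_sam_counts_equal_direct_counts(self, sim_plastome, tmp_path):
        """With error 0 the SAM-derived count table reproduces the direct
        count table exactly under the same seed."""
        plan = make_plan(sim_plastome, 5, ["Leaf"], efficiency=50.0, seed=2)
        paths, _ = simulate_reads(sim_plastome, plan, depth=25, read_length=60,
                                  error_rate=0.0, replicates={"Leaf": 1},
                                  seed=8, outdir=tmp_path)
        tables, _ = simulate_counts(sim_plastome, plan, depth=25,
                                    error_rate=0.0, replicates={"Leaf": 1},
                                    seed=8)
        from_sam = CountTable.from_sam(paths["Leaf-1"], sim_plastome, "Leaf-1")
        cols = ["A", "C", "G", "T"]
        assert from_sam.data[cols].equals(tables[0].data[cols])

    def test_zero_depth_yields_empty_valid_sam(self, sim_plastome, tmp_path):
        import pysam

        paths, _ = simulate_reads(sim_plastome, EditingPlan([]), depth=0,
                                  replicates={"Leaf": 1}, seed=0,
                                  outdir=tmp_path)
        with pysam.AlignmentFile(str(paths["Leaf-1"])) as af:
            assert af.references == (sim_plastome.id,)
            assert sum(1 for _ in af) == 0

    def test_antisense_site_detected_from_reads(self, sim_plastome, tmp_path):
        """Reads over an antisense gene yield a site reported as C-to-U in
        gene coordinates (G→A on the published strand)."""
        gene = next(g for g in sim_plastome.cds_genes()
                    if g.strand == ANTISENSE)
        offset = extract_cds(sim_plastome, gene).index("C", 3)
        from plastedit.plastome import cds_to_genome

        pos = cds_to_genome(gene, offset + 1)
        assert sim_plastome.sequence[pos - 1] == "G"
        plan = EditingPlan([PlannedSite(pos, ANTISENSE, {"Leaf": 80.0})])
        paths, _ = simulate_reads(sim_plastome, plan, depth=40, read_length=50,
                                  error_rate=0.0, replicates={"Leaf": 1},
                                  seed=3, outdir=tmp_path)
        table = CountTable.from_sam(paths["Leaf-1"], sim_plastome, "Leaf-1")
        sites = call_sites(sim_plastome, [table])
        assert len(sites) == 1
        site = sites[0]
        assert site.strand == ANTISENSE
        assert site.address.gene == gene.name
        from plastedit.annotate import annotate_site

        ann = annotate_site(sim_plastome, site)
        assert ">" in ann.codon_conversion  # resolves to a C-containing codon

    def test_sam_deterministic(self, sim_plastome, tmp_path):
        plan = make_plan(sim_plastome, 3, ["Leaf"], efficiency=40.0, seed=1)
        p1, _ = simulate_reads(sim_plastome, plan, depth=10, replicates={"Leaf": 1},
                               seed=2, outdir=tmp_path / "x")
        p2, _ = simulate_reads(sim_plastome, plan, depth=10, replicates={"Leaf": 1},
                               seed=2, outdir=tmp_path / "y")
        assert Path(p1["Leaf-1"]).read_bytes() == Path(p2["Leaf-1"]).read_bytes()


def test_pipeline_recovery_exact(sim_plastome, sim_counts):
    """Detection on error-free simulated counts reproduces the ledger's
    planted site list exactly (all true efficiencies ≥ 20%)."""
    plan, tables, ledger = sim_counts
    sites = call_sites(sim_plastome, tables)
    assert {(s.strand, s.genome_pos) for s in sites} == \
        ledger.expected_site_keys()


def test_ledger_roundtrip(tmp_path, sim_counts):
    from plastedit.simulate import GroundTruthLedger

    _, _, ledger = sim_counts
    path = tmp_path / "ledger.json"
    ledger.to_json(path)
    back = GroundTruthLedger.from_json(path)
    assert back.params == ledger.params
    assert back.sites == ledger.sites
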