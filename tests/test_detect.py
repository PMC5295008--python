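"""Editing-site calling, efficiency arithmetic and the two-threshold filter."""

import numpy as np
import pandas as pd
import pytest

from plastedit.detect import (ConsistencyError, CountTable, DetectError,
                              call_sites, efficiency, sites_to_tsv,
                              tissue_specificity)
from plastedit.plastome import ANTISENSE, SENSE, GeneModel, Plastome


def _plastome(seq: str) -> Plastome:
    # one sense gene covering everything keeps locate() trivial
    n = len(seq)
    return Plastome("mini", seq, n, [GeneModel("g1", SENSE, ((1, n),))])


def _table(sample, plastome, rows):
    """rows: {pos: (A, C, G, T)}; depth = column sum unless overridden."""
    recs = []
    for pos in range(1, plastome.length + 1):
        a, c, g, t = rows.get(pos, (0, 0, 0, 0))
        ref = plastome.sequence[pos - 1]
        if pos not in rows:
            counts = {"A": 0, "C": 0, "G": 0, "T": 0, ref: 100}
            a, c, g, t = counts["A"], counts["C"], counts["G"], counts["T"]
        recs.append({"pos": pos, "ref": ref, "A": a, "C": c, "G": g, "T": t,
                     "depth": a + c + g + t})
    return CountTable(sample, pd.DataFrame(recs))


class TestEfficiency:
    @pytest.mark.parametrize("edited,total,expected,printed", [
        (36, 100, 36.0, 36),
        (35, 100, 35.0, 35),
        (0, 50, 0.0, 0),
        (13, 40, 32.5, 33),  # stored exact, rounds to 33 at report time
    ])
    def test_values(self, edited, total, expected, printed):
        from plastedit.detect import round_percent

        eff = efficiency(edited, total)
        assert eff == expected
        assert round_percent(eff) == printed

    def test_zero_total_undefined(self):
        with pytest.raises(DetectError):
            efficiency(0, 0)

    def test_edited_beyond_total(self):
        with pytest.raises(DetectError):
            efficiency(5, 4)


class TestCallSites:
    def test_sense_site_efficiency(self):
        p = _plastome("ATGCCCTAA")
        t = _table("Leaf-1", p, {5: (0, 65, 0, 35)})
        sites = call_sites(p, [t])
        assert len(sites) == 1
        site = sites[0]
        assert (site.genome_pos, site.strand) == (5, SENSE)
        assert site.samples["Leaf-1"].efficiency == 35.0
        assert site.status("Leaf-1") == "partial"

    def test_support_must_exceed_five_reads(self):
        p = _plastome("ATGCCCTAA")
        t5 = _table("s", p, {5: (0, 95, 0, 5)})    # 5%, support 5 -> out
        t6 = _table("s", p, {5: (0, 94, 0, 6)})    # 6%, support 6 -> in
        assert call_sites(p, [t5]) == []
        assert len(call_sites(p, [t6])) == 1

    def test_non_c_reference_never_called(self):
        p = _plastome("ATATATATA")
        t = _table("s", p, {3: (50, 0, 0, 50), 4: (0, 0, 0, 100)})
        assert call_sites(p, [t]) == []

    def test_complete_editing(self):
        p = _plastome("ATGCCCTAA")
        t = _table("s", p, {5: (0, 0, 0, 100)})
        site = call_sites(p, [t])[0]
        assert site.samples["s"].complete
        assert site.status("s") == "complete"

    def test_antisense_g_to_a(self):
        """A genomic G with A-bearing reads is a C-to-U site on the
        antisense transcript."""
        p = _plastome("ATGGGGTAA")
        t = _table("s", p, {5: (40, 0, 60, 0)})
        site = call_sites(p, [t])[0]
        assert site.strand == ANTISENSE
        assert site.samples["s"].efficiency == 40.0

    def test_failing_samples_blank_not_zero(self, tmp_path):
        p = _plastome("ATGCCCTAA")
        t1 = _table("s1", p, {5: (0, 50, 0, 50)})
        t2 = _table("s2", p, {5: (0, 99, 0, 1)})  # fails both filters
        sites = call_sites(p, [t1, t2])
        site = sites[0]
        assert "s2" not in site.samples and "s2" in site.counts
        out = tmp_path / "sites.tsv"
        sites_to_tsv(sites, ["s1", "s2"], out)
        df = pd.read_csv(out, sep="\t", keep_default_na=False, dtype=str)
        assert df.loc[0, "s1"] == "50" and df.loc[0, "s2"] == ""

    def test_unknown_position_is_consistency_error(self):
        p = _plastome("ATGCCCTAA")
        t = _table("s", p, {5: (0, 50, 0, 50)})
        t.data.loc[0, "pos"] = 999
        with pytest.raises(ConsistencyError):
            call_sites(p, [t])

    def test_ref_mismatch_is_consistency_error(self):
        p = _plastome("ATGCCCTAA")
        t = _table("s", p, {5: (0, 50, 0, 50)})
        t.data.loc[0, "ref"] = "G" if p.sequence[0] != "G" else "C"
        with pytest.raises(ConsistencyError):
            call_sites(p, [t])

    def test_zero_depth_sample_skipped(self):
        p = _plastome("ATGCCCTAA")
        t1 = _table("s1", p, {5: (0, 0, 0, 0)})
        t2 = _table("s2", p, {5: (0, 20, 0, 80)})
        site = call_sites(p, [t1, t2])[0]
        assert "s1" not in site.samples and "s1" not in site.counts

    def test_support_mode_total(self):
        p = _plastome("ATGCCCTAA")
        # 3 edited of 50 = 6% efficiency; support=3 fails edited mode,
        # passes total mode (50 >= 6)
        t = _table("s", p, {5: (0, 47, 0, 3)})
        assert call_sites(p, [t]) == []
        assert len(call_sites(p, [t], support_mode="total")) == 1


def _bruteforce(plastome, tables, min_eff, min_reads):
    """Independent oracle: scan every position and both strands, apply the
    two-threshold rule literally."""
    expected = {}
    for table in tables:
        for _, row in table.data.iterrows():
            for strand, refbase, col in ((SENSE, "C", "T"), (ANTISENSE, "G", "A")):
                if row["ref"] != refbase or row["depth"] == 0:
                    continue
                eff = 100.0 * row[col] / row["depth"]
                if eff >= min_eff and row[col] >= min_reads:
                    expected.setdefault((strand, int(row["pos"])), set()).add(
                        table.sample_id)
    return expected


@pytest.mark.parametrize("seed,min_eff,min_reads", [
    (0, 5.0, 6), (1, 5.0, 6), (2, 0.0, 1), (3, 20.0, 10),
])
def test_oracle_equivalence_random_tables(seed, min_eff, min_reads):
    """call_sites agrees exactly with the brute-force two-threshold scan on
    random count tables (both strands, several thresholds)."""
    rng = np.random.default_rng(seed)
    n = 400
    seq = "".join(rng.choice(list("ACGT"), size=n))
    p = Plastome("r", seq, n, [GeneModel("g", SENSE, ((1, n),))])
    tables = []
    for s in range(3):
        depth = rng.integers(0, 60, size=n)
        edited = rng.binomial(depth, rng.uniform(0, 0.4, size=n))
        recs = []
        for i in range(n):
            ref = seq[i]
            counts = {"A": 0, "C": 0, "G": 0, "T": 0}
            counts[ref] = int(depth[i] - edited[i])
            alt = {"C": "T", "G": "A"}.get(ref, "A" if ref != "A" else "G")
            counts[alt] += int(edited[i])
            recs.append({"pos": i + 1, "ref": ref, **counts,
                         "depth": int(depth[i])})
        tables.append(CountTable(f"s{s}", pd.DataFrame(recs)))
    got = call_sites(p, tables, min_eff, min_reads, locate_sites=False)
    got_map = {(s.strand, s.genome_pos): set(s.samples) for s in got}
    assert got_map == _bruteforce(p, tables, min_eff, min_reads)


def test_threshold_monotonicity():
    """Raising either threshold never adds a site."""
    rng = np.random.default_rng(9)
    n = 300
    seq = "".join(rng.choice(list("ACGT"), size=n))
    p = Plastome("r", seq, n, [GeneModel("g", SENSE, ((1, n),))])
    depth = np.full(n, 50)
    edited = rng.binomial(depth, 0.15)
    recs = []
    for i in range(n):
        ref = seq[i]
        counts = {"A": 0, "C": 0, "G": 0, "T": 0, ref: int(depth[i] - edited[i])}
        alt = {"C": "T", "G": "A"}.get(ref, "A" if ref != "A" else "G")
        counts[alt] = counts.get(alt, 0) + int(edited[i])
        recs.append({"pos": i + 1, "ref": ref, **counts, "depth": 50})
    t = CountTable("s", pd.DataFrame(recs))
    keys = lambda eff, reads: {(s.strand, s.genome_pos) for s in
                               call_sites(p, [t], eff, reads, locate_sites=False)}
    base = keys(5.0, 6)
    assert keys(10.0, 6) <= base
    assert keys(5.0, 10) <= base
    assert keys(20.0, 12) <= keys(10.0, 6)


class TestTissueSpecificity:
    def _sites(self, p, passing):
        t = [
            _table(s, p, {5: (0, 20, 0, 80)} if s in passing else {})
            for s in ["Leaf-1", "Leaf-2", "Seed-1", "Seed-2"]
        ]
        return call_sites(p, t)

    def test_seed_specific(self):
        p = _plastome("ATGCCCTAA")
        sites = self._sites(p, {"Seed-1", "Seed-2"})
        groups = {"Leaf": ["Leaf-1", "Leaf-2"], "Seed": ["Seed-1", "Seed-2"]}
        prof = tissue_specificity(sites, groups)[(SENSE, 5)]
        assert prof == {"tissues": ["Seed"], "specific": True}

    def test_two_tissue_profile(self):
        p = _plastome("ATGCCCTAA")
        sites = self._sites(p, {"Leaf-1", "Seed-1"})
        groups = {"Leaf": ["Leaf-1", "Leaf-2"], "Seed": ["Seed-1", "Seed-2"]}
        prof = tissue_specificity(sites, groups)[(SENSE, 5)]
        assert prof == {"tissues": ["Leaf", "Seed"], "specific": False}

    def test_empty_group_map_is_error(self):
        with pytest.raises(DetectError):
            tissue_specificity([], {})

    def test_sample_in_two_tissues_is_error(self):
        with pytest.raises(DetectError):
            tissue_specificity([], {"a": ["s1"], "b": ["s1"]})


def test_count_table_tsv_roundtrip(tmp_path):
    p = _plastome("ATGCCCTAA")
    t = _table("Leaf-1", p, {5: (0, 65, 0, 35)})
    path = tmp_path / "leaf1.tsv"
    t.to_tsv(path)
    back = CountTable.from_tsv(path)
    assert back.sample_id == "Leaf-1"
    pd.testing.assert_frame_equal(back.data, t.data.reset_index(drop=True))


def test_count_table_validation():
    df = pd.DataFrame({"pos": [1], "ref": ["C"], "A": [0], "C": [5], "G": [0],
                       "T": [10], "depth": [10]})  # counts exceed depth
    with pytest.raises(DetectError):
        CountTable("s", df)
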