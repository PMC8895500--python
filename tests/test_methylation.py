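"""WGBS ICR methylation: allele assignment, dedup, site/ICR levels, tracks."""
import numpy as np
import pandas as pd
import pytest
from oracles import naive_site_levels

from imprintkit.core import ICRRegion, SnpTable
from imprintkit.methylation import (allelic_icr_methylation, assign_allele,
                                    compare_icr_groups, deduplicate_reads,
                                    export_methylation_track, icr_methylation,
                                    icr_methylation_by_sample, site_methylation,
                                    site_methylation_table)
from imprintkit.presets import rasgrf1_sex_dimorphic, balanced_design
from imprintkit.synthetic import simulate_cross, simulate_wgbs_calls


@pytest.fixture()
def snps() -> SnpTable:
    table = SnpTable()
    table.add("chr9", 100, "A", "G")
    table.add("chr9", 200, "C", "T")
    return table


class TestAssignAllele:
    def test_all_maternal_votes(self, snps):
        tag, _ = assign_allele([("chr9", 100, "A"), ("chr9", 200, "C")], snps)
        assert tag == "maternal"

    def test_mixture_is_conflicting(self, snps):
        tag, _ = assign_allele([("chr9", 100, "A"), ("chr9", 100, "G")], snps)
        assert tag == "conflicting"

    def test_no_snp_overlap_unassigned(self, snps):
        tag, ignored = assign_allele([("chr9", 999, "A")], snps)
        assert tag == "unassigned"
        assert ignored == 1

    def test_bisulfite_degenerate_ct_snp_uninformative(self, snps):
        # at a C/T SNP a read T is compatible with both alleles after
        # conversion, so it must not vote
        tag, _ = assign_allele([("chr9", 200, "T")], snps)
        assert tag == "unassigned"

    def test_bisulfite_aware_ga_matching_on_reverse_reads(self):
        table = SnpTable()
        table.add("chr1", 50, "G", "T")
        # on a reverse-orientation read, A is the converted maternal G
        tag, _ = assign_allele([("chr1", 50, "A")], table, orientation="reverse")
        assert tag == "maternal"
        # on a forward read no conversion explains A at a G/T SNP: no vote
        tag, _ = assign_allele([("chr1", 50, "A")], table, orientation="forward")
        assert tag == "unassigned"


def _calls(rows):
    cols = ["sample", "chrom", "pos", "read_id", "allele", "state",
            "read_start", "read_end", "strand"]
    return pd.DataFrame(rows, columns=cols)


class TestDeduplicateReads:
    def test_identical_span_collapses(self):
        calls = _calls([
            ("s", "chr1", 10, "r1", "unassigned", "methylated", 0, 100, "+"),
            ("s", "chr1", 10, "r2", "unassigned", "methylated", 0, 100, "+"),
        ])
        out, sizes = deduplicate_reads(calls)
        assert list(out["read_id"]) == ["r1"]
        assert sizes.max() == 2

    def test_opposite_strands_both_survive(self):
        calls = _calls([
            ("s", "chr1", 10, "r1", "unassigned", "methylated", 0, 100, "+"),
            ("s", "chr1", 10, "r2", "unassigned", "methylated", 0, 100, "-"),
        ])
        out, _ = deduplicate_reads(calls)
        assert len(out) == 2

    def test_duplicate_keeps_all_cpg_calls_of_keeper(self):
        calls = _calls([
            ("s", "chr1", 10, "r1", "unassigned", "methylated", 0, 100, "+"),
            ("s", "chr1", 30, "r1", "unassigned", "unmethylated", 0, 100, "+"),
            ("s", "chr1", 10, "r2", "unassigned", "methylated", 0, 100, "+"),
        ])
        out, _ = deduplicate_reads(calls)
        assert len(out) == 2 and set(out["pos"]) == {10, 30}

    def test_empty_input(self):
        out, sizes = deduplicate_reads(_calls([]))
        assert out.empty and sizes.empty

    def test_missing_coordinates_rejected(self):
        calls = pd.DataFrame({"sample": ["s"], "read_id": ["r"], "pos": [1],
                              "chrom": ["chr1"], "allele": ["unassigned"],
                              "state": ["methylated"]})
        with pytest.raises(ValueError, match="read_start"):
            deduplicate_reads(calls)


class TestSiteAndIcrLevels:
    def test_site_formula(self):
        assert site_methylation(["methylated"] * 3 + ["unmethylated"]) == 0.75

    def test_below_coverage_excluded_not_zero(self):
        assert np.isnan(site_methylation(["methylated", "methylated"]))

    def test_full_methylation(self):
        assert site_methylation(["methylated"] * 3) == 1.0

    def test_icr_unweighted_mean(self):
        levels = pd.DataFrame({
            "sample": "s", "chrom": "chr1", "pos": [10, 20],
            "n_reads": [100, 3], "level": [1.0, 0.5],
        })
        icr = ICRRegion("icr", "chr1", 0, 100)
        result = icr_methylation(levels, icr, "s")
        # each CpG counts once regardless of its coverage
        assert result.percent == pytest.approx(75.0)
        assert result.n_sites == 2

    def test_single_site(self):
        levels = pd.DataFrame({"sample": ["s"], "chrom": ["chr1"], "pos": [10],
                               "n_reads": [5], "level": [0.4]})
        icr = ICRRegion("icr", "chr1", 0, 100)
        assert icr_methylation(levels, icr, "s").percent == pytest.approx(40.0)

    def test_no_qualifying_sites_is_no_data(self):
        icr = ICRRegion("icr", "chr1", 0, 100)
        empty = pd.DataFrame(columns=["sample", "chrom", "pos", "n_reads", "level"])
        result = icr_methylation(empty, icr, "s")
        assert not result.has_data and np.isnan(result.percent)

    def test_oracle_equivalence_random_instances(self, rng):
        # site and ICR levels equal a naive recount, exactly
        for _ in range(200):
            n = int(rng.integers(1, 40))
            calls = _calls([
                ("s", "chr1", int(rng.integers(0, 5)) * 10,
                 f"r{i}", "unassigned",
                 "methylated" if rng.random() < 0.5 else "unmethylated",
                 i, i + 100, "+")
                for i in range(n)
            ])
            table = site_methylation_table(calls, min_reads=3)
            naive = naive_site_levels(calls)
            for row in table.itertuples(index=False):
                meth, total = naive[(row.sample, row.chrom, row.pos)]
                assert total >= 3
                assert row.level == meth / total
            kept = {k for k, (m, t) in naive.items() if t >= 3}
            assert kept == {(r.sample, r.chrom, r.pos)
                            for r in table.itertuples(index=False)}

    def test_monotonicity_of_added_calls(self):
        base = [("s", "chr1", 10, f"r{i}", "unassigned", "methylated", i, i + 100, "+")
                for i in range(3)]
        base.append(("s", "chr1", 10, "r3", "unassigned", "unmethylated", 7, 107, "+"))
        level0 = site_methylation_table(_calls(base))["level"].iloc[0]
        plus_meth = base + [("s", "chr1", 10, "r9", "unassigned", "methylated",
                             9, 109, "+")]
        plus_unmeth = base + [("s", "chr1", 10, "r9", "unassigned", "unmethylated",
                               9, 109, "+")]
        assert site_methylation_table(_calls(plus_meth))["level"].iloc[0] >= level0
        assert site_methylation_table(_calls(plus_unmeth))["level"].iloc[0] <= level0


class TestAllelicMethylation:
    def test_fully_methylated_maternal_allele(self):
        rows = [("s", "chr1", 10 * (i + 1), f"r{i}", "maternal", "methylated",
                 i, i + 100, "+") for i in range(5)]
        icr = ICRRegion("icr", "chr1", 0, 100)
        result = allelic_icr_methylation(_calls(rows), icr, "s", "maternal")
        assert result.percent == 100.0 and result.n_sites == 5

    def test_untagged_allele_is_no_data(self):
        rows = [("s", "chr1", 10, "r0", "maternal", "methylated", 0, 100, "+")]
        icr = ICRRegion("icr", "chr1", 0, 100)
        result = allelic_icr_methylation(_calls(rows), icr, "s", "paternal")
        assert not result.has_data

    def test_allelic_recovery_and_ordering(self):
        # 0.9/0.1 two-allele simulation: allelic estimates recover truth
        # +-5 points and bracket the total level
        scenario = rasgrf1_sex_dimorphic()
        samples = simulate_cross(balanced_design(n_per_group=1))
        samples = samples[(samples["genotype"] == "M+Z+")
                          & (samples["sex"] == "F")]
        calls = simulate_wgbs_calls(scenario, samples, seed=41)
        sid = samples["sample"].iloc[0]
        pat = allelic_icr_methylation(calls, scenario.icr, sid, "paternal")
        mat = allelic_icr_methylation(calls, scenario.icr, sid, "maternal")
        total = icr_methylation_by_sample(calls, [scenario.icr])["percent"].iloc[0]
        assert pat.percent == pytest.approx(90.0, abs=5.0)
        assert mat.percent == pytest.approx(5.0, abs=5.0)
        assert mat.percent < total < pat.percent

    def test_invalid_allele_rejected(self):
        icr = ICRRegion("icr", "chr1", 0, 100)
        with pytest.raises(ValueError, match="allele"):
            allelic_icr_methylation(_calls([]), icr, "s", "unassigned")


class TestGroupComparison:
    def _percents(self, per_group, icr="icr1"):
        rows, meta = [], []
        i = 0
        for (genotype, sex), values in per_group.items():
            for v in values:
                i += 1
                rows.append({"icr": icr, "sample": f"s{i}", "percent": v})
                meta.append({"sample": f"s{i}", "genotype": genotype, "sex": sex})
        return pd.DataFrame(rows), pd.DataFrame(meta)

    def _full_design(self, override=None):
        per_group = {(g, s): [88.0, 90.0, 92.0]
                     for g in ("M+Z+", "M-Z+", "M-Z-") for s in ("F", "M")}
        if override:
            per_group.update(override)
        return per_group

    def test_separated_genotypes_flagged(self):
        percents, meta = self._percents(self._full_design(
            {("M-Z-", "M"): [8.0, 10.0, 12.0]}))
        out = compare_icr_groups(percents, meta)
        row = out[(out["design"] == "genotype within M")
                  & (out["group_b"] == "M-Z-") & (out["group_a"] == "M+Z+")]
        assert row["p_value"].iloc[0] < 0.05
        assert row["stars"].iloc[0] in ("*", "**", "***")
        sex_row = out[(out["design"] == "sex within M-Z-")]
        assert sex_row["p_value"].iloc[0] < 0.05

    def test_identical_groups_ns(self):
        percents, meta = self._percents(self._full_design())
        out = compare_icr_groups(percents, meta)
        assert (out["stars"] == "ns").all()

    def test_undersized_group_rejected(self):
        percents, meta = self._percents(self._full_design(
            {("M-Z-", "F"): [50.0]}))
        with pytest.raises(ValueError, match="<2"):
            compare_icr_groups(percents, meta)


class TestTrackExport:
    def test_format_contract(self):
        levels = pd.DataFrame({"sample": ["s"], "chrom": ["chr9"],
                               "pos": [89774500], "n_reads": [4], "level": [0.75]})
        track = export_methylation_track(levels, "s")
        assert "chr9\t89774500\t89774501\t0.75" in track.splitlines()

    def test_empty_site_set_header_only(self):
        empty = pd.DataFrame(columns=["sample", "chrom", "pos", "n_reads", "level"])
        track = export_methylation_track(empty, "s")
        assert len(track.splitlines()) == 1
        assert track.startswith("track")

    def test_values_clipped_to_unit_interval(self):
        levels = pd.DataFrame({"sample": ["s", "s"], "chrom": ["chr1", "chr1"],
                               "pos": [5, 10], "n_reads": [3, 3],
                               "level": [1.2, -0.1]})
        values = [float(line.split("\t")[3])
                  for line in export_methylation_track(levels, "s").splitlines()[1:]]
        assert all(0.0 <= v <= 1.0 for v in values)
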