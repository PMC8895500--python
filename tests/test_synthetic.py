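"""The synthetic cross generator: contracts, determinism, recovery."""
import math

import numpy as np
import pandas as pd
import pytest

from imprintkit.core import ICRRegion
from imprintkit.methylation import icr_methylation_by_sample
from imprintkit.presets import synthetic_rasgrf1_amplicon
from imprintkit.synthetic import (AmpliconScenario, CrossDesign, GeneScenario,
                                  ICRScenario, simulate_allelic_counts,
                                  simulate_colony_reads, simulate_cross,
                                  simulate_wgbs_calls)


def _gene(gene_id="g", theta=0.5, groups=(("M+Z+", "F"),), **kw):
    defaults = dict(gene_length=1000, mean_expression=200.0, dispersion=0.05,
                    snp_informative_fraction=0.5, allelic_concentration=50.0)
    defaults.update(kw)
    return GeneScenario(gene_id=gene_id,
                        paternal_fraction={g: theta for g in groups}, **defaults)


class TestSimulateCross:
    def test_direct_construction(self):
        design = CrossDesign(n_embryos={("M+Z+", "F"): 2, ("M-Z-", "M"): 3})
        samples = simulate_cross(design)
        assert len(samples) == 5
        assert list(samples.columns) == ["sample", "genotype", "sex"]
        assert (samples.loc[samples["sex"] == "F", "genotype"] == "M+Z+").all()
        assert list(samples.loc[samples["sex"] == "M", "sample"]) == ["M1", "M2", "M3"]

    def test_deterministic(self):
        design = CrossDesign(n_embryos={("M-Z+", "F"): 4, ("M-Z+", "M"): 2}, seed=7)
        assert simulate_cross(design).equals(simulate_cross(design))

    def test_impossible_genotype_rejected(self):
        # the Zfp57-/- dam x Zfp57+/- sire cross cannot yield M+Z-
        with pytest.raises(ValueError, match="M\\+Z-"):
            CrossDesign(n_embryos={("M+Z-", "F"): 1})

    def test_zero_embryos_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            CrossDesign(n_embryos={("M+Z+", "F"): 0})


class TestAllelicCounts:
    def test_pure_paternal_boundary(self):
        samples = simulate_cross(CrossDesign(n_embryos={("M+Z+", "F"): 5}))
        gene = _gene(theta=1.0, snp_informative_fraction=1.0,
                     allelic_concentration=math.inf)
        counts = simulate_allelic_counts([gene], samples, seed=1)
        assert (counts["maternal_count"] == 0).all()
        assert (counts["paternal_count"] == counts["total_count"]).all()

    @pytest.mark.parametrize("theta", [0.05, 0.5, 0.95])
    def test_allelic_fraction_recovery(self, theta):
        # pooled paternal fraction over many embryos recovers theta +-0.02
        samples = simulate_cross(CrossDesign(n_embryos={("M+Z+", "F"): 250}))
        gene = _gene(theta=theta)
        counts = simulate_allelic_counts([gene], samples, seed=5)
        frac = counts["paternal_count"].sum() / (
            counts["maternal_count"] + counts["paternal_count"]).sum()
        assert frac == pytest.approx(theta, abs=0.02)

    def test_poisson_limit_at_zero_dispersion(self):
        samples = simulate_cross(CrossDesign(n_embryos={("M+Z+", "F"): 500}))
        gene = _gene(dispersion=0.0, mean_expression=100.0)
        totals = simulate_allelic_counts([gene], samples, seed=2)["total_count"]
        # Poisson: mean == variance (within Monte-Carlo slack)
        assert totals.mean() == pytest.approx(100.0, rel=0.05)
        assert totals.var() == pytest.approx(100.0, rel=0.2)

    def test_count_conservation(self):
        samples = simulate_cross(CrossDesign(n_embryos={("M-Z-", "M"): 20}))
        gene = _gene(groups=(("M-Z-", "M"),), snp_informative_fraction=0.3)
        counts = simulate_allelic_counts([gene], samples, seed=3)
        assert ((counts["maternal_count"] + counts["paternal_count"])
                <= counts["total_count"]).all()

    def test_missing_group_theta_named_in_error(self):
        samples = simulate_cross(CrossDesign(n_embryos={("M-Z-", "F"): 2}))
        with pytest.raises(ValueError, match=r"g.*M-Z-.*F"):
            simulate_allelic_counts([_gene()], samples, seed=1)

    def test_reproducible(self):
        samples = simulate_cross(CrossDesign(n_embryos={("M+Z+", "F"): 4}))
        a = simulate_allelic_counts([_gene()], samples, seed=9)
        b = simulate_allelic_counts([_gene()], samples, seed=9)
        assert a.equals(b)

    def test_expression_multiplier_scales_group(self):
        samples = simulate_cross(CrossDesign(
            n_embryos={("M+Z+", "F"): 150, ("M-Z-", "F"): 150}))
        gene = _gene(groups=(("M+Z+", "F"), ("M-Z-", "F")),
                     expression_multiplier={("M-Z-", "F"): 2.0},
                     dispersion=0.02)
        counts = simulate_allelic_counts([gene], samples, seed=4) \
            .merge(samples, on="sample")
        ratio = (counts.loc[counts["genotype"] == "M-Z-", "total_count"].mean()
                 / counts.loc[counts["genotype"] == "M+Z+", "total_count"].mean())
        assert ratio == pytest.approx(2.0, rel=0.1)


def _icr_scenario(hi=0.95, lo=0.05, depth=30.0, conv_fail=0.0, snp=1.0,
                  n_cpg=20, origin="maternal"):
    icr = ICRRegion("TestICR", "chr7", 1000, 2000, germline_origin=origin)
    group = ("M+Z+", "F")
    return ICRScenario(
        icr=icr, cpg_positions=[1010 + 20 * i for i in range(n_cpg)],
        methylated_allele_level={group: hi},
        unmethylated_allele_level={group: lo},
        read_depth=depth, conversion_failure_rate=conv_fail,
        snp_informative_fraction=snp,
    )


class TestWgbsCalls:
    def _one_sample(self):
        return simulate_cross(CrossDesign(n_embryos={("M+Z+", "F"): 1}))

    def test_noiseless_limit(self):
        calls = simulate_wgbs_calls(_icr_scenario(hi=1.0, lo=0.0), self._one_sample(),
                                    seed=1)
        mat = calls[calls["allele"] == "maternal"]
        pat = calls[calls["allele"] == "paternal"]
        assert (mat["state"] == "methylated").all()
        assert (pat["state"] == "unmethylated").all()
        assert not (calls["allele"] == "unassigned").any()

    def test_total_methylation_is_allelic_mixture(self):
        # equal allelic coverage: total ~ (0.95 + 0.05) / 2 = 0.50
        calls = simulate_wgbs_calls(_icr_scenario(), self._one_sample(), seed=2)
        pct = icr_methylation_by_sample(calls, [_icr_scenario().icr])
        assert pct["percent"].iloc[0] == pytest.approx(50.0, abs=5.0)

    def test_total_conversion_failure(self):
        calls = simulate_wgbs_calls(_icr_scenario(hi=0.0, lo=0.0, conv_fail=0.99999),
                                    self._one_sample(), seed=3)
        assert (calls["state"] == "methylated").all()

    def test_methylation_recovery_over_seeds(self):
        # mixture-mean recovery +-0.05 across 10 independent seeds
        scenario = _icr_scenario(hi=0.9, lo=0.1, snp=0.3)
        expected = (0.9 + 0.1) / 2 * 100
        samples = self._one_sample()
        for seed in range(10):
            calls = simulate_wgbs_calls(scenario, samples, seed=seed)
            pct = icr_methylation_by_sample(calls, [scenario.icr])
            assert pct["percent"].iloc[0] == pytest.approx(expected, abs=5.0), seed

    def test_empty_cpgs_rejected(self):
        icr = ICRRegion("X", "chr1", 0, 100)
        with pytest.raises(ValueError, match="CpG"):
            scenario = ICRScenario(
                icr=icr, cpg_positions=[],
                methylated_allele_level={("M+Z+", "F"): 0.9},
                unmethylated_allele_level={("M+Z+", "F"): 0.1})
            simulate_wgbs_calls(scenario, self._one_sample(), seed=1)

    def test_unsorted_cpgs_rejected(self):
        icr = ICRRegion("X", "chr1", 0, 100)
        with pytest.raises(ValueError, match="increasing"):
            ICRScenario(icr=icr, cpg_positions=[50, 40],
                        methylated_allele_level={}, unmethylated_allele_level={})

    def test_reproducible(self):
        samples = self._one_sample()
        a = simulate_wgbs_calls(_icr_scenario(), samples, seed=6)
        b = simulate_wgbs_calls(_icr_scenario(), samples, seed=6)
        assert a.equals(b)


class TestColonyReads:
    def test_full_conversion_removes_all_c(self):
        scenario = synthetic_rasgrf1_amplicon(true_methylation=0.0,
                                              conversion_failure_rate=0.0,
                                              pcr_duplication_rate=0.0)
        for _, read in simulate_colony_reads(scenario, seed=1):
            assert "C" not in read

    def test_full_methylation_retains_cpg_c(self):
        scenario = synthetic_rasgrf1_amplicon(true_methylation=1.0,
                                              pcr_duplication_rate=0.0)
        for _, read in simulate_colony_reads(scenario, seed=2):
            for idx in scenario.cpg_indices:
                assert read[idx] == "C"

    def test_duplicate_fraction_matches_rate(self):
        # duplication rate 0.5, 20 colonies -> ~10 duplicates expected;
        # average over seeds to beat binomial noise
        scenario = synthetic_rasgrf1_amplicon(true_methylation=0.5,
                                              n_colonies=20,
                                              pcr_duplication_rate=0.5)
        dups = []
        for seed in range(40):
            reads = simulate_colony_reads(scenario, seed=seed)
            assert len(reads) == 20
            dups.append(sum(1 for rid, _ in reads if rid.endswith("_dup")))
        # first read can never duplicate: expectation is 19 * 0.5 = 9.5
        assert np.mean(dups) == pytest.approx(9.5, abs=1.5)

    def test_invalid_colony_count_rejected(self):
        with pytest.raises(ValueError, match="n_colonies"):
            AmpliconScenario(name="x", amplicon_sequence="TTCATTACGTT",
                             true_methylation=0.5, n_colonies=0)

    def test_reproducible(self):
        scenario = synthetic_rasgrf1_amplicon()
        assert simulate_colony_reads(scenario, seed=8) == \
            simulate_colony_reads(scenario, seed=8)

    def test_index_partition_validated(self):
        with pytest.raises(ValueError, match="not C"):
            AmpliconScenario(name="x", amplicon_sequence="ATCGT",
                             true_methylation=0.5, cpg_indices=[0],
                             non_cpg_c_indices=[])
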