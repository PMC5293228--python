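"""Shared-locus counting, binomial enrichment and Bonferroni reporting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from crosstrait import (
    SnpAssoc,
    binomial_enrichment,
    bonferroni,
    build_report,
    count_nominal,
    direction_concordance,
    map_snps,
)
from crosstrait.enrichment import MappingTally, format_p_display

from conftest import TABLE1_NOMINAL_P


def snp(snp_id, chrom="1", a1="A", a2="G", pos=1000):
    return SnpAssoc(snp_id=snp_id, chrom=chrom, pos=pos, allele1=a1, allele2=a2, z=1.0)


def make_index_list():
    """128 index SNPs: 3 X-chromosomal, 14 indels, 111 mappable autosomal SNVs."""
    snps = [snp(f"rs_x{i}", chrom="X") for i in range(3)]
    snps += [
        SnpAssoc(snp_id=f"rs_indel{i}", chrom="2", pos=5000 + i, allele1="AT",
                 allele2="A", z=1.0)
        for i in range(10)
    ]
    snps += [
        SnpAssoc(snp_id=f"rs_sym{i}", chrom="2", pos=8000 + i, allele1="I",
                 allele2="D", z=1.0)
        for i in range(4)
    ]
    snps += [snp(f"rs{i}", pos=10_000 + i) for i in range(111)]
    return snps


class TestMapSnps:
    def test_reproduces_published_filter_cascade(self):
        """128 index SNPs minus 3 X minus 14 indels = 111 mappable; with 4
        absent from the target study, 107 are tested."""
        index = make_index_list()
        target = {f"rs{i}" for i in range(107)}  # rs107..rs110 missing
        tested, tally = map_snps(index, target)
        assert tally.n_input == 128
        assert tally.n_excluded_x == 3
        assert tally.n_excluded_indel == 14
        assert tally.n_mapped == 111
        assert tally.n_absent_from_target == 4
        assert tally.n_tested == len(tested) == 107

    def test_clean_autosomal_list_passes_unchanged(self):
        index = [snp(f"rs{i}") for i in range(5)]
        tested, tally = map_snps(index, {f"rs{i}" for i in range(5)})
        assert len(tested) == 5
        assert tally.n_excluded_x == tally.n_excluded_indel == 0

    def test_chr23_counts_as_x(self):
        _, tally = map_snps([snp("rs1", chrom="23")], set())
        assert tally.n_excluded_x == 1


class TestCountNominal:
    def test_all_null_counts_zero(self):
        assert count_nominal([1.0] * 10, 0.05) == 0

    def test_strict_inequality_at_boundary(self):
        assert count_nominal([0.049, 0.05, 0.051], 0.05) == 1

    def test_table1_rows_count_22(self):
        assert count_nominal(TABLE1_NOMINAL_P, 0.05) == 22

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            count_nominal([1.5], 0.05)
        with pytest.raises(ValueError):
            count_nominal([0.5], 1.0)


class TestBinomialEnrichment:
    def test_zero_successes_gives_one(self):
        assert binomial_enrichment(0, 107, 0.05) == 1.0

    def test_published_shared_hit_count(self):
        """22 nominal hits among 107 lookups at alpha 0.05."""
        p = binomial_enrichment(22, 107, 0.05)
        assert p == pytest.approx(1.46e-8, rel=5e-3)

    def test_all_successes_at_half(self):
        assert binomial_enrichment(5, 5, 0.5) == pytest.approx(0.03125, rel=1e-12)

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            binomial_enrichment(6, 5, 0.5)

    @pytest.mark.parametrize("n", [1, 5, 13, 30])
    def test_matches_brute_force_summation(self, n):
        """Exact-fraction tail sums (math.comb) agree to 1e-12 relative."""
        for p0 in (0.05, 0.3, 0.77):
            for k in range(n + 1):
                exact = sum(
                    math.comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(k, n + 1)
                )
                assert binomial_enrichment(k, n, p0) == pytest.approx(exact, rel=1e-12)

    def test_agrees_with_scipy_survival_function(self):
        for k, n, p0 in [(22, 107, 0.05), (3, 1000, 0.001), (250, 500, 0.5)]:
            assert binomial_enrichment(k, n, p0) == pytest.approx(
                binom.sf(k - 1, n, p0), rel=1e-10
            )


class TestBonferroni:
    def test_published_corrected_value(self):
        # rs2535627: nominal 4.68e-5 at m=111
        assert round(bonferroni(4.68e-5, 111), 4) == 0.0052

    def test_exactly_two_table1_rows_survive(self):
        corrected = bonferroni(np.array(TABLE1_NOMINAL_P), 111)
        assert int((corrected < 0.05).sum()) == 2

    def test_cap_and_display_convention(self):
        assert bonferroni(0.0098, 111) == 1.0
        assert format_p_display(1.0) == ">0.9999"
        assert format_p_display(0.0052) == "0.0052"

    def test_zero_passes_through(self):
        assert bonferroni(0.0, 111) == 0.0

    @settings(deadline=None, max_examples=100)
    @given(
        p=st.floats(0, 1),
        p2=st.floats(0, 1),
        m=st.integers(1, 10_000),
        m2=st.integers(1, 10_000),
    )
    def test_monotone_and_capped(self, p, p2, m, m2):
        assert bonferroni(p, m) <= 1.0
        if p <= p2:
            assert bonferroni(p, m) <= bonferroni(p2, m)
        if m <= m2:
            assert bonferroni(p, m) <= bonferroni(p, m2)


class TestDirectionConcordance:
    def test_all_same_sign(self):
        frac, flags = direction_concordance([(1.0, 2.0), (-0.5, -3.0)])
        assert frac == 1.0 and flags.all()

    def test_half_discordant(self):
        frac, _ = direction_concordance([(1.0, 1.0), (1.0, -1.0)])
        assert frac == 0.5

    def test_zero_counts_as_discordant_flag(self):
        frac, flags = direction_concordance([(0.0, 1.0)])
        assert frac == 0.0 and not flags[0]

    def test_truly_shared_effects_are_concordant(self):
        """Hits with a common true effect of size 4 in both studies agree in
        direction essentially always (P(discord) ~ 2*Phi(-4)^... negligible)."""
        rng = np.random.default_rng(88)
        effect = 4.0 * rng.choice([-1, 1], size=22)
        z1 = effect + rng.standard_normal(22)
        z2 = effect + rng.standard_normal(22)
        frac, _ = direction_concordance(np.column_stack([z1, z2]))
        assert frac > 0.9


class TestBuildReport:
    def make_tested(self, n=5):
        return [snp(f"rs{i}", pos=1000 + i) for i in range(n)]

    def test_rows_sorted_and_counts_consistent(self):
        tested = self.make_tested(5)
        p = np.array([0.2, 0.01, 0.6, 0.04, 0.9])
        z = np.array([1.0, 2.5, -0.4, 2.0, 0.1])
        tally = MappingTally(n_input=5, n_mapped=5, n_tested=5)
        report = build_report(tested, p, z, tally, m=10, alpha=0.05)
        assert list(report.table["p_corrected"]) == sorted(p)
        assert report.n_nominal == count_nominal(p, 0.05) == 2
        assert len(report.nominal_table) == 2
        assert report.n_bonferroni <= report.n_nominal <= report.tally.n_tested
        assert report.enrichment_p == pytest.approx(binomial_enrichment(2, 5, 0.05))

    def test_ties_broken_by_chrom_then_pos(self):
        tested = [snp("b", chrom="2", pos=500), snp("a", chrom="1", pos=900)]
        report = build_report(
            tested, [0.5, 0.5], [1.0, 1.0],
            MappingTally(n_input=2, n_mapped=2, n_tested=2), m=2,
        )
        assert list(report.table["snp_id"]) == ["a", "b"]

    def test_nearby_gene_annotation(self):
        import pandas as pd
        genes = pd.DataFrame(
            {"gene_id": ["TRANK1", "OTHER"], "chrom": ["1", "1"],
             "start": [900, 5000], "end": [1100, 6000]}
        )
        report = build_report(
            [snp("rs1", pos=1000)], [0.01], [2.5],
            MappingTally(n_input=1, n_mapped=1, n_tested=1), m=1,
            gene_annotations=genes,
        )
        assert report.table.loc[0, "nearby_gene"] == "TRANK1"

    def test_null_enrichment_p_is_calibrated(self):
        """Across 500 null datasets of 107 uniform p-values, the binomial
        enrichment p is < 0.05 in about 5% of runs."""
        rng = np.random.default_rng(555)
        hits = (rng.uniform(size=(500, 107)) < 0.05).sum(axis=1)
        pvals = np.array([binomial_enrichment(int(k), 107, 0.05) for k in hits])
        assert np.mean(pvals < 0.05) == pytest.approx(0.05, abs=0.02)
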