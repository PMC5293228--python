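"""Interval-to-gene assignment and permutation gene-set enrichment."""

import numpy as np
import pytest

from crosstrait import (
    GeneAnnotation,
    GeneSet,
    Interval,
    intervals_to_genes,
    read_gene_bed,
    read_gmt,
)
from crosstrait import test_gene_sets as run_gene_sets  # alias: keep pytest from collecting it
from crosstrait.genesets import (
    filter_sets_by_size,
    results_to_frame,
    write_gene_bed,
    write_gmt,
)


def gene(gid, start, end, chrom="1"):
    return GeneAnnotation(gid, chrom, start, end)


class TestGeneFormats:
    def test_gmt_round_trip(self, tmp_path):
        sets = [
            GeneSet("GO1", "first", frozenset({"A", "B", "C"})),
            GeneSet("GO2", "second", frozenset({"B", "D"})),
        ]
        path = tmp_path / "sets.gmt"
        write_gmt(sets, path)
        back = read_gmt(path)
        assert {(s.set_id, s.gene_ids) for s in back} == {
            (s.set_id, s.gene_ids) for s in sets
        }

    def test_short_gmt_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("GO1\tonly-description\n")
        with pytest.raises(ValueError):
            read_gmt(path)

    def test_bed_round_trip(self, tmp_path):
        genes = [gene("G1", 100, 200), gene("G2", 5000, 9000, chrom="2")]
        path = tmp_path / "genes.bed"
        write_gene_bed(genes, path)
        assert read_gene_bed(path) == genes

    def test_size_filter_uses_universe_intersection(self):
        universe = {f"G{i}" for i in range(30)}
        sets = [
            GeneSet("small", "", frozenset({"G1", "G2"})),
            GeneSet("ok", "", frozenset({f"G{i}" for i in range(12)} | {"ghost"})),
        ]
        kept = filter_sets_by_size(sets, universe, min_size=10, max_size=200)
        assert [s.set_id for s in kept] == ["ok"]
        assert "ghost" not in kept[0].gene_ids


class TestIntervalsToGenes:
    def test_gene_within_flank_assigned(self):
        iv = Interval("1", 100_000, 110_000, ("rs1",))
        g = gene("G1", 120_000, 125_000)  # 10 kb beyond the interval end
        assert intervals_to_genes([iv], [g], flank_bp=50_000)[iv] == {"G1"}

    def test_gene_beyond_flank_not_assigned(self):
        iv = Interval("1", 100_000, 110_000, ("rs1",))
        g = gene("G1", 170_001, 175_000)  # 60 kb beyond the end
        assert intervals_to_genes([iv], [g], flank_bp=50_000)[iv] == frozenset()

    def test_assignments_match_brute_force(self):
        intervals = [
            Interval("1", 1000, 2000, ("a",)),
            Interval("1", 10_000, 10_500, ("b",)),
            Interval("2", 500, 800, ("c",)),
        ]
        genes = [
            gene("G1", 500, 900), gene("G2", 2100, 2500), gene("G3", 5000, 6000),
            gene("G4", 10_400, 12_000), gene("G5", 100, 300, chrom="2"),
            gene("G6", 2000, 2400, chrom="2"),
        ]
        flank = 150
        got = intervals_to_genes(intervals, genes, flank_bp=flank)
        for iv in intervals:
            expected = {
                g.gene_id for g in genes
                if g.chrom == iv.chrom
                and g.start - flank <= iv.end and g.end + flank >= iv.start
            }
            assert got[iv] == expected

    def test_chr_prefix_normalized_with_warning(self):
        iv = Interval("chr1", 100, 200, ("rs1",))
        g = gene("G1", 150, 180, chrom="1")
        with pytest.warns(UserWarning, match="chr"):
            assert intervals_to_genes([iv], [g], flank_bp=0)[iv] == {"G1"}


class TestTestGeneSets:
    def test_unreachable_set_has_p_one(self):
        # the set's gene lives on a chromosome no interval can reach
        intervals = [Interval("1", 100, 200, ("rs1",))]
        genes = [gene("G1", 100, 5000), gene("FAR", 1, 1000, chrom="9")]
        genome = {"1": 10_000}
        sets = [GeneSet("S", "", frozenset({"FAR"}))]
        (res,) = run_gene_sets(
            intervals, genes, sets, n_perm=200, n_boot=100, seed=0, flank_bp=0,
            genome=genome, match_gene_count=False,
        )
        assert res.observed_overlap == 0
        assert res.empirical_p == 1.0

    def test_always_hit_set_has_p_one(self):
        # one gene covers the whole chromosome: every relocation hits it
        intervals = [Interval("1", 50, 60, ("rs1",))]
        genes = [gene("G1", 1, 10_000)]
        sets = [GeneSet("S", "", frozenset({"G1"}))]
        (res,) = run_gene_sets(
            intervals, genes, sets, n_perm=200, n_boot=100, seed=1, flank_bp=0,
            genome={"1": 10_000}, match_gene_count=False,
        )
        assert res.observed_overlap == 1
        assert res.empirical_p == 1.0

    def test_empirical_p_matches_exhaustive_enumeration(self):
        """On a one-chromosome toy genome the relocation null can be
        enumerated exactly; the permutation p must sit within Monte-Carlo
        error of the enumerated tail probability."""
        genome = {"1": 400}
        genes = [gene("G1", 40, 60), gene("G2", 140, 170), gene("G3", 300, 320)]
        intervals = [
            Interval("1", 35, 54, ("a",)),    # length 20, hits G1
            Interval("1", 150, 159, ("b",)),  # length 10, hits G2
            Interval("1", 200, 219, ("c",)),  # length 20, no gene
            Interval("1", 310, 314, ("d",)),  # length 5, hits G3
        ]
        sets = [
            GeneSet("S1", "", frozenset({"G1", "G3"})),
            GeneSet("S2", "", frozenset({"G2"})),
        ]
        flank = 0
        n_perm = 4000
        results = {
            r.set_id: r
            for r in run_gene_sets(
                intervals, genes, sets, n_perm=n_perm, n_boot=0, seed=7,
                flank_bp=flank, genome=genome, match_gene_count=False,
            )
        }
        # exact per-interval hit probabilities by enumerating every start
        for s in sets:
            set_genes = [g for g in genes if g.gene_id in s.gene_ids]
            hit_probs = []
            for iv in intervals:
                length = iv.length
                starts = range(1, genome["1"] - length + 2)
                hits = sum(
                    any(g.start <= st + length - 1 and g.end >= st for g in set_genes)
                    for st in starts
                )
                hit_probs.append(hits / len(list(starts)))
            observed = sum(
                any(g.start <= iv.end and g.end >= iv.start for g in set_genes)
                for iv in intervals
            )
            # tail P(X1+..+X4 >= observed) for independent Bernoullis
            dist = np.array([1.0])
            for p_hit in hit_probs:
                dist = np.convolve(dist, [1 - p_hit, p_hit])
            exact_tail = dist[observed:].sum()
            expected_p = (1 + n_perm * exact_tail) / (n_perm + 1)
            mc_err = 4 * np.sqrt(exact_tail * (1 - exact_tail) / n_perm) + 2 / n_perm
            assert results[s.set_id].observed_overlap == observed
            assert abs(results[s.set_id].empirical_p - expected_p) < mc_err

    def test_fixed_seed_is_bit_reproducible(self):
        genome = {"1": 5000}
        genes = [gene(f"G{i}", 100 + 300 * i, 250 + 300 * i) for i in range(15)]
        sets = [GeneSet("S", "", frozenset({"G2", "G5", "G9"}))]
        intervals = [Interval("1", 400, 700, ("rs1",)), Interval("1", 2000, 2300, ("rs2",))]
        kw = dict(n_perm=300, n_boot=150, seed=42, flank_bp=50, genome=genome)
        assert run_gene_sets(intervals, genes, sets, **kw) == run_gene_sets(
            intervals, genes, sets, **kw
        )

    def test_invariants_hold(self):
        rng = np.random.default_rng(9)
        genome = {"1": 20_000, "2": 15_000}
        genes = [gene(f"G{i}", 200 + 600 * i, 500 + 600 * i) for i in range(20)]
        genes += [gene(f"H{i}", 200 + 600 * i, 500 + 600 * i, chrom="2") for i in range(15)]
        ids = np.array([g.gene_id for g in genes], dtype=object)
        sets = [
            GeneSet(f"S{k}", "", frozenset(rng.choice(ids, size=6, replace=False)))
            for k in range(10)
        ]
        intervals = [
            Interval("1", 350, 900, ("a",)),
            Interval("2", 1000, 1400, ("b",)),
            Interval("1", 9000, 9600, ("c",)),
        ]
        n_perm = 400
        results = run_gene_sets(
            intervals, genes, sets, n_perm=n_perm, n_boot=200, seed=3,
            flank_bp=100, genome=genome,
        )
        for r in results:
            assert 1 / (n_perm + 1) <= r.empirical_p <= 1.0
            assert r.corrected_p >= r.empirical_p
        frame = results_to_frame(results)
        assert frame["empirical_p"].is_monotonic_increasing

    def test_null_sets_are_calibrated(self):
        """With sets independent of the (themselves random) intervals, about
        5% of sets reach empirical p < 0.05."""
        rng = np.random.default_rng(1)
        genome = {"1": 200_000}
        genes = [gene(f"G{i}", 1 + 500 * i, 100 + 500 * i) for i in range(400)]
        ids = np.array([g.gene_id for g in genes], dtype=object)
        sets = [
            GeneSet(f"S{k}", "", frozenset(
                rng.choice(ids, size=int(rng.integers(10, 60)), replace=False)))
            for k in range(150)
        ]
        intervals = [
            Interval("1", int(s), int(s) + int(ln) - 1, (f"rs{i}",))
            for i, (s, ln) in enumerate(
                zip(rng.integers(1, 197_000, size=40), rng.integers(200, 3000, size=40))
            )
        ]
        results = run_gene_sets(
            intervals, genes, sets, n_perm=400, n_boot=0, seed=2,
            flank_bp=0, genome=genome, match_gene_count=False,
        )
        frac = np.mean([r.empirical_p < 0.05 for r in results])
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            run_gene_sets([Interval("1", 1, 10, ("a",))], [gene("G1", 1, 5)], [], n_perm=10)
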