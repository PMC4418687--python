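from __future__ import annotations

import numpy as np
import pytest

from tnscan.essentiality import (
    CENTRAL_80,
    DEFAULT_POLICY,
    FLAG_EMPTY,
    NO_TRUNCATION,
    GeneTable,
    TruncationPolicy,
    build_gene_table,
    call_essential_regions,
    classify_genes,
    count_in_interval,
    count_ta_sites,
    effective_interval,
    essentiality_index,
    insertion_density,
    reads_per_ta,
)
from tnscan.formats_io import GeneAnnotation, GenomeRef
from tnscan.insertion_calling import filter_low_read_insertions
from tnscan.window_scan import WindowProfile, scan_windows

from tests.helpers import (
    make_library,
    oracle_ei,
    oracle_interval_count,
    oracle_regions,
    oracle_window_counts,
    random_library,
)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestEffectiveInterval:
    def test_plus_strand_default_trims(self, gene_plus):
        interval = effective_interval(gene_plus, DEFAULT_POLICY)
        assert (interval.start, interval.end) == (6, 80)

    def test_minus_strand_mirrors_trims(self, gene_minus):
        interval = effective_interval(gene_minus, DEFAULT_POLICY)
        assert (interval.start, interval.end) == (21, 95)

    def test_zero_policy_is_identity(self, gene_plus):
        interval = effective_interval(gene_plus, NO_TRUNCATION)
        assert (interval.start, interval.end) == (gene_plus.start, gene_plus.end)

    def test_nt_and_pct_combined_by_max(self):
        gene = GeneAnnotation("c1", "G", "", "", 1, 100, "+")
        policy = TruncationPolicy(pct_5prime=5, pct_3prime=0, nt_5prime=30,
                                  nt_3prime=0)
        interval = effective_interval(gene, policy)
        assert interval.start == 31  # 30 nt beats floor(5% of 100) = 5

    def test_over_trimmed_gene_flagged_empty(self):
        gene = GeneAnnotation("c1", "G", "", "", 10, 19, "+")
        policy = TruncationPolicy(pct_5prime=60, pct_3prime=60)
        interval = effective_interval(gene, policy)
        assert interval.empty
        assert FLAG_EMPTY in interval.flags

    def test_central_80_variant(self):
        gene = GeneAnnotation("c1", "G", "", "", 101, 200, "-")
        interval = effective_interval(gene, CENTRAL_80)
        assert (interval.start, interval.end) == (111, 190)


class TestCountInInterval:
    def test_membership_both_strands(self):
        lib = make_library(
            [("c1", 5, "+", 2), ("c1", 5, "-", 3), ("c1", 9, "+", 1)]
        )
        assert count_in_interval(lib, "c1", 1, 10) == 3
        assert count_in_interval(lib, "c1", 1, 10, mode="reads") == 6
        assert count_in_interval(lib, "c1", 11, 20) == 0

    def test_matches_oracle_on_random_library(self, rng):
        lib = random_library(rng, 2000, 150)
        for _ in range(30):
            a = int(rng.integers(1, 2000))
            b = int(rng.integers(a, 2001))
            for mode in ("unique_insertions", "reads"):
                assert count_in_interval(lib, "c1", a, b, mode) == \
                    oracle_interval_count(lib, "c1", a, b, mode)


class TestEssentialityIndex:
    def test_embedded_rule_two_distant_insertions(self):
        gene = GeneAnnotation("c1", "G", "", "", 1000, 2000, "+")
        lib = make_library([("c1", 1100, "+", 1), ("c1", 1900, "+", 1)])
        genome = GenomeRef("c1", 10_000)
        result = essentiality_index(gene, lib, genome, 500, NO_TRUNCATION)
        assert result.value == 1  # no 500 bp window holds both (gap 800)

    def test_zero_insertions_gives_zero(self):
        gene = GeneAnnotation("c1", "G", "", "", 5000, 5199, "+")
        result = essentiality_index(
            gene, make_library([]), GenomeRef("c1", 10_000), 550, NO_TRUNCATION
        )
        assert result.value == 0

    def test_short_gene_amid_dense_flanks_uses_encompassing_minimum(self):
        gene = GeneAnnotation("c1", "G", "", "", 5000, 5299, "+")
        entries = [("c1", p, "+", 1) for p in range(4000, 5000, 10)]
        entries += [("c1", p, "+", 1) for p in range(5300, 6300, 10)]
        lib = make_library(entries)
        genome = GenomeRef("c1", 10_000)
        result = essentiality_index(gene, lib, genome, 550, NO_TRUNCATION)
        expected = oracle_ei(gene, lib, 10_000, 550, 0, 0)
        assert result.value == expected
        own = count_in_interval(lib, "c1", 5000, 5299)
        assert result.value >= own  # flank insertions inflate short genes

    def test_truncation_applied_before_ei(self):
        # insertion sits in the trimmed 3' 20%, so default policy hides it
        gene = GeneAnnotation("c1", "G", "", "", 1001, 2000, "+")
        lib = make_library([("c1", 1950, "+", 4)])
        genome = GenomeRef("c1", 10_000)
        with_trim = essentiality_index(gene, lib, genome, 400)
        without = essentiality_index(gene, lib, genome, 400, NO_TRUNCATION)
        assert with_trim.value == 0
        assert without.value == 1

    def test_window_exceeding_contig_is_error(self):
        gene = GeneAnnotation("c1", "G", "", "", 10, 40, "+")
        with pytest.raises(ValueError):
            essentiality_index(
                gene, make_library([]), GenomeRef("c1", 100), 200
            )

    def test_matches_oracle_on_random_genomes(self, rng):
        for _ in range(20):
            length = int(rng.integers(2000, 10_000))
            lib = random_library(rng, length, int(rng.integers(10, 200)))
            genome = GenomeRef("c1", length)
            W = int(rng.integers(50, 1000))
            start = int(rng.integers(1, length - 600))
            end = start + int(rng.integers(100, 600))
            gene = GeneAnnotation(
                "c1", "G", "", "", start, min(end, length),
                "+" if rng.random() < 0.5 else "-",
            )
            got = essentiality_index(gene, lib, genome, W).value
            assert got == oracle_ei(gene, lib, length, W)

    def test_never_increases_after_read_filtering(self, rng):
        length = 20_000
        lib = random_library(rng, length, 400, max_count=6)
        genome = GenomeRef("c1", length)
        filtered = filter_low_read_insertions(lib, 3)
        for start in range(1000, 18_000, 2500):
            gene = GeneAnnotation("c1", f"G{start}", "", "", start, start + 900, "+")
            before = essentiality_index(gene, lib, genome, 400).value
            after = essentiality_index(gene, filtered, genome, 400).value
            assert after <= before

    def test_bounds_for_embedded_and_encompassing_rules(self, rng):
        length = 10_000
        lib = random_library(rng, length, 300)
        genome = GenomeRef("c1", length)
        long_gene = GeneAnnotation("c1", "L", "", "", 2000, 3500, "+")
        result = essentiality_index(long_gene, lib, genome, 300, NO_TRUNCATION)
        total = count_in_interval(lib, "c1", 2000, 3500)
        assert result.value <= total
        short_gene = GeneAnnotation("c1", "S", "", "", 6000, 6150, "+")
        result = essentiality_index(short_gene, lib, genome, 500, NO_TRUNCATION)
        assert result.value >= count_in_interval(lib, "c1", 6000, 6150)


class TestDensities:
    def test_density_is_count_over_length(self):
        gene = GeneAnnotation("c1", "G", "", "", 1, 500, "+")
        lib = make_library([("c1", p, "+", 5) for p in (100, 200, 300, 400)])
        result = insertion_density(gene, lib, policy=NO_TRUNCATION)
        assert result.value == pytest.approx(4 / 500)
        reads = insertion_density(gene, lib, mode="reads", policy=NO_TRUNCATION)
        assert reads.value == pytest.approx(20 / 500)

    def test_zero_insertions_zero_density(self, gene_plus):
        assert insertion_density(gene_plus, make_library([])).value == 0.0

    def test_annotated_denominator_never_larger(self):
        gene = GeneAnnotation("c1", "G", "", "", 1, 400, "+")
        lib = make_library([("c1", 100, "+", 1), ("c1", 200, "+", 1)])
        eff = insertion_density(gene, lib, denominator="effective_length")
        ann = insertion_density(gene, lib, denominator="annotated_length")
        assert ann.value <= eff.value


class TestTaNormalization:
    def test_overlapping_ta_runs(self):
        genome = GenomeRef("c1", 6, "TATATA")
        assert count_ta_sites(genome, "c1", 1, 6) == 3

    def test_no_t_means_zero(self):
        genome = GenomeRef("c1", 8, "ACGGCCGA")
        assert count_ta_sites(genome, "c1", 1, 8) == 0

    def test_reverse_complement_symmetry(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        genome = GenomeRef("c1", 300, seq)
        mirror = GenomeRef("c1", 300, _revcomp(seq))
        for _ in range(10):
            a = int(rng.integers(1, 300))
            b = int(rng.integers(a, 301))
            assert count_ta_sites(genome, "c1", a, b) == \
                count_ta_sites(mirror, "c1", 300 - b + 1, 300 - a + 1)

    def test_missing_sequence_is_error(self, gene_plus, bare_genome):
        with pytest.raises(ValueError, match="FASTA"):
            count_ta_sites(bare_genome, "c1", 1, 10)

    def test_reads_per_ta_scale_and_linearity(self):
        seq = "TA" * 150
        genome = GenomeRef("c1", 300, seq)
        gene = GeneAnnotation("c1", "G", "", "", 1, 200, "+")
        lib = make_library([("c1", p, "+", 6) for p in range(2, 200, 13)])
        full = reads_per_ta(gene, lib, genome, NO_TRUNCATION)
        halved = make_library([("c1", p, "+", 3) for p in range(2, 200, 13)])
        half = reads_per_ta(gene, halved, genome, NO_TRUNCATION)
        assert half.value == pytest.approx(full.value / 2)

    def test_zero_ta_sites_flagged_undefined(self):
        genome = GenomeRef("c1", 100, "G" * 100)
        gene = GeneAnnotation("c1", "G", "", "", 1, 100, "+")
        result = reads_per_ta(gene, make_library([]), genome, NO_TRUNCATION)
        assert result.value is None
        assert "no_ta_sites" in result.flags


class TestClassifyGenes:
    def test_le_rule_counts_at_cutoff(self):
        values = {f"G{i}": v for i, v in enumerate([0, 3, 6, 7, 12])}
        result = classify_genes(values, 6, rule="le")
        assert len(result.essential) == 3

    def test_cutoff_below_all_values(self):
        result = classify_genes({"G1": 5, "G2": 9}, 1, rule="le")
        assert len(result.essential) == 0

    def test_lt_with_cutoff_plus_one_equals_le(self):
        values = {f"G{i}": int(v) for i, v in enumerate([0, 1, 4, 6, 6, 7, 9])}
        le = classify_genes(values, 6, rule="le")
        lt = classify_genes(values, 7, rule="lt")
        assert le.essential == lt.essential

    def test_undefined_metric_excluded_and_counted(self):
        result = classify_genes({"G1": 2, "G2": None}, 3, rule="le")
        assert result.excluded == {"G2"}
        assert result.n_excluded == 1


class TestEssentialRegions:
    @staticmethod
    def _profile(counts, W, s):
        starts = np.arange(1, 1 + s * len(counts), s, dtype=np.int64)
        return WindowProfile("c1", W, s, "unique_insertions", starts,
                             np.array(counts, dtype=np.int64))

    def test_non_adjacent_low_windows_stay_separate(self):
        regions = call_essential_regions(self._profile([0, 0, 5, 0], 100, 100), 0)
        assert [(r.start, r.end) for r in regions] == [(1, 200), (301, 400)]
        assert [r.window_count for r in regions] == [2, 1]

    def test_all_above_cutoff_empty(self):
        assert call_essential_regions(self._profile([3, 4, 5], 100, 100), 1) == []

    def test_cutoff_at_max_merges_everything(self):
        regions = call_essential_regions(self._profile([3, 4, 5], 100, 50), 5)
        assert [(r.start, r.end, r.max_count) for r in regions] == [(1, 200, 5)]

    def test_matches_merge_oracle_on_random_profiles(self, rng):
        for _ in range(30):
            length = int(rng.integers(1000, 8000))
            lib = random_library(rng, length, int(rng.integers(5, 100)))
            W = int(rng.integers(20, 500))
            if W > length:
                continue
            s = int(rng.integers(1, 200))
            cutoff = int(rng.integers(0, 4))
            genome = GenomeRef("c1", length)
            regions = call_essential_regions(
                scan_windows(lib, genome, W, s), cutoff
            )
            expected = oracle_regions(
                oracle_window_counts(lib, "c1", length, W, s), W, cutoff
            )
            assert [
                (r.start, r.end, r.window_count, r.max_count) for r in regions
            ] == expected


class TestBuildGeneTable:
    @staticmethod
    def _setup(rng):
        length = 20_000
        genome = GenomeRef("c1", length)
        genes = [
            GeneAnnotation("c1", f"G{i}", "", "", s, s + 800, "+")
            for i, s in enumerate(range(1000, 18_000, 2000))
        ]
        libraries = {
            "a": random_library(rng, length, 200, name="a"),
            "b": random_library(rng, length, 150, name="b"),
        }
        return genome, genes, libraries

    def test_one_ei_column_per_library(self, rng):
        genome, genes, libraries = self._setup(rng)
        table = build_gene_table(
            genes, libraries,
            [{"metric": "ei", "library": n, "window_size": 400}
             for n in ("a", "b")],
            genomes={"c1": genome},
        )
        assert "a.EI.W400" in table.columns
        assert "b.EI.W400" in table.columns

    def test_rerun_appends_suffixed_duplicate(self, rng):
        genome, genes, libraries = self._setup(rng)
        analysis = [{"metric": "density", "library": "a"}]
        table = build_gene_table(genes, libraries, analysis)
        first = table.column("a.density")
        build_gene_table(genes, libraries, analysis, table=table)
        assert "a.density.2" in table.columns
        assert table.column("a.density") == first

    def test_ei_column_matches_per_gene_calls(self, rng):
        genome, genes, libraries = self._setup(rng)
        table = build_gene_table(
            genes, libraries,
            [{"metric": "ei", "library": "a", "window_size": 300}],
            genomes={"c1": genome},
        )
        column = table.column("a.EI.W300")
        for gene in genes:
            direct = essentiality_index(gene, libraries["a"], genome, 300)
            assert column[gene.locus_tag] == direct.value

    def test_unknown_library_is_error(self, rng):
        genome, genes, libraries = self._setup(rng)
        with pytest.raises(ValueError, match="unknown library"):
            build_gene_table(
                genes, libraries, [{"metric": "density", "library": "zzz"}]
            )
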