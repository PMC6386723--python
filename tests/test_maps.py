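"""Binned matrices, decay curves, rankings, attachment profiles."""

import math

import numpy as np
import pandas as pd
import pytest

from margifuse.binning import BinnedMatrix, GenomeBinning, row_normalize
from margifuse.maps import (
    attachment_level,
    bin_interactions,
    distance_decay,
    fusion_map,
    gene_pair_counts,
    profile_correlation,
)
from margifuse.pairs import classify, filter_remote


@pytest.fixture()
def binning_10mb():
    return GenomeBinning(10_000_000, {"chr1": 25_000_000, "chr2": 15_000_000})


class TestGenomeBinning:
    def test_bin_index_layout(self, binning_10mb):
        b = binning_10mb
        assert b.n_bins == 3 + 2
        assert b.bin_of("chr1", 1) == 0
        assert b.bin_of("chr1", 10_000_000) == 0
        assert b.bin_of("chr1", 10_000_001) == 1
        assert b.bin_of("chr2", 1) == 3          # chr2 offset after chr1's 3 bins
        assert b.chrom_of_bin(4) == "chr2"
        assert b.chrom_bin_range("chr1") == (0, 3)

    def test_roundtrip_dict(self, binning_10mb):
        assert GenomeBinning.from_dict(binning_10mb.to_dict()) == binning_10mb


class TestBinInteractions:
    def test_single_pair_lands_in_expected_cell(self, binning_10mb, make_pair_row):
        pair = make_pair_row("chr1", 5_000_000, "chr1", 15_000_000)
        m = bin_interactions(pair, binning_10mb)
        assert m.counts[0, 1] == 1
        assert m.total() == 1

    def test_empty_input_gives_empty_matrix(self, binning_10mb):
        empty = pd.DataFrame(columns=["read_id", "rna_chrom", "rna_pos", "rna_strand",
                                      "dna_chrom", "dna_pos", "dna_strand"])
        assert bin_interactions(empty, binning_10mb).total() == 0

    def test_totals_equal_brute_force_tally(self, small_genome, small_pairs):
        _, chrom_sizes = small_genome
        binning = GenomeBinning(1_000_000, chrom_sizes)
        sample = small_pairs.head(1_000)
        m = bin_interactions(sample, binning)
        tally: dict[tuple[int, int], int] = {}
        for r in sample.itertuples(index=False):
            key = (binning.bin_of(r.rna_chrom, r.rna_pos),
                   binning.bin_of(r.dna_chrom, r.dna_pos))
            tally[key] = tally.get(key, 0) + 1
        coo = m.counts.tocoo()
        assert {(int(i), int(j)): int(v)
                for i, j, v in zip(coo.row, coo.col, coo.data)} == tally
        assert m.total() == len(sample)

    def test_unknown_chromosome_error_and_skip(self, binning_10mb, make_pair_row):
        pair = make_pair_row("chrMT", 100, "chr1", 100)
        with pytest.raises(KeyError):
            bin_interactions(pair, binning_10mb)
        assert bin_interactions(pair, binning_10mb, on_unknown_chrom="skip").total() == 0


class TestRowNormalize:
    def test_rows_sum_to_one_or_zero(self, binning_10mb, make_pair_row):
        pairs = pd.concat([
            make_pair_row("chr1", 5_000_000, "chr1", 15_000_000),
            make_pair_row("chr1", 6_000_000, "chr2", 1_000_000),
            make_pair_row("chr2", 1_000, "chr1", 1_000),
        ], ignore_index=True)
        m = row_normalize(bin_interactions(pairs, binning_10mb))
        sums = np.asarray(m.counts.sum(axis=1)).ravel()
        for s in sums:
            assert s == pytest.approx(1.0) or s == 0.0
        assert m.normalization == "row-normalized"

    def test_known_row_values(self, binning_10mb, make_pair_row):
        pairs = pd.concat([
            make_pair_row("chr1", 1, "chr1", 15_000_000),
            make_pair_row("chr1", 2, "chr1", 15_000_000),
            make_pair_row("chr1", 3, "chr2", 1),
            make_pair_row("chr1", 4, "chr2", 1),
        ], ignore_index=True)
        m = row_normalize(bin_interactions(pairs, binning_10mb))
        assert m.counts[0, 1] == pytest.approx(0.5)
        assert m.counts[0, 3] == pytest.approx(0.5)

    def test_double_normalization_rejected(self, binning_10mb, make_pair_row):
        m = row_normalize(bin_interactions(
            make_pair_row("chr1", 1, "chr1", 1), binning_10mb))
        with pytest.raises(ValueError, match="already"):
            row_normalize(m)


class TestDistanceDecay:
    def test_single_populated_separation(self, binning_10mb, make_pair_row):
        pairs = pd.concat(
            [make_pair_row("chr1", 5_000_000, "chr1", 15_000_000, read_id=f"r{i}")
             for i in range(12)],
            ignore_index=True,
        )
        curve = distance_decay(pairs, binning_10mb, min_count=10)
        by_sep = curve.set_index("separation_bp")["n_bin_pairs"]
        assert by_sep[10_000_000] == 1
        assert by_sep.drop(10_000_000).eq(0).all()

    def test_min_count_above_everything_zeroes_curve(self, binning_10mb, make_pair_row):
        pairs = make_pair_row("chr1", 1, "chr1", 15_000_000)
        curve = distance_decay(pairs, binning_10mb, min_count=10)
        assert curve["n_bin_pairs"].eq(0).all()

    def test_equals_brute_force_enumeration(self, small_genome, small_pairs):
        _, chrom_sizes = small_genome
        binning = GenomeBinning(1_000_000, chrom_sizes)
        remote = filter_remote(classify(small_pairs))
        curve = distance_decay(remote, binning, min_count=3)

        # oracle: tally every (RNA bin, DNA bin) cell by loop, then threshold
        cells: dict[tuple[int, int], int] = {}
        for r in remote.itertuples(index=False):
            if r.rna_chrom != r.dna_chrom:
                continue
            key = (binning.bin_of(r.rna_chrom, r.rna_pos),
                   binning.bin_of(r.dna_chrom, r.dna_pos))
            cells[key] = cells.get(key, 0) + 1
        expect: dict[int, int] = {}
        for (i, j), v in cells.items():
            if v >= 3:
                sep = abs(i - j) * binning.bin_size_bp
                expect[sep] = expect.get(sep, 0) + 1
        got = curve.set_index("separation_bp")["n_bin_pairs"]
        for sep, n in expect.items():
            assert got[sep] == n
        assert got.sum() == sum(expect.values())

    def test_decay_non_increasing_on_power_law_sets(self, small_genome):
        """Beyond the first populated separation, a power-law library decays."""
        from margifuse import simulate as sim
        annotation, chrom_sizes = small_genome
        cfg = sim.SimConfig(proximal_fraction=0.0, distal_fraction=1.0,
                            gene_assign_fraction=0.0, n_read_pairs=50_000,
                            decay_exponent=1.5, seed=21)
        pairs = sim.simulate_imargi(annotation, chrom_sizes, cfg, [])
        curve = distance_decay(pairs, GenomeBinning(1_000_000, chrom_sizes), min_count=5)
        vals = curve["n_bin_pairs"].to_numpy()
        assert np.flatnonzero(vals).size > 3
        # the first separation bin is hollowed out by the proximal cutoff;
        # decay must hold from the modal separation onward
        peak = int(vals.argmax())
        head = vals[peak: peak + 4]
        assert (np.diff(head) <= 0).all()


class TestAttachmentProfiles:
    def test_dna_end_binning(self, make_pair_row):
        binning = GenomeBinning(100_000, {"chr1": 300_000})
        pairs = pd.concat([
            make_pair_row("chr1", 1, "chr1", 50_000),
            make_pair_row("chr1", 1, "chr1", 150_000),
        ], ignore_index=True)
        profile = attachment_level(pairs, binning)
        np.testing.assert_array_equal(profile, [1, 1, 0])

    def test_total_preserved(self, small_genome, small_pairs):
        _, chrom_sizes = small_genome
        profile = attachment_level(small_pairs, GenomeBinning(100_000, chrom_sizes))
        assert profile.sum() == len(small_pairs)

    def test_correlation_trivials(self):
        p = np.array([1.0, 2.0, 3.0])
        assert profile_correlation(p, p) == pytest.approx(1.0)
        assert profile_correlation(p, p[::-1]) == pytest.approx(-1.0)
        assert math.isnan(profile_correlation(p, np.ones(3)))

    def test_correlation_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        a, b = rng.poisson(4.0, 100).astype(float), rng.poisson(4.0, 100).astype(float)
        expected = (((a - a.mean()) * (b - b.mean())).mean() / (a.std() * b.std()))
        assert profile_correlation(a, b) == pytest.approx(expected, abs=1e-12)

    def test_correlation_symmetric_and_affine_invariant(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=50), rng.normal(size=50)
        r = profile_correlation(a, b)
        assert profile_correlation(b, a) == pytest.approx(r)
        assert profile_correlation(3.0 * a + 7.0, b) == pytest.approx(r)


class TestFusionMap:
    def test_intra_pair_fills_symmetric_cells(self, binning_10mb):
        annotation = pd.DataFrame({
            "gene_id": ["A", "B"], "chrom": ["chr1", "chr1"],
            "start": [4_999_000, 14_999_000], "end": [5_001_000, 15_001_000],
            "strand": ["+", "-"],
        })
        cat = pd.DataFrame({"gene_a": ["A"], "gene_b": ["B"], "recurrence": [1],
                            "pair_class": ["intrachromosomal"], "distance_bp": [9_998_000]})
        m = fusion_map(cat, annotation, binning_10mb)
        assert m.counts[0, 1] == 1 and m.counts[1, 0] == 1
        assert m.total() == 2

    def test_same_bin_pair_counts_once_on_diagonal(self, binning_10mb):
        annotation = pd.DataFrame({
            "gene_id": ["A", "B"], "chrom": ["chr1", "chr1"],
            "start": [1_000_000, 3_000_000], "end": [1_010_000, 3_010_000],
            "strand": ["+", "-"],
        })
        cat = pd.DataFrame({"gene_a": ["A"], "gene_b": ["B"], "recurrence": [1],
                            "pair_class": ["intrachromosomal"], "distance_bp": [1_990_000]})
        m = fusion_map(cat, annotation, binning_10mb)
        assert m.counts[0, 0] == 1
        assert m.total() == 1

    def test_total_counts_invariant(self, small_genome, small_susceptible, small_config):
        from margifuse import simulate as sim
        from margifuse.catalog import build_futra_pairs, filter_fusion_calls
        annotation, chrom_sizes = small_genome
        calls = sim.simulate_fusion_catalog(annotation, small_susceptible, small_config)
        cat = build_futra_pairs(filter_fusion_calls(calls), annotation)
        binning = GenomeBinning(1_000_000, chrom_sizes)
        m = fusion_map(cat, annotation, binning)
        genes = annotation.set_index("gene_id")
        diag = 0
        for r in cat.itertuples(index=False):
            ga, gb = genes.loc[r.gene_a], genes.loc[r.gene_b]
            ba = binning.bin_of(ga["chrom"], (ga["start"] + ga["end"]) // 2 + 1)
            bb = binning.bin_of(gb["chrom"], (gb["start"] + gb["end"]) // 2 + 1)
            diag += ba == bb
        assert m.total() == 2 * (len(cat) - diag) + diag


class TestGenePairCounts:
    def test_exclude_list_removes_gene(self, small_genome, small_pairs):
        annotation, _ = small_genome
        remote = filter_remote(classify(small_pairs))
        ranking = gene_pair_counts(remote, annotation)
        top_gene = ranking.loc[0, "gene_a"]
        pruned = gene_pair_counts(remote, annotation, exclude_genes=[top_gene])
        assert top_gene not in set(pruned["gene_a"]) | set(pruned["gene_b"])

    def test_empty_annotation_empty_ranking(self, small_pairs):
        empty = pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "strand"])
        assert len(gene_pair_counts(small_pairs, empty)) == 0
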