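import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import genostream as gs
from genostream.align import align_proteins
from genostream.features import greedy_cluster
from genostream.io import GeneTable
from genostream.tables import C_SIDECHAIN, N_SIDECHAIN

# textbook molecular formulas of the free amino acids: (C, N) atom counts;
# the backbone common to all residues contributes 2 C and 1 N
AA_FORMULA_CN = {
    "A": (3, 1), "R": (6, 4), "N": (4, 2), "D": (4, 1), "C": (3, 1),
    "E": (5, 1), "Q": (5, 2), "G": (2, 1), "H": (6, 3), "I": (6, 1),
    "L": (6, 1), "K": (6, 2), "M": (5, 1), "F": (9, 1), "P": (5, 1),
    "S": (3, 1), "T": (4, 1), "W": (11, 2), "Y": (9, 1), "V": (5, 1),
}


def genome_of(seq):
    return gs.GenomeRecord("g", [("c1", seq)])


def table_of(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "contig_id", "start", "end",
                                     "strand", "cds", "protein"])
    return GeneTable(df)


class TestGc:
    @pytest.mark.parametrize("seq,expected", [("ATGC", 50.0), ("AATT", 0.0), ("GGCN", 100.0)])
    def test_examples(self, seq, expected):
        assert gs.gc_content(genome_of(seq)) == expected

    def test_all_n_is_undefined(self):
        with pytest.raises(ValueError):
            gs.gc_content(genome_of("NNNN"))

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet="ACGTN", min_size=1, max_size=200))
    def test_matches_brute_force_counter(self, seq):
        unambiguous = [b for b in seq if b != "N"]
        if not unambiguous:
            return
        expected = 100.0 * sum(b in "GC" for b in unambiguous) / len(unambiguous)
        assert gs.gc_content(genome_of(seq)) == pytest.approx(expected)


class TestSpacers:
    def mk(self, coords, contig="c1"):
        return table_of([
            (f"g{i}", contig, s, e, "+", "", "") for i, (s, e) in enumerate(coords)
        ])

    def test_simple_gap(self):
        spacers, _ = gs.intergenic_spacers(self.mk([(1, 300), (321, 600)]))
        assert spacers == [20]

    def test_book_ended_is_zero(self):
        spacers, summ = gs.intergenic_spacers(self.mk([(1, 300), (301, 600)]))
        assert spacers == [0] and summ["n_overlaps"] == 0

    def test_overlap_clamped_and_flagged(self):
        spacers, summ = gs.intergenic_spacers(self.mk([(1, 300), (250, 600)]))
        assert spacers == [0] and summ["n_overlaps"] == 1

    def test_single_gene_contigs_give_missing_summary(self):
        t = table_of([("a", "c1", 1, 90, "+", "", ""), ("b", "c2", 1, 90, "+", "", "")])
        spacers, summ = gs.intergenic_spacers(t)
        assert spacers == [] and summ["mean"] is None and summ["median"] is None

    def test_no_spacer_across_contig_boundaries(self):
        t = table_of([("a", "c1", 1, 90, "+", "", ""), ("b", "c1", 101, 190, "+", "", ""),
                      ("c", "c2", 1, 90, "+", "", ""), ("d", "c2", 501, 590, "+", "", "")])
        spacers, _ = gs.intergenic_spacers(t)
        assert spacers == [10, 410]

    def test_span_conservation_on_generated_genome(self, lgc_genome):
        """Spacer sum + gene-length sum equals the span from first gene start
        to last gene end (exhaustive interval arithmetic oracle)."""
        genome, table, _ = lgc_genome
        spacers, summ = gs.intergenic_spacers(table)
        assert summ["n_overlaps"] == 0
        gene_len = int((table.df["end"] - table.df["start"] + 1).sum())
        span = int(table.df["end"].max() - table.df["start"].min() + 1)
        assert sum(spacers) + gene_len == span


class TestSizeDensity:
    def test_estimated_size(self):
        g = genome_of("A" * 100)
        g.completeness = 60.0
        assert gs.estimated_genome_size(g) == pytest.approx(100 * 100 / 60)

    def test_complete_genome_size_unchanged(self):
        g = genome_of("A" * 1234)
        assert gs.estimated_genome_size(g) == 1234

    def test_scaling_example(self):
        g = genome_of("A" * 2_400_000)
        g.completeness = 96.0
        assert gs.estimated_genome_size(g) == pytest.approx(2_500_000)

    def test_missing_completeness_is_error(self):
        g = genome_of("ACGT")
        g.completeness = None
        with pytest.raises(ValueError):
            gs.estimated_genome_size(g)

    def test_density_examples(self):
        t = table_of([(f"g{i}", "c1", 1 + 10 * i, 9 + 10 * i, "+", "", "") for i in range(20)])
        assert gs.gene_density(t, 2e6) == pytest.approx(10.0)
        empty = table_of([])
        assert gs.gene_density(empty, 1e6) == 0.0

    def test_density_invariant_to_completeness_scaling(self):
        # completeness-scaled count over completeness-scaled size == raw/raw
        t = table_of([(f"g{i}", "c1", 1 + 10 * i, 9 + 10 * i, "+", "", "") for i in range(50)])
        assert gs.gene_density(t, 1e6, completeness=62.0) == \
            pytest.approx(gs.gene_density(t, 1e6, completeness=100.0))


class TestArsc:
    def test_arginine(self):
        assert gs.arsc(["R"]) == (3.0, 4.0)

    def test_glycine(self):
        assert gs.arsc(["G"]) == (0.0, 0.0)

    def test_residue_weighted_mean(self):
        n, c = gs.arsc(["RK"])
        assert n == pytest.approx((3 + 1) / 2)

    def test_pooled_not_per_gene_averaged(self):
        # residue weighting: a long glycine protein dominates a short arginine one
        n, _ = gs.arsc(["G" * 9, "R"])
        assert n == pytest.approx(3 / 10)

    def test_empty_proteome_is_error(self):
        with pytest.raises(ValueError):
            gs.arsc([])

    def test_side_chain_table_matches_molecular_formulas(self):
        for aa, (c_total, n_total) in AA_FORMULA_CN.items():
            assert C_SIDECHAIN[aa] == c_total - 2, aa
            assert N_SIDECHAIN[aa] == n_total - 1, aa


class TestAminoAcidUsage:
    def test_simple_fractions(self):
        freq = gs.amino_acid_usage(["AAKK"])
        assert freq["A"] == 0.5 and freq["K"] == 0.5

    def test_sums_to_one(self, lgc_genome):
        _, table, _ = lgc_genome
        freq = gs.amino_acid_usage(table.proteins)
        assert sum(freq.values()) == pytest.approx(1.0, abs=1e-9)

    def test_low_gc_enriches_lysine_asparagine(self):
        """AT-rich codons (AAA/AAG, AAU/AAC) make K+N more frequent in the
        low-GC proteome than the high-GC one — a genetic-code consequence."""
        low = gs.generate_genome(gs.LGC_PROFILE, 150, seed=31)[1]
        high = gs.generate_genome(gs.HGC_PROFILE, 150, seed=32)[1]
        f_low = gs.amino_acid_usage(low.proteins)
        f_high = gs.amino_acid_usage(high.proteins)
        assert f_low["K"] + f_low["N"] > f_high["K"] + f_high["N"]


class TestParalogs:
    def test_identical_pair_counted_at_all_thresholds(self):
        counts = gs.count_paralogs(["MKVLAWFQRT" * 5] * 2)
        assert all(v == 2 for v in counts.values())

    def test_unrelated_proteins_make_no_paralogs(self, rng):
        # disjoint residue alphabets guarantee pairwise identity far below 30 %
        alphabets = ["ACD", "EFG", "HIK", "LMN", "PQR", "STV"]
        prots = ["".join(rng.choice(list(a), 80)) for a in alphabets]
        counts = gs.count_paralogs(prots)
        assert all(v == 0 for v in counts.values())

    def test_sixty_percent_pair_counted_only_below_its_identity(self, rng):
        """A constructed pair at exactly 60 % identity appears at the 50 and
        30 thresholds but not at 70 or 90 (exact-alignment oracle)."""
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        base = "".join(rng.choice(aas, 100))
        mutated = list(base)
        for i in rng.choice(100, size=40, replace=False):
            choices = [a for a in aas if a != mutated[i]]
            mutated[i] = choices[int(rng.integers(len(choices)))]
        mutated = "".join(mutated)
        oracle = align_proteins(base, mutated, scoring="simple")
        assert oracle.identity_percent == pytest.approx(60.0)
        counts = gs.count_paralogs([base, mutated])
        assert counts[90] == 0 and counts[70] == 0
        assert counts[50] == 2 and counts[30] == 2

    def test_monotone_in_threshold(self, lgc_genome):
        _, table, _ = lgc_genome
        counts = gs.count_paralogs(table.proteins[:80])
        ordered = [counts[t] for t in sorted(counts, reverse=True)]
        assert ordered == sorted(ordered)  # non-decreasing as threshold drops

    def test_planted_families_recovered(self):
        genome, table, truth = gs.generate_genome(gs.LGC_PROFILE, 80, seed=55)
        planted = sum(len(f) for f in truth.genomes[genome.genome_id]["paralog_families"])
        counts = gs.count_paralogs(table.proteins)
        assert planted == 7
        assert counts[90] >= planted


class TestFeatureVector:
    def test_compute_features_end_to_end(self, lgc_genome):
        genome, table, truth = lgc_genome
        v = gs.compute_features(genome, table, include_paralogs=False)
        rec = truth.genomes[genome.genome_id]
        assert v.gc_percent == pytest.approx(100 * rec["gc_fraction"])
        assert v.spacer_mean_bp == pytest.approx(np.mean(rec["spacers"][:-1]))
        assert v.assembly_len_bp == genome.total_length
        assert abs(sum(v.aa_freq.values()) - 1) < 1e-9

    def test_c_arsc_anticorrelated_with_gc(self):
        """Across proteomes spanning GC 30-50 % the calibrated generator
        reproduces the negative C-ARSC vs GC relationship (sign check)."""
        gcs, carscs = [], []
        for i, gc in enumerate((0.30, 0.35, 0.40, 0.45, 0.50)):
            p = gs.SubcladeProfile(name=f"x{i}", gc_target=gc, spacer_mean_bp=20,
                                   spacer_sd_bp=2, genes_per_mb=1000, omega=0.1)
            genome, table, _ = gs.generate_genome(p, 120, seed=60 + i)
            gcs.append(gs.gc_content(genome))
            carscs.append(gs.arsc(table.proteins)[1])
        r2, sign = gs.linear_r2(gcs, carscs)
        assert sign < 0
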