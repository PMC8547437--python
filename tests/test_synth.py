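import numpy as np
import pytest

import genostream as gs
from genostream.synth import (
    ParameterError,
    codon_distribution,
    cds_to_codons,
)
from genostream.tables import (
    CODON_AA,
    CODON_INDEX,
    NEIGHBOR_DEST,
    NEIGHBOR_IS_SYN,
    NEIGHBOR_IS_TS,
    SENSE_CODONS,
)


def profile(**kw):
    # gene length pinned so tiny test genomes stay valid regardless of the
    # density-derived default (which assumes hundreds of genes per genome)
    base = dict(name="t", gc_target=0.40, spacer_mean_bp=20.0, spacer_sd_bp=0.0,
                genes_per_mb=1000.0, omega=0.5, gene_len_mean_nt=900.0)
    base.update(kw)
    return gs.SubcladeProfile(**base)


class TestCodonDistribution:
    def test_gc_moment_matches_target(self):
        for gc in (0.31, 0.45, 0.60):
            p = codon_distribution(gc)
            from genostream.tables import CODON_GC
            assert p @ CODON_GC / 3 == pytest.approx(gc, abs=1e-10)

    def test_joint_arsc_calibration(self):
        from genostream.tables import CODON_C, CODON_GC, CODON_N
        p = codon_distribution(0.3055, 0.331, 3.08)
        assert p @ CODON_GC / 3 == pytest.approx(0.3055, abs=1e-9)
        assert p @ CODON_N == pytest.approx(0.331, abs=1e-9)
        assert p @ CODON_C == pytest.approx(3.08, abs=1e-9)

    def test_invalid_gc_rejected(self):
        with pytest.raises(ParameterError):
            codon_distribution(1.2)


class TestGenerateGenome:
    def test_zero_sd_spacers_are_exact(self):
        _, table, truth = gs.generate_genome(profile(spacer_mean_bp=20, spacer_sd_bp=0),
                                             n_genes=3, seed=1)
        spacers, summary = gs.intergenic_spacers(table)
        assert spacers == [20, 20]

    def test_measured_gc_within_three_binomial_sd(self):
        # oracle: direct base counting of the emitted sequence vs the
        # binomial sampling variance of the generator
        gc_target = 0.3055
        genome, _, _ = gs.generate_genome(profile(gc_target=gc_target), 2000, seed=2)
        seq = genome.contigs[0][1]
        n = len(seq)
        measured = (seq.count("G") + seq.count("C")) / n
        sd = np.sqrt(gc_target * (1 - gc_target) / n)
        assert abs(measured - gc_target) < 3 * sd

    def test_same_seed_byte_identical(self, tmp_path):
        out = []
        for run in range(2):
            genome, _, _ = gs.generate_genome(profile(), 50, seed=33)
            p = tmp_path / f"r{run}.fa"
            gs.write_fasta(genome.contigs, p)
            out.append(p.read_bytes())
        assert out[0] == out[1]

    def test_rrna_operon_planted_and_recorded(self):
        genome, table, truth = gs.generate_genome(profile(), 20, seed=4)
        (cid, start, end), = genome.rrna_intervals
        assert end - start + 1 == 4500
        assert end == genome.total_length  # planted at the contig end
        assert truth.genomes[genome.genome_id]["rrna_interval"] == [cid, start, end]

    def test_truth_accounts_for_every_gene_and_spacer(self):
        genome, table, truth = gs.generate_genome(profile(), 25, seed=5)
        rec = truth.genomes[genome.genome_id]
        assert rec["gene_count"] == len(table) == 25
        assert len(rec["spacers"]) == 25
        assert len(rec["gene_lengths"]) == 25
        span = sum(rec["gene_lengths"]) + sum(rec["spacers"]) + 4500
        assert span == genome.total_length

    def test_gene_length_multiple_of_three_and_translated(self):
        _, table, _ = gs.generate_genome(profile(), 10, seed=6)
        for row in table.df.itertuples():
            assert len(row.cds) % 3 == 0
            assert len(row.protein) == len(row.cds) // 3


class TestFragmentation:
    def test_split_preserves_sequence_and_genes(self):
        genome, table, _ = gs.generate_genome(profile(), 30, seed=44)
        frag, ftable = gs.fragment_genome(genome, table, n_contigs=4, seed=45)
        assert len(frag.contigs) == 4
        assert "".join(s for _, s in frag.contigs) == genome.contigs[0][1]
        assert len(ftable) == len(table)
        # coordinates remapped: CDS extracted from the new contig matches
        row = ftable.df.iloc[10]
        assert frag.sequence(row.contig_id)[row.start - 1: row.end] == row.cds

    def test_spacer_count_drops_by_breaks(self):
        genome, table, _ = gs.generate_genome(profile(), 30, seed=46)
        full, _ = gs.intergenic_spacers(table)
        frag, ftable = gs.fragment_genome(genome, table, n_contigs=4, seed=47)
        split, summ = gs.intergenic_spacers(ftable)
        # each contig break removes exactly one between-gene spacer
        assert len(split) == len(full) - 3
        assert summ["n_overlaps"] == 0

    def test_bad_contig_count_rejected(self):
        genome, table, _ = gs.generate_genome(profile(), 5, seed=48)
        with pytest.raises(gs.synth.ParameterError):
            gs.fragment_genome(genome, table, n_contigs=1)


class TestEvolveOrthologPair:
    CDS = None

    @classmethod
    def setup_class(cls):
        _, table, _ = gs.generate_genome(profile(), 5, seed=7)
        cls.CDS = table.df.loc[0, "cds"]

    def test_omega_zero_means_no_protein_change(self):
        from genostream.tables import translate_cds
        a, b, truth = gs.evolve_ortholog_pair(self.CDS, omega=0.0, kappa=2.0,
                                              target_sub_per_codon=0.4, seed=8)
        assert truth.pairs["a|b"]["nonsyn"] == 0
        assert translate_cds(a) == translate_cds(b) == translate_cds(self.CDS)

    def test_zero_divergence_returns_input(self):
        a, b, _ = gs.evolve_ortholog_pair(self.CDS, omega=1.0, kappa=2.0,
                                          target_sub_per_codon=0.0, seed=9)
        assert a == b == self.CDS

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError):
            gs.evolve_ortholog_pair("ATGTAAATG", omega=1.0, kappa=2.0,
                                    target_sub_per_codon=0.1, seed=10)

    def test_neutral_ratio_matches_enumeration_oracle(self):
        """At omega=1 realized nonsyn/syn counts match the mutation-opportunity
        ratio computed by exhaustive enumeration of single-nt changes."""
        kappa = 2.0
        # oracle: enumerate each codon's nine neighbours with ts weight kappa,
        # excluding stop codons, and accumulate syn/nonsyn proposal mass
        rng = np.random.default_rng(11)
        codons = rng.choice(61, size=4000, p=codon_distribution(0.40))
        syn_mass = nonsyn_mass = 0.0
        for c in codons:
            for j in range(9):
                if NEIGHBOR_DEST[c, j] < 0:
                    continue
                w = kappa if NEIGHBOR_IS_TS[c, j] else 1.0
                if NEIGHBOR_IS_SYN[c, j]:
                    syn_mass += w
                else:
                    nonsyn_mass += w
        expected_ratio = nonsyn_mass / syn_mass
        cds = "".join(SENSE_CODONS[c] for c in codons)
        total_syn = total_nonsyn = 0
        for rep in range(3):
            _, _, truth = gs.evolve_ortholog_pair(cds, omega=1.0, kappa=kappa,
                                                  target_sub_per_codon=0.2, seed=100 + rep)
            total_syn += truth.pairs["a|b"]["syn"]
            total_nonsyn += truth.pairs["a|b"]["nonsyn"]
        realized = total_nonsyn / total_syn
        assert realized == pytest.approx(expected_ratio, rel=0.10)

    def test_realized_divergence_tracks_target(self):
        _, table, _ = gs.generate_genome(profile(), 1, seed=12,)
        cds = table.df.loc[0, "cds"]
        _, _, truth = gs.evolve_ortholog_pair(cds, omega=1.0, kappa=2.0,
                                              target_sub_per_codon=0.3, seed=13)
        rec = truth.pairs["a|b"]
        total = rec["syn"] + rec["nonsyn"]
        expected = 0.3 * rec["n_codons"]
        assert total == pytest.approx(expected, rel=0.5)  # Poisson draw


class TestSimulateReads:
    def test_full_identity_reads_are_substrings(self):
        genome, _, _ = gs.generate_genome(profile(), 10, seed=14)
        reads, truth = gs.simulate_reads(genome, 50, read_len=80, identity=1.0, seed=15)
        seq = genome.contigs[0][1]
        for rid, r in reads:
            assert r in seq
            assert truth.reads[rid]["identity"] == 1.0

    def test_mean_identity_matches_binomial_expectation(self):
        genome, _, _ = gs.generate_genome(profile(), 40, seed=16)
        reads, truth = gs.simulate_reads(genome, 3000, read_len=100, identity=0.95, seed=17)
        realized = np.array([truth.reads[rid]["identity"] for rid, _ in reads])
        se = np.sqrt(0.95 * 0.05 / 100 / len(reads))
        assert realized.mean() == pytest.approx(0.95, abs=4 * se)

    def test_no_reads_gives_empty_output(self):
        genome, _, _ = gs.generate_genome(profile(), 5, seed=18)
        reads, truth = gs.simulate_reads(genome, 0, seed=19)
        assert reads == [] and truth.reads == {}

    def test_identity_out_of_range_rejected(self):
        genome, _, _ = gs.generate_genome(profile(), 5, seed=20)
        with pytest.raises(ParameterError):
            gs.simulate_reads(genome, 5, identity=1.5, seed=21)


class TestBundle:
    def test_bookkeeping(self, small_bundle):
        assert len(small_bundle.genomes) == 4  # 2 profiles x 2 genomes
        assert sorted(small_bundle.groups) == ["HGC", "LGC"]
        for gid in small_bundle.genomes:
            assert gid in small_bundle.truth.genomes

    def test_duplicate_profile_names_rejected(self):
        with pytest.raises(ParameterError, match="duplicate"):
            gs.build_subclade_dataset((profile(), profile()), n_genomes=1, seed=1, n_genes=5)

    def test_zero_abundance_means_zero_reads(self):
        p = profile(abundance_matrix=((0.0, 2.0),), n_stations=2)
        bundle = gs.build_subclade_dataset((p,), n_genomes=1, seed=3, n_genes=20,
                                           reads_per_unit_abundance=50)
        gid = bundle.groups["t"][0]
        st1 = [r for r, _ in bundle.reads_per_station["station_1"]]
        st2 = [r for r, _ in bundle.reads_per_station["station_2"]]
        assert not any(gid in r for r in st1)
        assert any(gid in r for r in st2)

    def test_groups_separate_on_gc_with_no_overlap(self, small_bundle):
        gc = {name: [gs.gc_content(small_bundle.genomes[g]) for g in members]
              for name, members in small_bundle.groups.items()}
        assert max(gc["LGC"]) < min(gc["HGC"])

    def test_determinism_byte_for_byte(self):
        a = gs.build_subclade_dataset(n_genomes=1, seed=99, n_genes=15,
                                      reads_per_unit_abundance=20)
        b = gs.build_subclade_dataset(n_genomes=1, seed=99, n_genes=15,
                                      reads_per_unit_abundance=20)
        assert [c for g in a.genomes.values() for c in g.contigs] == \
               [c for g in b.genomes.values() for c in g.contigs]
        assert a.reads_per_station == b.reads_per_station

    def test_ortholog_truth_recorded_per_gene(self, small_bundle):
        # families are planted in the shared ancestor, so every gene of every
        # genome carries an ancestor-lineage substitution record
        gid = small_bundle.groups["LGC"][0]
        assert all(f"ancestor|{gid}|{i}" in small_bundle.truth.pairs for i in range(60))
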