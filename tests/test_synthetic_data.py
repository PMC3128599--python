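"""Pedigree simulator: determinism, Mendelian consistency, planted truth."""

import numpy as np
import pytest

from amap.genotype_io import NOCALL, apply_qc, read_genotypes, read_map
from amap.roh_scan import scan
from amap.synthetic_data import (
    SimConfig,
    make_concordance_table,
    make_gene_fixture,
    simulate_cohort,
    write_cohort,
)
from amap.variant_effects import concordance

from conftest import tiny_config


class TestSimulateCohort:
    def test_same_seed_identical(self):
        cfg = tiny_config(seed=7)
        m1, p1, t1 = simulate_cohort(cfg)
        m2, p2, t2 = simulate_cohort(tiny_config(seed=7))
        assert np.array_equal(m1.calls, m2.calls)
        assert m1.snp_map == m2.snp_map
        assert [i.id for i in p1.individuals] == [i.id for i in p2.individuals]
        assert t1.normal_related_causal == t2.normal_related_causal

    def test_different_seed_differs(self):
        m1, _, _ = simulate_cohort(tiny_config(seed=1))
        m2, _, _ = simulate_cohort(tiny_config(seed=2))
        assert not np.array_equal(m1.calls, m2.calls)

    def test_cohort_composition(self, tiny_cohort):
        cfg, matrix, pedigree, truth = tiny_cohort
        assert matrix.statuses.count("affected") == cfg.n_affected
        assert matrix.statuses.count("carrier") == cfg.n_carrier
        assert len(truth.normal_related_causal) == cfg.n_normal_related
        assert matrix.n_snps == cfg.n_snps

    def test_mendelian_consistency(self, tiny_cohort):
        # every transmitted haplotype is a mosaic of its parent's two
        cfg, matrix, pedigree, truth = tiny_cohort
        haps = truth.haplotypes
        for member in pedigree.individuals:
            if member.sire is None:
                continue
            child = haps[member.id]
            for hap, parent in ((child[0], member.sire), (child[1], member.dam)):
                p0, p1 = haps[parent]
                assert np.all((hap == p0) | (hap == p1))

    def test_chip_calls_match_haplotypes_up_to_nocalls(self, tiny_cohort):
        cfg, matrix, pedigree, truth = tiny_cohort
        for row, sample in enumerate(matrix.sample_ids):
            expected = truth.haplotypes[sample].sum(axis=0)
            observed = matrix.calls[row]
            called = observed != NOCALL
            assert np.array_equal(observed[called], expected[called])

    def test_affected_homozygous_carriers_het_at_causal(self, tiny_cohort):
        cfg, matrix, pedigree, truth = tiny_cohort
        ci = truth.causal_index
        for sample in truth.affected_ids:
            assert truth.haplotypes[sample][:, ci].sum() == 2
        for sample in truth.carrier_ids:
            assert truth.haplotypes[sample][:, ci].sum() == 1

    def test_affected_autozygous_across_planted_segments(self, tiny_cohort):
        cfg, matrix, pedigree, truth = tiny_cohort
        ram0 = truth.haplotypes["RAM"][0]
        for seg in truth.segments:
            sl = slice(seg.start_index, seg.end_index + 1)
            for sample in truth.affected_ids:
                assert np.array_equal(truth.haplotypes[sample][0, sl], ram0[sl])
                assert np.array_equal(truth.haplotypes[sample][1, sl], ram0[sl])

    def test_scan_recovers_planted_segments(self):
        for seed in (1, 2, 3):
            cfg = tiny_config(seed=seed)
            matrix, _, truth = simulate_cohort(cfg)
            runs = [r for r in scan(matrix) if r.carrier_pass]
            assert len(runs) == 3
            for seg in truth.segments:
                hits = [
                    r for r in runs
                    if r.chromosome == seg.chromosome
                    and abs(r.start_index - seg.start_index) <= 2
                    and abs(r.end_index - seg.end_index) <= 2
                ]
                assert hits, f"segment {seg} not recovered at seed {seed}"

    def test_zero_nocall_rate_loses_no_planted_snp(self):
        # without missingness every planted SNP stays consensus-homozygous,
        # so each planted segment is wholly contained in a recovered run
        # (boundaries may still extend where flanking genotypes coincide)
        cfg = tiny_config(seed=3, nocall_rate=0.0)
        matrix, _, truth = simulate_cohort(cfg)
        assert not (matrix.calls == NOCALL).any()
        runs = scan(matrix)
        for seg in truth.segments:
            covering = [
                r for r in runs
                if r.chromosome == seg.chromosome
                and r.start_index <= seg.start_index
                and r.end_index >= seg.end_index
            ]
            assert len(covering) == 1
            assert covering[0].n_informative >= seg.n_snps

    def test_backcross_segregation_half_carriers(self):
        draws = []
        for seed in range(1, 11):
            _, _, truth = simulate_cohort(tiny_config(seed=seed))
            draws.extend(truth.f2_causal_draws)
        draws = np.array(draws)
        assert len(draws) >= 50
        het = (draws == "CT").mean()
        assert abs(het - 0.5) <= 3 * np.sqrt(0.25 / len(draws))

    def test_qc_failures_off_segment_and_filterable(self, tiny_cohort):
        cfg, matrix, pedigree, truth = tiny_cohort
        assert matrix.qc is not None
        protected = set()
        for seg in truth.segments:
            protected.update(range(seg.start_index - 2, seg.end_index + 3))
        assert not protected.intersection(truth.qc_forced_fail.tolist())
        filtered = apply_qc(matrix)
        assert filtered.n_snps <= matrix.n_snps - len(truth.qc_forced_fail)

    def test_segment_exceeding_chromosome_raises(self):
        with pytest.raises(ValueError, match="exceeds chromosome"):
            simulate_cohort(tiny_config(planted_segments=(("15", 0, 10_000),)))

    def test_writers_round_trip(self, tmp_path, tiny_cohort):
        cfg, matrix, pedigree, truth = tiny_cohort
        write_cohort(tmp_path, matrix, pedigree, truth)
        snp_map = read_map(tmp_path / "map.tsv")
        assert snp_map == matrix.snp_map
        loaded = read_genotypes(
            tmp_path / "report.csv", snp_map, tmp_path / "samples.csv"
        )
        assert loaded.sample_ids == matrix.sample_ids
        assert np.array_equal(loaded.calls, matrix.calls)
        assert loaded.qc is not None
        assert np.allclose(
            loaded.qc["gentrain"].to_numpy(), matrix.qc["gentrain"].to_numpy()
        )


class TestConcordanceTable:
    def test_default_margins_match_study_design(self, tiny_cohort):
        cfg, matrix, pedigree, truth = tiny_cohort
        table = make_concordance_table(cfg, truth)
        by_group = {}
        for row in table.rows:
            by_group.setdefault(row.group, {})[row.genotype] = row.count
        assert by_group["affected"] == {"TT": cfg.n_affected}
        assert by_group["carrier"] == {"CT": cfg.n_carrier}
        assert sum(by_group["normal_related"].values()) == cfg.n_normal_related
        assert "TT" not in by_group["normal_related"]
        assert by_group["control"] == {"CC": cfg.n_controls}

    def test_simulated_table_is_fully_concordant(self, tiny_cohort):
        cfg, matrix, pedigree, truth = tiny_cohort
        result = concordance(make_concordance_table(cfg, truth))
        assert result.overall == 1.0


class TestGeneFixture:
    def test_deterministic(self):
        a = make_gene_fixture(SimConfig(seed=4))
        b = make_gene_fixture(SimConfig(seed=4))
        assert a.cds == b.cds and a.amplicon == b.amplicon

    def test_reference_orf_is_clean(self, gene_fixture):
        from amap.variant_effects import translate_cds

        translation = translate_cds(gene_fixture.cds)
        assert not translation.terminated_early
        assert translation.stop_codon_number == len(gene_fixture.cds) // 3
        assert gene_fixture.cds.startswith("ATG")

    def test_exon6_carries_88_percent_of_orf(self, gene_fixture):
        lengths = gene_fixture.model.exon_lengths()
        assert len(lengths) == 6
        assert lengths[5] / sum(lengths) == pytest.approx(0.88, abs=0.005)

    def test_gene_spans_over_16_kb(self, gene_fixture):
        assert len(gene_fixture.model.sequence) > 16_000

    def test_amplicon_site_engineering(self, gene_fixture):
        amplicon = gene_fixture.amplicon
        pos, ref, alt = gene_fixture.variant
        assert amplicon.count("CATG") == 1
        mutated = amplicon[: pos - 1] + alt + amplicon[pos:]
        assert mutated.count("CATG") == 2

    def test_fixture_fragment_lengths_pairwise_distinct(self, gene_fixture):
        from amap.variant_effects import band_pattern

        pattern = band_pattern(gene_fixture.amplicon, gene_fixture.variant, "CT")
        all_lengths = [l for allele in pattern.allele_fragments for l in allele]
        # the shared leading fragment co-migrates; all others are distinct
        assert len(pattern.band_lengths) == 4

    def test_written_fixture_files(self, tmp_path, gene_fixture):
        from amap.synthetic_data import write_gene_fixture
        from Bio import SeqIO

        write_gene_fixture(gene_fixture, tmp_path)
        gene = next(SeqIO.parse(tmp_path / "gene.fa", "fasta"))
        amplicon = next(SeqIO.parse(tmp_path / "amplicon.fa", "fasta"))
        assert str(gene.seq) == gene_fixture.model.sequence
        assert str(amplicon.seq) == gene_fixture.amplicon
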