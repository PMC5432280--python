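import numpy as np
import pytest

from gsc_ncrna.errors import ConfigError
from gsc_ncrna.expression import compute_fpkm
from gsc_ncrna.io_formats import write_fasta, write_gtf
from gsc_ncrna.lncrna_pipeline import coding_potential
from gsc_ncrna.networks import find_seed_sites
from gsc_ncrna.synthetic_data import (
    PlantedTruth,
    SimulationConfig,
    circ_sequences,
    simulate_all,
    simulate_backsplice_reads,
    simulate_counts,
    simulate_mirnas,
)


class TestConfigValidation:
    def test_defaults_valid(self):
        SimulationConfig().validate()

    def test_negative_count_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(n_coding_genes=-1).validate()

    def test_bad_proportion(self):
        with pytest.raises(ConfigError):
            SimulationConfig(frac_female_biased_on_X=1.5).validate()

    def test_non_positive_dispersion(self):
        with pytest.raises(ConfigError):
            SimulationConfig(nb_dispersion=0.0).validate()

    def test_read_len_floor(self):
        with pytest.raises(ConfigError, match="read_len"):
            SimulationConfig(read_len=30).validate()

    def test_chrom_too_short(self):
        cfg = SimulationConfig(chrom_length_bp=30_000)
        with pytest.raises(ConfigError, match="too short"):
            simulate_all(cfg)

    def test_too_few_genes_for_roles(self):
        with pytest.raises(ConfigError, match="n_coding_genes"):
            SimulationConfig(n_coding_genes=5).validate()


class TestDeterminism:
    def test_genome_and_annotation_bytes(self, tmp_path):
        cfg = SimulationConfig(seed=1)
        paths = []
        for run in ("a", "b"):
            res = simulate_all(cfg)
            fa = tmp_path / f"{run}.fa"
            gtf = tmp_path / f"{run}.gtf"
            write_fasta(res.genome, fa)
            write_gtf(res.assembled_transcripts, gtf)
            paths.append((fa.read_bytes(), gtf.read_bytes()))
        assert paths[0] == paths[1]

    def test_counts_identical_for_same_seed(self):
        cfg = SimulationConfig(seed=7)
        r1 = simulate_all(cfg)
        t1 = simulate_counts(r1.assembled_transcripts, r1.truth, cfg)
        r2 = simulate_all(cfg)
        t2 = simulate_counts(r2.assembled_transcripts, r2.truth, cfg)
        assert t1.counts.equals(t2.counts)
        assert r1.truth.sex_biased == r2.truth.sex_biased

    def test_different_seeds_differ(self):
        r1 = simulate_all(SimulationConfig(seed=1))
        r2 = simulate_all(SimulationConfig(seed=2))
        assert r1.genome.seqs != r2.genome.seqs

    def test_mirnas_match_builder_stream(self, sim_result, sim_config):
        standalone = simulate_mirnas(sim_config)
        assert [(m.mirna_id, m.sequence) for m in standalone] == [
            (m.mirna_id, m.sequence) for m in sim_result.mirnas
        ]


class TestGenomeStructure:
    def test_gt_ag_introns_on_template_strand(self, sim_result):
        # independent scan of every intron of the emitted models vs the FASTA
        genome = sim_result.genome
        for t in sim_result.assembled_transcripts + sim_result.known_transcripts:
            seq = genome.seqs[t.chrom]
            for is_, ie in t.introns():
                if t.strand == "+":
                    assert seq[is_ : is_ + 2] == "GT" and seq[ie - 2 : ie] == "AG"
                else:
                    assert seq[is_ : is_ + 2] == "CT" and seq[ie - 2 : ie] == "AC"

    def test_planted_truth_closure(self, sim_result):
        ids = {t.transcript_id for t in sim_result.assembled_transcripts}
        truth = sim_result.truth
        genes = {t.gene_id for t in sim_result.assembled_transcripts}
        for rec in truth.circ_junctions:
            assert rec["hosting_gene"] in genes
            assert rec["host_transcript"] in ids
        for tid in (
            list(truth.lnc_classes)
            + truth.coding_ids
            + truth.novel_lnc_ids
            + truth.known_lnc_ids
        ):
            assert tid in ids
        circ_ids = {r["circ_id"] for r in truth.circ_junctions}
        for triple in truth.cerna_triples:
            assert triple["sponge_id"] in ids | circ_ids
            assert triple["mrna_id"] in ids
            assert triple["mirna_id"] in truth.mirnas

    def test_coding_genes_have_four_plus_exons(self, sim_result):
        by_id = {t.transcript_id: t for t in sim_result.assembled_transcripts}
        for tid in sim_result.truth.coding_ids:
            assert by_id[tid].n_exons >= 4

    def test_circ_junctions_internal_exons_by_default(self, sim_result):
        by_id = {t.transcript_id: t for t in sim_result.assembled_transcripts}
        for rec in sim_result.truth.circ_junctions:
            n = by_id[rec["host_transcript"]].n_exons
            assert not rec["uses_first_exon"]
            assert all(0 < i < n - 1 for i in rec["exon_indices"])

    def test_first_exon_circles_when_requested(self):
        cfg = SimulationConfig(seed=3, n_circ_first_exon=2)
        res = simulate_all(cfg)
        first = [r for r in res.truth.circ_junctions if r["uses_first_exon"]]
        assert len(first) == 2
        for rec in first:
            assert rec["exon_indices"][0] == 0

    def test_planted_junction_motifs(self, sim_result):
        genome = sim_result.genome
        for rec in sim_result.truth.circ_junctions:
            seq = genome.seqs[rec["chrom"]]
            a, d = rec["acceptor"], rec["donor"]
            if rec["strand"] == "+":
                assert seq[d : d + 2] == "GT" and seq[a - 2 : a] == "AG"
            else:
                assert seq[d : d + 2] == "CT" and seq[a - 2 : a] == "AC"

    def test_lnc_sequences_noncoding_and_mrnas_coding(self, sim_result):
        genome = sim_result.genome
        models = {t.transcript_id: t for t in sim_result.assembled_transcripts}
        for tid in sim_result.truth.lnc_classes:
            assert not coding_potential(models[tid].sequence(genome))[2]
        for tid in sim_result.truth.coding_ids:
            assert coding_potential(models[tid].sequence(genome))[2]

    def test_truth_json_roundtrip(self, sim_result, tmp_path):
        p = tmp_path / "truth.json"
        sim_result.truth.to_json(p)
        back = PlantedTruth.from_json(p)
        assert back == sim_result.truth


class TestBackspliceReads:
    def test_each_junction_supported(self, sim_result, sim_config, sim_reads):
        support = {}
        for a in sim_reads:
            if not a.read_id.startswith("bsj"):
                continue
            key = (a.chrom1, a.seg2[0], a.seg1[1])
            support[key] = support.get(key, 0) + 1
        for rec in sim_result.truth.circ_junctions:
            key = (rec["chrom"], rec["acceptor"], rec["donor"])
            assert support.get(key, 0) >= 1

    def test_segments_reversed_for_backsplice_rows(self, sim_reads, sim_config):
        for a in sim_reads:
            if a.read_id.startswith("bsj"):
                assert a.seg2[1] <= a.seg1[0]
                assert a.seg1[1] - a.seg1[0] >= 20
                assert a.seg2[1] - a.seg2[0] >= 20
                assert (a.seg1[1] - a.seg1[0]) + (a.seg2[1] - a.seg2[0]) == sim_config.read_len

    def test_duplicates_are_byte_identical_rows(self, sim_result):
        cfg = SimulationConfig(seed=5, pcr_dup_rate=0.5)
        res = simulate_all(cfg)
        rows = simulate_backsplice_reads(res.genome, res.truth, cfg)
        seen = {}
        n_dups = 0
        for a in rows:
            key = (a.read_id, a.sample_id, a.chrom1, a.chrom2, a.strand, a.seg1, a.seg2)
            if key in seen:
                n_dups += 1
            seen[key] = a
        assert n_dups > 0  # duplicates exist and equal an original row exactly

    def test_decoy_only_truth_yields_no_candidates(self, sim_result, sim_config):
        from gsc_ncrna.circrna_caller import call_junctions

        empty_truth = PlantedTruth(mirnas=sim_result.truth.mirnas)
        rows = simulate_backsplice_reads(sim_result.genome, empty_truth, sim_config)
        assert rows  # decoys are still emitted
        assert call_junctions(rows, sim_result.genome) == []


class TestCounts:
    def test_nb_marginal_moments(self):
        # sample variance over >= 1e4 draws within 5% of mu + d*mu^2
        rng = np.random.default_rng(0)
        mu, d = 80.0, 0.2
        n = 1.0 / d
        draws = rng.negative_binomial(n, n / (n + mu), size=20_000)
        expected_var = mu + d * mu * mu
        assert draws.mean() == pytest.approx(mu, rel=0.05)
        assert draws.var() == pytest.approx(expected_var, rel=0.05)

    def test_null_configuration(self):
        cfg = SimulationConfig(
            seed=11,
            fold_change_planted=1.0,
            frac_male_biased=0.0,
            frac_female_biased=0.0,
            n_coexpressed_pairs=0,
            n_cerna_triples=0,
            n_mirnas=0,
        )
        res = simulate_all(cfg)
        table = simulate_counts(res.assembled_transcripts, res.truth, cfg)
        assert res.truth.sex_biased == {}
        assert res.truth.coexpressed_pairs == []
        # same expected mean in both conditions
        ssc = table.counts[[c for c in table.counts.columns if c.startswith("SSC")]]
        fgsc = table.counts[[c for c in table.counts.columns if c.startswith("FGSC")]]
        ratio = ssc.values.mean() / fgsc.values.mean()
        assert 0.8 < ratio < 1.2

    def test_planted_pair_pcc_near_one_at_low_noise(self):
        cfg = SimulationConfig(seed=13, coexpr_dispersion=1e-6)
        res = simulate_all(cfg)
        table = simulate_counts(res.assembled_transcripts, res.truth, cfg)
        fpkm = compute_fpkm(table)
        for pair in res.truth.coexpressed_pairs:
            x = fpkm.loc[pair["noncoding_id"]].values
            y = fpkm.loc[pair["mrna_id"]].values
            r = np.corrcoef(x, y)[0, 1]
            if pair["sign"] == "positive":
                assert r > 0.999
            else:
                assert r < -0.999

    def test_female_biased_prefer_x(self):
        cfg = SimulationConfig(
            seed=17,
            n_coding_genes=60,
            n_circ_junctions=10,
            frac_female_biased_on_X=0.9,
            frac_male_biased_on_X=0.0,
        )
        res = simulate_all(cfg)
        table = simulate_counts(res.assembled_transcripts, res.truth, cfg)
        chrom_of = {t.transcript_id: t.chrom for t in res.assembled_transcripts}
        for rec in res.truth.circ_junctions:
            chrom_of[rec["circ_id"]] = rec["chrom"]
        female = [
            i for i, d in res.truth.sex_biased.items()
            if d == "female" and i in chrom_of and i not in
            {p["mrna_id"] for p in res.truth.coexpressed_pairs}
        ]
        on_x = sum(1 for i in female if chrom_of[i] == "chrX")
        assert on_x / len(female) > 0.5

    def test_rows_cover_transcripts_and_circles(self, sim_result, sim_table):
        ids = set(sim_table.counts.index)
        assert {t.transcript_id for t in sim_result.assembled_transcripts} <= ids
        assert {r["circ_id"] for r in sim_result.truth.circ_junctions} <= ids

    def test_planted_sites_exact(self, sim_result):
        genome = sim_result.genome
        models = {t.transcript_id: t for t in sim_result.assembled_transcripts}
        mirnas = {m.mirna_id: m for m in sim_result.mirnas}
        cseqs = circ_sequences(sim_result)
        for triple in sim_result.truth.cerna_triples:
            mir = mirnas[triple["mirna_id"]]
            if triple["sponge_kind"] == "circRNA":
                sites = find_seed_sites(cseqs[triple["sponge_id"]], mir, circular=True)
            else:
                sites = find_seed_sites(models[triple["sponge_id"]].sequence(genome), mir)
            assert [s.position for s in sites] == triple["sponge_sites"]
            msites = find_seed_sites(models[triple["mrna_id"]].sequence(genome), mir)
            assert [s.position for s in msites] == triple["mrna_sites"]

    def test_background_scrubbed_for_planted_mirnas(self, sim_result):
        genome = sim_result.genome
        models = {t.transcript_id: t for t in sim_result.assembled_transcripts}
        planted_pairs = {
            (t["sponge_id"], t["mirna_id"]) for t in sim_result.truth.cerna_triples
        } | {(t["mrna_id"], t["mirna_id"]) for t in sim_result.truth.cerna_triples}
        for mir in sim_result.mirnas:
            for tid in sim_result.truth.coding_ids + list(sim_result.truth.lnc_classes):
                if (tid, mir.mirna_id) in planted_pairs:
                    continue
                assert find_seed_sites(models[tid].sequence(genome), mir) == []
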