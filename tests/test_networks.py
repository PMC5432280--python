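import numpy as np
import pandas as pd
import pytest

from _oracles import pearson_oracle, seed_sites_oracle
from gsc_ncrna.errors import ConfigError
from gsc_ncrna.expression import compute_fpkm
from gsc_ncrna.io_formats import revcomp
from gsc_ncrna.networks import (
    MiRNA,
    build_cerna_network,
    build_cnc_network,
    find_seed_sites,
    pearson_cc,
)
from gsc_ncrna.synthetic_data import circ_sequences

LIBS = [f"L{i}" for i in range(6)]


class TestPearson:
    def test_identity(self):
        x = [1.0, 2.0, 5.0, 3.0, 8.0, 4.0]
        r, p = pearson_cc(x, x)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry(self):
        x = np.array([1.0, 2.0, 5.0, 3.0, 8.0, 4.0])
        r, _ = pearson_cc(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        x = [0.5, 2.25, 5.0, 3.5, 8.125, 4.0]
        y = [1.0, 1.5, 4.75, 2.0, 9.5, 3.25]
        r, _ = pearson_cc(x, y)
        assert r == pytest.approx(pearson_oracle(x, y), abs=1e-12)

    def test_constant_vector_undefined(self):
        r, p = pearson_cc([1.0] * 6, [1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert np.isnan(r) and np.isnan(p)

    def test_too_short_rejected(self):
        with pytest.raises(ConfigError):
            pearson_cc([1.0, 2.0], [3.0, 4.0])


class TestCncNetwork:
    def _latent_matrix(self, rng, sign, n_noise=0):
        u = rng.uniform(0.5, 4.0, size=6)
        nc = pd.DataFrame([1000 * u], index=["lncA"], columns=LIBS)
        target = 500 * u if sign > 0 else 500 * (5.0 - u)
        rows = {"mA": target}
        for i in range(n_noise):
            rows[f"noise{i}"] = rng.uniform(100, 1000, size=6)
        mr = pd.DataFrame(rows, index=LIBS).T
        return nc, mr

    def test_positive_pair_recovered(self):
        rng = np.random.default_rng(0)
        nc, mr = self._latent_matrix(rng, +1)
        (edge,) = build_cnc_network(nc, mr)
        assert (edge.noncoding_id, edge.mrna_id, edge.sign) == ("lncA", "mA", "positive")
        assert edge.pcc >= 0.99 and edge.p_value < 0.01 and edge.fdr < 0.01

    def test_negative_pair_sign(self):
        rng = np.random.default_rng(1)
        nc, mr = self._latent_matrix(rng, -1)
        (edge,) = build_cnc_network(nc, mr)
        assert edge.sign == "negative" and edge.pcc <= -0.99

    def test_median_collapse_of_transcripts(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        nc = pd.DataFrame([base], index=["lncA"], columns=LIBS)
        mr = pd.DataFrame(
            [base * 2, base * 100, base * 2 + 1],
            index=["tx1", "tx2", "tx3"],
            columns=LIBS,
        )
        gene_map = {"tx1": "g", "tx2": "g", "tx3": "g"}
        (edge,) = build_cnc_network(nc, mr, gene_map=gene_map)
        assert edge.mrna_id == "g"

    def test_independent_rows_no_edges(self):
        rng = np.random.default_rng(2)
        nc = pd.DataFrame(
            rng.uniform(10, 1000, size=(100, 6)),
            index=[f"l{i}" for i in range(100)],
            columns=LIBS,
        )
        mr = pd.DataFrame(
            rng.uniform(10, 1000, size=(100, 6)),
            index=[f"m{i}" for i in range(100)],
            columns=LIBS,
        )
        assert build_cnc_network(nc, mr) == []

    def test_top_k_filter(self):
        rng = np.random.default_rng(3)
        u = rng.uniform(0.5, 4.0, size=6)
        nc = pd.DataFrame([1000 * u, 2000 * u], index=["l1", "l2"], columns=LIBS)
        mr = pd.DataFrame(
            [500 * u, 800 * u, rng.uniform(10, 100, 6)],
            index=["m1", "m2", "m3"],
            columns=LIBS,
        )
        edges_all = build_cnc_network(nc, mr)
        edges_top = build_cnc_network(nc, mr, top_k_mrnas=1)
        assert len({e.mrna_id for e in edges_all}) == 2
        assert len({e.mrna_id for e in edges_top}) == 1

    def test_needs_three_shared_libraries(self):
        nc = pd.DataFrame([[1.0, 2.0]], index=["l"], columns=["A", "B"])
        mr = pd.DataFrame([[1.0, 2.0]], index=["m"], columns=["A", "B"])
        with pytest.raises(ConfigError):
            build_cnc_network(nc, mr)

    def test_edges_revalidate_from_raw_fpkm(self, sim_result, sim_table):
        fpkm = compute_fpkm(sim_table)
        truth = sim_result.truth
        nc_ids = [p["noncoding_id"] for p in truth.coexpressed_pairs]
        m_ids = [p["mrna_id"] for p in truth.coexpressed_pairs]
        edges = build_cnc_network(fpkm.loc[nc_ids], fpkm.loc[m_ids])
        assert edges
        for e in edges:
            r, _ = pearson_cc(fpkm.loc[e.noncoding_id].values, fpkm.loc[e.mrna_id].values)
            assert abs(r) >= 0.99 and r == pytest.approx(e.pcc, abs=1e-12)

    def test_planted_pairs_recovered_with_signs(self, sim_result, sim_table):
        fpkm = compute_fpkm(sim_table)
        truth = sim_result.truth
        nc_ids = [p["noncoding_id"] for p in truth.coexpressed_pairs]
        m_ids = [p["mrna_id"] for p in truth.coexpressed_pairs]
        edges = build_cnc_network(fpkm.loc[nc_ids], fpkm.loc[m_ids])
        got = {(e.noncoding_id, e.mrna_id): e.sign for e in edges}
        for pair in truth.coexpressed_pairs:
            assert got[(pair["noncoding_id"], pair["mrna_id"])] == pair["sign"]


class TestSeedSites:
    MIR = MiRNA("mirT", "UAGCAGCACAUAAUGGUUUGUG")

    def test_planted_7mer_m8_site(self):
        rc7 = self.MIR.seed_match_dna
        target = "CCCCC" + rc7 + "CCCCC"  # next base C: no A1 anchor
        (site,) = find_seed_sites(target, self.MIR)
        assert (site.position, site.site_type) == (5, "7mer_m8")

    def test_planted_8mer_site(self):
        target = "CCCCC" + self.MIR.seed_match_dna + "A" + "CCCC"
        (site,) = find_seed_sites(target, self.MIR)
        assert (site.position, site.site_type) == (5, "8mer")

    def test_7mer_a1_site(self):
        core6 = self.MIR.seed_match_dna[1:]
        target = "CCCCC" + core6 + "A" + "CCCC"
        (site,) = find_seed_sites(target, self.MIR)
        assert (site.position, site.site_type) == (5, "7mer_A1")

    def test_bare_6mer_not_reported(self):
        core6 = self.MIR.seed_match_dna[1:]
        target = "CCCCC" + core6 + "CCCC"
        assert find_seed_sites(target, self.MIR) == []

    def test_empty_target(self):
        assert find_seed_sites("", self.MIR) == []

    def test_overlapping_sites_all_reported(self):
        # two overlapping cores for a repetitive seed
        mir = MiRNA("rep", "U" + "AC" * 4 + "A" * 13)
        core = mir.seed_match_dna[1:]
        assert core[:-2] == core[2:]  # self-overlapping core
        target = mir.seed_match_dna + core[-2:] + "A"
        sites = find_seed_sites(target, mir)
        assert len(sites) >= 2
        positions = {s.position for s in sites}
        assert len(positions) == len(sites)

    def test_identical_seed_two_mirnas_same_sites(self):
        m1 = MiRNA("m1", "UAGCAGCACAUAAUGGUUUGUG")
        m2 = MiRNA("m2", "GAGCAGCACAUCCCCCCCCCCC")  # same nt 2-8
        assert m1.seed == m2.seed
        target = "CC" + m1.seed_match_dna + "ACC"
        s1 = find_seed_sites(target, m1)
        s2 = find_seed_sites(target, m2)
        assert [(s.position, s.site_type) for s in s1] == [
            (s.position, s.site_type) for s in s2
        ]

    def test_matches_bruteforce_oracle_random(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            mir = MiRNA("m", "".join("ACGU"[i] for i in rng.integers(0, 4, 22)))
            target = "".join("ACGT"[i] for i in rng.integers(0, 2, 300))  # AC-rich
            got = [(s.position, s.site_type) for s in find_seed_sites(target, mir)]
            assert got == seed_sites_oracle(target, mir.sequence)

    def test_circular_junction_spanning_site(self):
        rc8 = self.MIR.seed_match_dna + "A"
        circ = rc8[4:] + "CCCCCCCCCCCC" + rc8[:4]  # site wraps the junction
        (site,) = find_seed_sites(circ, self.MIR, circular=True)
        assert site.site_type == "8mer"
        assert site.position == len(circ) - 4
        assert find_seed_sites(circ, self.MIR, circular=False) == []

    def test_circular_matches_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            mir = MiRNA("m", "".join("ACGU"[i] for i in rng.integers(0, 4, 22)))
            circ = "".join("ACGT"[i] for i in rng.integers(0, 2, 120))
            got = sorted(
                (s.position, s.site_type) for s in find_seed_sites(circ, mir, circular=True)
            )
            assert got == sorted(seed_sites_oracle(circ, mir.sequence, circular=True))

    def test_reverse_complement_orientation(self):
        target = "CCCCC" + self.MIR.seed_match_dna + "ACCCC"
        assert find_seed_sites(target, self.MIR)
        assert find_seed_sites(revcomp(target), self.MIR) == []


class TestCernaNetwork:
    MIR1 = MiRNA("mir1", "UAGCAGCACAUAAUGGUUUGUG")
    MIR2 = MiRNA("mir2", "ACCCGUAGAUCCGAACUUGUGA")

    def _fpkm(self, ids, rng=None, correlated=True):
        rng = rng or np.random.default_rng(0)
        u = rng.uniform(0.5, 4.0, size=6)
        rows = {}
        for k, tid in enumerate(ids):
            if correlated:
                rows[tid] = (100 + 50 * k) * u
            else:
                rows[tid] = rng.uniform(10, 1000, size=6)
        return pd.DataFrame(rows, index=LIBS).T

    def test_shared_site_link(self):
        site1 = self.MIR1.seed_match_dna + "A"
        sponges = {"lncA": "CC" + site1 + "CC" * 20}
        mrnas = {"mA": "GG" * 10 + site1 + "GG" * 10}
        fpkm = self._fpkm(["lncA", "mA"])
        (link,) = build_cerna_network(sponges, mrnas, [self.MIR1], fpkm)
        assert (link.sponge_id, link.mirna_id, link.mrna_id) == ("lncA", "mir1", "mA")
        assert link.sponge_sites and link.mrna_sites
        assert abs(link.expr_pcc) >= 0.9

    def test_scrubbed_mrna_no_link(self):
        site1 = self.MIR1.seed_match_dna + "A"
        sponges = {"lncA": "CC" + site1 + "CC" * 20}
        mrnas = {"mA": "GG" * 40}
        fpkm = self._fpkm(["lncA", "mA"])
        assert build_cerna_network(sponges, mrnas, [self.MIR1], fpkm) == []

    def test_two_sponges_two_links(self):
        site1 = self.MIR1.seed_match_dna + "A"
        sponges = {
            "lncA": "CC" + site1 + "CC" * 20,
            "lncB": "TT" * 5 + site1 + "TT" * 15,
        }
        mrnas = {"mA": "GG" * 10 + site1 + "GG" * 10}
        fpkm = self._fpkm(["lncA", "lncB", "mA"])
        links = build_cerna_network(sponges, mrnas, [self.MIR1], fpkm)
        assert [(l.sponge_id, l.mrna_id) for l in links] == [
            ("lncA", "mA"),
            ("lncB", "mA"),
        ]

    def test_correlation_gate_blocks_link(self):
        site1 = self.MIR1.seed_match_dna + "A"
        sponges = {"lncA": "CC" + site1 + "CC" * 20}
        mrnas = {"mA": "GG" * 10 + site1 + "GG" * 10}
        fpkm = self._fpkm(["lncA", "mA"], rng=np.random.default_rng(5), correlated=False)
        assert build_cerna_network(sponges, mrnas, [self.MIR1], fpkm) == []

    def test_nested_loop_oracle_small(self):
        rng = np.random.default_rng(9)
        mirnas = [self.MIR1, self.MIR2]
        sponges, mrnas = {}, {}
        for i in range(20):
            seq = "".join("ACGT"[k] for k in rng.integers(0, 4, 150))
            if i % 3 == 0:
                mir = mirnas[i % 2]
                seq = seq[:40] + mir.seed_match_dna + "A" + seq[48:]
            sponges[f"s{i:02d}"] = seq
        for i in range(20):
            seq = "".join("ACGT"[k] for k in rng.integers(0, 4, 150))
            if i % 4 == 0:
                mir = mirnas[i % 2]
                seq = seq[:80] + mir.seed_match_dna + "A" + seq[88:]
            mrnas[f"m{i:02d}"] = seq
        u = rng.uniform(0.5, 4.0, size=6)
        fpkm = pd.DataFrame(
            {tid: (100 + 3 * k) * u for k, tid in enumerate(sorted(sponges) + sorted(mrnas))},
            index=LIBS,
        ).T
        links = build_cerna_network(sponges, mrnas, mirnas, fpkm)
        got = {(l.sponge_id, l.mirna_id, l.mrna_id) for l in links}

        # oracle: explicit nested loops over the documented rule
        expected = set()
        for sid, sseq in sponges.items():
            for mir in mirnas:
                s_hits = seed_sites_oracle(sseq, mir.sequence)
                if not s_hits:
                    continue
                for mid, mseq in mrnas.items():
                    if not seed_sites_oracle(mseq, mir.sequence):
                        continue
                    if abs(pearson_oracle(fpkm.loc[sid], fpkm.loc[mid])) >= 0.9:
                        expected.add((sid, mir.mirna_id, mid))
        assert got == expected and got

    def test_simulated_truth_recovery(self, sim_result, sim_table):
        truth = sim_result.truth
        fpkm = compute_fpkm(sim_table)
        genome = sim_result.genome
        models = {t.transcript_id: t for t in sim_result.assembled_transcripts}
        cseqs = circ_sequences(sim_result)

        sponges, circular_ids = {}, set()
        for triple in truth.cerna_triples:
            sid = triple["sponge_id"]
            if triple["sponge_kind"] == "circRNA":
                sponges[sid] = cseqs[sid]
                circular_ids.add(sid)
            else:
                sponges[sid] = models[sid].sequence(genome)
        # decoy sponges and targets (scrubbed by construction)
        for tid in truth.novel_lnc_ids:
            sponges.setdefault(tid, models[tid].sequence(genome))
        mrnas = {
            tid: models[tid].sequence(genome) for tid in truth.coding_ids
        }
        mirnas = sim_result.mirnas
        links = build_cerna_network(
            sponges, mrnas, mirnas, fpkm, circular_ids=circular_ids
        )
        got = {(l.sponge_id, l.mirna_id, l.mrna_id) for l in links}
        want = {
            (t["sponge_id"], t["mirna_id"], t["mrna_id"])
            for t in truth.cerna_triples
        }
        assert got == want
        by_key = {(l.sponge_id, l.mirna_id, l.mrna_id): l for l in links}
        for t in truth.cerna_triples:
            link = by_key[(t["sponge_id"], t["mirna_id"], t["mrna_id"])]
            assert [s.position for s in link.sponge_sites] == t["sponge_sites"]
            assert [s.position for s in link.mrna_sites] == t["mrna_sites"]
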