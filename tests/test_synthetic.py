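"""Synthetic repertoire generator: construction guarantees and signal dials."""

import numpy as np
import pytest

import tcrpred as tp


class TestGeneTable:
    def test_v_genes_pass_reconstruction_search(self, gene_table):
        for chain in "AB":
            for gene in gene_table.genes(chain, "V"):
                seq = gene_table.lookup(chain, "V", gene).sequence
                assert "C" in seq[-6:]

    def test_j_genes_pass_motif_search(self, gene_table):
        for chain in "AB":
            for gene in gene_table.genes(chain, "J"):
                seq = gene_table.lookup(chain, "J", gene).sequence
                head = seq[:11]
                assert any(head[p] in "FW" and seq[p + 1] == "G"
                           for p in range(len(head) - 1))

    def test_full_chain_reconstruction_succeeds(self, gene_table, synth):
        for rec in list(synth["positives"])[:20]:
            v = gene_table.lookup("A", "V", rec.v_gene_a).sequence
            j = gene_table.lookup("A", "J", rec.j_gene_a).sequence
            full = tp.reconstruct_full_sequence(rec.cdr3a, v, j)
            assert rec.cdr3a in full

    def test_same_seed_identical_table(self):
        a = tp.generate_gene_table(5, 3, seed=2)
        b = tp.generate_gene_table(5, 3, seed=2)
        assert all(a.lookup("A", "V", g) == b.lookup("A", "V", g)
                   for g in a.genes("A", "V"))


class TestRepertoireGeneration:
    def test_per_peptide_counts(self, gene_table):
        cfg = tp.SynthConfig(seed=3, near_duplicate_rate=0.0,
                             background_size=100)
        pos, bg = tp.generate_repertoire(cfg, gene_table)
        assert len(pos) == 4 * 200 and len(bg) == 100
        for spec in cfg.peptides:
            assert sum(r.peptide == spec.peptide for r in pos) == 200

    def test_reproducible_from_seed(self, gene_table):
        cfg = tp.SynthConfig(seed=4, background_size=50)
        a, _ = tp.generate_repertoire(cfg, gene_table)
        b, _ = tp.generate_repertoire(cfg, gene_table)
        assert [r.identity_key() for r in a] == [r.identity_key() for r in b]

    def test_zero_mutation_rate_keeps_motif_verbatim(self, gene_table):
        specs = tuple(tp.PeptideSpec(s.peptide, s.motif, n_positives=50,
                                     mutation_rate=0.0)
                      for s in tp.SynthConfig().peptides[:2])
        cfg = tp.SynthConfig(peptides=specs, seed=5, background_size=400,
                             near_duplicate_rate=0.0)
        pos, bg = tp.generate_repertoire(cfg, gene_table)
        for spec in specs:
            mine = [r for r in pos if r.peptide == spec.peptide]
            assert all(spec.motif in r.cdr3b for r in mine)
            bg_rate = np.mean([spec.motif in r.cdr3b for r in bg])
            assert bg_rate <= 0.01

    def test_v_gene_bias_frequency(self, gene_table):
        spec = tp.PeptideSpec("ELAGIGILTV", "FYNE", n_positives=600,
                              v_bias_gene="TRAV3", v_bias=0.85)
        other = tp.PeptideSpec("GILGFVFTL", "WQDR", n_positives=20)
        cfg = tp.SynthConfig(peptides=(spec, other), seed=6,
                             background_size=50, near_duplicate_rate=0.0)
        pos, _ = tp.generate_repertoire(cfg, gene_table)
        mine = [r for r in pos if r.peptide == "ELAGIGILTV"]
        freq = np.mean([r.v_gene_a == "TRAV3" for r in mine])
        assert freq == pytest.approx(0.85, abs=0.04)
        biased = [r for r in mine if r.v_gene_a == "TRAV3"]
        entry = gene_table.lookup("A", "V", "TRAV3")
        assert all(r.cdr1a == entry.cdr1 and r.cdr2a == entry.cdr2
                   for r in biased)

    def test_records_satisfy_domain_invariants(self, synth):
        for rep in (synth["positives"], synth["background"]):
            for r in list(rep)[:200]:
                r.validate()
                assert 6 <= len(r.cdr3a) <= 20 and 6 <= len(r.cdr3b) <= 20
        keys = [r.identity_key() for r in synth["positives"]]
        assert len(set(keys)) == len(keys)

    def test_oversized_motif_rejected(self):
        with pytest.raises(ValueError, match="motif"):
            tp.SynthConfig(peptides=(
                tp.PeptideSpec("GILGFVFTL", "WQDRWQDRW"),),
                cdr3_len_range=(10, 12))


class TestSignalDials:
    def test_hobohm_removes_injected_near_duplicates(self, gene_table):
        cfg = tp.SynthConfig(seed=7, near_duplicate_rate=0.2,
                             background_size=10)
        pos, _ = tp.generate_repertoire(cfg, gene_table)
        n_dups = pos.metadata["n_near_duplicates"]
        assert n_dups > 50
        reduced = tp.hobohm1_reduce(pos, 0.95)
        removed = len(pos) - len(reduced)
        assert removed >= 0.9 * n_dups

    def test_baseline_auc_decreases_with_motif_mutation_rate(self, gene_table):
        def mean_auc(rate, seed=8):
            specs = tuple(tp.PeptideSpec(s.peptide, s.motif, n_positives=120,
                                         mutation_rate=rate,
                                         v_bias_gene=s.v_bias_gene,
                                         v_bias=s.v_bias)
                          for s in tp.SynthConfig().peptides)
            cfg = tp.SynthConfig(peptides=specs, seed=seed,
                                 near_duplicate_rate=0.0, background_size=600)
            pos, bg = tp.generate_repertoire(cfg, gene_table)
            aucs = []
            for spec in specs:
                mine = tp.Repertoire([r for r in pos
                                      if r.peptide == spec.peptide])
                cut = int(0.8 * len(mine))
                db = tp.PeptideDatabase(spec.peptide, mine[:cut])
                aucs.append(tp.auc(tp.predict_set(mine[cut:], db),
                                   tp.predict_set(bg[:200], db)))
            return float(np.mean(aucs))

        a0, a25, a50 = mean_auc(0.0), mean_auc(0.25), mean_auc(0.5)
        noise = 0.02
        assert a0 >= a25 - noise and a25 >= a50 - noise
        assert a0 > a50

    def test_perturbation_grades_similarity(self, synth):
        rng = np.random.default_rng(10)
        base = tp.Repertoire([r for r in synth["positives"]
                              if r.peptide == "GILGFVFTL"][:30])
        sims_prev = None
        for g in (0, 3, 6):
            moved = tp.perturb_positives(base, g, rng, protect_motif="WQDR")
            nn, _ = tp.nearest_neighbor_similarity(moved, base,
                                                   tp.CDR3_ONLY_WEIGHTS)
            mean_sim = float(nn.mean())
            if sims_prev is not None:
                assert mean_sim < sims_prev
            sims_prev = mean_sim
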