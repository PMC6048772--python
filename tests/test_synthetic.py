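import math

import numpy as np
import pytest

from ukq import synthetic
from ukq.index_builder import build_index
from ukq.model import BuildParams, ConfigError, QuantParams, QuantResult, revcomp
from ukq.quantifier import quantify

from _oracle import oracle_index


def _uniform_tpm(gene_ids):
    return {g: 1e6 / len(gene_ids) for g in gene_ids}


class TestSimulateTranscriptome:
    def test_deterministic_for_fixed_seed(self):
        cfg = synthetic.TranscriptomeSimConfig(n_genes=15, seed=42)
        t1, m1 = synthetic.simulate_transcriptome(cfg)
        t2, m2 = synthetic.simulate_transcriptome(cfg)
        assert t1 == t2 and m1.entries == m2.entries

    def test_full_paralogy_collapses_index(self):
        cfg = synthetic.TranscriptomeSimConfig(
            n_genes=6, paralog_fraction=1.0, isoforms_per_gene=(1, 2), seed=3
        )
        trs, gmap = synthetic.simulate_transcriptome(cfg)
        idx = build_index(trs, gmap, BuildParams(12))
        assert all(c == 0 for c in idx.gene_kmer_count.values())
        _, oracle_counts = oracle_index(trs, gmap, 12)
        assert idx.gene_kmer_count == oracle_counts

    def test_isoforms_share_configured_core(self):
        cfg = synthetic.TranscriptomeSimConfig(
            n_genes=5, isoforms_per_gene=(2, 3), shared_exon_fraction=0.6,
            paralog_fraction=0.0, seed=11,
        )
        trs, gmap = synthetic.simulate_transcriptome(cfg)
        by_gene = {}
        for tr in trs:
            by_gene.setdefault(tr.gene_id, []).append(tr.sequence)
        for seqs in by_gene.values():
            if len(seqs) < 2:
                continue
            # all isoforms contain the same central core
            core_len = int(round(0.6 * len(seqs[0])))
            start = (len(seqs[0]) - core_len) // 2
            core = seqs[0][start : start + core_len]
            assert all(core in s for s in seqs)

    def test_near_full_gene_coverage_without_sharing(self):
        # random 16-mer collisions across a few dozen kb are vanishingly rare
        for seed in range(5):
            cfg = synthetic.TranscriptomeSimConfig(
                n_genes=30, isoforms_per_gene=(1, 1), paralog_fraction=0.0,
                shared_exon_fraction=0.0, transcript_length=(500, 2000), seed=seed,
            )
            trs, gmap = synthetic.simulate_transcriptome(cfg)
            idx = build_index(trs, gmap, BuildParams(16))
            covered = sum(1 for c in idx.gene_kmer_count.values() if c > 0)
            assert covered == len(gmap.gene_ids)

    def test_infeasible_shared_core_rejected(self):
        with pytest.raises(ConfigError):
            synthetic.TranscriptomeSimConfig(
                transcript_length=(2, 5), shared_exon_fraction=0.05
            )


class TestSimulateReads:
    def _toy(self, seed=7):
        cfg = synthetic.TranscriptomeSimConfig(
            n_genes=10, isoforms_per_gene=(1, 2), paralog_fraction=0.0, seed=seed
        )
        return synthetic.simulate_transcriptome(cfg)

    def test_error_free_reads_are_exact_substrings(self):
        trs, gmap = self._toy()
        cfg = synthetic.ReadSimConfig(
            true_tpm=_uniform_tpm(gmap.gene_ids), n_reads=300, error_rate=0.0, seed=5
        )
        reads, _ = synthetic.simulate_reads(trs, gmap, cfg)
        haystack = {tr.sequence for tr in trs}
        for read in reads:
            assert any(
                read.sequence in s or revcomp(read.sequence) in s for s in haystack
            )

    def test_reproducible_and_exact_count(self):
        trs, gmap = self._toy()
        cfg = synthetic.ReadSimConfig(
            true_tpm=_uniform_tpm(gmap.gene_ids), n_reads=1000, seed=9
        )
        r1, t1 = synthetic.simulate_reads(trs, gmap, cfg)
        r2, t2 = synthetic.simulate_reads(trs, gmap, cfg)
        assert len(r1) == 1000
        assert r1 == r2
        assert t1.equals(t2)
        assert t1["n_reads_drawn"].sum() == 1000

    def test_draw_ratio_matches_binomial_oracle(self):
        trs, gmap = self._toy()
        genes = gmap.gene_ids
        tpm = {g: 0.0 for g in genes}
        tpm[genes[0]], tpm[genes[1]] = 250_000.0, 750_000.0
        n = 10_000
        cfg = synthetic.ReadSimConfig(true_tpm=tpm, n_reads=n, error_rate=0.0, seed=13)
        _, truth = synthetic.simulate_reads(trs, gmap, cfg)
        drawn = truth.set_index("gene_id")["n_reads_drawn"]
        p = 0.25
        se = math.sqrt(n * p * (1 - p))
        assert abs(drawn[genes[0]] - n * p) <= 3 * se
        assert drawn[genes[0]] + drawn[genes[1]] == n

    def test_paired_mode_yields_mate_pairs(self):
        trs, gmap = self._toy()
        cfg = synthetic.ReadSimConfig(
            true_tpm=_uniform_tpm(gmap.gene_ids), n_reads=200, paired=True, seed=21
        )
        reads, _ = synthetic.simulate_reads(trs, gmap, cfg)
        assert len(reads) == 200
        mates = [r.mate.value for r in reads]
        assert mates[0::2] == ["mate1"] * 100 and mates[1::2] == ["mate2"] * 100

    def test_read_longer_than_all_transcripts_rejected(self):
        trs, gmap = self._toy()
        cfg = synthetic.ReadSimConfig(
            true_tpm=_uniform_tpm(gmap.gene_ids), n_reads=10, read_length=50_000
        )
        with pytest.raises(ConfigError):
            synthetic.simulate_reads(trs, gmap, cfg)

    def test_error_rate_lowers_mapping_rate_at_k32(self):
        # a substitution corrupts up to 2k-1 consecutive windows, so noisy
        # reads must map less often; check the direction over 5 seeds
        trs, gmap = self._toy()
        tpm = _uniform_tpm(gmap.gene_ids)
        idx = build_index(trs, gmap, BuildParams(32))
        params = QuantParams(step_size=12, accept_count=2)
        for seed in range(5):
            rates = []
            for err in (0.0, 0.02):
                cfg = synthetic.ReadSimConfig(
                    true_tpm=tpm, n_reads=2000, error_rate=err, seed=seed
                )
                reads, _ = synthetic.simulate_reads(trs, gmap, cfg)
                rates.append(quantify(reads, idx, params).mapping_rate)
            assert rates[1] < rates[0]


class TestEvaluateEstimates:
    def _result(self, gene_ids, tpm):
        return QuantResult(
            gene_ids=list(gene_ids),
            counts={g: 1 for g in gene_ids},
            kmer_counts={g: 10 for g in gene_ids},
            fpkm={g: 0.0 for g in gene_ids},
            tpm=dict(tpm),
        )

    def _truth(self, gene_ids, values):
        import pandas as pd

        return pd.DataFrame({"gene_id": list(gene_ids), "true_tpm": list(values)})

    def test_perfect_estimates(self):
        genes = [f"g{i}" for i in range(10)]
        vals = np.linspace(1, 10, 10) * 1e4
        truth = self._truth(genes, vals)
        res = self._result(genes, dict(zip(genes, vals)))
        scc, mad = synthetic.evaluate_estimates(truth, res)
        assert scc == pytest.approx(1.0) and mad == 0.0

    def test_reversed_ranking(self):
        genes = [f"g{i}" for i in range(10)]
        vals = np.linspace(1, 10, 10) * 1e4
        truth = self._truth(genes, vals)
        res = self._result(genes, dict(zip(genes, vals[::-1])))
        scc, _ = synthetic.evaluate_estimates(truth, res)
        assert scc == pytest.approx(-1.0)

    def test_permutation_null_near_zero(self):
        rng = np.random.default_rng(77)
        genes = [f"g{i:03d}" for i in range(200)]
        vals = rng.lognormal(size=200)
        vals = vals / vals.sum() * 1e6
        truth = self._truth(genes, vals)
        sccs = []
        for _ in range(20):
            perm = rng.permutation(vals)
            res = self._result(genes, dict(zip(genes, perm)))
            scc, _ = synthetic.evaluate_estimates(truth, res)
            sccs.append(abs(scc))
        assert np.mean(sccs) < 0.1

    def test_too_few_genes_errors(self):
        genes = ["g1", "g2"]
        truth = self._truth(genes, [5e5, 5e5])
        with pytest.raises(ValueError):
            synthetic.evaluate_estimates(truth, self._result(genes, {g: 0.0 for g in genes}))

    def test_exclude_uncovered_drops_na_genes(self):
        genes = [f"g{i}" for i in range(6)]
        vals = [1e5, 2e5, 3e5, 1.5e5, 2.5e5, 5e4]
        truth = self._truth(genes, vals)
        res = self._result(genes, dict(zip(genes, vals)))
        res.kmer_counts["g5"] = 0
        res.tpm["g5"] = float("nan")
        scc_incl, mad_incl = synthetic.evaluate_estimates(truth, res)
        scc_excl, mad_excl = synthetic.evaluate_estimates(truth, res, exclude_uncovered=True)
        assert mad_excl == 0.0
        assert mad_incl > 0.0  # NA scored as zero estimate
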