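"""Synthetic-data generator: determinism, self-consistency, planted effects."""

import filecmp

import numpy as np
import pytest

from clipcircuit.readsets import ReadIndex
from clipcircuit.seeds import families_from_table, scan_sites
from clipcircuit.simulate import (SimulationConfig, simulate_clip_reads,
                                  simulate_contrasts, simulate_transcriptome,
                                  write_dataset)


class TestConfig:
    def test_rejects_invalid_probabilities(self):
        with pytest.raises(ValueError):
            SimulationConfig(site_concentration=1.5)

    def test_rejects_nonpositive_depth(self):
        with pytest.raises(ValueError):
            SimulationConfig(depth_per_library=0)


class TestDeterminism:
    def test_outputs_are_byte_identical_across_runs(self, tmp_path, small_config):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_dataset(small_config, d1)
        write_dataset(small_config, d2)
        files = [p.name for p in d1.iterdir()]
        match, mismatch, errors = filecmp.cmpfiles(d1, d2, files, shallow=False)
        assert sorted(match) == sorted(files)
        assert not mismatch and not errors

    def test_different_seeds_differ(self, small_config):
        import dataclasses
        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        t1 = simulate_transcriptome(small_config)
        t2 = simulate_transcriptome(other)
        assert t1.seqs != t2.seqs


class TestTranscriptome:
    def test_scan_recovers_every_implanted_site(self, small_transcriptome):
        tr = small_transcriptome
        fams = {f.family_id: f for f in families_from_table(tr.mirnas)}
        for s in tr.truth.sites:
            seq = tr.seqs[s.transcript_id]
            found = scan_sites(seq, fams[s.family_id], s.transcript_id)
            assert any(
                f.tx_start == s.tx_start and f.site_type == "8mer" for f in found
            ), f"implanted site {s} not recovered"

    def test_zero_site_probability_leaves_only_sponge_site(self):
        cfg = SimulationConfig(seed=3, n_mrna=50, n_lncrna=10,
                               site_prob_per_utr=0.0, depth_per_library=1000)
        tr = simulate_transcriptome(cfg)
        assert len(tr.truth.sites) == 1
        assert tr.truth.sites[0].is_sponge_site
        assert tr.truth.target_genes == []

    def test_sponge_is_designated_lncrna(self, small_transcriptome):
        truth = small_transcriptome.truth
        sponge_sites = [s for s in truth.sites if s.is_sponge_site]
        assert len(sponge_sites) == 1
        assert sponge_sites[0].transcript_id == truth.sponge_feature_id


class TestClipReads:
    def test_knockout_ablates_family_sites_but_preserves_background(
        self, small_config, small_transcriptome
    ):
        truth = small_transcriptome.truth
        rng = np.random.default_rng(4)
        wt = simulate_clip_reads(small_config, truth, "WT", rng)
        ko = simulate_clip_reads(small_config, truth, "mirna_ko",
                                 np.random.default_rng(5))
        iw, ik = ReadIndex(wt), ReadIndex(ko)
        fam0 = [s for s in truth.sites if s.family_index == 0]
        wt_site = sum(iw.count_overlapping(s.chrom, s.g_start, s.g_end, s.strand)
                      for s in fam0)
        ko_site = sum(ik.count_overlapping(s.chrom, s.g_start, s.g_end, s.strand)
                      for s in fam0)
        assert ko_site < 0.15 * wt_site
        # transcripts without family-0 sites keep their totals within noise
        fam0_tx = {s.transcript_id for s in fam0}
        untouched = [t for t in truth.tx_length if t not in fam0_tx][:50]
        wt_tot = sum(iw.count_overlapping(f"chr_{t}", 0, truth.tx_length[t],
                                          truth.strand[t]) for t in untouched)
        ko_tot = sum(ik.count_overlapping(f"chr_{t}", 0, truth.tx_length[t],
                                          truth.strand[t]) for t in untouched)
        assert ko_tot == pytest.approx(wt_tot, rel=0.2)

    def test_read_lengths_and_strands_match_annotations(
        self, small_config, small_transcriptome
    ):
        truth = small_transcriptome.truth
        reads = simulate_clip_reads(small_config, truth, "WT",
                                    np.random.default_rng(6))
        assert np.all(reads.ends - reads.starts == small_config.read_length)
        # all reads lie within their transcript's chromosome bounds
        for chrom in np.unique(reads.chroms)[:20]:
            tx = str(chrom)[4:]
            sel = reads.chroms == chrom
            assert reads.starts[sel].min() >= 0
            assert reads.ends[sel].max() <= truth.tx_length[tx]
            assert set(reads.strands[sel]) == {truth.strand[tx]}

    def test_unknown_genotype_errors(self, small_config, small_transcriptome):
        with pytest.raises(ValueError):
            simulate_clip_reads(small_config, small_transcriptome.truth, "het")

    def test_doubling_depth_tightens_relative_totals(self, small_transcriptome):
        """NB scaling: higher depth lowers the CV of per-transcript totals."""
        import dataclasses
        truth = small_transcriptome.truth
        base = SimulationConfig(seed=11, n_mrna=300, n_lncrna=30,
                                depth_per_library=60_000, nb_dispersion=0.0)
        cvs = []
        for depth in (20_000, 160_000):
            cfg = dataclasses.replace(base, depth_per_library=depth)
            reads = simulate_clip_reads(cfg, truth, "WT", np.random.default_rng(8))
            idx = ReadIndex(reads)
            rel_err = []
            expr_sum = sum(truth.expression.values())
            for t in sorted(truth.tx_length)[:150]:
                mean = depth * truth.expression[t] / expr_sum
                if mean < 5:
                    continue
                obs = idx.count_five_prime_in(f"chr_{t}", 0, truth.tx_length[t],
                                              truth.strand[t])
                rel_err.append((obs - mean) / mean)
            cvs.append(np.std(rel_err))
        assert cvs[1] < cvs[0]


class TestContrasts:
    def test_planted_directions_and_padj_monotonicity(self, small_config,
                                                      small_transcriptome):
        truth = small_transcriptome.truth
        mut, ko = simulate_contrasts(small_config, truth,
                                     np.random.default_rng(9))
        targets = set(truth.target_genes)
        mut_t = mut[mut.gene_id.isin(targets)]["log2fc"].mean()
        mut_b = mut[~mut.gene_id.isin(targets)]["log2fc"].mean()
        ko_t = ko[ko.gene_id.isin(targets)]["log2fc"].mean()
        assert mut_t > mut_b + 0.1
        assert ko_t < -0.1
        # padj decreases with |log2fc|
        srt = mut.sort_values("log2fc", key=abs)
        assert srt["padj"].is_monotonic_decreasing

    def test_zero_beta_gives_null_tables(self, small_transcriptome):
        import dataclasses
        cfg = SimulationConfig(seed=11, n_mrna=300, n_lncrna=30,
                               depth_per_library=60_000, repression_beta=0.0)
        mut, _ = simulate_contrasts(cfg, small_transcriptome.truth,
                                    np.random.default_rng(10))
        targets = set(small_transcriptome.truth.target_genes)
        t_mean = mut[mut.gene_id.isin(targets)]["log2fc"].mean()
        se = cfg.noise_sigma / np.sqrt(len(targets))
        assert abs(t_mean) < 4 * se
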