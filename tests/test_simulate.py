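"""Generator determinism, planted structure and emitted artifacts."""

import numpy as np
import pytest

from modcall import io as mio
from modcall.consensus import call_sites
from modcall.models import PipelineConfig, Region
from modcall.motif import DRACH, match_motif
from modcall.simulate import (
    SimParams,
    emit_tool_tables,
    plant_truth_sites,
    simulate_study,
    simulate_transcriptome,
    write_study,
)

N_DRACH_OF_1024 = 18 / 1024  # DRACH k-mers among all uniform 5-mers


def test_same_seed_gives_byte_identical_outputs(tmp_path):
    p = SimParams(n_transcripts=50, n_truth_sites=60, seed=1)
    a = write_study(simulate_study(p), tmp_path / "a")
    b = write_study(simulate_study(p), tmp_path / "b")
    for key in a:
        assert a[key].read_bytes() == b[key].read_bytes(), key


def test_zero_transcripts_give_empty_outputs(tmp_path):
    study = simulate_study(SimParams(n_transcripts=0))
    paths = write_study(study, tmp_path)
    assert paths["fasta"].read_text() == ""
    assert len(mio.read_region_table(paths["regions"])) == 0
    assert len(mio.read_counts(paths["counts"])) == 0


def test_zero_length_cds_rejected():
    with pytest.raises(ValueError, match="CDS"):
        SimParams(len_cds_range=(0, 10))


def test_region_lengths_recompute_from_emitted_files(tmp_path):
    paths = write_study(simulate_study(SimParams(seed=3, n_transcripts=20,
                                                 n_truth_sites=40)), tmp_path)
    seqs = mio.read_fasta(paths["fasta"])
    regions = mio.read_region_table(paths["regions"])
    assert len(seqs) == len(regions) == 20
    for row in regions.itertuples(index=False):
        total = row.len_5utr + row.len_cds + row.len_3utr
        assert total == row.total_len == len(seqs[row.transcript_id])


class TestPlanting:
    def test_forced_drach_fraction_one(self):
        p = SimParams(n_transcripts=20, n_truth_sites=100,
                      frac_drach_at_truth=1.0, seed=2)
        txs, truth = plant_truth_sites(simulate_transcriptome(p), p, p.rng())
        assert len(truth) == 100
        assert all(match_motif(s.kmer, DRACH) for s in truth)

    def test_kmer_matches_edited_sequence_and_spacing_held(self):
        p = SimParams(n_transcripts=20, n_truth_sites=150, seed=4)
        txs, truth = plant_truth_sites(simulate_transcriptome(p), p, p.rng())
        by_id = {t.transcript_id: t for t in txs}
        per_tx = {}
        for s in truth:
            assert s.kmer == by_id[s.transcript_id].kmer_at(s.position)
            assert s.rate_stress > s.rate_control
            per_tx.setdefault(s.transcript_id, []).append(s.position)
        for positions in per_tx.values():
            positions.sort()
            gaps = np.diff(positions)
            assert (gaps >= p.min_spacing).all()

    def test_unforced_kmers_match_drach_at_background_rate(self):
        # with no planting the DRACH fraction is the uniform 5-mer
        # expectation 18/1024, up to binomial noise (4 SE)
        p = SimParams(n_transcripts=200, n_truth_sites=1000,
                      frac_drach_at_truth=0.0, seed=5)
        _, truth = plant_truth_sites(simulate_transcriptome(p), p, p.rng())
        assert len(truth) == 1000
        frac = np.mean([match_motif(s.kmer, DRACH) for s in truth])
        se = np.sqrt(N_DRACH_OF_1024 * (1 - N_DRACH_OF_1024) / len(truth))
        assert abs(frac - N_DRACH_OF_1024) <= 4 * se

    def test_planted_rate_means_recovered(self):
        p = SimParams(n_transcripts=100, n_truth_sites=500, seed=6)
        _, truth = plant_truth_sites(simulate_transcriptome(p), p, p.rng())
        assert abs(np.mean([s.rate_stress for s in truth]) - 0.48) <= 0.03
        assert abs(np.mean([s.rate_control for s in truth]) - 0.27) <= 0.03

    def test_pure_3utr_weights_place_all_sites_in_3utr(self):
        p = SimParams(n_transcripts=20, n_truth_sites=80,
                      region_weights_truth=(0, 0, 1), seed=7)
        txs, truth = plant_truth_sites(simulate_transcriptome(p), p, p.rng())
        by_id = {t.transcript_id: t for t in txs}
        assert all(
            by_id[s.transcript_id].region_of(s.position) is Region.THREE_UTR
            for s in truth
        )


class TestToolTables:
    def test_no_false_positives_means_candidates_near_truth(self):
        p = SimParams(n_transcripts=20, n_truth_sites=60,
                      fp_rate_per_tool=0.0, seed=8)
        rng = p.rng()
        txs, truth = plant_truth_sites(simulate_transcriptome(p, rng), p, rng)
        xp, nc = emit_tool_tables(txs, truth, p, rng)
        truth_pos = {(s.transcript_id, s.position) for s in truth}
        assert {(r.transcript_id, r.position) for r in xp.itertuples()} == truth_pos
        allowed = {
            (tid, pos + d) for tid, pos in truth_pos for d in range(-2, 3)
        }
        assert {(r.transcript_id, r.position) for r in nc.itertuples()} <= allowed

    def test_truth_rows_pass_detector_filters(self):
        p = SimParams(n_transcripts=20, n_truth_sites=60,
                      fp_rate_per_tool=0.0, seed=9)
        rng = p.rng()
        txs, truth = plant_truth_sites(simulate_transcriptome(p, rng), p, rng)
        xp, nc = emit_tool_tables(txs, truth, p, rng)
        assert (xp["pvalue"] < 0.01).all()
        assert (xp["rate_stress"] > xp["rate_control"]).all()
        assert (
            nc[["p_gmm_logit", "p_ks_intensity", "p_ks_dwell"]].max(axis=1)
            < 0.01
        ).all()


class TestAncillary:
    def test_known_fraction_one_covers_every_truth_matching_call(self, cfg):
        from modcall.known import intersect_known

        p = SimParams(n_transcripts=25, n_truth_sites=80, known_frac=1.0,
                      known_drach_only=False, known_decoy_factor=0.0,
                      frac_low_count=0.0, seed=10)
        study = simulate_study(p)
        sites, _ = call_sites(
            study.xpore["male"], study.nanocompore["male"], study.counts, cfg
        )
        report = intersect_known(sites, study.known)
        truth_iv = {
            s.transcript_id: [] for s in study.truth["male"]
        }
        for s in study.truth["male"]:
            truth_iv[s.transcript_id].append((s.position, s.position + 5))
        for site, row in zip(sites, report.per_site.itertuples()):
            overlaps_truth = any(
                site.start < e and t_start < site.end
                for t_start, e in truth_iv.get(site.transcript_id, [])
            )
            if overlaps_truth:
                assert row.overlaps

    def test_zero_de_fraction_gives_zero_overlap(self, cfg):
        from modcall.report import de_overlap

        p = SimParams(n_transcripts=25, n_truth_sites=60,
                      frac_modified_genes_de=0.0, frac_other_genes_de=0.0,
                      seed=11)
        study = simulate_study(p)
        sites, _ = call_sites(
            study.xpore["male"], study.nanocompore["male"], study.counts, cfg
        )
        gene_map = {t: tx.gene_id for t, tx in study.transcripts.items()}
        ov = de_overlap(sites, study.de, gene_map, cfg)
        assert ov.percent == 0.0

    def test_all_low_counts_empty_the_funnel(self, cfg):
        p = SimParams(n_transcripts=15, n_truth_sites=40, frac_low_count=1.0,
                      low_count_range=(3.0, 3.0), seed=12)
        study = simulate_study(p)
        assert (study.counts == 3.0).all()
        sites, funnel = call_sites(
            study.xpore["male"], study.nanocompore["male"], study.counts, cfg
        )
        assert sites == []
        assert funnel["collapsed_sites"] == 0
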