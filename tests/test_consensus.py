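"""Per-tool filters, cross-tool matching and single-linkage collapsing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modcall.consensus import (
    call_sites,
    collapse_sites,
    cross_tool_match,
    filter_eligible_transcripts,
    filter_nanocompore,
    filter_xpore,
)
from modcall.models import PipelineConfig

from conftest import nano_frame, xpore_frame


CFG = PipelineConfig()


def bruteforce_clusters(positions, window):
    """Transitive closure of the 'within window' relation, O(n^2)."""
    positions = sorted(positions)
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) <= window:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(positions[i])
    return sorted(tuple(sorted(g)) for g in groups.values())


def paired_candidates(positions, transcript="tx1"):
    """One xpore + one nanocompore candidate at each position."""
    xp = xpore_frame(
        [{"transcript_id": transcript, "position": p} for p in positions]
    )
    nc = nano_frame(
        [{"transcript_id": transcript, "position": p} for p in positions]
    )
    return xp, nc


class TestXporeFilter:
    @pytest.mark.parametrize(
        "pvalue,rs,rc,kept",
        [
            (0.005, 0.48, 0.27, True),  # significant, stress-ward
            (0.005, 0.20, 0.40, False),  # wrong direction
            (0.01, 0.5, 0.2, False),  # boundary p is strict
        ],
    )
    def test_significance_and_direction(self, pvalue, rs, rc, kept):
        df = xpore_frame(
            [{"pvalue": pvalue, "rate_stress": rs, "rate_control": rc}]
        )
        out = filter_xpore(df, CFG)
        assert (len(out) == 1) is kept

    def test_missing_rate_column_is_reported(self):
        df = xpore_frame([{}]).drop(columns=["rate_control"])
        with pytest.raises(ValueError, match="rate_control"):
            filter_xpore(df, CFG)

    def test_order_preserved(self):
        df = xpore_frame(
            [{"position": p, "pvalue": 0.001} for p in (30, 10, 20)]
        )
        out = filter_xpore(df, CFG)
        assert list(out["position"]) == [30, 10, 20]


class TestNanocomporeFilter:
    @pytest.mark.parametrize(
        "ps,kept",
        [
            ((0.001, 0.003, 0.009), True),
            ((0.001, 0.003, 0.02), False),  # one test fails
        ],
    )
    def test_all_three_tests_required(self, ps, kept):
        df = nano_frame(
            [
                {
                    "p_gmm_logit": ps[0],
                    "p_ks_intensity": ps[1],
                    "p_ks_dwell": ps[2],
                }
            ]
        )
        assert (len(filter_nanocompore(df, CFG)) == 1) is kept

    def test_empty_input_gives_empty_output(self):
        out = filter_nanocompore(nano_frame([]).reindex(
            columns=nano_frame([{}]).columns), CFG)
        assert out.empty

    def test_invalid_pvalue_rows_dropped_with_warning(self, caplog):
        df = nano_frame(
            [{"p_gmm_logit": 0.0}, {"p_gmm_logit": 0.001}]
        )
        with caplog.at_level("WARNING"):
            out = filter_nanocompore(df, CFG)
        assert len(out) == 1
        assert "outside (0, 1]" in caplog.text


class TestEligibility:
    @pytest.mark.parametrize("count,kept", [(16, True), (15, False)])
    def test_strict_threshold(self, count, kept):
        df = xpore_frame([{}])
        counts = pd.Series({"tx1": float(count)})
        out = filter_eligible_transcripts(df, counts, CFG)
        assert (len(out) == 1) is kept

    def test_missing_transcript_treated_as_zero(self, caplog):
        df = xpore_frame([{}])
        with caplog.at_level("WARNING"):
            out = filter_eligible_transcripts(df, pd.Series(dtype=float), CFG)
        assert out.empty
        assert "absent from the read-count table" in caplog.text


class TestCrossToolMatch:
    @pytest.mark.parametrize(
        "xp_pos,nc_pos,tx_nc,survive",
        [
            (100, 108, "tx1", True),  # |d| = 8 <= 10
            (100, 111, "tx1", False),  # |d| = 11 > 10
            (100, 100, "tx2", False),  # transcript mismatch
        ],
    )
    def test_partner_within_window(self, xp_pos, nc_pos, tx_nc, survive):
        xp = xpore_frame([{"position": xp_pos}])
        nc = nano_frame([{"transcript_id": tx_nc, "position": nc_pos}])
        xs, ns = cross_tool_match(xp, nc, CFG)
        assert (len(xs) == 1) is survive
        assert (len(ns) == 1) is survive


class TestCollapse:
    def test_window_gap_splits_clusters(self):
        xp, nc = paired_candidates([100, 105, 118])
        sites = collapse_sites(xp, nc, CFG)
        assert [(s.start, s.end) for s in sites] == [(100, 110), (118, 123)]

    def test_single_position_pair_gives_width_five(self):
        xp, nc = paired_candidates([42])
        (site,) = collapse_sites(xp, nc, CFG)
        assert (site.start, site.end) == (42, 47)
        assert site.n_xpore == site.n_nanocompore == 1

    def test_chain_merges_past_window_span(self):
        # single linkage: consecutive gaps of 8 chain into one site even
        # though the total span exceeds the 10 nt window
        xp, nc = paired_candidates([0, 8, 16, 24])
        sites = collapse_sites(xp, nc, CFG)
        assert [(s.start, s.end) for s in sites] == [(0, 29)]

    def test_representative_stats_from_max_differential_supporter(self):
        xp = xpore_frame(
            [
                {"position": 100, "rate_stress": 0.4, "rate_control": 0.3,
                 "pvalue": 1e-5, "kmer": "AAAAA"},
                {"position": 104, "rate_stress": 0.6, "rate_control": 0.2,
                 "pvalue": 1e-3, "kmer": "GGACU"},
            ]
        )
        nc = nano_frame([{"position": 102, "p_ks_dwell": 0.004}])
        (site,) = collapse_sites(xp, nc, CFG)
        assert site.kmer == "GGACU"
        assert site.rate_stress == 0.6
        assert site.best_p_xpore == 1e-5
        assert site.best_p_nanocompore == 0.004

    @settings(max_examples=200, derandomize=True)
    @given(
        positions=st.lists(
            st.integers(min_value=0, max_value=400), min_size=1, max_size=50
        ),
        window=st.integers(min_value=0, max_value=25),
    )
    def test_scan_equals_transitive_closure(self, positions, window):
        cfg = PipelineConfig(collapse_window=window)
        xp, nc = paired_candidates(sorted(set(positions)))
        sites = collapse_sites(xp, nc, cfg)
        expected = bruteforce_clusters(set(positions), window)
        got = [(s.start, s.end) for s in sites]
        assert got == [(g[0], g[-1] + 5) for g in expected]

    @settings(max_examples=100, derandomize=True)
    @given(
        positions=st.lists(
            st.integers(min_value=0, max_value=300), min_size=1, max_size=30
        ),
        window=st.integers(min_value=0, max_value=15),
    )
    def test_wider_window_never_increases_site_count(self, positions, window):
        xp, nc = paired_candidates(sorted(set(positions)))
        n_narrow = len(collapse_sites(xp, nc, PipelineConfig(collapse_window=window)))
        n_wide = len(
            collapse_sites(xp, nc, PipelineConfig(collapse_window=window + 5))
        )
        assert n_wide <= n_narrow

    def test_collapsing_collapsed_midpoints_is_idempotent(self):
        xp, nc = paired_candidates([0, 8, 40, 45, 90])
        sites = collapse_sites(xp, nc, CFG)
        mids = [s.midpoint for s in sites]
        xp2, nc2 = paired_candidates(mids)
        again = collapse_sites(xp2, nc2, CFG)
        assert len(again) == len(sites)

    def test_every_site_supported_by_both_tools(self, study, cfg):
        sites, _ = call_sites(
            study.xpore["male"],
            study.nanocompore["male"],
            study.counts,
            cfg,
        )
        assert sites, "expected calls from the simulated study"
        assert all(s.n_xpore >= 1 and s.n_nanocompore >= 1 for s in sites)
        assert all(s.rate_stress > s.rate_control for s in sites)
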