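"""Dual-detector consensus calling of differential modification sites.

Signal-level detectors for nanopore direct RNA-seq disagree often; the
workflow implemented here trades sensitivity for stringency by keeping
only candidates that (i) pass each detector's own significance filter,
(ii) lie on transcripts with enough read coverage for detection, and
(iii) are corroborated by the other detector within a small window,
then collapsing nearby survivors into unique modification sites.

Filters use strict inequalities at the thresholds (p < 0.01, average
read count > 15).  Cross-tool matching precedes collapsing; collapsing
is single-linkage, so a chain of candidates each within the window of
the next merges into one site even if the total span exceeds the
window.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .models import ModSite, PipelineConfig

logger = logging.getLogger(__name__)

XPORE_COLUMNS = [
    "transcript_id",
    "position",
    "kmer",
    "rate_stress",
    "rate_control",
    "pvalue",
]
NANOCOMPORE_COLUMNS = [
    "transcript_id",
    "position",
    "kmer",
    "p_gmm_logit",
    "p_ks_intensity",
    "p_ks_dwell",
]
NANO_P_COLUMNS = ["p_gmm_logit", "p_ks_intensity", "p_ks_dwell"]


def filter_xpore(
    candidates: pd.DataFrame, cfg: PipelineConfig
) -> pd.DataFrame:
    """Keep candidates with p < threshold and a stress-ward rate shift.

    Row order is preserved.
    """
    for col in ("rate_stress", "rate_control", "pvalue"):
        if col not in candidates.columns:
            raise ValueError(f"xpore-like table is missing column {col!r}")
    keep = (candidates["pvalue"] < cfg.p_xpore) & (
        candidates["rate_stress"] > candidates["rate_control"]
    )
    return candidates.loc[keep].copy()


def filter_nanocompore(
    candidates: pd.DataFrame, cfg: PipelineConfig
) -> pd.DataFrame:
    """Keep candidates significant in all three tests (worst p < alpha).

    Rows with any p-value outside (0, 1] are invalid detector output and
    are dropped with a warning.
    """
    for col in NANO_P_COLUMNS:
        if col not in candidates.columns:
            raise ValueError(
                f"nanocompore-like table is missing column {col!r}"
            )
    pvals = candidates[NANO_P_COLUMNS]
    valid = ((pvals > 0) & (pvals <= 1)).all(axis=1)
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning(
            "dropping %d nanocompore-like rows with p-values outside (0, 1]",
            n_bad,
        )
    ok = candidates.loc[valid]
    keep = ok[NANO_P_COLUMNS].max(axis=1) < cfg.alpha_nanocompore
    return ok.loc[keep].copy()


def filter_eligible_transcripts(
    candidates: pd.DataFrame,
    readcounts: Mapping[str, float] | pd.Series,
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """Drop candidates on transcripts below the coverage floor.

    Transcripts absent from the read-count table are treated as count 0
    (undetectable) and reported in a warning.
    """
    counts = pd.Series(readcounts, dtype=float)
    missing = sorted(set(candidates["transcript_id"]) - set(counts.index))
    if missing:
        logger.warning(
            "%d transcripts with candidates are absent from the read-count "
            "table and treated as count 0 (e.g. %s)",
            len(missing),
            missing[:3],
        )
    avg = candidates["transcript_id"].map(counts).fillna(0.0)
    return candidates.loc[avg > cfg.min_avg_readcount].copy()


def _positions_by_transcript(df: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        tid: np.sort(grp["position"].to_numpy())
        for tid, grp in df.groupby("transcript_id", sort=True)
    }


def cross_tool_match(
    xpore_pass: pd.DataFrame,
    nanocompore_pass: pd.DataFrame,
    cfg: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain candidates corroborated by the other tool within the window.

    A candidate survives iff a filtered candidate from the other tool
    exists on the same transcript with |delta position| <= window.
    Returns the surviving subsets of both inputs.
    """
    xp_pos = _positions_by_transcript(xpore_pass)
    nc_pos = _positions_by_transcript(nanocompore_pass)

    def survivors(df: pd.DataFrame, other: dict[str, np.ndarray]) -> pd.DataFrame:
        if df.empty:
            return df.copy()
        keep = np.zeros(len(df), dtype=bool)
        for i, (tid, pos) in enumerate(
            zip(df["transcript_id"].to_numpy(), df["position"].to_numpy())
        ):
            partners = other.get(tid)
            if partners is not None and len(partners):
                j = np.searchsorted(partners, pos)
                near = []
                if j > 0:
                    near.append(pos - partners[j - 1])
                if j < len(partners):
                    near.append(partners[j] - pos)
                keep[i] = min(near) <= cfg.collapse_window
        return df.loc[keep].copy()

    return survivors(xpore_pass, nc_pos), survivors(nanocompore_pass, xp_pos)


def collapse_sites(
    xpore_surviving: pd.DataFrame,
    nanocompore_surviving: pd.DataFrame,
    cfg: PipelineConfig,
) -> list[ModSite]:
    """Single-linkage collapse of surviving candidates into unique sites.

    Candidates from both tools are pooled, sorted by (transcript_id,
    position, tool), and scanned; a gap greater than the window between
    consecutive positions starts a new cluster.  Each cluster becomes
    one ModSite spanning [min position, max position + 5).
    """
    xp = xpore_surviving.assign(tool="xpore")
    nc = nanocompore_surviving.assign(tool="nanocompore")
    pooled = pd.concat([xp, nc], ignore_index=True, sort=False)
    if pooled.empty:
        return []
    pooled = pooled.sort_values(
        ["transcript_id", "position", "tool"], kind="mergesort"
    ).reset_index(drop=True)

    new_tx = pooled["transcript_id"].ne(pooled["transcript_id"].shift())
    gap = pooled["position"].diff()
    new_cluster = new_tx | (gap > cfg.collapse_window)
    cluster_id = new_cluster.cumsum()

    sites: list[ModSite] = []
    for _, grp in pooled.groupby(cluster_id, sort=True):
        xp_rows = grp[grp["tool"] == "xpore"]
        nc_rows = grp[grp["tool"] == "nanocompore"]
        if xp_rows.empty or nc_rows.empty:
            # cross-tool matching guarantees both tools per cluster; a
            # one-tool cluster can only arise from hand-built input
            logger.warning(
                "cluster on %s lacks support from both tools; skipped",
                grp["transcript_id"].iloc[0],
            )
            continue
        start = int(grp["position"].min())
        end = int(grp["position"].max()) + 5
        diff = xp_rows["rate_stress"] - xp_rows["rate_control"]
        rep = xp_rows.loc[diff.idxmax()]
        nano_worst = nc_rows[NANO_P_COLUMNS].max(axis=1)
        site = ModSite(
            site_id="",
            transcript_id=str(grp["transcript_id"].iloc[0]),
            start=start,
            end=end,
            n_xpore=len(xp_rows),
            n_nanocompore=len(nc_rows),
            best_p_xpore=float(xp_rows["pvalue"].min()),
            best_p_nanocompore=float(nano_worst.min()),
            rate_stress=float(rep["rate_stress"]),
            rate_control=float(rep["rate_control"]),
            kmer=str(rep["kmer"]),
        )
        sites.append(site)

    # stable, reproducible ids after sorting by coordinate
    sites.sort(key=lambda s: (s.transcript_id, s.start))
    return [
        dataclasses.replace(s, site_id=f"site_{i + 1:05d}")
        for i, s in enumerate(sites)
    ]


def call_sites(
    xpore: pd.DataFrame,
    nanocompore: pd.DataFrame,
    readcounts: Mapping[str, float] | pd.Series,
    cfg: PipelineConfig,
) -> tuple[list[ModSite], dict[str, int]]:
    """Run the full consensus funnel and report per-stage counts.

    Eligibility is applied before the significance filters; the funnel
    dictionary mirrors the workflow stages (per-tool candidates in,
    per-tool pass, cross-tool retained, collapsed sites).
    """
    funnel: dict[str, int] = {
        "xpore_candidates": len(xpore),
        "nanocompore_candidates": len(nanocompore),
    }
    xp = filter_eligible_transcripts(xpore, readcounts, cfg)
    nc = filter_eligible_transcripts(nanocompore, readcounts, cfg)
    xp = filter_xpore(xp, cfg)
    nc = filter_nanocompore(nc, cfg)
    funnel["xpore_pass"] = len(xp)
    funnel["nanocompore_pass"] = len(nc)
    xp, nc = cross_tool_match(xp, nc, cfg)
    funnel["cross_tool_retained"] = len(xp) + len(nc)
    sites = collapse_sites(xp, nc, cfg)
    funnel["collapsed_sites"] = len(sites)
    return sites, funnel
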