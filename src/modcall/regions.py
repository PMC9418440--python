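"""Region assignment, per-region densities and metagene profiles.

Sites are assigned to 5'UTR/CDS/3'UTR by the integer midpoint of their
collapsed interval; positional distributions use region-local normalized
coordinates (rel_pos in [0, 1)) so regions of different lengths are
comparable, following standard metagene practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import ModSite, Region, REGIONS, TranscriptModel


@dataclass(frozen=True)
class RegionAssignment:
    site_id: str
    transcript_id: str
    region: Region
    rel_pos: float


def assign_region(site: ModSite, tx: TranscriptModel) -> RegionAssignment:
    """Assign a site to a region by its interval midpoint.

    A collapsed interval can straddle a region boundary; the integer
    midpoint ``floor((start + end - 1) / 2)`` decides, deterministically
    and symmetrically.  ``rel_pos`` is the midpoint's fractional offset
    within the assigned region.
    """
    if site.start < 0 or site.end > tx.total_len:
        raise ValueError(
            f"site {site.site_id} [{site.start}, {site.end}) extends beyond "
            f"transcript {tx.transcript_id} of length {tx.total_len}"
        )
    mid = site.midpoint
    region = tx.region_of(mid)
    rstart, rend = tx.region_bounds(region)
    rel = (mid - rstart) / (rend - rstart)
    return RegionAssignment(
        site_id=site.site_id,
        transcript_id=tx.transcript_id,
        region=region,
        rel_pos=rel,
    )


def assign_regions(
    sites: Sequence[ModSite], transcripts: Mapping[str, TranscriptModel]
) -> pd.DataFrame:
    """Region assignment for every site, as a tidy table."""
    rows = []
    for s in sites:
        a = assign_region(s, transcripts[s.transcript_id])
        rows.append(
            {
                "site_id": a.site_id,
                "transcript_id": a.transcript_id,
                "region": a.region.value,
                "rel_pos": a.rel_pos,
            }
        )
    return pd.DataFrame(
        rows, columns=["site_id", "transcript_id", "region", "rel_pos"]
    )


def region_summary(
    assignments: pd.DataFrame,
    transcripts: Mapping[str, TranscriptModel],
    eligible_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-region site counts and per-nucleotide densities.

    The density denominator sums region lengths over eligible
    transcripts only (those with enough coverage to contribute sites at
    all); including undetectable transcripts would deflate every
    density.  A region with zero total length gets a missing density.
    """
    ids = set(eligible_ids) if eligible_ids is not None else set(transcripts)
    counts = {r: 0 for r in REGIONS}
    if len(assignments):
        vc = assignments["region"].value_counts()
        for r in REGIONS:
            counts[r] = int(vc.get(r.value, 0))
    lengths = {
        r: sum(transcripts[t].region_length(r) for t in ids) for r in REGIONS
    }
    rows = []
    for r in REGIONS:
        total_nt = lengths[r]
        density = counts[r] / total_nt if total_nt > 0 else np.nan
        rows.append(
            {
                "region": r.value,
                "n_sites": counts[r],
                "total_nt": total_nt,
                "sites_per_nt": density,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MetageneProfile:
    """Site densities over a concatenated 5'UTR | CDS | 3'UTR axis.

    ``densities`` is a (3, n_bins) matrix normalized to sum to 1 over
    all bins whenever any site exists.
    """

    n_bins: int
    densities: np.ndarray
    n_sites: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, region in enumerate(REGIONS):
            for b in range(self.n_bins):
                rows.append(
                    {
                        "region": region.value,
                        "bin": b,
                        "density": self.densities[i, b],
                    }
                )
        return pd.DataFrame(rows)

    @property
    def flat(self) -> np.ndarray:
        return self.densities.reshape(-1)


def _histogram_3xB(assignments: pd.DataFrame, n_bins: int) -> np.ndarray:
    counts = np.zeros((3, n_bins))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    for i, region in enumerate(REGIONS):
        vals = assignments.loc[
            assignments["region"] == region.value, "rel_pos"
        ].to_numpy()
        # rel_pos lives in [0, 1); the final edge is inclusive regardless
        counts[i], _ = np.histogram(vals, bins=edges)
    return counts


def metagene_profile(
    assignments: pd.DataFrame,
    n_bins: int = 20,
    per_transcript: bool = False,
) -> MetageneProfile:
    """Positional profile over the concatenated three-region axis.

    By default all sites are pooled before histogramming.  With
    ``per_transcript=True`` each transcript's histogram is normalized to
    unit mass first and the mean over transcripts is taken, which weighs
    transcripts equally rather than sites.
    """
    n_sites = len(assignments)
    if per_transcript and n_sites:
        mats = []
        for _, grp in assignments.groupby("transcript_id", sort=True):
            m = _histogram_3xB(grp, n_bins)
            mats.append(m / m.sum())
        counts = np.mean(mats, axis=0)
    else:
        counts = _histogram_3xB(assignments, n_bins)
    total = counts.sum()
    densities = counts / total if total > 0 else counts
    return MetageneProfile(n_bins=n_bins, densities=densities, n_sites=n_sites)
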