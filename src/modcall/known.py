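"""Intersection of called sites with a known-modification database.

The database is consumed as a transcript-space BED6 (an RMBase-style
catalog already projected onto transcript coordinates; genomic liftover
is out of scope).  Overlap is strict half-open interval intersection,
optionally padded by ``slop`` nucleotides on each side of a site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

from .models import ModSite

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapReport:
    """Per-site overlap flags plus per-type overlap counts.

    ``per_site`` has one row per called site (site_id, overlaps,
    mod_types with distinct matched types ';'-joined); ``per_type``
    counts each site once per distinct matched type.
    """

    per_site: pd.DataFrame
    per_type: pd.Series

    @property
    def n_overlapping(self) -> int:
        return int(self.per_site["overlaps"].sum())


def intersect_known(
    sites: Sequence[ModSite],
    known: pd.DataFrame,
    slop: int = 0,
) -> OverlapReport:
    """Flag sites whose intervals intersect known-modification records.

    ``known`` is a BED-like frame with transcript_id/start/end/name
    columns, name holding the modification type.  A site may match
    multiple records; it is counted once per distinct type.
    """
    trees: dict[str, IntervalTree] = {}
    for row in known.itertuples(index=False):
        if row.start >= row.end:
            raise ValueError(
                f"known record on {row.transcript_id} has empty interval "
                f"[{row.start}, {row.end})"
            )
        trees.setdefault(row.transcript_id, IntervalTree()).addi(
            row.start, row.end, row.name
        )

    rows = []
    for s in sites:
        tree = trees.get(s.transcript_id)
        hits = (
            sorted({iv.data for iv in tree.overlap(s.start - slop, s.end + slop)})
            if tree is not None
            else []
        )
        rows.append(
            {
                "site_id": s.site_id,
                "transcript_id": s.transcript_id,
                "start": s.start,
                "end": s.end,
                "overlaps": bool(hits),
                "mod_types": ";".join(hits),
            }
        )
    per_site = pd.DataFrame(
        rows,
        columns=[
            "site_id",
            "transcript_id",
            "start",
            "end",
            "overlaps",
            "mod_types",
        ],
    )
    type_counts: dict[str, int] = {}
    for types in per_site.loc[per_site["overlaps"], "mod_types"]:
        for t in types.split(";"):
            type_counts[t] = type_counts.get(t, 0) + 1
    per_type = (
        pd.Series(type_counts, dtype=int, name="n_sites")
        .sort_index()
        .sort_values(ascending=False, kind="mergesort")  # ties alphabetical
    )
    return OverlapReport(per_site=per_site, per_type=per_type)


def type_breakdown(report: OverlapReport) -> pd.DataFrame:
    """Overlap counts per modification type, descending."""
    return (
        report.per_type.rename_axis("mod_type")
        .reset_index()
        .rename(columns={"n_sites": "n_sites"})
    )
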