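"""Readers and writers for the pipeline's file formats.

All tabular formats are single-header TSV; coordinates on disk follow
the same 0-based half-open convention used in memory.  FASTA and
detector tables may use DNA (T) or RNA (U) alphabets; everything is
normalized to RNA on ingest.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .consensus import NANOCOMPORE_COLUMNS, XPORE_COLUMNS
from .models import ModSite, TranscriptModel

REGION_TABLE_COLUMNS = [
    "transcript_id",
    "gene_id",
    "len_5utr",
    "len_cds",
    "len_3utr",
    "total_len",
]
BED6_COLUMNS = ["transcript_id", "start", "end", "name", "score", "strand"]
SITES_EXTRA_COLUMNS = [
    "n_xpore",
    "n_nanocompore",
    "best_p_xpore",
    "best_p_nanocompore",
    "rate_stress",
    "rate_control",
    "kmer",
]


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def write_fasta(
    path: str | Path, sequences: Mapping[str, str], width: int = 70
) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA sequences as RNA strings (T mapped to U)."""
    if Path(path).stat().st_size == 0:
        return {}
    fa = Fasta(str(path))
    return {name: _to_rna(str(fa[name][:])) for name in fa.keys()}


def write_region_table(
    path: str | Path, transcripts: Sequence[TranscriptModel]
) -> None:
    df = pd.DataFrame(
        [
            {
                "transcript_id": t.transcript_id,
                "gene_id": t.gene_id,
                "len_5utr": t.len_5utr,
                "len_cds": t.len_cds,
                "len_3utr": t.len_3utr,
                "total_len": t.total_len,
            }
            for t in transcripts
        ],
        columns=REGION_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_region_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(REGION_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"region table missing columns: {sorted(missing)}")
    return df


def read_transcripts(
    fasta_path: str | Path, region_path: str | Path
) -> dict[str, TranscriptModel]:
    """Assemble TranscriptModels from a FASTA and a region table."""
    seqs = read_fasta(fasta_path)
    regions = read_region_table(region_path)
    out: dict[str, TranscriptModel] = {}
    for row in regions.itertuples(index=False):
        if row.transcript_id not in seqs:
            raise ValueError(
                f"transcript {row.transcript_id} in region table but not FASTA"
            )
        out[row.transcript_id] = TranscriptModel(
            transcript_id=row.transcript_id,
            gene_id=row.gene_id,
            len_5utr=int(row.len_5utr),
            len_cds=int(row.len_cds),
            len_3utr=int(row.len_3utr),
            sequence=seqs[row.transcript_id],
        )
    return out


def _read_candidate_table(
    path: str | Path,
    canonical: Sequence[str],
    colmap: Mapping[str, str] | None,
) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if colmap:
        df = df.rename(columns=dict(colmap))
    missing = set(canonical) - set(df.columns)
    if missing:
        raise ValueError(
            f"{Path(path).name}: missing columns {sorted(missing)} "
            "(use a column mapping to absorb nonstandard headers)"
        )
    df = df[list(canonical)].copy()
    df["kmer"] = df["kmer"].map(_to_rna)
    df["position"] = df["position"].astype(int)
    return df


def read_xpore_table(
    path: str | Path, colmap: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read an xpore-like candidate table (optionally remapping headers)."""
    return _read_candidate_table(path, XPORE_COLUMNS, colmap)


def read_nanocompore_table(
    path: str | Path, colmap: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a nanocompore-like candidate table with three test p-values."""
    return _read_candidate_table(path, NANOCOMPORE_COLUMNS, colmap)


def read_counts(path: str | Path) -> pd.Series:
    """Per-transcript average read counts, indexed by transcript id."""
    df = pd.read_csv(path, sep="\t")
    for col in ("transcript_id", "avg_read_count"):
        if col not in df.columns:
            raise ValueError(f"read-count table missing column {col!r}")
    return df.set_index("transcript_id")["avg_read_count"].astype(float)


def read_de_table(path: str | Path, log2: bool = False) -> pd.DataFrame:
    """Differential-expression results (gene_id, fold_change, fdr).

    ``fold_change`` is linear by default; pass ``log2=True`` if the file
    stores log2 fold-changes, and they are converted on ingest.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "fold_change", "fdr"} - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    df = df.copy()
    if log2:
        df["fold_change"] = 2.0 ** df["fold_change"].astype(float)
    return df


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED6 with the name column holding the modification type."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(
                    f"{Path(path).name}:{lineno}: expected >= 6 BED columns, "
                    f"got {len(parts)}"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{Path(path).name}:{lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise ValueError(
                    f"{Path(path).name}:{lineno}: empty interval "
                    f"[{start}, {end})"
                )
            rows.append(
                {
                    "transcript_id": parts[0],
                    "start": start,
                    "end": end,
                    "name": parts[3],
                    "score": parts[4],
                    "strand": parts[5],
                }
            )
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


def write_bed(path: str | Path, records: pd.DataFrame) -> None:
    records[BED6_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def sites_to_frame(sites: Sequence[ModSite]) -> pd.DataFrame:
    cols = [f.name for f in dataclasses.fields(ModSite)]
    return pd.DataFrame(
        [dataclasses.asdict(s) for s in sites], columns=cols
    )


def write_sites_bed(path: str | Path, sites: Sequence[ModSite]) -> None:
    """ModSites as BED6+ (score = -log10 best xpore p, capped at 300)."""
    with open(path, "w") as fh:
        fh.write(
            "#"
            + "\t".join(
                ["transcript_id", "start", "end", "site_id", "score", "strand"]
                + SITES_EXTRA_COLUMNS
            )
            + "\n"
        )
        for s in sites:
            score = min(-np.log10(max(s.best_p_xpore, 1e-300)), 300.0)
            fields = [
                s.transcript_id,
                str(s.start),
                str(s.end),
                s.site_id,
                f"{score:.3f}",
                "+",
                str(s.n_xpore),
                str(s.n_nanocompore),
                repr(s.best_p_xpore),
                repr(s.best_p_nanocompore),
                repr(s.rate_stress),
                repr(s.rate_control),
                s.kmer,
            ]
            fh.write("\t".join(fields) + "\n")


def read_sites_bed(path: str | Path) -> list[ModSite]:
    sites: list[ModSite] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            if len(p) < 13:
                raise ValueError(
                    f"{Path(path).name}: not a modcall sites BED (13 columns)"
                )
            sites.append(
                ModSite(
                    site_id=p[3],
                    transcript_id=p[0],
                    start=int(p[1]),
                    end=int(p[2]),
                    n_xpore=int(p[6]),
                    n_nanocompore=int(p[7]),
                    best_p_xpore=float(p[8]),
                    best_p_nanocompore=float(p[9]),
                    rate_stress=float(p[10]),
                    rate_control=float(p[11]),
                    kmer=_to_rna(p[12]),
                )
            )
    return sites
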