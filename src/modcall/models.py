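"""Core data model: transcripts, called sites, and pipeline thresholds.

Coordinate conventions used throughout the package
--------------------------------------------------
* All coordinates are transcript-local, 0-based, half-open.
* ``position`` on a detector candidate or truth site always denotes the
  FIRST base of the 5-mer centred on the putatively modified base.
* Sequences are RNA over ``{A, C, G, U}``; readers map T to U on ingest.
* A transcript is partitioned into 5'UTR = [0, u), CDS = [u, u + c) and
  3'UTR = [u + c, total); a region boundary base belongs to the
  downstream region.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

import yaml

RNA_ALPHABET = "ACGU"


class Region(str, Enum):
    """mRNA region in which a site falls."""

    FIVE_UTR = "5utr"
    CDS = "cds"
    THREE_UTR = "3utr"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: canonical region order (5' to 3'), used for metagene axes and tables
REGIONS = (Region.FIVE_UTR, Region.CDS, Region.THREE_UTR)


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript's region architecture and sequence.

    The coordinate frame for every downstream computation.
    """

    transcript_id: str
    gene_id: str
    len_5utr: int
    len_cds: int
    len_3utr: int
    sequence: str

    def __post_init__(self) -> None:
        if self.len_5utr < 0 or self.len_3utr < 0:
            raise ValueError(
                f"{self.transcript_id}: UTR lengths must be non-negative"
            )
        if self.len_cds <= 0:
            raise ValueError(f"{self.transcript_id}: CDS length must be positive")
        if len(self.sequence) != self.total_len:
            raise ValueError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} "
                f"!= sum of region lengths {self.total_len}"
            )
        bad = set(self.sequence) - set(RNA_ALPHABET)
        if bad:
            raise ValueError(
                f"{self.transcript_id}: non-RNA characters {sorted(bad)!r}"
            )

    @property
    def total_len(self) -> int:
        return self.len_5utr + self.len_cds + self.len_3utr

    def region_bounds(self, region: Region) -> tuple[int, int]:
        """Half-open [start, end) of a region in transcript coordinates."""
        u, c = self.len_5utr, self.len_cds
        if region is Region.FIVE_UTR:
            return 0, u
        if region is Region.CDS:
            return u, u + c
        return u + c, self.total_len

    def region_length(self, region: Region) -> int:
        s, e = self.region_bounds(region)
        return e - s

    def region_of(self, pos: int) -> Region:
        """Region containing a 0-based position (boundary -> downstream)."""
        if not 0 <= pos < self.total_len:
            raise ValueError(
                f"position {pos} outside transcript {self.transcript_id} "
                f"of length {self.total_len}"
            )
        if pos < self.len_5utr:
            return Region.FIVE_UTR
        if pos < self.len_5utr + self.len_cds:
            return Region.CDS
        return Region.THREE_UTR

    def kmer_at(self, pos: int, k: int = 5) -> str:
        if pos < 0 or pos + k > self.total_len:
            raise ValueError(
                f"k-mer [{pos}, {pos + k}) outside transcript "
                f"{self.transcript_id}"
            )
        return self.sequence[pos : pos + k]


@dataclass(frozen=True)
class ModSite:
    """A collapsed high-confidence differentially modified site.

    ``start``/``end`` span the supporting candidate 5-mers (half-open).
    Representative rates and k-mer come from the supporting xpore-like
    candidate with the largest modification-rate differential;
    ``best_p_nanocompore`` is the minimum, over nanocompore-like
    supporters, of each supporter's worst (maximum) test p-value.
    """

    site_id: str
    transcript_id: str
    start: int
    end: int
    n_xpore: int
    n_nanocompore: int
    best_p_xpore: float
    best_p_nanocompore: float
    rate_stress: float
    rate_control: float
    kmer: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.site_id}: empty interval")
        if self.n_xpore < 1 or self.n_nanocompore < 1:
            raise ValueError(
                f"{self.site_id}: consensus sites need support from both tools"
            )

    @property
    def midpoint(self) -> int:
        """Integer midpoint, floor((start + end - 1) / 2)."""
        return (self.start + self.end - 1) // 2


@dataclass
class PipelineConfig:
    """Every threshold of the consensus workflow, in one place.

    Defaults follow the study design this pipeline implements: per-tool
    significance at 0.01 (all three nanocompore-like tests below alpha;
    xpore-like t-test p below ``p_xpore`` with a stress-ward rate shift),
    cross-tool retention and collapsing within 10 nt, transcript
    eligibility at average read count strictly greater than 15, and
    differential-expression calls at |FC - 1| > 0.20 with FDR < 0.05.
    """

    alpha_nanocompore: float = 0.01
    p_xpore: float = 0.01
    collapse_window: int = 10
    min_avg_readcount: float = 15.0
    de_abs_fc: float = 0.20
    de_fdr: float = 0.05
    n_backgrounds: int = 10
    flank_logo: int = 5
    metagene_bins: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_nanocompore", "p_xpore", "de_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.collapse_window < 0:
            raise ValueError("collapse_window must be >= 0")
        if self.n_backgrounds < 1 or self.metagene_bins < 1:
            raise ValueError("n_backgrounds and metagene_bins must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def gene_map_from_transcripts(
    transcripts: Iterable[TranscriptModel],
) -> dict[str, str]:
    """transcript_id -> gene_id lookup."""
    return {t.transcript_id: t.gene_id for t in transcripts}
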