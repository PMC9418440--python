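"""Degenerate-motif matching and enrichment against region-matched backgrounds.

m6A deposition is strongly biased toward the DRACH sequence context
(D = A/G/U, R = A/G, then invariant A and C, H = A/C/U; 18 concrete
5-mers).  A catalog of genuine differential-m6A sites should therefore
show DRACH k-mers far in excess of region-matched random positions,
while an arbitrary control motif of equal degeneracy should not.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import ModSite, PipelineConfig, Region, TranscriptModel
from .regions import assign_regions

logger = logging.getLogger(__name__)

IUPAC_RNA: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "S": frozenset("CG"),
    "W": frozenset("AU"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}


@dataclass(frozen=True)
class DegenerateMotif:
    """An IUPAC-degenerate motif and its concrete k-mer expansion."""

    pattern: str

    def __post_init__(self) -> None:
        bad = set(self.pattern) - set(IUPAC_RNA)
        if bad:
            raise ValueError(f"non-IUPAC codes in motif: {sorted(bad)!r}")
        if not self.pattern:
            raise ValueError("empty motif pattern")

    @property
    def expansion(self) -> frozenset[str]:
        sets = [sorted(IUPAC_RNA[c]) for c in self.pattern]
        return frozenset("".join(p) for p in itertools.product(*sets))

    def __len__(self) -> int:
        return len(self.pattern)


DRACH = DegenerateMotif("DRACH")
#: control motif of equal degeneracy (reversed pattern; expansion is
#: disjoint from DRACH because position 2 is invariant C vs R = A/G)
CONTROL_MOTIF = DegenerateMotif("HCARD")


def match_motif(kmer: str, motif: DegenerateMotif) -> bool:
    """True iff every base of ``kmer`` lies in the motif's IUPAC class."""
    if len(kmer) != len(motif):
        raise ValueError(
            f"k-mer length {len(kmer)} != motif length {len(motif)}"
        )
    return all(base in IUPAC_RNA[code] for base, code in zip(kmer, motif.pattern))


def motif_frequency(kmers: Sequence[str], motif: DegenerateMotif) -> float:
    if len(kmers) == 0:
        raise ValueError("cannot compute motif frequency of zero k-mers")
    return sum(match_motif(k, motif) for k in kmers) / len(kmers)


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed vs background motif frequency and their ratio.

    ``empirical_p`` is the fraction of background sets whose frequency
    reaches the observed one; with 10 backgrounds it is descriptive
    (resolution 0.1), not a calibrated test.
    """

    motif: DegenerateMotif
    observed_freq: float
    background_freqs: tuple[float, ...]
    n_sites: int

    @property
    def background_mean(self) -> float:
        return float(np.mean(self.background_freqs))

    @property
    def background_sd(self) -> float:
        return float(np.std(self.background_freqs, ddof=1))

    @property
    def ratio(self) -> float:
        mean = self.background_mean
        if mean == 0:
            return float("inf") if self.observed_freq > 0 else float("nan")
        return self.observed_freq / mean

    @property
    def empirical_p(self) -> float:
        return float(
            np.mean([f >= self.observed_freq for f in self.background_freqs])
        )


def sample_backgrounds(
    sites: Sequence[ModSite],
    transcripts: Mapping[str, TranscriptModel],
    cfg: PipelineConfig,
    rng: np.random.Generator | None = None,
    eligible_ids: Iterable[str] | None = None,
) -> list[list[tuple[str, int]]]:
    """Draw region-matched random non-modified site positions.

    Returns ``cfg.n_backgrounds`` independent sets of (transcript_id,
    position) pairs, each with the same per-region composition as
    ``sites``.  Positions are k-mer starts drawn uniformly over regions
    of eligible transcripts, excluding anything whose 5-mer comes within
    ``cfg.collapse_window`` nt of a called site interval.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    k = 5
    ids = set(eligible_ids) if eligible_ids is not None else set(transcripts)
    assignments = assign_regions(sites, transcripts)
    needed = assignments["region"].value_counts().to_dict()

    # exclude k-mer starts whose 5-mer comes within `window` nt of a site:
    # interval gap([pos, pos+5), [start, end)) <= window
    excluded: dict[str, list[tuple[int, int]]] = {}
    for s in sites:
        excluded.setdefault(s.transcript_id, []).append(
            (
                s.start - cfg.collapse_window - k,
                s.end + cfg.collapse_window + 1,
            )
        )

    # allowed k-mer start positions, pooled per region
    pool: dict[Region, list[tuple[str, int]]] = {r: [] for r in Region}
    for tid in sorted(ids):
        tx = transcripts[tid]
        mask = np.ones(max(tx.total_len - k + 1, 0), dtype=bool)
        for lo, hi in excluded.get(tid, []):
            mask[max(lo, 0) : min(hi, len(mask))] = False
        for pos in np.nonzero(mask)[0]:
            pool[tx.region_of(int(pos))].append((tid, int(pos)))

    sets: list[list[tuple[str, int]]] = []
    for _ in range(cfg.n_backgrounds):
        drawn: list[tuple[str, int]] = []
        for region in Region:
            n = int(needed.get(region.value, 0))
            if n == 0:
                continue
            avail = pool[region]
            if not avail:
                raise ValueError(
                    f"no background positions available in {region.value} "
                    f"but {n} sites fall there"
                )
            idx = rng.choice(len(avail), size=n, replace=len(avail) < n)
            drawn.extend(avail[i] for i in np.atleast_1d(idx))
        sets.append(drawn)
    return sets


def enrichment(
    sites: Sequence[ModSite],
    backgrounds: Sequence[Sequence[tuple[str, int]]],
    transcripts: Mapping[str, TranscriptModel],
    motif: DegenerateMotif = DRACH,
) -> EnrichmentResult:
    """Motif frequency among site k-mers vs background position k-mers.

    The k-mer tested for each site is its representative k-mer (from the
    max-differential supporting candidate); a site matches if that k-mer
    matches the motif (per-site any-match convention).
    """
    if len(sites) == 0:
        raise ValueError("enrichment requires at least one site")
    observed = motif_frequency([s.kmer for s in sites], motif)
    bg_freqs = tuple(
        motif_frequency(
            [transcripts[tid].kmer_at(pos) for tid, pos in bset], motif
        )
        for bset in backgrounds
    )
    return EnrichmentResult(
        motif=motif,
        observed_freq=observed,
        background_freqs=bg_freqs,
        n_sites=len(sites),
    )


def enrichment_table(
    results: Sequence[EnrichmentResult],
) -> pd.DataFrame:
    rows = [
        {
            "motif": r.motif.pattern,
            "n_sites": r.n_sites,
            "observed_freq": r.observed_freq,
            "background_mean": r.background_mean,
            "background_sd": r.background_sd,
            "ratio": r.ratio,
            "empirical_p": r.empirical_p,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def per_kmer_breakdown(
    sites: Sequence[ModSite], motif: DegenerateMotif = DRACH
) -> pd.DataFrame:
    """Counts of each concrete site k-mer, flagged for motif membership."""
    counts = pd.Series([s.kmer for s in sites]).value_counts()
    df = counts.rename_axis("kmer").reset_index(name="n_sites")
    df["matches_motif"] = [match_motif(k, motif) for k in df["kmer"]]
    return df


@dataclass(frozen=True)
class ConsensusMatrix:
    """Base counts around site k-mer starts (window = 5 + 2 * flank nt)."""

    flank: int
    counts: np.ndarray  # (window, 4) in A, C, G, U order
    n_sites: int

    @property
    def frequencies(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            freq = np.where(totals > 0, self.counts / totals, 0.0)
        return freq

    def to_frame(self) -> pd.DataFrame:
        offsets = np.arange(-self.flank, 5 + self.flank)
        df = pd.DataFrame(self.frequencies, columns=list("ACGU"))
        df.insert(0, "offset", offsets)
        return df


def consensus_matrix(
    sites: Sequence[ModSite],
    transcripts: Mapping[str, TranscriptModel],
    flank: int = 5,
) -> ConsensusMatrix:
    """Base-frequency matrix around site k-mer starts.

    Windows truncated by transcript ends are dropped.  Typically applied
    to the subset of sites overlapping known m6A annotations, where the
    expected picture is the DRACH consensus.
    """
    width = 5 + 2 * flank
    counts = np.zeros((width, 4), dtype=int)
    base_index = {b: i for i, b in enumerate("ACGU")}
    used = 0
    for s in sites:
        tx = transcripts[s.transcript_id]
        # anchor at the representative k-mer start
        kstart = tx.sequence.find(s.kmer, s.start, s.end)
        anchor = kstart if kstart >= 0 else s.start
        lo, hi = anchor - flank, anchor + 5 + flank
        if lo < 0 or hi > tx.total_len:
            continue
        for i, base in enumerate(tx.sequence[lo:hi]):
            counts[i, base_index[base]] += 1
        used += 1
    if used == 0:
        logger.warning("consensus_matrix: no sites with complete windows")
    return ConsensusMatrix(flank=flank, counts=counts, n_sites=used)
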