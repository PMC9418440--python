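"""Synthetic benchmark generator for the consensus workflow.

Builds a toy transcriptome with planted ground-truth differentially
modified sites and emits every input artifact the pipeline consumes:
two detector candidate tables per condition comparison ("xpore-like"
and "nanocompore-like" dialects), a transcript FASTA plus region table,
a known-modification BED, a differential-expression table and a
per-transcript read-count table.

The generator's defaults encode the statistical structure the analysis
assumes about real direct RNA-seq data: planted sites are
modified at a mean rate of 0.48 under stress vs 0.27 in controls, 80%
of them sit in a DRACH sequence context, placement favors the 3'UTR
with a pile-up near the CDS boundary while 5'UTRs (being short) carry
the highest per-nucleotide density, and a fraction of sites is shared
between the two sexes of the study design.

Everything is driven by one ``numpy`` Generator seeded from
``SimParams.seed``; identical parameters give byte-identical output
files.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as mio
from .models import (
    ModSite,
    PipelineConfig,
    Region,
    REGIONS,
    RNA_ALPHABET,
    TranscriptModel,
)
from .motif import DRACH, match_motif

logger = logging.getLogger(__name__)

DRACH_KMERS = tuple(sorted(DRACH.expansion))
SEXES = ("male", "female")


@dataclass(frozen=True)
class TruthSite:
    """A planted ground-truth modified site (first base of the 5-mer)."""

    transcript_id: str
    position: int
    kmer: str
    rate_stress: float
    rate_control: float

    def __post_init__(self) -> None:
        if not self.rate_stress > self.rate_control:
            raise ValueError("planted sites must be stress-ward")
        if not (0 <= self.rate_control and self.rate_stress <= 1):
            raise ValueError("rates must lie in [0, 1]")


@dataclass
class SimParams:
    """Study conditions for the synthetic benchmark.

    ``n_truth_sites`` is the number of planted sites per sex;
    ``frac_shared`` of them are common to both sexes.  Rates are drawn
    from normals around the configured means (sd ``rate_sd``), clipped
    to [0, 1] and redrawn until stress > control.  False candidates
    appear independently per tool at ``fp_rate_per_tool`` per
    nucleotide; a fraction ``fp_pass_fraction`` of them passes that
    tool's own significance filter but co-occurs across tools only by
    chance.
    """

    n_transcripts: int = 60
    n_truth_sites: int = 400
    frac_drach_at_truth: float = 0.8
    mean_rate_stress: float = 0.48
    mean_rate_control: float = 0.27
    rate_sd: float = 0.08
    region_weights_truth: tuple[float, float, float] = (0.2, 0.2, 0.6)
    utr3_boundary_beta: tuple[float, float] = (1.0, 3.0)
    fp_rate_per_tool: float = 0.001
    fp_pass_fraction: float = 0.5
    jitter_max: int = 2
    min_spacing: int = 11
    frac_shared: float = 0.2
    len_5utr_range: tuple[int, int] = (50, 200)
    len_cds_range: tuple[int, int] = (300, 1500)
    len_3utr_range: tuple[int, int] = (200, 800)
    frac_low_count: float = 0.1
    low_count_range: tuple[float, float] = (1.0, 15.0)
    high_count_range: tuple[float, float] = (16.0, 400.0)
    known_frac: float = 0.15
    known_drach_only: bool = True
    known_decoy_factor: float = 2.0
    frac_modified_genes_de: float = 0.05
    frac_other_genes_de: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "frac_drach_at_truth": self.frac_drach_at_truth,
            "mean_rate_stress": self.mean_rate_stress,
            "mean_rate_control": self.mean_rate_control,
            "fp_pass_fraction": self.fp_pass_fraction,
            "frac_shared": self.frac_shared,
            "frac_low_count": self.frac_low_count,
            "frac_modified_genes_de": self.frac_modified_genes_de,
            "frac_other_genes_de": self.frac_other_genes_de,
        }
        for name, v in fracs.items():
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        w = self.region_weights_truth
        if len(w) != 3 or any(x < 0 for x in w) or sum(w) == 0:
            raise ValueError(
                "region_weights_truth must be 3 non-negative weights, not all 0"
            )
        if self.len_cds_range[0] <= 0:
            raise ValueError("CDS length range must be positive")
        if self.n_transcripts < 0 or self.n_truth_sites < 0:
            raise ValueError("counts must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_transcriptome(
    params: SimParams, rng: np.random.Generator | None = None
) -> list[TranscriptModel]:
    """Random transcripts with uniform sequences over {A, C, G, U}.

    Region lengths are drawn uniformly from the configured ranges; one
    gene per transcript.  Motifs are planted later by
    :func:`plant_truth_sites`, which rewrites selected 5-mers.
    """
    if rng is None:
        rng = params.rng()
    bases = np.array(list(RNA_ALPHABET))
    out: list[TranscriptModel] = []
    for i in range(params.n_transcripts):
        u = int(rng.integers(params.len_5utr_range[0], params.len_5utr_range[1] + 1))
        c = int(rng.integers(params.len_cds_range[0], params.len_cds_range[1] + 1))
        t3 = int(rng.integers(params.len_3utr_range[0], params.len_3utr_range[1] + 1))
        seq = "".join(rng.choice(bases, size=u + c + t3))
        out.append(
            TranscriptModel(
                transcript_id=f"tx{i + 1:04d}",
                gene_id=f"gene{i + 1:04d}",
                len_5utr=u,
                len_cds=c,
                len_3utr=t3,
                sequence=seq,
            )
        )
    return out


def _sample_position(
    tx: TranscriptModel, region: Region, params: SimParams, rng: np.random.Generator
) -> int | None:
    """One candidate k-mer start in a region (3'UTR biased to CDS edge)."""
    rstart, rend = tx.region_bounds(region)
    rend = min(rend, tx.total_len - 4)  # 5-mer must fit the transcript
    if rend <= rstart:
        return None
    if region is Region.THREE_UTR:
        a, b = params.utr3_boundary_beta
        off = int(rng.beta(a, b) * (rend - rstart))
        return min(rstart + off, rend - 1)
    return int(rng.integers(rstart, rend))


def plant_truth_sites(
    transcripts: Sequence[TranscriptModel],
    params: SimParams,
    rng: np.random.Generator | None = None,
    n_sites: int | None = None,
) -> tuple[list[TranscriptModel], list[TruthSite]]:
    """Plant ground-truth sites, rewriting DRACH 5-mers into sequences.

    Returns the (possibly sequence-edited) transcripts and the planted
    sites.  Placement follows ``region_weights_truth`` with the 3'UTR
    draw biased toward the CDS boundary; sites on the same transcript
    keep a minimum spacing of ``min_spacing`` nt so that planted sites
    map one-to-one onto collapsed calls.  Transcripts too short to host
    a 5-mer are skipped with a warning.
    """
    if not transcripts:
        raise ValueError("plant_truth_sites needs at least one transcript")
    if rng is None:
        rng = params.rng()
    n = params.n_truth_sites if n_sites is None else n_sites

    seqs = {t.transcript_id: list(t.sequence) for t in transcripts}
    by_id = {t.transcript_id: t for t in transcripts}
    placed: dict[str, list[int]] = {t.transcript_id: [] for t in transcripts}

    weights = np.asarray(params.region_weights_truth, dtype=float)
    weights = weights / weights.sum()
    region_lengths = {
        r: np.array([t.region_length(r) for t in transcripts], dtype=float)
        for r in REGIONS
    }
    usable = [t for t in transcripts if t.total_len >= 5]
    for t in transcripts:
        if t.total_len < 5:
            logger.warning(
                "transcript %s too short to host a 5-mer; skipped",
                t.transcript_id,
            )
    if not usable:
        raise ValueError("no transcript can host a 5-mer")

    records: list[tuple[str, int]] = []
    max_tries = 200
    for _ in range(n):
        pos = None
        tid = None
        for _try in range(max_tries):
            region = REGIONS[int(rng.choice(3, p=weights))]
            lens = region_lengths[region]
            if lens.sum() == 0:
                continue
            ti = int(rng.choice(len(transcripts), p=lens / lens.sum()))
            tx = transcripts[ti]
            if tx.total_len < 5:
                continue
            cand = _sample_position(tx, region, params, rng)
            if cand is None:
                continue
            if all(
                abs(cand - p) >= params.min_spacing
                for p in placed[tx.transcript_id]
            ):
                pos, tid = cand, tx.transcript_id
                break
        if pos is None:
            logger.warning(
                "could not place a truth site after %d tries; planting %d "
                "of %d requested sites",
                max_tries,
                len(records),
                n,
            )
            break
        placed[tid].append(pos)
        records.append((tid, pos))
        if rng.random() < params.frac_drach_at_truth:
            kmer = DRACH_KMERS[int(rng.integers(len(DRACH_KMERS)))]
            seqs[tid][pos : pos + 5] = list(kmer)

    edited = [
        dataclasses.replace(t, sequence="".join(seqs[t.transcript_id]))
        for t in transcripts
    ]
    edited_by_id = {t.transcript_id: t for t in edited}
    truth = [
        TruthSite(
            transcript_id=tid,
            position=pos,
            kmer=edited_by_id[tid].kmer_at(pos),
            rate_stress=rs,
            rate_control=rc,
        )
        for (tid, pos), (rs, rc) in zip(records, _draw_rates(len(records), params, rng))
    ]
    return edited, truth


def _draw_rates(
    n: int, params: SimParams, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Per-site (stress, control) rates; redrawn until stress > control."""
    out: list[tuple[float, float]] = []
    for _ in range(n):
        for _try in range(1000):
            rs = float(np.clip(rng.normal(params.mean_rate_stress, params.rate_sd), 0, 1))
            rc = float(np.clip(rng.normal(params.mean_rate_control, params.rate_sd), 0, 1))
            if rs > rc:
                out.append((rs, rc))
                break
        else:  # pragma: no cover - means are pathological
            raise RuntimeError("could not draw stress > control rates")
    return out


def _log_uniform(
    rng: np.random.Generator, lo: float, hi: float, size: int | None = None
):
    """Log-uniform draws on [lo, hi); spans orders of magnitude."""
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def emit_tool_tables(
    transcripts: Sequence[TranscriptModel],
    truth: Sequence[TruthSite],
    params: SimParams,
    rng: np.random.Generator | None = None,
    cfg: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detector candidate tables for one condition comparison.

    Every truth site appears in both dialects with passing p-values;
    the xpore-like row sits at the exact planted position and carries
    the planted rates, the nanocompore-like row is jittered by 0..2 nt.
    False candidates are injected independently per tool at
    ``fp_rate_per_tool`` per nucleotide; a fraction passes that tool's
    single-tool filter but rarely finds cross-tool support.
    """
    if rng is None:
        rng = params.rng()
    if cfg is None:
        cfg = PipelineConfig()
    by_id = {t.transcript_id: t for t in transcripts}

    xp_rows: list[dict] = []
    nc_rows: list[dict] = []
    for site in truth:
        tx = by_id[site.transcript_id]
        xp_rows.append(
            {
                "transcript_id": site.transcript_id,
                "position": site.position,
                "kmer": site.kmer,
                "rate_stress": site.rate_stress,
                "rate_control": site.rate_control,
                "pvalue": float(_log_uniform(rng, 1e-6, cfg.p_xpore)),
            }
        )
        jitter = int(rng.integers(0, params.jitter_max + 1))
        if jitter and rng.random() < 0.5:
            jitter = -jitter
        pos = int(np.clip(site.position + jitter, 0, tx.total_len - 5))
        p3 = _log_uniform(rng, 1e-6, cfg.alpha_nanocompore, size=3)
        nc_rows.append(
            {
                "transcript_id": site.transcript_id,
                "position": pos,
                "kmer": tx.kmer_at(pos),
                "p_gmm_logit": float(p3[0]),
                "p_ks_intensity": float(p3[1]),
                "p_ks_dwell": float(p3[2]),
            }
        )

    for tx in transcripts:
        n_pos = max(tx.total_len - 4, 0)
        if n_pos == 0:
            continue
        for tool in ("xpore", "nanocompore"):
            n_fp = int(rng.binomial(n_pos, params.fp_rate_per_tool))
            if n_fp == 0:
                continue
            positions = rng.choice(n_pos, size=n_fp, replace=False)
            for pos in sorted(int(p) for p in positions):
                passing = rng.random() < params.fp_pass_fraction
                if tool == "xpore":
                    if passing:
                        p = float(_log_uniform(rng, 1e-6, cfg.p_xpore))
                        rc = float(rng.uniform(0.05, 0.5))
                        rs = float(min(rc + rng.uniform(0.05, 0.4), 1.0))
                    else:
                        p = float(_log_uniform(rng, cfg.p_xpore, 1.0))
                        r1, r2 = rng.uniform(0.05, 0.6, size=2)
                        rs, rc = float(max(r1, r2)), float(min(r1, r2))
                    xp_rows.append(
                        {
                            "transcript_id": tx.transcript_id,
                            "position": pos,
                            "kmer": tx.kmer_at(pos),
                            "rate_stress": rs,
                            "rate_control": rc,
                            "pvalue": p,
                        }
                    )
                else:
                    if passing:
                        p3 = _log_uniform(rng, 1e-6, cfg.alpha_nanocompore, size=3)
                    else:
                        p3 = _log_uniform(rng, 1e-6, 1.0, size=3)
                        p3[int(rng.integers(3))] = float(
                            _log_uniform(rng, cfg.alpha_nanocompore, 1.0)
                        )
                    nc_rows.append(
                        {
                            "transcript_id": tx.transcript_id,
                            "position": pos,
                            "kmer": tx.kmer_at(pos),
                            "p_gmm_logit": float(p3[0]),
                            "p_ks_intensity": float(p3[1]),
                            "p_ks_dwell": float(p3[2]),
                        }
                    )

    xp = pd.DataFrame(xp_rows, columns=mio.XPORE_COLUMNS)
    nc = pd.DataFrame(nc_rows, columns=mio.NANOCOMPORE_COLUMNS)
    xp = xp.sort_values(["transcript_id", "position"], kind="mergesort")
    nc = nc.sort_values(["transcript_id", "position"], kind="mergesort")
    return xp.reset_index(drop=True), nc.reset_index(drop=True)


def emit_ancillary(
    transcripts: Sequence[TranscriptModel],
    truth: Sequence[TruthSite],
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Known-modification BED, DE-results table and read-count table.

    The known-mod BED annotates ``known_frac`` of truth sites as m6A
    (restricted to DRACH-context sites by default, the context in which
    curated m6A databases operate) plus random decoy records of mixed
    modification types placed away from truth sites.  DE status is
    assigned to a small fraction of modified genes (and of unmodified
    genes), with fold-change and FDR fields drawn consistently with the
    |FC - 1| > 0.20, FDR < 0.05 thresholds.  Read counts place a
    fraction of transcripts below the eligibility floor of 15.
    """
    if rng is None:
        rng = params.rng()
    by_id = {t.transcript_id: t for t in transcripts}

    # --- known-modification BED ---------------------------------------
    pool = [
        s
        for s in truth
        if not params.known_drach_only or match_motif(s.kmer, DRACH)
    ]
    n_known = int(round(params.known_frac * len(pool)))
    order = rng.permutation(len(pool))
    chosen = [pool[i] for i in order[:n_known]]
    bed_rows = [
        {
            "transcript_id": s.transcript_id,
            "start": s.position,
            "end": s.position + 5,
            "name": "m6A",
            "score": "0",
            "strand": "+",
        }
        for s in chosen
    ]
    truth_pos = {}
    for s in truth:
        truth_pos.setdefault(s.transcript_id, []).append(s.position)
    n_decoys = int(round(params.known_decoy_factor * n_known))
    decoy_types = ["m6A", "pseudouridine", "m5C"]
    tries = 0
    while len(bed_rows) < n_known + n_decoys and tries < 50 * (n_decoys + 1):
        tries += 1
        tx = transcripts[int(rng.integers(len(transcripts)))]
        if tx.total_len < 5:
            continue
        pos = int(rng.integers(0, tx.total_len - 4))
        near = truth_pos.get(tx.transcript_id, [])
        if any(abs(pos - p) < params.min_spacing for p in near):
            continue
        bed_rows.append(
            {
                "transcript_id": tx.transcript_id,
                "start": pos,
                "end": pos + 5,
                "name": decoy_types[int(rng.integers(len(decoy_types)))],
                "score": "0",
                "strand": "+",
            }
        )
    known = pd.DataFrame(bed_rows, columns=mio.BED6_COLUMNS)
    if len(known):
        known = known.sort_values(
            ["transcript_id", "start"], kind="mergesort"
        ).reset_index(drop=True)

    # --- differential-expression table --------------------------------
    modified_genes = sorted({by_id[s.transcript_id].gene_id for s in truth})
    all_genes = sorted({t.gene_id for t in transcripts})
    other_genes = [g for g in all_genes if g not in set(modified_genes)]
    de_genes: set[str] = set()
    for genes, frac in (
        (modified_genes, params.frac_modified_genes_de),
        (other_genes, params.frac_other_genes_de),
    ):
        k = int(round(frac * len(genes)))
        order = rng.permutation(len(genes))
        de_genes.update(genes[i] for i in order[:k])
    de_rows = []
    for g in all_genes:
        if g in de_genes:
            lfc = float(rng.uniform(np.log2(1.3), np.log2(3.0)))
            if rng.random() < 0.5:
                lfc = -lfc
            fc = float(2.0**lfc)
            fdr = float(_log_uniform(rng, 1e-8, 0.05))
        else:
            fc = float(2.0 ** rng.uniform(-0.1, 0.1))
            fdr = float(rng.uniform(0.05, 1.0))
        de_rows.append({"gene_id": g, "fold_change": fc, "fdr": fdr})
    de = pd.DataFrame(de_rows, columns=["gene_id", "fold_change", "fdr"])

    # --- read-count table ---------------------------------------------
    count_rows = []
    for t in transcripts:
        if rng.random() < params.frac_low_count:
            c = float(rng.uniform(*params.low_count_range))
        else:
            c = float(rng.uniform(*params.high_count_range))
        count_rows.append(
            {"transcript_id": t.transcript_id, "avg_read_count": round(c, 2)}
        )
    counts = pd.DataFrame(count_rows, columns=["transcript_id", "avg_read_count"])
    return known, de, counts


@dataclass
class StudyData:
    """All in-memory artifacts of one simulated two-sex study."""

    params: SimParams
    transcripts: dict[str, TranscriptModel]
    truth: dict[str, list[TruthSite]]  # per sex
    xpore: dict[str, pd.DataFrame]  # per sex
    nanocompore: dict[str, pd.DataFrame]  # per sex
    known: pd.DataFrame
    de: pd.DataFrame
    counts: pd.Series


def simulate_study(
    params: SimParams, cfg: PipelineConfig | None = None
) -> StudyData:
    """Simulate a full two-sex study sharing one transcriptome.

    A pool of ``n_truth_sites * (2 - frac_shared)`` sites is planted
    once (so sequence edits are consistent), then partitioned into
    shared, male-specific and female-specific sites; shared sites get
    independent per-sex rate draws around the same means.
    """
    rng = params.rng()
    transcripts = simulate_transcriptome(params, rng)
    if params.n_transcripts == 0:
        return StudyData(
            params=params,
            transcripts={},
            truth={s: [] for s in SEXES},
            xpore={s: pd.DataFrame(columns=mio.XPORE_COLUMNS) for s in SEXES},
            nanocompore={
                s: pd.DataFrame(columns=mio.NANOCOMPORE_COLUMNS) for s in SEXES
            },
            known=pd.DataFrame(columns=mio.BED6_COLUMNS),
            de=pd.DataFrame(columns=["gene_id", "fold_change", "fdr"]),
            counts=pd.Series(dtype=float, name="avg_read_count"),
        )

    n = params.n_truth_sites
    n_shared = int(round(params.frac_shared * n))
    pool_size = 2 * n - n_shared
    transcripts, pool = plant_truth_sites(
        transcripts, params, rng, n_sites=pool_size
    )
    if len(pool) < pool_size:
        n_shared = min(n_shared, len(pool))
    order = rng.permutation(len(pool))
    shared = [pool[i] for i in order[:n_shared]]
    rest = [pool[i] for i in order[n_shared:]]
    half = (len(rest) + 1) // 2
    male_only, female_only = rest[:half], rest[half:]

    female_shared = [
        dataclasses.replace(s, rate_stress=rs, rate_control=rc)
        for s, (rs, rc) in zip(shared, _draw_rates(len(shared), params, rng))
    ]
    truth = {
        "male": sorted(
            shared + male_only, key=lambda s: (s.transcript_id, s.position)
        ),
        "female": sorted(
            female_shared + female_only,
            key=lambda s: (s.transcript_id, s.position),
        ),
    }

    xpore: dict[str, pd.DataFrame] = {}
    nanocompore: dict[str, pd.DataFrame] = {}
    for sex in SEXES:
        xpore[sex], nanocompore[sex] = emit_tool_tables(
            transcripts, truth[sex], params, rng, cfg
        )
    union = sorted(
        {(s.transcript_id, s.position): s for s in pool}.values(),
        key=lambda s: (s.transcript_id, s.position),
    )
    known, de, counts = emit_ancillary(transcripts, union, params, rng)
    return StudyData(
        params=params,
        transcripts={t.transcript_id: t for t in transcripts},
        truth=truth,
        xpore=xpore,
        nanocompore=nanocompore,
        known=known,
        de=de,
        counts=counts.set_index("transcript_id")["avg_read_count"],
    )


def write_study(study: StudyData, outdir: str | Path) -> dict[str, Path]:
    """Write every artifact of a simulated study to ``outdir``.

    File naming convention consumed by ``report.run_pipeline``:
    transcripts.fa, regions.tsv, counts.tsv, known_sites.bed,
    de_results.tsv, and per-sex xpore_{sex}.tsv / nanocompore_{sex}.tsv.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    txs = [study.transcripts[k] for k in sorted(study.transcripts)]
    paths["fasta"] = outdir / "transcripts.fa"
    mio.write_fasta(paths["fasta"], {t.transcript_id: t.sequence for t in txs})
    paths["regions"] = outdir / "regions.tsv"
    mio.write_region_table(paths["regions"], txs)

    paths["counts"] = outdir / "counts.tsv"
    study.counts.rename("avg_read_count").rename_axis(
        "transcript_id"
    ).reset_index().to_csv(paths["counts"], sep="\t", index=False)
    paths["known"] = outdir / "known_sites.bed"
    mio.write_bed(paths["known"], study.known)
    paths["de"] = outdir / "de_results.tsv"
    study.de.to_csv(paths["de"], sep="\t", index=False)

    for sex in SEXES:
        paths[f"xpore_{sex}"] = outdir / f"xpore_{sex}.tsv"
        study.xpore[sex].to_csv(paths[f"xpore_{sex}"], sep="\t", index=False)
        paths[f"nanocompore_{sex}"] = outdir / f"nanocompore_{sex}.tsv"
        study.nanocompore[sex].to_csv(
            paths[f"nanocompore_{sex}"], sep="\t", index=False
        )
        tdf = pd.DataFrame(
            [dataclasses.asdict(s) for s in study.truth[sex]],
            columns=[
                "transcript_id",
                "position",
                "kmer",
                "rate_stress",
                "rate_control",
            ],
        )
        paths[f"truth_{sex}"] = outdir / f"truth_{sex}.tsv"
        tdf.to_csv(paths[f"truth_{sex}"], sep="\t", index=False)
    return paths
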