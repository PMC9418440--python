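"""Cross-sex sharing, DE overlap, summary statistics and orchestration.

This module holds the arithmetic behind the study-level headline
numbers — how many sites the two sexes share and in how many genes,
what fraction of modified sites falls inside differentially expressed
genes, the eligibility rate of the transcriptome, and the stress/control
modification-rate fold — plus ``run_pipeline``, which chains the whole
workflow (consensus -> regions -> motif -> known-db -> report) per sex
and writes a machine-readable funnel summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as mio
from .consensus import call_sites
from .known import intersect_known, type_breakdown
from .models import ModSite, PipelineConfig, TranscriptModel
from .motif import (
    CONTROL_MOTIF,
    DRACH,
    consensus_matrix,
    enrichment,
    enrichment_table,
    per_kmer_breakdown,
    sample_backgrounds,
)
from .regions import assign_regions, metagene_profile, region_summary

logger = logging.getLogger(__name__)

SEXES = ("male", "female")


@dataclass(frozen=True)
class SexComparison:
    """Shared vs sex-specific sites, matched within the collapse window."""

    n_male: int
    n_female: int
    shared: int
    male_specific: int
    female_specific: int
    genes_shared: int

    @property
    def mean_sites_per_gene(self) -> float:
        if self.genes_shared == 0:
            return float("nan")
        return self.shared / self.genes_shared


def sex_overlap(
    sites_male: Sequence[ModSite],
    sites_female: Sequence[ModSite],
    gene_map: Mapping[str, str],
    cfg: PipelineConfig | None = None,
) -> SexComparison:
    """Greedy nearest-neighbor matching of site midpoints across sexes.

    Candidate pairs on the same transcript with midpoint distance
    <= collapse_window are taken closest-first (ties broken toward the
    5'-most partner); each site matches at most once.  Unmatched sites
    are sex-specific.  ``genes_shared`` counts distinct genes carrying
    at least one shared pair.
    """
    if cfg is None:
        cfg = PipelineConfig()
    by_tx_f: dict[str, list[int]] = {}
    for j, s in enumerate(sites_female):
        by_tx_f.setdefault(s.transcript_id, []).append(j)

    pairs: list[tuple[int, int, int, int, int]] = []
    for i, sm in enumerate(sites_male):
        for j in by_tx_f.get(sm.transcript_id, []):
            sf = sites_female[j]
            d = abs(sm.midpoint - sf.midpoint)
            if d <= cfg.collapse_window:
                pairs.append((d, sf.midpoint, sm.midpoint, i, j))
    pairs.sort()

    matched_m: set[int] = set()
    matched_f: set[int] = set()
    shared_genes: set[str] = set()
    n_shared = 0
    for d, _fmid, _mmid, i, j in pairs:
        if i in matched_m or j in matched_f:
            continue
        matched_m.add(i)
        matched_f.add(j)
        n_shared += 1
        tid = sites_male[i].transcript_id
        shared_genes.add(gene_map.get(tid, tid))
    return SexComparison(
        n_male=len(sites_male),
        n_female=len(sites_female),
        shared=n_shared,
        male_specific=len(sites_male) - n_shared,
        female_specific=len(sites_female) - n_shared,
        genes_shared=len(shared_genes),
    )


@dataclass(frozen=True)
class DEOverlap:
    """Sites harbored in differentially expressed genes."""

    n_sites_in_de_genes: int
    n_sites_total: int
    n_de_genes_hit: int
    n_sites_unmapped: int

    @property
    def percent(self) -> float:
        if self.n_sites_total == 0:
            return 0.0
        return 100.0 * self.n_sites_in_de_genes / self.n_sites_total


def significant_de_genes(de: pd.DataFrame, cfg: PipelineConfig) -> set[str]:
    """Genes passing |FC - 1| > de_abs_fc and FDR < de_fdr (linear FC)."""
    sig = (np.abs(de["fold_change"] - 1.0) > cfg.de_abs_fc) & (
        de["fdr"] < cfg.de_fdr
    )
    return set(de.loc[sig, "gene_id"])


def de_overlap(
    sites: Sequence[ModSite],
    de: pd.DataFrame,
    gene_map: Mapping[str, str],
    cfg: PipelineConfig | None = None,
) -> DEOverlap:
    """Fraction of modified sites inside differentially expressed genes.

    Sites on transcripts absent from the gene map are excluded from the
    denominator and counted in ``n_sites_unmapped`` with a warning.
    """
    if cfg is None:
        cfg = PipelineConfig()
    de_genes = significant_de_genes(de, cfg)
    n_in, n_total, n_unmapped = 0, 0, 0
    genes_hit: set[str] = set()
    for s in sites:
        gene = gene_map.get(s.transcript_id)
        if gene is None:
            n_unmapped += 1
            continue
        n_total += 1
        if gene in de_genes:
            n_in += 1
            genes_hit.add(gene)
    if n_unmapped:
        logger.warning(
            "%d sites on transcripts missing from the gene map were excluded",
            n_unmapped,
        )
    return DEOverlap(
        n_sites_in_de_genes=n_in,
        n_sites_total=n_total,
        n_de_genes_hit=len(genes_hit),
        n_sites_unmapped=n_unmapped,
    )


@dataclass(frozen=True)
class RateFoldSummary:
    """Per-sex mean modification rates and their stress/control fold."""

    mean_stress: dict[str, float]
    mean_control: dict[str, float]

    def fold(self, sex: str) -> float:
        return self.mean_stress[sex] / self.mean_control[sex]

    @property
    def mean_fold(self) -> float | None:
        """Cross-sex mean of the per-sex folds; None with a single sex."""
        if len(self.mean_stress) < 2:
            return None
        return float(np.mean([self.fold(s) for s in self.mean_stress]))


def rate_fold_summary(
    sites_by_sex: Mapping[str, Sequence[ModSite]],
) -> RateFoldSummary:
    """Mean representative rates per sex and the fold between conditions."""
    mean_stress: dict[str, float] = {}
    mean_control: dict[str, float] = {}
    for sex, sites in sites_by_sex.items():
        if len(sites) == 0:
            raise ValueError(f"no sites for {sex}; cannot summarize rates")
        mean_stress[sex] = float(np.mean([s.rate_stress for s in sites]))
        mean_control[sex] = float(np.mean([s.rate_control for s in sites]))
    return RateFoldSummary(mean_stress=mean_stress, mean_control=mean_control)


@dataclass(frozen=True)
class EligibilitySummary:
    """Transcripts with enough coverage for modification detection."""

    n_eligible: int
    n_total: int

    @property
    def percent(self) -> float:
        if self.n_total == 0:
            return 0.0
        return 100.0 * self.n_eligible / self.n_total


def eligibility_summary(
    readcounts: pd.Series, cfg: PipelineConfig | None = None
) -> EligibilitySummary:
    """How many transcripts clear the detection floor (count > 15)."""
    if cfg is None:
        cfg = PipelineConfig()
    counts = pd.Series(readcounts, dtype=float)
    return EligibilitySummary(
        n_eligible=int((counts > cfg.min_avg_readcount).sum()),
        n_total=len(counts),
    )


def run_pipeline(
    indir: str | Path,
    outdir: str | Path,
    cfg: PipelineConfig | None = None,
    sexes: Sequence[str] = SEXES,
    make_plots: bool = False,
) -> dict:
    """Execute the full workflow on a study directory and write outputs.

    Expects the naming convention of ``simulate.write_study``
    (transcripts.fa, regions.tsv, counts.tsv, known_sites.bed,
    de_results.tsv, xpore_{sex}.tsv, nanocompore_{sex}.tsv).  Per sex it
    writes called sites (BED6+), region summary, metagene profile,
    motif enrichment, consensus matrix and known-overlap tables, then a
    cross-sex comparison and a summary.json mirroring the workflow
    funnel.  Any stage failure aborts with the stage name and cause.
    """
    if cfg is None:
        cfg = PipelineConfig()
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "load inputs"
    try:
        transcripts = mio.read_transcripts(
            indir / "transcripts.fa", indir / "regions.tsv"
        )
        counts = mio.read_counts(indir / "counts.tsv")
        known = mio.read_bed(indir / "known_sites.bed")
        de = mio.read_de_table(indir / "de_results.tsv")
        gene_map = {t.transcript_id: t.gene_id for t in transcripts.values()}
        eligible = set(counts.index[counts > cfg.min_avg_readcount]) & set(
            transcripts
        )

        summary: dict = {"config": dataclasses.asdict(cfg), "per_sex": {}}
        sites_by_sex: dict[str, list[ModSite]] = {}
        for sex in sexes:
            stage = f"consensus calling ({sex})"
            xp = mio.read_xpore_table(indir / f"xpore_{sex}.tsv")
            nc = mio.read_nanocompore_table(indir / f"nanocompore_{sex}.tsv")
            sites, funnel = call_sites(xp, nc, counts, cfg)
            sites_by_sex[sex] = sites
            mio.write_sites_bed(outdir / f"sites_{sex}.bed", sites)

            stage = f"region characterization ({sex})"
            assignments = assign_regions(sites, transcripts)
            rsum = region_summary(assignments, transcripts, eligible)
            rsum.to_csv(
                outdir / f"region_summary_{sex}.tsv", sep="\t", index=False
            )
            profile = metagene_profile(assignments, cfg.metagene_bins)
            profile.to_frame().to_csv(
                outdir / f"metagene_{sex}.tsv", sep="\t", index=False
            )

            stage = f"motif enrichment ({sex})"
            enr_rows = []
            if sites:
                rng = np.random.default_rng(cfg.seed)
                backgrounds = sample_backgrounds(
                    sites, transcripts, cfg, rng, eligible
                )
                for motif in (DRACH, CONTROL_MOTIF):
                    enr_rows.append(
                        enrichment(sites, backgrounds, transcripts, motif)
                    )
                per_kmer_breakdown(sites).to_csv(
                    outdir / f"site_kmers_{sex}.tsv", sep="\t", index=False
                )
            enr = enrichment_table(enr_rows)
            enr.to_csv(outdir / f"enrichment_{sex}.tsv", sep="\t", index=False)

            stage = f"known-site intersection ({sex})"
            overlap = intersect_known(sites, known)
            overlap.per_site.to_csv(
                outdir / f"known_overlap_{sex}.tsv", sep="\t", index=False
            )
            type_breakdown(overlap).to_csv(
                outdir / f"known_types_{sex}.tsv", sep="\t", index=False
            )
            m6a_sites = [
                s
                for s, row in zip(sites, overlap.per_site.itertuples())
                if row.overlaps and "m6A" in row.mod_types.split(";")
            ]
            cmat = consensus_matrix(m6a_sites, transcripts, cfg.flank_logo)
            cmat.to_frame().to_csv(
                outdir / f"consensus_matrix_{sex}.tsv", sep="\t", index=False
            )

            funnel["known_overlap"] = overlap.n_overlapping
            summary["per_sex"][sex] = {
                "funnel": funnel,
                "region_counts": dict(
                    zip(rsum["region"], rsum["n_sites"].astype(int))
                ),
                "drach_ratio": (
                    float(enr_rows[0].ratio) if enr_rows else None
                ),
                "control_motif_ratio": (
                    float(enr_rows[1].ratio) if enr_rows else None
                ),
                "n_known_m6a": len(m6a_sites),
            }
            if make_plots:
                stage = f"plots ({sex})"
                from . import plots

                plots.metagene_plot(
                    profile, outdir / f"metagene_{sex}.png", title=sex
                )
                plots.logo_plot(
                    cmat, outdir / f"consensus_logo_{sex}.png", title=sex
                )

        stage = "cross-sex comparison"
        if set(("male", "female")) <= set(sexes):
            comp = sex_overlap(
                sites_by_sex["male"], sites_by_sex["female"], gene_map, cfg
            )
            summary["sex_comparison"] = {
                **dataclasses.asdict(comp),
                "mean_sites_per_gene": (
                    round(comp.mean_sites_per_gene, 2)
                    if comp.genes_shared
                    else None
                ),
            }

        stage = "DE overlap"
        summary["de_overlap"] = {}
        for sex in sexes:
            ov = de_overlap(sites_by_sex[sex], de, gene_map, cfg)
            summary["de_overlap"][sex] = {
                **dataclasses.asdict(ov),
                "percent": round(ov.percent, 2),
            }

        stage = "rate summary"
        nonempty = {s: v for s, v in sites_by_sex.items() if v}
        if nonempty:
            rf = rate_fold_summary(nonempty)
            summary["rates"] = {
                "mean_stress": {k: round(v, 3) for k, v in rf.mean_stress.items()},
                "mean_control": {
                    k: round(v, 3) for k, v in rf.mean_control.items()
                },
                "fold_per_sex": {
                    s: round(rf.fold(s), 3) for s in rf.mean_stress
                },
                "mean_fold": (
                    round(rf.mean_fold, 1) if rf.mean_fold is not None else None
                ),
            }
        elig = eligibility_summary(counts, cfg)
        summary["eligibility"] = {
            "n_eligible": elig.n_eligible,
            "n_total": elig.n_total,
            "percent": round(elig.percent, 1),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage: {stage}") from exc

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary
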