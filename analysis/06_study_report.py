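#!/usr/bin/env python
"""Study-level summary: sex sharing, DE overlap, rates, eligibility.

Matches sites across sexes (greedy nearest-neighbor within 10 nt),
measures how many sites fall in differentially expressed genes
(|FC - 1| > 20%, FDR < 0.05), summarizes stress/control modification
rates and the transcript eligibility rate, and writes report.json.
"""

import dataclasses
import json
from pathlib import Path

from modcall import io as mio
from modcall.models import PipelineConfig
from modcall.report import (
    de_overlap,
    eligibility_summary,
    rate_fold_summary,
    sex_overlap,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    study_dir = RESULTS / "study"
    cfg = PipelineConfig()
    regions = mio.read_region_table(study_dir / "regions.tsv")
    gene_map = dict(zip(regions["transcript_id"], regions["gene_id"]))
    counts = mio.read_counts(study_dir / "counts.tsv")
    de = mio.read_de_table(study_dir / "de_results.tsv")
    sites = {
        sex: mio.read_sites_bed(RESULTS / f"sites_{sex}.bed")
        for sex in ("male", "female")
    }

    comp = sex_overlap(sites["male"], sites["female"], gene_map, cfg)
    rf = rate_fold_summary(sites)
    elig = eligibility_summary(counts, cfg)
    out = {
        "sex_comparison": {
            **dataclasses.asdict(comp),
            "mean_sites_per_gene": round(comp.mean_sites_per_gene, 2),
        },
        "de_overlap": {},
        "rates": {
            "mean_stress": {k: round(v, 3) for k, v in rf.mean_stress.items()},
            "mean_control": {k: round(v, 3) for k, v in rf.mean_control.items()},
            "mean_fold": round(rf.mean_fold, 2),
        },
        "eligibility": {
            "n_eligible": elig.n_eligible,
            "n_total": elig.n_total,
            "percent": round(elig.percent, 1),
        },
    }
    for sex in ("male", "female"):
        ov = de_overlap(sites[sex], de, gene_map, cfg)
        out["de_overlap"][sex] = {
            **dataclasses.asdict(ov),
            "percent": round(ov.percent, 2),
        }
        print(
            f"{sex}: {ov.n_sites_in_de_genes}/{ov.n_sites_total} sites "
            f"({ov.percent:.2f}%) in {ov.n_de_genes_hit} DE genes"
        )
    print(
        f"shared: {comp.shared} sites in {comp.genes_shared} genes "
        f"({comp.mean_sites_per_gene:.2f} sites/gene); "
        f"rate fold {rf.mean_fold:.2f}; "
        f"eligible {elig.n_eligible}/{elig.n_total} ({elig.percent:.1f}%)"
    )
    (RESULTS / "report.json").write_text(json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    main()
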