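#!/usr/bin/env python
"""Call high-confidence consensus modification sites per sex.

Applies the eligibility filter (average read count > 15), each
detector's significance filter (all three nanocompore-like tests below
alpha = 0.01; xpore-like p < 0.01 with stress > control), retains only
cross-tool-supported candidates within 10 nt, collapses survivors into
unique sites, and benchmarks the calls against the planted truth.
"""

import json
from pathlib import Path

import pandas as pd

from modcall import io as mio
from modcall.benchmark import evaluate_calls
from modcall.consensus import call_sites
from modcall.models import PipelineConfig
from modcall.simulate import TruthSite

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 2024


def main() -> None:
    study_dir = RESULTS / "study"
    cfg = PipelineConfig(seed=SEED)
    counts = mio.read_counts(study_dir / "counts.tsv")
    funnel_all = {}
    for sex in ("male", "female"):
        sites, funnel = call_sites(
            mio.read_xpore_table(study_dir / f"xpore_{sex}.tsv"),
            mio.read_nanocompore_table(study_dir / f"nanocompore_{sex}.tsv"),
            counts,
            cfg,
        )
        mio.write_sites_bed(RESULTS / f"sites_{sex}.bed", sites)
        truth = [
            TruthSite(**r)
            for r in pd.read_csv(
                study_dir / f"truth_{sex}.tsv", sep="\t"
            ).to_dict("records")
        ]
        bench = evaluate_calls(sites, truth, cfg.collapse_window)
        funnel["precision"] = round(bench.precision, 3)
        funnel["recall"] = round(bench.recall, 3)
        funnel_all[sex] = funnel
        print(
            f"{sex}: {funnel['collapsed_sites']} sites "
            f"(precision {bench.precision:.3f}, recall {bench.recall:.3f})"
        )
    (RESULTS / "funnel.json").write_text(json.dumps(funnel_all, indent=2) + "\n")


if __name__ == "__main__":
    main()
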