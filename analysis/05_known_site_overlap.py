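#!/usr/bin/env python
"""Cross-check called sites against the known-modification catalog.

Intersects per-sex site calls with the (transcript-space) known-mod
BED, tabulates overlaps by modification type, and builds the base
consensus matrix around known-m6A-overlapping sites — which should
reproduce the DRACH consensus, C invariant at k-mer position 4.
"""

from pathlib import Path

from modcall import io as mio
from modcall.known import intersect_known, type_breakdown
from modcall.models import PipelineConfig
from modcall.motif import consensus_matrix
from modcall.plots import logo_plot

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    study_dir = RESULTS / "study"
    cfg = PipelineConfig()
    transcripts = mio.read_transcripts(
        study_dir / "transcripts.fa", study_dir / "regions.tsv"
    )
    known = mio.read_bed(study_dir / "known_sites.bed")
    for sex in ("male", "female"):
        sites = mio.read_sites_bed(RESULTS / f"sites_{sex}.bed")
        report = intersect_known(sites, known)
        report.per_site.to_csv(
            RESULTS / f"known_overlap_{sex}.tsv", sep="\t", index=False
        )
        type_breakdown(report).to_csv(
            RESULTS / f"known_types_{sex}.tsv", sep="\t", index=False
        )
        m6a = [
            s
            for s, row in zip(sites, report.per_site.itertuples())
            if row.overlaps and "m6A" in row.mod_types.split(";")
        ]
        mat = consensus_matrix(m6a, transcripts, cfg.flank_logo)
        mat.to_frame().to_csv(
            RESULTS / f"consensus_matrix_{sex}.tsv", sep="\t", index=False
        )
        logo_plot(mat, RESULTS / f"consensus_logo_{sex}.png", title=sex)
        c_freq = mat.frequencies[cfg.flank_logo + 3, "ACGU".index("C")]
        print(
            f"{sex}: {report.n_overlapping}/{len(sites)} sites overlap known "
            f"records ({len(m6a)} m6A); C at k-mer position 4: {c_freq:.0%}"
        )


if __name__ == "__main__":
    main()
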