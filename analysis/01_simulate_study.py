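#!/usr/bin/env python
"""Simulate the synthetic two-sex study used by the downstream analyses.

Generates a 60-transcript toy transcriptome with 400 planted
differentially modified sites per sex (20% shared), emits the two
detector candidate tables per sex plus the ancillary inputs
(known-modification BED, DE table, read counts) and writes everything
under results/study/.
"""

from pathlib import Path

from modcall.simulate import SimParams, simulate_study, write_study

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 2024


def main() -> None:
    params = SimParams(seed=SEED)
    study = simulate_study(params)
    paths = write_study(study, RESULTS / "study")
    for sex in ("male", "female"):
        print(
            f"{sex}: {len(study.truth[sex])} truth sites, "
            f"{len(study.xpore[sex])} xpore-like and "
            f"{len(study.nanocompore[sex])} nanocompore-like candidates"
        )
    print(f"wrote {len(paths)} files to {RESULTS / 'study'}")


if __name__ == "__main__":
    main()
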