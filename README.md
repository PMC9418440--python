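# modcall

Consensus calling and characterization of **differential RNA-modification
sites** from nanopore direct RNA-seq (dRNA-seq) detector outputs.

## The problem

Signal-level detectors for dRNA-seq (e.g. an Xpore-style Gaussian-mixture
rate model, or a Nanocompore-style intensity/dwell comparison) report
per-position candidate modification differences between two conditions —
but each tool alone is noisy, and their statistical machinery differs.
A standard way to build a trustworthy catalog is to demand *concordance*:
keep only candidates that pass each detector's own significance filter
**and** are corroborated by the other detector nearby, then collapse the
survivors into unique sites.  `modcall` implements that consensus
workflow for a stress-vs-control, two-sex study design, plus the
downstream characterization used to validate such a catalog:

* **consensus calling** — per-tool filters (all three nanocompore-like
  test p-values < α = 0.01; xpore-like t-test p < 0.01 with
  stress-ward rate shift), transcript eligibility (average read count
  > 15), cross-tool retention within 10 nt, and single-linkage
  collapsing of candidates ≤ 10 nt apart into `ModSite`s;
* **region analysis** — 5′UTR/CDS/3′UTR assignment by interval midpoint,
  per-region counts and per-nucleotide densities, 20-bin-per-region
  metagene profiles;
* **motif analysis** — DRACH (D=A/G/U, R=A/G, A, C, H=A/C/U; 18 k-mers)
  enrichment against 10 region-matched random background site sets, an
  equal-degeneracy control motif (HCARD), and the base consensus matrix
  around known-m6A-overlapping sites;
* **known-site intersection** — strict half-open interval overlap with a
  transcript-space known-modification BED (RMBase-style), typed counts;
* **study report** — cross-sex shared/specific sites (greedy
  nearest-neighbor within 10 nt), overlap with differential-expression
  results (|FC − 1| > 20 %, FDR < 0.05), modification-rate folds,
  eligibility summary;
* **synthetic benchmark** — a generator that emulates every input with
  planted ground truth (stress rate ≈ 0.48 vs control ≈ 0.27,
  80 % DRACH-context sites, 3′UTR-biased placement peaking near the CDS
  boundary, per-tool false candidates), so the whole workflow is
  testable end to end without any sequencing data.

All coordinates are transcript-local, 0-based, half-open; a candidate's
`position` is the first base of its 5-mer; RNA alphabet (T→U on ingest).

## Worked example

```sh
python analysis/01_simulate_study.py
python analysis/02_call_consensus_sites.py
python analysis/03_region_distribution.py
python analysis/04_motif_enrichment.py
python analysis/05_known_site_overlap.py
python analysis/06_study_report.py
```

Output from a run of the first two steps:

```
male: 400 truth sites, 492 xpore-like and 496 nanocompore-like candidates
female: 400 truth sites, 500 xpore-like and 503 nanocompore-like candidates
male: 367 sites (precision 1.000, recall 0.935)
female: 377 sites (precision 1.000, recall 0.953)
```

i.e. of 400 planted sites per sex, the consensus funnel recovers ~94 %
with no false calls — false candidates pass single-tool filters but
almost never find cross-tool support within 10 nt.  The later steps
print the characterization, e.g.:

```
male: densities per nt 5utr=1.12e-02, cds=1.78e-03, 3utr=6.76e-03
male: DRACH 0.80 observed vs 0.0243 background (ratio 33.1); control motif ratio 0.00
male: 49/367 sites overlap known records (49 m6A); C at k-mer position 4: 100%
shared: 75 sites in 43 genes (1.74 sites/gene); rate fold 1.82; eligible 56/60 (93.3%)
```

Most sites land in 3′UTRs while the short 5′UTRs carry the highest
per-nucleotide density; site k-mers are strongly DRACH-enriched over
region-matched backgrounds while a control motif is not; and calls
overlapping the known-m6A catalog reproduce the DRACH consensus
(invariant C at k-mer position 4).

The same workflow is scriptable via the `modcall` CLI
(`simulate`, `call`, `annotate`, `enrich`, `intersect`, `run-all`), e.g.

```sh
modcall call --xpore X.tsv --nanocompore N.tsv --counts C.tsv \
    --window 10 --alpha 0.01 --p-xpore 0.01 -o sites.bed
```

File formats (all TSV single-header; BED6+ for sites) are documented in
`src/modcall/io.py`.

## Layout

```
src/modcall/     library (simulate, consensus, regions, motif, known,
                 report, benchmark, datasets, io, plots, cli)
analysis/        numbered narrative drivers writing under results/
tests/           pytest suite (unit, property and end-to-end checks)
docs/methods.md  models, assumptions, parameter choices, limitations
```
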