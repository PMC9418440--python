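# Methods

## The consensus model

Two signal-level detectors examine the same dRNA-seq libraries per
condition comparison and report per-position evidence of differential
modification:

* an **xpore-like** table: per (transcript, position) the estimated
  modification rate in each condition (fraction of molecules modified,
  from a two-Gaussian current-intensity mixture) and a t-test p-value
  for the rate difference;
* a **nanocompore-like** table: three test p-values per position
  (a GMM/logit comparison, a KS test on current intensity, a KS test
  on dwell time).

The caller treats each detector's statistics as given (it never
recomputes them) and applies, in order:

1. **Eligibility** — drop candidates on transcripts whose average read
   count is ≤ 15; below that coverage the detectors cannot call
   modifications reliably, so such transcripts are undetectable rather
   than unmodified.  Applied before the significance filters so the
   funnel counts refer to detectable transcripts.
2. **Per-tool significance** — xpore-like: p < 0.01 *and*
   rate_stress > rate_control (the workflow targets stress-ward
   modification gains); nanocompore-like: max of the three p-values
   < 0.01, i.e. all three tests must agree.  Strict inequalities at
   both thresholds.
3. **Cross-tool retention** — a candidate survives iff the other tool
   has a filtered candidate on the same transcript within 10 nt
   (|Δ position| ≤ 10).
4. **Collapsing** — surviving candidates from both tools are pooled,
   sorted by (transcript, position, tool), and merged single-linkage: a
   gap > 10 nt starts a new cluster.  Each cluster becomes one
   `ModSite` spanning [min position, max position + 5).  Chaining can
   produce clusters wider than the window; that is the intended
   consequence of pairwise collapsing, not a bug.

Matching precedes collapsing (retain both-tool candidates, then merge).
The alternate order gives different results; this order is fixed and
tested.  Each site's representative rates and k-mer come from the
supporting xpore-like candidate with the largest rate differential — a
deterministic, direction-consistent summary; `best_p_nanocompore` is
the minimum over supporters of each supporter's *worst* test p-value,
mirroring the all-three-tests rule.  Sorting ties break by
(transcript id, position, tool name) for reproducibility.

### Degenerate cases

Empty candidate tables, transcripts missing from the read-count table
(treated as count 0, warned), and p-values outside (0, 1] (invalid
detector output; row dropped with a warning) are all handled
explicitly.  Collapsing the midpoints of an already-collapsed catalog
changes nothing (idempotence), and widening the window can only reduce
the site count (monotonicity); both are property-tested against a
brute-force transitive-closure oracle.

## Downstream characterization

**Regions.**  Transcripts carry a 5′UTR | CDS | 3′UTR architecture in
0-based half-open coordinates; a boundary base belongs to the
downstream region.  A collapsed interval may straddle a boundary, so
sites are assigned by the integer midpoint `floor((start + end − 1)/2)`
— deterministic and symmetric.  Per-nucleotide densities divide region
site counts by the summed region length over *eligible* transcripts
only; including undetectable transcripts would deflate every density.
Metagene profiles histogram the midpoint's region-relative position
(rel_pos ∈ [0, 1)) into 20 bins per region and normalize the 60-bin
vector to unit mass; pooled histogramming is the default, with
per-transcript averaging available via a flag (the two conventions
weigh sites vs transcripts differently).

**Motif enrichment.**  The DRACH motif (18 concrete 5-mers) is matched
against each site's representative k-mer (per-site any-match; a
per-k-mer breakdown table is also emitted).  Backgrounds are 10
independent sets of random positions with the same per-region
composition as the sites, drawn uniformly from regions of eligible
transcripts, excluding any 5-mer within 10 nt of a called site.  The
enrichment ratio is observed frequency over the mean background
frequency; the empirical p from 10 backgrounds has resolution 0.1 and
is reported as descriptive, not as a calibrated test.  The control
motif is fixed to HCARD: the reversed pattern, with equal degeneracy
(18 k-mers) and an expansion disjoint from DRACH, chosen
deterministically rather than per-seed so results are comparable across
runs.  Note a structural consequence of disjointness: if a fraction *f*
of site k-mers is genuinely DRACH, any DRACH-disjoint motif is observed
at sites at only (1 − *f*) times its background rate.  With the
benchmark's *f* = 0.8 the control-motif ratio is therefore expected
near 0.2 — depleted, which like a ratio near 1 is evidence of *no
enrichment*; the unit tests pin this derived value.

**Known-modification intersection.**  The known catalog is consumed as
a transcript-space BED6 (name column = modification type).  Genomic
coordinates are *not* lifted over; projecting a genome-space catalog
onto transcripts is the caller's responsibility and out of scope here.
Overlap is strict half-open interval intersection via an interval tree
(oracle-checked against all-pairs), with an optional `--slop` pad
(default 0).  A site matching several records counts once per distinct
modification type.  The consensus matrix tallies bases over
`sequence[kstart − flank : kstart + 5 + flank]` anchored at each
known-m6A-overlapping site's representative k-mer start (flank 5 nt);
windows truncated by transcript ends are dropped.

**Study report.**  Cross-sex sharing matches site midpoints on the same
transcript greedily, closest pair first, distance ties broken toward
the 5′-most partner, each site used at most once; "shared per gene"
divides shared-pair count by distinct genes carrying shared pairs.
DE overlap flags genes with |FC − 1| > 0.20 and FDR < 0.05 (linear
fold-change; log2 input converted on ingest) and reports the fraction
of sites harbored in such genes.  Transcript→gene mapping comes from
the region table; isoforms of one gene pool their sites without
deduplication.  The run orchestrator chains all stages per sex and
writes a summary JSON whose funnel counts (per-tool pass → cross-tool
retained → collapsed → known-overlap) are monotone non-increasing.

## The synthetic benchmark

The generator emulates the statistical structure the analysis assumes,
with planted ground truth, so every stage is testable without
sequencing data.  Defaults (one `SimParams` object; a fixed seed makes
all outputs byte-identical across reruns):

| parameter | default | rationale |
| --- | --- | --- |
| transcripts | 60 | enough region diversity at desk scale |
| truth sites per sex | 400 | tight precision/recall and rate estimates |
| region lengths (5′UTR, CDS, 3′UTR) | U(50–200), U(300–1500), U(200–800) nt | short 5′UTRs, long CDS, mid 3′UTRs |
| mean rate stress/control | 0.48 / 0.27 (sd 0.08, clipped to [0, 1], redrawn until stress > control) | the condition contrast the caller targets |
| DRACH fraction at truth sites | 0.8 | strongly m6A-flavored catalog |
| region weights (5′, CDS, 3′) | 0.2 / 0.2 / 0.6 | most sites 3′UTR, yet highest per-nt density in the short 5′UTRs |
| 3′UTR placement | offset ~ Beta(1, 3) × length | pile-up near the CDS boundary |
| min spacing between truth sites | 11 nt | planted sites map ~1:1 onto collapsed calls |
| cross-tool positional jitter | 0–2 nt (nanocompore-like row) | detectors disagree slightly on position |
| false candidates | 0.001/nt per tool, half passing single-tool filters | realistic per-tool noise that rarely co-occurs |
| low-coverage transcripts | 10 % below count 15 | exercises the eligibility gate |
| shared fraction between sexes | 0.2 | a minority of sites common to both sexes |
| known-catalog coverage | 15 % of DRACH-context truth sites + 2× decoys | m6A databases operate in DRACH context |
| DE genes | 5 % of modified and 5 % of other genes | sparse DE/modification overlap |

Passing p-values are drawn log-uniform on [10⁻⁶, threshold), failing
ones log-uniform on [threshold, 1), spanning orders of magnitude like
real detector output.  The xpore-like row sits at the exact planted
position with the planted rates; sequence edits (DRACH planting)
happen once on a pooled site set before the sexes are partitioned, so
both sexes see one consistent transcriptome.

**What the generator does not emulate** — and hence what green tests do
*not* establish about real data: no raw current signal or per-read
events; independent (not position-correlated) false candidates; exact
per-site detector concordance beyond the modeled 0–2 nt jitter; no
isoform structure (one transcript per gene); uniform background
sequence rather than real transcriptome composition; detector p-values
are sampled, not computed from signal, so calibration of the upstream
statistics is untested by construction.

## Benchmarking convention

A call matches a truth site when the gap between the call interval and
the truth 5-mer interval is ≤ 10 nt, many-to-many: with 11 nt minimum
truth spacing and 0–2 nt jitter, two truth sites can occasionally chain
into one cluster, and many-to-many matching keeps precision and recall
well-defined in that case.  At default conditions the caller measures
precision ≈ 1.0 and recall ≈ 0.94 (recall is bounded by the ~10 % of
truth sites placed on low-coverage, ineligible transcripts).

## Numerical and interface choices

* Thresholds are strict (`p < 0.01`, `count > 15`); boundary values
  fail.
* Cross-tool distance and collapsing both use ≤ 10 nt, one
  configurable `collapse_window`.
* Site scores in BED output are −log10 of the best xpore-like p-value,
  capped at 300.
* The sequence-logo figure is drawn directly from the consensus
  frequency matrix with scaled letters (a visualization of frequencies,
  not information content).
* Quantities quoted at fixed decimals in summaries follow the source
  printing convention of the values they are compared against
  (truncation for sites/gene and overlap percentages).

## Problem sizes

Analyses and tests run the benchmark at 20–100 transcripts and
60–600 truth sites, and calibration checks pool 20 seeded replicates;
these sizes give stable estimates (binomial SEs well inside the asserted
tolerances) while keeping any run to minutes on one CPU.

## Known limitations

* Detector output dialects are normalized via a user-supplied column
  mapping; exotic headers require that mapping.
* The empirical enrichment p-value from 10 backgrounds is coarse by
  design.
* No genome↔transcript coordinate conversion anywhere; all inputs must
  share the transcript coordinate space.
* `best_p_*` summaries are minima over supporters and are not corrected
  for cluster size.
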