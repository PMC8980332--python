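# Methods

## Motif model and scanning

A TF binding profile is a 4 × L position frequency matrix (PFM) of base
counts. The position weight matrix (PWM) entry for base *b* at column
*j* is

```
pwm[b, j] = log2( (pfm[b, j] + p·bg[b]) / (colsum_j + p) / bg[b] )
```

with pseudocount *p* = 1.0 distributed by the background frequencies and
a uniform background bg = 0.25 by default (both configurable). A
window's **raw score** is the per-column PWM sum; the **relative score**
rescales it to [0, 1] between the matrix's minimum and maximum
attainable scores, so 1.0 marks an exact consensus match. Scanning
slides every motif over both strands (minus-strand windows are scored on
the reverse complement, reported at forward coordinates, 0-based
half-open) and keeps windows with relative score ≥ 0.80, the common
web-scanner default for nominating candidate sites.

Numerical choices worth knowing:

- Score bounds and window scores are accumulated **sequentially
  left-to-right over motif columns**, so a consensus window attains
  `score_max` bit-exactly and an anti-consensus window attains
  `score_min` bit-exactly; the scanner's output is reproducible by a
  naive per-window enumeration down to the last bit (the test suite
  asserts exactly this).
- An `N` base contributes the column minimum, so ambiguous sequence can
  lose hits but never gain them.
- Tie order in output is fixed as (start, motif_id, strand).

## TFBS density and the activity classifier

For each candidate CRM, hits at relative score ≥ 0.80 are split by raw
score into a lenient set (score > 10) and a strict set (score > 11).
Within each set, hits whose start lies within 5 bp (inclusive) of the
cluster's first hit collapse into one "TFBS count" — anchor-based
greedy clustering, pooled across motifs and strands, which makes the
count independent of input order. Neighbour-based chaining (distance to
the previous hit) is available via configuration. Densities are counts
per 100 bp of the **full** candidate length.

Long tandem repeats can carry spurious dense motif matches. Repeats
with unit ≤ 6 bp, ≥ 3 full copies and span ≥ 12 bp (covering both a
CTCCCT-type hexamer repeat and (AC)n microsatellites) are detected
automatically as maximal intervals; hits **fully contained** in a
repeat interval are dropped (partially overlapping hits are kept —
conservative), while the density denominator keeps the full length.
A user-supplied mask can override the detector.

Classification: a candidate with density > 1.7 per 100 bp in the
lenient set **and** > 1 per 100 bp in the strict set lies in quadrant A2
and is predicted active. Both inequalities are strict — a point on a
cut line is not above it. The quadrant labels besides A2 are a fixed
but arbitrary convention here (A1: above the strict-set cut only,
A3: above the lenient-set cut only, A4: below both). An OR combine rule
is selectable.

## Peak nomination

Coverage is read from bedGraph or wiggle (fixedStep/variableStep) text
into dense per-base arrays; gaps read as zero. The search region for a
gene runs from the end of the nearest upstream gene body to the start of
the nearest downstream gene body, **including** the gene's own body —
intragenic non-exonic peaks are eligible (active modules are known to
sit in introns of unrelated genes). With no neighbour the region
extends to the chromosome edge; an overlapping neighbour clips that side
to zero extension with a warning.

A peak is called at each local maximum with tip value ≥ 20 (plateau
summits report their leftmost position); its borders are the outermost
contiguous positions with signal still ≥ 20% of the tip (closed on the
≥ side, half-open interval emitted). Overlapping extents from distinct
maxima merge into one peak, keeping the higher tip. Peaks sharing ≥ 1 bp
with any exon of any gene are removed. Surviving peaks become candidates
named `<gene>_<ordinal>` with their extracted sequences.

BigWig input is out of scope: the reader handles the text dialects
(bedGraph, wiggle); binary tracks should be converted upstream.

## Marker genes and the TF panel

Cells with < 20% mitochondrial reads **and** > 900 detected genes are
kept; both bounds are strict, so a cell at exactly 900 genes or exactly
20% mito is removed. Counts are normalised per cell to
`ln(1 + count/total × 10,000)` (scale factor configurable).

For a target cluster, genes expressed (count > 0) in ≥ 25% of either
group are tested with a two-sided Wilcoxon rank-sum test on the
log-normalised values. The test is **exact** — a tie-aware dynamic
program over the permutation distribution of the rank sum — up to a
combined sample size of 50, and the normal approximation with tie and
continuity corrections (scipy) above that. The log2 fold change is the
log-ratio of mean **depth-normalised (linear-scale)** expression with an
ε = 1e-9 guard: on this scale a gene whose underlying mean is k-fold
higher reports log2FC ≈ log2(k), which is the behaviour the marker
filter (log2FC > 2) presumes; computing the ratio on log-transformed
values instead would compress a 16-fold effect to roughly log2FC 2 and
make the filter unusable. Genes pass with log2FC > 2 and p < 0.05; no
multiple-testing correction enters the pass flag (a Benjamini–Hochberg
column is emitted for reference). Passing markers intersected with a TF
gene list, in marker order, form the TF panel used for scanning.

Clustering itself is out of scope; cluster labels are an input.

## Stitched CRM design

Peaks from several stage tracks are unioned (overlaps merged, higher tip
kept, provenance labels concatenated). Candidates sharing ≥ 1 bp
(configurable) with any other-tissue peak are rejected; exonic peaks are
excluded with the same rule as above — the two filters are independent
interval-overlap removals and commute. Survivors are concatenated on
the forward strand in ascending genomic start order (no spacer by
default; an optional spacer flag exists but breaks the
length-conservation identity). The budget check is
`stitched + cargo + overhead ≤ 4,700 bp`; overhead (ITRs, promoter,
polyA) defaults to 0 and should be supplied by the user.

## Synthetic data: what it emulates and what it does not

The generator produces every pipeline input with known ground truth, in
the same coordinate conventions the analysis consumes:

- **Motif-planted sequences**: i.i.d. background at a chosen GC content
  with consensus sites written at stated positions/strands. Synthetic
  profiles put `sharpness × 100` counts on the consensus base per column.
- **Coverage tracks**: analytic triangular/Gaussian/plateau shapes on a
  zero baseline, with closed-form 20%-of-tip boundary truth and optional
  Gaussian noise. In the demo presets the half-widths are chosen so the
  boundary position clears the cut with a margin far above float
  round-off (e.g. triangular half-widths where 0.8·hw is non-integer),
  keeping noise-free recovery exactly testable.
- **Count matrices**: negative-binomial counts (var = µ + αµ², default
  µ = 8, α = 0.5) for 100 target + 300 rest cells over 1,000 genes, so a
  synthetic cell carries a few thousand counts and ~96% detected genes —
  comfortably the regime the > 900-genes QC gate expects of a real cell.
  Planted markers multiply their cluster mean by a stated fold (16× by
  default); mito genes and deliberate QC violators (high-mito,
  low-complexity cells) can be injected.

A single integer seed drives per-component substreams; identical
configuration gives byte-identical files.

What passing tests on this data do **not** show: real chromatin tracks
have correlated noise, irregular peak shapes and overlapping elements;
real scRNA-seq has depth variation, doublets and batch structure; real
genomes have repeat families far beyond short tandem repeats; and real
TF binding deviates from additive PWM scoring. The tests certify the
method's mechanics and its stated decision rules, not in-vivo activity
of any particular locus.

## Default parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| relative_threshold | 0.80 | motif-scan relative-score cut |
| thr_low / thr_high | 10 / 11 | raw log-odds cuts for the two density axes |
| density_x_cut / density_y_cut | 1.7 / 1.0 | per-100-bp density cuts (strict >) |
| merge_window_bp | 5 | hit-merging window (inclusive, anchor-based) |
| tip_min / boundary_frac | 20 / 0.2 | peak tip floor and border fraction |
| log2fc_min / p_max / min_pct | 2 / 0.05 / 0.25 | marker filters |
| max_mito_frac / min_genes | 0.20 / 900 | cell QC (both strict) |
| limit_bp | 4,700 | AAV packaging limit |
| pseudocount / background | 1.0 / uniform | PWM construction |
| repeat unit / copies / span | ≤ 6 / ≥ 3 / ≥ 12 bp | tandem-repeat mask |

The raw-score cuts 10/11 are interpreted as raw log-odds scores (the
score column of the JASPAR web scanner); a relative score is bounded by
1 and cannot exceed 10. Both score columns are emitted so either
reading can be applied downstream.

## Design choices in open corners

- "Within 5 bp" merging is inclusive (≤ 5) and anchor-based; chaining
  semantics were not fully specified, and anchor-based was chosen for
  order-independence (neighbor-based is one flag away).
- Repeat correction is automatic here (it was a manual step in the
  original workflow), with the stated defaults and a mask override.
- Peaks whose extents overlap merge into one reported peak to avoid
  double-counting a single accessible region.
- Stitching uses whole called intervals, forward strand, ascending
  start; the convention is recorded in the output FASTA header and
  component table.
- The CLI covers each stage and the end-to-end prescreen with flags
  only; a config-file layer was considered and dropped as redundant
  given the small option surface.
- The acceptance script reports measured quantities (oracle agreement
  percentages, recovered densities, recall, determinism flags) rather
  than wet-lab figures, which are outside what a computational rerun
  can reproduce.

## Problem sizes

The test suite and acceptance script run on deliberately small inputs —
sequences of 0.1–24 kb, panels of 3–4 motifs, 400–410 cells, 50
simulated loci — chosen as the smallest sizes at which every decision
rule (thresholds, boundaries, merges, budgets) is exercised with
non-trivial margins. The full suite completes in well under a minute.

## Known limitations

- PWM scoring is additive and unweighted across the TF panel; weighting
  sites by TF affinity or activity would likely sharpen the prescreen
  but is intentionally not done here.
- No p-value calibration of motif scores, no higher-order background
  models, no motif discovery.
- The classifier's cuts were established on one glial cell type in
  retina; applying them to other cell types is an extrapolation.
- Stitched constructs can include silencers or lose specificity in
  vivo; the designer checks geometry and budget, not function.
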