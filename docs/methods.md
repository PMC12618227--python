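# Methods

This note documents the models, assumptions and numerical choices behind each
pipeline stage, what the synthetic generators do and do not emulate, and the
known limitations. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Amplicon filtration

### Model

A low-biomass specimen's ASV table is treated as a mixture of (i) reagent and
environmental contamination, shared across controls and specimens at high
pooled abundance and prevalence; (ii) batch-linked artifacts confined to one
sequencing batch; (iii) well-to-well leakage from neighboring plate
positions; and (iv) sparse genuine taxa absent from controls. The five
ordered filters each target one mode; removal means zeroing counts so the
matrix shape (and the audit trail) is preserved, with fully-zeroed ASVs
pruned only at write-out.

### Changepoint-derived thresholds

Both data-driven cutoffs come from a descending curve over the pooled
controls: per-ASV pooled proportion (step 1) and per-genus prevalence
(step 2). The changepoint is the single split minimizing the two-segment
within-segment sum of squares — equivalent to an exhaustive split search and
therefore directly checkable against a brute-force oracle. Two choices are
worth making explicit:

* **Returned value.** The cutoff is the midpoint between the last value of
  the upper segment and the first value of the lower segment. The split
  *index* alone does not define a usable threshold; the midpoint is the only
  value guaranteed to lie strictly between the two regime levels whenever a
  break exists.
* **Detectability gate.** A split is accepted only when the two segment
  means differ by ≥ 4×. Any *sorted* noise sample produces a smoothly
  decreasing curve on which a least-squares split always "improves" the fit;
  the gate distinguishes a genuine regime break (ratios in the planted and
  realistic cases are 10–200×) from sorted-noise curvature. When no split
  passes, the shipped fallbacks fire (0.045 % proportion, 8.3 % prevalence)
  and the report records that they did.

### Reference sets and conventions

* Step-1 pooled proportions are computed over specimens; controls enter only
  the threshold derivation. Proportions use each sample's *original* library
  total (carried on the table as `library_totals`), not the post-removal row
  sum — this is what makes the whole pipeline idempotent: zeroing a dominant
  contaminant must not renormalize the survivors across the cutoff.
* Step-2 prevalence is derived on controls and applied to all samples
  (controls + specimens); detection is ≥ 1 read (configurable).
* ASVs lacking a genus assignment form per-ASV singleton genera, so
  genus-level rules degrade gracefully to ASV-level ones.
* Step 4 is a transparent surrogate for probabilistic source tracking:
  within a batch, an ASV leaves a specimen when an adjacent control well
  (Chebyshev ≤ 1, diagonals included) carries it at ≥ relative abundance.
  The step takes any callable with the same contract, so an external tool
  can replace the surrogate without touching the pipeline.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `proportion_cutoff` fallback | 0.045 % | step-1 cutoff when no changepoint |
| `prevalence_cutoff` fallback | 8.3 % | step-2 cutoff when no changepoint |
| `min_ratio` | 4 | segment-mean ratio for changepoint acceptance |
| `detection_min` | 1 read | prevalence detection floor |

## 2. Shotgun genome selection

Reads are informative only if their top-scoring hits (bit scores tied within
a relative 1e-6 — exact equality on computed scores is brittle) name a single
species; a read split across two congeneric species is removed, per the
stricter reading of the two-species clause. Greedy set cover selects, at
each step, the genome covering the most uncovered reads, breaking ties by
summed bit score over those reads and then lexicographic accession — fully
deterministic and order-invariant. MAG-derived and assembly-anomalous
genomes are excluded before covering.

Greedy rather than exact cover: greedy is deterministic, fast, and on the
read-hit structures this pipeline actually sees (reads drawn from a handful
of source genomes, sparse spurious hits) it matches the exhaustive optimum —
the acceptance run verifies equality on 200 seeded instances with ≤ 12
genomes. On dense adversarial instances greedy can exceed the optimum; the
unit suite asserts the classical harmonic-ratio bound there.

Post-cover filters: control taxa match at species rank with genus fallback;
the short-hit filter removes assigned hits strictly below the median
assigned alignment length, *recomputed per run* (a realized value of ~139 bp
on one dataset is a statistic, not a constant; an override flag pins it when
needed); the coverage filter removes species whose pooled assigned bases
divided by the unique covered length (union of hit intervals when
coordinates exist, genome length otherwise) strictly exceeds 2. Per-sample
tables are pooled into one bulk sample before the final cover, with a
per-sample mode available.

## 3. Spatial 16S-positive cell calling

Cells with fewer than 20 total transcripts are dropped before any
computation. The background model is a single dataset-wide negative-probe
rate p = Σ negprobe / Σ total over all cells, giving b_c = p·total_c; a
mean-of-per-cell-ratios variant sits behind a config switch. The floor at
the 5th percentile of non-zero b_c prevents low-RNA cells from inflating
normalized counts. Host- and bacterial-chemistry negative probes are treated
identically.

The ROC threshold maximizes Youden's J over midpoints between consecutive
sorted unique normalized values of the pseudo-labelled subset (zero-raw
negatives, normalized > 20 positives); ties take the smallest candidate.
With near-zero negatives and > 20 positives this construction naturally
yields thresholds near 10 — the midpoint of the gap. Positivity is strict
(`norm > threshold`).

The intracellularity criterion is purely geometric: per axis, the median
bacterial coordinate must fall inside [Q1, Q3] (inclusive, linear-interpolated
quartiles) of all the cell's transcript coordinates; cells with < 4
transcripts fail with a reason code. Neighborhood labels use 2-D Euclidean
centroid distances within each FOV: positive neighborhoods within 30 µm of a
16S-positive tumor cell (precedence), candidate negative neighborhoods
within 30 µm of a negative tumor cell, exclusion for cells > 30 µm from
every tumor cell or candidate negatives within 100 µm of any positive cell.
z enters only the centrality criterion. FOV geometry is fixed at
4,256 px × 0.12 µm/px (area ≈ 260,835 µm²); extracellular density divides by
FOV area minus summed cell area, and the stage errors out if cell areas
reach the FOV area.

## 4. DSP processing

Geometric statistics replace zeros with a pseudo-count of 0.5 (configurable)
before logs; the geometric SD of a single value is 1 by convention, so a
single negative probe gives LOQ = that value. Detection is strict
(count > LOQ). The Q3 normalization target is the geometric mean of per-ROI
Q3 values — the transform's fixed point, so renormalizing is a no-op — which
follows the platform's published convention since only "Q3 normalization" is
named. Background subtraction uses the per-ROI negative-probe geometric
mean, floored at 0; 16S counts are background-*divided* instead (the
"background normalization" reading). Quartile annotation is inclusive on
both boundaries; the degenerate all-equal case resolves every ROI to `mid`
rather than simultaneously low and high. The protein path keeps targets with
SNR > 2 against the per-ROI IgG geometric mean in ≥ 10 % of ROIs.

## 5. Sequence overlap

Local alignment with match/mismatch/gap = 1/−1/−2 on either strand (the
backend is Biopython's `PairwiseAligner`; the test oracle is an independent
full-matrix Smith–Waterman). Identity is matches over aligned columns; the
95 % "overlap threshold" is read as alignment identity, with coverage
reported separately as percent length matching over the tumor sequence.
Thresholds are strict: 95.0 and 98.0 exactly do not qualify. Cross-patient
exclusion disqualifies a same-patient overlap when any other patient's
sequence of the species matches at ≥ the same identity (above the 95 %
floor). Sequences without species labels are compared against everything and
reported as `unassigned`.

## 6. Synthetic generators

Each generator is a pure function of its config + seed (single
`numpy.random.default_rng` stream, no global state) and emits a truth
sidecar sufficient to score recovery.

* **Amplicon.** Per-sample ASV weights are *absolute* library proportions
  (gamma-distributed around their class means) with the remainder of the
  library modeled as off-table reads; counts are one multinomial draw per
  sample and `library_totals` is the configured library size. Contaminants
  (2 % each) appear in every sample; genuine taxa (0.1 % each) in ~10 % of
  tumors, stratified across batches — a genuine taxon has no batch
  association, so the generator must not create one by sampling accident;
  batch artifacts in ~30 % of one batch's specimens; low-level noise ASVs
  only in controls, giving the control curves their lower regime. Plate
  wells are assigned row-major with controls interleaved so the adjacency
  surrogate has structure.
* **Spatial.** Cells are non-overlapping disks packed by rejection sampling
  (a packing error is raised when the density is infeasible); host
  transcripts and negative probes are uniform in the disk; planted bacterial
  transcripts cluster at the centroid (σ = r/8) so the central-50 % criterion
  holds by construction; extracellular bacterial transcripts are uniform
  outside every cell. Defaults: 4 FOVs × 80 cells, r = 8 µm, 100 host
  transcripts/cell, 1 % negative-probe rate, 30 planted cells with ~30
  bacterial transcripts each (normalized counts ≈ 30 ≫ the ~1-count
  background, so pseudo-positives exist and separation is comfortable),
  extracellular rate 2×10⁻⁴ /µm².
* **Shotgun.** Ten 5-kb genomes (two species per genus), reads of 120–300 bp
  from a known clean subset at 2 % substitution; ~10 % of reads engineered to
  tie across genera (planted low-informativity); flagged contaminant genomes
  alternate MAG/anomaly flags. Hits carry true coordinates so the coverage
  filter can exercise interval unions.
* **DSP.** Poisson counts around log-normal target levels (median ~100)
  over a negative-probe floor (~5), ROI depth factors, half the ROIs with an
  elevated 16S level, QC columns drawn to pass the default gates.

What passing on these generators shows — and does not. The generators
reproduce the *statistical separations* each rule exploits, not real data's
messiness: no chimeras or taxonomic misassignment, no segmentation errors or
optical crowding, disk-shaped cells, no genuine taxa shared with controls,
independent noise. Perfect recovery scores on synthetic truth therefore
validate the implementations and their thresholds' logic, not the biological
error rates to expect on real tissue.

## 7. Problem sizes

The shipped defaults (52 amplicon samples × 94 ASVs, 320 cells across 4
FOVs, 60 reads × 10 genomes, 24 ROIs × 115 targets, 200 cover instances)
were chosen as the smallest sizes at which every rule has non-trivial
structure — multiple batches, interleaved wells, tied bit scores, quartile
boundaries — while the full test suite and acceptance run stay in the
seconds range.

## 8. Known limitations

* The well-leakage surrogate is a deterministic adjacency rule, not a
  mixture model; it cannot apportion partial contamination.
* The changepoint detector fits exactly one break; curves with several
  regimes return only the most prominent split.
* The coverage filter's "unique sequence length" falls back to whole-genome
  length when hit coordinates are absent, which underestimates depth.
* Alignment identity on repetitive or low-complexity sequence can qualify
  spurious overlaps; the cross-patient exclusion mitigates but does not
  eliminate this.
* Downstream model fitting (differential expression, mixed models) is out of
  scope; the package only prepares their inputs (normalized matrices,
  neighborhood labels, the neighbor-expression covariate).
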