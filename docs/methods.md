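# Methods

## The experimental design being modelled

An *ex vivo* galactose-cataract study cultures rat lenses in 30 mM galactose
until a cortical opacity forms, then adds histone-acetyltransferase (HAT)
inhibitors to see whether the opacity reverses.  Its transcriptomic arm
hybridises thirteen microarrays: one untreated control lens, three lenses
after 4 days and three after 6 days in galactose, and six single treated
lenses (C646, CBP30, CPTH2, the combinations C646+CPTH2 and CBP30+CPTH2, and
TH1834).  Three of the treatments reverse the opacity (the two combinations
and TH1834); the three single agents C646, CBP30 and CPTH2 do not.  The
analysis question is: which genes does galactose turn on (or off), and which
of those changes do the *effective* treatments undo — while discarding genes
that also respond to the ineffective single agents, since those responses
cannot explain the therapeutic effect.

## Statistical primitives

**Single-array contrasts.**  Most contrasts in this design pit one array
against one other array, so there is no between-replicate variance.  The
package computes those p-values at the probe level: a two-tailed
equal-variance Student's t-test on the log2 probe intensities of a gene
between the two arrays (each gene carries ≥ 2 probes; the simulator's
default is 10).  This treats probe replication as the only available
within-pair variance source — a deliberate, documented choice; how the
original analysis obtained its per-replicate p-values is not stated in the
source material, so per-array counts from any deposited data should not be
expected to match ours exactly.  When only a gene-level matrix is available
(e.g. a processed GEO table), every screen degrades to a fold-change-only
mode with an explicit warning, using the 1.5-fold threshold in place of the
p criterion.

**Fold changes** are ratios of linear means (never of log means), applied
two-sidedly (fc > k or fc < 1/k).  Zero signals are floored at a
configurable epsilon (2⁻¹⁰ linear) before any log2.

**No multiple-testing correction is applied anywhere.**  The cascade uses
raw thresholds p < 0.1 / 0.05 / 0.01, which mirrors the screening design it
implements; the p-values are screening scores, not calibrated error rates.

**Ties.**  p-thresholds are strict (p < α); the fold gate keeps fold ≥
min_fold (the gate *eliminates* genes varying by less than the threshold).

**Degenerate inputs.**  Zero variance on both sides of a t-test yields p = 1
when the means agree (flagged) and p = 0 when they differ — the limit of the
statistic.  Contrasts with fewer than two probes or replicates per side are
errors, not silent NaNs.

## The extraction cascade

1. **Low-signal filter** — drop genes with linear signal < 5 in *every*
   galactose array, plus blank/unnamed identifiers.
2. **Per-replicate screens** — each galactose array vs the control at
   p < α, either direction; three-way Venn partitions per day summarise
   replicate agreement.
3. **Reversal screen** — for the "up" arm, a gene must be up vs control
   (p < α) in ≥ 1 galactose array and down (p < α) in ≥ 1
   effective-treatment array *relative to a galactose array in which it
   qualified*.  The pairing choice (treatment vs the qualifying galactose
   array, rather than vs an arbitrary one) is the package's decision; the
   screen is run at α ∈ {0.1, 0.05, 0.01} to expose threshold nesting, and
   per-day (Day 4 / Day 6) with union and intersection reported.
4. **Median screen** — the six galactose arrays collapse to a per-probe
   median pseudo-array.  A gene qualifies as galactose-up when ≥ 4 of the 6
   galactose arrays individually beat the control at p < α (gene mode:
   median fold > 1.5), and is kept for a treatment when it is down (p < α)
   vs the pseudo-array in that treatment.  The ≥ 4-of-6 quorum approximates
   "the median exceeds the control" while retaining a per-array test; it is
   configurable (`median_min_up`).
5. **Monotherapy subtraction** (combinations only) — drop genes that meet
   the same down-vs-representative criterion under either component single
   agent.  "Altered by monotherapy" therefore means: same test, same α,
   mono array substituted for the combo array.
6. **Fold gate** (TH1834 only) — TH1834's single agent *is* the effective
   drug, so subtraction is impossible; instead genes changing by < 2-fold
   between the galactose representative (median signal) and the TH1834
   array are eliminated.
7. **Assembly** — the per-treatment candidate sets union into one flagged
   list; every stage's GeneSet carries a provenance trail from which each
   reported count can be reconstructed.

**Monotonicity caveat.**  Raising α can only grow the screen stages
(2–4), and the package's property tests assert that nesting.  It does *not*
hold for stage 5: a larger α also enlarges the mono-altered sets being
subtracted, so subtracted outputs may shrink.

## Temporal trajectory classes

Two steps: control → Day 4 (single control array, so fold-of-means > 1.5
only) and Day 4 → Day 6 (3 vs 3 arrays: p < 0.05 *and* fold > 1.5).
Classes: `early_plateau` (up, then flat), `monotonic_rise` (up, then further
up), `early_peak` (up, then down), `late_rise` (step-1 fold < 1.5, then up),
`unchanged`, `other` (the mirrored down arm and remaining combinations —
the down arm uses the same thresholds symmetrically, a documented
assumption).  "No step-1 increase" for `late_rise` means fold < 1.5, not
merely non-significant.  The classes are exclusive and exhaustive by
construction.

## Lens-opacity statistic

The cortical equatorial opacity of a lens photographed from above is the
mean 8-bit brightness (0–255) over the outer 20% of the lens radius.  The
lens is detected by Otsu thresholding as the largest bright connected
component; centre = intensity-weighted centroid, radius = √(area/π).  The
annulus mask is 0.8·r < d ≤ r.  "Weighted average" is implemented as the
pixel-area-weighted (i.e. plain) mean, with a pluggable weights hook since
the original measurement mode is unspecified.  Treatment effect is the
paired per-lens difference after − before, with geometry detected on the
*before* image and reused for the after image; groups are summarised as
mean ± SE.  Colour inputs pass through the standard luma transform.

## qPCR confirmation

Per replicate, target expression is normalised to Gapdh as
2^(Ct_ref − Ct_target) (efficiency fixed at 2; no standard-curve
correction).  Groups are compared to the galactose group by a two-tailed
equal-variance Student's t-test on the normalised values, significant at
p < 0.05.  A candidate is confirmed for a treatment when it shows a
significant directional decrease vs galactose in that treatment *and* a
significant difference in the untreated control (the induction itself),
*and* — for combinations — no significant decrease under either component
monotherapy.  Direction is enforced: a small p with a higher treated mean
does not count.

## Synthetic data: what it emulates and what it does not

The microarray simulator draws per-gene baselines N(6, 1.5²) on log2,
plants class-specific per-condition offsets, and generates 10 log-normal
probes per gene per array (Gaussian SD 0.4 on log2 — the standard
multiplicative microarray noise shape; per-array scaling is off so the n=1
contrasts stay interpretable).  The signal value is the linear mean of a
gene's probes.  Default class sizes (70 treatment-reversed, 30
monotherapy-confounded, 4 × 40 temporal, 40 down-restored, remainder null
of 5000) were chosen so the planted candidate union sits near the scale of
a realistic screen; the galactose effect is 1.5 log2 units and the temporal
second step 1.0.  Monotherapy-confounded genes are reduced by the single
agents *and* their combinations, so the subtraction stage is genuinely
exercised rather than trivially empty.

The simulator does **not** model array spatial artifacts, background
correction, batch effects, probe-affinity biases, or correlated genes.
Passing recovery tests therefore demonstrates that the cascade's logic is
correct and well-calibrated under its own noise model — not that the
specific counts from any real hybridisation would be reproduced.  Real
single-array p-values also depend on the (unstated) method used upstream of
a processed matrix; see "Statistical primitives".

The lens-image simulator plants a brightness increment only in the cortical
annulus of an ideal disk; it omits specular highlights, vignetting and
off-axis geometry.  The qPCR simulator writes
Ct_target = base − log2(expression) + noise with a constant-in-expectation
reference, so zero-noise recovery is exact by construction — its role is to
verify the normalisation and decision logic, not amplification chemistry.

## Problem sizes and numerical choices

The shipped test-suite and acceptance-script runs use 5000 genes × 10
probes × 13 arrays for the full-design checks, 2000 genes for null
calibration, and 250–400 genes for the shared unit fixtures — sizes at
which every planted effect is comfortably powered and a complete run takes
well under a minute of compute.  PCA is computed by SVD of gene-centred,
control-subtracted log2 signals (samples as observations); hierarchical
clustering is average linkage on the (1 − Pearson) distance between
samples — the linkage/distance used in the original figures is unstated, so
this is a documented package choice.  Heatmap values follow the
control-subtraction convention on linear signals (the control column is
identically zero).

## Known limitations

- The probe-level p-value for single-array pairs is a modelling decision,
  not a reconstruction of the original (unstated) method; counts on real
  deposited data will depend on matching that method and the upstream
  normalisation.
- No moderated-variance (empirical-Bayes) estimator and no FDR control are
  offered, by scope.
- GEO series-matrix ingestion parses the table and title lines only; probe
  annotation, CEL-level processing and normalisation are out of scope — the
  pipeline entry point is a processed signal matrix.
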