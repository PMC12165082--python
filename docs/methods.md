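# Methods

## Copy-number arm

**Model.** A cell's binned read counts are treated as negative-binomial
draws around an expectation proportional to (copy state / 2) × depth ×
GC-bias(gc). The pipeline estimates the relative copy-number track, not
absolute ploidy: ratios are taken against the *sample mean* bin count, so a
cell with a large altered fraction has its diploid level shifted below 1.
The diploid baseline is restored after segmentation by centering log2
ratios on the largest-mass segment mode (the mode holding the most bins
within a ±0.1 log2 window). This replaces HMM-based diploid-region
detection and is equivalent for near-diploid cells, the regime of the
exfoliated-cell application; it would mis-center a genome-doubled cell
whose dominant state is tetraploid.

**GC correction.** Lowess of count on GC fraction (span 0.3, two robustness
iterations), applied as corrected = count · mean(fit)/fit(gc), with the
mean count preserved exactly. The fit is two-pass: bins whose first-pass
corrected level is more than 25 % from the sample median are masked and the
curve refit on the near-baseline bins. Without the mask, a large CNA leaks
into the GC curve (altered bins occupy a nonrandom slice of GC space) and
leaves a spatially structured residual that biases breakpoint placement.
MAPD is computed after GC correction, on ratios, as the *mean* absolute
adjacent-bin difference restricted to within-chromosome pairs; cells above
0.45 fail QC.

**Segmentation.** Native circular binary segmentation on log2 ratios, per
chromosome: the candidate split is the circular arc maximizing the
segment-vs-rest mean-difference statistic |Δ|/√(1/m + 1/(n−m)); it is
accepted when its permutation p-value is ≤ α = 10⁻⁴ (up to 10,000
permutations, vectorized in chunks, stopping at the first exceedance since
one already forbids p ≤ α; the permutation generator is seeded). Accepted
splits recurse. Three standard auxiliary steps: (i) single-bin outliers
more than 4 noise SDs from their ±2-bin neighborhood median are shrunk to
median ± 2 SD before segmentation — zero-count dropout bins are floored at
ratio 2⁻⁶ before the log and would otherwise dominate the max statistic;
(ii) each breakpoint is re-located at the two-sample-statistic optimum
between its neighboring boundaries (up to 5 sweeps) — the initial arc
argmax is not revisited by recursion otherwise; (iii) an undo pass merges
adjacent segments whose mean difference is under 1.0 noise SD (SD estimated
from the median absolute adjacent difference). Minimum segment width is
2 bins. Gain/loss states use centered log2 thresholds ±0.25 — midway
between neutral and a single-copy change (+0.58 / −1.0) — and burden is the
altered fraction of the *autosomal* genome in base pairs.

**Precision limits.** At MAPD 0.3 the generator implies ~16 reads/bin; the
per-bin log2 SNR of a single-copy deletion is ≈ 2 and of a single-copy gain
≈ 1.2. Breakpoints of deletions localize within ±2 bins ≥ 90 % of the time
(200-replicate simulation); single-copy gains localize within ±2 bins only
~65–70 % of the time, and this matches the exhaustive maximum-statistic
oracle on the same data — it is an information limit of the data at that
noise level, not an implementation gap. Detection (as opposed to ±2-bin
localization) of 50-bin single-copy events of either sign exceeds 90 %.

**Concordance calling.** Cells are "CNA-bearing" when QC passes and at
least one autosomal segment is non-neutral. For a pair, the score is the
Pearson correlation of segment-projected centered log2 ratios over the
union of bins altered in either cell; when a projected vector is constant
on that support (exactly one altered segment), Pearson is undefined and the
uncentered cosine correlation is used, which preserves the identical → 1 /
mirrored → −1 limits. Cells join a clone by single-linkage at score ≥ 0.8,
and clones of ≥ 2 cells are malignant. The threshold, linkage and minimum
clone size are re-derivations (the original quantitative criterion is in
prior work not reproduced here) and are configurable.

## Imaging arm

The cascade order is fixed: tile → detect → confidence filter (> 0.3) →
NMS (suppress IoU > 0.5) → QC → segment → route → classify. The
confidence filter runs before NMS. Tiles are 1024×1024 with right/bottom
remainders padded in the slide's modal border color and flagged. All
coordinates are 0-based, x right / y down, boxes half-open.

**Models.** The four trainable stages are compact seeded classical
learners, chosen because the scientific content here is the cascade, the
loss definitions and the operating thresholds rather than any specific
backbone: a color-distance proposal generator whose foreground threshold is
selected by proposal F1 on training patches, with a logistic confidence
model over region features (labels = IoU ≥ 0.5 matches to ground truth); a
random forest over morphometric/texture features (crops resized to
224×224) for the seven QC categories (high-quality, blurry, incomplete,
fragment, clump, impurity, nucleus-only); a pixel-wise logistic
cell/background classifier (resolution-independent, so masks are predicted
at native crop size; largest component kept, holes filled; an empty mask
flags the crop out of the cascade); and per-channel regularized logistic
malignancy classifiers over nucleus/cell area ratio, contour irregularity
(perimeter²/4πA), chromatin texture, brightness and size features. The
gradient-training losses used by detectors and segmenters in this setting
are provided as exact numpy formulas and verified against closed forms:
L_total = 0.5·L_IoU + L_obj + L_cls with L_IoU = mean(1 − IoU²) over
matched foreground pairs (0 when none), and Dice+BCE = mean BCE on logits
+ (1 − Dice on sigmoid probabilities).

**Routing and calibration.** A cell routes large when the longer bounding
side of its mask exceeds 90 px (boundary → small), then is centered on the
channel's canonical canvas (254² / 90²) after background removal with the
modal border color. Channel classifiers are trained on a 7:2:1
train/validation/test split; the operating threshold is the smallest
validation score achieving specificity ≥ 0.998 (a benign-score quantile;
max score + ε with a warning when unattainable), so specificity on the
calibration split holds by construction and per-cell sensitivity is the
traded quantity. ETC% uses QC-passed cells as denominator.

## Diagnosis

Slide call: ETC% ≥ cutoff, boundary positive, cutoff 0.2 % by default.
Cutoff discovery scans midpoints of sorted unique values and keeps, among
candidates with maximal specificity, the one maximizing sensitivity
(Youden's index available as an alternative; the rule is recorded in the
output). Proportion CIs are exact Clopper–Pearson (configurable to Wald);
AUC is the normalized rank-sum statistic (equal to the trapezoidal area)
with a Hanley–McNeil Wald interval. Metrics with a zero margin are reported
as undefined rather than raising. Reported percentages round half-up to one
decimal. Sensitivity-corrected proportions cap at 100 % with a warning.
Group comparisons (Mann–Whitney, paired Wilcoxon with p = 1 for identical
vectors, Pearson chi-square) delegate to scipy.

## Synthetic data

The generator defines the study conditions. CNA arm: negative-binomial
counts (overdispersion α, default 0.01; LP-WGS bin counts are overdispersed
relative to Poisson), a quadratic multiplicative GC-bias curve (the minimal
shape a lowess correction must remove), and a target-MAPD mechanism that
derives mean depth analytically from MAPD = (2/√π)·σ with σ² = 1/depth + α;
an unreachable target (σ² ≤ α) raises with the achievable floor. Planted
clones share identical events across cells (clonal concordance), arm-scale
by default (tens of bins) as in real tumor profiles. Imaging arm: cells are
irregular closed contours (low-order harmonic perturbations) with a
concentric nucleus; malignancy is encoded *continuously* by higher
nucleus-to-cytoplasm ratio (0.55 ± 0.12 vs 0.30 ± 0.09), contour
irregularity and chromatin texture amplitude, with overlapping
class-conditional distributions so classifiers cannot be trivially perfect.
These effect sizes are free parameters of the generator, not estimates of
real cytomorphometry. Junk objects mirror the six QC reject classes. Slides
place objects on a jittered grid (pitch 235 px) with occupancy tracking, so
masks never overlap; exactly round(n·fraction/100) cells are malignant.
Cohorts draw malignant slide fractions from a lognormal with median 0.3 %
(straddling the 0.2 % operating point) and controls from an exponential
with mean 0.04 %, with a low-sensitivity perfectly-specific conventional
cytology column for comparison statistics.

What the synthetic data does **not** emulate: real Pap-stain color
variation, focus and scanner artifacts, touching cell sheets, the true
morphometric distributions of tumor cells, and genome-wide waves or
replication-timing structure in bin counts. Passing tests therefore
demonstrate the pipeline's statistical machinery and contracts, not
clinical performance on patient slides.

## Problem sizes

Defaults chosen for a desk-scale, single-CPU workflow: demo runs use 3
synthetic chromosomes × 100 bins and 12 cells for the CNA arm; detector
training uses 6–8 annotated 1024² patches; QC and segmentation train on a
few hundred rendered crops; channel benchmarks use ~800 cells per channel;
breakpoint-recovery simulations use 200 replicates of a 100-bin chromosome.

## Known limitations

Single-copy-gain breakpoints localize to ±2 bins only ~2/3 of the time at
MAPD 0.3 (information-limited, above). The diploid-mode centering assumes
the dominant state is diploid. The concordance criterion is a stand-in for
the original (unavailable) rule. The imaging models are classical learners
on engineered features: adequate for the rendered distributions, but they
would not transfer to real slides, and no claim is made that they
reproduce real-data discrimination. Tumor-cell clusters (as opposed to
single cells) are out of scope by design.
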