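# Methods

## Scope and model

The package reproduces, in silico, a rapid fluorescence-cytology workflow
for breast FNAB smears: a red cytoplasmic stain marking
oxidative-stress-rich cells plus a blue nuclear stain, followed by a
rule-based four-category slide diagnosis and a three-reader majority vote.
Because no image data are deposited with the source study, every stage is
exercised on synthetic smears with exact ground truth; the printed
cross-tabulations of the clinical cohort are replayed through the same
metrics engine as packaged count tables.

## Synthetic smear generator

**Scene.** Cell positions follow a Neyman–Scott clustered point process:
cluster parents uniform in the field, offspring displaced by an isotropic
Gaussian (sd `cluster_radius`, default 12 µm), plus uniformly scattered
singletons. A Matérn-style hard core (`min_separation`, default 6.5 µm,
20-retry rejection) prevents nuclei from interpenetrating, as in a smear
monolayer; in very dense clusters the constraint is soft (the last draw is
accepted), so occasional overlaps remain, which is also realistic.
Cluster occupancy is fixed at the configured mean when dispersion is 0,
otherwise negative-binomial with variance `mean + dispersion·mean²`.

**Cells.** Nuclear major axes are lognormal per class: malignant median
13 µm (σ_log 0.15, ≈ 96 % of nuclei ≥ 10 µm), benign and normal epithelium
median 7 µm (≈ 0–0.2 % ≥ 10 µm), stroma 6 µm. This reproduces the bimodal
size separation from which the 10-µm enlargement threshold was derived.
Axis ratios: malignant 0.55–0.85, benign/normal 0.75–0.95 (rounder),
stromal 0.45–0.75 (spindled). Nuclear boundaries are ellipses with a
smooth radial perturbation r(θ) = r₀(1 + a·Σₖ aₖcos(kθ+φₖ)), k = 3..6,
unit-normalized aₖ; the amplitude a is the per-cell irregularity
(malignant 0.20 ± 0.08, others ≈ 0.02), and a = 0 gives a perfect ellipse.
The cytoplasm is the nuclear boundary scaled by 1.4–1.8; red is rendered
on the cytoplasmic annulus only, matching the red-cytoplasm /
blue-nucleus appearance of the assay. Red levels (arbitrary camera
units): malignant 1500 ± 300, benign epithelium 350 ± 120 (weak but
detectable — the false-positive substrate), normal epithelium and stroma
unstained. A multiplicative `dilution_factor` ∈ [0, 1] attenuates all red
signal, modelling reagent dilution by excess mounting liquid (the
reported false-negative mechanism).

**Camera.** Background 100 counts, additive Gaussian read noise
(sd 10), optional Poisson shot noise, 16-bit clipped output. Default
field 256 × 256 µm at 0.5 µm/px (512 × 512 px), standing in for one
high-power field; the source study reports no pixel calibration, so these
are explicit, configurable stand-ins chosen for desk-scale runtime.
Overlapping cells combine by per-pixel maximum so uniform intensities stay
flat (the median of a constant region is that constant).

**Determinism.** One integer seed drives everything; cohort slides use
substreams at a fixed stride (10007) so each slide is independently
reproducible; rendering derives per-cell boundary shapes from
(seed, cell index), so identical (cells, config) give bit-identical
images.

**Cohort defaults.** 63 malignant / 30 benign / 33 normal slides, the
composition of the clinical cohort. Malignant slides are guaranteed at
least one cluster with ≥ 5 red malignant cells (aspirates of carcinoma
shed such aggregates in this regime); benign slides carry weakly red
epithelial aggregates; normal slides are fully unstained.

## Measurement chain

Nuclei: Gaussian smoothing (σ 1 px), global Otsu threshold (overridable),
distance-transform watershed with peak separation 2.5 µm — about the
radius of the smallest retained nucleus, so touching small nuclei are
separable — minimum area that of a 4-µm disc (debris), border-touching
nuclei discarded (their truncated shapes would be mismeasured as
irregular). Axes come from the second-central-moment ellipse (within
1 px-equivalent of the analytic value for 6–16-µm ellipses across
rotations; Feret-style measures are not used); circularity uses the
Crofton perimeter, which is unbiased for digitized smooth shapes.

Red positivity: a pixel is red when ≥ median + 3 × 1.4826·MAD of the red
channel (robust background; an ε floor on the MAD makes a constant
channel yield an empty mask). Cytoplasm per cell: red-positive pixels in
a 5-µm ring around the nucleus, each assigned to its nearest nucleus
(shared blobs partition without double counting); `red_positive` requires
at least a 2-µm-disc of such area; `median_red` is the median red
intensity over those pixels. The 5-µm ring is the standard whole-cell
approximation where cytoplasmic extent is undefined.

## Classification and readers

Aggregation = single-linkage components of red-positive centroids at
≤ 25 µm. Category 4 iff some component of size ≥ 5 has a member with
major axis ≥ 10 µm (inclusive) or circularity < 0.8; else 3 if a ≥ 5
component exists; else 2 if any red cell; else 1. Only category 4 is
positive. Two deliberate readings of ambiguous prose: groups of exactly
4 cells are *not* aggregates (the positive criterion states ≥ 5 in both
places it appears), and the positive rule is the enlarged-OR-irregular
disjunction, with the high-N/C conjunction available as an option
(`require_high_nc`, off by default). "Irregular" has no published numeric
definition; circularity < 0.8 is the package's operationalization, and
the slide takes the worst category any cluster supports.

Readers jitter the geometric thresholds multiplicatively
(lognormal, sd 0.05) and flip the final call with probability 0.02;
both default values are small and are constrained only by the closed-form
panel-error identity 3p²(1−p) + p³, which the tests verify by Monte
Carlo. Consensus is a strict majority of an odd panel; an even panel is
an error because no tie rule exists.

## Statistics

Metrics use dual denominators: the insufficiency rate divides by all
submitted slides, accuracy by evaluable slides only. Percentages are
reported at one decimal, rounded half-up, as in the printed tables; full
precision is kept internally. The comparator mapping counts
"atypical" as test-negative — the only mapping consistent with the
printed specificity arithmetic — and is configurable. McNemar is exact
(binomial) by default, p = min(1, 2·BinCDF(min(b,c); b+c, ½)), with the
continuity-corrected χ² as an option; b + c = 0 returns p = 1 with a
degenerate flag. Mann–Whitney uses mid-ranks, exact enumeration when
n ≤ 20 without ties, otherwise the tie- and continuity-corrected normal
approximation. Both are verified against full enumeration oracles in the
tests. The slide-level "aggregate-region intensity" is the median of
member `median_red` over the largest cluster.

## Problem sizes

Tests and the acceptance script run the full 126-slide default cohort
once (≈ 25 s) and 100 generator replicates of the 60-vs-60 intensity
contrast; distribution-recovery checks use 500–600 cells. These sizes
make Monte-Carlo tolerances (≈ 5 % on medians, binomial CIs on rates)
meaningful while keeping a laptop-scale run.

## What the synthetic data do and do not show

The generator reproduces the *statistical structure* the decision rule
assumes — size bimodality around 10 µm, red-intensity contrast,
aggregated vs sparse arrangement, the cohort composition — so passing
tests show the chain of measurement, rule, vote and statistics is
faithful and well-calibrated on that structure. They do not show
performance on real smears: no optical PSF, autofluorescence,
out-of-focus light, three-dimensional cell clumps, staining batch
effects, or genuinely ambiguous cytology. The clinical accuracy figures
in the replay outputs are properties of the published counts, not of the
simulator. Residual synthetic false positives arise from spindled
stromal nuclei near the circularity cut inside benign aggregates and
from unsplit nuclear clumps — qualitatively the same mechanisms the
source study reports for its false positives.

## Known limitations

- Single 2-D focal plane; no whole-slide stitching or 40× low-power
  geometry beyond the tiled ROI scan.
- The reader model is exchangeable (no per-reader bias or correlated
  errors beyond the shared slide).
- The per-slide joint distribution of index and comparator calls is not
  published, so the packaged replay table is a marginal-consistent
  completion; paired statistics on it are illustrative only.
- Intensity units are arbitrary; no camera gain or exposure model.
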