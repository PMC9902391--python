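# Methods

## Problem and pipeline

Dicentric chromosomes (DICs) carry two centromeres; their frequency per
metaphase is the standard biomarker for absorbed radiation dose.  The
package automates the image side of dicentric scoring in four steps:
locate metaphase spreads in low-magnification fields, extract chromosome
bodies from high-magnification spread images, triage and split the
extracted objects by simple morphology, and classify the surviving
chromosome tiles with a two-stage CNN cascade.  Each step is an
independent module with explicit parameters; the pipeline module wires
them together behind a validated YAML configuration.

## Metaphase locating (10x)

At low magnification a metaphase spread is a cluster of thin strokes
("pore-like"), while nuclei and large impurities are compact
("blocky-like").  The locator thresholds the field with Otsu's criterion
(foreground = darker class), then removes the pore-like content with a
morphological opening whose disk radius (default 4 px) exceeds half a
stroke width but not half a nucleus radius.  Subtracting the opened mask
from the original keeps exactly the thin content; a closing at radius 4
fuses neighbouring strokes of one spread into a solid clump, a small
opening (radius 2) then drops isolated debris specks (a pure closing is
extensive and cannot remove anything, so the tidy-up needs an opening
half to discard debris); a final dilation (radius 12) merges each
cluster into one candidate blob.  8-connected components below 200 px
are dropped; each candidate's centroid is computed over its surviving
stroke content (not the inflated blob, whose asymmetry would bias it)
and reported in 0-based (row, col) coordinates with half-open boxes.  None of the radii are
dictated by the published description, so they are exposed in
`LocatorParams` and calibrated on the synthetic fields.

Disk morphology is implemented by thresholding Euclidean distance
transforms (erosion: EDT of the mask > r; dilation: EDT of the complement
<= r), which is exact for the continuous disk and much faster than
sliding a large rasterised footprint.

A spread is accepted for scoring when its post-triage chromosome-object
count lies in 46 ± 3 (adhesive clusters and acentric fragments justify
the slack).  The count is only known after extraction and triage, so the
pipeline applies the screen there, even though the rule belongs
conceptually to the locating stage.

## Chromosome extraction (100x)

Binarization is two-cluster k-means on luminance (mean of RGB).  In one
dimension with k = 2 Lloyd's algorithm converges to a threshold
partition, so the implementation iterates the two cluster means on the
intensity histogram with centers initialised at the observed minimum and
maximum — fully deterministic, no random restarts.  Whether the original
system clustered RGB vectors or luminance is not documented; luminance is
the simpler reading and makes the k-means/threshold equivalence exact.

Nuclei and contaminants are removed by subtracting the morphological
opening of the binarized mask.  The opening disk must be larger than the
half-width of the widest chromosome (65/2 px) or the subtraction would
delete wide chromosomes along with the nuclei; the default radius is
therefore 36 px, and the synthetic nuclei are rendered with radii 55–95
px so they survive the opening and are removed.  A 3×3 median filter
(majority vote) clears residual specks; because a median filter can also
round background concavities outward, the cleaned mask is intersected
with the k-means mask so the extraction chain is anti-extensive end to
end.  "Retrieving" the chromosomes is implemented as 8-connected
component labeling with tight bounding boxes and background-filled RGB
crops — deterministic, and contract-equivalent to edge-following on a
clean binary mask.

## Triage and adhesive-mass splitting

Two features drive the rule table: WH, the short side of the minimum-area
enclosing rectangle (rotating calipers over the convex hull of the pixel
corners, so a 1-px line has WH = 1), and IH, the number of background
components fully enclosed by the body (4-connected background inside a
1-px pad; the outside is then a single component).  General chromosomes
have IH 0, dicentrics 1, tricentrics 2, and one arm crossing can add 1,
so IH ≤ 3 for genuine chromosome objects.  The published rule is applied
verbatim and totally: WH < 25 or IH > 3 ⇒ impurity; else WH > 65 ⇒
adhesive mass; else individual.  Both boundaries are inclusive on the
chromosome side (WH = 25 and IH = 3 are individuals).

Masses are split by marker-controlled watershed on the Euclidean distance
transform of the mask.  Marker generation is not specified in the source
description beyond a minimum seed-point area of 150 px, and the obvious
reading (components of the EDT above a fixed fraction of its maximum)
cannot both separate two overlapping 30-px-radius disks and respect the
150-px filter — the saddle between such disks sits at ~75% of the peak,
and any threshold above it leaves regions smaller than 150 px.  The
default seed method is therefore *distance-maxima*: reconstruct the EDT
from itself minus h (h = 0.22 × max) and take the regional-maximum
plateaus of the reconstruction as markers.  Each marker is the set of
pixels within depth h of a genuine peak, so blob pairs whose connecting
waist is more than ~23% shallower than their cores produce separate
markers of substantial area, while centromeric pinches (~18% deep by
construction) do not split a single chromosome.  Markers below 150 px are
discarded before flooding; with ≤ 1 survivor the mass passes through
unsplit.  Flooding with `skimage.segmentation.watershed` restricted to
the mask assigns every mask pixel to exactly one marker, so the segments
are disjoint and conserve area exactly.  Split segments re-enter triage
once (recursion capped at depth 2).  The fraction-of-maximum thresholding
variant is kept as `seed_method="distance-threshold"`.

Known limitation, shared with the original system: symmetric mid-body
crossings produce no neck in the distance transform and cannot be split
into two connected regions by any watershed; the synthetic adhesive
fixtures therefore model the common shallow end-to-side (telomere)
contact, and the splitting guarantee is statistical (≥ 80% at crossing
angles ≥ 60°), not universal.

## Two-stage CNN cascade

Crops are rescaled aspect-preservingly so the longer side is 151 px,
centred on a background-coloured 151×151 canvas, and scaled to [0, 1]
(the engine additionally subtracts a fixed 0.85 input mean before the
first convolution; centred inputs make small-batch SGD far better
conditioned).  Stage 1: conv 8@5×5, conv 8@3×3, pool 3, conv 16@3×3,
pool 2, conv 32@3×3, pool 5, conv 64@3×3, then fc 20, fc 10, fc 2 with
softmax; ReLU after every conv and fc except the output.  Stage 2 widens
the filters to 16/24/40/40/64 and inserts dropout 0.5 and 0.3 before the
first two fully connected layers.  Convolution padding and pool strides
are not stated in the source; valid convolutions with stride 1 and pool
stride equal to the pool window reconcile every printed layer size into
the positive spatial trace 151→147→145→48→46→23→21→4→2, flattening to
64·2·2 = 256.

The softmax output is read as the probability of the non-DIC class (0 =
DIC, 1 = non-DIC); a tile is called DIC iff its score < 0.5, with the tie
going to the majority (non-DIC) class.  The cascade rule: stage-1
non-DIC calls are final; stage-1 DIC calls are re-scored by stage 2,
whose call is final.  Cascade positives are therefore always a subset of
stage-1 positives — false and true positive counts can only shrink.

Training follows the published recipe: SGD with momentum 0.9, weight
decay 1e-4, batch size 256, 50 epochs, learning rate 0.001 dropped ×10
after half the epochs; a seeded 7:2:1 train/validation/test split; DIC
tiles duplicated ×3 (stage 1) or ×2 (stage 2) in the train and validation
streams; "50 iterations" is read as 50 epochs.  Stage 2 trains on the
stage-1 false positives plus all DIC tiles; when stage 1 yields fewer
than `min_negatives` false positives the pool is topped up with the
lowest-scoring (most DIC-like) negatives so the pool stays roughly
class-balanced, which is how the full-scale stage-2 set is composed.
Augmentation helpers (mirror, pan with background fill, Gaussian noise)
preserve labels.  All randomness — split, subsampling, shuffling, weight
init, dropout — flows from one seeded generator per training call.

The layer engine is a deliberate, self-contained CPU implementation:
float32 channels-last tensors throughout, direct convolutions as
jit-compiled loops with the output-channel axis innermost (which
vectorises well on a single core), max-pool with stride = window via
reshape and stored argmax, dropout with inverted scaling, and combined
softmax/cross-entropy gradients.  The input convolution skips its
(unused) input gradient.  Backpropagation is verified against numeric
differentiation on a small smooth stack.

## Evaluation

Confusion counts treat DIC as the positive class.  ACC, TPR, TNR, PPV
and NPV are computed from the counts; any metric with a zero denominator
is reported as an explicit undefined marker, never silently as 0.
Printed percentages round half-up to one decimal, which reproduces every
cell of the published comparison table from its raw counts.  The cascade
projection composes per-stage per-class accuracies: surviving
false-positive mass r·Π(1−a_i) against surviving true-positive mass
Π(d_i) at population ratio r; composing the printed accuracies gives
54.7% after one stage and 22.8% after two — the second differs from the
printed 22.6%, which was evidently computed from unrounded accuracies,
so only the first-stage value is treated as exactly reproducible.
Subgroup accuracy (e.g. for long-arm-entangled chromosomes) is
(size − misidentified)/size.

## Synthetic data: what it emulates and what it does not

Chromosome bodies are thick polylines: near-straight backbones (total
turn capped so the bend sagitta stays ~1 px and WH tracks the requested
width to ±3 px), half-width profiles with tapered tips (×0.45) and
Gaussian centromeric pinches (×0.82), widths drawn from the 25–65 px
triage range, lengths 90–200 px.  A k-centromere body carves k−1
enclosed gaps (half the local body half-width, ≥30 px² each) between
consecutive centromeres, so rendered IH equals the centromere count
minus one by construction — verified at ≥95% over renders.  Long-arm
entangled confusers loop the backbone over itself (loop radius
0.6–1.0 × width, loop position anywhere from mid-body to tip), giving a
genuinely DIC-like enclosed hole with only one centromere.  Scenes
composite dark bodies (~60/255 ± texture) on a light background
(~230/255) with a slight violet tint and Gaussian sensor noise; 10x
fields render spreads as dense clusters of ~46 thin strokes, nuclei as
blocky ellipses, debris as specks.  Adhesive masses are formed by
shallow end-to-side contact (a tapered tip penetrating 1–5 px into a
neighbour's flank).  All placement is rejection-sampled with a 3-px
clearance margin for non-overlap scenes; identical seeds give
pixel-identical images and byte-identical corpus manifests.

Not emulated: G-banding patterns, staining chemistry, optical PSF,
focus variation, and the full morphological diversity of real
karyotypes.  Passing tests on this corpus demonstrate that the
implementation is correct and that the cascade mechanism behaves as
designed; they say nothing about accuracy on real slides, which the
original system established on ~710,000 expert-labeled images.

## Desk-scale training conditions

The published models trained for ~70 GPU-hours on 710,000 images; that
regime is out of reach on a CPU, so the cascade property is demonstrated
at desk scale: per seed, a ~5,060-tile corpus at the 45:1 non-DIC:DIC
population ratio, stage 1 trained on a 600-tile subsample of the train
split (mirroring the subsample the original system drew from its
corpus) for a few epochs at batch 16 with learning rate 0.01, stage 2
on the mined hard set for a few more epochs, and evaluation on the
validation+test splits, which receive no weight updates (stage-2 mining
is restricted to the train split for this reason).  Counts are pooled
over three seeds.  The desk-scale learning rate is higher than the
published 0.001 because only a few hundred SGD steps fit in the budget;
the published value remains the `TrainingConfig` default.

## Numerical and degenerate-input conventions

Constant images raise explicit degenerate-histogram/cluster errors.
Empty masks raise on WH/IH; an empty extraction mask yields an empty
object list.  Coordinates are 0-based (row, col); boxes are half-open.
Watershed ties inside `skimage` flooding are deterministic, and segment
areas always sum exactly to the mass area.  Report JSON is serialised
with sorted keys and 6-decimal floats, so identical configurations and
seeds give byte-identical reports.
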