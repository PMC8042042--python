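# Methods

`crstress` quantifies how lossy JPEG 2000 compression affects a small CNN
that classifies two-view mammography-like studies as malignant versus
non-malignant. Because clinical mammograms cannot ship with a software
package, the pipeline runs end-to-end on a synthetic phantom cohort whose
design isolates the one mechanism under study: diagnostic evidence that
lives at high spatial frequency is the first casualty of rate-controlled
wavelet compression. This note records the model, the parameters that
matter, the numerical conventions, and what the synthetic results do and
do not say about real data.

## The phantom cohort

A *study* is four 16-bit views (LCC, LMLO, RCC, RMLO; default 320x256
each, height x width) with a study label in {normal, benign, malignant}, a
binary lesion mask per view, and manifest metadata (exam date, BI-RADS,
surgery flag). The breast is a half-ellipse of band-limited Gaussian
texture (white noise smoothed with a 3 px kernel, sd 3500 counts around a
tissue mean of 22000) over a dark field; the flat chest-wall edge sits on
the left for left-laterality views and on the right for right-laterality
views, so the standard half-image crop keeps the tissue.

The malignant phenotype is a *lesion complex*: a low-contrast Gaussian
mass (sigma 4-6 % of image width, amplitude 0.35 x A) plus a cluster of
6-12 compact Gaussian specks (sigma 0.7-1.3 % of width, amplitude
0.7-1.0 x A, scattered with sd 3.5 % of width around the mass), where
the peak amplitude A = separability x 18000 counts. The benign/
dense-tissue phenotype is a *smooth structure* drawn from a 50/50
mixture of two families: (a) the same complex convolved per speck with a
Gaussian of sigma 2.5-4.0 % of width (closed form, integrated energy
conserved), which shares the complex's extended lumpy footprint; and
(b) a single smooth mass parameterized by its integrated energy
(U(420, 780) x A px^2 at width 256, scaled with area), which straddles
the complex's energy budget and post-blur width.

* **Malignant** studies render the complex as-is on both views of one
  side (15 % are bifocal; lesion multiplicity is drawn identically for
  benign studies so it carries no label signal). The sharp specks play
  the role of microcalcifications: compact, high-contrast,
  high-frequency evidence. The ground-truth mask is the half-peak
  contour of the complex.
* **Benign** studies render smooth structures at lesion positions. No
  mask is recorded, matching the convention that only malignant findings
  carry an annotation.
* **Every** view, whatever its label, additionally receives 2-5
  *dense-tissue islands* — smooth structures at random tissue positions.
  **Normal** studies have texture and islands only.

This design is the load-bearing choice of the package, and each
ingredient closes a measured shortcut. A pilot with plain Gaussian blobs
failed instructively: heavy compression *improved* classification,
because the encoder kept each blob's low-frequency signature while
denoising the texture around it. Matching the smooth family's shape
removes the blob-shape shortcut; matching its energy removes a
peak-brightness shortcut (blurring a sharp complex otherwise leaves it
~2x brighter than pre-smoothed structures, measurable as a 0.83
single-feature AUROC at the extreme CR); and several islands per view
remove both the "any blob means disease" and the "brightest blob"
shortcuts that would otherwise keep extreme-CR models near a detection
ceiling. What remains is the mechanism of interest: in real mammograms
the malignant/benign distinction rests heavily on fine structure
(microcalcifications, spiculated margins), which is exactly what a
rate-starved wavelet code discards first.

Default cohort parameters: class weights (0.62, 0.18, 0.20) for
normal/benign/malignant — a roughly 4:1 non-malignant:malignant mix as in
a cancer-enriched screening population — with `separability = 0.8`. Label
counts come from one seeded multinomial draw, every study from a child
seed, so a cohort is a pure function of (seed, n).

The manifest-level cohort filter reproduces the selection logic of a
longitudinal screening archive: a non-malignant subject enters only with
two consecutive exams at least 365 days apart carrying the same BI-RADS
score (most recent exam kept; "one year" is read as >= 365 days, and
"consecutive" as the subject's two most recent exams); a malignant
subject enters only after surgery (latest, i.e. preoperative, exam kept).

## Compression and accounting

Encoding uses OpenJPEG (through Pillow) in irreversible 9/7 mode with the
encoder's rate parameter, as a raw J2K codestream so byte counts carry no
container overhead. The compression ratio is defined on the raw pixel
buffer, CR = (H x W x 2 bytes) / codestream bytes — container-independent
and reproducible, since the "file size" of an uncompressed image depends
on its wrapper. Because the encoder honours a requested rate only
approximately, `compress_to_target_cr` bisects the requested rate in log
space until the achieved CR is within a relative tolerance (default 10 %,
at most 20 encodes); an unreachable target (the codestream has a floor of
a few hundred bytes) raises an error that names the best achievable CR.
CR 1 is stored losslessly (reversible 5/3) and decodes bit-exactly.

Fidelity is PSNR = 10 log10((2^16-1)^2 / MSE) in dB; the exact
reconstruction, whose PSNR is infinite, is reported with the conventional
label 100.

The clinical-scale experiment grid has eleven CR conditions (1, 15, 20,
25, 50, 100, 500, 1K, 5K, 10K, 11K). At 320x256 the codestream floor caps
the reachable CR near 900, so desk-scale runs keep the low conditions and
substitute "extreme" conditions probed at runtime as ~0.5x and ~0.95x of
the maximum reachable CR (typically ~450 and ~870). The contrast of
interest — mild versus near-floor compression — is preserved at the
smaller scale; absolute CR values are not comparable to the clinical
grid.

## Preprocessing

Each view is resized to 30 % per axis (bilinear; output extent
round-half-up), then cropped: keep the chest-wall half of the columns
(floor(W/2)) and drop the fifth of rows away from the breast (top fifth
for MLO, bottom fifth for CC; floor(H/5) rows). The CC and MLO crops of a
side are concatenated along x (CC leftmost, shorter image zero-padded at
the bottom) and divided by 65535. Masks ride through the same geometry
with nearest-neighbour resampling and are unioned. At the default extent
this yields 77x76 side inputs. A side input's label is 1 iff the study is
malignant — deliberately, both sides of a malignant study are positive
even though only one carries the lesion, mirroring study-level labelling;
the consequences for training are handled below.

## Classifier and training

CNN3: three blocks of [6x6 convolution, stride 2, padding 2 -> batch
normalization -> ReLU -> 2x2 max pooling], a flatten, two hidden fully
connected layers (256, 64) each with batch norm + ReLU, and a single
sigmoid logit. Channel widths (16, 32, 64), epochs (30), and batch size
(32) are package defaults; the conv geometry is fixed. Loss is binary
cross-entropy on logits; the optimizer is Adam with lr 1e-4, beta1 0.9,
beta2 0.999, eps 1e-8. (A learning rate of 0.5 appears in the source
literature for this architecture; it diverges in practice and is treated
as a typo, with the rate exposed in `TrainConfig`.) A study's score is
the max of its two side probabilities ("suspicious on either side").

The network and its gradients are implemented in-package as a compact
numpy engine (`crstress._nn`: im2col convolution, batch norm, max pool,
Adam, stable BCE), which also supplies the exact activations/gradients
Grad-CAM needs; correctness is pinned against finite differences in the
test suite. Everything is seeded — initialization, batch order — so runs
reproduce bit-for-bit on one thread.

**Best-epoch selection.** The retained parameters are those of the epoch
with the best *study-level validation AUROC* (validation sides grouped by
subject, max rule), not the best validation BCE. With side-level label
noise — the healthy contralateral side of every malignant study is
labelled 1 — validation BCE is non-monotone in discrimination: as the
model grows confident, its penalty on those unavoidably-misscored sides
swamps the loss even while ranking improves. In pilots, best-BCE
checkpointing repeatedly selected epoch 1 of 30 (study AUROC ~0.6 where
later epochs reached ~0.93). `TrainConfig(checkpoint="loss")` restores
plain best-validation-loss selection.

## Evaluation design

Subjects are split at study level (both sides travel together). Five
stratified folds define the 20 % test sets; each fold's remaining 80 % is
split 7:1 into train and validation — the 7:1:2 ratio composed with
5-fold cross-validation. AUROC is trapezoidal ROC integration and AUPRC
is step-wise (average-precision) integration, both via scikit-learn, with
exhaustive pair-counting and hand-stepped PR oracles in the tests. Fold
summaries report mean, sample sd, and the normal-approximation 95 % CI
(mean +/- 1.96 sd/sqrt(k)). A fold whose test set degenerates to one
class is skipped with a warning and k reduced accordingly.

The cross-CR matrix trains five-fold models at each grid CR and scores
every model on every test CR (ordered pairs; the diagonal is the
single-CR experiment). The augmentation experiment trains on the union of
the training subjects' images over a nested CR prefix (CR1; CR1+15; ...)
— multiplying the training set size by the number of mixed CRs — and
evaluates on each single-CR test set; validation and test sets are never
augmented.

## Saliency

Grad-CAM: channel weights are the spatial mean of the logit gradient at
a chosen conv block's ReLU output; the weighted sum is ReLU-gated,
bilinearly upsampled to the input extent and max-normalized. Using the
logit rather than the sigmoid probability changes the map only by a
positive factor, which normalization removes. The target block defaults
to the deepest conv block whose activation grid is still at least
16x16 — at large input sizes that is simply the last block, but at the
desk extent (77x76 inputs) the deeper blocks collapse to 9x9 and 2x2
grids with little or no localization left (measured: median
encapsulation 0.0 at the 2x2 block and a low/extreme tie at the 9x9
block, versus a clear contrast at the 38x38 block), so the rule selects
the first block there. The block is configurable per call. The encapsulation score binarizes the heatmap at
its own 0.8 quantile (top 20 % of pixels salient; ReLU-zero pixels never
salient) and reports the fraction of lesion-mask pixels inside the
salient region, so a uniformly random map scores ~0.2 in expectation —
the chance floor. Maps remain coarse at desk scale; the score is
meaningful as a paired comparison between conditions, not as an absolute
localization metric.

## Problem sizes and numerical conventions

Package-default experiment size: 400 subjects at 320x256, five folds,
trimmed epoch budgets for the scripted experiments (the trend experiments
use 20 epochs). These sizes were chosen so a full robustness analysis
runs on a laptop-class single core in minutes while leaving the fold CIs
narrow enough to read the compression trend; they are configuration, not
architecture, and scale up freely.

Conventions worth stating once: row 0 is the image top and column 0 its
left edge; resize extents round half up, crop extents use floor;
encoder rate bisection starts at the target itself (OpenJPEG usually
lands within a few percent on the first try); fold seeds derive
deterministically from the experiment seed (`seed*100 + fold`);
training is float32, metric accumulation float64.

## Limitations

The phantom abstracts away almost everything about real mammography:
anatomy (no glandular structure, pectoral muscle, or skin line), device
physics (no noise model, scatter, or detector response), lesion
morphology (Gaussian masses and specks rather than spiculated masses and
true calcification clusters), and population structure (no age, density,
or stage covariates). Absolute performance numbers on the phantom
therefore transfer to no clinical setting. What the package does support
is *relative* statements under a controlled mechanism — performance as a
function of CR, cross-CR generalization asymmetries, augmentation
benefit, and saliency drift — because these depend on the interaction
between the codec's frequency allocation and where the class signal
lives, which the phantom models explicitly. The desk-scale extreme CRs
(~450/~810) stand in for the clinical grid's 10K/11K conditions only in
the sense of "near the codestream floor"; the absolute ratios differ by
an order of magnitude because the images do too.
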