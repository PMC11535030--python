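# Methods

## Problem setting

A cancer genome is a set of *SV contigs*: derivative-chromosome sequences
assembled from ordered, oriented reference segments joined at structural-
variant (SV) breakpoints, each carried by one parental haplotype with an
integer copy number μ(g).  A cancer Hi-C experiment observes, in reference
coordinates, the *sum* of the contact maps of all contigs.  neohic predicts
that mixture from sequence: it encodes each contig with its copy number,
predicts per-contig contact maps with a convolutional network, projects them
back to reference coordinates, sums them into haplotype and total Hi-C, and
annotates the SV-created domain structure (neo-TADs, enhancer hijacking).

## CSCN encoding

A contig of length l is encoded as a 4 × l integer matrix: column j holds
μ(g) in the row of base j (row order A, C, G, T) and zeros elsewhere;
ambiguous bases give all-zero columns.  With μ = 1 this is one-hot encoding.
SNPs are substituted in reference orientation before reverse-complementing
"−" segments (phased VCFs are reference-stranded).  Two prediction modes
exist: *encoding* feeds the μ-scaled matrix to the network; *decoding* feeds
the one-hot matrix and multiplies the predicted contacts by μ afterwards —
decoding is exactly linear in μ by construction, encoding learns its
copy-number response.  Decoding is the right mode when the training material
is mostly diploid (the copy-number response cannot be learned); encoding when
the training genome itself carries CNAs.

## Zigzag-pole targets

For a prediction window of n bins the regression target is the vector of
n − 1 contact values, one per genomic distance d = 1 .. n−1; for each d the
bin pair whose midpoint is closest to the window centre is chosen (ties break
to the smaller index; the mirrored tie choice is kept alongside so
reverse-complement augmentation is an exact involution).  Self-interaction
(d = 0) is excluded — raw Hi-C diagonals are dominated by self-ligation.
The geometry fixes the pole length: a 1-Mb + 40-kb window at 40-kb
resolution gives 25 targets, a 2-Mb window 49, a 1-Mb + 20-kb window at
10-kb resolution 101.

## Network and training

The network is a deepC/DeepSEA-family stack: five convolution layers
(300, 600, 600, 900, 900 units; kernels 8, 8, 8, 4, 4; ReLU; max-pool widths
4, 5, 5, 5, 2; dropout 0.2) compress the base-pair input 1000-fold, ten
gated dilated convolution blocks (100 units, kernel 3, dilation
1, 2, 4, 8, 16, 32, 64, 128, 256, 1; residual `tanh ⊙ sigmoid` gating) model
window-wide context, and a dense head maps the flattened features to the
pole — separate weights per genomic distance.  Optional pretrained weights
can be loaded into the convolution stack (the chromatin-feature transfer
entry point); the default is seeded He initialization.

Training uses the summed-haplotype scheme: only windows free of SV
breakpoints are used (*breakpoint removal*), so genomic distances agree
between haplotypes, the reference projection is the identity, and exactly
two contigs per window suffice.  Both haplotype windows are forwarded,
their poles summed, and the mean squared error against the observed **raw**
total counts is minimized with Adam (learning rate 0.001, epsilon 0.1),
L2 strength 0.001 on all trainable weights, batch size 1, at most 10
epochs, keeping the best-validation parameters.  Targets are kept in raw
count units deliberately: the Adam epsilon of 0.1 is calibrated for
raw-count gradient magnitudes, and normalizing the targets would let the
epsilon dominate the adaptive denominator and freeze the lower layers.
The head bias is initialized to the per-distance mean of the training
targets so the step budget is spent on sequence-specific structure rather
than on the overall distance decay.  Predicted counts are clamped at zero
on output.  At test time the forward prediction and the prediction on the
reverse-complemented input are averaged.

Two augmentations can double the training data each: re-binning raw read
pairs on a half-bin-shifted grid, and reverse-complement training with the
mirrored pole.  Transfer to a larger window copies the convolution and
dilated stacks verbatim and re-initializes only the distance-specific head.

The convolution stack can also be pretrained on a cheap sequence-feature
task before contact training — the package's analog of transferring a
chromatin-feature model.  Short genomic tiles (4 kb, one per pooled feature
position) are labelled with per-position occupancy of a sequence feature
(for the synthetic world, the TAD-boundary motif on either strand; tiles
are emitted in random orientation so the detector is strand-symmetric), and
the stack — *including the 1×1 channel projection that feeds the dilated
blocks* — plus a temporary position-shared logistic head is fit with
minibatch Adam on the per-position cross-entropy.  Pretraining through the
projection matters: a random projection from the wide convolution output to
the narrow dilated-block width buries the learned feature direction, and a
head trained on such features can only memorize windows.  Tiles are ~1000x
shorter than prediction windows, so pretraining costs a small fraction of
the main training while removing the hardest part of the optimization
(discovering localized sequence detectors from a contact-level loss with
batch size 1).

When a pretrained trunk is supplied, contact training runs in *transfer
mode*: the convolution stack and projection stay frozen and only the
dilated blocks and the distance head update (backpropagation stops at the
trunk).  At desk-scale sample counts, fine-tuning the trunk trades its
transferable features for window memorization; freezing it makes held-out
accuracy rise steadily over epochs instead of depending on the optimization
trajectory.  Best-epoch selection uses the mean per-distance correlation on
the validation poles (the deployment metric) rather than validation MSE,
whose differences between structure-learning and mean-predicting models are
masked by the counting-noise floor.

## Contig-to-total conversion

Each contig bin is assigned the reference bin contributing the most bases
(*maximum match*; e.g. a 40-kb contig bin holding 30 kb of one reference bin
and 10 kb of the next maps to the first; equal overlaps break to the lower
reference bin).  A contig bin pair projects to the canonicalized reference
pair, or to nothing if either bin has no reference overlap.  Projected
values are summed per reference pair into haplotype matrices and the total;
a provenance ledger (reference pair → contributing contig pairs) is kept.
The merge conserves the upper-triangle grand total exactly.

*SV windows* are the reference pairs whose signal exists only because of a
rearrangement: a contribution flags its pair when the contig bin pair
straddles a segment junction **and** the reference relationship differs from
the contig one (different chromosomes, or a different bin distance).
Copy-number-scaled contacts at reference adjacency are deliberately not SV
windows, and pairs folding onto the reference diagonal are dropped —
self-interaction bins are excluded from contact modelling throughout, so
they carry no comparable prediction.

## Contig-specific normalization

ICE balancing is applied per contig matrix, not to the total: per-contig
maps are free of copy-number and SV biases, so iterative correction removes
only residual per-bin multiplicative bias.  The observed matrix factorizes
as c(i′,j′) = b(i′) b(j′) t(i′,j′) with the balanced t satisfying, for each
non-empty row, Σ over |i′−j′| > 1 of t = 1.  The diagonal and first
off-diagonal are masked from the marginal constraint; all-zero rows are
dropped from balancing and reported with NaN bias.  Band-limited matrices
(NaN outside the predicted band) balance on the *mean* of each row's
observed masked entries — sum-based balancing of a zero-filled band would
inflate truncated edge rows and manufacture contrast artifacts.  Defaults:
tolerance 1e−8 on the marginal deviation (so marginals are equal well within
1e−6), at most 300 iterations.  Consequences verified in
tests: t is invariant to any positive scaling of the input (hence to μ),
balancing is idempotent, and the factorization reconstructs the input to
rounding error.  Note that with the mask, a constant matrix does *not*
balance to exactly equal biases — edge rows have fewer unmasked terms.

## TAD calling

TADs are called by recursive spectral bisection.  Sign changes of the
first four nontrivial eigenvectors of the symmetric normalized Laplacian of
the contact submatrix propose contiguous boundaries (the Fiedler vector
alone only proposes near-central splits on decay-dominated windows);
because the eigenvectors are smooth, each proposal is expanded by ±3 bins
and the candidate with the best *distance-matched contrast* is taken: the mean over distances d of
(mean within-domain contact at d) / (mean cross-boundary contact at d),
d up to the smaller domain size.  Matching distances keeps the universal
distance decay from manufacturing splits.  Observed (count) matrices are
ICE-normalized before calling; *predicted* contact bands are called raw —
model outputs carry no per-bin experimental bias, and balancing a narrow,
block-dominated band absorbs the domain signal into the bias estimate and
can invert the contrast at the very boundaries of interest.  A split is accepted when the
contrast exceeds a per-level threshold (1.5, 1.35, 1.25 for primary,
secondary, tertiary), domains keep at least 3 bins, and the accepted
partition is refined recursively — children nest in parents by
construction.  A uniform matrix yields one domain.  Bit-compatibility with
any external TAD caller is not a goal.

## Neo-TADs and enhancer hijacking

A contig TAD is a *neo-TAD* when its span crosses an SV junction, or when
no reference TAD reproduces its reference projection at reciprocal overlap
≥ 0.9.  For a neo-TAD, the number of *overlapping TADs* counts other
contigs' TADs whose reference contact footprint (the set of reference pairs
with non-zero contribution from inside the TAD) shares more than 10 % of the
neo-TAD's footprint.

A TE/SE hijacking event of a gene in a neo-TAD requires both: (1) the gene
and the enhancer do not co-exist in any reference TAD expanded by a ±40-kb
offset (absorbing boundary-calling error), and (2) their bin pair lies in an
SV window with predicted contact > 0.  Gene and enhancer positions are
reduced to the bin of their interval midpoint.  Enlarging the offset can
only remove events.  Neo-loop calling is out of scope; externally produced
loop lists (BEDPE) can be intersected with the same machinery.

## Evaluation metrics

**DSC** (distance-stratified correlation): Pearson correlation between
prediction and observation computed per genomic distance d = 1 .. D, then
averaged with equal weight; strata with fewer than 3 valid pairs or zero
variance are excluded (not NaN-propagated).  DSC is invariant to
per-distance affine rescaling with positive slope, so it measures
position-specific structure, not the shared decay.  **Window Pearson** is
the plain correlation over a window's (or SV-window pair set's) entries —
used where distance stratification is meaningless, i.e. on SV-derived
contacts.

**Overexpression stage**: expression is regressed on integer copy number in
reference samples (ordinary least squares); each neo-TAD sample is scored by
its Cook's distance against that line (the sample is added to the reference
set, the standard leverage/residual formula with p = 2 applies, and deleting
it recovers the reference fit exactly — the identity the tests exploit).
A sample is called overexpressed when D > 4/n with a positive residual from
the reference line.  A gene is *recurrent* when more than half of its
neo-TAD samples are called and it has at least 4 SE-hijacking samples; its
overexpression threshold is the minimum expression among called samples.
Constant copy number among references falls back to an intercept-only fit.

## Synthetic data generator

The generator emulates every input the pipeline consumes: a random reference
genome (uniform base composition), two phased SNP sets (per-base Bernoulli,
default 1e−3), SV contigs of the five canonical classes, and raw contact
matrices.  Counts follow a Poisson distance-decay + TAD-block model: for
contig bins i ≠ j,

    λ(i,j) = μ · depth · |i−j|^(−α) · enrichment^[same TAD block],

with α = 1, depth = 100 expected reads per bin pair at one-bin distance, and
4-fold within-block enrichment; the diagonal gets 10 · μ · depth, mimicking
the inflated self-interaction of raw Hi-C that the pole extraction must
exclude.  Counts are sampled on the upper triangle and mirrored.

TAD structure is tied to sequence: the reference carries a planted 12-bp
boundary motif (a G run, a deliberately simple CTCF-proxy) at positions with
exponential spacing of mean `tad_mean_size` (60 kb), and the blocks of *any*
contig are the motif occurrences in that contig's own realized sequence, on
either strand.  This preserves the property that rearrangements reshape
domains — duplications and translocations create junction-spanning blocks
with no reference counterpart — while making contact structure a function of
sequence that a model can actually learn.  The generator does **not** model
read-level noise, Hi-C overdispersion, GC/mappability bias, loops,
compartments, or subclonal (fractional) copy number; passing the recovery
study therefore demonstrates that the pipeline's machinery is correct and
trainable, not that the network matches experimental Hi-C.

## Desk-scale recovery study

The end-to-end study simulates a 4-Mb diploid genome (two 2-Mb chromosomes,
4-kb resolution): a ~100-kb tandem duplication on haplotype 1 of chr1 and a
reciprocal translocation t(chr1;chr2) on haplotype 2, with breakpoints
placed in the interior of TAD blocks (between motifs), the way a positive
control is constructed.  A synthetic gene sits just upstream of the chr1
translocation breakpoint and a super-enhancer just downstream of the chr2
breakpoint, so the fusion contig juxtaposes them inside one junction TAD;
decoy annotations (a TE sharing the gene's reference TAD, distant gene and
TE) exercise the suppression rules.

SV-free 200-kb windows are split 80/10/10 (train/validation/test 1) with
breakpoint-containing windows set aside as test 2.  The trunk (convolution
stack plus channel projection) is first pretrained on boundary-motif
occupancy (3000 minibatch steps over 2000 balanced 4-kb tiles drawn
genome-wide; sequence-only, no contact targets involved).  The scaled-down
predictor (window 104 kb at 4-kb resolution → 25 targets, units divided by
10, dropout off) then trains in transfer mode — trunk frozen, dilated
blocks and distance head updating — on every second window position for up
to 10 epochs (~1600 batch-1 steps), keeping the state of the epoch with
the best validation correlation (validation poles at every position).
Reverse-complement augmentation is available but off here: at this step
budget it splits optimization over the symmetrized problem and lowers
held-out accuracy; the pretext task carries the strand symmetry instead.  Recovery is
measured as (a) DSC on test-1 windows of the strand-averaged summed-
haplotype prediction against the simulated raw total, (b) Pearson
correlation on SV-window pairs of the merged prediction around every SV
junction, (c) recovery of a junction-crossing neo-TAD at the duplication
after per-contig ICE and TAD calling, and (d) recovery of the planted SE
hijacking event at the translocation.  The noise-free intensity oracle puts
the DSC ceiling of this design near 0.96.  Problem sizes (200-kb split
windows, stride-2 center sampling, ≤10 epochs) were chosen so the full study
runs in minutes on one CPU core.

The overexpression stage is validated separately on planted fixtures: 90
samples with expression linear in copy number (unit noise), 8 neo-TAD
samples boosted by 5 standard deviations; the 4/n + positive-residual rule
is expected to recover all planted samples, and the Cook's distances are
checked against an independent leave-one-out refit oracle.

## Numerical and design choices

* Coordinates are 0-based half-open; bin b covers [b·res, (b+1)·res).
* Maximum-match ties break to the lower reference bin index.
* Zigzag tie-break: smaller i; the mirrored choice is stored for exact
  reverse-complement augmentation.
* Self-interaction exclusion means d = 0 only; d = 1 is included (pole
  length n − 1 forces this arithmetic).
* The L2 strength applies to all trainable weights (coupled with Adam).
* Contigs with fractional or subclonal copy number are out of scope; μ is a
  positive integer.
* The triplet text dialect is extended with a five-column interchromosomal
  form, since translocation contacts cannot be expressed chrom-locally.
* Band-limited predicted matrices use NaN for never-targeted entries;
  NaN-aware code paths treat them as absent (merge) or as zeros
  (normalization input).

## Known limitations

* The CNN engine is a compact CPU implementation; full-size configurations
  build and run forward but training them is impractical without
  accelerator hardware, and no attempt is made to reproduce published
  trained weights.
* The Poisson generator understates the dispersion of real Hi-C; thresholds
  tuned here (TAD contrast, reciprocal overlap) would need re-examination on
  experimental data.
* The spectral TAD caller is deterministic but its contrast thresholds are
  package conventions, not re-derivations of any published tool's output.
* Subclonal copy number, read-level simulation and loop calling are out of
  scope.
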