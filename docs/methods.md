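# Methods

This note documents the models and procedures `slidemae` implements, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish.

## Hybrid slide representation

A slide is tiled into non-overlapping l×l-pixel patches (default l=224 at
10×, 1 µm/px). A fixed patch encoder maps each foreground patch to a
d-vector; only foreground vectors and their integer grid coordinates are
stored (one HDF5 group per slide; float32 features). Coordinates are
0-based with x = column, y = row; patch (x, y) covers the half-open pixel
square [x·l, (x+1)·l) × [y·l, (y+1)·l). Background positions are
reconstructed as zero vectors when a region is materialised, which keeps
the store linear in tissue area rather than slide area.

Foreground is decided on a thumbnail-resolution tissue mask (0.3125×,
32 µm/px): a pixel is tissue iff it is not near-white (min channel < 220)
and red+blue dominate green (blue ≥ green and red ≥ green − 10) — an H&E
"purple" rule; the raw mask is cleaned by 3×3 binary closing then opening.
A patch is foreground iff ≥ 5% of its footprint on the mask is tissue; the
boundary is compared in integer arithmetic so exactly 5% counts. Computing
the fraction at thumbnail rather than full resolution is an approximation
(a patch footprint covers ~7×7 mask pixels at the default scales).

Two encoders ship. `HashingPatchEncoder` hashes patch bytes into a
pseudo-random vector — deterministic plumbing for tests, no visual
structure. `RandomProjectionEncoder` resizes the patch to 16×16×3 and
applies a frozen Gaussian projection; it preserves pixel-space similarity
(Johnson–Lindenstrauss) which is the property the pretext task needs. The
encoder interface is pluggable, so a CNN backend can be dropped in where a
deep-learning stack is available; pretrained CNN weights are deliberately
out of scope here.

## Region encoder

Regions are n×n patch windows (default n=20, i.e. 4480 px) containing at
least 25% foreground; sampled regions of one slide overlap by at most 50%
of the region area. The encoder is a pre-norm ViT-style transformer:
L layers (default 12), H heads (default 8), width d (default 512, matching
common patch-feature dimensions), MLP hidden size 4d with GELU, dropout 0.1
in attention and MLP (training mode only).

Positions enter as `concat(P_x[x], P_y[y])` from two learnable n_max×(d/2)
tables added to every patch token (not to the class token). Background
cells are excluded from attention by an additive −∞ bias before the
softmax, which yields *exactly* zero weight on padded keys and
renormalises each row over valid keys; background features are also
force-zeroed at input, so no value at a padded position can influence any
output (verified bit-exactly in the tests). In the no-position limit
(zeroed tables, one layer) the encoder is permutation-equivariant over
patches, which the tests use as a closed-form sanity check.

**Positional initialisation.** Tokens and positional tables default to
Normal(0, 0.02), the BERT/ViT convention. That convention presumes input
embeddings of comparably small scale; when order-one patch features are
fed directly and the optimisation budget is short, a 0.02-scale position
is invisible to attention and the model converges to position-agnostic
averaging. `pos_init_sd` is therefore a model hyperparameter; the toy
profile sets it to 1.0 (the synthetic features' scale). The full-scale
profile keeps 0.02.

## Masked pre-training

Blockwise masking accumulates rectangles — area uniform between a minimum
block size and the cells still needed, aspect ratio log-uniform in
[0.3, 1/0.3], placement uniform with clipping at the grid edge so per-cell
coverage is spatially unbiased — until the masked fraction reaches p
(default 0.5, counted over *all* cells; achieved rate within ±0.05 of p by
construction). The minimum block area is 16 patches on a full 20×20 region
and scales proportionally for smaller grids; a fixed 16 would cover a
quarter of a toy 8×8 region in a single block and leave masked cells with
no visible context. Masked foreground cells are replaced by the learnable
mask token; unmasked and background cells are excluded from the loss.

The restoration loss pools the masked foreground patches of the whole
batch into one list of length k and averages

    L_i = α‖x_i − y_i‖² + β·l(x_i, y_i),
    l(x_i, y_i) = −log [ exp(−‖x_i−y_i‖²/τ) / Σ_{j≤k} exp(−‖x_j−y_i‖²/τ) ]

with α=2, β=1, τ=0.1 by default. The contrastive softmax uses *negated*
squared distances as logits: a literal positive sign inside the exponent
would reward a large positive-pair distance and contradict the term's
purpose (pulling the restored feature toward its own target while pushing
it from the other pooled targets), so the standard sign is used. Both
terms are computed with log-sum-exp stabilisation; the mean (not sum) over
the pool is the reduction.

Training follows linear warmup to the peak rate then cosine decay to zero
(peak 4e-5 over 8000/400 000 steps at full scale; 3e-3 over 50/1500 steps
in the toy profile, chosen so the toy run converges within minutes on one
CPU). AdamW uses β=(0.9, 0.999) and weight decay 0.05 applied to matrix
weights only — norm gains, biases, positional tables and tokens are
exempt, the usual ViT practice. 80% of slides (by slide, not by region)
train the model; the held-out 20% only monitor the loss, and the
best-monitor checkpoint is kept.

## Fine-tuning and evaluation

Regions are sampled per slide (random with the overlap cap, or a
deterministic raster whose stride respects the cap), encoded without
masking, and their class tokens averaged into the slide representation. A
"regions × coverage" schema controls sampling: coverage c keeps a uniform
c-fraction of each region's foreground patches and backgrounds the rest,
preserving the positional structure of the kept patches.

A linear head maps the representation to a Cox risk score or class
logits. The Cox loss is the negative log partial likelihood with risk set
{j : T_j ≥ T_i} (Breslow for ties; censored subjects enter only through
risk sets). Parameter groups: head at 1e-3 (survival) / 3e-3
(classification), backbone at 1e-5. The monitor metric (validation loss
for survival, validation macro AUC for classification) must improve
strictly; after `patience` = 5 stagnant epochs training stops and the
best-epoch weights are restored. An epoch is one pass over the training
slides.

Metrics: Harrell's concordance index — a pair (i, j) is comparable iff
δ_i = 1 and T_i < T_j strictly, risk ties count ½ — and macro-averaged
one-vs-rest AUC (classes absent from the labels are excluded with a
warning).

## Attention maps

Per-layer attention is head-averaged; rollout multiplies the per-layer
matrices with later layers on the left (A = A_L···A_1) so the class-token
row of A reads "information flowing into the final class token". The row
is restricted to patch columns and renormalised to sum to one over
foreground. No residual ½(A+I) correction is applied by default (the plain
recursive product); if the class-token row carries essentially no patch
mass — the identity-attention edge case — the map falls back to uniform
over foreground with a warning so the unit-sum contract always holds.
Query-key maps show one query patch's head-averaged row at a chosen
layer, class column dropped and renormalised. Adaptation maps are the
elementwise difference of fine-tuned and pre-trained rollout maps and sum
to zero over foreground. Slide-level heatmaps paint per-patch values at
patch footprints, averaging where regions overlap, on a diverging red
(high) / blue (low) scale with transparent background.

## Synthetic cohorts

The generator emulates the two statistics the method exploits. (1) Motif
structure: each slide carries a latent field over a small set of tissue
motifs, built by nearest-centroid classification of independently smoothed
Gaussian fields (correlation length 2.5 patches), so motif patches form
contiguous territories. The motif centroids — the "tissue vocabulary" —
draw from their own fixed seed shared by every cohort, because tissue
appearance is common across datasets; without this, pre-training and
fine-tuning cohorts would live in unrelated feature spaces and transfer
would be impossible by construction. (2) Feature continuity: patch
features are the motif centroid plus Gaussian noise that is itself
spatially smooth (correlation length 1.5 patches, marginal sd 0.75
against unit-scale centroids). Both properties matter. Smooth rather than
white noise means context carries instance-level information — as tissue
continuity does in real slides — without which the contrastive term
degenerates to an unsatisfiable instance-discrimination problem. Noise at
three quarters of the centroid scale leaves single-patch motif identity
genuinely ambiguous, so aggregating context (what pre-training teaches)
helps downstream; with near-noiseless patches the slide label is
decodable from composition alone and pre-training has nothing to add.
Foreground is a thresholded smooth blob covering ~80% of the grid.

Outcomes depend on spatial co-occurrence, not composition: the survival
log-hazard is 1.5 × the z-scored adjacency count of one motif pair
(exponential times, independent uniform censoring calibrated to a 30%
rate), and the classification label indicates which of two designated
motif pairs is more often adjacent. Both are invisible to a bag-of-patches
model by construction.

## Toy-scale experiment protocols

`slidemae.experiments` packages three seeded protocols. The *context*
protocol pre-trains a toy encoder (d=32, L=2, H=4, n=8 regions, 1500
steps, batch 8) on a 24-slide cohort and measures masked restoration
error on the held-out monitor slides against the best context-free
constant predictor (the mean foreground feature). The *transfer* protocol
fine-tunes that encoder on an independent 80-slide classification cohort
— three repetitions, each pairing a pre-trained-initialised and a
from-scratch branch on identical seeds, slides, splits and schedules —
and scores both branches on a further independent 64-slide test cohort;
means over the paired repetitions are reported so the comparison is not
decided by one optimisation trajectory. The *survival* protocol
fine-tunes a Cox head the same way and reports the test-cohort c-index.
The toy fine-tuning backbone rate is 1e-4 rather than the full-scale
1e-5: over the ~250 optimisation steps of a toy fine-tune, the
full-scale rate leaves the backbone numerically frozen (and the class
token receives no gradient during pre-training, since the restoration
loss reads only patch outputs), which would reduce both branches to
linear probes.

What the toy results do *not* show: real WSI feature distributions
(ResNet embeddings are neither Gaussian nor isotropic), magnification
effects, staining variation, or the full-scale optimisation regime
(400 000 steps, batch 64, d=512). The toy profile was sized to run each
protocol in minutes on a single CPU while leaving the qualitative claims
— restoration learns context, pre-training transfers — testable.

## Numerical and degenerate-input choices

- Masked softmax rows with no valid key return all zeros (cannot occur in
  a legal region, which must contain ≥1 foreground patch).
- A batch whose mask plans cover no foreground patch raises
  (pre-training skips such batches with a warning counter).
- Cox loss requires ≥1 event; the c-index requires ≥1 comparable pair;
  both raise informative errors otherwise.
- The restoration pool distance matrix is computed with log-sum-exp; the
  k=1 InfoNCE term is exactly 0.
- Equal-risk ties contribute ½ to the c-index; tied event times share a
  Breslow denominator.
- Checkpoints store float64 weights plus the model config; loading
  reconstructs the architecture and verifies shapes.

## Known limitations

- The numpy autodiff engine is single-threaded and eager; it is sized for
  the toy profile and would be impractical at d=512, L=12, batch 64.
- The paper-scale profile is exposed in configuration but not exercised
  end-to-end by the tests.
- Region proposal is rejection sampling with a 1000-proposal cap per
  region; on slides with very little tissue it may return fewer regions
  than requested (with a warning) rather than search exhaustively.
- The contrastive term and the L2 term pull in different directions when
  pool entries are near-duplicates; on small pools the compromise raises
  the restoration error above the pure-L2 optimum. The default α=2, β=1
  keeps both terms, as the combination is what the downstream tasks
  benefit from.
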