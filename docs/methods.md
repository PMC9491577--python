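# Methods

This note documents the models, the synthetic data, the numerical choices,
and the limits of what the test suite demonstrates.

## Problem setting

The package decodes which of N image classes a person is looking at — or
imagining — from multichannel EEG, and studies two questions around that
task: whether the representation evoked by *seeing* an image is also
present (weaker, noisier) while *imagining* it, so that pooling the two
tasks at training time improves the hard imagination task; and whether the
channel-attention weights of the trained network can be read back as
statements about which frequency bands and electrodes carry the signal.
A third component conditions an image generator on the classifier's EEG
feature vector.

## Preprocessing

Raw sessions are band-pass filtered 1–50 Hz with a 4th-order Butterworth
applied forward-backward (zero phase, so epoch timing is preserved).
Visual sessions are cut into one 500 ms epoch per stimulus; each 10 s
imagination period is cut into 20 non-overlapping 500 ms segments that all
inherit the cue's label. Epoch windows are half-open `[t, t+500 ms)` with
0-based sample indices.

Trials whose peak-to-peak amplitude exceeds 300 µV on any channel are
dropped and logged — an automatic surrogate for manual inspection of
movement artifacts; the threshold is a config knob. Ocular artifacts are
removed by ICA (FastICA, fixed seed, fit on the continuous band-passed
recording, which has far more samples than any epoch): components whose
absolute Pearson correlation with the Fp1/Fp2 time courses exceeds 0.6 are
subtracted. Because the removal is one linear map, the same fitted cleaner
applies to continuous data and to epochs; the pipeline fits on continuous
data and cleans the surviving epochs. Rejection precedes ICA cleaning in
the pipeline order.

Epochs are then decimated to 250 Hz (Chebyshev anti-alias filter,
zero-phase), average-referenced per time point, and each channel is
z-scored over time within the trial. A 500 ms epoch ends up as 125
samples. Note the order: the average-reference identity (channel sums
exactly zero) holds *before* z-scoring; the per-channel standardization
afterwards perturbs it slightly.

## The classifier

The network is a filter-bank variant of the compact EEGNet family. Its
first layer is a bank of 16 band-pass FIR kernels of 65 taps whose only
learnable parameters are, per filter, a low cutoff f₁ and a bandwidth b:

    g[n] = (2 f₂ sinc(2 f₂ tₙ) − 2 f₁ sinc(2 f₁ tₙ)) · w_hamming[n],
    f₁ = 1 Hz + |raw_low|,   f₂ = f₁ + 4 Hz + |raw_band|,

unit-energy normalized, with f₂ soft-clipped below Nyquist
(min(x, c) = x − relu(x − c), so the gradient survives everywhere below
the clip). The absolute-value-plus-floor construction guarantees
f₁ ≥ 1 Hz and b ≥ 4 Hz for any raw value while staying differentiable;
the passband is readable directly from the two scalars, which is what the
interpretation stage exploits.

Each band-passed copy of the electrodes is collapsed by a depthwise
spatial convolution (kernel spanning all channels, depth multiplier 2), so
spatial filter k belongs to band-pass filter ⌊k/2⌋. A
squeeze-and-excitation gate then produces one weight per feature map:

    a = σ( MLP(avgpool_t(x)) + MLP(maxpool_t(x)) ),   out = x · (1 + a),

with a single shared hidden layer of width maps/r (r = 8 by default).
The residual multiplicative form `x·(1+a)` is a deliberate choice: the
gate modulates rather than replaces the maps, and the gate vector `a` is
the attention map used downstream. The rest of the stack is standard:
ELU, average-pool 4, dropout, separable convolution (depthwise kernel 8,
same padding, then pointwise to 32 maps), ELU, average-pool 3, dropout,
flatten (32 × 10 = 320 at 125 input samples), dense 512 → dense 2048 →
softmax over the classes. The 2048-unit layer is the *EEG feature* layer:
its output is pulled toward image-embedding targets during visual trials
and conditions the generator.

Batch normalization follows each convolution (statistics over batch and
time, per feature map; evaluation mode uses running statistics), and
dropout is 0.5 at full scale. Temporal convolutions use same padding so
the pooling arithmetic 125 → 31 → 10 holds.

### Numerical core

No deep-learning framework is used: the package carries a small
reverse-mode autodiff engine over NumPy arrays (`sincdecode.autodiff`)
and a layer library (`sincdecode.nn`) built on it. Convolutions use
sliding-window views with einsum contractions; input gradients scatter-add
per kernel tap. Every primitive's gradient is tested against central
finite differences. Computation is float64 throughout the networks;
synthetic raw sessions are float32 to bound memory.

## Training

The loss is cross-entropy plus a feature-matching term,

    L = CE(softmax(logits), y) + MSE(F_eeg, F_target)  over visual trials,

where the MSE is averaged over feature dimensions and over the trials of
the batch that came from the visual task (imagining subjects saw no
image, so no target exists there; the term vanishes on all-imagination
batches). Targets come from a `FeatureProvider`: a deterministic map from
class label to a unit-norm vector (2048-dim at full scale). The provider
stands in for a pretrained image network's penultimate layer; any
per-image embedding source can be plugged in instead.

Data are split 80/10/10 stratified per class label (imagination segments
of one block may cross splits — the split is per label, matching how the
study protocol divides the data). Optimization is Adam at 5·10⁻⁴ with
early stopping on validation loss (patience 30 at full scale; the
best-validation epoch's parameters are restored). Validation loss, not
accuracy, is the stopping criterion — the conventional choice. For the
mixed regime the stopping criterion is the loss on the pooled validation
set of both tasks. Default batch sizes are 128 (visual, mix) and 64
(imagine), which roughly equalizes steps per epoch when the visual set is
about twice the imagination set; in the desk-scale experiments the two
task sets are equal-sized and a single batch size of 64 keeps the same
parity. Mixed batches are drawn from the pooled training set without
enforcing task ratios — the simplest scheme consistent with pooling; a
task-ratio option would be a straightforward extension.

## Interpretation

With a trained model and a dataset, attention values are extracted per
trial in evaluation mode and averaged: A_ave = (1/n) Σ Aᵢ. Two linear
read-outs follow.

*Spatial*: F_WS = Σⱼ A_ave[j] · |Fⱼ| over the depthwise kernels' absolute
channel weights, divided by its maximum. The absolute value reflects that
a large weight matters regardless of sign; the attention weight reflects
that highly-gated maps matter more. Per-frequency-block maps restrict the
sum to filters whose passband overlaps the block (Low < 15 Hz, Mid 15–35,
High > 35; a filter spanning a boundary joins every block it overlaps —
membership is computed from passband overlap rather than picked by hand,
and an explicit index list can be supplied instead). Difference maps are
taken before any renormalization, so they are antisymmetric.

*Spectral*: the attention-weighted sum of the sinc kernels themselves
(spatial filter j contributes its parent kernel), normalized by its
maximum and then Fourier-transformed (n_fft = 1024 zero-padded, <0.25 Hz
bins at 250 Hz). Normalization precedes the transform, following the
algorithm ordering rather than the figure caption where the two differ.
Filters are ranked by average attention, descending, ties broken by
ascending index; each carries its (f₁, f₂) and center frequency
(f₁+f₂)/2.

These read-outs characterize the classifier, not the cortex: a map weight
is where *the model* looks, which coincides with the source only insofar
as the model is right.

## The conditioned generator

The generator seeds a transposed-convolution stack with
z = eeg ⊙ (μ + σ ⊙ ε), where μ, σ are trainable 2048-vectors and ε is
standard normal, redrawn each forward pass (fixed by seed when sampling).
σ is used unconstrained, exactly as the conditioning formula states; a
positivity transform is not applied. z is reshaped to a 1×1 spatial map
and upsampled 1→4→8→16→32→64 through five blocks (512/256/128/64/3
filters, kernel 4, stride 1 then 2, valid then same padding; batch norm +
LeakyReLU(0.2) between blocks, tanh at the output). 64×64 is the only
output size consistent with that block arithmetic, so training images are
resized to it.

The discriminator is a VGG-style stack of ten 3×3 conv blocks
(64,64,128,128,256,256,256,512,512,512 filters — the VGG16 progression
truncated to ten blocks), max-pooled after blocks 2, 4, 7 and 10, with
dropout 0.3 after each pool and dense layer, feeding a real/fake head
(1024→1, sigmoid) and a class head (1024→1024→N, softmax). Discriminator
loss: BCE(real→1) + BCE(fake→0) + CE(class | real). Generator loss:
BCE(fake→1) + CE(class | fake). Adam at 10⁻⁴ with β₁ = 0.5, batch 16.

Two structural consequences are used as tests: zeroing the EEG feature
vector forces z = 0 and hence a noise-independent image (conditioning
pathway integrity), and after even a short training run the between-class
variance of mean generated images exceeds the within-class variance over
noise resamples.

## Synthetic data: what it emulates and what it does not

Each class carries a band-limited oscillation — a Hann-enveloped sinusoid
with carrier drawn uniformly from the class band and random phase per
trial — projected onto a class-specific scalp topography (a Gaussian bump
over channel index plus random texture, unit norm), on top of pink (1/f)
background noise matched to a target SNR over the signal spans, plus
sporadic 300 ms half-cosine frontal transients (unit weight on Fp1/Fp2,
exponential decay toward posterior channels) at a configurable rate per
minute. Pink noise rather than white is deliberate: the sinc layer must
find narrow bands against a 1/f background, as in real EEG.

`shared_fraction` controls what fraction of each class signature's power
comes from a generator (band + topography) common to both tasks; the
remainder is task-specific, with task-specific bands drawn by permuting
the class-band assignment. At 1 the tasks share their class code entirely
(visual training transfers); at 0 the codes are unrelated (transfer sits
at chance). Imagination runs default 8 dB below the visual SNR
(`imagine_snr_db`), encoding the study's premise that imagination
signatures are far weaker than perception signatures. Per-subject
topography jitter (`topo_jitter`, default 0.1) is exposed as a knob
without any claim of fidelity to real inter-subject variability.

Defaults mirror the full layout: 4 subjects, 40 classes, 50 visual
stimuli per class at 500 ms, one 10 s imagination block per class, 128
channels at 2 kHz — hence the identities 4 × 40 × 20 = 3200 imagination
trials and 40 × 50 = 2000 stimulus images.

What the generator does *not* model: no head-model forward projection (a
topography is a weight vector over channel index, not electrode
geometry), no eye movements beyond the stereotyped transients, no
inter-trial dependence, no non-stationarity, no gray-canvas/mask stimuli.
Consequently, passing tests show that the pipeline recovers the structure
it is pointed at under EEG-like noise; they say nothing about decoding
accuracy on real recordings.

## Desk-scale study conditions

The reference experiments (`sincdecode.experiments`) run on one CPU core
in minutes and use: 8 classes, 16 channels, 500 Hz native rate, a
narrower model (8 sinc filters, attention reduction 4, dense 64/128,
dropout 0.25), ICA disabled (no artifacts are injected there), and Adam
as above with up to 50 epochs, patience 10.

* *Transfer study*: 2 subjects, 20 visual trials per class, visual SNR
  +2 dB, imagination −14 dB, shared fraction 0.9; all three regimes are
  trained with batch 64 and compared on the imagination and visual test
  splits.
* *Recovery study*: one subject, 40 visual trials per class, class bands
  tiling 8–16 Hz, sign-flipped random patterns on channels 4–7 (class
  identity lives jointly in carrier frequency and spatial phase), SNR
  +10 dB, no topography jitter; success = a top-3 attention-ranked filter
  overlapping the planted band *and* the spatial map's top decile
  intersecting the planted channels. Two details matter here. The
  planted patterns are zero-mean over channels — otherwise the average
  reference copies each class's pattern mean onto the whole montage and
  the model can decode from that leak without ever concentrating a
  kernel on the planted channels. And this study trains at lr 2·10⁻³
  rather than the classifier default: the weighted-kernel read-out
  reflects learned structure only once the depthwise weights have moved
  well beyond their random initialization; at the default step size the
  map is still dominated by the init.
* *Generator smoke study*: a three-block generator to 16×16 images,
  two-block discriminator, 200 steps, batch 16, on synthetic class-coded
  Gabor images with class feature vectors (64-dim) as conditioning.

These scales are the package's own choice of desk-scale problem size;
the full-scale configurations remain the defaults of every module.

## Known limitations

* The NumPy networks are CPU-bound and single-threaded beyond BLAS; the
  full 128-channel, 40-class model trains, but slowly — the package is a
  faithful, testable implementation, not a high-throughput trainer.
* FastICA occasionally fails to converge within its iteration budget on
  short recordings; the fitted removal is still applied (warning logged).
* Early stopping for the mixed regime uses the pooled validation loss;
  per-task stopping criteria are not implemented.
* The subject-asymmetric mixed protocol (one subject's imagination data
  pooled with *all* subjects' visual data) is supported by concatenating
  trial sets accordingly, but the reference experiments pool
  symmetrically.
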