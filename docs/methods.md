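# Methods

`optomap` reimplements an unsupervised behavior-space phenotyping pipeline
for optogenetic activation screens in freely walking flies: raw video (or
ground-truthed synthetic sessions) is distilled into a 2D map of postural
dynamics, and trial-structured red-light stimulation is scored for which
map regions it activates, with what timing, and how strongly the evoked
behavior depends on what the animal was doing beforehand. This note
documents the models, the estimators, the numerical choices, and what the
synthetic benchmark does and does not establish.

## The measurement model

**Frame preparation.** Each grayscale fly-centered frame is segmented by
Canny edge detection followed by morphological dilation (radius 3 px),
hole filling, largest-component selection, and an erosion one size smaller
than the dilation so thin appendages survive while the mask hugs the
outline. Canny thresholds are set per frame from gradient quantiles (low
0.1, high 0.3 of the maximum gradient). Flies are assumed identical in
shape but variable in size: foreground intensities of ≥100 sampled frames
are split by a two-component Gaussian mixture into bright body pixels
(head/thorax/abdomen) and dim appendage pixels, and every frame is
uniformly rescaled by `sqrt(reference_area / body_area)` so body-pixel
counts match a common reference. A degenerate mixture (component means
closer than 10 intensity units) falls back to an Otsu split, and to the
full foreground area when even that is undefined. Rotational alignment
maximizes the angular cross-correlation of polar Fourier-transform
magnitudes against a common reference; we use the **log**-magnitude
spectrum (the raw spectrum is dominated by the DC-adjacent peak and yields
~1–2° errors; log compression brings recovery below 0.5°), 360 angular
bins (1°/bin) with quadratic interpolation of the correlation peak, and
radial bins to half the image size. The magnitude spectrum is blind to
half-turns; of the two candidate angles we keep the one placing more mass
in the image's top half (synthetic flies are rendered head-up — real data
would need an anatomical prior). Translational alignment is an
integer-pixel argmax of the spatial cross-correlation; sub-pixel
refinement is not attempted because the downstream features are wavelet
amplitudes of PCA modes, insensitive at that scale. Frames that cannot be
segmented, or whose mask reaches into the border strip where the edge
detector is blind (twice the dilation radius), are flagged invalid and
propagate as gaps.

**Postural decomposition.** Aligned frames are Radon-transformed at 2°
angular spacing (90 projection angles). The projection is implemented by
forward splatting — each pixel's value is split linearly between the two
offset bins its center projects onto — so each projection sums exactly to
the image mass (library implementations based on backward warping leak a
few tenths of a percent at object edges, which would contaminate the
variance ranking). The smallest set of highest-variance Radon pixels
capturing 95% of the total variance is retained (the count this produces
is dataset-specific and is recorded, not hard-coded), and PCA over those
pixels — exact SVD up to 20,000 pixels, seeded randomized solver beyond —
keeps the top 50 modes by default. Frames are centered with the training
mean; Radon pixels are not variance-normalized (plain PCA). Projections of
the aligned frames onto the eigenmodes give the postural time series.

**Spectral features.** Each mode series is transformed with analytic
Morlet wavelets (nondimensional frequency ω₀ = 5, scale–frequency relation
s = (ω₀ + √(2+ω₀²))/(4πf)) on 25 dyadically spaced channels from 1 to
50 Hz; only amplitudes are kept. Channels are normalized so a unit
sinusoid at a channel's center frequency reads an amplitude of 1 on that
channel (verified to within 5% across the bank), fixing the otherwise
arbitrary per-scale convention. Per frame, the mode × channel amplitudes
are flattened, floored at ε = 1e-12 (so KL divergences stay finite) and
normalized to a probability vector. Behaviors faster than the 50 Hz
Nyquist limit are invisible by construction: a 60 Hz drive sampled at
100 fps appears at its 40 Hz alias. A step change in frequency content
spreads over roughly a second — the transform's temporal smoothing — which
is why evoked density can appear to rise slightly *before* stimulus onset
and why ground-truth labels are only well defined for frames whose
neighborhood holds a single latent state.

**Embedding.** Distances between frames are Kullback–Leibler divergences
of their spectral probability vectors, computed in bulk as a single matrix
product. Because whole datasets are far too large for a direct t-SNE
minimization, a training set is distilled hierarchically: 600 exemplars
per session, pooled into groups of 36,000, each group re-subsampled
keeping twice as many points as the previous round, until one pool of at
most 36,000 remains (at desk scale these sizes shrink proportionally; a
guard terminates the recursion when a round can no longer shrink the
pool). Importance subsampling draws exemplars with probability inversely
proportional to their cell's occupancy count in a histogrammed 2D
mini-embedding of the session, so every occupied cell of behavior space
contributes the same expected number of exemplars and rare behaviors are
strongly over-represented relative to uniform sampling (a 5%-occupancy
state rises to ≥25% of exemplars in the tested two-state condition). The
mini-embedding is a Hellinger PCA — PCA of the square-rooted probability
rows — rather than a per-session t-SNE: the subsample only needs an
inverse-density weighting over occupied feature space, the square root is
the variance-stabilizing map for probability vectors (a log map explodes
near-zero channels), and the PCA route keeps the many seeded benchmark
runs tractable on one CPU; a KL t-SNE mini-embedding remains available via
`method="tsne"`. t-SNE itself runs on the precomputed KL distance matrix
(asymmetric, as the divergence is; the standard symmetrization of
affinities applies) with perplexity 32 and 1000 iterations by default,
seeded.

**Re-embedding.** Out-of-sample frames are placed by minimizing the
t-SNE-style cost of each new point against the fixed training map,
restricted to its 64 nearest training rows by KL distance, with momentum
gradient descent (40 iterations). The out-of-sample kernel perplexity is
deliberately sharp (4) so a row near-identical to a training exemplar is
dominated by its twin; a row at *zero* KL distance from an exemplar
inherits the exemplar's position outright — the embedding is a function of
the feature vector, so duplicates must coincide (the threshold, 5e-5 bits,
covers the single-precision noise floor of the distance computation).
Points failing the gradient-norm convergence test fall back to the median
position of their 10 nearest training rows. Training rows re-embedded
through this path land within 1% of the map extent of their trained
positions (median well below 0.1%); the residual handful reflect the
restriction of the cost to a neighborhood rather than the full map.

**Map geometry.** All analyses share one square grid over the training
embedding's bounding box padded by 10% (210×210 cells at full scale).
Densities are histograms convolved with an isotropic Gaussian and
renormalized; σ conventions follow the study's three printed values — 1.5
for maps and the significance analysis, 2 for entropy curves, 3 for
video-style visualization. Regions are watershed basins of the negated
smoothed density seeded at local maxima (minimum peak separation 3 px),
with cells below the 0.35 quantile of positive density as background;
raising that threshold can only remove regions, never add them. Human
curation is supported only as a JSON override file (label renames and
merges). Distances to regions are Euclidean distance transforms on the
grid; the trial-assignment rule's "within 5 pixels" is `<= 5.0`.

## Trial statistics

For fly i and cycle n, ρᵢₙᵒⁿ is the mean map density during the first 3 s
of stimulation and ρᵢₙᵒᶠᶠ during t = 30–45 s after onset — the 15 s window
furthest from stimulation (the figure legends' "last 15 s of the recovery
period" variant is available by configuration). The LED contrast is
χᵢₙ = ρᵢₙᵒⁿ − (ρᵢ,ₙ₋₁ᵒᶠᶠ + ρᵢₙᵒᶠᶠ)/2, undefined for the first cycle, and
summing to zero over cells by construction. Two cellwise two-sided
Wilcoxon rank-sum tests are applied with samples pooled over flies ×
cycles: ρᵒⁿ vs ρᵒᶠᶠ within the experimental arm, and χ experimental vs
control. The rank-sum test uses the exact null for small tie-free samples
and the tie-corrected normal approximation otherwise (verified against a
full enumeration oracle); cells where every observation coincides get
p = 1. Šidák correction uses α′ = 1 − (1−α)^(1/m) with m = ⌈2^H⌉, H the
Shannon entropy (bits) of the mean experimental density — an effective
support size, deliberately an over-estimate of the number of independent
comparisons, shared by both tests. A cell is *significantly activated*
when both tests pass at α′ **and** its mean χ is positive: cells drained
by the stimulus are significant shifts too, but they are the shadow of the
activation, not the evoked behavior, and the screen's unit of report is
the activated region. Significant regions are connected components of
that mask, each associated with its overlapping watershed regions; zero
significant regions is a valid outcome.

Entropy curves assign each embedded point its phase in the 60 s cycle,
pool points across trials and flies within ±200 ms of each phase (periodic
at the cycle boundary; 41 frames per cycle at 100 fps), smooth the pooled
histogram with σ = 2, and report Shannon entropy in bits (the curve as
printed in the source text lacks the minus sign and base; the standard
definition is used, consistent with 2^H and the log₂ elsewhere). The
baseline-subtracted variant removes the mean over the off-window phases.
Region time courses are sliding 3 s window occupancies per fly and cycle,
averaged with their standard deviation. Per-neuron maps average each
line's positive significant mean-χ map across the lines targeting that
neuron.

## Context mutual information

Each trial is assigned the region containing (or within 5 px of) the
argmax cell of its smoothed density over the first post-onset second
(ties: smaller distance, then smaller label id; row-major within the
argmax), with a zero label when every region is farther than the
tolerance. MI between the pre-stimulus density (t = −1.5 to −0.5 s; the
figure text's "−1.5 to 0.5" variant is rejected as it would leak
post-onset frames) and that label is the plug-in estimate on the grid,
with label-conditional densities averaged over trials, 0·log 0 = 0, and
zero-marginal cells excluded. It is bounded by log₂(N+1) for N regions
plus the zero label, invariant to relabeling and to adding empty regions.

The plug-in estimate is biased upward roughly as 1/n_trials. The
correction draws random trial subsets at fractions {0.5, 0.625, 0.75,
0.875} **without replacement** — each subset is a genuine smaller
experiment, so the subset means trace the finite-size bias path — adds the
full sample at fraction 1, fits the means linearly against 1/n, and
reports the intercept; the subset variance is extrapolated the same way
for the error bar (falling back to the largest subsampled fraction's
variance when the intercept is not positive). Resampling *with*
replacement was tried first and rejected: bootstrap reweighting of a fixed
sample leaves the underlying conditional-density estimates in place, so
the mean MI barely moves with nominal subset size and the extrapolation
cannot remove the bias. On shuffled labels the corrected MI centers on
zero while the raw plug-in stays positive; on a deterministic synthetic
context map the corrected value at 180 trials matches the exact
chain-level computation to within a few percent (averaged over seeded
replicate sessions — a single 180-trial session carries ~0.1 bits of
irreducible sampling noise). The "partial MI" per region is the pointwise
decomposition p(Rₖ)p(x|Rₖ)log₂[p(x|Rₖ)/Σₗp(x|Rₗ)p(Rₗ)], which sums to the
raw MI by construction.

## The synthetic arena

The generator emulates the screen's structure: 12-fly sessions (6
experimental + 6 control), 30 cycles of 15 s on / 45 s off at 100 fps. The
latent behavior process is a discrete-time Markov chain at frame
resolution (bout durations arise from self-transition probabilities —
semi-Markov dwell structure is approximated, not modeled). Each state
drives sinusoidal oscillations of designated posture modes at
state-specific frequencies (defaults: five states at 2–40 Hz primaries
with a second mode at f/1.7 and amplitude 0.6, all below Nyquist, chosen
well separated on the dyadic channel grid), with per-bout random phases so
wavelet amplitudes are stable within bouts, plus Gaussian noise
(sd 0.05). Control flies run the identical chain with the LED having no
effect. Line archetypes: *null* (T_on = T_off), *activated* (LED drives a
target state: per-frame jump probability 0.08 into it, dwell ~0.998),
*chained* (LED drives state a, which flows into state b after ~3 s,
emulating run-then-freeze), and *context* lines.

Context lines inject a controlled amount of mutual information. At each
onset the evoked target is drawn once per trial: with probability δ it is
a fixed permutation of the pre-stimulus state — read at the *start* of the
analysis pre-window, 1.5 s before onset, which is precisely the quantity
the pre-window density measures — and with probability 1−δ an independent
draw from a base distribution (uniform by default); the target is held for
the stimulation window. δ = 0 therefore makes the evoked response exactly
context-free, δ = 1 deterministic. (A per-frame mixing of a context map
into T_on was implemented first and rejected: any δ > 0 makes the mapped
state absorbing within a few frames, so δ cannot interpolate the injected
information.) Two oracles are computed by exact enumeration over the known
chain: the state-level MI between pre-state and evoked target (stationary
distribution × the δ-mixed draw), which is provably non-decreasing in δ;
and the window-level asymptotic MI, which combines forward
transition-matrix powers (the window-averaged occupancy conditioned on the
anchor state) with the evoked-label distribution — exact when each state
owns a disjoint map territory, which the benchmark geometry guarantees.

An optional renderer draws an ellipse-bodied fly with a head blob and
appendage blobs whose angles follow the mode series, under a global
rotation/translation random walk, flagging frames where the fly leaves the
image; it emits the acquisition rig's text dialects (LED log sampled every
few frames, centroid CSV). The cartoon is deliberately minimal — it
exercises segmentation, size normalization and alignment, not fly
biomechanics.

For MI estimator studies a *state-cluster emulation* bypasses the
posture/wavelet/embedding stages: frames are placed directly at their
latent state's Gaussian cluster on a unit-square map (five clusters on a
circle, sd 0.01–0.03 map units). This is the asymptotic geometry a
well-separated embedding converges to, and it makes 180-trial MI
experiments take a second instead of a minute; the embedding itself is
validated separately. The estimator-study geometry uses tight clusters, a
24 px grid and σ = 1 so per-trial densities are nearly deterministic given
the chain path — then the only bias source is trial-count noise, which is
the 1/n law the prescribed extrapolation removes. With broad smoothing or
wide clusters the conditional densities leak across territories and the
disjoint-support oracle no longer describes the measured asymptote; that
regime is reported honestly by the oracle refusing nothing but simply
diverging, and is avoided in the calibration.

## Problem sizes and test scale

The full-scale defaults are the study's printed parameters (30 cycles,
210-px grid, 600/36,000 subsampling quotas, 50 modes, 25 channels). The
test suite and the acceptance script run a reduced scale chosen once:
5 latent states, 10 posture modes, 10 cycles (30 for the acceptance
strong-effect line and all MI runs), feature rows strided every 5 frames
(windows select frames by original index, so striding thins sampling
without changing alignment), training sets of ~1,000–1,200 exemplars,
t-SNE at 350–500 iterations, and a 24 px analysis grid. The map grid
scales with the per-trial window support deliberately (a 3 s window holds
60 strided points regardless of how many cycles are recorded): per-trial
densities on a finer grid are so sparse that only the activated core
reaches significance, understating the recovered region. Entropy time courses at
test scale use a coarser grid still (16–32 px): pooled phase windows
contain only ~60 trials, and the plug-in entropy's sampling noise on a
fine grid would swamp the ±0.2-bit flatness band that the null benchmark
checks; at full scale the printed σ = 2 on the full grid is appropriate.
Runtimes: one 12-fly, 10-cycle line analysis ≈ 20 s on one CPU; the
acceptance script ≈ 6–8 min; the test suite ≈ 20 min, dominated by the two
20-seed benchmark loops.

## What the synthetic benchmark does and does not show

Passing tests establish that the estimators are implemented correctly
(oracle equivalence, closed forms), that the pipeline's false-positive
control holds under its own null, that implanted effects of realistic
magnitude are recovered in the right map locations with the right timing,
and that injected context dependence is measured quantitatively. They do
not establish performance on real video: the cartoon fly lacks true
postural articulation, occlusions, illumination drift and identity errors;
latent states are discrete and their spectra stationary within bouts,
whereas real behaviors drift continuously; and the map's semantic
interpretation (which basin is "head grooming") is human curation by
construction. The renderer's head-up convention stands in for an
anatomical orientation prior that real data would require.

## Known limitations

- The hierarchical subsampling reduces to a single importance-subsample
  round at desk scale; the multi-round path is exercised only at small n.
- The re-embedding cost is local (64 neighbors); far-field repulsion is
  ignored, which is visible as rare ~2%-of-extent displacements of
  re-embedded training rows.
- m = ⌈2^H⌉ treats both Wilcoxon tests with one shared comparison count;
  the source describes the construction for the first test only.
- The bias-corrected MI's error bar is a variance extrapolation, not a
  confidence interval; for near-zero MI the variance intercept is often
  negative and the fallback (largest-fraction variance) is conservative.
- `run_pipeline`'s cache keys hash configuration and seeds, not code:
  editing the source requires clearing the artifact store.
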