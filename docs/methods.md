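# Methods

## Signal model

A facial video records `P(x, y, t) = α(x, y) p(t) + β(x, y) w(t)` plus
sensor noise: the blood-volume pulse `p(t)` and the ambient illumination
`w(t)`, mixed by unknown location-dependent gains. `α` is non-zero only on
skin; `β` applies everywhere. The task is to recover the dominant frequency
of `p(t)` — the heart rate — without knowing `α`, `β` or `w`.

Two patch traces `P̄ᵢ(t) = ᾱᵢ p(t) + β̄ᵢ w(t)` and `P̄ⱼ(t)` form a 2×2
linear mixture of the same two sources, which FastICA inverts up to sign,
scale and permutation, provided the gain ratios `ᾱ/β̄` differ between the
two patches. This is why patch-local gains matter: patches whose pixels are
partly missing or non-skin have effectively time-varying gains and break
the stationary-mixture assumption — the motivation for the two selection
stages.

## Pipeline stages and parameters

**Joint detection/alignment** (`joint_align`). Candidates are
(window, shape) pairs; features are intensity differences of pixel pairs
indexed relative to the nearest landmark of the shape (offsets are
fractions of the window side, bounded by 0.25; out-of-window references
clamp to the border so near-edge shapes stay scoreable). Each cascade
stage is a depth-limited regression tree on the 0/1 labels with per-node
feature subsampling; leaf scores are clipped to [0, 1], so the running
score is non-decreasing and early rejection (`fⁱ < θⁱ`) is sound. `θⁱ` is
set so 99% (configurable) of surviving positives pass. Representative
shapes (default 3: left/frontal/right) are complete-linkage clusters under
the symmetric Hausdorff distance, members similarity-aligned (Umeyama)
before coordinate-wise averaging. Scanning uses 3 scales per octave, a
stride of 25% of the window side (configurable), ties broken by smaller
area then scan order, and a fine 1-px local pass around the coarse winner.
Grayscale for features is rounded BT.601 luma. The refinement stage is a
small cascaded linear (ridge) regressor on shape-indexed features — a
deliberately compact stand-in for a full local-binary-feature aligner,
sufficient to demonstrate that the jointly produced initial shape converges
better than a mean-shape initialization.

**Patch mesh** (`patch_mesh`). The Delaunay triangulation is computed once
on the first valid frame and the vertex triples are re-used on every frame;
re-triangulating per frame would break patch identity. Rasterization
assigns a pixel to a triangle iff its center lies inside, with a half-open
(top-left style) edge-ownership rule so patches partition the landmark
convex hull exactly — no pixel is counted twice and none is lost.
Missing-landmark gaps up to 5 frames are filled by linear interpolation;
longer gaps invalidate those frames. Off-frame clipping reduces a patch's
pixel count rather than invalidating it: that count drop is precisely the
instability signal the next stage consumes.

**Skin filtering** (`skin_map`). BT.601 full-range Cb-Cr, histogram of
64×64 bins (4-wide; smooths the sparse statistics of a small training set);
posterior `h_skin/h_total` per bin, unseen bins → 0 (no Laplace smoothing
by default, exposed as a config). A patch's score is its mean posterior
over pixels, averaged across frames — per-frame filtering is deliberately
avoided so the patch set stays fixed for ICA. Keep iff score ≥ 0.7.

**Stability selection** (`stability_select`). Quartiles use linear
interpolation between order statistics ("type 7"); the IQR is computed once
over the whole clip, matching the 30-s protocol. Ties in the ranking break
toward the smaller patch id, making selection deterministic. Selection
ranks the skin-filtered patches (filter order follows the pipeline).

**Pulse estimation** (`pulse_estimator`). Traces are detrended with a 10-s
moving average (removes `w`'s drift and ramp without touching the ≥0.7 Hz
band) and z-scored. Up to 100 distinct patch pairs are sampled without
replacement (seeded). Near-collinear pairs (|ρ| > 0.999) and FastICA
convergence failures are skipped. PSDs use Welch with 10-s Hann segments,
50% overlap, zero-padded to a 0.01 Hz grid. The pulse component of a pair
is the one with the larger in-band peak-to-total power ratio — the
illumination component keeps most of its power below 0.7 Hz after
unmixing, so this ratio separates them. A hypothesis abstains when its
in-band peak fraction (peak / in-band total) is below 0.02; this floor was
calibrated so white-noise Welch spectra (max ≈ 0.011 at these settings)
always abstain while even a tone at half the noise amplitude clears it.
Voting bins are 1/30 Hz wide (the native resolution of a 30-s clip), tiling
0.7–4 Hz; ties go to the bin with more summed peak power;
`HR = 60 · f_HR`. If every pair abstains, the pipeline (not the library
primitive, which raises) falls back to the strongest in-band Welch peak of
the pooled mean trace, so the tool reports an HR for every clip.

**Metrics** (`metrics`). Pulse-band SNR: energy within ±0.1 Hz of the true
frequency and its first harmonic over the remaining 0.7–4 Hz energy (the
±0.1 Hz half-width, ≈6 bpm, quantifies the otherwise loose notion of
"around" the peak; the denominator is bounded to the search band).
Agreement: RMSE, mean error ± sample (n−1) SD, Bland–Altman limits
`Me ± 1.96·SDe` (x-axis: mean of the two methods), Pearson r (flagged
undefined for constant inputs), and the well-estimation rate with a strict
`|error| < 5` bpm inequality.

## The synthetic scene

The generator renders exactly the additive model above, plus the
disturbances the selection stages exist to reject. Defaults define the
study conditions: 30 s at 30 fps, 96×96 px, pulse amplitude 2% of mean skin
intensity (the physiological order of magnitude), a harmonic-rich pulse
(fundamental + 0.3× first harmonic, so the SNR harmonic term is
exercised), illumination = 0.1 Hz sinusoid + ramp + band-limited "screen
flicker" reaching into the pulse band, rigid sway (3 px, 3°, 8 s period)
plus a 1-px low-pass random tremor, smoothly varying facial shading
(σ = 8 intensity units — what makes fixed-coordinate patches see motion as
in-band noise), per-pixel sensor noise σ = 2, and temporally smoothed
landmark jitter of 0.1 px (aligner error is correlated over frames; white
jitter would inflate frame-difference statistics unrealistically).
Textures are sampled bilinearly under motion, modeling a camera's
sub-pixel integration.

Occluders: glasses and a beard (static, face-attached, chromaticity
several σ outside the skin cluster) and a nose-like occluder whose position
oscillates at 0.5 Hz (±0.24 face-radii, with a small vertical component);
the adjacent nose landmarks move with it, so neighbouring triangles'
areas — and pixel counts — genuinely oscillate. A patch is labelled
*unstable* in the ground truth iff its jitter-free area's relative range
over the clip exceeds 10%: adjacency to moving landmarks alone is not
sufficient (an all-nose triangle translates rigidly; a triangle whose
opposite edge parallels the motion keeps its area). The background is
given frame-to-frame dynamic noise and its own flicker realization — the
scene behind a subject is lit through a different mix of sources than the
face. Both details matter: a static, identically-lit background makes
background patches either mutually collinear (silently skipped) or perfect
illumination references that let ICA cancel the face flicker, flattering
non-adaptive baselines beyond anything seen in practice.

The skin-model training set (78 images by default) pairs random elliptical
"skin" regions drawn from the configured Cb-Cr Gaussian cluster with
uniform-random backgrounds.

A companion toy detection task renders dot-pattern faces in three poses
(soft Gaussian blobs at landmark positions on a bright plate) with noise
windows, near-miss shapes, wrong-pose shapes, shifted boxes and wrong-scale
crops as negatives — enough structure for the cascade to learn joint
box+shape scoring, small enough to train in seconds.

**What the generator does not model**: photo-realistic appearance, BRDF
physics beyond the additive decomposition, compression artifacts, 3-D
head rotation (yaw is emulated by in-plane motion and the oscillating
self-occlusion), or aligner failure correlated with pose. Passing tests on
these scenes therefore demonstrate the pipeline's selection logic and
spectral estimation under controlled mixtures — not performance on any
real-video corpus.

## Evaluation cohorts

*Recovery*: the stock scene at 48/72/100/140 bpm across seeds; an estimate
counts as correct within one voting bin (2 bpm).

*Ablations*: a 20-clip cohort under vigorous conditions — sway 6 px / 6°,
2-px tremor, flicker at 0.8 relative amplitude — comparing the full
pipeline, the pipeline without stability selection, and a non-adaptive
baseline (8×8 static grid over the detector box with a 20%→35% margin, no
skin filter; cells sized comparably to the median triangle patch). Each
clip gets its own estimator seed so pair sampling is not shared across the
cohort. The degradation is graded: unstable nose patches poison the
no-selection variant (their occlusion waveform's harmonic falls inside the
pulse band and votes coherently), while the grid baseline additionally
inherits background cells whose flicker votes dominate once no skin filter
removes them.

*SNR trend*: kept vs rejected patches are compared on flicker-free clips;
a scene-wide in-band illumination sits in the SNR denominator of every
patch alike and would mask the patch-local contrast the trend is about.

Problem sizes throughout (clip length, cohort counts, oracle set sizes)
are chosen to make each property measurable with comfortable statistical
margins on a single CPU.

## Known limitations

- The abstention floor and component-choice rule are calibrated to the
  default Welch settings; very short clips (< ~15 s) change both.
- The voting-bin width (1/30 Hz) assumes ≈30-s clips; the bin center
  quantizes HR to 2-bpm resolution.
- The toy detector's training is seed-sensitive (single tree per stage);
  the packaged configuration is deterministic, but retraining with other
  feature-spec seeds varies the planted-face hit rate by ~±10%.
- With an in-band *periodic* illumination (e.g. a rolling-shutter beat
  tone), a pulse hypothesis is physically indistinguishable from the
  flicker for any pairwise-ICA method; the generator deliberately uses
  band-limited noise flicker instead.
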