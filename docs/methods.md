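# Methods

This note records the models, numerical choices and open design decisions
behind `ecgdigitize`, and what the synthetic tests do and do not establish
about real data.

## Segmentation networks

Two residual U-Nets operate in NCHW float32 on the CPU (implemented in
NumPy with hand-written backward passes; gradient correctness is verified
against finite differences in the test suite).

**Main network** (4 classes: background, grid, signal, text; RGB input).
Encoder widths (32, 64, 128, 256, 320, 320, 320, 320). The exact recipe —
chosen so the default configuration has 22,554,340 trainable parameters
(22.6 M at one decimal) — is:

* stem: 3×3 conv (no bias) → InstanceNorm → LeakyReLU(0.01) to width 32;
* per level, one residual block: two (3×3 conv, InstanceNorm, LeakyReLU)
  stages at constant width with an identity shortcut over the pair;
* between levels, a 2×2 stride-2 conv (no bias) → InstanceNorm → LeakyReLU
  that also changes the channel count;
* decoder per level: bilinear ×2 upsample, 1×1 conv + InstanceNorm +
  LeakyReLU down to the skip width, concatenation with the skip, then two
  (3×3 conv, InstanceNorm, LeakyReLU) stages (2w→w, w→w) with a 1×1
  projection shortcut over the pair;
* head: 3×3 conv (with bias) to the class count.

Convolutions followed by a normalization carry no bias. Input sizes must be
divisible by 2^(levels−1); the inference wrapper reflect-pads and crops
back, and images longer than 1024 px are processed in 1024-px tiles with
128-px overlap blended by a cosine ramp (tiled and whole-image inference
agree to ~1e−3 mean absolute difference).

**Lead-text network**: same recipe with widths (32, 64, 128, 256, 256), one
input channel (the text-probability plane) and 13 output classes
(background + the 12 standard leads), ~5.8 M parameters.

## Training

Loss = soft Dice + focal. The Dice term is 1 − mean over classes of
(2Σpₜ + ε)/(Σp + Σt + ε) with ε = 1 on soft softmax outputs; the focal term
is the mean of (1−p_t)^γ(−log p_t) with γ = 2 and no class weights (γ and
weights are configurable; the defaults were chosen as the common practice
values). Convolution kernels are updated with Muon — momentum 0.95,
Nesterov, the momentum buffer orthogonalized by five quintic Newton–Schulz
iterations on the (out, in·k·k) reshape, scaled by √max(1, rows/cols) — and
normalization affine parameters and biases with AdamW (β = 0.9/0.999,
weight decay 0.001). A pure-AdamW fallback flag exists. The learning rate
decays by cosine from 3.7e−3 to 3.7e−4 over 20,000 batches, then stays
constant. Default batch 12 at 1024² crops is the full-scale recipe;
desk-scale runs in the tests and CLI use width (8, 16, 32) models, 96²
crops, batch 2–4 and a few hundred steps, which reach foreground Dice
> 0.95 when overfitting a fixed batch and ~0.97 signal Dice on unseen
renders of the same distribution. Non-finite loss aborts training with a
diagnostic.

## Perspective correction

Coordinates: origin at the top-left pixel center, x = column, y = row,
angles from the +x axis; ρ may be negative. Each pixel votes its grid
probability into (θ, ρ = x cos θ + y sin θ) bins for every θ on the axis
(coarse: [−π/4, 3π/4) at 0.5°, ρ resolution 1 px). The angle–angle value at
(θᵢ, θⱼ) is the variance of bilinear samples along the segment from
(θᵢ, ρ_min) to (θⱼ, ρ_max), one sample per ρ bin. Because a pencil of
near-parallel gridlines always spans a narrow angular range, the search is
restricted to |θᵢ − θⱼ| ≤ 30°, which cuts the O(n³) sampling cost; the
inner loop is JIT-compiled when numba is available, with a pure-NumPy
fallback. After the two ~90°-separated coarse maxima are found (the second
peak must reach 2 % of the first; the first must exceed the map median by
4 MADs, otherwise a dewarp-failure signal is raised), each family is
refined by a fine Hough at 0.02° over ±2° windows around its two angles.

The rectifying homography sends both families' vanishing points (the
intersection of each family's two extreme lines) to infinity: the plane at
infinity row is set from the cross product of the vanishing points
(normalized at the image center), the family nearest θ = 0 is aligned with
the image y axis and the other with the x axis, signs are chosen so the
Jacobian at the image center has a positive diagonal (no flip), and each
axis is scaled to unit magnification at the center. The remaining
per-axis scale ambiguity is immaterial because grid calibration estimates
the two axes independently downstream; equalizing the two grid spacings
after calibration is available to consumers that want square pixels. The
crop is the bounding box of signal probability > 0.5 dilated by two
major-grid units (or 2 % of the long side before calibration is known).

An important practical constraint, visible in the synthetic experiments:
the variance search requires the 1 mm comb to be *resolved* along the
family line, i.e. the minor spacing must be ≳4 px in the (max-pooled ≤2048)
map. Real scans and phone photos satisfy this comfortably (600 dpi ≈
23.6 px/mm); the test fixtures therefore use grid spacings of 8–12 px.

## Grid calibration

Profiles are the raw soft-probability column/row sums (no thresholding —
the probabilities already weight uncertain pixels). The autocorrelation is
exact over valid indices (no wrap-around). The comb template has unit
Gaussian bumps (σ = d/12, floor 0.5 px) at multiples of d with weight 3 at
multiples of 5d; a moving-average baseline (window 1.5d) is subtracted from
the autocorrelation before scoring so the template needs no DC term. The
score is the normalized correlation over a lag window of 10.5 minor
periods starting at lag d/2: a d-proportional window keeps the score a
smooth function of d (with hundreds of fixed lags the peak becomes narrower
than any practical search step) while still covering two major periods,
which disambiguates d from its subharmonics. The search is a coarse sweep
over [3, 80] px at 0.25 px followed by four refinement rounds shrinking the
step ×0.2 to below 0.01 px. A best score under 0.2 raises a
calibration-failure signal; the pipeline then falls back to a configured
default spacing with a warning.

## Layout identification

Markers are the mass-weighted centroids of each lead class's probability
above 0.5, one per lead identity (when a lead's mass splits into several
blobs the largest blob wins); classes with under 3 probability-pixels are
dropped. Matching pairs detected and template markers *by lead identity* —
the text network names each marker, which makes the assignment unambiguous
and makes "missing" naturally mean "template leads not detected". The
registration fit is a single shared least-squares scale with per-axis
translation. A single scale is deliberate: with independent per-axis
scales, any two layouts whose markers differ only by row count (3×4 versus
3×4 with a rhythm strip — three equally spaced rows either way) become
exactly affine-equivalent and the cost cannot separate them; the shared
scale preserves the row-pitch-to-column-pitch ratio as evidence. Cost is
(λ·|missing| + Σ Euclidean residuals)/|G| with λ = 0.5 (half the
normalized image width per undetected lead); ties keep the earlier
candidate; when nothing matches at all the configured default template is
returned with a warning. Candidate layouts are read from a YAML file; the
built-ins are 3×4+rhythm (the default), 3×4, 6×2 and 12×1.

## Trace extraction

Components are 8-connected pixels of the signal map thresholded at 0.5;
components under 10 px are discarded as specks. A component is deemed
*problematic* (a candidate for snipping) when its row extent exceeds one
layout band or >20 % of its columns hold ≥2 disjoint vertical runs. The
snip path walks left to right, confined to the component's per-column
vertical extent, choosing greedily with one-step lookahead among
right/right-up/right-down/up/down moves (at most 3 vertical moves per
column, never undoing the previous vertical move) the move minimizing
accumulated signal probability; path pixels are removed from the component
only. Detection and snipping iterate to convergence or 10 rounds.

Chaining solves a square linear sum assignment from right endpoints to left
endpoints (scipy's Jonker–Volgenant-family solver). Forward connections
cost |Δcolumn| + 2·|Δrow|. Backward candidates are the wrap-around matches
that make the square assignment feasible: between different components the
column distance wraps around the panel (off the right edge, back in from
the left), while a self-connection uses the component's own extent; both
are penalized ×2. Under this cost every cycle of the optimal permutation
contains exactly one cheap, droppable wrap edge — so genuine fragments
chain — while an isolated speck's cheapest option is the self-connection,
which is rejected as noise (unless the component is at least half the mass
of the band's largest chain: a lone full-width trace is not noise). An
additive (non-wrapping) backward cost was tried first and is provably
wrong: a chain then pays about twice its span for its wrap edge, so full
fragmentation is always cheaper and no chain ever forms. Endpoint overlaps
up to 10 px still count as forward, because printed panels in one row abut
and their traces overlap by a line width.

Because a printed row is one continuous pen stroke across its panels,
components are grouped per layout *row band*, chained within the band, and
each panel samples its column range of the band's chain. The printed-area
geometry is estimated from the components themselves: horizontal extent
from the pixel bounding box, vertical extent from the span of component
mean rows (the lead baselines), which is insensitive to waveform amplitude
since R equally tall bands have baselines spanning (R−1)/R of the content
height.

The trace value in a column is the probability-weighted mean row of the
chain's pixels, negated (up on paper = positive voltage) and scaled by the
calibration; the per-lead baseline is the median of finite values. Columns
without pixels are NaN. Resampling to the target rate (default 1000 Hz)
interpolates linearly inside finite runs only; NaN gaps are never bridged.
When a lead appears both in the grid and as a rhythm strip, the strip wins
where finite. No lead is ever dropped: failures only widen the NaN regions,
except that a page with no detectable grid structure at all (both the
dewarp and the calibration fail) or with under 1 % traceable samples is
reported as all-NaN — there is no ECG paper to read.

## Evaluation metrics

SNR follows the power-ratio definition after alignment: both series are
zero-centered *per compared overlap window* (an open choice; centering once
over the full record leaves window-mean offsets in the noise term, which
dominates for short panel windows), and the integer-sample shift within
±100 ms (1 ms granularity at 1000 Hz) maximizing SNR is found by exhaustive
search, reported positive when the reconstruction lags the truth. NaN
samples in the reconstruction score as zero on the centered scale by
default — making the all-zeros reconstruction exactly 0 dB — with a strict
mode that excludes them instead; strict mode is the right view for
synthetic round trips, where 75 % of each grid lead's record is unprinted
by construction. Zero residual returns an infinity sentinel, excluded from
aggregate means and counted separately. RMSE is reported in µV and
correlation is Pearson's r; RMSE² = (signal power/N)·10^(−SNR/10) holds
exactly on aligned centered pairs and is asserted in the tests.

## Synthetic data

The simulator writes each beat as five Gaussian waves (P, Q, R, S, T; base
centers −170/−42/0/+36/+300 ms, widths 25/10/13/13/60 ms, amplitudes
0.12/−0.12/1.10/−0.25/0.35 mV) at 70 bpm with 3 % RR jitter. Leads I and II
are frontal-plane projections of per-wave dipole axes — QRS axis uniform in
42–52°, P near 42–58°, T 5–25° below the QRS axis — with independent
per-lead amplitude jitter (0.82–1.18); III, aVR, aVL, aVF are derived so
the Einthoven/Goldberger identities hold exactly, and chest leads get
independent per-wave scales (0.55–1.3). Baseline wander (0.08 mV scale
sines at 0.15–0.4 Hz) and white noise (8 µV) are applied to the source
channels before derivation. The axis and jitter ranges were chosen so that
every derived lead keeps physiologically plausible power (lead III and aVL
otherwise collapse toward zero for mid-range axes, which no real ECG
archive exhibits lead-wide).

Renders draw the 1 mm/5 mm grid (line widths scaling with resolution),
lead traces at the configured speed/gain (25 or 50 mm/s, 10 mm/mV), and
lead-name text from Pillow's built-in font, with exact class and lead-text
masks; adjacent panels in a row are separated by a ~2 px pen lift so
segments are distinct components. An optional 1 mV calibration pulse and
mild thermal-fade brightness fields are available. Perspective augmentation
jitters the corners (magnitude tied to the maximum tilt), composites a
procedural background (white/gradient/noise/table), and records the exact
homography; zero tilt is the exact identity. Everything is deterministic
per seed.

What the synthetic fixtures do **not** capture: real photo backgrounds,
lens blur and exposure variation, handwriting, stains, wrinkled or curved
paper, and real ECG morphology beyond the Gaussian model. Passing the
synthetic suites therefore demonstrates the geometry, calibration,
matching and vectorization machinery and the trainability of the networks
— not clinical-grade accuracy on degraded archives, which requires training
the full-width model on a much richer render distribution.

## Problem sizes in the test suite

The suites run on one CPU in a few minutes by scaling sizes, as a design
choice: demonstration models use widths (8, 16, 32) (~38 k parameters) on
96² crops; end-to-end fixtures render at 100 dpi (3.94 px/mm); the
oracle-mask round trip renders at 600 dpi/50 mm/s like a flatbed scan and
requires ≥25 dB on every lead; homography recovery uses 50 seeded warps of
420×520 grid maps (tilt up to 20° plus perspective) with a median
post-rectification gridline deviation well under 0.5°. The full-width
training recipe remains available through the same configuration objects.
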