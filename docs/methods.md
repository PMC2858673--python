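# Methods

`stereopop` simulates how a neuronal population that explicitly encodes
*only* horizontal binocular disparity and orientation can nevertheless be
read out to recover the full two-dimensional (horizontal + vertical)
disparity of a stimulus.  This note records the model, its parameters,
the numerical choices, and what the simulations do and do not establish.

## Stimuli

Stimuli are uniform-disparity Gaussian-noise stereograms (`stimuli`).
The left image is i.i.d. standard-normal contrast, default 81×81 pixels.
The right image equals the left shifted by an integer disparity
(Δx, Δy) — convention `I_R(x, y) = I_L(x − dx, y − dy)`, x rightward,
y upward, origin at the image centre — with freshly drawn noise in the
strip uncovered by the shift.  An anticorrelated pair negates the whole
right image, so it is the exact sign-flipped twin of the correlated pair
drawn from the same stream (this makes the per-unit antisymmetry
C → −C an identity rather than a statistical statement).

What the generator does *not* emulate: natural-image spectra and sparse
structure, sub-pixel or spatially varying disparity, monocular occlusion
at depth edges, vergence/eye-position geometry.  Results therefore speak
to the population-coding question — is vertical disparity recoverable in
principle from this population? — not to performance on natural scenes.

## Encoding population

Each binocular simple cell (`population`) is a pair of monocular Gabor
receptive fields

    ρ(x, y) = exp(−((x−cx)² + (y−cy)²) / 2σ²) · cos(2πf u′ + ψ),

with isotropic envelope, carrier along u′ = cosθ·(x−cx) + sinθ·(y−cy),
the axis orthogonal to the preferred orientation θ (measured from
vertical, counter-clockwise positive).  The two eyes share (θ, f, σ) but
differ in carrier phase (±Δφ/2) and centre (±(Δx_pos, Δy_pos)/2, left
eye taking the − signs); the cyclopean centre is (0, 0) for every cell.

A phase disparity Δφ on its own shifts a unit's preferred disparity by
Δφ/(2πf) along û = (cosθ, sinθ).  Each unit is therefore assigned the
position disparity

    (Δx_pos, Δy_pos) = (Δx_enc, 0) − û · Δφ/(2πf),

which cancels that shift and tunes the whole population to zero vertical
disparity while spanning Δx_enc ∈ {−10 … 10} px horizontally.  The
cancellation is a narrowband approximation: the exact peak of the mean
response is pulled back toward the position disparity by ε solving
2πf·tan(2πf ε) = −(g + ε)/2σ², g = Δφ/2πf.  At σ = 0.35λ this residual
is ≈ 0.07σ for |Δφ| = π/2 — at most ~1 px for the lowest-frequency
channel, and 0 px after rounding to the integer grid for f ≥ 0.0707 —
so empirical peaks sit at (Δx_enc, 0) for all but the widest units.
The `empirical_peak` routine measures this directly and is the contract
test that fixes all sign conventions.

Default grid (6 θ × 2 φ × 21 Δx_enc × 5 f × 5 Δφ = 6300 simple cells,
3150 complex units):

| parameter | values | units |
|---|---|---|
| θ | −60, −30, 0, 30, 60, 90 | deg from vertical |
| φ | 0, π/2 (quadrature pair) | rad |
| Δx_enc | −10 … 10 step 1 | px |
| f | 0.200, 0.112, 0.0707, 0.0420, 0.0250 | cyc/px |
| Δφ | 0, ±π/4, ±π/2 | rad |
| σ | 0.35/f | px |

The frequency list is taken verbatim and λ defined as 1/f; note
0.112 cyc/px and the conventional period 8.41 px quoted for such
geometric series are not exact reciprocals — the frequencies are
authoritative here.

**Envelope width.** σ = 0.35λ (σf = 0.35) is the default.  The
effective binocular correlation of a unit is estimated from only a
handful of independent image samples per receptive field — the count
scales with (σf)² — so the envelope bandwidth directly sets the
stimulus-driven response variance, which is the decoder's dominant
noise source.  Narrower envelopes (e.g. σ = 0.25λ) degrade decoding
accuracy several-fold under otherwise identical conditions; the factor
is exposed in `PopulationConfig(sigma_factor=...)` for such
sensitivity runs.

## Encoder

For each eye, v = Σ_pixels ρ·I (exact inner products; `EncoderBank`
evaluates them as separable complex-Gabor contractions with BLAS, and a
naive per-pixel route is kept and cross-checked to 1e−8).  Complex
units pool the quadrature phase pair; splitting the binocular energy
E = M + B into monocular M = Σ_φ(v_L² + v_R²) and binocular
B = Σ_φ 2v_L v_R terms gives the effective binocular correlation

    C = B / M ∈ [−1, 1],

the correlation coefficient between the filtered local image patches.
C = 1 exactly whenever the stimulus shift equals the unit's interocular
transformation (any image, Δφ = 0), and flips sign under
anticorrelation.  Two phases suffice: pooling more uniformly spaced
phases leaves C unchanged (tested).

Caveats: (i) the identity C = 1 holds to < 1e−6 while the envelope
tails stay inside the image overlap; for the widest units (σ = 14 px)
at |Δx_enc| near 10 on 81×81 images, truncation raises |C − 1| to ~1e−5
(the error is quadratic in the truncated-tail mismatch).  (ii) A
stimulus with zero energy in both apertures gives M = 0; C is then
defined as 0 (neutral evidence) — unreachable with continuous noise.

Spiking: each unit emits a Poisson count with mean R_m = U(1 + C),
U = 1 spike by default (CV ≥ 70% even for optimally driven units; the
mean for an uncorrelated stimulus is U).  Means are clipped to [0, 2U]
to absorb float excursions of C beyond ±1.  Poisson noise turns out to
be a minor contributor to decoding error; the dominant noise is
stimulus-driven variability of C itself.

## Templates and decoder

For every disparity on the 21×21 decoding grid (441 points, −10…10 px),
`build_templates` averages C over fresh stereograms and stores the
noise-free mean count W = U(1 + ⟨C⟩) — the analytic Poisson expectation
(averaging actual draws is available as a validation switch).  Template
image streams (SeedSequence spawn key 1) are disjoint from test streams
(key 2).

A decoding unit for grid point (Δx_dec, Δy_dec) responds with the
half-wave-rectified Pearson correlation across the 3150 encoding units
between the single-trial counts R and its template column:
P = ⌊Corr(R, W)⌋.  The estimate is the argmax of P.  Conventions the
statistic itself does not define: zero variance ⇒ r = 0; argmax ties
⇒ smallest Δx²+Δy², then lexicographic (Δy, Δx), with the tie set
recorded and the trial flagged degenerate (an all-zero rectified map is
always degenerate — anticorrelated stimuli must not silently decode as
a confident (0,0)).  Degenerate trials are excluded from RMS statistics
and reported as a failure rate (configurable).

## Experiments and profiles

`run_rms_experiment` decodes noisy single-trial responses at given test
disparities and reports per-component RMS error.  Two profiles:
`full` (500 template images per disparity, 1000 test trials, 40 images
per decoder-surface point) for full-scale runs, and `ci`
(50 / 200 / 10) — the scaled-down profile used by the test suite, which
preserves the qualitative structure (RMS ordering over |Δy_test|,
sub-pixel recovery at small vertical disparity, the
correlated/anticorrelated dissociation) at a few CPU-minutes.
Reported RMS always carries n, seed and profile.

Decoding accuracy is highest at Δy_test = 0, where encoding units tuned
to the exact 2D stimulus disparity exist; it remains sub-pixel per
component at Δy_test = 2 — where *no* unit matches the stimulus, so
the vertical component is read purely from the slanted population
pattern — and degrades gracefully at large |Δy_test|, with the sign of
the vertical disparity still recovered at −8 px.  Template Monte-Carlo
noise adds to the error, so the scaled-down profile's RMS sits
measurably above what the full profile (runnable via
`stereopop evaluate --profile full`) attains under the same test
conditions.  For anticorrelated stimuli
the Pearson map is negative at most grid points and the single-decoder
tuning surface is flat, versus clearly peaked for correlated input;
the maximum over all 441 grid points, however, rides on the Pearson
sampling-noise floor (3150 strongly inter-correlated units at U = 1),
so the mean anticorrelated peak response is suppressed several-fold
relative to correlated input rather than to strictly zero.

## Known limitations

* Integer-pixel disparities only; no sub-grid interpolation of the
  estimate.
* All units share one cyclopean position; no retinotopic map, no
  eye-position or head-centric geometry.
* No interneuronal noise correlations; Poisson spiking without temporal
  structure.
* The decoder is template matching, not a probabilistic ideal observer;
  its accuracy bounds the information available, from below.
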