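# Methods

This note documents the models, numerical conventions and design choices
behind `figground`, in the spirit of a model-documentation page: what is
simulated, what the defaults mean, and what passing tests do and do not
demonstrate.

## Stimulus model

**Canvas.** Stimuli are rendered on a retinotopic raster
(`CanvasGeometry`, default 80° × 60° at 2 px/°) using a linear
degree-to-pixel mapping, appropriate for a head-fixed observer with the
display centered on the receptive fields under study.  Exact-arctangent
conversions (`angular_geometry`) are used for the freely moving
touchscreen geometry, where the same physical figure spans 15°–143°
depending on viewing distance (23 cm – 1 cm on a 24-cm-wide screen showing
a 200-px-wide movie).

**Textures.** Gratings are cosine luminance patterns in [0, 1] with mean
0.5 (default 0.06 cpd at 45°/135°).  Naturalistic noise has an *exact*
1/|f| amplitude spectrum with randomized phases, standardized to RMS
contrast 0.18 about the 0.5 mean and clipped at ±2.5 SD; the exact
spectral envelope (rather than 1/f-filtered white noise) keeps the
radially averaged log-log amplitude slope at −1 for every seed.  The RMS
contrast value is a synthesis choice (natural-texture contrasts are not
standardized); it sets the overall scale of Nat-condition responses.

**Trial movies.** A square figure (27° side) is pasted over the background
after both are displaced: background shifted by its displacement first,
the figure patch — rigidly carrying its own texture — drawn on top at the
displaced figure location.  Accretion–deletion thus emerges from the
painter's algorithm rather than being modeled explicitly.  Displacements
follow ±3.5° sinusoids at 1 Hz, counterphase by default; they are rounded
to whole canvas pixels so that the "figure invisible at zero relative
displacement" property of same-texture conditions holds bit-exactly.
Trials are 250 ms at 56 Hz = 14 frames.

**Condition construction.** Cross uses an orthogonal figure grating.  Iso
defaults to the *pop-out* construction used for neural recordings: the
figure patch is cut from the background grating itself, so the
figure-ground phase difference is created entirely by the opponent motion
(reaching ≈150° of phase at peak separation).  The behavioral variant
with a fixed static phase offset is available via
`condition_spec(..., static_phase_offset=...)`.  Nat cuts the figure from
the same 1/f texture; two fixed texture seeds serve as the two Nat
variants, mirroring the use of two fixed textures per experiment.
CrossTex/IsoTex rotate or offset the background crop.

**Session protocol.** A figure-map session presents each of the six
condition-variants as a contiguous block (condition order and
within-condition variant order randomized), each block flashing the figure
at all 128 grid positions × 10 repeats in shuffled order.  The motion
oscillation clock runs continuously across trials, so each trial starts at
one of four phases (250 ms dwell × 1 Hz); repeats of a position therefore
sample different displacement branches.  This matters: with a single
frozen branch per position, repeated identical movies would give the
decoder a deterministic texture-displacement signature in every condition
and overstate position information in the motion-only conditions.

## Population model

**LN cells.** Each cell is a Gabor filter (θ, ω ~ U(0, π), σ ~ U(2°, 7°),
1/λ ~ U(0.05, 0.3) cpd, γ = 1) applied to mean-subtracted frames,
rectified at zero per frame, and averaged over the 14 frames of a trial.
Filters are truncated at ±3σ and normalized to unit energy, so responses
are in stimulus-contrast units; this makes the mean-scaled noise model
(below) comparable across cells of different envelope size.  Mean
subtraction (removing the 0.5 gray level) prevents the low-frequency DC
leakage of large-envelope Gabors from dominating responses.  RF centers
are sampled uniformly over the position grid's span (±22.5° azimuth,
±10.5° elevation) — the center distribution of the original simulation is
not specified, and the grid span is where position information lives.

**Divisive surround.** `r = r_ff / (1 + β·ρ)` with β = 0.95.  ρ is the
Pearson correlation between 100-dimensional orientation-energy vectors
measured inside the RF (distance < 2σ) and in the annulus (2σ–5σ).  The
energy bank tiles 20 orientations × 5 log-spaced frequency bands over the
model range, each kernel unit-norm with envelope width λ/2; energies are
rectified correlation maps, block-averaged (4-px pooling) and averaged over
each region.  Each frequency ring is normalized by its regional mean
before the correlation: input spectra fall steeply with frequency, and
without ring normalization the shared frequency profile dominates ρ and
hides the orientation (mis)match the surround term is meant to measure.
ρ is evaluated on the frame of maximal figure-ground separation and shared
across the four oscillation-phase branches of a position (the
center–surround texture relationship is essentially phase-invariant);
cells whose energy vectors are degenerate (uniform input) keep their
feedforward rate.  With these conventions, Iso figures give ρ > 0
(suppression) and Cross figures ρ < 0 (facilitation) for cells whose
annulus actually reaches the background — for σ ≲ 4° the whole 5σ
surround of a figure-centered cell lies inside the 27° figure and ρ is
positive in every condition, which is a geometric fact of the stimulus,
not a failure of the model.

**Noise.** Trial responses receive additive zero-mean Gaussian noise with
variance `noise_factor × popmean`, where `popmean` is the mean response
over all neurons and trials of the condition, followed by rectification.
The second argument of the noise law is a variance (consistent with
"variance proportional to the mean response").  `noise_factor = 2` is the
headline operating point.

**Archetypes.** Idealized cells used as ground truth: a *figure cell*
fires iff the figure rectangle intersects its RF disc (its figure map is
the square dilated by the disc — the closed-form oracle used in tests); a
*border cell* fires iff the figure edge of its preferred orientation
crosses the RF with the figure on the preferred side; an *ON simple cell*
is a rectified Gaussian-kernel luminance filter (phase- and
texture-sensitive by construction).

## Receptive-field estimation

Sparse noise presents one black or white 3.5° square per 100-ms frame
(strictly alternating polarity) on an 18 × 32 grid for 8000 frames.  The
map is the response-triggered average with black events sign-flipped into
a single signed map (separate ON/OFF maps optional).  Fitting uses an
axis-aligned 5-parameter-plus-offset 2D Gaussian
(`scipy.optimize.curve_fit`), multi-started from the absolute peak and the
magnitude centroid, tie-broken by residual.  `GOF = 1 − MSE/Var(RF)`;
significance shuffles event locations (100 shuffles, p < 0.01 ≙ "GOF
exceeds ≥ 99/100 shuffles").  Inclusion requires GOF > 0.1, response mass
≥ 100 (the spike-count criterion, read as summed response mass for
rate-valued synthetic data), shuffle significance, and an RF center within
a configurable window — default the central 15° × 10°; the stricter
4°-radius variant is selectable, since both windows are in legitimate use
for different analyses.

## Modulation statistics

`FGM = (R_fig − R_back)/(R_fig + R_back)` and
`BOM = (R_left − R_right)/(R_left + R_right)`, where each R is the mean
over that zone's trials (variants pooled per condition, or one variant at
a time for per-variant indices).  The default (`results`) zone convention
is monitor-centered: figure = central 2 × 2 grid block (40 trials/variant),
background = outermost columns (160), borders = columns 4 and 12 (80
each).  Column 4 and 12 sit ±4 columns from the grid's central column —
where a 27° figure places its border over a centrally located RF.  The
`methods` convention centers the 2 × 2 block on the fitted RF and takes
background as positions farther than 1.5 RF widths (RF width
= 2·√(σx·σy)).  The figure block is ~6° × 6° at the 3° grid spacing.
Significance uses a 500-shuffle bootstrap of zone identity with the
small-sample correction p = (1 + #{|null| ≥ |obs|})/(n + 1), two-sided on
|index|.  Per-cell counts of significant conditions are compared with the
Binomial(6, 0.05) false-positive expectation.  Zone time courses use
one-sided two-sample t-tests (figure > ground) per bin at α = 0.01.

## Decoding

Figure azimuth (bins 1–16) is treated as a continuous ridge-regression
target.  Each of 100 iterations draws a fresh 50/50 trial split and, when
a subset size is requested, a fresh neuron subset; the penalty is chosen
on the training half by `sklearn.RidgeCV` over 10 log-spaced values
spanning 10⁻³–10³.  Performance is the held-out coefficient of
determination (1 − SS_res/SS_tot, possibly negative); summaries report the
mean and the 2.5–97.5 percentile range over iterations.  Within a
condition the two variants are pooled before splitting.  The permuted-label
null runs the identical pipeline on shuffled azimuth labels.  The
side-generalization observer is a regularized logistic readout of figure
side trained on one pattern set and tested on a disjoint one.

## Problem sizes

The published simulation used 25,000 LN cells.  The packaged experiments
run a 1,000-cell pool and decode from 200-neuron subsets redrawn each
iteration — the subset resampling is what gives decoding summaries their
iteration-to-iteration spread, as with any finite recorded population.
Calibration runs use 500 null cells × 6 conditions with 200-shuffle
bootstraps.  These sizes are the package's defaults for its own
experiments; all of them are parameters.

## What the synthetic data does and does not emulate

The generator reproduces the stimulus ensemble, the trial structure, the
response nonlinearity and the mean-scaled trial noise of a recorded
session.  It does not emulate spiking dynamics, adaptation, correlated
(shared) noise, eye movements, or the diversity of real cortical cell
types; archetype cells are deliberately idealized.  Passing tests
therefore certify the analysis chain and the model's qualitative
behavior — e.g. that position decoding degrades from Cross to Iso to Nat
under mean-scaled noise — not quantitative agreement with any recorded
dataset.

## Known limitations

* Displacements are quantized to whole canvas pixels (0.5° at the default
  resolution); sub-pixel rendering would break the bit-exact invisibility
  invariant and is not attempted.
* The surround term uses a single representative frame per stimulus; fully
  time-resolved surround modulation is out of scope.
* The Gaussian RF fit is axis-aligned; oriented RFs are absorbed into
  σx/σy and GOF.
* Greedy one-to-one Jaccard matching does not globally optimize the
  assignment; ties and multi-way overlaps resolve by descending overlap.
* The archive-data reader is a schema (HDF5 container) rather than a
  downloader; no test depends on external data.
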