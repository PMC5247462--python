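# Methods

## Model

The simulator implements a three-stage rate network of border-ownership
(BO) selectivity on a retinotopic grid (reference size 100 × 100, all
geometry scales proportionally for other sizes):

* **V1** — oriented local contrast.  Quadrature Gabor energy at four edge
  orientations (σ = 2 px, 0.25 cycles/px), rescaled so a full-contrast
  edge maps to 2.0 and divisively normalized by a Gaussian pool of
  neighbourhood contrast (σ = 4 px).  Parietal feedback multiplies the
  drive by `exp(0.6 · pp_norm)`, so attention acts as a contrast gain ≥ 1.
* **V2** — BO-selective cells.  Ten cell types per preferred side, each
  defined by paired facilitatory/suppressive Gaussian surround regions on
  opposite sides of the classical receptive field (CRF).  The feedforward
  drive is `O¹(O¹ + O²)` where `O¹` is the pooled V1 rate at the cell's
  position and `O² = CF − CS` the facilitatory-minus-suppressive surround
  pool of the V1 rate map; multiplying by `O¹` gates the cell off when
  nothing falls on its CRF.  One module-wide inhibitory unit receives the
  summed rates of all BO cells and inhibits them all.
* **PP (posterior parietal)** — a saliency/attention field driven by the
  smoothed, pooled V1 rates plus a Gaussian attention bias, with its own
  module-wide inhibitory unit.  Its normalized activity is the feedback
  field to V1.  There is no PP→V2 connection: attention reaches BO cells
  only through the V1 contrast gain.

Every unit obeys `τ·dA/dt = −A + μF(A) − γF(A_inh) + I + η` with the
current-to-rate transfer `F(x) = 1/(T_r − τ·ln(1 − 1/(τx)))` for
`τx > 1` and zero otherwise.  Printed constants: τ = 10 ms, T_r = 0.5 ms,
μ = 0.95, γ = 0.8, κ = 0.05, λ = 0.1, uniform current noise ±0.25 redrawn
per unit per 0.1 ms step, feedback weight 0.6.

The BO signal is `ν(t) = Σ_N rate(left-preferring) − Σ_N
rate(right-preferring)` at the recorded edge (mean over the four grid
nodes bracketing the midline), in Hz.  ν is defined on discharge rates
`F(A)`, not on the current-like activities: the activities carry the
±0.25 noise even in silent cells (an equivalent ~45 Hz floor), which
would make the paper-style "reaches 0 Hz" and "exceeds 10 Hz" indices
meaningless, whereas rates are exactly zero below rheobase.

## Why the dynamics behave as reported

The recurrent gain μ = 0.95 places active cells near a saddle-node ghost
of the self-excitation map: `A = μF(A) + I` has a tangency near A ≈ 0.155
(activity units).  Three consequences carry the paper's findings:

* **Slow ambiguous decay.**  After the square is replaced by an ambiguous
  edge the surround term is balanced (`O² ≈ 0` for every selected cell
  type) and the remaining drive `O¹²` sits just below the ignition point,
  so the formerly dominant population drifts down through the ghost —
  decay times of ~120–150 ms after the switch, an order of magnitude
  slower than the membrane constant.
* **Fast flip.**  Flipping the square drives the opposite population
  hard while the old one loses its facilitation and keeps receiving the
  inhibitory unit's output (sustained by the newly active population):
  the signal crosses zero ~50 ms after the switch.
* **Duration independence.**  The decay bottleneck is the passage through
  the ghost, which depends only weakly on the starting amplitude, and the
  inhibitory unit (whose lingering activity scales with the pre-switch
  amplitude) compresses the remaining amplitude dependence.

## Calibration

The available text prints the dynamical constants but not the
inter-module connection gains.  Five gains are therefore calibration
constants of this implementation, fixed once at the 50 × 50 scale and
never varied per experiment: `v1_to_v2_gain = 0.16` (pooled V1 rate →
O¹), `surround_gain = 1.6` (surround convolution → O²), `inh_scale_v2 =
0.006` and `inh_scale_pp = 0.02` (normalization of the κ·ΣF inhibitory
input; with the printed κ alone the sum over all grid units would
saturate the inhibitory unit for any stimulus), `pp_afferent_gain = 0.3`,
and the cue amplitude 1.0 with σ = 20 reference px.  They were chosen so
that the model sits in the regime described above: a 40-px square evokes
a sustained positive ν; the ambiguous edge leaves a balanced drive just
below ignition; cueing modulates detection speed in the tens of
milliseconds.  The inhibitory-pool scale is referenced to the 100-px
grid and scaled by (100/grid) because the active population is
edge-dominated and grows linearly with the grid side.

The invalid attention cue sits fully outside the mirrored square
position (one square-width beyond the midline).  Placing it adjacent to
the edge would let its Gaussian spill onto the recorded location and
*speed* detection; fully outside, it acts only through the parietal
inhibitory unit and the feedback normalization, slowing detection as in
the behavioural paradigm.

## Stimuli

Figures are luminance squares (side 40 reference px, white 1.0 or black
0.0 on gray 0.5) whose vertical edge lies exactly on the midline between
the two central pixel columns, so mirror symmetry is an exact pixel
operation.  The ambiguous edge is the enlarged-square limit: a bipartite
field with the same local edge polarity.  The five bi-stable
random-block figures are full-height half-field textures (10-px blocks,
luminance ±0.15 with 50% gray cells) sharing a coherent ±0.25 midline
contour; candidate textures are screened for (i) surround balance at the
recorded edge (neither side owns the border) and (ii) bi-stability (an
attention-like gain on either half hands that side a positive surround
margin), and the five shipped generation seeds were further verified in
the full network, analogous to the original psychophysics where stimuli
were established as bi-stable before use.  The shipped surround cell
types were likewise generated once from a fixed master seed: random
candidates pass only if their surround signal prefers the correct side
for squares of 24–48 px *and* is side-neutral for an isolated edge.

## Numerics

Classical fixed-step RK4 at dt = 0.1 ms.  Within a step all inputs
(noise, drives) are frozen; the per-step noise is treated as a
piecewise-constant external current.  Slow inter-module signals — the
surround convolutions and the smoothed parietal afferent — are refreshed
every 2 ms (20 steps), short against τ = 10 ms.  Sub-rheobase units emit
exactly zero rate and receive no recurrence, so they are advanced with
the closed-form linear-RK4 update; units are promoted to the full
nonlinear path when their activity exceeds half the rheobase or their
drive could approach it (a drift-bound argument in `bodyn/_engine.py`
shows promotion always happens before a unit can fire).  Two
approximations are knowingly accepted and bounded by tests: silent units
see the inhibitory term frozen at the step start, and V1 units whose
drive can never reach rheobase carry unit attention gain — neither can
change any emitted rate.  Surround kernels are rasterized with a 4-px
guard band excluding the CRF column (the surround pools contrast
*outside* the receptive field) and each region is normalized to unit
mass, making facilitatory/suppressive mass balance exact.  Contrast
extraction replicates the frame border (the frame is a window into a
larger scene); zero padding would create spurious contrast for
half-plane stimuli.

## Index extraction

Crossing indices use a 5 ms moving average (half the membrane constant):
decay time is the first time after the switch at which the smoothed ν
loses its pre-switch sign (sign taken from the 50 ms before the switch),
response time the first time it exceeds 10 Hz.  Trials without a
crossing are excluded from means with a logged count.  Exponential fits
`a·exp(−(t−t₀)/τ_fit) + c` are least squares on the raw signal.
Condition comparisons use Welch's two-sided t-test.

## Problem sizes and what the tests show

All simulation experiments run at the 50 × 50 half scale with the
calibration above; unit tests use 16–40 px grids.  The half-scale
configuration is the documented operating point of the package — the
timing indices (decay ≈ 575–630 ms across figure durations, flip ≈
548 ms, response times ≈ 32/46/50 ms for valid/neutral/invalid) are
properties of this configuration.  Synthetic stimuli exercise exactly
the geometry the model was built for (vertical mid-line borders, flat
luminance figures); passing tests say nothing about natural images,
oblique contours, or absolute physiological time scales (the paper
itself notes its model decays several times faster than the recorded
cells and its response times are far below human reaction times).

## Known limitations

* The absolute scale of ν depends on unprinted gains; only orderings and
  crossing times are treated as reproducible.
* Attention spread, cue placement and the random-block texture statistics
  are this package's constructions; the original psychophysics stimuli
  are not reproducible from the available text.
* No V4/grouping feedback, no PP→V2 connection, no inhibition of return,
  no spiking or NMDA dynamics — the persistent seconds-long activation
  seen physiologically is out of scope, as in the source model.
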