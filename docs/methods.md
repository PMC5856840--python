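# Methods

`coatkit` models the growth and curvature acquisition of clathrin-coated
structures (CCSs) during clathrin-mediated endocytosis (CME) and converts
per-event fluorescence dynamics into predicted steady-state morphology and
size distributions that can be compared with electron-microscopy (EM)
snapshots. This note records the models, the assumptions behind them, the
tunable parameters, and the choices made where the design was open.

## Coat geometry

A curved coat is a spherical cap with tip radius `R` (nm) and contact angle
`θ` (rad): `θ = π/2` is a hemispherical dome, `θ → π` a complete sphere.
Its surface area is `S = 2πR²(1 − cos θ)`; its projected area — the
silhouette measured in TEM of a metal replica — is `πR² sin²θ` up to the
hemisphere and saturates at the equatorial disc `πR²` beyond it. We use the
silhouette, not the rim disc, for `θ > π/2`: a replica outline shows the
widest circle, and only this convention bounds the surface-to-projected
correction factor by 4, consistent with the factor-4 sphere relation. The
correction factor `S/P` is `2/(1 + cos θ)` for `θ ≤ π/2` and `2(1 − cos θ)`
above, rising monotonically from 1 (flat) through 2 (dome) to 4 (sphere).

Pits are parameterised with a maximal contact angle `θ_max` (default 160°)
rather than `π`, because a complete sphere degenerates the membrane neck;
`θ_max` is exposed as configuration everywhere it enters.

## Growth laws

**Flat (constant-area) law.** A flat coat can add triskelia only at its
edge, balanced by a process coupled to the disc area:
`dA/dt = α√A − βA`, with closed-form solution
`A(t) = A_max (1 − e^{−(t−t0)/τ})²`, `A_max = (α/β)²`, `τ = 2/β`. The
closed form is verified against direct ODE integration in the test suite.
Under the constant-area hypothesis the coat reaches `A_max` flat and then
bends at constant surface area; during that bending the tip radius shrinks
as the angle grows, and the silhouette follows `S(1 + cos θ)/2`
(or `S/(2(1 − cos θ))` past the hemisphere).

**Flat-to-curved law.** The coat grows flat by the same law but starts to
bend at a fraction `f* = 0.70` of its final content. Bending proceeds on a
sphere of fixed tip radius, with the contact angle increasing linearly
(`dθ/dt = ω`) until `θ_max`, which stops growth intrinsically. The radius
is fixed per event by `S_final = 2πR²(1 − cos θ_max)` and the initial angle
by surface continuity, `cos θ0 = 1 − f*(1 − cos θ_max)`. Linear-in-time
bending is the minimal closure for "regulation by curvature"; the curve
functions are isolated behind the model interface so an alternative
angular law can be swapped in without touching fitting or prediction code.
Note that this law makes the *surface* continuous at the transition while
the *silhouette* drops abruptly — bending shrinks the TEM footprint.

**Morphology timeline.** The curved phase of either law is split into dome
and pit sub-intervals in the duration ratio 40:60, the dome:pit abundance
ratio of steady-state EM snapshots (with constant nucleation flux,
abundance is proportional to duration). The AP2 plateau is defined as the
time the fitted curve reaches `(1 − ε) A_max`, `ε = 0.05` by default; an
asymptotic curve never "reaches" its plateau, so a tolerance criterion is
unavoidable and `ε` is a configuration knob.

## Track analysis

Fits use bounded trust-region least squares in the observable
parametrisation `(A_max, τ, t0)` (flat law) or
`(S_final, τ, ω[, t0][, f*])` (two-phase law; `t0` is tied to `τ` when the
transition time is pinned to the AP2 plateau). Initialisation: `A_max` at
the 95th intensity percentile, `t0` at the first frame above 10% of it,
`τ` at a quarter of the track span. A fit is flagged non-converged when the
optimiser fails, the relative standard error of the asymptote exceeds 0.5,
or the fitted curve covers less than 75% of its asymptote at the last
frame — the latter catches still-rising profiles whose plateau lies beyond
the track (e.g. a linear ramp). Two-phase fits stop at the smoothed CLC
maximum so the post-scission intensity drop does not bias the parameters.
Non-converged fits and tracks shorter than 6 frames are excluded from
ensemble statistics; exclusion counts are reported.

Offsets between the channels are measured on plateau-normalized series.
The AP2 normaliser is the fitted plateau value; the CLC normaliser is
estimated by least-squares matching of the CLC series to the normalized
fitted AP2 curve over the pre-plateau frames (during flat growth both
channels are proportional to coat area). This pooled estimate is exact on
noise-free data and avoids the large variance of a single interpolated
sample — with a 5% threshold rule downstream, a ±5% scale error on the
normaliser is the difference between a usable and a useless detector. The
CLC maximum is located on a 3-frame centred moving average (window
configurable); its value is read from the raw frame so that noiseless
recovery stays exact.

The 5% transition rule ("CLC exceeds AP2 by δ = 0.05") returns the first
frame *from which* the normalized excess holds for every remaining frame
of the evaluation window, with at least 2 frames in that suffix, and only
once the fitted AP2 curve has reached 50% of its plateau. The suffix
formulation encodes that a bent coat does not revert; a plain
first-crossing rule false-fires with probability near 1 on a ~100-frame
stalled plateau at 5% frame noise. The additive form is the default (at
the plateau both channels are ≈1, so additive and multiplicative differ
negligibly); a multiplicative variant is available by flag.

Shock analysis bins tracks by start time relative to the shock onset into
half-open 3-minute intervals `[k·180, (k+1)·180)`; pre-onset tracks pool
into one baseline group. Per bin we report the median and mean lifetime,
AP2 plateau duration (track end minus fitted plateau time) and time
offset. Stalled-coat morphology prediction classifies each track by the
threshold rule (no crossing in the window → flat) and splits crossed
tracks dome:pit by drawing a uniform time in their curved span.

## Snapshot ensembles

A steady-state EM snapshot is emulated by pooling all frames of all
events: a sample is a (track, uniform time in its lifetime) pair, so
longer-lived events contribute proportionally. A per-track-uniform
weighting is available behind a flag. Each sample is labelled by the
event's timeline and assigned the projected area of its fitted curve via
the cap geometry; intensities convert to nm² through a single linear
calibration scale. Records below the TEM detection limit (default
1000 nm², roughly the smallest outline confidently identifiable as a
clathrin lattice; no printed value exists, so this is configuration and
the removal count is always reported) are discarded before comparison.
Predicted and measured projected-area distributions are compared with
Welch's two-sided unequal-variance t-test and summarised with mean,
median and 10th/90th percentiles.

## Synthetic data

The generators emit every input the pipeline reads, with one seed driving
all randomness and a ground-truth sidecar for recovery tests. Study
conditions (generator defaults): frame interval 3 s; lifetimes lognormal
with median 60 s and log-SD 0.25 (right-skewed, typical of BSC-1 CME
events); final coat surface lognormal with median 3×10⁴ nm² (a pit of
θ_max = 160° and ~50 nm tip radius); time offset between AP2 plateau and
CLC maximum lognormal with median 10 s; configured intensity offset 0.15;
additive Gaussian noise with SD 5% of the channel amplitude (a plausible
magnitude for background-corrected TIRF spot sums; not a measured value),
optional Poisson resampling; 4 cells as grouping units.

Two empirical quantities the generator emulates are mutually inconsistent
under a purely geometric CLC curve: a clathrin content of 70% at the
transition implies a normalized CLC maximum of ≈1.43, i.e. an intensity
offset of ≈0.40, not the measured ≈0.15 (the two numbers come from
different cells and sample sizes). The default (`ap2_plateau`) scenario
therefore treats the intensity offset as the configured observable and
rescales the curved-phase CLC rise affinely onto the spherical surface
curve; the `two_phase` scenario keeps the geometric surface curve with its
intrinsic overshoot and content `f*`. Tests that check offset machinery
use the first; tests of geometric consistency use the second.

The offset construction is exact only when the frame grid is commensurate
with the configured offset (the grid is anchored at scission); at the
default 3 s interval with a 10 s offset the plateau falls between frames
and recovery carries an O(frame interval) interpolation error of order
1%. Exactness tests therefore use a 2 s interval with a fixed 10 s offset.

The shock generator nucleates events uniformly on an imaging clock. An
event whose flat-to-curved transition falls in the stall window
(onset + latency, + stall duration) stalls with the configured probability
(default 0.7): both channels freeze at their transition values until the
window ends plus an exponential reversion tail, then the curved phase
resumes; tracks truncate at the observation end. A coat still stalled at
truncation never shows a threshold crossing and is read as flat.

What the generators do *not* model: photobleaching, camera gain drift,
detection/tracking failures, spot merging, cargo heterogeneity, or any
pixel-level image structure. Passing recovery tests therefore demonstrate
correctness of the estimators under the stated noise model, not robustness
to all features of real microscopy data; the readers accept external
tables (with column remapping) precisely so real data can be analysed
without code changes.

## Numerical choices and limitations

- Angles are radians internally; the CLI accepts degrees.
- Units are fixed: nm, nm², s, a.u.; no auto-detection.
- Degenerate Welch input (both sides constant and equal) returns t = 0,
  p = 1 by convention.
- The affine estimator requires non-collinear landmarks (rank check with a
  scale-relative tolerance) and interpolates exactly at three pairs.
- Timelines with a zero-length curved phase are valid (all flat); a
  dome fraction of 1 leaves the pit interval empty.
- Fits assume a single event per track (one rise, one plateau/maximum);
  compound or re-nucleating events should be split upstream.
- The constant-area arm of model comparison deliberately keeps
  non-saturating fits: predicting "still flat" from an unconstrained
  asymptote is the observable failure mode that discriminates the models.
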