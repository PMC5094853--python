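# Methods

This note documents the models, conventions, numerical choices and known
limitations of stillforge. It is the reference for anyone extending the
package or interpreting its test results.

## The measurement model

A still exposure records each reflection `hkl` only partially. With
reciprocal setting matrix `A = U·B` (orientation times reciprocal cell), the
reciprocal vector `q = A·hkl` sits a signed distance

    δ = ‖q + s0‖ − 1/λ       (Ewald offset, Å⁻¹; s0 = beam direction / λ)

from the Ewald sphere. The recorded fraction is modelled with a Lorentzian
rocking curve,

    p(δ) = r_s² / (r_s² + 4δ²),     r_s(s) = γ0 + γe·(s/2),

so `p(0) = 1` and `p = 1/2` at `|δ| = r_s/2`. `γ0` (Å⁻¹) is the
resolution-independent reflecting range; `γe` (dimensionless here) scales
the resolution-dependent part. This effective width absorbs mosaic spread,
beam divergence and spectral dispersion together; the toolkit does not model
them separately. The same functional form is used by the simulator and the
refiner — parameter recovery is therefore well-posed by construction, and
passing recovery tests demonstrate the machinery, not that this particular
rocking curve is the physically correct one for any real instrument.
(Tabulated refined values for this class of experiment sit around
γ0 ≈ 2–3·10⁻⁴ Å⁻¹ and γe ≈ 3·10⁻³, which are the defaults.)

A raw observation is modelled as

    I_raw = G · exp(−B·s²/2) · p · I_true + ε,    ε ~ N(0, σ_bg²),

with per-frame linear scale `G` and temperature factor `B` (Å²). The full
intensity estimate divides all three factors out; σ is divided by the same
factor, so I/σ is invariant under correction and negative measurements keep
their sign. Observations with `p < 10⁻³` are excluded from merging (the
correction would amplify noise without adding information).

Conventions: beam along +z; detector perpendicular at distance D (mm);
detector coordinates in mm with origin on the beam axis; misset angles are
intrinsic x-y-z Euler angles in degrees; reciprocal quantities in Å⁻¹;
`s = 2 sinθ/λ = 1/d`.

## Ground truth and the simulator

True intensities follow acentric Wilson statistics:
`I_true(hkl) = Σᵢfᵢ²(s) · exp(−B_true·s²/2) · E`, with `E` a unit-mean
exponential deviate and `Σfᵢ²` the squared-scattering-factor sum of the
asymmetric unit (4-Gaussian form factors for H, C, N, O, S, Ca; default
composition = average protein residue × 100). Everything is acentric: centric
zones and their distinct intensity statistics are deliberately ignored, which
slightly idealises the L-test and Wilson moments relative to real space
groups.

`B_true` defaults to 0, i.e. the truth is expressed on the ideal random-atom
scale. This is a scale convention, not a physics claim: pseudo-Wilson scaling
(below) brings every frame onto exactly that scale, so with `B_true = 0` the
pipeline's merged output and the generator's truth live on the same scale and
can be compared directly. A non-zero `B_true` is supported (used in Wilson-
plot tests) but the pipeline's output is then flattened relative to the truth
by the same convention.

Each simulated frame draws: a uniform random orientation; wavelength
`λ(1 + N(0, 0.005))`; a pulse scale `G` from a Gaussian with FWHM equal to
100% of its mean, truncated positive; `B ~ N(20, 5)` Å²; cell edges jittered
by 0.1%. All non-absent reflections with `|δ| ≤ 3·r_s` and `d ≥ d_min` are
recorded with the model above, σ taken from the expected (pre-noise) signal —
a σ that fluctuated with the recorded intensity would make inverse-variance
merging biased low. The *recorded* frame carries the true λ, the true
(jittered) cell, and an orientation deliberately mis-estimated by a small
random rotation (default 0.02°; the benchmark uses 0.05°, a typical indexing
accuracy) — that error is what post-refinement must recover.

Mis-indexed frames are injected by shifting every recorded Miller index by
+1 along l while leaving positions and the recorded beam centre untouched.
They are generated with the c* axis within 30° of the detector plane: the
one-index ambiguity along a long axis physically arises only when that
crowded node row runs transverse to the beam, and only then does the refined
beam centre shift by the full ~λD/c. A second crystal form (c halved, its
own independent truth) can be mixed in; the per-frame generation record
(`FrameTruth`) is written for tests only and never read by the pipeline.

The background σ of the benchmark is calibrated at run time to 5% of the
mean recorded signal (measured on a small noiseless pre-simulation), which
yields a negative-intensity fraction of ~10%, inside the 4–16% range typical
of background-subtracted still data.

## Pseudo-Wilson scaling

Per frame, partiality-corrected intensities of reflections with
`I/σ > 0.5` are normalised per reflection by `Σfᵢ²(s)` (normalising before
shell-averaging removes the envelope's curvature across a wide shell),
averaged in equal-reciprocal-volume shells (shells with < 5 selected
reflections dropped; ≥ 2 shells required), and the line
`ln(⟨I/Σf²⟩) vs s²` is fitted by ordinary least squares: intercept `ln G0`,
slope `−B0/2`. A config switch `wilson_denominator: f|f2` selects a literal
`Σfᵢ` normalisation instead of `Σfᵢ²`; the default is `f2`, which is what
Wilson statistics require and what makes recovery exact on Wilson-distributed
truth. The single-frame estimate carries irreducible Wilson sampling noise
(shell means of ~10–100 exponential deviates), so per-frame values scatter
by several percent even on noiseless data; the estimator itself is unbiased
(verified by Monte-Carlo and by deterministic-envelope simulations).

Legacy mean-intensity scaling (every frame scaled to the grand mean) is
retained for comparison.

## Post-refinement

Each cycle refines every frame against the current merged reference by
bounded Nelder–Mead minimisation of

    T_pr = (1/N) Σ [(I_ref − I_full)/σ_full]²,

in stages: (G, B); (γ0, γe); a joint (G, B, γ0, γe) polish — the scale and
reflecting-range parameters are strongly coupled through the partiality
correction and alternating the two stages alone converges slowly; two
rotations perpendicular to the beam (a rotation about the beam does not move
δ); and the three orthorhombic cell edges. The spot-position target
`T_xy = ⟨‖x_obs − x_pred‖²⟩` (mm²) is added with weight 10 mm⁻² in the two
geometric stages. Bounds: G ∈ [10⁻³, 10³], B ∈ [−10, 300] Å²,
γ0 ∈ [10⁻⁵, 10⁻²], γe ∈ [0, 0.1], rotations ±0.5°, cell edges ±2%; 200
function evaluations per stage (600 for the joint polish). A stage is
accepted only if it lowered the target, so `T_pr` never increases across
accepted steps; a frame whose refinement fails to reduce `T_pr` is reverted
and flagged. Frames need ≥ 20 reference-matched observations above the
`I/σ > −3` threshold.

**Gauge fixing.** `T_pr` is exactly invariant under a common scale and a
common B shift applied to every frame together with the reference, so the
overall (G, B) of the merged set is a gauge freedom: left alone it drifts
from cycle to cycle. After every re-merge the reference is re-anchored to
the ideal Wilson scale (its fitted Wilson intercept divided out, its fitted
slope flattened) — the same convention the pseudo-Wilson initial scaling
defines. The anchor's intercept carries ~1–2% sampling noise from the finite
exponential-deviate realisation, and a soft near-degenerate valley couples
(γ0, γe, G, B) across cycles; consequently per-frame G values recovered from
a self-consistent run can sit a few percent from the generating values as a
common factor even when the merged data correlate with the truth at > 99%.
Identifiability proper (refinement against the generating reference) recovers
G to < 1% and γ0/γe to a few percent; the recovery tests are split
accordingly.

After each cycle, frames whose refined cell edges or ln G deviate from the
dataset medians by more than 3 robust standard deviations (1.4826·MAD) are
rejected and the reference is rebuilt; the cycle history records CC½,
R_merge, completeness, the merged set's overall Wilson B and mean parameter
shifts. Ten cycles are the default; in the benchmark the accepted frame set
stabilises within ~6 cycles and CC½ changes per cycle fall well below half a
percentage point thereafter.

## Merging and statistics

Corrected observations with `I/σ ≥ −3` (configurable) are grouped by
symmetry-unique index (Laue group mmm for P2₁2₁2₁, Friedel pairs merged, no
anomalous treatment; screw-axis absences excluded) and combined by
inverse-variance weighting. Statistics: completeness against the
absence-filtered unique set; mean multiplicity; CC½ by seeded random
half-splitting of each index's observations (the simplest defensible
estimator; the split seed is recorded, and two seeds move CC½ by < 2 points
on the benchmark); still R_merge over indices with multiplicity ≥ 2; mean
I/σ. Shells partition d*³ uniformly (equal reciprocal volume), default 10–20
shells. The resolution cutoff rule keeps shells from low resolution until
CC½ first drops below 0.25. Merged negative intensities are reported as-is
(no truncation or French–Wilson conversion).

## Diagnostics

**L-test.** Each unique reflection is paired with a random neighbour within
`|Δh|+|Δk|+|Δl| ≤ 4` that is not a symmetry mate, so the pair shares its
local Wilson envelope; `L = (I₁−I₂)/(I₁+I₂)` is clipped to [−1, 1] and pairs
with non-positive sum are dropped (both conditions only bite when negative
intensities are present). Untwinned acentric expectations ⟨|L|⟩ = 1/2,
⟨L²⟩ = 1/3; perfect twin 3/8, 1/5. Under this package's Gaussian-additive
noise model, *truncating* negative observations before merging biases weak
intensities upward and compresses both L statistics downward toward the twin
values, while keeping them inflates the statistics upward through noisy
near-zero pair sums; the seed-stable, tested property is that directional
compression. Which of the two distortions is larger depends on the noise
model and regime, so no claim is made about their relative magnitude.

**Beam-centre diagnostics.** Because predicted spot positions depend on the
beam centre only through a rigid shift, the T_xy-optimal centre within a
search disc has a closed form: recorded centre + mean(observed − predicted),
projected back onto the disc (default radius 0.5 mm; legacy wide search
4.0 mm). A frame mis-indexed by one index along an axis of length c shows a
refined centre displaced by ≈ λD/c (1.34 mm for the 291 Å axis at
λ = 1.3047 Å, D = 299.82 mm); frames whose radial deviation from the dataset
median exceeds max(0.25 mm, 0.5·λD/c) are flagged. On 100 benchmark frames
with 8 injected shifts this flags exactly the 8 (clean-frame deviations are
two orders of magnitude below threshold).

**Truth comparison.** CC is the Pearson correlation of merged vs. true
intensities (as %); R = Σ|I_merged − k·I_true| / Σ I_merged with `k` the
least-squares scale (recorded in the output). R is invariant under global
rescaling of either side.

## Spot finding

Background = image median, σ = 1.4826·MAD (robust to the spots themselves);
pixels above `background + min_height·σ` are grouped by 8-connectivity;
components of ≥ min_area pixels become spots with excess-intensity-weighted
centroids. The grid search scores every (min_area ∈ 2–22, min_height ∈ 2–15)
pair by F1 against known reference positions with a 2 px one-to-one match
radius — a surrogate for integration-quality ranking, which is out of scope —
and breaks ties toward the largest thresholds (the most conservative corner
of a perfect-score plateau).

## Benchmark conditions and problem sizes

The standard benchmark (`stillforge.synthdata.benchmark_config`) is a
30×40×50 Å P2₁2₁2₁ crystal to 2.5 Å — about 2 300 unique reflections and
~125 observations per frame — with 120 frames and the jitters listed above;
ten cycles run in a couple of minutes on one core. The completeness
benchmark uses the long 69.4×170.8×291.2 Å cell at 5 Å (15 700 uniques,
~1 300 observations/frame, 300 frames, merge only). These sizes were chosen
so the whole suite runs comfortably on a laptop while keeping every
statistic well-sampled; the machinery itself is size-agnostic.

What passing on these simulations does **not** show: robustness to pixel-
level integration artefacts, detector metrology errors, non-Lorentzian
rocking profiles, per-shot spectra, centric statistics, or radiation damage —
none of which the generator emulates.

## Known limitations

- Orthorhombic cells only in the refiner's cell stage (a, b, c); P1 and
  P2₁2₁2₁ only in the symmetry layer.
- One detector panel, no tilt or distance refinement.
- The partiality model is shared between simulator and refiner; real-data
  performance depends on how well that model fits the instrument.
- CC½ by random splitting underestimates slightly at very low multiplicity.
- The L-test requires enough local pairs (≥ 500) and an index set dense
  enough for neighbour pairing.
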