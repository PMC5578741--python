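# Methods

## Receptor model

A signaling team is a trimer of receptor dimers that switches between an
active and an inactive state as one unit. The per-dimer free-energy
difference (active minus inactive, kBT) is linear in temperature and in
the methylation level:

    f_i = f0([L]) + (T − T0)·f1 − [g0 + (T − T0)·g1]·m,

with the ligand term f0([L]) = f0(0) + ln[(1 + [L]/Koff)/(1 + [L]/Kon)]
from two-state binding (Koff < Kon for an attractant, so f0 grows with
ligand toward f0(0) + ln(Kon/Koff)). The team's activity is
A = 1/(1 + e^F) with F the sum of its three dimer contributions. Tar and
Tsr share all parameters except the ligand term: Tar responds only to
MeAsp, Tsr only to serine. Teams assemble by random mixing, so the four
compositions (0–3 Tar) carry binomial weights C(3,n)·p^n·(1−p)^(3−n) with
p the Tar expression fraction (0.5 for a 1:1 ratio). All dimers in a team
share one methylation level.

Adaptation follows saturating methylation kinetics,

    dm/dt = γR·(mtot−m)/(mtot−m+N0)·(1−A) − γB·m/(m+N0)·A,

whose steady state obeys

    (mtot−m)/(mtot−m+N0)·(1−A)/(1−A0) = m/(m+N0)·A/A0.

N0 controls how abruptly (de)methylation slows near the limits m = 0 and
m = mtot. At N0 = 0 the fixed point is A = A0 exactly (perfect
adaptation); at N0 > 0 teams near saturation — e.g. Tar-rich teams under
saturating MeAsp — cannot restore A0, and this imprecision is the
mechanism behind the response inversion of mixed ensembles.

### Default parameters

| parameter | default | units | role |
|---|---|---|---|
| f1 | 1.2 | kBT/°C | temperature slope of the free energy |
| g0 | 0 | kBT/methyl | methylation coefficient at T0 |
| g1 | 0.2 | kBT/(methyl·°C) | temperature slope of the methylation coefficient |
| T0 | 24 | °C | reference temperature |
| mtot | 8 | — | methylation sites per dimer |
| N0 | 2 | — | methylation-saturation parameter |
| A0 | 1/3 | — | adapted activity set point |
| dT_step | 3 | °C | stimulus temperature step |
| f0_sat | 15 | kBT | ligand-saturation offset used for normalization |

γR and γB fix only the time scale of adaptation, not its end point; the
defaults γB = 1, γR = A0/(1−A0) = 0.5 (arbitrary time units) make the
N0 = 0 fixed point reproduce A0. With these f and g values the adapted
methylation of a single receptor type approaches f1/g1 = 6 from below as
temperature rises, so single-type responses decay with temperature but
never change sign; an inversion requires both receptor types and N0 > 0.

## Thermal-response curves

The response at temperature T is R(T) = [Ā(T+dT) − Ā(T)] / ΔĀ, where Ā is
the composition-weighted adapted activity. Two evaluation modes are
provided because the step response of an adapting pathway is
time-dependent:

* `transient` (default): Ā(T+dT) is evaluated with each team's
  methylation frozen at its T-adapted value — the initial amplitude a
  FRET measurement reports before re-adaptation sets in.
* `re_adapted`: the ensemble fully re-adapts at T+dT; under perfect
  adaptation this response is identically zero, which serves as the null.

ΔĀ is the activity drop at the lowest grid temperature when the
normalizing receptor (Tar by default) is driven from the ligand-free
adapted state to saturation (f0 = f0_sat) with methylation frozen,
mirroring how measured responses are normalized against a saturating
attractant stimulus. R < 0 is labeled thermophilic (kinase activity falls
on warming, attractant-like), R > 0 cryophilic; the inversion temperature
is the linearly interpolated zero crossing of the first adjacent grid pair
with a strict sign change. The default grid is 24–39 °C in 3 °C steps.

## Numerical choices

* Steady states are found by bisection of the balance residual h(m) on
  [0, mtot] (interval tolerance 1e-12, 200 iterations; exact h = 0
  resolves to the lower m). h(0) > 0 > h(mtot) for finite free energies,
  so a root is always bracketed; a solution pinned within 1e-9 of a
  boundary with residual above 1e-8 is flagged `boundary`.
* The perfect-adaptation variant (N0 = 0) solves A(m) = A0 in closed form
  without clipping m to [0, mtot] ("unbounded"), since clipping would
  itself truncate adaptation and mask the perfect-adaptation null. The
  bounded bisection solver remains available via `unbounded=False`.
* At T = T0 with g0 = 0 the activity does not depend on m and the
  unbounded adapted state degenerates; it is evaluated in the limit
  T → T0+ (adaptation at T0 + 1e-6, with a warning). The logistic is
  evaluated via `scipy.special.expit`, which saturates smoothly for
  |F| ≳ 37 instead of overflowing.
* The methylation ODE is integrated with LSODA (rtol 1e-8, atol 1e-10),
  clipping m into [0, mtot] inside the right-hand side; the occupancy
  fractions x/(x+N0) take the 0/0 limit as 0, which keeps the box
  forward-invariant including at N0 = 0.
* Growth rate is the least-squares slope of ln(OD) in a sliding window
  (default 5 points); ties resolve to the earliest window. An OD floor of
  1e-4 is applied before the log; blank subtraction is the caller's
  responsibility. Note that with read noise comparable to the baseline OD
  the windowed log-slope at early times is noise-dominated and
  overestimates µmax; widening the window or restricting to OD well above
  the noise floor mitigates this.
* The half-max growth delay interpolates ln(OD) linearly between the
  samples bracketing half the maximal OD.

## Tracking pipeline

Stages run in the assay's order and only remove or group records:
particle filters (keep area ≥ 5 px and eccentricity ≤ 0.95 — the
thresholds are strict, boundary values survive), nearest-neighbor linking,
motility filter (motile iff std(Y)/std(X) < 18, population std over all
track points; std(X) = 0 is non-motile), path-length filter (cumulative
step displacement ≥ 10 px; traveled distance, not point count or net
displacement), then histogram and TMC over the pooled X of viable tracks.
The TMC formula is implemented exactly as printed, which assigns +1 to
accumulation at the *left* (low-X) cutoff; because the warm wall of the
physical device sits at high X unless the image is flipped, a
`warm_positive` option negates the sign for reporting. X cutoffs default
to the observed extremes but should be supplied for cross-run
comparability.

Linking processes candidate track–detection pairs in ascending distance
order and caps the link distance at 25 px ≈ 3× the per-frame flow
displacement (30 µm/s ÷ 12 fps ÷ 0.3 µm/px = 8.33 px/frame); a swimming
cell's per-frame displacement (flow plus ~6 px of swimming) stays well
below this, while unrelated cells in a dilute suspension essentially never
come that close. Tracks terminate on the first missed frame (no gap
closing, no Kalman prediction).

## Synthetic data

The trajectory generator emulates the statistical structure of the
microfluidic assay: cells advected along the flow axis Y at 8.33 px/frame
in a 1667 px (500 µm) channel imaged at 12 fps and 0.3 µm/px, reflecting
walls in X. Motile cells swim with run-and-tumble persistence — a
per-axis velocity of magnitude 6 px/frame (≈22 µm/s) reversing with
probability 0.1 per frame, plus 1 px Gaussian jitter and an optional mean
cross-channel drift; persistence matters because uncorrelated steps of
realistic size cannot reproduce both the large cross-channel spread of
swimming cells (needed to pass the std-ratio motility filter) and
per-frame displacements small enough for unambiguous linking. Non-motile
cells ride the flow with 0.1 px X jitter. Defaults simulate 25 motile and
10 non-motile cells for 60 frames (a ~5 s transit of the imaged field),
seeded cells spread over 2000 px of channel length to emulate the dilute
suspensions used in practice. Areas ≥ 5 px and eccentricities < 0.95 are
drawn so simulated cells pass the particle filters; a separate generator
produces spurious detections (area < 5 px or eccentricity > 0.95) that
the filters must remove exactly.

The generators are pure functions of config + seed. They do not emulate:
temperature-dependent swimming speed (deliberately outside scope),
centroid localization noise, cell division or death, out-of-plane loss,
or crowding. Cell–cell close encounters do occur at the default density
and can fragment or swap greedy nearest-neighbor tracks, as in real data;
ground-truth recovery is therefore exact only on realizations free of
such encounters, and the test suite asserts exact recovery on fixed seeds
verified to be encounter-free while checking statistical properties
(drift-free TMC null within 3 standard errors over 50 seeds, drift sign
in ≥95% of replicates) across all seeds. Passing these tests shows the
pipeline implements its stated rules faithfully on data with known truth;
it does not validate the biological realism of real trajectories.

The growth generator produces logistic curves od(t) = baseline +
K/(1 + e^{−r(t−t0)}) with Gaussian read noise (defaults K = 0.6 OD,
r = 0.6/h, t0 = 6 h, baseline 0.01, σ = 0.01, 16 h every 0.1 h — typical
of a minimal-medium plate-reader well). The half-max delay of this shape
sits slightly before t0 (−ln(1 + baseline·…)/r ≈ −0.06 h at the
defaults), well inside the 0.25 h recovery tolerance used in the tests.

## Problem sizes

End-to-end checks use 50 trajectory replicates (35 cells × 60 frames
each), 1,000 random model configurations against a 10^5-point dense-scan
oracle of the steady-state residual, 100 ODE-vs-algebra comparisons, and
100 growth-curve seeds; these sizes give stable statistics for every
assertion while keeping the full suite fast.

## Known limitations

* The model is a population-average steady-state description: no
  receptor-cluster spatial structure, no cell-to-cell variability, no
  stochastic kinase noise.
* Model parameters are adopted, not fitted; the package deliberately
  contains no fitting of the free-energy parameters to FRET data.
* The inversion temperature is a model output on a temperature grid; the
  package does not predict absolute accumulation positions in a physical
  channel.
* Two growth-delay definitions (half-max OD and time to maximal rate)
  coexist in the field and can differ by hours on slow-lag curves; both
  are exposed and the discrepancy is surfaced rather than resolved.
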