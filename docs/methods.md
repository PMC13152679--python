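# Methods notes

This note records the models the package implements, the parameters that
matter, the numerical choices, and what the synthetic fixtures do and do
not demonstrate.

## Signal model and processing order

A recording is a T×Y×X intensity stack per spectral channel with frame rate
(Hz), pixel size (µm/px) and optional stimulus frames carried in a JSON
sidecar. Frame *i* maps to t = i/frame_rate (0-based); a stimulus "time" is
the start of its frame.

ΔF/F = (F − F0)/F0 with two baseline conventions:

* `prestim_mean` — F0 is the mean over frames [0, prestim_end); when
  `prestim_end` is not given it defaults to the first stimulus frame.
* `trial_median` — F0 is the median over all frames (used when no
  pre-stimulus epoch exists).

For movies F0 is per pixel, computed before any spatial aggregation;
aggregating first and converting the mean trace is a separate, explicit
path because the two orders differ under spatial heterogeneity.
Non-positive F0 anywhere is an error (dead or clipped region), never
silently patched.

For spontaneous recordings the default stage order is **bleach-correct →
low-pass → ΔF/F (median) → detect events**. Whether correction precedes or
follows filtering in the original workflow is not determinable from the
protocol alone; the order is fixed here and recorded in each run's
provenance file so results are comparable across runs.

## Photobleach correction

F(t) = A₁e^(−t/τ₁) + A₂e^(−t/τ₂) + C, fitted by bounded trust-region least
squares on the full trace; corrected trace = F − fit + C (the asymptotic
level is kept so ΔF/F remains interpretable). Choices that matter:

* τ bounds (2 frame periods, 10× trace duration]; τ initial values from
  log-linear fits of the first and last thirds.
* **Identifiability bounds**: a decay much slower than the record is
  first-order indistinguishable from a constant, so the unconstrained
  problem has a flat valley trading A₂ against C that can push C far below
  the data and wreck downstream ΔF/F. Amplitudes are therefore capped at
  2× the observed range and C is confined to [min − range/4, max]. Inside
  the identifiable regime these bounds are inactive (the generator
  round-trip recovers all five parameters to ≲0.05%).
* **Robust loss** (soft-L1, scale 3% of the range): brief transients riding
  on the trend act as outliers rather than bending the fitted
  exponentials; a 300-count transient on an 800-count bleach trend loses
  <2% of its amplitude. On clean traces the loss is quadratic near zero,
  so exact fits are unaffected.
* Non-convergence returns the input unchanged with a flagged status.
* Optional per-frame weights can emphasize the early frames where
  bleaching is fastest (off by default).

## Low-pass filter

Third-order Butterworth, default cutoff 0.68 Hz, built in second-order
sections and applied forward–backward (`sosfiltfilt`). Zero-phase operation
was chosen because triggered-average timing must not be lagged; a causal
single-pass mode exists behind a flag. Forward–backward squares the
magnitude response, so the gain at the cutoff is exactly 1/2 and DC gain is
exactly 1. At the reference 1.47 Hz sampling, Nyquist is 0.735 Hz: the
default cutoff is valid but near-Nyquist, which the SOS formulation keeps
numerically stable; cutoffs at or above Nyquist are rejected with the
Nyquist value in the message.

## Grid hotspot mapping

Non-overlapping square tiling (default 8×8 px) anchored at the top-left
pixel; trailing partial squares are discarded (logged) so all squares have
equal area. Per square, the trace is the spatial mean of its pixels.

Activity rule: baseline mean and sample SD over the pre-stimulus ΔF/F
frames, peak = max ΔF/F in the response window (default stimulus → +30 s),
active ⇔ peak > mean + k·SD with k = 2, strict. Decisions taken where the
protocol is ambiguous:

* Baseline SD is per square, not pooled — spatial heterogeneity is the
  measurement, pooling would wash it out.
* With repeated stimulations, per-trial peaks *and* per-trial baseline
  statistics are averaged per square before thresholding.
* A square with zero baseline SD is flagged degenerate; because the
  inequality is strict, a fully constant square can never be active, while
  a noiseless square that genuinely responds still passes (peak > mean).
  No division by the SD ever occurs.
* Peaks are taken on unfiltered ΔF/F (the low-pass stage belongs to the
  spontaneous-activity pathway only).

Condition comparison pairs squares by grid index and reports percent
active ROIs and integrated (full-field mean) peak ΔF/F per condition with
fractional changes relative to the first condition.

## Rise–decay kinetics

y(x) = α(1−e^(−x/τON))e^(−x/τOFF) + β for x = t − t0 ≥ 0, with t0 the
stimulus onset (the model's time origin is not inherent in the equation; it
is fixed at the stimulus here). The model peak is at
x* = τON·ln(1 + τOFF/τON) with height α·f + β where f < 1; the initial α is
corrected by f evaluated at the initial τ values, otherwise α is
systematically underestimated. Initialization: β ← pre-t0 mean, τON ←
time-to-peak/2, τOFF ← post-peak 1/e time; bounds τ ∈ (frame period/10,
10× fit duration]; τ parameters are fitted in log space. Because the
product model has shallow valleys when τON ≈ τOFF, three additional
multi-starts jitter the τ initials ±50% log-uniformly from a fixed seed;
the lowest-SSE candidate is returned. Measured recovery: exact (≪1%) on
noiseless traces; at peak-SNR 10 and 10 Hz sampling, per-parameter median
relative errors run 4–10% over 100 replicates.

Per-grid fitting covers active squares only; failed fits are reported with
`converged = false`, excluded from the τ histograms and counted.

## Event detection and triggered responses

Wave detection z-scores the processed calcium trace against its full-trace
mean and sample SD; candidates are strict local maxima with z > 3; events
closer than 10 s are resolved by keeping the larger (earlier frame on
ties). The trigger for averaging is the frame *prior* to the peak,
implemented literally; both channels are cut with identical triggers so
cross-channel coupling is read on a common time base. Windows (60 s total)
that would run off the trace drop their event, with counts reported.
Response amplitude: in the 10 s flanks before/after the trigger, the peak
of the mean trace is replaced by the mean of a 3 s window centered on it,
clipped to the flank (clipping, rather than rejection, keeps
border-adjacent peaks measurable and is logged); response = after − before.
The measure is invariant to constant offsets and linear in trace scale.

## Small-sample statistics

Paired t on differences with df = n−1 (two-sided p = 1 − t/√(t²+2) in
closed form at df = 2, used as a numerical cross-check). Mann–Whitney U
from midranks; for n₁+n₂ ≤ 12 without ties the p-values come from full
enumeration of all C(n₁+n₂, n₂) assignments; ties fall back to a seeded
permutation test (10⁵ draws); larger samples use the normal approximation
with continuity correction. One- and two-sided p are always reported and
the method labeled, because published values for groups this small are
often one-sided exact tails. No multiple-testing correction is applied by
default (an explicit choice; the upstream analyses report uncorrected
p-values).

## Synthetic data: what it emulates, what it does not

The generator is the package's ground-truth instrument, not a biophysical
model. Concentration = uniform background + Σ hotspots × Σ events, with
spatially Gaussian hotspots (peak-normalized) and the rise–decay kernel
(peak-normalized) as the temporal drive — the kernel deliberately reuses
the fitting model so kinetic recovery is exact by construction, and event
fields superpose linearly. Sensors apply a Hill transform; defaults give
both sensors dff_max = 1 and n = 1 with Kd = 0.02 µM (GRAB-like) vs 20 µM
(nIRCat-like), so the linear-regime response ratio is Kd_g/Kd_n = 10⁻³,
matching the reported three-orders-of-magnitude contrast. Rendering:
counts = f0·(1+ΔF/F)·B(t) + ε with B a double exponential normalized to
B(0)=1 (so f0 is the true baseline), Gaussian noise by default (Poisson
mode available — Gaussian keeps SNR directly controllable), clipped to
[0, 65535] with a logged count. All randomness derives from one explicit
seed; identical configs render bit-identical movies.

Not modeled: dopamine diffusion/uptake (no PDE), optics (PSF, pinhole,
sectioning), sensor cross-reactivity, motion, dark/read-noise structure.
Consequently, passing tests demonstrate the *analysis* is correct and
self-consistent, not that real tissue obeys the forward model.

**Fixture geometry.** The evoked fixture places hotspots (σ = 1 µm) at the
centers of distinct grid squares in a 64×64-px field (0.75 µm/px, 1.47
frames/s, stimulus at frame 30, three trials). At these defaults the
neighbor-square leakage of a hotspot is ~3 orders of magnitude below the
2-SD threshold while the hotspot's own square sits far above it, so the
expected active set equals the hotspot squares by construction. The mild
double-exponential bleach (≈3% over a trial) is what makes the k = 2 rule
well-posed on synthetic data: baseline SD is dominated by the
deterministic downward trend, and the response-window maximum of a
signal-free square sits *below* the baseline mean, so white-noise maxima
cannot cross the threshold (with temporally white noise alone, the max of
~40 response frames hovers near 2 SD and the rule would be a coin flip —
real recordings avoid this because baseline activity is temporally
correlated, which the bleach trend stands in for). Amplitudes are bimodal
(strong 45–60 µM, weak ~4 µM): under a 0.4× "quinpirole" scaling the weak
hotspots drop below threshold and the strong ones stay, giving a
well-defined ROI reduction that is cross-checked against a brute-force
oracle on the same movies. The wave fixture spaces 20 global transients
45 s apart (calcium kernel τON 0.5 s / τOFF 1.5 s, 0.3 µM drive): sparse
enough that wave peaks stand > 3 SD above the full-trace statistics, the
regime the z-score rule assumes; the dopamine channel sees a 0.2 µM drive
against its 20 µM Kd (ΔF/F ≈ 10⁻²), the low-SNR regime in which coupling
is read from calcium-triggered averages.

Problem sizes throughout (64×64 fields, 120–1400 frames, 100-replicate
recovery runs, 200-instance oracle sweeps) are chosen so the full suite
and the acceptance script each complete in well under a minute while every
statistical margin above is still decisive.

## Known limitations

* The exact Mann–Whitney enumerator is O(C(n₁+n₂, n₂)); the default
  exactness threshold (n₁+n₂ ≤ 12) keeps it instantaneous and is
  configurable.
* Bleach correction assumes at most two exponential components; faster
  multi-phase decays will leave residual trend (visible in the reported
  residual norm).
* The grid analysis does not merge adjacent active squares into release
  sites, and no sub-square localization is attempted.
* Kinetic fits assume a single release event per window; overlapping
  events bias τOFF upward.
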