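# Methods

## The measurement chain

A trial is a constant-velocity treadmill run recorded as 3-component
ground-reaction force (GRF) at 1000 Hz, optional fore-aft marker
trajectories at 200 Hz, and a configuration (body mass, belt velocity,
per-leg unloaded leg lengths, prosthesis model / stiffness category /
height offset, bench prosthesis stiffness k_RSP). Axes are lab-fixed with
vertical positive up and anterior positive forward; files store SI units.

**Filtering.** Forces are low-pass filtered with a Butterworth design of
order 2 applied forward and backward (`scipy.signal.sosfiltfilt`), the
standard biomechanics reading of a "4th-order zero-phase" filter: the
magnitude response is squared (effective 4th-order roll-off, exactly 1/2
power at the cutoff) and the phase is zero. Cutoffs: 30 Hz (GRF), 7 Hz
(markers). A single-pass variant is retained behind
`FilterSpec.zero_phase=False` for sensitivity checks.

**Contact detection.** Samples with filtered vertical GRF ≥ 30 N form
candidate contacts; aerial gaps shorter than 20 ms are merged and contacts
shorter than 50 ms discarded (sprint contact times are ~100-140 ms, so
both guards are far from real events). Intervals are half-open
[onset, offset): contact time is (offset − onset)/rate and stance plus
aerial samples partition the trace exactly. Legs are labelled by strict
alternation from the configured first-contact leg; a marker consistency
check reports the belt speed seen by each leg's marker during stance.

**Step metrics.** A step runs from one stance onset to the next
(opposite-leg) onset and is attributed to the leg that starts it:
step time = contact + subsequent aerial time, step frequency its
reciprocal, contact length = belt velocity × contact time. The last
stance of a trial has no observed aerial time and is dropped. Stance
average vertical GRF is the mean of the filtered vertical channel over
the stance; the peak resultant uses all three channels. Trial summaries
are per-leg means over complete steps (step frequency as the mean of
per-step frequencies, not the reciprocal of mean step time) plus the
arithmetic both-legs average. A maximum-velocity attempt is valid when at
least 8 strides are completed while fore-aft position is held (drift of
stance-onset marker positions ≤ 0.3 m by default; the threshold is a
package choice — the criterion is qualitative in the field).

**Spring-mass estimates.** With the leg modelled as a massless linear
spring under a point mass:

* contact angle θ = asin(v·t_c / 2L₀), assuming the leg sweeps
  symmetrically about vertical; the belt velocity from the configuration
  is used (the marker estimate is QC only);
* Δy, the downward CoM excursion during stance, comes from double
  integration of f_v/m − g over exactly one stride (onset to next
  same-leg onset). The free velocity constant is set so the mean vertical
  velocity over the stride vanishes — the stride-periodic closure of
  steady running — and the excursion is read touchdown-to-minimum within
  the stance. A stride whose mean force deviates from body weight by more
  than 15% is rejected as non-steady rather than silently integrated;
* ΔL = Δy + L₀(1 − cos θ), k_leg = peak vGRF / ΔL in kN/m, and
  ΔRSP = mean affected-leg peak resultant GRF / k_RSP.

Affected-leg estimates always use the trochanter-to-prosthesis-tip
length, unaffected-leg estimates the trochanter-to-floor length.

**Touchdown refinement.** Zero-phase filtering smears the loading edge
symmetrically in time, so the 30 N crossing precedes the true foot strike
by ~3-4 ms; anchoring Δy there reads the CoM height while still airborne
and inflates Δy by several percent. When the raw vertical channel is
available the Δy anchor is therefore taken at the touchdown instant
obtained by fitting a line to the raw rising edge between 50 and 600 N
and extrapolating to zero force (accurate to ~0.1 ms on simulated
sessions, robust to 5 N sensor noise). Contact time itself deliberately
remains threshold-defined — it is the field's definition — and thus
carries the edge smear; consequences are quantified below.

**Symmetry and statistics.** SI = (x_AL − x_UL)/(0.5(x_AL + x_UL)) from
trial-level per-leg means (not per-step SIs averaged); zero is perfect
symmetry, positive means the affected leg is larger, and SI ∈ (−2, 2) for
positive inputs. Group tests are two-sided one-sample t-tests against
zero with Bonferroni correction. Configuration effects on maximum
velocity use linear mixed models with a random subject intercept
(statsmodels `MixedLM`, REML): prosthesis model treatment-coded against
the slowest-mean model (so faster models appear as positive contrasts),
stiffness (category or kN/m), height and any velocity covariate
continuous. P-value conventions follow the statsmodels defaults (Wald);
the contract pinned by tests is exact coefficient recovery in the
noiseless limit and calibrated type-I error under the null, not a
specific degrees-of-freedom method. Percent differences between
configuration means are 100·(a − b)/b, reported to one decimal.

## The simulator

The generator is a conservative two-leg spring-loaded inverted pendulum
(SLIP). Stance integrates

    m·ẍ = F_s (x − x_f)/L,   m·z̈ = F_s z/L − m·g,   F_s = k (L₀ − L)

with the foot fixed, flight is ballistic, touchdown occurs when the CoM
descends to L₀·cos(α) for the incoming leg, takeoff when the spring
regains its rest length. Integration uses `solve_ivp` (DOP853,
rtol 1e-11) with terminal event location; mechanical energy drifts by
< 1e-8 % over 20 re-integrated strides, and each stance satisfies the
impulse-momentum identity to < 1e-5 %.

A steady gait is a fixed point of the apex-to-apex return map over one
stride (one stance per leg). Because the system is conservative, matching
apex height across the cycle also matches apex forward speed, so the
fixed point is located by a one-dimensional bracketed root search
(residual < 1e-6 m). Sessions tile the converged cycle on the 1000 Hz
force grid via dense-output interpolation (never by integrating on the
coarse grid), add seeded Gaussian sensor noise (one master seed, child
streams for force and marker channels), and synthesize marker traces in
the treadmill frame: a marker rides the belt backward at the
cycle-average speed during its own stance and returns along a C¹ cubic
Hermite arc during swing. The medio-lateral force channel is pure sensor
noise. `truth.csv` carries exact per-stance contact/aerial times, average
and peak forces, spring compression, CoM excursion and energies.

Default parameters emulate the study conditions: 75 kg athlete, ~8 m/s,
1000 Hz forces / 200 Hz markers, leg stiffness 18 (affected) and 22
(unaffected) kN/m, touchdown angles 0.50 rad — at 8 m/s the SLIP admits
periodic running only for angles near 0.45-0.55 rad, and 0.50 rad yields
sprint-like contact times (~0.11-0.14 s) and stance-average forces
(~2.5-3 body weights). Force noise defaults to 5 N (measurement noise is
not characterized in the source literature; 5 N is far below the 30 N
threshold and typical of instrumented treadmills), marker noise to 1 mm.

`force_asymmetry_params()` encodes the benchmark condition of an affected
leg applying ~6% lower stance-average force (truth SI ≈ −0.062): the
affected leg is set 1.5 cm longer (prosthetic side is prescribed 2-8 cm
taller), slightly softer (19.5 vs 20 kN/m) and lands ~1° steeper. This
realization keeps contact-time asymmetry near zero, which matters for
recovery accuracy (below).

## What the synthetic data do and do not show

The generator reproduces the *structure* of treadmill sprint data —
alternating asymmetric stances, realistic force magnitudes and timing,
belt-riding markers, additive noise — with exact ground truth, so passing
tests demonstrate that the chain recovers what it claims from data obeying
the spring-mass idealization. Real limbs are not conservative linear
springs: human vertical GRF traces are skewed (especially the intact
leg), prostheses dissipate a few percent of energy per bounce, belt speed
fluctuates, and marker motion includes skin/socket artifact. None of that
is modelled (an optional per-leg energy-loss factor is deliberately out
of the benchmark path). In particular, in a conservative SLIP the softer
leg carries *more* stance-average force, the opposite sign to human
amputee data — asymmetry magnitudes and signs in synthetic sessions are
modelling choices, not predictions.

## Numerical behaviour worth knowing

* **Recovery accuracy (measured on noiseless synthetic sweeps, k = 14-26
  kN/m at 8 m/s):** estimated k_leg is strictly monotone in true k but
  systematically ~10-12% low, dominated by the symmetric-sweep contact
  angle overestimating ΔL; Δy is recovered to < 0.2% with touchdown
  refinement. These are properties of the estimator chain itself, which
  is kept faithful to its standard definitions.
* **Edge smear:** threshold-crossing contact times are ~6-8 ms long per
  stance after zero-phase filtering; onset-to-onset quantities (step
  time, step frequency) are unbiased because the shift cancels. When
  contact-time asymmetry is large, the smear dilutes the stiffer leg's
  stance-average force relatively more and can bias force SIs by ~0.01.
* **Degenerate inputs** raise typed exceptions rather than NaNs: zero SI
  denominators, zero-variance t-test samples, non-positive compressions,
  contact lengths exceeding the 2L₀ sweep, drifting (non-steady) strides,
  single-subject mixed-model designs, and rank-deficient fixed designs
  (aliased terms are named).
* **Problem sizes.** Tests and the acceptance script use 6-10-stride
  sessions, a 5-point stiffness sweep, 20-stride conservation runs and
  200 mixed-model replicates; the full suite runs in well under a minute.

## Open choices made here

* "4th-order Butterworth" is read as two passes of a 2nd-order design
  (zero phase); the single-pass literal reading is available but not
  default.
* Step frequency aggregates as the mean of per-step frequencies;
  reciprocal-of-mean-step-time differs in the third decimal on realistic
  asymmetry and is not exposed.
* ΔRSP is computed and reported (affected-leg mean peak resultant over
  k_RSP) but feeds no downstream quantity.
* The fore-aft position-hold criterion for a valid top-speed trial uses
  marker touchdown positions when available and otherwise falls back to a
  double-integrated fore-aft impulse drift, with a logged notice.
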