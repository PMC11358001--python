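# Methods

## Model

A preparation (native left-ventricular fiber bundle, permeabilized fiber
bundle, or isolated permeabilized cardiomyocyte) is modeled as a parallel
arrangement of viscoelastic elements, one per structural component. During
a hold at strain ε following a stretch, component *i* produces

    F_i(t) = E_i(ε) + V_i(ε) · exp(−t/τ_i),        V_i(ε) = E_i(ε) · v_i(ε)

where `E_i` is a second-order polynomial in strain with zero intercept
(zero force at slack length), `v_i` is the viscous amplitude fraction
(scalar or per-strain table, linearly interpolated) and `τ_i` the
relaxation time constant. The total force is the sum over intact
components, so noise-free traces superpose exactly and each stretch–hold
step relaxes as a single exponential whenever all components share one τ.
During the loading ramp the force is the instantaneous elastic sum plus the
full viscous amplitude — a phenomenological choice that makes the hold
onset continuous and equal to the peak; the model has no true rate-dependent
dashpot, because the analysis it feeds never varies ramp rate. Release
ramps and rest periods carry the relaxed (elastic-only) force.

Interactions between components:

* **Tensegrity (loss coupling).** When a source component is absent, the
  target loses a fixed fraction of both its elastic and viscous force.
  Default: severing actin costs titin 6% of its force (`ACTIN_TITIN_LOSS`,
  chosen once inside the observed 5–10% range); titin has no reciprocal
  effect on actin.
* **Gating.** The microtubule network shields the sarcolemma's elastic
  term (it contributes only once the microtubules are gone) and is required
  for the sarcolemma's high-strain viscous term (which vanishes when the
  microtubules are disrupted). Gates are evaluated per force type against
  the current present-set, never against history order, so the end state is
  order-independent while *measured per-step* contributions of gated or
  coupled components are history-dependent — both properties are asserted
  by tests.

Treatments map one-to-one to removals (colchicine → microtubules, Triton →
sarcolemma, GLN-40 → actin, TEVp → titin), except that TEVp on a wild-type
sample (no engineered cleavage cassette) removes nothing.

## Decomposition

Hold windows are detected as plateaus in the strain channel: contiguous
runs at least 1 s long whose level exceeds 0.5 strain percentage points and
stays within 0.1 points. The peak index is located within the first 10% of
the window after an edge-normalized 51-sample running mean — on clean
stress-relaxation data this is the first hold sample; the smoothing only
prevents noise from dragging the peak late. The relaxation segment
[i_peak, i_end) is fitted with `F_ss + A·exp(−(t−t_peak)/τ)` by bounded
least squares (initial values: `F_ss` ← mean of the final 5% of the window,
`A` ← raw peak − `F_ss`, τ ← 1 s; bounds τ ∈ [1 ms, 10 × hold],
A ∈ [−peak, 2·peak]).

The reported peak force is the fitted value at the peak time,
`F_peak = F_ss + A`, so `F_elastic = F_ss`, `F_viscous = A` and
`F_elastic + F_viscous = F_peak` holds exactly. On noise-free relaxation
data this equals the raw sample maximum; under additive noise the raw
maximum of ~10³ samples is biased upward by O(σ·√log n), which at 1%
noise is comparable to the entire viscous amplitude of a low-strain step,
whereas the fitted peak is unbiased. This estimator choice is the
package's resolution of the genuinely open raw-max-vs-fit question; the
raw maximum is still used as a fallback when the optimizer fails. Poor
fits are flagged (`rising_force`, `negative_viscous`, `nonconvergence`,
`poor_fit` for r² < 0.8), never raised, and negative viscous values are
retained rather than clipped, since clipping would bias the paired
subtraction. One-phase fits only; no drift correction or filtering.

Normalization divides all forces by a reference computed from
pre-treatment data only: the highest elastic/viscous force at the 20% step
(fiber experiments), the mean at the 25% step (titin-cleavage fibers on the
six-step 30% protocol), or the cell's own pre-treatment 20% value
(cardiomyocytes). Contributions are ratios, so the choice of rule cancels
in the shares; it matters for plotting and cross-sample comparison.

## Contribution estimation and the budget

Technical replicates are decomposed independently and averaged per strain
before the pre/post ratio is taken; the paired two-sided t-test runs on the
per-replicate pre/post values (identically-zero differences give p = 1 by
convention, zero-variance non-zero differences p = 0), and families of
per-strain p-values are adjusted by step-down Holm–Šidák. A full two-way
repeated-measures ANOVA is deliberately not implemented: the inferential
surface here is per-strain contributions, and the per-strain paired test
with multiplicity adjustment answers exactly that question.

The native-scale budget chain: the microtubule share `c_MT` is measured
directly on native fibers; the sarcolemma share, measured against the
post-colchicine baseline, is rescaled by `(1 − c_MT)`; the remainder is an
intracellular + ECM pool whose ECM fraction is
`x = 1 − (titin share in fibers)/(titin share in cells)` — the ECM can only
depress the *relative* titin contribution where it is present — and titin
and actin take their cell-measured shares of the non-ECM part; desmin
receives the residual. Negative intermediates are clipped to zero with a
logged warning and the budget renormalized to sum exactly to one. Because
the per-cohort estimates come from different animals, the inputs can
oversubscribe the total slightly, in which case the residual clips to zero;
the chain is a strategy object and alternates can be registered. Shares at
the regime strains (low = 10%, high = 20%) are interpolated from measured
strains via a quadratic (≥3 strains), linearly (2), or held constant (1).

## Synthetic data and calibration

The simulator stands in for force recordings that were never deposited. It
emulates: five-step native-fiber protocols to 20% strain with 10-s holds
sampled at 1 kHz, six-step permeabilized-fiber protocols to 30%,
single-cardiomyocyte 20% stretches with 7-s holds, exponential stress
relaxation, treatment-induced removal with the coupling rules above,
additive Gaussian force noise (σ as a fraction of the trace maximum) and a
multiplicative per-replicate scale that persists across treatment stages
(the same physical sample keeps its scale, as in a paired design). All
randomness flows from one seed; identical seeds give identical traces.

`calibrate_components` inverts a share schedule into component laws. With
the zero-intercept constraint a component's share can be pinned exactly at
up to two anchor strains per experiment (one anchor means a constant
share); viscous shares are pinned exactly at *every* protocol step through
per-strain viscous-fraction tables. The total elastic curve is ε + 2ε²
(relative units, mildly convex); stronger convexity would make steeply
rising shares (e.g. the ECM's) unrepresentable by non-negative
zero-intercept quadratics. Schedules are validated for share sums ≤ 1 per
force type and non-negativity of every polynomial on [0, 0.30], and
calibration errors name the offending component.

The packaged `paper_defaults` ladder encodes each cohort separately —
exactly as the underlying study used different animals per experiment — and
solves the coupling arithmetic so the *pipeline-measured* drops equal the
target percentages (e.g. the microtubule raw share includes the small
sarcolemma share it unmasks; raw actin schedules subtract the titin force
lost through tensegrity; the actin-first cardiomyocyte cohort is fully
determined by a 30% actin drop, a 19% desmin residual and the 6% loss
fraction). Share values at strains the study never quantified are fillers
chosen once for plausibility (ECM share growing with strain, small flat
desmin) and marked `printed=False`.

## Defaults and units

| Parameter | Default | Why |
|---|---|---|
| τ (all components) | 1.0 s | no time constants are reported; recovery of `F_ss` is τ-insensitive for τ ≪ hold (asserted for τ ∈ [0.05, 2] s) |
| ramp rate | 1.0 strain/s | length changes were manual or motor-driven without stated rates |
| rest between steps | 1.0 s simulated at slack | the ~1-min experimental wait carries no force information here |
| sampling rate | 1000 Hz | matches the recordings |
| viscous/elastic total ratio | 0.5 | sets viscous amplitudes at a realistic fraction of elastic force |
| actin→titin loss | 0.06 | inside the reported 5–10% band |
| noise σ_rel | 0.01 | reproduces s.e.m.-scale replicate spread |
| regime strains | 10% / 20% | the low/high comparison points |

Strains are dimensionless fractions internally; the CLI prints percent with
an explicit `%`. Forces are relative units throughout (normalization makes
absolute scale irrelevant).

## What passing tests do and do not show

The simulator generates ideal single-exponential relaxation with additive
Gaussian noise. Real recordings contain multi-exponential relaxation,
drift, solution-change artifacts, incomplete treatments and sample-to-sample
heterogeneity beyond a scale factor — none of which are emulated. Recovery
of configured shares to 0.5 percentage points noise-free (and 2 points
under 1% noise with the cohorts' replicate counts; ~10 seeds per check, a
problem size chosen to keep the suite fast) therefore validates the
*pipeline* — segmentation, fitting, normalization, paired subtraction,
composition — not the biological measurements themselves. The budget chain
is one consistent reconstruction of the cross-preparation argument; the
ECM-inference step in particular is a modeling choice, not measured
arithmetic. Cardiomyocyte experiments provide only a single strain (20%),
so low-strain cell shares are constant extrapolations.
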