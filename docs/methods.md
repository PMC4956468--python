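# Methods

`gatecycle` models spontaneous (ATP-free) gating of CFTR-like channels as a
linear three-state Markov chain and rebuilds the complete analysis chain a
single-channel electrophysiologist would apply to excised-patch records:
simulation, idealization, dead-time-aware maximum-likelihood rate
estimation, and thermodynamic double-mutant-cycle energetics.

## The C-O-B gating model

A channel occupies one of three states,

    C  <--r_CO / r_OC-->  O  <--r_OB / r_BO-->  B

with C the long-lived interburst closed state, O the conducting open state,
and B a brief "flickery" blocked state visited from within a burst.  Direct
C-B transitions do not exist.  All four rate constants are per second; the
open state carries the unitary current `i_unit` (default −0.64 pA, ~8 pS at
−80 mV).  Derived quantities:

- mean burst duration  τ_b = (1/r_OC)(1 + r_OB/r_BO)
- mean interburst duration  τ_ib = 1/r_CO
- opening rate 1/τ_ib, closing rate 1/τ_b
- stationary open probability π_O from detailed balance on the linear chain,
  and K_eq = P_o/(1 − P_o).

A burst is a maximal interval in {O, B} (it necessarily begins and ends in
O, because B is reachable only from O); flickers are internal to bursts.

## Synthetic patch records

`simulate` draws exact continuous-time (Gillespie) state paths per channel,
superposes N independent channels into an open-count level path, and renders
a current record: level × i_unit sampled at `fs` (default 10 kHz), convolved
with a Gaussian acquisition filter (default corner 2 kHz), then white
Gaussian noise added post-filter (default SD 0.15·|i_unit|, emulating
amplifier noise at the acquisition bandwidth).  The Gaussian filter uses the
−3 dB corner convention σ_t = 0.1325/f_c, truncated at ±4σ; its exact
10–90% step rise time is 0.3397/f_c.

The default recording protocol emulates the study design: a high-P_o
"bracket" segment (ATP present; used to count active channels), an ATP-free
segment in which spontaneous gating is sampled, and a second bracket.  Desk
scale uses 30 s / 120 s / 30 s; the field-scale protocol (2.5 / 5 / 2.5 min)
is a configuration choice, not a code change.  Channels carry their state
across segment boundaries.

### The four-construct dataset

`make_construct_datasets` generates labelled datasets for the gain-of-function
background construct (BG = P355A-K978C) and the three further corners of the
R555K × T1246N mutant cycle.  The defaults encode the reported study
conditions:

| construct | target P_o | r_CO (s⁻¹) | patches |
|---|---|---|---|
| BG | 0.15 | 0.1140 | 21 |
| R555K | 0.034 | 0.0227 | 18 |
| T1246N | 0.044 | 0.0297 | 19 |
| R555K-T1246N | 0.11 | 0.0798 | 20 |

All four spontaneous schemes share r_OC = 0.645 s⁻¹, r_OB = 1 s⁻¹ and
r_BO = 100 s⁻¹, giving τ_b = 1.566 s and ~10 ms flickers: the reported
phenotype is that the mutations act almost entirely on the opening rate
while closing rates are little affected, so per-construct r_CO is solved
from the target stationary P_o.  The exact flicker rates of the background
construct are not published; r_OB and r_BO were chosen once to give ~10 ms
flickers at a modest (~1 s⁻¹) entry rate and are not tuned further.  The
bracket scheme (r_CO = 1, r_OC = 0.25, same flickers) has P_o ≈ 0.80,
matching the reported ATP-driven open probability of the background.
Channels per patch are drawn uniformly from 2–6 (records with more than 7
superimposed openings would be excluded from kinetic analysis anyway); all
per-patch seeds derive deterministically from a master seed.

What the generator deliberately does not emulate: baseline drift, 50/60 Hz
hum, slow amplitude rundown, ATP-washout kinetics inside the ATP-free
segment, phosphorylation heterogeneity between channels, and any
ATP-concentration dependence.  Passing tests therefore demonstrate
correctness of the analysis chain under ideal stationary C-O-B gating, not
robustness to every artifact of real patch records.

## Idealization

Traces are refiltered digitally at the analysis bandwidth (default 50 Hz,
same Gaussian kernel convention), baseline-subtracted (designated
zero-current windows, emulating chloride-removal segments), and idealized by
half-amplitude threshold crossing generalized to stacked levels: each sample
is assigned the nearest integer multiple of i_unit (thresholds half-way
between adjacent levels), clipped to [0, max_level].  The active-channel
count is the maximum simultaneously open level seen in the brackets.

A fixed dead time t_d = 6 ms (matching the 50 Hz analysis bandwidth) is then
imposed on the event list: every event shorter than t_d is absorbed into the
preceding event (a leading short event is absorbed forward), and adjacent
equal-level events merge.  Total duration is conserved exactly and every
surviving dwell is ≥ t_d.  The same rule is applied to ground-truth event
lists in recovery tests, so simulator and fitter are mutually consistent.

The analyzed window drops a fixed leading fraction (default 20%) of the
ATP-free segment — a deterministic stand-in for the visual selection of the
quasi-steady stretch after ATP washout (e.g. the last ~4 min of a 5-min
segment).  Boundary-censored events are excluded from dwell sets; the
time-average P_o over the window is Σ(level·dwell)/(N·Σ dwell).

## Maximum-likelihood kinetics with dead time

For N independent channels the aggregated chain lives on occupation states
(n_C, n_O, n_B); every single transition changes the open count, so the
within-class generator of a conductance level is diagonal and the dwell
density of level k is a mixture of exponentials weighted by the stationary
entry distribution into the class.  `CobModel` fits the four rates by
maximizing the histogram-style likelihood — dwells treated as independent
draws from their level's density, which is what fitting "the set of
dwell-time histograms for all conductance levels" means; dwell-sequence
correlations are not used.

The dead time is handled by two complementary devices:

1. **Truncation-renormalization**: each level density is renormalized over
   [t_d, ∞), matching the removal of sub-t_d events from the records.
2. **First-order bridged-excursion correction**: a sortie to an adjacent
   level lasting < t_d that returns is invisible in the idealized record —
   it is absorbed into the surrounding dwell.  The within-class generator
   therefore gains effective transitions
   m(c→c′) = Σ_b q(c,b)·(1 − e^(−λ_b t_d))·q(b,c′)/λ_b and correspondingly
   reduced visible exit rates.  For one channel this reproduces the exact
   geometric-sum result (a missed ~10 ms flicker extends the apparent open
   dwell); without it, r_OC + r_OB would be underestimated by ~35% at the
   default flicker rates.  The correction vanishes at t_d = 0.  The durations
   of bridged gaps (< t_d each) are neglected; for N ≥ 2 the treatment is
   first-order in the miss probability, which leaves a residual ~10% bias on
   r_CO/r_OC for three superimposed channels — documented, and well inside
   the recovery tolerances used in the tests.  The exact sequence-conditional
   missed-event likelihood (Hawkes–Jalali–Colquhoun) is intentionally out of
   scope.

Optimization runs in log-rate space with box bounds [10⁻⁴, 10⁴] s⁻¹,
method-of-moments starting values (shut dwells split at max(5 t_d, 50 ms)
into flicker and interburst pools), five multi-starts, L-BFGS-B followed by
a Nelder–Mead polish (the mixture spectra make numerical gradients noisy
near the optimum).  Standard errors come from the observed information in
log-rate space (delta method).

**Flicker identifiability.**  On flicker-poor data the blocked state can
impersonate the interburst state (label switching): a spurious four-parameter
optimum can beat the true flicker-free solution by well under a nat while
wrecking τ_b.  `fit` therefore also fits the reduced C-O submodel (r_OB
pinned at its lower bound) and keeps the full scheme only when it improves
the log-likelihood by more than 2 nats (AIC with two extra parameters);
results carry a `reduced` flag.  Separately, a converged full fit with
r_BO < 1/t_d (flickers slower than the resolution limit) is flagged
`flicker_resolved = False`: r_OB and r_BO are then unreliable although τ_b
remains meaningful.

Records are fitted per patch and summarized per construct as mean ± SD/SEM
over patches; there is no pooled-likelihood mode.

## Mutant-cycle energetics

All energies are in kT units (kT ≡ 1).  For a transition A→B,
ΔΔG°(B−A) = −kT ln(u/v) with u, v the gating parameter of two constructs:
K_eq for ground-state legs, opening rate for ΔΔG°(T−C), closing rate for
ΔΔG°(T−O).  Legs are computed from construct *means* of the parameter (the
variance treatment below presumes this), not from per-patch ΔΔG values.  The
coupling energy is the difference between parallel sides of the cycle; both
evaluations are computed and asserted equal (an algebraic identity on the
means).  If the native interaction is restored in the double mutant, ΔΔG_int
sums the interaction changes of both pairs; this caveat rides along as a
flag, never as a numeric correction.

Uncertainty uses the second-order power-series approximation for
independent normal u, v,

    var(ln(u/v)) ≈ cu² + cv² + ½·cu²·cv² − ¼·(cu⁴ + cv⁴),   c = σ/m,

with σ the across-patch SD.  A warning is raised when either CV exceeds 0.2.
The package ships an exact-sampling Monte-Carlo oracle (normal draws,
non-positive draws rejected with a warning above 1% rejection) for
validation.  Quadrature of the defining integrals shows the truncation error
of the approximation is ~2.6% at CV = 0.1 and ~11% at CV = 0.2 — usable, but
larger than folklore suggests; the tests pin these figures.

SEMs follow the mean-count rule: SEM(leg) = √(var/n̄) with n̄ the mean of
the two corner counts, and SEM(ΔΔG_int) = √((var₁+var₂)/n̄) with n̄ the
four-corner mean.  Significance is a two-tailed one-sample Student's t test
of ΔΔG_int against zero with df = n̄ − 1; the exact test construction behind
the originally reported p-values is not recoverable, so p-values here are
indicative, not reproduction targets.

## Free-energy profiles

`energetics` assembles pairwise C / T‡ / O profile comparisons from P_o and
τ_b: open-state stabilization kT·ln(K_eq ratio), closing-barrier shift
ΔΔG°(T−O) = kT·ln(τ_b ratio), and transition-state stabilization as their
difference (the closure identity holds exactly by construction).  The
built-in reference table uses literature gating parameters — WT spontaneous
(P_o = 5.3×10⁻⁵, τ_b = 60 ms), the gain-of-function background
(P_o = 0.15, τ_b = 1566 ms) and ATP-bound hydrolysis-deficient K1250R
(P_o ≈ 0.6 taken at face value, τ_b = 9323 ms) — and computes 8.1 / 3.3 /
4.8 kT for WT→background and 10.3 / 5.0 / 5.2 kT for WT→K1250R.  Note
ln(9323/60) = 5.05 rounds to 5.0, not the commonly quoted ~5.1 (presumably
from unrounded inputs); the computed value is reported as is.

## Numerical choices and problem sizes

- Stationary distributions use the detailed-balance closed form (single
  channel) and the multinomial composition (aggregated chain).
- Mixture decompositions use dense eigendecomposition of the small
  within-class matrices ((N−k+1)² at level k, N ≤ 7); real parts are taken,
  and non-finite densities map to −∞ log-likelihood.
- Default test-scale problem sizes: rate-recovery fits use ~2500 bursts
  (30 000 s single-channel, 3 × 10 000 s three-channel); the four-construct
  dataset uses the reported patch counts (21/18/19/20) at desk-scale
  durations.  These sizes keep the full pipeline to a few minutes while
  leaving Monte-Carlo error well inside the stated tolerances.
- Degenerate inputs: single-level dwell sets are rejected; sparse levels
  (< 10 events at the boundary levels) warn; patches whose brackets show no
  openings are reported as having no active channels and contribute P_o = 0
  but no K_eq value.

## Known limitations

- The histogram likelihood ignores dwell-sequence information; it is less
  efficient than the exact aggregated-Markov likelihood and its missed-event
  treatment is first-order (see above).
- Threshold idealization (no HMM) is used by design; at low signal-to-noise
  it will fabricate level crossings that the 50 Hz refilter only mitigates.
- The variance approximation degrades beyond CV ≈ 0.2; heavy-tailed
  per-patch K_eq distributions (few bursts per patch) can exceed that.
- Energetic interpretation of ΔΔG_int assumes the mutations do not perturb
  states other than those compared; the package computes, it does not argue.
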