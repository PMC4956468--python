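# gatecycle

Single-molecule gating kinetics and mutant-cycle energetics for CFTR-like
ion channels.

CFTR, the chloride channel mutated in cystic fibrosis, opens and closes as
its two nucleotide-binding domains (NBDs) dimerize and separate.  Channels
also gate *spontaneously*, without ATP — rarely in the wild-type protein,
robustly in gain-of-function backgrounds — and the energetics of those
openings report on whether the NBD interface tightens during pore opening
even with no nucleotide bound.  `gatecycle` is a reusable, tested pipeline
for that style of analysis.  It is aimed at single-channel
electrophysiologists who want the complete chain from patch-current records
(real or simulated) to coupling free energies, with every step testable
against ground truth.

## What it computes

Gating is modelled as a linear three-state Markov scheme

    C  <--r_CO / r_OC-->  O  <--r_OB / r_BO-->  B

(interburst closed, open, flickery blocked), with mean burst duration
τ_b = (1/r_OC)(1 + r_OB/r_BO) and mean interburst duration τ_ib = 1/r_CO.
The pipeline stages, each an importable module:

- **simulate** — exact Gillespie state paths for N independent channels,
  superposed into open-count level paths and rendered as noisy, Gaussian-
  filtered current records under a bracket / ATP-free / bracket protocol;
  four default "constructs" reproduce a published mutant cycle's open
  probabilities (0.15 / 0.034 / 0.044 / 0.11).
- **idealize** — 50 Hz refiltering, baseline subtraction, multi-level
  half-amplitude idealization, channel counting from the high-P_o brackets,
  and imposition of a fixed 6 ms dead time.
- **kinetics** — `CobModel(dwellset).fit()` → `CobResults`: maximum-
  likelihood C-O-B rates from the dwell-time histograms of all conductance
  levels, with truncation-renormalization plus a first-order missed-event
  (bridged-flicker) correction for the dead time, standard errors, and a
  `summary()` table.
- **cycle** — `MutantCycle(...).fit()` → `CouplingResult`: thermodynamic
  double-mutant-cycle legs ΔΔG° = −kT·ln(u/v), the coupling energy
  ΔΔG_int, the second-order variance approximation for log-ratios with its
  Monte-Carlo oracle, SEM rules using mean corner counts, and a Student's
  t test.  All energies in kT units.
- **energetics** — free-energy profiles (C / T‡ / O) from P_o and τ_b, the
  end-to-end report over the four-construct dataset, and the worked
  arithmetic for literature gating parameters.

## Worked example

Free-energy arithmetic from literature gating parameters (also available as
`gatecycle reproduce` on the command line):

```python
>>> from gatecycle import open_state_stabilization, barrier_shift_from_tb
>>> open_state_stabilization(0.000053, 0.15)   # WT -> background, kT
8.110644...
>>> barrier_shift_from_tb(0.060, 1.566)        # closing barrier shift, kT
3.261935...
```

The background double mutation stabilizes the spontaneously open channel by
8.1 kT relative to wild type but raises the closing barrier by only 3.3 kT,
so the transition state is stabilized by 4.8 kT — the pore is still closed
at the transition state.  The same arithmetic for ATP-bound, hydrolysis-
deficient K1250R gives 10.3 / 5.0 / 5.2 kT (ln(9323/60) = 5.05 computes to
5.0 at one decimal; see docs/methods.md).

Recovering rate constants from a simulated single-channel record
(30 000 s, 6 ms dead time, true rates 0.1 / 0.5 / 2 / 100 s⁻¹):

```python
>>> from gatecycle import (GatingScheme, simulate_path, superpose,
...                        impose_dead_time, extract_dwells, fit_cob)
>>> from gatecycle.idealize import events_from_level_path
>>> s = GatingScheme(0.1, 0.5, 2.0, 100.0)
>>> events = events_from_level_path(superpose([simulate_path(s, 30000.0, seed=42)]))
>>> res = fit_cob(extract_dwells(impose_dead_time(events, 0.006), n_channels=1))
>>> print(res.summary())
C-O-B maximum-likelihood fit
==============================================
patch: <unnamed>   channels: 1   dead time: 6.0 ms
events: 15809   log-likelihood: 2270.28   converged: True
----------------------------------------------
    rate  estimate (s^-1)    std err
    r_CO          0.09974    0.00201
    r_OC           0.4964       0.01
    r_OB            1.995     0.0319
    r_BO            99.68        1.4
----------------------------------------------
tau_b  =     2054.8 ms   closing rate = 0.4867 /s
tau_ib =    10026.2 ms   opening rate = 0.09974 /s
P_o (stationary) = 0.1667
```

All four rates land within ~2% of truth even though ~36% of the ~10 ms
flickers are shorter than the dead time and invisible in the record.

The full synthetic study — simulate the four constructs, idealize, extract
per-patch open probabilities, and fit the K_eq mutant cycle — runs with:

```sh
gatecycle report --no-fit --out report.json
```

which prints, for the default dataset (master seed 0),

```
K_eq: ddG_int = -2.39 ± 0.18 kT (p = 6.2e-11)
```

— a stabilizing R555–T1246 interaction formed on spontaneous pore opening,
within sampling error of the value implied by the generating schemes
(−2.60 kT from the target open probabilities).

## Layout

```
src/gatecycle/    scheme, simulate, datasets, idealize, kinetics, cycle,
                  energetics, io, cli
tests/            pytest suite incl. end-to-end acceptance checks
docs/methods.md   model, assumptions, numerical choices, limitations
```
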