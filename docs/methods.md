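# Methods

## Scope and model sketch

`cryodsd` models toehold-mediated DNA strand-displacement circuits at the
level of effective mass-action kinetics. Three layers:

1. a **structural compiler** (`circuit`) that turns a declarative gate/wiring
   description into the inventory of prepared molecules;
2. a **kinetic layer** (`kinetics`, `freezethaw`) that instantiates reaction
   templates over that inventory and integrates the resulting ODE system,
   isothermally or through alternating freeze/thaw phases;
3. **reporting** (`reporting`) that normalizes endpoints, classifies ON/OFF
   at 0.4 and computes comparison statistics (completion times, average
   rates, fold speedups).

`design` generates three-letter-code domain sequences and `fixtures`/`config`
/`cli` provide deterministic toy inputs and the I/O surface.

## Displacement kinetics

Each displacement step is one irreversible bimolecular reaction; reversible
toehold binding and branch-migration intermediates are not resolved. The
thermodynamic disadvantage of a short toehold appears as a smaller effective
rate constant:

    k(m) = k_ref · fold_per_nt^(min(m, saturation_len) − 4)

with defaults `k_ref = 5.3e3 /M/s` (4-nt reference), `fold_per_nt = 10`,
`saturation_len = 6` — the canonical ~order-of-magnitude-per-nucleotide
growth that saturates around 6 nt. `k_ref` is calibrated from the observed
endpoint behaviour of the basic 4-nt reaction at the 50 nM operating
concentration: the equal-concentration irreversible second-order law

    x(t) = kC0·t / (1 + kC0·t)

puts 95 % conversion at t95 = 19/(kC0); requiring t95 ≈ 20 h gives
k = 19/(50 nM · 20 h) ≈ 5.3e3 /M/s. The package treats 25 °C and 37 °C rates
as equal (no Arrhenius correction): there is no temperature-resolved rate
data to calibrate one, and all temperature dependence of the protocol is
absorbed into the freeze-episode boost.

## Gate architecture and reaction templates

A two-input gate compiles to six prepared molecules; with a terminal
reporter that is seven excluding inputs, and cascades of two and three gates
give 13 and 19 — the unique counting convention consistent with those
totals (one "molecule" = one annealed complex or strand as prepared, weight
complexes counted once). Per gate the CRN instantiates:

| template         | reaction                          | toehold |
|------------------|-----------------------------------|---------|
| switching        | Sw_i + W_i → W_i*                 | 8 nt    |
| displacement     | input_i + W_i* → I                | 5 nt    |
| transmit         | I + Sd → sig                      | 5 nt    |
| threshold_absorb | sig + Th → inert                  | 8 nt    |
| report           | sig + R → F                       | 8 nt    |

Both displacement branches release the *same* intermediate I, which the
transmit complex converts to the gate's output signal — this is what makes
the gate compute a sum, and it is why a single transmit reaction suffices
(6 reactions per gate, 7 with a reporter). Switching is modelled as one
bimolecular hybridization at the long-toehold rate with the subsequent
intramolecular conformational opening taken as instantaneous. Upstream
signal species act directly as downstream inputs; no translator species are
introduced.

Two design choices matter for correct threshold logic and deviate from the
obvious "everything at 50 nM" default:

- **Transmit capacity.** `Sd` is prepared at the *sum* of the gate's weight
  concentrations (100 nM for a standard two-input gate). If it were 50 nM,
  the transmitted signal would saturate at one input-equivalent and
  AND(1,1) would be indistinguishable from AND(1,0) against the 40 nM
  threshold. A transmit complex that "calculates the sum" must be able to
  carry it.
- **Endpoint reporting.** Threshold and reporter complexes both react at
  the saturated long-toehold rate. If the reporter is present during
  operation it splits impinging signal with the threshold in proportion to
  their concentrations (both deplete exponentially in the same integral),
  so a one-input AND would read ~0.55 normalized — thresholding fails.
  The wet protocol adds the reporter only after the last cycle;
  `simulate_circuit` and `simulate_freeze_thaw` therefore default to
  withholding reporters during operation and appending a 30 min reporting
  phase (`reporter_timing="after"`); `"during"` is available for
  reporter-only experiments such as the basic reaction.

With these choices the stoichiometry is exact: a 40 nM threshold always
absorbs its full 40 nM before surplus signal reaches downstream species
(the threshold runs 10× faster than transmit and has no competing sink
during operation), so OFF-state leakage through an AND gate is one
input-equivalent minus the threshold (≈ 10 nM → ≈ 0.2 normalized) and ON
states sit near 1.0. Simulated truth tables classify correctly at 0.4 with
wide margins (OFF ≤ 0.25, ON ≥ 0.96 across all 32 combinations of the four
benchmark circuits).

## Freeze-thaw cycling

One cycle is: a eutectic window (default the whole 1-min freeze episode)
in which every bimolecular rate constant is multiplied by a boost factor,
an optional dead remainder of the freeze episode with no flux (bulk ice),
and a 5-min thaw phase at nominal rates; concentrations are continuous
across phase boundaries. Unimolecular steps are never boosted, and all
bimolecular steps share one boost (well-mixed brine assumption).

The anion enters through a single per-cycle **dose** δ — the effective
bimolecular exposure k·C₀·t delivered per cycle to the reference 4-nt
reaction. The boost is back-computed so the window plus thaw phase deliver
exactly δ:

    boost = (δ − kC0·t_thaw) / (kC0·eutectic_window)

Under dose additivity the basic reaction's conversion after n cycles is
nδ/(1+nδ), so half-completion lands at the first cycle with nδ ≥ 1. The
default doses δ = 1, 1/3, 1/6, 1/8 for SO₄²⁻, Ac⁻, Cl⁻, NO₃⁻ are the unique
values that put half-completion at cycles 1, 3, 6 and 8 under this model
(boosts ≈ 57.9, 16.0, 5.5, 2.9 at defaults). Brine-vein thickness
(0.04/0.14/0.15/0.22 μm) is carried as a recorded covariate with a
monotonicity check — boost strictly decreasing in vein thickness — rather
than a predictive law: a 1/thickness scaling does not reproduce the
observed cycle counts, so we do not pretend it does.

Because the default doses put half-completion *exactly* on a cycle boundary
(nδ = 1 ⇒ conversion exactly 0.5), `cycles_to_fraction` compares with a
1e-6 absolute tolerance so integrator round-off cannot flip the integer
answer; this is far below any physically meaningful conversion difference.

## Reporting statistics

- `normalize`: affine map, baseline → 0 and maximum level → 1; the plateau
  maximum is the mean of the last five points when a plateau exists. Truth
  tables normalize all combinations of one circuit together (baseline = the
  minimum endpoint, maximum = the largest), as parallel experiments are.
- `classify`: ON at or above 0.4; a value exactly at threshold is ON.
- `speedup(system, n)`: the system's isothermal completion time (a table of
  quoted constants — 20 h basic, 4 h OR, 16 h AND, 10 h AND-OR, 12 h
  OR-AND-OR, 36 h 8-pattern network — not fitted quantities) divided by the
  protocol duration n·(t_freeze + t_thaw), rounded to the nearest integer
  for reporting. With the default schedule this yields 25-, 8-, 17-, 17-
  and 120-fold for 8, 5, 6, 7 and 3 cycles respectively.
- `average_rate`: output fraction per cycle (cycling) or per hour
  (isothermal). Published per-cycle fold comparisons for single gates
  ("almost 15-fold" OR, "~30-fold" AND) use a rate measure that is not
  reconstructible as a completion-time ratio; the package reports both the
  time-ratio speedup and the average rate and does not claim to reproduce
  those two figures.

## Sequence design

Designed (top) strands use the three-letter alphabet {A, T, C}: no G on a
designed strand, so G and C never co-occur; bottom strands are derived
reverse complements. Rules: at most 3 consecutive A, at most 3 consecutive
T, at most 2 consecutive C ("runs of fewer than four A/T, fewer than three
C"), C content within 30–70 % per domain (the band is applied per domain).
Generation is rejection sampling from a seeded RNG, deterministic per seed.
The library screen bounds the longest exact shared substring *and* the
longest antiparallel complementary stretch between any two accepted domains
(default ≤ 6 nt), computed by dynamic programming and cross-checked in the
tests against a brute-force substring oracle. Thermodynamic validation with
a secondary-structure predictor is deliberately out of scope; the substring
heuristic is a screening proxy, not an ensemble calculation.

## Network-scale compilation

`build_network` realizes a weighted-sum + threshold classifier as, per
output, a binary tree of two-input zero-threshold (adder) gates whose
leaves are input signals repeated by their integer weights, with the root
gate carrying the decision threshold as a concentration
((t − 0.5)·operating concentration). The 8-pattern fixture uses
template-matching weights (each output's weights are its own pattern's
pixels, threshold = pixel count) over eight seeded, jittered 12×12 digit
glyphs, resampled so no pattern contains another — which guarantees each
pattern activates exactly its own output under the Boolean weighted-sum
oracle. The compiled fixture network is ~530 gates / ~3200 molecules.
Limitation: at concentration level, analog summation saturates at each
gate's transmit capacity, so the compiled tree is a structural realization
(species counts, wiring, thresholds) validated against the Boolean oracle,
not an ODE-faithful analog adder for sums beyond two input-equivalents.

## Numerical choices

- Integrator: `scipy.integrate.solve_ivp` with LSODA, rtol 1e-8, atol
  1e-8 nM, ≥ 200 output points per protocol segment (600 for isothermal
  runs). The tight atol is needed to hold conserved-moiety drift below the
  1e-6 relative target on ~50 nM totals.
- Conservation checking computes the left null space of the stoichiometric
  matrix (SVD) and tracks every conserved linear combination along the
  trace; tests require < 1e-6 relative drift. Spiking the reporter in after
  the last cycle is a genuine material addition, so global conservation of
  the reporter moiety is only expected on closed traces.
- `completion_time` interpolates linearly between grid points and returns
  an explicit not-reached sentinel with the maximum attained fraction.
- Degenerate inputs: zero-concentration inputs produce identically zero
  flux; boost = 1 reduces cycling to isothermal kinetics (verified to 1e-6);
  a dose not exceeding the thaw-phase contribution is rejected rather than
  silently producing boost < 1.

## What the synthetic conditions do and do not show

The simulations reproduce the *endpoint logic* and the *cycle-resolved
dose arithmetic* of the protocol under idealized assumptions: no leak
reactions (an optional background-rate hook exists but defaults to off),
no fluorophore photophysics or freeze-induced fluorescence loss, no
spatial brine-vein geometry, no ice-nucleation stochasticity, and anion
doses chosen to match the observed half-completion cycle counts rather
than derived from vein microstructure. Passing tests therefore demonstrate
internal consistency of the model and exact reproduction of the published
counting/timing arithmetic — not a first-principles prediction of eutectic
reaction acceleration. Problem sizes used throughout (single reactions and
1-3-gate circuits for ODE work, ≤ 10 cycles, the 8-pattern network compiled
but evaluated with the Boolean oracle) are the package's chosen desk-scale
study conditions.
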