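# Methods

## Labelling model

The simulator propagates 1,2-¹³C₂ glucose label through four well-mixed
metabolite pools — G6P, F6P, GAP and Ru5P — connected by constant fluxes
(steady-state metabolism: pool sizes do not change during the 0–900 s
labelling window, so only isotopic composition evolves). Each pool's
mass-isotopologue distribution (MID) `x` obeys

    dx/dt = (total influx / pool size) · (flux-weighted input MID − x),

i.e. first-order relaxation towards the composition of what flows in. At
t = 0 every pool is unlabelled.

Isotopologues are tracked as labelled-carbon counts, not positional
isotopomers. This is exact for this tracer because the two labels always
occupy C1–C2 of hexoses, so position is implied by count and the
atom-transition rules close over counts:

- **Oxidative branch** (G6P → 6PG → Ru5P + CO₂): C1 is lost, so an
  mk hexose yields an m(k−1) pentose (k ≥ 1); m2 G6P → m1 Ru5P.
- **Glycolytic cleavage** (F6P → trioses): the labels ride the C1–C3
  fragment; the GAP pool receives an equal mixture of that fragment and the
  unlabelled C4–C6 fragment. DHAP is lumped with GAP (one triose node).
- **Non-oxidative branch** (F6P + GAP → Ru5P): the product carries the
  labels of the F6P C1–C2 fragment plus those of the GAP unit — hence m2
  (or m4) Ru5P. The transketolase/transaldolase steps are collapsed into one
  net flux; the reversibility of the branch is represented only by that net
  flux, not by exchange fluxes.

CO₂ is a sink (no refixation). Mass shifts above m2 are simulated (Ru5P m4
is representable) but the measurement tables report m0–m2 by default, as an
MRM method targeting this tracer would.

## Parameters and defaults

| parameter | default | units | meaning |
|---|---|---|---|
| tracer_fraction | 0.5 | — | tracer share of medium glucose (1:1 spike) |
| purity | 1.0 | — | fraction of tracer molecules that are m2; impurity dilutes towards m0 before mixing |
| v_glycolysis | 0.05 | amount/s | glucose → G6P |
| v_ox | 0.006 | amount/s | oxidative branch G6P → Ru5P |
| v_nonox | 0.004 | amount/s | net non-oxidative F6P/GAP → Ru5P |
| v_lower | 0.04 | amount/s | F6P → trioses |
| pools G6P/F6P/GAP/Ru5P | 1 / 20 / 5 / 0.4 | amount | pool sizes |
| time grid | 0, 10, 60, 120, 240, 480, 900 | s | sampling times |
| replicates | 3 | — | per condition/time |
| noise sd_fraction | 0.01 | — | additive Gaussian noise on fractions |
| knockdown scale | 0.4 | — | flux scaling in knockdown scenarios |
| n_draws | 1000 | — | Monte Carlo draws per fit |
| p13C | 0.0107 | — | natural ¹³C abundance (correction optional, off by default) |

Absolute pool sizes and fluxes are not identifiable from the experiment this
package emulates, so the defaults are order-of-magnitude choices fixed by
two kinetic requirements rather than by measurement: (i) G6P must label fast
(turnover 0.05 s⁻¹) and Ru5P must be a small fast pool, so that the m1
accumulation rate tracks Ru5P turnover `(v_ox + v_nonox)/pool` and hence
responds to oxidative-branch suppression; (ii) the F6P and GAP nodes — which
lump the larger downstream hexose/triose phosphate pools (FBP, DHAP) — must
label slowly (≈ 0.002 and 0.008 s⁻¹), so that the m2 accumulation rate is
limited upstream of Ru5P and is insensitive to an oxidative-only knockdown.
Requirement (ii) is what makes the simulated experiment reproduce the
observed branch specificity: suppressing only the oxidative branch leaves
the fitted m2 dilution rate essentially unchanged, while suppressing both
branches slows it. With equal-sized pools everywhere, any knockdown would
reduce total Ru5P influx and drag both readouts down together. Knockdown
scenarios scale v_ox by 0.4 (6PGD-like) or both v_ox and v_nonox by 0.4
(AR/SREBP1-like); these effect sizes are synthetic choices.

Measurement noise is additive Gaussian on fractions followed by clamping to
[0, 1] and renormalisation — the simplest model consistent with small,
roughly constant replicate error bars. It does not emulate
intensity-dependent (shot-noise) variance, missing isotopologues, or drift,
so passing tests demonstrate correct inference under well-behaved noise, not
robustness to pathological LC-MS data.

## Pre-processing

Intensities are normalised per sample to fractions. Natural-abundance
correction builds the lower-triangular binomial matrix
`M[i, j] = C(n−j, i−j) p^(i−j) (1−p)^(n−i)` mapping a tracer-derived MID to
the measured envelope, and inverts it by nonnegative least squares (direct
inversion can yield negative fractions on noisy data); entries below 1e-12
are clamped to zero before renormalisation. Correction is optional and off
by default — the run manifest records whether it was applied. Only ¹³C is
corrected; ²H/¹⁸O/¹⁵N abundance and resolution effects are out of scope.
Samples whose tables carry a partial envelope (e.g. m0–m2 of a six-carbon
metabolite) are corrected on a zero-padded envelope, which is exact when the
missing channels are truly empty and approximate otherwise.

## Turnover estimation and testing

Each isotopologue time series is fitted with
`m(t) = m_max (1 − e^(−D t)) + m_initial` by bounded least squares
(m_initial, m_max ∈ [0, 1], D ∈ [0, 10] s⁻¹, analytic Jacobian,
xtol = ftol = 1e-12). Exponential fits are initialisation-sensitive, so five
deterministic starts are used (D ∈ {1e-4 … 1} s⁻¹, m_initial from the t = 0
mean, m_max from the data range) and the best kept. All three parameters are
fitted — m_initial is not pinned to the t = 0 measurement. Observations are
sorted into a canonical order before optimisation, so the fit is exactly
invariant to input permutation. A flat series returns D = 0 with a
degeneracy flag; fewer than four distinct time points (or a grid without
t = 0) is an error.

The Monte Carlo scheme is a parametric bootstrap on observations: each draw
perturbs every data point with Gaussian noise of its time point's replicate
standard deviation (pooled across time points where fewer than two
replicates exist), refits starting from the point estimate, and records D.
Draws that fail to converge or end with every parameter on a bound are
flagged and excluded (a warning is logged above 5 % dropped). Treatment and
control draws come from independent substreams spawned off one master seed
and are paired by index; the one-sided empirical p-value is
`p = (r + 1)/(n + 1)` with `r` the number of retained pairs where
D_treatment − D_control ≥ 0 and `n` the retained pair count, so p can never
fall below 1/(n + 1). The direction tests for a flux decrease by default; a
flag reverses it. D is reported in s⁻¹ throughout; unit conversion is left
to presentation. No multiple-testing correction is applied across targets.

## Numerical integration

The labelling ODEs are smooth and non-stiff at these turnover rates and are
integrated with adaptive RK45 (rtol 1e-9, atol 1e-11), two orders of
magnitude below measurement noise; a test verifies agreement within 1e-6
against a 100× tighter tolerance. The isotopic steady state is computed in
closed form by evaluating the fixed point along the feed-forward cascade
(G6P = medium MID, F6P = G6P, GAP = triose split, Ru5P = flux-weighted
branch mix), and trajectories are tested to converge to it.

## QC

Steady-state enrichment QC compares the mean ¹³C enrichment of a reference
metabolite (default G6P) at the final time point across conditions; a
condition differing from control by more than 0.05 (absolute) is flagged,
since branch fluxes can only be compared across conditions when precursor
labelling is equal. The 0.05 threshold is a pragmatic default, configurable.

## Problem sizes used in the test suite

The suite exercises the full pipeline at reduced Monte Carlo depth where the
quantity under test is an ordering or a calibration rather than a single
p-value: null calibration uses 200 runs × 200 draws, branch-specificity
orderings use 20 seeds × 100–200 draws, and the headline knockdown test uses
the full n = 1000 draws. These sizes give stable medians while keeping the
whole suite to a few minutes on one core.

## Known limitations

- No TCA refixation, no exchange (bidirectional) fluxes in the non-oxidative
  branch, no compartmentation; pool sizes are constant across conditions,
  whereas real knockdowns can change them (6PG accumulation under 6PGD loss).
- Labelled-count tracking is tracer-specific; arbitrary tracers or networks
  (full EMU/cumomer machinery) are out of scope.
- The CSTR fit treats each isotopologue curve as a single exponential; for a
  cascade of pools this yields an effective rate, which is precisely what
  makes it a useful branch-specific surrogate but not an absolute flux.
- Empirical p-values are Monte Carlo-resolution limited at 1/(n + 1).
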