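# Methods

## Scope

`sarm1tk` implements the quantitative core of a SARM1-regulation study: a
dual-site activator/inhibitor kinetic model of NADase activity, initial-rate
extraction from discontinuous product-accumulation assays, one-site ITC
binding analysis, and rigid-body superposition of ARM-domain structures,
plus seeded generators that emulate each input type.

## Dual-effector rate law (`kinetic_model`)

A single readily reversible effector I binds two independent sites on the
enzyme, one activating and one inhibitory:

    V = Vmax · A([I]) · B([I]) · [S] / (Km + [S])
    A = X + (1 − X) / (1 + ([I]/Ka)^n_act)
    B = Y + (1 − Y) / (1 + ([I]/Ki)^n_inh)

Assumptions: rapid-equilibrium binding at both sites, no effector
consumption during the assay, and multiplicative (independent) regulatory
factors. Both factors are exactly 1 at [I] = 0, so A·B is the fold change of
activity relative to the substrate-only control and is independent of [S].
With X > 1, Y < 1 and Ka < Ki the curve is biphasic.

The published rendering of this equation is typographically ambiguous about
where the Hill exponent sits; we parameterise the two limbs with independent
exponents `n_act` and `n_inh` (default equal), which contains every reading
as a special case and matches the convention of reporting one Hill
coefficient per effector.

Parameters and units: `vmax` milliU/mg (= nmol·min⁻¹·mg⁻¹), `km`/`ka`/`ki`
µM, `x_act`/`y_res`/Hill exponents dimensionless. Package-wide units are µM,
minutes, µL, milliU/mg.

### Fitting

`fit_dual_effector` minimises (optionally 1/y²-weighted) squared residuals
with `scipy.optimize.least_squares` (trust-region reflective) in
log-parameter space for the positive parameters. Because the biphasic
surface has local optima that swap the roles of Ka and Ki, the fit is
multi-started from 32 Latin-hypercube points (deterministic for a given
seed) plus one data-informed guess; the best run by RSS wins, with ties
broken by the lower Ka. Bounds: Ka, Ki ∈ [10⁻³, 10⁶] µM; X ∈ [0, 10³];
Y ∈ [10⁻⁶, 1]; n ∈ [0.25, 8]. Fold-kind data fix the baseline at 1, so
`vmax`/`km` are not estimated there and the report says so.

Identifiability is reported, not silently absorbed: estimates within 1% of
a bound (log-relative for log parameters, relative to the bound's magnitude
for linear ones) are flagged *pinned*, and dose grids with no response
variation are flagged *unidentifiable* — flat data are fit perfectly by a
degenerate manifold (e.g. cancelling limbs with Ka = Ki and X·Y = 1), so the
parameter values themselves carry no information.

`fit_michaelis_menten` fits the two-parameter hyperbola in log space from a
half-saturation-based start; noiseless model data are recovered to machine
precision, and designs sampling only [S] ≫ Km are flagged.

`peak_effector_response` brackets the fold-activation maximum on a 2000-point
log grid and polishes it by golden-section search; tests compare it against
dense-grid brute force (10⁵–10⁶ points).

## Rate extraction (`assay_rates`)

Each mole of ADPR or cADPR corresponds to one NAD cleaved, so their sum
estimates substrate consumption; nicotinamide is excluded to avoid double
counting. The analysis window is the maximal *prefix* of time points with
consumption ≤ 20% of S₀ (boundary inclusive); later points are never
re-admitted after a crossing because true consumption is monotone — a dip
back under threshold can only be noise. The rate is the free-intercept OLS
slope over the window (a forced-zero intercept would bias rates when a small
t = 0 background is present, and the convention is not specified by the
protocol we emulate). Conversion: slope µM/min = nmol·ml⁻¹·min⁻¹, divided by
enzyme in mg/ml gives milliU/mg.

## One-site ITC (`itc_binding`)

Overflow-cell dilution: after cumulative injected volume Vk, totals are
Mt·exp(−Vk/V₀) and Xt·(1 − exp(−Vk/V₀)) — the standard smooth convention
for perfusion cells. The cell volume is not part of the emulated protocol
text; the default 170 µL is typical of the low-volume instrument class, and
all recovery analyses are self-consistent in V₀. Bound complex is the
stable root of the 1:1 quadratic, clipped to [0, min(nM, X)]; tests check
it against a bisection oracle at 10⁻⁹ µM. Injection heat is
dH·V₀·([MX]k − [MX]k−1·(1 − vk/V₀)) + q_offset, i.e. enthalpy of newly
formed complex corrected for complex displaced into the overflow; negative
dH is exothermic, heats are µJ. Fitting uses multi-start least squares over
(n, Kd, dH, q_offset) with Kd starts log-spaced around the cell
concentration and dH scaled from the observed total heat; a fitted c-value
(n·Mt/Kd) outside [1, 1000] flags weak Kd identifiability. The fit works on
absolute heats; first-injection discard is available but off by default.
Simulation defaults to 25 injections (the upper end of the 20–25 range used
for the ARM-domain titrations).

## Structure comparison (`structure_compare`)

PDB/mmCIF reading goes through gemmi with author chain ids and author
numbering; altlocs resolve to the highest-occupancy conformer (ties → 'A').
Residues pair by intersection of author numbers when the paired identities
agree ≥ 90%; otherwise a global sequence alignment (biopython, BLOSUM
scoring) pairs non-gapped columns — the fallback covers cross-species
comparisons where numbering differs. Superposition is the closed-form
Kabsch solution (SVD of the covariance of centred pairs with reflection
correction), followed by iterative outlier rejection: up to 5 cycles, each
dropping pairs whose deviation exceeds 2.0 × the current RMSD, stopping at a
fixed point. This mimics refinement-style alignment, whose published
retained-atom counts are below the full common length; both the cycle count
and σ are configurable, and `reject_cycles=0` gives the plain all-pair
RMSD. Polar contacts are heavy-atom N/O pairs within 3.5 Å — no angle term
or hydrogen placement, since crystal structures at the relevant resolution
carry no hydrogens. Buried surface area is out of scope.

## Synthetic data (`synthetic_data`)

Generators are pure functions of (inputs, seed); a global seed fans out to
per-stream child seeds via `numpy.random.SeedSequence.spawn`, so the three
generators draw independent but reproducible streams.

Noise families: multiplicative unit-mean lognormal for fold-activation
(responses are positive ratios; default CV 5%, nominal for triplicate
enzyme assays), additive Gaussian clipped at zero for product
concentrations, additive Gaussian for heats. Replicate structure defaults
to n = 3.

Scenario presets encode the study system's qualitative behaviours. Basal
activities use the published values (wild-type 18.12 milliU/mg, K193R
pocket mutant 17.75 milliU/mg) and Km(NAD) = 70 µM. The per-effector
regulatory parameters were *not* published in machine-readable form, so the
presets are this package's own choices consistent with the qualitative
record: VMN biphasic with low-µM Ka (its ARM-domain Kd is 2.83 µM) and an
inhibitory limb two orders higher (X = 10, Y = 0.15, Ka = 3 µM, Ki = 300 µM,
n = 2), NMN monotone on the tested range with weaker induction and higher Ka
(X = 5, Ka = 30 µM, Y = 1), K193R flat (X = 1, Y = 1), plus a neutral
control. The default dose grid is a zero anchor plus a log ladder from
0.1 µM to 3 mM spanning both limbs. The time-course generator produces
exactly linear accumulation capped at S₀ with a default cADPR share of 10%
(cADPR is the minor product; the true split is not recorded). What passing
tests show is therefore self-consistency — the pipeline recovers what the
model generated under realistic noise — not agreement with any particular
wet-lab dataset: real dose-response data carry batch effects, effector
depletion and instrument drift that these generators deliberately omit.

## Numerical choices and degenerate inputs

- Dual-effector and MM fits run positive parameters in log space; tolerances
  xtol = ftol = gtol ≈ 10⁻¹⁴–10⁻¹⁵ so noiseless recovery is limited by the
  optimiser, not the stopping rule.
- `bound_complex` uses the subtraction-stable quadratic root and clips into
  the physical interval.
- Flat rate series are not flagged "negative slope" for slopes within
  round-off of zero.
- Self-superposition returns RMSD 0 with the identity rotation; rejection
  guards against emptying the pair set (< 3 pairs stops the cycle).
- All-zero rate vectors return Vmax = 0 with Km = NaN and a flag.

## Problem sizes

Tests and the acceptance script run at the experiment's own scale: 8-point
substrate grids, 11-point dose ladders in triplicate, 25-injection
isotherms, 50-replicate noise studies, and toy 4–80-residue structures for
superposition oracles. These match the emulated assays; nothing is scaled
down from them.

## Known limitations

- No profile-likelihood confidence intervals; identifiability is reported
  via pinned/c-value flags only.
- The ITC path starts from integrated heats; thermogram baseline correction
  and peak integration are out of scope, as are multi-site binding models.
- Hydrogen-bond detection is a distance-only proxy and will overcount
  relative to criteria with angular terms.
- The kinetic model is steady-state and cannot represent time-dependent
  activation or substrate depletion feedback; the assay module's 20% rule
  is exactly the guard that keeps data inside its validity regime.
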