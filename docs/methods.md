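# Methods

This note documents the models, conventions and numerical choices behind
`mcapop`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Fermentation smoothing model

Anaerobic batch cultivation is described by coupled ODEs. Substrate uptake
(s ∈ {glucose, xylose}) follows Monod kinetics gated by a first-order lag:

    dc_s/dt = −Y_s · c_x · c_s/(k_m,s + c_s) · (1 − e^(−t/τ))

Biomass grows in proportion to substrate consumption
(`dc_x/dt = −μ_glu dc_glu/dt − μ_xyl dc_xyl/dt`), and each product
accumulates through substrate-specific yields
(`dc_p/dt = −Σ_s Y_{s,p} dc_s/dt`). Measured ethanol additionally loses a
first-order evaporation term, `dc_eth,meas/dt = dc_eth/dt − e·c_eth`, with
`e = a − b·v` linear in the broth volume. The evaporation sink is written,
as in the source model, against the cumulative produced ethanol `c_eth`; a
variant acting on the measured concentration would differ only in the late
plateau and is not implemented. The lag constant τ is shared by both
substrates. Integration uses LSODA at rtol 1e-8.

**Maximum-likelihood fit.** The estimator assumes independent Gaussian
errors with species-specific standard deviations (default: 2% of the species
maximum, matching the synthetic noise model), which makes the ML problem a
weighted least squares. It runs in two steps: step 1 estimates
{Y_s, k_m,s, τ, μ_s} from the glucose/xylose/CDW subsystem; step 2 freezes
them and estimates the product yields plus the effective evaporation rate.
Parameters are optimized in log-space (positivity) with a trust-region
reflective solver and a wide (±6 log-units) box that keeps the optimizer off
the Y/k_m correlation ridge. The initial state (glucose, xylose, CDW at
inoculation) is estimated jointly with the step-1 parameters: seeding the ODE
with the noisy first observation — the inoculum especially — propagates
exponentially through the biomass equation and visibly biases every kinetic
estimate. With one experiment at fixed volume only `e = a − b·v` is
identifiable; `b` is kept from the initial guess and `a` reported as
`e + b·v`. A flat-likelihood warning is raised when a substrate never falls
below its fitted Monod constant.

**Units.** Concentrations g/l, rates g/gCDW/h; `SpecificRates.in_mmol`
converts to mmol/gDW/h via molar masses. Growth enters the stoichiometric
scenario in biomass C-mol units (25 g per C-mol of a CH1.8O0.5N0.2-type
lumped composition).

## Synthetic fermentation fixture

The generator's defaults define the study conditions for every recovery
test: initial state 20 g/l glucose, 50 g/l xylose, 0.15 g/l CDW; sampling
every 15 min over 140 h (automated sampling); iid Gaussian noise at 2% of
each species' maximum, clipped at zero. Fixture parameters: Y_glu = 5.0,
Y_xyl = 0.35 g/gCDW/h; k_m,glu = 8, k_m,xyl = 30 g/l (low-affinity uptake,
plausible for hexose-transporter-mediated transport of both sugars);
τ = 8 h; μ_glu = 0.05, μ_xyl = 0.02 gCDW/g; glucose yields
0.40/0.08/0.02/0.40 g/g to ethanol/glycerol/acetate/CO₂ and xylose yields
0.12/0.03/0.01/0.12/0.65 with xylitol dominating; e = a − b·v with
a = 0.012 1/h, b = 0.004 1/(h·l), v = 1.5 l. These values were chosen once,
by Fisher-information (Cramér–Rao) analysis plus a 20-seed Monte-Carlo
calibration, to make all step-1 parameters identifiable at the 2% noise
level while preserving the qualitative batch landmarks: glucose consumed
first (depletion ≈ 25 h), xylose incompletely consumed at 140 h (~17 g/l
left), xylitol accumulating to ~21 g/l, and simultaneous consumption of both
sugars at the 12 h analysis point. A shorter (~15 h) glucose phase renders
k_m,glu and τ unidentifiable at this noise level — the information bound
itself exceeds 30% — so the fixture deliberately runs a slower glucose
phase. What the generator does **not** emulate: autocorrelated instrument
drift, heteroscedastic HPLC errors, volume loss by sampling, pH/temperature
excursions, replicate structure. Passing recovery tests therefore show
estimator correctness under the stated error model, not robustness to real
instrument pathologies.

## Reduced glucose–xylose network

33 reactions over 30 internal metabolites (cytosol + mitochondria) and 10
boundary pools: upper glycolysis (HXT, HXK, PGI, allosteric PFK, FBA, TPI), a
lumped lower glycolysis (GLY: GA3P → pyruvate, 2 ATP + NADH), glycerol
(GPD1) / ethanol (PDC, ADH1) / acetate (ALD, NADP-linked) branches, the
xylose route (XTR, NADPH-linked XRI and NADH-linked XRII, XDH, XK, xylitol
export XLT), oxidative PPP lump (ZWF) and non-oxidative lump (RPE, RKI, TKT),
a mitochondrial block (pyruvate transport, PDH and TCA lumps, an
NADH-dehydrogenase analog NDR with P/O = 2 consuming O₂), ATP maintenance
(ATPM), transport/exchange steps, and a lumped biomass reaction that consumes
G6P, ATP, NADPH and molecular oxygen and leaves surplus cytosolic and
mitochondrial NADH behind (the stoichiometric root of the growth–NDR
coupling). Glucose and xylose transport are separate reactions with no shared
capacity term, so any interdependence found between them is a network
property, not transporter competition. Four conserved moieties (ATP/ADP,
NAD/NADH, NADP/NADPH cytosolic, NAD/NADH mitochondrial) give the reduced
structure rank 26.

Elemental bookkeeping is carbon-only (lumped acetyl units are C2; cofactors
carry their carbon skeletons), so every reaction is exactly carbon balanced
and `validate_balances` checks all 33. AMP is a fixed boundary pool acting
only as the PFK activator; adenylate kinase, malic enzyme and the
lactate/succinate/malate branches are not part of the reduction. Standard
Gibbs energies are plausible literature-scale values per reaction (uniport
transporters get ΔG° = 0 so Γ is the concentration ratio). Cofactor
concentrations are bounded to physiological windows (ATP 2–6 mM, ADP
0.3–1.5 mM, NAD 1–4 mM, NADH 0.05–0.3 mM, NADP 0.05–0.3 mM, NADPH 0.2–1 mM,
mitochondrial NAD/NADH analogous) — measured-level knowledge integrated as
bounds; all other intracellular species use the configurable default
1e-8–1e-1 M.

**Scenario (12 h co-consumption).** `make_scenario` simulates the
fermentation fixture to 12 h, converts the specific rates to mmol/gDW/h and
bounds the corresponding transporters (and growth) at ±20%. The oxygen
uptake rate is capped at 2 mmol/gDW/h (residual oxygen at the analysis time
point; the biomass reaction requires some). The lumped PDH flux is capped at
0.3 mmol/gDW/h (anaerobic repression of oxidative pyruvate metabolism), which
makes mitochondrial NADH turnover growth-dominated and is what couples NDR
flux to growth. Lower bounds keep both xylose-reductase isoforms
flux-carrying (the NADPH-preferring isoform carries ≥40% of uptake),
otherwise LP vertex solutions zero one of them. The reference flux solve
maximizes ATP maintenance; any objective can be supplied.

## Thermodynamics

Displacement: `Γ = (1/K_eq) Π P_j^{|s|} / Π S_i^{|s|}`; `ΔG = RT ln Γ` with
R = 8.314 J/mol/K; `ΔG° = −RT ln K_eq` (the standard relation; a source
formulation equating the concentration ratio itself with an energy is a
dimensional slip and is not reproduced). Default temperature 303.15 K
(cultivation at 30 °C), configurable. Water and protons are excluded from Γ
by the activity-1 convention. Displacement classification uses six bins:
far (0, 0.1], middle [0.1, 0.9], near [0.9, 1), and the three spanning
combinations.

**TFA encoding.** Variables: fluxes v, log-concentrations ln x, one binary
per ΔG°-carrying non-exchange reaction. Constraints: internal mass balance
N·v = 0; flux bounds; big-M coupling `v ≤ M_v z`, `v ≥ −M_v(1−z)`,
`ΔG ≤ −ε + M_G(1−z)`, `ΔG ≥ ε − M_G z` with ε = 1e-3 kJ/mol and M's derived
from the bound magnitudes. Solved with HiGHS (`scipy.optimize.milp`). The
returned profile's mass balance is re-verified by matrix multiplication, not
trusted from the solver. FVA solves the same MILP twice per reaction.

**Concentration sampling.** The feasible set in ln x is a polytope (box ∩
directional half-spaces). A hit-and-run chain starts at the Chebyshev center
(LP) and walks with uniform line sampling; defaults burn-in 1000, thinning
10, both configurable. Fixed seeds give identical output. Every profile
carries Γ, ΔG and K_eq per flux-carrying reaction, oriented along the net
flux direction. An independent checker (`recheck_profile`) recomputes ΔG
from raw log-concentrations and asserts sign consistency through a separate
code path.

## Kinetic mechanisms and elasticities

Every mechanism is written with a *separable* binding polynomial — one factor
per site — so each sampled saturation σ is exactly the occupancy of its site
and the σ's can be drawn independently (uniform on (0,1) by default;
configurable). For net flux S → P the scaled elasticities decompose into a
thermodynamic and a saturation part:

    ε_S = a·h/(1−Γ) − φ_S ,   ε_P = −b·h·Γ/(1−Γ) − φ_P

with a, b the absolute stoichiometric exponents, h the Hill coefficient
(1 for non-Hill forms), and φ the denominator occupancy: φ = a·h·σ for
Michaelis–Menten/ordered/Hill sites and
φ = Σ k x̃^k / Σ x̃^k (x̃ = σ/(1−σ)) for convenience sites of order > 1. The
ordered Bi-Bi/Bi-Ter/Ter-Bi denominators are used in this separable
(independent-site) parameterization — a documented simplification of the
full ordered forms whose complete rate expressions are not reproduced here.
PFK carries the allosteric specification: Hill coefficient h = 4 with AMP
(activator) and ATP (inhibitor) competing for one regulatory site, modeled
as a concerted two-state active fraction `f = u/(u+w)`,
u = (1−σ_AMP)^(−h), w = (1−σ_ATP)^(−h), contributing `+h σ_AMP (1−f)` and
`−h σ_ATP (1−f)`; ATP's substrate-site and regulatory-site contributions
add. The closed forms were derived symbolically once; the sympy rate-law
builder (`rate_law_expr`/`operating_point`) remains in the package and the
test suite re-derives every elasticity by symbolic and finite-difference
differentiation of the explicit laws (agreement to 1e-6 relative or better).

Exchange reactions and zero-flux reactions get zero elasticity rows;
boundary metabolite levels are parameters and are off by default. Enzyme
activity elasticities are identically 1 (v ∝ e). Γ outside (0,1) for a
flux-carrying reaction is an error.

## Control analysis

With N_R the independent-row stoichiometry, L the link matrix (N = L·N_R),
v the steady-state fluxes, E the scaled elasticities and x the sampled
concentrations:

    A  = N_R diag(v)
    L̃  = diag(1/x) L diag(x_indep)
    C^x = −(A E L̃)^{−1} A          (concentration control, independent rows)
    C^v = I + E L̃ C^x              (flux control)

The summation theorems (flux rows → 1, concentration rows → 0) hold by
construction since A·1 = N_R v = 0; they are asserted to 1e-8 on every
retained sample. The Jacobian `(A E L̃) diag(1/x_indep)` decides local
stability: retained iff every eigenvalue real part < −1e-12 (marginal cases
rejected and counted). Samples with condition number above 1e12 are flagged
degenerate and excluded (counted separately). An independent loop-built
Jacobian assembly (`stability_check`) re-verifies the filter in the tests.
Turnover control coefficients are the flux-weighted sums
`C_q^tMet = Σ (v_i/tMet) C_q^{v_i}` over producing reactions.

`respond` uses the linear interpretation (predicted % change =
C × % activity change) by default, matching the worked response arithmetic;
the log-linear extrapolation `(fold^C − 1)·100` is available behind
`mode="power"` and is non-default. Parameters are per-reaction enzyme
activities; growth responses treat the biomass reaction as a flux target.

## Population statistics

`run_pipeline(n_conc, n_sat, seed)` crosses displacement profiles with
saturation draws; counts (generated / degenerate / unstable / stable /
retained) are kept so population sizes are auditable, and run metadata
(seeds, model hash, flux hash) identifies a population. Pruning is
non-destructive (a new population referencing the retained samples).
Summaries report the mean, the closest-50% band (the ⌈n/2⌉ samples nearest
the mean, ties at the cutoff included — the error-bar convention of the
population bar charts) alongside conventional quartiles, a sign-consistency
fraction, and an `indeterminate` flag when the band straddles zero ("spread
around zero" operationalized, since no numeric criterion is stated in the
source). Rankings order by |mean| with lexicographic tie-break. Correlations
are Pearson product-moment.

**Problem sizes used.** The reference population is 200 displacement
profiles × 5 saturation draws (1000 linearizations, of which the stable
~60–90% are retained; seconds on one CPU). Parameter recovery uses 20
replicate batches; sampler uniformity is checked at n = 10,000 in a 1-D
polytope (Kolmogorov–Smirnov distance < 0.05). Many independent
displacement draws (rather than many saturation draws per displacement) were
chosen because cross-sample correlations converge with the number of
independent thermodynamic states.

## Known limitations

- The packaged network is a reduction: ~33 reactions standing in for a
  ~100-reaction model. Population statistics on it reproduce *sign-level*
  behavior (correlation signs, pruning shifts, coupling directions), not the
  magnitudes a full reconstruction would give.
- Separable binding polynomials understate denominator coupling in ordered
  multi-substrate mechanisms.
- The fermentation error model is iid Gaussian per species; the fit is not
  replicate-aware and models gas transfer only through the linear ethanol
  evaporation term.
- Linear response predictions extrapolate a local derivative to finite
  (twofold) changes; a gene deletion is a large perturbation and the linear
  figure is a ranking tool, not a quantitative forecast.
- TFA big-M formulations can be numerically delicate for very wide
  concentration bounds; bounds beyond the defaults should be sanity-checked
  against the solver's feasibility report.
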