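# Methods

## Model

A bivalent ligand (an IgG-scaffold molecule: two epitope-binding arms, one
Fc leg) couples epitope-bearing cells to a supported bilayer carrying mobile
Fc receptors.  Species densities follow the law of mass action with the
standard bivalent-ligand statistical factors: the first arm binds with
factor 2 (`[LM] = 2 K1 L [M]`), and the second arm's symmetry factor 1/2
cancels it for the doubly bound complex (`[LMM] = K1 Kx L [M]^2`); mixed
mobile–immobile complexes keep the factor 2.  Composite constants for every
other construction order (e.g. receptor-first bridge assembly, constant
`2 K1 K2 / KR`) follow from detailed balance, making all species densities
path-independent — a property the test suite asserts to 1e-12 rather than
assumes.  Complexes with two immobile epitopes are excluded structurally:
at the reference density of 80 epitopes/um^2 the probability of a neighbor
within a ~10 nm arm span, `1 - exp(-pi rho r^2)`, is below 3%.

Per cell, five constraints determine the equilibrium: mobile-epitope
conservation weighted by the contact fraction theta, immobile-epitope
conservation outside and inside the contact region, receptor conservation
(`R = RT / (1 + KR L + KA A)` for a sparse-cell bilayer; a finite-reservoir
variant is available behind the `beta` parameter), and the linear
contact-area growth law `theta Acell = Ans + B_in theta Acell / sigma`.
Free mobile species partition into the contact region (`M_in = pE M_out`,
`R_in = pR R_out`, both 0.75 by default); free immobile epitopes inside are
an independent unknown because they cannot redistribute.  Four immobility
models are supported: fully mobile, constant `f_I`, and `f_I` linear in
theta or in the cross-linked fraction X (baseline 0.13, the measured
resting immobile CD2 fraction).  X counts only epitopes held in
doubly-epitope-bound ligands, two per ligand.

## Solution strategy

With a sparse-cell bilayer the system reduces exactly rather than requiring
a five-dimensional root search: R is explicit; the two immobile closures
are explicit in the outside free mobile density `u`; the bridge equation
`B(u) = sigma` is strictly monotone in `u` (one bracketed Brent root); and
mobile conservation then gives theta in closed form.  Feedback immobility
adds an outer one-dimensional root in `f_I`, enumerated on a log-spaced
grid from small values upward; when several self-consistent `f_I` exist the
smallest is returned (a cell starts from minimal immobility), with a
sub-bracket re-scan guarding against crossings the grid might skip.  The
original residual vector (each conservation law scaled by its conserved
total) is re-evaluated at every returned solution and must fall below 1e-9;
this is property-tested over 1000 random parameter draws.

Degenerate regimes are handled explicitly: when immobile epitopes alone can
supply sigma bonds the contact area diverges, so above the threshold
`f_I* = sigma (1 + 2 K1 L + 2 K1 K2 L pR R) / (2 K1 K2 L pR R rhoT)` the
cell is flagged as fully flattened (theta capped at 1, reported via
`SolveReport.capped`, never an exception); theta is likewise capped
whenever a direct solution exceeds 1.  Adhesion decisions always use
Ans = 0 — nonspecific forces enlarge existing contacts but do not initiate
them — while realized contact areas of adhered cells include the
nonspecific offset.

In the fully mobile special case the boundary collapses to two quadratics
in `u`; their resultant is a cubic in L whose positive roots are the window
`[L_min, L_max]`, and at fixed L the positive quadratic root gives the
minimal adhering density.  Because the bond balance pins `u` independently
of theta, theta is linear in the cell's epitope density and population
conditional means reduce to `E[N | N > N_min]` — closed forms used both as
the fitting fast path and as an independent oracle for the generic solver
(agreement to 1e-8 over random sweeps).

## Population layer and numerics

Per-cell epitope counts follow a Weibull distribution (shape c, scale from
the mean via the Gamma-function formula; shape 1 is exponential), a
lognormal alternative, or an empirical piecewise-constant histogram.  The
fraction bound is the survival function at the minimal adhering count.
Conditional means over adhered cells use the substitution `t = -ln SF(N)`,
under which the conditional expectation becomes `int f e^-s ds` evaluated
by Gauss–Laguerre quadrature — the rule's weights sum to one, so it is
itself a conditional average; the rule is doubled until successive
estimates agree to 1e-8.  Conditional means are always reported alongside
the adhered fraction and come back NaN (with a `defined` flag) when no cell
adheres, so they cannot be misread as zeros.  With lognormal counts the
conditional bond count passes through an interior minimum and rises as the
dose falls — the adhered remnant is drawn from an ever heavier tail — which
the suite asserts as a qualitative property.

Boundary root-finding scans 60 points per decade of ligand concentration
over 1e-15 to 1e-2 M and polishes each bracket by bisection in log10 L;
phase-diagram boundaries bisect the population criterion (default: 50% of
cells adhered, fixed distribution shape while the mean varies; a
single-cell criterion is available).  Nonspecific IgG maps exactly onto
effective parameters `RT/(1+KA A)`, `KR/(1+KA A)` because the model depends
on KA and A only through the receptor balance; the closed-form low-dose
boundary scales as `L_min ~ sigma (1+KA A) / (K1 Kx K2 pR RT pE^2 rhoT^2)`.
The high-dose closed form retains the arm-loading factor
`2 K1 L / (1 + 2 K1 L)` (a quadratic in L): at the reference constants the
top of the window is still partially cross-link-dominated, so the
closed-form L_max brackets the true value from above, within two-fold at
high epitope counts and looser near the fitted mean.

## Reference parameters

Fixed physical constants for the alefacept / CD2 / Fc-gamma-RIIIb system:
cell area 800 um^2 (64,000 epitopes at 80 um^-2), partition coefficients
0.75, K1 = 1e5 /M (single-site CD58–CD2, Kd = 10 uM), and Kx = 31.25 um^2
from inverting the bivalent Scatchard initial-slope relation
`1/K_app = 4 K1 (1+Kx rho)^2 / (2+Kx rho)` at a 1 nM apparent cellular
affinity.  The slope relation constrains only the product `K1 Kx rho0`; the
split between K1 and Kx is fixed by requiring the lower adhesion boundary
to be cross-link-dominated, which reproduces the exact inverse-square
dependence of L_min on the ligand–epitope constants (a tenfold weakening
shifts L_min a hundredfold).  Best-fit sets per immobility variant (sigma
~ 204 um^-2, K2 ~ 0.4-0.6 um^2, KR ~ 4e5-4.3e6 /M, Ans = 0, Weibull c
1.2-1.6, mean count 5,200-17,000, contact-area immobility slope 23) are
bundled as `best_fit_params`; KA defaults to KR since the competing IgG
presents the same Fc to the same receptor.

## Synthetic data

The generator emulates the study design the fitter expects: titrations at
two bilayer receptor densities (1200 and 4800 um^-2) across 0.001-10 uM
ligand, 300 cells scored per point.  Adhered fractions carry exact binomial
sampling noise; conditional mean areas and bond counts are averages over
the sampled adhered cells degraded by multiplicative lognormal noise
(CV 0.1 by default — the paper-scale experiments report only "a few
hundred" cells per point and no noise model, so the CVs are a design
choice).  Points with no adhered cell emit missing values.  Everything is
driven by one integer seed, and each dataset carries its generating
parameters for recovery experiments.  What the generator does not emulate:
optical measurement bias in contact areas, cell-to-cell variation in
anything but epitope count, bilayer heterogeneity, and kinetic effects —
passing recovery tests therefore demonstrates the estimator's
self-consistency under the model's own assumptions, not robustness to real
instrument systematics.

## Fitting

The objective pools squared residuals over all doses and receptor
densities: adhered fractions enter unscaled; mean areas and mean bond
counts are each rescaled by their dataset maximum so all observables run
between zero and one (the normalizer is configurable).  Rows where the
model expects fewer than half an adhered cell in the sample contribute no
conditional residuals — conditional means are undefined there, not zero.
The search is a log/sqrt-transformed Nelder–Mead with seeded multistart
(positive parameters in log space; Ans, f0 and the immobility slope in
sqrt space so the boundary value 0 is reachable — the constant-immobility
fit indeed lands on f0 = 0 for fully mobile data); model-evaluation
failures incur a large finite penalty so the simplex can retreat.
Bootstrap uncertainty resamples dataset rows with replacement and refits
each replicate from the original optimum; 95% intervals are percentile
intervals, and all stochastic steps (starts, resampling) derive from one
seed.  Fixed-parameter sensitivity scans refit while holding pE, pR or Kx
at grid values: the fitted K2 absorbs the assumed Kx nearly inversely
(the boundary constrains the product K1 Kx K2) while the fitted mean count
is comparatively stable.

## Problem sizes

The default test and acceptance configurations use 17-point dose grids at
two receptor densities, 300 cells per titration point, 10 optimizer starts
for headline fits, 100 bootstrap replicates, and a 20-experiment
calibration check of bootstrap coverage with the nonspecific area pinned at
its generating value (keeping replicate refits on the closed-form path);
these sizes make the full suite reproducible on a single CPU while leaving
every statistical claim testable at conventional 3-sigma tolerances.

## Known limitations

The model is strictly an equilibrium theory: no kinetics of contact
nucleation or growth, no force-dependent bond rupture, and no membrane
mechanics beyond the linear area-per-bond law.  The immobility feedback
models are phenomenological linear forms clamped to [0, 1].  Conditional
averages at doses far outside the window are dominated by the extreme
upper tail of the count distribution, where any parametric family is least
trustworthy; the theta = 1 cap bounds but does not resolve that regime.
The closed-form high-dose boundary is an over-estimate whenever bivalent
bridges still dominate at the top of the window.
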