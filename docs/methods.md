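# Methods

## Model and assumptions

The model tracks six proteins of the yeast meiotic-initiation pathway
as dimensionless relative levels. Rim11, Ume6 and Sok2 are treated as
conserved one-unit pools whose phosphorylation state is the only
regulated quantity, so their active fractions are confined to [0, 1]
and only (de)phosphorylation terms appear. Ime1, pIme1 and Ime2 carry
explicit synthesis and degradation. All regulatory influences that are
not explicit variables — PKA, Cln3/Cdc28, Msn2/4, Snf1, Ndt80 — are
folded into existing terms: PKA into the phosphorylation rates of Sok2
and Rim11, the Ime2-adjacent interactions into the cooperative Ime2
auto-regulation term. The model therefore describes the initiation
window only; it makes no claims about middle or late sporulation.

Three feedback loops structure the dynamics:

1. **pSok2 ⊣ Ime1 ⊣ pSok2** (double-negative, functionally positive):
   inhibitory Hill factors with half-maximum constants `c_ime1` and
   `c_sok2`.
2. **Ime1 → Ime2 ⊣ Ime1** (negative): Ime2-activated Ime1 degradation,
   maximum rate `d2_ime1`, half-maximum `c1`. This loop terminates the
   Ime1 pulse; removing it (`d2_ime1 = 0`, `c1 = ∞`) leaves Ime2
   production unopposed by its saturating degradation and Ime2 grows
   without bound.
3. **Ime2 → Ime2** (positive auto-regulation): Hill term with maximum
   rate `s2_ime2`, half-maximum `c2` and coefficient `hill_n`
   (default 5; exposed as a parameter because the cooperativity is
   precisely what creates bistability).

Parameter defaults are the published kinetic constants: synthesis
rates `s_ime1 = s_ime2 = 10 /h`, `s2_ime2 = 3 /h`; degradation
`d_ime1 = d2_ime1 = d_pime1 = 1 /h` (1-h Ime1 half-life),
`d_ime2 = 8 /h` (≈5-min Ime2 half-life via ln 2/t½); the
(de)phosphorylation rates encode which phosphoform dominates in
meiosis (`u_rim11 > p_rim11`, `p_ume6 > u_ume6`, `u_sok2 > p_sok2`);
and five dimensionless half-maximum constants (`c_sok2 = 0.05`,
`c_ime1 = 0.01`, `c1 = 0.01`, `c2 = 1.4`, `c3 = 2`). The helper
`rate_from_half_life` returns the exact exponential-decay conversion
ln 2/t½ without rounding.

`c_ime1`, `c_sok2`, `c1` and `c2` accept the distinguished value
`inf`, evaluated as the analytic limit of the term they gate
(inhibition factor → 1; gated degradation/synthesis term → 0) rather
than as floating-point arithmetic, which keeps the right-hand side
finite and exact under loop deletion.

## Knockout semantics

A virtual gene deletion removes the gene product permanently: the
protein's state variables are clamped to zero with zero derivative,
and its synthesis rates are zeroed (`s_ime1` for *IME1*; `s_ime2` and
`s2_ime2` for *IME2*). For the three conserved pools, deleting the
gene empties the pool, so the tracked phosphoform is clamped at zero
(the untracked form appears nowhere else in the equations). This
reproduces every published knockout phenotype: zero Ime2 for the four
sporulation-deficient deletions, non-transient elevated Ime1 for
*ime2Δ*, and damped oscillations with enhanced Ime2 for *sok2Δ*.
Knockouts, feedback modes and raw parameter overrides compose; later
edits shadow earlier ones, and resolution is order-independent for
non-conflicting edits.

## Numerical integration and steady states

Time courses use `scipy.integrate.solve_ivp` (LSODA by default, with
the analytic Jacobian) at relative tolerance 1e-8 / absolute 1e-10 on
a uniform output grid; the default window is 24 h with 0.025-h spacing,
enough to resolve the ~6-h Ime1 peak. A stiff/non-stiff solver pair
(BDF vs RK45) agrees on the wild-type trajectory to 1e-6 max-norm,
mirroring the original multi-solver confirmation. Tiny negative
excursions (> −1e-9) are clamped to zero before evaluating Hill terms;
larger negatives raise an error.

Divergence: any component exceeding 1e3 (wild-type levels are O(1))
terminates integration via a solver event and flags the trajectory.
The only diverging regime is deletion of the negative feedback loop,
where Ime2 grows roughly linearly (~4–5 units/h) and crosses the bound
near t ≈ 200 h; divergence checks therefore integrate to 400 h.

Steady states integrate to t = 500 h and polish the endpoint with a
damped Newton iteration on the free (non-clamped) variables using the
analytic Jacobian, with backtracking confined to the admissible box;
if Newton fails the relaxed endpoint is returned. Convergence demands
a right-hand-side max-norm below 1e-10.

Transient features: the peak is the global interior maximum of the
gridded series, refined by local quadratic interpolation; the width is
the full width at half maximum above a zero baseline (the meiotic
proteins start at zero, so "half maximum" needs no baseline estimate).
Local maxima are counted with a prominence filter at 1e-3 of the
signal range (floored at 1e-6) so near-equilibrium ripple does not
masquerade as oscillation; damped oscillation = at least two maxima of
strictly decreasing height.

## Bifurcation analysis

Equilibria are found by multi-start root finding (Powell hybrid with
analytic Jacobian, residual tolerance 1e-10) from a 60-point grid:
pool fractions at their quasi-steady closed forms, Ime1 in
{0.01, 0.05, 0.2, 0.5, 1}, Ime2 at 12 log-spaced points in
[1e-3, 50] — the high-efficiency branch sits far above 1, so the start
grid must reach it. Duplicates are merged at 1e-6 max-norm. Stability
comes from the eigenvalues of the Jacobian restricted to free
variables, with margin 1e-8 on the leading real part; labels are
confirmed in the tests by perturb-and-integrate.

Branches over a parameter use bidirectional grid sweeps with warm
starts from neighbouring grid points plus the fresh multi-start at
every point; this finds disconnected branches without pseudo-arclength
continuation, which a 6-D system this cheap does not need. Grids are
logarithmic for half-maximum constants (they vary over orders of
magnitude) and linear for rates. A coupled scan multiplies `p_sok2`
and `p_rim11` by one common factor to emulate PKA activity.

Bistable windows are located by scanning the count of stable
equilibria and refining each bounding fold point by bisection on the
"≥ 2 stable" predicate to parameter tolerance 1e-3. With `hill_n = 5`
the c2 window is ≈ [0.51, 0.68]; coefficients 1 and 3 are monostable;
7 widens the window to ≈ [0.45, 0.77].

One structural finding worth recording: along the `c_ime1`, `c_sok2`
and PKA-scale scans the model has a *unique* equilibrium at every
value. The "two stable branches separated by an unstable branch"
picture arises because that single branch loses stability through a
Hopf-type instability in a middle window (where trajectories show
sustained or slowly damped oscillations) and restabilizes at high
Ime2. Scan ranges in the tests are chosen wide enough to show both
stable segments (e.g. `c_ime1` up to 30; the high branch restabilizes
near `c_ime1` ≈ 2). Genuine saddle-node bistability — three
coexisting equilibria — occurs in the `c2` scan. Limit cycles are not
continued; only equilibria are classified.

## Sensitivity analysis (MPSA)

All 19 kinetic constants are sampled simultaneously by Latin hypercube
(`scipy.stats.qmc.LatinHypercube`, seeded) with uniform marginals on
the linear range [baseline/10, baseline·10]; a log-uniform option
exists but is off by default. Each sample is integrated from the
mitotic state over 0–24 h on a 97-point grid — the transient window in
which the pathway's behaviour is defined; each of the six variables
gets its own objective (sum of squared errors against the baseline
trajectory) and its own acceptable/unacceptable split at the mean
objective. Sensitivity is the two-sample Kolmogorov–Smirnov distance
between the class-conditional distributions of each parameter's
sampled values, hence always in [0, 1].

Samples whose integration diverges or fails receive an infinite
objective: they are always unacceptable, and the mean threshold is
computed over finite objectives only (an infinite mean would have made
every finite sample acceptable, destroying the classification).
Degenerate splits (all samples on one side, e.g. a clamped variable
under a knockout) yield NaN sensitivities with a warning rather than a
fabricated zero.

The default design is 5,000 samples; the test suite runs 1,000 (and
smaller structural checks at 30–120), which is enough to reproduce the
qualitative rankings stably — for Ime2 the top two parameters are
`s2_ime2` and `d_ime2`; Rim11 and pSok2 are dominated by their
dephosphorylation rates, pUme6 by its phosphorylation rate. Exact bar
heights depend on the objective's time grid and are not comparable
across implementations.

## Synthetic validation screen

The validation pipeline correlates simulated steady-state Ime2 for six
genotypes (wild type + five deletions) with experimental
sporulation/pre-sporulation ratios. The real genome-wide screen is
external data and deliberately not bundled; a two-column TSV loader
accepts it. The synthetic stand-in draws
`ratio = (a·Ime2 + b)·exp(ε)`, `ε ~ N(0, σ²)`, with defaults `a = 1`,
`b = 0.1`, `σ = 0.2`: multiplicative log-normal noise because ratios
are positive fold-type quantities; the offset keeps zero-Ime2
genotypes at a small positive floor as real screens do; σ = 0.2 gives
a noise level at which the panel's signal (four exact zeros vs two
positives) clearly survives — the median Pearson r across 200 seeds
exceeds 0.8, while σ = 0 gives r = 1 exactly by the affine link.

What the synthetic screen does *not* emulate: genotype-specific
measurement error, the ~360 other sporulation-affecting genes, or any
saturation in the phenotype-to-ratio map. Passing the synthetic
pipeline therefore demonstrates the correctness of the correlation
machinery and the knockout panel, not agreement with experiment; the
published r = 0.85 is reproducible only with the external table.

## Known limitations

- Variables are relative levels in an SK1-calibrated abstraction; no
  units of concentration, no cell-to-cell variability, no stochastic
  simulation (the model is deterministic by construction).
- Sustained oscillations encountered in the Hopf window of the
  double-negative-loop scans are reported only through trajectory
  features; there is no limit-cycle continuation.
- Fold-point refinement bisects on the stable-equilibrium count, so a
  window narrower than the scan grid at its widest point could be
  missed; the published windows are far wider than the default grids.
- The MPSA classification threshold (mean objective) follows the
  published method; rankings, not absolute sensitivities, are the
  meaningful output.
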