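# Methods

This note records the models implemented in `srpkpd`, their assumptions,
the numerical choices, and what the synthetic-data experiments do and do
not demonstrate.

## Cellular pharmacokinetic model

Each compound `N` in the metabolite chain (CP-506 → CP-506H → CP-506M →
CP-506M-Cl₂ → sink) has an extracellular concentration `Ce` and an
intracellular concentration `Ci` coupled by first-order transmembrane
exchange.  With volume ratio `vr = Vi/Ve`:

    dCe_N/dt = −k_loss,N·Ce_N − vr·(k_in,N·Ce_N − k_out,N·Ci_N)
    dCi_N/dt =  k_met,N−1·Ci_N−1 + k_in,N·Ce_N − k_out,N·Ci_N − k_met,N·Ci_N

Assumptions: all rates first order (uptake was experimentally
concentration-independent over 0.3–30 µM, which this reproduces exactly
— the model is linear in the initial concentration); prodrug activation
is strictly intracellular and oxygen-gated; metabolite "metabolism"
(`k_met0` of CP-506H/M/M-Cl₂) is chemical instability and is not gated;
extracellular loss follows the measured medium half-lives.  Degradation
and the terminal metabolic step feed an explicit sink, so total mass is
conserved identically — the conservation tests check the implementation,
not the chemistry.

**Oxygen gate.** `g(O₂) = 1/(1 + (O₂/K)^h)` with `K = 0.1 µM`, `h = 2`:
fully open at anoxia, `g(1 µM) < 0.01`, matching the qualitative
requirement of complete inhibition above 1 µM O₂.  All quantitative
experiments here run at O₂ = 0 (gate = 1) or air (gate ≈ 0), so the
functional form between those extremes is never exercised.

**Key constants** (1/min unless noted): prodrug `k_in = 3.7`,
`k_out = 0.06`, activator `k_met0 = 0.12` vs target `0.0019`; metabolite
`k_in = 0.9`, `k_out = 0.25/0.4/0.3`, `k_met0 = 0.09/0.1/0.1`;
half-lives 30 h / 0.18 h / 0.13 h / 4.52 h.  Default monolayer geometry:
5×10⁵ cells of 2.5 pl in 850 µl of medium (`vr ≈ 1.5×10⁻³`).  The cell
volume is not a measured quantity; because `vr` is small the fits are
insensitive to it.

**Numerics.** The system is linear and time-invariant, so trajectories
are evaluated with the matrix exponential — exact to machine precision,
no step-size or tolerance knobs.  An adaptive ODE solve at rtol 1e-11
serves as the independent oracle in the tests.

**Fitting.** All fits are bounded nonlinear least squares
(`scipy.optimize.least_squares`) on log₁₀ parameters with seeded
multi-starts; residuals are log-concentration differences (equivalent to
proportional weighting, appropriate for LC-MS/MS error that scales with
signal); censored (< LLOQ = 0.01 µM) points are excluded.  The protocol
is sequential: aerobic data (metabolism closed) determine `k_in`/`k_out`;
these are then frozen while anoxic data determine the prodrug `k_met0`
and the metabolite constants.  Standard errors come from the Jacobian at
the optimum (delta method back to the natural scale).

**Identifiability.** Metabolite `k_in` is weakly identified in
monolayers — extracellular metabolite levels are tiny, so re-uptake
barely influences the data.  Its estimate is bounded to a plausible range
and the pipeline does not propagate it downstream (the prior value is
used instead); metabolite `k_out` and `k_met0`, and all prodrug
constants, recover well (see the seeded-recovery tests).

## Multicellular-layer transport model

The flux chamber is donor reservoir / MCL / support membrane / receiver.
Within the MCL each compound obeys Fick's second law with reaction; the
metabolic scaling factor `φ` multiplies the exchange term in **both** the
extracellular and intracellular equations (the equations as printed),
and `k_met0` itself is not additionally scaled.  The support layer has no
cells; the reservoirs are perfectly mixed ODE compartments coupled by
boundary flux; interfaces carry concentration continuity (partition
coefficient 1) and flux continuity.

Geometry defaults (donor = receiver = 8.5 ml, exposed area 0.6 cm²,
support 130 µm) are plausible chamber dimensions rather than measured
ones; every synthetic dataset carries its geometry in its provenance, so
generator and fitter are always self-consistent and the recovery
experiments do not depend on these choices.  Intra- and extracellular
volume fractions inside the MCL are both 0.5, which makes the printed
equations exactly mass-conservative.

**Numerics.** Conservative finite-volume method of lines, uniform grid,
50 nodes per layer (halving the step changes reservoir curves by
< 0.5%); trapezoidal (Crank–Nicolson) stepping at Δt = 0.25 min on a
factorised sparse operator — unconditionally stable against the stiff
exchange terms and exactly conserving the discrete mass invariant.
Against the closed-form two-reservoir slab solution (equilibration rate
`(D·A/L)(1/V_d + 1/V_r)` after a lag `L²/6D`) the solver agrees to ~0.01%.

**Staged estimation.** `D_sup` from bare-membrane curves; `L_MCL` from
the ¹⁴C-urea standard with its tissue diffusivity fixed at
3.67×10⁻⁷ cm²/s; `D_MCL` from supraoxic MCL curves (uptake constants
frozen from the monolayer stage; with the gate closed no metabolites
exist, so the fit uses the prodrug records); `φ` from anoxic curves with
everything else frozen and the condition-matched `D_sup` (anoxic stirring
gives 0.717×10⁻⁶ cm²/s vs 1.32×10⁻⁶ supraoxic).  Each stage is a
one-parameter, monotone objective; a single optimiser start suffices.
The urea support-membrane diffusivity is not separately known and
defaults to the drug's `D_sup` — again only generator/fitter
self-consistency matters for the recovery experiments.

## Spheroid models

**Lattice ABM.** Cells occupy cubic sites (10 µm pitch); volume grows
exponentially at rate `ln2/T_d · O₂/(O₂+K_grow)` and cells divide at
`V_div = 1000 µm³` into two half-volume daughters.  A daughter takes a
uniformly random empty von-Neumann neighbour; failing that, the column of
cells along the lattice direction with the shortest occupied run is
pushed outward by one site (minimal displacement, random tie-break) —
this keeps grown spheroids compact and approximately spherical.  Oxygen
is solved quasi-statically on radial shells (spherically averaged
consumption, Michaelis-limited, Dirichlet boundary outside the rim);
cells below 0.15 µM O₂ are tagged and lyse 24 h later, vacating their
site.  The default consumption (3.6 fmol/cell/min at saturation) makes a
few-hundred-µm spheroid develop a hypoxic core — an effective knob, not
a claim.  No motility or mechanics; motion only via division pushes.

**Exposure.** Occupancy is frozen for the 4 h treatment.  The
extracellular field diffuses through the intercellular space (cell volume
fraction 0.5 per occupied site) with `D_s = 1.93×10⁻⁷ cm²/s` in tissue
and `D_M = 1.32×10⁻⁶ cm²/s` in medium; per-cell intracellular kinetics
are exactly the monolayer model with the line-specific `k_met0`.  Medium
handling: `well-mixed` (empty sites clamped at the bath concentration;
default), `closed` (sealed box, used for conservation checks), `bath`
(whole extracellular field clamped; the uniform-field limit and the
single-cell oracle mode).  Under anoxic exposure the O₂ field is clamped
to zero, as in the experiments.

Numerics: explicit FTCS diffusion on a flat list of active sites at 0.9×
the stability limit; intracellular pools advance by an exact exponential
update against the frozen local `Ce`, with the exchange and AUC integrals
taken from the same closed form so that mass balances identically and
the per-cell trajectories match the monolayer ODE to < 1% (the
single-cell oracle test).  Concentrations below 1e-30 µM are flushed to
zero (subnormal-float arithmetic is pathologically slow and such values
are physically meaningless).  The hot loop is compiled with numba.

**Continuum surrogate.** Radial shells (3 µm) carrying `Ce` plus per-line
`Ci` pools with the same kinetics, volume fractions 0.5/0.5, an optional
unstirred medium shell (default 100 µm), and a constant-concentration
outer boundary (prodrug at the applied dose, metabolites at zero — a
large well).  Crank–Nicolson at Δt = 0.1 min.  Deterministic and ~0.2 s
per exposure, it is the preferred route for radial-gradient predictions.
On an idealised compact lattice ball the two implementations agree
within ~20% per depth bin (innermost bin excluded — it averages only a
handful of cells); the residual difference is lattice discretisation at
small radii and the fuzzy surface of stochastic growth.

**Kill model.** Kill probability is proportional to the intracellular
concentration of the cytotoxic metabolites and zero for the prodrug, so
the hazard integral over an exposure gives `SF = exp(−k_d·Σ_N AUC_N)`
with one `k_d` for all metabolites (0.01 in monolayers, 0.0256 in
spheroids).  The default readout averages survival probabilities
(deterministic); a seeded Bernoulli mode realises individual deaths for
regrowth simulations and is bit-reproducible for a given seed.  Note a
scale consequence of the published constants: metabolite AUCs reach
hundreds of µM·min per µM of applied prodrug in activator cells, so
`k_d·AUC` crosses 1 at sub-µM nominal doses; survival scenarios in the
generators therefore sample sub-µM concentration grids where the
surviving fraction is informative rather than saturated at 0.

**Radial profiles.** Depth is measured from the outermost occupied site
(lattice) or the sphere surface (surrogate); intracellular means are
binned in 10 µm depth bins.  "Penetration depth" is operationalised as
the depth where intracellular prodrug first falls below 1% of the
outermost bin (log-linear interpolation between bins) — the threshold is
a reporting convention, configurable.

## Dose-response conventions

4PL curves are fitted on the log-concentration axis (zero-concentration
controls normalise but are excluded); the IC50 is the interpolated
crossing of 50% **of control**, which equals the 4PL midpoint only when
`bottom = 0` and `top = 1`.  Fits whose midpoint lands far outside the
tested range (beyond 30× either end) or whose span is < 0.05 raise a
non-convergence error rather than returning an extrapolation; curves
that plateau above 50% of control report a greater-than-range sentinel.
Fold ratios are reported to three significant figures.

## Synthetic data

Generators reproduce the statistical structure the analysis assumes:
multiplicative lognormal noise with 10% CV (mean-preserving; a stand-in
for unreported replicate-level variability), censoring below the 0.01 µM
LLOQ, three replicates (or chambers), binomial colony counts given cells
plated and a 60% plating efficiency, and mono-exponential media decays
at the measured half-lives.  Every file embeds its generating parameters
and seed, so estimate-versus-truth round trips are always possible, and
identical seeds give byte-identical files.

What passing recovery tests show: the estimators are consistent and
unbiased at the assumed noise model and the published parameter values.
What they do not show: robustness to structural error — real assays have
correlated errors, matrix effects, partial-volume artefacts in the
intracellular extraction, and biological replicate variation none of
which the generators emulate.

## Problem sizes

Recovery experiments use 20 seeds (monolayer and chamber stages of the
acceptance script; 5 seeds for the chamber stages inside the test suite)
at n = 3 replicates and 10% CV.  Spheroid growth tests use 120–250
founder cells over 2–4 days (thousands of cells at endpoint); lattice
exposure tests use compact balls of 40–80 µm radius; gradient
predictions use the 300 µm continuum surrogate.  These sizes were chosen
so the full suite and the acceptance script each complete in minutes on
a single CPU while keeping every estimate's sampling error well inside
the tolerance it is compared against.

## Known limitations

- No mechanistic lysosomal sequestration; the large cell-uptake factor
  is represented phenomenologically through `k_in/k_out`.
- Nitro-radical-anion chemistry is lumped into `k_met0`; branch products
  (the diols and CP-506H-Cl₂) appear only in the media-stability
  generator, not in the kinetic chain.
- The oxygen-gate shape between 0 and 1 µM O₂ is an assumption;
  quantitative work here never samples it.
- The chamber model is one-dimensional; stirring hydrodynamics enter
  only through condition-specific `D_sup` values.
- Aerobic steady-state Ci/Ce from the rate constants is 61.7, while the
  measured ratio was reported as ~50 (and ~40 anoxic vs 20.6 implied);
  the package treats the published rate constants as the generating
  truth and does not force reconciliation.
- Lattice spheroids grown stochastically have rough surfaces; continuum
  comparisons are made against idealised balls.
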