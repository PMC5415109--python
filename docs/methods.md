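# Methods

## Scope and model

`lysodimer` post-processes protein MD output; it does not run MD. Its
three analysis stages mirror the workflow for studying aggregation onset
in a destabilised protein: (i) detect partial unfolding of a monomer from
trajectory metrics, (ii) judge the stability of candidate dimers, and
(iii) rank stable dimers by a nonequilibrium estimate of their binding
free energy. The human-lysozyme system (130 residues, α-domain 1–42 +
81–130, β-domain 43–80, four disulfides C6–C128/C30–C116/C65–C81/C77–C95,
hydrophobic pocket Y54/I59/C65/C81/L84/L85 guarded by the D67 and R62
side-chain networks) supplies the default selections and thresholds, but
every residue id, pair and threshold is configurable.

## Structure and trajectory handling

PDB reading is fixed-column (v3). Alternate locations are resolved at
parse time by highest occupancy, ties to the lexicographically smallest
code — a deterministic convention matching common practice. Hydrogens are
parsed but excluded from the backbone/Cα/pocket selections because all
metrics here are heavy-atom metrics. Insertion codes are rejected with an
explicit error rather than silently renumbered. Multi-model PDB is the
trajectory interchange format: models must share one atom table, and
models whose atoms are listed in a permuted order are reordered onto
model-1 order by (chain, residue, atom name). The frame interval is
caller-supplied metadata, defaulting to 5 ps (the production save
interval of the underlying simulations). Crystallographic waters are
retained on input; selections decide what is used.

## Superposition and RMSD

Superposition is the closed-form least-squares fit via SVD of the
covariance matrix with the determinant correction, so reflections are
never returned. Degenerate fit sets (< 3 atoms, collinear) raise instead
of producing an arbitrary transform. "Backbone" means the standard
four-atom set {N, CA, C, O}; because the source data report only
"backbone atoms", the crystal-pair RMSD check carries a ±0.15 Å
selection-convention tolerance around its 1.87 Å target. For the global
RMSD series the fit set equals the measurement set. The per-residue
profile fits globally on the backbone and measures each residue's Cα
deviation, averaged per frame over the analysis window (the alternative —
deviation from a time-averaged structure — is deliberately not used; it
measures fluctuation rather than displacement from the reference state).
Cross-structure atom matching is by (chain, residue id, atom name), so a
point mutant maps onto the wild type through the shared backbone.
Default averaging windows are trailing windows (25 ns worth of frames by
default) and are config-driven.

## Distance analyses

Contact distances specified by element pairs ("O–O", "N–O") are minima
over the cross-product of the residues' side-chain donor/acceptor sets
(e.g. Arg {NE, NH1, NH2} × Asp {OD1, OD2}); this is the standard contact
definition when no single atom pair is named. Waters are counted as their
oxygen site only, one site per molecule. All distances use the
orthorhombic minimum-image convention when a box is present and raw
Euclidean distances otherwise; triclinic boxes are out of scope.
π-stacking is quantified by unweighted centroids of the aromatic ring
heavy atoms (6 atoms for Tyr/Phe, 5 for His). Centers of mass use
standard atomic masses by element; unknown elements are an error rather
than a silent unit-mass fallback.

Hydration scans report per-frame mean ± sd of the water count inside
probe spheres following the center atom; radii default to {3, 4, 5, 6} Å
and means are reported at full precision. Counts are time-averaged over
the analysis window, and means are non-decreasing in radius by set
inclusion (enforced as an invariant).

## Unfolding and dissociation classifiers

The loop-opening coordinate (T70–D49 Cα distance by default) is
summarised by sample moments — the maximum-likelihood Gaussian — plus a
histogram (0.5 Å bins). A marked departure from Gaussianity (|skewness|
> 0.5 or |excess kurtosis| > 1) clears a `gaussian_fit_ok` flag: a
bimodal opening distribution means two conformational states were mixed
into one window and a single mean is not a faithful summary. The
folded/unfolded verdict is a strict `mean > 20 Å` rule; 20 Å sits between
the observed folded-state (14–18.3 Å) and unfolded-state (23.5 Å)
averages.

Dimer dissociation uses the center-of-mass separation series: the dimer
is dissociated iff the separation exceeds baseline mean + 10 Å at some
frame and never returns below that limit afterwards. The sustained rule
exists because production runs are terminated after separation —
persistence, not a transient spike, is the event of interest. The
threshold crossing is reported as `dissociation_time` (the termination
event), and the estimated departure from the bound state
(`onset_time`) is obtained by back-tracking from the crossing to the last
frame inside the baseline noise band (mean + 3 sd). For a drift of
2 Å/ns the 10 Å crossing lags the true departure by 5 ns, so onset
back-tracking is what recovers the departure time to within one frame.

## Work integration and Jarzynski reconstruction

Work is integrated against the restraint reference displacement,
$W = \int F\, dz_{\mathrm{ref}}$ with $dz_{\mathrm{ref}} = v\,dt$ — the
stiff-spring convention in which $z_{\mathrm{ref}}$ plays the role of the
reaction coordinate. Integrating against the particle displacement
instead was considered and rejected: under a stiff spring the reference
schedule is the controlled coordinate, and the exponential average then
converges to the restraint free energy
$G(z_{\mathrm{ref}}) = -k_BT\,\ln\!\int e^{-(U(z)+\frac{1}{2}k_s(z-z_{\mathrm{ref}})^2)/k_BT}\,dz$,
which the synthetic module evaluates exactly by quadrature as the
validation reference. Trapezoidal integration is used (exact for the
linear-in-$z_{\mathrm{ref}}$ forces of the frozen-particle limit), with
linear interpolation onto a common grid (default 0.1 Å spacing over
[z0, z0 + 15 Å]); requesting grid points outside the logged span is an
error, never an extrapolation.

The exponential average is computed with a max-shifted log-sum-exp, so
profiles with works of thousands of kcal/mol do not overflow. The
Boltzmann constant is 0.0019872 kcal/mol/K (kT = 0.5962 kcal/mol at
300 K). No finite-sample bias correction is applied: the exponential
average is known to overestimate profiles when work fluctuations exceed
kT, and the package documents rather than corrects this, reporting the
second-order cumulant estimator ⟨W⟩ − var(W)/2kT separately for
near-Gaussian diagnostics. The Jensen bound ΔG(z) ≤ ⟨W(z)⟩ is an exact
property of the estimator and is asserted, not assumed.

Binding affinity is read from a profile as mean ΔG over a bulk window
minus the global minimum. The far-end plateau-minus-minimum reduction was
chosen over the raw endpoint value because it is insensitive to where
exactly the pull ends once the bulk is reached, and it is non-negative by
construction. Ranking is by descending affinity with ties (within 1e-9
kcal/mol) broken by label order and reported explicitly.

## Synthetic data: what it emulates and what it does not

The **toy pulling engine** integrates overdamped Langevin dynamics
(Euler–Maruyama): dz = [−U′(z) + k_s(z_ref − z)] dt/γ + √(2kT dt/γ) ξ.
Overdamped rather than inertial dynamics because it is the simplest
process for which the Jarzynski identity holds exactly, and inertia adds
parameters without test value. Initial coordinates are drawn from the
equilibrium density of U + spring at z0 (inverse-CDF sampling on a dense
grid) — a requirement of the identity, not a convenience. The step-size
bound dt < γ/(max|U″| + k_s) is enforced as a hard configuration error;
there is no silent blow-up. Defaults γ = 0.2 kcal·ns/mol/Å²,
dt = 2.5 × 10⁻⁴ ns keep the per-step relaxation fraction small against
the stiffest default spring. Potentials are harmonic, linear-ramp and
quartic double-well, each with closed-form energy, gradient and free
energy.

The **mock trajectory generator** decorates a reference structure with:
per-atom Ornstein–Uhlenbeck positional noise (per-component RMS 0.25 Å,
correlation time 0.1 ns) so time correlation resembles real MD rather
than white jitter, amplified threefold in the designated flexible loop
(residues 65–77 by default, emulating the elevated C65–C77-loop
mobility); a rigid per-frame loop displacement along the opening axis
drawn i.i.d. from Normal(target, 1.0 Å), giving the approximately
Gaussian opening marginals seen in the real histograms; and pocket waters
placed uniformly inside the probe sphere with Poisson-distributed counts,
surplus slots parked far from the protein so the atom table stays fixed.
Ground truth (configured means, expected classifications) is always
emitted as a sidecar record so tests recover parameters without reaching
into generator internals. The dissociating-dimer generator translates a
second chain linearly after a configurable onset.

What the generator does **not** emulate: force-field energetics,
solvent dynamics, secondary-structure changes, correlated collective
modes beyond the single loop displacement, or any coupling between
loop opening and pocket hydration (they are controlled independently).
Passing parameter-recovery tests therefore demonstrates that the
*measurement and classification machinery* is correct and unbiased at
realistic noise levels — not that the physical conclusions of any MD
study are reproduced.

The **synthetic crystal stand-ins** encode the published residue-level
facts of the two structures (130 residues, the four disulfide bridges at
bond geometry, the pocket and guard residues, Asp→His at 67) on a
compact generated backbone; the variant's backbone is displaced by a
smoothed, rigid-mode-free random field concentrated in the 55–80 loop
region and scaled so the fitted backbone RMSD matches the published
1.87 Å difference. They are labelled synthetic throughout and are
generated geometry, not crystallographic coordinates; checks built on
them validate the parse → select → superpose → measure pipeline as
parameter recovery.

## Problem sizes and numerical tolerances

Default validation sizes are chosen so the whole suite runs in well under
a minute of compute per stage: 200 traces for Jarzynski recovery (max
error vs. the exact curve ≲ 0.1 kcal/mol, tolerance 0.3), 50 traces per
complex for ranking, 2000 frames for opening-mean recovery (tolerance
3·sd/√n), 0.25 ns frame spacing for dissociation detection (onset
recovered within one frame). Superposition agrees with an independent
quaternion-eigenvalue oracle to 1e-9 Å; distance and count primitives
agree with brute-force loops exactly.

## Known limitations

- Orthorhombic boxes only; no triclinic minimum image.
- Per-residue RMSD profiles require unique ascending residue ids, i.e.
  single-chain input (select a chain first for dimers).
- The NAMD pulling-log dialect reader projects positions/forces onto the
  protocol direction; other engines' formats must be converted to the
  TSV schema (`time_ns`, `z_A`[, `force_kcal_mol_A`]).
- DCD trajectories are not read; multi-model PDB is the interchange
  format (text-only, round-trips to 3 decimals by PDB precision).
- No umbrella-sampling/WHAM alternative and no error bars beyond what a
  caller can bootstrap over traces.
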