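# Methods

This note records the models implemented in `oligoccs`, the parameter
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical decisions a user should know before
trusting a result.

## Travelling-wave CCS calibration

Travelling-wave ion mobility yields drift times with no closed-form relation
to collision cross section; calibration against reference ions is the
standard route. The implemented protocol:

1. **EDC correction.** Measured drift times include a m/z-dependent transfer
   delay: `td' = td − c·sqrt(m/z)/1000` (ms). The coefficient `c` is an
   instrument setting, not a fit parameter; the default 1.41 is a common
   Synapt value and is configurable. A non-positive corrected time raises —
   it means `c` is inconsistent with the data.
2. **Reference normalisation.** Each calibrant CCS is normalised by charge
   and reduced mass, `ccs' = ccs / (z·sqrt(1/μ))`, `μ = m·M_gas/(m+M_gas)`.
   The drift gas defaults to N₂ (28.0134 Da; 4.0026 Da for He). The proton
   mass 1.00728 Da converts m/z to mass.
3. **Power-law fit.** `ln ccs'` on `ln td'` by ordinary least squares —
   unweighted, matching common practice and exactly testable: two distinct
   calibrants determine (A, B) exactly, and noise-free synthetic calibrants
   recover the generating parameters to machine precision. Per-calibrant
   relative CCS errors are stored as fit residuals.

`apply` and `invert` are exact inverses including the EDC term; the
synthetic-data generator uses the inverse to plant drift times.

A note on conventions: some write-ups print the reference normalisation as a
multiplication by `sqrt(1/μ)` rather than a division. The two conventions
differ only in the absolute scale of A; CCS values are identical as long as
`fit` and `apply` use the same convention, which this package guarantees.

## n/z assignment and ion-mobility deconvolution

For a monomer mass M, a feature at m/z is compatible with every (n, z)
satisfying `|mz − (n·M + z·1.00728)/z| ≤ tol`, n ≤ 12, z ≤ 12 by default.
The ppm tolerance defaults to 200 (modest TOF resolution at high m/z).
Only proton adducts are modelled.

Candidates with equal n/z overlap **exactly**, so the m/z dimension alone
cannot split them. Deconvolution computes, per candidate, the calibrated CCS
at the candidate's charge and its relative deviation from the nearest
growth-family prediction for state n (families outside their domain of
existence do not predict). Candidate weights are a Gaussian kernel of that
deviation with width 3% — chosen because the I₂/I₃/L family curves
themselves separate by more than 5% beyond the dimer — and the feature's
intensity is split proportionally, conserving the total exactly. With no
families yet (bootstrap first pass) the lowest-n candidate takes the whole
intensity. Features with no candidates are returned as unassigned, never
dropped.

**Known limitation: ladder ghosts.** A species at (n, z) also matches
(kn/g, kz/g) candidates; the candidate CCS scales by the charge ratio, and
for some state pairs that scaled value lands within a few percent of another
family's curve (e.g. a linear-family octamer at z = 12 projects onto a
hexamer candidate at z = 9 close to the isotropic curve). On such states a
deterministic fraction of intensity is shared with the ghost, and with
measurement noise that fraction fluctuates. Consequences: per-feature
intensity shares on the true label reach ~0.85 rather than 1.0 at these
states even noise-free (the top label is still correct), and per-state
enrichment ratios at single-charge-state high oligomers scatter around the
planted value. Aggregating the enrichment signal over the boosted states
(n ≥ 8) averages this out; the tests check the aggregate. This is a physical
ambiguity of the n/z + CCS observables, not an implementation artifact.

Relative intensities are fractions of total assigned signal per state,
including the monomer. Enrichment ratios divide two variants' relative
intensities per state; a state missing from the denominator is reported as
NaN (undefined), never infinity. Because relative intensities are
normalised, a planted k-fold boost of states n ≥ n₀ appears as
`k·T_other/T_boosted` (≈ 2.87 for k = 3 with the default decay), not as k
itself.

Peptide masses are average masses from a standard residue table plus one
water (18.0153 Da); the value for the 40-residue amyloid-β peptide is
4329.86 Da (a dodecamer rounds to 52 kDa). Concentration from tyrosine
absorbance uses Beer–Lambert with ε = 1490 M⁻¹cm⁻¹ for a single-Tyr peptide.

## Growth families and the deviation profile

Isotropic (spherical) growth follows from volume additivity:
`V_n = n·V_1` gives `CCS_n = CCS_1 · n^(2/3)` for the cross-section of a
sphere. Isotropic families are anchored at the most intense compact monomer
CCS at z = 2 (I₂) and z = 3 (I₃); the linear family L is an OLS line over
states n ≥ 4, where elongated growth takes over. Family membership assigns
each (n, z) to the family minimising relative CCS deviation, if within 5%
(the membership tolerance is a package decision, exposed in config);
otherwise unclassified. The derived I₂ family is restricted to n ≤ 2: it is
anchored on a single monomer state, and extending a one-point family across
all states would open spurious deconvolution channels.

The deviation-ratio profile divides the intensity-weighted mean CCS per
state by the theoretical I₃ isotropic value; 1.0 means perfectly spherical
growth. Two OLS lines are fitted to the (n, ratio) points on [1, 4] and
[4, 10]; the breakpoint is fixed at n = 4, not estimated (an optional free
breakpoint was considered and rejected — the regime change is a modelling
input here, and estimating it from ≤ 10 points is unstable).

## Structure metrics

* **PA-CCS.** The projection approximation: the orientation-averaged area of
  the molecule's shadow, treating atoms as hard spheres (Bondi vdW radii;
  unknown elements fall back to 1.70 Å with a logged warning). Orientations
  are uniform random axes; per orientation the union area of the projected
  disks is estimated by hit-or-miss sampling of the bounding box (512 plane
  samples by default). The estimator's standard error scales as
  1/√(orientations); `return_sem=True` reports it. PA systematically
  underestimates drift-gas CCS for large concave ions; a scale factor
  (default 1.0) is exposed for buffer-gas calibration but no trajectory
  method is attempted. The structure-side CCS method is deliberately the
  cheapest defensible one; treat absolute values as comparative.
* **SASA.** Shrake–Rupley with a golden-spiral quadrature (960 points/atom
  by default, minimum 32) and probe 1.4 Å; neighbours from a k-d tree. An
  isolated atom reproduces 4π(r+probe)² exactly up to quadrature. The
  hydrophobic fraction sums atoms in {Ala, Val, Leu, Ile, Met, Phe, Cys,
  Trp} — the Kyte–Doolittle-positive set plus Trp; the set is an argument.
* **Contact maps.** Minimum heavy-atom distance per residue pair, reported
  in nm (coordinates are Å internally everywhere else). Intra-chain maps are
  symmetric with zero diagonal.
* **Compactness.** Defined here as `4π·r_eq² / SASA`, where `r_eq` is the
  radius of the sphere with the structure's Monte-Carlo volume, both volume
  and SASA taken over the *probe-inflated* body (probe 1.4 Å). Using the
  same body in numerator and denominator makes the isoperimetric inequality
  bound the score by 1 (the sphere minimises surface at fixed volume);
  Monte-Carlo noise is clamped to [0, 1]. A packed-sphere fixture scores
  ≥ 0.9, a linear chain far lower. The 0–1 range is the defining contract;
  the specific formula is a package decision isolated in one function so it
  can be swapped.
* **Clustering.** The gromos (Daura) algorithm: repeatedly take the frame
  with the most RMSD-neighbours within the cutoff (0.4 nm default) as a
  cluster centre and remove the cluster. Deterministic; neighbour-count ties
  break to the lowest frame index; clusters are relabelled largest-first.
  RMSD uses SVD-based Kabsch superposition on all atoms (handles degenerate
  planar/collinear sets; cross-checked against MDAnalysis in the tests).

## Synthetic data: what the stated world is

The generator emulates a nanoESI oligomer measurement of a ~4330 Da monomer
(the computed 40-residue amyloid-β average mass) with:

* states n = 1–10 and geometric abundance decay 0.6 per state — "no
  preferred oligomeric state", a gradual intensity decrease;
* charge states per (n, family): a ±1 window with triangular weights around
  `round(3·n^(2/3))`, clipped to z ≤ 12; the linear family's window is
  shifted +3 charges (elongated species expose more surface and hold more
  charge), which also keeps the families charge-separated through n = 6;
* monomer CCS anchors 600 Å² (z = 2) and 700 Å² (z = 3) — deliberately
  round numbers, not literature values;
* growth modes: `isotropic` (a single I₃ world), `linear_above_4`
  (isotropic to the tetramer, then a linear family continuous at n = 4 with
  slope 0.45 × the I₃ anchor per state), and `mixture` (isotropic dominates
  n ≤ 4, the linear family takes over above — the realistic mode);
* a variant-dependent boost: the stapled-hairpin-like configuration
  multiplies abundances at n ≥ 8 by 3;
* noise: additive Gaussian 20 ppm on m/z, additive Gaussian 1% on drift
  time, multiplicative lognormal 5% on intensity — plausible for a
  TOF/TWIMS instrument at this m/z. Identical config + seed is
  byte-identical.

It does **not** model isotope structure, adducts other than protons,
chemical noise, detector saturation, or gas-phase unfolding of high-charge
monomers. A green recovery test therefore establishes that the analysis
inverts its own stated world — not that it would resolve every ambiguity of
real spectra, where peak shapes, adducts and unfolded conformers add
overlap the generator omits.

Calibrant tables are generated from a known power law with a globular-scaling
CCS assignment (3.8·m^(2/3), small per-charge expansion) over a
melittin/ubiquitin/β-lactoglobulin-like mass ladder. Sphere-cluster
structures provide geometry oracles: `merged` conserves volume exactly
(radius r₁·n^(1/3)), so its cross-sections recover the 2/3 exponent to
machine precision; `chain` is the elongated counterpart.

## Numerical decisions

* OLS everywhere (`numpy.polyfit`); no weighting, no robust loss — matching
  the conventions of the calibration protocol and keeping every fit exactly
  testable against closed forms.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); the pipeline itself draws none, so reruns
  are byte-identical.
* Equal family deviations in classification break ties by family order
  (I₂, I₃, L) — relevant only at the n = 4 breakpoint where I₃ and L
  coincide by construction.
* Floats in generated CSV/TSV inputs are written at %.17g and read with
  round-trip parsing so that write→read is exact.
* Degenerate inputs raise `ValueError` with the violated constraint named;
  pipeline stages wrap failures in stage-tagged errors with distinct exit
  codes.

## Known limitations

* Per-state enrichment at single-charge-state high oligomers is
  noise-sensitive (ladder ghosts, above); use the aggregate.
* PA-CCS and the compactness score are comparative, not absolute,
  observables.
* Only multi-model PDB is accepted for conformational ensembles; no
  trajectory formats.
* The deviation profile requires an I₃ anchor; datasets with no z = 3
  monomer fall back to any isotropic family present.
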