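# Methods

`sirnakit` analyses how a fixed 2'-O-methyl / 2'-fluoro chemical
modification template interacts with siRNA sequence to determine duplex
stability and silencing activity.  Real molecular-dynamics trajectories
of these duplexes are expensive and not redistributable, so the package
pairs exact, data-driven components (the curated duplex table and
nearest-neighbor thermodynamics) with a synthetic structural stage that
emulates the statistical features of duplex ensembles at desk scale.
This note records the models, the tunable parameters, and the limits of
what the synthetic stage can show.

## Dataset and activity rule

The packaged table holds 15 parent/modified duplex pairs (11 targeting
SERPINA6, 4 targeting AGT): 21-mer strands with a 19-bp core, 3'-dTdT
overhangs, in vitro IC50 (nM) and UV-melting Tm (degrees C).  Modified
strands follow one template: 2'-F at guide positions 2, 6, 14, 16 and
passenger positions 5, 7, 8, 9; 2'-OMe everywhere else in the core.
IC50 values above the assay ceiling are stored as an explicit censored
state, never as the number 100; they take part in classification but
are excluded from every correlation and regression.

A modified duplex is *inactive* when its IC50 is censored or at least
100-fold above its parent's, otherwise *active*.  On the packaged table
this yields 8 active and 7 inactive duplexes, and a three-way loss
binning of 6 censored / 4 moderate (>10-fold, measurable) /
5 unaffected.  The fold-change boundary uses ">= 100 means inactive";
no tabulated pair sits on the boundary, so the choice of closed side
is immaterial here.

## Nearest-neighbor thermodynamics

Duplex formation enthalpy and entropy are sums of the 18 core
dinucleotide-stack increments plus a helix-initiation term and one
terminal penalty per A:U core end, using the published Watson-Crick RNA
parameters at the 1 M NaCl reference (shipped as a checksummed data
file; all 16 stacks resolve to 10 unique entries by reverse-complement
symmetry).  Free energy: dG37 = dH - 310.15 dS / 1000.  Melting
temperature of a non-self-complementary duplex:
Tm(K) = 1000 dH / (dS + R ln(CT/4)) at CT = 4 uM total strands (the
2 uM duplex melting condition).  No salt correction is applied by
default; an optional entropy shift proportional to phosphate count and
ln[Na+] is available.  Because the acceptance statistics are
correlations, the constant offset between the 1 M reference and the
PBS measurement condition is immaterial.

Modified duplexes are scored with unmodified increments; the model has
no 2'-OMe/2'-F terms, so its absolute predictions are most faithful for
parents (predicted vs measured parent Tm correlates at r = 0.99 here).

The positional decomposition assigns position i the enthalpy of its
flanking stacks.  Two conventions are implemented because the exact
published convention is not available: `flank-average` (default; the
mean of the one or two flanking stack dH values) and `flank-sum`.  The
default was calibrated once against the reported band for inactive
duplexes at guide position 2 (-9 to -14 kcal/mol), which flank-average
reproduces.  Note that summing the flank-sum profile double-counts
every stack (each stack flanks two positions), so that total equals
exactly twice the stack sum.

Per-stack "predicted Tm" features push each stack's increments plus the
initiation term through the two-state Tm relation.  Single stacks do
not melt two-state; the value is a relative stability ranking feature.

## Synthetic structures and ensembles

The builder constructs an idealized A-form duplex: Watson-Crick
base-pair templates placed on a helix with rise 2.81 A and twist
32.7 degrees per step, pair planes normal to the axis (zero
inclination or displacement; fiber-derived rise/twist are kept, the
other fiber parameters are dropped for simplicity).  Base geometry
uses regular-polygon rings with standard bond lengths; the relative
pose of each pair is solved once by least squares against canonical
hydrogen-bond distance constraints, with donor-H-to-acceptor spacings
weighted up so every designed pair forms near-linear hydrogen bonds
(3 for G:C, 2 for A:U) under the package's own detection criteria.

Sugars are two-state: ring templates are generated at pseudorotation
phases near 18 degrees (C3'-endo, the default state) or 162 degrees
(C2'-endo), with puckering realized as cosine out-of-plane
displacements around a regular pentagon and the phase calibrated
against the package's own pseudorotation classifier.  The glycosidic
torsion is set per pucker state (chi = -158 deg for C3'-endo, -100 deg
for C2'-endo, both anti), so pucker flips also carry the chi shift
observed between the conformer classes.  2'-OMe adds the O-methyl
group (+3 atoms vs 2'-OH), 2'-F replaces the 2'-hydroxyl (-1 atom),
and dT uses deoxyribose plus thymine.  Phosphate branches and 2'
substituents are aimed radially outward so the backbone and the methyl
groups face solvent, which is why built modified duplexes always show
larger SASA and volume than their parents.  Backbone connectivity
between consecutive residues is approximate; no bonded energies are
ever computed, so only nonbonded geometry matters.

`synthesize_ensemble` draws statistically independent frames (no
kinetics, no solvent, no time axis):

* **pucker flips** — each residue is C2'-endo with its target occupancy
  (independent Bernoulli per frame), geometrically realized by swapping
  the precomputed N/S sugar blocks;
* **terminal fraying** — each terminal core pair opens with probability
  `fray_prob` by displacing its guide base 7 A along the glycosidic
  direction, beyond hydrogen-bond range;
* **thermal noise** — isotropic Gaussian displacement of every atom,
  default sigma 0.1 A.

The noise default deserves a comment: per-atom *independent* noise is
not the same thing as the collective RMSF of a trajectory.  Sigma was
chosen so that endocyclic torsion perturbations stay well inside the
72-degree pucker classification windows (at 0.1 A about 2% of frames
fall outside both windows and classify "other"); much larger values
degrade ring geometry into unclassifiable noise, which no physical
ensemble does.  Occupancy recovery is therefore reported as the
C2'-endo fraction of the two-state (classifiable) frames, which is an
unbiased estimate of the Bernoulli parameter.  Identical
(duplex, spec, seed) triples give bit-identical frames.

Ensembles round-trip through multi-model PDB (MODEL/ENDMDL, guide =
chain G, passenger = chain P); on read, nonbonded parameters are joined
by (residue name, atom name) and an unresolvable atom is an explicit
error.

## Features

All features are rotation/translation invariant functions of a frame.
Defaults (all exposed as keyword arguments, all pinned in regression
tests): hydrogen bond = donor-acceptor <= 3.5 A and donor-H-acceptor
angle >= 135 deg (closed boundaries; donors are N-H/O-H groups found by
nearest-heavy-atom assignment within 1.4 A, acceptors are N/O/F without
hydrogens, intra-residue contacts excluded); NBP counts residue pairs
with >= 2 base-base hydrogen bonds; base stack = ring-centroid distance
<= 4.5 A with inter-normal angle <= 30 deg; Shrake-Rupley SASA on a
960-point deterministic Fibonacci lattice with probe 1.4 A; volume by
0.5 A voxelization of the van der Waals union, density =
mass/volume x 1.66054; RMSD by covariance-SVD superposition
(reference = first frame by default); pseudorotation by the standard
endocyclic-torsion relation with windows C3'-endo [-18, 54) and
C2'-endo [126, 198) and near-flat rings (amplitude < 5 deg) classified
"other"; chi = O4'-C1'-N9-C4 (purines) / O4'-C1'-N1-C2 (pyrimidines).
The common shorthand "chi (O4'-C1'-N-C1)" conflicts with the IUPAC
atom choice; the IUPAC atoms are used.

## Energies

Strand-strand interaction energy is dE = dEel + dEvdW + dEsolv over
cross-strand atom pairs: Coulomb with k = 332.0636 kcal A/(mol e^2),
Lennard-Jones 12-6 with Lorentz-Berthelot mixing, and solvation as a
generalized-Born polar cross term (pairwise HCT descreening radii with
offset 0.09 A, dielectric 78.5) plus a nonpolar term
gamma (SASA_complex - SASA_guide - SASA_passenger) with gamma = 0.0054
kcal/mol/A^2.  Born radii are computed once per frame on the complex
and held fixed, which makes the polar term pairwise additive; together
with per-atom SASA attribution (passenger atoms are attributed to the
nearest guide residue) the per-position profile dE_i sums exactly to
the total strand-strand dE.

The parameter table (charges, LJ, masses) is a packaged, internally
consistent approximation in the style of a standard nucleic-acid force
field with added 2'-F/2'-OMe entries.  Two deliberate choices: (1) each
residue is neutralized at assignment time by spreading its net charge
over its heavy atoms — a counterion-condensation surrogate that keeps
strand-strand electrostatics from being dominated by net-charge
repulsion while preserving hydrogen-bond polarity; (2) no claim of
comparability with any simulation force field is made — energies are
meaningful relative to each other within this package.  On built
duplexes the total dE is negative (duplex-forming) and G:C positions
are more negative than A:U positions, the orderings the analysis needs.

Quasi-harmonic entropy diagonalizes the mass-weighted covariance of
atomic fluctuations (frames superimposed on the first frame unless
disabled) and sums quantum harmonic-oscillator mode entropies at T;
zero modes are dropped, and fewer than 3N+1 frames triggers a warning.
Duplex TdS = T(S_complex - S_guide - S_passenger).

## Statistics

Pearson r carries a two-sided p from the t-transform with n-2 degrees
of freedom (cross-checked against a permutation oracle).  Per-position
active/inactive contrasts use Welch's t with Cohen's d (pooled SD) and
report both raw and Benjamini-Hochberg-adjusted p.  The active/inactive
separator is a soft-margin linear SVM (C = 1, configurable), fit on the
full (position, dE_i) plane; per-position 1-D fits are available by
slicing the input.  Feature ranking for ln[IC50] (natural log of nM)
is a ridge regression on standardized features with the penalty chosen
by leave-one-out cross-validation, ranked by |standardized weight| with
ties broken by column order; a lasso or linear SVR can be swapped in by
the caller since the interface only consumes (features, response).

## What the synthetic stage does and does not show

Passing tests demonstrate internal correctness (oracle equivalence of
the numerical kernels, exact energy partitions, recoverability of
generator parameters) and the sequence-driven directional effects:
modified > parent in SASA and volume for all 15 built pairs, G:C
positions more strongly paired than A:U, inactive modified duplexes
carrying more negative position-2 stack enthalpies than active ones,
and seed-region A/U bias among active sequences.  They do not
reproduce trajectory-derived magnitudes: long-time conformational
relaxation, sequence-dependent flexibility, solvent structure, and
force-field-accurate energetics are all outside the generator's model,
so quantities such as absolute interaction energies, entropy
magnitudes, or MD-grade correlation coefficients with IC50 are
internally consistent numbers, not predictions of the measured system.

## Problem sizes

The default analysis operates on the 30 tabulated duplexes (about
1,350-1,430 atoms each when built), 10,000-frame ensembles for
occupancy recovery, 100 seeded replicates for the planted-feature
recovery rate, and 960-point SASA / 0.5 A voxel grids; these sizes keep
a full run in the minutes range on one CPU while leaving binomial and
Monte-Carlo error well inside the asserted tolerances.
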