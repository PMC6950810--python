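# Methods and conventions

This note records the models behind each analysis stage, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that affect results.

## Units and indexing

Lengths are Å, energies kJ/mol, times ps, temperatures K, charges e.
Two interfaces follow the umbrella-sampling literature instead and use
nm for the reaction coordinate and kJ/mol/nm² for spring constants
(`wham_pmf`, `synthetic_data.sample_biased_windows`); the Coulomb
prefactor is f = 138.935458 kJ·mol⁻¹·nm·e⁻² and kT(300 K) =
2.494 kJ/mol (k_B = 0.008314462618 kJ/mol/K). Residue numbers are
1-based as in PDB files; atom indices are 0-based and never appear in
reports.

## Superposition and RMSF

Rigid-body fits are unweighted least squares (Kabsch). No mass
weighting anywhere: the analyses select specific backbone atoms
(N/CA/C), whose masses are similar, and an unweighted fit keeps the
reaction coordinate a purely geometric object. Fits with fewer than 3
atoms or a collinear atom set are rejected.

RMSF uses a two-pass mean: frames are fitted to frame 0, the mean of
the fitted frames is computed, every frame is refitted to that mean and
the mean recomputed. The per-atom RMSF is the RMS deviation from this
final mean; per-residue values are unweighted means over the residue's
selected atoms. The convention is covered by a test asserting RMSF is
invariant under a global rigid transformation of all frames (1e-6 Å).
Whether to use all backbone atoms or N/CA/C only is left to the
analysis selection.

## PCA reaction coordinates and landscapes

The covariance matrix of the analysis-selection coordinates is
accumulated over fitted, concatenated frames (two passes: mean, then
centered outer products — memory stays O((3M)²) regardless of frame
count) and diagonalized with a symmetric eigensolver. Eigenvalues are
clipped at 0 (round-off can produce −1e-17) and sorted descending.
Eigenvector sign is arbitrary; it is fixed by making each vector's
largest-magnitude component positive so projections are reproducible
across runs and BLAS builds. Projection of a single structure yields a
length-1 series, used to place reference conformations on a landscape.

Landscapes are normalized 2D histograms (Σ ρ·Δx·Δy = 1) reported as
ln ρ. Default 50×50 bins; auto-ranges pad the data span by 2%; a
zero-variance axis cannot be auto-ranged and raises with a hint to pass
an explicit range. Empty bins are flagged and serialized as "NA", never
−inf. Iso-density outlines are bin-boundary polylines around the set
{ln ρ ≥ level}; ln ρ is reported as sampled — no reweighting into a
free-energy surface is attempted.

## Contacts and distances

A frame is a contact iff the minimum heavy-atom distance between the
two groups is strictly below the cutoff (default 5 Å); a tie at exactly
the cutoff is a non-contact. Occupancy is the contact fraction over
frames. **No periodic-boundary treatment is applied anywhere**: inputs
must be whole, unwrapped molecules. Raw output of a periodic simulation
box must be unwrapped before analysis, otherwise distances across the
box boundary are wrong.

Distance monitors take explicit (chain, residue number, atom name)
triples — nothing is hard-coded, since reference numbering schemes
differ between structures. The tRNA-elbow monitor accepts both the
ASCII (O3') and typographic (O3′) primes. Running averages are centered
moving means with truncated edges; the window must be odd.

## Monte Carlo volume overlap

Atoms are spheres of their van der Waals radius; radii come from a
user-editable parameter table keyed by (residue_name, atom_name) with a
Bondi-radius element fallback. The Bondi set is this package's default
and is documented as such, not asserted to match any force field — pass
a table to reproduce a specific radius assignment.

The integration box is the axis-aligned extent of the atom centers
padded by `box_padding` (default: the maximum radius of the integrated
atoms), and is additionally widened if any sphere would be truncated.
By default all three volumes V_A, V_B, V_AB of the overlap identity
V_overlap = V_A + V_B − V_AB are estimated on one common random point
stream: the identity then holds exactly point-by-point, V_overlap ≥ 0
always (a point in both groups is in each), the estimate is
lower-variance, and overlap symmetry under group swap is exact. An
independent-stream mode (`common_stream=False`) replicates the literal
three-independent-integrations protocol. The reported standard error is
binomial: box_volume · √(p(1−p)/n). The RNG is a seeded PCG64; the seed
is recorded in every result. Snapshot scans preselect receptor atoms
within `neighbor_cutoff` (default 10 Å) of the probe before
integrating, and accept `fit_selection=None` for frames already in the
reference frame.

## Interaction enthalpies

Per frame, over all cross pairs (a∈A, b∈B) with r ≤ cutoff (default
1 nm): Coulomb f·qₐq_b/(ε_r·r) plus Lennard-Jones 4ε[(σ/r)¹²−(σ/r)⁶]
with Lorentz–Berthelot combination (σ arithmetic, ε geometric). This is
a plain real-space cutoff sum — no Ewald/PME and no switching function.
For group–group interaction enthalpies this is the standard
decomposition approximation; absolute values differ from a
PME-consistent rerun by the neglected long-range tail, which is why the
correlation of the enthalpy with a distance series (Pearson) is the
recommended readout rather than absolute enthalpies. Groups must be
disjoint moieties; no intramolecular exclusion lists are applied. Pairs
closer than 0.1 Å abort with the pair and frame named. Group order is
canonicalized internally so the sum is bitwise symmetric in (A, B).
Summary statistics over per-simulation correlation coefficients use the
sample SD (n−1); a single coefficient has its SD flagged undefined.

## WHAM

Windows carry nm-valued samples under harmonic biases ½k(x−c)². The
self-consistent equations are iterated in log space (logsumexp) until
the maximum change of the window free-energy constants is below
`tolerance` (default 1e-6 kJ/mol, max 10⁵ iterations; non-convergence
raises with the residual). Defaults: T = 300 K (the analysis
temperature is configurable; 300 K is the conventional default),
100 bins spanning the window-center range ± 3 bias standard deviations
(sample span for unbiased windows). Samples outside the binned range
are dropped. Windows whose sample supports do not form a connected
overlap graph raise — a disconnected profile has undefined relative
offsets. The PMF is −kT ln ρ shifted to minimum 0; never-visited bins
are flagged, not −inf.

Bootstrap errors resample each window's retained samples with
replacement (within-window bootstrap — the alternative of resampling
whole windows estimates a different, between-window variance), rerun
WHAM on identical bins, align each replicate's minimum to 0, and report
the per-bin SD across replicates (default 300 replicates; a single
replicate is degenerate and yields zero errors with a warning).

Evaluation convention: accuracy statements about reconstructed profiles
are made over the well-sampled region — bins between the 0.5th and
99.5th percentile of the pooled window samples. Outside the sampled
support the estimator is shot-noise dominated (a 3σ tail bin of the
outermost window holds a handful of samples and its −kT ln ρ scatters
by ~1 kJ/mol) and no method can determine the profile there.

The initial-sample discard (equilibration) is a per-window sample
count; converting a discard time requires the output stride and is the
caller's responsibility.

## Subunit rotation angles

The angle is a fit-difference rotation: fit the frame to the reference
on the core selection, extract the least-squares rotation mapping the
reference body coordinates onto the fitted frame's body coordinates,
report θ from trace(R) = 1 + 2cos θ signed by the rotation axis'
projection onto a user-declared reference axis (positive =
counterclockwise viewed from the axis' positive end; range (−180°,
180°]). This is a self-contained definition, not a replication of any
particular published axis convention, so absolute angles are comparable
only within one choice of reference structure and axis; the 0° origin
is the supplied reference (conventionally the classical, unrotated
state). Composition (two successive rotations add) and decoupling (a
rigid rotation of body+head registers zero head swivel when the body is
the fit core) are covered by tests.

## Synthetic generators: what they emulate, and what they do not

`generate_hinge_trajectory` builds domains as cubic lattices of
pseudo-backbone N/CA/C triplets at 3.8 Å Cα spacing — no
stereochemistry, bonds, or side chains, since no downstream stage needs
them. Domain 1 moves along a planted unit mode (a linearized rigid
rotation about a hinge axis at the domain-1/2 boundary) with a
per-frame amplitude series (default: three sine periods, amplitude
3 Å); isotropic Gaussian jitter (default σ = 0.03 Å) is added to every
coordinate. The default jitter is chosen so the planted mode dominates
the mobile-domain covariance by better than 10³:1 in variance — the
regime the generator is contractually meant to produce (component-1
alignment |cos| > 0.99, projection correlation > 0.999). Real
trajectories have correlated, anisotropic fluctuations one to two
orders of magnitude larger; passing the recovery tests therefore shows
the estimator chain is correct, not that real data would be this clean.
Planted "coupled" interface atom pairs are chosen so the geometric
derivative of their distance along the mode matches the requested sign
(one interface opens while the other closes); their noiseless distance
series are recorded as ground truth. Generators are deterministic per
spec+seed, and the ground-truth sidecar (JSON) records the full spec.

`sample_biased_windows` draws exact Gaussian samples for flat/harmonic
potentials (biased density is Gaussian: variance kT/k, or kT/(a+k) with
mean kc/(a+k) for U = ½ax²). Double-well/tabulated potentials use
overdamped Euler–Maruyama dynamics with γ = 1, step 0.1/(k + max|U″|)
(so kΔt/γ ≤ 0.1), burn-in ten bias relaxation times, subsampling every
10 steps; moves with energy jumps > 20 kT are counted and more than 1%
of them aborts with advice to shrink the step. Brownian samples are
correlated — population ratios are reliable, per-sample independence is
not assumed by any test.

`generate_overlap_fixture` pairs a fixed probe sphere with a receptor
sphere translating along x; the analytic sphere–sphere lens volume
π(r₁+r₂−d)²(d²+2d(r₁+r₂)−3(r₁−r₂)²)/(12d) (smaller-sphere volume for
d ≤ |r₁−r₂|, 0 for d ≥ r₁+r₂) is the recorded ground truth, verified
during development against a 400³ grid integration.

## Pipeline

One YAML config drives one run: selections are labeled strings
("chain:start-end[,start-end][:NAMES]"), stages execute in the fixed
order contacts → rmsf → pca → distance → landscape → overlap →
enthalpy → wham, outputs are TSVs written via a `.partial` rename so a
crashed stage never leaves a truncated file, and the manifest records
package version, seed, parameters and SHA-256 checksums of the inputs.
Identical config + seed reproduces every output byte-identically.

## Problem sizes used in the shipped checks

Mode recovery: 2000 frames × 300 analysis atoms. WHAM: 51 windows ×
10⁴ samples, 100 bins, 300 bootstrap replicates. MC volumes: 10⁶
points (single sphere, disjoint pair) and 10⁷ points (lens). Brute
-force oracles run on ≤ 50-atom systems. These sizes give oracle
discrepancies far below the asserted bounds while keeping the whole
suite in the tens of seconds.

## Known limitations

- No periodic-boundary handling; inputs must be unwrapped.
- Coulomb sums are plain cutoff; absolute interaction enthalpies are
  not PME-consistent (correlations are the robust readout).
- No analytic union-of-spheres volume; MC error is binomial only (no
  quasi-random variance reduction).
- WHAM is 1D with harmonic biases; no MBAR, no autocorrelation-based
  inefficiency weighting.
- Rotation angles follow this package's fit-difference definition;
  absolute values are not comparable across other axis conventions.
- PDB parsing keeps the highest-occupancy altloc and the first model;
  no mmCIF writer, no bond perception.
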