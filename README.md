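# domainmotion

Analysis toolbox for interdomain motion in molecular-dynamics
trajectories, built around the workflow used to characterize how a
multi-domain GTPase (EF-Tu) rearranges on the ribosome after GTP
hydrolysis: a domain rotates about a hinge helix, one domain interface
opens while another closes, an antibiotic (kirromycin) can sterically
block the closure, and the associated free-energy profile can be
reconstructed from umbrella sampling.

It is aimed at structural-bioinformatics users who have trajectories (or
deposited structures) and want the standard post-processing quantities
without a full simulation stack.

## What it computes

- **PCA reaction coordinates** (`pca_landscape`): frames are rigid-body
  fitted to a reference on a "core" selection (e.g., backbone N/CA/C of
  the static domains), the covariance matrix **C** of the mobile-domain
  coordinates is diagonalized, and the per-frame projection
  *q(t) = (x(t) − ⟨x⟩)·v₁* onto an eigenvector serves as a collective
  reaction coordinate. 2D log-probability-density landscapes
  ln ρ(q, d) and iso-density outlines place conformations on that map.
- **RMSF and contact occupancy** (`superpose`, `contacts_distances`):
  per-residue root mean-square fluctuation about the fitted mean
  structure; occupancy = fraction of frames in which the minimum
  heavy-atom distance between a residue and a target group (e.g., a
  nucleotide β-phosphate) is below 5 Å.
- **Residue-distance monitors** (`contacts_distances`): Cα–Cα interface
  distances, the tRNA-elbow O3′–O3′ distance, running averages.
- **Monte Carlo van der Waals volume overlap** (`mc_volume`):
  V = (points inside ≥1 sphere)/(total points) × (box volume), and
  V_overlap = V_A + V_B − V_AB for a probe (e.g., an antibiotic pose)
  against receptor snapshots — the steric-block test.
- **Interaction enthalpies** (`energetics`): cutoff Coulomb +
  Lennard-Jones (Lorentz–Berthelot) sums between disjoint atom groups,
  and their Pearson correlation with distance series.
- **WHAM free-energy profiles** (`wham_pmf`): self-consistent weighted
  histogram analysis over harmonically biased umbrella windows
  (½k(x−c)², k in kJ/mol/nm²), PMF = −kT ln ρ shifted to min 0, with
  within-window bootstrap errors.
- **Subunit rotation angles** (`subunit_rotation`): signed rigid-body
  rotation of a body selection relative to a fitted core (30S body
  rotation / head swivel style).
- **Synthetic generators** (`synthetic_data`): a planted-hinge toy
  protein, exact Boltzmann samples from biased 1D potentials, and
  analytic sphere-overlap fixtures — every analysis stage is testable
  against known ground truth without downloads.

## Worked example

Generate a hinge trajectory with a planted mode and recover it:

```python
import numpy as np
import domainmotion as dm

spec = dm.HingeSpec(residues_per_domain=40, n_frames=1000, seed=42,
                    coupled_distance_signs=(1, -1))
trajectory, truth = dm.generate_hinge_trajectory(spec)
r1, r2, r3 = truth.domain_residue_ranges
fit_sel = dm.select_residues(trajectory.topology, "A", [r2, r3],
                             atom_names={"N", "CA", "C"}, label="D2+D3 backbone")
analysis_sel = dm.select_residues(trajectory.topology, "A", [r1], label="D1")

model = dm.build_pca(trajectory, trajectory.topology, fit_sel, analysis_sel)
proj = dm.project(model, trajectory, 0)
alignment = abs(model.eigenvectors[0] @ truth.mode_for(analysis_sel))
print(f"component-1 alignment with planted mode: {alignment:.4f}")
print(f"variance explained by component 1: "
      f"{model.eigenvalues[0] / model.eigenvalues.sum():.4f}")

ia, ib, sign = truth.coupled_pairs[1]
top = trajectory.topology
d = dm.residue_distance(
    trajectory,
    ("A", int(top.residue_numbers[ia]), str(top.atom_names[ia])),
    ("A", int(top.residue_numbers[ib]), str(top.atom_names[ib])),
)
print(f"corr(reaction coordinate, closing interface distance): "
      f"{np.corrcoef(proj.values, d.values)[0, 1]:+.3f}")
```

prints

```
component-1 alignment with planted mode: 1.0000
variance explained by component 1: 0.9318
corr(reaction coordinate, closing interface distance): +0.954
```

The leading covariance eigenvector coincides with the planted hinge mode
(cosine 1.0000); it carries 93% of the mobile-domain variance (the rest
is the isotropic thermal jitter, spread over the remaining modes); and
the reaction coordinate tracks the planted interface distance (the sign
of an eigenvector, hence of the correlation, is conventional — the
package fixes it by making the largest eigenvector component positive).

The same operations are available from the shell via the `dm` CLI
(`dm simulate hinge`, `dm pca`, `dm rmsf`, `dm distance`, `dm wham`,
`dm overlap`, `dm run --config run.yaml`, …); `dm run` writes every
stage's TSV plus a manifest with seeds and input checksums so a run is
byte-for-byte reproducible.

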