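# Methods

This note records the models, conventions and design choices behind each
stage of the pipeline, what the synthetic generator does and does not
emulate, and the numerical decisions a user should know before trusting or
extending the results.

## Data model and conventions

Coordinates are held in Å throughout; XTC input (stored in nm) is converted
on read. Author residue numbering and chain identifiers are preserved
end-to-end — including non-contiguous numbering — so outputs can label
residues the way the source structure does (D27, R151, C459). Altloc groups
collapse to the highest-occupancy conformer at parse time. Atom order is
stable: every matrix, selection and trajectory indexes into the topology
order, and selections are deterministic and idempotent.

Each trajectory carries an `analysis_start` index: the equilibration
discard. Every statistic (RMSF, DCCM, PCA, occupancies, energies, networks)
uses frames from `analysis_start` on; the RMSD series alone covers all
frames, since it is the diagnostic used to choose the cut. Frame stride for
the expensive stages (SASA, energies) is a configuration knob, not something
inferred from the data.

## Superposition and fluctuation metrics

Rigid-body fits minimise unweighted least squares via the Kabsch/SVD
construction with the determinant corrected to +1 (no reflections);
collinear references are rejected as rank-deficient. The fit selection and
the measurement selection may differ (fit on Cα, measure anywhere).

RMSF supports two references one flag apart: the atom's position in the
first analysis frame (default) and its trajectory mean. The conventions
differ — the initial-reference value is never smaller — so writers record
which was used. Fluctuations are measured after superposing each frame onto
the first analysis frame unless `fit=False`.

## Dynamic cross-correlation

C_ij is the normalised covariance of full 3-D displacement vectors (not
per-axis), with displacements taken about the trajectory mean after
frame-wise superposition — the common convention in trajectory toolchains;
an initial-structure reference is available by flag. Atoms with numerically
zero variance get NaN rows/columns (reported missing, never 0). The 0.3
display mask exists purely for presentation: network edge weights always use
the unmasked matrix.

## Essential dynamics

PCA is the eigendecomposition of the 3N×3N covariance of superposed
Cartesian coordinates. A "shared space" for two systems is built by pooling
their post-equilibration frames, each superposed to one common reference;
projecting system B onto system A's modes is the alternative construction
and remains available by calling `project` with A's model. Eigenvector signs
are fixed (largest-|loading| positive) so projections are reproducible
across runs and platforms. With fewer frames than 3N the covariance is
rank-deficient; the fit warns and the trailing eigenspace is degenerate —
only the leading, well-separated spectrum is meaningful.

Free-energy landscapes use G_i = −k_B T ln(N_i/N_max) with
k_B = 0.0019872041 kcal·mol⁻¹·K⁻¹ and T defaulting to 310 K (the simulated
temperature). The most populated bin is exactly 0; empty bins are undefined
(NaN), not capped — a plotting layer may cap them. Default grid 100×100 in
PC space. k-means on projections uses k-means++ with 50 restarts and a fixed
seed; clusters are reported largest-first with medoid (nearest-to-centroid)
frames; k defaults to 5.

## Interactions and surfaces

SASA is Shrake–Rupley quadrature on spheres of radius r_atom + probe
(probe 1.4 Å) with a deterministic golden-spiral point set (960 points
default; doubling changes a converged surface by <0.5%). Radii come from the
parameter table when present, else a Bondi-like element table. Interface
area uses the half-buried-surface convention,
(SASA_A + SASA_B − SASA_AB)/2, stated in the output header because the
alternative ×2 convention is equally common.

Occupancies are exact frame counts — occupancy × frames is an integer; no
smoothing. Criteria: residue contact, minimum heavy-atom distance ≤ 4.5 Å;
hydrogen bond, donor–acceptor ≤ 3.5 Å plus D–H···A ≥ 135° when hydrogens
exist (the heavy-atom fallback is recorded in output metadata); salt bridge,
anion carboxylate O to cation N ≤ 4.0 Å, where Arg contributes its terminal
guanidinium nitrogens (NE is treated as an H-bond donor instead — the
criteria are deliberately disjoint enough that one residue pair can carry
both interaction types with independent occupancies); hydrophobic, apolar
side-chain carbon pair ≤ 4.5 Å. Two distinct persistence thresholds exist on
purpose: "stable" interactions at ≥0.70, and network edges at ≥0.75; both
inclusive, both configurable, never mixed.

## Binding energetics

Single-trajectory end-point protocol: receptor and ligand conformations are
the complex frames, so bonded/internal terms cancel and ΔE_int is reported
as exactly 0. Cross-group electrostatics use Coulomb's law with
332.0636 kcal·Å·mol⁻¹·e⁻² and the solute dielectric (default 1); LJ is in
r_min/ε form (ε_ij geometric mean, r_min additive) over all cross pairs with
no cutoff — the systems are small enough that a cutoff would only add a
convergence knob.

The polar solvation slot is a generalized-Born model: Still's pairwise
functional with f_ij = √(r² + R_iR_j·exp(−r²/4R_iR_j)) and
Hawkins–Cramer–Truhlar pairwise-descreening effective radii with no radius
offset and a uniform screening factor (0.8 default). With no offset an
isolated atom's effective radius equals its intrinsic radius, so the Born
ion is analytic — the anchor for exact testing. The slot is an interface: a
Poisson–Boltzmann backend could replace it without touching the ledger
around it. Solvent dielectric 80, zero ionic strength. The nonpolar term is
the linear SASA relation γ·SASA + b with γ = 0.00542 kcal·mol⁻¹·Å⁻² and
b = 0.92 kcal/mol. The conformational-entropy term is excluded and the field
says so explicitly, so the energy ledger
(ΔE_MM = ΔE_vdW+ΔE_ele+ΔE_int, ΔG_sol = ΔE_polar+ΔE_nonpolar,
ΔG = ΔE_MM+ΔG_sol) holds to machine precision per frame.

Per-residue decomposition attributes every pairwise term half to each
partner residue; GB self terms follow their atom; the SASA term follows each
atom's buried area, with the single leftover −b offset spread evenly over
residues. Rows therefore sum to the total exactly (tested to 0.05 kcal/mol
against independently computed totals).

## Community networks

Nodes are residues (Cα-anchored labels `chain:resnum`); an edge requires
contact persistence ≥0.75 (heavy-atom criterion by default; Cα–Cα mode
exists for sensitivity checks but at 4.5 Å excludes nearly all non-bonded
pairs). Edge length is −log|C_ij|: the absolute value is required because
anti-correlations would otherwise have undefined weights, and |C| is floored
at 1e-6 so weights stay finite (the floor is recorded). Consecutive-residue
edges are retained by default.

Girvan–Newman removes the edge of maximal weighted-shortest-path betweenness
(Brandes; recomputed only within the affected component, which is exact),
snapshots the component partition whenever connectivity changes, and keeps
the snapshot of maximal Newman–Girvan modularity (computed on the original
unweighted edge structure). The divisive sequence stops after
`max_communities` components (default unlimited; the pipeline uses 30) —
the modularity peak of any modular graph sits far earlier. Communities
smaller than 3 residues are omitted from reports; memberships are still
recorded. Intercommunity coupling is Σ|C_ij| over crossing edges.

## The synthetic generator

The generator stands in for undeposited production MD. It emulates exactly
the statistical features the pipeline consumes:

- two bead chains across a 7.5 Å interface gap, ligand M numbered 1–91 and
  receptor P with gapped author numbering (145–170, 230–250, 450–470), so
  the planted interactions carry the labels D27-K237, D28-R235, D28-K239,
  F81-Y152, E82-R151 and hub C459;
- Gaussian residue fluctuations with block covariance (within a block the
  planted pairwise correlation is exactly ρ = σ_shared²/σ_total²);
- collective modes with Gaussian amplitudes — an interface "breathing"
  translation and a sine-shaped internal wave — plus a deterministic
  approach/departure drift of the receptor chain;
- interaction schedules: each planted pair is ON in exactly k = occ·F frames
  chosen by a seeded permutation; on ON frames the follower atom sits at the
  bound distance from its anchor partner (inside its criterion, outside the
  others), on OFF frames at 8 Å plus an out-of-plane offset. Polar
  occupancies are therefore exact rationals regardless of the noise level,
  because only controlled atoms enter those criteria. Contact-type
  occupancies additionally depend on backbone bead distances, so exactness
  tests for them use the quiet fixture (no collective modes, amplitude
  0.25 Å), while full-scenario tests assert direction only;
- community structure: intra-block (i, i+2) contact schedules densify each
  covariance block into a graph community; a hub residue's contacts stitch
  the interface community together in the wt-like arm and are deleted in the
  mutant-like arm.

Default study conditions: 500 frames per system, 310 K, thresholds as above.
The wt-like/mutant-like contrasts (occupancy levels patterned after a
destabilised-interface comparison, narrow basin vs one dominant mode,
approaching vs departing drift, hub intact vs deleted) are the only planted
differences between the arms.

What the generator does **not** emulate: force-field-consistent dynamics,
kinetics, solvent, secondary structure, or realistic side-chain geometry.
The trajectories are Gaussian ensembles; passing tests demonstrate that each
analysis stage recovers known statistical structure at realistic magnitudes,
not that the pipeline's numbers would match any particular real system. In
particular the binding energies are on the scale of tens of kcal/mol only
because the planted charge pairs make them so; their absolute values carry
no physical meaning.

Dispersion parameters live on the backbone beads only (side-group
pseudo-atoms carry charge and GB radii but no LJ well): scheduled approaches
of planted atoms then cannot create steric-clash spikes in the energy
average, while bead–bead packing still gives the vdW term its distance
dependence.

## Problem sizes and runtime choices

The shipped analyses run at 500 frames, ~160 residues and ~340 atoms per
system; SASA-bearing stages subsample frames (stride 10–25) and the
scenario-level binding energy averages every 5th frame with a 240-point
quadrature — the scheduled electrostatics toggle per frame, so the energy
mean needs samples more than quadrature accuracy. All stages are exact in
the frame set they are given; strides only trade statistical precision.

## Known limitations

- The PB polar term is a GB surrogate; absolute solvation energies differ
  from a grid PB solver, though the decomposition machinery is agnostic.
- Heavy-atom hydrogen-bond detection (no angle term without hydrogens)
  over-counts borderline donor–acceptor approaches.
- Girvan–Newman with max-modularity stopping can split large, loosely knit
  blocks into sub-communities; the planted-structure tests pin down the
  regimes where recovery is exact.
- Mass-weighted fitting is not implemented (uniform weights; the intended
  inputs are Cα-like selections).
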