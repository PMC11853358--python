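# ppidyn

Comparative trajectory analysis for two-chain protein complexes.

`ppidyn` implements the standard post-processing workflow used to explain why
a binder (here, a monobody-like ligand chain) holds one receptor variant more
stably than a point mutant: fluctuation metrics, dynamic cross-correlation,
essential dynamics, interface geometry and interaction occupancies,
implicit-solvent binding energetics, and residue community networks — plus a
synthetic-trajectory generator with fully known planted structure, so every
stage can be validated against ground truth even when the original production
trajectories are not available.

## What it computes

For a complex of a ligand chain **M** and a receptor chain **P** with frames
x(t):

- **RMSD / RMSF** after least-squares (Kabsch) superposition, with the
  fluctuation reference selectable between the initial structure and the
  trajectory mean.
- **Dynamic cross-correlation matrix (DCCM)** of Cα displacement vectors:
  C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨Δr_i²⟩⟨Δr_j²⟩) ∈ [−1, 1].
- **Essential dynamics**: eigendecomposition of the 3N×3N Cartesian
  covariance; variance fractions λ_i/Σλ, projections, subspace similarity
  RMSIP = √((1/k)ΣΣ(α_i^A·α_j^B)²), overlap matrices, porcupine vectors, and
  free-energy landscapes G_i = −k_B T ln(N_i/N_max) over any two reaction
  coordinates, with k-means representative conformations.
- **Interactions**: Shrake–Rupley SASA, buried interface area
  (SASA_A + SASA_B − SASA_AB)/2, and exact frame-count occupancies of
  contacts (≤4.5 Å), hydrogen bonds (D–A ≤ 3.5 Å, D–H···A ≥ 135° when
  hydrogens exist), salt bridges (N–O ≤ 4.0 Å) and hydrophobic contacts; a
  "stable" interaction persists for ≥70% of analysis frames.
- **Binding free energy** (single-trajectory end-point):
  ΔG = ΔE_vdW + ΔE_ele + ΔE_int + ΔE_polar + ΔE_nonpolar, with a
  generalized-Born polar term (Still functional, HCT effective radii; the
  Born-ion limit is exact), ΔE_nonpolar = γ·SASA + b
  (γ = 0.00542 kcal·mol⁻¹·Å⁻², b = 0.92 kcal/mol), ΔE_int ≡ 0 by protocol,
  and the conformational-entropy term excluded; plus a per-residue
  decomposition whose rows sum to the total.
- **Community networks**: residues as nodes, edges for pairs within 4.5 Å in
  ≥75% of frames, weighted d_ij = −log|C_ij|; Girvan–Newman divisive
  communities kept at maximum modularity (minimum reported size 3), weighted
  betweenness, and intercommunity coupling strengths.

## Worked example

```python
from ppidyn.pipeline import scenario_contrasts

c = scenario_contrasts(seed=3)
print(f"RMSD      wt {c['wt']['rmsd_mean_A']:.2f} A   mut {c['mut']['rmsd_mean_A']:.2f} A")
print(f"dG_bind   wt {c['wt']['dG_binding_mean']:.1f}     mut {c['mut']['dG_binding_mean']:.1f} kcal/mol")
print(f"PC1 frac  wt {c['wt']['pc1_variance_fraction']:.2f}   mut {c['mut']['pc1_variance_fraction']:.2f}")
key = (('M', 82), ('P', 151), 'saltbridge')
print(f"E82-R151  wt {100*c['wt']['planted_polar_occupancies'][key]:.1f}%  "
      f"mut {100*c['mut']['planted_polar_occupancies'][key]:.1f}%")
```

prints

```
RMSD      wt 0.84 A   mut 1.33 A
dG_bind   wt -31.3     mut -13.8 kcal/mol
PC1 frac  wt 0.22   mut 0.79
E82-R151  wt 77.8%  mut 3.4%
```

The wild-type-like arm fluctuates in a narrower basin (lower RMSD, variance
spread over many components), binds more favourably, and keeps its planted
interface salt bridge occupied at exactly the scheduled fraction; the
mutant-like arm concentrates its motion in one dominant component and loses
the interface interactions. These are the planted contrasts the generator
imposes — the analysis recovers them rather than assuming them.

The `analysis/` directory holds numbered drivers that run the same sequence
step by step on datasets written to disk (generate → fluctuations → DCCM →
essential dynamics → interface/interactions → energetics → network →
comparison report), each writing its tables under `results/`.

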