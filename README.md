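# abdock

Post-docking analytics for antibody–antigen complex prediction.

Predicting how an antibody engages its antigen is still hard: physics-based
docking generates hundreds of candidate poses, AI structure predictors attach
confidence estimates to their models, and the practical questions are always
the same — *which pose do I trust, how good is it really, and what kinds of
interfaces does my pipeline fail on?*  `abdock` implements the analytics layer
that answers those questions for docking campaigns that start from ensembles
of AI-modelled antibodies:

* **Confidence standardization and composite rescoring.**  Antibody-model
  confidences (predicted errors / B-factor-style values) are Z-scored per
  modeling tool and sign-flipped into a *model certainty*.  Docked poses are
  re-ranked by the equal-weight composite

  `composite = Z_pLDDT + Z_pTM + Z_ipTM + Z_phys`

  where the interchain TM-style confidence (ipTM) is computed directly from
  the predicted-aligned-error probability bins:
  `ipTM = max_i mean_{j in other chain} Σ_k p_ijk · 1/(1 + (e_k/d0(N))²)`,
  with `d0(N) = max(1.24·(N−15)^⅓ − 1.8, 1)`.

* **DockQ quality evaluation.**  `DockQ = (fnat + 1/(1+(iRMS/1.5)²) +
  1/(1+(LRMS/8.5)²)) / 3` against a native reference, with the two
  application-specific success regimes: *epitope mapping* (DockQ ≥ 0.23) and
  *antibody design* (DockQ ≥ 0.49).

* **Ensemble RMSD diagnostics.**  Framework-fitted backbone RMSD over CDR
  loops: *free-RMSD* (mean over all model pairs of a free-antibody ensemble),
  *bound-RMSD* (per model against the antigen-bound reference) and
  *best bound-RMSD*.

* **Interface property panel.**  Per-residue relative solvent accessibility in
  the complexed/uncomplexed states (Shrake–Rupley SASA, Tien et al. reference
  areas) classifies residues into interior / surface / support / rim / core;
  the panel reports buried surface area and summed Levy stickiness per region,
  a global packing density (atoms per interface-ellipse area) and a
  surface-complementarity index from opposing surface normals.

* **Benchmark statistics.**  Campaign manifest enumeration, naive vs
  certainty-guided model selection, top-N success rates with bootstrap error
  bars (200 iterations over antibody models), and success-vs-failure
  discriminant statistics (standardized differences + Welch t-tests) over the
  interface panel.

A synthetic fixture module generates deterministic toy complexes, graded pose
decoys with known true DockQ, and confidence bundles with a controllable
quality-correlation ρ, so the whole pipeline runs and is tested entirely
offline.

## Worked example

Rescoring a graded decoy set with correlated confidence bundles:

```python
from abdock import synthetic, confidence, interface

native, ann = synthetic.make_toy_complex(synthetic.ToyComplexSpec(seed=1))
decoys = synthetic.make_pose_decoys(native, n_decoys=10, seed=1)
bundles = [
    synthetic.make_confidence_bundle(d.true_dockq, fidelity=0.8, seed=i,
                                     pose_id=d.pose_id)
    for i, d in enumerate(decoys)
]
ranked = confidence.rescore_poses(bundles)
truth = {d.pose_id: d.true_dockq for d in decoys}
for i, s in enumerate(ranked[:5], 1):
    print(f"{i:>4} {s.pose_id:>18} {s.total:>9.2f} {truth[s.pose_id]:>10.3f}")

panel = interface.interface_property_panel(native)
print(f"interface SA total: {panel.sa_total:.1f} A^2  "
      f"stickiness: {panel.stickiness_total:.3f}  "
      f"GD: {panel.global_density:.3f} atoms/A^2  "
      f"SC: {panel.surface_complementarity:.2f}")
```

prints

```
   1     toy-1-decoy000      9.81      1.000
   2     toy-1-decoy001      4.84      0.694
   3     toy-1-decoy002     -0.05      0.258
   4     toy-1-decoy004     -1.09      0.133
   5     toy-1-decoy003     -1.23      0.214
interface SA total: 368.7 A^2  stickiness: 0.081  GD: 0.137 atoms/A^2  SC: 0.37
```

The composite ranking recovers the true quality ordering almost perfectly at
fidelity 0.8: the native-like decoy (DockQ 1.0) tops the list with a composite
of 9.8 standard-deviation units, and the far-off decoys sink.  The panel line
summarises the native interface: ~370 Å² buried, mildly sticky (poly-alanine
toy chains), with a positive surface-complementarity index.

A thin CLI mirrors the library: `abdock dockq`, `abdock panel`,
`abdock rescore`, `abdock manifest`, `abdock select`, `abdock success`,
`abdock bootstrap`, `abdock discriminants` and `abdock fixtures` (see
`abdock --help`).

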