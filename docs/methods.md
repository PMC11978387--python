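# Methods

This note documents the models, conventions and numerical choices behind
`abdock`, and what the synthetic fixtures do and do not demonstrate.

## Structures and RMSD diagnostics

Structures are read with gemmi (PDB and mmCIF, author numbering preserved);
only the first model's polymer ATOM records are kept, waters and HETATM
excluded, and for alternate locations the highest-occupancy conformer wins
(first on ties).  Chain roles (heavy / light / antigen) come from an explicit
map or a chain-id heuristic (H → heavy, L → light, everything else antigen);
anything the heuristic cannot type is an error rather than a guess.

CDR annotation partitions antibody chains by Chothia residue-number windows
(H1 26–32, H2 52–56, H3 95–102, L1 24–34, L2 50–56, L3 89–97); insertion
codes count as separate residues, so an H3 with insertions at position 100
reports the full loop length.  The numbering scheme is a parameter: metrics
derived from the annotation (H3 length, per-region RMSD) are only meaningful
relative to the scheme used, and no claim is made that any particular
published benchmark used these exact windows.

Superposition is the closed-form least-squares (Kabsch/SVD) fit with a
reflection guard, over backbone atoms (N, CA, C, O) by default.  Region RMSD
fits on one residue set (typically framework) and measures on another
(typically a CDR loop) *without refitting*, which is what makes loop-swing
diagnostics meaningful.  Residue correspondence across models of the same
antibody is by (chain id, residue number, insertion code) — models of one
sequence share numbering, and cross-antibody alignment is out of scope.
Ensemble reports average the framework-fitted region RMSD over all unordered
model pairs (free-RMSD) and against a bound reference (bound-RMSD, with the
per-region minimum as best bound-RMSD).

## Confidence and composite rescoring

Standardization uses the population convention (divide by n, not n−1)
throughout; a population with zero spread is an error for the public
`zscore`, while inside `rescore_poses` a spread-free metric contributes zero
to every pose (all poses identical on that axis carry no ranking signal).
Model certainty is the sign-flipped Z-score of per-model predicted errors,
pooled per modeling tool across systems — tools are never mixed in one
population.

pTM/ipTM are computed from predicted-aligned-error probability bins as the
expected TM-style score `sum_k p_ijk / (1 + (e_k/d0)^2)`, averaged per
aligned residue over the masked partners and maximised over residues.
`d0(N) = 1.24 (N−15)^{1/3} − 1.8`, clamped at 1.0 Å, with N the number of
residues in scope (the full complex by default; the interchain mask only
changes which j are averaged).  A point-estimate PAE matrix is accepted as a
delta distribution on the nearest bin of a 0.5–31.5 Å grid.

The composite is the strictly unweighted sum of the four standardized
components.  Physics scores are oriented per engine before standardization
(ProPOSE energies are lower-better and sign-flipped; ZDOCK scores
higher-better); standardization scope is the pose population of one
antibody-antigen system, with physics scores standardized per engine by
default — pooling engines' native score scales is rejected unless there is
only one engine.  Ranking ties break deterministically by (total desc,
Z_ipTM desc, pose id asc), preferring interface confidence.

## DockQ

`DockQ = (fnat + 1/(1+(iRMS/1.5)^2) + 1/(1+(LRMS/8.5)^2)) / 3` with the
standard constants: native contacts at 5 Å over heavy atoms, interface
residues at 10 Å, receptor = antibody and ligand = antigen (the antigen is
the docked mobile body; multi-chain antigens are one rigid ligand).  Classes:
acceptable ≥ 0.23, medium ≥ 0.49, high ≥ 0.80.  Bit-exact agreement with any
specific external DockQ release is not a goal; the closed form and its
constants are.

## Interface panel

SASA is Shrake–Rupley sphere sampling with a deterministic golden-spiral
point set (960 points/atom, probe 1.4 Å), Bondi van der Waals radii, summed
per residue over heavy atoms.  Determinism is exact for a fixed point-set
orientation; rigid rotations of the whole complex move atoms relative to the
fixed quadrature directions, so rotational invariance holds only to
quadrature error (≈1% on totals at 960 points).  Relative SA divides by
fully-exposed Gly-X-Gly reference areas (Tien et al. 2013, theoretical);
values above 100% at termini are reported unclamped.  The uncomplexed state
is the rigid separation of the two sides with coordinates unchanged, so
ΔrSA ≥ 0 holds exactly (same quadrature, fewer occluders).

Classification follows the rSA truth table: interior (rSA_c < 25%, ΔrSA = 0),
surface (rSA_c > 25%, ΔrSA = 0), support (rSA_c < 25%, ΔrSA > 0), rim
(rSA_c > 25%, ΔrSA > 0), core (rSA_u > 25%, rSA_c < 25%, ΔrSA > 0).  Core is
the more specific refinement and takes precedence over support.  Boundary
cases at exactly 25% go to the more exposed class (surface / rim), and
ΔrSA > 0 is tested with a 1e-6 tolerance to absorb quadrature noise.
Whether classification should run per side against its own unbound state or
over the whole complex is genuinely open; each side is classified against its
own uncomplexed state here, which keeps the two sides' panels independent.
Region stickiness sums the Levy et al. (2012) per-residue scale (shipped as a
versioned CSV; missing residue types either raise or skip with a warning).

Global density: interface atoms are those with any SASA loss on
complexation; the centered gyration tensor of their coordinates gives
principal moments λ1 ≥ λ2 ≥ λ3, converted to equivalent uniform-ellipsoid
semi-axes a_i = sqrt(5 λ_i), and GD = N / (π a b) over the two largest axes.
With this convention a uniform disk of radius R gives GD = N / (π R² · 5/4),
which is the oracle the tests pin.  The alternative reading of the
prose-level definition (atoms per ellipsoid *volume*) is exposed behind the
`convention="ellipsoid-volume"` flag; the ellipse-area reading is the default
because an areal density is what a packing proxy at an interface measures.

Surface complementarity tessellates each side's accessible surface (dot
surface, 240 points/atom) restricted to the binding patch — points on
interface atoms that the partner side occludes — and projects the points
back onto the van der Waals spheres, so apposed faces at atomic contact are
near-coincident instead of separated by two probe radii.  Each element is
matched to the nearest element of the opposing patch and the index is the
weighted mean of −(n̂_a·n̂_b) with weights area × exp(−(d/w)²), w = 1 Å,
symmetrised over both directions.  The decay enters the weights as well as
the scores, so distant, poorly apposed patches neither inflate nor dilute the
index; it is bounded in [−1, 1], parallel flat surfaces at contact approach
1, and misaligned ones score lower.  This is a self-contained index with the
stated functional form, not a reimplementation of any specific published SC
program; only orderings and limits are asserted about it.

## Benchmark statistics

Manifest totals are pure dimension products; the shipped default campaign
(81 systems, 3 antibody-modeling tools × 4 models, 2 docking engines × 100
poses) yields 194,400 pose records, 32,400 per ensemble per engine, and a
5 × 5 = 25-model per-system budget for the template-free comparators.

Success is top-N: a system succeeds at a threshold when any of its N
best-ranked poses reaches it (0.23 epitope mapping, 0.49 antibody design);
empty systems count as failures.  Bootstrap error bars resample antibody
models within systems with replacement (200 iterations, percentile 2.5–97.5
interval); resampling whole systems instead is a parameter, since the
stratification of "bootstrapping the models" is ambiguous.  Certainty
filtering drops models below a threshold, excludes systems with no
survivors, reports the surviving count and mean H3 length, and marks results
below 5% representation as suppressed rather than deleting them.
Discriminant statistics use Cohen's-d pooled standard deviations for the
standardized difference and Welch (unequal-variance) t-tests, with the
conventional star coding; groups with fewer than two systems are skipped
with a warning.

## Synthetic fixtures

Toy complexes are idealized poly-alanine-like chains (3.8 Å CA spacing,
backbone N/CA/C/O plus a pseudo-side-chain CB facing the partner) with an
engineered contact patch: the first `interface_size` residue pairs sit
within the contact distance and all other antigen residues are held ≥ 20 Å
away.  A 0.03 Å seeded jitter breaks exact degeneracies while keeping
generation bit-reproducible.  Chain adjacency means the contact set can
include one antibody residue adjacent to the designated window; the antigen
side is exactly the designated window.

Decoys rigidly rotate the antigen about its centroid (seeded random axis)
and translate it along the separation direction per a graded schedule
(default 0–90° and 0–30 Å over n decoys), with true DockQ computed by the
quality module and stored.  Confidence bundles drive each metric by its own
effective quality `q_eff = ρ·q + (1−ρ)·u` (u uniform), so ρ = 1 gives
noiseless strictly monotone links and ρ = 0 quality-independent metrics; the
PAE tensor is a discretized Gaussian (σ = 2 Å) over 1-Å bins whose
interchain mean error decreases with quality.  Problem sizes in tests and in
the acceptance script (10–100 decoys, 100 trials, 200-system certainty
benchmarks) were chosen as the smallest sets where the statistical
assertions are stable across seeds.

What the fixtures emulate: graded pose quality, confidence metrics with
tunable signal, certainty/quality/H3-length correlations.  What they do not:
real side-chain chemistry, docking-engine score distributions, antibody
conformational ensembles, or crystal-structure interfaces.  Passing tests
therefore demonstrate the correctness and internal consistency of the
analytics — standardization, scoring, classification, statistics — not the
field performance of any docking or prediction tool on real complexes.

## Known limitations

* SASA and SC are quadrature-based; rotational invariance is approximate
  (≈1% and ≈0.05 respectively at default point counts).
* CDR windows are number-range based; structures renumbered under other
  schemes must be annotated with `scheme` set accordingly (only Chothia
  windows ship today).
* The SC index is package-specific; compare values only within runs of this
  package with identical constants.
* Certainty populations must be pooled per modeling tool by the caller; the
  package enforces but cannot infer population membership.
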