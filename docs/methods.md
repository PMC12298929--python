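# Methods

## Overview

`oncopocketome` maps ligandable pockets on protein–protein complexes. For
each two-chain complex it runs pocket detection three ways — on each
detached partner and on the bound complex — classifies every pocket as
*interface* (on a detached partner, enclosing part of the other partner),
*allosteric-like* (on a detached partner, away from the interaction
region; a candidate anchor site for degrader molecules), or *equilibrium*
(present only in the bound complex, lined by residues of both chains);
maps crystallographic-ligand occupancy transferred from superposed
homologous structures; computes geometric/energetic pocket descriptors;
validates detected sites against known binder contacts with the Matthews
correlation coefficient (MCC); and aggregates per-cancer interaction
networks with hub flags.

## Structure preparation

Input complexes are reduced to the two declared partner chains. Waters,
nucleic acids, metals, crystallization artifacts (glycerol, PEG fragments,
sulfate, …; a config-exposed list, since "artifact" has no canonical
definition) and stray ligands are removed; cofactors on a whitelist (NAD,
FAD, GSH, hemes, SAM, PLP, CoA, …) are retained and flagged. Alternate
locations resolve to the highest-occupancy conformer, ties broken by
altloc letter. Every removal is logged as `<residue> removed: <reason>`.
When a complex is split into detached partners, a cofactor is assigned to
the protein chain with the nearest heavy atom. Coordinates stay in the
file's frame; residue numbering follows PDB convention (1-based, with
insertion codes).

## Grid, burial, and the surrogate interaction fields

The structure is embedded in an axis-aligned voxel grid (default spacing
0.8 Å, padding 6 Å). Voxels whose center falls inside any atom's van der
Waals sphere form the protein occupancy mask.

**Burial.** At every exterior voxel, 50 rays along a fixed
Fibonacci-sphere direction set are marched through the occupancy mask in
steps of one spacing up to 12 Å; burial is the fraction of rays that enter
the mask. The fixed direction set makes the quantity fully deterministic.
The same machinery yields the per-voxel "buriedness" used by the
buried-volume descriptor.

**Probe fields.** Five probes are computed: H (shape), DRY (hydrophobic),
OH2 (water-like polar), O (H-bond acceptor), N1 (H-bond donor). The
genuine GRID force field is proprietary, so a documented surrogate is
used, with every well depth in config:

* a Lennard-Jones 6-12 term with probe- and element-class-dependent well
  depths (DRY is attractive only near C/S atoms; near N/O it contributes
  only a capped repulsion), evaluated over atoms within 8 Å;
* for the polar probes, a Gaussian bonus well near protein N/O atoms
  (depth 4.2 kcal/mol for OH2, 5.5 for O near donors and N1 near
  acceptors; optimum 2.9 Å, width 0.45 Å);
* a **flat core**: inside the contact distance the energy is held at −ε
  instead of climbing the repulsive wall. The pocket criterion thresholds
  a *point* field at voxel centers; with a probe-center repulsive wall the
  ~1.3 Å shell of exterior voxels lining a cavity wall scores positive and
  a large fraction of true cavity volume is lost.

Energies are in kcal/mol, attractive negative; voxels inside the protein
carry a +inf sentinel; exterior voxels with no atom within the cutoff are
exactly 0. The downstream thresholds (−0.5 DRY, −3.5 OH2, −1.0/−4.5
surface-export cutoffs) are meaningful on this surrogate scale and are all
config keys.

One upstream description calls the hydrophobic probe "CRY" in a figure and
"DRY" in the text, and names "OH1" where the probe list has OH2; this
package exposes a single hydrophobic probe (DRY) and a single water-like
polar probe (OH2).

## Pocket detection

Seed voxels are exterior voxels with burial ≥ 0.6 **and** DRY energy
≤ −0.2 kcal/mol. The seed mask is smoothed by a morphological opening
(erosion then dilation with a spherical structuring element of radius 1
voxel), split into 26-connected components, and components smaller than
150 Å³ are dropped (drug-size filter). None of these four numbers is
canonical — the upstream recipe says only "sufficiently buried and
hydrophobic" and "large enough" — so all are documented config defaults.
Pocket ordering is deterministic: descending volume, ties by smallest
voxel index. Lining residues are those with a heavy atom within 4 Å of a
pocket voxel center.

On synthetic monomers with planted spherical cavities of 200–1000 Å³ the
detector returns exactly one pocket within 4% of the analytic volume at
default parameters (the guaranteed band is ≤ 25%).

## Classification

"Fraction of the partner contained in the pocket" is operationalized as
the fraction of partner heavy-atom *centers* inside pocket voxels: exact,
order-independent, and checkable by a counting oracle (whether the
upstream tool used atom counts, voxel overlap, or vdW volume is unstated).
A detached-partner pocket is *interface* iff this fraction strictly
exceeds 0 (strict inequality; the threshold is config). A complex pocket
is *equilibrium* iff its lining residues span both chains. Homodimer
chains are distinguished by chain id, so homo-interactions behave as two
partners.

## Ligand transfer and occupancy

Homologous structures are superposed onto the reference partner by a
least-squares rigid (Kabsch) fit of CA atoms paired by shared
(chain, residue number, insertion code) — homologs of the same protein
share numbering; reflections are corrected to proper rotations.
Alignments with RMSD > 3.0 Å are discarded (the source text reads
"RMSD *lower* than 3.0 Å were excluded", which would discard exactly the
good alignments; the quality-control intent is implemented, boundary
inclusive). Harvested HETATM residues become candidate poses unless they
are waters, metals, cofactors, artifacts, or smaller than 6 heavy atoms
(exclusions are recorded with reasons, and excluded poses never score).
A pocket is *ligand-bound* iff some pose has strictly more than 30% of its
heavy atoms inside the pocket voxels — atom-center counting again, the
consistent reading of "30% of the atomic structure of the ligand".

## Descriptors

All pocket descriptors are computed on the voxel set and are invariant
under rigid motion of structure plus pocket.

**Boundary surface area** uses a normal-weighted face count: each exposed
voxel face contributes `spacing² · |n̂·e|`, with the outward normal
estimated from the gradient of a Gaussian-smoothed occupancy (σ = 1
voxel) and weight 1 where the gradient vanishes. A raw face count
overestimates the area of smooth bodies by a factor approaching 3/2 (the
mean of the ℓ¹ norm of a unit normal over the sphere), which would break
the closed forms below; the weighted sum instead converges to the true
area (per-axis face density is |nᵢ| dA, so the weights give Σnᵢ² dA = dA)
while isolated voxels and flat slabs reduce to the plain count. With this
estimator: a single voxel of edge h has surface 6h² exactly; a digitized
6 Å sphere at 0.5 Å spacing is within ~3% of 4πr².

* **Globularity** = area of the sphere with the pocket's volume / measured
  boundary area, capped at 1. Sphere → 1, elongated bar → < 1, and
  elongating an ellipsoid at fixed volume strictly decreases it.
* **Rugosity** = volume / boundary area (Å). Kept literally as
  volume-over-surface even though the conventional "rugosity" is the
  reciprocal ratio; closed forms r/3 (sphere) and h/6 (single voxel).
* **Hydrophobic / hydrophilic volume** = voxel count strictly below the
  DRY (−0.5 kcal/mol) / OH2 (−3.5 kcal/mol) threshold × voxel volume.
* **Exposed to solvent** (area proxy) = boundary voxels whose clearance
  from the protein van der Waals *surface* is ≥ 2.2 Å, × spacing². The
  clearance is measured from the surface, not atom centers: boundary
  voxels of a fully enclosed cavity sit up to vdW + h√3 ≈ 3.1 Å from the
  nearest atom *center*, so a center-distance reading would give closed
  cavities spurious exposure.
* **Buried volume** = pocket volume × mean per-voxel ray-collision
  fraction (the same 50 fixed directions as burial). Because the upstream
  definition is ambiguous about "points with low buried volume", the
  low-buriedness subvolume (voxels with collision fraction < 0.5) is
  reported alongside; the volume-weighted mean is the headline value.

**Ligand panel** (a reduced surrogate for a proprietary 128-descriptor
3D panel, which is out of scope): molecular weight, polar and hydrophobic
volume proxies (counts of N/O and C/S atoms × reference sphere volumes),
radius of gyration, H-bond acceptor/donor counts, and the **integy
moment** — the distance from the center of mass to the centroid of the
hydrophilic atoms (N/O; 0 with a warning when there are none). PCA over
the standardized panel (constant columns dropped with a warning) uses
scikit-learn; explained-variance fractions are reported sorted.

## Validation metric and networks

MCC is computed on the binary residue confusion matrix over a universe
defaulting to all residues of the evaluated chain; a zero margin makes the
usual formula undefined and is reported as a flagged 0. Observed binder
contacts use a 5 Å heavy-atom cutoff (config; the upstream criterion is
unstated).

Networks are one undirected graph per cancer type over the interaction
table; nodes carry interface/allosteric-like pocket counts. A protein is a
**hub** iff it has ≥ 2 interaction partners; a homodimer self-loop counts
as a single partner. The hub table reports per-cancer degrees and a
cross-cancer degree over the union of partners. Exports: GraphML plus a
Cytoscape-importable edge/node CSV pair.

## Synthetic data: what it emulates, and what it does not

The generator builds pseudo-proteins from poly-alanine-like residues
(five carbon atoms per residue, ordinary chain/residue bookkeeping,
standard PDB output) with analytically known ground truth:

* **cavity monomers** — concentric Fibonacci-sphere atom shells (innermost
  radius r + 1.7 Å, three shells 1.4 Å apart, so the wall is solid under
  vdW union) around a spherical cavity of volume (4/3)πr³, or a lattice
  slab with a hemispherical surface bite of volume (2/3)πr³;
* **interface dimers** — a chain-A cavity opening through a 3 Å tunnel,
  with a chain-B rod whose tip sits inside (ground truth for interface and
  equilibrium classification at one site);
* **flat dimers** — two flat slabs whose facing surfaces enclose a groove
  only in contact (ground truth for equilibrium pockets; separated slabs
  have no pocket anywhere);
* **homolog ensembles** — rigid-motion copies of a base monomer with
  planted ligands placed so that exactly n of N heavy atoms lie inside the
  base cavity, fixing the post-superposition overlap fraction at n/N.

All randomness flows through one seeded generator and coordinates are
rounded to 0.001 Å, so a fixed seed reproduces files byte-for-byte.

These fixtures exercise geometry, bookkeeping and thresholds exactly, but
they are not proteins: no sequence realism, no side-chain chemistry, no
polar/apolar texture beyond what a test constructs, no conformational
variability beyond iid jitter. Passing tests therefore demonstrate that
the algorithms implement their definitions correctly and recover planted
ground truth — not that the surrogate energy scale reproduces any
particular experimental pocket census.

## Numerical choices

* 26-connectivity for components; ball structuring elements (ℓ² ≤ r).
* Grid dims = floor(span/spacing) + 1 per axis after padding; voxel
  centers at origin + index·spacing.
* Degenerate inputs are errors, not silences: empty structures, missing
  chains, pockets with no lining residues, < 3 CA pairs, empty binders,
  non-subset MCC inputs, sub-voxel cavity radii.
* Determinism: fixed Fibonacci directions, seeded generators, sorted
  outputs, config-hash provenance on every table (the hash covers the
  scientific parameters and ignores the output path). The end-to-end demo
  is byte-identical across runs at a fixed seed.
* Problem sizes in the test suite: monomers of ~1000–3000 atoms, grids of
  ~40–80 voxels per axis, cavities of 200–1000 Å³ — sizes at which every
  stage also has a brute-force oracle (ray walks, morphology by
  definition, RMSD by direct evaluation, MCC by confusion-matrix
  counting).

## Known limitations

* The energy surrogate is a documented stand-in calibrated for thresholded
  detection, not for reproducing GRID energies; absolute
  hydrophobic/hydrophilic volumes are comparable within a run, not across
  force fields.
* CA pairing by residue id assumes homologs share numbering; renumbered
  crystal forms would need an alignment-based pairing.
* Electrostatics, protonation, solvent screening and conformational
  ensembles are out of scope; equilibrium pockets are detected on a single
  bound conformation.
* Multi-copy assemblies (e.g. hexamers) must be reduced to two declared
  partner chains by the caller; the pipeline does not guess.
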