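# oncopocketome

Grid-based detection, classification and ligandability mapping of binding
pockets on protein–protein complexes, with per-cancer interaction networks
and hub analysis.

## The problem

Protein–protein interactions (PPIs) drive most oncogenic signalling, and a
PPI with a solved co-crystal structure can be attacked in two ways: with a
modulator binding at the interface, or with a degrader (PROTAC) anchored
at a pocket away from the interface. Both strategies start from the same
question — *where on this complex are the ligandable pockets, and what
kind are they?* This package answers it for any set of two-chain
complexes. It is aimed at structural bioinformaticians and computational
chemists triaging PPI targets, and it ships a synthetic-structure
generator with analytic ground truth so the entire pipeline is testable
without downloading a single crystal structure.

## The method

For each complex the pocket search runs three ways: on each **detached
partner** (the complex split into chains) and on the **bound complex**.
Detection embeds the structure in a voxel grid (0.8 Å spacing) and
computes, at every exterior voxel *p*,

* **burial** `b(p)` — the fraction of 50 fixed-direction rays from *p*
  that strike the protein within 12 Å, and
* **probe fields** `E_probe(p)` — surrogate molecular-interaction-field
  energies (kcal/mol) for the probes H, DRY (hydrophobic), OH2 (polar),
  O (acceptor), N1 (donor).

Voxels with `b(p) ≥ 0.6` and `E_DRY(p) ≤ −0.2` are seeds; a morphological
opening (erosion/dilation, spherical element) smooths them; 26-connected
components of at least 150 Å³ become pockets. Each pocket is then
classified:

| category | where found | rule |
|---|---|---|
| interface | detached partner | fraction of partner atoms inside pocket > 0 |
| allosteric-like | detached partner | otherwise |
| equilibrium | bound complex | lining residues from both chains |

Crystallographic ligands are transferred from homologous structures by
Kabsch superposition on paired CA atoms (alignments kept if RMSD ≤ 3 Å);
a pocket is **ligand-bound** if a transferred ligand has > 30% of its
heavy atoms inside the pocket. Pockets carry six descriptors
(globularity, rugosity, hydrophobic/hydrophilic volume, buried volume,
solvent exposure); site predictions are validated against observed binder
contacts with the Matthews correlation coefficient

```
MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
```

and per-cancer networks flag **hub** proteins (≥ 2 interaction partners).
See `docs/methods.md` for every definition, default and design choice.

## Worked example

A synthetic dimer plants a 5.5 Å cavity on chain A with a chain-B helix
rod inserted through its mouth — so the ground truth is known: the
detached-A pocket must contain B (interface), and the joint cleft on the
complex must be lined by both chains (equilibrium).

```python
from oncopocketome import (SyntheticSpec, make_interface_dimer, split_partners,
                           detect_pockets, classify_detached, classify_complex,
                           partner_fraction, compute_pocket_descriptors,
                           compute_fields, GridParams)

spec = SyntheticSpec(kind="interface_dimer", cavity_radius=5.5, seed=1)
complex_structure, truth = make_interface_dimer(spec)
part_a, part_b = split_partners(complex_structure)

params = GridParams()
field_a = compute_fields(part_a, params, probes=("DRY", "OH2"))
pockets_a = detect_pockets(part_a, source="detached_partner_A",
                           grid_params=params, field=field_a)
p = pockets_a[0]
print(f"volume {p.volume:.1f}  partner fraction {partner_fraction(p, part_b):.2f}"
      f"  category {classify_detached(p, part_b)}")
d = compute_pocket_descriptors(p, field_a, part_a, params)
print(f"globularity {d.globularity:.3f}  rugosity {d.rugosity:.3f}")

for q in detect_pockets(complex_structure, source="complex"):
    print(f"complex pocket {q.volume:.1f} A^3 -> {classify_complex(q)}")
```

prints

```
volume 749.1  partner fraction 0.73  category interface
globularity 0.982  rugosity 1.845
complex pocket 605.7 A^3 -> equilibrium
```

The detached-A pocket (749 Å³, near-spherical: globularity 0.98) encloses
73% of the partner atoms, so it is an interface pocket; on the bound
complex the same site survives as a 606 Å³ equilibrium pocket lined by
both chains — the classic signature of a cleft that exists only around
the inserted partner.

The same pipeline runs from the shell: `oncopocketome demo -o demo_out`
performs the full deterministic run (three synthetic complexes plus a
homolog-ensemble ligand transfer) and writes pocket tables, ligand
occupancy, per-cancer GraphML networks and a hub table; `oncopocketome
run table.csv --structures dir/` does the same for your own complexes
(CSV columns: `protein_a, protein_b, cancer_types, structure_file,
chain_a, chain_b`).

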