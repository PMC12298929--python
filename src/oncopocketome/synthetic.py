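"""Synthetic pseudo-protein structures with analytically known ground truth.

Pocket detection can only be validated offline if the cavities are planted
with known geometry.  This module builds:

* **cavity monomers** — carbon atom shells enclosing a spherical (or
  hemispherical, surface-open) cavity of radius r, so the open cavity
  volume is exactly (4/3)πr³ (or half of it);
* **interface dimers** — a chain-A cavity connected to the surface by a
  narrow tunnel, with a chain-B rod inserted through the tunnel so its tip
  sits inside the cavity (ground truth: the detached-A pocket contains B);
* **flat dimers** — two flat slabs that only jointly enclose a groove
  (ground truth for equilibrium pockets); optionally separated so no
  groove exists;
* **homolog ensembles** — rigid-motion copies of a base monomer with
  planted ligands whose in-cavity atom counts (hence overlap fractions)
  are fixed by construction.

Pseudo-proteins are poly-alanine-like: residues of a few carbon atoms with
ordinary chain/residue bookkeeping, written as standard PDB.  They make no
claim to chemical realism — downstream code only consumes elements,
coordinates and residue ids.  All randomness flows through one seeded
generator; coordinates are rounded to 0.001 Å so fixed seed means
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .grid import fibonacci_sphere
from .ligands import Superposition
from .structures import AtomRecord, Structure

CARBON_VDW = 1.70
SHELL_GAP = 1.4          # Å between concentric atom shells (solid wall)
N_SHELLS = 3
POINT_AREA = 1.95        # Å² of shell area per atom (≈1.5 Å point spacing)
ATOMS_PER_RESIDUE = 5
MIN_CAVITY_RADIUS = 0.8  # Å; smaller cavities enclose no voxel at default spacing
CLASH_DISTANCE = 2.0     # Å; closer inter-chain heavy atoms are an error


@dataclass
class SyntheticSpec:
    kind: str                         # cavity_monomer | interface_dimer |
                                      # flat_dimer | homolog_ensemble
    cavity_radius: float = 5.0        # Å
    cavity_center: tuple = (0.0, 0.0, 0.0)
    n_shell_atoms: int = 0            # atoms on the innermost shell; 0 = auto
    noise_sigma: float = 0.0          # Å, iid Gaussian jitter
    seed: int = 0
    ligand_plan: list = dfield(default_factory=list)  # [(n_inside, n_total)]
    cavity_style: str = "sphere"      # sphere | hemisphere (cavity_monomer)
    chain_separation: float = 0.0     # extra Å between flat_dimer slabs

    def __post_init__(self):
        kinds = ("cavity_monomer", "interface_dimer", "flat_dimer",
                 "homolog_ensemble")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")
        if self.cavity_radius <= 0:
            raise ValueError("cavity_radius must be positive")
        for n_in, n_tot in self.ligand_plan:
            if n_in > n_tot:
                raise ValueError("ligand_plan: n_inside cannot exceed n_total")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def cavity_volume(spec: SyntheticSpec) -> float:
    """Analytic open-cavity volume (Å³)."""
    v = 4.0 / 3.0 * np.pi * spec.cavity_radius**3
    return v / 2.0 if spec.cavity_style == "hemisphere" else v


# ---------------------------------------------------------------------------
# Atom bookkeeping
# ---------------------------------------------------------------------------

_ATOM_NAMES = ("CA", "CB", "CG", "CD", "CE")


def _atoms_from_points(
    points: np.ndarray, chain: str, first_residue: int = 1,
    element: str = "C", het: bool = False, residue_name: str = "ALA",
) -> list[AtomRecord]:
    atoms = []
    pts = np.round(np.asarray(points, dtype=float), 3)
    for i, p in enumerate(pts):
        res_index = i // ATOMS_PER_RESIDUE
        atoms.append(
            AtomRecord(
                serial=i + 1,
                name=_ATOM_NAMES[i % ATOMS_PER_RESIDUE],
                element=element,
                coord=tuple(p),
                residue_name=residue_name,
                chain=chain,
                resseq=first_residue + res_index,
                het=het,
            )
        )
    return atoms


def _shell_points(radius: float, n_points: int) -> np.ndarray:
    return fibonacci_sphere(n_points) * radius


def _auto_shell_count(radius: float) -> int:
    return max(32, int(np.ceil(4.0 * np.pi * radius**2 / POINT_AREA)))


def _cavity_shell_points(spec: SyntheticSpec) -> np.ndarray:
    """Concentric shells of atom centers around the cavity (cavity frame)."""
    r_in = spec.cavity_radius + CARBON_VDW
    pts = []
    for k in range(N_SHELLS):
        radius = r_in + k * SHELL_GAP
        n = spec.n_shell_atoms if (spec.n_shell_atoms and k == 0) else _auto_shell_count(radius)
        pts.append(_shell_points(radius, n))
    return np.concatenate(pts, axis=0)


# ---------------------------------------------------------------------------
# Cavity monomer
# ---------------------------------------------------------------------------

def make_cavity_monomer(spec: SyntheticSpec):
    """Pseudo-protein with a planted cavity of analytic volume.

    Returns ``(structure, ground_truth)`` where ground_truth carries the
    analytic cavity volume and the rim (innermost-shell) residue ids.
    """
    if spec.kind != "cavity_monomer":
        raise ValueError("spec.kind must be 'cavity_monomer'")
    if spec.cavity_radius < MIN_CAVITY_RADIUS:
        raise ValueError(
            f"cavity radius {spec.cavity_radius} Å encloses no voxel at the "
            f"default grid spacing; minimum is {MIN_CAVITY_RADIUS} Å"
        )
    rng = spec.rng()
    if spec.cavity_style == "hemisphere":
        pts = _hemisphere_block_points(spec)
    else:
        pts = _cavity_shell_points(spec)
    if spec.noise_sigma > 0:
        pts = pts + rng.normal(0.0, spec.noise_sigma, size=pts.shape)
    pts = pts + np.asarray(spec.cavity_center, dtype=float)[None, :]

    atoms = _atoms_from_points(pts, chain="A")
    structure = Structure(atoms, provenance=f"synthetic:{spec.kind}:{spec.seed}")

    center = np.asarray(spec.cavity_center, dtype=float)
    r_rim = spec.cavity_radius + CARBON_VDW + 0.1
    rim = frozenset(
        a.residue_id
        for a in atoms
        if np.linalg.norm(np.asarray(a.coord) - center) <= r_rim
    )
    ground_truth = {
        "cavity_volume": cavity_volume(spec),
        "cavity_lining_residue_ids": rim,
        "cavity_center": tuple(center),
        "cavity_radius": spec.cavity_radius,
    }
    return structure, ground_truth


def _hemisphere_block_points(spec: SyntheticSpec) -> np.ndarray:
    """Lattice slab (top surface z = 0) with a hemispherical bite at the
    origin: an invagination open to the solvent from above."""
    r_in = spec.cavity_radius + CARBON_VDW
    half = r_in + 8.0
    depth = r_in + 4.0
    step = 1.5
    ax = np.arange(-half, half + 1e-6, step)
    az = np.arange(-depth, 0.0 + 1e-6, step)
    gx, gy, gz = np.meshgrid(ax, ax, az, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    d = np.sqrt((pts**2).sum(axis=1))
    return pts[d > r_in - 1e-9]


# ---------------------------------------------------------------------------
# Dimers
# ---------------------------------------------------------------------------

TUNNEL_RADIUS = 3.0  # Å; atoms inside this cylinder (z > 0) are removed


def _check_clash(a: Structure, b: Structure) -> None:
    from scipy.spatial import cKDTree

    ta = cKDTree(a.coords())
    d, _ = ta.query(b.coords())
    if float(d.min()) < CLASH_DISTANCE:
        raise ValueError(
            f"chains clash: minimum inter-chain distance {d.min():.2f} Å "
            f"< {CLASH_DISTANCE} Å"
        )


def make_interface_dimer(spec: SyntheticSpec):
    """Cavity on chain A with a chain-B rod inserted through a tunnel.

    For ``kind='interface_dimer'``: A's cavity opens to the surface through
    a tunnel along +z and B's rod tip reaches inside the cavity.  Ground
    truth: the pocket on detached A contains part of B, and the joint cleft
    is lined by both chains.

    For ``kind='flat_dimer'``: two flat slabs facing each other across a
    groove that exists only in the complex (``chain_separation`` adds extra
    distance; 50 Å apart there is no groove).  Ground truth records whether
    a shared-lining groove exists.
    """
    if spec.kind == "interface_dimer":
        return _interface_dimer(spec)
    if spec.kind == "flat_dimer":
        return _flat_dimer(spec)
    raise ValueError("spec.kind must be 'interface_dimer' or 'flat_dimer'")


def _interface_dimer(spec: SyntheticSpec):
    rng = spec.rng()
    pts = _cavity_shell_points(spec)
    rho = np.sqrt(pts[:, 0] ** 2 + pts[:, 1] ** 2)
    keep = ~((pts[:, 2] > 0) & (rho < TUNNEL_RADIUS))
    pts = pts[keep]
    if spec.noise_sigma > 0:
        pts = pts + rng.normal(0.0, spec.noise_sigma, size=pts.shape)
    center = np.asarray(spec.cavity_center, dtype=float)
    pts = pts + center[None, :]
    chain_a = _atoms_from_points(pts, chain="A")

    # B: a rod of atoms descending the tunnel, tip inside the cavity
    r_out = spec.cavity_radius + CARBON_VDW + (N_SHELLS - 1) * SHELL_GAP
    z_top = r_out + 4.0
    z_tip = -0.3 * spec.cavity_radius
    zs = np.arange(z_tip, z_top + 1e-6, 1.5)
    spiral = np.column_stack(
        [0.8 * np.cos(2.1 * zs), 0.8 * np.sin(2.1 * zs), zs]
    )
    rod = spiral + center[None, :]
    chain_b = _atoms_from_points(rod, chain="B")

    sa = Structure(chain_a, provenance=f"synthetic:interface_dimer:A:{spec.seed}")
    sb = Structure(chain_b, provenance=f"synthetic:interface_dimer:B:{spec.seed}")
    _check_clash(sa, sb)
    combined = Structure(
        chain_a + chain_b,
        provenance=f"synthetic:interface_dimer:{spec.seed}",
    )
    n_tip = int((zs < 0).sum())
    ground_truth = {
        "pocket_on_A_contains_B": True,
        "shared_lining": True,
        "n_b_atoms_in_cavity": n_tip,
        "cavity_center": tuple(center),
        "cavity_radius": spec.cavity_radius,
    }
    return combined, ground_truth


SLAB_HALF_WIDTH = 13.0
SLAB_THICKNESS = 5.0
SLAB_STEP = 1.6
CONTACT_GAP = 6.5  # Å between facing surface atom planes when in contact


def _slab_points(z_lo: float, z_hi: float) -> np.ndarray:
    ax = np.arange(-SLAB_HALF_WIDTH, SLAB_HALF_WIDTH + 1e-6, SLAB_STEP)
    az = np.arange(z_lo, z_hi + 1e-6, SLAB_STEP)
    gx, gy, gz = np.meshgrid(ax, ax, az, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def _flat_dimer(spec: SyntheticSpec):
    rng = spec.rng()
    gap = CONTACT_GAP + spec.chain_separation
    pa = _slab_points(-SLAB_THICKNESS, 0.0)
    pb = _slab_points(gap, gap + SLAB_THICKNESS)
    if spec.noise_sigma > 0:
        pa = pa + rng.normal(0.0, spec.noise_sigma, size=pa.shape)
        pb = pb + rng.normal(0.0, spec.noise_sigma, size=pb.shape)
    chain_a = _atoms_from_points(pa, chain="A")
    chain_b = _atoms_from_points(pb, chain="B")
    sa = Structure(chain_a)
    sb = Structure(chain_b)
    _check_clash(sa, sb)
    combined = Structure(
        chain_a + chain_b, provenance=f"synthetic:flat_dimer:{spec.seed}"
    )
    in_contact = spec.chain_separation < 2.0
    ground_truth = {
        "pocket_on_A_contains_B": False,
        "shared_lining": in_contact,
        "groove_exists": in_contact,
    }
    return combined, ground_truth


# ---------------------------------------------------------------------------
# Homolog ensembles
# ---------------------------------------------------------------------------

@dataclass
class HomologEntry:
    structure: Structure              # moved copy (protein + planted ligand)
    transform: Superposition          # the known rigid motion base -> copy
    ligand_truth: list                # [(ligand_id, n_inside, n_total)]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def make_homolog_ensemble(spec: SyntheticSpec):
    """Base cavity monomer plus rigid-motion copies with planted ligands.

    One copy (and one ligand) per ``ligand_plan`` entry.  In each copy the
    ligand has exactly ``n_inside`` atoms within the base cavity (radius
    0.6 r around the center) and the rest far outside the protein, so after
    an exact superposition the pocket-overlap fraction is n_inside/n_total
    by construction.  Returns ``(base_structure, base_truth, entries)``.
    """
    if spec.kind != "homolog_ensemble":
        raise ValueError("spec.kind must be 'homolog_ensemble'")
    base_spec = SyntheticSpec(
        kind="cavity_monomer",
        cavity_radius=spec.cavity_radius,
        cavity_center=spec.cavity_center,
        n_shell_atoms=spec.n_shell_atoms,
        noise_sigma=0.0,
        seed=spec.seed,
    )
    base, base_truth = make_cavity_monomer(base_spec)
    rng = spec.rng()
    center = np.asarray(spec.cavity_center, dtype=float)
    r_far = spec.cavity_radius + CARBON_VDW + (N_SHELLS - 1) * SHELL_GAP + 8.0

    elements_cycle = ("C", "N", "C", "O", "C")
    entries: list[HomologEntry] = []
    for copy_index, (n_in, n_tot) in enumerate(spec.ligand_plan):
        R = _random_rotation(rng)
        t = rng.uniform(-20.0, 20.0, size=3)
        # ligand atoms in the base frame
        d_in = fibonacci_sphere(max(n_in, 1))[:n_in]
        radii_in = 0.6 * spec.cavity_radius * rng.uniform(0.3, 1.0, size=n_in)
        inside_pts = center[None, :] + d_in * radii_in[:, None]
        n_out = n_tot - n_in
        d_out = fibonacci_sphere(max(n_out, 1))[:n_out]
        outside_pts = center[None, :] + d_out * (
            r_far + rng.uniform(0.0, 4.0, size=n_out)[:, None]
        )
        lig_pts = np.concatenate([inside_pts, outside_pts], axis=0)

        prot_pts = np.asarray([a.coord for a in base.atoms])
        if spec.noise_sigma > 0:
            prot_pts = prot_pts + rng.normal(0.0, spec.noise_sigma, size=prot_pts.shape)
        moved_prot = prot_pts @ R.T + t[None, :]
        moved_lig = lig_pts @ R.T + t[None, :]

        atoms = _atoms_from_points(moved_prot, chain="A")
        lig_id = f"LIG:{copy_index}"
        lig_atoms = []
        n_res = atoms[-1].resseq
        for i, p in enumerate(np.round(moved_lig, 3)):
            lig_atoms.append(
                AtomRecord(
                    serial=len(atoms) + i + 1,
                    name=f"L{i + 1}",
                    element=elements_cycle[i % len(elements_cycle)],
                    coord=tuple(p),
                    residue_name="LIG",
                    chain="A",
                    resseq=n_res + 1,
                    het=True,
                )
            )
        structure = Structure(
            atoms + lig_atoms,
            provenance=f"synthetic:homolog:{spec.seed}:{copy_index}",
        )
        transform = Superposition(
            rotation=R, translation=t, rmsd=0.0, n_paired_atoms=len(atoms)
        )
        entries.append(
            HomologEntry(
                structure=structure,
                transform=transform,
                ligand_truth=[(lig_id, n_in, n_tot)],
            )
        )
    return base, base_truth, entries
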