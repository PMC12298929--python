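"""Pocket detection: seed selection, morphological smoothing, size filtering.

Candidate pocket points are exterior voxels that are both sufficiently
buried and hydrophobic (DRY energy below a cutoff).  The seed mask is
smoothed by a morphological opening (erosion then dilation with a spherical
structuring element), split into 26-connected components, and components too
small to hold a drug-like molecule are discarded.

None of the thresholds below are canonical: the cited detection recipe
("sufficiently buried and hydrophobic", "large enough") leaves them open,
so they are all explicit config with documented defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grid import GridParams, VolumetricField, compute_fields
from .structures import ResidueId, Structure


@dataclass
class PocketParams:
    burial_min: float = 0.6        # minimum ray-hit fraction for a seed voxel
    dry_max: float = -0.2          # kcal/mol (surrogate scale); seed if DRY <= this
    erosion_radius: int = 1        # voxels; spherical structuring element
    dilation_radius: int = 1
    min_volume: float = 150.0      # Å^3; drug-size filter
    contact_cutoff: float = 4.0    # Å; voxel-to-atom distance defining lining


@dataclass
class Pocket:
    """A 26-connected voxel set on a grid, with bookkeeping."""

    indices: np.ndarray                 # (n, 3) int voxel indices, lex-sorted
    origin: np.ndarray                  # grid origin (Å)
    spacing: float
    source: str = "complex"             # detached_partner_A/B or complex
    lining_residues: frozenset = frozenset()
    category: str = "unclassified"
    descriptors: dict = dfield(default_factory=dict)
    ligand_occupancy: list = dfield(default_factory=list)
    pocket_id: str = ""

    @property
    def n_voxels(self) -> int:
        return len(self.indices)

    @property
    def volume(self) -> float:
        return self.n_voxels * self.spacing**3

    def voxel_centers(self) -> np.ndarray:
        return self.origin[None, :] + self.indices.astype(float) * self.spacing

    def index_set(self) -> set[tuple[int, int, int]]:
        return {tuple(ijk) for ijk in self.indices}

    def contains_points(self, points: np.ndarray) -> np.ndarray:
        """True for each point whose nearest voxel belongs to the pocket."""
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        idx = np.rint((pts - self.origin[None, :]) / self.spacing).astype(int)
        members = self.index_set()
        return np.asarray([tuple(i) in members for i in idx], dtype=bool)

    @property
    def is_ligand_bound(self) -> bool:
        return len(self.ligand_occupancy) > 0


def ball_element(radius: int) -> np.ndarray:
    """Spherical structuring element of the given voxel radius."""
    if radius < 1:
        raise ValueError("structuring-element radius must be >= 1")
    r = int(radius)
    ax = np.arange(-r, r + 1)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    return gx**2 + gy**2 + gz**2 <= r * r + 1e-9


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def select_seed_voxels(
    field: VolumetricField,
    burial_min: float = PocketParams.burial_min,
    dry_max: float = PocketParams.dry_max,
) -> np.ndarray:
    """Boolean mask of exterior voxels that are buried and hydrophobic."""
    if field.burial is None:
        raise ValueError("burial field not computed")
    if "DRY" not in field.probes:
        raise ValueError("DRY probe field not computed")
    dry = field.probes["DRY"]
    return (~field.inside_protein) & (field.burial >= burial_min) & (dry <= dry_max)


def morphological_opening(
    mask: np.ndarray, erosion_radius: int = 1, dilation_radius: int = 1
) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, structure=ball_element(erosion_radius))
    return ndimage.binary_dilation(eroded, structure=ball_element(dilation_radius))


def cluster_and_smooth(
    seed_mask: np.ndarray, erosion_radius: int = 1, dilation_radius: int = 1
) -> list[np.ndarray]:
    """Open the seed mask and split it into 26-connected components.

    Specks removed entirely by the erosion are dropped; thin bridges between
    regions are cut, so the result may hold more components than the input.
    Components are returned ordered by (descending size, smallest index).
    """
    opened = morphological_opening(seed_mask, erosion_radius, dilation_radius)
    labels, n = ndimage.label(opened, structure=_CONN26)
    comps = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
        comps.append(idx[order])
    comps.sort(key=lambda c: (-len(c), tuple(c[0])))
    return comps


def size_filter(pockets: list[Pocket], min_volume: float) -> list[Pocket]:
    """Keep pockets large enough for drug-like molecules; order preserved."""
    return [p for p in pockets if p.volume >= min_volume]


def lining_residues(
    pocket: Pocket, structure: Structure, contact_cutoff: float = 4.0
) -> frozenset:
    """Residues with >= 1 heavy atom within the cutoff of a pocket voxel center."""
    heavy = structure.heavy_atoms()
    tree = cKDTree(np.asarray([a.coord for a in heavy]))
    centers = pocket.voxel_centers()
    found: set[ResidueId] = set()
    for hits in tree.query_ball_point(centers, r=contact_cutoff):
        for i in hits:
            found.add(heavy[i].residue_id)
    if not found:
        raise ValueError(
            f"pocket has no lining residues at cutoff {contact_cutoff} Å"
        )
    return frozenset(found)


def detect_pockets(
    structure: Structure,
    source: str = "complex",
    grid_params: GridParams | None = None,
    pocket_params: PocketParams | None = None,
    field: VolumetricField | None = None,
) -> list[Pocket]:
    """Full detection on one structure: fields -> seeds -> opening -> pockets.

    Pockets are ordered deterministically by descending volume, ties broken
    by the lexicographically smallest voxel index.
    """
    gp = grid_params or GridParams()
    pp = pocket_params or PocketParams()
    if field is None:
        field = compute_fields(structure, gp, probes=("DRY",))
    seeds = select_seed_voxels(field, pp.burial_min, pp.dry_max)
    comps = cluster_and_smooth(seeds, pp.erosion_radius, pp.dilation_radius)
    pockets = []
    for idx in comps:
        # dilation may re-enter the protein mask; pocket voxels never do
        keep = ~field.inside_protein[idx[:, 0], idx[:, 1], idx[:, 2]]
        idx = idx[keep]
        if len(idx) == 0:
            continue
        pockets.append(
            Pocket(
                indices=idx,
                origin=field.origin,
                spacing=field.spacing,
                source=source,
            )
        )
    pockets = size_filter(pockets, pp.min_volume)
    pockets.sort(key=lambda p: (-p.volume, tuple(p.indices[0])))
    for k, p in enumerate(pockets):
        p.pocket_id = f"{source}:{k}"
        p.lining_residues = lining_residues(p, structure, pp.contact_cutoff)
    return pockets


def pocket_to_pdb(pocket: Pocket, path: str) -> None:
    """Write one HETATM pseudo-atom per voxel center, for visualization."""
    centers = pocket.voxel_centers()
    with open(path, "w") as fh:
        for i, (x, y, z) in enumerate(centers, start=1):
            fh.write(
                f"HETATM{i % 100000:5d}  C   PKT P   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")
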