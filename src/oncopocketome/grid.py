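"""Voxel grids, burial and surrogate molecular-interaction-field probes.

The structure is embedded in an axis-aligned grid.  At every exterior voxel
we compute (a) *burial* — the fraction of 50 fixed Fibonacci-sphere ray
directions that run into protein within a cutoff — and (b) probe
interaction energies for a small panel of chemical probes:

===== =======================================================
probe meaning
===== =======================================================
H     shape / steric probe
DRY   hydrophobic probe (attractive only near C and S atoms)
OH2   water-like polar probe (hydrophilic regions)
O     hydrogen-bond acceptor probe (senses donor N sites)
N1    hydrogen-bond donor probe (senses acceptor O sites)
===== =======================================================

The true GRID force field is proprietary; the energies here come from a
documented surrogate: a Lennard-Jones 6-12 term with probe- and
element-class-dependent well depths, plus a distance-Gaussian polar bonus
for the polar probes near N/O atoms.  Energies are in kcal/mol with
attractive values negative; all well depths and thresholds live in
:class:`GridParams` so downstream cutoffs stay meaningful on this scale.

Burial is evaluated by marching each ray through the protein occupancy
mask in steps of one grid spacing — fully deterministic for a fixed
direction set.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from . import chemdata
from .structures import Structure

PROBES = ("H", "DRY", "OH2", "O", "N1")


def fibonacci_sphere(n: int) -> np.ndarray:
    """`n` near-uniform unit vectors (golden-spiral construction)."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + 5.0**0.5) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass
class GridParams:
    spacing: float = 0.8          # Å per voxel edge
    padding: float = 6.0          # Å of empty margin around the bounding box
    burial_rays: int = 50         # fixed Fibonacci directions
    burial_ray_cutoff: float = 12.0  # Å; rays stop here
    probe_set: tuple[str, ...] = PROBES
    energy_cutoff: float = 8.0    # Å; LJ neighbourhood radius
    polar_cutoff: float = 4.0     # Å; polar bonus neighbourhood
    probe_radius: float = 1.7     # Å; probe vdW radius in the LJ mixing rule
    # LJ well depths (kcal/mol) per probe and atom class; "rep" is a pure
    # r^-12 repulsion used where a probe has no attractive term.
    well_depths: dict = dfield(
        default_factory=lambda: {
            "H": {"C": 0.10, "S": 0.10, "N": 0.10, "O": 0.10, "other": 0.10},
            "DRY": {"C": 0.25, "S": 0.22, "N": 0.0, "O": 0.0, "other": 0.05,
                    "rep": 0.05},
            "OH2": {"C": 0.12, "S": 0.12, "N": 0.12, "O": 0.12, "other": 0.12},
            "O": {"C": 0.12, "S": 0.12, "N": 0.12, "O": 0.12, "other": 0.12},
            "N1": {"C": 0.12, "S": 0.12, "N": 0.12, "O": 0.12, "other": 0.12},
        }
    )
    # Gaussian polar bonus: depth (kcal/mol), optimum distance, width (Å),
    # and the protein atom elements it applies to.
    polar_terms: dict = dfield(
        default_factory=lambda: {
            "OH2": {"depth": 4.2, "r0": 2.9, "sigma": 0.45,
                    "elements": ("N", "O")},
            "O": {"depth": 5.5, "r0": 2.9, "sigma": 0.45, "elements": ("N",)},
            "N1": {"depth": 5.5, "r0": 2.9, "sigma": 0.45, "elements": ("O",)},
        }
    )

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.padding < 0:
            raise ValueError("padding must be non-negative")
        # normalize sequences so configs round-trip YAML losslessly
        self.probe_set = tuple(self.probe_set)
        for term in self.polar_terms.values():
            term["elements"] = tuple(term["elements"])


@dataclass
class VolumetricField:
    """Axis-aligned voxel grid with per-probe energies and burial."""

    origin: np.ndarray            # Å; center of voxel (0,0,0)
    spacing: float
    dims: tuple[int, int, int]
    inside_protein: np.ndarray    # bool (nx, ny, nz)
    burial: np.ndarray | None = None
    probes: dict[str, np.ndarray] = dfield(default_factory=dict)

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        return self.origin[None, :] + np.asarray(indices, dtype=float) * self.spacing

    def point_to_index(self, points: np.ndarray) -> np.ndarray:
        """Nearest voxel index for each point (may fall outside the grid)."""
        return np.rint(
            (np.asarray(points, dtype=float) - self.origin[None, :]) / self.spacing
        ).astype(int)

    def in_bounds(self, indices: np.ndarray) -> np.ndarray:
        idx = np.asarray(indices)
        ok = np.ones(len(idx), dtype=bool)
        for a in range(3):
            ok &= (idx[:, a] >= 0) & (idx[:, a] < self.dims[a])
        return ok

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    def all_exterior_indices(self) -> np.ndarray:
        return np.argwhere(~self.inside_protein)


def build_grid(structure: Structure, params: GridParams | None = None) -> VolumetricField:
    """Embed the structure in a voxel grid and mask its van der Waals volume."""
    params = params or GridParams()
    coords = structure.coords(heavy_only=True)
    if coords.size == 0:
        raise ValueError("cannot grid an empty structure")
    lo = coords.min(axis=0) - params.padding
    hi = coords.max(axis=0) + params.padding
    span = hi - lo
    dims = (np.floor(span / params.spacing + 1e-9).astype(int) + 1)
    inside = np.zeros(tuple(dims), dtype=bool)
    h = params.spacing

    elements = structure.elements(heavy_only=True)
    for pt, el in zip(coords, elements):
        r = chemdata.vdw_radius(el)
        lo_i = np.maximum(np.ceil((pt - r - lo) / h - 1e-9).astype(int), 0)
        hi_i = np.minimum(np.floor((pt + r - lo) / h + 1e-9).astype(int), dims - 1)
        if np.any(lo_i > hi_i):
            continue
        ax = [np.arange(lo_i[a], hi_i[a] + 1) for a in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        centers = np.stack([gx, gy, gz], axis=-1) * h + lo
        d2 = ((centers - pt) ** 2).sum(axis=-1)
        mark = d2 <= r * r + 1e-12
        inside[gx[mark], gy[mark], gz[mark]] = True

    return VolumetricField(
        origin=lo, spacing=h, dims=tuple(int(d) for d in dims), inside_protein=inside
    )


# ---------------------------------------------------------------------------
# Burial
# ---------------------------------------------------------------------------

def _ray_offsets(params: GridParams) -> np.ndarray:
    """Integer voxel offsets along each ray, shape (rays, steps, 3)."""
    dirs = fibonacci_sphere(params.burial_rays)
    n_steps = int(np.floor(params.burial_ray_cutoff / params.spacing))
    k = np.arange(1, n_steps + 1, dtype=float)
    return np.rint(dirs[:, None, :] * k[None, :, None]).astype(int)


def compute_burial(
    field: VolumetricField,
    structure: Structure | None = None,
    params: GridParams | None = None,
) -> VolumetricField:
    """Fill ``field.burial``: per-voxel fraction of rays that hit protein.

    Rays march through the occupancy mask in unit-voxel steps; a ray "hits"
    if any sampled voxel lies inside the protein.  Voxels inside the protein
    are assigned burial 1.  Deterministic for fixed parameters.
    """
    params = params or GridParams(spacing=field.spacing)
    offsets = _ray_offsets(params)  # (R, S, 3)
    dims = np.asarray(field.dims)
    inside = field.inside_protein

    burial = np.zeros(field.dims, dtype=np.float32)
    burial[inside] = 1.0
    ext = np.argwhere(~inside)
    if len(ext) == 0:
        field.burial = burial
        return field

    hits = np.zeros(len(ext), dtype=np.int16)
    chunk = 20000
    for start in range(0, len(ext), chunk):
        idx = ext[start : start + chunk]  # (N, 3)
        nhit = np.zeros(len(idx), dtype=np.int16)
        for r in range(offsets.shape[0]):
            pos = idx[:, None, :] + offsets[r][None, :, :]  # (N, S, 3)
            valid = np.all((pos >= 0) & (pos < dims[None, None, :]), axis=2)
            pc = np.clip(pos, 0, dims - 1)
            hit = inside[pc[..., 0], pc[..., 1], pc[..., 2]] & valid
            nhit += hit.any(axis=1).astype(np.int16)
        hits[start : start + chunk] = nhit
    burial[ext[:, 0], ext[:, 1], ext[:, 2]] = hits / float(offsets.shape[0])
    field.burial = burial
    return field


def voxel_buriedness(
    field: VolumetricField, indices: np.ndarray, params: GridParams | None = None
) -> np.ndarray:
    """Ray-hit fraction for an arbitrary set of voxel indices."""
    params = params or GridParams(spacing=field.spacing)
    offsets = _ray_offsets(params)
    dims = np.asarray(field.dims)
    inside = field.inside_protein
    idx = np.asarray(indices)
    nhit = np.zeros(len(idx), dtype=np.int32)
    for r in range(offsets.shape[0]):
        pos = idx[:, None, :] + offsets[r][None, :, :]
        valid = np.all((pos >= 0) & (pos < dims[None, None, :]), axis=2)
        pc = np.clip(pos, 0, dims - 1)
        hit = inside[pc[..., 0], pc[..., 1], pc[..., 2]] & valid
        nhit += hit.any(axis=1).astype(np.int32)
    return nhit / float(offsets.shape[0])


# ---------------------------------------------------------------------------
# Probe fields
# ---------------------------------------------------------------------------

def _element_class(el: str) -> str:
    el = el.upper()
    if el in ("C",):
        return "C"
    if el in ("S", "SE"):
        return "S"
    if el == "N":
        return "N"
    if el == "O":
        return "O"
    return "other"


def compute_probe_field(
    field: VolumetricField,
    structure: Structure,
    probe: str,
    params: GridParams | None = None,
) -> VolumetricField:
    """Fill ``field.probes[probe]`` with surrogate interaction energies.

    Exterior voxels with no atom inside the cutoff get exactly 0; interior
    voxels get +inf (they can never be pocket points).
    """
    params = params or GridParams(spacing=field.spacing)
    if probe not in PROBES:
        raise ValueError(f"unknown probe {probe!r}; expected one of {PROBES}")

    coords = structure.coords(heavy_only=True)
    raw_elements = structure.elements(heavy_only=True)
    elements = [_element_class(e) for e in raw_elements]
    energy = np.zeros(field.dims, dtype=np.float32)

    ext = np.argwhere(~field.inside_protein)
    centers = field.voxel_centers(ext)
    tree_atoms = cKDTree(coords)
    tree_vox = cKDTree(centers)
    pairs = tree_atoms.sparse_distance_matrix(
        tree_vox, max_distance=params.energy_cutoff, output_type="coo_matrix"
    )
    ai, vi, dist = pairs.row, pairs.col, pairs.data
    dist = np.maximum(dist, 0.6)  # clamp to avoid numeric blow-up

    eps_table = params.well_depths[probe]
    el_class = np.asarray([elements[i] for i in ai])
    eps = np.asarray([eps_table.get(c, eps_table["other"]) for c in el_class])
    atom_radii = np.asarray([chemdata.vdw_radius(e) for e in raw_elements])
    radii = atom_radii[ai]
    rmin = radii + params.probe_radius
    x6 = (rmin / dist) ** 6
    e = eps * (x6 * x6 - 2.0 * x6)
    # flat core: a grid point closer than the contact distance sits at the
    # well floor rather than on the repulsive wall (the pocket criterion
    # thresholds a point field, not a probe-center field)
    core = dist < rmin
    e[core] = -eps[core]
    rep = eps_table.get("rep", 0.0)
    if rep:
        zero = eps == 0.0
        e[zero] = np.minimum(rep * x6[zero] * x6[zero], 1.0)

    if probe in params.polar_terms:
        term = params.polar_terms[probe]
        polar = np.isin(el_class, term["elements"]) & (dist <= params.polar_cutoff)
        e[polar] -= term["depth"] * np.exp(
            -((dist[polar] - term["r0"]) ** 2) / (2.0 * term["sigma"] ** 2)
        )

    flat = np.zeros(len(ext), dtype=np.float64)
    np.add.at(flat, vi, e)
    energy[ext[:, 0], ext[:, 1], ext[:, 2]] = flat
    energy[field.inside_protein] = np.inf
    field.probes[probe] = energy
    return field


def compute_fields(
    structure: Structure,
    params: GridParams | None = None,
    probes: Sequence[str] = ("DRY",),
) -> VolumetricField:
    """Convenience: grid + burial + the requested probe fields."""
    params = params or GridParams()
    field = build_grid(structure, params)
    compute_burial(field, structure, params)
    for p in probes:
        compute_probe_field(field, structure, p, params)
    return field


def distance_to_protein(field: VolumetricField) -> np.ndarray:
    """Euclidean distance (Å) from each voxel center to the protein mask."""
    return ndimage.distance_transform_edt(
        ~field.inside_protein, sampling=field.spacing
    )


# ---------------------------------------------------------------------------
# OpenDX-style export
# ---------------------------------------------------------------------------

def write_dx(field: VolumetricField, probe: str, path: str) -> None:
    """Dump one scalar field in OpenDX text format for visual inspection."""
    data = field.probes[probe] if probe in field.probes else field.burial
    if data is None:
        raise ValueError(f"field {probe!r} not computed")
    nx, ny, nz = field.dims
    vals = np.where(np.isfinite(data), data, 0.0).ravel(order="C")
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.4f} {:.4f} {:.4f}\n".format(*field.origin))
        fh.write(f"delta {field.spacing:.4f} 0 0\n")
        fh.write(f"delta 0 {field.spacing:.4f} 0\n")
        fh.write(f"delta 0 0 {field.spacing:.4f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {vals.size} data follows\n"
        )
        for start in range(0, vals.size, 3):
            row = vals[start : start + 3]
            fh.write(" ".join(f"{v:.5f}" for v in row) + "\n")
        fh.write('attribute "dep" string "positions"\n')
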