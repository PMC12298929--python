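"""Geometric and energetic pocket descriptors, and a reduced ligand panel.

Pocket descriptors (all rigid-motion invariant, computed on the voxel set):

* **globularity** — surface area of the sphere with the pocket's volume,
  divided by the pocket's measured boundary area; 1.0 for a sphere, < 1.0
  for elongated shapes.
* **rugosity** — volume / boundary area (Å); higher for wrinkled pockets.
  (Reported literally as volume-over-surface.)
* **hydrophobic volume** — volume of pocket voxels with DRY energy below a
  threshold (default −0.5 kcal/mol on the surrogate scale).
* **hydrophilic volume** — likewise with the OH2 field below −3.5 kcal/mol.
* **exposed to solvent** — area proxy: boundary voxels at least 2.2 Å from
  every protein heavy atom, × spacing².
* **buried volume** — volume × mean per-voxel ray-collision fraction
  (50 fixed directions); the low-buriedness subvolume is reported alongside.

Boundary area uses a normal-weighted face count: every exposed voxel face
contributes spacing² × |n̂·e|, with the outward normal n̂ estimated from the
gradient of a Gaussian-smoothed occupancy and weight 1 where the gradient
vanishes.  For smooth bodies the weighted sum converges to the true surface
area (the per-axis face density is |nᵢ| dA, so weights give Σnᵢ² dA = dA),
while isolated voxels and flat slab faces reduce to the plain face count —
this keeps the closed forms exact: a single voxel of edge h has area 6h²
(rugosity h/6) and a digitized sphere of radius r approaches 4πr²
(rugosity r/3, globularity 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from sklearn.decomposition import PCA

from . import chemdata
from .grid import GridParams, VolumetricField, voxel_buriedness
from .pockets import Pocket
from .structures import Structure

DRY_THRESHOLD = -0.5       # kcal/mol, hydrophobic volume
OH2_THRESHOLD = -3.5       # kcal/mol, hydrophilic volume
SOLVENT_MIN_DIST = 2.2     # Å, exposed-to-solvent criterion
BURIED_N_RAYS = 50
# MIF surface export thresholds (hydrophobic / donor / acceptor)
MIF_EXPORT_THRESHOLDS = {"DRY": -1.0, "N1": -4.5, "O": -4.5}


# ---------------------------------------------------------------------------
# Voxel-set geometry
# ---------------------------------------------------------------------------

def _mask_from_indices(indices: np.ndarray, pad: int = 4):
    idx = np.asarray(indices, dtype=int)
    lo = idx.min(axis=0) - pad
    shape = idx.max(axis=0) - lo + 1 + pad
    mask = np.zeros(tuple(shape), dtype=bool)
    loc = idx - lo
    mask[loc[:, 0], loc[:, 1], loc[:, 2]] = True
    return mask


def surface_area(
    indices: np.ndarray, spacing: float, method: str = "weighted",
    smoothing_sigma: float = 1.0,
) -> float:
    """Boundary area (Å²) of a voxel set.

    ``method="faces"`` is the raw exposed-face count × spacing²;
    ``method="weighted"`` applies the normal-weighted correction described
    in the module docstring (the default everywhere).
    """
    mask = _mask_from_indices(indices)
    if method == "weighted":
        smooth = ndimage.gaussian_filter(mask.astype(float), sigma=smoothing_sigma)
        grads = np.gradient(smooth)
        gnorm = np.sqrt(sum(g * g for g in grads))
    total = 0.0
    for axis in range(3):
        for shift in (1, -1):
            neighbor = np.roll(mask, shift, axis=axis)
            if shift == 1:
                neighbor[(slice(None),) * axis + (0,)] = False
            else:
                neighbor[(slice(None),) * axis + (-1,)] = False
            exposed = mask & ~neighbor
            if method == "faces":
                total += exposed.sum()
            else:
                w = np.ones(exposed.sum())
                g_axis = np.abs(grads[axis][exposed])
                g_all = gnorm[exposed]
                ok = g_all > 1e-9
                w[ok] = g_axis[ok] / g_all[ok]
                total += w.sum()
    return float(total) * spacing**2


def globularity(indices: np.ndarray, spacing: float) -> float:
    """Equivalent-sphere area over measured area, capped at 1."""
    n = len(indices)
    if n == 0:
        raise ValueError("empty pocket")
    volume = n * spacing**3
    s_eq = (36.0 * np.pi) ** (1.0 / 3.0) * volume ** (2.0 / 3.0)
    s = surface_area(indices, spacing)
    return min(1.0, s_eq / s)


def rugosity(indices: np.ndarray, spacing: float) -> float:
    """Volume over boundary area (Å)."""
    n = len(indices)
    if n == 0:
        raise ValueError("empty pocket")
    return n * spacing**3 / surface_area(indices, spacing)


def _thresholded_volume(
    pocket: Pocket, field_values: np.ndarray, threshold: float
) -> float:
    vals = field_values[
        pocket.indices[:, 0], pocket.indices[:, 1], pocket.indices[:, 2]
    ]
    return float((vals < threshold).sum()) * pocket.spacing**3


def hydrophobic_volume(
    pocket: Pocket, field: VolumetricField, threshold: float = DRY_THRESHOLD
) -> float:
    """Volume of pocket voxels with DRY energy strictly below the threshold."""
    return _thresholded_volume(pocket, field.probes["DRY"], threshold)


def hydrophilic_volume(
    pocket: Pocket, field: VolumetricField, threshold: float = OH2_THRESHOLD
) -> float:
    """Volume of pocket voxels with OH2 energy strictly below the threshold."""
    return _thresholded_volume(pocket, field.probes["OH2"], threshold)


def boundary_voxels(pocket: Pocket) -> np.ndarray:
    """Indices of pocket voxels with at least one exposed face."""
    mask = _mask_from_indices(pocket.indices, pad=1)
    lo = pocket.indices.min(axis=0) - 1
    eroded = ndimage.binary_erosion(mask)
    boundary = mask & ~eroded
    return np.argwhere(boundary) + lo


def exposed_to_solvent(
    pocket: Pocket, structure: Structure, min_dist: float = SOLVENT_MIN_DIST
) -> float:
    """Area proxy (Å²): boundary voxels >= min_dist clear of the protein.

    Clearance is measured from the van der Waals *surface* (center distance
    minus the atom radius): a fully enclosed cavity, whose boundary voxels
    all hug the wall within a voxel diagonal, scores exactly 0, while open
    mouths score positive.
    """
    bnd = boundary_voxels(pocket)
    centers = pocket.origin[None, :] + bnd.astype(float) * pocket.spacing
    coords = structure.coords(heavy_only=True)
    radii = np.asarray([chemdata.vdw_radius(e)
                        for e in structure.elements(heavy_only=True)])
    tree = cKDTree(coords)
    k = min(16, len(coords))
    d, idx = tree.query(centers, k=k)
    d = d.reshape(len(centers), k)
    idx = idx.reshape(len(centers), k)
    surface_clearance = (d - radii[idx]).min(axis=1)
    return float((surface_clearance >= min_dist).sum()) * pocket.spacing**2


def buried_volume(
    pocket: Pocket,
    field: VolumetricField,
    params: GridParams | None = None,
    low_cutoff: float = 0.5,
) -> tuple[float, float]:
    """(volume-weighted buriedness in Å³, low-buriedness subvolume in Å³).

    Per-voxel buriedness is the fraction of 50 fixed-direction rays that
    collide with the protein mask; the headline value is pocket volume ×
    mean buriedness.
    """
    b = voxel_buriedness(field, pocket.indices, params)
    headline = float(pocket.volume * b.mean())
    low = float((b < low_cutoff).sum()) * pocket.spacing**3
    return headline, low


@dataclass
class PocketDescriptors:
    volume: float
    globularity: float
    rugosity: float
    hydrophilic_volume: float
    hydrophobic_volume: float
    buried_volume: float
    low_buriedness_volume: float
    exposed_to_solvent: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def compute_pocket_descriptors(
    pocket: Pocket,
    field: VolumetricField,
    structure: Structure,
    params: GridParams | None = None,
) -> PocketDescriptors:
    """The full descriptor panel for one pocket (fields must include DRY, OH2)."""
    bur, low = buried_volume(pocket, field, params)
    desc = PocketDescriptors(
        volume=pocket.volume,
        globularity=globularity(pocket.indices, pocket.spacing),
        rugosity=rugosity(pocket.indices, pocket.spacing),
        hydrophilic_volume=hydrophilic_volume(pocket, field),
        hydrophobic_volume=hydrophobic_volume(pocket, field),
        buried_volume=bur,
        low_buriedness_volume=low,
        exposed_to_solvent=exposed_to_solvent(pocket, structure),
    )
    pocket.descriptors.update(desc.as_dict())
    return desc


# ---------------------------------------------------------------------------
# Ligand descriptors
# ---------------------------------------------------------------------------

HYDROPHILIC_ELEMENTS = ("N", "O")
_POLAR_SPHERE = 4.0 / 3.0 * np.pi * 1.5**3  # Å³ per polar atom (proxy)
_APOLAR_SPHERE = 4.0 / 3.0 * np.pi * 1.7**3


def integy_moment(
    coords: np.ndarray,
    elements: list[str],
    hydrophilic_elements=HYDROPHILIC_ELEMENTS,
) -> float:
    """Distance from the center of mass to the hydrophilic-atom centroid.

    Zero (flagged via a warning) when the molecule has no hydrophilic atom.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    masses = np.asarray([chemdata.atomic_mass(e) for e in elements])
    com = (coords * masses[:, None]).sum(axis=0) / masses.sum()
    philic = [i for i, e in enumerate(elements) if e.upper() in hydrophilic_elements]
    if not philic:
        warnings.warn("no hydrophilic atoms; integy moment defined as 0",
                      stacklevel=2)
        return 0.0
    centroid = coords[philic].mean(axis=0)
    return float(np.linalg.norm(centroid - com))


def ligand_descriptors(coords: np.ndarray, elements: list[str]) -> dict:
    """Reduced surrogate 3D panel for one ligand (heavy atoms only)."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    elements = [e.upper() for e in elements]
    masses = np.asarray([chemdata.atomic_mass(e) for e in elements])
    com = (coords * masses[:, None]).sum(axis=0) / masses.sum()
    rg = float(np.sqrt((masses * ((coords - com) ** 2).sum(axis=1)).sum() / masses.sum()))
    n_polar = sum(1 for e in elements if e in HYDROPHILIC_ELEMENTS)
    n_apolar = sum(1 for e in elements if e in ("C", "S"))
    return {
        "molecular_weight": float(masses.sum()),
        "polar_volume": n_polar * _POLAR_SPHERE,
        "hydrophobic_volume": n_apolar * _APOLAR_SPHERE,
        "integy_moment": integy_moment(coords, elements)
        if n_polar
        else 0.0,
        "radius_of_gyration": rg,
        "n_hba": sum(1 for e in elements if e in ("N", "O")),
        "n_hbd": sum(1 for e in elements if e == "N"),
    }


def descriptor_pca(table: pd.DataFrame, n_components: int = 2):
    """Standardize columns, drop constant ones (warning), run PCA.

    Returns (scores DataFrame, loadings DataFrame, explained-variance
    fractions sorted descending).
    """
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns for PCA")
    std = table.std(axis=0, ddof=0)
    constant = std[std == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping constant columns: {constant}", stacklevel=2)
        table = table.drop(columns=constant)
        std = std.drop(constant)
    if table.shape[1] < 2:
        raise ValueError("fewer than 2 non-constant columns")
    z = (table - table.mean(axis=0)) / std
    n_components = min(n_components, z.shape[1], z.shape[0])
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(z.to_numpy())
    cols = [f"PC{i + 1}" for i in range(n_components)]
    scores_df = pd.DataFrame(scores, index=table.index, columns=cols)
    loadings_df = pd.DataFrame(pca.components_.T, index=table.columns, columns=cols)
    return scores_df, loadings_df, pca.explained_variance_ratio_


def export_mif_surfaces(
    field: VolumetricField, out_prefix: str,
    thresholds: dict = MIF_EXPORT_THRESHOLDS,
) -> list[str]:
    """Write thresholded probe fields (OpenDX text) for visualization.

    Note: the hydrophobic surface is exported from the DRY probe; one cited
    figure calls this probe "CRY", treated here as the same hydrophobic
    probe.
    """
    from .grid import write_dx

    paths = []
    for probe, thr in thresholds.items():
        if probe not in field.probes:
            continue
        vals = field.probes[probe]
        clipped = VolumetricField(
            origin=field.origin,
            spacing=field.spacing,
            dims=field.dims,
            inside_protein=field.inside_protein,
            probes={probe: np.where(vals < thr, vals, 0.0)},
        )
        path = f"{out_prefix}_{probe}.dx"
        write_dx(clipped, probe, path)
        paths.append(path)
    return paths
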