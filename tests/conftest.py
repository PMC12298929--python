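"""Shared fixtures: synthetic structures with known ground truth.

Everything is generated at test time from seeded specs; the expensive
detection runs are session-scoped so many tests can share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from oncopocketome.classify import classify_complex, classify_detached
from oncopocketome.grid import GridParams, compute_fields
from oncopocketome.pockets import detect_pockets
from oncopocketome.structures import split_partners
from oncopocketome.synthetic import (
    SyntheticSpec,
    make_cavity_monomer,
    make_homolog_ensemble,
    make_interface_dimer,
)


@pytest.fixture(scope="session")
def cavity_bundle():
    """Cavity monomer (~350 Å³), its fields and its detected pockets."""
    spec = SyntheticSpec(kind="cavity_monomer", cavity_radius=4.37, seed=11)
    structure, truth = make_cavity_monomer(spec)
    params = GridParams()
    field = compute_fields(structure, params, probes=("DRY", "OH2"))
    pockets = detect_pockets(
        structure, source="detached_partner_A", grid_params=params, field=field
    )
    return {
        "spec": spec,
        "structure": structure,
        "truth": truth,
        "field": field,
        "params": params,
        "pockets": pockets,
    }


@pytest.fixture(scope="session")
def hemisphere_bundle():
    """Surface-open hemispherical invagination (mouth at z = 0)."""
    spec = SyntheticSpec(
        kind="cavity_monomer", cavity_radius=5.0, seed=12,
        cavity_style="hemisphere",
    )
    structure, truth = make_cavity_monomer(spec)
    params = GridParams()
    field = compute_fields(structure, params, probes=("DRY",))
    return {"structure": structure, "truth": truth, "field": field,
            "params": params}


@pytest.fixture(scope="session")
def interface_bundle():
    """Interface dimer: cavity on A, B rod inserted; all three pocket runs."""
    spec = SyntheticSpec(kind="interface_dimer", cavity_radius=5.5, seed=13)
    complex_structure, truth = make_interface_dimer(spec)
    part_a, part_b = split_partners(complex_structure)
    pockets_a = detect_pockets(part_a, source="detached_partner_A")
    pockets_complex = detect_pockets(complex_structure, source="complex")
    for p in pockets_a:
        classify_detached(p, part_b)
    for p in pockets_complex:
        classify_complex(p)
    return {
        "complex": complex_structure,
        "truth": truth,
        "part_a": part_a,
        "part_b": part_b,
        "pockets_a": pockets_a,
        "pockets_complex": pockets_complex,
    }


@pytest.fixture(scope="session")
def flat_bundle():
    """Flat dimer in contact: a groove exists only in the complex."""
    spec = SyntheticSpec(kind="flat_dimer", seed=14)
    complex_structure, truth = make_interface_dimer(spec)
    part_a, _ = split_partners(complex_structure)
    pockets_complex = detect_pockets(complex_structure, source="complex")
    pockets_a = detect_pockets(part_a, source="detached_partner_A")
    for p in pockets_complex:
        classify_complex(p)
    return {
        "complex": complex_structure,
        "truth": truth,
        "part_a": part_a,
        "pockets_a": pockets_a,
        "pockets_complex": pockets_complex,
    }


@pytest.fixture(scope="session")
def homolog_bundle():
    """Base monomer + rigid-motion copies with planted ligands."""
    spec = SyntheticSpec(
        kind="homolog_ensemble", cavity_radius=5.0, seed=15,
        ligand_plan=[(4, 10), (8, 10), (2, 10), (10, 10)],
    )
    base, base_truth, entries = make_homolog_ensemble(spec)
    pockets = detect_pockets(base, source="detached_partner_A")
    return {"spec": spec, "base": base, "truth": base_truth,
            "entries": entries, "pockets": pockets}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
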