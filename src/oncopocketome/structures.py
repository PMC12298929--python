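"""Reading, cleaning and splitting protein structures.

A complex destined for pocket analysis is reduced to the two chains that
form the protein-protein interaction: waters, nucleic acids, crystallization
artifacts and stray ligands are removed, while biologically bound cofactors
(NAD, FAD, GSH, ...) are retained and flagged.  Every removal is logged so a
preparation can be audited.

PDB files are parsed and written through :mod:`gemmi`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import gemmi
import numpy as np

from . import chemdata

ResidueId = tuple[str, int, str]  # (chain id, sequence number, insertion code)


@dataclass(frozen=True)
class AtomRecord:
    """One heavy (or hydrogen) atom of a structure."""

    serial: int
    name: str
    element: str
    coord: tuple[float, float, float]
    residue_name: str
    chain: str
    resseq: int
    icode: str = ""
    het: bool = False
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def residue_id(self) -> ResidueId:
        return (self.chain, self.resseq, self.icode)

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Structure:
    """An atomic model: either a raw parse or a prepared (cleaned) one."""

    atoms: list[AtomRecord]
    provenance: str = ""
    retained_cofactors: list[ResidueId] = field(default_factory=list)
    prep_log: list[str] = field(default_factory=list)

    # -- basic accessors ---------------------------------------------------
    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    @property
    def residue_ids(self) -> list[ResidueId]:
        seen: dict[ResidueId, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_id, None)
        return list(seen)

    def coords(self, heavy_only: bool = True) -> np.ndarray:
        pts = [a.coord for a in self.atoms if (a.is_heavy or not heavy_only)]
        return np.asarray(pts, dtype=float).reshape(-1, 3)

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_heavy]

    def elements(self, heavy_only: bool = True) -> list[str]:
        return [a.element for a in self.atoms if (a.is_heavy or not heavy_only)]

    def subset(self, predicate) -> "Structure":
        return Structure(
            atoms=[a for a in self.atoms if predicate(a)],
            provenance=self.provenance,
            retained_cofactors=[
                r
                for r in self.retained_cofactors
                if any(a.residue_id == r for a in self.atoms if predicate(a))
            ],
        )

    def residue_atoms(self) -> dict[ResidueId, list[AtomRecord]]:
        out: dict[ResidueId, list[AtomRecord]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_id, []).append(a)
        return out

    def translated(self, shift: Sequence[float]) -> "Structure":
        s = np.asarray(shift, dtype=float)
        atoms = [
            replace(a, coord=tuple(np.asarray(a.coord) + s)) for a in self.atoms
        ]
        return Structure(atoms, self.provenance, list(self.retained_cofactors))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        atoms = [
            replace(a, coord=tuple(R @ np.asarray(a.coord) + t))
            for a in self.atoms
        ]
        return Structure(atoms, self.provenance, list(self.retained_cofactors))


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

def read_pdb(path: str | os.PathLike) -> Structure:
    """Parse a PDB (or mmCIF) file into a :class:`Structure`."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    atoms: list[AtomRecord] = []
    serial = 0
    model = st[0]
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            for atom in res:
                serial += 1
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=atom.name,
                        element=atom.element.name.upper(),
                        coord=(atom.pos.x, atom.pos.y, atom.pos.z),
                        residue_name=res.name.strip(),
                        chain=chain.name,
                        resseq=res.seqid.num,
                        icode=(res.seqid.icode or "").strip(),
                        het=het,
                        occupancy=atom.occ,
                        altloc="" if atom.altloc in ("", "\0") else atom.altloc,
                    )
                )
    if not atoms:
        raise ValueError(f"no atoms parsed from {path}")
    return Structure(atoms, provenance=os.path.basename(str(path)))


def to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.provenance or "model"
    model = gemmi.Model("1")
    # group atoms per chain first: gemmi references are invalidated by
    # later add_chain/add_residue calls, so each chain is built completely
    # before being handed to the model
    by_chain: dict[str, list[AtomRecord]] = {}
    for a in structure.atoms:
        by_chain.setdefault(a.chain, []).append(a)
    for chain_name, atoms in by_chain.items():
        ch = gemmi.Chain(chain_name)
        for a in atoms:
            res = None
            if len(ch) > 0:
                last = ch[len(ch) - 1]
                if (
                    last.seqid.num == a.resseq
                    and (last.seqid.icode or " ").strip() == a.icode
                    and last.name == a.residue_name
                ):
                    res = last
            if res is None:
                r = gemmi.Residue()
                r.name = a.residue_name
                r.seqid = gemmi.SeqId(a.resseq, a.icode or " ")
                r.het_flag = "H" if a.het else "A"
                ch.add_residue(r)
                res = ch[len(ch) - 1]
            atom = gemmi.Atom()
            atom.name = a.name
            atom.element = gemmi.Element(a.element.capitalize())
            atom.pos = gemmi.Position(*a.coord)
            atom.occ = a.occupancy
            atom.altloc = a.altloc or "\0"
            res.add_atom(atom)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(structure: Structure, path: str | os.PathLike) -> None:
    to_gemmi(structure).write_minimal_pdb(str(path))


# ---------------------------------------------------------------------------
# Preparation
# ---------------------------------------------------------------------------

def _resolve_altlocs(atoms: list[AtomRecord], log: list[str]) -> list[AtomRecord]:
    """Keep the highest-occupancy conformer per (residue, atom name).

    Ties are broken by altloc letter order.
    """
    groups: dict[tuple[ResidueId, str], list[AtomRecord]] = {}
    for a in atoms:
        groups.setdefault((a.residue_id, a.name), []).append(a)
    kept: list[AtomRecord] = []
    for key, grp in groups.items():
        if len(grp) == 1:
            kept.append(grp[0])
            continue
        best = sorted(grp, key=lambda a: (-a.occupancy, a.altloc))[0]
        kept.append(replace(best, altloc=""))
        log.append(
            f"{key[0][0]}/{key[0][1]}{key[0][2]} {key[1]}: kept altloc "
            f"'{best.altloc}' of {len(grp)} conformers"
        )
    kept.sort(key=lambda a: a.serial)
    return kept


def prepare(
    raw: Structure,
    partner_chains: tuple[str, str],
    cofactor_whitelist: Iterable[str] = chemdata.DEFAULT_COFACTORS,
    artifact_blacklist: Iterable[str] = chemdata.DEFAULT_ARTIFACTS,
) -> Structure:
    """Clean a raw structure down to the two interacting partner chains.

    Removes waters, nucleic acids, artifacts, metals and stray ligands;
    retains whitelisted cofactors on the partner chains; resolves alternate
    locations.  Raises if a partner chain is absent or nothing remains.
    """
    cofactors = frozenset(r.upper() for r in cofactor_whitelist)
    artifacts = frozenset(r.upper() for r in artifact_blacklist)
    pa, pb = partner_chains
    present = set(raw.chains)
    for ch in (pa, pb):
        if ch not in present:
            raise ValueError(f"partner chain {ch!r} not present in structure")

    log: list[str] = []
    retained: list[ResidueId] = []
    kept: list[AtomRecord] = []
    dropped: dict[tuple[ResidueId, str], str] = {}

    for rid, atoms in raw.residue_atoms().items():
        name = atoms[0].residue_name.upper()
        het = atoms[0].het
        reason = None
        if rid[0] not in (pa, pb):
            reason = "chain not a declared partner"
        elif name in chemdata.WATER_RESIDUES:
            reason = "water"
        elif name in chemdata.NUCLEIC_RESIDUES:
            reason = "nucleic acid"
        elif name in chemdata.AMINO_ACIDS and not het:
            reason = None
        elif name in cofactors:
            retained.append(rid)
            reason = None
        elif name in chemdata.METAL_RESIDUES:
            reason = "metal"
        elif name in artifacts:
            reason = "crystallization artifact"
        elif het or name not in chemdata.AMINO_ACIDS:
            reason = "ligand not on cofactor whitelist"
        if reason is None:
            kept.extend(atoms)
        else:
            dropped[(rid, name)] = reason

    for (rid, name), reason in sorted(dropped.items()):
        log.append(f"{name} {rid[0]}/{rid[1]}{rid[2]} removed: {reason}")

    kept = _resolve_altlocs(kept, log)
    if not kept:
        raise ValueError("structure empty after preparation")
    return Structure(
        atoms=kept,
        provenance=raw.provenance,
        retained_cofactors=sorted(retained),
        prep_log=log,
    )


def split_partners(complex_structure: Structure) -> tuple[Structure, Structure]:
    """Split a prepared two-chain complex into its detached partners.

    Cofactor (HETATM) residues are assigned to the protein chain with the
    nearest heavy atom, so a cofactor bound across the interface still ends
    up on exactly one side and the two outputs partition the atoms.
    """
    protein_chains = sorted(
        {a.chain for a in complex_structure.atoms if not a.het}
    )
    if len(protein_chains) != 2:
        raise ValueError(
            f"expected exactly two protein chains, found {protein_chains}"
        )
    ca, cb = protein_chains
    chain_pts = {
        c: np.asarray(
            [a.coord for a in complex_structure.atoms if not a.het and a.chain == c and a.is_heavy]
        )
        for c in (ca, cb)
    }

    def owner(rid: ResidueId, atoms: list[AtomRecord]) -> str:
        if not atoms[0].het:
            return rid[0]
        pts = np.asarray([a.coord for a in atoms if a.is_heavy])
        dmin = {}
        for c in (ca, cb):
            diff = chain_pts[c][None, :, :] - pts[:, None, :]
            dmin[c] = float(np.sqrt((diff**2).sum(axis=2)).min())
        return ca if dmin[ca] <= dmin[cb] else cb

    part: dict[str, list[AtomRecord]] = {ca: [], cb: []}
    cof: dict[str, list[ResidueId]] = {ca: [], cb: []}
    for rid, atoms in complex_structure.residue_atoms().items():
        dest = owner(rid, atoms)
        part[dest].extend(atoms)
        if rid in complex_structure.retained_cofactors:
            cof[dest].append(rid)

    out = []
    for c in (ca, cb):
        out.append(
            Structure(
                atoms=sorted(part[c], key=lambda a: a.serial),
                provenance=f"{complex_structure.provenance}:{c}",
                retained_cofactors=sorted(cof[c]),
            )
        )
    return out[0], out[1]
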