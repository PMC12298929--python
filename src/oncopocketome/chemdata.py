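"""Small chemical reference tables shared across modules.

These are curated defaults, exposed so a pipeline config can override them:
the preparation rules only say *what kind* of residue to drop or keep
(waters, nucleic acids, crystallization artifacts, cofactors), not the
exact residue codes, which differ between PDB entries.
"""

from __future__ import annotations

#: Water residue names (always removed during preparation).
WATER_RESIDUES = frozenset({"HOH", "WAT", "DOD", "H2O", "TIP", "SOL"})

#: Nucleic-acid residue names (RNA + DNA, removed during preparation).
NUCLEIC_RESIDUES = frozenset(
    {"A", "C", "G", "U", "I", "DA", "DC", "DG", "DT", "DU", "DI", "N"}
)

#: Cofactors retained on the partner chains during preparation.
DEFAULT_COFACTORS = frozenset(
    {
        "NAD", "NAI", "NAP", "NDP",  # nicotinamide dinucleotides
        "FAD", "FMN",                # flavins
        "GSH", "GDS",                # glutathione
        "HEM", "HEC", "HEA", "HEB",  # hemes
        "SAM", "SAH",                # S-adenosyl methionine/homocysteine
        "PLP", "TPP", "TDP",         # pyridoxal / thiamine phosphates
        "COA", "ACO",                # coenzyme A
        "BTN", "B12",                # biotin, cobalamin
    }
)

#: Common crystallization additives treated as artifacts.
DEFAULT_ARTIFACTS = frozenset(
    {
        "GOL", "EDO", "PEG", "PG4", "P6G", "1PE", "2PE", "PGE", "MPD",
        "DMS", "ACT", "ACY", "FMT", "EOH", "IPA", "MOH", "BME", "TRS",
        "EPE", "MES", "CIT", "FLC", "TLA", "SO4", "PO4", "NO3", "CO3",
        "BCT", "CL", "BR", "IOD", "F", "NH4", "AZI", "SCN", "CAC",
    }
)

#: Monatomic metal ions (excluded from ligand harvesting).
METAL_RESIDUES = frozenset(
    {
        "NA", "K", "LI", "RB", "CS", "MG", "CA", "SR", "BA", "ZN", "FE",
        "FE2", "MN", "CU", "CU1", "NI", "CO", "CD", "HG", "PB", "AL",
        "AU", "AG", "PT", "W", "MO", "V", "CR", "GA", "YB", "SM",
    }
)

#: Standard amino-acid residue names (kept as polymer).
AMINO_ACIDS = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
        "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
        "TYR", "VAL", "MSE", "SEC", "PYL",
    }
)

#: Van der Waals radii (Å) used for the protein occupancy mask.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}
DEFAULT_VDW = 1.70

#: Atomic masses (Da) for centers of mass and molecular weights.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "SE": 78.971,
}
DEFAULT_MASS = 12.011


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


def atomic_mass(element: str) -> float:
    return ATOMIC_MASSES.get(element.upper(), DEFAULT_MASS)
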