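"""End-to-end orchestration: config, per-interaction pocket runs, outputs.

An interaction table (CSV: protein_a, protein_b, cancer_types
semicolon-separated, structure_file, chain_a, chain_b) drives the run.  For
every interaction the complex is prepared, pockets are detected three ways
(detached partner A, detached partner B, whole complex), classified,
described, and aggregated into per-cancer networks with hub flags.  Every
output table carries the config hash for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field as dfield
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as cls
from . import descriptors as desc
from . import ligands as lig
from . import network as net
from . import pockets as pk
from . import structures as sio
from . import synthetic as syn
from .grid import GridParams, compute_fields

logger = logging.getLogger("oncopocketome")


@dataclass
class PipelineConfig:
    grid: GridParams = dfield(default_factory=GridParams)
    pocket: pk.PocketParams = dfield(default_factory=pk.PocketParams)
    partner_fraction_threshold: float = 0.0
    max_rmsd: float = lig.DEFAULT_MAX_RMSD
    overlap_threshold: float = lig.DEFAULT_OVERLAP_THRESHOLD
    min_ligand_heavy_atoms: int = lig.DEFAULT_MIN_HEAVY_ATOMS
    contact_cutoff: float = net.DEFAULT_CONTACT_CUTOFF
    dry_volume_threshold: float = desc.DRY_THRESHOLD
    oh2_volume_threshold: float = desc.OH2_THRESHOLD
    solvent_min_dist: float = desc.SOLVENT_MIN_DIST
    seed: int = 0
    output_dir: str = "pocketome_out"

    def to_dict(self) -> dict:
        d = asdict(self)
        # tuples -> lists for clean YAML round-trips
        return json.loads(json.dumps(d, default=list))

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls_, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls_.from_dict(d)

    @classmethod
    def from_dict(cls_, d: dict) -> "PipelineConfig":
        d = dict(d)
        grid = d.pop("grid", {})
        pocket = d.pop("pocket", {})
        for key in ("probe_set",):
            if key in grid and isinstance(grid[key], list):
                grid[key] = tuple(grid[key])
        gp = GridParams(**grid)
        pp = pk.PocketParams(**pocket)
        valid = {f.name for f in dataclasses.fields(cls_)}
        rest = {k: v for k, v in d.items() if k in valid}
        return cls_(grid=gp, pocket=pp, **rest)

    def config_hash(self) -> str:
        """Hash of the scientific parameters (the output path is excluded)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _detect_all(structure: sio.Structure, config: PipelineConfig):
    """Detached-A, detached-B and complex pocket sets for one complex."""
    part_a, part_b = sio.split_partners(structure)
    out = {}
    fields = {}
    for source, st in (
        ("detached_partner_A", part_a),
        ("detached_partner_B", part_b),
        ("complex", structure),
    ):
        field = compute_fields(st, config.grid, probes=("DRY", "OH2"))
        out[source] = pk.detect_pockets(
            st, source=source, grid_params=config.grid,
            pocket_params=config.pocket, field=field,
        )
        fields[source] = field
    return part_a, part_b, out, fields


def _classify_all(pockets_by_source, part_a, part_b, config: PipelineConfig):
    rule = cls.ClassificationRule(config.partner_fraction_threshold)
    for p in pockets_by_source["detached_partner_A"]:
        cls.classify_detached(p, part_b, rule)
    for p in pockets_by_source["detached_partner_B"]:
        cls.classify_detached(p, part_a, rule)
    for p in pockets_by_source["complex"]:
        cls.classify_complex(p)


def _pocket_rows(interaction_id, row, pockets_by_source, fields, structures,
                 config: PipelineConfig):
    rows = []
    for source, plist in pockets_by_source.items():
        st = structures[source]
        field = fields[source]
        for p in plist:
            d = desc.compute_pocket_descriptors(p, field, st, config.grid)
            rows.append(
                {
                    "interaction": interaction_id,
                    "protein_a": row.protein_a,
                    "protein_b": row.protein_b,
                    "pocket_id": p.pocket_id,
                    "source": source,
                    "category": p.category,
                    "n_voxels": p.n_voxels,
                    "volume": round(p.volume, 3),
                    "n_lining_residues": len(p.lining_residues),
                    "lining_residues": ";".join(
                        f"{c}{n}{i}" for c, n, i in sorted(p.lining_residues)
                    ),
                    "ligand_bound": p.is_ligand_bound,
                    **{k: round(v, 3) for k, v in d.as_dict().items()},
                }
            )
    return rows


def run_pocketome(
    config: PipelineConfig,
    interactions: pd.DataFrame,
    structure_dir: str | os.PathLike,
) -> dict:
    """Run the full pocketome over an interaction table.

    Returns a bundle dict with the pocket table, per-protein summary,
    per-cancer networks and hub table; also writes them under
    ``config.output_dir``.  Unreadable structures skip their row (logged);
    the bundle records partial failure.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    pocket_rows: list[dict] = []
    failures: list[str] = []
    summary_counts: dict[str, dict] = {}

    for i, row in enumerate(interactions.itertuples(index=False)):
        interaction_id = f"{row.protein_a}--{row.protein_b}"
        path = Path(structure_dir) / str(row.structure_file)
        try:
            raw = sio.read_pdb(path)
            prepared = sio.prepare(raw, (str(row.chain_a), str(row.chain_b)))
            part_a, part_b, pockets_by_source, fields = _detect_all(
                prepared, config)
        except Exception as exc:  # a bad row must not kill the run
            logger.warning("skipping %s: %s", interaction_id, exc)
            failures.append(f"{interaction_id}: {exc}")
            continue
        _classify_all(pockets_by_source, part_a, part_b, config)
        structures = {
            "detached_partner_A": part_a,
            "detached_partner_B": part_b,
            "complex": prepared,
        }
        pocket_rows.extend(
            _pocket_rows(interaction_id, row, pockets_by_source, fields,
                         structures, config)
        )
        for prot, source in (
            (str(row.protein_a), "detached_partner_A"),
            (str(row.protein_b), "detached_partner_B"),
        ):
            c = summary_counts.setdefault(
                prot, {"n_interface_pockets": 0, "n_allosteric_pockets": 0})
            for p in pockets_by_source[source]:
                if p.category == cls.INTERFACE:
                    c["n_interface_pockets"] += 1
                elif p.category == cls.ALLOSTERIC:
                    c["n_allosteric_pockets"] += 1
        logger.info(
            "%s: A=%d B=%d complex=%d pockets", interaction_id,
            len(pockets_by_source["detached_partner_A"]),
            len(pockets_by_source["detached_partner_B"]),
            len(pockets_by_source["complex"]),
        )

    pockets_df = pd.DataFrame(pocket_rows)
    summary_df = pd.DataFrame(
        [{"protein": k, **v} for k, v in sorted(summary_counts.items())]
    )

    cancers = sorted(
        {
            c.strip()
            for cell in interactions["cancer_types"].astype(str)
            for c in cell.split(";")
            if c.strip()
        }
    )
    networks = {
        cancer: net.build_network(interactions, summary_df, cancer)
        for cancer in cancers
    }
    hubs = net.hub_table(networks)

    category_tally = (
        pockets_df.groupby("category").size().to_dict() if len(pockets_df) else {}
    )
    bundle = {
        "config_hash": chash,
        "pockets": pockets_df,
        "summary": summary_df,
        "networks": networks,
        "hubs": hubs,
        "category_tally": category_tally,
        "failures": failures,
    }

    for name, df in (("pockets", pockets_df), ("protein_summary", summary_df),
                     ("hubs", hubs)):
        out = df.copy()
        out.insert(0, "config_hash", chash)
        out.to_csv(outdir / f"{name}.csv", index=False)
    for cancer, g in networks.items():
        net.export_graphml(g, str(outdir / f"network_{cancer}.graphml"))
        net.export_cytoscape_csv(
            g, str(outdir / f"edges_{cancer}.csv"), str(outdir / f"nodes_{cancer}.csv")
        )
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(
            {
                "config_hash": chash,
                "n_interactions": int(len(interactions)),
                "n_failures": len(failures),
                "category_tally": {k: int(v) for k, v in sorted(category_tally.items())},
            },
            fh, indent=2, sort_keys=True,
        )
    return bundle


def validate_sites(config: PipelineConfig, cases: list[dict]) -> pd.DataFrame:
    """Known-binder validation: per case, was a pocket found at the site,
    and the MCC of the best pocket's lining residues.

    Each case: {"name", "structure": Structure (binder removed),
    "binder": Structure}.  Detection = any pocket whose lining intersects
    the observed contact residues; MCC universe = all residues of the
    evaluated structure.
    """
    rows = []
    for case in cases:
        st, binder = case["structure"], case["binder"]
        observed = net.observed_contact_residues(st, binder, config.contact_cutoff)
        pockets = pk.detect_pockets(
            st, source="detached_partner_A",
            grid_params=config.grid, pocket_params=config.pocket,
        )
        universe = frozenset(st.residue_ids)
        best_mcc, detected = float("nan"), False
        for p in pockets:
            if p.lining_residues & observed:
                detected = True
            comp = net.compute_mcc(p.lining_residues, observed, universe)
            if np.isnan(best_mcc) or comp.mcc > best_mcc:
                best_mcc = comp.mcc
        rows.append(
            {
                "case": case.get("name", "case"),
                "n_pockets": len(pockets),
                "detected": detected,
                "best_mcc": best_mcc,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["detection_rate"] = (
        float(df["detected"].mean()) if len(df) else float("nan")
    )
    return df


# ---------------------------------------------------------------------------
# Synthetic demo
# ---------------------------------------------------------------------------

def write_demo_inputs(directory: str | os.PathLike, seed: int = 0) -> pd.DataFrame:
    """Generate the synthetic demo complexes and their interaction table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dimer, _ = syn.make_interface_dimer(
        syn.SyntheticSpec(kind="interface_dimer", cavity_radius=5.5, seed=seed))
    flat, _ = syn.make_interface_dimer(
        syn.SyntheticSpec(kind="flat_dimer", seed=seed + 1))
    apart, _ = syn.make_interface_dimer(
        syn.SyntheticSpec(kind="flat_dimer", seed=seed + 2, chain_separation=50.0))
    names = ["ifdimer.pdb", "flatdimer.pdb", "apartdimer.pdb"]
    for st, name in zip((dimer, flat, apart), names):
        sio.write_pdb(st, directory / name)
    table = pd.DataFrame(
        [
            ("PROT1", "PROT2", "LUSC;HNSC", names[0], "A", "B"),
            ("PROT3", "PROT4", "LUSC", names[1], "A", "B"),
            ("PROT5", "PROT6", "BRCA", names[2], "A", "B"),
        ],
        columns=["protein_a", "protein_b", "cancer_types", "structure_file",
                 "chain_a", "chain_b"],
    )
    table.to_csv(directory / "interactions.csv", index=False)
    return table


def run_demo(output_dir: str | os.PathLike, seed: int = 0) -> dict:
    """Deterministic end-to-end run on the synthetic fixtures."""
    output_dir = Path(output_dir)
    config = PipelineConfig(seed=seed, output_dir=str(output_dir))
    table = write_demo_inputs(output_dir / "structures", seed=seed)
    bundle = run_pocketome(config, table, output_dir / "structures")

    # ligand mapping on a synthetic homolog ensemble
    spec = syn.SyntheticSpec(
        kind="homolog_ensemble", cavity_radius=5.0, seed=seed,
        ligand_plan=[(8, 10), (2, 10)],
    )
    base, _, entries = syn.make_homolog_ensemble(spec)
    base_pockets = pk.detect_pockets(
        base, source="detached_partner_A",
        grid_params=config.grid, pocket_params=config.pocket,
    )
    lig_rows = []
    if base_pockets:
        pocket = base_pockets[0]
        for entry in entries:
            sup = lig.superpose(entry.structure, base)
            if sup.rmsd > config.max_rmsd:
                continue
            for pose in lig.harvest_ligands(entry.structure, sup):
                if pose.excluded:
                    continue
                frac = lig.overlap_fraction(pose, pocket)
                lig_rows.append(
                    {
                        "ligand_id": pose.ligand_id,
                        "n_atoms": len(pose.atoms),
                        "pocket_id": pocket.pocket_id,
                        "overlap_fraction": round(frac, 4),
                        "bound": frac > config.overlap_threshold,
                    }
                )
    lig_df = pd.DataFrame(lig_rows)
    lig_df.insert(0, "config_hash", config.config_hash())
    lig_df.to_csv(output_dir / "ligands.csv", index=False)
    bundle["ligands"] = lig_df
    return bundle
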