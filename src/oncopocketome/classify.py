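"""Pocket classification: interface, allosteric-like, equilibrium.

Three categories, determined by where a pocket was found and who lines it:

* *interface* — detected on a detached partner, and the pocket encloses part
  of the other partner (partner fraction strictly greater than the rule
  threshold, default 0);
* *allosteric-like* — detected on a detached partner, away from the
  interaction region (candidate degrader anchor sites);
* *equilibrium* — detected on the bound complex and lined by residues from
  both chains; it exists only in the bound state.

"Fraction of volume of the interacting partner" is operationalized as the
fraction of partner heavy-atom centers falling inside pocket voxels: exact,
order-independent and checkable by a counting oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .pockets import Pocket
from .structures import Structure

INTERFACE = "interface"
ALLOSTERIC = "allosteric_like"
EQUILIBRIUM = "equilibrium"
UNCLASSIFIED = "unclassified"

DETACHED_SOURCES = ("detached_partner_A", "detached_partner_B")


@dataclass
class ClassificationRule:
    """Strict-inequality threshold on the partner fraction (default 0)."""

    partner_fraction_threshold: float = 0.0
    both_partners_required: bool = True

    def __post_init__(self):
        if not (0.0 <= self.partner_fraction_threshold < 1.0):
            raise ValueError("partner_fraction_threshold must be in [0, 1)")


def partner_fraction(pocket: Pocket, partner: Structure) -> float:
    """Fraction of partner heavy-atom centers lying inside pocket voxels."""
    pts = partner.coords(heavy_only=True)
    if len(pts) == 0:
        return 0.0
    lo = pocket.origin + pocket.indices.min(axis=0) * pocket.spacing
    hi = pocket.origin + pocket.indices.max(axis=0) * pocket.spacing
    # frame sanity check: a partner entirely far outside the pocket's box
    # most likely means the two objects are in different frames
    margin = 25.0
    if np.any(pts.max(axis=0) < lo - margin) or np.any(pts.min(axis=0) > hi + margin):
        if np.linalg.norm(pts.mean(axis=0) - (lo + hi) / 2) > 100.0:
            warnings.warn(
                "partner bounding box is far from the pocket grid; "
                "frames may differ — returning fraction 0",
                stacklevel=2,
            )
            return 0.0
    inside = pocket.contains_points(pts)
    return float(inside.sum()) / float(len(pts))


def classify_detached(
    pocket: Pocket, partner: Structure, rule: ClassificationRule | None = None
) -> str:
    """Interface iff the partner fraction strictly exceeds the threshold."""
    rule = rule or ClassificationRule()
    if pocket.source not in DETACHED_SOURCES:
        raise ValueError(
            f"classify_detached expects a detached-partner pocket, got "
            f"source={pocket.source!r}"
        )
    frac = partner_fraction(pocket, partner)
    category = INTERFACE if frac > rule.partner_fraction_threshold else ALLOSTERIC
    pocket.category = category
    pocket.descriptors["partner_fraction"] = frac
    return category


def classify_complex(pocket: Pocket, chain_of_residue: dict | None = None) -> str:
    """Equilibrium iff lining residues are contributed by both chains.

    ``chain_of_residue`` maps residue id -> chain id; by default the chain
    is read off the residue id itself.
    """
    if pocket.source != "complex":
        raise ValueError(
            f"classify_complex expects a complex pocket, got source="
            f"{pocket.source!r}"
        )
    chains = set()
    for rid in pocket.lining_residues:
        if chain_of_residue is not None:
            if rid not in chain_of_residue:
                raise KeyError(f"residue {rid} has no chain assignment")
            chains.add(chain_of_residue[rid])
        else:
            chains.add(rid[0])
    category = EQUILIBRIUM if len(chains) >= 2 else UNCLASSIFIED
    pocket.category = category
    return category


def partner_residue_share(pocket: Pocket) -> tuple[float, float]:
    """Per-chain fractions of an equilibrium pocket's lining residues.

    Returned in chain-id order; the two fractions sum to 1.
    """
    if pocket.category != EQUILIBRIUM:
        raise ValueError("partner_residue_share is defined for equilibrium pockets")
    chains = sorted({rid[0] for rid in pocket.lining_residues})
    counts = {c: 0 for c in chains}
    for rid in pocket.lining_residues:
        counts[rid[0]] += 1
    total = sum(counts.values())
    fracs = tuple(counts[c] / total for c in chains)
    if len(fracs) != 2:
        raise ValueError(
            f"equilibrium pocket lined by {len(fracs)} chains; expected 2"
        )
    return fracs
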