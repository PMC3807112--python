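"""Sub-network robustness (degrees of freedom) and essential metabolites.

Every metabolite *unique* to a sub-network — touched by at least one member
reaction and by no reaction outside it — contributes a steady-state mass
balance over the member fluxes.  The degrees of freedom of that system,

    DOF = |reactions| − rank(S restricted to unique metabolites × members),

measure robustness: a series pathway has DOF 1 (one flux sets them all, so
any single knockout stops the whole pathway), whereas n parallel reactions
with no unique metabolites keep n degrees of freedom and shrug off single
knockouts.  Low DOF marks fragile, drug-attractive sub-networks.

Blocking a unique metabolite m (mimicking competitive inhibition of every
enzyme processing m) removes all member reactions touching m; if the DOF
remaining for the surviving reactions is zero, m is *essential* — the
sub-network cannot operate without it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import MetabolicModel
from .subnetworks import SubNetwork

__all__ = [
    "RobustnessReport",
    "unique_metabolites",
    "subnetwork_dof",
    "essential_metabolites",
    "analyze_subnetwork",
    "robustness_table",
]

RANK_RTOL = 1e-9  # singular values ≤ RANK_RTOL·σ_max count as zero


def _members(subnet: "SubNetwork | set[str] | frozenset[str]") -> set[str]:
    if isinstance(subnet, SubNetwork):
        return set(subnet.reactions)
    return set(subnet)


def unique_metabolites(
    subnet: "SubNetwork | set[str]", model: MetabolicModel
) -> frozenset[str]:
    """Non-boundary metabolites touched only by the sub-network's reactions."""
    members = _members(subnet)
    unknown = members - set(model.reaction_ids)
    if unknown:
        raise KeyError(f"sub-network reactions not in model: {sorted(unknown)}")
    inside: set[str] = set()
    outside: set[str] = set()
    for rxn in model.reactions:
        target = inside if rxn.id in members else outside
        target.update(rxn.stoichiometry)
    return frozenset(
        m for m in inside - outside if not model.get_metabolite(m).is_boundary
    )


def _rank(S: np.ndarray) -> int:
    if S.size == 0:
        return 0
    sv = np.linalg.svd(S, compute_uv=False)
    if sv.size == 0 or sv[0] == 0:
        return 0
    return int(np.sum(sv > RANK_RTOL * sv[0]))


def _restricted_matrix(
    model: MetabolicModel, reactions: list[str], metabolites: list[str]
) -> np.ndarray:
    S = np.zeros((len(metabolites), len(reactions)))
    row = {m: i for i, m in enumerate(metabolites)}
    for j, rid in enumerate(reactions):
        for mid, coef in model.get_reaction(rid).stoichiometry.items():
            if mid in row:
                S[row[mid], j] = coef
    return S


def subnetwork_dof(
    subnet: "SubNetwork | set[str]",
    model: MetabolicModel,
    unique: frozenset[str] | None = None,
) -> int:
    """DOF = |member reactions| − rank of the unique-metabolite balances."""
    members = sorted(_members(subnet))
    if unique is None:
        unique = unique_metabolites(subnet, model)
    S = _restricted_matrix(model, members, sorted(unique))
    return len(members) - _rank(S)


def essential_metabolites(
    subnet: "SubNetwork | set[str]", model: MetabolicModel
) -> frozenset[str]:
    """Unique metabolites whose blocking drives the remaining DOF to zero.

    Blocking m removes every member reaction with a nonzero coefficient for
    m; the DOF of the surviving reactions is computed against the surviving
    unique metabolites.  An emptied reaction set has DOF 0 by convention
    (nothing can run), so a metabolite touching every member is essential.
    """
    members = _members(subnet)
    unique = unique_metabolites(subnet, model)
    essential: set[str] = set()
    for m in sorted(unique):
        surviving = sorted(
            r for r in members if m not in model.get_reaction(r).stoichiometry
        )
        remaining_unique = sorted(unique - {m})
        if not surviving:
            essential.add(m)
            continue
        S = _restricted_matrix(model, surviving, remaining_unique)
        if len(surviving) - _rank(S) == 0:
            essential.add(m)
    return frozenset(essential)


@dataclass
class RobustnessReport:
    subnetwork_id: str
    n_reactions: int
    unique_metabolites: frozenset[str]
    dof: int
    essential_metabolites: frozenset[str]

    def to_dict(self) -> dict:
        return {
            "subnetwork_id": self.subnetwork_id,
            "n_reactions": self.n_reactions,
            "n_unique_metabolites": len(self.unique_metabolites),
            "unique_metabolites": sorted(self.unique_metabolites),
            "dof": self.dof,
            "essential_metabolites": sorted(self.essential_metabolites),
        }


def analyze_subnetwork(subnet: SubNetwork, model: MetabolicModel) -> RobustnessReport:
    unique = unique_metabolites(subnet, model)
    return RobustnessReport(
        subnetwork_id=subnet.id or f"subnet_{subnet.rank:03d}",
        n_reactions=subnet.n_reactions,
        unique_metabolites=unique,
        dof=subnetwork_dof(subnet, model, unique=unique),
        essential_metabolites=essential_metabolites(subnet, model),
    )


def robustness_table(
    reports: list[RobustnessReport], path: str | Path | None = None
) -> str:
    """Flat TSV (one row per sub-network); the unique-metabolite-count and
    DOF columns are the inputs of the summary histograms."""
    lines = [
        "subnetwork_id\tn_reactions\tn_unique_metabolites\tdof\tessential_metabolite_ids"
    ]
    for r in reports:
        lines.append(
            "\t".join(
                [
                    r.subnetwork_id,
                    str(r.n_reactions),
                    str(len(r.unique_metabolites)),
                    str(r.dof),
                    ",".join(sorted(r.essential_metabolites)) or "-",
                ]
            )
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def reports_to_json(reports: list[RobustnessReport]) -> str:
    return json.dumps([r.to_dict() for r in reports], indent=2)
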