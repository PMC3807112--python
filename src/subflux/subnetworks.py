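"""Detection of phenotype-correlated metabolic sub-networks.

Two-phase procedure over the null-space angle geometry:

1. *Seeding* — restrict to non-blocked reactions whose h-value reaches
   ``h_min``, connect pairs whose projection angle is at most ``theta_max``
   degrees, and take the connected components with at least ``min_seed``
   members.  Components of significant, geometrically close reactions are the
   candidate cores.
2. *Expansion* — add every remaining reaction fully stoichiometrically
   coupled to a seed member (the union of the seeds' full-coupling classes),
   so the output is a connected functional unit even when the expression
   evidence covers only part of a pathway.

Sub-networks are ranked by reaction count (ties: mean seed h, then first
reaction id).  Overlapping sub-networks are reported as-is, never merged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .geometry import ReactionGeometry, angle_matrix, coupling_class_of
from .model import MetabolicModel, format_equation
from .stats import ReactionHValues

__all__ = [
    "SubNetwork",
    "seed_clusters",
    "expand_with_coupled",
    "detect_subnetworks",
    "rank_subnetworks",
    "subnetworks_to_json",
    "write_subnetwork_report",
]

H_MIN = 0.95  # correlation mode; the two-group cohort mode relaxes to 0.80
H_MIN_TWO_GROUP = 0.80
THETA_MAX = 15.0  # degrees, seed-graph edge threshold
MIN_SEED = 2


@dataclass
class SubNetwork:
    """A detected sub-network: significant seed plus its coupling closure."""

    reactions: tuple[str, ...]
    seed_reactions: frozenset[str]
    added_by_coupling: frozenset[str]
    metabolites: frozenset[str]
    mean_h: float
    rank: int = 0
    id: str = ""

    def __post_init__(self) -> None:
        assert self.seed_reactions | self.added_by_coupling == set(self.reactions)
        assert not (self.seed_reactions & self.added_by_coupling)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)


def seed_clusters(
    geometry: ReactionGeometry,
    h: ReactionHValues,
    h_min: float = H_MIN,
    theta_max: float = THETA_MAX,
    min_seed: int = MIN_SEED,
) -> list[frozenset[str]]:
    """Connected components of significant reactions in the angle graph.

    Restricts to non-blocked reactions with h ≥ ``h_min``; edges where
    θ ≤ ``theta_max``; components smaller than ``min_seed`` are dropped.
    Returned largest first (ties by smallest member id) for determinism.
    """
    if not 0 < h_min < 1:
        raise ValueError("h_min must be in (0, 1)")
    if not 0 < theta_max <= 90:
        raise ValueError("theta_max must be in (0, 90]")
    ids = geometry.reaction_ids
    hvals = h.table["h"]
    keep = np.array(
        [
            (rid in hvals.index and hvals[rid] >= h_min) and not blocked
            for rid, blocked in zip(ids, geometry.blocked_mask)
        ]
    )
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        return []
    theta = angle_matrix(geometry)
    g = nx.Graph()
    g.add_nodes_from(idx.tolist())
    sub = theta[np.ix_(idx, idx)] <= theta_max
    ii, jj = np.nonzero(np.triu(sub, k=1))
    g.add_edges_from(zip(idx[ii].tolist(), idx[jj].tolist()))
    comps = [frozenset(ids[k] for k in c) for c in nx.connected_components(g)]
    comps = [c for c in comps if len(c) >= min_seed]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def expand_with_coupled(
    seed: frozenset[str] | set[str],
    geometry: ReactionGeometry,
    model: MetabolicModel,
    h: ReactionHValues | None = None,
    tol_angle: float | None = None,
) -> SubNetwork:
    """Close a seed under full stoichiometric coupling.

    The result is the union of the full-coupling classes of every seed
    member; ``added_by_coupling`` holds the reactions contributed by the
    closure alone.  The induced metabolite set (non-boundary metabolites
    touched by any member reaction) is recorded.
    """
    from .geometry import TOL_ANGLE

    if not seed:
        raise ValueError("seed must be non-empty")
    tol = TOL_ANGLE if tol_angle is None else tol_angle
    members: set[str] = set()
    for rid in sorted(seed):
        members |= coupling_class_of(geometry, rid, tol_angle=tol)
    members |= set(seed)
    mets: set[str] = set()
    for rid in members:
        for mid in model.get_reaction(rid).stoichiometry:
            if not model.get_metabolite(mid).is_boundary:
                mets.add(mid)
    seed_f = frozenset(seed)
    if h is not None:
        hv = h.table["h"]
        mean_h = float(np.mean([hv.get(r, 0.0) for r in sorted(seed_f)]))
    else:
        mean_h = 0.0
    order = {r: i for i, r in enumerate(model.reaction_ids)}
    return SubNetwork(
        reactions=tuple(sorted(members, key=order.get)),
        seed_reactions=seed_f,
        added_by_coupling=frozenset(members - seed_f),
        metabolites=frozenset(mets),
        mean_h=mean_h,
    )


def rank_subnetworks(subnets: list[SubNetwork]) -> list[SubNetwork]:
    """Sort by reaction count desc, mean seed h desc, first reaction id asc."""
    ordered = sorted(
        subnets,
        key=lambda s: (-s.n_reactions, -s.mean_h, min(s.reactions)),
    )
    out = []
    for k, s in enumerate(ordered, start=1):
        out.append(
            SubNetwork(
                reactions=s.reactions,
                seed_reactions=s.seed_reactions,
                added_by_coupling=s.added_by_coupling,
                metabolites=s.metabolites,
                mean_h=s.mean_h,
                rank=k,
                id=f"subnet_{k:03d}",
            )
        )
    return out


def detect_subnetworks(
    geometry: ReactionGeometry,
    h: ReactionHValues,
    model: MetabolicModel,
    h_min: float = H_MIN,
    theta_max: float = THETA_MAX,
    min_seed: int = MIN_SEED,
    tol_angle: float | None = None,
) -> list[SubNetwork]:
    """Seed, expand and rank in one call (the pipeline's main entry point)."""
    seeds = seed_clusters(geometry, h, h_min=h_min, theta_max=theta_max, min_seed=min_seed)
    subnets = [
        expand_with_coupled(s, geometry, model, h=h, tol_angle=tol_angle)
        for s in seeds
    ]
    return rank_subnetworks(subnets)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def subnetworks_to_json(subnets: list[SubNetwork]) -> str:
    payload = [
        {
            "id": s.id,
            "rank": s.rank,
            "n_reactions": s.n_reactions,
            "mean_h": s.mean_h,
            "reactions": list(s.reactions),
            "seed_reactions": sorted(s.seed_reactions),
            "added_by_coupling": sorted(s.added_by_coupling),
            "metabolites": sorted(s.metabolites),
        }
        for s in subnets
    ]
    return json.dumps(payload, indent=2)


def write_subnetwork_report(
    subnets: list[SubNetwork], model: MetabolicModel, path: str | Path
) -> None:
    """Human-readable report: per sub-network, each reaction's stoichiometry
    followed by the list of genes associated to it."""
    lines: list[str] = []
    for s in subnets:
        lines.append(f"# Sub-network {s.rank} ({s.n_reactions} reactions, mean h = {s.mean_h:.4f})")
        for rid in s.reactions:
            rxn = model.get_reaction(rid)
            tag = "seed" if rid in s.seed_reactions else "coupled"
            lines.append(f"{rid}\t{format_equation(rxn, model)}\t[{tag}]")
            genes = ", ".join(sorted(rxn.genes)) if rxn.genes else "-"
            lines.append(f"  genes: {genes}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")
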