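"""Metabolic model container, parsers and gene–reaction mapping.

A model is a list of metabolites and reactions plus a stoichiometric matrix
``S`` (rows = non-boundary metabolites, columns = reactions).  Boundary
metabolites — declared with the compartment tag ``b`` in the tabular format,
or via the SBML ``boundaryCondition`` flag — are exempt from mass balance and
excluded from ``S``, so exchange reactions are not forced to zero flux.

Two input formats are supported: SBML Level 3 (through cobrapy) and a small
tabular format, one reaction per TSV row::

    reaction_id  equation                     gpr                 subsystem
    R1           A[c] + 2 B[c] => C[m]        (g1 and g2) or g3   glycolysis

``=>`` marks an irreversible reaction, ``<=>`` a reversible one.  Metabolite
tokens are ``id[compartment]``.  Gene–reaction rules are boolean expressions
over gene ids with ``and``/``or`` and parentheses (case-insensitive).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import numpy as np
from cobra.core.gene import GPR

logger = logging.getLogger(__name__)

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelValidationError",
    "EquationParseError",
    "read_model",
    "write_model",
    "map_genes_to_reactions",
    "model_summary",
]

BOUNDARY_COMPARTMENT = "b"


class ModelValidationError(ValueError):
    """A structural inconsistency in a metabolic model."""


class EquationParseError(ValueError):
    """A reaction equation string that cannot be interpreted."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str
    name: str = ""
    is_boundary: bool = False


@dataclass
class Reaction:
    """A reaction with signed stoichiometry (negative = consumed)."""

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    gpr: GPR | None = None
    subsystem: str = ""

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        zeros = [m for m, c in self.stoichiometry.items() if c == 0]
        if zeros:
            raise ModelValidationError(
                f"reaction {self.id!r}: zero coefficient for {zeros}"
            )

    @property
    def genes(self) -> frozenset[str]:
        return self.gpr.genes if self.gpr is not None else frozenset()

    def gpr_string(self) -> str:
        return self.gpr.to_string() if self.gpr is not None else ""


class MetabolicModel:
    """An ordered collection of metabolites and reactions with its S matrix."""

    def __init__(
        self,
        metabolites: list[Metabolite],
        reactions: list[Reaction],
        genes: set[str] | None = None,
        id: str = "model",
    ) -> None:
        self.id = id
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self.genes: set[str] = set(genes) if genes is not None else set()
        for r in self.reactions:
            self.genes |= r.genes
        self._validate()
        self._S: np.ndarray | None = None

    # -- lookups -----------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def internal_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if not m.is_boundary]

    @property
    def compartments(self) -> set[str]:
        return {m.compartment for m in self.metabolites}

    def reaction_index(self, rid: str) -> int:
        try:
            return self._rxn_index[rid]
        except KeyError:
            raise KeyError(f"unknown reaction id {rid!r}") from None

    def get_reaction(self, rid: str) -> Reaction:
        return self.reactions[self.reaction_index(rid)]

    def get_metabolite(self, mid: str) -> Metabolite:
        return self._met_by_id[mid]

    # -- stoichiometric matrix --------------------------------------------
    @property
    def S(self) -> np.ndarray:
        """Dense stoichiometric matrix, non-boundary metabolites × reactions."""
        if self._S is None:
            internal = self.internal_metabolites
            row = {m.id: i for i, m in enumerate(internal)}
            S = np.zeros((len(internal), len(self.reactions)))
            for j, rxn in enumerate(self.reactions):
                for mid, coef in rxn.stoichiometry.items():
                    i = row.get(mid)
                    if i is not None:
                        S[i, j] = coef
            self._S = S
        return self._S

    # -- validation --------------------------------------------------------
    def _validate(self) -> None:
        mids = [m.id for m in self.metabolites]
        if len(set(mids)) != len(mids):
            dup = sorted({x for x in mids if mids.count(x) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dup = sorted({x for x in rids if rids.count(x) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        self._met_by_id = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: j for j, r in enumerate(self.reactions)}
        for r in self.reactions:
            missing = [m for m in r.stoichiometry if m not in self._met_by_id]
            if missing:
                raise ModelValidationError(
                    f"reaction {r.id!r} references unknown metabolites {missing}"
                )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MetabolicModel({self.id!r}, {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions, {len(self.genes)} genes)"
        )


# ---------------------------------------------------------------------------
# Equation parsing (tabular format)
# ---------------------------------------------------------------------------

_ARROWS = ("<=>", "=>")
_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)\[(\w+)\]$")


def parse_equation(
    equation: str, reaction_id: str = "?"
) -> tuple[dict[tuple[str, str], float], bool]:
    """Parse ``"2 A[c] + B[c] <=> C[m]"`` into ((met, compartment) -> coef, reversible)."""
    eq = equation.strip()
    if "<=>" in eq:
        arrow, reversible = "<=>", True
    elif "=>" in eq:
        arrow, reversible = "=>", False
    else:
        raise EquationParseError(
            f"reaction {reaction_id!r}: no '=>' or '<=>' arrow in {equation!r}"
        )
    lhs, rhs = eq.split(arrow)
    stoich: dict[tuple[str, str], float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            m = _TERM_RE.match(term)
            if m is None:
                raise EquationParseError(
                    f"reaction {reaction_id!r}: cannot parse term {term!r}"
                )
            coef = float(m.group(1)) if m.group(1) else 1.0
            if coef == 0:
                raise EquationParseError(
                    f"reaction {reaction_id!r}: zero coefficient in term {term!r}"
                )
            key = (m.group(2), m.group(3))
            stoich[key] = stoich.get(key, 0.0) + sign * coef

    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    stoich = {k: v for k, v in stoich.items() if v != 0}
    if not stoich:
        raise EquationParseError(
            f"reaction {reaction_id!r}: equation {equation!r} cancels to nothing"
        )
    return stoich, reversible


def format_equation(rxn: Reaction, model: MetabolicModel) -> str:
    """Inverse of :func:`parse_equation` for a reaction in a model."""

    def side(items: list[tuple[str, float]]) -> str:
        parts = []
        for mid, coef in items:
            comp = model.get_metabolite(mid).compartment
            c = abs(coef)
            prefix = "" if c == 1 else (f"{int(c)} " if c == int(c) else f"{c} ")
            parts.append(f"{prefix}{mid}[{comp}]")
        return " + ".join(parts)

    lhs = [(m, c) for m, c in rxn.stoichiometry.items() if c < 0]
    rhs = [(m, c) for m, c in rxn.stoichiometry.items() if c > 0]
    arrow = "<=>" if rxn.reversible else "=>"
    return f"{side(lhs)} {arrow} {side(rhs)}".strip()


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

TABLE_COLUMNS = ["reaction_id", "equation", "gpr", "subsystem"]


def _read_table(path: str) -> MetabolicModel:
    import csv

    reactions: list[Reaction] = []
    met_comp: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "reaction_id" not in reader.fieldnames:
            raise ModelValidationError(
                f"{path}: header row with columns {TABLE_COLUMNS} required"
            )
        for row in reader:
            rid = row["reaction_id"].strip()
            if not rid or rid.startswith("#"):
                continue
            stoich_keys, reversible = parse_equation(row["equation"], rid)
            stoich: dict[str, float] = {}
            for (mid, comp), coef in stoich_keys.items():
                prev = met_comp.get(mid)
                if prev is not None and prev != comp:
                    raise ModelValidationError(
                        f"metabolite {mid!r} declared in compartments "
                        f"{prev!r} and {comp!r}; qualify ids per compartment"
                    )
                met_comp[mid] = comp
                stoich[mid] = coef
            gpr_str = (row.get("gpr") or "").strip()
            gpr = GPR.from_string(gpr_str) if gpr_str else None
            reactions.append(
                Reaction(
                    id=rid,
                    stoichiometry=stoich,
                    reversible=reversible,
                    gpr=gpr,
                    subsystem=(row.get("subsystem") or "").strip(),
                )
            )
    metabolites = [
        Metabolite(
            id=mid,
            compartment=comp,
            is_boundary=(comp == BOUNDARY_COMPARTMENT),
        )
        for mid, comp in sorted(met_comp.items())
    ]
    return MetabolicModel(metabolites, reactions)


def _read_sbml(path: str) -> MetabolicModel:
    from cobra.io import read_sbml_model

    cm = read_sbml_model(path)
    metabolites = [
        Metabolite(
            id=m.id,
            compartment=m.compartment or "",
            name=m.name or "",
            is_boundary=bool(getattr(m, "boundary_condition", False))
            or m.compartment == BOUNDARY_COMPARTMENT,
        )
        for m in cm.metabolites
    ]
    reactions = []
    for r in cm.reactions:
        stoich = {m.id: float(c) for m, c in r.metabolites.items() if c != 0}
        gpr = r.gpr if r.gpr is not None and r.gpr.to_string() else None
        reactions.append(
            Reaction(
                id=r.id,
                stoichiometry=stoich,
                reversible=bool(r.reversibility),
                gpr=gpr,
                subsystem=r.subsystem or "",
            )
        )
    return MetabolicModel(metabolites, reactions, id=cm.id or "model")


def read_model(path: str, format: str = "table") -> MetabolicModel:
    """Read a metabolic model from ``path`` (``format`` in {'table', 'sbml'})."""
    if format == "table":
        return _read_table(path)
    if format == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


def write_model(model: MetabolicModel, path: str) -> None:
    """Serialize a model in the tabular format (round-trips with read_model)."""
    lines = ["\t".join(TABLE_COLUMNS)]
    for r in model.reactions:
        lines.append(
            "\t".join([r.id, format_equation(r, model), r.gpr_string(), r.subsystem])
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Gene mapping and summary
# ---------------------------------------------------------------------------


def map_genes_to_reactions(
    model: MetabolicModel, gene_set: set[str]
) -> dict[str, frozenset[str]]:
    """Per reaction, the subset of ``gene_set`` occurring as leaves of its GPR.

    Any leaf match counts: complexes (and) and isozymes (or) are not
    distinguished.  Genes in ``gene_set`` matching no reaction are ignored
    (their count is logged).
    """
    mapping = {r.id: frozenset(gene_set & r.genes) for r in model.reactions}
    matched = set().union(*mapping.values()) if mapping else set()
    unmatched = gene_set - matched
    if unmatched:
        logger.info(
            "%d of %d genes matched no reaction GPR", len(unmatched), len(gene_set)
        )
    return mapping


def model_summary(model: MetabolicModel) -> dict:
    """Counts of reactions, metabolites, genes and compartments (JSON-able)."""
    return {
        "model_id": model.id,
        "n_reactions": len(model.reactions),
        "n_metabolites": len(model.metabolites),
        "n_internal_metabolites": len(model.internal_metabolites),
        "n_genes": len(model.genes),
        "compartments": sorted(model.compartments),
    }


def summary_json(model: MetabolicModel) -> str:
    return json.dumps(model_summary(model), indent=2)
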