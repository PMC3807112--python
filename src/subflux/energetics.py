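"""Energetics audit of a closed metabolic cycle.

The packaged ``fa_cycle`` fixture encodes the apparently futile cycle of
simultaneous fatty-acid synthesis and degradation: cytosolic acetyl-CoA is
carboxylated (ACC) and condensed onto a growing acyl chain (FAS, consuming
2 NADPH per C2 unit), the elongated acyl-CoA enters the mitochondrion via the
carnitine shuttle (CPT1/CACT/CPT2), one β-oxidation round regenerates
mitochondrial acetyl-CoA (yielding 1 FADH2 and 1 NADH), citrate synthase and
the citrate–malate antiporter return the C2 unit to the cytosol, and
ATP-citrate lyase regenerates cytosolic acetyl-CoA; the paired malate
dehydrogenases close the oxaloacetate/malate loop, moving one further NADH
equivalent from cytosol to mitochondrion.  One elongation/β-oxidation round
is amortized per cycled acetyl-CoA: a synthetic carrier-return step brings
the shortened acyl chain back to the cytosol, and the 2-ATP fatty-acid
activation cost is excluded as chain-length-amortized.

Cofactors (ATP, NAD(P)H, FADH2, CoA, carnitine, CO2, Pi) are declared
external (boundary) so the carbon skeleton alone defines a one-dimensional
steady-state flux space; their compartment is encoded in the metabolite id
suffix (``atp_c``, ``nadh_m``).  The audit computes the unique normalized
flux, sums the cofactor turnover per compartment, and converts the
mitochondrial reduced cofactors into respiratory ATP at a configurable P/O
ratio, with FADH2 yielding 2/3 of NADH's P/O.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.linalg import null_space

from .model import MetabolicModel, read_model

__all__ = [
    "CycleLedger",
    "CycleStructureError",
    "load_fa_cycle",
    "cycle_flux",
    "cofactor_ledger",
    "respiratory_yield",
    "audit_cycle",
]

FADH2_PO_FACTOR = 2.0 / 3.0  # FADH2 P/O relative to NADH P/O
COMPARTMENT_NAMES = {"c": "cytosol", "m": "mitochondrion"}
LEDGER_COFACTORS = ("atp", "nadph", "nadh", "fadh2")


class CycleStructureError(ValueError):
    """The cycle's steady-state flux space is not one-dimensional."""


def load_fa_cycle() -> MetabolicModel:
    """The packaged fatty-acid synthesis/β-oxidation/citrate-shuttle cycle."""
    ref = resources.files("subflux.data").joinpath("fa_cycle.tsv")
    with resources.as_file(ref) as path:
        return read_model(str(path), format="table")


def cycle_flux(
    model: MetabolicModel,
    cycle_reactions: list[str] | None = None,
    basis_unit: str = "accoa_c",
) -> dict[str, float]:
    """Unique steady-state flux, normalized to one cycled unit of ``basis_unit``.

    The internal-metabolite balance of the cycle reactions must admit exactly
    a one-dimensional flux space; otherwise a :class:`CycleStructureError`
    reporting the nullity is raised.  The flux is oriented and scaled so the
    turnover (gross production) of the basis metabolite is 1.
    """
    rids = list(cycle_reactions) if cycle_reactions is not None else model.reaction_ids
    cols = [model.reaction_index(r) for r in rids]
    S = model.S[:, cols]
    touched = np.any(S != 0, axis=1)
    S = S[touched]
    K = null_space(S) if S.size else np.eye(len(cols))
    d = K.shape[1] if K.size else 0
    if d != 1:
        raise CycleStructureError(
            f"cycle flux space has dimension {d}, expected 1 "
            f"({len(rids)} reactions, {S.shape[0]} balanced metabolites)"
        )
    v = K[:, 0]
    if basis_unit not in model.metabolite_ids:
        raise KeyError(f"basis metabolite {basis_unit!r} not in model")
    def turnover(vec: np.ndarray) -> float:
        # gross production of the basis metabolite under flux `vec`
        return sum(
            max(coef * vec[j], 0.0)
            for j, rid in enumerate(rids)
            for mid, coef in model.get_reaction(rid).stoichiometry.items()
            if mid == basis_unit
        )

    # orient so the basis metabolite is produced, then normalize its turnover
    if turnover(v) < turnover(-v):
        v = -v
    t = turnover(v)
    if t < 1e-12:
        raise CycleStructureError(
            f"basis metabolite {basis_unit!r} is not turned over by the cycle"
        )
    v = v / t
    return {rid: float(v[j]) for j, rid in enumerate(rids)}


def _cofactor_key(metabolite_id: str) -> tuple[str, str] | None:
    """Parse ``atp_c`` → ('atp', 'cytosol'); None for non-ledger species."""
    if "_" not in metabolite_id:
        return None
    name, _, comp = metabolite_id.rpartition("_")
    if name.lower() not in LEDGER_COFACTORS:
        return None
    return name.lower(), COMPARTMENT_NAMES.get(comp, comp)


@dataclass
class CycleLedger:
    """Net cofactor production (+) / consumption (−) per cycled basis unit."""

    net: dict[tuple[str, str], float] = field(default_factory=dict)

    def net_of(self, cofactor: str, compartment: str) -> float:
        return self.net.get((cofactor, compartment), 0.0)

    # -- convenience views used by the audit -------------------------------
    @property
    def atp_consumed(self) -> float:
        return -sum(v for (c, _), v in self.net.items() if c == "atp")

    @property
    def nadph_consumed_cytosol(self) -> float:
        return -self.net_of("nadph", "cytosol")

    @property
    def nadh_consumed_cytosol(self) -> float:
        return -self.net_of("nadh", "cytosol")

    @property
    def nadh_produced_mitochondrion(self) -> float:
        return self.net_of("nadh", "mitochondrion")

    @property
    def fadh2_produced_mitochondrion(self) -> float:
        return self.net_of("fadh2", "mitochondrion")

    @property
    def mitochondrial_reduced(self) -> float:
        """Reduced cofactors gained in the mitochondrion per cycle."""
        return self.nadh_produced_mitochondrion + self.fadh2_produced_mitochondrion

    @property
    def cytosolic_oxidized(self) -> float:
        """Reduced cofactors spent in the cytosol per cycle."""
        return self.nadph_consumed_cytosol + self.nadh_consumed_cytosol

    def to_dict(self) -> dict:
        # entries are rational multiples of the cycled unit; round off SVD noise
        return {
            "net": {f"{c}[{comp}]": round(v, 10) for (c, comp), v in sorted(self.net.items())},
            "atp_consumed": round(self.atp_consumed, 10),
            "nadph_consumed_cytosol": round(self.nadph_consumed_cytosol, 10),
            "nadh_consumed_cytosol": round(self.nadh_consumed_cytosol, 10),
            "nadh_produced_mitochondrion": round(self.nadh_produced_mitochondrion, 10),
            "fadh2_produced_mitochondrion": round(self.fadh2_produced_mitochondrion, 10),
            "mitochondrial_reduced": round(self.mitochondrial_reduced, 10),
            "cytosolic_oxidized": round(self.cytosolic_oxidized, 10),
        }


def cofactor_ledger(model: MetabolicModel, flux: dict[str, float]) -> CycleLedger:
    """Sum signed cofactor coefficients weighted by flux, per compartment."""
    net: dict[tuple[str, str], float] = {}
    for rid, v in flux.items():
        for mid, coef in model.get_reaction(rid).stoichiometry.items():
            key = _cofactor_key(mid)
            if key is not None:
                net[key] = net.get(key, 0.0) + coef * v
    net = {k: v for k, v in net.items() if abs(v) > 1e-12}
    return CycleLedger(net=net)


def respiratory_yield(
    ledger: CycleLedger, po_nadh: float
) -> tuple[float, float]:
    """(gross, net) respiratory ATP per cycle at NADH P/O ``po_nadh``.

    The respirable pool is the mitochondrial gain — NADH and FADH2 produced
    in the mitochondrion — with FADH2 credited at 2/3 of NADH's P/O.  Net
    subtracts the ATP the cycle itself consumes.
    """
    if po_nadh < 0:
        raise ValueError("P/O ratio must be non-negative")
    gross = (
        ledger.nadh_produced_mitochondrion * po_nadh
        + ledger.fadh2_produced_mitochondrion * FADH2_PO_FACTOR * po_nadh
    )
    net = gross - ledger.atp_consumed
    return float(gross), float(net)


def audit_cycle(
    model: MetabolicModel,
    cycle_reactions: list[str] | None = None,
    basis_unit: str = "accoa_c",
    po_nadh: float = 1.5,
) -> dict:
    """Full audit: flux, ledger and respiratory yield as a JSON-able dict."""
    flux = cycle_flux(model, cycle_reactions, basis_unit=basis_unit)
    ledger = cofactor_ledger(model, flux)
    gross, net = respiratory_yield(ledger, po_nadh)
    return {
        "basis_unit": basis_unit,
        "po_nadh": po_nadh,
        "flux": {k: round(v, 12) for k, v in flux.items()},
        "ledger": ledger.to_dict(),
        "gross_respiratory_atp": round(gross, 10),
        "net_cycle_atp": round(net, 10),
    }
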