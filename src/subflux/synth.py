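"""Synthetic scenarios with known ground truth.

Toy metabolic models are composed from motif templates — series chains with
exchange reactions (each one a full-coupling class), diamonds (two parallel
branches between shared endpoints), and disconnected copies — with one
synthetic gene attached per internal reaction.  Expression matrices emulate
the cell-line study design: a growth-rate phenotype spanning a 4-fold range
across samples, planted-pathway genes monotonically tied to it, and decoy
genes that are pure noise.  Every generated scenario is checked at build time
against an LP flux-coupling audit (independent of the null-space geometry) so
the planted pathway really is a full-coupling class, and regenerating with
the same seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model import MetabolicModel, Metabolite, Reaction, write_model
from cobra.core.gene import GPR

__all__ = [
    "SyntheticScenario",
    "make_toy_model",
    "make_expression",
    "make_scenario",
    "lp_fully_coupled",
]

GROWTH_RATE_RANGE = (0.01, 0.04)  # 1/h; 4-fold spread across the sample panel
DEFAULT_N_SAMPLES = 60  # the cell-line panel size
DEFAULT_EFFECT = 1.0
DEFAULT_NOISE_SD = 0.5


# ---------------------------------------------------------------------------
# Model motifs
# ---------------------------------------------------------------------------


def _chain_motif(tag: str, length: int) -> tuple[list[Metabolite], list[Reaction], list[str]]:
    """Series chain of ``length`` internal reactions with in/out exchanges."""
    mets = [Metabolite(f"{tag}_m{i}", "c") for i in range(length + 1)]
    b_in = Metabolite(f"{tag}_xin", "b", is_boundary=True)
    b_out = Metabolite(f"{tag}_xout", "b", is_boundary=True)
    rxns = [Reaction(f"{tag}_EXIN", {b_in.id: -1.0, mets[0].id: 1.0})]
    for i in range(length):
        rid = f"{tag}_R{i + 1}"
        rxns.append(
            Reaction(
                rid,
                {mets[i].id: -1.0, mets[i + 1].id: 1.0},
                gpr=GPR.from_string(f"g_{rid}"),
            )
        )
    rxns.append(Reaction(f"{tag}_EXOUT", {mets[-1].id: -1.0, b_out.id: 1.0}))
    return [b_in, *mets, b_out], rxns, [r.id for r in rxns]


def _diamond_motif(tag: str) -> tuple[list[Metabolite], list[Reaction], list[str]]:
    """Two parallel branches A→B plus exchanges; branches are uncoupled."""
    a = Metabolite(f"{tag}_A", "c")
    b = Metabolite(f"{tag}_B", "c")
    b_in = Metabolite(f"{tag}_xin", "b", is_boundary=True)
    b_out = Metabolite(f"{tag}_xout", "b", is_boundary=True)
    rxns = [
        Reaction(f"{tag}_EXIN", {b_in.id: -1.0, a.id: 1.0}),
        Reaction(
            f"{tag}_B1", {a.id: -1.0, b.id: 1.0}, gpr=GPR.from_string(f"g_{tag}_B1")
        ),
        Reaction(
            f"{tag}_B2", {a.id: -1.0, b.id: 1.0}, gpr=GPR.from_string(f"g_{tag}_B2")
        ),
        Reaction(f"{tag}_EXOUT", {b.id: -1.0, b_out.id: 1.0}),
    ]
    return [b_in, a, b, b_out], rxns, [r.id for r in rxns]


def make_toy_model(
    n_chains: int = 2,
    chain_length: int = 5,
    n_diamonds: int = 1,
    seed: int = 0,
) -> tuple[MetabolicModel, list[frozenset[str]]]:
    """Compose motifs into one model; returns (model, planted full-coupling classes).

    Each chain motif (internal reactions plus its two exchanges) is a
    full-coupling class and a candidate planted pathway.  Diamond branches
    provide uncoupled background.  ``seed`` only fixes the id ordering hook
    for reproducibility; topology is deterministic given the counts.
    """
    if n_chains < 0 or n_diamonds < 0 or chain_length < 1:
        raise ValueError("counts must be non-negative and chain_length >= 1")
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    planted: list[frozenset[str]] = []
    for k in range(n_chains):
        m, r, ids = _chain_motif(f"C{k + 1}", chain_length)
        mets += m
        rxns += r
        planted.append(frozenset(ids))
    for k in range(n_diamonds):
        m, r, _ = _diamond_motif(f"D{k + 1}")
        mets += m
        rxns += r
    model = MetabolicModel(mets, rxns, id=f"toy_seed{seed}")
    _assert_planted_coupled(model, planted)
    return model, planted


# ---------------------------------------------------------------------------
# LP flux-coupling audit (geometry-free)
# ---------------------------------------------------------------------------


def lp_fully_coupled(
    model: MetabolicModel, rid_i: str, rid_j: str, bound: float = 1e3, tol: float = 1e-6
) -> bool:
    """LP audit of full coupling: with v_j fixed to 1 over S·v = 0, reactions
    are fully coupled iff min and max of v_i agree and are nonzero."""
    S = model.S
    n = S.shape[1]
    i = model.reaction_index(rid_i)
    j = model.reaction_index(rid_j)
    if i == j:
        return True
    bounds = [(-bound, bound)] * n
    bounds[j] = (1.0, 1.0)
    vals = []
    for sign in (+1.0, -1.0):
        c = np.zeros(n)
        c[i] = sign
        res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
        if not res.success:
            return False  # v_j cannot carry flux: not coupled to anything
        vals.append(sign * res.fun)
    lo, hi = min(vals), max(vals)
    return (hi - lo) < tol and abs(lo) > tol


def _assert_planted_coupled(
    model: MetabolicModel, planted: list[frozenset[str]]
) -> None:
    for cls in planted:
        members = sorted(cls)
        ref = members[0]
        for other in members[1:]:
            if not lp_fully_coupled(model, ref, other):
                raise AssertionError(
                    f"planted pathway member {other} not fully coupled to {ref}"
                )
        for outsider in sorted(set(model.reaction_ids) - cls)[:3]:
            if lp_fully_coupled(model, ref, outsider):
                raise AssertionError(
                    f"outside reaction {outsider} unexpectedly coupled to {ref}"
                )


# ---------------------------------------------------------------------------
# Expression + phenotype
# ---------------------------------------------------------------------------


def make_expression(
    model: MetabolicModel,
    planted_reactions: frozenset[str] | set[str],
    n_samples: int = DEFAULT_N_SAMPLES,
    effect: float = DEFAULT_EFFECT,
    noise_sd: float = DEFAULT_NOISE_SD,
    n_decoys: int = 150,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, dict[str, bool]]:
    """Expression matrix (genes × samples), growth-rate phenotype, truth flags.

    Growth rates are log-uniform over a 4-fold range; genes of the planted
    reactions follow ``effect``·z(rank(μ)) plus Gaussian noise of sd
    ``noise_sd``; all other model genes and ``n_decoys`` extra decoy genes
    are standard-normal noise.
    """
    if n_samples < 8:
        raise ValueError("need at least 8 samples")
    rng = np.random.default_rng(seed)
    lo, hi = GROWTH_RATE_RANGE
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    phen = pd.Series(mu, index=samples, name="growth_rate")

    planted_genes: set[str] = set()
    for rid in planted_reactions:
        planted_genes |= set(model.get_reaction(rid).genes)
    background = sorted(model.genes - planted_genes)
    decoys = [f"decoy_{i + 1:04d}" for i in range(n_decoys)]
    genes = sorted(planted_genes) + background + decoys

    from scipy.stats import rankdata

    z = rankdata(mu)
    z = (z - z.mean()) / z.std()
    X = rng.standard_normal((len(genes), n_samples))
    for gi, g in enumerate(genes):
        if g in planted_genes:
            X[gi] = effect * z + noise_sd * rng.standard_normal(n_samples)
    expr = pd.DataFrame(X, index=pd.Index(genes, name="gene"), columns=samples)
    truth = {g: (g in planted_genes) for g in genes}
    return expr, phen, truth


@dataclass
class SyntheticScenario:
    model: MetabolicModel
    planted_pathways: list[frozenset[str]]
    planted: frozenset[str]  # the pathway carrying the expression signal
    expression: pd.DataFrame
    phenotype: pd.Series
    truth: dict
    seed: int

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_model(self.model, out / "model.tsv")
        self.expression.to_csv(out / "expression.tsv", sep="\t")
        self.phenotype.rename("value").to_csv(
            out / "phenotype.tsv", sep="\t", index_label="sample"
        )
        (out / "truth.json").write_text(
            json.dumps(
                {
                    "seed": self.seed,
                    "planted_pathway": sorted(self.planted),
                    "planted_pathways": [sorted(p) for p in self.planted_pathways],
                    "planted_genes": sorted(
                        g for g, flag in self.truth["genes"].items() if flag
                    ),
                },
                indent=2,
            ),
            encoding="utf-8",
        )


def make_scenario(
    seed: int = 0,
    n_chains: int = 2,
    chain_length: int = 5,
    n_diamonds: int = 1,
    n_samples: int = DEFAULT_N_SAMPLES,
    effect: float = DEFAULT_EFFECT,
    noise_sd: float = DEFAULT_NOISE_SD,
    n_decoys: int = 150,
) -> SyntheticScenario:
    """Default benchmark: signal planted on the first chain's gene-bearing
    reactions; the expected sub-network is that chain's full-coupling class
    (exchanges included, reachable only through coupling expansion)."""
    model, planted_pathways = make_toy_model(
        n_chains=n_chains, chain_length=chain_length, n_diamonds=n_diamonds, seed=seed
    )
    planted = planted_pathways[0]
    signal_reactions = {
        rid for rid in planted if model.get_reaction(rid).genes
    }
    expr, phen, gene_truth = make_expression(
        model,
        signal_reactions,
        n_samples=n_samples,
        effect=effect,
        noise_sd=noise_sd,
        n_decoys=n_decoys,
        seed=seed,
    )
    truth = {
        "genes": gene_truth,
        "signal_reactions": sorted(signal_reactions),
        "expected_subnetwork": sorted(planted),
    }
    return SyntheticScenario(
        model=model,
        planted_pathways=planted_pathways,
        planted=planted,
        expression=expr,
        phenotype=phen,
        truth=truth,
        seed=seed,
    )
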