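"""Hypergeometric overlap between unique-metabolite sets of two collections.

Two sub-network collections (e.g. growth-correlated vs mortality-correlated)
are compared by the metabolites exclusive to each: drawing |B| metabolites
from a universe of all non-boundary model metabolites containing |A| marked
ones, the upper-tail probability P[X ≥ observed overlap] under the fixed-size
hypergeometric null quantifies enrichment.  The tail is summed in log space
so genome-scale configurations do not underflow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .model import MetabolicModel
from .robustness import unique_metabolites
from .subnetworks import SubNetwork

__all__ = ["OverlapResult", "collection_unique_metabolites", "hypergeom_overlap"]


@dataclass
class OverlapResult:
    n_universe: int
    n_A: int
    n_B: int
    n_overlap: int
    log_p: float  # natural log of the upper-tail probability

    @property
    def p_value(self) -> float:
        return float(np.exp(self.log_p))

    def to_dict(self) -> dict:
        return {
            "n_universe": self.n_universe,
            "n_A": self.n_A,
            "n_B": self.n_B,
            "n_overlap": self.n_overlap,
            "p_value": self.p_value,
            "log10_p": self.log_p / np.log(10.0),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def collection_unique_metabolites(
    subnets: list[SubNetwork], model: MetabolicModel, top_n: int | None = None
) -> frozenset[str]:
    """Metabolites appearing in the top-``top_n`` sub-networks and nowhere else.

    Uniqueness is relative to the whole model: the union of the collection's
    reactions is treated as one reaction set and metabolites touched by any
    outside reaction are excluded.
    """
    if top_n is not None:
        if top_n < 1:
            raise ValueError("top_n must be >= 1")
        subnets = sorted(subnets, key=lambda s: s.rank or 10**9)[:top_n]
    union: set[str] = set()
    for s in subnets:
        union |= set(s.reactions)
    if not union:
        return frozenset()
    return unique_metabolites(union, model)


def hypergeom_overlap(
    n_universe: int, n_A: int, n_B: int, n_overlap: int
) -> OverlapResult:
    """Upper-tail hypergeometric probability of an overlap ≥ ``n_overlap``.

    Population ``n_universe`` with ``n_A`` marked elements; ``n_B`` draws;
    p = P[X ≥ n_overlap], accumulated with a log-sum-exp over the exact
    log-pmf so that vanishing tails keep a meaningful log value.
    """
    if not (0 <= n_A <= n_universe and 0 <= n_B <= n_universe):
        raise ValueError("set sizes must lie within the universe")
    if not 0 <= n_overlap <= min(n_A, n_B):
        raise ValueError("overlap must be between 0 and min(n_A, n_B)")
    ks = np.arange(n_overlap, min(n_A, n_B) + 1)
    if n_overlap == 0:
        log_p = 0.0  # an overlap of at least zero is certain
    else:
        log_p = float(
            min(0.0, logsumexp(hypergeom.logpmf(ks, n_universe, n_A, n_B)))
        )
    return OverlapResult(
        n_universe=n_universe, n_A=n_A, n_B=n_B, n_overlap=n_overlap, log_p=log_p
    )
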