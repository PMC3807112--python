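"""Gene-level phenotype association scores and per-reaction h-values.

Genes are scored against the phenotype either by Spearman rank correlation
with a continuous growth rate (cell-line mode) or by a Welch two-sample
t-test between outcome groups (patient-cohort mode).  Benjamini–Hochberg FDR
selection, optionally direction-restricted, yields significant gene sets;
selections from two array platforms can be intersected after probe→gene
mapping.  Gene evidence is lifted to reactions as an h-value:

    h(reaction) = 1 − min{ one-sided p(g) : g a GPR leaf of the reaction }

so h close to 1 means at least one associated gene shows strong evidence of
association in the requested direction.  Reactions without any scored gene
carry h = 0 and are flagged unscored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .model import MetabolicModel

__all__ = [
    "growth_rate_from_doubling",
    "spearman_scores",
    "ttest_scores",
    "fdr_select",
    "intersect_platforms",
    "reaction_h_values",
    "one_sided_p",
]

SCORE_COLUMNS = ["statistic", "p_value", "undefined"]


def growth_rate_from_doubling(t_d: float | np.ndarray) -> float | np.ndarray:
    """Specific growth rate μ = ln(2)/t_d for a doubling time in hours."""
    t = np.asarray(t_d, dtype=float)
    if np.any(t <= 0):
        raise ValueError("doubling time must be strictly positive")
    mu = math.log(2) / t
    return float(mu) if np.isscalar(t_d) else mu


def _check_alignment(expr: pd.DataFrame, phen: pd.Series) -> pd.Series:
    missing = [s for s in expr.columns if s not in phen.index]
    if missing:
        raise ValueError(f"phenotype missing samples: {missing[:5]}")
    return phen.loc[expr.columns]


def spearman_scores(
    expr: pd.DataFrame, phen: pd.Series, platform: str = ""
) -> pd.DataFrame:
    """Per-gene Spearman rank correlation with a numeric phenotype.

    ``expr`` is genes × samples; ties get midranks; p-values are two-sided
    from the t approximation on n−2 degrees of freedom.  Zero-variance genes
    are flagged ``undefined`` (statistic and p NaN) and excluded from FDR.
    """
    phen = _check_alignment(expr, phen)
    n = expr.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples for correlation scoring")
    X = expr.to_numpy(dtype=float)
    rx = sps.rankdata(X, axis=1)
    ry = sps.rankdata(phen.to_numpy(dtype=float))
    rx_c = rx - rx.mean(axis=1, keepdims=True)
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum(axis=1) * (ry_c**2).sum())
    undefined = denom == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx_c @ ry_c) / denom
        rho = np.clip(rho, -1.0, 1.0)
        t = rho * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - rho**2))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    rho[undefined] = np.nan
    p[undefined] = np.nan
    out = pd.DataFrame(
        {"statistic": rho, "p_value": p, "undefined": undefined}, index=expr.index
    )
    out["platform"] = platform
    return out


def ttest_scores(
    expr: pd.DataFrame,
    groups: pd.Series,
    case_label: str = "deceased",
    platform: str = "",
) -> pd.DataFrame:
    """Per-gene Welch t-test between two sample groups.

    Positive statistic = higher mean in the ``case_label`` group (for the
    survival analysis: higher in patients who died).  Welch's unequal-variance
    form keeps the statistic finite when one group is constant.
    """
    groups = _check_alignment(expr, groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {list(labels)}")
    if case_label not in set(labels):
        raise ValueError(f"case label {case_label!r} not among groups {list(labels)}")
    case = expr.loc[:, groups == case_label].to_numpy(dtype=float)
    ctrl = expr.loc[:, groups != case_label].to_numpy(dtype=float)
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    res = sps.ttest_ind(case, ctrl, axis=1, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    undefined = ~np.isfinite(t)
    # both groups constant and equal: define t = 0, p = 1 (no evidence)
    t = np.where(undefined, 0.0, t)
    p = np.where(undefined, 1.0, p)
    out = pd.DataFrame(
        {"statistic": t, "p_value": p, "undefined": False}, index=expr.index
    )
    out["platform"] = platform
    return out


def one_sided_p(scores: pd.DataFrame, direction: str = "positive") -> pd.Series:
    """One-sided p-values for the requested direction.

    For ``positive``: p/2 when the statistic is positive, 1 − p/2 otherwise
    (and symmetrically for ``negative``); ``two_sided`` returns p unchanged.
    """
    p = scores["p_value"]
    stat = scores["statistic"]
    if direction == "two_sided":
        return p
    if direction not in ("positive", "negative"):
        raise ValueError(f"unknown direction {direction!r}")
    concordant = stat > 0 if direction == "positive" else stat < 0
    return pd.Series(
        np.where(concordant, p / 2.0, 1.0 - p / 2.0), index=scores.index
    )


def fdr_select(
    scores: pd.DataFrame, q: float = 0.05, direction: str = "two_sided"
) -> set[str]:
    """Benjamini–Hochberg selection at FDR level ``q``.

    ``direction='positive'`` (or ``'negative'``) restricts the test family to
    genes whose statistic has the concordant sign and halves their two-sided
    p-values before BH; ``'two_sided'`` uses all defined genes as-is.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    s = scores.loc[~scores["undefined"].astype(bool)]
    if direction in ("positive", "negative"):
        concordant = s["statistic"] > 0 if direction == "positive" else s["statistic"] < 0
        s = s.loc[concordant]
        pvals = s["p_value"].to_numpy() / 2.0
    elif direction == "two_sided":
        pvals = s["p_value"].to_numpy()
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if len(pvals) == 0:
        return set()
    reject, _, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return set(s.index[reject])


def intersect_platforms(
    sel_a: set[str],
    sel_b: set[str],
    id_map: pd.Series | dict | None = None,
) -> set[str]:
    """Intersect two selections after mapping probe ids to a common gene space.

    ``id_map`` maps probe id → gene id; ids absent from the map pass through
    unchanged (already in gene space).  Many-to-one probe collapses keep the
    gene selected if any of its probes was selected, which matches collapsing
    the score table by minimum p before selection.
    """

    mapping = dict(id_map) if id_map is not None else {}

    def mapped(sel: set[str]) -> set[str]:
        return {mapping.get(x, x) for x in sel}

    return mapped(sel_a) & mapped(sel_b)


def collapse_probes(scores: pd.DataFrame, id_map: pd.Series | dict) -> pd.DataFrame:
    """Collapse a probe-level score table to gene level by minimum p-value."""
    mapping = pd.Series(id_map)
    genes = scores.index.to_series().map(mapping).fillna(scores.index.to_series())
    out = scores.assign(_gene=genes.to_numpy())
    out = out.sort_values("p_value").groupby("_gene", sort=True).first()
    out.index.name = scores.index.name
    return out


@dataclass
class ReactionHValues:
    """Per-reaction significance lifted from gene-level one-sided p-values."""

    table: pd.DataFrame  # index reaction_id; columns h, contributing_gene, scored

    def h(self, rid: str) -> float:
        return float(self.table.loc[rid, "h"])

    def scored_reactions(self) -> set[str]:
        return set(self.table.index[self.table["scored"]])


def reaction_h_values(
    scores: pd.DataFrame,
    model: MetabolicModel,
    direction: str = "positive",
    aggregation: str = "min_p",
) -> ReactionHValues:
    """h-value per reaction: 1 − aggregated one-sided p over its GPR genes.

    ``min_p`` (default) takes the most significant gene — an OR-like rule
    under which one strongly associated isozyme suffices.  ``fisher``
    combines the gene p-values with Fisher's method instead.  Reactions whose
    GPR contains no scored gene get h = 0 and ``scored = False``.
    """
    p1 = one_sided_p(scores, direction)
    p1 = p1.loc[~scores["undefined"].astype(bool)]
    rows = []
    for rxn in model.reactions:
        genes = sorted(g for g in rxn.genes if g in p1.index)
        if not genes:
            rows.append((rxn.id, 0.0, "", False))
            continue
        pvals = p1.loc[genes].astype(float)
        if aggregation == "min_p":
            best = pvals.idxmin()
            h = 1.0 - float(pvals.loc[best])
            contrib = best
        elif aggregation == "fisher":
            stat, p_comb = sps.combine_pvalues(
                np.clip(pvals.to_numpy(), 1e-300, 1.0), method="fisher"
            )
            h = 1.0 - float(p_comb)
            contrib = ",".join(genes)
        else:
            raise ValueError(f"unknown aggregation {aggregation!r}")
        rows.append((rxn.id, h, contrib, True))
    table = pd.DataFrame(
        rows, columns=["reaction_id", "h", "contributing_gene", "scored"]
    ).set_index("reaction_id")
    return ReactionHValues(table=table)
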