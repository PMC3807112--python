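"""Null-space geometry of the stoichiometric matrix.

Steady-state fluxes satisfy ``S·v = 0``; the kernel of ``S`` is therefore the
space of all admissible flux distributions.  Each reaction corresponds to a
coordinate axis of flux space; projecting the unit vector ``e_i`` of reaction
``i`` onto the kernel gives ``p_i = K·Kᵀ·e_i`` where the columns of ``K`` are
an orthonormal kernel basis.  The angle between two projections measures how
tightly the steady-state fluxes of the two reactions are tied to each other:
fully coupled reactions (fluxes proportional in every steady state) project
onto collinear vectors and have a zero angle, even when they share no
metabolite.  Reactions whose projection has zero norm can carry no flux in any
steady state ("blocked").

Angles are folded to [0, 90] degrees with an absolute cosine, so the measure
is invariant to the arbitrary sign with which a reversible reaction is
written.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import null_space

from .model import MetabolicModel

__all__ = [
    "ReactionGeometry",
    "BlockedReactionError",
    "compute_geometry",
    "angle",
    "angle_matrix",
    "full_coupling_sets",
    "export_angle_table",
]

TOL_BLOCKED = 1e-8  # projection norm at or below which a reaction is blocked
TOL_ANGLE = 1e-4  # degrees; default threshold for "fully coupled"


class BlockedReactionError(ValueError):
    """Angle requested for a reaction that carries no steady-state flux."""


@dataclass
class ReactionGeometry:
    """Orthonormal kernel basis and per-reaction projections.

    ``K`` has one row per reaction and one column per kernel dimension; the
    projection of reaction ``i`` is ``p_i = K·K[i]``, whose norm equals
    ``‖K[i]‖`` because the basis is orthonormal.

    ``K`` spans the kernel of the *column-normalized* S (each reaction's
    stoichiometric vector scaled to unit length), which makes every angle
    invariant to rescaling a reaction's stoichiometry; dividing the rows of
    ``K`` by ``column_norms`` recovers raw-unit flux directions.
    """

    reaction_ids: list[str]
    K: np.ndarray  # n_reactions × d, orthonormal columns
    norms: np.ndarray  # ‖p_i‖ per reaction
    tol_blocked: float = TOL_BLOCKED
    column_norms: np.ndarray | None = None  # original ‖S[:, i]‖ per reaction

    @property
    def nullity(self) -> int:
        return self.K.shape[1]

    @property
    def blocked_mask(self) -> np.ndarray:
        return self.norms <= self.tol_blocked

    @property
    def blocked(self) -> frozenset[str]:
        ids = np.asarray(self.reaction_ids, dtype=object)
        return frozenset(ids[self.blocked_mask])

    def projection(self, i: int) -> np.ndarray:
        """The kernel projection p_i of reaction i, in flux-space coordinates."""
        return self.K @ self.K[i]

    def index(self, rid: str) -> int:
        try:
            return self._index[rid]
        except AttributeError:
            self._index = {r: j for j, r in enumerate(self.reaction_ids)}
            return self._index[rid]

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.K).tobytes())
        h.update("\n".join(self.reaction_ids).encode())
        return h.hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            K=self.K,
            norms=self.norms,
            reaction_ids=np.asarray(self.reaction_ids, dtype=object),
            tol_blocked=self.tol_blocked,
            column_norms=self.column_norms
            if self.column_norms is not None
            else np.ones(len(self.reaction_ids)),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ReactionGeometry":
        with np.load(path, allow_pickle=True) as z:
            return cls(
                reaction_ids=[str(r) for r in z["reaction_ids"]],
                K=z["K"],
                norms=z["norms"],
                tol_blocked=float(z["tol_blocked"]),
                column_norms=z["column_norms"],
            )


def _s_content_hash(S: np.ndarray, reaction_ids: list[str]) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(S).tobytes())
    h.update(str(S.shape).encode())
    h.update("\n".join(reaction_ids).encode())
    return h.hexdigest()[:16]


def compute_geometry(
    model: MetabolicModel,
    tol_blocked: float = TOL_BLOCKED,
    cache_dir: str | Path | None = None,
) -> ReactionGeometry:
    """Orthonormal kernel basis of S and per-reaction projection norms.

    The basis comes from a rank-revealing SVD (``scipy.linalg.null_space``);
    nullity is ``n_reactions − rank(S)``.  A nullity of zero is legal and
    marks every reaction blocked.  With ``cache_dir`` set, the decomposition
    is cached on disk keyed by a content hash of S (it dominates runtime on
    genome-scale models).

    Columns of S are normalized to unit Euclidean norm first.  Rescaling a
    reaction's stoichiometry only changes its flux unit, so it must not move
    any angle; normalization makes that exact, and it cannot change which
    pairs are fully coupled (collinearity of kernel rows survives any column
    scaling).
    """
    if not model.reactions:
        raise ValueError("model has no reactions")
    S = model.S
    col_norms = np.linalg.norm(S, axis=0)
    S = S / np.where(col_norms == 0, 1.0, col_norms)
    rids = model.reaction_ids
    cache_file = None
    if cache_dir is not None:
        cache_file = Path(cache_dir) / f"kernel_{_s_content_hash(S, rids)}.npz"
        if cache_file.exists():
            return ReactionGeometry.load(cache_file)
    n = S.shape[1]
    if S.shape[0] == 0:  # no internal metabolites: kernel is all of flux space
        K = np.eye(n)
    else:
        K = null_space(S)
        if K.size == 0:
            K = np.zeros((n, 0))
    norms = np.linalg.norm(K, axis=1) if K.shape[1] else np.zeros(n)
    geom = ReactionGeometry(
        reaction_ids=list(rids),
        K=K,
        norms=norms,
        tol_blocked=tol_blocked,
        column_norms=col_norms,
    )
    if cache_file is not None:
        cache_file.parent.mkdir(parents=True, exist_ok=True)
        geom.save(cache_file)
    return geom


def _check_not_blocked(geometry: ReactionGeometry, idx: int) -> None:
    if geometry.norms[idx] <= geometry.tol_blocked:
        raise BlockedReactionError(
            f"angle undefined for blocked reaction {geometry.reaction_ids[idx]!r}"
        )


def angle(geometry: ReactionGeometry, i: int, j: int) -> float:
    """Pairwise projection angle in degrees, folded to [0, 90].

    θ = arccos(|p_i·p_j| / (‖p_i‖·‖p_j‖)); the absolute value folds
    anti-parallel projections (a reaction and its direction-reversed fully
    coupled partner) onto zero.
    """
    _check_not_blocked(geometry, i)
    _check_not_blocked(geometry, j)
    K = geometry.K
    cos = abs(float(K[i] @ K[j])) / (geometry.norms[i] * geometry.norms[j])
    return float(np.degrees(np.arccos(np.clip(cos, 0.0, 1.0))))


def angle_matrix(geometry: ReactionGeometry, block_size: int = 2048) -> np.ndarray:
    """Full symmetric angle matrix in degrees; blocked reactions are NaN.

    Computed in row blocks so genome-scale use does not need an intermediate
    larger than ``block_size × n``.
    """
    K = geometry.K
    n = K.shape[0]
    norms = geometry.norms.copy()
    bad = geometry.blocked_mask
    safe = np.where(bad, 1.0, norms)
    theta = np.empty((n, n))
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        G = np.abs(K[start:stop] @ K.T)
        cos = G / np.outer(safe[start:stop], safe)
        theta[start:stop] = np.degrees(np.arccos(np.clip(cos, 0.0, 1.0)))
    theta[bad, :] = np.nan
    theta[:, bad] = np.nan
    idx = np.flatnonzero(~bad)
    theta[idx, idx] = 0.0
    return theta


def full_coupling_sets(
    geometry: ReactionGeometry, tol_angle: float = TOL_ANGLE
) -> list[frozenset[str]]:
    """Partition non-blocked reactions into full-coupling classes.

    Two reactions are related when their angle is at most ``tol_angle``
    degrees; classes are the transitive closure (connected components) of
    that relation, returned largest first.
    """
    import networkx as nx

    theta = angle_matrix(geometry)
    ids = geometry.reaction_ids
    alive = np.flatnonzero(~geometry.blocked_mask)
    g = nx.Graph()
    g.add_nodes_from(alive.tolist())
    sub = theta[np.ix_(alive, alive)] <= tol_angle
    ii, jj = np.nonzero(np.triu(sub, k=1))
    g.add_edges_from(zip(alive[ii].tolist(), alive[jj].tolist()))
    classes = [frozenset(ids[k] for k in comp) for comp in nx.connected_components(g)]
    return sorted(classes, key=lambda c: (-len(c), min(c)))


def coupling_class_of(
    geometry: ReactionGeometry, rid: str, tol_angle: float = TOL_ANGLE
) -> frozenset[str]:
    """The full-coupling class containing reaction ``rid`` (itself if blocked)."""
    i = geometry.index(rid)
    if geometry.norms[i] <= geometry.tol_blocked:
        return frozenset([rid])
    K, norms = geometry.K, geometry.norms
    safe = np.where(geometry.blocked_mask, 1.0, norms)
    cos = np.abs(K @ K[i]) / (safe * norms[i])
    theta = np.degrees(np.arccos(np.clip(cos, 0.0, 1.0)))
    mask = (theta <= tol_angle) & ~geometry.blocked_mask
    return frozenset(np.asarray(geometry.reaction_ids, dtype=object)[mask])


def export_angle_table(
    geometry: ReactionGeometry, path: str | Path, theta_max: float = 90.0
) -> int:
    """Write pairs with θ ≤ ``theta_max`` as TSV; returns the number of rows."""
    theta = angle_matrix(geometry)
    ids = geometry.reaction_ids
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("reaction_id_1\treaction_id_2\ttheta_degrees\n")
        ii, jj = np.nonzero(np.triu(theta <= theta_max, k=1))
        for i, j in zip(ii, jj):
            fh.write(f"{ids[i]}\t{ids[j]}\t{theta[i, j]:.6f}\n")
            n += 1
    return n
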