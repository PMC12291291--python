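"""Annotating clusters, single cells and cell groups with cRegulon weights.

Cluster-level annotation is the fitted association matrix A itself (each row
a convex weight vector over modules).  A single cell with expression vector
``e`` over the cluster's target genes is scored by e R^T X; a cell group
composed of known cluster proportions p is scored by the convex combination
p A.  Association-plot coordinates place cell types at the A-weighted linear
combination of module coordinates (and recover module coordinates from cell
coordinates by least squares).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grn import RegulatoryNetwork

__all__ = [
    "AnnotationResult",
    "PlotCoordinates",
    "annotate_cells",
    "annotate_group",
    "association_coordinates",
    "cregulon_coordinates",
    "plot_association",
]


@dataclass
class AnnotationResult:
    """Cluster/cell/group scores over L cRegulons with reporting thresholds."""

    cluster_scores: np.ndarray
    cell_scores: np.ndarray | None = None
    group_scores: np.ndarray | None = None
    relevance_threshold: float = 0.01
    strong_threshold: float = 0.1

    def relevant(self, level: str = "cluster") -> np.ndarray:
        return self._scores(level) >= self.relevance_threshold

    def strong(self, level: str = "cluster") -> np.ndarray:
        return self._scores(level) >= self.strong_threshold

    def _scores(self, level: str) -> np.ndarray:
        scores = {
            "cluster": self.cluster_scores,
            "cell": self.cell_scores,
            "group": self.group_scores,
        }[level]
        if scores is None:
            raise ValueError(f"no {level}-level scores present")
        return scores


@dataclass
class PlotCoordinates:
    """2-D coordinates for cell types (u) and cRegulons (u_prime)."""

    u: np.ndarray
    u_prime: np.ndarray


def annotate_cells(
    expr_vectors: np.ndarray,
    network: RegulatoryNetwork,
    x: np.ndarray,
    normalize: bool = True,
) -> np.ndarray:
    """Score cells against the L modules: score = e R^T X per cell.

    ``expr_vectors`` is cells x N over the network's target genes.  With
    ``normalize`` (default, for comparability across modules) each row is
    scaled to sum to 1; all-zero rows are left at 0.
    """
    e = np.atleast_2d(np.asarray(expr_vectors, dtype=float))
    if e.shape[1] != network.n_tgs:
        raise ValueError(
            f"expression vectors have {e.shape[1]} genes but the network has "
            f"{network.n_tgs} target genes (first network TG: "
            f"{network.tg_ids[0]!r})"
        )
    scores = e @ network.strength.T @ np.asarray(x, dtype=float)
    if normalize:
        sums = scores.sum(axis=1, keepdims=True)
        nonzero = sums[:, 0] > 0
        scores[nonzero] = scores[nonzero] / sums[nonzero]
    return scores


def annotate_group(
    cluster_proportions: np.ndarray, cluster_scores: np.ndarray
) -> np.ndarray:
    """Convex combination of cluster annotation rows: p A = sum_k p_k A_k."""
    p = np.asarray(cluster_proportions, dtype=float)
    a = np.asarray(cluster_scores, dtype=float)
    if p.ndim != 1 or p.shape[0] != a.shape[0]:
        raise ValueError("one proportion per cluster is required")
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"proportions must sum to 1 (got {p.sum():.8g})")
    return p @ a


def association_coordinates(a_matrix: np.ndarray, u_prime: np.ndarray) -> PlotCoordinates:
    """Cell-type coordinates as the A-weighted combination of module
    coordinates: U = A U'."""
    a = np.asarray(a_matrix, dtype=float)
    up = np.asarray(u_prime, dtype=float)
    if up.shape != (a.shape[1], 2):
        raise ValueError("u_prime must be L x 2")
    return PlotCoordinates(u=a @ up, u_prime=up)


def cregulon_coordinates(a_matrix: np.ndarray, u: np.ndarray) -> PlotCoordinates:
    """Module coordinates from cell-type coordinates by least squares:
    U' = A^+ U (Moore-Penrose pseudo-inverse)."""
    a = np.asarray(a_matrix, dtype=float)
    u = np.asarray(u, dtype=float)
    if u.shape != (a.shape[0], 2):
        raise ValueError("u must be K x 2")
    if np.linalg.matrix_rank(a) < a.shape[1]:
        warnings.warn(
            "association matrix is rank-deficient; returning the minimum-norm "
            "module coordinates",
            stacklevel=2,
        )
    return PlotCoordinates(u=u, u_prime=np.linalg.pinv(a) @ u)


def plot_association(
    a_matrix: np.ndarray,
    u: np.ndarray,
    cluster_ids=None,
    module_ids=None,
    edge_threshold: float = 0.02,
    ax=None,
):
    """Association plot: cell types at ``u``, modules at A^+ u, with edges
    drawn where the association score is at least ``edge_threshold``."""
    import matplotlib.pyplot as plt

    a = np.asarray(a_matrix, dtype=float)
    coords = cregulon_coordinates(a, u)
    if ax is None:
        _fig, ax = plt.subplots()
    k, l = a.shape
    cluster_ids = cluster_ids or [f"cluster{i + 1}" for i in range(k)]
    module_ids = module_ids or [f"M{i + 1}" for i in range(l)]
    for ki in range(k):
        for li in range(l):
            if a[ki, li] >= edge_threshold:
                ax.plot(
                    [coords.u[ki, 0], coords.u_prime[li, 0]],
                    [coords.u[ki, 1], coords.u_prime[li, 1]],
                    color="grey",
                    linewidth=4 * a[ki, li],
                    zorder=1,
                )
    ax.scatter(coords.u[:, 0], coords.u[:, 1], c="tab:blue", zorder=2)
    ax.scatter(
        coords.u_prime[:, 0], coords.u_prime[:, 1], c="tab:red", marker="s", zorder=2
    )
    for ki, name in enumerate(cluster_ids):
        ax.annotate(name, coords.u[ki])
    for li, name in enumerate(module_ids):
        ax.annotate(name, coords.u_prime[li])
    return ax
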