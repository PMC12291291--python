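"""Per-cluster TF x TF combinatorial-effect matrices.

Two TFs act combinatorially in a cluster when (a) they regulate the same
target genes specifically — measured by the connection specificity index
(CSI) of their regulatory-strength profiles — and (b) both are specifically
active in that cluster — measured by the expression specificity index (ESI).
The combinatorial effect C_ij = CSI_ij * ESI_i * ESI_j feeds the joint
module decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grn import RegulatoryNetwork

__all__ = [
    "ExpressionSummary",
    "CombinatorialEffect",
    "regulatory_pcc",
    "csi",
    "esi",
    "combinatorial_matrix",
    "expression_summaries",
]


@dataclass
class ExpressionSummary:
    """Per-TF mean expression inside vs. outside one cell cluster."""

    mean_in: np.ndarray
    mean_out: np.ndarray

    def __post_init__(self) -> None:
        self.mean_in = np.asarray(self.mean_in, dtype=float)
        self.mean_out = np.asarray(self.mean_out, dtype=float)
        if self.mean_in.shape != self.mean_out.shape or self.mean_in.ndim != 1:
            raise ValueError("mean_in and mean_out must be 1-D of equal length")
        if (self.mean_in < 0).any() or (self.mean_out < 0).any():
            raise ValueError("mean expressions must be non-negative")


@dataclass
class CombinatorialEffect:
    """PCC, CSI, ESI and the resulting C matrix for one cell cluster."""

    cluster_id: str
    pcc: np.ndarray
    csi: np.ndarray
    esi: np.ndarray
    c: np.ndarray
    epsilon: float
    tf_ids: list[str]


def regulatory_pcc(network: RegulatoryNetwork) -> np.ndarray:
    """Pearson correlation of every pair of TF rows of R across the TGs.

    TFs with a constant (zero-variance) regulatory profile have undefined
    correlations; those entries are set to 0 with a warning so downstream
    matrices stay finite.
    """
    r = network.strength
    m, n = r.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 TFs and 2 TGs for correlations")
    centered = r - r.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    degenerate = norms == 0
    if degenerate.any():
        warnings.warn(
            "constant regulatory profile for "
            f"{[network.tf_ids[i] for i in np.nonzero(degenerate)[0]]}; "
            "their correlations are set to 0",
            stacklevel=2,
        )
    safe = np.where(degenerate, 1.0, norms)
    pcc = (centered @ centered.T) / np.outer(safe, safe)
    pcc[degenerate, :] = 0.0
    pcc[:, degenerate] = 0.0
    np.fill_diagonal(pcc, 1.0)
    np.clip(pcc, -1.0, 1.0, out=pcc)
    return pcc


def csi(pcc: np.ndarray, epsilon: float = 0.05) -> np.ndarray:
    """Connection specificity index.

    CSI_ij = #{l : PCC_il <= PCC_ij - eps and PCC_jl <= PCC_ij - eps} / M,
    with l running over all M TFs (including i and j themselves; with unit
    diagonal those self terms essentially never count).
    """
    pcc = np.asarray(pcc, dtype=float)
    m = pcc.shape[0]
    if pcc.shape != (m, m):
        raise ValueError("PCC matrix must be square")
    if not 0 <= epsilon < 1:
        raise ValueError("epsilon must lie in [0, 1)")
    out = np.empty((m, m))
    thresh = pcc - epsilon  # thresh[i, j] = PCC_ij - eps
    # chunk over j to keep the M x M x M indicator bounded in memory
    step = max(1, int(4e7) // max(m * m, 1))
    for start in range(0, m, step):
        stop = min(start + step, m)
        t = thresh[:, start:stop]  # M x J
        cond_i = pcc[:, None, :] <= t[:, :, None]  # i, j, l
        cond_j = pcc.T[None, start:stop, :] <= t[:, :, None]
        out[:, start:stop] = (cond_i & cond_j).sum(axis=2) / m
    return out


def esi(expr: ExpressionSummary, delta_scale: float = 1e-6) -> np.ndarray:
    """Expression specificity index: clamp01(mean_in / mean_out - 0.5).

    A zero out-of-cluster mean is floored at ``delta_scale`` times the global
    mean expression, so TFs expressed only inside the cluster clamp to 1
    rather than dividing by zero.
    """
    mean_in, mean_out = expr.mean_in, expr.mean_out
    overall = np.concatenate([mean_in, mean_out])
    delta = delta_scale * (overall.mean() if overall.any() else 1.0)
    delta = max(delta, np.finfo(float).tiny)
    ratio = mean_in / np.maximum(mean_out, delta)
    return np.clip(ratio - 0.5, 0.0, 1.0)


def combinatorial_matrix(
    network: RegulatoryNetwork,
    expr: ExpressionSummary,
    epsilon: float = 0.05,
) -> CombinatorialEffect:
    """Assemble C = CSI ∘ outer(ESI, ESI) for one cluster.

    The diagonal (a TF's own CSI times its squared ESI) is kept: the
    decomposition fits C ~ X A X^T whose diagonal carries each TF's module
    scale, and dropping it measurably biases the recovered cluster
    associations toward the extremes.
    """
    if len(expr.mean_in) != network.n_tfs:
        raise ValueError("expression summary length does not match TF count")
    pcc = regulatory_pcc(network)
    csi_mat = csi(pcc, epsilon)
    esi_vec = esi(expr)
    c = csi_mat * np.outer(esi_vec, esi_vec)
    return CombinatorialEffect(
        cluster_id=network.cluster_id,
        pcc=pcc,
        csi=csi_mat,
        esi=esi_vec,
        c=c,
        epsilon=epsilon,
        tf_ids=list(network.tf_ids),
    )


def expression_summaries(
    expr: np.ndarray, labels: np.ndarray, cluster_order: list | None = None
) -> dict:
    """Split a genes x cells expression matrix into per-cluster in/out means.

    Returns ``{cluster: ExpressionSummary}`` where ``mean_in`` averages the
    cluster's cells and ``mean_out`` all remaining cells.
    """
    expr = np.asarray(expr, dtype=float)
    labels = np.asarray(labels)
    if expr.shape[1] != labels.shape[0]:
        raise ValueError("one label per cell is required")
    clusters = cluster_order if cluster_order is not None else list(dict.fromkeys(labels))
    out = {}
    for cl in clusters:
        mask = labels == cl
        if not mask.any() or mask.all():
            raise ValueError(f"cluster {cl!r} must have cells both in and out")
        out[cl] = ExpressionSummary(
            mean_in=expr[:, mask].mean(axis=1),
            mean_out=expr[:, ~mask].mean(axis=1),
        )
    return out
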