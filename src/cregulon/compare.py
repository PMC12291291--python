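"""Comparative statistics: module transition scores and differential degrees.

The transition score quantifies how much one module's top TFs also load on
another module (and vice versa); the differential degree combines the
absolute and relative change of a module's annotation between two cell
groups, with permutation backgrounds supplying significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TransitionScore",
    "DifferentialResult",
    "transition_score",
    "differential_degree",
    "differential_significance",
    "timepoint_change_test",
]


@dataclass
class TransitionScore:
    """Forward/backward loadings between two TF modules and their blend."""

    fs: float
    bs: float
    ts: float
    weights: tuple[float, float]
    module_i_tfs: list[str]
    module_j_tfs: list[str]


@dataclass
class DifferentialResult:
    """Observed differential degrees with a permutation background."""

    d: np.ndarray
    background: np.ndarray  # n_background x L
    z: np.ndarray
    p: np.ndarray
    fdr: np.ndarray
    n_background: int
    seed: int


def transition_score(
    x: np.ndarray,
    module_i_tfs: list[str],
    module_j_tfs: list[str],
    tf_ids: list[str],
    weights: tuple[float, float] = (0.5, 0.5),
    module_i: int = 0,
    module_j: int = 1,
) -> TransitionScore:
    """Transition score between module i and module j.

    FS = mean loading of module i's TFs in X column j; BS = mean loading of
    module j's TFs in X column i; TS = w1 * FS + w2 * BS (default 0.5/0.5).
    """
    if not module_i_tfs or not module_j_tfs:
        raise ValueError("module TF sets must be non-empty")
    pos = {t: i for i, t in enumerate(tf_ids)}
    for tf in list(module_i_tfs) + list(module_j_tfs):
        if tf not in pos:
            raise ValueError(f"TF {tf!r} not in the TF universe")
    x = np.asarray(x, dtype=float)
    fs = float(np.mean([x[pos[t], module_j] for t in module_i_tfs]))
    bs = float(np.mean([x[pos[t], module_i] for t in module_j_tfs]))
    ts = weights[0] * fs + weights[1] * bs
    return TransitionScore(
        fs=fs,
        bs=bs,
        ts=float(ts),
        weights=tuple(weights),
        module_i_tfs=list(module_i_tfs),
        module_j_tfs=list(module_j_tfs),
    )


def differential_degree(
    a1: np.ndarray, a2: np.ndarray, min_floor: float = 1e-4
) -> np.ndarray:
    """Per-module differential degree: (max - min) * (max / min).

    The minimum is floored at ``min_floor`` so a vanishing annotation does
    not produce an infinite degree.
    """
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    if a1.shape != a2.shape:
        raise ValueError("score vectors must have equal length")
    if (a1 < 0).any() or (a2 < 0).any():
        raise ValueError("annotation scores must be non-negative")
    hi = np.maximum(a1, a2)
    lo = np.maximum(np.minimum(a1, a2), min_floor)
    return (hi - np.minimum(a1, a2)) * (hi / lo)


def differential_significance(
    cells_group1: np.ndarray,
    cells_group2: np.ndarray,
    annotator,
    n_background: int = 50,
    seed: int = 0,
    min_floor: float = 1e-4,
) -> DifferentialResult:
    """Permutation Z-test for the differential degree between two cell groups.

    ``annotator`` maps a cells x features array to a length-L score vector.
    The background redistributes the pooled cells into pseudo-groups of the
    observed sizes ``n_background`` times; each module's observed degree is
    converted to a Z-score against the background mean and SD, a two-sided
    normal p-value, and a Benjamini-Hochberg FDR.
    """
    g1 = np.atleast_2d(np.asarray(cells_group1, dtype=float))
    g2 = np.atleast_2d(np.asarray(cells_group2, dtype=float))
    if g1.shape[0] < 2 or g2.shape[0] < 2:
        raise ValueError("each group needs at least 2 cells")
    observed = differential_degree(annotator(g1), annotator(g2), min_floor)
    pooled = np.vstack([g1, g2])
    n1 = g1.shape[0]
    rng = np.random.default_rng(seed)
    background = np.empty((n_background, observed.shape[0]))
    for t in range(n_background):
        perm = rng.permutation(pooled.shape[0])
        background[t] = differential_degree(
            annotator(pooled[perm[:n1]]), annotator(pooled[perm[n1:]]), min_floor
        )
    mu = background.mean(axis=0)
    sigma = background.std(axis=0, ddof=1)
    z = (observed - mu) / np.maximum(sigma, np.finfo(float).tiny)
    p = 2.0 * stats.norm.sf(np.abs(z))
    fdr = multipletests(p, method="fdr_bh")[1]
    return DifferentialResult(
        d=observed,
        background=background,
        z=z,
        p=p,
        fdr=fdr,
        n_background=n_background,
        seed=seed,
    )


def timepoint_change_test(
    cells_t1: np.ndarray,
    cells_t2: np.ndarray,
    annotator,
    observed_change: float,
    n_perm: int = 10000,
    seed: int = 0,
    change_fn=None,
) -> float:
    """Permutation p-value for an annotation change between two time points.

    The pooled cells are randomly re-divided into disjoint pseudo-groups of
    the observed sizes N1 and N2 ``n_perm`` times; the p-value is the
    fraction of permuted changes strictly exceeding the observed change.
    Disjoint splits keep the permutation null exchangeable with the observed
    (disjoint) grouping, so the p-values are not anti-conservative.
    ``change_fn(s1, s2)`` reduces two length-L score vectors to the scalar
    change (default: the largest absolute per-module difference).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if change_fn is None:
        change_fn = lambda s1, s2: float(np.max(np.abs(np.subtract(s2, s1))))
    t1 = np.atleast_2d(np.asarray(cells_t1, dtype=float))
    t2 = np.atleast_2d(np.asarray(cells_t2, dtype=float))
    pooled = np.vstack([t1, t2])
    n1 = t1.shape[0]
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        change = change_fn(annotator(pooled[perm[:n1]]), annotator(pooled[perm[n1:]]))
        if change > observed_change:
            exceed += 1
    return exceed / n_perm
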