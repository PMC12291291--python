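"""Turning module loadings into discrete cRegulons.

A fitted X column scores every TF's participation in one module.  The
module's TF pairs are the outer-product combinatorial effects CE_ij =
X_il * X_jl that are extreme against a Gamma null fitted to the module's
positive pair effects; its target genes are TF-TG edges whose rank-1
projected regulatory strength X_l (X_l^T R^k) is extreme against a Gaussian
null; the regulatory elements carrying each selected edge are pulled from
the network's TF-RE-TG triplets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .grn import RegulatoryNetwork

__all__ = [
    "CRegulon",
    "pair_effects",
    "significant_tf_pairs",
    "select_targets",
    "attach_res",
    "extract_cregulons",
]


@dataclass
class CRegulon:
    """One module's significant TF pairs with its per-cluster subnetworks."""

    module_index: int
    tf_pairs: list[tuple[str, str, float, float]]
    module_tfs: list[str]
    gamma_params: tuple[float, float] | None
    targets: dict = field(default_factory=dict)  # cluster -> list of (tf, tg, score, p)
    res: dict = field(default_factory=dict)  # cluster -> list of (tf, re, tg, co_bound)
    gaussian_params: dict = field(default_factory=dict)  # cluster -> (mean, sd)


def pair_effects(x: np.ndarray, module: int) -> np.ndarray:
    """Pairwise combinatorial effect of module ``l``: CE_ij = X_il * X_jl."""
    x = np.asarray(x, dtype=float)
    if not 0 <= module < x.shape[1]:
        raise IndexError(f"module index {module} out of range")
    col = x[:, module]
    return np.outer(col, col)


def _fit_gamma(values: np.ndarray) -> tuple[float, float]:
    """Gamma(shape, scale) with location fixed at 0; MLE with a
    method-of-moments fallback when the likelihood fit fails."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shape, _loc, scale = stats.gamma.fit(values, floc=0)
        if np.isfinite(shape) and np.isfinite(scale) and shape > 0 and scale > 0:
            return float(shape), float(scale)
    except Exception:
        pass
    mean, var = values.mean(), values.var(ddof=1)
    var = max(var, np.finfo(float).tiny)
    return float(mean**2 / var), float(var / mean)


def significant_tf_pairs(
    ce_matrix: np.ndarray,
    alpha: float = 0.05,
    tf_ids: list[str] | None = None,
) -> tuple[list[tuple[str, str, float, float]], tuple[float, float] | None]:
    """TF pairs whose combinatorial effect is extreme under a Gamma null.

    The null is fitted to the strictly positive upper-triangle CE values of
    this module; a pair is kept when its upper-tail probability is <= alpha.
    Returns (pairs sorted by CE descending, fitted (shape, scale)).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    ce = np.asarray(ce_matrix, dtype=float)
    m = ce.shape[0]
    labels = tf_ids if tf_ids is not None else [f"TF{i + 1}" for i in range(m)]
    iu = np.triu_indices(m, k=1)
    vals = ce[iu]
    positive = vals[vals > 0]
    if positive.size < 3:
        warnings.warn(
            "fewer than 3 positive pair effects; Gamma null unfittable",
            stacklevel=2,
        )
        return [], None
    shape, scale = _fit_gamma(positive)
    pvals = stats.gamma.sf(vals, shape, scale=scale)
    keep = (vals > 0) & (pvals <= alpha)
    pairs = [
        (labels[i], labels[j], float(v), float(p))
        for i, j, v, p in zip(iu[0][keep], iu[1][keep], vals[keep], pvals[keep])
    ]
    pairs.sort(key=lambda rec: -rec[2])
    return pairs, (shape, scale)


def select_targets(
    x: np.ndarray,
    module: int,
    network: RegulatoryNetwork,
    module_tfs: list[str],
    alpha_tg: float = 0.01,
) -> tuple[list[tuple[str, str, float, float]], tuple[float, float] | None]:
    """Co-regulated targets of a module in one cluster.

    Scores every TF-TG pair by the rank-1 projection S = X_l (X_l^T R^k),
    restricts to the module's TFs and to TGs they actually regulate
    (R_ij > 0), fits a Gaussian to those scores, and keeps edges whose
    upper-tail probability is <= alpha_tg.
    """
    x = np.asarray(x, dtype=float)
    col = x[:, module]
    s = np.outer(col, col @ network.strength)  # M x N rank-1 score matrix
    tf_pos = {t: i for i, t in enumerate(network.tf_ids)}
    rows = [tf_pos[t] for t in module_tfs if t in tf_pos]
    records = []
    for i in rows:
        for j in np.nonzero(network.strength[i] > 0)[0]:
            records.append((i, j, s[i, j]))
    if not records:
        warnings.warn("no TF-TG candidates for this module/cluster", stacklevel=2)
        return [], None
    scores = np.array([rec[2] for rec in records])
    mean = float(scores.mean())
    sd = float(scores.std(ddof=1)) if scores.size > 1 else 0.0
    if sd <= np.finfo(float).tiny:
        # all scores identical: nothing is extreme
        pvals = np.full(scores.size, 0.5)
    else:
        pvals = stats.norm.sf(scores, loc=mean, scale=sd)
    edges = [
        (network.tf_ids[i], network.tg_ids[j], float(sc), float(p))
        for (i, j, sc), p in zip(records, pvals)
        if p <= alpha_tg
    ]
    edges.sort(key=lambda rec: -rec[2])
    return edges, (mean, sd)


def attach_res(
    edges: list[tuple[str, str, float, float]],
    triplets: list[tuple[str, str, str, float]],
) -> list[tuple[str, str, str, bool]]:
    """Attach the regulatory elements carrying each selected TF-TG edge.

    Returns (tf, re, tg, co_bound) records, where ``co_bound`` marks REs
    used by at least two selected TFs on the same TG.
    """
    wanted = {(tf, tg) for tf, tg, _s, _p in edges}
    records = [
        (tf, re, tg) for tf, re, tg, _score in triplets if (tf, tg) in wanted
    ]
    users: dict[tuple[str, str], set[str]] = {}
    for tf, re, tg in records:
        users.setdefault((re, tg), set()).add(tf)
    return [
        (tf, re, tg, len(users[(re, tg)]) > 1) for tf, re, tg in records
    ]


def extract_cregulons(
    results,
    networks: list[RegulatoryNetwork] | None = None,
    alpha_pair: float = 0.05,
    alpha_tg: float = 0.01,
) -> list[CRegulon]:
    """Assemble one CRegulon per fitted module from a decomposition."""
    x = results.x
    tf_ids = results.tf_ids or [f"TF{i + 1}" for i in range(x.shape[0])]
    out = []
    for l in range(results.n_modules):
        ce = pair_effects(x, l)
        pairs, gamma_params = significant_tf_pairs(ce, alpha_pair, tf_ids)
        member_set = {tf for tf1, tf2, _c, _p in pairs for tf in (tf1, tf2)}
        order = np.argsort(x[:, l])[::-1]
        module_tfs = [tf_ids[i] for i in order if tf_ids[i] in member_set]
        creg = CRegulon(
            module_index=l,
            tf_pairs=pairs,
            module_tfs=module_tfs,
            gamma_params=gamma_params,
        )
        if networks is not None and module_tfs:
            for net in networks:
                edges, gauss = select_targets(x, l, net, module_tfs, alpha_tg)
                creg.targets[net.cluster_id] = edges
                creg.gaussian_params[net.cluster_id] = gauss
                creg.res[net.cluster_id] = attach_res(edges, net.triplets)
        out.append(creg)
    return out
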