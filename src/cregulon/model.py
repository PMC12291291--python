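"""Joint decomposition of combinatorial-effect matrices into TF modules.

The model seeks a shared non-negative TF-loading matrix ``X`` (M TFs x L
modules) and, per cell cluster k, a diagonal association matrix ``A_k``
(stored as a length-L vector of convex weights) minimising

    sum_k [ ||C^k - X A_k X^T||_F^2  -  mu * ||C^k ∘ (X A_k X^T)||_1 ]

subject to X >= 0, each X column having 2-norm <= 1, each X row summing to
<= 1, and each A_k being a non-negative vector summing to 1.  The first term
factorises the shared module structure; the second rewards reconstructing
exactly the large combinatorial-effect entries, and its weight mu is set
from the initial factorisation so that both terms start balanced.

Solved by multiplicative updates

    X   <- X ∘ [(4 + 2 mu) sum_k C^k X A_k] / [sum_k 4 X A_k X^T X A_k]
    A_k <- A_k ∘ diag[(1 + mu) X^T C^k X] / diag[X^T X A_k X^T X]

run unprojected — the reward term deliberately inflates the reconstruction
scale, and clamping the factors inside the loop turns that inflation into a
winner-take-all collapse of the columns — and followed at convergence by a
single projection onto the constraint set: each column's norm is absorbed
into the A weights, rows with sum above 1 are rescaled, and each A_k is
renormalised to a convex weight vector.  Iteration stops when the relative
objective change drops below ``tol``.  Because the objective is non-convex,
the fit restarts from several seeded initialisations (symmetric NMF of the
mean C matrix) and keeps the restart with the smallest reconstruction error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CRegulonModel",
    "CRegulonResults",
    "objective",
    "initialize",
    "select_mu",
    "fit_decomposition",
    "select_n_modules",
]

_EPS = 1e-10


def _as_c_list(c_list) -> list[np.ndarray]:
    mats = [np.asarray(c, dtype=float) for c in c_list]
    if not mats:
        raise ValueError("need at least one combinatorial-effect matrix")
    m = mats[0].shape[0]
    for c in mats:
        if c.shape != (m, m):
            raise ValueError("all C matrices must be square with equal size")
    return mats


def objective(c_list, x: np.ndarray, a: np.ndarray, mu: float) -> float:
    """Value of the regularised factorisation loss at (X, A)."""
    mats = _as_c_list(c_list)
    total = 0.0
    for k, c in enumerate(mats):
        recon = (x * a[k]) @ x.T
        total += float(((c - recon) ** 2).sum()) - mu * float(np.abs(c * recon).sum())
    return total


def _symmetric_nmf(c: np.ndarray, rank: int, seed: int, n_iter: int = 500) -> np.ndarray:
    """Symmetric NMF C ~ X X^T via the damped multiplicative rule
    X <- X ∘ (1 - beta + beta * (C X) / (X X^T X)), beta = 1/2."""
    m = c.shape[0]
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(c.mean(), _EPS) / max(rank, 1))
    x = rng.uniform(0.1, 1.0, size=(m, rank)) * scale
    for _ in range(n_iter):
        numer = c @ x
        denom = x @ (x.T @ x)
        x = x * (0.5 + 0.5 * numer / np.maximum(denom, _EPS))
    return x


def _project(x: np.ndarray, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map factors onto the constraint set.

    Column norms are absorbed into the A weights (which leaves every
    reconstruction X A_k X^T unchanged), rows with sum above 1 are scaled
    down, and each A_k row is renormalised to sum 1 (uniform fallback for an
    all-zero row).
    """
    x = np.maximum(x, 0.0)
    col_norms = np.sqrt((x**2).sum(axis=0))
    scale = np.maximum(col_norms, _EPS)
    x = x / scale
    a = np.maximum(a, 0.0) * scale**2
    sums = a.sum(axis=1, keepdims=True)
    # renormalising A rows rescales each reconstruction by 1/sum; compensate
    # with a shared column scale (capped at 1 by the norm constraint) so the
    # projection is as reconstruction-neutral as the constraints allow
    mean_sum = float(np.mean(sums)) if np.all(sums > _EPS) else 1.0
    x = x * min(1.0, np.sqrt(mean_sum))
    uniform = np.full_like(a, 1.0 / a.shape[1])
    a = np.where(sums > _EPS, a / np.maximum(sums, _EPS), uniform)
    row_sums = x.sum(axis=1)
    x = x / np.maximum(row_sums, 1.0)[:, None]
    return x, a


def initialize(c_list, n_modules: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Initial (X0, A0): symmetric NMF of the mean C matrix, uniform A rows.

    X0 is capped onto the constraint set (columns scaled down to unit norm,
    rows to unit sum) so the initial factors are feasible; A0 stays uniform.
    """
    mats = _as_c_list(c_list)
    m = mats[0].shape[0]
    if n_modules < 1:
        raise ValueError("number of modules must be >= 1")
    if n_modules > m:
        raise ValueError(f"cannot extract {n_modules} modules from {m} TFs")
    c0 = np.mean(mats, axis=0)
    x0 = _symmetric_nmf(c0, n_modules, seed)
    col_norms = np.sqrt((x0**2).sum(axis=0))
    x0 = x0 / np.maximum(col_norms, 1.0)
    row_sums = x0.sum(axis=1)
    x0 = x0 / np.maximum(row_sums, 1.0)[:, None]
    a0 = np.full((len(mats), n_modules), 1.0 / n_modules)
    return x0, a0


def select_mu(c_list, x0: np.ndarray, a0: np.ndarray) -> float:
    """mu balancing the two loss terms at the initial factorisation:
    sum_k ||C^k - X0 A0k X0^T||_F^2  /  sum_k sum_ij [C^k ∘ (X0 A0k X0^T)]_ij."""
    mats = _as_c_list(c_list)
    numer = 0.0
    denom = 0.0
    for k, c in enumerate(mats):
        recon = (x0 * a0[k]) @ x0.T
        numer += float(((c - recon) ** 2).sum())
        denom += float((c * recon).sum())
    if denom <= _EPS:
        warnings.warn(
            "degenerate initialisation (zero overlap with C); mu set to 0",
            stacklevel=2,
        )
        return 0.0
    return numer / denom


def _fit_single(
    mats: list[np.ndarray],
    n_modules: int,
    mu: float | None,
    seed: int,
    tol: float,
    max_iter: int,
    x_init: np.ndarray | None = None,
) -> "CRegulonResults":
    if x_init is not None:
        x = np.asarray(x_init, dtype=float).copy()
        a = np.full((len(mats), n_modules), 1.0 / n_modules)
    else:
        x, a = initialize(mats, n_modules, seed)
    if mu is None:
        mu = select_mu(mats, x, a)
    trace = [objective(mats, x, a, mu)]
    converged = False
    for it in range(max_iter):
        # X update
        numer = np.zeros_like(x)
        denom = np.zeros_like(x)
        for k, c in enumerate(mats):
            numer += (c @ x) * a[k]
            denom += 4.0 * (((x * a[k]) @ (x.T @ x)) * a[k])
        x = x * ((4.0 + 2.0 * mu) * numer) / np.maximum(denom, _EPS)
        # A update (per cluster, diagonal only)
        gram = x.T @ x
        gram_sq = gram * gram  # symmetric, so (G A G)_ll = sum_m G_lm^2 a_m
        for k, c in enumerate(mats):
            num_a = (1.0 + mu) * np.einsum("il,ij,jl->l", x, c, x, optimize=True)
            den_a = gram_sq @ a[k]
            a[k] = a[k] * num_a / np.maximum(den_a, _EPS)
        if not (np.isfinite(x).all() and np.isfinite(a).all()):
            raise FloatingPointError(
                f"non-finite values encountered at iteration {it + 1}"
            )
        trace.append(objective(mats, x, a, mu))
        prev, cur = trace[-2], trace[-1]
        if abs(prev - cur) < tol * max(abs(prev), _EPS):
            converged = True
            break
    x, a = _project(x, a)
    trace.append(objective(mats, x, a, mu))
    return CRegulonResults(
        x=x,
        a=a,
        mu=mu,
        n_modules=n_modules,
        loss_trace=np.asarray(trace),
        seed=seed,
        converged=converged,
    )


def _reconstruction_error(mats, x, a) -> float:
    return float(
        sum(((c - (x * a[k]) @ x.T) ** 2).sum() for k, c in enumerate(mats))
    )


def fit_decomposition(
    c_list,
    n_modules: int,
    mu: float | None = None,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 1000,
    n_restarts: int = 5,
    x_init: np.ndarray | None = None,
) -> "CRegulonResults":
    """Run the multiplicative-update algorithm.

    The reward weight mu is calibrated once, on the canonical initialisation
    derived from ``seed``, and shared by every restart so their objectives
    are comparable.  The fit then restarts ``n_restarts`` times from seeded
    symmetric-NMF initialisations and returns the solution with the smallest
    objective.  An explicit ``x_init`` bypasses the restarts.
    """
    mats = _as_c_list(c_list)
    if mu is None:
        x0, a0 = initialize(mats, n_modules, seed)
        mu = select_mu(mats, x0, a0)
    if x_init is not None:
        return _fit_single(mats, n_modules, mu, seed, tol, max_iter, x_init=x_init)
    best = None
    best_obj = np.inf
    for sub in np.random.SeedSequence(seed).generate_state(max(n_restarts, 1)):
        res = _fit_single(mats, n_modules, mu, int(sub % 2**31), tol, max_iter)
        obj = float(res.loss_trace[-1])
        if obj < best_obj:
            best, best_obj = res, obj
    best.seed = seed
    return best


def elbow_point(candidates, losses, threshold: float = 0.05) -> int:
    """Smallest candidate whose relative loss decrease to the next candidate
    is at most ``threshold``; the last candidate when none qualifies."""
    chosen = candidates[-1]
    for i in range(len(candidates) - 1):
        drop = (losses[i] - losses[i + 1]) / max(abs(losses[i]), _EPS)
        if drop <= threshold:
            chosen = candidates[i]
            break
    return chosen


def select_n_modules(
    c_list,
    l_range,
    seed: int = 0,
    elbow_threshold: float = 0.05,
    **fit_kwargs,
) -> tuple[int, pd.DataFrame]:
    """Elbow rule on final loss versus number of modules.

    Fits once per candidate L and returns the smallest L whose relative loss
    decrease to the next candidate is at most ``elbow_threshold``, together
    with the full loss table for plotting.  The loss compared across
    candidates is the Frobenius reconstruction error, which unlike the full
    objective is comparable between fits with different reward weights mu.
    """
    candidates = list(l_range)
    if not candidates or sorted(candidates) != candidates:
        raise ValueError("l_range must be non-empty and ascending")
    mats = _as_c_list(c_list)
    losses = []
    for L in candidates:
        res = fit_decomposition(mats, L, seed=seed, **fit_kwargs)
        losses.append(_reconstruction_error(mats, res.x, res.a))
    table = pd.DataFrame({"n_modules": candidates, "loss": losses})
    return elbow_point(candidates, losses, elbow_threshold), table


class CRegulonModel:
    """TF combinatorial-module model over K cell clusters.

    Parameters
    ----------
    effects : sequence of CombinatorialEffect or M x M arrays
        One symmetric combinatorial-effect matrix per cell cluster.
    tf_ids, cluster_ids : optional label vectors; inferred from
        CombinatorialEffect inputs when omitted.
    """

    def __init__(self, effects, tf_ids=None, cluster_ids=None):
        from .effect import CombinatorialEffect

        c_list = []
        inferred_tfs = None
        inferred_clusters = []
        for k, eff in enumerate(effects):
            if isinstance(eff, CombinatorialEffect):
                c_list.append(eff.c)
                inferred_clusters.append(eff.cluster_id)
                if inferred_tfs is None:
                    inferred_tfs = list(eff.tf_ids)
                elif inferred_tfs != list(eff.tf_ids):
                    raise ValueError("all clusters must share one TF label space")
            else:
                c_list.append(np.asarray(eff, dtype=float))
                inferred_clusters.append(f"cluster{k + 1}")
        self.c_list = _as_c_list(c_list)
        m = self.c_list[0].shape[0]
        self.tf_ids = list(tf_ids) if tf_ids is not None else (
            inferred_tfs or [f"TF{i + 1}" for i in range(m)]
        )
        self.cluster_ids = (
            list(cluster_ids) if cluster_ids is not None else inferred_clusters
        )
        if len(self.tf_ids) != m:
            raise ValueError("tf_ids length does not match matrix size")
        if len(self.cluster_ids) != len(self.c_list):
            raise ValueError("cluster_ids length does not match number of clusters")

    @classmethod
    def from_networks(cls, networks, expression, epsilon: float = 0.05):
        """Build the model from per-cluster RegulatoryNetwork objects and a
        mapping ``{cluster_id: ExpressionSummary}`` of TF expression."""
        from .effect import combinatorial_matrix

        effects = [
            combinatorial_matrix(net, expression[net.cluster_id], epsilon)
            for net in networks
        ]
        return cls(effects)

    @property
    def n_tfs(self) -> int:
        return self.c_list[0].shape[0]

    @property
    def n_clusters(self) -> int:
        return len(self.c_list)

    def objective(self, x, a, mu) -> float:
        return objective(self.c_list, x, a, mu)

    def initialize(self, n_modules: int, seed: int = 0):
        return initialize(self.c_list, n_modules, seed)

    def select_mu(self, x0, a0) -> float:
        return select_mu(self.c_list, x0, a0)

    def fit(
        self,
        n_modules: int,
        mu: float | None = None,
        seed: int = 0,
        tol: float = 1e-4,
        max_iter: int = 1000,
        n_restarts: int = 5,
    ) -> "CRegulonResults":
        res = fit_decomposition(
            self.c_list,
            n_modules,
            mu=mu,
            seed=seed,
            tol=tol,
            max_iter=max_iter,
            n_restarts=n_restarts,
        )
        res.model = self
        res.tf_ids = list(self.tf_ids)
        res.cluster_ids = list(self.cluster_ids)
        return res

    def select_n_modules(self, l_range, seed: int = 0, elbow_threshold: float = 0.05):
        return select_n_modules(
            self.c_list, l_range, seed=seed, elbow_threshold=elbow_threshold
        )


@dataclass
class CRegulonResults:
    """Fitted decomposition: shared TF loadings and per-cluster associations."""

    x: np.ndarray
    a: np.ndarray
    mu: float
    n_modules: int
    loss_trace: np.ndarray
    seed: int
    converged: bool
    model: CRegulonModel | None = None
    tf_ids: list[str] = field(default_factory=list)
    cluster_ids: list[str] = field(default_factory=list)

    @property
    def module_ids(self) -> list[str]:
        return [f"M{l + 1}" for l in range(self.n_modules)]

    @property
    def x_frame(self) -> pd.DataFrame:
        tfs = self.tf_ids or [f"TF{i + 1}" for i in range(self.x.shape[0])]
        return pd.DataFrame(self.x, index=tfs, columns=self.module_ids)

    @property
    def a_frame(self) -> pd.DataFrame:
        clusters = self.cluster_ids or [
            f"cluster{k + 1}" for k in range(self.a.shape[0])
        ]
        return pd.DataFrame(self.a, index=clusters, columns=self.module_ids)

    def top_tfs(self, module: int, n: int = 20) -> list[str]:
        """TFs of one module ranked by loading, largest first."""
        order = np.argsort(self.x[:, module])[::-1][:n]
        tfs = self.tf_ids or [f"TF{i + 1}" for i in range(self.x.shape[0])]
        return [tfs[i] for i in order if self.x[i, module] > 0]

    def extract_cregulons(
        self,
        networks=None,
        alpha_pair: float = 0.05,
        alpha_tg: float = 0.01,
    ):
        from .assembly import extract_cregulons

        return extract_cregulons(
            self, networks=networks, alpha_pair=alpha_pair, alpha_tg=alpha_tg
        )

    def annotate_cells(self, expr_vectors, network, normalize: bool = True):
        from .annotation import annotate_cells

        return annotate_cells(expr_vectors, network, self.x, normalize=normalize)

    def annotate_group(self, cluster_proportions):
        from .annotation import annotate_group

        return annotate_group(cluster_proportions, self.a)

    def association_coordinates(self, u_prime=None, u=None):
        from .annotation import association_coordinates, cregulon_coordinates

        if u_prime is not None:
            return association_coordinates(self.a, u_prime)
        if u is not None:
            return cregulon_coordinates(self.a, u)
        raise ValueError("provide module coordinates u_prime or cluster coordinates u")

    def transition_score(self, module_i_tfs, module_j_tfs, weights=(0.5, 0.5)):
        from .compare import transition_score

        tfs = self.tf_ids or [f"TF{i + 1}" for i in range(self.x.shape[0])]
        return transition_score(self.x, module_i_tfs, module_j_tfs, tfs, weights)

    def summary(self) -> str:
        lines = [
            "cRegulon decomposition",
            "======================",
            f"TFs: {self.x.shape[0]}   clusters: {self.a.shape[0]}   "
            f"modules: {self.n_modules}",
            f"mu: {self.mu:.6g}   seed: {self.seed}   "
            f"iterations: {len(self.loss_trace) - 1}   converged: {self.converged}",
            f"initial loss: {self.loss_trace[0]:.6g}   "
            f"final loss: {self.loss_trace[-1]:.6g}",
            "",
            "Top TFs per module:",
        ]
        for l in range(self.n_modules):
            tops = ", ".join(self.top_tfs(l, n=5))
            lines.append(f"  {self.module_ids[l]}: {tops}")
        lines.append("")
        lines.append("Cluster associations (rows sum to 1):")
        lines.append(self.a_frame.round(4).to_string())
        return "\n".join(lines)
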