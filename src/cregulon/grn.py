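"""Per-cluster pseudo-bulk profiles and trans-regulatory TF->TG networks.

This stage sits upstream of the combinatorial model: single-cell counts from
one cell cluster are merged into pseudo-bulk CPM profiles, and a PECA2-style
trans-regulatory score combines motif binding, regulatory-element (RE)
openness, RE--target-gene interaction priors, a TF--gene correlation prior
and pseudo-bulk expression into a TF x TG strength matrix ``R``.  The core
model also accepts precomputed ``R`` matrices directly, so this module is
optional for users who already ran an external GRN builder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClusterCounts",
    "PseudoBulkProfile",
    "PriorData",
    "RegulatoryNetwork",
    "pseudobulk",
    "trans_regulatory_score",
]


@dataclass
class ClusterCounts:
    """Raw per-cluster count matrices: genes x cells (RNA) and peaks x cells (ATAC)."""

    cluster_id: str
    gene_counts: np.ndarray
    peak_counts: np.ndarray
    gene_ids: list[str]
    peak_ids: list[str]

    def __post_init__(self) -> None:
        self.gene_counts = np.asarray(self.gene_counts, dtype=float)
        self.peak_counts = np.asarray(self.peak_counts, dtype=float)
        if self.gene_counts.ndim != 2 or self.peak_counts.ndim != 2:
            raise ValueError("count matrices must be 2-D (features x cells)")
        if (self.gene_counts < 0).any() or (self.peak_counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(self.gene_ids) != self.gene_counts.shape[0]:
            raise ValueError(
                f"gene_ids length {len(self.gene_ids)} != matrix rows "
                f"{self.gene_counts.shape[0]}"
            )
        if len(self.peak_ids) != self.peak_counts.shape[0]:
            raise ValueError(
                f"peak_ids length {len(self.peak_ids)} != matrix rows "
                f"{self.peak_counts.shape[0]}"
            )
        if self.gene_counts.shape[1] < 1 or self.peak_counts.shape[1] < 1:
            raise ValueError("each modality needs at least one cell")


@dataclass
class PseudoBulkProfile:
    """CPM-scaled pseudo-bulk expression (pe) and chromatin openness (po)."""

    cluster_id: str
    pe: np.ndarray
    po: np.ndarray
    gene_ids: list[str]
    peak_ids: list[str]
    totals: tuple[float, float]
    accessible_mask: np.ndarray


@dataclass
class PriorData:
    """Regulatory priors: motif binding B (TF x RE), RE-TG interaction I,
    and TF-TG expression correlation D in [-1, 1]."""

    motif_binding: pd.DataFrame
    re_tg_interaction: pd.DataFrame
    tf_tg_correlation: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.motif_binding.to_numpy() < 0).any():
            raise ValueError("motif binding strengths must be non-negative")
        if (self.re_tg_interaction.to_numpy() < 0).any():
            raise ValueError("RE-TG interaction strengths must be non-negative")
        if (np.abs(self.tf_tg_correlation.to_numpy()) > 1 + 1e-12).any():
            raise ValueError("TF-TG correlations must lie in [-1, 1]")


@dataclass
class RegulatoryNetwork:
    """One cluster's TF x TG regulatory strength matrix plus optional
    (tf, re, tg, score) triplets recording which REs carry each edge."""

    cluster_id: str
    strength: np.ndarray
    tf_ids: list[str]
    tg_ids: list[str]
    triplets: list[tuple[str, str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.strength = np.asarray(self.strength, dtype=float)
        if self.strength.shape != (len(self.tf_ids), len(self.tg_ids)):
            raise ValueError("strength shape does not match tf/tg label lengths")
        if (self.strength < 0).any():
            raise ValueError("regulatory strengths must be non-negative")
        tfs, tgs = set(self.tf_ids), set(self.tg_ids)
        for tf, _re, tg, _s in self.triplets:
            if tf not in tfs:
                raise ValueError(f"triplet TF {tf!r} not in tf_ids")
            if tg not in tgs:
                raise ValueError(f"triplet TG {tg!r} not in tg_ids")

    @property
    def n_tfs(self) -> int:
        return self.strength.shape[0]

    @property
    def n_tgs(self) -> int:
        return self.strength.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.strength, index=self.tf_ids, columns=self.tg_ids)


def pseudobulk(
    counts: ClusterCounts, accessibility_threshold: float = 2.0
) -> PseudoBulkProfile:
    """Merge cells into CPM-scaled pseudo-bulk profiles.

    pe_i = (sum_c E_ic / e) * 1e6 over RNA reads, po_r likewise over ATAC
    reads; peaks with po >= ``accessibility_threshold`` (default 2 CPM) are
    flagged accessible and become the candidate REs downstream.
    """
    if accessibility_threshold < 0:
        raise ValueError("accessibility threshold must be non-negative")
    e = float(counts.gene_counts.sum())
    o = float(counts.peak_counts.sum())
    if e == 0:
        raise ValueError(
            f"cluster {counts.cluster_id!r}: RNA count matrix is all zero"
        )
    if o == 0:
        raise ValueError(
            f"cluster {counts.cluster_id!r}: ATAC count matrix is all zero"
        )
    pe = counts.gene_counts.sum(axis=1) / e * 1e6
    po = counts.peak_counts.sum(axis=1) / o * 1e6
    return PseudoBulkProfile(
        cluster_id=counts.cluster_id,
        pe=pe,
        po=po,
        gene_ids=list(counts.gene_ids),
        peak_ids=list(counts.peak_ids),
        totals=(e, o),
        accessible_mask=po >= accessibility_threshold,
    )


def trans_regulatory_score(
    profile: PseudoBulkProfile,
    priors: PriorData,
    tf_ids: list[str],
    tg_ids: list[str],
    accessible_only: bool = True,
) -> RegulatoryNetwork:
    """PECA2-style trans-regulatory score.

    R_ij = (sum_r B_ir * PO_r * I_rj) * 2^|D_ij| * sqrt(PE_i * PE_j),
    with r running over the cluster's accessible REs (all REs when
    ``accessible_only`` is False).  A (tf, re, tg, score) triplet is emitted
    for every term B_ir * PO_r * I_rj > 0, scored by that term's contribution.
    """
    gene_pos = {g: idx for idx, g in enumerate(profile.gene_ids)}
    for label, ids in (("TF", tf_ids), ("TG", tg_ids)):
        for name in ids:
            if name not in gene_pos:
                raise ValueError(
                    f"{label} {name!r} missing from the pseudo-bulk gene labels"
                )
    b = priors.motif_binding.reindex(index=tf_ids)
    if b.isna().any().any():
        missing = b.index[b.isna().any(axis=1)][0]
        raise ValueError(f"TF {missing!r} missing from the motif-binding prior")
    re_ids = list(priors.motif_binding.columns)
    peak_pos = {p: idx for idx, p in enumerate(profile.peak_ids)}
    for re_id in re_ids:
        if re_id not in peak_pos:
            raise ValueError(f"RE {re_id!r} missing from the openness profile")
    i_mat = priors.re_tg_interaction.reindex(index=re_ids, columns=tg_ids)
    if i_mat.isna().any().any():
        raise ValueError("RE-TG interaction prior does not cover all REs/TGs")
    d_mat = priors.tf_tg_correlation.reindex(index=tf_ids, columns=tg_ids)
    if d_mat.isna().any().any():
        raise ValueError("TF-TG correlation prior does not cover all TFs/TGs")

    po = np.array([profile.po[peak_pos[p]] for p in re_ids])
    mask = (
        np.array([profile.accessible_mask[peak_pos[p]] for p in re_ids])
        if accessible_only
        else np.ones(len(re_ids), dtype=bool)
    )
    po_eff = np.where(mask, po, 0.0)

    b_arr = b.to_numpy(dtype=float)
    i_arr = i_mat.to_numpy(dtype=float)
    d_arr = d_mat.to_numpy(dtype=float)
    pe_tf = np.array([profile.pe[gene_pos[t]] for t in tf_ids])
    pe_tg = np.array([profile.pe[gene_pos[g]] for g in tg_ids])

    cis = (b_arr * po_eff) @ i_arr  # TF x TG sum over REs
    strength = cis * np.power(2.0, np.abs(d_arr)) * np.sqrt(np.outer(pe_tf, pe_tg))

    triplets: list[tuple[str, str, str, float]] = []
    for ti, tf in enumerate(tf_ids):
        active = np.nonzero(b_arr[ti] * po_eff)[0]
        for ri in active:
            contrib = b_arr[ti, ri] * po_eff[ri] * i_arr[ri]
            for gi in np.nonzero(contrib)[0]:
                triplets.append((tf, re_ids[ri], tg_ids[gi], float(contrib[gi])))

    return RegulatoryNetwork(
        cluster_id=profile.cluster_id,
        strength=strength,
        tf_ids=list(tf_ids),
        tg_ids=list(tg_ids),
        triplets=triplets,
    )
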