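"""Readers/writers for the on-disk formats and run configuration.

Matrices travel either as dense TSV (header row of column labels, first
column of row labels) or as MatrixMarket files with sidecar one-label-per-
line row/column files.  Triplet tables are TSV with a tf/re/tg/score header.
Floating-point outputs are written with 6 significant digits.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio

__all__ = [
    "RunConfig",
    "read_matrix",
    "write_matrix",
    "read_triplets",
    "write_triplets",
]

_FLOAT_FMT = "%.6g"


@dataclasses.dataclass
class RunConfig:
    """Resolved numeric defaults of a pipeline run; written beside outputs."""

    epsilon: float = 0.05
    min_po: float = 2.0
    alpha_pair: float = 0.05
    alpha_tg: float = 0.01
    tol: float = 1e-4
    max_iter: int = 1000
    relevance_threshold: float = 0.01
    strong_threshold: float = 0.1
    n_background: int = 50
    n_perm: int = 10000
    lambda_weight: float = 0.5
    mu_weight: float = 0.5
    seed: int = 0
    n_modules: int | None = None
    l_range: list[int] | None = None

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _check_labels(labels, what: str, path) -> list[str]:
    labels = [str(x) for x in labels]
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"{path}: duplicate {what} label {lab!r}")
        seen.add(lab)
    return labels


def read_matrix(path, kind: str = "dense-tsv") -> pd.DataFrame:
    """Read a labeled matrix.

    ``kind='dense-tsv'``: TSV with a header row and row labels in the first
    column.  ``kind='mtx+labels'``: MatrixMarket file ``X.mtx`` with sidecar
    label files ``X.rows.txt`` and ``X.cols.txt`` (one label per line).
    """
    path = Path(path)
    if kind == "dense-tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        bad = df.columns[~df.dtypes.map(lambda d: np.issubdtype(d, np.number))]
        if len(bad):
            col = bad[0]
            row = int(pd.to_numeric(df[col], errors="coerce").isna().idxmax()) \
                if df.index.dtype.kind in "iu" else df[col].first_valid_index()
            raise ValueError(
                f"{path}: non-numeric values in column {col!r} (near row {row!r})"
            )
        df.index = _check_labels(df.index, "row", path)
        df.columns = _check_labels(df.columns, "column", path)
        return df
    if kind == "mtx+labels":
        mat = spio.mmread(path)
        mat = mat.toarray() if hasattr(mat, "toarray") else np.asarray(mat)
        rows_file = path.with_suffix("").with_suffix(".rows.txt")
        cols_file = path.with_suffix("").with_suffix(".cols.txt")
        rows = _check_labels(
            rows_file.read_text().splitlines(), "row", rows_file
        )
        cols = _check_labels(
            cols_file.read_text().splitlines(), "column", cols_file
        )
        if len(rows) != mat.shape[0]:
            raise ValueError(
                f"{rows_file}: {len(rows)} labels for {mat.shape[0]} matrix rows"
            )
        if len(cols) != mat.shape[1]:
            raise ValueError(
                f"{cols_file}: {len(cols)} labels for {mat.shape[1]} matrix columns"
            )
        return pd.DataFrame(mat, index=rows, columns=cols)
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_matrix(df: pd.DataFrame, path, kind: str = "dense-tsv") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if kind == "dense-tsv":
        df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
        return
    if kind == "mtx+labels":
        spio.mmwrite(path, np.asarray(df.to_numpy(), dtype=float))
        path.with_suffix("").with_suffix(".rows.txt").write_text(
            "\n".join(map(str, df.index)) + "\n"
        )
        path.with_suffix("").with_suffix(".cols.txt").write_text(
            "\n".join(map(str, df.columns)) + "\n"
        )
        return
    raise ValueError(f"unknown matrix kind {kind!r}")


def read_triplets(path) -> list[tuple[str, str, str, float]]:
    """Read a (tf, re, tg, score) TSV; scores must be non-negative."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    expected = ["tf", "re", "tg", "score"]
    if list(df.columns[:4]) != expected:
        raise ValueError(
            f"{path}: expected header columns {expected}, got {list(df.columns)}"
        )
    scores = pd.to_numeric(df["score"], errors="coerce")
    if scores.isna().any():
        row = int(scores.isna().idxmax()) + 2  # 1-based, after header
        raise ValueError(f"{path}: non-numeric score at line {row}")
    if (scores < 0).any():
        row = int((scores < 0).idxmax()) + 2
        raise ValueError(f"{path}: negative score at line {row}")
    return [
        (str(tf), str(re), str(tg), float(s))
        for tf, re, tg, s in zip(df["tf"], df["re"], df["tg"], scores)
    ]


def write_triplets(triplets, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(triplets, columns=["tf", "re", "tg", "score"])
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
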