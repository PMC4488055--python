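"""Eigengene-based connectivity scoring of network nodes.

A node's importance combines its normalized degree with its coupling to the
dominant expression trend of the (sub)network:

    SCORE_i = d_i / d_max + 2 * |cor(X_i, E)|

where d_i is the node's degree within the scored network, d_max the maximum
such degree, X_i the node's expression vector over samples, and E the
network eigengene — the first principal component of the column-standardized
node-expression matrix (the WGCNA module-eigengene convention).  Scores lie
in [0, 3]; the degree term contributes at most 1 and the correlation term at
most 2, so variance coupling dominates the ranking.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network_core import InteractionNetwork

__all__ = ["Eigengene", "NodeScore", "compute_eigengene", "score_node",
           "rank_mirnas"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Eigengene:
    """Unit-norm eigengene over samples plus its explained-variance share.

    The sign is fixed so the mean correlation with the expression columns
    is non-negative.
    """

    values: np.ndarray
    explained_variance_fraction: float


@dataclass(frozen=True)
class NodeScore:
    node: str
    d_i: int
    d_max: int
    abs_cor: float
    score: float


def _standardize(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column z-scores; returns (standardized matrix, constant-column mask)."""
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=0)
    constant = sd == 0
    safe_sd = np.where(constant, 1.0, sd)
    z = (matrix - mean) / safe_sd
    z[:, constant] = 0.0
    return z, constant


def compute_eigengene(expr: pd.DataFrame | np.ndarray) -> Eigengene:
    """First principal component over samples of the standardized matrix.

    ``expr`` has samples as rows and nodes as columns.  Constant columns are
    ignored (flagged with a warning); if every column is constant there is no
    expression variance to summarize and an error is raised.
    """
    matrix = np.asarray(expr, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("expression matrix needs >= 2 samples (rows)")
    z, constant = _standardize(matrix)
    if constant.all():
        raise ValueError("all expression columns are constant")
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant expression column(s) ignored "
            "for eigengene computation",
            stacklevel=2,
        )
    u, s, _ = np.linalg.svd(z[:, ~constant], full_matrices=False)
    eigengene = u[:, 0]
    # sign convention: mean correlation with the columns is >= 0
    cors = _column_correlations(z[:, ~constant], eigengene)
    if cors.mean() < 0:
        eigengene = -eigengene
    explained = float(s[0] ** 2 / np.sum(s**2))
    return Eigengene(values=eigengene, explained_variance_fraction=explained)


def _column_correlations(z: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Pearson correlation of each standardized column with vector e."""
    e_centered = e - e.mean()
    e_norm = np.linalg.norm(e_centered)
    col_norms = np.linalg.norm(z, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cors = (z.T @ e_centered) / (col_norms * e_norm)
    return np.nan_to_num(cors, nan=0.0)


def score_node(d_i: int, d_max: int, abs_cor: float) -> float:
    """SCORE = d_i/d_max + 2*abs_cor."""
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    if not 0 <= d_i <= d_max:
        raise ValueError(f"d_i must lie in [0, d_max]; got {d_i}, {d_max}")
    if not 0.0 <= abs_cor <= 1.0:
        raise ValueError(f"abs_cor must lie in [0, 1]; got {abs_cor}")
    return d_i / d_max + 2.0 * abs_cor


def rank_mirnas(
    net: InteractionNetwork,
    expr: pd.DataFrame,
    top_k: int = 20,
    degree_mode: str = "total",
) -> list[NodeScore]:
    """Rank the network's miRNA nodes by eigengene-based connectivity.

    ``expr`` is a samples x nodes DataFrame whose columns cover the miRNA
    nodes (missing nodes are excluded with a warning).  The eigengene is
    computed from the scored miRNAs' expression submatrix; degree is the
    node's total (in+out) degree within ``net`` by default
    (``degree_mode`` in {"total", "in", "out"}).  Ordering: descending
    score, ties broken by degree then lexical id; the top ``top_k`` are
    returned.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if degree_mode not in ("total", "in", "out"):
        raise ValueError(f"unknown degree_mode {degree_mode!r}")
    mirnas = sorted(
        n for n in net.nodes if net.nodes[n].get("kind") == "mirna"
    )
    missing = [m for m in mirnas if m not in expr.columns]
    if missing:
        logger.warning(
            "%d miRNA node(s) missing from expression matrix, excluded: %s",
            len(missing), missing[:10],
        )
    scored = [m for m in mirnas if m in expr.columns]
    if not scored:
        raise ValueError("no miRNA node has an expression column")

    sub = expr[scored]
    eigengene = compute_eigengene(sub)
    z, constant = _standardize(np.asarray(sub, dtype=float))
    cors = np.abs(_column_correlations(z, eigengene.values))
    cors[constant] = 0.0
    if constant.any():
        warnings.warn(
            "constant expression column(s) assigned abs_cor = 0",
            stacklevel=2,
        )

    degree_of = {
        "total": lambda n: net.degree(n),
        "in": lambda n: net.in_degree(n),
        "out": lambda n: net.out_degree(n),
    }[degree_mode]
    degrees = {m: int(degree_of(m)) for m in scored}
    d_max = max(1, max(degrees.values()))

    scores = [
        NodeScore(
            node=m,
            d_i=degrees[m],
            d_max=d_max,
            abs_cor=float(cors[i]),
            score=score_node(degrees[m], d_max, float(np.clip(cors[i], 0, 1))),
        )
        for i, m in enumerate(scored)
    ]
    scores.sort(key=lambda s: (-s.score, -s.d_i, s.node))
    return scores[:top_k]
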