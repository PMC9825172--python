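"""Transcription-unit level statistics.

Gene expression is aggregated to TUs (mean over member coding genes),
the gene clustering is transferred to TUs by seeded k-means, immediate
responses are labeled up/down/nc against a log2-ratio threshold, and
5'->3' expression gradients are computed from fold-change tables.
TPM normalization and the qPCR ddCt quantity live here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, FoldChangeTable, TranscriptionUnit

logger = logging.getLogger(__name__)


def aggregate_to_tu(
    matrix: ExpressionMatrix, tus: Sequence[TranscriptionUnit]
) -> tuple[ExpressionMatrix, list[str]]:
    """Mean expression over each TU's quantified member genes.

    TUs with no quantified genes are excluded and returned in the
    skipped list.
    """
    idx = {g: i for i, g in enumerate(matrix.gene_ids)}
    tu_ids, rows, skipped = [], [], []
    for tu in tus:
        present = [idx[g] for g in tu.genes if g in idx]
        if not present:
            skipped.append(tu.tu_id)
            continue
        tu_ids.append(tu.tu_id)
        rows.append(matrix.values[present].mean(axis=0))
    if skipped:
        logger.info("aggregate_to_tu: %d TUs had no quantified genes", len(skipped))
    if not tu_ids:
        raise ValueError("no TU has any quantified gene")
    return ExpressionMatrix(tu_ids, matrix.samples, np.array(rows), matrix.unit), skipped


@dataclass
class KMeansResult:
    labels: np.ndarray  # 1-based cluster per observation
    centers: np.ndarray
    n_iter: int
    empty_clusters: list[int]  # 1-based ids of clusters that lost all members


def kmeans_seeded(
    X: np.ndarray, centers: np.ndarray, tol: float = 1e-8, max_iter: int = 300
) -> KMeansResult:
    """Lloyd's algorithm initialized exactly at the supplied centers.

    K stays fixed; a cluster that captures no points keeps its previous
    center and is reported as empty rather than being reseeded (the
    transfer must preserve the gene-clustering geometry).
    """
    X = np.asarray(X, dtype=float)
    centers = np.array(centers, dtype=float, copy=True)
    if X.shape[1] != centers.shape[1]:
        raise ValueError(
            f"dimension mismatch: data has {X.shape[1]} features, "
            f"centers have {centers.shape[1]}"
        )
    K = centers.shape[0]
    labels = np.zeros(len(X), dtype=int)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        new_centers = centers.copy()
        for k in range(K):
            mask = labels == k
            if mask.any():
                new_centers[k] = X[mask].mean(axis=0)
        shift = np.sqrt(((new_centers - centers) ** 2).sum(axis=1)).max()
        centers = new_centers
        if shift <= tol:
            break
    empty = [k + 1 for k in range(K) if not (labels == k).any()]
    if empty:
        logger.warning("kmeans_seeded: clusters %s are empty", empty)
    return KMeansResult(labels + 1, centers, n_iter, empty)


@dataclass
class ResponseLabel:
    """up/down/nc labels from the immediate post/pre induction log2 ratio."""

    labels: dict[str, str]
    ratios: dict[str, float]
    theta: float

    def counts(self) -> dict[str, int]:
        out = {"up": 0, "down": 0, "nc": 0}
        for v in self.labels.values():
            out[v] += 1
        return out


THETA_GENE = 0.01  # permissive gene-level threshold (directionality census)
THETA_TU = 0.15  # stricter TU-level threshold (extremes only)


def immediate_response(
    matrix: ExpressionMatrix,
    pre_indices=(0, 1),
    post_indices=(2, 3),
    theta: float = THETA_GENE,
    delta: float = 0.5,
) -> ResponseLabel:
    """Label items by r = log2((mean_post + d)/(mean_pre + d)).

    ``down`` if r < -theta, ``up`` if r > theta, else ``nc``; the
    inequalities are strict, so r exactly at +-theta is ``nc``.
    """
    pre = matrix.values[:, list(pre_indices)].mean(axis=1)
    post = matrix.values[:, list(post_indices)].mean(axis=1)
    r = np.log2((post + delta) / (pre + delta))
    labels = {}
    for gid, ri in zip(matrix.gene_ids, r):
        labels[gid] = "down" if ri < -theta else ("up" if ri > theta else "nc")
    return ResponseLabel(labels, dict(zip(matrix.gene_ids, map(float, r))), theta)


def tu_gradient(
    fc: FoldChangeTable, tus: Sequence[TranscriptionUnit], min_genes: int = 2
) -> pd.DataFrame:
    """5'->3' response gradient: delta = log2fc(first) - log2fc(last) per TU.

    A positive delta means the downstream (3') gene responds less (or
    more negatively) than the promoter-proximal gene. TUs with fewer
    than ``min_genes`` genes, or with members missing from the
    fold-change table, are skipped.
    """
    rows = []
    n_missing = 0
    known = set(fc.log2fc.index)
    for tu in tus:
        if len(tu.genes) < min_genes:
            continue
        if not set(tu.genes) <= known:
            n_missing += 1
            continue
        for contrast in fc.contrasts:
            rows.append(
                {
                    "tu_id": tu.tu_id,
                    "contrast": contrast,
                    "delta_log2fc": fc.get(tu.genes[0], contrast)
                    - fc.get(tu.genes[-1], contrast),
                    "n_genes": len(tu.genes),
                }
            )
    if n_missing:
        logger.info("tu_gradient: %d TUs skipped (genes missing from table)", n_missing)
    return pd.DataFrame(rows, columns=["tu_id", "contrast", "delta_log2fc", "n_genes"])


def tpm(counts: ExpressionMatrix, gene_lengths_nt: Mapping[str, float]) -> ExpressionMatrix:
    """Transcripts-per-kilobase-million normalization of raw counts.

    rate_g = counts_g / (length_g / 1000); TPM_g = 1e6 * rate_g / sum(rate)
    per sample, so every column sums to 1e6.
    """
    if counts.unit != "counts":
        raise ValueError("tpm() expects a counts matrix")
    lengths = np.array([gene_lengths_nt[g] for g in counts.gene_ids], dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.values / (lengths[:, None] / 1000.0)
    denom = rate.sum(axis=0)
    if (denom == 0).any():
        bad = [counts.samples.sample_ids[i] for i in np.flatnonzero(denom == 0)]
        raise ValueError(f"zero-count library in sample(s): {', '.join(bad)}")
    return ExpressionMatrix(
        list(counts.gene_ids), counts.samples, rate / denom * 1e6, unit="TPM"
    )


def delta_delta_ct(
    ct_target: Mapping[str, float],
    ct_reference_gene: Mapping[str, float],
    sample: str,
    reference_state: str,
) -> tuple[float, float]:
    """qPCR relative quantification against a reference gene and state.

    dCt(state) = Ct_target(state) - Ct_refgene(state); the raw ddCt is
    dCt(sample) - dCt(reference_state) and the returned log2 fold
    change is its negation, so a drop in target Ct (more transcript)
    gives a positive value. Returns (log2_fold_change, raw_ddct).
    """
    d_sample = ct_target[sample] - ct_reference_gene[sample]
    d_ref = ct_target[reference_state] - ct_reference_gene[reference_state]
    ddct = d_sample - d_ref
    return -ddct, ddct
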