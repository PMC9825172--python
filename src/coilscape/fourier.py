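"""Model-based time-series clustering on normalized Fourier features.

The chain is: arcsinh variance stabilization of TPM, discrete Fourier
transform of each gene's series, amplitude normalization of each
non-DC component by the mean amplitude of the other non-DC components,
then Gaussian mixture clustering of the stacked real/imaginary parts of
components 1..m over a range of cluster numbers K, selecting the K
that maximizes BIC = 2*logL - p*ln(n).

The normalization makes the features scale-free: a gene's response
shape, not its absolute expression level, determines its cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.mixture import GaussianMixture

from .core import Classification, ExpressionMatrix

logger = logging.getLogger(__name__)


def arcsinh_transform(x):
    """ln(x + sqrt(x^2 + 1)) for x >= 0; ~ ln(2x) for large x."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("arcsinh transform expects non-negative expression values")
    return np.arcsinh(x)


def dft(series):
    """One-sided DFT: X_k = sum_t x_t exp(-2*pi*i*k*t/N), k = 0..N//2."""
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[None, :]
    n = series.shape[-1]
    if n < 4:
        raise ValueError("need at least 4 time points")
    return np.fft.rfft(series, axis=-1)


def normalize_components(X):
    """Normalize each non-DC component by the mean amplitude of the others.

    X'_k = X_k / mean{|X_j| : j >= 1, j != k}. Rows where any required
    denominator is zero (fewer than two non-zero components) are marked
    excluded rather than producing infinities.

    Returns (X_normalized for k >= 1, excluded boolean per row).
    """
    X = np.atleast_2d(np.asarray(X, dtype=complex))
    amps = np.abs(X[:, 1:])  # non-DC amplitudes
    q = amps.shape[1]
    if q < 2:
        raise ValueError("need at least two non-DC components to normalize")
    total = amps.sum(axis=1, keepdims=True)
    denom = (total - amps) / (q - 1)  # mean over j != k
    excluded = (denom == 0).any(axis=1)
    safe = np.where(denom == 0, 1.0, denom)
    return X[:, 1:] / safe, excluded


@dataclass
class FourierFeatures:
    """Stacked Re/Im of normalized components 1..m per gene.

    Columns are ordered Re(X'_1), Im(X'_1), ..., Re(X'_m), Im(X'_m).
    """

    gene_ids: list[str]
    m: int
    matrix: np.ndarray
    excluded: dict[str, str]

    def __post_init__(self):
        if not np.isfinite(self.matrix).all():
            raise ValueError("feature matrix must be finite")
        if self.matrix.shape != (len(self.gene_ids), 2 * self.m):
            raise ValueError("feature matrix shape mismatch")


def build_features(
    matrix: ExpressionMatrix,
    sample_indices=None,
    m: int = 6,
    min_total_signal: float = 1.0,
) -> FourierFeatures:
    """arcsinh -> DFT -> normalize -> stack Re/Im of components 1..m.

    Genes whose summed expression over the used samples falls below
    ``min_total_signal`` (or whose spectrum has fewer than two non-zero
    components) are excluded and reported, never silently dropped.
    """
    if sample_indices is not None:
        matrix = matrix.subset_samples(list(sample_indices))
    n_samples = len(matrix.samples)
    if m > n_samples // 2:
        raise ValueError(f"m={m} exceeds N/2={n_samples // 2} available components")
    values = matrix.values
    totals = values.sum(axis=1)
    excluded: dict[str, str] = {}
    low = totals < min_total_signal
    X = dft(arcsinh_transform(values))
    Xn, degenerate = normalize_components(X)
    keep = ~(low | degenerate)
    for gid, is_low, is_degen in zip(matrix.gene_ids, low, degenerate):
        if is_low:
            excluded[gid] = "low_signal"
        elif is_degen:
            excluded[gid] = "degenerate_spectrum"
    comps = Xn[keep][:, :m]
    feats = np.empty((comps.shape[0], 2 * m))
    feats[:, 0::2] = comps.real
    feats[:, 1::2] = comps.imag
    kept_ids = [g for g, k in zip(matrix.gene_ids, keep) if k]
    if excluded:
        logger.info("excluded %d genes from features: %s", len(excluded),
                    sorted(set(excluded.values())))
    return FourierFeatures(kept_ids, m, feats, excluded)


@dataclass
class MixtureModel:
    """Fitted Gaussian mixture with full covariances."""

    K: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    log_likelihood: float
    bic: float  # 2*logL - p*ln(n), maximized
    n_params: int
    n_restarts: int
    seed: int
    converged: bool
    _gm: GaussianMixture | None = None

    def predict(self, features: np.ndarray) -> np.ndarray:
        """1-based cluster labels."""
        return self._gm.predict(features) + 1


def _ridge(features: np.ndarray) -> float:
    cov = np.cov(features, rowvar=False)
    return 1e-6 * np.trace(np.atleast_2d(cov)) / features.shape[1]


def fit_mixture(
    features, K: int, n_restarts: int = 20, seed: int = 0, max_iter: int = 500
) -> MixtureModel:
    """EM for a full-covariance Gaussian mixture; best of ``n_restarts``.

    Covariances are ridge-regularized by 1e-6 * trace/dim of the data
    covariance. Deterministic given the seed.
    """
    X = features.matrix if isinstance(features, FourierFeatures) else np.asarray(features)
    n, d = X.shape
    if n <= K * (d + 1):
        raise ValueError(f"too few observations ({n}) for K={K} in {d} dimensions")
    gm = GaussianMixture(
        n_components=K,
        covariance_type="full",
        n_init=n_restarts,
        reg_covar=max(_ridge(X), 1e-12),
        random_state=seed,
        max_iter=max_iter,
        init_params="k-means++",
    )
    gm.fit(X)
    if not gm.converged_:
        logger.warning("EM did not converge for K=%d after %d iterations", K, max_iter)
    log_l = float(gm.score(X) * n)
    p = int(gm._n_parameters())
    bic = 2.0 * log_l - p * np.log(n)
    return MixtureModel(
        K=K,
        weights=gm.weights_,
        means=gm.means_,
        covariances=gm.covariances_,
        log_likelihood=log_l,
        bic=bic,
        n_params=p,
        n_restarts=n_restarts,
        seed=seed,
        converged=bool(gm.converged_),
        _gm=gm,
    )


@dataclass
class ClusteringResult:
    labels: dict[str, int]  # gene -> 1-based cluster
    chosen_k: int
    bic_by_k: pd.DataFrame  # columns K, bic, log_likelihood, converged
    model: MixtureModel
    relabel_map: dict[int, int] | None = None


def select_k(
    features: FourierFeatures,
    k_range=range(2, 11),
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
) -> ClusteringResult:
    """Fit each K and keep the maximal-BIC model; ties go to smaller K."""
    rows, models = [], {}
    for K in k_range:
        model = fit_mixture(features, K, n_restarts=n_restarts, seed=seed,
                            max_iter=max_iter)
        models[K] = model
        rows.append(
            {"K": K, "bic": model.bic, "log_likelihood": model.log_likelihood,
             "converged": model.converged}
        )
    table = pd.DataFrame(rows)
    best_k = int(table.loc[table["bic"].idxmax(), "K"])  # idxmax -> first max
    best = models[best_k]
    labels = dict(zip(features.gene_ids, (int(c) for c in best.predict(features.matrix))))
    return ClusteringResult(labels=labels, chosen_k=best_k, bic_by_k=table, model=best)


def sort_clusters_by_reference(
    labels: dict[str, int], reference: Classification
) -> dict[int, int]:
    """Map cluster ids to the rank order of a reference classification.

    Greedy assignment: repeatedly pick the (cluster, reference class)
    pair with the smallest hypergeometric enrichment p-value over the
    shared items; the cluster takes that class's rank. Clusters left
    unassigned are appended in decreasing size order.
    """
    shared = set(labels) & set(reference.labels)
    if not shared:
        raise ValueError("no shared items between clustering and reference")
    N = len(shared)
    clusters = sorted(set(labels.values()))
    classes = reference.classes
    class_rank = {c: i + 1 for i, c in enumerate(classes)}
    members = {c: {g for g in shared if labels[g] == c} for c in clusters}
    ref_members = {r: reference.items_in(r) & shared for r in classes}
    pairs = []
    for c in clusters:
        for r in classes:
            x = len(members[c] & ref_members[r])
            p = float(hypergeom.sf(x - 1, N, len(ref_members[r]), len(members[c])))
            pairs.append((p, c, r))
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))
    relabel: dict[int, int] = {}
    used_classes: set[str] = set()
    for p, c, r in pairs:
        if c in relabel or r in used_classes:
            continue
        relabel[c] = class_rank[r]
        used_classes.add(r)
    leftover = sorted((c for c in clusters if c not in relabel),
                      key=lambda c: (-len(members[c]), c))
    next_rank = len(classes) + 1
    for c in leftover:
        relabel[c] = next_rank
        next_rank += 1
    return relabel


def log2_rel_profile(
    matrix: ExpressionMatrix, pre_indices=(0, 1), delta: float = 0.5
) -> pd.DataFrame:
    """Per-gene log2 ratio of each sample to the mean pre-induction level.

    value_i = log2((x_i + delta) / (mean_pre + delta)); the pseudocount
    delta (TPM) guards zero expression.
    """
    values = matrix.values
    pre = values[:, list(pre_indices)].mean(axis=1, keepdims=True)
    out = np.log2((values + delta) / (pre + delta))
    return pd.DataFrame(out, index=matrix.gene_ids, columns=matrix.samples.sample_ids)
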