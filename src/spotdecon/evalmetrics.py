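"""Benchmark metrics for deconvolution output.

Against simulated ground truth: per-spot RMSE and Jensen–Shannon
divergence of the proportion rows. On real data without ground truth: the
correlation between per-state signature expression and predicted
proportions, summarized by Frobenius distances of permuted submatrices to
the signature–signature reference correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import SignatureSet, SpotDataset

__all__ = [
    "EvalReport",
    "deconvolution_error",
    "signature_correlation_matrix",
    "align_factors",
    "frobenius_signature_distance",
]


@dataclass
class EvalReport:
    rmse: np.ndarray               # per spot
    jsd: np.ndarray                # per spot, in nats (<= ln 2)
    mean_rmse: float
    mean_jsd: float
    corr_matrix: np.ndarray | None = None
    frobenius_distances: np.ndarray | None = None
    mean_frobenius: float | None = None


def _check_simplex(c: np.ndarray, name: str, tol: float = 1e-6) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    if c.ndim != 2:
        raise ValueError(f"{name} must be 2-D")
    if np.any(c < -tol) or np.max(np.abs(c.sum(axis=1) - 1.0)) > tol:
        raise ValueError(f"{name} rows must lie on the probability simplex")
    return np.clip(c, 0.0, None)


def deconvolution_error(c_gt: np.ndarray, c_pred: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Per-spot RMSE and Jensen–Shannon divergence, plus their means.

    RMSE_i = sqrt(Σ_k (gt_ik − pred_ik)² / K). JSD uses the bounded
    mixture-midpoint form, ½KL(p‖m) + ½KL(q‖m) with m = (p+q)/2, natural
    log, and the 0·log 0 := 0 convention, so identical rows give 0 and
    disjoint point masses give ln 2.
    """
    gt = _check_simplex(c_gt, "c_gt")
    pred = _check_simplex(c_pred, "c_pred")
    if gt.shape != pred.shape:
        raise ValueError("shape mismatch between truth and prediction")
    K = gt.shape[1]
    rmse = np.sqrt(((gt - pred) ** 2).sum(axis=1) / K)

    m = 0.5 * (gt + pred)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_pm = np.where(gt > 0, gt * (np.log(gt) - np.log(m)), 0.0).sum(axis=1)
        kl_qm = np.where(pred > 0, pred * (np.log(pred) - np.log(m)), 0.0).sum(axis=1)
    jsd = 0.5 * kl_pm + 0.5 * kl_qm
    return rmse, jsd, float(rmse.mean()), float(jsd.mean())


def signature_correlation_matrix(c_pred: np.ndarray, data: SpotDataset,
                                 sigs: SignatureSet) -> np.ndarray:
    """Correlation between signature expression and predicted proportions.

    Per state k the signature track is the mean raw count over its marker
    genes, c̄_ik = Σ_g x_ig s_kg / Σ_g s_kg, row-normalized across states to
    sum to 1 per spot; entry (k, l) is the Pearson correlation of signature
    track k with predicted column l. Constant columns give NaN entries.
    """
    c_pred = np.asarray(c_pred, dtype=float)
    sigs = sigs.restricted_to(set(data.gene_names))
    idx = {g: i for i, g in enumerate(data.gene_names)}
    tracks = []
    for state in sigs.state_names:
        cols = [idx[g] for g in sigs.markers[state]]
        tracks.append(data.counts[:, cols].mean(axis=1))
    sig = np.column_stack(tracks).astype(float)
    denom = sig.sum(axis=1, keepdims=True)
    denom[denom == 0] = 1.0
    sig = sig / denom

    K, L = sig.shape[1], c_pred.shape[1]
    A = np.full((K, L), np.nan)
    for k in range(K):
        sk = sig[:, k] - sig[:, k].mean()
        nk = np.sqrt((sk ** 2).sum())
        if nk == 0:
            continue
        for l in range(L):
            pl = c_pred[:, l] - c_pred[:, l].mean()
            nl = np.sqrt((pl ** 2).sum())
            if nl == 0:
                continue
            A[k, l] = float(sk @ pl / (nk * nl))
    return A


def align_factors(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Greedy one-to-one alignment of factors (columns) to states (rows).

    Repeatedly assigns the globally best remaining (state, factor) pair,
    then orders the assigned pairs by descending diagonal correlation.
    Returns ``(aligned_matrix, column_permutation)`` restricted to the
    assigned square block. Used for reference-free outputs whose factor
    count may exceed the state count.
    """
    A = np.asarray(A, dtype=float)
    K, L = A.shape
    n = min(K, L)
    work = np.where(np.isnan(A), -np.inf, A.copy())
    pairs = []
    rows_left, cols_left = set(range(K)), set(range(L))
    for _ in range(n):
        best = max(((work[r, c], r, c) for r in rows_left for c in cols_left))
        _, r, c = best
        pairs.append((r, c))
        rows_left.discard(r)
        cols_left.discard(c)
    pairs.sort(key=lambda rc: -A[rc[0], rc[1]])
    rows = np.array([r for r, _ in pairs])
    cols = np.array([c for _, c in pairs])
    return A[np.ix_(rows, cols)], cols


def frobenius_signature_distance(A_corr: np.ndarray, A_sig: np.ndarray,
                                 n_sub: int = 1000, sub_side: int = 10,
                                 seed: int = 0
                                 ) -> tuple[np.ndarray, float]:
    """Frobenius distances of random permuted submatrices to the reference.

    Each draw selects `sub_side` distinct cell states in a random order
    (without replacement within the draw) and applies the same index set to
    both axes of the deconvolution-to-signature correlation and of the
    signature–signature reference; the draw's distance is the Frobenius
    norm of the submatrix difference. Returns all distances and their mean.
    `sub_side` larger than the state count is clamped with a warning.
    """
    A_corr = np.asarray(A_corr, dtype=float)
    A_sig = np.asarray(A_sig, dtype=float)
    if A_corr.shape != A_sig.shape or A_corr.shape[0] != A_corr.shape[1]:
        raise ValueError("matrices must be square and aligned")
    K = A_corr.shape[0]
    if sub_side > K:
        warnings.warn(f"sub_side={sub_side} clamped to the {K} states")
        sub_side = K
    rng = np.random.default_rng(seed)
    d = np.empty(n_sub)
    for i in range(n_sub):
        idx = rng.permutation(K)[:sub_side]
        diff = A_corr[np.ix_(idx, idx)] - A_sig[np.ix_(idx, idx)]
        d[i] = np.sqrt(np.nansum(diff ** 2))
    return d, float(d.mean())
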