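"""Empirical priors for the deconvolution model.

Three quantities are computed from the data before inference:

* an enrichment matrix ``A`` (spots x states) — per-spot signature scores
  (marker mean expression minus a bin-matched random control set), passed
  through ReLU + epsilon and row-normalized into a Dirichlet base measure;
* anchor rankings ``R`` — per state, spots ordered by descending enrichment;
  the top ``n_anchor`` are the anchor spots, assumed near-pure in that state;
* a spatially smoothed library-size prior ``l̃`` — the mean total count over
  each spot's neighborhood (array-coordinate distance < w, self included).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core_io import SignatureSet, SpotDataset

__all__ = [
    "PriorBundle",
    "gene_set_score",
    "score_matrix",
    "build_proportion_prior",
    "rank_anchors",
    "library_size_prior",
    "build_priors",
]


@dataclass
class PriorBundle:
    """Empirical Dirichlet prior, anchor rankings and library prior."""

    A: np.ndarray                 # (S, K) strictly positive rows summing to 1
    raw_scores: np.ndarray        # (S, K) scores before ReLU/normalization
    R: np.ndarray                 # (S, K) spot indices ranked by descending A[:, k]
    n_anchor: int
    lib_prior: np.ndarray         # (S,) strictly positive
    state_names: list[str]
    alpha: float = 50.0
    epsilon: float = 1e-5
    window: int = 3

    def __post_init__(self):
        if np.any(self.A <= 0):
            raise ValueError("A must be strictly positive")
        if np.max(np.abs(self.A.sum(axis=1) - 1.0)) > 1e-8:
            raise ValueError("A rows must sum to 1")
        if np.any(self.lib_prior <= 0):
            raise ValueError("library prior must be strictly positive")

    @property
    def anchors(self) -> np.ndarray:
        """(n_anchor, K) top-ranked spot indices per state."""
        return self.R[: self.n_anchor]

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.A, columns=self.state_names).to_csv(
            outdir / "prior_A.csv", index=False)
        pd.DataFrame({"lib_prior": self.lib_prior}).to_csv(
            outdir / "prior_library.csv", index=False)
        (outdir / "prior_config.json").write_text(json.dumps({
            "alpha": self.alpha, "epsilon": self.epsilon,
            "window": self.window, "n_anchor": self.n_anchor,
            "states": self.state_names}, indent=2))


def _normalized_log_expression(data: SpotDataset) -> np.ndarray:
    """log1p counts after scaling each spot to the median library size."""
    lib = data.library_sizes().astype(float)
    lib = np.where(lib > 0, lib, 1.0)
    target = np.median(lib)
    return np.log1p(data.counts * (target / lib)[:, None])


def gene_set_score(data: SpotDataset, markers, seed: int, *,
                   n_bins: int = 25, n_ctrl: int = 50,
                   expr: np.ndarray | None = None) -> np.ndarray:
    """Per-spot enrichment score of a marker gene set.

    The score is the markers' mean expression minus the mean expression of a
    control gene set drawn at random from expression bins matched to the
    markers (so highly expressed markers are compared against comparably
    expressed controls). Expression is log1p of library-size-normalized
    counts; the draw is deterministic given `seed`.
    """
    name_to_idx = {g: i for i, g in enumerate(data.gene_names)}
    marker_idx = np.array([name_to_idx[g] for g in markers if g in name_to_idx],
                          dtype=int)
    if marker_idx.size == 0:
        raise ValueError("no marker gene present in the data")
    if expr is None:
        expr = _normalized_log_expression(data)
    G = expr.shape[1]
    gene_mean = expr.mean(axis=0)
    # equal-size expression bins by rank (stable, ties by gene order)
    order = np.argsort(gene_mean, kind="stable")
    bin_of = np.empty(G, dtype=int)
    bin_of[order] = np.minimum((np.arange(G) * n_bins) // G, n_bins - 1)

    rng = np.random.default_rng(seed)
    marker_set = set(marker_idx.tolist())
    ctrl: list[int] = []
    for b in sorted(set(bin_of[marker_idx].tolist())):
        pool = np.flatnonzero((bin_of == b) & ~np.isin(np.arange(G), marker_idx))
        if pool.size == 0:
            continue
        take = min(n_ctrl, pool.size)
        ctrl.extend(rng.choice(pool, size=take, replace=False).tolist())
    if not ctrl:  # markers fill every bin they occupy; compare against all others
        pool = np.flatnonzero(~np.isin(np.arange(G), marker_idx))
        if pool.size == 0:
            raise ValueError("no control genes available")
        ctrl = pool.tolist()
    ctrl_idx = np.array(sorted(set(ctrl)), dtype=int)
    return expr[:, marker_idx].mean(axis=1) - expr[:, ctrl_idx].mean(axis=1)


def score_matrix(data: SpotDataset, sigs: SignatureSet, seed: int, *,
                 n_bins: int = 25, n_ctrl: int = 50) -> np.ndarray:
    """Raw enrichment scores for every state, (S, K)."""
    expr = _normalized_log_expression(data)
    cols = []
    for j, state in enumerate(sigs.state_names):
        cols.append(gene_set_score(
            data, sigs.markers[state], seed + j,
            n_bins=n_bins, n_ctrl=n_ctrl, expr=expr))
    return np.column_stack(cols)


def build_proportion_prior(raw: np.ndarray, epsilon: float = 1e-5) -> np.ndarray:
    """ReLU(raw) + epsilon, then row-normalize to the probability simplex."""
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("non-finite scores")
    A = np.maximum(raw, 0.0) + epsilon
    return A / A.sum(axis=1, keepdims=True)


def rank_anchors(A: np.ndarray, n_anchor: int = 60) -> np.ndarray:
    """Per state, spot indices sorted by descending A[:, k], ties by index.

    Returns the full (S, K) ranking; callers slice the top `n_anchor` rows
    for the anchor sets.
    """
    S = A.shape[0]
    if n_anchor > S:
        raise ValueError("n_anchor exceeds the number of spots")
    return np.argsort(-A, axis=0, kind="stable")


def library_size_prior(data: SpotDataset, w: int = 3) -> np.ndarray:
    """Locally averaged library size.

    l̃_i = mean total count over spots j with Euclidean array-coordinate
    distance |r_j - r_i| < w, the spot itself included. With no neighbor
    inside the window the spot keeps its own total count.
    """
    totals = data.library_sizes().astype(float)
    coords = data.array_coords.astype(float)
    D = cdist(coords, coords)
    mask = D < w
    out = (mask * totals[None, :]).sum(axis=1) / mask.sum(axis=1)
    return np.where(out > 0, out, 1.0)


def build_priors(data: SpotDataset, sigs: SignatureSet, seed: int = 0, *,
                 alpha: float = 50.0, epsilon: float = 1e-5, window: int = 3,
                 n_anchor: int = 60, n_bins: int = 25,
                 n_ctrl: int = 50) -> PriorBundle:
    """Assemble the full prior bundle from data + signatures."""
    sigs = sigs.restricted_to(set(data.gene_names))
    raw = score_matrix(data, sigs, seed, n_bins=n_bins, n_ctrl=n_ctrl)
    A = build_proportion_prior(raw, epsilon)
    n_anchor = min(n_anchor, data.n_spots)
    R = rank_anchors(A, n_anchor)
    lib = library_size_prior(data, window)
    return PriorBundle(A=A, raw_scores=raw, R=R, n_anchor=n_anchor,
                       lib_prior=lib, state_names=list(sigs.state_names),
                       alpha=alpha, epsilon=epsilon, window=window)
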