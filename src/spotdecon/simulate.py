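"""Spatially structured synthetic spot data with known ground truth.

A synthetic single-cell reference (disjoint marker blocks up-regulated per
cell type, negative-binomial cells) is mixed onto a square capture grid:
per-type spatial proportion fields come from 2-D Gaussian-process draws
passed through a softmax; expected library sizes are gamma-distributed;
each spot draws a handful of cells, assigned to types multinomially and
matched to reference cells by library size. A parametric renderer turns
the per-spot cell density into a pseudo-histology image (Gaussian point
spread + speckle noise) so histology integration is testable offline.

Everything is deterministic given the seeds it is handed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .core_io import HistologyImage, SignatureSet, SpotDataset

__all__ = [
    "SyntheticReference",
    "SimulatedDataset",
    "make_synthetic_reference",
    "simulate_proportion_fields",
    "sample_library_sizes",
    "simulate_spots",
    "render_pseudo_histology",
    "retrieve_de_signatures",
    "simulate_dataset",
]

MARKER_BLOCK_SIZE = 10  #: genes per type-specific marker block


@dataclass
class SyntheticReference:
    """Synthetic single-cell reference with disjoint marker blocks."""

    type_names: list[str]
    type_means: np.ndarray          # (n_types, G) expected counts per cell
    cell_counts: np.ndarray         # (n_cells, G) NB-sampled profiles
    cell_types: np.ndarray          # (n_cells,) type index
    gene_names: list[str]
    marker_blocks: dict[str, list[str]]

    @property
    def n_types(self) -> int:
        return len(self.type_names)

    def cell_libraries(self) -> np.ndarray:
        return self.cell_counts.sum(axis=1)

    def signatures(self) -> SignatureSet:
        return SignatureSet(list(self.type_names),
                            {t: list(g) for t, g in self.marker_blocks.items()})


@dataclass
class SimulatedDataset:
    """Grid spot data plus the ground truth that generated it."""

    data: SpotDataset
    truth_proportions: np.ndarray   # (S, K) realized type fractions
    truth_library: np.ndarray       # (S,) expected library sizes
    truth_density: np.ndarray       # (S,) cells per spot
    reference: SyntheticReference
    cell_assignments: list[np.ndarray] = field(default_factory=list)
    image: HistologyImage | None = None

    def signatures(self) -> SignatureSet:
        return self.reference.signatures()


def make_synthetic_reference(n_types: int, n_genes: int,
                             n_cells_per_type: int, fold: float,
                             seed: int, *, base_mean: float = 1.0,
                             nb_theta: float = 10.0) -> SyntheticReference:
    """Build a reference with one disjoint 10-gene marker block per type.

    Baseline per-gene means are lognormal around `base_mean`; within a
    type's block the mean is multiplied by `fold`. Cells are NB draws
    around the type mean scaled by a lognormal per-cell size factor.
    """
    if n_genes < 2 * MARKER_BLOCK_SIZE * n_types:
        raise ValueError(
            f"need n_genes >= {2 * MARKER_BLOCK_SIZE * n_types} "
            f"for {n_types} disjoint marker blocks plus background")
    if n_types < 1 or n_cells_per_type < 1 or fold <= 0:
        raise ValueError("invalid sizes")
    rng = np.random.default_rng(seed)
    gene_names = [f"GENE{j:05d}" for j in range(n_genes)]
    baseline = base_mean * rng.lognormal(0.0, 0.5, size=n_genes)
    type_names = [f"type{t}" for t in range(n_types)]
    means = np.tile(baseline, (n_types, 1))
    blocks: dict[str, list[str]] = {}
    for t in range(n_types):
        lo = t * MARKER_BLOCK_SIZE
        block = slice(lo, lo + MARKER_BLOCK_SIZE)
        means[t, block] *= fold
        blocks[type_names[t]] = gene_names[block]

    labels = np.repeat(np.arange(n_types), n_cells_per_type)
    size_factor = rng.lognormal(0.0, 0.3, size=labels.size)
    mu = means[labels] * size_factor[:, None]
    # NB(mean mu, inverse-dispersion theta) via gamma-Poisson mixture
    lam = rng.gamma(nb_theta, mu / nb_theta)
    counts = rng.poisson(lam).astype(np.int64)
    return SyntheticReference(type_names, means, counts, labels,
                              gene_names, blocks)


def retrieve_de_signatures(ref: SyntheticReference, n_top: int = 30
                           ) -> SignatureSet:
    """Benchmark-style signature retrieval from a single-cell reference.

    Mirrors how signatures are obtained in practice: per type, genes are
    ranked by log fold change (mean log1p CP10K expression in-type minus
    out-of-type) and the top `n_top` become that type's markers. Run on a
    reference draw independent of the one that generated the spots, this
    yields realistically noisy gene sets rather than the exact planted
    marker blocks.
    """
    lib = np.maximum(ref.cell_counts.sum(axis=1, keepdims=True), 1)
    lognorm = np.log1p(ref.cell_counts / lib * 1e4)
    markers = {}
    for t, name in enumerate(ref.type_names):
        in_t = ref.cell_types == t
        lfc = lognorm[in_t].mean(axis=0) - lognorm[~in_t].mean(axis=0)
        top = np.argsort(-lfc, kind="stable")[:n_top]
        markers[name] = [ref.gene_names[j] for j in top]
    return SignatureSet(list(ref.type_names), markers)


def _se_cholesky(n: int, lengthscale: float, jitter: float = 1e-6) -> np.ndarray:
    x = np.arange(n, dtype=float)
    K = np.exp(-0.5 * (x[:, None] - x[None, :]) ** 2 / lengthscale ** 2)
    return np.linalg.cholesky(K + jitter * np.eye(n))


def simulate_proportion_fields(grid_side: int, n_types: int,
                               lengthscale: float | None = None,
                               seed: int = 0, *,
                               gain: float = 3.0) -> np.ndarray:
    """Softmaxed squared-exponential GP fields, one per type.

    The grid kernel factorizes over rows and columns, so each field is an
    exact draw sampled as L_r Z L_c^T with 1-D Cholesky factors. `gain`
    scales the fields before the softmax and sets how sharply types
    segregate into regions (3 gives near-pure patches with mixed borders,
    qualitatively like tumor sections). Returns (grid_side^2, n_types) rows
    summing to 1, spots in row-major order.
    """
    if grid_side < 2:
        raise ValueError("grid_side must be >= 2")
    if lengthscale is None:
        lengthscale = grid_side / 5.0
    if lengthscale <= 0:
        raise ValueError("lengthscale must be positive")
    rng = np.random.default_rng(seed)
    L = _se_cholesky(grid_side, lengthscale)
    fields = np.stack([
        (L @ rng.standard_normal((grid_side, grid_side)) @ L.T).ravel()
        for _ in range(n_types)
    ], axis=1)
    logits = gain * fields
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def sample_library_sizes(S: int, shape: float = 7.0, scale: float = 1000.0,
                         seed: int = 0) -> np.ndarray:
    """I.i.d. gamma expected library sizes (Visium-like defaults)."""
    if shape <= 0 or scale <= 0:
        raise ValueError("gamma parameters must be positive")
    return np.random.default_rng(seed).gamma(shape, scale, size=S)


def simulate_spots(ref: SyntheticReference, fields: np.ndarray,
                   libs: np.ndarray, cells_per_spot: tuple[int, int] = (5, 12),
                   seed: int = 0, *, grid_side: int | None = None,
                   pixels_per_spot: int = 10) -> SimulatedDataset:
    """Mix reference cells onto the grid according to the truth fields.

    Per spot: the cell count n_i is uniform over `cells_per_spot`
    (inclusive); types are multinomial from the spot's proportion row; for
    each drawn cell of type t the reference cell of type t whose library
    size is closest to libs_i / n_i is used (ties to the lower cell index).
    Spot counts are the exact sum of the chosen cells' counts and the
    recorded truth is the realized type fraction.
    """
    S, K = fields.shape
    if K != ref.n_types:
        raise ValueError("field/type mismatch")
    if len(libs) != S:
        raise ValueError("library vector length mismatch")
    for t in range(K):
        if not np.any(ref.cell_types == t):
            raise ValueError(f"reference type {t} has no cells")
    if grid_side is None:
        grid_side = int(round(np.sqrt(S)))
        if grid_side * grid_side != S:
            raise ValueError("non-square spot count needs explicit grid_side")
    rng = np.random.default_rng(seed)
    cell_libs = ref.cell_libraries()
    by_type = [np.flatnonzero(ref.cell_types == t) for t in range(K)]

    counts = np.zeros((S, ref.cell_counts.shape[1]), dtype=np.int64)
    truth = np.zeros((S, K))
    density = np.zeros(S, dtype=int)
    assignments: list[np.ndarray] = []
    lo, hi = cells_per_spot
    for i in range(S):
        n_i = int(rng.integers(lo, hi + 1))
        type_draw = rng.multinomial(n_i, fields[i])
        target = libs[i] / n_i
        chosen = []
        for t in range(K):
            if type_draw[t] == 0:
                continue
            cand = by_type[t]
            best = cand[int(np.argmin(np.abs(cell_libs[cand] - target)))]
            chosen.extend([best] * type_draw[t])
        chosen = np.array(chosen, dtype=int)
        counts[i] = ref.cell_counts[chosen].sum(axis=0)
        truth[i] = type_draw / n_i
        density[i] = n_i
        assignments.append(chosen)

    rows, cols = np.divmod(np.arange(S), grid_side)
    pix = (np.column_stack([rows, cols]) * pixels_per_spot
           + pixels_per_spot // 2).astype(float)
    data = SpotDataset(
        counts=counts,
        gene_names=list(ref.gene_names),
        spot_ids=[f"spot_{r}_{c}" for r, c in zip(rows, cols)],
        array_coords=np.column_stack([rows, cols]),
        pixel_coords=pix,
    )
    return SimulatedDataset(data=data, truth_proportions=truth,
                            truth_library=np.asarray(libs, dtype=float),
                            truth_density=density, reference=ref,
                            cell_assignments=assignments)


def render_pseudo_histology(sim: SimulatedDataset, psf_sigma: float = 2.0,
                            noise_sd: float = 0.05, seed: int = 0,
                            *, pixels_per_spot: int = 10) -> HistologyImage:
    """Parametric grayscale pseudo-histology from the cell-density truth.

    Normalized density is splatted at each spot's pixel position, blurred
    with a Gaussian point-spread function and corrupted with clipped
    Gaussian speckle; output values lie in [0, 1].
    """
    if sim.truth_density is None:
        raise ValueError("simulation lacks density truth")
    coords = sim.data.pixel_coords.astype(int)
    H = coords[:, 0].max() + pixels_per_spot // 2 + 1
    W = coords[:, 1].max() + pixels_per_spot // 2 + 1
    img = np.zeros((H, W))
    dens = sim.truth_density.astype(float)
    peak = dens.max()
    if peak > 0:
        img[coords[:, 0], coords[:, 1]] = dens / peak
    if psf_sigma > 0:
        img = gaussian_filter(img, psf_sigma)
        if img.max() > 0:
            img = img / img.max()
    if noise_sd > 0:
        img = img + np.random.default_rng(seed).normal(0, noise_sd, img.shape)
    out = HistologyImage(np.clip(img, 0.0, 1.0)[:, :, None])
    sim.image = out
    return out


def simulate_dataset(mode: str = "major", grid_side: int = 50, seed: int = 0,
                     *, n_genes: int | None = None,
                     n_cells_per_type: int = 200, fold: float = 5.0,
                     lengthscale: float | None = None,
                     lib_shape: float = 7.0, lib_scale: float = 1000.0,
                     cells_per_spot: tuple[int, int] = (5, 12),
                     with_image: bool = False) -> SimulatedDataset:
    """One-call simulation presets.

    ``mode='major'`` plants 5 cell types (the coarse-granularity setting),
    ``mode='fine'`` plants 10; each type carries a disjoint 10-gene marker
    block. Sub-seeds for the reference, fields, libraries, mixing and
    renderer are derived from `seed`.
    """
    n_types = {"major": 5, "fine": 10}.get(mode)
    if n_types is None:
        raise ValueError("mode must be 'major' or 'fine'")
    if n_genes is None:
        n_genes = 60 * n_types
    ss = np.random.SeedSequence(seed).generate_state(5) % (2 ** 31)
    ref = make_synthetic_reference(n_types, n_genes, n_cells_per_type,
                                   fold, int(ss[0]))
    fields = simulate_proportion_fields(grid_side, n_types, lengthscale,
                                        int(ss[1]))
    libs = sample_library_sizes(grid_side * grid_side, lib_shape, lib_scale,
                                int(ss[2]))
    sim = simulate_spots(ref, fields, libs, cells_per_spot, int(ss[3]),
                         grid_side=grid_side)
    if with_image:
        render_pseudo_histology(sim, seed=int(ss[4]))
    return sim
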