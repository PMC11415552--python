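"""Downstream spatial analyses on deconvolution output.

Multi-sample integration (joint markers, per-sample priors), spatial hubs
(clusters of spots with similar inferred cell-state composition), hub
region classification (intratumoral / peritumoral / stromal), sample-mixing
entropy in latent space, a spatial cross-correlation index for cell-state
colocalization, and distance-binned expression profiles around a set of
source spots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from sklearn.neighbors import NearestNeighbors

from .core_io import SignatureSet, SpotDataset
from .priors import PriorBundle, build_priors

__all__ = [
    "HubAssignment",
    "integrate_samples",
    "identify_hubs",
    "classify_hub_regions",
    "mixing_entropy",
    "spatial_cross_correlation",
    "diffused_expression_profile",
]


@dataclass
class HubAssignment:
    """Per-spot hub labels (0 = largest hub) and the clustering parameters."""

    hub_label: np.ndarray
    k_neighbors: int
    resolution: float
    seed: int
    region: dict[int, str] | None = None

    @property
    def n_hubs(self) -> int:
        return int(self.hub_label.max()) + 1


# ---------------------------------------------------------------------------
# multi-sample integration


def integrate_samples(datasets: list[SpotDataset], sigs: SignatureSet, *,
                      seed: int = 0, refine: bool = True,
                      **prior_kwargs
                      ) -> tuple[SpotDataset, list[PriorBundle], SignatureSet]:
    """Joint markers across samples, per-sample priors, merged dataset.

    Each sample is restricted to the shared gene namespace; markers are
    refined per sample (archetype alignment, when `refine`) and unioned per
    state across samples; the proportion prior is then recomputed on every
    sample with the joint markers, while library priors never mix spots
    across samples. The merged dataset carries sample labels for joint
    training.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two samples")
    common = set(datasets[0].gene_names)
    for d in datasets[1:]:
        common &= set(d.gene_names)
    if not common:
        raise ValueError("samples share no genes")
    aligned = []
    for d in datasets:
        keep = [i for i, g in enumerate(d.gene_names) if g in common]
        aligned.append(d.subset_genes(np.array(keep)))

    per_sample_sigs = []
    for s, d in enumerate(aligned):
        local = sigs.restricted_to(set(d.gene_names))
        if refine:
            from .archetypes import fit_archetypes, refine_signatures
            model = fit_archetypes(d)
            local, _, _ = refine_signatures(local, model, None, d,
                                            seed=seed + s)
        per_sample_sigs.append(local)

    joint_markers: dict[str, list[str]] = {}
    names: list[str] = []
    for ss in per_sample_sigs:
        for state in ss.state_names:
            if state not in joint_markers:
                joint_markers[state] = []
                names.append(state)
            for g in ss.markers[state]:
                if g not in joint_markers[state]:
                    joint_markers[state].append(g)
    joint = SignatureSet(names, joint_markers)

    bundles = [build_priors(d, joint, seed, **prior_kwargs) for d in aligned]

    gene_order = aligned[0].gene_names
    col = [{g: i for i, g in enumerate(d.gene_names)} for d in aligned]
    counts = np.vstack([
        d.counts[:, [col[s][g] for g in gene_order]]
        for s, d in enumerate(aligned)
    ])
    labels = [f"sample{s}" for s, d in enumerate(aligned) for _ in d.spot_ids]
    merged = SpotDataset(
        counts=counts,
        gene_names=list(gene_order),
        spot_ids=[f"sample{s}:{sid}" for s, d in enumerate(aligned)
                  for sid in d.spot_ids],
        array_coords=np.vstack([d.array_coords for d in aligned]),
        sample_labels=labels,
    )
    return merged, bundles, joint


# ---------------------------------------------------------------------------
# hubs


def identify_hubs(c: np.ndarray, k_neighbors: int = 30,
                  resolution: float = 1.0, seed: int = 0) -> HubAssignment:
    """Cluster spots by inferred composition into spatial hubs.

    A k-nearest-neighbor graph on the proportion vectors (Euclidean) is
    reweighted by the Jaccard overlap of neighbor sets and partitioned by
    Leiden modularity optimization at the given resolution; labels are
    relabeled by descending hub size.
    """
    c = np.asarray(c, dtype=float)
    if k_neighbors >= c.shape[0]:
        raise ValueError("k_neighbors must be below the number of spots")
    # exact duplicate rows are collapsed before the graph build: they carry
    # no composition information of their own and would otherwise make the
    # neighbor sets (and hence the partition) arbitrary
    uniq, inverse = np.unique(c, axis=0, return_inverse=True)
    if uniq.shape[0] == 1:
        return HubAssignment(hub_label=np.zeros(c.shape[0], dtype=int),
                             k_neighbors=k_neighbors, resolution=resolution,
                             seed=seed)
    c = uniq
    S = c.shape[0]
    k_neighbors = min(k_neighbors, S - 1)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(c)
    _, ind = nn.kneighbors(c)
    neigh = [set(row[1:].tolist()) for row in ind]  # exclude self

    edges, weights = [], []
    seen = set()
    for i in range(S):
        for j in neigh[i]:
            key = (i, j) if i < j else (j, i)
            if key in seen:
                continue
            seen.add(key)
            inter = len(neigh[i] & neigh[j])
            union = len(neigh[i] | neigh[j])
            w = inter / union if union else 0.0
            if w > 0:
                edges.append(key)
                weights.append(w)
    g = ig.Graph(n=S, edges=edges)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights=weights, resolution_parameter=resolution, seed=seed)
    raw = np.array(part.membership)
    spot_labels = raw[inverse]
    sizes = np.bincount(spot_labels, minlength=raw.max() + 1)
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty_like(order)
    relabel[order] = np.arange(len(order))
    return HubAssignment(hub_label=relabel[spot_labels],
                         k_neighbors=k_neighbors,
                         resolution=resolution, seed=seed)


def classify_hub_regions(hubs: HubAssignment, c: np.ndarray,
                         tumor_states: list[int], coords: np.ndarray,
                         threshold: float = 0.2,
                         boundary_rank: int = 1) -> dict[int, str]:
    """Intratumoral / peritumoral / stromal classification of hubs.

    A hub is intratumoral iff the hub mean of the summed tumor-state
    proportions exceeds `threshold` (strict). Remaining hubs are ranked by
    the mean distance of their spots to the nearest intratumoral spot;
    ranks up to `boundary_rank` are peritumoral, the rest stromal.
    """
    if not tumor_states:
        raise ValueError("tumor_states must be nonempty")
    c = np.asarray(c, dtype=float)
    coords = np.asarray(coords, dtype=float)
    labels = hubs.hub_label
    tumor_frac = c[:, tumor_states].sum(axis=1)
    region: dict[int, str] = {}
    intratumoral = []
    for h in range(hubs.n_hubs):
        if tumor_frac[labels == h].mean() > threshold:
            region[h] = "intratumoral"
            intratumoral.append(h)
    others = [h for h in range(hubs.n_hubs) if h not in region]
    if not intratumoral:
        warnings.warn("no intratumoral hub found; remaining hubs labeled stromal")
        for h in others:
            region[h] = "stromal"
        return region
    tumor_mask = np.isin(labels, intratumoral)
    D = cdist(coords, coords[tumor_mask]).min(axis=1)
    ranked = sorted(others, key=lambda h: D[labels == h].mean())
    for r, h in enumerate(ranked, start=1):
        region[h] = "peritumoral" if r <= boundary_rank else "stromal"
    hubs.region = region
    return region


# ---------------------------------------------------------------------------
# entropy, spatial correlation, diffusion profiles


def mixing_entropy(z: np.ndarray, sample_labels, k_neighbors: int = 30
                   ) -> np.ndarray:
    """Shannon entropy of the sample composition of each spot's latent
    neighborhood (natural log, 0·log 0 := 0). 0 means one sample only;
    ln(M) means neighbors spread uniformly over M samples."""
    z = np.asarray(z, dtype=float)
    labels = np.asarray(sample_labels)
    S = z.shape[0]
    if k_neighbors >= S:
        raise ValueError("k_neighbors must be below the number of spots")
    uniq, enc = np.unique(labels, return_inverse=True)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(z)
    _, ind = nn.kneighbors(z)
    H = np.zeros(S)
    for i in range(S):
        frac = np.bincount(enc[ind[i, 1:]], minlength=len(uniq)) / k_neighbors
        nzf = frac[frac > 0]
        H[i] = float(-(nzf * np.log(nzf)).sum())
    return H


def spatial_cross_correlation(x: np.ndarray, y: np.ndarray,
                              coords: np.ndarray,
                              dist_threshold: float = np.sqrt(3)) -> float:
    """Spatial cross-correlation index between two per-spot quantities.

    SCI = (N / 2 Σ τ) · Σ_ij τ_ij (x_i − x̄)(y_j − ȳ) / (s_x s_y) with
    binary neighbor weights τ_ij = 1 when the coordinate distance of two
    distinct spots is below `dist_threshold` (√3 selects immediate
    neighbors on both hexagonal arrays and square grids), and
    s = √Σ(v − v̄)². Symmetric in x, y and invariant to positive affine
    rescaling of either argument.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    coords = np.asarray(coords, dtype=float)
    N = len(x)
    xc, yc = x - x.mean(), y - y.mean()
    sx, sy = np.sqrt((xc ** 2).sum()), np.sqrt((yc ** 2).sum())
    if sx == 0 or sy == 0:
        raise ValueError("zero variance input")
    tau = (cdist(coords, coords) < dist_threshold).astype(float)
    np.fill_diagonal(tau, 0.0)
    tau_sum = tau.sum()
    if tau_sum == 0:
        raise ValueError("empty weight matrix: no spot pair within threshold")
    num = float(xc @ tau @ yc)
    return N / (2.0 * tau_sum) * num / (sx * sy)


def diffused_expression_profile(expr: np.ndarray, coords: np.ndarray,
                                source_spots, window: int = 7,
                                smooth_sigma: float = 1.5,
                                sample_labels=None):
    """Expression as a function of distance to the nearest source spot.

    Per sample, each spot's distance to its nearest source is computed with
    a KD-tree, expression is averaged within integer distance bins and
    smoothed with a centered moving average of size `window`; the mean and
    s.d. across samples are then Gaussian-smoothed with `smooth_sigma`.
    Returns ``(bins, mean, sd)``. Use ``window=1, smooth_sigma=0`` for the
    raw binned profile.
    """
    expr = np.asarray(expr, dtype=float)
    coords = np.asarray(coords, dtype=float)
    source_spots = np.asarray(list(source_spots), dtype=int)
    if source_spots.size == 0:
        raise ValueError("source_spots must be nonempty")
    if sample_labels is None:
        sample_labels = np.zeros(len(expr), dtype=int)
    labels = np.asarray(sample_labels)
    source_mask = np.zeros(len(expr), dtype=bool)
    source_mask[source_spots] = True

    dist = np.empty(len(expr))
    for s in np.unique(labels):
        m = labels == s
        src = source_mask & m
        if not src.any():
            raise ValueError(f"sample {s} has no source spot")
        tree = cKDTree(coords[src])
        dist[m], _ = tree.query(coords[m])
    bins_all = np.round(dist).astype(int)
    n_bins = bins_all.max() + 1
    bins = np.arange(n_bins)

    profiles = []
    for s in np.unique(labels):
        m = labels == s
        prof = np.full(n_bins, np.nan)
        for b in range(n_bins):
            sel = m & (bins_all == b)
            if sel.any():
                prof[b] = expr[sel].mean()
        # fill gaps by nearest available bin before smoothing
        valid = ~np.isnan(prof)
        prof = np.interp(bins, bins[valid], prof[valid])
        if window > 1:
            prof = uniform_filter1d(prof, size=window, mode="nearest")
        profiles.append(prof)
    P = np.vstack(profiles)
    mean, sd = P.mean(axis=0), P.std(axis=0)
    if smooth_sigma > 0:
        mean = gaussian_filter1d(mean, smooth_sigma, mode="nearest")
        sd = gaussian_filter1d(sd, smooth_sigma, mode="nearest")
    return bins, mean, sd
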