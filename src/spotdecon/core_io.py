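"""Data containers and I/O for spot-level spatial transcriptomics.

Reads 10x-style Matrix Market triplets or dense CSV count matrices together
with a spot-coordinate table, marker-gene signature sets (JSON or CSV) and
optional full-resolution histology images; preprocesses counts (mito/ribo
filtering, highly-variable-gene selection unioned with signature markers);
extracts per-spot image patches; writes deconvolution results.

Counts stay raw integers throughout — the count model consumes untransformed
transcripts, so no normalization is ever applied to the stored matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.io import mmread

__all__ = [
    "SpotDataset",
    "SignatureSet",
    "HistologyImage",
    "PatchSet",
    "load_spot_dataset",
    "load_signatures",
    "load_histology_image",
    "preprocess",
    "extract_patches",
    "write_deconvolution",
]

#: case-insensitive gene-symbol prefixes treated as mitochondrial/ribosomal
MITO_RIBO_PREFIXES = ("MT-", "MRPL", "MRPS", "RPS", "RPL")


@dataclass
class SpotDataset:
    """Raw spot x gene counts with spatial coordinates.

    counts is an (S, G) nonnegative integer array; ``array_coords`` are
    integer (row, col) positions on the capture grid; ``pixel_coords`` are
    optional real (row, col) positions in full-resolution image space.
    """

    counts: np.ndarray
    gene_names: list[str]
    spot_ids: list[str]
    array_coords: np.ndarray
    pixel_coords: np.ndarray | None = None
    sample_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = np.round(self.counts).astype(np.int64)
        if len(self.gene_names) != self.counts.shape[1]:
            raise ValueError("gene_names length mismatch")
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError("duplicate gene names; collapse before constructing")
        if len(self.spot_ids) != self.counts.shape[0]:
            raise ValueError("spot_ids length mismatch")
        self.array_coords = np.asarray(self.array_coords)
        if self.array_coords.shape != (self.counts.shape[0], 2):
            raise ValueError("array_coords must be (S, 2)")
        if self.pixel_coords is not None:
            self.pixel_coords = np.asarray(self.pixel_coords, dtype=float)
            if self.pixel_coords.shape != (self.counts.shape[0], 2):
                raise ValueError("pixel_coords must be (S, 2)")
        if not self.sample_labels:
            self.sample_labels = ["sample0"] * self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def subset_genes(self, keep: np.ndarray) -> "SpotDataset":
        keep = np.asarray(keep)
        return replace(
            self,
            counts=self.counts[:, keep],
            gene_names=[self.gene_names[i] for i in keep],
        )


@dataclass
class SignatureSet:
    """Named cell states with their marker gene lists (order-preserving)."""

    state_names: list[str]
    markers: dict[str, list[str]]

    def __post_init__(self):
        for state in self.state_names:
            genes = self.markers.get(state, [])
            if len(genes) == 0:
                raise ValueError(f"state {state!r} has an empty marker list")
            # dedupe, keep first occurrence
            self.markers[state] = list(dict.fromkeys(genes))

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def all_markers(self) -> list[str]:
        seen: dict[str, None] = {}
        for state in self.state_names:
            for g in self.markers[state]:
                seen.setdefault(g)
        return list(seen)

    def restricted_to(self, genes: set[str]) -> "SignatureSet":
        """Intersect marker lists with `genes`; drop states left empty."""
        names, markers = [], {}
        for state in self.state_names:
            kept = [g for g in self.markers[state] if g in genes]
            if kept:
                names.append(state)
                markers[state] = kept
        if not names:
            raise ValueError("no signature state retains a marker present in the data")
        return SignatureSet(names, markers)


@dataclass
class HistologyImage:
    """Full-resolution image, values in [0, 1], 1 (gray) or 3 (RGB) channels."""

    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[:, :, None]
        if self.pixels.ndim != 3 or self.pixels.shape[2] not in (1, 3):
            raise ValueError("image must be HxW, HxWx1 or HxWx3")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("image values must lie in [0, 1]")

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]


@dataclass
class PatchSet:
    """Per-spot image patches, (S, P, P, C), aligned with spot order."""

    patches: np.ndarray

    def __post_init__(self):
        self.patches = np.asarray(self.patches, dtype=np.float64)
        if self.patches.ndim != 4:
            raise ValueError("patches must be (S, P, P, C)")

    @property
    def patch_side(self) -> int:
        return self.patches.shape[1]

    def flattened(self) -> np.ndarray:
        return self.patches.reshape(self.patches.shape[0], -1)


# ---------------------------------------------------------------------------
# loading


def _collapse_duplicate_genes(counts: np.ndarray, genes: list[str]):
    """Sum rows of duplicated gene symbols (first-occurrence order kept)."""
    if len(set(genes)) == len(genes):
        return counts, genes
    order: dict[str, int] = {}
    for g in genes:
        order.setdefault(g, len(order))
    out = np.zeros((counts.shape[0], len(order)), dtype=counts.dtype)
    for j, g in enumerate(genes):
        out[:, order[g]] += counts[:, j]
    return out, list(order)


def load_spot_dataset(counts_path: str | Path, coords_path: str | Path,
                      format: str = "csv") -> SpotDataset:
    """Load counts + coordinates into a :class:`SpotDataset`.

    ``format='mtx10x'``: `counts_path` is a directory containing
    ``matrix.mtx``, ``barcodes.tsv`` and ``features.tsv`` (columns: id,
    symbol, type), genes x barcodes as in the 10x convention.
    ``format='csv'``: dense matrix, first column spot_id, header = symbols.

    The coordinates CSV (columns spot_id, array_row, array_col and optional
    pixel_row, pixel_col) fixes the spot order; duplicated gene symbols are
    summed into a single column.
    """
    counts_path, coords_path = Path(counts_path), Path(coords_path)
    if not coords_path.exists():
        raise FileNotFoundError(coords_path)

    if format == "mtx10x":
        d = counts_path
        if not d.is_dir():
            raise FileNotFoundError(f"expected a 10x directory at {d}")
        mat = np.asarray(mmread(str(d / "matrix.mtx")).todense())
        barcodes = pd.read_csv(d / "barcodes.tsv", header=None, sep="\t")[0].tolist()
        feats = pd.read_csv(d / "features.tsv", header=None, sep="\t")
        genes = feats[1].tolist() if feats.shape[1] > 1 else feats[0].tolist()
        counts = mat.T  # spots x genes
        spot_ids = barcodes
    elif format == "csv":
        if not counts_path.exists():
            raise FileNotFoundError(counts_path)
        df = pd.read_csv(counts_path, index_col=0)
        counts = df.to_numpy()
        genes = [str(g) for g in df.columns]
        spot_ids = [str(s) for s in df.index]
    else:
        raise ValueError(f"unknown format {format!r}")

    if np.any(counts < 0):
        raise ValueError("negative entries in count matrix")
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("non-integer entries in count matrix")
    counts = np.round(counts).astype(np.int64)
    counts, genes = _collapse_duplicate_genes(counts, [str(g) for g in genes])

    coords = pd.read_csv(coords_path)
    missing = [s for s in coords["spot_id"].astype(str) if s not in set(spot_ids)]
    if missing:
        raise ValueError(f"coordinate spots absent from count matrix: {missing[:5]}")
    idx = {s: i for i, s in enumerate(spot_ids)}
    order = [idx[s] for s in coords["spot_id"].astype(str)]
    pixel = None
    if {"pixel_row", "pixel_col"} <= set(coords.columns):
        pixel = coords[["pixel_row", "pixel_col"]].to_numpy(dtype=float)
    return SpotDataset(
        counts=counts[order],
        gene_names=genes,
        spot_ids=coords["spot_id"].astype(str).tolist(),
        array_coords=coords[["array_row", "array_col"]].to_numpy(dtype=int),
        pixel_coords=pixel,
    )


def load_signatures(path: str | Path) -> SignatureSet:
    """Read signatures from JSON ``{state: [genes]}`` or CSV (state, gene)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        if not isinstance(raw, dict) or not raw:
            raise ValueError("signature JSON must be a non-empty mapping")
        names = list(raw)
        markers = {k: [str(g) for g in v] for k, v in raw.items()}
    else:
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("signature CSV needs (state, gene) columns")
        scol, gcol = df.columns[:2]
        names = list(dict.fromkeys(df[scol].astype(str)))
        markers = {
            s: df.loc[df[scol].astype(str) == s, gcol].astype(str).tolist()
            for s in names
        }
    return SignatureSet(names, markers)


def load_histology_image(path: str | Path) -> HistologyImage:
    """Read a PNG/TIFF image and normalize each channel to [0, 1]."""
    arr = iio.imread(Path(path))
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.max() > 1.0:
        arr = arr / 255.0
    return HistologyImage(np.clip(arr, 0.0, 1.0))


# ---------------------------------------------------------------------------
# preprocessing


def _is_mito_ribo(gene: str) -> bool:
    g = gene.upper()
    return any(g.startswith(p) for p in MITO_RIBO_PREFIXES)


def _dispersion_ranking(counts: np.ndarray) -> np.ndarray:
    """Rank genes by descending variance-to-mean ratio of log1p counts.

    Computed on raw (unnormalized) counts so the statistic of a gene does
    not depend on which other genes are present — this makes the selection
    exactly idempotent under re-application. Ties resolve by gene order.
    """
    logx = np.log1p(counts.astype(np.float64))
    mean = logx.mean(axis=0)
    var = logx.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    # stable sort on negated dispersion -> descending, ties by gene index
    return np.argsort(-disp, kind="stable")


def preprocess(data: SpotDataset, sigs: SignatureSet | None,
               n_hvg: int = 2000) -> SpotDataset:
    """Mito/ribo filter then highly-variable-gene selection.

    Removes genes with mitochondrial/ribosomal prefixes, ranks the rest by
    dispersion and keeps the top `n_hvg` unioned with every signature marker
    present in the data. Counts remain raw integers.
    """
    keep_mask = np.array([not _is_mito_ribo(g) for g in data.gene_names])
    filtered = data.subset_genes(np.flatnonzero(keep_mask))
    if n_hvg > filtered.n_genes:
        raise ValueError(
            f"n_hvg={n_hvg} exceeds the {filtered.n_genes} genes "
            "surviving the mito/ribo filter"
        )
    ranking = _dispersion_ranking(filtered.counts)
    hvg_idx = set(ranking[:n_hvg].tolist())
    if sigs is not None:
        name_to_idx = {g: i for i, g in enumerate(filtered.gene_names)}
        for g in sigs.all_markers():
            if g in name_to_idx:
                hvg_idx.add(name_to_idx[g])
    keep = np.array(sorted(hvg_idx))
    return filtered.subset_genes(keep)


# ---------------------------------------------------------------------------
# histology patches


def extract_patches(data: SpotDataset, img: HistologyImage, P: int = 26) -> PatchSet:
    """Per-spot PxP windows centered on the spot's pixel coordinate.

    Windows are half-open ``[c - P//2, c - P//2 + P)`` per axis; parts
    falling outside the image are zero-padded, so borders are bit-exact.
    """
    if data.pixel_coords is None:
        raise ValueError("dataset has no pixel coordinates")
    H, W, C = img.pixels.shape
    patches = np.zeros((data.n_spots, P, P, C))
    half = P // 2
    for i, (r, c) in enumerate(data.pixel_coords):
        r0 = int(round(r)) - half
        c0 = int(round(c)) - half
        rs, re = max(r0, 0), min(r0 + P, H)
        cs, ce = max(c0, 0), min(c0 + P, W)
        if rs < re and cs < ce:
            patches[i, rs - r0:re - r0, cs - c0:ce - c0] = img.pixels[rs:re, cs:ce]
    return PatchSet(patches)


# ---------------------------------------------------------------------------
# results


def write_deconvolution(result, outdir: str | Path, *, config: dict | None = None,
                        seed: int | None = None) -> dict[str, Path]:
    """Write proportions/latent/library CSVs and a JSON run manifest."""
    import spotdecon

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not np.all(np.isfinite(result.c)):
        raise ValueError("non-finite proportions")
    paths = {}
    props = pd.DataFrame(result.c, index=result.spot_ids, columns=result.state_names)
    props.index.name = "spot_id"
    paths["proportions"] = outdir / "proportions.csv"
    props.to_csv(paths["proportions"], float_format="%.17g")

    latent = pd.DataFrame(
        result.z, index=result.spot_ids,
        columns=[f"z{j}" for j in range(result.z.shape[1])],
    )
    latent.index.name = "spot_id"
    paths["latent"] = outdir / "latent.csv"
    latent.to_csv(paths["latent"], float_format="%.17g")

    lib = pd.DataFrame({"library": result.l}, index=result.spot_ids)
    lib.index.name = "spot_id"
    paths["library"] = outdir / "library.csv"
    lib.to_csv(paths["library"], float_format="%.17g")

    manifest = {
        "package": "spotdecon",
        "version": getattr(spotdecon, "__version__", "unknown"),
        "numpy": np.__version__,
        "seed": seed,
        "config": config or {},
        "n_spots": int(result.c.shape[0]),
        "n_states": int(result.c.shape[1]),
    }
    paths["manifest"] = outdir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, default=str))
    return paths
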