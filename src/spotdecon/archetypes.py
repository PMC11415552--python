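"""Archetypal analysis of spot expression.

Fits a convex polytope to the spots in principal-component space (principal
convex hull analysis, PCHA), so that each spot is a convex combination of a
few archetypes and each archetype is a convex combination of spots. The
archetypes proxy the "purest" spots — those dominated by a single cell
state — and are used to refine signature gene sets or to seed new states
when no signatures are given.

Pipeline: estimate the archetype count from the data's intrinsic dimension
(Fisher separability) and the explained-variance curve; fit W, B by
alternating projected-gradient descent under row-simplex constraints;
merge archetypes closer than a resolution radius; collect each archetype's
nearest-spot community and its rank-sum marker genes; align communities to
known states with stable-marriage matching and append markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .core_io import SignatureSet, SpotDataset
from .priors import PriorBundle, _normalized_log_expression, build_priors

__all__ = [
    "ArchetypeModel",
    "pca_embedding",
    "estimate_intrinsic_dimension",
    "estimate_n_archetypes",
    "fit_pcha",
    "merge_archetypes",
    "archetype_communities",
    "community_markers",
    "stable_marriage",
    "refine_signatures",
    "fit_archetypes",
]


@dataclass
class ArchetypeModel:
    """Fitted polytope plus derived communities/markers/alignment."""

    X_pc: np.ndarray                       # (S, P_pc) PCA embedding
    W: np.ndarray                          # (S, D_a) row-simplex
    B: np.ndarray                          # (D_a, S) row-simplex
    H: np.ndarray                          # (D_a, P_pc) archetype coordinates
    sse_trace: list[float]
    merged_map: np.ndarray | None = None   # original archetype -> survivor
    surviving: np.ndarray | None = None    # surviving archetype indices
    communities: list[np.ndarray] = field(default_factory=list)
    community_markers_: list[list[str]] = field(default_factory=list)
    alignment: dict[int, int] = field(default_factory=dict)  # community -> state

    @property
    def n_archetypes(self) -> int:
        return self.H.shape[0]

    @property
    def surviving_H(self) -> np.ndarray:
        if self.surviving is None:
            return self.H
        return self.H[self.surviving]


def pca_embedding(data: SpotDataset, n_pc: int = 30) -> np.ndarray:
    """Top principal components of the log-normalized expression."""
    expr = _normalized_log_expression(data)
    n_pc = min(n_pc, expr.shape[0] - 1, expr.shape[1])
    pca = PCA(n_components=n_pc, svd_solver="full")
    return pca.fit_transform(expr)


# ---------------------------------------------------------------------------
# intrinsic dimension (Fisher separability)


def _separability_probability(n: float, alpha: float) -> float:
    """Mean inseparability probability for a uniform n-ball at threshold alpha."""
    return (1.0 - alpha ** 2) ** ((n + 1.0) / 2.0) / (alpha * np.sqrt(2.0 * np.pi * n))


def estimate_intrinsic_dimension(X: np.ndarray, alpha: float = 0.8) -> float:
    """Fisher-separability estimate of the intrinsic dimension.

    Points are centered, whitened in their PCA basis and projected to the
    unit sphere; the empirical fraction of Fisher-inseparable ordered pairs
    (<x, y> >= alpha after normalization) is inverted through the
    uniform-ball separability law to yield an effective dimension.
    """
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    cov_eigval, cov_eigvec = np.linalg.eigh(np.cov(Xc.T))
    keep = cov_eigval > max(1e-12, 1e-8 * cov_eigval.max(initial=0.0))
    if not np.any(keep):
        raise ValueError("degenerate input: all points identical")
    Z = Xc @ cov_eigvec[:, keep] / np.sqrt(cov_eigval[keep])
    norms = np.linalg.norm(Z, axis=1)
    nz = norms > 1e-12
    Z = Z[nz] / norms[nz, None]
    S = Z.shape[0]
    if S < 3:
        raise ValueError("need at least 3 distinct points")
    gram = Z @ Z.T
    np.fill_diagonal(gram, -np.inf)
    p_hat = float(np.mean(gram >= alpha))
    p_hat = max(p_hat, 1.0 / (S * (S - 1)))  # resolution floor
    # invert p(alpha, n) for n (monotone decreasing in n)
    lo, hi = 1.0, 200.0
    if _separability_probability(lo, alpha) < p_hat:
        return lo
    if _separability_probability(hi, alpha) > p_hat:
        return hi
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _separability_probability(mid, alpha) > p_hat:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# PCHA


def _project_rows_to_simplex(V: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    n, d = V.shape
    U = np.sort(V, axis=1)[:, ::-1]
    css = np.cumsum(U, axis=1) - 1.0
    ind = np.arange(1, d + 1)
    cond = U - css / ind > 0
    rho = cond.sum(axis=1)
    theta = css[np.arange(n), rho - 1] / rho
    return np.maximum(V - theta[:, None], 0.0)


def _furthest_point_init(X: np.ndarray, D_a: int) -> np.ndarray:
    """Row-simplex B selecting D_a mutually distant spots (deterministic)."""
    S = X.shape[0]
    centroid = X.mean(axis=0)
    first = int(np.argmax(np.linalg.norm(X - centroid, axis=1)))
    chosen = [first]
    mind = np.linalg.norm(X - X[first], axis=1)
    for _ in range(D_a - 1):
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        mind = np.minimum(mind, np.linalg.norm(X - X[nxt], axis=1))
    B = np.zeros((D_a, S))
    B[np.arange(D_a), chosen] = 1.0
    return B


def _pcha_objective(X: np.ndarray, W: np.ndarray, B: np.ndarray) -> float:
    R = X - W @ (B @ X)
    return float(np.sum(R * R))


def _monotone_pg_update(V, grad, step, project, objective, f_prev,
                        max_halvings: int = 40):
    """Projected-gradient step with halving; never increases the objective."""
    t = step
    for _ in range(max_halvings):
        V_new = project(V - t * grad)
        f_new = objective(V_new)
        if f_new <= f_prev:
            return V_new, f_new
        t *= 0.5
    return V, f_prev


def fit_pcha(X_pc: np.ndarray, D_a: int, max_iter: int = 200,
             tol: float = 1e-6):
    """Principal convex hull analysis by alternating projected gradients.

    Minimizes ``||X' - W B X'||_F^2`` with the rows of W (S x D_a) and B
    (D_a x S) constrained to the probability simplex; archetypes are
    ``H = B X'``. B starts from a furthest-point selection of spots, and
    every accepted step is non-increasing in the objective.

    Returns ``(W, B, H, sse_trace)``.
    """
    X = np.asarray(X_pc, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite input")
    S = X.shape[0]
    if not 1 <= D_a <= S:
        raise ValueError("D_a must lie in [1, S]")
    B = _furthest_point_init(X, D_a)
    W = np.full((S, D_a), 1.0 / D_a)
    f = _pcha_objective(X, W, B)
    trace = [f]
    for _ in range(max_iter):
        f_prev = f
        # W step: f(W) = ||X - W H||^2, Lipschitz const 2||H H^T||
        H = B @ X
        GW = 2.0 * (W @ H - X) @ H.T
        LW = 2.0 * np.linalg.norm(H @ H.T, 2) + 1e-12
        W, f = _monotone_pg_update(
            W, GW, 1.0 / LW, _project_rows_to_simplex,
            lambda V: _pcha_objective(X, V, B), f)
        # B step: f(B) = ||X - W B X||^2
        GB = 2.0 * W.T @ (W @ (B @ X) - X) @ X.T
        LB = (2.0 * np.linalg.norm(W.T @ W, 2) *
              np.linalg.norm(X @ X.T, 2) + 1e-12)
        B, f = _monotone_pg_update(
            B, GB, 1.0 / LB, _project_rows_to_simplex,
            lambda V: _pcha_objective(X, W, V), f)
        trace.append(f)
        if f_prev - f <= tol * max(f_prev, 1e-12):
            break
    return W, B, B @ X, trace


def _explained_variance(X: np.ndarray, sse: float) -> float:
    tss = float(np.sum((X - X.mean(axis=0)) ** 2))
    return 1.0 - sse / max(tss, 1e-300)


def estimate_n_archetypes(X_pc: np.ndarray, tol_ev: float = 1e-3,
                          max_archetypes: int = 30,
                          search_max_iter: int = 60) -> int:
    """Choose the archetype count D_a.

    The Fisher-separability intrinsic dimension gives a lower bound (a
    d-dimensional simplex needs d+1 vertices); D_a then grows until the
    explained-variance gain of one more archetype falls below `tol_ev`.
    """
    X = np.asarray(X_pc, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 spots")
    if float(np.sum((X - X.mean(axis=0)) ** 2)) <= 1e-12:
        raise ValueError("degenerate input: zero variance")
    id_lb = int(np.ceil(estimate_intrinsic_dimension(X)))
    D = max(2, min(id_lb, max_archetypes))
    _, _, _, tr = fit_pcha(X, D, max_iter=search_max_iter)
    ev = _explained_variance(X, tr[-1])
    while D < max_archetypes:
        _, _, _, tr = fit_pcha(X, D + 1, max_iter=search_max_iter)
        ev_next = _explained_variance(X, tr[-1])
        if ev_next - ev < tol_ev:
            break
        D, ev = D + 1, ev_next
    return D


# ---------------------------------------------------------------------------
# merging, communities, markers


def merge_archetypes(model: ArchetypeModel, r: float = 100.0) -> ArchetypeModel:
    """Merge archetypes closer than radius `r` in PC space.

    Scanning archetypes in index order, each one is merged into the closest
    earlier survivor when their Euclidean distance is below `r`; `r = 0`
    keeps everything.
    """
    H = model.H
    D = H.shape[0]
    merged = np.arange(D)
    survivors = [0]
    for i in range(1, D):
        d = np.linalg.norm(H[survivors] - H[i], axis=1)
        j = int(np.argmin(d))
        if d[j] < r:
            merged[i] = survivors[j]
        else:
            survivors.append(i)
    model.merged_map = merged
    model.surviving = np.array(survivors)
    return model


def archetype_communities(model: ArchetypeModel, n_neighbor: int = 20
                          ) -> list[np.ndarray]:
    """Per surviving archetype, the n_neighbor nearest spots (by PC distance)."""
    X = model.X_pc
    if n_neighbor > X.shape[0]:
        raise ValueError("n_neighbor exceeds the number of spots")
    comms = []
    for h in model.surviving_H:
        d = np.linalg.norm(X - h, axis=1)
        comms.append(np.argsort(d, kind="stable")[:n_neighbor])
    model.communities = comms
    return comms


def _ranksum_scores(expr: np.ndarray, in_mask: np.ndarray):
    """One-sided Wilcoxon rank-sum z and p per gene (in-group greater).

    Normal approximation with tie correction, vectorized across genes.
    """
    S, G = expr.shape
    n1 = int(in_mask.sum())
    n2 = S - n1
    ranks = stats.rankdata(expr, axis=0)
    R1 = ranks[in_mask].sum(axis=0)
    U = R1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction per gene
    tie_term = np.zeros(G)
    for g in range(G):
        _, cnt = np.unique(expr[:, g], return_counts=True)
        tie_term[g] = np.sum(cnt ** 3 - cnt)
    var = n1 * n2 / 12.0 * ((S + 1) - tie_term / (S * (S - 1)))
    var = np.maximum(var, 1e-30)
    z = (U - mu) / np.sqrt(var)
    p = stats.norm.sf(z)
    return z, p


def community_markers(data: SpotDataset, communities: list[np.ndarray],
                      n_marker: int = 30) -> list[list[str]]:
    """Top marker genes of each community by one-sided rank-sum test.

    Genes are ranked by evidence of over-expression in the community versus
    all other spots (p ascending, ties by mean log-expression difference
    descending, then gene order).
    """
    expr = _normalized_log_expression(data)
    S = expr.shape[0]
    out = []
    for comm in communities:
        comm = np.asarray(comm)
        if comm.size == 0:
            raise ValueError("empty community")
        if comm.size >= S:
            raise ValueError("community covers all spots; no out-group")
        mask = np.zeros(S, dtype=bool)
        mask[comm] = True
        _, p = _ranksum_scores(expr, mask)
        effect = expr[mask].mean(axis=0) - expr[~mask].mean(axis=0)
        order = np.lexsort((np.arange(len(p)), -effect, p))
        out.append([data.gene_names[i] for i in order[:n_marker]])
    return out


# ---------------------------------------------------------------------------
# alignment


def stable_marriage(pref_a: list[list[int]], pref_b: list[list[int]]
                    ) -> dict[int, int]:
    """Gale–Shapley stable matching; side `a` proposes.

    `pref_a[i]` ranks the b-indices for proposer i (best first), `pref_b[j]`
    ranks the a-indices for acceptor j. Sizes may differ; the matching
    covers ``min(len(a), len(b))`` pairs and has no blocking pair.
    """
    nA, nB = len(pref_a), len(pref_b)
    for i, p in enumerate(pref_a):
        if sorted(p) != list(range(nB)):
            raise ValueError(f"proposer {i} preferences are not a permutation")
    for j, p in enumerate(pref_b):
        if sorted(p) != list(range(nA)):
            raise ValueError(f"acceptor {j} preferences are not a permutation")
    rank_b = [{a: r for r, a in enumerate(p)} for p in pref_b]
    next_prop = [0] * nA
    engaged_b: dict[int, int] = {}
    match_a: dict[int, int] = {}
    free = list(range(nA - 1, -1, -1))
    while free:
        a = free.pop()
        if next_prop[a] >= nB:
            continue  # exhausted all options; stays unmatched
        b = pref_a[a][next_prop[a]]
        next_prop[a] += 1
        if b not in engaged_b:
            engaged_b[b] = a
            match_a[a] = b
        elif rank_b[b][a] < rank_b[b][engaged_b[b]]:
            loser = engaged_b[b]
            del match_a[loser]
            free.append(loser)
            engaged_b[b] = a
            match_a[a] = b
        else:
            free.append(a)
    return match_a


def refine_signatures(sigs: SignatureSet | None, model: ArchetypeModel,
                      priors: PriorBundle | None, data: SpotDataset, *,
                      seed: int = 0, n_marker: int = 30
                      ) -> tuple[SignatureSet, PriorBundle, list[int]]:
    """Align communities to cell states and refine signatures/anchors.

    Preferences on both sides come from Euclidean distances between each
    community's spot centroid and each state's anchor-spot centroid in PC
    space; states propose, so each state gets its best feasible community.
    Matched communities contribute their marker genes to the state's set,
    after which the prior bundle (scores, A, anchors) is rebuilt from
    scratch. Unmatched communities are returned ranked most-distant-first
    as candidate novel states.

    With no signatures (reference-free mode) every community becomes its
    own state named ``archetype_<d>`` with its top markers.
    """
    if not model.communities:
        archetype_communities(model)
    if not model.community_markers_:
        model.community_markers_ = community_markers(
            data, model.communities, n_marker)
    markers = model.community_markers_
    nC = len(model.communities)

    if sigs is None or sigs.n_states == 0:
        names = [f"archetype_{d}" for d in range(nC)]
        new_sigs = SignatureSet(names, dict(zip(names, [list(m) for m in markers])))
        new_priors = build_priors(data, new_sigs, seed)
        model.alignment = {d: d for d in range(nC)}
        return new_sigs, new_priors, []

    if priors is None:
        priors = build_priors(data, sigs, seed)
    X = model.X_pc
    comm_centroids = np.vstack([X[c].mean(axis=0) for c in model.communities])
    anchor_centroids = np.vstack([
        X[priors.anchors[:, k]].mean(axis=0) for k in range(len(priors.state_names))
    ])
    D = cdist(anchor_centroids, comm_centroids)  # states x communities
    pref_states = [list(np.argsort(D[k], kind="stable")) for k in range(D.shape[0])]
    pref_comms = [list(np.argsort(D[:, d], kind="stable")) for d in range(D.shape[1])]
    match = stable_marriage(pref_states, pref_comms)  # state -> community

    new_markers = {s: list(sigs.markers[s]) for s in sigs.state_names}
    model.alignment = {}
    for k, d in match.items():
        state = priors.state_names[k]
        model.alignment[d] = k
        for g in markers[d]:
            if g not in new_markers[state] and g in set(data.gene_names):
                new_markers[state].append(g)
    new_sigs = SignatureSet(list(sigs.state_names), new_markers)
    new_priors = build_priors(data, new_sigs, seed,
                              alpha=priors.alpha, epsilon=priors.epsilon,
                              window=priors.window, n_anchor=priors.n_anchor)
    matched = set(match.values())
    novel = [d for d in range(nC) if d not in matched]
    novel.sort(key=lambda d: -D[:, d].min())
    return new_sigs, new_priors, novel


def fit_archetypes(data: SpotDataset, *, n_pc: int = 30,
                   n_archetypes: int | None = None, merge_radius: float = 100.0,
                   n_neighbor: int = 20, n_marker: int = 30,
                   max_iter: int = 200, tol: float = 1e-6) -> ArchetypeModel:
    """Full archetype pipeline: PCA, count selection, PCHA, merge, communities."""
    X = pca_embedding(data, n_pc)
    D_a = n_archetypes if n_archetypes is not None else estimate_n_archetypes(X)
    W, B, H, trace = fit_pcha(X, D_a, max_iter=max_iter, tol=tol)
    model = ArchetypeModel(X_pc=X, W=W, B=B, H=H, sse_trace=trace)
    merge_archetypes(model, merge_radius)
    archetype_communities(model, min(n_neighbor, data.n_spots))
    model.community_markers_ = community_markers(data, model.communities, n_marker)
    return model
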