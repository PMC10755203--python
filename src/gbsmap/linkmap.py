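"""F2 linkage-group construction and genetic-map ordering.

Pairwise recombination fractions between consensus-window loci are estimated
by maximum likelihood for an F2 intercross with codominant markers: the 3x3
joint genotype table has class probabilities that are the standard two-locus
functions of r (with the double-heterozygote class pooling both phases).
Maximisation is a dense grid (step 0.001) with golden-section refinement —
deterministic, no EM convergence ambiguity.  Linkage groups are connected
components of the thresholded (r, LOD) graph; within a group loci are ordered
by a minimum-spanning-tree backbone with insertion and windowed-ripple
polishing under a count objective (sum over adjacent pairs of expected
recombinant gametes), and cumulative positions accrue via the Kosambi map
function d = 25 ln((1+2r)/(1-2r)) cM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree, shortest_path

from .genotyping import GenotypeMatrix, U

__all__ = [
    "kosambi_cm",
    "kosambi_r",
    "segregation_pvalues",
    "RFEstimate",
    "estimate_rf",
    "pairwise_rf",
    "group_loci",
    "order_loci",
    "LinkageGroup",
    "GeneticMap",
    "build_genetic_map",
]

_LN10 = np.log(10.0)


def kosambi_cm(r):
    """Kosambi map distance in cM: d = 25 ln((1+2r)/(1-2r)).

    Defined for 0 <= r < 0.5; raises on values outside the domain.
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must satisfy 0 <= r < 0.5")
    d = 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    return float(d) if d.ndim == 0 else d

def kosambi_r(d):
    """Inverse Kosambi: r = tanh(d / 50) / 2 for d >= 0 cM."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# recombination fraction MLE
# ---------------------------------------------------------------------------

# joint F2 genotype classes, row genotype x column genotype, flattened 3x3:
# indices g1 * 3 + g2 with 0=AA, 1=AB, 2=BB


def _class_probs(r: np.ndarray) -> np.ndarray:
    """(..., 9) joint class probabilities as functions of r."""
    r = np.asarray(r, dtype=float)
    c = 1.0 - r
    pp = (c * c) / 4.0  # parental homozygote pair
    pr = (c * r) / 2.0  # homozygote x heterozygote
    rr = (r * r) / 4.0  # recombinant homozygote pair
    hh = (c * c + r * r) / 2.0  # double heterozygote (both phases)
    return np.stack([pp, pr, rr, pr, hh, pr, rr, pr, pp], axis=-1)


def _loglik(n9: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Multinomial log likelihood; n9 (..., 9) counts against r (...,)."""
    p = _class_probs(r)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), -np.inf)
        terms = np.where(n9 > 0, n9 * lp, 0.0)
    return terms.sum(axis=-1)


_GRID = np.concatenate([np.arange(0.001, 0.5, 0.001), [0.5]])


def segregation_pvalues(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-locus chi-square p-value against 1:2:1 F2 segregation.

    Grossly distorted windows (typically allele-specific dropout at
    polymorphic restriction sites) violate the premise of the F2 two-locus
    likelihood — two loci distorted toward the same homozygote fake tight
    linkage — so callers exclude them from recombination-fraction estimation
    and from misjoin tracks, and flag them in reports.  Loci with no
    informative individuals get p = 1.
    """
    from scipy.stats import chi2

    codes = matrix.codes
    obs = np.stack([(codes == g).sum(axis=1) for g in range(3)], axis=1).astype(float)
    n = obs.sum(axis=1, keepdims=True)
    exp = n * np.array([0.25, 0.5, 0.25])
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(n[:, 0] > 0, ((obs - exp) ** 2 / np.maximum(exp, 1e-12)).sum(axis=1), 0.0)
    return chi2.sf(stat, df=2)


def _golden_refine(n9: np.ndarray, lo: np.ndarray, hi: np.ndarray, iters: int = 30) -> np.ndarray:
    """Vectorised golden-section maximisation of the log likelihood on
    per-row brackets [lo, hi]."""
    invphi = (np.sqrt(5.0) - 1) / 2
    a, b = lo.astype(float).copy(), hi.astype(float).copy()
    for _ in range(iters):
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        take_c = _loglik(n9, c) >= _loglik(n9, d)
        b = np.where(take_c, d, b)
        a = np.where(take_c, a, c)
    mid = (a + b) / 2
    return np.clip(mid, 0.0, 0.5)


@dataclass(frozen=True)
class RFEstimate:
    """Maximum-likelihood recombination fraction between two loci."""

    r: float
    lod: float
    n_informative: int
    reliable: bool = True


def _counts9(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    ok = (x != U) & (y != U)
    xi, yi = x[ok].astype(np.int64), y[ok].astype(np.int64)
    n9 = np.bincount(xi * 3 + yi, minlength=9).astype(np.float64)
    return n9, int(ok.sum())


def _mle_from_counts(n9: np.ndarray) -> tuple[float, float]:
    ll_grid = _loglik(np.broadcast_to(n9, (_GRID.size, 9)), _GRID)
    best = int(np.argmax(ll_grid))
    lo = max(0.0, _GRID[best] - 0.001)
    hi = min(0.5, _GRID[best] + 0.001)
    r_hat = float(_golden_refine(n9[None, :], np.array([lo]), np.array([hi]))[0])
    # exact boundary: no recombinant observations => r = 0
    if n9[[1, 2, 3, 5, 6, 7]].sum() == 0:
        r_hat = 0.0
    ll_hat = float(_loglik(n9[None, :], np.array([r_hat]))[0])
    ll_null = float(_loglik(n9[None, :], np.array([0.5]))[0])
    lod = max(0.0, (ll_hat - ll_null) / _LN10)
    return min(r_hat, 0.5), lod


def estimate_rf(x, y, min_informative: int = 10) -> RFEstimate:
    """Estimate r between two genotype code vectors over {0:A,1:H,2:B,3:U}.

    Pairs with U in either vector are dropped.  Estimates based on fewer than
    ``min_informative`` joint observations are flagged unreliable.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("genotype vectors differ in length")
    n9, n = _counts9(x, y)
    if n == 0:
        return RFEstimate(r=0.5, lod=0.0, n_informative=0, reliable=False)
    r, lod = _mle_from_counts(n9)
    return RFEstimate(r=r, lod=lod, n_informative=n, reliable=n >= min_informative)


def rf_standard_error(n9: np.ndarray, r: float, eps: float = 1e-4) -> float:
    """SE of r from observed Fisher information (numeric second derivative)."""
    r0 = min(max(r, 2 * eps), 0.5 - 2 * eps)
    ll = lambda v: _loglik(np.asarray(n9, dtype=float)[None, :], np.array([v]))[0]
    d2 = (ll(r0 + eps) - 2 * ll(r0) + ll(r0 - eps)) / eps**2
    if d2 >= 0:
        return float("inf")
    return float(1.0 / np.sqrt(-d2))


def pairwise_rf(matrix: GenotypeMatrix) -> dict[str, np.ndarray]:
    """All-pairs recombination fractions for a genotype matrix.

    Returns square symmetric arrays ``r``, ``lod`` and ``n`` (informative
    count); diagonals are r=0, lod=0.
    """
    codes = matrix.codes
    L, n_ind = codes.shape
    onehot = np.stack([(codes == g).astype(np.float32) for g in range(3)])  # (3, L, n)
    # joint counts for every ordered genotype pair
    n9 = np.empty((L, L, 9), dtype=np.float64)
    for a in range(3):
        for b in range(3):
            n9[:, :, a * 3 + b] = onehot[a] @ onehot[b].T
    n_inf = n9.sum(axis=2)

    iu, ju = np.triu_indices(L, k=1)
    flat = n9[iu, ju, :]  # (P, 9)

    logp = np.empty((9, _GRID.size))
    p = _class_probs(_GRID)  # (G, 9)
    with np.errstate(divide="ignore"):
        logp = np.log(p).T  # (9, G); grid excludes 0 so no -inf
    ll = flat @ logp  # (P, G)
    best = np.argmax(ll, axis=1)
    lo = np.maximum(_GRID[best] - 0.001, 0.0)
    hi = np.minimum(_GRID[best] + 0.001, 0.5)
    r_hat = _golden_refine(flat, lo, hi)
    # exact-zero boundary: no recombinant observations => r = 0
    rec_mass = flat[:, [1, 2, 3, 5, 6, 7]].sum(axis=1)
    r_hat = np.where(rec_mass == 0, 0.0, r_hat)
    ll_hat = _loglik(flat, r_hat)
    ll_null = _loglik(flat, np.full(r_hat.size, 0.5))
    lod = np.maximum(0.0, (ll_hat - ll_null) / _LN10)

    r_mat = np.zeros((L, L))
    lod_mat = np.zeros((L, L))
    r_mat[iu, ju] = r_hat
    r_mat[ju, iu] = r_hat
    lod_mat[iu, ju] = lod
    lod_mat[ju, iu] = lod
    return {"r": r_mat, "lod": lod_mat, "n": n_inf}


# ---------------------------------------------------------------------------
# grouping and ordering
# ---------------------------------------------------------------------------


def group_loci(
    r_mat: np.ndarray,
    lod_mat: np.ndarray,
    max_rf: float = 0.35,
    min_lod: float = 6.0,
) -> list[np.ndarray]:
    """Single-linkage grouping: connected components of the graph with an
    edge wherever r <= max_rf and LOD >= min_lod.

    Returns locus-index arrays sorted by decreasing size (ties by smallest
    member); singleton groups are returned too and may be filtered by the
    caller.
    """
    adj = (r_mat <= max_rf) & (lod_mat >= min_lod)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups = [np.flatnonzero(labels == c) for c in range(n_comp)]
    groups.sort(key=lambda g: (-g.size, int(g[0])))
    return groups


def _objective(order: np.ndarray, w: np.ndarray) -> float:
    return float(w[order[:-1], order[1:]].sum())


def order_loci(
    group: np.ndarray,
    r_mat: np.ndarray,
    n_mat: np.ndarray | None = None,
    max_window: int = 6,
) -> np.ndarray:
    """Order loci of one linkage group.

    Builds the minimum spanning tree of the complete r-weighted subgraph,
    takes its weighted longest path as the backbone, inserts the remaining
    loci at the cost-minimising adjacency, then polishes with windowed 2-opt
    reversals (window <= ``max_window``) under the count objective
    (sum of adjacent r * n_informative).  The objective never increases
    during polishing.  Orientation of the result is arbitrary.
    """
    group = np.asarray(group)
    m = group.size
    if m <= 2:
        return group.copy()
    sub_r = r_mat[np.ix_(group, group)]
    if n_mat is not None:
        sub_n = n_mat[np.ix_(group, group)]
    else:
        sub_n = np.ones_like(sub_r)
    w = sub_r * sub_n  # count objective weights

    eps = 1e-9
    mst = minimum_spanning_tree(csr_matrix(sub_r + eps)).toarray()
    mst = np.maximum(mst, mst.T)
    tree = csr_matrix(mst)

    # weighted diameter of the tree via two sweeps
    d0 = shortest_path(tree, method="D", indices=0)
    u = int(np.nanargmax(np.where(np.isfinite(d0), d0, -1)))
    du, pred = shortest_path(tree, method="D", indices=u, return_predecessors=True)
    v = int(np.nanargmax(np.where(np.isfinite(du), du, -1)))
    path = [v]
    while path[-1] != u:
        path.append(int(pred[path[-1]]))
    backbone = list(path)

    remaining = [i for i in range(m) if i not in set(backbone)]
    # insert nearest-to-backbone first
    while remaining:
        best = None
        for node in remaining:
            # cost of inserting at each slot (ends included)
            costs = [w[node, backbone[0]]]
            for a, b in zip(backbone[:-1], backbone[1:]):
                costs.append(w[a, node] + w[node, b] - w[a, b])
            costs.append(w[backbone[-1], node])
            slot = int(np.argmin(costs))
            cost = costs[slot]
            if best is None or cost < best[0]:
                best = (cost, node, slot)
        _, node, slot = best
        backbone.insert(slot, node)
        remaining.remove(node)

    order = np.array(backbone)
    obj = _objective(order, w)
    improved = True
    guard = 0
    while improved and guard < 200:
        improved = False
        guard += 1
        for width in range(2, min(max_window, m) + 1):
            for s in range(0, m - width + 1):
                e = s + width  # reverse order[s:e]
                left = order[s - 1] if s > 0 else None
                right = order[e] if e < m else None
                delta = 0.0
                if left is not None:
                    delta += w[left, order[e - 1]] - w[left, order[s]]
                if right is not None:
                    delta += w[order[s], right] - w[order[e - 1], right]
                if delta < -1e-12:
                    order[s:e] = order[s:e][::-1]
                    new_obj = _objective(order, w)
                    assert new_obj <= obj + 1e-9, "polishing must not increase the objective"
                    obj = new_obj
                    improved = True
    return group[order]


@dataclass
class LinkageGroup:
    """Ordered loci of one group with cumulative Kosambi positions (cM)."""

    name: str
    loci: np.ndarray  # locus indices into the genotype matrix, in map order
    positions_cm: np.ndarray

    def __len__(self) -> int:
        return self.loci.size

    @property
    def length_cm(self) -> float:
        return float(self.positions_cm[-1]) if len(self) else 0.0


@dataclass
class GeneticMap:
    """A genetic map: ordered linkage groups over genotype-matrix loci."""

    groups: list[LinkageGroup]

    def to_frame(self, loci: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for oi, (li, pos) in enumerate(zip(g.loci, g.positions_cm)):
                rows.append(
                    (
                        g.name,
                        oi,
                        loci["contig"].iat[li],
                        int(loci["window_index"].iat[li]),
                        float(pos),
                        int(li),
                    )
                )
        return pd.DataFrame(
            rows,
            columns=["group", "order_index", "contig", "window_index", "position_cm", "locus_index"],
        )


def build_genetic_map(
    ordered_groups: list[np.ndarray],
    r_mat: np.ndarray,
    name_prefix: str = "LG",
) -> GeneticMap:
    """Cumulative Kosambi positions from adjacent recombination fractions.

    Adjacent r >= 0.5 is clamped to 0.499 with a warning.  The first locus of
    each group sits at 0 cM.
    """
    groups = []
    for gi, order in enumerate(ordered_groups):
        order = np.asarray(order)
        if order.size == 0:
            continue
        adj = r_mat[order[:-1], order[1:]] if order.size > 1 else np.empty(0)
        if np.any(adj >= 0.5):
            warnings.warn("adjacent recombination fraction >= 0.5 clamped to 0.499")
            adj = np.minimum(adj, 0.499)
        pos = np.concatenate(([0.0], np.cumsum(kosambi_cm(adj)))) if order.size > 1 else np.zeros(1)
        groups.append(
            LinkageGroup(name=f"{name_prefix}{gi + 1:02d}", loci=order, positions_cm=pos)
        )
    return GeneticMap(groups=groups)
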